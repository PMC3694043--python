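"""Multipoint nonparametric allele-sharing linkage.

The machinery is the classic inheritance-vector formulation: for each family
the hidden state at a map position is a binary vector with one bit per
meiosis of every non-founder (0 = grandpaternal allele transmitted,
1 = grandmaternal).  A hidden Markov model over marker positions — emission
from observed genotypes by summation over founder-allele assignments,
transition flipping each meiosis bit independently with the Haldane
recombination fraction — yields the multipoint posterior over inheritance
vectors.  Affected-pair allele sharing (S_pairs) is scored against its exact
null moments under the uniform inheritance-vector distribution, and family
Z-scores are combined into a one-parameter allele-sharing LOD (the linear
likelihood-ratio model with a single non-negative sharing parameter delta,
truncated at zero).  Pointwise significance is the standard normal tail
p = 1 - Phi(sqrt(2 ln10 LOD)).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .pedio import MarkerMap, Pedigree
from .stratify import StratifiedCohort

DEFAULT_MEIOSIS_BUDGET = 16
DEFAULT_DELTA_CAP = 2.0
_TWO_LN10 = 2.0 * np.log(10.0)


class LinkageError(ValueError):
    pass


def haldane_theta(d_cm) -> np.ndarray | float:
    """Haldane map function: recombination fraction for a distance in cM.

    theta = 0.5 (1 - exp(-2 d / 100)), no interference; theta in [0, 0.5).
    """
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise LinkageError("genetic distance must be non-negative")
    theta = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(theta) if np.isscalar(d_cm) else theta


# ---------------------------------------------------------------------------
# pedigree layout: meiosis bits and founder-allele labels per vector


@dataclass
class PedigreeLayout:
    """Inheritance-vector bookkeeping for one family.

    ``pat_label``/``mat_label`` map individual id to a length-V integer array
    giving the founder-allele label carried on the paternal / maternal
    chromosome under each of the V inheritance vectors.  Founders carry
    constant labels (2i, 2i+1).
    """

    family_id: str
    founder_ids: list[str]
    nonfounder_ids: list[str]
    n_bits: int
    n_vectors: int
    pat_label: dict[str, np.ndarray]
    mat_label: dict[str, np.ndarray]


def build_layout(pedigree: Pedigree) -> PedigreeLayout:
    founders = [m.indiv_id for m in pedigree.founders]
    topo = pedigree.topological_nonfounders()
    n_bits = 2 * len(topo)
    V = 1 << n_bits
    bits = (np.arange(V)[:, None] >> np.arange(n_bits)[None, :]) & 1  # (V, n_bits)

    pat: dict[str, np.ndarray] = {}
    mat: dict[str, np.ndarray] = {}
    for i, fid in enumerate(founders):
        pat[fid] = np.full(V, 2 * i, dtype=np.int64)
        mat[fid] = np.full(V, 2 * i + 1, dtype=np.int64)
    for j, ind in enumerate(topo):
        b_p = bits[:, 2 * j]
        b_m = bits[:, 2 * j + 1]
        pat[ind.indiv_id] = np.where(
            b_p == 0, pat[ind.father_id], mat[ind.father_id]
        )
        mat[ind.indiv_id] = np.where(
            b_m == 0, pat[ind.mother_id], mat[ind.mother_id]
        )
    return PedigreeLayout(
        family_id=pedigree.family_id,
        founder_ids=founders,
        nonfounder_ids=[t.indiv_id for t in topo],
        n_bits=n_bits,
        n_vectors=V,
        pat_label=pat,
        mat_label=mat,
    )


_GRID_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _assignment_grid(n_codes: int, n_slots: int) -> np.ndarray:
    """All n_codes^n_slots index tuples, memoized (shared across markers)."""
    key = (n_codes, n_slots)
    if key not in _GRID_CACHE:
        ranges = [np.arange(n_codes)] * n_slots
        _GRID_CACHE[key] = np.stack(
            np.meshgrid(*ranges, indexing="ij"), axis=-1
        ).reshape(-1, n_slots)
    return _GRID_CACHE[key]


def _marker_emission(
    pedigree: Pedigree,
    layout: PedigreeLayout,
    marker: int,
    freqs: dict[int, float],
) -> np.ndarray:
    """P(observed genotypes at one marker | inheritance vector), length V.

    Sums over every assignment of allele codes to the 2F founder-allele
    slots, weighting by population allele frequencies (founder-allele
    peeling by direct enumeration; exact for the small families handled
    here).
    """
    codes = np.array(sorted(freqs), dtype=np.int64)
    fvec = np.array([freqs[int(c)] for c in codes])
    n_slots = 2 * len(layout.founder_ids)
    n_assign = len(codes) ** n_slots
    if n_assign > 1 << 18:
        raise LinkageError(
            f"{layout.family_id}: founder-allele enumeration too large "
            f"({n_assign} assignments)"
        )
    idx = _assignment_grid(len(codes), n_slots)  # (n_assign, n_slots) code indices
    grid = codes[idx]
    prior = np.prod(fvec[idx], axis=1)

    compat = np.ones((n_assign, layout.n_vectors), dtype=bool)
    for iid, ind in pedigree.members.items():
        g1, g2 = int(ind.genotypes[marker, 0]), int(ind.genotypes[marker, 1])
        if g1 == 0:
            continue
        a1 = grid[:, layout.pat_label[iid]]  # (n_assign, V)
        a2 = grid[:, layout.mat_label[iid]]
        compat &= ((a1 == g1) & (a2 == g2)) | ((a1 == g2) & (a2 == g1))
    return prior @ compat


def _mix_bits(x: np.ndarray, theta: float, n_bits: int) -> np.ndarray:
    """One HMM transition: each meiosis bit flips independently w.p. theta."""
    if n_bits == 0:
        return x
    y = x.reshape((2,) * n_bits)
    for ax in range(n_bits):
        y = (1.0 - theta) * y + theta * np.flip(y, axis=ax)
    return y.reshape(-1)


@dataclass
class InheritanceDistribution:
    """Multipoint posterior over inheritance vectors for one family.

    ``posterior`` has shape (n_positions, V); every row sums to 1.
    """

    family_id: str
    layout: PedigreeLayout
    chromosomes: np.ndarray
    positions_cm: np.ndarray
    posterior: np.ndarray
    log_likelihood: float


def lander_green_ibd(
    pedigree: Pedigree,
    marker_map: MarkerMap,
    allele_freqs: list[dict[int, float]],
    max_meiosis_bits: int = DEFAULT_MEIOSIS_BUDGET,
    extra_positions: dict[int, np.ndarray] | None = None,
) -> InheritanceDistribution:
    """Forward-backward multipoint inheritance-vector posterior.

    Chromosomes are independent; within each, emissions at marker positions
    condition on all markers of that chromosome.  ``extra_positions`` may
    add evaluation points (cM per chromosome) carrying uniform emissions.
    Raises on a meiosis budget overrun or a zero-likelihood marker
    (unresolved Mendelian inconsistency).
    """
    layout = build_layout(pedigree)
    if layout.n_bits > max_meiosis_bits:
        raise LinkageError(
            f"{pedigree.family_id}: {layout.n_bits} meiosis bits exceed "
            f"budget {max_meiosis_bits}"
        )
    V = layout.n_vectors
    out_chrom: list[np.ndarray] = []
    out_pos: list[np.ndarray] = []
    out_post: list[np.ndarray] = []
    loglik = 0.0
    for chrom in np.unique(marker_map.chromosomes):
        midx = marker_map.chromosome_indices(chrom)
        mpos = marker_map.positions_cm[midx]
        points: list[tuple[float, int]] = [(float(p), int(m)) for p, m in zip(mpos, midx)]
        if extra_positions and int(chrom) in extra_positions:
            have = set(np.round(mpos, 9))
            for p in extra_positions[int(chrom)]:
                if round(float(p), 9) not in have:
                    points.append((float(p), -1))
        points.sort()
        pos = np.array([p for p, _ in points])
        emis = np.empty((len(points), V))
        for row, (_, m) in enumerate(points):
            if m < 0:
                emis[row] = 1.0
            else:
                emis[row] = _marker_emission(pedigree, layout, m, allele_freqs[m])
                if emis[row].max() <= 0.0:
                    raise LinkageError(
                        f"{pedigree.family_id}: zero likelihood at marker "
                        f"{marker_map.marker_ids[m]} (Mendelian inconsistency?)"
                    )
        thetas = haldane_theta(np.diff(pos))
        n = len(points)
        fwd = np.empty((n, V))
        f = emis[0] / V
        norm_f = f.sum()
        loglik += np.log(norm_f)
        fwd[0] = f / norm_f
        for j in range(1, n):
            f = _mix_bits(fwd[j - 1], float(thetas[j - 1]), layout.n_bits) * emis[j]
            norm_f = f.sum()
            if norm_f <= 0.0:
                raise LinkageError(
                    f"{pedigree.family_id}: zero likelihood on chr{chrom}"
                )
            loglik += np.log(norm_f)
            fwd[j] = f / norm_f
        bwd = np.ones(V)
        post = np.empty((n, V))
        post[n - 1] = fwd[n - 1]
        for j in range(n - 2, -1, -1):
            bwd = _mix_bits(bwd * emis[j + 1], float(thetas[j]), layout.n_bits)
            bwd /= bwd.sum()
            p = fwd[j] * bwd
            post[j] = p / p.sum()
        out_chrom.append(np.full(n, int(chrom)))
        out_pos.append(pos)
        out_post.append(post)
    return InheritanceDistribution(
        family_id=pedigree.family_id,
        layout=layout,
        chromosomes=np.concatenate(out_chrom),
        positions_cm=np.concatenate(out_pos),
        posterior=np.vstack(out_post),
        log_likelihood=float(loglik),
    )


# ---------------------------------------------------------------------------
# allele-sharing statistics


def _pair_ibd_vector(layout: PedigreeLayout, a: str, b: str) -> np.ndarray:
    """Alleles shared IBD between two individuals per inheritance vector.

    Multiset intersection of the two founder-allele label pairs (0, 1 or 2).
    """
    pa, ma = layout.pat_label[a], layout.mat_label[a]
    pb, mb = layout.pat_label[b], layout.mat_label[b]
    direct = (pa == pb).astype(np.int8) + (ma == mb).astype(np.int8)
    crossed = (pa == mb).astype(np.int8) + (ma == pb).astype(np.int8)
    return np.maximum(direct, crossed)


def s_pairs_vector(layout: PedigreeLayout, affected: list[str]) -> np.ndarray:
    """S_pairs score per inheritance vector: IBD summed over affected pairs."""
    if len(affected) < 2:
        raise LinkageError("S_pairs needs at least two scored affecteds")
    s = np.zeros(layout.n_vectors)
    for a, b in itertools.combinations(sorted(affected), 2):
        s += _pair_ibd_vector(layout, a, b)
    return s


def s_all_vector(layout: PedigreeLayout, affected: list[str]) -> np.ndarray:
    """Whittemore-Halpern S_all score per inheritance vector.

    Averages, over the 2^|A| ways of picking one allele per affected, the
    product of factorials of founder-allele multiplicities among the picked
    alleles.  Rewards alleles shared by many affecteds at once.
    """
    if len(affected) < 2:
        raise LinkageError("S_all needs at least two scored affecteds")
    affected = sorted(affected)
    total = np.zeros(layout.n_vectors)
    for picks in itertools.product((0, 1), repeat=len(affected)):
        chosen = np.stack(
            [
                layout.pat_label[a] if side == 0 else layout.mat_label[a]
                for a, side in zip(affected, picks)
            ]
        )  # (|A|, V)
        total += _picked_score(np.sort(chosen, axis=0))
    return total / (1 << len(affected))


def _picked_score(sorted_labels: np.ndarray) -> np.ndarray:
    """Product of factorials of label run lengths along axis 0."""
    from scipy.special import factorial

    k, V = sorted_labels.shape
    score = np.ones(V)
    run = np.ones(V)
    for r in range(1, k):
        same = sorted_labels[r] == sorted_labels[r - 1]
        score *= np.where(same, 1.0, factorial(run))
        run = np.where(same, run + 1, 1.0)
    score *= factorial(run)
    return score


@dataclass
class FamilyNPL:
    """Standardized per-family allele-sharing score along the map."""

    family_id: str
    chromosomes: np.ndarray
    positions_cm: np.ndarray
    s_observed: np.ndarray
    null_mean: float
    null_sd: float
    z: np.ndarray | None  # None when the family is uninformative


def npl_pairs(
    pedigree: Pedigree,
    inheritance_dist: InheritanceDistribution,
    retained_affecteds: list[str],
    statistic: str = "pairs",
) -> FamilyNPL:
    """Score a family's allele sharing among the retained affecteds.

    The null mean and SD are exact moments of the scoring function under
    the uniform inheritance-vector distribution; Z = (S - mu0) / sd0.
    Families whose scoring function is constant (sd0 = 0) are flagged
    uninformative and excluded from combination.
    """
    layout = inheritance_dist.layout
    if statistic == "pairs":
        s_vec = s_pairs_vector(layout, list(retained_affecteds))
    elif statistic == "all":
        s_vec = s_all_vector(layout, list(retained_affecteds))
    else:
        raise LinkageError(f"unknown statistic {statistic!r}")
    mu0 = float(s_vec.mean())
    sd0 = float(s_vec.std())
    s_obs = inheritance_dist.posterior @ s_vec
    z = None if sd0 < 1e-12 else (s_obs - mu0) / sd0
    return FamilyNPL(
        family_id=pedigree.family_id,
        chromosomes=inheritance_dist.chromosomes,
        positions_cm=inheritance_dist.positions_cm,
        s_observed=s_obs,
        null_mean=mu0,
        null_sd=sd0,
        z=z,
    )


# ---------------------------------------------------------------------------
# Kong-Cox one-parameter allele-sharing LOD


def _delta_upper(z: np.ndarray, cap: float) -> np.ndarray:
    """Feasible upper bound for delta per position: keep 1 + delta z > 0."""
    zneg = np.where(z < 0, -z, 0.0)
    worst = zneg.max(axis=0)
    with np.errstate(divide="ignore"):
        bound = np.where(worst > 0, 0.999999 / np.where(worst > 0, worst, 1.0), cap)
    return np.minimum(bound, cap)


def kong_cox_curve(
    z_matrix: np.ndarray, delta_cap: float = DEFAULT_DELTA_CAP, iters: int = 80
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized maximization of sum_i log10(1 + delta z_i) per column.

    ``z_matrix`` is (n_families, n_positions).  The objective is concave in
    delta, so golden-section search on [0, delta_max] converges to the
    global maximum; delta_max enforces positivity of every factor (with an
    absolute cap when no family score is negative).  Returns (delta_hat,
    LOD), both length n_positions, LOD truncated at 0.
    """
    z = np.atleast_2d(np.asarray(z_matrix, dtype=float))
    if z.shape[0] == 0:
        raise LinkageError("no informative families to combine")
    hi = _delta_upper(z, delta_cap)
    lo = np.zeros_like(hi)

    def f(delta: np.ndarray) -> np.ndarray:
        return np.log10(1.0 + delta[None, :] * z).sum(axis=0)

    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo.copy(), hi.copy()
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(iters):
        take_left = fc >= fd
        b = np.where(take_left, d, b)
        a = np.where(take_left, a, c)
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc, fd = f(c), f(d)
    delta_hat = 0.5 * (a + b)
    lod = f(delta_hat)
    zero = lod <= 0.0
    return np.where(zero, 0.0, delta_hat), np.where(zero, 0.0, lod)


def kong_cox_lod(
    family_scores, delta_cap: float = DEFAULT_DELTA_CAP
) -> tuple[float, float]:
    """Combine per-family Z scores at one position into (delta_hat, LOD)."""
    z = np.asarray(list(family_scores), dtype=float)
    if z.size == 0:
        raise LinkageError("no informative families at this position")
    delta, lod = kong_cox_curve(z[:, None], delta_cap=delta_cap)
    return float(delta[0]), float(lod[0])


def lod_to_pvalue(lod):
    """Pointwise p for an allele-sharing LOD: 1 - Phi(sqrt(2 ln10 LOD)).

    A LOD of 0 maps to p = 0.5; negative LODs are invalid (curves are
    truncated at zero upstream).  Strictly decreasing in LOD.
    """
    arr = np.asarray(lod, dtype=float)
    if np.any(arr < 0):
        raise LinkageError("LOD must be non-negative")
    p = norm.sf(np.sqrt(_TWO_LN10 * arr))
    return float(p) if np.isscalar(lod) else p


# ---------------------------------------------------------------------------
# genome scan


@dataclass
class LODCurve:
    """Combined allele-sharing LOD along the map for one cohort."""

    label: str
    chromosomes: np.ndarray
    positions_cm: np.ndarray
    marker_ids: list[str]
    z_combined: np.ndarray
    delta: np.ndarray
    lod: np.ndarray
    pointwise_p: np.ndarray
    n_families: int

    @property
    def max_lod(self) -> float:
        return float(self.lod.max())

    @property
    def argmax(self) -> tuple[int, float]:
        """(chromosome, position) of the genome-wide maximum."""
        i = int(self.lod.argmax())
        return int(self.chromosomes[i]), float(self.positions_cm[i])

    def chromosome_max(self) -> dict[int, float]:
        return {
            int(c): float(self.lod[self.chromosomes == c].max())
            for c in np.unique(self.chromosomes)
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.label,
                "chrom": self.chromosomes,
                "pos_cm": self.positions_cm,
                "marker_id": self.marker_ids,
                "z": self.z_combined,
                "delta": self.delta,
                "lod": self.lod,
                "p": self.pointwise_p,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


class MultipointEngine:
    """Shared multipoint machinery for scanning many cohorts over one map.

    Per-family inheritance-vector posteriors are computed once and cached;
    per-family Z curves are cached per retained-affected set, so stratified
    subgroups and permutation replicates reuse all the heavy work.
    """

    def __init__(
        self,
        pedigrees: list[Pedigree],
        marker_map: MarkerMap,
        allele_freqs: list[dict[int, float]] | None = None,
        statistic: str = "pairs",
        max_meiosis_bits: int = DEFAULT_MEIOSIS_BUDGET,
        grid_cm: float | None = None,
    ):
        self.pedigrees = {p.family_id: p for p in pedigrees}
        self.marker_map = marker_map
        self.statistic = statistic
        self.max_meiosis_bits = max_meiosis_bits
        self.allele_freqs = (
            allele_freqs
            if allele_freqs is not None
            else self._estimate_freqs(pedigrees, marker_map)
        )
        self.extra_positions = self._grid_positions(grid_cm)
        self._dist_cache: dict[str, InheritanceDistribution | None] = {}
        self._z_cache: dict[tuple[str, frozenset[str]], np.ndarray | None] = {}
        self._axes: tuple[np.ndarray, np.ndarray, list[str]] | None = None

    @staticmethod
    def _estimate_freqs(
        pedigrees: list[Pedigree], marker_map: MarkerMap
    ) -> list[dict[int, float]]:
        from .qc import founder_allele_freqs

        freqs = []
        for m in range(len(marker_map)):
            fr = founder_allele_freqs(pedigrees, m)
            if fr is None:
                raise LinkageError(
                    f"no founder genotypes to estimate frequencies at "
                    f"{marker_map.marker_ids[m]}"
                )
            freqs.append(fr)
        return freqs

    def _grid_positions(self, grid_cm: float | None) -> dict[int, np.ndarray] | None:
        if grid_cm is None:
            return None
        out = {}
        for chrom in np.unique(self.marker_map.chromosomes):
            pos = self.marker_map.positions_cm[
                self.marker_map.chromosome_indices(chrom)
            ]
            out[int(chrom)] = np.arange(pos.min(), pos.max() + 1e-9, grid_cm)
        return out

    def inheritance(self, family_id: str) -> InheritanceDistribution | None:
        """Cached multipoint posterior; None when the family is skipped."""
        if family_id not in self._dist_cache:
            ped = self.pedigrees[family_id]
            try:
                dist = lander_green_ibd(
                    ped,
                    self.marker_map,
                    self.allele_freqs,
                    max_meiosis_bits=self.max_meiosis_bits,
                    extra_positions=self.extra_positions,
                )
            except LinkageError as exc:
                if "meiosis bits" in str(exc):
                    warnings.warn(str(exc), stacklevel=2)
                    dist = None
                else:
                    raise
            self._dist_cache[family_id] = dist
            if dist is not None and self._axes is None:
                nearest = self._nearest_markers(dist.chromosomes, dist.positions_cm)
                self._axes = (dist.chromosomes, dist.positions_cm, nearest)
        return self._dist_cache[family_id]

    def _nearest_markers(self, chroms: np.ndarray, pos: np.ndarray) -> list[str]:
        out = []
        for c, p in zip(chroms, pos):
            idx = self.marker_map.chromosome_indices(int(c))
            j = idx[np.abs(self.marker_map.positions_cm[idx] - p).argmin()]
            out.append(self.marker_map.marker_ids[j])
        return out

    def z_curve(self, family_id: str, retained: frozenset[str]) -> np.ndarray | None:
        key = (family_id, retained)
        if key not in self._z_cache:
            dist = self.inheritance(family_id)
            if dist is None or len(retained) < 2:
                self._z_cache[key] = None
            else:
                npl = npl_pairs(
                    self.pedigrees[family_id], dist, sorted(retained), self.statistic
                )
                self._z_cache[key] = npl.z
        return self._z_cache[key]

    def z_matrix(self, cohort: StratifiedCohort) -> tuple[list[str], np.ndarray]:
        """Stacked informative-family Z curves for a stratified cohort."""
        fams, rows = [], []
        for fid in sorted(cohort.families):
            z = self.z_curve(fid, cohort.families[fid])
            if z is not None:
                fams.append(fid)
                rows.append(z)
        if not rows:
            raise LinkageError(f"cohort {cohort.label}: no informative families")
        return fams, np.vstack(rows)

    def scan(self, cohort: StratifiedCohort) -> LODCurve:
        """Genome scan: combine family scores into a LOD curve with p-values."""
        fams, zmat = self.z_matrix(cohort)
        delta, lod = kong_cox_curve(zmat)
        if self._axes is None:  # pragma: no cover - set by z_matrix
            raise LinkageError("no family posterior computed")
        chroms, pos, nearest = self._axes
        return LODCurve(
            label=cohort.label,
            chromosomes=chroms,
            positions_cm=pos,
            marker_ids=nearest,
            z_combined=zmat.sum(axis=0) / np.sqrt(zmat.shape[0]),
            delta=delta,
            lod=lod,
            pointwise_p=lod_to_pvalue(lod),
            n_families=len(fams),
        )


def scan_genome(
    cohort_pedigrees: list[Pedigree],
    marker_map: MarkerMap,
    cohort: StratifiedCohort,
    allele_freqs: list[dict[int, float]] | None = None,
    statistic: str = "pairs",
    grid_cm: float | None = None,
) -> LODCurve:
    """One-shot genome scan for a single stratified cohort."""
    engine = MultipointEngine(
        cohort_pedigrees,
        marker_map,
        allele_freqs=allele_freqs,
        statistic=statistic,
        grid_cm=grid_cm,
    )
    return engine.scan(cohort)
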