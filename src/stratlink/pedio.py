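"""Pedigree, marker-map and sub-phenotype file I/O and the shared data model.

The canonical interchange formats are the whitespace-delimited PED dialect
(six-column prefix ``family indiv father mother sex affection`` followed by
two integer allele codes per marker, ``0`` = missing), the four/five-column
MAP dialect (``chrom marker_id cM bp [band]``), and a headed TSV of
sub-phenotype assignments.  All readers transparently accept gzip.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

MISSING_PARENT = "0"

SEX_MALE = "male"
SEX_FEMALE = "female"
SEX_UNKNOWN = "unknown"

AFFECTED = "affected"
UNAFFECTED = "unaffected"
UNKNOWN = "unknown"

_SEX_CODES = {"1": SEX_MALE, "2": SEX_FEMALE}
_AFF_CODES = {"2": AFFECTED, "1": UNAFFECTED, "0": UNKNOWN, "-9": UNKNOWN}
_SEX_OUT = {SEX_MALE: "1", SEX_FEMALE: "2", SEX_UNKNOWN: "0"}
_AFF_OUT = {AFFECTED: "2", UNAFFECTED: "1", UNKNOWN: "0"}

SUBTYPES = ("g1", "g2", "g3", "g4")
DX_CLASSES = ("strict", "broad")


class PedigreeError(ValueError):
    """Structural or parse problem in pedigree/map/subtype input."""


@dataclass
class Individual:
    """One pedigree member with genotypes over the shared marker panel.

    ``genotypes`` is an ``(n_markers, 2)`` integer array of allele codes;
    0 means missing.  Both alleles of a genotype are missing or both present.
    """

    family_id: str
    indiv_id: str
    father_id: str
    mother_id: str
    sex: str
    affection: str
    genotypes: np.ndarray

    @property
    def is_founder(self) -> bool:
        return self.father_id == MISSING_PARENT and self.mother_id == MISSING_PARENT

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes, dtype=np.int16)
        if g.ndim != 2 or g.shape[1] != 2:
            raise PedigreeError(
                f"{self.family_id}/{self.indiv_id}: genotypes must be (n_markers, 2)"
            )
        half = (g == 0).sum(axis=1) == 1
        if half.any():
            m = int(np.nonzero(half)[0][0])
            raise PedigreeError(
                f"{self.family_id}/{self.indiv_id}: half-missing genotype at marker {m}"
            )
        self.genotypes = g


@dataclass
class Pedigree:
    """A single family: members keyed by individual id, canonically sorted."""

    family_id: str
    members: dict[str, Individual] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.members = {k: self.members[k] for k in sorted(self.members)}

    @property
    def founders(self) -> list[Individual]:
        return [m for m in self.members.values() if m.is_founder]

    @property
    def nonfounders(self) -> list[Individual]:
        return [m for m in self.members.values() if not m.is_founder]

    @property
    def affected_ids(self) -> list[str]:
        return [i for i, m in self.members.items() if m.affection == AFFECTED]

    def validate(self) -> None:
        for ind in self.members.values():
            has_f = ind.father_id != MISSING_PARENT
            has_m = ind.mother_id != MISSING_PARENT
            if has_f != has_m:
                raise PedigreeError(
                    f"{self.family_id}/{ind.indiv_id}: one known and one unknown "
                    "parent (both or neither required)"
                )
            if has_f:
                for pid, want in ((ind.father_id, SEX_MALE), (ind.mother_id, SEX_FEMALE)):
                    if pid not in self.members:
                        raise PedigreeError(
                            f"{self.family_id}/{ind.indiv_id}: dangling parent "
                            f"reference {pid!r}"
                        )
                    if self.members[pid].sex != want:
                        raise PedigreeError(
                            f"{self.family_id}: parent {pid} of {ind.indiv_id} "
                            f"must be {want}"
                        )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(iid: str) -> None:
            if state.get(iid) == 1:
                raise PedigreeError(f"{self.family_id}: {iid} is its own ancestor")
            if state.get(iid) == 2:
                return
            state[iid] = 1
            ind = self.members[iid]
            for pid in (ind.father_id, ind.mother_id):
                if pid != MISSING_PARENT:
                    visit(pid)
            state[iid] = 2

        for iid in self.members:
            visit(iid)

    def topological_nonfounders(self) -> list[Individual]:
        """Non-founders ordered so every parent precedes its children."""
        order: list[Individual] = []
        done = {m.indiv_id for m in self.founders}
        pending = {m.indiv_id: m for m in self.nonfounders}
        while pending:
            progressed = False
            for iid in sorted(pending):
                ind = pending[iid]
                if ind.father_id in done and ind.mother_id in done:
                    order.append(ind)
                    done.add(iid)
                    del pending[iid]
                    progressed = True
            if not progressed:  # pragma: no cover - guarded by validate()
                raise PedigreeError(f"{self.family_id}: unresolved parent ordering")
        return order


@dataclass
class MarkerMap:
    """Autosomal marker panel: ids, chromosome, genetic position, frequencies.

    Markers are stored in (chromosome, cM) order; within a chromosome
    positions are strictly increasing (duplicates jittered on read).
    ``allele_freqs`` holds one ``{allele_code: freq}`` dict per marker or
    ``None`` when frequencies are to be estimated from founders downstream.
    """

    marker_ids: list[str]
    chromosomes: np.ndarray
    positions_cm: np.ndarray
    physical_bp: np.ndarray | None = None
    bands: list[str] | None = None
    allele_freqs: list[dict[int, float] | None] | None = None

    def __post_init__(self) -> None:
        self.chromosomes = np.asarray(self.chromosomes, dtype=int)
        self.positions_cm = np.asarray(self.positions_cm, dtype=float)
        if np.any(self.positions_cm < 0):
            raise PedigreeError("genetic positions must be non-negative")
        order = np.lexsort((self.positions_cm, self.chromosomes))
        if not np.array_equal(order, np.arange(len(order))):
            self._reorder(order)
        for chrom in np.unique(self.chromosomes):
            pos = self.positions_cm[self.chromosomes == chrom]
            if np.any(np.diff(pos) <= 0):
                raise PedigreeError(
                    f"chr{chrom}: positions not strictly increasing (jitter on read)"
                )
        if self.allele_freqs is not None:
            for mid, fr in zip(self.marker_ids, self.allele_freqs):
                if fr is not None and abs(sum(fr.values()) - 1.0) > 1e-9:
                    raise PedigreeError(f"{mid}: allele frequencies must sum to 1")

    def _reorder(self, order: np.ndarray) -> None:
        self.marker_ids = [self.marker_ids[i] for i in order]
        self.chromosomes = self.chromosomes[order]
        self.positions_cm = self.positions_cm[order]
        if self.physical_bp is not None:
            self.physical_bp = self.physical_bp[order]
        if self.bands is not None:
            self.bands = [self.bands[i] for i in order]
        if self.allele_freqs is not None:
            self.allele_freqs = [self.allele_freqs[i] for i in order]

    def __len__(self) -> int:
        return len(self.marker_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def chromosome_indices(self, chrom: int) -> np.ndarray:
        return np.nonzero(self.chromosomes == chrom)[0]

    def thin(self, min_spacing_cm: float) -> np.ndarray:
        """Indices of a greedily thinned panel with the requested spacing.

        Keeps the first marker of each chromosome and every subsequent
        marker at least ``min_spacing_cm`` beyond the last kept one — a
        coarse guard against inter-marker LD, which the multipoint model
        does not represent.  Use with :meth:`subset` and
        :func:`subset_genotypes`.
        """
        keep = []
        last: dict[int, float] = {}
        for i, (chrom, pos) in enumerate(zip(self.chromosomes, self.positions_cm)):
            if chrom not in last or pos - last[chrom] >= min_spacing_cm:
                keep.append(i)
                last[chrom] = pos
        return np.asarray(keep)

    def subset(self, keep: np.ndarray) -> "MarkerMap":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.nonzero(keep)[0]
        return MarkerMap(
            marker_ids=[self.marker_ids[i] for i in keep],
            chromosomes=self.chromosomes[keep],
            positions_cm=self.positions_cm[keep],
            physical_bp=None if self.physical_bp is None else self.physical_bp[keep],
            bands=None if self.bands is None else [self.bands[i] for i in keep],
            allele_freqs=None
            if self.allele_freqs is None
            else [self.allele_freqs[i] for i in keep],
        )


@dataclass(frozen=True)
class SubtypeAssignment:
    """Per-affected sub-phenotype cluster label and diagnosis class."""

    family_id: str
    indiv_id: str
    subtype: str  # g1..g4 or "none"
    dx_class: str  # strict | broad

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPES + ("none",):
            raise PedigreeError(f"unknown subtype token {self.subtype!r}")
        if self.dx_class not in DX_CLASSES:
            raise PedigreeError(f"unknown dx_class token {self.dx_class!r}")


class SubtypeTable:
    """Lookup of SubtypeAssignment by (family_id, indiv_id)."""

    def __init__(self, assignments: list[SubtypeAssignment]):
        self.assignments = sorted(
            assignments, key=lambda a: (a.family_id, a.indiv_id)
        )
        self._index = {(a.family_id, a.indiv_id): a for a in self.assignments}
        if len(self._index) != len(self.assignments):
            raise PedigreeError("duplicate (family_id, indiv_id) in subtype table")

    def subtype_of(self, family_id: str, indiv_id: str) -> str:
        a = self._index.get((family_id, indiv_id))
        return a.subtype if a is not None else "none"

    def dx_of(self, family_id: str, indiv_id: str) -> str:
        # Individuals missing from the table default to the strict class.
        a = self._index.get((family_id, indiv_id))
        return a.dx_class if a is not None else "strict"

    def __len__(self) -> int:
        return len(self.assignments)

    def __iter__(self):
        return iter(self.assignments)


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_ped(path, marker_count: int) -> list[Pedigree]:
    """Read a PED file into one validated :class:`Pedigree` per family.

    Families and members come out canonically sorted regardless of input
    row order.  Raises :class:`PedigreeError` with the offending line number
    on malformed rows, wrong genotype column counts, dangling parent
    references or half-known parent pairs.
    """
    families: dict[str, dict[str, Individual]] = {}
    ncols = 6 + 2 * marker_count
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != ncols:
                raise PedigreeError(
                    f"line {lineno}: expected {ncols} columns "
                    f"(6 + 2x{marker_count}), got {len(fields)}"
                )
            fam, iid, fid, mid, sex_c, aff_c = fields[:6]
            try:
                alleles = np.array(fields[6:], dtype=np.int16).reshape(-1, 2)
            except ValueError as exc:
                raise PedigreeError(f"line {lineno}: non-integer allele code") from exc
            ind = Individual(
                family_id=fam,
                indiv_id=iid,
                father_id=fid,
                mother_id=mid,
                sex=_SEX_CODES.get(sex_c, SEX_UNKNOWN),
                affection=_AFF_CODES.get(aff_c, UNKNOWN),
                genotypes=alleles,
            )
            if iid in families.setdefault(fam, {}):
                raise PedigreeError(f"line {lineno}: duplicate individual {fam}/{iid}")
            families[fam][iid] = ind
    pedigrees = [Pedigree(fam, members) for fam, members in sorted(families.items())]
    for ped in pedigrees:
        ped.validate()
    return pedigrees


def write_ped(path, pedigrees: list[Pedigree]) -> None:
    with _open_text(path, "wt") as fh:
        for ped in sorted(pedigrees, key=lambda p: p.family_id):
            for ind in ped.members.values():
                row = [
                    ind.family_id,
                    ind.indiv_id,
                    ind.father_id,
                    ind.mother_id,
                    _SEX_OUT[ind.sex],
                    _AFF_OUT[ind.affection],
                ]
                row.extend(str(a) for a in ind.genotypes.ravel())
                fh.write(" ".join(row) + "\n")


DUPLICATE_CM_EPSILON = 1e-6


def read_map(path, jitter_epsilon: float = DUPLICATE_CM_EPSILON) -> MarkerMap:
    """Read a MAP file (chrom, id, cM, bp[, band]); autosomes 1-22 only.

    Rows outside chromosomes 1-22 (e.g. X) are dropped with a logged count.
    Duplicate genetic positions within a chromosome are jittered forward by
    ``jitter_epsilon`` cM in stable marker_id order, since the multipoint
    HMM needs strictly positive inter-marker distances.
    """
    rows = []
    dropped = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) not in (4, 5):
                raise PedigreeError(f"line {lineno}: expected 4 or 5 columns")
            chrom_s, mid, cm_s, bp_s = fields[:4]
            band = fields[4] if len(fields) == 5 else ""
            try:
                chrom = int(chrom_s)
            except ValueError:
                chrom = -1
            if not 1 <= chrom <= 22:
                dropped += 1
                continue
            try:
                cm = float(cm_s)
            except ValueError as exc:
                raise PedigreeError(f"line {lineno}: non-numeric cM {cm_s!r}") from exc
            try:
                bp = int(bp_s)
            except ValueError as exc:
                raise PedigreeError(f"line {lineno}: non-integer bp {bp_s!r}") from exc
            rows.append((chrom, cm, mid, bp, band))
    if dropped:
        logger.warning("read_map: dropped %d non-autosomal rows", dropped)
        warnings.warn(f"read_map: dropped {dropped} non-autosomal rows", stacklevel=2)
    if not rows:
        raise PedigreeError("map file has no autosomal markers")
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    # jitter duplicate cM positions forward, stable in marker_id order
    for i in range(1, len(rows)):
        chrom, cm, mid, bp, band = rows[i]
        prev = rows[i - 1]
        if chrom == prev[0] and cm <= prev[1]:
            logger.warning("read_map: %s jittered off duplicate position", mid)
            rows[i] = (chrom, prev[1] + jitter_epsilon, mid, bp, band)
    return MarkerMap(
        marker_ids=[r[2] for r in rows],
        chromosomes=np.array([r[0] for r in rows]),
        positions_cm=np.array([r[1] for r in rows]),
        physical_bp=np.array([r[3] for r in rows]),
        bands=[r[4] for r in rows],
    )


def write_map(path, mmap: MarkerMap) -> None:
    with _open_text(path, "wt") as fh:
        for i, mid in enumerate(mmap.marker_ids):
            bp = 0 if mmap.physical_bp is None else int(mmap.physical_bp[i])
            band = "" if mmap.bands is None else mmap.bands[i]
            row = f"{mmap.chromosomes[i]}\t{mid}\t{mmap.positions_cm[i]:.6f}\t{bp}"
            if band:
                row += f"\t{band}"
            fh.write(row + "\n")


SUBTYPE_HEADER = ["family_id", "indiv_id", "subtype", "dx_class"]


def read_subtypes(path, pedigrees: list[Pedigree] | None = None) -> SubtypeTable:
    """Read the sub-phenotype TSV (header ``family_id indiv_id subtype dx_class``).

    When ``pedigrees`` is given, assignments naming individuals absent from
    the cohort are flagged with a warning, and a subtype other than "none"
    on a non-affected individual raises.
    """
    assignments = []
    with _open_text(path) as fh:
        header = fh.readline().split()
        if header != SUBTYPE_HEADER:
            raise PedigreeError(f"subtype table must start with header {SUBTYPE_HEADER}")
        for lineno, line in enumerate(fh, start=2):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise PedigreeError(f"line {lineno}: expected 4 columns")
            assignments.append(SubtypeAssignment(*fields))
    table = SubtypeTable(assignments)
    if pedigrees is not None:
        index = {p.family_id: p for p in pedigrees}
        for a in table:
            ped = index.get(a.family_id)
            if ped is None or a.indiv_id not in ped.members:
                warnings.warn(
                    f"subtype row for unknown individual {a.family_id}/{a.indiv_id}",
                    stacklevel=2,
                )
            elif a.subtype != "none" and ped.members[a.indiv_id].affection != AFFECTED:
                raise PedigreeError(
                    f"{a.family_id}/{a.indiv_id}: subtype {a.subtype} on a "
                    "non-affected individual"
                )
    return table


def write_subtypes(path, table: SubtypeTable) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(SUBTYPE_HEADER) + "\n")
        for a in table:
            fh.write(f"{a.family_id}\t{a.indiv_id}\t{a.subtype}\t{a.dx_class}\n")


def _trio_compatible(child: np.ndarray, father: np.ndarray, mother: np.ndarray) -> np.ndarray:
    """Vectorized per-marker trio compatibility (True where compatible).

    A marker is compatible when some ordered assignment places one child
    allele with the father and the other with the mother; untyped
    individuals never conflict.
    """

    def from_parent(allele, parent):
        missing = (parent[:, 0] == 0) | (allele == 0)
        return missing | (allele == parent[:, 0]) | (allele == parent[:, 1])

    c0, c1 = child[:, 0], child[:, 1]
    way1 = from_parent(c0, father) & from_parent(c1, mother)
    way2 = from_parent(c1, father) & from_parent(c0, mother)
    return way1 | way2


def subset_genotypes(pedigrees: list[Pedigree], keep: np.ndarray) -> list[Pedigree]:
    """New pedigrees restricted to the marker columns in ``keep``.

    Use together with :meth:`MarkerMap.subset` so genotype columns stay
    aligned with the marker panel after QC filtering.
    """
    keep = np.asarray(keep)
    if keep.dtype == bool:
        keep = np.nonzero(keep)[0]
    out = []
    for ped in pedigrees:
        members = {
            iid: replace(ind, genotypes=ind.genotypes[keep])
            for iid, ind in ped.members.items()
        }
        out.append(Pedigree(ped.family_id, members))
    return out


def mendelian_check(pedigree: Pedigree, marker_map: MarkerMap | None = None) -> np.ndarray:
    """Count Mendelian inconsistencies per marker within one family.

    Each child with known parents contributes one error at every marker
    where no allele-to-parent assignment is consistent.  Pure scan;
    deterministic.
    """
    n_markers = next(iter(pedigree.members.values())).genotypes.shape[0]
    errors = np.zeros(n_markers, dtype=int)
    for ind in pedigree.nonfounders:
        father = pedigree.members[ind.father_id].genotypes
        mother = pedigree.members[ind.mother_id].genotypes
        ok = _trio_compatible(ind.genotypes, father, mother)
        errors += ~ok
    return errors
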