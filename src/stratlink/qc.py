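"""Marker-level quality control for family SNP panels.

Filters mirror standard array-era linkage QC: minor allele frequency,
missing-genotype rate, an exact Hardy-Weinberg test, and a per-marker
Mendelian-error budget.  Allele frequencies and the HWE test use founder
genotypes only, so relatedness within sibships cannot inflate either.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedio import MarkerMap, Pedigree, mendelian_check


class QCError(ValueError):
    pass


@dataclass
class QCThresholds:
    maf_min: float = 0.05
    missing_max: float = 0.10
    hwe_alpha: float = 0.001
    mendel_max: int = 1


@dataclass
class QCReport:
    """Per-marker QC metrics and the exclusion reasons actually applied."""

    marker_ids: list[str]
    maf: np.ndarray
    missing_rate: np.ndarray
    hwe_p: np.ndarray
    mendel_errors: np.ndarray
    excluded_by: list[frozenset[str]] = field(default_factory=list)
    kept_indices: np.ndarray | None = None  # surviving marker columns

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_ids,
                "maf": self.maf,
                "missing_rate": self.missing_rate,
                "hwe_p": self.hwe_p,
                "mendel_errors": self.mendel_errors,
                "excluded_by": [",".join(sorted(e)) for e in self.excluded_by],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _founder_alleles(cohort: list[Pedigree], marker: int) -> np.ndarray:
    alleles = []
    for ped in cohort:
        for ind in ped.founders:
            g = ind.genotypes[marker]
            if g[0] != 0:
                alleles.append(g[0])
                alleles.append(g[1])
    return np.asarray(alleles, dtype=int)


def compute_maf(cohort: list[Pedigree], marker: int) -> float:
    """Minor allele frequency at one marker from founder chromosomes only.

    Returns ``nan`` when every founder is untyped (undefined marker).
    Ties at 0.5 return 0.5.
    """
    alleles = _founder_alleles(cohort, marker)
    if alleles.size == 0:
        return float("nan")
    _, counts = np.unique(alleles, return_counts=True)
    if counts.size == 1:
        return 0.0
    return float(min(counts.max(), alleles.size - counts.max()) / alleles.size)


def founder_allele_freqs(cohort: list[Pedigree], marker: int) -> dict[int, float] | None:
    """Full founder allele-frequency spectrum at one marker (or None)."""
    alleles = _founder_alleles(cohort, marker)
    if alleles.size == 0:
        return None
    codes, counts = np.unique(alleles, return_counts=True)
    return {int(c): float(n) / alleles.size for c, n in zip(codes, counts)}


def hwe_exact_test(genotype_counts: dict[str, int]) -> float:
    """Two-sided exact Hardy-Weinberg test on founder genotype counts.

    ``genotype_counts`` holds counts keyed ``AA``/``Aa``/``aa``.  The p-value
    is the total probability, conditional on the observed allele counts, of
    every heterozygote configuration whose probability does not exceed the
    observed one.  Monomorphic markers return 1.0.
    """
    n_aa = int(genotype_counts.get("AA", 0))
    n_ab = int(genotype_counts.get("Aa", 0))
    n_bb = int(genotype_counts.get("aa", 0))
    if min(n_aa, n_ab, n_bb) < 0:
        raise QCError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise QCError("need at least one genotype")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0  # monomorphic
    # P(n_het | allele counts) over all feasible heterozygote counts, via the
    # standard conditional recurrence; normalize at the end.
    hets = np.arange(rare % 2, rare + 1, 2)
    logp = np.zeros(len(hets))
    for i in range(1, len(hets)):
        h = hets[i]
        # p(h) / p(h-2) = (n_rare_hom(h-2) * n_common_hom(h-2) * 4) / (h * (h-1))
        prev_rare_hom = (rare - hets[i - 1]) // 2
        prev_common_hom = n - hets[i - 1] - prev_rare_hom
        logp[i] = logp[i - 1] + np.log(4.0 * prev_rare_hom * prev_common_hom) - np.log(
            hets[i] * (hets[i] - 1.0)
        )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = prob[np.nonzero(hets == n_ab)[0][0]]
    return float(prob[prob <= obs * (1 + 1e-12)].sum())


def _marker_stats(cohort: list[Pedigree], thresholds: QCThresholds):
    n_markers = next(iter(cohort[0].members.values())).genotypes.shape[0]
    all_geno = np.concatenate(
        [ind.genotypes[None] for ped in cohort for ind in ped.members.values()]
    )  # (n_indiv, n_markers, 2)
    missing_rate = (all_geno[:, :, 0] == 0).mean(axis=0)

    maf = np.empty(n_markers)
    hwe_p = np.empty(n_markers)
    founder_geno = np.concatenate(
        [ind.genotypes[None] for ped in cohort for ind in ped.founders]
    )
    for m in range(n_markers):
        maf[m] = compute_maf(cohort, m)
        g = founder_geno[:, m, :]
        g = g[g[:, 0] != 0]
        if g.size == 0 or np.isnan(maf[m]) or maf[m] == 0.0:
            hwe_p[m] = 1.0
            continue
        codes = np.unique(g)
        if len(codes) > 2:
            # multi-allelic: collapse to minor vs rest for the exact test
            counts_per = {c: int((g == c).sum()) for c in codes}
            minor = min(counts_per, key=lambda c: (counts_per[c], c))
            is_minor = g == minor
            n_ab = int((is_minor.sum(axis=1) == 1).sum())
            n_aa = int((is_minor.sum(axis=1) == 2).sum())
            n_bb = len(g) - n_aa - n_ab
        else:
            a = codes[0]
            n_minor = (g == a).sum(axis=1)
            n_aa = int((n_minor == 2).sum())
            n_ab = int((n_minor == 1).sum())
            n_bb = int((n_minor == 0).sum())
        hwe_p[m] = hwe_exact_test({"AA": n_aa, "Aa": n_ab, "aa": n_bb})

    # cohort-total inconsistency count per marker; the exclusion budget
    # (mendel_max) is compared against this total
    mendel = np.zeros(n_markers, dtype=int)
    for ped in cohort:
        mendel += mendelian_check(ped)
    return maf, missing_rate, hwe_p, mendel


def apply_filters(
    cohort: list[Pedigree],
    marker_map: MarkerMap,
    thresholds: QCThresholds | None = None,
) -> tuple[MarkerMap, QCReport]:
    """Apply MAF / missingness / HWE / Mendelian filters to the marker panel.

    Rules compose order-independently: each marker is tested against every
    rule and excluded when any fails.  Raises :class:`QCError` if no marker
    survives.
    """
    thresholds = thresholds or QCThresholds()
    maf, missing_rate, hwe_p, mendel = _marker_stats(cohort, thresholds)
    excluded_by: list[frozenset[str]] = []
    keep = np.ones(len(marker_map), dtype=bool)
    for m in range(len(marker_map)):
        reasons = set()
        if np.isnan(maf[m]) or maf[m] < thresholds.maf_min:
            reasons.add("MAF")
        if missing_rate[m] > thresholds.missing_max:
            reasons.add("MISSING")
        if hwe_p[m] < thresholds.hwe_alpha:
            reasons.add("HWE")
        if mendel[m] > thresholds.mendel_max:
            reasons.add("MENDEL")
        excluded_by.append(frozenset(reasons))
        keep[m] = not reasons
    report = QCReport(
        marker_ids=list(marker_map.marker_ids),
        maf=maf,
        missing_rate=missing_rate,
        hwe_p=hwe_p,
        mendel_errors=mendel,
        excluded_by=excluded_by,
        kept_indices=np.nonzero(keep)[0],
    )
    if not keep.any():
        raise QCError("no marker survives QC")
    return marker_map.subset(keep), report
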