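"""Transmission disequilibrium test on trios from stratified cohorts.

Counts transmissions (b) versus non-transmissions (c) of a target allele
from heterozygous parents to affected children and tests b = c with the
McNemar chi-square (b - c)^2 / (b + c) on 1 df.  Robust to population
stratification because every comparison is within-family.

By default one affected child per family is used (the proband: the first
retained affected in sorted id order) to avoid sibling non-independence;
``all_affecteds=True`` scores every retained affected, with a warning.
Trios missing either parent's genotype are dropped — no single-parent
reconstruction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .pedio import Pedigree
from .stratify import StratifiedCohort


class TDTError(ValueError):
    pass


@dataclass
class TransmissionCounts:
    marker_id: str
    target_allele: int
    b: int  # transmissions of the target allele from het parents
    c: int  # non-transmissions
    n_trios: int
    n_skipped: int


def _resolve_transmissions(child, father, mother) -> tuple[tuple[int, int], tuple[int, int]] | None:
    """Ordered (father_transmitted, mother_transmitted) allele pair.

    Returns None for incompatible trios.  When both phase assignments are
    possible the transmission multiset from heterozygous parents is the
    same either way, so the first consistent assignment is returned.
    """
    c0, c1 = int(child[0]), int(child[1])
    fa = {int(father[0]), int(father[1])}
    mo = {int(mother[0]), int(mother[1])}
    for tf, tm in ((c0, c1), (c1, c0)):
        if tf in fa and tm in mo:
            return tf, tm
    return None


def count_transmissions(
    cohort: list[Pedigree],
    stratified: StratifiedCohort,
    marker: int,
    marker_id: str,
    target_allele: int,
    all_affecteds: bool = False,
) -> TransmissionCounts:
    """Tally b/c for one marker over the cohort's fully genotyped trios.

    Each heterozygous parent of a scored affected child contributes exactly
    one transmission or non-transmission of ``target_allele``; homozygous
    parents are uninformative.  Mendelian-inconsistent trios are skipped
    and counted in ``n_skipped``.
    """
    if all_affecteds:
        warnings.warn(
            "scoring all affected children per family; sibling transmissions "
            "are not independent",
            stacklevel=2,
        )
    index = {p.family_id: p for p in cohort}
    b = c = trios = skipped = 0
    for fid in sorted(stratified.families):
        ped = index[fid]
        children = sorted(stratified.families[fid])
        if not all_affecteds:
            children = children[:1]  # the proband
        for cid in children:
            child = ped.members[cid]
            if child.is_founder:
                continue
            fa = ped.members[child.father_id].genotypes[marker]
            mo = ped.members[child.mother_id].genotypes[marker]
            cg = child.genotypes[marker]
            if cg[0] == 0 or fa[0] == 0 or mo[0] == 0:
                skipped += 1
                continue
            resolved = _resolve_transmissions(cg, fa, mo)
            if resolved is None:
                skipped += 1
                continue
            tf, tm = resolved
            trios += 1
            for transmitted, parent in ((tf, fa), (tm, mo)):
                if parent[0] == parent[1]:
                    continue  # homozygous parent: uninformative
                if transmitted == target_allele:
                    b += 1
                elif target_allele in (int(parent[0]), int(parent[1])):
                    c += 1
    return TransmissionCounts(marker_id, target_allele, b, c, trios, skipped)


def tdt_statistic(counts: TransmissionCounts) -> tuple[float, float]:
    """McNemar chi-square and p for one marker's transmission counts."""
    b, c = counts.b, counts.c
    if b + c == 0:
        raise TDTError(f"{counts.marker_id}: no informative transmissions")
    stat = (b - c) ** 2 / (b + c)
    return float(stat), float(chi2.sf(stat, df=1))


def tdt_scan(
    cohort: list[Pedigree],
    stratified: StratifiedCohort,
    marker_ids: list[str],
    marker_index: dict[str, int],
    target_allele: int = 2,
    all_affecteds: bool = False,
) -> pd.DataFrame:
    """TDT over a set of markers; rows without informative trios are kept
    with NaN statistics."""
    rows = []
    for mid in marker_ids:
        counts = count_transmissions(
            cohort,
            stratified,
            marker_index[mid],
            mid,
            target_allele,
            all_affecteds=all_affecteds,
        )
        if counts.b + counts.c == 0:
            stat, p = np.nan, np.nan
        else:
            stat, p = tdt_statistic(counts)
        rows.append(
            {
                "marker_id": mid,
                "cohort": stratified.label,
                "b": counts.b,
                "c": counts.c,
                "chi2": stat,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
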