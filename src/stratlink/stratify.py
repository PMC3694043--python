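"""Multi-level stratification of multiplex families by sub-phenotype.

Three nested levels reduce cohort heterogeneity step by step:

* **G level** — a family joins subgroup ``Gk`` when at least one affected
  member carries sub-phenotype cluster label ``gk``; every affected sibling
  stays in, whatever their own label.
* **Gs level** — within a ``Gk`` family only the affected siblings whose own
  label is ``gk`` are retained; families left with fewer than two retained
  affecteds are no longer multiplex and drop out.
* **Gender level** — ``Gks`` families split into male-only (``GkM``) and
  female-containing (``GkFc``) pedigrees, judged on the retained concordant
  affecteds only.

Cohorts come in two stages: ``n1`` counts only strictly diagnosed affecteds;
``n2`` additionally counts broad-spectrum affecteds, which can promote
families into (or enlarge them within) every label.  Affected individuals
removed by a filter are treated downstream as phenotype-unknown, never as
unaffected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .pedio import SEX_FEMALE, SEX_UNKNOWN, Pedigree, SubtypeTable

SUBGROUP_INDICES = (1, 2, 3, 4)


@dataclass(frozen=True)
class StratifiedCohort:
    """A named family subset with the retained affected individuals.

    ``families`` maps family_id to the frozenset of retained affected
    individual ids (the scoring set for linkage).  ``provenance`` records
    the filter steps applied, in order.
    """

    label: str
    stage: str  # "n1" | "n2"
    families: dict[str, frozenset[str]]
    provenance: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n_families(self) -> int:
        return len(self.families)

    def manifest(self) -> pd.DataFrame:
        rows = [
            {
                "label": self.label,
                "family_id": fid,
                "retained": ",".join(sorted(ids)),
                "provenance": ";".join(self.provenance),
            }
            for fid, ids in sorted(self.families.items())
        ]
        return pd.DataFrame(rows, columns=["label", "family_id", "retained", "provenance"])


def _stage_affected(ped: Pedigree, subtypes: SubtypeTable, stage: str) -> list[str]:
    """Affected individuals countable at a stage (n1 = strict dx only)."""
    out = []
    for iid in ped.affected_ids:
        if stage == "n2" or subtypes.dx_of(ped.family_id, iid) == "strict":
            out.append(iid)
    return out


def build_all_cohort(
    cohort: list[Pedigree], subtypes: SubtypeTable, stage: str = "n1"
) -> StratifiedCohort:
    """The undivided multiplex cohort (label ALL): every family with >=2
    stage-countable affecteds, all of them retained."""
    families = {}
    for ped in cohort:
        aff = _stage_affected(ped, subtypes, stage)
        if len(aff) >= 2:
            families[ped.family_id] = frozenset(aff)
    return StratifiedCohort("ALL", stage, families, (f"multiplex@{stage}",))


def assign_G_level(
    cohort: list[Pedigree], subtypes: SubtypeTable, k: int, stage: str = "n1"
) -> StratifiedCohort:
    """Proband-subtype grouping: families with >=1 affected of subtype gk.

    All stage-countable affected siblings are retained regardless of their
    own subtype, so one family may belong to several G-level subgroups.
    """
    target = f"g{k}"
    families = {}
    for ped in cohort:
        aff = _stage_affected(ped, subtypes, stage)
        if len(aff) < 2:
            continue
        if any(subtypes.subtype_of(ped.family_id, iid) == target for iid in aff):
            families[ped.family_id] = frozenset(aff)
    return StratifiedCohort(
        f"G{k}", stage, families, (f"multiplex@{stage}", f"proband:{target}")
    )


def assign_Gs_level(
    cohort: list[Pedigree],
    subtypes: SubtypeTable,
    k: int,
    stage: str = "n1",
    g_cohort: StratifiedCohort | None = None,
) -> StratifiedCohort:
    """Concordant-sibling grouping: keep only gk-labelled affecteds.

    Discordant (or unlabelled) affected siblings are removed from scoring
    and recoded as phenotype-unknown downstream; families left with fewer
    than two concordant affecteds drop out entirely.
    """
    if g_cohort is None:
        g_cohort = assign_G_level(cohort, subtypes, k, stage)
    target = f"g{k}"
    families = {}
    for fid, retained in g_cohort.families.items():
        concordant = frozenset(
            iid for iid in retained if subtypes.subtype_of(fid, iid) == target
        )
        if len(concordant) >= 2:
            families[fid] = concordant
    return StratifiedCohort(
        f"G{k}s",
        stage,
        families,
        g_cohort.provenance + (f"concordant:{target}",),
    )


def split_gender(
    gs_cohort: StratifiedCohort, cohort: list[Pedigree]
) -> tuple[StratifiedCohort, StratifiedCohort]:
    """Split a Gs-level cohort into male-only (GM) and female-containing (GFc).

    A family goes to GFc iff at least one retained concordant affected is
    female; families with a retained affected of unknown sex are excluded
    from both halves with a warning.
    """
    index = {p.family_id: p for p in cohort}
    gm, gfc = {}, {}
    for fid, retained in gs_cohort.families.items():
        sexes = {index[fid].members[iid].sex for iid in retained}
        if SEX_UNKNOWN in sexes:
            warnings.warn(
                f"{gs_cohort.label}: family {fid} has a retained affected of "
                "unknown sex; excluded from gender split",
                stacklevel=2,
            )
            continue
        (gfc if SEX_FEMALE in sexes else gm)[fid] = retained
    base = gs_cohort.label.rstrip("s")
    return (
        StratifiedCohort(
            f"{base}M", gs_cohort.stage, gm, gs_cohort.provenance + ("gender:male-only",)
        ),
        StratifiedCohort(
            f"{base}Fc",
            gs_cohort.stage,
            gfc,
            gs_cohort.provenance + ("gender:female-containing",),
        ),
    )


def merge_subgroups(a: StratifiedCohort, b: StratifiedCohort) -> StratifiedCohort:
    """Strict set union of two subgroups (for shared-locus follow-up).

    A family present in both contributes once, with the union of its
    retained affecteds.  Merging a cohort with itself is the identity.
    """
    if a.label == b.label:
        return a
    if a.stage != b.stage:
        raise ValueError("cannot merge cohorts from different stages")
    families = dict(a.families)
    for fid, ids in b.families.items():
        families[fid] = families.get(fid, frozenset()) | ids
    return StratifiedCohort(
        f"{a.label}&{b.label}",
        a.stage,
        families,
        (f"merge({a.label},{b.label})",) + a.provenance + b.provenance,
    )


def expand_cohort(
    n1_cohort: StratifiedCohort, cohort: list[Pedigree], subtypes: SubtypeTable
) -> StratifiedCohort:
    """Rebuild an n1 cohort at stage n2 (broad-spectrum affecteds added).

    Family sets grow monotonically for ALL, G, Gs and Fc labels.  Male-only
    labels are the one exception: a family gains GFc membership (and leaves
    GM) when the added broad-spectrum affected is female, so GM(n1) is
    contained in GM(n2) union GFc(n2) rather than in GM(n2) alone.
    """
    if n1_cohort.stage != "n1":
        raise ValueError("expand_cohort expects an n1-stage cohort")
    return _build_label(n1_cohort.label, cohort, subtypes, "n2")


def _build_label(
    label: str, cohort: list[Pedigree], subtypes: SubtypeTable, stage: str
) -> StratifiedCohort:
    if "&" in label:
        left, right = label.split("&", 1)
        return merge_subgroups(
            _build_label(left, cohort, subtypes, stage),
            _build_label(right, cohort, subtypes, stage),
        )
    if label == "ALL":
        return build_all_cohort(cohort, subtypes, stage)
    if not label.startswith("G"):
        raise ValueError(f"unknown cohort label {label!r}")
    k = int(label[1])
    suffix = label[2:]
    if suffix == "":
        return assign_G_level(cohort, subtypes, k, stage)
    if suffix == "s":
        return assign_Gs_level(cohort, subtypes, k, stage)
    if suffix in ("M", "Fc"):
        gs = assign_Gs_level(cohort, subtypes, k, stage)
        gm, gfc = split_gender(gs, cohort)
        return gm if suffix == "M" else gfc
    raise ValueError(f"unknown cohort label {label!r}")


def build_catalogue(
    cohort: list[Pedigree], subtypes: SubtypeTable, stage: str = "n1"
) -> dict[str, StratifiedCohort]:
    """The full stratification catalogue: ALL plus the 16 subgroups
    {G1..G4} x {-, s, M, Fc}, deterministically ordered."""
    out: dict[str, StratifiedCohort] = {"ALL": build_all_cohort(cohort, subtypes, stage)}
    for k in SUBGROUP_INDICES:
        g = assign_G_level(cohort, subtypes, k, stage)
        gs = assign_Gs_level(cohort, subtypes, k, stage, g_cohort=g)
        gm, gfc = split_gender(gs, cohort)
        out[g.label] = g
        out[gs.label] = gs
        out[gm.label] = gm
        out[gfc.label] = gfc
    return out
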