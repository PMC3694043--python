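"""Shared fixtures: hand-built pedigrees and a small simulated cohort."""

import numpy as np
import pytest

import stratlink as sl


def make_individual(fam, iid, father, mother, sex, affection, genotypes):
    return sl.Individual(
        fam, iid, father, mother, sex, affection,
        np.asarray(genotypes, dtype=np.int16),
    )


def make_nuclear(fam, parent_genos, child_specs):
    """Build a nuclear family.

    ``parent_genos`` is (father_genotypes, mother_genotypes); ``child_specs``
    is a list of (iid, sex, affection, genotypes).
    """
    fg, mg = parent_genos
    members = {
        "FA": make_individual(fam, "FA", "0", "0", "male", "unaffected", fg),
        "MO": make_individual(fam, "MO", "0", "0", "female", "unaffected", mg),
    }
    for iid, sex, aff, g in child_specs:
        members[iid] = make_individual(fam, iid, "FA", "MO", sex, aff, g)
    ped = sl.Pedigree(fam, members)
    ped.validate()
    return ped


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-family simulated cohort with no linked locus (null labels)."""
    scenario = sl.SimulationScenario(
        n_families=40,
        n_chromosomes=2,
        markers_per_chrom=20,
        spacing_cm=4.0,
        maf_range=(0.2, 0.5),
        subtype_probs=(0.4, 0.2, 0.2, 0.2),
        concordance=0.5,
        broad_fraction=0.15,
        sibship_size_dist={2: 0.7, 3: 0.3},
        seed=42,
    )
    return sl.simulate_cohort(scenario)
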