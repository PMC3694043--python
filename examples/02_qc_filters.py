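"""Marker QC on a noisy cohort: MAF, missingness, exact HWE, Mendel budget.

Simulates a cohort with 3% missing genotypes and planted genotyping errors,
applies the standard filter set, and prints the exclusion tally.
"""


import stratlink as sl

scenario = sl.SimulationScenario(
    n_families=50,
    n_chromosomes=1,
    markers_per_chrom=60,
    spacing_cm=2.0,
    maf_range=(0.02, 0.5),  # include some rare markers for the MAF rule
    missing_rate=0.03,
    mendel_error_rate=0.002,
    seed=21,
)
pedigrees, marker_map, _, truth = sl.simulate_cohort(scenario)

thresholds = sl.QCThresholds(maf_min=0.05, missing_max=0.10, hwe_alpha=0.001,
                             mendel_max=1)
kept_map, report = sl.apply_filters(pedigrees, marker_map, thresholds)
pedigrees = sl.subset_genotypes(pedigrees, report.kept_indices)

frame = report.to_frame()
n_excluded = (frame["excluded_by"] != "").sum()
print(f"markers in: {len(marker_map)}   surviving: {len(kept_map)}   "
      f"excluded: {n_excluded}")
for reason in ("MAF", "MISSING", "HWE", "MENDEL"):
    n = frame["excluded_by"].str.contains(reason).sum()
    print(f"  excluded by {reason}: {n}")
print(f"planted Mendelian errors: {len(truth['noise']['mendel_errors'])} "
      f"(markers over the <={thresholds.mendel_max} budget are dropped)")
# Frequencies and HWE come from founders only, so sibship relatedness cannot
# masquerade as disequilibrium.
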