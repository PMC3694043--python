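"""Stratified multipoint linkage scan: the undivided cohort versus the
concordant subgroup that privately carries the risk locus.

Simulates the subtype-private-locus benchmark (locus at chr2:50 cM,
sibling relative risk 2.0, carried only by g1-concordant families), scans
ALL and G1s, and prints the peak table.
"""

import stratlink as sl
from stratlink.synthetic_data import subtype_private_locus_scenario

pedigrees, marker_map, subtypes, _ = sl.simulate_cohort(
    subtype_private_locus_scenario(seed=1002)
)
catalogue = sl.build_catalogue(pedigrees, subtypes, stage="n2")
engine = sl.MultipointEngine(pedigrees, marker_map)

curves = [engine.scan(catalogue[label]) for label in ("ALL", "G1s")]
for curve in curves:
    chrom, pos = curve.argmax
    print(f"{curve.label:5s} ({curve.n_families:3d} families): "
          f"max LOD {curve.max_lod:.2f} at chr{chrom}:{pos:.0f} cM "
          f"(pointwise p {sl.lod_to_pvalue(curve.max_lod):.2g})")

print("\ntop peaks per cohort:")
print(sl.peak_table(curves, top_k=2).to_string(index=False))
# The concordant subgroup sharpens the signal at the simulated locus even
# though it scans fewer families than the undivided cohort — heterogeneity,
# not sample size, was the limiting factor.
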