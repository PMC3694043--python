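# Methods

This note documents the models, algorithms, parameter choices and
limitations behind `stratlink`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model and file formats

Pedigrees are nuclear or small multi-generation families without loops.
An individual either has both parents in the family file or neither;
half-known parent pairs are rejected, which keeps founder identification
trivial and matches the sib-pair structure of multiplex collections.
Genotypes are unordered pairs of small integer allele codes (0 = missing;
half-missing calls rejected). The PED dialect is the de-facto six-column
standard; the marker map carries sex-averaged genetic positions in cM on a
single shared map (no sex-specific maps). Duplicate map positions are
jittered forward by 1e-6 cM in stable marker-id order because the
multipoint HMM needs strictly positive inter-marker distances. Only
autosomes (1–22) are modelled; X-linked inheritance needs a different
hidden-state space and is out of scope.

Sub-phenotype assignments (cluster labels g1–g4 plus a strict/broad
diagnosis class) are an *input*, produced upstream by clustering of
diagnostic-instrument severity scores; this package consumes them and never
re-derives them. Affected individuals absent from the table count as
unlabelled ("none") and strict-diagnosis.

## Marker quality control

Four marker-level rules, composable in any order: minor allele frequency
below `maf_min` (default 0.05), missing-call rate above `missing_max`
(default 0.10), exact Hardy–Weinberg test below `hwe_alpha` (default 0.001,
the conventional array-QC value; the test is the exact conditional
enumeration over heterozygote counts), and cohort-total Mendelian
inconsistencies above `mendel_max` (default 1). Allele frequencies and HWE
use founder genotypes only, so sibship relatedness cannot inflate either —
standard practice for family data. Individual-level QC (heterozygosity,
sex checks) is out of scope.

## Multipoint inheritance-vector HMM

The hidden state at a map position is the inheritance vector: one bit per
meiosis of every non-founder (two bits per child), bit 0 meaning the parent
transmitted its own paternal allele. For a family with m meioses the state
space has 2^m vectors; the per-family budget is 16 bits (configurable),
and larger families are skipped with a warning rather than approximated.
No founder-couple symmetry reduction is applied — the plain state space is
comfortably small for the nuclear sibships this package targets, and the
unreduced representation keeps scoring functions and the enumeration oracle
one-to-one with meioses.

*Emission.* P(genotypes | vector) sums over all assignments of allele codes
to the 2F founder-allele slots, weighting by population frequencies; each
individual's genotype must match the unordered pair of founder alleles its
labels select. Missing genotypes impose no constraint (summed over, no
imputation). This direct founder-allele peeling is exact and, for SNPs in
nuclear families, costs 16 assignments per marker. A marker whose emission
vanishes for every vector (an unresolved Mendelian inconsistency) raises an
error naming the family and marker.

*Transition.* Between adjacent positions each meiosis bit flips
independently with the Haldane recombination fraction
θ(d) = (1 − e^(−2d/100))/2 — no interference, the standard choice for
SNP-panel multipoint work. The transition operator is applied one bit-axis
at a time (tensor mixing), so a step costs m·2^m operations instead of 4^m.

*Posterior.* Scaled forward–backward per chromosome conditions on all
markers of that chromosome (chromosomes are independent). Founder
haplotypes are assumed to be in linkage equilibrium, so emissions are
independent across markers given the vector path; dense panels violating
this should be thinned upstream. Founder allele frequencies default to
founder counts pooled over the cohort (most parents are genotyped in the
collections this emulates, which keeps ancestry-specific frequencies from
biasing sharing); external frequencies can be supplied.

Evaluation positions default to the marker grid; a uniform cM grid can be
added, with grid points carrying uniform emissions.

## Allele-sharing score and LOD

The default per-family score is S_pairs: expected alleles shared
identical-by-descent summed over all pairs of *retained* affecteds (the
stratification step decides who is retained; removed affecteds are treated
as phenotype-unknown, never as unaffected). The Whittemore–Halpern S_all
score is available as an option. Null mean and SD are exact moments of the
scoring function under the uniform vector distribution, so
Z = (E[S | data] − μ₀)/σ₀ is the usual "perfect-data-standardized" score:
under incomplete marker information its variance is below 1, making the
downstream LOD conservative rather than inflated. Families whose scoring
function is constant (σ₀ = 0, e.g. a lone scored affected) are excluded as
uninformative.

Family scores combine through the one-parameter linear likelihood-ratio
model: LOD(x) = max over δ ∈ [0, δ_max] of Σ_i log₁₀(1 + δ Z_i(x)). The
objective is concave, so a vectorized golden-section search (80 iterations,
interval error ≪ 1e-6) finds the global maximum per position; a dense-grid
oracle in the test suite confirms agreement to 1e-4. δ_max enforces
positivity of every factor — just inside 1/|min Z_i| when some family
scores negatively — with an absolute cap of 2.0 when none does. The model
is one-sided (δ ≥ 0), so the LOD is truncated at zero, and its pointwise
significance is the normal tail p = 1 − Φ(√(2 ln10 · LOD)); LOD 0 maps to
p = 0.5. The test suite verifies this conversion against 32 published
LOD/p table pairs at their printed precision.

## Stratification semantics

"Multiplex" means at least two affected individuals relevant to the label's
rule. G-level membership requires one affected with the group's subtype and
retains *all* affecteds (so one family can join several G groups); Gs-level
retains only concordant affecteds and drops no-longer-multiplex families;
the gender split assigns a family to GFc iff any retained affected is
female, judged on retained affecteds only. Merging subgroups is strict set
union (family-wise, with unions of retained sets). Stage n1 counts only
strict-diagnosis affecteds; stage n2 adds broad-spectrum ones. Family sets
grow monotonically from n1 to n2 for ALL, G, Gs and Fc labels; GM is the
exception — a family leaves GM for GFc when its added broad-spectrum
affected is female — so the invariant is GM(n1) ⊆ GM(n2) ∪ GFc(n2).

## Study-wide permutation

The null replicate permutes family-level label vectors (each family's
ordered subtype/dx labels for its affecteds) as units among families with
the same number of affecteds, preserving the multiset of vectors, every
pedigree and all genotypes — the minimal randomization that destroys the
label–genotype association while keeping subgroup sizes realistic. Each
replicate rebuilds the full 16-subgroup catalogue and rescans it (the
engine caches family posteriors and score curves, so replicates cost only
the combination step). The max statistic is taken over the 16
label-dependent subgroups and *excludes* ALL: the undivided cohort's curve
is invariant under label permutation, and including it would pin the
observed and replicate maxima to the same value whenever ALL dominates,
voiding calibration. The empirical p is (r + 1)/(N + 1) by default (raw
r/N available for compatibility with older conventions); N = 100 bounds
resolution at ~0.01 and is the default, with every replicate seed recorded
for exact rerun. Calibration is verified by a 100 × (N = 100) uniformity
study in the acceptance suite. One consequence worth knowing: when most
families carry the locus, label permutation leaves much of the signal in
place and the study-wide p is honestly large — the statistic measures
label association, not raw linkage.

## TDT

One affected child per family (the proband, first retained affected in
sorted id order) avoids sibling non-independence; scoring all affecteds is
available behind a warning. Trios missing either parent's genotype are
dropped (no single-parent reconstruction). With both parents typed the
transmission multiset from heterozygous parents is phase-invariant, so
counting is deterministic; Mendelian-inconsistent trios are skipped and
counted. The statistic is (b − c)²/(b + c) against χ²(1); swapping the
target allele exchanges b and c and leaves it unchanged.

## Synthetic cohorts

The generator emulates the *structure* the pipeline assumes, not a
population: nuclear families ascertained as fully affected sibships,
founder haplotypes drawn at the map's allele frequencies in linkage
equilibrium, offspring by gene-dropping with Haldane recombination.
Defaults describe the motivating study scale: 392 families, sibships
{2: 0.8, 3: 0.2}, 22 chromosomes × 200 markers at 1 cM with MAF ~
U(0.1, 0.5), subtype mix (0.45, 0.10, 0.25, 0.20) with the severe
language-impaired cluster most prevalent, intra-family concordance 0.3
(roughly the observed survival of concordant-sib families), broad-spectrum
fraction 0.12, female affected probability 0.2, no noise.

A risk locus is parameterized by the sibling relative risk λs through the
no-dominance single-locus identity z = (1/(4λs), 1/2, 1/2 − 1/(4λs)).
In a family whose proband pair is concordant for the locus's target
subtype, each non-proband sib draws its IBD state with the proband from
that triple ("star conditioning"), so proband pairs realize the triple
exactly and other pairs inherit induced excess sharing (P(share) = 0.53 per
chromosome copy at λs = 2 versus the exact 0.625 for proband pairs — a
mild understatement of multi-sib information). Meiosis indicators extend
from the locus outward by Haldane recombination, so sharing decays with
distance exactly as the multipoint model expects. Affection status is not
modelled through penetrances; families are multiplex by construction,
which matches how such collections are ascertained but means the generator
cannot produce unaffected genotyped siblings or singleton families.

Noise injection masks calls at a given rate and plants genotyping errors as
single-allele flips verified to create a trio inconsistency (flips at
het × het parent markers can never conflict and are re-drawn elsewhere, so
the realized error rate can fall slightly short of nominal; all injected
positions are recorded).

Two canonical study conditions ship with the package. The
*subtype-private-locus* benchmark (100 families, λs = 2.0 locus at
chr2:50 cM private to g1-concordant families, two 100 cM chromosomes at
2 cM spacing, MAF U(0.3, 0.5)) uses a cohort enriched for the target
subtype (90% g1 probands, concordance 0.95, ≈85 concordant families): a
power analysis puts the combined score needed for reliable genome-wide
localization at μ_Z ≈ 3.4, which at the per-pair increment of a λs = 2.0
locus (E[Z] ≈ 0.37 per sib pair) requires the concordant subgroup near
full cohort strength, while the undivided cohort remains diluted by
discordant families so the subgroup-versus-ALL contrast stays informative.
The *null calibration* condition (30 families, no locus, default-like
subtype mix, two 50 cM chromosomes) is sized so that a full
100-permutation study repeats 100 times within a test-suite budget.

## Numerical and degenerate-input choices

Emission uses exact summation (no log-space; per-marker products of ≤1
magnitudes over ≤16 assignments), with forward scaling for the chain.
Zero-likelihood markers raise; empty subgroups contribute max LOD 0 to
permutation replicates; monomorphic markers get HWE p = 1 and MAF 0; MAF
ties at 0.5 return 0.5. Peak calling reports local maxima, suppressing a
candidate within 30 cM of a stronger accepted peak unless the curve dips
by ≥1 LOD between them (one peak per region, configurable). Heat-map rows
are ordered genomically — a reproducible default in place of any supervised
ordering.

## Known limitations

Exact inheritance vectors limit family size (16-bit default budget); no
X chromosome; no LD modelling between markers; no population structure or
ethnicity in the generator; the TDT offers no single-parent or haplotype
variants; observed LODs from the restricted source cohorts are not
reproducible here and are represented instead by the printed-value LOD→p
checks and the simulation benchmarks above.
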