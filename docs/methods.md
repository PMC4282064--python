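# Methods

This note documents the models, estimators, and design choices behind
`weaverkin`, the assumptions they make, and what the validation suite does
and does not demonstrate.

## Relatedness estimation

Pairwise relatedness uses the Queller–Goodnight moment estimator for
codominant markers in **ratio-of-sums** form: per-locus numerator and
denominator contributions are accumulated over all mutually typed loci and
over both dyad directions (each individual once as focal) before the single
final division. The alternative — averaging per-locus ratios — is unstable
with a modest marker panel because individual locus denominators can be
arbitrarily small; pooling first is the convention of the kinship software
used in colonial-bird field studies and is what we validate against.

Reference allele frequencies are simple allele counts over **the whole
genotyped population, all colonies pooled, including the focal dyad**.
This matches the biology the package targets: juvenile and adult dispersal
mix alleles across colonies, and single colonies (7–128 birds) are far too
small to act as their own reference. No leave-two-out bias correction is
applied; with hundreds of reference individuals its effect is far below the
estimator's sampling noise. Missing calls are skipped per dyad — no
imputation. Two degeneracies return NaN with a warning rather than a
number: a dyad with no mutually typed locus, and a pooled denominator of
zero (possible when a heterozygote's two alleles carry all the frequency
mass at every shared locus).

Properties the test suite enforces: exact (1e-12) agreement with an
independently coded brute-force implementation on random fixtures; exact
exchange symmetry; self-relatedness 1; and calibration against gene-dropped
pedigree truth — with 17 loci of ~9.5 alleles, class means over 500 dyads
land within 0.02 of 0.5 (parent–offspring, full sib), 0.25 (half sib) and
0 (unrelated). The estimator's per-dyad noise at that panel size is
substantial (SD ≈ 0.1–0.15), which is why every downstream analysis treats
relatedness dyadically and statistically rather than classifying dyads.

Marker QC follows standard practice: observed heterozygosity over typed
individuals; unbiased expected heterozygosity `2n/(2n−1)·(1−Σp²)`;
Hardy–Weinberg by Monte Carlo shuffling of the 2n alleles among individuals
(robust at small colony-study sample sizes where the chi-square
approximation is not, default 10,000 reps); null-allele frequency by the
Chakraborty moment `(He−Ho)/(He+Ho)`; linkage disequilibrium by a G-statistic
permutation test on the two-locus genotype table (margins are permutation-
invariant, so the expected table is computed once), flagged by
Benjamini–Hochberg step-up.

## Association networks

An edge joins two birds that entered at least one common nest chamber within
the same observation series, whatever the activity — the gambit of the group
applied to chamber co-use. The default edge weight is the **number of
distinct shared chambers**, the most literal reading of "used the same nest
chambers"; co-entry counts and the simple-ratio index are available as
dialects (`dialect=` in `build_network`) because the right accrual rule is
genuinely underdetermined, and dyadic results should be — and in our planted
simulations are — robust to the choice. Isolated observed birds stay in the
network; immigrants observed at a colony belong to its network; edges never
cross colonies.

Centrality is normalised to compare colonies of different sizes: degree
`k = strength / ((n−1)·w_max)` and betweenness divided by `(n−1)(n−2)/2`,
with shortest paths measured on edge length `1/weight` (strong association
= short distance). Both are invariant to uniform weight rescaling, and `B`
is defined as 0 for networks too small to have intermediaries (n < 3).

Community detection is the Girvan–Newman procedure with **weighted** edge
betweenness, recomputed after every removal; a partition is recorded
whenever the component count grows, weighted modularity
`Q = Σ_c (e_cc − a_c²)` is evaluated on every recorded partition, and the
argmax is selected with ties resolved toward fewer communities. The initial
partition (connected components; the trivial single community for a
connected graph, Q = 0) is always recorded, so a selected split can only
have Q < 0 if the graph is disconnected from the start. Field software has
reported negative selected Q values; we keep the full Q profile in the
report so any selection convention can be audited after the fact.

## Permutation inference

All dyadic tests respect the row/column dependence of matrix data by
permuting **node identities**, never cells:

* **QAP** — Pearson R over off-diagonal cells; null from joint row/column
  shuffles of one matrix. Per-colony coefficients are pooled across colonies
  with a one-sample t-test against zero, the second-stage convention for
  multi-group network studies.
* **MRQAP** — OLS on vectorised off-diagonals with Dekker
  double-semi-partialing: each predictor is residualised on the others, the
  residual matrix is permuted, and its coefficient recomputed. Permuting
  only the unique part of each predictor keeps the test for one predictor
  honest when predictors are correlated — exactly the situation of
  relatedness vs spatial proximity.
* **Node-label tests** — the observed statistic is a class mean difference;
  labels are shuffled **within colonies** because the metrics are
  normalised per colony and colony membership is not exchangeable.

Every p-value uses `p = (k+1)/(n_perm+1)`, so p ≥ 1/(n_perm+1) and a
recorded seed reproduces it exactly. Tests are two-tailed unless stated.

The one-sample Wilcoxon signed-rank test is exact for n ≤ 25 retained
differences — the null distribution of the positive-rank sum is built by
convolution over sign assignments, with average ranks doubled to stay on an
integer lattice so ties are handled exactly — and uses a tie-corrected
normal approximation with continuity correction above that. The statistic
reported is V = sum of positive-difference ranks; zero differences are
dropped.

## Spatial kin statistics

A bird's **primary chamber** is its most-visited chamber (ties to the
lexicographically first id). The **nearest quartile** of a focal chamber is
the `ceil(0.25·(C−1))` other chambers closest to it, ties again broken by
id; defined this way the set is deterministic and never empty. **Local
relatedness** is the mean relatedness between a focal bird and the distinct
occupants of its quartile chambers, focal excluded, optionally restricted to
one sex (all headline contrasts use same-sex neighbours).

The **building-location score** of a builder is, for each chamber *u* it
uses, the fraction of its thatch-building events located above *u* or *u*'s
quartile, averaged over used chambers weighted by entry counts. It lies in
[0, 1], is invariant to visit-count rescaling, and falls back (with a
warning) to an unweighted average when a builder has no entry records.

The relatedness–distance decline is tested by an OLS slope of dyadic r on
inter-chamber distance with a Mantel-type null that permutes the
bird-to-chamber assignment within the colony. Contrasts that a field
analysis would fit with colony random effects (builders vs non-builders in
local relatedness; colony vs population relatedness) are run here as
colony-stratified permutation analogues — conditioning on colony by
permuting only within it plays the role of the random intercept, with no
distributional assumptions. Mixed-model coefficients are therefore not
comparable quantities and are not produced. An optional dyad filter
(`outlier_r_min`, default off) masks extreme negative estimates, logging
the count.

### Chance level of the building score

Testing builder scores against the fixed benchmark μ = 0.25 ("a quarter of
the chambers") is exact only when the own-or-quartile area is actually a
quarter of the colony: its true share is `(ceil(0.25(C−1))+1)/C`, ≈ 0.33 in
a 9-chamber colony and still ≈ 0.26 at C = 100. The pipeline therefore
reports two Wilcoxon tests: the fixed-μ = 0.25 version (the headline,
comparable with field convention) and a geometry-corrected version testing
`score − chance(colony)` against zero. Under a uniform-building null the
fixed-μ test rejects by design in small colonies; the corrected test is the
calibrated one, and it is the one the null-calibration suite checks.

### Sampling units for the colony-vs-population contrast

The Wilcoxon for "is within-colony relatedness above the population mean"
uses **per-individual mean within-colony relatedness** as its sampling unit,
the convention of field analyses that report n in individuals. Dyadic
summaries sharing an individual are dependent, so the test is approximate:
at the scales of the calibration suite the all-birds version holds its
nominal size (empirical rejection ≈ 0.055 at α = 0.05), while per-sex
versions become anticonservative when a colony holds only a handful of
same-sex birds (≈ 0.12 at 8 males per colony). Colony means would be the
independent-unit alternative but are markedly conservative (≈ 0.01–0.03)
because the estimator's population-level sum constraint couples colonies
negatively. Treat per-sex p-values near the threshold with care in small
colonies; the planted-effect analyses are unaffected (their effects are far
from threshold).

## The synthetic colony generator

The generator produces datasets with the statistical structure the analysis
assumes, at the scale of a multi-colony field study: 23 colonies with
lognormal sizes (mean 31.7, SD 27.7, clipped to [7, 128]); 17 microsatellite
loci with ~9.5 ± 4.8 alleles (Dirichlet(1) founder frequencies, floor of 2);
per-allele mistyping at 0.007; heavy-tailed chamber-entry counts (lognormal,
mean 6.6, SD 9.5); 64% of birds using several chambers (2.8 ± 2.4);
38.5% of adults building with a 71.8% male share and ~8 events per builder;
self-directed building probability 0.608. Sex ratio is 1:1; age is the
generation index (no age effects are planted, but the column exists so
age-covariate code paths run).

Demography: overlapping generations over 5 cycles; monogamous pairs form
within colonies and persist; offspring disperse at maturity with
sex-specific probabilities (female 0.8, male 0.15 — male philopatry);
colonies are culled back to target size uniformly at random. Pedigree
relatedness (twice the kinship coefficient, tabular method) is carried in
the truth record for recovery scoring.

Four independent dials plant the effects, all male-specific because male
philopatry is the mechanism that generates kin neighbourhoods in this
system, and the female-side null results are part of the pattern to be
recovered:

| dial | meaning | null | default |
|------|---------|------|---------|
| `kin_spatial_clustering` (κ) | males settle near settled male kin (softmax on kin-weighted proximity) | 0 = uniform placement | 8 |
| `kin_association_bias` (λ) | males pick extra chambers preferring kin-occupied ones | 0 = proximity only | 4 |
| `builder_kin_effect` | male builder identity biased toward high local pedigree relatedness | 0 = random builders | 2.5 |
| `self_directed_building_prob` | a building event lands above the own-or-quartile area of the chamber in use | `uniform_building=True` places events uniformly | 0.608 |

κ and λ are phenomenological dials, not mechanistic claims: the real
dependence structure between chamber sharing, spatial proximity, and kinship
is unknown. Their defaults (and the builder effect) were set so that the
planted male-specific pattern is recovered reliably at field scale — that is
the generator's purpose: to provide a world in which the pipeline's power
and calibration can both be measured. Non-self-directed building events are
placed uniformly over chambers *outside* the own-or-quartile area, so the
own-area hit rate equals the dial exactly and the observed 60.8% maps onto
`self_directed_building_prob = 0.608` with no correction.

`null_config()` defines the global null: every dial at zero, building
uniform, and dispersal complete and colony-uniform for both sexes, which
makes colony membership exchangeable with respect to kinship — the exact
null of every downstream test. Under it the calibration suite verifies that
all four headline tests reject at rates inside the binomial 99% CI of
α = 0.05 over 200 replicate datasets.

What the generator does **not** emulate: mated pairs are placed
independently rather than co-resident; there is no multi-year observation
structure (one series per colony); no microsatellite mutation; no
nest-collapse or thermal mechanics; no extra-pair paternity. Passing the
validation suite therefore shows the pipeline recovers kin structure of the
planted form at field-study scale and power — it does not certify behaviour
under real-data pathologies such as systematic genotyping artefacts,
observation bias toward particular chambers, or inter-annual turnover.

## Validation suite sizes and numerical choices

The statistical acceptance checks run at: 200 random fixtures for the
estimator oracle; 500 dyads per class for gene-drop calibration; 100
graphs of ≤ 7 nodes for betweenness enumeration (edge weights are powers of
two so path lengths are exact in floating point and length ties are
genuine); 1000 null simulations × 999 permutations for the size of each
permutation test; 200 replicates for MRQAP recovery and for the global-null
suite (12 colonies of ~16 birds, 3 generations — calibration is
scale-invariant, so the null suite uses small colonies); 50 replicates at
the full 23-colony scale for planted-effect recovery, with permutation
counts reduced (99–199) since recovery checks read observed effect
directions and coarse significance, not fine p-resolution.

Determinism: every stochastic routine takes a seed; the pipeline derives
per-test seeds from one master seed via a generator, so a rerun with the
same config reproduces the report hash. Dataset simulation is byte-stable
given its seed.

Known limitations, beyond those noted above: the Girvan–Newman loop is
O(E²·V) and is the slow path for large, dense colonies (it can be switched
off per run); QAP requires complete matrices, so the pipeline mean-imputes
the rare NaN relatedness dyads within a colony submatrix before testing;
and the fixed-μ quartile Wilcoxon inherits the geometry bias described
above whenever colonies have few chambers.
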