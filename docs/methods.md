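# Methods

This note documents the models and procedures implemented in `dignet`, the
assumptions behind them, the parameters that matter, and the choices made
where the design was genuinely open. No empirical claim here goes beyond
what the test suite and `scripts/acceptance.py` themselves compute.

## 1. Preprocessing

Order of operations: probe collapsing → imputation → per-gene
standardization → per-sample rank replacement.

* **Probe collapsing.** A probe mapping to more than one gene is
  discarded; multiple probes of one gene are averaged (arithmetic mean).
* **Imputation** is k-nearest-neighbour over genes (default k = 10):
  for an incomplete gene, neighbours are the complete genes closest in
  Euclidean distance over the gene's observed samples, and each missing
  cell is filled with the neighbours' mean at that sample. Genes missing
  more than 5 % of samples (configurable) are dropped with a warning.
  KNN was chosen over centroid-based schemes because scattered missing
  cells make per-cluster centroids ill-defined.
* **Standardization** is a per-gene z-score (population SD). Per-gene
  rather than per-sample, because downstream co-expression is computed
  across samples within a gene pair. Zero-variance genes are dropped.
* **Rank replacement** substitutes each sample's values with within-sample
  ranks (average ranks on ties). Tie-free samples then share the exact
  marginal 1..G, which is what removes profile-level batch shifts.
  Ranking last makes the earlier z-score inert for correlation purposes;
  both are kept because the z-score still governs the imputation distances
  and keeps the written artifacts scale-free. Correlations downstream are
  therefore Spearman-like; for the strong module correlations the pipeline
  targets, the rank attenuation (≈ 0.96·r for bivariate normal data at
  r ≈ 0.95) is immaterial against the 0.75 threshold.

Profiles are always processed separately and never concatenated.

## 2. Differential-interaction calling

Co-expression edges require r ≥ r_min (default 0.75, positive tail only;
an `use_abs` flag exists but defaults off) **and** p ≤ 0.05, with the
p-value from the t transform of r at n−2 degrees of freedom. P-values are
deliberately not multiple-testing corrected: the r-threshold is the
operative filter and the p-threshold only guards small-n flukes.

A condition-specific PPIN is the intersection (as unordered pairs) of a
condition's co-expression edges with the global PPIN; isolated genes are
not members. A **DIG** is a gene with degree ≥ 1 in *both* condition
networks whose neighbour sets differ. Genes exclusive to one network are
not DIGs — commonality first; this is the conservative reading, and it
also makes the call symmetric in the condition labels. Profiles aggregate
by union (a comprehensive rather than consensus list).

`clustering_agreement` scores how well a gene set separates the two sample
groups: average-linkage hierarchical clustering of samples (Euclidean),
cut at two clusters, scored by the best of the two cluster↔group
assignments. Note that rewired genes differ between conditions in their
*correlation structure*, not their means, so on synthetic data this score
sits near chance — it is reported, not asserted, there.

## 3. The synergistic regulatory network

miRNA→gene rows must carry `supporting_experiments ≥ 5` and
`pan_cancer ≥ 3` (both inclusive). TF→gene tables merge by deduplicated
union. The network keeps regulatory edges only when the gene target is a
DIG; miRNA and TF nodes are kept regardless, so the regulator layer
(miRNA→TF, TF→miRNA) survives intact. Gene–gene edges are the supplied
co-expressed-and-interacting DIG pairs. A TF whose coding gene is itself a
DIG is one node carrying both roles; self-regulation is excluded.

Degree for the power-law check is total degree (in + out + undirected),
binned at raw integer degrees; the fit is least squares of log10 frequency
on log10 degree, returning slope and R². Networks where all nodes share
one degree raise a degeneracy error rather than fitting a point.

## 4. Motif definitions and mining

* **Triplet** requires the miRNA–TF edge (either direction) closing the
  feed-forward loop. A `require_regulator_edge=False` flag gives the
  looser co-targeting definition for sensitivity analysis.
* **Crosstalk** requires a gene–gene edge, TF→g₁ and miRNA→g₂; both
  orientations of the pair are examined and the role order is recorded.
* **Joint** requires the full four regulator→gene edges over a gene–gene
  pair.
* Crosstalk and joint are **mutually exclusive** by default, joint taking
  precedence on the full pattern (they are two different regulation modes);
  `exclusive=False` restores the overlapping reading, under which every
  joint quadruple also matches the crosstalk pattern — a relation the test
  suite asserts.

All three finders are index-based exact enumerations; a literal
brute-force scan over node triples/quadruples serves as an independent
oracle and is checked for set equality on random typed networks.

Subnets are unions of instance nodes/edges with multiplicity collapsed.
Hubs are ranked by total degree within the subnet, ties broken
lexicographically. Cachets count **distinct** co-regulated genes per
miRNA–TF pair (not instances); the cutoff is ceil(0.01 · n_pairs) with
ties at the cutoff kept.

## 5. Null models and significance

**Motif enrichment.** The null is degree-preserving randomization by
double-edge swaps performed *within* each edge-type class (default 10×
class edge count attempted swaps per class), so typed in-/out-/undirected
degrees are conserved per node and an edge can never change class —
the conservative typed reading of "constant degree distribution".
P = N_high/N_perm with a strict "more", Z = (N_real − N_mean)/SD with
sample SD; SD = 0 degenerates to z = 0 (equal) or signed infinity.
Permutation streams derive from one seed via `SeedSequence.spawn`, so runs
are reproducible and permutations independent.

**Hub tests.** The hypergeometric upper tail P(X ≥ m) is used for the
probability that a regulator with n targets hits m of the M disease genes
in a universe of N. (The textbook "1 − Σ_{i=1}^{m}" form mis-states this
tail; the standard upper tail is what an enrichment p-value means, and the
implementation is checked against brute-force pmf summation for all
populations N ≤ 60.) The randomization test redraws the disease gene set
uniformly from the universe and counts iterations with at least the real
overlap; Benjamini–Hochberg at FDR 0.01 is applied across hubs on the
empirical p-values.

## 6. Survival

Cox proportional hazards is fit by `lifelines.CoxPHFitter` (partial
likelihood, Newton-type steps, precision 1e-7). Continuous synthetic event
times make ties a measure-zero event, where the Efron and Breslow
approximations coincide. Rank-deficient designs trigger a collinearity
warning plus a small ridge penalty (1e-4) rather than a hard failure.

PI is the linear predictor under the fitted β. The median split puts
strictly-above-median samples in the high-risk group, strictly-below in
low-risk, and deals exact-median ties one at a time (low first) to the
smaller group, so group sizes always differ by at most one. The split is
compared by the two-sample log-rank test; ranking quality by Harrell's C
(higher PI should fail earlier; PI ties count ½). β is fit on the same
cohort that is split — the standard single-cohort biomarker evaluation —
so the log-rank p of a *fitted* PI is exploratory, not a calibrated test;
calibration checks in the test suite therefore split on a fixed,
survival-independent coefficient.

## 7. The synthetic-data generator

What it emulates, and deliberately does not:

* **PPIN**: Barabási–Albert preferential attachment (heavy-tailed degrees)
  with deterministic extra wiring — per module, one "stable pair" edge, and
  for every rewired gene, anchor edges into both its control-condition and
  disease-condition modules. It does not emulate protein complexes,
  interaction confidence scores, or database noise.
* **Expression**: module genes load on a shared standard-normal factor,
  x = √w·f + noise_sd·√(1−w)·ε, giving within-module correlation
  w/(w + noise_sd²(1−w)) — at the defaults (w = 0.85, noise_sd = 0.5)
  about 0.96, i.e. strong, clean modules. A rewired gene keeps its
  variance but swaps factors between conditions. There are no mean shifts,
  batch effects beyond what ranking removes, or heavy-tailed noise.
* **Regulatory layers**: planted motifs sit on dedicated gene pools
  (triplets reuse the joint pool with fresh regulator pairs; crosstalk and
  joint pools are disjoint), background edges are uniform at configurable
  densities, and background edges that would upgrade a planted crosstalk
  to a joint are rejected, so every planted instance remains recoverable
  by its own finder. Evidence attributes: planted rows draw uniformly from
  the passing region (5–12 experiments, 3–6 pan-cancer), background rows
  from 1–10 and 0–5, so the evidence filter sees both outcomes.
* **Survival**: exponential event times with rate
  baseline_hazard·exp(PI), baseline 0.02 per month (median ≈ 35 months at
  PI = 0); censoring is independent with per-sample rate λ·p/(1−p), which
  censors each sample with probability exactly p. No time-varying effects
  or competing risks.

The anchor construction is what makes planted recovery clean rather than
tuned: a rewired gene is guaranteed PPI partners in both conditions
(sensitivity), while its anchors have co-expression support in only one
condition and are excluded from DIGs by the commonality rule. Residual
false positives come from stray backbone edges that happen to fall inside
a module, with a per-edge discordance probability set by sampling noise
around the r-threshold — about 5 % of unplanted genes at the default
geometry, proportionally more in very small scenarios (the compact
120-gene configuration used in the fast pipeline test runs nearer 15 %).

Passing tests on this generator demonstrate correctness of the machinery
under its assumptions (linear co-expression, proportional hazards,
uniform background regulation); they do not certify performance on real
microarray or clinical data, where effect sizes, noise and confounding
are less forgiving.

## 8. Problem sizes and numerical choices

Default study conditions: 500 genes, 30 samples/group, 10 modules × 10
genes, 20 rewired genes, 30 miRNAs, 20 TFs, 4 planted motifs per class,
20 % censoring. The demo and acceptance script use 200 permutations for
enrichment and 1000 iterations for hub randomization; the multi-seed
recovery study uses 5 seeds; calibration checks in the test suite use 20
seeds × 200 permutations. These sizes were chosen so every property of
interest (recovery, calibration, power) is measured with comfortable
margins at desk scale.

Other numerical choices: correlations are clipped to [−1, 1] before the t
transform; permutation SD uses ddof = 1; hub target indices and all
sampled collections iterate in sorted order so outputs are byte-identical
across runs; stage seeds derive from the global seed through fixed
`SeedSequence` offsets so stages can be re-run in isolation.

## 9. Known limitations

* Only pairwise Pearson/Spearman co-expression; no partial correlation or
  mutual information.
* DIG calling is binary (neighbour sets equal or not); no effect size on
  the amount of rewiring.
* The crosstalk/joint exclusivity decision changes crosstalk counts
  materially in dense networks; both behaviours are exposed, one must be
  chosen.
* The hub randomization test resamples gene *sets*, not degree-matched
  sets; regulators with very large target counts are mildly favoured.
* Survival evaluation refits β per cohort; no transfer or cross-validation
  mode beyond the optional penalizer.
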