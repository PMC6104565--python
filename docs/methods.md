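# Methods

This note records the models, parameter choices, and numerical decisions
behind `dbdr`, and what the synthetic experiments do and do not show.

## Pathway deregulation scoring

For each pathway the analysis is run per (subtype, dataset): the samples
entering the fit are the analyzed subtype's tumors plus the control group;
other subtypes are excluded, so each subtype's curve is anchored by its own
contrast with normal tissue.

**Standardization.** Member genes present in the matrix are centered by the
control mean and scaled by the control SD (ddof = 1). Genes with control SD
≤ 1e-8 are dropped and logged; a pathway with fewer than 3 usable genes, or
a cohort with fewer than 3 controls, is skipped with a structured
degenerate-pathway record. No expression-level or variance-percentile
filter is applied.

**Dimension reduction.** Samples (as points in standardized gene space) are
reduced by SVD to the smallest number of principal components explaining
≥ `var_expl` = 0.85 of variance, capped at `max_components` = 10.

**Principal curve.** Hastie–Stuetzle fixed-point iteration. The curve is
initialized as the first principal component (with `max_iter = 0` the
returned arc-lengths are exactly the first-PC scores shifted to start at
zero, which the tests use as the initialization contract). Each iteration
projects all points onto the current polyline (exact per-segment orthogonal
projection, arc-length = cumulative length to the segment start plus the
within-segment offset) and then smooths each coordinate against arc-length
with a **local-linear scatterplot smoother** over a rank-window of
`span` = 0.3 of the points (windows truncated at the edges; degenerate
windows fall back to the window mean). Local *linear* fits matter: they
reproduce collinear data exactly, including at the boundaries, which makes
a straight line a true fixed point of the iteration — a running-mean
smoother shrinks the curve ends and breaks the analytic limit.

**Convergence.** Iteration stops when the *relative* change of the mean
squared projection distance falls below `tol` = 1e-4, or after
`max_iter` = 50 iterations. On noise-dominated pathways the iteration can
oscillate indefinitely around the fixed point; such fits are flagged
non-converged (the flag is metadata, not an error) and the returned curve
is the **best iterate** — the one with the smallest mean squared projection
distance — rather than the arbitrary last one. Ties in arc-length are
broken by stable sample order; the smoother never subsamples, so the fit
uses no randomness.

**Score.** The curve is oriented so the median control arc-length is at the
low end (parameterization flipped if the median control exceeds the median
tumor position), then min–max normalized to [0, 1] over all samples in the
run. A pathway whose arc-length range is zero scores 0 everywhere and is
flagged degenerate.

## Ranking and consensus

PDSz is the row-wise z-score of the PDS matrix over all samples of the run
(tumors + controls jointly; ddof = 1). Zero-SD rows become all-zero and are
flagged. Each (subtype, dataset) is summarized by the **median PDSz over
the subtype's tumor samples only** — controls would dilute a subtype
deregulation summary; this is an interpretation choice, recorded here
because the joint alternative is defensible. Top-k selection (default
k = 30; the synthetic studies use k = 10 of 20 pathways) sorts descending
with ties broken lexicographically by pathway id; the cross-dataset
consensus is the set intersection of the two top-k lists, reported in
mean-rank order. Profile clustering uses correlation distance (1 − Pearson)
with average linkage — the standard expression-profile default; the
distance/linkage choice is not dictated by the method.

## Differential expression

One self-contained route serves both platforms (counts arrive already
upper-quartile log2-normalized): per gene a Welch two-sample t on log2
values, Welch–Satterthwaite degrees of freedom, two-sided p, and
Benjamini–Hochberg adjustment over all tested genes. Genes with zero
variance in both groups get t = 0, p = 1 (p = 0 if the constant means
differ). Status calls use |log2FC| > 1 and BH-adjusted p < 0.001; since
adjusted p < 0.001 implies FDR < 0.1, the stricter bound governs and both
knobs stay configurable. No empirical-Bayes variance moderation and no
count-dispersion modeling: the acceptance surface here is calibration
(type-I error, planted-effect recovery), not concordance with any
particular external fitter.

When two platforms are analyzed, their DE calls are merged for
prioritization with a configurable rule, default **union** ('either'): a
gene is a candidate target when either platform flags it, and the reported
log2FC comes from the first (microarray) dataset. The union default
reflects two facts: the DE criterion of the method is per subtype, not per
platform; and on the counts platform the same biological shift yields a
smaller log2FC (see the generator below), so demanding that both platforms
clear a fixed absolute fold-change cut would systematically drop true
targets. The strict 'both' (direction-agreeing intersection) and 'first'
variants remain available.

## Drug prioritization and recommendation

Interaction-direction vocabulary: inhibitory = {inhibitor, antagonist,
blocker, suppressor, negative modulator}; activating = {inducer, activator,
agonist, positive modulator, stimulator}; matching is case-insensitive
after trimming, and unknown claim types deliberately fall to "other" (hence
effect Undetermined) rather than erroring. The effect of a drug on a
differentially expressed target is sign logic only — no magnitude model:
counter-regulation (inhibit an up gene, activate a down gene) is
Homeostasis, co-regulation is Anti-homeostasis. Gene and drug name matching
is exact, case-insensitive, whitespace-trimmed; no synonym resolution. A
gene in several consensus pathways yields one record per pathway. The
tripartite network has pathway, gene, and drug layers with pathway–gene and
gene–drug edges only.

Per-patient selection uses an inclusive PDS threshold, default 0.45: the
worked case-study profiles exclude pathways at PDS ≤ 0.406 and include
≥ 0.466, so any default in (0.406, 0.466) reproduces them; 0.45 is exposed
as a config/CLI knob. Pathways above threshold but with no homeostasis
record are reported as `no_druggable_target`. Conflict screening tests all
unordered drug pairs against the drug–drug interaction table and greedily
drops the drug whose best supporting pathway has the lower PDS (ties: the
lexicographically later name) until conflict-free; the rule is
deterministic and idempotent. The screening rule itself is a design choice
of this package — the underlying method only requires the final set to be
conflict-free.

## Synthetic data

The generator emulates the statistical structure of a two-cohort
breast-cancer study, not its biology:

- **Cohort layout.** Default 94-sample cohorts with Table-style subtype
  composition (Basal 12, Her2 8, LumA 40, LumB 20, Control 14); the
  recovery studies use a single-subtype design (60 tumors / 30 controls)
  stated with each study.
- **Baselines.** Per-gene log2 baselines ~ N(7, 1.5²), shared across
  platforms.
- **Microarray platform.** Gaussian noise (SD `noise_sd` = 1) on the log2
  scale; a planted effect of *e* control-SDs shifts the gene's mean by
  *e*·`noise_sd` log2 units.
- **Counts platform.** Negative-binomial counts (dispersion α = 0.1) with
  mean 2^baseline, per-sample scaling to a fixed 75th percentile (1000)
  and log2(x+1). A planted effect of *e* control-SDs multiplies the mean
  by 2^(e·s) where s = sqrt(1/μ + α)/ln 2 is the delta-method SD of log2
  counts — so "effect in control-SD units" means the same thing on both
  platforms, while the implied absolute log2FC is smaller than on the
  microarray platform for well-expressed genes (≈ 0.46·e at high μ).
- **Planted pathways.** Per subtype, listed pathways shift half their
  member genes up and half down by default (`up_fraction` configurable);
  the principal-curve score is direction-agnostic, and the one-directional
  setting exists for DE-direction studies. Effect sizes are calibration
  choices — no published per-pathway effect sizes exist for real subtype
  deregulation. Gene sets are disjoint blocks by default with an optional
  overlap fraction.
- **Drug tables.** Each gene is druggable with probability 0.3; druggable
  (gene, drug) pairs carry an interaction with probability 0.01 over a
  40-drug universe, typed from the standard claim vocabulary; planted
  shifted genes get one dedicated counter-regulating drug each so recovery
  has a known answer. The drug–drug conflict list samples unordered pairs
  at rate 0.02.
- **Determinism.** All randomness flows from one seed through
  `SeedSequence` spawning; identical seeds give byte-identical outputs.

What the generator does **not** model: probe-level artifacts, batch
effects, read-level sequencing, gene–gene correlation beyond the planted
shifts, overlapping subtype signatures, and drug-name synonymy. Passing
recovery tests therefore show that the pipeline detects coordinated
pathway shifts of the stated size under clean conditions; they do not
certify performance on real cohorts.

## Study sizes and limitations

The multi-seed studies use: consensus recovery — 20 pathways × 50 genes, 3
planted at 1.5 control-SD, 60 tumors/30 controls per platform, k = 10, 20
seeds; clustering — the default 94-sample 4-subtype cohort, 20 seeds; DE
null — 2000 genes at n = 30/30; null consensus — 200 seeds at 30
tumors/14 controls. These sizes are the package's stated study conditions;
per-replicate seeds derive from one base seed.

Known limitations:

- At the scaled-down cohort sizes, the subtype-vs-platform clustering
  result is marginal for the small arms (Her2 n = 8, Basal n = 12): the
  per-subtype mutual-nearest-neighbor rate is high, but the joint event
  "all four subtypes pair in one seed" hovers near the 90% level and
  fluctuates across base seeds. Real cohorts (hundreds of tumors per
  subtype, ~300 pathways) give far less noisy profiles; profiles never
  pair by platform in these experiments.
- The principal-curve iteration is flagged non-converged on most
  pure-noise pathways; this is inherent to projection–smoothing on
  unstructured clouds and harmless for ranking (such pathways carry no
  signal), but the flags should be consulted before interpreting any
  single pathway's PDS.
- BH adjustment is delegated to statsmodels and hierarchical clustering to
  scipy; both are verified in the tests against brute-force definitions
  and invariance properties respectively.
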