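# Methods

`metaboruta` re-implements, as a tested and reusable pipeline, a
plasma-metabolomics workflow for discriminating animal populations (here:
three heavy-pig breeds) from a targeted concentration panel. This note
documents the statistical model behind each stage, the tunable parameters
and their defaults, what the synthetic generator does and does not emulate,
and the numerical conventions.

## Data model

The unit of analysis is a `MetabolitePanel`: a samples × metabolites matrix
of absolute concentrations (µM) from a targeted assay (a Biocrates-p180-like
panel of ~186 analytes over seven subclasses: amino acids, acylcarnitines,
biogenic amines, hexoses, lyso-phosphatidylcholines, phosphatidylcholines,
sphingomyelins), plus per-sample metadata (group label, sex, carcass weight,
QC-replicate flag) and per-metabolite metadata (analyte class, limit of
detection). Missing values are distinct from zeros: a zero is a measured
concentration, an NA token (`""`, `NA`, `<LOD`) is absence of a usable
measurement. Files are wide UTF-8 TSV (CSV accepted); a long format was
deliberately not supported — targeted-panel exports are wide, and one layout
keeps parsing and round-tripping trivial.

## Quality control

Metabolites are screened by three rules applied in fixed precedence, so each
exclusion carries exactly one reason:

1. **CV** — intraplate coefficient of variation across QC replicate
   injections, `100·sd/mean` (sample sd), above `cv_max` (default 20%).
   An undefined CV (fewer than 2 replicates, zero mean) also excludes.
2. **LOD_QC** — QC replicate values below the metabolite's LOD. Default
   rule is *all* replicates below (configurable to *any*): a metabolite
   whose QC injections are unquantifiable is unreliable everywhere.
3. **LOD_SAMPLES** — more than `lod_sample_frac` (default 30%) of
   biological samples below the LOD.
4. **NA_ZERO** — more than `na_zero_frac` of biological samples missing or
   zero. No cutoff is standard for this rule; the default mirrors the
   30% LOD-sample rule and is configurable.

Below-LOD values in retained metabolites are kept as reported; no LOD/2
imputation is applied (an optional mode exists for robustness checks, off by
default).

Samples are never removed by QC. An advisory outlier screen scores each
biological sample by the robust z (median/MAD, consistency factor 1.4826) of
its Euclidean distance from the centroid in unit-variance-scaled metabolite
space; scores above 3.5 flag the sample. The method and cutoff are package
decisions — outlier identification has no single standard — and flagging is
advisory so that the default cleaned sample set equals the input sample set.

## Covariate residualization

Systematic sex and body-size effects would confound any group comparison,
so each metabolite is residualized before analysis. Per metabolite *j*, an
ordinary least squares fit over the pooled biological samples of **all**
groups jointly:

    y_ij = β0_j + βw_j · w_i + βs_j · s_i + ξ_ij

with `w` the carcass weight (kg) and `s` a 0/1 sex contrast (two-level
factor, levels sorted lexically, mapping recorded in the output). The
residuals ξ̂ replace the concentrations downstream. Group labels never enter
the design, so group signal survives; the pooled fit (rather than per-group)
keeps a single consistent adjustment whose residuals are reused by every
comparison. The fit is on raw concentrations by default — multiplicative
effects on log concentrations are approximately linear at these effect
sizes — with a log10 option for sensitivity analysis. NA concentrations are
excluded from that metabolite's fit and give NA residuals; rank-deficient
terms (constant weight, single sex level) are dropped with a warning and an
NaN coefficient.

## All-relevant feature selection (shadow features)

The selector answers "which metabolites carry *any* information about the
group label", not "which minimal subset predicts best". Each iteration
appends one independently permuted *shadow* copy of every surviving
feature, fits a random-forest classifier on `[real | shadow]`, and scores a
*hit* for each real feature whose Gini importance exceeds the
`perc`-percentile of the shadow importances (default 100 = the best
shadow). Under the null a feature hits with probability ½, so after a
5-iteration burn-in two-sided binomial tests on the hit counts promote
features to **Confirmed** or demote them to **Rejected**; rejected features
and their shadows leave the model, undecided features at `max_iter` stay
**Tentative**. The default multiple-testing correction is the two-step
scheme of the reference implementations (Benjamini–Hochberg across the
still-tentative features *and* a Bonferroni-style `alpha/iteration` bound);
a plain Bonferroni mode is available. Only Confirmed counts as selected;
Tentative never does.

Defaults: `alpha=0.05`, `perc=100`, `max_iter=100`, 500 trees per internal
forest (`max_features=sqrt`, `max_depth=7`). The internal forest is
deliberately smaller than the 1,000-tree evaluation forest — importance
*ranks* against shadows stabilize long before importance values do. The
whole run is deterministic given its seed.

## Stability validation

A single selector run on 24–36 samples is fragile. Every selection is
therefore repeated under a leave-one-out × multi-seed grid: each biological
sample is held out in turn and the selector runs `n_seeds` (default 5)
times on the remaining N−1 samples, giving `5·N` runs — 120 for a 12-vs-12
pairwise comparison, 180 for the 3×12 multi-class setup. Per-run seeds are
`crc32(base_seed:seed_index:held_out_id)`, so any run is individually
reproducible. A run that would leave a class below 2 samples is skipped,
logged, and excluded from the run total. Retention categories:

* `highly_reliable` — Confirmed in 100% of runs,
* `moderately_reliable` — Confirmed in ≥ 90% of runs (e.g. 108/120),
* `unstable` — anything less.

Both thresholds are configurable. The multi-class setup runs the same
machinery with a 3-level response (no one-vs-rest decomposition); because
all classes must separate simultaneously, it is the stricter criterion and
selects fewer metabolites than the union of the pairwise runs.

## Evaluation

For each selected metabolite in a pairwise comparison:

* **Δ%** = `100·(x̄₂ − x̄₁) / ((x̄₁ + x̄₂)/2)`, on pre-adjustment
  concentrations: a descriptive contrast of real concentration levels,
  whereas the inferential statistics below run on residuals. The symmetric
  mean in the denominator makes Δ% antisymmetric under group swap and
  bounds |Δ%| by 200; negative means the second-listed group is lower.
* **Mann–Whitney U** (orientation: pairs with group-1 value greater, ties
  ½) with two-sided p — exact null distribution when `n1·n2 ≤ 400` with no
  ties, else normal approximation with tie and continuity correction; the
  method used is recorded per test.
* **ROC-AUC** = `max(U, n1·n2 − U)/(n1·n2)`: the normalized U statistic,
  oriented ≥ 0.5 (direction-free discrimination; direction lives in Δ%).
* **Bonferroni** significance at `alpha/n_tests`, where `n_tests` is the
  number of metabolites that survived QC — not the number selected.
* **MDG and OOB** from a 1,000-tree random forest grown on the selected
  metabolites only. MDG is reported on the R `randomForest` scale
  (per-tree sum of sample-weighted Gini decreases, averaged over trees,
  times the sample count). OOB error is the fraction of samples
  misclassified by out-of-bag votes; misclassified ids are listed.

Within-group structure is screened by Pearson correlation matrices over a
group's samples, flagging |r| ≥ 0.5 regardless of p-value; constant
metabolites yield NA rows.

## PCA

Columns are centered and scaled to unit variance (sample sd), then
decomposed by full SVD. Component signs follow the convention that each
component's largest-magnitude loading is positive, so scores are
reproducible across platforms. Zero-variance and NA-bearing metabolites are
dropped with a warning. Run before and after selection, the PC1 explained
fraction quantifies how much the selected subset concentrates group-related
variance.

## Synthetic panels and what they show

The generator emulates a single-plate targeted experiment: log-normal
concentrations (log-mean U(−2.3, 4.6) ≈ 0.1–100 µM, log-sd U(0.2, 0.6));
three groups of 12 (first group 5 castrated males / 7 gilts, others 6/6);
carcass weight N(125, 6) kg; multiplicative group effects (default fold
1.5–3) planted on 6 metabolites per group pair; sex and weight effects on
the log scale for a random ~30% of metabolites; within-family correlation
via one shared latent factor per block of 8 metabolites inside each analyte
class (ρ = 0.5); two QC replicates at 5% CV; LODs at the 2% quantile of
each metabolite's base distribution. One metabolite is planted to fail the
CV rule (its replicates are rescaled to the failing CV exactly — with two
replicates the sample CV is noisy and the failure would otherwise be left
to chance), three to fail the QC-below-LOD rule and one the
samples-below-LOD rule, mirroring a realistic exclusion structure
(181/186 retained). The nominal 5% replicate CV keeps spurious CV
exclusions rare (a 2-replicate CV estimate of a true 8% CV crosses the 20%
cutoff ~1% of the time, which over 186 metabolites would add 2–3 spurious
exclusions per panel).

Ground truth (`SyntheticTruth`) records, per group pair, the metabolites
whose log-means actually differ with their realized fold change, plus
covariate effects, correlation blocks and the planted QC failures — the
reference for sensitivity/false-discovery scoring.

Not emulated: batch/plate effects beyond one plate, drift, missingness
mechanisms tied to concentration (NA injection is uniform and off by
default), heavy-tailed measurement error, and realistic inter-class
correlation differences. Passing recovery tests therefore shows the
pipeline recovers multiplicative group effects under log-normal noise with
covariate confounding — not that it handles assay artefacts beyond the QC
rules modelled here.

## Problem sizes and numerical choices

The test suite and the acceptance script run reduced problem sizes chosen
for one CPU: 12–40-metabolite panels, selector forests of 40–100 trees with
25–40 iterations (the production defaults are 500 and 100), 200–1,000-tree
evaluation forests. At these sizes, recovery on the strong-signal fixture
(fold 3–4, 12 vs 12, full 5-seed × leave-one-out grid) is complete
(sensitivity 1.0, FDP 0.0 at seed 1); the acceptance script recomputes
these numbers at run time. Other conventions: stable sorts and fixed sort
keys for every written table (byte-identical reruns); `%.6g` float
formatting; NA written as the literal `NA`; per-run seeds kept below 2³¹;
ties in the MWU always handled by the tie-corrected normal approximation;
the moderately-reliable boundary uses floating comparison of
`retained/total ≥ 0.90` (exactly 108/120 qualifies; 107/120 = 0.8917 does
not).

## Known limitations

* Boruta-family selections depend on forest hyperparameters; two
  implementations can disagree near the decision boundary. The stability
  grid is the mitigation, not a cure.
* The OLS adjustment assumes additive covariate effects on the raw scale;
  strongly multiplicative confounding is better served by the log10 mode.
* With 12 samples per group the exact MWU p-values are granular; Bonferroni
  at 0.05/181 is conservative.
* The advisory outlier score assumes roughly elliptical scaled data; it is
  a screen, not a test.
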