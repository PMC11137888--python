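# Methods

This note records the statistical model behind each component, the
parameter choices that matter, and the places where the published
tools' descriptions leave room for interpretation and a decision had to
be made.

## The data model

A Ct value is the PCR cycle at which a reaction's fluorescence crosses
a fixed threshold; it is logarithmic in starting template amount (one
cycle ≈ one doubling at 100 % efficiency). All methods therefore treat
Ct as log-scale data. The working decomposition, which the synthetic
generator implements literally, is

    Ct_ij = baseline_i + shift_{i, g(j)} + b_j + eps_ij

with `baseline_i` the gene's typical abundance, `shift_{i,g}` a
systematic gene × condition regulation (a *bad* reference gene has
large shifts), `b_j ~ N(0, tau^2)` a per-sample loading effect shared
by every gene in the sample (RNA input, RT efficiency), and
`eps_ij ~ N(0, noise_sd_i^2)` gene-specific noise. Missing or
non-positive Ct values are rejected at the door rather than imputed:
none of the four stability methods defines missing-data handling, and a
silent imputation would change their statistics.

Technical replicates, when present as repeated sample columns, are
averaged to one Ct per (gene, sample) on request (`average_replicates`)
because every stability method consumes exactly one value per sample;
the flag defaults to off so that accidental duplicate ids surface as
errors.

## Screening (FPKM)

Per gene: MF (mean FPKM), SD with the n−1 denominator (configurable to
n), CV = 100·SD/MF. Thresholds are inclusive (MF ≥ 10, CV ≤ 20 %). An
optional allow-list stands in for annotation credibility, which is not
derivable from expression values. The generator draws log-normal FPKM
with `sigma^2 = ln(1 + cv^2)`, `mu = ln(mean) − sigma^2/2`, so designed
mean and CV are the distribution's true moments; note that at 42
samples the *realized* CV of an 18 %-CV design crosses the 20 % cutoff
in roughly 15 % of draws — the screen is a noisy instrument near its
boundary, and the tests assert the Monte-Carlo rate (~0.85), not an
idealized one.

## Comparative ΔCt

For each ordered gene pair the per-sample difference Ct_i − Ct_k is
taken; its SD over samples (n−1) measures the pair's disagreement, and
a gene's value is the arithmetic mean of its pair SDs. Because only
differences enter, the shared loading effect b_j cancels exactly — the
method is blind to sample-loading variation by construction. The pair
SD matrix is exposed in the result's `detail`.

## BestKeeper

Per-gene descriptives of raw Ct (mean, min, max, dispersion, CV) plus
Pearson correlation against the BestKeeper index, the per-sample
geometric mean Ct over all candidates. Dispersion defaults to the
sample SD; the original spreadsheet's mean absolute deviation from the
arithmetic mean is available as `deviation="mad"` for cross-tool
comparison. Working on raw Ct means the loading effect does *not*
cancel — this deliberate asymmetry versus ΔCt/geNorm/NormFinder is
asserted in the tests on the tau = 1, noise = 0 synthetic scenario. A
zero-variance gene has no defined correlation; it is reported as
missing with a warning instead of raising, since the dispersion ranking
is still valid.

## geNorm

Ct is first transformed to relative quantities `Q = E^(minCt − Ct)`
with E the amplification factor (default 2.0 for all genes, since the
transform is conventionally written base 2; per-gene factors from
standard-curve fits are accepted). The minimum is the *per-gene*
minimum *within the analyzed sample subset* — the published transform
descriptions rarely say which minimum, but the per-gene choice makes
each row's maximum exactly 1 and keeps subset analyses self-contained.
Since any per-gene constant cancels in the log-ratios, this choice
cannot change M, the ranking, or V; it only fixes the scale of Q.

M_j is the mean over partners of SD(log2 Q_j/Q_k) (n−1). With all
E = 2, log2(Q_j/Q_k) = (Ct_k − Ct_j) + const, so first-round M equals
the ΔCt pair-SD mean — a cross-method identity asserted to 1e−10 in
the tests. Ranking is by iterative exclusion of the highest-M gene; a
tie at the maximum removes the lexicographically larger id (recorded in
the exclusion trace), and the two survivors are jointly most stable.

V(n/n+1) is the SD over samples of log2(NF_n/NF_{n+1}), NF_n being the
per-sample geometric mean of the top-n genes' quantities. The optimal
count is the smallest n with V < 0.15 (threshold configurable); when no
n qualifies the result is the sentinel `"undetermined"`, which
downstream recommendation treats as "use the full panel" with a
warning. For the comprehensive ranking the tied top pair enters as
ranks (1, 1) with the next gene at 3 — mirroring classic geNorm output
— with a sequential (1, 2) alternative behind a flag; the choice moves
geomeans only in the third decimal.

## NormFinder

Implemented from the model-based algorithm's variance mathematics on
y = −Ct (Ct is already log-scale; the sign flip makes larger = more
template and cancels everywhere). Steps, for I genes and G groups of
sizes n_g:

1. Center each sample over genes: z_igj = y_igj − mean_i(y_igj). This
   removes b_j exactly and leaks 1/I of every other gene's variation
   into z — the source of the later bias correction.
2. Per (gene, group): sample variance s²_ig (n−1) and mean z̄_ig.
3. Bias-corrected intragroup variance
   σ̂²_ig = max(0, (I/(I−2)) · (s²_ig − Σ_i' s²_i'g / (I(I−1)))),
   which is unbiased for the true noise variance under the model (the
   tests verify ≤ 5 % bias at I = 10, n_g = 20 over 1000 replicates;
   measured ≈ 1.5–2.5 %). The floor at 0 guards small-sample
   negativity; with comparable gene variances it engages rarely.
4. With ≥ 2 groups: raw differences d_ig = z̄_ig − mean_g z̄_ig (these
   sum to 0 over genes within each group), the variance of true group
   differences γ̂² = max(0, Σ d²/((G−1)(I−1)) − mean(σ̂²/n_g)), and the
   empirical-Bayes shrinkage d̃ = d · γ̂²/(γ̂² + σ̂²/n_g). When γ̂² = 0
   all d̃ collapse to 0.
5. Stability ρ_i = mean_g(|d̃_ig| + sqrt(σ̂²_ig/n_g)), an equal-weight
   average over groups regardless of n_g (the symmetric treatment of
   conditions). A single group reduces to ρ_i = sqrt(σ̂²_i).

The companion best-pair search scores each pair by
mean_g(|(d̃_i + d̃_k)/2| + sqrt((σ̂²_i + σ̂²_k)/(4 n_g))): averaging two
genes halves independent noise and lets opposite-sign regulation
cancel, so an anti-correlated pair can beat two individually better
genes. Ties break lexicographically. At least 3 genes are required
(the correction divides by I−2) and every group needs n_g ≥ 2.

## Comprehensive ranking

Geometric mean of the per-method integer ranks, equal weights,
within-method ties carrying the shared minimum rank. The final order is
ascending geomean with lexicographic tie-break. The recommended set is
the optimal-n head of this ordering.

## Quantification

Standard curves are ordinary least squares of Ct on log10
concentration; E = 10^(−1/slope), percent efficiency (E−1)·100, so the
canonical slope −3.32193 is exactly 100 %. Slopes ≥ 0 and series with
fewer than 3 points are errors. Normalization factors are per-sample
geometric means of the chosen reference genes' quantities. Fold changes
are ratio_j = target_Q_j / NF_j scaled so the calibrator aggregate is
1; the aggregate is the arithmetic mean of calibrator ratios by
default (geometric optional — the published descriptions of ΔΔCt
normalization are silent on this, and the two differ only when
calibrator replicates disagree). Classic ΔΔCt (all E = 2) is the
default; efficiency-corrected quantification passes per-gene E.
Significance testing of fold changes is out of scope; per-sample folds
are exported for external statistics.

## Synthetic presets and what they do (and do not) show

The presets mirror a three-stage growth series (3 × 3), a four-tissue
comparison (4 × 3), a control/drought contrast per tissue (6 groups ×
3) and their union, with 10 genes named after common plant reference
genes: eight quiet ones (noise 0.2 cycles), one progressively regulated
gene (TUBB, 1.5-cycle span across conditions, noise 0.6) and one
high-scatter gene (EF1A, noise 1.0). Loading SD tau defaults to 0.3
cycles, a typical pipetting/input spread. The benchmark design used for
recovery checks (10 genes, 3 × 6, one gene with a 1.5-cycle shift in
one group and noise 0.6 versus 0.2) is recovered at the bottom of all
four rankings in 100 % of 200 seeded runs.

What passing these tests shows: the four statistics implement their
definitions, respond to the two programmed variance sources, and are
invariant to exactly the nuisance terms their constructions cancel.
What they do not show: behavior under the things real qPCR data add —
amplification inhibitors, efficiency drift between plates, truncated or
missing Ct at low abundance, non-normal heavy-tailed noise, and
correlated regulation among candidate genes. The generator draws
independent normal noise on the log scale; real candidate panels can
fail in correlated ways no stability statistic detects from Ct data
alone.

## Numerical choices

- All SDs and variances use the n−1 denominator unless a flag says
  otherwise.
- Rank ties share the minimum integer rank everywhere.
- Degenerate inputs: constant genes give zero stability values for all
  methods (tied at rank 1) and an undefined BestKeeper correlation
  (warned, reported missing); variance floors at 0 in NormFinder;
  efficiency factors ≤ 1 are parameter errors.
- Determinism: every stochastic step takes an explicit seed; rerunning
  a pipeline with the same config and inputs produces byte-identical
  outputs (asserted in the tests).
- Problem sizes in the recovery checks — 200 seeds for ranking
  recovery, 1000 replicates for variance unbiasedness, 42 samples for
  the screening Monte-Carlo — are the package's benchmark conditions
  and complete in a few seconds.

## Known limitations

- One grouping factor only; no multi-factor or nested designs.
- No missing-data handling (by design; fail fast).
- BestKeeper's p-value-based gene exclusion (SD > 1 rule) is not
  applied; the descriptives and index correlations are reported as-is.
- The comprehensive ranking reproduces the geometric-mean aggregation,
  not any web service's internal re-computation quirks.
- Table-level reproduction of the published taro study requires its
  raw Ct table, which its authors distribute on request; the relevant
  tests document the expected layout and fail informatively without it.
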