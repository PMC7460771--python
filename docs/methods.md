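# Methods

## Count model and differential expression

Counts for gene *g* in sample *j* are modelled as negative binomial,
`y_gj ~ NB(mean = μ_g s_j, dispersion = φ)`, with `Var = μ + φμ²` and a
**single common dispersion** shared across genes. Tagwise or trended
shrinkage is deliberately out of scope: with 3–4 replicates per arm the
common-dispersion exact test is the standard small-sample choice, and the
simulator generates data from exactly this model so that parameter-recovery
tests are well-posed.

The DE stages are:

* **Expression filter** — keep genes with CPM ≥ 1 in at least
  (smallest-group-size) samples. The criterion used by the original midgut
  and cell analyses is not documented beyond the surviving gene count, so
  the rule is a configuration knob (`min_cpm`, `min_samples`) with this
  conventional default.
* **TMM normalization** — trimmed (30% on M, 5% on A), precision-weighted
  mean of per-gene log2 ratios against a reference column (the sample whose
  75th CPM percentile is closest to the mean). Factors are normalized to
  geometric mean 1; depth stays in the library size. Ranks use average tie
  handling. Columns proportional to the reference short-circuit to a factor
  of 1.
* **Library equalization** — counts are scaled to the geometric mean of
  effective library sizes (library size × factor) and rounded
  **half-to-even** to integers. This is a documented simplification of the
  quantile-based pseudo-count adjustment used by the reference RNA-seq
  tooling; a session cross-check against that tooling showed identical TMM
  factors (8 decimals) and dispersion/p-values agreeing to within a few
  percent, which is the expected footprint of this simplification.
* **Common dispersion** — maximize the conditional log-likelihood given
  per-group totals, summed over genes and groups: for a group of *n* counts
  *y* with total *z* and *r = 1/φ*,
  `ℓ(r) = Σ_i lnΓ(y_i + r) − n lnΓ(r) + lnΓ(n r) − lnΓ(z + n r)`.
  The 1-D search runs over δ = φ/(1+φ) ∈ [10⁻⁶, 0.999] with bounded Brent
  (xatol 10⁻⁸). Groups with a single replicate carry no conditional
  information and are skipped; all-singleton designs are an error.
* **Exact test** — condition on the total *s* of the two group sums; the
  group sum of *n* NB(μ, φ) variables is NB(nμ, φ/n). All splits
  *a = 0..s* whose joint probability does not exceed the observed one are
  accumulated. A relative tie tolerance of 10⁻¹² makes the ≤ comparison
  reproducible across float orderings. φ = 0 degenerates to the
  conditional binomial (Poisson limit). *s* = 0 returns p = 1 by
  convention. Everything is computed in log space with `logsumexp`.
* **BH adjustment** — the step-up formula `q_(i) = min_{j≥i} p_(j)·m/j`,
  capped at 1.
* **log2FC** — second contrast group over first on equalized group means
  with a +0.5 stabilizing offset. The project-wide convention is
  **heme_excess over heme_deficient**, so negative log2FC = down in heme =
  import-consistent, matching the sign convention of the published
  candidate table.

## Soft clustering

Profiles are replicate-averaged log2 CPM (offset 0.5) per treatment,
z-standardized per gene (population sd); genes with constant profiles are
dropped and logged. Clustering is fuzzy c-means with Euclidean distance,
alternating the membership and centroid updates until max|Δu| < 10⁻⁶ or
200 iterations, best of 5 seeded restarts initialized at distinct data
points. The objective Σ u^m d² is asserted non-increasing every iteration.
Membership updates are computed on distance ratios scaled by the per-row
minimum so fuzzifiers arbitrarily close to 1 cannot overflow; a profile
coincident with a centroid takes membership 1 there (limit convention).

**Fuzzifier.** The minimum-hypersphere estimator
`m(N, D) = 1 + (1418/N + 22.05) D⁻² + (12.33/N + 0.243) D^(−0.0406 ln N − 0.1134)`
is implemented and is the default when no value is configured. With only
three treatment dimensions it returns m ≈ 3.7, which is designed to prevent
false clusters in random data but diffuses memberships: with six clusters
the maximum membership then rarely exceeds the 0.5 reporting threshold.
The recovery studies therefore run at **m = 1.5**, a conventional value for
short, well-separated expression profiles; it is recorded in every run
artifact, and any analysis can override it in configuration.

**Cluster count.** Candidate counts are scanned upward and the selected c
is the largest for which the minimum pairwise centroid distance exceeds
0.5 standardized units, i.e. the largest c before clusters start
duplicating. On z-standardized 3-dimensional profiles every row has norm
√3 ≈ 1.73 and genuinely distinct shapes sit ≳ 2 apart while split halves of
one shape sit ≈ 0.2 apart, so 0.5 cleanly separates the two regimes.

**Pattern labels.** For the three-arm design
(normal_serum, heme_deficient, heme_excess): import-like iff the
heme-deficient coordinate is the strict maximum and heme-excess the strict
minimum; export-like iff reversed; serum-response iff normal_serum is the
strict extremum (the screen's serum-present condition differs from both
serum-free arms in nutrient content, so a serum-driven gene moves alone);
anything else — including ties — is labelled other, a deliberately
conservative choice. Negating every profile exactly swaps the
import/export labels. The serum-response rule is an explicit formalization
of what the original analysis judged narratively.

Genes are reported in a cluster only at membership strictly > 0.5.

## TM-domain enrichment

Universe = the annotated (by default, expressed) gene set; K of G genes
carry ≥ 1 TM segment. The null is `n_draws = 30` subsets of the query's
size n drawn **without replacement**; the test statistic is
`z = (observed − mean(draws)) / sd(draws)` with the n−1 sample sd and a
two-tailed normal p. Thirty draws is kept as the default because it is the
screen's own design, but it is statistically thin: the calibration study
(10,000 null replicates) measures a type-I rate of ≈ 0.06 at nominal 0.05,
an honest property of the 30-draw z null, and every result carries the
exact hypergeometric mean `nK/G` and variance
`n(K/G)(1−K/G)(G−n)/(G−1)` alongside. A degenerate null (sd = 0) returns
p ∈ {0, 1} with a warning flag.

## Candidate prioritization

Midgut chain: q < α (α swept 10⁻⁴–0.05 in the original analysis; default
0.05 for the candidate stage), tm_count ≥ 2, function class in
{transport, unknown} (the whitelist encodes the manual curation that
removed enzymes and ROS-response genes), non-mitochondrial. "2-fold" is
implemented as |log2FC| ≥ 1 inclusive. Cultured-cell chain additionally
requires (strict mode) or unions (union mode) a concordant cluster
pattern, mirroring the screen's alternation between "DEG and …" and "DEG
and/or present in … cluster". Cross-dataset tallies count, per gene, the
number of datasets whose candidate set contains it.

Genes absent from the annotation default to tm_count 0, function class
`other`, non-mitochondrial (logged) — conservative in every filter. When a
gene has several protein isoforms in a topology file, the per-gene TM count
is the maximum across isoforms.

## Synthetic data

The generator emulates the structure of the study's experiments: up to 4
datasets sharing one gene universe, 2–3 media conditions × 3 replicates,
NB counts with a common dispersion (default φ0 = 0.1), gene baselines
log2-normal on the CPM scale (Normal(5, 2)), library sizes
Uniform(0.8, 1.2) × 5·10⁵ reads, and 8,000 genes by default. Planted
classes shift log2 means by ±Δ (default Δ = 1, the screen's 2-fold
threshold): importers +Δ in deficiency / −Δ in excess, exporters mirrored,
serum responders +Δ under serum only, mitochondrial genes +Δ in excess.
The annotation gives planted transporters 2–14 TM segments and a 32%
genome-wide background of ≥ 1-TM genes (calibrated to the screen's
observed-vs-expected baseline of ≈ 185/587 ≈ 31.5%). Randomness flows from
one root seed through per-dataset substreams, so adding a dataset never
perturbs earlier ones.

The simulator deliberately omits batch effects, gene-length bias, tagwise
dispersion heterogeneity, and correlated genes. Passing recovery tests
therefore demonstrates correctness of the algorithms under their own model
assumptions — not robustness of the screen to the messier variance
structure of real midgut libraries (the original midgut replicates were
visibly noisier than cultured cells).

## Study problem sizes

Evaluation studies are sized to finish in seconds while leaving their
conclusions stable across seeds: dispersion recovery at 2,000 genes ×
4/group; DE sensitivity and cluster recovery over 10 simulation seeds
(2,000 / 800 genes); enrichment calibration over 10,000 replicate tests on
a 2,000-gene universe; enrichment power over 100 seeds at the screen's own
scale (n = 587 of 8,000). The published-table replays are exact and
instantaneous.

## Known limitations

* Library equalization is scaling + rounding, not quantile adjustment;
  exact-test p-values can differ from the reference tooling by a few
  percent in the tails.
* The common-dispersion assumption understates gene-specific variance
  heterogeneity in real data.
* The 30-draw resampling null is mildly anti-conservative (~0.06 at
  nominal 0.05); use the reported hypergeometric moments or raise
  `n_draws` when calibration matters.
* Cluster-count selection by centroid duplication has no optimality
  guarantee; it is a reproducible, parameter-light heuristic.
* The bundled published tables encode overlap *degrees*, not which
  specific cell datasets matched; set reconstructions from them are
  canonical, and only degree statistics are meaningful.
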