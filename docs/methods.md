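# Methods

## Model and procedure

The test addresses the homogeneity of `h` independent multinomial
samples over `k` categories. Under the null all groups share one
category-probability vector `p = (p_1, …, p_k)`; the pooled estimator is
`p̂_i = Σ_j Y_ij / Σ_j n_j` and the Pearson statistic

    Q = Σ_{j=1..h} Σ_{i=1..k} (Y_ij − n_j p̂_i)² / (n_j p̂_i)

is referred to the chi-square distribution with `(h−1)(k−1)` degrees of
freedom. When the category probabilities are specified a priori
(goodness-of-fit regime) no parameters are estimated and the reference
distribution has `h(k−1)` degrees of freedom.

Neutrosophic extension: an indeterminacy measure `I ∈ [I_L, I_U]`,
`0 ≤ I_L ≤ I_U`, expresses the uncertain fraction of the counting
process. The statistic becomes the interval `Q_N ∈ [Q_L, Q_U]` via the
decomposition `Q_N = Q_det + Q_coef · I`:

* **Multiplicative (simplified) form** — for determinate counts with
  relative indeterminacy: `Q_coef = Q_det = Q`, so
  `Q_N = (1 + I) · Q`. This is the canonical internal representation;
  the additive decomposition is derived from it for display.
* **Two-sum (general) form** — for genuinely interval-valued counts
  (a lower and an upper table): `Q_det` is the Pearson sum of the lower
  table with probabilities pooled from the lower table, `Q_coef` the
  Pearson sum of the upper table with upper-table estimates, giving
  `Q_U = Q(lower) + Q(upper) · I_U`. The two forms coincide exactly when
  the tables coincide. The pooled estimator's own indeterminacy is not
  propagated as a separate quantity: each endpoint estimate comes from
  its own table, and indeterminacy enters the statistic only through
  `I`. No combination rule for estimator-level and statistic-level
  indeterminacy is defined, so none is invented.

Because the statistic is an interval, the decision is trichotomous with
respect to the critical value `c`:

* `Q_U ≤ c` → do not reject;
* `Q_L > c` → reject;
* `Q_L ≤ c < Q_U` → indeterminate.

This rule is conservative in both directions and collapses to the
classical accept/reject comparison whenever the interval lies entirely on
one side, which holds in every bundled example. At `I = [0, 0]` the
interval is degenerate and the procedure is exactly the classical Pearson
test (verified against an independently coded brute-force sum, the 2×2
closed form `N(ad−bc)²/((a+b)(c+d)(a+c)(b+d))`, and
`scipy.stats.chi2_contingency` without continuity correction).

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `alpha` | significance level | 0.05 | conventional level of the bundled analysis |
| `I = [I_L, I_U]` | indeterminacy interval (dimensionless fraction) | `[0, 0]` | classical test unless the user asserts indeterminacy |
| `critical_value_override` | replace the `1−α` chi-square quantile | none | see "Critical value" below |
| `round_q_to` (sweep only) | decimal places for `Q_L` before sweeping | none (full precision) | see "Reporting precision" below |

Indeterminacy endpoints above 1 (indeterminate part exceeding the
determinate quantity) are rejected by default; `allow_above_one=True`
downgrades the rejection to a warning. Sweeps fix `I_L = 0` and vary
`I_U` over a default 20-point grid (0, 0.01–0.09 by 0.01, 0.1–1.0 by
0.1).

### Critical value

By default the critical value is computed as the `1 − α` chi-square
quantile (`7.8147` at `α = 0.05`, df = 3). The bundled BRCA2 analysis
instead uses the tabulated value `9.35`, which is the 0.975 quantile at
df = 3; since at `α = 0.05` that choice is not derivable from the stated
level, it is reproduced only through the explicit
`critical_value_override` and never silently substituted. Both decisions
agree on the example by a wide margin.

### Reporting precision in sweeps

Published sweep tables typically rescale the *reported* statistic: the
BRCA2 sweep's entries equal `(1 + I_U) × 0.00664`, i.e. the statistic
rounded to five decimal places, not the full-precision `0.0066404881`
(visible at `I_U = 0.1`: `0.007304` vs `0.007305`). `round_q_to=5`
reproduces such tables digit for digit; the default keeps full
precision.

### Minimum expected counts

Expected cells below 5 trigger the classical adequacy warning; only an
expected cell of exactly 0 (a zero pooled probability or an empty group)
is an error, since the statistic is then undefined. Probability vectors
must sum to 1 within 1e−9 absolute.

## Synthetic data and Monte Carlo calibration

`generate_null_table` draws each group from
`multinomial(n_j, null_probabilities)`; `generate_synthetic_fasta` draws
per-record base counts the same way and emits a seeded permutation of
exactly those bases, so counting the file recovers the generating totals
identically. The Monte Carlo drivers spawn one independent substream per
replicate from a single root seed (`numpy.random.SeedSequence`), making
results bit-reproducible and independent of execution order.

What the generators emulate: multinomial sampling of composition counts
under a shared (null) or per-group (alternative) probability vector, at
the sample sizes of interest. What they do not emulate: positional or
autocorrelation structure of real DNA, sequencing error profiles,
coverage variation, or any mechanism that would make counts
overdispersed relative to the multinomial. Passing calibration therefore
shows the test behaves correctly *for multinomial data*; it does not
certify behaviour under overdispersion.

Calibration experiments in the test suite use h = 2 groups, k = 4
categories, 500 observations per group and 2000 replicates for the
type-I error check (a few seconds of compute), and 300–1000 replicates
for the power and monotonicity checks — sizes at which three binomial
standard errors give a ±1.5-percentage-point band around the nominal
level. With `I = [0, 0]` the empirical type-I error sits within that
band; widening the interval moves borderline rejections into the
indeterminate state, so on identical seeds the rejection rate is
non-increasing in `I_U`. No distributional claim is made for `Q_U` under
the null — the operating characteristics of the interval decision are
measured, not assumed.

## Numerical and design choices

* The classical condition is `I_L = I_U = 0`. (A reduction at `I_L = 0`
  alone would make the 5 %-indeterminacy example classical, which it is
  not; the degenerate-interval reading is the consistent one.)
* `NeutrosophicValue` stores `(determinate, coefficient, indeterminacy)`
  and derives the endpoints, so the structural identities
  `lower = d + c·I_L`, `upper = d + c·I_U` cannot be violated by
  construction.
* Count tables: CSV/TSV with a category-label header row and group
  labels in the first column; thousands separators are stripped so
  published tables paste in verbatim. Parsing errors name the offending
  cell. Ambiguity codes and gaps in FASTA input are excluded from
  counts (never errors) and tallied per group; sequences are uppercased
  before counting; the category order is fixed A, C, G, T.
* Decision-to-exit-code mapping in the CLI (0 do-not-reject / 3 reject /
  4 indeterminate, 2 usage error) makes the trichotomy visible to shell
  pipelines. Results go to stdout or `--out`; logs and a reproducibility
  manifest (command, resolved parameters, input SHA-256 digests, tool
  version) go to stderr.

## Limitations

* Asymptotic test only: no exact or permutation variant, no continuity
  correction, no multiple-testing adjustment across tables.
* The interval decision is conservative by design; with very wide
  indeterminacy intervals most borderline datasets land in the
  indeterminate state rather than being forced to a verdict.
* Indeterminacy is treated as a user-supplied interval on the statistic
  (or as paired count tables); the package does not estimate `I` from
  data.
* General neutrosophic interval arithmetic (products, quotients of
  arbitrary neutrosophic numbers) is out of scope; only the operations
  the test needs are implemented.
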