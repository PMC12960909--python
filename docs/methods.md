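# Methods

## Model

Per-sample mutation counts relative to a fixed reference genome are modeled
as a Gaussian stochastic process `m(t)` with drift:

* **Null (Brownian) model.** `dm/dt = κ + ξ(t)` with white noise,
  `⟨ξ(t)ξ(t′)⟩ = D·δ(t−t′)`, giving `⟨m(t)⟩ = m₀ + κt` and
  `Var m(t) = D·t`. When `κ = D` the mean and variance coincide — the
  Poissonian clock regime.
* **Challenging (fractional Brownian) model.** The noise is time-correlated,
  `⟨ξ(t)ξ(t′)⟩ = ½Dα(α−1)|t−t′|^(α−2)`, giving the same mean but
  `Var m(t) = D·t^α`. `α < 1` is subdiffusion (constrained evolution),
  `α > 1` superdiffusion; at `α = 1` the models coincide.

κ is the evolution rate per time-interval unit (per week for the default
7-day bins), m₀ the initial mutational load of the founding lineage, D the
diffusivity of the mutation-count spread, and α the anomalous-diffusion
exponent (related to the Hurst exponent of the underlying process).

## Estimation

Samples are binned into half-open windows of `interval_days` (default 7 d,
roughly a generation time for fast-evolving RNA viruses) anchored at the
earliest collection date. Bin k yields the sample mean μ_k, the unbiased
(N_k−1 denominator) variance σ²_k, and the reliability weight
`w_k = tanh(N_k/15)`, which discounts thinly sampled intervals and saturates
toward 1 as bins grow. Time is measured in interval units, `t_k = k`. Bins
with a single sample keep their mean but contribute no variance point; empty
bins are absent rather than interpolated — fits operate on the observed
(t, statistic) pairs only. More than 30 sequences per bin is advisable for
stable variances; the package logs a warning below that, but does not drop
bins (a hard threshold would silently discard information).

* **Mean fit.** Weighted least squares of μ_k on t_k with weights w_k gives
  κ (slope) and m₀ (intercept, always estimated and reported). 95% CIs use
  the t distribution with n−2 degrees of freedom.
* **Variance rescaling.** The stochastic models assume a sharp initial
  condition, while real populations start with standing variation, so the
  earliest defined bin variance σ²₀ is subtracted from the whole series and
  time is shifted so the series starts at (0, 0). Negative rescaled values
  are retained — clamping them to zero would bias D downward.
* **Null variance fit.** Weighted through-origin regression,
  `D = Σ w t y / Σ w t²`, CI with n−1 degrees of freedom.
* **Challenging variance fit.** Weighted nonlinear least squares of
  `D·t^α` by Levenberg–Marquardt, initialized at the null slope and α = 1.
  Standard errors come from the estimated covariance of the fit; CIs use
  n−2 degrees of freedom. α is unconstrained; α ≤ 0 or α > 3 is flagged as
  degenerate rather than clipped. If the optimizer fails to converge, the
  selection falls back to the null model with a warning.
* **Model selection.** Both models are scored with
  `AICc = n ln(2π) + n ln(RSS/n) + n + 2p + 2p(p+1)/(n−p−1)` on the
  *weighted* RSS. The t = 0 point carries no information about a power law
  and is excluded from the challenging fit; the null RSS is computed on the
  same surviving point set so both AICc values share n and the comparison is
  valid. A perfect fit (RSS = 0) maps to −∞; exact ties resolve to the
  simpler null model.

## Mutation calling

Each sample is aligned globally to the reference (MAFFT subprocess, or the
builtin affine-gap aligner: match +2, mismatch −1, gap open −5, gap extend
−1 — the contract is alignment validity, not parity with MAFFT). From the
aligned pair: a column with two differing A/C/G/T bases is one substitution;
a maximal gap run in the reference row is one insertion (anchored to the base
on its left, position 0 before base 1); a maximal gap run in the query row is
one deletion, unless it touches either end of the alignment, in which case it
is terminal missing data (truncated sequencing), not a deletion. N and other
IUPAC ambiguity codes in the sample are missing data and never produce
substitutions. Counting a multi-base indel as a single event keeps the
per-sample count an event count; categories satisfy
total = substitutions + indels by construction. The genome position filter
keeps events whose reference anchor lies in the window.

## Synthetic data

The generator emulates a surveillance collection of one expanding lineage:
at interval k it draws `samples_per_interval` counts from a Gaussian with
mean `m₀ + κ·k` and variance `D·k^α`, rounds to the nearest integer and
floors at zero; bin 0 is deterministic at m₀ (the processes' zero initial
variance). Population-level sampling of the per-bin marginals reproduces
exactly the moment structure the fitter consumes; simulating correlated
fractional-Brownian paths per lineage would add realism the estimators never
see and is deliberately out of scope.

The default initial load m₀ = 10 matters: with m₀ = 0 and κ·k of order one,
the floor at zero truncates the low-time bins, measurably suppresses their
variance (e.g. 0.64 instead of 1.0 at k = 1 for the white-noise regime) and
makes linear variance growth look convex — enough to flip model selection
toward the power law on a large fraction of white-noise datasets. A founding
lineage that already carries mutations relative to the reference is also the
realistic situation (an emerging variant is never the reference itself), and
m₀ enters the fitted model only as the mean intercept, cancelling out of
every variance. Mutated positions are drawn without replacement and always
changed to a different base, so the pipeline's called substitution count
equals the intended count exactly (round-trip identity). All randomness
flows from a single seed; reruns are bit-identical.

The validation study uses two regimes of 30 trajectories each — white noise
(κ = 0.5, D = 1, α = 1) and subdiffusion (κ = 0.5, D = 1, α = 0.5) — with 20
intervals × 50 samples, exceeding the ≥30-per-bin guidance while keeping the
study to seconds on one core. What passing it shows: the estimators recover
κ to within a few percent and α to within ≈0.05 on average, and AICc selects
the generating model in ~90% of white-noise and ~100% of subdiffusive
replicates (the asymmetry is expected: AICc occasionally rewards the extra
parameter on noise, while genuine curvature is essentially never missed at
this signal-to-noise). What it does not show: robustness to real-data
features the generator omits — correlated sampling of related genomes,
alignment errors, uneven and gappy temporal coverage, per-bin sample sizes
varying over orders of magnitude, indels, or rate shifts over time
(piecewise clocks are out of scope).

## Numerical and design choices

* Degrees of freedom: n−2 (mean fit), n−1 (through-origin null), n−2
  (two-parameter power law).
* σ²₀ is taken from the earliest bin with a *defined* variance, since the
  first bin may hold a single sample.
* Dates must be complete ISO-8601 days; partial dates are dropped and
  counted, never imputed (imputation would inject artificial variance into
  the bins).
* Filters are per-sample and independent, so application order cannot change
  the surviving set; the report attributes each removal to the first failing
  filter in the fixed order length → %N → date → metadata. The %N rule
  removes strictly above the threshold (≤1% N is tolerated at the default);
  ambiguity codes other than N do not count toward it.
* Metadata id/date column names default to `id`/`date` and are configurable;
  the join is exact, case-sensitive string match.
* Sequence input is case-normalized to uppercase with U mapped to T.
* The builtin aligner is deterministic (first optimal alignment); full-run
  determinism holds for fixed inputs, config and seed.

## Known limitations

* A single global clock per category: no lineage segmentation, piecewise
  rates, or time-varying κ.
* CIs are Wald-type (t-multiplier × standard error); no profile-likelihood
  or bootstrap intervals, and no bootstrap model selection.
* The variance-of-variance heteroscedasticity is handled only through the
  sample-size weights w_k, not through a full generalized-least-squares
  error model.
* The builtin aligner is O(L²) in sequence length; for long genomes at scale
  the external MAFFT backend is the practical choice.
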