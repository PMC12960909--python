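# evoclock

Generalized molecular-clock inference from populations of dated genome
sequences.

Classical molecular-clock analyses summarize evolution by a single rate: the
expected number of mutations per unit time. Large genomic-surveillance
collections (thousands of dated sequences of the same lineage) contain more
information than that — in particular, how the *spread* of mutation counts
across the population grows with time. `evoclock` models the per-sample
mutation count `m(t)` relative to a reference genome as a stochastic process
with

```
⟨m(t)⟩      = m₀ + κ·t            (mean: evolution rate κ, initial load m₀)
Var m(t)    = D·t^α               (variance: diffusivity D, exponent α)
```

and asks whether the population diffuses through genotype space like Brownian
motion (`α = 1`, the null model, compatible with a Poissonian clock when
`κ = D`) or like fractional Brownian motion with memory (`α ≠ 1`, the
challenging model; `α < 1` means constrained, subdiffusive evolution). The
two variance models are fitted by weighted least squares — a straight line
through the origin for the null, a Levenberg–Marquardt power law for the
challenging — and compared with the corrected Akaike information criterion

```
AICc_i = n·ln(2π) + n·ln(RSS_i/n) + n + 2p_i + 2p_i(p_i+1)/(n−p_i−1)
```

where `RSS_i` is the weighted residual sum of squares, `p₁ = 1`, `p₂ = 2`,
and each time interval's residual is weighted by `w_k = tanh(N_k/15)` so
sparsely sampled intervals count less. It is intended for anyone analyzing
dated sequence collections — e.g. viral variant surveillance — who wants
rate *and* dispersion parameters with confidence intervals, plus a principled
test for anomalous diffusion.

## Pipeline

`evoclock run` takes a multi-FASTA (first record = reference genome) and a
TSV with sample ids and collection dates, then:

1. joins sequences with metadata and applies quality filters
   (minimum length, ≤1% unresolved `N` bases by default, date range,
   metadata predicates);
2. aligns every sample to the reference and calls mutation events —
   substitutions and indels (one event per contiguous gap run; terminal gap
   runs are treated as incomplete sequencing, not deletions);
3. bins samples into intervals (default 7 days) anchored at the earliest
   collection date and computes per-bin mean, unbiased variance and weight;
4. fits the mean line (κ, m₀), rescales the variance series to start at
   (0, 0), fits both variance models and selects one by AICc.

## Worked example

```
$ evoclock simulate --alpha 0.5 --n-intervals 20 --samples-per-interval 40 \
      --reference-length 500 --seed 11 --out demo_fixture
fixture with 800 samples written to demo_fixture

$ evoclock run demo_fixture/sequences.fasta demo_fixture/metadata.tsv \
      --mutation-type substitutions --plot --out demo_out
substitutions: challenging model | kappa=0.4999/interval CI95=(0.4809, 0.5189) | D=0.9286 | alpha=0.5412 | delta_AICc=5.402
```

The fixture simulates a subdiffusive population with true κ = 0.5 mutations
per week, D = 1 and α = 0.5. The run recovers κ̂ = 0.50 per 7-day interval
with a 95% CI covering the truth, estimates D̂ = 0.93 and α̂ = 0.54, and the
power-law variance model beats the linear one by 5.4 AICc units — correctly
flagging constrained (subdiffusive) evolution. `demo_out/substitutions/`
contains the per-bin statistics TSV, the full fit/selection JSON (point
estimates, 95% CIs, weighted RSS, AICc per model) and a two-panel PDF of the
mean and variance fits; `demo_out/run_config.json` replays the run
bit-identically via `evoclock run --config`.

`evoclock validate` reruns the built-in two-regime simulation study
(white-noise vs. subdiffusive trajectories) and prints selection rates and
parameter-recovery summaries.

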