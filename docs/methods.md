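# Methods

## The observer model

`sifibci` implements a Bayesian causal-inference (BCI) observer for the
sound-induced flash illusion extended to two stimulus dimensions:
**numerosity** (how many flashes/beeps) and **time** (when each stream
starts).  On a bimodal trial the observer receives four noisy internal
measurements —

- numerosity evidence `x_V ~ N(s_V, sigma_V^2)` and `x_A ~ N(s_A, sigma_A^2)`
  around the true counts,
- onset evidence `t_V ~ N(s_Vt, sigma_Vt^2)` and `t_A ~ N(s_At, sigma_At^2)`
  around the true first-stimulus onsets (ms, relative to the onset of the
  first stimulus in the trial) —

and entertains two causal structures: a single shared source (C = 1) or two
independent sources (C = 2).  The two dimensions are conditionally
independent given C, so each structure's likelihood is the product of a
numerosity factor and a temporal factor.  With Gaussian priors over the
latent source (`N(mu_p, sigma_p^2)` for numerosity, `N(mu_tp, sigma_tp^2)`
for onset time) every marginal likelihood integral is available in closed
form:

- C = 1: the evidence pair is jointly Gaussian with common mean `mu` and
  covariance `[[s1^2 + sp^2, sp^2], [sp^2, s2^2 + sp^2]]` (the shared source
  induces the off-diagonal term);
- C = 2: the product of two univariate marginals `N(x_i; mu, s_i^2 + sp^2)`.

The posterior probability of a common cause mixes these factors with the
prior `p_common`:

    p(C=1 | x_V, x_A, t_V, t_A)
      = L_num(C=1) L_t(C=1) p_common /
        [L_num(C=1) L_t(C=1) p_common + L_num(C=2) L_t(C=2) (1 - p_common)]

Conditional estimates are precision-weighted means — of one cue and the
prior under segregation, of both cues and the prior under fusion — and the
reported estimate is the posterior-weighted mix of the two (model
averaging, the readout minimising expected squared error).  The continuous
estimate is mapped onto the three response keys by rounding to the nearest
of {0, 1, 2} (ties up, clamped).  Unisensory trials bypass causal inference
entirely: with one modality absent the causal structure is undefined, so
the present cue is read out through the single-cue precision-weighted
estimate.

### Normalisation of the causal posterior

The package normalises the posterior by the standard Bayes denominator (sum
of the two joint numerators), which guarantees
`p(C=1|·) + p(C=2|·) = 1`.  An alternative denominator — the product of the
per-dimension mixture marginals — is available via
`posterior_common_cause(..., denominator="factorized")` for sensitivity
analyses; that expression is not a normalised posterior (the ratio can
exceed 1, e.g. whenever both dimensional factors individually favour a
common cause), so its output is clipped to [0, 1].  All shipped variants
and all fitting use the standard form.

### Parameters

| parameter  | meaning                                   | units      | default |
|------------|-------------------------------------------|------------|---------|
| `sigma_V`  | visual numerosity noise SD                | numerosity | 0.63    |
| `sigma_A`  | auditory numerosity noise SD              | numerosity | 0.33    |
| `p_common` | prior probability of a common cause       | —          | 0.62    |
| `mu_p`     | numerosity prior mean                     | numerosity | 1.43    |
| `sigma_p`  | numerosity prior SD                       | numerosity | 1.33    |
| `sigma_Vt` | visual onset noise SD                     | ms         | 60      |
| `sigma_At` | auditory onset noise SD                   | ms         | 40      |
| `mu_tp`    | temporal prior mean                       | ms         | 100     |
| `sigma_tp` | temporal prior SD                         | ms         | 500     |

The five numerosity-side parameters are free in fitting; the four temporal
parameters are fixed a priori (observers report only numerosity, so the
temporal dimension is under-constrained by the data).  The defaults above
(`default_observer_params()` plus `FIXED_TEMPORAL`) are representative
group-mean values for human observers in this task and serve as the
generating truth for synthetic cohorts.  Auditory numerosity evidence being
roughly twice as precise as visual is what makes beeps capture flashes —
the fission (1F2B) and fusion (2F1B) illusions — while large temporal
discrepancy withdraws the common-cause belief and releases the capture.

### Model variants

| variant         | free parameters                                  | k | constraint |
|-----------------|--------------------------------------------------|---|------------|
| `bci_2d`        | sigma_V, sigma_A, p_common, sigma_p, mu_p        | 5 | full model |
| `bci_1d`        | same                                             | 5 | temporal likelihood factors fixed at 1 |
| `forced_fusion` | sigma_V, sigma_A, sigma_p, mu_p                  | 4 | causal posterior pinned at 1 |
| `mle_flat`      | sigma_V, sigma_A                                 | 2 | forced fusion without the numerosity prior |

The variants nest exactly: at `p_common = 1` the full model's likelihood is
bit-for-bit the forced-fusion likelihood on the same data and Monte Carlo
seed, and with uninformative onset noise the 2D posterior converges to the
1D posterior.  Note that "uninformative" means enormous *sensory* onset
noise; an enormous temporal *prior* SD is not neutral — under independent
causes the two onsets spread over the prior twice, so widening the prior
actually favours the common-cause structure.

An optional log-normal numerosity likelihood family (evidence log-normal
around the latent source, Gaussian prior truncated to positive sources) is
provided for robustness checks.  It has no closed form and is evaluated by
trapezoidal quadrature on a fixed grid over the source; estimates are
posterior means under the same quadrature.  It is not wired into the
shipped fitting variants.

## The response likelihood and fitting

Responses enter the likelihood as a multinomial over the 3×3 joint
(flash report, beep report) cells per bimodal condition (3 cells for
unisensory conditions): the joint cell preserves the cross-modal response
correlation the model predicts.  Cell probabilities have no closed form for
bimodal trials, so they are approximated by Monte Carlo: `n_mc` (default
10,000) simulated trials per condition, with **common random numbers** —
one fixed block of standard-normal draws per fit, reused for every
parameter proposal.  This makes the simulated likelihood a deterministic,
optimizer-safe function of the parameters (the surface is piecewise
constant at resolution ~1/n_mc, which Nelder-Mead tolerates).  Each cell
probability is floored at `eps = 1e-4` and the table renormalised; the
floor guards `log 0` and acts as a minimal lapse allowance without adding a
free parameter.

Optimisation is Nelder-Mead in a transformed space — a log-scale logistic
for SDs and a plain logistic for `p_common` and `mu_p`, each mapping the
real line onto its bound interval (`sigma_V, sigma_A ∈ [0.05, 5]`,
`sigma_p ∈ [0.1, 10]`, `mu_p ∈ [0, 3]`, `p_common ∈ [0.01, 0.99]`) — with
10 restarts: one from the centre of the box plus Latin-hypercube starts.
An explicit initial simplex (steps of 0.4 in transformed units) is
supplied because the optimizer's default simplex collapses at coordinates
near zero, exactly where the centre start sits.  Convergence failure of
every restart is reported through the `converged` flag.

Two numerical details matter for extreme parameter values: the bivariate
determinant and quadratic form of the common-cause likelihood are expanded
into sums of non-negative terms (`det = v1 v2 + (v1 + v2) vp` and
`quad = v2 d1² + v1 d2² + vp (d1 − d2)²`), because the textbook
`(v1+vp)(v2+vp) − vp²` form cancels catastrophically when the prior
variance dominates; and the hot path computes the posterior through a
log-likelihood-ratio and a single logistic, so `p_common ∈ {0, 1}` yields
exactly 0 or 1 and the nesting identities hold in floating point.

Goodness of fit is `R² = 1 − SS_res/SS_tot` over the stacked vector of
observed response-category proportions (every condition × present modality
× category, 108 entries for the full design) against predicted
probabilities, with `SS_tot` about the grand mean of the observed
proportions.  No standard definition exists for this quantity in the
discrete-report setting; this proportion-vector convention is the package's
choice and is what all reported R² values mean.  `BCIResults.rsquared`
uses the fit's own prediction tables; `BCIResults.rsquared_at()` recomputes
with a larger prediction sample (default 100,000) to strip Monte Carlo
noise from the predictions.

BIC is `k ln n − 2 log L` with `n` the number of trials (200 in the default
design) and `k` the variant's free-parameter count.  Group comparison
reports per-observer BIC, group means/SEs, and Bonferroni-corrected paired
t-tests of the reference variant against each alternative.

## The synthetic-data generator

`build_design()` reproduces the study design: 4 bimodal flash/beep pairings
(1F1B, 1F2B, 2F1B, 2F2B) × 4 SOAs (0, 150, 300, 500 ms) plus 4 unisensory
conditions (1F, 2F, 1B, 2B) — 20 conditions × 10 repetitions = 200 trials,
pseudorandomised per seed.  Which modality leads at non-zero SOA is an
explicit `lead` field (default `visual_first`: the lagging auditory stream
starts `soa` ms after the visual one); the leading stream defines time 0.
Only first onsets enter the model; the 50-ms inter-stimulus interval
between double stimuli is design metadata.  `generate_cohort()` spawns one
deterministic random stream per observer from a master seed and simulates
every trial through the full generative model; optional between-observer
parameter heterogeneity draws each observer's parameters from truncated
normals around the base values.

What the generator does *not* emulate: lapses and key errors, attention or
fatigue drift over the session, sequential (inter-trial) dependencies,
response biases beyond the numerosity prior, and any deviation from the
Gaussian evidence model.  Passing recovery tests therefore certify the
estimation machinery under the model's own assumptions — they do not
certify that human data satisfy those assumptions.

## Validation experiments and problem sizes

The test suite validates, end to end:

- closed-form likelihoods and the causal posterior against adaptive
  quadrature of the defining integrals (absolute agreement < 1e-8 over
  1,000 randomised parameter/evidence draws);
- parameter recovery: 8 synthetic observers, 200 trials each, generated at
  the default parameters and refit (`n_mc` 10,000, 10 restarts); cohort
  means of all five free parameters must return the truth within
  max(20 % relative, 2 cohort SEs);
- self-fit variance explained: mean R² over the same cohort (predictions
  at 100,000 draws) at least 0.93;
- model recovery: BIC identifies the generating variant on 12-observer
  cohorts (reduced settings: `n_mc` 5,000, 4 restarts), and does not
  spuriously prefer the full model on forced-fusion data by more than the
  one-parameter penalty ln 200;
- the qualitative illusion signature: flash-report accuracy in 1F2B and
  2F1B non-decreasing in SOA (100,000 draws per condition, common random
  numbers across SOA levels to sharpen the comparison).

`scripts/acceptance.py` repeats the recovery experiment at the study's
cohort size (24 observers) and reports the cohort-mean recovered `sigma_V`
and mean self-fit R².  At these sizes the full test suite runs in ~4–5 min
and the script in ~9 min on one CPU.

## Known limitations

- Monte Carlo cell probabilities give the likelihood a granularity of
  ~1/n_mc; estimates inherit a small jitter (visible mostly in `sigma_p`
  and `mu_p`, which are weakly identified from 200 trials of 0–2 counts).
  Recovered `sigma_V` runs a few percent high at the default design size.
- The discrete 0/1/2 readout is deterministic rounding; no lapse/guessing
  parameter is modelled beyond the probability floor.
- The R² definition is a package convention (see above); other conventions
  (e.g. squared correlation) would give different absolute values.
- Paired t-tests use df = number of observers − 1 and assume exchangeable
  per-observer BIC differences.
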