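# sifibci

Bayesian causal inference across numerosity and time for the
**sound-induced flash illusion** (SiFI): simulate flash-beep numerosity
experiments from a parameterized ideal observer, fit the observer model to
trial-level report data by maximum likelihood, and compare nested model
variants by BIC.

## The problem

When a brief flash is paired with a discrepant number of beeps, observers
often report the number of *beeps* as the number of flashes — one flash
with two beeps is seen as two flashes (fission), two flashes with one beep
as one (fusion).  Whether the brain merges or separates the two streams
should depend on whether it infers that they came from a single event, and
that inference should weigh evidence from *every* available stimulus
dimension: not just how many flashes and beeps occurred, but also whether
the streams started at the same time.

`sifibci` implements this as a two-dimensional Bayesian causal inference
(BCI) observer.  On each bimodal trial the observer receives noisy
numerosity evidence `x_V, x_A` and noisy onset evidence `t_V, t_A`,

    x_V ~ N(s_V, σ_V²)    x_A ~ N(s_A, σ_A²)
    t_V ~ N(s_Vt, σ_Vt²)  t_A ~ N(s_At, σ_At²)

computes the posterior probability that the streams share a common cause,

    p(C=1 | x_V, x_A, t_V, t_A) ∝ p(x_V, x_A | C=1) p(t_V, t_A | C=1) p(C=1),

(all marginal likelihoods in closed Gaussian form), and reports the
model-averaged numerosity estimate

    ŝ_A = p(C=1|·) ŝ(A, C=1) + p(C=2|·) ŝ(A, C=2),

rounded to the nearest of the response keys {0, 1, 2}.  Five parameters are
free — the sensory noise SDs σ_V and σ_A, the common-cause prior p_common,
and the numerosity prior (μ_p, σ_p) — while the four temporal parameters
(σ_Vt = 60, σ_At = 40, μ_tp = 100, σ_tp = 500 ms) are fixed a priori.
Four nested variants are shipped: the full 2D model, a numerosity-only 1D
model, forced fusion, and flat-prior cue combination (MLE).  See
`docs/methods.md` for the complete model account.

The intended users are researchers in multisensory perception who want a
reproducible reference implementation of multidimensional BCI for
discrete-report paradigms: to simulate predictions, run parameter- and
model-recovery studies, or fit their own flash-beep datasets (flat CSV,
one row per trial).

## Worked example

```python
import sifibci as sb

# simulate one observer from the reference parameters over the 200-trial design
design = sb.build_design(seed=0)
spec = sb.CohortSpec(n_observers=1, master_seed=0)
observer = sb.generate_cohort(spec, design)[0]

# fit the full two-dimensional causal-inference model
model = sb.FlashBeepBCI(observer, variant="bci_2d",
                        config=sb.FitConfig(n_mc=10_000, restarts=4, seed=42))
result = model.fit()
print(result.summary())
```

```
Flash-beep causal-inference model fit
======================================================
Observer:        obs01
Variant:         bci_2d (causal inference over numerosity and timing)
Trials:          200
Free parameters: 5
Log-likelihood:  -159.830
BIC:             346.152
R-squared:       0.9581
Converged:       True   (restarts=4, n_mc=10000, seed=42)
------------------------------------------------------
parameter       estimate
sigma_V           0.5894
sigma_A           0.3105
p_common          0.5954
sigma_p           1.5812
mu_p              1.4170
------------------------------------------------------
Fixed temporal parameters (ms): sigma_Vt=60, sigma_At=40, mu_tp=100, sigma_tp=500
```

The observer was generated at σ_V = 0.63, σ_A = 0.33, p_common = 0.62,
σ_p = 1.33, μ_p = 1.43; the fit recovers these within the sampling noise of
a single 200-trial session, and R² = 0.958 says the fitted model reproduces
95.8 % of the variance in this observer's response-category proportions.
The behavioural signature is visible in the raw data:

```python
acc = sb.accuracy_summary(observer)
print(acc[(acc.n_flashes == 1) & (acc.n_beeps == 2)]
      [["condition", "flash_accuracy", "beep_accuracy"]].to_string(index=False))
```

```
  condition  flash_accuracy  beep_accuracy
  1F2B_soa0             0.3            0.9
1F2B_soa150             0.5            1.0
1F2B_soa300             0.5            1.0
1F2B_soa500             0.6            0.9
```

At simultaneity the fission illusion drives flash accuracy to 0.3 (most
single flashes are reported as two); as the onset asynchrony grows the
causal posterior withdraws and flash accuracy recovers, while beep reports
stay accurate throughout — auditory numerosity evidence is about twice as
precise as visual.

The same workflow is scriptable from the shell:

```bash
sifibci simulate --out runs/sim --n-observers 24 --seed 0
sifibci fit      --data runs/sim --out runs/fits --variant bci_2d
sifibci compare  --data runs/sim --out runs/cmp
sifibci recover  --out runs/rec --n-observers 8 --seed 1
```

Every run writes a `manifest.json` (configuration, seeds, package version)
from which its outputs can be regenerated exactly.

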