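# glyctest

Model-based evaluation of the **glycerol test** for Menière's disease.

The glycerol test probes whether the hearing loss of a hydropic inner ear
is partially reversible: after oral glycerol intake, a transient
improvement of the low-frequency hearing thresholds a few hours later is
read as a positive result.  The test statistic is the **mean threshold
reduction (MTR)** — the mean improvement in dB across the five lowest
audiometric frequencies (125–1500 Hz) between the pre-test audiogram and
the one taken four hours after intake.  Because audiometric thresholds are
measured in 5 dB steps, the MTR is always an integer.

The catch is that audiometry is noisy: the distribution of observed MTRs
largely reflects measurement error rather than the glycerol effect.
`glyctest` implements a simple generative model that separates the two
and then asks how good the test actually is:

* **True-effect template.**  A fraction *p₀* of patients shows no
  glycerol-induced effect; the rest have a true MTR following a
  *flattened* gamma distribution (shape 2, scale *θ*): the rising flank
  of the gamma density on [0, θ] is replaced by a constant plateau of
  height 1/(3θ) and the result renormalized.  The continuous density is
  discretized to the integer MTR lattice, and all mass at MTR ≤ 1 dB is
  pooled and spread equally over {−1, 0, 1} dB.
* **Convolution with measurement error.**  The observed MTR distribution
  is *f* = *g* ∗ *h*, the template *g* convolved with a zero-mean
  Gaussian error *h* whose SD σ is estimated from test-retest data (the
  hour-3 vs hour-4 audiogram pair, where the glycerol effect has already
  saturated).
* **Least-squares CDF fit.**  (p₀, θ) are fitted by a derivative-free
  simplex search minimizing the squared differences between model and
  empirical cumulative distributions, with σ held fixed.
* **Biased-audiometry simulator.**  The test-retest error histogram shows
  an excess of exact zeros; the package reproduces it by simulating an
  investigator who ignores a 5 dB change with probability 0.8 and shrinks
  a 10 dB change to 5 dB with probability 0.3, given a per-threshold
  estimation SD of 4.43 dB.
* **Monte-Carlo ROC analysis.**  With a *virtual gold standard* (disease
  positive iff the true MTR ≥ τ, default 2 dB), true MTRs are sampled
  from the fitted template, observed through Gaussian noise, and the
  ROC curve and its area (AUC) are computed — alongside an exact
  closed-form AUC, ``Σᵢⱼ P(i)P(j)Φ((tᵢ−tⱼ)/(σ√2))``, used as an oracle.

A synthetic-cohort generator produces serial audiograms (pre-test plus
hourly audiograms, saturating effect time course, 5 dB quantization,
optional investigator bias, hidden ground truth), so the entire chain is
testable without clinical data.

## Worked example

```python
import numpy as np
from glyctest import (
    CohortConfig, ErrorModel, GoldStandard, PipelineConfig,
    auc_closed_form, build_template, generate_cohort, run_full_analysis, run_roc,
)
from glyctest import presets

# the template fitted on the 354-case reference cohort (all patients)
params = presets.REFERENCE_FITS["all"]          # p0 = 0.378, theta = 3.89 dB
template = build_template(params)
print("P(true MTR <= 1) =", round(template.prob_at_most(1), 3))

# how accurate is the test at the current error level (sigma = 2.45 dB)?
auc = run_roc(params, ErrorModel(2.45), GoldStandard(2.0), n=100_000, seed=1).auc
print("AUC =", round(auc, 3))
print("closed form =", round(auc_closed_form(params, ErrorModel(2.45), GoldStandard(2.0)), 3))

# full chain on a synthetic cohort generated from the same truth
cohort = generate_cohort(CohortConfig(n_cases=2000, seed=1,
    template_params_by_group={"all": params}))
report = run_full_analysis(cohort, PipelineConfig(sigma_override=2.45, roc_n=20_000, seed=1))
f = report.fits["all"]
print(f"error SD = {report.error_summary['sd']:.2f} dB")
print(f"fitted p0 = {f['p0']:.3f}, theta = {f['theta']:.2f} dB")
```

Output:

```
P(true MTR <= 1) = 0.458
AUC = 0.926
closed form = 0.924
error SD = 2.59 dB
fitted p0 = 0.359, theta = 3.86 dB
```

So under this template almost every other patient shows no or almost no
true effect, yet the test distinguishes responders (true MTR ≥ 2 dB) from
non-responders with an AUC above 0.9 — "rather high accuracy" in the
usual classification of diagnostic tests.  On the synthetic cohort the
fit recovers the generating parameters; the error SD estimated from the
hour-3/hour-4 pair is a few percent above √(2/5)·σ_single because of the
5 dB quantization.

## Command line

```sh
glyctest simulate --out sim --n-cases 354 --seed 1
glyctest full --cases sim/cases.csv --sigma 2.45 --out analysis
glyctest roc --preset good --sigma 1.2 --tau 2 --out roc_good
glyctest error-analysis --simulate-bias --n 100000 --out errors
```

The canonical case CSV has columns
`case_id,ear,hour,freq_hz,threshold_db` (ear L/R, hour 0–4, thresholds in
multiples of 5 dB); `glyctest full` accepts any such file.

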