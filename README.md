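# dfcstates

Dynamic functional connectivity (dFC) state analysis of emotion-regulation
brain networks, for researchers studying how the interplay of large-scale
networks reconfigures in major depressive disorder (MDD) and responds to
antidepressant treatment.

Resting-state fMRI time series from 36 seed regions (four large-scale
networks involved in emotion regulation) are analysed with a
sliding-window approach: within each 22-TR Gaussian-tapered window the
inter-regional covariance is estimated with the graphical LASSO

&nbsp;&nbsp;&nbsp;&nbsp;Θ̂ = argmax<sub>Θ≻0</sub> log det Θ − tr(SΘ) − λ‖Θ‖₁,off

with λ chosen per subject by repeated 5-fold cross-validation, and the
regularised correlations are Fisher z-transformed. Windows from all
participants are clustered with k-means under the correlation distance
d(x, c) = 1 − corr(x, c) (elbow criterion over k = 2–9, 100 restarts) into
recurring **dFC states**. Per subject and state the package computes the
occurrence proportion, the dFC strength (mean z-FC of the state's
windows), the average weighted local efficiency

&nbsp;&nbsp;&nbsp;&nbsp;E<sub>loc</sub>(i) = Σ<sub>j≠h∈N(i)</sub> (w<sub>ij</sub> w<sub>ih</sub> / d<sub>jh</sub>(N<sub>i</sub>))<sup>1/3</sup> / (k<sub>i</sub>(k<sub>i</sub>−1)),

and static FC. Group comparisons use a GLM with age, sex and mean
framewise displacement as covariates (BH-FDR across each test family);
post-treatment windows are re-assigned to baseline states by maximum
correlation and compared with paired t-tests split by treatment response
(HAMD reduction rate > 50%). Baseline state-dependent FC predicts the
reduction rate with leave-one-out cross-validated multivariate regression,
assessed by permutation (10,000 shuffles, 95th-percentile rule).

Because no raw clinical fMRI ships with the package, a first-class
synthetic cohort generator (`dfcstates.simulate`) produces
hidden-Markov state-switching BOLD-like cohorts with planted group
differences (state occupancy tilts, one attenuated amygdala–cuneus edge)
and a planted outcome trait — ground truth for validating every stage.

## Worked example

```python
from dfcstates import (
    SyntheticCohortSpec, simulate_cohort, PipelineConfig,
    run_baseline, run_longitudinal, run_prediction,
)

spec = SyntheticCohortSpec(n_mdd=10, n_hc=10, n_post=10, seed=7)
cohort = simulate_cohort(spec)
config = PipelineConfig(lambda_fixed=0.1, k_fixed=4, n_init=20,
                        n_perm=1000, seed=1)

base = run_baseline(cohort.timeseries, cohort.clinical, config)
for r in base.occupancy_tests:
    print(f"{r.measure}: t = {r.t_statistic:+.2f}, p = {r.p_value:.3f}")

longi = run_longitudinal(cohort.timeseries, cohort.clinical, base, config)
preds = run_prediction(base, cohort.clinical, config, states=[2])
```

Output (abridged):

```
states: k = 4
  occurrence_state1: t = -0.27, p = 0.792, q = 0.792
  occurrence_state2: t = -2.30, p = 0.036, q = 0.073
  occurrence_state3: t = +2.64, p = 0.018, q = 0.073
  occurrence_state4: t = +1.16, p = 0.266, q = 0.355
  responders, state 2 occurrence: t = +2.38, p = 0.076
  responders, state 3 occurrence: t = -2.27, p = 0.086
  state2: r = +0.770, permutation p = 0.015, significant = True
  sfc:    r = +0.160, permutation p = 0.299, significant = False
```

Patients occupy one state less and another more than controls (the
planted occupancy tilt; states are numbered by overall occurrence, so
pipeline state numbers need not match planted ones), responders trend
back toward control occupancy after treatment, and the state-specific FC
predicts the outcome while whole-scan static FC does not. At this small
demonstration size (10 + 10 subjects) the FDR-corrected q-values remain
above 0.05 — detection power at the study's reference size (20 + 20) is
quantified by `dfcstates.studies` and the acceptance suite instead.

A thin CLI mirrors the stages:

```bash
dfcstates simulate --out data/ --n-mdd 20 --n-hc 20 --seed 0
dfcstates run-all --data data/ --out results/ --lambda-fixed 0.1 --k-fixed 4
```

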