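# mrds-nmix

Abundance estimation for grouped animals when **both** groups and the
individuals inside detected groups are imperfectly detected.

Surveys of grouped animals (elk herds, cetacean pods, waterbird
colonies) usually correct for missed groups — via distance sampling,
double-observer protocols, or their combination (mark–recapture–
distance-sampling, MRDS) — while treating the recorded group size as
exact. Ground-truthing studies repeatedly find that 10–30% of
individuals in detected groups are missed, so abundance estimates built
on recorded sizes are biased low. This package implements the
MRDS-Nmix estimator, which folds an N-mixture count model into the MRDS
framework: each observer records an independent count of every detected
group, true group size becomes a latent variable, and the counts are
zero-truncated binomial thinnings of it.

## Model

For group *i* with two conditionally independent observers *j*:

```
d_i ~ Uniform(0, w)                     distance to transect
z_i ~ Bernoulli(Ω)                      data-augmentation membership
n_i ~ ZTPoisson(λ)                      true group size
log σ_i = β0 + β1 log n_i               size effect on detectability
p_i  = p0 · z_i · exp(−d_i²/(2σ_i²))    group detection
y_ij ~ Bernoulli(p_i)                   detection history
r_i  = r0 · exp(−d_i²/(2τ²))            individual detection
c_ij ~ ZTBinomial(r_i, n_i)             observer count (where y_ij = 1)
```

Total abundance is the derived quantity `N = Σ z_i n_i`. Fitting is by
Metropolis-within-Gibbs MCMC over the augmented state (compiled with
numba); a constant-`r` variant and the standard reduced MRDS model
(recorded size treated as exact) share the same interface. See
`docs/methods.md` for priors, sampler details and limitations.

## Worked example

Simulate one survey under study scenario 2 (mean group size 1, strong
distance decay of individual detection) and fit both estimators:

```sh
$ mrds-nmix simulate --scenario 2 --seed 7 --out survey.csv
scenario 2: 126 of 200 groups detected, true abundance 320

$ mrds-nmix fit --data survey.csv --variant mrds_nmix_distance_r --seed 1
N: posterior mean 341.7, 95% CI (287, 412); converged=True

$ mrds-nmix fit --data survey.csv --variant mrds_reduced --seed 1
N: posterior mean 278.5, 95% CI (239, 325); converged=True
```

The survey found 126 of 200 groups and, because individual detection
falls with distance, the recorded sizes under-count the 320 animals
actually present. The MRDS-Nmix posterior mean (341.7) holds the truth
well inside its credible interval; the reduced MRDS model, which trusts
the recorded sizes, lands 13% low (278.5) with an interval that barely
reaches the truth. Over many replicates the reduced model is biased low
by roughly the uncounted fraction of individuals (15-28% in the harder
scenarios) while MRDS-Nmix stays within a few percent.

The same comparison at scale (this is the bias/coverage/RMSE study;
with `-R 200` it is an overnight run, scaled-down runs report
Monte-Carlo standard errors alongside every metric):

```sh
mrds-nmix study --scenarios 2,12 -R 50 --seed 0 \
    --records-out records.csv --summary-out summary.csv
```

Python API equivalent:

```python
import numpy as np, mrds_nmix as mx

scn = mx.scenario_table()[1]            # scenario 2
data, truth = mx.simulate_dataset(scn, np.random.default_rng(7))
fit = mx.fit(data, mx.ModelConfig(variant="mrds_nmix_distance_r"),
             mx.SamplerConfig(seed=1))
print(fit.point, (fit.ci_low, fit.ci_high), truth.n_total)
fit.summary()                           # posterior means, R-hat, ESS
```

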