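# navcoc

**Hierarchical Bayes estimation of animal navigation ability from satellite
tracks.**

How precisely does a migrating animal know where it is? If an animal is
steering for the great-circle route between its departure and destination,
its day-to-day *cross-track deviations* from that route carry the answer.
`navcoc` takes raw Argos-style satellite fixes all the way to a posterior
distribution for each animal's **circle of confusion** — the radius around
its position within which it cannot resolve its own location from indirect
cues — and for the population it belongs to.

The pipeline, aimed at movement ecologists with multi-animal tag datasets:

1. **Regularize** irregular multi-fix-per-day tracks to one robust location
   per 24 h window — Minimum Covariance Determinant (MCD) location for
   windows with ≥ 4 fixes, coordinate-wise median below that — so Argos
   outliers never reach the model.
2. **Segment** the migratory leg: start at the smoothed travel-rate peak
   (first post-tagging week excluded), end at the first persistent reversal
   of longitude change; manual per-animal bounds are first-class.
3. **Deviations**: signed great-circle cross-track distance of each daily
   location from the route (positive = left of the direction of travel).
4. **Fit** the hierarchical state-space model by MCMC (a Gibbs sampler with
   exact forward-filtering backward-sampling; no external MCMC engine):

       y_{j,t} = x_{j,t} + eps_{j,t},           eps ~ N(0, sigma_eps^2)
       x_{j,t} = gamma_j x_{j,t-1} + sigma_j e_t,  e_t ~ t_nu

       CoC_j = sigma_j / sqrt(1 - gamma_j^2)

   with gamma_j = 2 Beta(a, b) - 1 and sigma_j half-normal across animals,
   heavy-tailed t process errors to absorb foraging detours and current
   deflections, and an informative prior on the measurement SD (2 ± 0.02
   km). Outputs include per-animal CoC, the hierarchical mean, and the
   predictive CoC for an unobserved animal.
5. **Compare** competing fits (sexes pooled vs separate; full track vs
   after a current crossing) by the minimum posterior predictive loss
   statistic `D_k = P + k/(k+1) G` under squared-error loss.

A synthetic-data module generates full Argos-like tracks with known truth
(AR(1)-t deviations, outliers, dwell phases, optional mid-track drift
events), so every stage is testable without any deposited tracking data.

## Worked example

Simulate six animals with known navigation ability, fit the hierarchical
model, and compare:

```python
import numpy as np
from navcoc import (SimulationSpec, simulate_population,
                    CircleOfConfusionModel, coc_interval)

pop = simulate_population(SimulationSpec(n_per_group=3, T=90, seed=7))
model = CircleOfConfusionModel(grouping="common", n_chains=2,
                               n_iter=4000, n_burnin=2000, thin=2,
                               seed=42).fit(pop["series"])
print(model.summary_.round(2))
```

```
             2.5%     50%   97.5%
parameter
coc_mean    58.92   74.77  104.71
coc_pred*   31.15   71.85  158.76
a           49.67  281.99  488.83
b            1.80    8.03   16.89
theta       13.41   23.72   29.63
tau          1.06    4.46   21.06
sigma_eps    1.96    2.00    2.04
nu           4.28    6.83   20.44
coc[T00]    68.19   95.23  157.14
gamma[T00]   0.94    0.97    0.99
sigma[T00]  19.98   24.14   29.23
...
```

`coc_mean` is the population mean circle of confusion (posterior median
74.8 km here — these animals cannot place themselves more precisely than
~75 km, and 1.96 × CoC ≈ 147 km is the radius of their 95% positional
interval). `coc_pred*` is the predictive distribution for an unobserved
animal — wider, since it adds between-animal variation. Per-animal
medians recover the simulated truth to within the precision a 90-day
series allows (e.g. `T00`: true 97.4 km, estimated 95.2 km); `sigma_eps`
sits at its informative prior and `nu ≈ 4-7` reflects the heavy-tailed
shocks the data were generated with.

Model comparison between pooled and sex-separated hierarchies:

```python
from navcoc.compare import posterior_predictive_replicates, mppl, select_model

results = {}
for name, grouping in (("common", "common"), ("separate", "by_sex")):
    m = CircleOfConfusionModel(grouping=grouping, n_chains=2, n_iter=4000,
                               n_burnin=2000, thin=2, seed=42).fit(pop["series"])
    mu, v, y = posterior_predictive_replicates(m.samples_, pop["series"], seed=0)
    results[name] = mppl(mu, v, y)
select_model(results)       # smallest D_inf wins; ranks checked across k
```

The same steps are available from the shell:

```bash
navcoc simulate --seed 1 --out fixes.csv --truth truth.csv
navcoc regularize --input fixes.csv --step-hours 24 --out daily.csv
navcoc segment --daily daily.csv --out bounds.csv
navcoc deviations --daily daily.csv --bounds bounds.csv --out dev.csv
navcoc fit --deviations dev.csv --grouping common --seed 1 --out posterior.csv
```

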