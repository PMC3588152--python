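# commstab

Statistical analysis of **portfolio effects** — the tendency for the total
abundance of a community to be more stable over time than its constituent
populations — and of the **diversity–stability relationship (DSR)** that
links species richness to community stability. The package is for
community ecologists analysing species-by-time abundance tables and for
theoreticians exploring how asynchrony, overyielding, mean–variance
scaling and evenness jointly shape the DSR.

## The model

A community of *n* species is treated as a set of stationary random
variables, summarised by the vector of temporal mean abundances
**m** = (m₁, …, mₙ) and the temporal variance–covariance matrix **V**.
Community synchrony is measured with the synchrony index

φ = v_c / (Σᵢ √vᵢᵢ)² ,  v_c = Σᵢⱼ vᵢⱼ ,

the variance of total abundance divided by what it would be under perfect
synchrony. φ always lies in [0, 1], at any richness. Writing
CV_c = √v_c / M for the community CV (M = Σᵢ mᵢ) and
CV̄_s = Σᵢ √vᵢᵢ / M for the abundance-weighted mean species CV, the exact
identity

**CV_c = √φ · CV̄_s**

holds for *any* means, variances and correlations: community variability
is the product of a synchrony term and a weighted population-variability
term. Adding Taylor's power law vᵢ = a·mᵢᵇ and the overyielding law
mₙ(i) = m₁(i)/nˣ factorises the population term further,

CV_c(n) = √φ · n^{x(2−b)/2} · √a Σᵢ m₁(i)^{b/2} / Σᵢ m₁(i),

separating a diversity-driven *mean-abundance effect* n^{x(2−b)/2} from a
diversity-independent average single-species variability. When all
species share a variance, φ has the closed form
φ = (1 + (n−1)ρ̄)/n in terms of the mean pairwise correlation ρ̄.

The simulator assembles communities with lognormal mean abundances
(unevenness controlled by the log-scale σ), Taylor-law variances, and
random correlation matrices drawn through a hyperspherical (Cholesky-
angle) parameterisation with angles uniform on [0, π], which makes the
expected mean pairwise correlation zero at every richness and evenness.

## Worked example

```python
import numpy as np
from commstab import CommunityStability, ScalingParams, theoretical_moments, simulate_timeseries

# a 4-species community whose variances follow Taylor's law (a=1, b=2)
# and whose pairwise correlations are all 0.1
moments = theoretical_moments(4, ScalingParams(a=1, b=2, x=0),
                              m1=[1.0, 2.0, 3.0, 4.0], correlation=0.1)
series = simulate_timeseries(moments, T=500, rng=np.random.default_rng(1))

res = CommunityStability(series).fit()
print(res.summary())
```

prints

```
Community Stability Results
============================================
No. species                                4
No. time points                          500
Synchrony index (phi)                 0.3671
Mean pairwise correlation             0.1067
Community CV                          0.5913
Weighted population CV                0.9760
Total mean abundance                 10.3760
Evenness (E_var)                      0.8323
--------------------------------------------
Taylor power law  v = a * m^b
  a                                   0.9029
  b                                   2.0495
  R-squared                           0.9902
============================================
```

The estimated synchrony index 0.367 sits near its equal-variance
prediction (1 + 3·0.1)/4 = 0.325 plus sampling noise; the community CV
0.591 equals √0.3671 × 0.976, the identity above; and the Taylor fit
recovers the generating exponent b = 2 from 500 time points. The same
analysis runs from the shell on a CSV:

```bash
dsr estimate --input abundances.csv --taylor --json
dsr theory --n-grid 2,8 --rho-bar 0.2          # phi = 0.6 and 0.3
dsr simulate --sigma 2 --b 1.5 --replicates 200 --output out.csv
dsr experiment evenness-synchrony --seed 1 --output panel.csv
```

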