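# soilstruct

Analysis pipeline for soil physicochemical data from rock-amendment field
trials (enhanced mineral weathering with crushed basalt, liming): soil
water retention and hydraulic conductivity model fitting, a
Kullback-Leibler pore-structure index, aggregate organic-carbon
accounting, and amendment dilution mass balance.

## Who this is for

Soil physicists and biogeochemists who measure water retention
(evaporation method plus dew-point dry-range points), wet-sieved
aggregate fractions with organic carbon, particle-size distributions and
basic soil chemistry on amendment trials, and want a reproducible,
scriptable path from those laboratory tables to fitted hydraulic
parameters, structure indices, enrichment factors and dilution-corrected
concentrations.

## The models

**Bimodal Kosugi retention curve.** Water content at suction head *h*
(cm) is a two-domain lognormal mixture

θ(h) = θr + w(θs−θr)·½erfc[ln(h/h_m1)/(σ1√2)] + (1−w)(θs−θr)·½erfc[ln(h/h_m2)/(σ2√2)]

with residual/saturated contents θr, θs, domain weight w, median heads
h_m1, h_m2 and spreads σ1, σ2. The matching Mualem-type conductivity
curve K(h) = Ks·Se^τ·[a·erfc(σ1/√2 + erfc⁻¹(2Se₁)) + b·erfc(σ2/√2 +
erfc⁻¹(2Se₂))]²/(4(a+b)²) adds Ks and a tortuosity exponent τ, with
a = (w/h_m1)·e^{σ1²/2}, b = ((1−w)/h_m2)·e^{σ2²/2}. Fitting is bounded
nonlinear least squares from a seeded Latin-hypercube multistart.

**KL structure index.** The Young-Laplace relation r [cm] = 0.149/h maps
the fitted retention curve to a pore-radius density p(r); the same
texture without structural pores gives a reference density q(r) (built
from the cumulative particle-size distribution and refitted with the
same model, θs fixed at 0.30). The index is

KLD = ∫ p(r) ln[p(r)/q(r)] dr over r ∈ [0.1, 1490] μm,

larger meaning a pore system further from single-grain packing, i.e.
more developed structure.

**Aggregate OC enrichment.** E_OC = OC_class/OC_bulk per wet-sieving
class (>500, 250–500, 53–250, <53 μm), on sand-corrected mass fractions.

**Amendment dilution.** B = ΣM_rock/(M_soil + ΣM_rock) over the
incorporation depth; concentrations are corrected as Ĉ = C(1+B)
(exact de-mixing Ĉ = C/(1−B) available), and rock grain-size classes are
mapped to aggregate classes for per-class dilution.

## Worked example

```python
import numpy as np
from soilstruct import (KosugiBimodalParams, fit_kosugi_bimodal, water_points,
                        psd_from_retention, reference_psd, kl_divergence,
                        ReferenceSoilSpec, basalt_contribution,
                        AmendmentSchedule, Application)
from soilstruct.synthetic import simulate_retention_dataset

truth = KosugiBimodalParams(theta_r=0.05, theta_s=0.50, w=0.7, hm1=50.0,
                            sigma1=0.8, hm2=2000.0, sigma2=1.2)
ret = simulate_retention_dataset(truth, n_points=100, noise_sd=0.003, seed=1)
fit = fit_kosugi_bimodal(ret)
wp = water_points(fit.params, bulk_density=1.32)

spec = ReferenceSoilSpec(
    size_um=np.array([0.5, 2.0, 10.0, 53.0, 200.0, 2000.0]),
    cum_mass_fraction=np.array([0.04, 0.11, 0.40, 0.76, 0.89, 1.0]),
    theta_r_fixed=fit.params.theta_r)
q, _ = reference_psd(spec)
kld = kl_divergence(psd_from_retention(fit.params), q)

apps = (tuple(Application(2016+i, 50.0, "Blue Ridge", (0.06,0.31,0.27,0.36))
              for i in range(4))
        + tuple(Application(2020+i, 40.0, "Pioneer Valley", (0.06,0.17,0.38,0.39))
                for i in range(2)))
B = basalt_contribution(AmendmentSchedule(applications=apps))
```

prints (via the obvious `print` statements):

```
RMSE theta = 0.0025
fitted: theta_r=0.049 theta_s=0.500 w=0.704 hm1=50.2 sigma1=0.807 hm2=2046 sigma2=1.164
Fc = 30.6 vol-%  PWP = 5.5 vol-%  Wa = 25.1 vol-%  phi = 0.50
KL structure index = 0.565
basalt contribution B = 0.100;  corrected OC for 15.0 mg/g = 16.50 mg/g
```

The fit recovers the generating parameters from noisy data with a
water-content RMSE below measurement noise; field capacity (pF 1.8),
wilting point (pF 4.2) and plant-available water are read off the fitted
curve in vol-%; the structure index is positive because the synthetic
soil's coarse structural pore domain has no counterpart in its
texture-only reference; and six annual basalt applications (4 × 50 +
2 × 40 t ha⁻¹) worked into 18 cm of soil at bulk density 1.4 g cm⁻³
make up 10% of the amended mass, so a measured 15.0 mg g⁻¹ OC corrects
to 16.50 mg g⁻¹.

A full synthetic trial (3 treatments × 2 depths × 3 blocks) and the
chained pipeline are available from the command line:

```
soilstruct simulate --seed 1 --out-dir trial/
soilstruct pipeline --input-dir trial/ --output-dir results/
```

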