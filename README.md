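# pulsetox

Dose–response and recuperation analysis for **pulsed pesticide exposure in
bumble-bee micro-colonies**.

Trace residues of neonicotinoid insecticides such as imidacloprid occur in
the nectar and pollen of treated crops, and dietary exposure at parts-per-
billion levels suppresses brood production (eggs + larvae) in *Bombus
terrestris*. Because mass-flowering crops bloom for only a few weeks, a
realistic exposure is *pulsed*: a period feeding on contaminated syrup
("on dose") followed by a clean period ("off dose") during which colonies
may recuperate. `pulsetox` implements the statistical machinery for this
design end to end, for ecotoxicologists who want to fit, invert and report
such dose–response relationships — or to simulate the design when planning
a study.

## The model

Brood counts per colony are overdispersed Poisson with a lognormal colony
random effect:

```
y_i ~ Poisson(μ_i),   log μ_i = α + β·log10(d_i + 1) + λ_i,   λ_i ~ N(0, σ_λ²)
```

where `d_i` is the dietary dosage in µg kg⁻¹ syrup (mass ppb). The model is
fitted by MCMC (adaptive Metropolis-within-Gibbs with interweaving; vague
priors dominated by the likelihood). The *median-colony* curve
`exp(α + β·log10(d+1))` supports closed-form effect concentrations,

```
EC_p = 10^( ln(1 − p/100) / β ) − 1 ,
```

pointwise 95% credible bands over the posterior draws of (α, β), and
Table-style percent-reduction reports. Recuperation is quantified per
colony as `ΔX = X_off − X_on` and tested for dose dependence with Spearman
rank correlation (exact permutation p for small n); feeding endpoints are
fitted with a fixed-bottom log-logistic model; partial Pearson correlation
relates brood to food intake while controlling for dosage.

A synthetic-data generator reproduces the full study design — nine dosages
by serial dilution (factor 0.4 from a 125 µg L⁻¹ stock, syrup density
1.27 kg L⁻¹, i.e. 98.43 … 0.06 ppb plus control), six colonies per level in
two trials, 14-day on/off periods — so every stage is testable without any
raw data.

## Worked example

```python
import pulsetox as pt

# Closed-form effect concentrations from the reported best-fit curves
print(pt.ec(pt.BROOD_ON_DOSE, 50))       # EC50 = 1.44 ppb
print(pt.ec(pt.BROOD_ON_DOSE, 10))       # EC10 = 0.15 ppb
print(pt.ec(pt.BROOD_PULSE_TOTAL, 50))   # EC50 > 98.43 ppb

# Percent brood reduction at realistic field residues (14-day exposure)
print(pt.reduction_table(pt.BROOD_ON_DOSE)["reduction_pct"].round().tolist())
# [18.0, 37.0, 56.0, 84.0]   at 0.3 / 0.8 / 1.9 / 10.0 ppb

# Simulate a study and refit it
records = pt.simulate_dataset(seed=1)            # 60 colonies x 2 periods
wide = pt.period_table(records)
est = pt.BayesianPoissonDoseResponse(
    n_retained=5000, burn_in=2000, n_chains=2, random_state=1
).fit(wide["dosage_ugkg"], wide["brood_on"])
print(est.summary_.round(3))
#                mean  median     sd   q2.5  q97.5
# alpha         1.519   1.527  0.354  0.797  2.182
# beta         -1.436  -1.422  0.423 -2.308 -0.643
# sigma_lambda  1.739   1.715  0.257  1.311  2.307
print(pt.ec_from_posterior(est.posterior_, 50))
# EC50 = 2.07 ppb (95% CrI 1.00-10.98)

res = pt.recuperation_test(records, "brood")
print(f"rho={res.rho:.2f}, p={res.p_value:.3f}")  # rho=0.27, p=0.040
```

The fitted interval comfortably covers the generating coefficients
(α = 2.002, β = −1.788, σ_λ = 1.89); a single 60-colony study is noisy at
this overdispersion, which is exactly what the credible intervals convey.
The positive Spearman coefficient says colonies previously on higher doses
gained the most brood after the dose was removed.

The same pipeline is scriptable from the shell:

```bash
pulsetox simulate --seed 1 --out dataset.csv
pulsetox fit dataset.csv --response on --seed 1 --outdir run/
pulsetox ec --alpha 2.002 --beta -1.788
pulsetox report --alpha 2.002 --beta -1.788
pulsetox recuperation dataset.csv --variable pollen_gpd
pulsetox run-all --seed 1 --outdir run/
```

## Layout

| module | contents |
| --- | --- |
| `pulsetox.colonies` | `ColonyRecord`, `ExposureDesign`, CSV IO, dilution-ladder arithmetic |
| `pulsetox.simulate` | `GeneratorConfig`, brood/feeding/oviposition simulators |
| `pulsetox.bhm` | `BayesianPoissonDoseResponse`, priors, MCMC, diagnostics |
| `pulsetox.curves` | curve evaluation, `ec`, credible bands, reduction tables |
| `pulsetox.recuperation` | ΔX statistics, Spearman/partial correlation, trend + log-logistic fits |
| `pulsetox.pipeline`, `pulsetox.cli` | end-to-end runs, `pulsetox` console script |

See `docs/methods.md` for the statistical details and design choices.
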