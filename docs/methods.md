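# Methods

## The experimental design being modelled

The unit of observation is a standardised micro-colony (one *Bombus
terrestris* queen plus four adult workers) kept for 28 days split into two
14-day periods: an "on dose" period feeding ad libitum on syrup spiked with
imidacloprid, and an "off dose" period on clean syrup. Nine dosages are
produced by serial dilution (factor 0.4) from a 125 µg L⁻¹ stock; with a
syrup density of 1.27 kg L⁻¹ this gives 98.43, 39.37, 15.75, 6.30, 2.52,
1.01, 0.40, 0.16 and 0.06 µg kg⁻¹ (mass ppb) plus an undosed control. Six
colonies per level are split evenly over two replicate trials (60 colonies).
Endpoints per colony and period: brood (total eggs + larvae collected at
period end), daily syrup and pollen consumption (g/day, evaporation-
corrected), day of first oviposition (absent if none occurred in the
period), and worker deaths.

Dosages are stored in µg kg⁻¹ everywhere downstream; µg L⁻¹ appears only at
ingestion, converted through the density. Rounding (e.g. 125/1.27 → 98.43)
is purely presentational; stored values are unrounded.

## Dose–response model

For colony *i* with dosage *d_i* and brood count *y_i*:

* y_i ~ Poisson(μ_i)
* log μ_i = α + β·log10(d_i + 1) + λ_i
* λ_i ~ Normal(0, σ_λ²)

The covariate log is **base 10** in every module. This is a substantive
convention, not a cosmetic one: with the 14-day coefficients
(α = 2.002, β = −1.788) the base-10 convention yields EC₅₀ = 1.44 ppb and
EC₁₀ = 0.15 ppb exactly, while natural log does not.

The "best-fit" curve reported, inverted and banded by `pulsetox.curves` is
the **median-colony** curve exp(α + β·log10(d+1)), i.e. λ = 0. The marginal
mean across colonies carries an extra exp(σ_λ²/2) factor and would not
reproduce the published EC values or reduction tables; it is available
implicitly through the posterior λ draws for predictive checks.

`EC_p = 10^(ln(1 − p/100)/β) − 1` follows from inverting the percent
reduction `100·(1 − exp(β·log10(d+1)))`, which is independent of α. An EC
whose solution exceeds the top of the tested ladder (98.43 ppb by default)
is reported as "> limit"; the numeric inversion is retained on the estimate
object so nothing is lost, but no extrapolated point value is headline
output. Note that inverting the printed 28-day coefficients
(2.770, −0.198) gives an EC₁₀ of ≈ 2.40 ppb, slightly below the commonly
quoted 2.5 ppb; that gap is what two-to-three-digit coefficient rounding
produces and is deliberately left as is.

### Priors

No priors are inherited from anywhere: defaults are vague — Normal(0, 100²)
on α and β, Uniform(0, 10) on σ_λ — and are dominated by the likelihood at
n = 60. All are configurable through `PriorSpec` /
`BayesianPoissonDoseResponse` parameters, which is the supported way to do
prior-sensitivity analysis.

### Sampler

The likelihood is non-conjugate, so the sampler is Metropolis-within-Gibbs
with an interweaving structure, operating on the colony log-means
θ_i = α + β·log10(d_i+1) + λ_i:

1. **θ update** — vectorised elementwise random-walk Metropolis (the θ_i
   are conditionally independent); per-colony step sizes adapt toward 44%
   acceptance during burn-in only, so retained draws come from a
   time-homogeneous chain.
2. **(α, β) | θ, σ_λ** — exact Gaussian conditional: given θ the model is a
   linear regression of θ on log10(d+1) with noise σ_λ and Gaussian priors.
3. **(α, β) centered step** — a covariance-adapted joint random walk that
   holds the residuals λ fixed and moves the coefficients through the
   Poisson likelihood. Step 2 alone mixes slowly when σ_λ ≈ 0 (θ pinned to
   the line); this complement restores mixing in that regime.
4. **σ_λ | λ** — exact draw: with the uniform prior, σ_λ² is inverse-gamma
   ((n−1)/2, Σλ²/2) truncated at the prior bound (sampled by precision
   rejection).
5. **σ_λ ancillary step** — a log-scale move holding u = λ/σ_λ fixed,
   rescaling λ through the likelihood. This breaks the funnel between σ_λ
   and the residuals when overdispersion is near zero.

Steps 2+3 and 4+5 are the standard ancillarity–sufficiency interweaving
pair; together they give effective sample sizes in the hundreds-to-
thousands per 5,000 retained draws both at σ_λ ≈ 0 and at σ_λ ≈ 1.9.
Initialisation: α = log(mean(y)+0.5), β = 0, λ = 0, σ_λ = 1 (overridable).
Defaults retain 40,000 draws per chain after a 7,000-iteration burn-in,
with two chains for diagnosability. Convergence is summarised by the
classic split-chain variance-ratio R̂ (flagged above 1.05, or when
undefined because a chain has zero variance) and by effective sample size;
a flag raises a `ConvergenceWarning`, never a silent pass. λ draws are
retained to enable posterior predictive checks.

Single-dosage data leave β unidentifiable; the fit refuses with an error
directing the user to `beta_fixed=0` (intercept-only).

### Credible bands and reduction tables

Bands are pointwise 2.5/97.5 percentiles of exp(α_j + β_j·log10(d+1)) over
the joint posterior draws j (λ excluded, median-colony convention), with
linear interpolation between order statistics; the point curve is the
posterior median. Reduction tables evaluate 100·(1 − exp(β·log10(d+1)))
per draw; default scenario dosages 0.3, 0.8, 1.9 and 10.0 ppb cover
residues reported for oilseed-rape nectar in Europe and North America and
the upper end used in semi-field trials. Values are stored unrounded and
rounded to integers only at presentation.

## Recuperation statistics

ΔX = X_off − X_on per colony (positive = recovery); colonies missing a
period are excluded with a warning and a reported count. Dose dependence is
Spearman's rank correlation: ρ is the Pearson correlation of mid-ranks
(average ranks on ties); the two-sided p-value is exact (full permutation
enumeration) for n ≤ 8 and the t approximation with df = n−2 otherwise —
micro-colony studies are often small, and at the full design size (n = 60)
the asymptotic value matches standard software. Partial Pearson correlation
uses the first-order formula r_xy·z = (r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²))
with a t test on df = n−3; it equals the correlation of OLS residuals, and
that equivalence is enforced in the tests.

The group-level recuperation trend regresses **group-mean** deltas on
ln(dosage) by OLS, excluding the control (ln 0 undefined). Colony-level
points can be passed instead; group means are the default because that is
how such trends are conventionally plotted.

Feeding endpoints use a fixed-bottom three-parameter log-logistic,
`response = top/(1 + (d/EC₅₀)^h)`, fitted by least squares
(`scipy.optimize.curve_fit`, positive-parameter bounds), with
`EC_p = EC₅₀·(p/(100−p))^{1/h}` and the same beyond-range marker as the
brood ECs. Data whose response *increases* with dose raise an explicit
no-effect error rather than returning a nonsense fit.

## Synthetic-data generator

Defaults are the study conditions: brood curves (2.002, −1.788) with
SD(λ) = 1.89 on dose and (2.770, −0.198) with SD(λ) = 1.25 for the 28-day
total, over the default dosing design.

* **On-dose brood**: Poisson with median-colony mean exp(α_on + β_on·L),
  L = log10(d+1), and lognormal colony effect (σ_on).
* **Off-dose brood**: no off-dose curve is observed directly, so the
  off-dose median-colony mean is defined by subtraction — 28-day-total
  curve minus on-dose curve, floored at ε = 0.01 — with its own lognormal
  effect (σ_off). The median colony's 28-day total then follows the 28-day
  curve, and the expected recuperation delta rises with dosage (saturating
  at the top of the ladder, where the on-dose mean is already ≈ 0).
* **Feeding**: log-logistic suppression on dose with multiplicative
  lognormal noise (CV 0.2). Pollen EC₅₀ defaults to 4.4 ppb (the reported
  feeding EC₅₀); syrup EC₅₀ to 120 ppb, beyond the tested range, matching
  the qualitative observation that syrup suppression never reached half.
  Tops (2.0 g/day syrup, 0.44 g/day pollen) are realistic for a
  queen-plus-four-workers unit — the pollen figure corresponds to a ~6 g
  pollen ball over 14 days. Off dose, syrup reverts to its control level
  while pollen overshoots in proportion to prior dosage (rebound 0.3 at
  the top), mirroring the observed compensatory elevation.
* **Oviposition**: on-dose day ~ round(Normal(4.2, 1.5)) independent of
  dose, but absent with probability rising steeply (power 8) to 0.9 at the
  top dosage; off-dose mean day 1.3 + 3.0·L, so ≈ 7.3 days at 98.4 ppb.
  Days beyond the period length count as absent — absence is a
  distinguished value, never day 0.
* **Worker deaths** are constant 0: mortality was negligible in this
  design and simulating it is out of scope.
* A `trial_effect` (log-scale offset for trial 2) exists and defaults to 0;
  printed group data give no way to calibrate it.

Identical seeds give identical datasets; `simulate_dataset` spawns
independent substreams per component from one seed, so component calls
reproduce exactly the values embedded in the composed dataset.

**What passing tests do and do not show.** The generator matches the
analysis model's assumptions by construction (counts exactly
Poisson-lognormal, noise exactly multiplicative, no trial effect, no
within-period time structure, no dependence between feeding and brood noise
beyond their shared dose response). Parameter-recovery and coverage results
on these data therefore validate the *inference machinery*, not the model's
adequacy for any real dataset — real colonies can violate the lognormal
overdispersion shape, drift over trials, or couple feeding and fecundity
more intimately.

## Numerical and testing choices

* Percentiles everywhere use linear interpolation between order statistics
  (`numpy.percentile` default), verified against a sort-based oracle.
* The EC inversion and percent reduction round-trip to 1e-9 over
  p ∈ {1, 10, 50, 90}.
* Overdispersion contract: Var(Y) = M + M²(e^{σ²}−1) with M the marginal
  mean. The quantitative check runs at σ = 0.5 and n = 10,000 within 15%
  (at σ = 1.89 the fourth moment makes a sample-variance comparison
  hopeless at any feasible n; there the test asserts variance > mean).
* Sampler validation is distributional: posterior means collapse onto an
  independently coded Newton–Raphson Poisson-GLM fit (within 0.05 at
  n = 600, σ ≈ 0); a 1-D quadrature oracle checks the intercept-only
  posterior mean; and 50 replicate fits at the full study design (n = 60,
  5,000 retained draws, single chain) give ≥ 80% coverage of both
  generating coefficients by the 95% credible intervals. Replicate counts
  and chain lengths in the suite are scaled to keep the whole run around a
  minute while leaving the binomial coverage margin wide (true coverage
  ≈ 95% makes 40/50 a ≥ 99.9% event).
* CSV round trips are exact: reads use the `round_trip` float parser.

## Known limitations

* The off-dose generative mean is an emulation choice (subtraction with a
  floor), not an observed relationship; alternatives (e.g. an explicit
  off-dose curve) would change recuperation deltas at high dosage.
* The sampler is single-threaded pure NumPy; at the default 2 × 47,000
  iterations on 60 colonies a fit takes on the order of ten seconds, which
  is fine for this design but would not scale to thousands of colonies.
* ANCOVA trial pooling and the continuous-exposure ANOVA are routine
  off-the-shelf tests and are deliberately not re-implemented; the pipeline
  accepts pooled data.
* No multiple-testing correction is applied anywhere, matching the
  conventional reporting for this kind of study.
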