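# Methods

This note records the models implemented in `oraflux`, the assumptions
and numerical choices behind them, and what the synthetic-data generator
does and does not emulate.

## Systemic disposition

Disposition is a linear mammillary model (1–3 compartments) over drug
*amounts*, with elimination k10 = CL/Vc from the central compartment and
first-order exchange k12/k21 (and k13/k31) with peripheral compartments.
Central concentration is amount/(Vc·body mass). The closed-form solution
via eigendecomposition is used for bolus and first-order-oral inputs
(with a matrix-exponential fallback when the eigenvector matrix is
ill-conditioned); arbitrary input-rate functions integrate with LSODA at
rtol 1e-9.

The published parameter set is per-kg (Vc 0.47 L/kg) but no body mass is
stated; the package defaults to 70 kg everywhere and exposes it. The
printed terminal half-life of 4.62 h is reproduced by the rate-matrix
eigenvalues at ~80 kg (4.34 h at 70 kg); parameter-recovery tests are
constructed to be mass-invariant, and no agreement beyond this
consistency is forced.

**Fitting.** The objective is Σ(Cᵢ−Ĉᵢ)²/Ĉᵢ² (weights 1/Ĉ², i.e. relative
least squares), minimized over log-scale parameters by a Hooke–Jeeves
pattern search (exploratory coordinate moves + pattern moves,
step-halving from 0.5 to 1e-6) with 10 multi-starts around a
non-compartmental initial guess, each start polished by Nelder–Mead.
Oral profiles co-estimate a first-order ka (optional lag). Model
selection uses the Gaussian weighted-least-squares forms
AIC = n·ln(WRSS/n) + 2p and SC = n·ln(WRSS/n) + p·ln(n) (the source
names the criteria but not the likelihood form). WRSS/n is floored at
1e-14 in the criteria: below ~1e-7 relative residual, fits are
numerically indistinguishable, so equally perfect models tie and the
parameter-count penalty decides — this is what makes noise-free
self-refits select the generating model rather than an overfit.

**NCA.** Cmax/Tmax from the sampled maximum; AUC by linear trapezoid;
λz by log-linear regression over the best-R² choice of 3–8 terminal
points, rejected when the implied decline over the tail is under 5%
(flat tails give no AUC∞). AUC estimates therefore miss any area before
the first sample; oracle comparisons in the tests include the origin.

## Biopharmaceutical inputs

- **Papp** is flux/(area·donor concentration), flux being the slope of
  the cumulative receiver amount vs time regression (amounts are assumed
  already corrected for sampling replacement). The published equation's
  layout prints as a product; the standard quotient is implemented, the
  only form consistent with the stated units.
- **Papp→Peff** is a log10-linear map. The default calibration is a
  single-point anchor — Papp 2.69e-6 cm/s ↦ Peff 0.31e-4 cm/s with unit
  slope — chosen so that the documented "10-fold increase to 3.1" is
  reproduced; the unit of "3.1" is taken as 1e-4 cm/s (the conventional
  unit). Both intercept and slope are overridable.
- **Weibull fits** use least squares with multistart over shape
  b ∈ {0.5, 1, 2}. F∞ is bounded by min(1.05, 1.15·max observed):
  on 6-h-truncated profiles the asymptote is otherwise unidentifiable
  and inflates food-effect extrapolations. Because the dissolution data
  are biphasic (gastric segment then media switch), a single Weibull
  tracks the 30-min anchor to about ±0.015 rather than exactly.
- **f1/f2** follow the regulatory definitions with percent-scale
  profiles, interpolation of the test profile onto the reference grid,
  and truncation one point beyond 85% release. f1 is asymmetric in
  (reference, test); f2 is symmetric.
- Solubility is a lookup table by prandial state and nearest pH; no
  Henderson–Hasselbalch extrapolation is attempted (rivaroxaban is
  effectively non-ionizable over gut pH: pKa 13.6 acidic / 1.6 basic).

## Gut absorption model

Nine compartments in fixed order with first-order transit. Defaults:
gastric emptying t½ 0.25 h fasted / 1.0 h fed; small-intestinal mean
residence 0.26/0.96/0.75/0.59/0.43/0.31 h (≈3.3 h total); caecum 4.5 h;
ascending colon 13 h. Compartment pH fasted
1.6/6.0/6.2/6.4/6.6/6.9/7.4/6.4/6.8; fed gastric pH 4.5 with a −0.3
small-intestinal shift. Fluid volumes are anatomical volumes times a
water fraction (stomach 1.0, small intestine 0.4, colon 0.02 — colonic
free water deliberately reduced from the conventional 10% to 2%). The
fed stomach uses a 500 mL meal volume. Transit times, volumes and pH are
conventional ACAT-literature values, all exposed through
`build_physiology` overrides.

Local solubilities come from the biorelevant table (fasted: FaSSGF
stomach, FaSSIF small intestine; fed: FeSSGF stomach, FeSSIF small
intestine). The colon uses the fasted (FaSSIF-like) entry in both
states, since no fed colonic medium is defined.

**Dissolution** uses the Johnson / Wang–Flanagan rate
(3·D·M)/(ρ·r·h)·(Cs−C) per particle-size bin with diffusion layer
h = min(r, 30 µm); bin radii shrink with the cube root of remaining bin
mass (pooled across compartments). The PSD is discretized from d10/d50/d90
by matching a log-normal mass distribution (7 equal-mass quantile bins);
rivaroxaban: d10 0.7, d50 3.8, d90 9.4 µm. Dissolution is one-way
(driving force floored at zero); supersaturation is removed instead by
first-order precipitation of the excess with time constant
`precipitation_time` (default 900 s) into a 1 µm precipitate bin, which
may redissolve downstream. Release-profile-driven tablets deliver
dose·dF/dt from an unreleased pool (which transits like solid) into
solution, distributed across compartments in proportion to local
unreleased mass; the same precipitation term enforces the solubility cap
continuously, which keeps the right-hand side smooth for the stiff
solver.

**Absorption** is dA/dt = Peff·ASF·C·V per compartment — ASF (1/cm) is
consumed as data (the two published columns are built in; the generating
formula is proprietary and out of scope), lumping surface-to-volume and
regional effects. Absorbed drug enters the central disposition
compartment directly; first-pass extraction is implicitly carried by the
disposition parameters, which were fitted to oral data (F% reported by
the simulator is fraction *absorbed*).

**Numerics.** LSODA at rtol 1e-8 (atol scaled to 0.1% of a dose
microgram), max step 0.5 h; ~100 state variables (9 compartments ×
(bins+1) solid pools, dissolved, unreleased, regional-absorbed
accumulators, exit, plus disposition). Mass balance
(undissolved + dissolved + absorbed + exited = dose) is checked at every
output time and a violation beyond 0.1% raises with advice to tighten
rtol; in practice it holds to near machine precision because every term
is a transfer between tracked pools.

## Two-stage IVIVC

The impulse reference is the 10 mg *oral solution* (no IV data exist),
so the UIR embeds solution-phase absorption and the deconvolved Fabs is
"fraction absorbed relative to solution" — it may exceed a strict
absorbed-fraction reading. The UIR is a polyexponential with rates
constrained negative (the printed form shows bare exponents; decaying
terms are the only physical reading), fitted by variable projection:
rates optimized by nonlinear least squares on 1/Ĉ²-weighted residuals,
coefficients re-solved by iteratively reweighted linear least squares at
each step, 8 seeded multi-starts. Sign-indefinite responses trigger a
hinge-penalty refit. An oral profile over a two-compartment disposition
needs three exponentials; the workflow uses n_terms=3 and reaches
R² ≥ 0.99 on clean input.

**Deconvolution** solves C = ∫r·UIR on a piecewise-constant rate basis
(intervals between observations) by nonnegative least squares; the
interval integrals of the UIR are exact (closed-form exponential
integrals). If the system's condition number exceeds 1e10 a small ridge
penalty is applied with a warning. No Loo–Riegelman path is needed — the
constrained solver subsumes it.

**Correlation** Fabs(t) = AbsScale·Diss(Tscale·t − Tshift) is fitted by
bounded least squares (multistart over Tscale); the slope and R² of
observed-vs-modeled Fabs are reported (slope ≈ 1 supports Level A).
Prediction builds the input staircase from *cumulative* release
differences — exact interval masses even for release much faster than
the grid — and any release implied before t = 0 by a negative Tshift is
delivered as an instantaneous input so mass is conserved.

**Validation** reports both %PE orientations plus the ratio: the
published internal-validation table computes its fasted rows as
(Pred−Obs)/Obs but its fed rows as (Obs−Pred)/Pred (the printed ratios
confirm the flip), and neither is silently corrected here. Verdicts use
the standard orientation: each |%PE| ≤ 15%, mean ≤ 10%.

## Virtual trials

Subject sampling applies independent multiplicative log-normal factors
(median 1, truncated to bounds) with default CVs: clearance and volumes
30%, gastric emptying 25%, intestinal transit and fluid volumes 20%;
pH jitters additively (σ 0.15, truncated ±0.3) with solubility re-looked
up at the jittered pH. These magnitudes are conventional; the reference
engine's distributions are unpublished. A warning fires if bounds clip
more than 1% of draws. Summaries are geometric means and geometric CVs;
cross-population geometric-mean ratios carry log-scale Welch-t
confidence intervals at both 90% (the standard bioequivalence interval,
used for the BE flag against 80–125%) and 80% (also reported, as some
analyses quote it). Subjects are sampled independently per arm —
within-subject crossover correlation is not modeled (a documented
limitation of single-period parallel sampling); `run_trial` accepts any
pre-built subject sets, which is the hook for paired designs.

## Synthetic data

The generator emulates the USP-IV biphasic dissolution experiment: a
first-order gastric segment pinned to the 30-min anchor (fasted 11.0%,
fed 27.7%), then an intestinal Weibull segment constrained through the
later anchors (fasted 80% at 360 min; fed 80% at 210 min and 90% at
330 min) with weak pulls toward first-order intestinal release and a
near-complete asymptote where the anchors leave directions free.
Unsatisfiable anchor sets raise an error naming the violated constraint.
Replicate noise is multiplicative log-normal (default CV 5% — a stand-in;
the experimental 12-replicate variability is shown only as error bars),
truncated to [0, 1]. Plasma profiles are simulated from the disposition
model with first-order absorption (ka = 2 h⁻¹ puts the solution Tmax and
Cmax inside the reported ranges), proportional log-normal noise, and
LLOQ censoring (default 0.5 µg/L, censored points dropped, not imputed).

What this does *not* emulate: tablet-to-tablet content variability,
autocorrelated assay error, irregular clinical sampling, or digitized
literature curves — so passing tests demonstrate internal consistency of
the pipeline under the stated study conditions, not agreement with any
particular clinical dataset. Published end-to-end quantities that depend
on the unpublished full curves (the correlation triple 0.595/1.494/0.188,
f1 28 / f2 38) are treated as plausibility bands: the synthetic pipeline
reproduces their direction and rough magnitude, not their digits.

## Problem sizes and determinism

Default grids are 0.25 h steps over 24 h (0.2 h over 30 h for gut-model
property checks); dissolution sampling follows a 17-point USP-IV
schedule over 6 h. The test suite runs the virtual-trial checks at 2–4
subjects per population (the degeneracy and permutation properties are
size-independent) and the clearance-recovery Monte Carlo over 4 noise
seeds; the CLI defaults to the full 3×50-subject design. All randomness
flows through explicit integer seeds; repeated runs are bit-identical.

## Known limitations

- No gut-wall or hepatic first-pass module: bioavailability beyond
  absorbed fraction lives inside the fitted disposition parameters.
- No transporters, enterohepatic recirculation, or nucleation-based
  precipitation kinetics (first-order only).
- The gastric/intestinal media switch is represented only through
  compartment-local solubilities, not time-varying media in one vessel.
- Fed-state physiology adjusts emptying, pH, gastric volume and
  solubility; bile-salt-mediated dissolution-rate enhancement beyond the
  solubility term is not modeled separately.
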