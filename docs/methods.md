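# Methods

## Chamber gas exchange

The measurement model is a single pair of infrared gas analyzers
(absolute concentrations of the supply stream; supply–sample
differentials) multiplexed over canopy chambers plus two empty
reference chambers, visiting each chamber for 120 s and logging every
10 s; only the last 40 s of a visit (after tube flushing) are averaged
into one row per visit. Transpiration per leaf area follows from the
water-vapor mass balance of the chamber,

E = F_m (W_sample − W_supply) / (A_leaf (1 − W_sample)),

with the sign convention that a transpiring plant yields positive E
(the differential is taken sample-minus-supply; written the other way
round the same expression returns −E, and both conventions circulate in
the literature). Canopy stomatal conductance

g_c = E (1 − (W_leaf + W_sample)/2) / (W_leaf − W_sample)

neglects boundary-layer conductance, which is defensible only for
strongly fan-mixed chambers at high flow; g_c is undefined when the air
is at or above leaf saturation, and such rows (typically near-saturated
nights) are excluded and counted rather than raised. Leaf temperature
is taken equal to chamber air temperature — the chambers are
temperature-controlled and no leaf thermocouple stream is modelled — so
W_leaf = e_sat(T_air)/P. Saturation vapor pressure uses the Buck (1981)
liquid-water fit (Tetens available behind a config switch; they differ
by <0.5% over 0–40 °C, well below analyzer noise). VPD is computed
against the sample stream, e_sat(T_air) − W_sample·P, because chamber
air is the boundary condition the stomata see. Empty-chamber
differentials are interpolated in time, averaged over the two
references and subtracted from plant differentials; this removes slow
system drift but not per-record analyzer noise.

Internal water-vapor unit is mol mol⁻¹ throughout; readers accept
ppt (parts per thousand) and convert on ingest.

## Conductance response models

Three response curves are calibrated, all with a Gaussian likelihood
whose residual sd σ is itself a calibrated parameter under a uniform
prior (not profiled out):

* g_c(D) = g_c,ref − m·ln(D/D_ref), D_ref = 1 kPa. The log form is the
  standard stomatal VPD response; g_c,ref is by construction g_c at the
  reference VPD. A slope-to-reference ratio m/g_c,ref = 0.6/ln 2 makes
  conductance fall 60% from 1 to 2 kPa, which is used as the generator
  default.
* Relative conductance under falling water potential:
  g_c,rel(Ψ) = 1/(1 + exp(s(Ψ50 − Ψ))); the water potential at stomatal
  closure is defined as g_c,rel = 0.05. The closure point is invariant
  to any affine rescaling of the conductance data, which is why the
  model takes relative conductance as input.
* Foliar ABA vs tension: ABA(Ψ) = ABA₀ + r·(−Ψ), linear with a slope
  that can be compared between treatments.

These functional forms are this package's own defaults, chosen to match
the derived quantities usually reported (reference conductance at
1 kPa, a closure water potential, a common ABA accumulation rate); all
three are pluggable `ResponseModel` implementations.

## Vulnerability curves

Percent loss of conductivity along a flow-centrifuge series is
PLC_i = 100(1 − k_i/k_ref) with k_ref the first-spin (−0.84 MPa)
conductivity — near-maximal for this protocol, which describes no
separate flush maximum. Curves are fitted on the raw
(unclamped) PLC series: clamping censors the measurement noise at the
bounds while the Gaussian likelihood would treat the clamped values as
exact, which biases the steepness posterior; the clamped series is what
gets reported and plotted. The curve model is the two-parameter
Weibull in tension magnitude, PLC(Ψ) = 100(1 − exp(−(|Ψ|/b)^c)); b
(MPa) is the tension at ≈63.2% loss, c the steepness, and
|P_x| = b(−ln(1 − x/100))^{1/c}. Tensions are reported as −MPa
magnitudes. Curves are fitted per branch and merged per treatment
(a pooled fit across branches is possible by passing a single branch
label).

## DE-MCzs sampler

Calibration uses differential-evolution MCMC with memory and snooker
updates (ter Braak & Vrugt 2008): three parallel chains propose jumps
as scaled difference vectors γ(z₁ − z₂) between rows of a memory matrix
Z of past states (γ = 2.38/√(2d), with probability 0.1 γ = 1 to allow
mode-to-mode jumps, plus a tiny uniform-scale perturbation), and with
probability 0.1 a snooker move along the line from the current state to
a random memory point, whose Metropolis ratio carries the
(|x*−z|/|x−z|)^{d−1} volume correction. Chain states are appended to Z
every 10 generations. Defaults are 30,000 iterations with a 10,000
burn-in; convergence is assessed per parameter with the Gelman–Rubin
diagnostic at ≤1.1 and non-convergence is flagged on the result, never
silently accepted. Runs are bit-reproducible from the seed.

Per-unit (tree or branch) posteriors are merged into treatment
posteriors by equal-weight concatenation after deterministic
subsampling to the shortest unit length — units are weighted equally,
not pooled hierarchically. Treatment differences are called meaningful
when equal-tailed 95% credible intervals are disjoint; this is a
deliberately conservative decision rule (its effective false-positive
rate is far below 0.05). Posterior-predictive bands draw 5,000
parameter vectors with replacement and summarize the model curve per
grid point; they show parameter uncertainty, not observation noise.

## Group statistics

Traits measured per tree or branch are compared with two-sided
Mann–Whitney U tests (exact null distribution for combined n ≤ 12
without ties, tie-corrected normal approximation otherwise; fully tied
data return p = 1 with a warning). Wood-anatomy metrics covary strongly
with branch size, and treatments can differ systematically in branch
diameter, so they are compared with a generalized least squares model
y ~ treatment + centered ln(cross-sectional area) with a separate
residual variance per treatment, fitted by iteratively reweighted least
squares to a 1e-10 relative log-likelihood tolerance. The Wald test on
the treatment coefficient uses a t reference with n − 3 df. The
default variance estimator is REML-corrected: simulation at the sample
sizes typical here (10–15 branches per treatment) puts the ML Wald
test's type-I error near 0.07, while REML is close to the nominal 0.05;
plain ML remains available (`reml=False`) and its likelihood is pinned
against an independent optimizer oracle in the tests. Tests are
two-sided at α = 0.05 with no multiplicity correction, matching common
reporting practice for this kind of trait table.

## Synthetic data generator

The generator emulates the study conditions end to end. Treatment
contrasts are multiplicative eCO₂/aCO₂ factors defaulting to the
elevated-CO₂ effects (reference conductance ×0.45; stomatal density
×1.23; epidermal density ×1.25; vein-to-epidermis distance ×1.67; leaf
width ×1.40; conduit diameter ×0.92; lumen fraction ×0.89; specific
conductivity ×0.81; leaf-to-sapwood ratio ×1.24; stomata length,
stomatal index, ABA and vulnerability unchanged). The conduit-density
factor is derived from the lumen and diameter effects
(0.89/0.92² ≈ 1.05) so the three wood effects are mutually consistent.

Chamber records are generated by inverting the analysis equations: a
true conductance from the log-VPD model (lognormal tree-to-tree
variation of the reference conductance, CV 6%, plus additive slot-level
physiological scatter of sd 0.01 mol m⁻² s⁻¹ — real conductance–VPD
clouds show such scatter, and the additive constant-variance form
matches the constant-σ Gaussian likelihood the calibration assumes) is
converted to transpiration and then to the supply
mole fraction that would have produced it, given the 10 L min⁻¹ flow,
the tree's leaf area and the VPD forcing; analyzer noise
(sd 1e-4 mol mol⁻¹ per 10-s record) and a slow sinusoidal
empty-chamber drift (offset 0.03 ppt, amplitude 0.2 ppt, 1-day period)
are added after the inversion. Forcings (diurnal VPD 0.9–2.1 kPa over a
16-h day at 24 °C/19.7 °C day/night, PAR 450 ± 50 µmol m⁻² s⁻¹) are
held constant within each 120-s multiplexer slot, mimicking discrete
chamber control; as a consequence the noise-free pipeline recovers the
injected conductance exactly (to 1e-10), making the analysis equations
testable against their exact inverse. The generator validates the
humidity budget (supply air must stay drier than the sample but above
zero); default shoot leaf areas (0.022 m², eCO₂ ×1.2) are chosen so
that every scenario, including null-effect controls, is physically
realizable at the fixed flow. A CO₂-drawdown protocol
(900/400/200 ppm, 2 days each, constant day VPD) generates conductance
with *no* CO₂ response — the null hypothesis that stage of the
pipeline summarizes with per-tree medians per level.

Conduit tables draw lognormal minor semi-axes (median 7 µm, σ = 0.25)
with uniform eccentricity 1–1.6, about 1,750 conduits per section
(a deliberate scale-down from the tens of thousands a full digitized
cross-section yields, keeping the default pipeline run in minutes on
one CPU); branch cross-sectional area is lognormal, eCO₂ branches
systematically ~15% thicker, and conduit size scales with area^0.15 so
the GLS covariate is exercised. Branch-level noise CVs (3% size, 3%
count, and tree-level 6% for cell densities with SD–ED correlation 0.8)
were fixed by simulating the study's sample sizes: they give the stated
effects standardized magnitudes ≥ ~2.5, consistent with the significance
pattern these effect sizes are reported with, while null effects stay
at the nominal false-positive rate. Vulnerability truth is Weibull
scale 5.5 MPa, shape 6 (the two-parameter curve through the published
P12/P50/P88 triplet); series step −0.82 MPa from −0.84 MPa and stop at
the first step whose true PLC ≥ 90%, with conductivity noise equivalent
to 5 PLC points. The dry-down runs Ψ from −0.5 to −3 MPa over 25
observations with closure at −2.1 MPa (logistic Ψ50 = −1.119 MPa,
s = 3 MPa⁻¹) and a common ABA slope of 150 ng g⁻¹ MPa⁻¹ in both
treatments.

What the generator does *not* emulate: soil–plant water balance and
stomatal dynamics (conductance is a static function of VPD or Ψ),
photosynthesis (CO₂ columns are pass-through), leaf energy balance,
analyzer calibration drift other than the additive H₂O baseline, and
open-vessel or fatigue artifacts in the centrifuge series. Passing
tests therefore demonstrate that the estimators recover what the
models inject under realistic noise — not that the models are adequate
for any particular real dataset.

## Numerical choices and degenerate inputs

Ideal-gas molar flow with R = 8.314462618 J mol⁻¹ K⁻¹; water constants
for Hagen–Poiseuille at 20 °C (η = 1.002e-9 MPa s, ρ = 998.2 kg m⁻³).
Conduit axis columns require an explicit radius/diameter convention —
particle-analysis exports differ and a silent factor two is the
dominant failure mode; lumen area defaults to the ellipse πab. Visits
shorter than the averaging window fall back to all available records
with a warning; a chamber with no visits yields no rows, not an error.
GLS refuses groups with fewer than 3 observations; the Mann–Whitney
test warns and returns p = 1 on fully tied data. Percent contrasts are
computed on treatment medians for Bayesian quantities and on means for
trait tables; anatomy rows report size-adjusted group values (the GLS
prediction at the mean log area), since unadjusted means confound the
treatment effect with the systematic branch-size difference.

## Known limitations

Single-level merging only (no partial pooling); no alternative samplers
(HMC/NUTS) or model selection; the CO₂-step stage reports per-tree
medians and paired differences rather than mixed-effect modelling; the
CI-overlap decision rule is conservative and its "not meaningful"
verdicts are weaker evidence of equality than an equivalence test would
give; Ψ_leaf enters the dry-down models as measured, with no
errors-in-variables treatment.
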