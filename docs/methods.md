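# Methods

This note documents the models implemented in `protonleak`, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the numerical decisions a maintainer should know about.

## Conductance from I–V recordings

The small-signal specific conductance is the ordinary-least-squares slope of
current (pA) against voltage (mV) inside a fit window, divided by membrane
area (cm²); pA/mV is numerically nS, so the result is in nS/cm² with no
hidden unit factors. The default window is −50…+50 mV, the standard ohmic
range for bilayer work; it is configurable because the reversal-shift
measurement reuses the same fit. The zero-current potential is −a/g for the
fitted line I = a + g·U and is reported as undefined (flagged, not NaN) when
|g| falls below a data-scaled machine tolerance, e.g. on an all-zero trace.

The voltage dependence of conductance is modelled as G(Ψ) = G₀·exp(b·|Ψ|),
symmetric in the sign of the potential. The fit is nonlinear least squares
with relative (1/G) weighting, started from a log-linear regression.
Relative weighting is deliberate: conductances span decades and their errors
are multiplicative, and an unweighted fit would let the largest conductances
dominate and bias the curve high in log space.

Inhibitor series are expressed as relative conductance
(G(c) − G₀)/(G_max − G₀): full inhibition maps to 0, no inhibitor to 1.
Values below zero (possible with noise when G(c) dips under the protein-free
baseline) are clipped to 0 and flagged rather than silently altered.

## Inhibition dose–response

The sigmoid rel(c) = 1 − (I_max/100)·c^h/(c^h + EC50^h) is anchored at
rel(0) = 1 by construction — there is no free intercept. The Hill slope is
fixed at h = 1 by default, making EC50 and I_max the only fit parameters; a
free-h fit is available behind a flag. For fixed h the model is linear in
I_max, so the fit profiles I_max out in closed form and minimises over
log-EC50 alone (80-point grid plus bounded scalar refinement, xatol 1e-10 in
log space). This is exact to the stated bounds — EC50 constrained to the
positive concentration range × [0.01, 100], I_max to [0, 100] % — fast
enough for bootstrap loops, and free of starting-value failures. Fits are
unweighted: titration points are treated as equally informative.

Uncertainty comes from a seeded case-resampling bootstrap (percentile 95 %
intervals, at least 200 resamples). When a series carries more than one
replicate id, whole replicates are resampled, since the independent
experimental unit is the titration, not the point. Resamples that lose too
many distinct concentrations to be fittable are skipped; an error is raised
if more than half are lost. A fit whose I_max interval includes zero is
flagged `reliable = False` ("no reliable inhibition") — the rule under which
low-effect compounds are excluded from potency tables.

Two statistical caveats are documented deliberately. First, a single 8-point
titration with 10 % multiplicative noise determines EC50 only to roughly
±20–30 % (the Fisher-information bound for a partial inhibitor with
I_max ≈ 64 % gives sd(ln EC50) ≈ 0.33 nearly independent of the
concentration span); per-titration EC50 scatter of that size is intrinsic to
the design, and averaging over ≥3 independent titrations is what brings the
reported uncertainty down to ~10 %. The estimator itself is near-efficient
and essentially unbiased (EC50 bias ≈ +4 %, I_max bias ≈ 0.03 % over 500
simulated titrations). Second, percentile bootstrap intervals on n = 8
points undercover: empirical coverage is ≈ 86 % rather than the nominal
95 %, a known small-sample property of case resampling; with replicate-level
resampling on larger designs coverage approaches nominal.

## FCS fitting and stoichiometry

The autocorrelation model is G(τ) = 1 + 1/(n·(1 + τ/τ_D)) with the long-lag
baseline fixed at 1, not fitted. Initial values are taken from the data —
n from the amplitude 1/(G(τ_min) − 1), τ_D from the half-decay lag — and
refined by least squares in (log n, log τ_D), which keeps both parameters
positive without explicit bounds. A curve must supply at least 10 lags
spanning two decades; a flat curve raises a no-signal error instead of
returning a meaningless fit. The diffusion coefficient is D = ω²/4τ_D with
ω = 0.16 µm (calibration value for the confocal cross-section diameter). An
optional two-component decay (two residence times under one amplitude,
fraction kept in (0,1) by a logistic transform) is available for mixed
populations; it reports the amplitude-weighted mean residence time.

Proteins per liposome is the particle-number ratio after/before detergent,
assuming complete solubilization with one protein per micelle at 2 % SDS.
Replicated measurements can be combined as the mean of per-replicate ratios
(the default, matching how a replicate-averaged 8.67 arises from counts whose
pooled ratio is 8.64) or as the pooled ratio; both are exposed.

Stoichiometry: lipids per liposome is 8πr²/A_L (both leaflets), so
ρ = ⟨N⟩·A_L/(8πr²) and the familiar "1:x" form is 1/ρ (displayed at 3
significant figures; the exact value is retained). The defaults r = 50 nm
(from the 100 nm extrusion pore) and A_L = 0.6 nm² are configurable —
extruded liposomes can exceed the nominal pore size, and ρ scales with 1/r².

The ratio estimator carries a structural bias the package makes measurable:
only liposomes containing at least one labelled protein are visible before
SDS, so on a Poisson(λ) occupancy ensemble the ratio converges to the
zero-truncated mean λ/(1 − e^{−λ}), not to λ (e.g. 1.582 at λ = 1). The
Poisson ensemble generator and the analytic oracle let tests quantify this
empty-liposome bias directly.

## Turnover number

Imposing ΔpH = 1 (cis side raised from 7.34 to 8.34) shifts the zero-current
potential; the shift is estimated as the difference of the linear-window
intercepts of the two traces, matching the convention used for the
conductance itself rather than point interpolation. The proton flux density
is J = G_H·ΔU_rev/F (S/cm² × V / (C/mol) = mol s⁻¹ cm⁻²) and the per-carrier
turnover k = J·N_A/σ, with σ = ρ·2/A_L·10¹⁴ carriers/cm². Physical constants
come from scipy.constants and are recorded in every result object.

G_H defaults to the protein-mediated conductance — total (protein + fatty
acid) minus the fatty-acid-only control — because the fatty-acid flip-flop
current is not carrier turnover; using the total conductance instead is an
explicit option and the choice is logged in the result's provenance. The
ideal Nernst shift U_N = (RT/F)·ln 10·ΔpH (60.7 mV at 306 K for ΔpH = 1) is
reported alongside, and the transference ratio ΔU_rev/U_N is flagged, never
clipped, when it falls outside [0, 1]. With the bundled study-condition
values (G_H = 1310 nS/cm², ρ = 1:12,000, A_L = 0.6 nm²) the ideal-Nernst
turnover is ≈ 17.9 s⁻¹ and a 49 mV shift gives ≈ 14.5 s⁻¹.

## Synthetic data: what it emulates and what it does not

Generators are seeded (`GeneratorConfig.seed`); a fixed config yields
byte-identical output, and zero-noise output satisfies the generating model
to machine precision. Noise magnitudes are not constrained by any published
value, so the defaults were chosen once as instrument-realistic and kept:

- I–V traces: additive Gaussian current noise, sd 0.5 pA — steady-state
  averaged patch-amplifier noise; voltage grid −50…+50 mV in 10 mV steps.
- Dose–response: multiplicative Gaussian noise, cv 0.05 by default
  (0.1 in the stress experiments); default design of 8 log-spaced
  concentrations spanning ±1.5 decades around EC50.
- FCS: Gaussian noise with sd 0.02·(G−1) + 10⁻⁴ — fluctuations proportional
  to the correlation amplitude plus a floor; 120 log-spaced lags over six
  decades.
- Liposome ensembles: independent Poisson occupancies.

Not emulated: detector-level photon statistics, FCS triplet/misalignment
artifacts, bilayer capacitance transients, leak/seal drift, labelling
efficiency below one dye per protein, or correlated titration errors.
Passing tests therefore demonstrate correctness of the estimators under the
assumed error structure, not robustness to every instrumental pathology.

## Problem sizes and numerical choices

Simulation-based tests use sizes chosen to make Monte-Carlo error small
relative to the tolerances they check: 500 simulated titrations for
recovery/bias experiments, 200–500 bootstrap resamples per interval, 10⁵–10⁶
liposomes for ensemble convergence (the zero-truncated-Poisson check uses an
analytic delta-method standard error, not an eyeballed tolerance), and 1000
random traces for the OLS oracle-equivalence property. Degenerate inputs
fail loudly: empty grids, non-positive lags, negative concentrations, flat
responses and flat correlation curves all raise typed exceptions rather than
producing numbers.

The pipeline writes one JSON record per stage and a manifest with SHA-256
hashes of every output, the seed and the package version; reruns with the
same config are identical modulo the manifest timestamp. Stage dependencies
are validated before execution (a turnover request without conductance and
FCS stages fails naming the missing stage), and a stage failure is recorded
in the manifest as partial completion with the diagnostic.

## Known limitations

- The single-component correlation model is implemented as the primary form
  even though mixed liposome/micelle populations can be bimodal; which exact
  model produced a given published particle count is not always recoverable,
  and the two-component option exists for sensitivity analysis.
- The turnover calculus assumes the reversal shift reflects proton
  selectivity of the protein-mediated conductance alone; multi-ion
  (Goldman–Hodgkin–Katz) effects, buffering and unstirred layers are out of
  scope.
- EC50 from a single low-replicate titration is intrinsically imprecise (see
  above); the package reports bootstrap intervals precisely so that this
  uncertainty is visible rather than hidden behind a point estimate.
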