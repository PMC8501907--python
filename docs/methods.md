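# Methods

`leafphys` fits and simulates the standard response-curve models of leaf
ecophysiology. This note records the models as implemented, the numerical
choices behind the fitting machinery, what the synthetic-data generator
does and does not emulate, and the design decisions that were genuinely
open.

## Canonical data model

All analysis functions consume a tidy observation table (a pandas
DataFrame) with fixed column names and units: `A_net` and `Q` in
umol m-2 s-1, CO2 mole fractions (`C_i`, `C_a`, `C_s`) in umol mol-1,
`g_sw` in mol m-2 s-1, `T_leaf`/`T_air` in K, `RH` as a 0-1 fraction, `D`
in kPa, `psi` in MPa, `PLC` and `RWC` in percent. `standardize_columns`
translates instrument dialects (built-in maps for the Li-Cor 6400 and 6800
export vocabularies, shipped as editable JSON; transcribed from instrument
manuals and common usage, so they are a package decision, not an external
standard). `enforce_units` converts declared source units to the canonical
ones and records unit state in `DataFrame.attrs`, which is what makes the
operation idempotent: a column already marked canonical is never converted
twice.

## Nonlinear fitting machinery

Every nonlinear fit uses `scipy.optimize.least_squares` (trust-region
reflective, box bounds) restarted over a grid of starting values built
around moment-based initial guesses, keeping the lowest-SSR converged
solution. Multi-start matters here: peaked temperature responses and the
min-rule CO2 response have genuine local minima. Grids are capped at 500
starts; tolerances are `xtol = ftol = 1e-12`, at most 1000 function
evaluations per start.

Standard errors come from the Gauss-Newton covariance `s^2 (J'J)^-1` at
the optimum. Two honesty rules apply:

* a parameter whose Jacobian column is numerically zero (the data carry no
  information about it — e.g. `J_max` when no observation is
  RuBP-regeneration-limited) gets an **infinite** SE and an explicit
  warning, never the misleading zero that a pseudo-inverse would produce;
* any SE/estimate ratio above 1 triggers an "unidentifiable" warning, the
  practical screening rule for untrustworthy nonlinear fits.

AIC/BIC use the Gaussian log-likelihood with the error variance counted as
a parameter, matching R's `AIC(nls_fit)` convention. Linear-in-parameters
models (the quadratic temperature polynomial; the three light-respiration
regressions) are solved by ordinary least squares — exact, and the natural
oracle for them is the normal equations.

## Models

**Light response (A-Q).** Non-rectangular hyperbola with parameters
(`A_sat`, `phi_J`, `theta_J`, `R_d`); the `theta_J -> 0` limit is handled
analytically as the rectangular hyperbola. Gross assimilation is the lower
quadratic root, so it is bounded by both `phi_J*Q` and `A_sat`.

**CO2 response (A-Ci, FvCB).** `A_mod = min(A_c, A_j, A_p) - R_d` with
`A_c = V_cmax (C_i - G*)/(C_i + K_m)`, `A_j = J (C_i - G*)/(4 C_i + 8 G*)`,
`A_p = 3 V_TPU`. The fit estimates (`V_cmax`, `J_max`, `R_d`) by direct NLS
on the min rule (no smoothing), treating `J = J_max` — a saturating-light
assumption appropriate for the Q = 1500 umol m-2 s-1 protocols the
generator mirrors. `V_TPU` joins the fit only when the three highest-CO2
points flatten (slope < 0.01 umol m-2 s-1 per umol mol-1) or on request;
the TPU branch is the constant `3 V_TPU` form without an export-fraction
term. Kinetic constants (`Gamma_star`, `K_c`, `K_o`) are the Bernacchi
tobacco set (see `constants.py`) Arrhenius-scaled to the curve's mean
`T_leaf`; per-point adjustment is available behind a flag. A fixed
mesophyll conductance can be supplied to fit on a chloroplastic basis via
`C_c = C_i - A/g_mc`.

**Temperature responses.** Seven forms: Arrhenius; the peaked
(entropy/deactivation) form and its (T_opt, k_opt) re-parameterisation;
the Kruse log-quadratic in inverse temperature; macromolecular rate theory
(MMRT); and log-polynomial (Heskel) and plain quadratic polynomials in
degC. All T_ref-anchored forms return `k_ref` exactly at `T_ref` (298.15 K
by default). Under that anchoring the MMRT activation entropy cancels
algebraically from `ln k(T) - ln k(T_ref)`, so the MMRT fit estimates
(`k_ref`, `dH`, `dCp`) only; this is a property of the anchored
parameterisation, not an approximation. The peaked form's optimum has the
closed form `T_opt = H_d / (dS - R ln(E_a/(H_d - E_a)))`, which the tests
check against a brute-force argmax on a 0.001 K grid.

**Forward simulation.** Demand (the FvCB min rule at chloroplastic CO2)
is balanced against the linear supply `g_tc (C_air - C_c)` by Brent root
finding on (1e-6, C_air + 500) with a bisection polish, guaranteeing a
supply-demand residual below 1e-10 umol m-2 s-1. Electron transport
responds to light through the non-rectangular hyperbola with
(`phi_J`, `theta_J`, `J_max`). Leaf temperature is a required input: the
package deliberately ships no energy-balance model, but an external leaf
temperature solver can feed `T_leaf` directly.

**Light respiration.** Kok: OLS of `A_net` on `Q` in a configurable
low-light window (default 40-100 umol m-2 s-1; the method fixes the idea,
not the window). Yin: OLS on `Q * phi_PSII / 4`. Walker-Ort: per-irradiance
low-Ci A-Ci lines, then OLS of intercepts on slopes, whose coefficients are
(-C_i*, -R_light). `R_light` is always reported as a positive magnitude.
With exactly two irradiance levels the Walker-Ort point estimate is exact
but SEs are undefined and flagged.

**Variable-J mesophyll conductance.** Harley-style per-observation
algebra (`C_c`, `g_mc`, `dCc/dA` — formulas in the module docstring).
Records with `dCc/dA` in [10, 50] are reliable; the bounds are inclusive
(a documented reading of "between 10 and 50"). The summary `g_mc` is the
mean over reliable records (median is a one-line change if preferred);
records where `J_F <= 4 (A + R_light)` or `C_i <= C_c` are excluded with a
reason string. No default fluorescence calibration is invented: `J_F`
must be measured or `calib` supplied.

**Stomatal models.** Ball-Berry, Leuning and Medlyn in their standard
explicit forms (Medlyn in the common explicit approximation of the
optimal-stomata result, not the implicit root). Ball-Berry humidity is a
fraction, not percent. The Leuning CO2 compensation point `Gamma` is held
fixed (user-supplied) for identifiability; `D0` is estimated.

**Hydraulic vulnerability.** Sigmoidal `PLC = 100/(1 + exp(a(psi - b)))`
and Weibull `PLC = 100 (1 - exp(-(-psi/b_w)^c_w))`, both fitted; derived
thresholds use the sigmoidal tangent convention `P_e = b + 2/a`,
`P_50 = b`, `P_max = b - 2/a`. Internally water potential is <= 0 MPa;
inputs given as positive tensions are auto-negated with a notice. The PLC
basis is used throughout (relative conductivity is `1 - PLC/100`).

**Pressure-volume curves.** The post-turgor-loss linear region of
`1/|psi|` vs `100 - RWC` is found by growing the point set from the driest
end and keeping the largest set with R^2 >= 0.995 (configurable; with an
unreachable threshold the best-R^2 region is used with a warning). The
intercept gives `pi_o = -1/intercept`; turgor is `psi` minus the fitted
osmotic line; the TLP is the interpolated first zero-turgor crossing (with
a small tolerance so grid points lying exactly at zero turgor are caught
despite round-off); `C_ft` is the pre-TLP slope of RWC fraction vs `psi`
and the elastic modulus the pre-TLP slope of turgor vs RWC fraction.
Because the region selection itself responds to noise, the within-region
OLS standard error understates the sampling variability of `pi_o`; the
reported SEs for `pi_o`, `psi_TLP` and `RWC_TLP` therefore come from a
pairs bootstrap (100 resamples, fixed internal seed for reproducibility)
that re-runs the entire selection pipeline, floored at the delta-method
value.

**Meta layer.** `fit_many` applies any conforming fitting callable per
group with per-group failure capture; `compile_data` flattens grouped
results to parameter tables, fitted-value tables or figure collections;
`analyze_sensitivity` re-runs a fitter over a <= 2-factor grid of assumed
inputs; `compute_sensitivity` adds the local measures

    parameter effect    PE(p) = (m(p) - m(p_ref)) / m(p_ref)
    control coefficient CE(p) = PE(p) / ((p - p_ref)/p_ref)

relative to a user-defined reference point. These finite-difference
relative forms are the package's documented stand-ins for the cited
definitions in the sensitivity literature; CE tends to the analytic
elasticity d ln m / d ln p as the step shrinks. On two-factor grids CE for
one factor is defined along the axis where the other factor is at its
reference (NaN elsewhere), so axis slices reproduce one-factor runs
exactly.

## Synthetic data: what it emulates and what it does not

`generate_synthetic_curve` evaluates the forward model of each curve kind
at known true parameters over protocol-style driver grids and adds i.i.d.
Gaussian noise (seeded; identical design + seed gives identical bytes).
Default designs: light responses at {0, 25, 50, 75, 100, 125, 150, 375,
1500} umol m-2 s-1; CO2 responses at 12 Ci set-points from 50 to 1500
umol mol-1 (optionally replicated over a 17.5-40 degC leaf-temperature
series in 2.5 degC steps); temperature responses at 11 points over
278-328 K; Kok/Yin windows with 7 light levels and Walker-Ort with 8
irradiances (enough residual degrees of freedom that +/-3 SE intervals
behave nearly normally); PV curves built from ideal symplastic dilution
(`pi = 100 pi_o / RWC`) with a linear turgor segment.

Default noise standard deviations, chosen once as representative of good
instrument practice: 0.3 (A-Q) and 0.5 (A-Ci) umol m-2 s-1 on `A_net`, 1.0
on temperature-response rates of order 50-100, 0.005 mol m-2 s-1 on
`g_sw`, 0.05 umol m-2 s-1 in the respiration windows, 0.1 on `A_net` for
variable-J inputs, 2 PLC points, 0.01 MPa on PV water potentials.

What the generator does **not** emulate: heteroscedastic or drift noise,
instrument stability filtering, leaks and diffusion artefacts at low CO2,
fluorescence calibration error (the generated `phi_PSII` is exactly
consistent with `J_F`), or correlated errors between `A_net` and `C_i`
(which share sensors in a real IRGA). Passing recovery tests therefore
demonstrates correctness of the estimators under the stated error model,
not robustness to instrument pathology.

## Validation protocol

`scripts/acceptance.py --seed S --out results/acceptance.json` recomputes,
from scratch: noiseless round-trip recovery error for every family; 200
noisy replicates per family with the fraction of parameter checks whose
truth lies within +/-3 reported SE (parameters whose SE is undefined by
construction in a replicate — an unidentifiable `J_max`, the two-line
Walker-Ort — are excluded); solver residuals on 100 random parameter
draws; the reliability filter on a constructed table whose `dCc/dA` values
include exactly-representable boundary cases 10 and 50; meta-layer grid
bookkeeping and the identity-function control coefficient; and byte-level
determinism of a fixed-seed run. Problem sizes (200 replicates, 100 draws)
are the package's validation defaults and complete in a few minutes on one
core.

## Known limitations

* C3 biochemistry only; no C4/CAM pathways.
* A-Ci fitting is Ci-basis (plus fixed-g_mc conversion); no variable-g_mc
  or full Cc-basis estimation.
* The Kok method is the plain two-parameter regression, without
  curvature corrections.
* `fit_aci_response` assumes saturating light when equating the fitted
  electron-transport parameter with `J_max`; at sub-saturating light the
  estimate is the realised `J`, not the capacity.
* Local (reference-relative) sensitivity only; no global variance-based
  methods.
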