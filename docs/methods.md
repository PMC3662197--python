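# Methods

## Scope

`thermolipase` implements the computational side of a lipase bioprospecting
workflow: (i) classification and selection of strains screened for
extracellular lipase production in two modes (Rhodamine-B/olive-oil agar
halos, liquid-culture pNPP activities), (ii) two-step series
thermal-deactivation kinetics fitted to residual-activity time courses, (iii)
Arrhenius activation-energy regression of the fitted rate constants, (iv)
pH/temperature activity-profile summaries, and (v) seeded synthetic-data
generators so that every stage can be validated without laboratory data.

## The deactivation model

Thermal inactivation is modelled as a series mechanism through a partially
active intermediate,

    E0 --k1--> E1 --k2--> E2,

with first-order rate constants k1 and k2 (min⁻¹) and specific-activity
ratios α1 = E1/E0 and α2 = E2/E0. The final state is taken as fully inactive
(α2 = 0), so the observed residual activity (fraction of the t = 0 activity)
is

    α(t) = [1 + α1·k1/(k2 − k1)]·e^(−k1·t) − [α1·k1/(k2 − k1)]·e^(−k2·t).

Assumptions: both transitions are first order and irreversible; the measured
activity is a population average E0 + α1·E1 normalized to 1 at t = 0; α1 is
physically confined to [0, 1]. Under these constraints α(0) = 1 exactly, α is
nonincreasing and α → 0.

**Singular branch.** The closed form is undefined at k1 = k2; when
|k2 − k1| < 10⁻⁸·k1 the analytic limit α = (1 + α1·k1·t)·e^(−k1·t) is used.
The switch tolerance was chosen so that the worst-case discontinuity across
the branch boundary is below 10⁻⁷ (tested against a stiff ODE integration of
the two-state system at 10⁻¹²/10⁻¹⁴ tolerances).

## Fitting

`TwoStepDeactivation.fit` minimizes the unweighted sum of squared residuals
with `scipy.optimize.least_squares` (trust-region reflective) under
α1 ∈ [0, 1], k1, k2 > 0. No ordering k2 < k1 is imposed. Because the
biexponential SSR surface has local minima — including a mirror mode in which
k1 plays the role of an instantaneous activity drop — the fit is multistarted
(default 16 starts): the first start is data-driven (k1 from the slope of
ln α over the first two time points, k2 from the last two, α1 from the
mid-course level) and the rest perturb the rate constants over ±2 decades.
Among converged starts within a relative SSR tolerance of 10⁻⁶ of the best,
the solution with the smaller k1 is returned, which resolves the mirror-mode
label ambiguity. Standard errors come from the Jacobian-based covariance
s²·(JᵀJ)⁻¹ at the optimum (pseudo-inverse, so boundary/ridge solutions return
finite but honest numbers); they are linearized SEs and understate the
uncertainty when a parameter sits on a bound.

The nested comparison model is the single exponential α = e^(−k·t), fitted the
same way with k > 0. A fitted total decay k·(t_max − t_min) below 10⁻³ is
flagged non-identifiable (the data carry no decay signal). Model preference
uses the Gaussian-likelihood AIC, n·ln(SSR/n) + 2p; the two-step model is
preferred only when it improves AIC by more than 10 (configurable — a
deliberately conservative default for nested models). An SSR at
rounding-error level (≤ n·10⁻²⁴) is treated as a perfect fit, whose AIC is
the −∞ limit.

Half-lives solve α(t) = 1/2 by geometric bracket expansion plus Brent's
method; the curve's monotone decay to 0 guarantees a unique crossing.

## Arrhenius regression

ln k is regressed on 1/T (T in kelvin, offset 273.15) by ordinary least
squares; Ea = −slope·R with R = 8.314 J·mol⁻¹·K⁻¹, reported in kJ/mol. An
optional 1/SE² weighting (delta-method SEs on the log scale) is provided but
is not the default, since the published analysis used plain linear
regression. Identical rate constants at all temperatures give a degenerate
fit, reported as Ea = 0 with R² = 0 and a flag. The packaged activation
energies (`table2_ea.csv`) are reference context only: they were regressed
from unrounded per-replicate constants, so OLS on the rounded table means
does not reproduce them; tests therefore compare the implementation against
an independent closed-form OLS oracle, not against those printed values.

## Screening

Liquid-culture activities are the mean of the 48 h and 72 h measurements. A
printed 0.000 is a measured zero and enters the mean; a "−"/"ND" entry is a
non-detection and contributes nothing; a strain is class `none` only when
both entries are non-detections. The class boundary is strict: `significant`
means mean > 0.05 nkat/mL. These conventions are the only ones that
reproduce the packaged table's 56/19/26 partition (a max-of-two-timepoints
statistic, for instance, yields 7 rather than 19 `low` strains). Halo
positivity counts "+" or "++" at either time point. Percentages are rounded
half-up to one decimal.

The high-producer selection rule takes the union of strains with mean
activity > 0.75 nkat/mL and strains with an intense ("++") halo at either
time point; "intense" must mean "++" because one selected strain (SP93, mean
0.62 nkat/mL) can only have qualified on its halo. Applied to the packaged
table the rule yields ten strains — the nine that were characterized further
plus SP95 (mean 0.814 nkat/mL, no halo). The implementation applies the rule
as written and exposes the per-criterion breakdown (`SelectionResult`)
rather than hard-coding the nine; the pipeline report lists strains selected
on activity alone so the anomaly is visible.

The pNPP assay conversion is unit arithmetic: released pNP (nmol) =
ΔA410/slope with a per-pH calibration slope in AU/nmol; dividing by the
incubation time (s) and sample volume (mL) gives nkat/mL. Readings below the
blank clamp to zero.

## Synthetic data

`simulate_timecourse` draws each observation as the closed-form curve plus
independent additive Gaussian noise on the activity-fraction scale
(default SD 0.02, a typical triplicate scatter for this assay; the noise
distribution is an assumption — only SD error bars are available for the
real data). Defaults: 3 replicates, explicit integer seed, no truncation at
zero (truncation is opt-in so that fits to simulated data stay unbiased; it
exists to mimic instruments that cannot report negative activities).

Two sampling layouts are provided. `default_time_grid` is the routine 1-h
window (0–60 min, 5-min steps). For thermostability parameter-recovery
studies, `design_time_grid(k1, k2)` schedules 13 points the way an
experimentalist samples a biphasic decay: about half linear over the fast
phase (to 3/k1) and the rest geometric out to 2/k2. This is not cosmetic: a
Fisher-information analysis shows that with slow constants of order
10⁻⁴ min⁻¹ a 60-min window leaves (α1, k1, k2) on a likelihood ridge
(linearized SE of α1 ≈ 0.5), while the phase-spanning design recovers all
three parameters to a few percent at noise SD 0.02 — the precision at which
such parameters are in fact reported. One caveat the tests document: when
the fast-phase amplitude 1 − α1 is small (≈ 0.12 for one packaged parameter
set), the information bound on k1 is ≈ 19% regardless of the 13-point
layout, so ±15% recovery for that set is at the mercy of the noise draw.

`simulate_screen` draws class labels (none/low/significant) from a
multinomial, then draws activities consistent with the label (low: both time
points uniform on (0, 0.05], so the mean respects the boundary; significant:
log-uniform over 0.055–2.5 nkat/mL, the range spanned by real screens). Halo
scores are drawn independently of the liquid class at a configurable rate,
reproducing the plate/liquid discordance seen in real dual-mode screens. The
generator does not emulate growth kinetics, carbon-source induction, plate
images, or correlation between halo intensity and liquid titer — tests built
on it validate the analysis chain, not the biology of induction.

`simulate_arrhenius_series` evaluates k(T) = k_ref·exp(−Ea/R·(1/T − 1/T_ref))
exactly, for round-trip tests of the regression.

## Recovery-study conditions

The acceptance-level recovery checks simulate triplicate 13-point
phase-spanning courses at noise SD 0.02 for each packaged parameter set, fit
with 16 multistarts, and use the median fitted parameter over 5
independently seeded experiments as the recovery statistic (medians are also
what the generator's own recovery invariant is stated in). Tolerances: α1
within ±0.05 for every set; k1 and k2 within ±15% where the phases are well
separated (k1/k2 ≥ 50). The model-preference check uses 100 seeded
replicates per scenario. These problem sizes run the full suite in under two
minutes on one core.

## Known limitations

- Linearized SEs only; no profile likelihood or bootstrap. The "±" values in
  the packaged parameter table are assumed to be regression SEs.
- Time courses are expected pre-normalized (α(0) ≡ 1); per-replicate
  normalization of raw activities is out of scope.
- No deactivation variants with an active final state (α2 ≠ 0), more than
  one intermediate, or global fits across temperatures.
- Arrhenius fits assume linearity in 1/T; no Eyring or curved models.
- Activity-profile optima are grid-restricted by design (no interpolation),
  so an optimum is only as fine as the measurement grid.
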