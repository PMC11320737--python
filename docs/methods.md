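# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `mabdev`, in the package's own terms.

## Colloidal self-interaction (DLS)

The apparent diffusion coefficient of a monodisperse protein in the dilute
regime is modelled as linear in concentration,
D_app(c) = D0·(1 + kD·c), with D0 the self-diffusion coefficient at
infinite dilution and kD the diffusion interaction parameter. Negative kD
indicates net attractive protein–protein interactions. The fit is ordinary
least squares of D_app on c — exact and iteration-free — with
kD = slope/intercept. Concentrations are user-facing mg/mL, so the raw
ratio is in mL/mg; it is reported ×1000 in mL/g, the unit of the
conventional −15 mL/g screening threshold. The kD standard error comes
from the delta method for a ratio using the full 2×2 OLS covariance.
The threshold comparison is strict (kD < −15 flags); boundary equality
passes. The regression uses all supplied rows (replicates pooled, not
averaged); because OLS point estimates are invariant to row order and to
whole-dataset duplication, this choice does not move the estimate, only
the nominal standard errors.

Dilute-regime trends for the Stokes–Einstein extrapolation are
D(c) = A·e^(−r·c), fitted by OLS on log D (a deterministic linearization;
a nonlinear polish is available behind `nonlinear_refine=True` but off by
default), and Z-average diameter log10 Z = a·log10 c + b by OLS. The
theoretical viscosity is η(c) = k_B·T/(3π·d_H(c)·D(c)) at T = 298 K
(configurable), with d_H the Z-average *diameter*; 3π with diameter is
identical to the textbook 6π with radius. Output is converted Pa·s → cP.
Note the extrapolation's known bias: trends measured at 1–20 mg/mL carry
no crowding information, so high-concentration values are order-of-
magnitude indicators only. Monotone growth of η(c) requires the
exponential diffusion decay to dominate the power-law size growth
(a/c < r on the grid); it is not automatic whenever d_H grows and D
decays, since growing d_H by itself *lowers* η.

## Viscosity–concentration models

Three empirical models cover the concentrated regime, all anchored at the
buffer viscosity η0 = 1.13 cP (default; the DLS dispersant value 1.26 cP
is a separate configuration key used only for DLS):

* exponential growth η = Y0·e^(k·c): nonlinear least squares (lmfit),
  seeded from the log-linearized OLS solution;
* Tomar ln(η/η0) = ln A + B·c: pure OLS on the log scale (exact);
* modified Ross–Minton η = η0·exp([η]c/(1 − (k/v)[η]c)) with [η] the
  intrinsic viscosity (mL/g, converted to mL/mg internally), k the
  crowding factor and v the Simha shape parameter: bounded least squares
  with a 3×3×3 multistart grid over ([η], k, v). Starts whose optimum
  leaves the denominator nonpositive anywhere on the data span are
  rejected; infeasible regions carry a graded penalty so the solver has a
  slope back to feasibility. **Identifiability:** k and v enter only
  through k/v, so only [η] and k/v are determined by data; the reported
  (k, v) pair is one representative of the optimum ray. The model form is
  a pluggable callable should a different crowding closure be preferred.

Records are first filtered to steady measurements whose pressure-over-
sensor-position linear fit has R² ≥ 0.998 (strict at the boundary: 0.998
is kept), then shear-rate replicates per concentration are averaged after
a Newtonian-plateau check (max/min ratio ≤ 1.05) — instruments report one
apparent viscosity per concentration and the generated fluids are
Newtonian, so a larger spread is treated as an error rather than silently
averaged. Interpolation evaluates the fitted closed form; evaluation
beyond 1.25× the fitted span warns of extrapolation.

## Intrinsic viscosity and Huggins coefficient

From relative viscosity η_rel = η/η0, specific η_sp = η_rel − 1 and
reduced η_red = η_sp/c (c converted mg/mL → g/mL so η_red is mL/g), the
dilute-regime law is η_red = [η] + k_H·[η]²·c. OLS of η_red on c (g/mL)
gives [η] as intercept and x = k_H[η]² as slope; k_H = x/[η]² is stored
bit-exactly as that ratio. The uncertainty uses first-order (delta-method)
propagation,

σ_kH = |k_H|·sqrt((σx/x)² + (2σ[η]/[η])²),

degenerating to σx/[η]² at zero slope. The formula deliberately carries no
slope–intercept covariance term; the Monte-Carlo validation in the test
suite therefore perturbs [η] and x independently by their standard errors
(10⁵ draws), which checks the first-order approximation itself. A full
joint-sampling MC would add the (negative) OLS covariance contribution,
raising σ_kH by tens of percent in dilute designs — users wanting that
should propagate from the covariance matrix directly. Regression is
unweighted (replicates pooled). k_H > 0.5 (strict) is classified
"poor solvent".

## Thermal unfolding (nanoDSF)

The 350/330 nm intensity ratio is smoothed with a Savitzky–Golay local
polynomial (default window 11 grid points, order 3) and differentiated by
centred differences (`numpy.gradient`). Local maxima with prominence above
`min_prominence` (default 0.1) × the derivative maximum are the domain
transition midpoints Tm1, Tm2, … in temperature order. T_agg is the
derivative argmax of the scattering trace when present. T_onset is the
first temperature where the smoothed derivative exceeds 10 % (configurable)
of the first peak's height — an explicit package convention, since
instrument software does not document its onset rule. The ramp rate
(2 °C/min typical) is metadata; analysis operates on the temperature grid.
For noisy traces a wider smoothing window (e.g. 15–31 points) than the
default is appropriate; window choice trades peak-merging against noise
peaks, and the detected-peak-count guarantee in the tests holds for
transition separations ≥5× width.

## AC-SINS

Plasmon peaks are localized by fitting a quadratic to the points within
±window/2 (default ±20 nm) of the raw absorbance argmax and reporting the
vertex — sub-grid resolution on ~1 nm grids. A concave-up fit or a vertex
escaping the window falls back to the raw argmax. The red shift is the
fitted sample peak minus the fitted control peak, referenced to the
conjugate-only control by default; the plate passes QC only when the
negative control peaks strictly below 535 nm. Peak positions are invariant
to absorbance rescaling.

## SPR kinetics (1:1 Langmuir)

For analyte concentration C the association phase is
R(t) = Rmax·C/(C + K_D)·(1 − e^(−(ka·C+kd)·t)) and dissociation decays as
R_end·e^(−kd·(t − t_assoc)); K_D = kd/ka. The global fit shares ka, kd and
Rmax across all injections, optimizing log10 ka and log10 kd (bounded) for
scale robustness. χ² is the DOF-corrected mean squared residual
Σr²/(n − 3), the common instrument convention. Dissociation-only data
leave ka unidentifiable and raise an error rather than returning a
meaningless estimate. Mass-transport limitation and bivalent analyte
models are out of scope.

## Stability flagging (aSEC)

Each (day, condition) row carries %monomer, %HMwS, %LMwS summing to
100 ± 0.01. Rules: monomer_fail iff %monomer < 95 (strict); hmws_fail iff
HMwS growth from the condition's day-0 baseline exceeds 2 percentage
points (strict; day-0 rows can never fail it). An `absolute` mode compares
the HMwS level itself to the ceiling instead, since threshold phrasing in
practice is sometimes level-based; delta-from-baseline is the default.
The earliest failing day is reported per condition.

## Homology-model ranking

Every geometric quality metric is min–max normalized across candidate
models onto [0, 1] with 0 = best after orientation alignment (metrics
declare `higher_is_better`); the packing score uses the inverted form,
i.e. the opposite orientation convention to the regular metrics. Constant
metrics map to all-zeros rather than dividing by zero. The composite NDV
is the unweighted mean; selection minimizes composite NDV with ties broken
by lowest heavy-atom RMSD-to-average and then lexical model id, making the
choice fully deterministic. NDV is invariant to affine rescaling of any
input metric. Computing the geometric scores from structures is out of
scope — the package consumes score tables.

## Synthetic data

Generators are pure functions of (parameters, seed): additive Gaussian
noise on the observable scale, `numpy.random.default_rng` seeded per call.
What they emulate — and do not:

* DLS: the exact linear D_app law and log-linear Z-average growth; no
  cumulant analysis, polydispersity or multi-species effects.
* Viscosity: the three closed forms with shear-independent (Newtonian)
  values and a perfect pressure-fit R² of 1.0; no shear thinning or
  pressure transients.
* Thermograms: sums of logistic sigmoids (chosen because the logistic
  derivative peaks exactly at its midpoint, giving analytic test oracles);
  real traces have sloping baselines and asymmetric transitions.
* Spectra: Gaussian plasmon bumps; real AC-SINS spectra are asymmetric.
* Sensorgrams: ideal 1:1 phases with no drift, bulk shift or mass
  transport.
* Purity: linear per-day drift with per-condition deltas constrained to
  sum to ~0, preserving the 100 % closure by construction.
* Score tables: independent Gaussian metric draws plus a gamma-distributed
  RMSD column.

Passing round-trip tests on these generators demonstrates estimator
correctness under the assumed data model, not robustness to instrument
artifacts absent from it.

Default study conditions used by the `analysis/` drivers: DLS at 0.5–20
mg/mL, viscometry at 10–150 mg/mL with interpolation at 180 mg/mL, the
dilute intrinsic-viscosity regime at 5–50 mg/mL, a 20–95 °C ramp, five
SPR analyte concentrations (1–100 nM), and purity monitoring at days
0–57 under 5 °C, 25 °C and freeze–thaw conditions. Replicate counts in
comparable studies are small (N = 2–3); within-replicate noise magnitudes
are rarely published, so generator noise defaults are configurable
choices (e.g. 1–2 % of signal for DLS, 0.02 cP for viscosity, 5×10⁻⁴ on
the DSF ratio, 0.2 RU for SPR) rather than measured values.

## Numerical conventions

* All screening comparisons are strict inequalities; boundary equality
  never flags.
* OLS is implemented once via closed-form normal equations (exact,
  deterministic) and reused by every linear(izable) fit; nonlinear fits go
  through lmfit's trust-region least squares.
* Concentration units: mg/mL user-facing everywhere; g/mL internally where
  mL/g outputs require it ([η], k_H, reduced viscosity, kD reporting).
* Degenerate inputs raise typed errors (`InvalidInputError`,
  `DegenerateFitError`, `DomainError`, `EmptyResultError`,
  `FitFailureError`, `NoTransitionError`) rather than returning NaNs.
* Problem sizes in tests and drivers (e.g. 20 seeded Ross–Minton oracle
  problems, 10⁵ Monte-Carlo draws, 50 ranking tables, 10-seed SPR noise
  studies) were chosen as the smallest sizes that exercise the stochastic
  claims convincingly; all are package choices and easily scaled up in
  user code.

## Known limitations

* The Ross–Minton (k, v) pair is reported but only k/v is identified.
* The GSE extrapolation inherits the dilute-regime trend fits' bias at
  formulation concentrations.
* σ_kH is first-order and covariance-free by specification of the formula;
  see above for when that understates the uncertainty.
* Correlation analysis reports coefficients and pair counts, not
  p-values, by default; with two molecules and a handful of replicates,
  descriptor–measurement correlations are descriptive, not inferential.
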