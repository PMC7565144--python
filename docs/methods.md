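# Methods

## Model

`csclineage` implements average (deterministic) population dynamics of a
unidirectional cancer stem cell hierarchy.  Three compartments — cancer stem
cells (CSC), intermediate progenitors (P), and terminally differentiated
cells (D) — evolve under eight first-order pseudo-reactions, each with one
rate constant k_j (per day): CSC symmetric renewal (k1), CSC asymmetric
division (k2), CSC symmetric differentiation (k3), P renewal (k4), P terminal
differentiation (k5), and per-compartment death (k6, k7, k8).  Balancing
production, division and death per compartment gives the linear system

    dCSC/dt = (k1 − k3 − k6)·CSC
    dP/dt   = (k2 + 2k3)·CSC + (k4 − k5 − k7)·P
    dD/dt   = 2k5·P − k8·D

with total burden N = CSC + P + D and tumor volume V = N / ρ at constant
density ρ = 3.2×10⁵ cells/mm³ (configurable; an order-of-magnitude figure
for epithelial tumors).  Dead cells are removed immediately — no dead-cell
compartment is tracked.  Plasticity (D→CSC), quiescence, multiple CSC
lineages, and spatial structure are deliberately outside the model.

Because the dynamics are linear, only rate *ratios* shape the solution; the
parameter space is expressed as Φ ratios relative to k1 (Φ_5/4 relative to
k4).  The published working point is Φ = (1, 0.01, 5.35, 0.8, 0.01, 0.1, 1),
i.e. k = (1, 1, 0.01, 5.35, 4.28, 0.01, 0.1, 1) at k1 = 1.  It satisfies five
biological constraints evaluated by `check_constraints`: k6 < k7 < k8 (death
accelerates with differentiation), a stationary long-run CSC fraction, and a
bulk dominated by differentiated cells (P/N ≤ 0.2, D/N ≥ 0.8).

## Closed form and numerics

The system is lower-triangular, so its eigenvalues are the compartment
exponents a = k1−k3−k6, b = k4−k5−k7, c = −k8, and the solution is a
combination of exponentials whose coefficients are divided differences of
exp over the exponents.  `closed_form` evaluates these via the overflow-safe
form dt·e^{max·dt}·(1−e^{−s})/s; nodes closer than 1e−9 (relative) switch to
the confluent limit (dt·e^{a·dt}, dt²/2·e^{a·dt}), so repeated exponents
never produce NaNs.  The closed form is the *oracle*; the simulation engine
(`simulate`) integrates the ODEs numerically with LSODA (rtol 1e−10, atol
1e−12) and is required by the tests to agree with the closed form to ≤1e−8
relative error.  Long-run compartment fractions come from the dominant
eigenvector (`asymptotic_fractions`); when a ≤ b the P-led mode is reported
with a flag instead of failing.  `integrate_to_equilibrium` integrates the
*normalized* fraction ODE df/dt = Jf − (1ᵀJf)f, which cannot overflow even at
k1 = 1 where absolute counts would exceed float range within ~700 days; it is
the independent cross-check of the analytic mode.

## Treatments

Therapy enters in two forms only: windowed multiplicative (or replacement)
modification of a rate constant over a half-open window [start, end), and
instantaneous fractional kills per compartment.  The integrator restarts at
every window edge and event time so discontinuities are never smoothed
across.  Factors multiply the *baseline* rate; overlapping factor modifiers
compose multiplicatively (logged).  Tiny negative counts from integrator
drift (> −1e−9·N) are clamped to zero; larger negatives raise.

A pure ODE never reaches zero, so a deterministic model cannot distinguish
"eradicated" from "vanishingly small".  `simulate` therefore accepts an
`extinction_threshold` (cells): at schedule breakpoints, compartments below
it are set to zero.  The default is 0 (pure ODE semantics); scenario
analyses and the pipeline default use 1 cell — a sub-single-cell
deterministic population is biologically extinct.  Relapse is
operationalized as the volume re-attaining its pre-treatment value with
positive slope; this is the simplest reading of relapse days off volume
curves and is a package choice, not a field standard.

The scenario library hard-wires the studied configurations: bulk kills of
95–99.99%, CSC-directed killing (k6×100), P-directed killing (k7×15 or
×100), forced differentiation (Φ_5/4 0.8→1.1, i.e. k5×1.375; separately
k5×1.20), CSC renewal inhibition (k1÷1000), and their combinations, plus
ovarian-cancer presets (chemo as an equal death-rate elevation of all three
compartments, CPI613 as a k6 elevation).  The chemo/CPI613 magnitudes were
never published; they are free keyword arguments (defaults 10 and 100) meant
to be calibrated with `fit_treatment`.

## Fitting

With Φ fixed, every rate is proportional to k1, so calibrating a growth
curve is a 1-D problem.  `fit_growth` minimizes the sum of squared volume
residuals over k1 with a bounded Brent search; the bracket is derived
deterministically from the data's crude log-slope (guess/20 to guess×20), so
fits are reproducible from inputs alone.  The objective is on arithmetic
volumes by default (late, large measurements dominate, matching how
exponential growth curves are fitted visually); `log_objective=True` switches
to log-volumes.  An optional initial-count scale is profiled out in closed
form.  `fit_treatment` fits the multiplier a treatment applies to one (or
several, for bulk chemo) rate constants over a known window, searching over
log10(factor) in [−2, 5]; flat-objective regions are detected and logged.
`constrained_phi_search` grid-evaluates Φ candidates, screens them with the
(scale-invariant) constraint set before fitting, and returns passing
combinations sorted by objective.

Initial compartment splits: experiments report only the inoculum size and
CSC fraction.  The non-CSC remainder is split P:D per the dominant-mode
ratio by default (`split_policy="asymptotic"`), with `all_p`/`all_d` as
explicit alternatives.

## Synthetic data

The original validation curves were digitized from third-party figures and
exist nowhere as numbers, so the generator produces datasets with the same
structure instead: exponential hierarchical growth under the published Φ,
the *printed* inoculum designs (3×10⁴ cells at 2% or 0.31% CSC; 1×10⁶ cells;
3% and 7.65% CSC for the ovarian series; a four-week CSC-directed course
starting day 1), weekly sampling, and multiplicative lognormal noise
(default σ = 0.1 — xenograft volume error scales with size; σ = 0 reproduces
the deterministic curve exactly).  Absolute time scales (k1 per experiment)
were never published; templates use 0.1/day (0.07 for the 120-day colon
course, 0.08 for the ovarian series), chosen once for realistic overall
doubling times of roughly a week.  The 120-day base tumor template seeds the
inoculum at the model's equilibrium CSC share (0.18%, inside the 0.1–2.5%
range reported for sorted CSC fractions): an established, serially passaged
xenograft carries the equilibrium composition, and an off-equilibrium
inoculum would inject a ~1/(a−b) ≈ 1400-day compositional transient that the
scenario comparisons are not about.  Each dataset carries its generating
parameters as ground truth (and in a JSON sidecar on disk), so recovery
tests never re-derive them.

What passing tests show — and do not show: parameter recovery and scenario
behavior are demonstrated on data generated *by the model itself* plus
idealized noise.  Real xenograft series have correlated errors, measurement
floors, animal-to-animal heterogeneity and non-exponential late growth; none
of these are emulated, so the tests validate the machinery, not the model's
biological adequacy.

## Sizes and tolerances

Recovery studies use 50 replicate seeds at n = 11 weekly points (chosen to
keep the full suite around a few seconds); noiseless k1 recovery is required
to 0.1%, median error under 5% noise to 5%.  Closed-form/integrator
agreement is required to 1e−8 relative over 50 random parameter draws on
[0, 20/k1].  Fraction equilibration stops when the drift rate falls below
1e−12/day (fraction error ~1e−10 at the published spectral gap of 0.01/day).
Scenario comparisons run the 120-day base course to day 420 on a 0.5-day
reporting grid.

## Known limitations

* The relapse and extinction definitions are operational choices; results
  near their thresholds (e.g. a compartment hovering around one cell at a
  breakpoint) flip qualitatively with the threshold.
* Treatment multipliers of strongly saturating interventions are weakly
  identified from volume data alone (flat objective); the fitter flags but
  cannot cure this.
* The Φ grid search is exhaustive and meant for coarse grids; it makes no
  attempt at continuous optimization over the seven-dimensional ratio space.
* With `extinction_threshold=0` and deep-decay scenarios, compartment counts
  can fall many orders below one cell; integrator `atol` must be tightened
  (e.g. 1e−30) for the sub-1e−12 fraction regime to be resolved.
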