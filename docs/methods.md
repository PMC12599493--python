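# Methods

This note documents the models behind `probioferm`, the provenance of every
default parameter, the numerical choices, and what the synthetic-data
generators do and do not emulate.

## Screening designs and effect estimation

Plackett–Burman designs are taken as columns of a normalized Hadamard matrix
of order N: Paley construction I (orders 8, 12, 20, 24, from the quadratic
residues of the prime N − 1), Sylvester doubling (16), and Paley
construction II with q = 17 (36). Every construction is checked at build
time against H·Hᵀ = N·I, and every issued design against column balance and
pairwise orthogonality, so the statistical properties — not a pinned layout
— are the contract. The exact run sheet a commercial DoE package would emit
is not reproducible and is not needed: on an orthogonal design all main
effects are estimated independently regardless of which Hadamard
representative is used.

The reference screening structures are 36 base runs + 1 center run for the
14-factor biomass medium screen and 12 + 1 for the 5-factor EPS screen.
With intercept and a 0/1 center-point (curvature) term these leave residual
degrees of freedom 21 and 6, which reproduce the published significance
margins t₀.₉₇₅(21) = 2.080 and t₀.₉₇₅(6) = 2.447 and are the only
decomposition consistent with both.

Coding uses z = (natural − center)/half-range; natural-unit coefficients
are coded coefficients divided by half-ranges, with the intercept absorbing
the centering offsets. Standardized effects are t-ratios (coefficient/SE),
the Pareto-chart convention. The OLS itself is delegated to statsmodels;
the test suite checks it against a direct normal-equations solution on
random instances.

One data repair: the printed MgSO₄ factor row lists levels 0 / 0.25 / 0.125,
which violates low ≤ center ≤ high; the bundled factor table uses
0 / 0.25 / 0.5, restoring the doubling pattern of the neighboring rows. No
regression coefficient depends on this. The response units of the biomass
screen are never stated and are treated as opaque throughout.

## Lactate inhibition kinetics

Two inhibition models are implemented:

* **Sigmoidal** μ(x) = μmax/(1 + e^{λ(x−x₀)}). Strictly decreasing, never
  exactly zero, μ(x₀) = μmax/2. The exponent is clipped at ±700 so extreme
  arguments return the limiting value, never NaN/overflow.
* **Power law** μ(x) = μmax(1 − (x/c)ⁿ) for x < c, else 0. The ceiling c is
  a hard tolerance: growth is fully blocked there.

Parameter fixture: μmax = 2.14 h⁻¹ and x₀ = 12.10 g/L are published values.
The steepness λ is not published anywhere; the fixture sets
λ = ln 2/(60 − 12.10) ≈ 0.01447 L/g so that μ(60 g/L) = μmax/3 exactly,
matching the reported three-fold rate reduction at 60 g/L. For the power
law, c = 120 g/L is the published blocking concentration and n = 2 is a
documented free choice. Because the sigmoid's operational "tolerance" is
ambiguous (the curve never reaches zero), it is defined as the
concentration where μ drops below 1% of μmax (configurable).

**Fitting.** Unweighted nonlinear least squares on μ (no weighting scheme
is published). The default start follows a simple heuristic (μmax ← 1.1×max
observed μ; x₀ ← concentration nearest half-max; λ ← ln 2 over the
half-max-to-third-max gap; c ← first concentration with μ ≤ 5% of max, n ←
1). On the challenge grid this heuristic can land far from the optimum —
the fixture curve covers only the lower half of the sigmoid, so μmax is an
extrapolated parameter — and the fitter therefore also polishes from a
deterministic profile scan: for a grid of candidate μmax values the
remaining parameters have closed-form conditional estimates
(ln(μmax/μ − 1) is linear in x for the sigmoid; ln(1 − μ/μmax) is linear in
ln x for the power law), and the lowest-SSE polished solution wins. When an
explicit initialization is supplied, only that start is used, which makes
refitting from a recovered optimum idempotent. Non-convergence never
raises: the report carries `converged=False` with the best parameters
found. r² is 1 − SS_res/SS_tot; AICc in model comparison uses k = 4 (three
curve parameters plus the noise variance).

**Growth-rate extraction.** μ is the least-squares slope of ln OD600 versus
time. When no window is given, the contiguous span of ≥ 4 points with
maximal r² is used (ties: longer, then earlier, span); a perfectly flat
series returns μ = 0 with SE 0. The 5 h bottle-challenge protocol does not
state how μ was extracted, so automatic window selection is an explicit
design choice here.

**Tolerance line.** The 24 h challenge assay's final pH versus initially
added lactate is fit by OLS; the tolerance concentration is the analytic
crossing (pH_target − intercept)/slope. With the published line
0.0219x + 4.3153 and target pH 7 this gives 122.6 g/L (reported as 122).
The 122 g/L (pH line) and 120 g/L (μ curve) figures are kept as two
distinct read-outs; no reconciliation is attempted.

## Fermentation model

State (V, X, S, P, E) with balances given in the `fedbatch` module
docstring. Key choices:

* **Lactate is yield-coupled to substrate consumption** (dP = Y_PS·q_S·X −
  DP) rather than Luedeking–Piret, because the process yield is defined and
  measured as lactate produced per substrate consumed; this makes
  P-formed = Y_PS × S-consumed an exact invariant of the ODEs. Y_PS > 1 g/g
  is allowed verbatim (amino-acid co-catabolism); no elemental balance is
  enforced.
* **EPS** uses Luedeking–Piret (α μ + β)X since no EPS yield is defined.
* **Monod K_S = 0.1 g/L** (not published): growth is substrate-limited only
  near depletion, which is what makes the 1 g/L feed trigger meaningful.
* **Maintenance (m_S, default 0) and the β EPS term are scaled by the
  product-inhibition factor** μ_inh(P)/μmax and gated on substrate
  availability. This keeps two structural invariants exact: an exhausted
  unfed batch is stationary, and terminal P can never exceed the power-law
  ceiling c under any feed policy.
* **pH control is abstracted away** (held at 7 by the titrant loop); gas
  transfer, heat balance and titrant volume are out of scope.

Integration uses LSODA with rtol 1e-8/atol 1e-9, event detection for the
feed trigger (S crossing from above), the designed glucose total, and the
volume cap, with output sampled at ≤ dt_max spacing. Negative S round-off
is clamped at zero. Halving dt_max moves the terminal state by far less
than 0.1%.

**Feed design.** The glucose total M solves
P_target(V₀ + M/S_f) = P₀V₀ + Y_PS(S₀V₀ + M) by fixed-point iteration to
0.1% closure; simulating the designed policy therefore converges onto the
target titer from below as the residual sugar is consumed. The published
"exponential profile ranging from 8 to 10 g/L·h⁻¹" is interpreted as the
volumetric glucose delivery rate referenced to the *current* broth volume,
ramping exponentially between the endpoints over the estimated feeding
window (the authors' exact functional form is unknowable; the ramp constant
is configurable). The feed trigger defaults to 1 g/L, the midpoint of the
stated 1 ± 0.5 g/L band, and the feed concentration to 550 g/L, the
midpoint of the stated 500–600 g/L.

**Calibration fixtures.** Two kinetic configurations are bundled, both
using the sigmoid inhibition fixture: batch-optimized (Y_PS 1.11, Y_XS
0.215 = 4.3/20, α_E 0.5) and fed-batch (Y_PS 1.21, Y_XS 0.107 ≈ 10.7/100,
α_E 0.35), each back-computed once from the corresponding published process
summary row. The two Y_XS values differ because the wet process is not
constant-yield across modes; simulated wet-lab titers other than the
yield-forced lactate balance are calibration echoes, not predictions. The
viability proxy CFU/mL = k_viab·X/1000 uses k_viab = 1.59×10¹² CFU/g DCW,
calibrated once from the fed-batch row (1.7×10¹⁰ CFU/mL at 10.7 g DCW/L).

## KPIs

Yield and productivity are plain ratios (yield deliberately uncapped).
Fold changes carry an explicit `FoldConvention`: by default one decimal
below 10 and nearest integer at ≥ 10, with a two-decimal variant for
precisely quoted ratios; rounding is half-up. Published tables omit
substrate consumption and durations, so those are back-computed from the
printed yields and productivities and marked as consistency fixtures in
`fixtures.py`. Two published narrative inconsistencies are surfaced but not
adjudicated: the viability fold-change sentence swaps the 28- and 3-fold
ratios relative to its own table, and the bottle EPS increase appears as
both "13 times" (1.81/0.14) and "12.5-fold" (1807/144 mg/L).

## Wound closure

Closure % = 100(A₀ − A_t)/A₀ per field of view; crossing times to fixed
thresholds by linear interpolation between bracketing samples, with an
optional running-max envelope for non-monotone noisy curves (how the
original time-lapse software extracted crossing times is not stated).
Group summaries report mean ± sd (sd, not sem — the published ± is
unlabeled) over fields, censored fields excluded from means and counted.
Closure values are invariant to rescaling all areas, and crossing time is
non-decreasing in threshold for monotone curves.

## Synthetic data

All generators are pure functions of (config, seed) via
`numpy.random.default_rng`; at zero noise each is the exact inverse of its
fitting stage. Noise defaults are free parameters (the study reports
duplicates/triplicates but no error model): screening sd = 5% of the clean
response range, μ relative sd 1%, pH sd 0.05, fermentation observables
optionally lognormal-multiplicative, scratch timescale jitter sd 0.8 h with
plateau jitter 2%.

The scratch generator uses a zero-anchored logistic per field whose 20%
crossing is solved to match the group mean (control 8.8 h, treated 5.3 h)
and whose plateau matches the reported residual areas (65% / 95% closure).
A single logistic cannot also reproduce the published control 80% crossing
at 37.7 h — the real control curve slows late in the watch window — so
generator calibration is asserted only at the 20% threshold.

What passing tests show: the estimators recover known ground truth under
the stated noise models, and the simulator obeys its mass balances. What
they do not show: fidelity to the unpublished raw data (screening run
responses, μ datasets, fermentation time courses and area trajectories were
never deposited), strain behavior outside 42 °C/pH 7, or EPS kinetic form
(Luedeking–Piret is a modeling choice). Wet-lab outcomes (titers,
viability counts) enter only as calibration fixtures and fold-change
arithmetic.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data at
the study's own scales: 37- and 13-run designs, the 11-point lactate grid,
50-replicate recovery studies, 5 fields per scratch group, and ≤ 40 h
simulated fermentations — the full pipeline executes in well under a
minute.
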