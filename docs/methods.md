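# Methods

## Model

Each neural block is a single-compartment membrane with four currents:
fast sodium (gates m, h), delayed-rectifier potassium (gate n), leak, and a
slow Nav1.8 sodium current (gates mS, hS) representing the
nociceptor-specific "pain channel".  The state of a block is
(E, m, h, n, mS, hS); E is in mV, gates are open fractions in [0, 1].  The
unit system is fixed to mV/ms/pA/pF/nS throughout, chosen so that pA/pF =
mV/ms and nS·mV = pA and no conversion factors appear anywhere.

The pain pathway is a strictly feedforward chain of five such blocks,
TG → PAG → thalamus → M1 → S1.  The coupling is instantaneous and scalar:
block k receives I_k(t) = G · E_{k−1}(t).  The published value G = 0.45 S/m
is a bulk tissue conductivity with no accompanying geometry, so it is read
here as a scalar gain of 0.45 nS-equivalent (mV → pA); it is configurable.
The external noxious stimulus enters the TG block only; tDCS is a constant
current (pA) added to the M1 block's input.  No electric-field or electrode
geometry model is attempted, and the reciprocal cortical connections
discussed in the source literature are deliberately absent: the chain is
the computational object.

### Rate conventions

The potassium opening rate is implemented in two variants.  The literal
form, alpha_n(E) = 0.006(E+45)/(1 − exp((E+45)/12)), is negative for
E > −45 mV, which breaks gate boundedness and contradicts every reference
equilibrium.  The default `continuation_consistent` variant flips the sign
of the exponent in the denominator (the classic Hodgkin–Huxley form),
1 − exp(−(E+45)/12), and reproduces all reference n values to six decimals.
Both variants are exposed (`RateConvention`); they differ in nothing else.
The removable 0/0 singularity at E = −45 mV is evaluated by its analytic
series within |E+45| < 1e−6 mV.

### The h/hS inconsistency (and what it breaks)

The six reference equilibrium vectors from the independent MatCont
continuation of this model satisfy the m, n, mS steady-state formulas and
the current-balance identity to print rounding, but their h and hS entries
are irreconcilable with the stated inactivation rates (e.g. at
E = −16.826666 mV the stated kinetics give hS_inf ≈ 0.0105 against a
reference 0.260367).  The kinetics actually used for that continuation
cannot be recovered from the available material, and this package does not
guess replacements: the stated equations are implemented literally and the
mismatch is surfaced by `mhhnet audit` and by a regression-documenting test.

This has a concrete dynamical consequence, which the test suite measures
rather than hides: with the literal inactivation kinetics the slow-sodium
current at equilibrium is roughly twenty-fold weaker than in the reference
run, and the single block has **no unstable equilibrium and no sustained
oscillation for g_NaS ≲ 265 nS at any input current** (verified by an
eigenvalue scan over E ∈ [−80, 30] mV, g_NaS ∈ [0, 300] nS and several Cm,
and by long simulations from spiking initial conditions).  Consequently the
reference regime g_NaS = 100 nS produces damped transients, not the
sustained spiking and the harmonic–bursting–harmonic orbit structure seen
in the reference analysis; the two acceptance tests asserting those qualitative
features fail, and are left failing, as an accurate statement about the
literal kinetics.  The model's genuine Hopf window lives at higher
conductance (e.g. g_NaS = 280 nS: subcritical Hopf at I0 ≈ −55.4 pA,
supercritical at −23.1 pA, slow stable cycle in between with periods of a
few hundred ms), and the self-consistency checks (continuation vs orbit
diagram, sqrt-amplitude growth, inside/outside of the two-parameter Hopf
curve) run there.

### Parameters

Committed defaults, used by every analysis unless overridden:

| parameter | value | meaning |
|---|---|---|
| Cm (TG) | 5 pF | reference membrane capacitance |
| Cm (others) | 10.1245 pF | permittivity-scaled from TG (below) |
| g_Naf | 25 nS | fast sodium maximal conductance |
| g_K | 20 nS | potassium maximal conductance |
| g_L | 5 nS | leak conductance |
| g_NaS | 100 nS | slow (Nav1.8) sodium conductance; the pain parameter |
| E_Na, E_K, E_L | 60, −75, −55 mV | Nernst potentials |
| G | 0.45 nS | chain coupling gain (mV → pA) |
| E0 | −60 mV | initial potential, gates at steady state |

Capacitance of the non-TG blocks comes from the parallel-plate relation
C = ε0·εr·A/d used purely as a ratio (A/d is never specified):
Cm = 5 pF · (4.07e7 / 2.01e7) = 10.1244 pF.  Equilibria and fold positions
are Cm-independent (Cm only rescales dE/dt); Hopf positions are not, so
every continuation records the Cm it used.  Continuation defaults to the
TG value, 5 pF.

## Synthetic TN stimulus

TN pain is irregular and episodic; it is emulated by a telegraph process:
the input current alternates between exact zero (silent intervals) and a
fresh uniform draw within user bounds, with independent exponential hold
times of mean `dwell` (default 25 ms) on both states.  The process is
fully determined by its seed and is piecewise constant, so the simulator
integrates segment-by-segment and no discontinuity ever crosses an
adaptive solver step.  What this generator does *not* emulate: temporal
correlation between attack amplitudes, circadian or use-dependent attack
clustering, and any afferent population structure.  Tests that pass on
this input therefore validate the network's response machinery and the
metric pipeline, not the clinical statistics of TN episodes.

## Numerics

* **Integration.** `scipy.integrate.solve_ivp` with LSODA (stiff-capable),
  rtol 1e−8, atol 1e−10, fixed 0.01 ms output grid for metrics.  Failures
  raise with the failure time attached.
* **Metrics.** Peak counting uses prominence (default 1 mV) on the
  post-transient window (default: first 20 % excluded); sum of squares
  optionally removes the mean (recorded in the output); phase lag is the
  argmax of the normalized cross-correlation, positive when the second
  series is delayed.
* **Equilibria.** The 6-D equilibrium problem reduces to a scalar current
  balance in E (gates eliminated through their steady states); damped
  Newton with an expanding-bracket bisection fallback; residual ≤ 1e−10.
* **Jacobians.** Analytic structure; the rate derivatives dα/dE, dβ/dE use
  a complex step (h = 1e−20), exact to machine precision.
* **Continuation.** Pseudo-arclength predictor–corrector with tangent from
  the bordered system, step halving on corrector failure (floor 1e−8,
  partial branch returned with a warning status).  Test functions recorded
  per point: det(J) for folds and the pair-sum product Π_{i<j}(λi+λj) for
  Hopf points.  Sign changes are bisected along the branch to 1e−8 in the
  parameter; the refined root is classified by its critical pair — a
  complex-conjugate pair is a Hopf, two real eigenvalues summing to zero a
  neutral saddle.  Eigenvalue marginality band for stability labels: 1e−8.
* **Normal forms.** The first Lyapunov coefficient uses the standard
  projection formula with B and C as directional finite differences of the
  (analytic) right-hand side at complex directions, critical eigenvector at
  unit norm and ⟨p, q⟩ = 1.  The magnitude therefore carries this scaling
  convention; the *sign* is the contract (L1 < 0 supercritical).  |L1| ≤
  1e−10 is flagged as a possible Bautin degeneracy.  Fold quadratic
  coefficient: a = ⟨p, B(q,q)⟩/2 on the null vectors.
* **Two-parameter Hopf curves.** Fully extended system (equilibrium +
  critical eigenpair + normalization against a per-step reference vector),
  pseudo-arclength in 3n+3 unknowns; the curve terminates with an explicit
  reason when the pair collides on the real axis, leaves the parameter
  ranges, or closes on its start.
* **Orbit diagrams.** Per parameter value: simulate, drop the transient
  (default 50 %), collect local extrema of the observed potential
  (prominence 0.05 mV), and classify by gap-clustering the sorted extrema
  with a 0.5 mV tolerance: ≤ 2 clusters is periodic (harmonic), more is
  multi-extremum ("bursting"), and a sub-tolerance spread is a fixed point.
  Misclassification near onset is possible while slow transients decay;
  the self-consistency tests therefore compare onset locations at a
  2-grid-step tolerance.

## Dose-response mapping

"Exponential" is committed to mean y = a·e^{bx} + c.  The 2-parameter
variant (c = 0) is the default for three-point data so one residual degree
of freedom remains as a sanity check; the 3-parameter variant solves three
points exactly (the rate b is found by a bracketed root of the monotone
difference ratio, stable near b = 0 via expm1).  The S1→VAS map inverts
the strictly monotone S1-vs-dose fit and evaluates the VAS-vs-dose fit at
the recovered dose, clipping to [0, 10].  Queries outside the calibration
dose range are flagged as extrapolation; doses strictly between
calibration points are flagged as interpolation, because no measurements
support intermediate doses.  The packaged calibration file
(`data/vas_calibration_approx.csv`) is an approximate, clearly labelled
example — three group-mean VAS values around 0/1/2 mA — not measured data;
with three points no confidence statements are made, deliberately.

## Design choices made where the design was open

* Chain order and membership fixed to TG → PAG → thalamus → M1 → S1; the
  trigeminal nerve itself is represented by the external stimulus into TG
  rather than a sixth block.
* Continuation operates on a single block by default (the reference
  analysis is six-dimensional); chain-level continuation would only add
  block-triangular copies of the same spectra.
* tDCS is a constant current into M1's input; polarity is the sign of the
  amplitude.
* The tDCS experiment reports sum of squares, peak-to-peak and peak count
  without asserting a direction of change: the source material itself is
  internally inconsistent on whether S1 activity rises or falls under
  stimulation, so the table is the deliverable.
* Feedforward causality is asserted in tests at integration tolerance
  (~1e−3 mV), not bitwise: all thirty states are integrated jointly, so a
  downstream perturbation alters the adaptive step sequence upstream even
  though the upstream *solution* is unchanged.

## Problem sizes used by the shipped tests

Chosen as the package's own benchmark scale: single-block runs of 3–5 s of
model time at 0.5 ms output step for the slow oscillation regime; chain
runs of 100–500 ms at 0.02–0.05 ms step; orbit diagrams over ≈ 20
parameter values; Hopf-curve sections of ≈ 250 steps per direction.  At
these sizes the full suite completes in a few minutes on one core.

## Known limitations

* The h/hS kinetics question above: quantitative agreement with the
  reference Hopf/limit-point parameter positions, L1 magnitudes and peak
  counts is out of reach by construction; only algebraic identities on the
  reference states and the model's own self-consistency are validated.
* No temperature dependence, stochastic channel gating, morphology,
  calcium or synaptic currents; blocks differ only in capacitance.
* No limit-cycle continuation or period-doubling/chaos analysis; the
  codim-2 surface is limited to flagging possible Bautin points.
* The VAS layer is a two-fit composition on sparse calibration data and
  inherits all of its uncertainty; flags, not error bars, communicate this.
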