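# mhhnet

A conductance-based simulator of the trigeminal-neuralgia pain pathway with
numerical bifurcation analysis and transcranial direct current stimulation
(tDCS) experiments.

Trigeminal neuralgia (TN) is a severe, shock-like facial neuropathic pain.
`mhhnet` models its processing pathway as five serially coupled neural
blocks — trigeminal ganglion (TG) → periaqueductal gray (PAG) → thalamus →
motor cortex (M1) → somatosensory cortex (S1) — each a modified
Hodgkin–Huxley (MHH) membrane carrying, besides the classic fast sodium,
potassium and leak currents, a slow Nav1.8 sodium current: the
nociceptor-specific "pain channel" whose conductance g<sub>NaS</sub> is the
central control parameter.  The package is for computational
neuroscientists studying pain-network dynamics and stimulation effects.

## Model

Each block obeys the six-variable MHH system (units: mV, ms, pA, pF, nS)

```
Cm dE/dt = I − g_Naf m³h (E−E_Na) − g_K n⁴ (E−E_K) − g_L (E−E_L) − g_NaS mS³hS (E−E_Na)
dg/dt    = α_g(E)(1−g) − β_g(E) g      for g ∈ {m, h, n, mS, hS}
```

with voltage-dependent opening/closing rates α, β per gate.  The chain is
strictly feedforward: block *k* receives I<sub>k</sub>(t) = G·E<sub>k−1</sub>(t)
with a scalar gain G = 0.45 nS, the noxious stimulus drives TG, and tDCS is
a constant extra current added to M1's input.  TN-like input is a seeded
telegraph process alternating between silence and a uniform random level.

On top of the simulator sit the dynamical-systems tools used to analyse
this model: equilibrium solving with analytic Jacobians, pseudo-arclength
continuation with Hopf/limit-point detection (first Lyapunov and fold
normal-form coefficients by the projection method), two-parameter Hopf-curve
continuation in the (I₀, g<sub>NaS</sub>) plane, brute-force orbit diagrams,
and an exponential dose-response layer mapping S1 activity onto the 0–10
visual-analog pain scale (VAS).

## Worked example

Locate the oscillation window of a single block deep in the slow-sodium
regime (g_NaS = 280 nS), then run a tDCS experiment on the full chain:

```python
import mhhnet as M
from mhhnet.bifurcation import (continue_branch, detect_bifurcations,
                                mhh_system, solve_equilibrium)

params = M.BlockParams(gNaS=280.0)
eq = solve_equilibrium(params, 0.0, guess=-38.0)
f, jac, jac_p = mhh_system(params, free="I0")
branch = continue_branch(f, eq.state, 0.0, (-80.0, 20.0), jac=jac,
                         jac_p=jac_p, ds=1.0, direction=-1, max_steps=400)
for b in detect_bifurcations(branch):
    print(f"{b.kind} at I0 = {b.param:.3f} pA, "
          f"L1 = {b.coefficient:.2e}, omega = {b.omega:.4f} rad/ms")

spec = M.StimulusSpec(kind="tn_random", bounds=(0.0, 30.0), dwell=25.0,
                      seed=7, duration=300.0)
table = M.tdcs_experiment(M.NetworkConfig(), spec, [0.0, 40.0], dt=0.02)
print(table.to_string(index=False))
```

```
Hopf at I0 = -55.380 pA, L1 = 1.55e-02, omega = 0.0161 rad/ms
Hopf at I0 = -23.099 pA, L1 = -1.22e-02, omega = 0.0251 rad/ms
 tdcs_amplitude  sum_squares  peak_to_peak  n_peaks
            0.0 2.309591e+07     23.588429        1
           40.0 2.463821e+07     38.147101        0
```

The branch carries a subcritical Hopf (L1 > 0) at I₀ ≈ −55.4 pA and a
supercritical one (L1 < 0) at I₀ ≈ −23.1 pA; between them the equilibrium
is unstable and a stable slow limit cycle (period of a few hundred ms)
exists — outside, the block settles to rest.  The tDCS table reports S1
metrics for the identical seeded stimulus with and without a 40 pA current
into M1: here tDCS raises the S1 peak-to-peak range and sum of squares.

The same analyses are available from the shell:

```sh
mhhnet simulate --config experiment.yaml --out trace.csv
mhhnet continue --param I0 --range -80 20 --gnas 280 --start 0 --out branch.csv
mhhnet orbit --param gNaS --start 30 --stop 120 --num 19 --out orbit.csv
mhhnet tdcs --amplitudes 0,20,50 --out tdcs.csv
mhhnet vas --vas-calibration vas.csv --s1-calibration s1.csv --s1 60
mhhnet audit
```

Every output CSV is paired with a JSON manifest (config echo, seed,
tolerances, version) sufficient to regenerate it.

`mhhnet audit` checks the package against six reference equilibrium states
from an independent MatCont continuation of this model: the activation
gates (m, n, mS) and the current-balance identities reproduce the reference
bifurcation parameters to print rounding, while the h/hS inactivation
columns of the reference run are documented as inconsistent with the
model's stated inactivation kinetics (see `docs/methods.md`).

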