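# Methods

## Scope and model family

`boldsim` computes simulated BOLD signals from spiking network activity in
an on-line fashion: at every integration step, per-neuron *source variables*
are reduced to one input value per hemodynamic-model input, and the
hemodynamic model advances one Euler step on the same clock as the network.
The hemodynamic models are members of the Balloon family; they describe a
venous compartment that inflates with normalized blood inflow and the
resulting deoxyhemoglobin dynamics, and they are deliberately small (≈10
equations) so that users can modify or replace them through the equation
grammar.

## The equation grammar and its integrator

A model is two text blocks plus metadata. The parameters block is
`name = value` per line (values may be constant expressions over earlier
parameters). The equations block declares, one per line and in evaluation
order, either an ODE (`d<var>/dt = rhs`) or an algebraic assignment
(`var = rhs`), with optional trailing annotations `: init=…, min=…, max=…`.
Expressions use `+ - * / **`, parentheses and unary minus; `**` is
right-associative. Input signals are read with `sum(NAME)`, and `NAME` must
be a declared input; bare input names are rejected so that the data flow
from monitor to model is explicit.

Semantics, chosen for testability and stated here because they matter for
reproduction:

* **Units.** The grid is in ms; rate constants are s⁻¹ and time constants
  s. The ODE update is `x ← x + (dt/1000)·rhs`.
* **Declaration order, sequential environment.** Each equation sees the
  environment as updated so far within the step (algebraic lines read the
  just-updated ODE variables; forward references read the previous step's
  value). Two runs with identical inputs are bit-identical.
* **Initial state.** ODE variables start at their `init` (default 0);
  algebraic variables are evaluated once at construction with inputs at 0,
  so a model whose rest state satisfies all equations is an exact fixed
  point of the integrator.
* **Clamps** (`min`/`max`) apply immediately after a variable's own update,
  before the next line reads it. The alternative (clamping at step end) was
  rejected because a dependent algebraic line could then observe an
  out-of-bounds value.
* **Failures are loud.** A non-finite value aborts integration with the
  variable name and simulated time; division by zero is treated as
  non-finite. Nothing propagates silently.
* Internally each model is compiled once into a single specialized Python
  step function (constants inlined, one function call per step); a
  per-equation interpreter with identical arithmetic is kept as the
  diagnostic path and the two are exercised against each other in the tests.

Forward Euler at network dt (0.1–1 ms) is ample for hemodynamics with
second-scale time constants: halving dt changes the reference pulse
response by <1e-4, and the measured convergence order is 1 (error ratio ≈ 2
per halving).

## Balloon parameters

Defaults (all overridable):

| parameter | value | unit | meaning |
|---|---|---|---|
| φ | 1.0 | – | input gain |
| κ | 1/1.54 | s⁻¹ | flow-signal decay |
| γ | 1/2.46 | s⁻¹ | flow-signal feedback; steady flow = 1 + φI/γ |
| E₀ | 0.34 | – | resting O₂ extraction fraction |
| τ₀ | 0.98 | s | mean venous transit time |
| α | 0.33 | – | Grubb flow–volume exponent |
| V₀ | 0.02 | – | resting venous volume fraction |
| ε | 1.43 | – | intra/extravascular signal ratio |
| ν₀ | 40.3 | s⁻¹ | frequency offset (revised k₁) |
| r₀ | 25 | s⁻¹ | slope (revised k₂) |
| TE | 0.04 | s | echo time |

These are the standard revised-Balloon literature values. The four classic
variants differ only in the coefficient set (classic vs revised) and BOLD
equation (non-linear vs linearized); both coefficient triples are emitted
as algebraic lines inside the definitions so they remain visible and
overridable through the grammar.

## The two-input model

CBF and CMRO2 are driven in parallel by separate damped oscillators. Three
behavioural requirements constrain the CMRO2 chain: it must respond
*faster* than CBF, *without* over/undershoot, and *equal* constant inputs
must give equal steady amplitudes. A critically damped oscillator with the
CBF feedback rate γ satisfies the second and third but not the first — its
rise time (1/√γ ≈ 1.6 s) is comparable to the CBF chain's, and under the
reference inputs (I_CBF = 0.2, I_CMRO2 = 0.05) the four-fold larger CBF
input then dominates the early response and **no initial dip occurs**
(verified by integration). We therefore make the CMRO2 oscillator stiff —
`gamma_CMRO2 = 16·gamma`, critically damped
(`kappa_CMRO2 = 2·sqrt(gamma_CMRO2)`, rise time ≈ 0.4 s) — and scale its
input gain internally by `gamma_CMRO2/gamma`, which keeps the steady-state
response to a constant input identical to the CBF chain's
(`r − 1 = f_in − 1 = φc/γ`). Both rates are parameters; an underdamped
choice triggers a warning because an oscillating CMRO2 contradicts the
model's design intent.

The venous outflow includes a viscoelastic lag,
`f_out = v^{1/α} + τ_visc·dv/dt` with
`dv/dt = (f_in − v^{1/α})/(τ₀ + τ_visc)` and `τ_visc = 6 s` by default, so
the volume (and hence part of the post-stimulus undershoot) recovers
slowly. The deoxyhemoglobin balance uses r directly:
`dq/dt = (r − f_out·q/v)/τ₀`. At an equal-input fixed point f_in = r =
f_out and q = v = f_in^α, which makes the non-linear BOLD plateau negative
(q = v > 1 ⇒ BOLD = V₀(k₁+k₃)(1−v) < 0) — the signature of sustained
stimulation when CBF does not outpace CMRO2.

## The monitor pipeline

Per input variable and step: (1) average the mapped source variable over
each population's neurons; (2) if a normalization window W > 0 is set,
replace the average x by `(x − B)/B`, where B is that population's mean of
the averaged signal over the first W ms of the recording; (3) weight each
population by `N_pop/N_region` (overridable); (4) sum. Order fixed as
average → normalize → scale → sum; normalization is per population with its
own baseline.

While the window fills, model inputs are held at exactly 0 — the model
still integrates and stays at rest, so normalized recordings are flat for
the first W ms. A baseline with |B| ≤ 1e-9 raises immediately: the relative
deviation is only meaningful for source variables with a stable non-zero
resting mean (a quiescent population activated later, or a variable still
ramping up during the window, are both misuses and fail loudly).

Synaptic-current source variables are exposed as magnitudes
(|g·(E_rev − v)|), so inhibitory (GABA) activity contributes *positively*
to flow-driving sums such as `I_AMPA + 1.5·I_GABA`; with signed currents an
inhibition-driven flow increase could not be expressed. Derived source
expressions are registered on the population and evaluated per neuron by
the same expression engine, then averaged.

The six built-in coupling hypotheses: A (CBF ← total synaptic activity
`syn`), B (CBF ← `g_AMPA`), C (CBF ← firing rate `r`) on the classic model;
D (CBF ← `I_AMPA + 1.5·I_GABA`, CMRO2 ← `I_AMPA`), E (as D but the
inhibitory population's CMRO2 source is its rate), F (as D but CMRO2 ←
`I_AMPA^{1/3}`) on the two-input model; baseline normalization on for all
six. For E the population order is [excitatory, inhibitory].

## The microcircuit

Structure: `corE` (regular-spiking, 80 % of recorded neurons), `corI`
(fast-spiking, 20 %), a Poisson population equal in size to corE; five
projections — Poisson→corE, Poisson→corI (AMPA), corE→corI (AMPA),
corI→corE, corI→corI (GABA) — each post-synaptic neuron receiving exactly
10 synapses from distinct pre-synaptic neurons. Totals are therefore
1.8·n_recorded neurons and 10·(2·N_corE + 3·N_corI) connections (450 and
5,500 at n_recorded = 250, doubling with size). The corI→corI projection is
required for these counts to close and provides the usual interneuron
self-inhibition.

Neuron models are the 2007 biophysical Izhikevich forms with textbook
parameter sets (RS: C=100 pF, k=0.7, v_r=−60, v_t=−40, v_peak=35 mV,
a=0.03, b=−2, c=−50, d=100; FS: C=20, k=1, v_r=−55, v_t=−40, v_peak=25,
a=0.2, b=0.025 with cubic recovery below v_b=v_r, c=−45, d=0). The simple
2003 form (RS a=0.02, b=0.2, c=−65, d=8, with a per-step noise current of
amplitude 5.0) is used in the two-population demo. Conductances decay with
the exact exponential factor `exp(−dt/τ)`, τ = 10 ms (difference from an
Euler decay is O(dt²)); reversal potentials are 0 mV (AMPA) and −90 mV
(GABA); spikes are delivered with a one-step (dt) delay so the update order
is unambiguous.

Weights are log-normal (location −1.5, shape 0.93, in log-conductance
units) scaled per projection (Poisson→corE 2.0, Poisson→corI 2.0,
corE→corI 1.0, corI→corE 1.0, corI→corI 0.5); the Poisson baseline rate is
15 Hz with a per-realization 5 % jitter of the mean. These construction
constants were calibrated once so that the default circuit fires sparsely
and stably (corE ≈ 2–3 Hz, corI ≈ 10 Hz, an in-vivo-like cortical regime
with a steady synaptic-activity mean — the condition the baseline
normalization requires); they are configuration entries
(`MicrocircuitConfig`), not fitted claims about any particular dataset.

**What the generator emulates, and what it does not.** The microcircuit
produces irregular, sparse, asynchronous firing with feed-forward and
feedback inhibition, enough to give every monitored source variable a
stationary resting mean and a clear stimulus response. It has no functional
processing, no synaptic plasticity, no NMDA or neuromodulation, homogeneous
random connectivity, and no fitted match to any experimental EPSP or rate
distribution. Tests passing on it therefore demonstrate the monitor's
arithmetic and the models' dynamics, not the biological validity of any
coupling hypothesis on real data.

## Experiment protocols and problem sizes

All microcircuit experiments share one clock: 2 s initialization (not
recorded), recording starts with a 5 s baseline window, stimulus onset
10 s into the recording. The brief stimulus multiplies the Poisson rate by
5 for 100 ms (25 s total recording); the sustained stimulus by 1.2 for 20 s
(45 s default). Seed-averaged traces are arithmetic means across
realizations aligned on the recording clock; all monitors of a comparison
attach to the *same* network instance per seed, so differences between
their traces cannot come from different network realizations.

The reference protocol uses 40 realizations. The shipped test suite runs
2–3 and the acceptance script 10 (25 s resting runs at n_recorded = 250);
the asserted quantities are sign/ordering properties and 20-s time
averages, which are stable at these sizes.

## Known limitations

* No measurement-noise model for the BOLD signal (physiological or
  instrumental), and no spatial extent of activation.
* The two-input model's exact coefficients are a design choice satisfying
  the family's qualitative constraints; other parameterizations with the
  same properties exist.
* Baseline normalization requires a stationary non-zero resting mean of the
  source variable; this is enforced, not worked around.
* The equation grammar is scalar and explicit-Euler only — no stiff
  solvers, no symbolic simplification, no code generation beyond the
  specialized Python step function.
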