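"""On-line BOLD monitor: from per-neuron source variables to model inputs.

For every input variable of the attached hemodynamic model, each step of the
monitor applies the preprocessing chain

1. **average** the per-neuron source variable over each population,
2. optionally **normalize** per population against a baseline B (the mean of
   the averaged signal over an initial window): ``(x - B) / B``,
3. **scale** each population signal by its share of the region of interest
   (``N_pop / N_region`` by default, overridable),
4. **sum** across populations,

then advances the hemodynamic model by one Euler step with the resulting
input values and appends the recorded variables.  While the baseline window
is filling, model inputs are held at 0 (the model still integrates, staying
at rest), so normalized recordings are flat until the window completes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dsl import ModelDefinition, ModelRunner
from .models import get_model
from .recording import TimeSeries

__all__ = [
    "MonitorConfig",
    "MonitorState",
    "BoldMonitor",
    "BaselineError",
    "population_average",
    "compute_baseline",
    "normalize",
    "scale_and_sum",
    "hypothesis_monitor",
    "HYPOTHESIS_IDS",
]

#: baselines smaller than this are rejected: the relative deviation is only
#: meaningful for source variables with a relatively constant non-zero mean
BASELINE_EPS = 1e-9


class BaselineError(ValueError):
    """Raised when a normalization baseline is unusable (near zero)."""


# --------------------------------------------------------------------------
# the four pipeline primitives
# --------------------------------------------------------------------------

def population_average(values) -> float:
    """Arithmetic mean of a per-neuron value vector."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot average an empty population")
    return float(values.mean())


def compute_baseline(history) -> float:
    """Baseline B: mean of the per-step averaged signal over the window."""
    history = np.asarray(history, dtype=float)
    if history.size == 0:
        raise ValueError("baseline window contains no samples")
    return float(history.mean())


def normalize(x: float, B: float) -> float:
    """Relative deviation from baseline, ``(x - B) / B``.

    A near-zero baseline is a hard error: source variables must have a
    relatively constant non-zero resting mean for this to be meaningful.
    """
    if abs(B) <= BASELINE_EPS:
        raise BaselineError(
            f"baseline {B!r} is too close to zero for relative normalization; "
            "choose a source variable with a non-zero resting mean"
        )
    return (x - B) / B


def scale_and_sum(signals, sizes, overrides=None) -> float:
    """Scale per-population signals by ROI share and sum them.

    Default weights are ``N_pop / N_region`` (they sum to one for any
    partition of the region); ``overrides`` replaces them wholesale.
    """
    signals = np.asarray(signals, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if signals.shape != sizes.shape:
        raise ValueError("signals and sizes must have matching shapes")
    if overrides is not None:
        weights = np.asarray(overrides, dtype=float)
        if weights.shape != signals.shape:
            raise ValueError(
                f"override weights have length {weights.size}, "
                f"expected {signals.size}"
            )
    else:
        weights = sizes / sizes.sum()
    return float(np.dot(weights, signals))


# --------------------------------------------------------------------------
# configuration and state
# --------------------------------------------------------------------------

@dataclass
class MonitorConfig:
    """Configuration of one BOLD monitor.

    Attributes
    ----------
    populations:
        The ROI: a list of population objects exposing ``size`` and
        ``get_variable(name) -> per-neuron array``.
    model:
        A :class:`ModelDefinition` or the name of a built-in model.
    mapping:
        input-variable name -> source-variable name; the value may also be a
        list with one source name per population (in ``populations`` order).
    normalize_window:
        Baseline window length in ms; 0 disables normalization.
    scaling_overrides:
        Optional per-population weights replacing the N_pop/N_region default.
    recorded_variables:
        Model variables (and/or input names) appended each step; defaults to
        the model's output variable.
    start_time:
        Informational offset (ms) stored with the recordings.
    """

    populations: list
    model: "ModelDefinition | str" = "balloon_RN"
    mapping: dict = field(default_factory=lambda: {"I_CBF": "r"})
    normalize_window: float = 0.0
    scaling_overrides: list | None = None
    recorded_variables: list | None = None
    start_time: float = 0.0

    def resolved_model(self) -> ModelDefinition:
        return get_model(self.model) if isinstance(self.model, str) else self.model

    def source_for(self, input_name: str, pop_index: int) -> str:
        src = self.mapping[input_name]
        if isinstance(src, str):
            return src
        return src[pop_index]

    def validate(self) -> None:
        model = self.resolved_model()
        if not self.populations:
            raise ValueError("monitor needs at least one population")
        unknown = set(self.mapping) - set(model.inputs)
        if unknown:
            raise ValueError(
                f"mapping targets {sorted(unknown)} are not inputs of "
                f"model {model.name!r} (inputs: {list(model.inputs)})"
            )
        missing = set(model.inputs) - set(self.mapping)
        if missing:
            raise ValueError(f"no source variable mapped for input(s) "
                             f"{sorted(missing)}")
        for inp in model.inputs:
            src = self.mapping[inp]
            if not isinstance(src, str) and len(src) != len(self.populations):
                raise ValueError(
                    f"per-population source list for {inp!r} has "
                    f"{len(src)} entries for {len(self.populations)} populations"
                )
        if self.scaling_overrides is not None and \
                len(self.scaling_overrides) != len(self.populations):
            raise ValueError(
                f"scaling_overrides has {len(self.scaling_overrides)} entries "
                f"for {len(self.populations)} populations"
            )
        if self.normalize_window < 0:
            raise ValueError("normalize_window must be >= 0")


@dataclass
class MonitorState:
    """Mutable state of a running monitor."""

    baselines: "dict[tuple[str, int], float]" = field(default_factory=dict)
    baseline_sums: "dict[tuple[str, int], float]" = field(default_factory=dict)
    baseline_count: int = 0
    baseline_ready: bool = False
    recording_active: bool = False
    t: float = 0.0                # ms since recording start
    rows: list = field(default_factory=list)


class BoldMonitor:
    """Runs the preprocessing pipeline on-line and integrates the model.

    Attach to a :class:`~boldsim.network.Network` via ``attach_monitor``; the
    network calls :meth:`step` once per grid step after updating the
    populations.  Call :meth:`start` when the warm-up is over.
    """

    def __init__(self, config: MonitorConfig):
        config.validate()
        self.config = config
        self.model = config.resolved_model()
        self.runner = ModelRunner(self.model)
        recorded = config.recorded_variables or [self.model.output]
        known = set(self.model.variables) | set(self.model.inputs)
        unknown = set(recorded) - known
        if unknown:
            raise ValueError(f"cannot record unknown variable(s) "
                             f"{sorted(unknown)}")
        self.recorded = list(recorded)
        self.state = MonitorState()
        self._sizes = np.array([p.size for p in config.populations], float)
        if config.scaling_overrides is not None:
            self._weights = [float(w) for w in config.scaling_overrides]
        else:
            self._weights = [float(p.size) / self._sizes.sum()
                             for p in config.populations]
        self._window_steps: int | None = None

    # -- lifecycle ---------------------------------------------------------

    def start(self) -> None:
        """Begin recording (and the baseline window, if normalizing)."""
        self.state = MonitorState(recording_active=True)
        self.runner = ModelRunner(self.model)

    # -- pipeline ----------------------------------------------------------

    @staticmethod
    def _pop_average(pop, name: str) -> float:
        getter = getattr(pop, "get_average", None)
        if getter is not None:
            return getter(name)
        return population_average(pop.get_variable(name))

    def _input_value(self, input_name: str) -> float:
        cfg = self.config
        baselines = self.state.baselines
        normalizing = cfg.normalize_window > 0
        total = 0.0
        for i, (pop, w) in enumerate(zip(cfg.populations, self._weights)):
            x = self._pop_average(pop, cfg.source_for(input_name, i))
            if normalizing:
                B = baselines[(input_name, i)]   # validated non-zero
                x = (x - B) / B
            total += w * x
        return total

    def _accumulate_baseline(self) -> None:
        cfg = self.config
        st = self.state
        for input_name in self.model.inputs:
            for i, pop in enumerate(cfg.populations):
                key = (input_name, i)
                x = self._pop_average(pop, cfg.source_for(input_name, i))
                st.baseline_sums[key] = st.baseline_sums.get(key, 0.0) + x
        st.baseline_count += 1

    def _finish_baseline(self) -> None:
        st = self.state
        if st.baseline_count == 0:
            raise ValueError(
                "baseline window is longer than the elapsed recording"
            )
        for key, total in st.baseline_sums.items():
            st.baselines[key] = total / st.baseline_count
        # reject unusable baselines immediately, naming the population
        for (input_name, i), B in st.baselines.items():
            if abs(B) <= BASELINE_EPS:
                raise BaselineError(
                    f"baseline for input {input_name!r}, population "
                    f"{self.config.populations[i].name!r} is ~0 ({B!r}); "
                    "relative normalization needs a non-zero resting mean"
                )
        st.baseline_ready = True

    def step(self, dt: float) -> None:
        """One monitor step: pipeline -> model Euler step -> record."""
        st = self.state
        if not st.recording_active:
            return
        if self._window_steps is None:
            self._window_steps = int(round(self.config.normalize_window / dt))
        normalizing = self.config.normalize_window > 0
        in_window = normalizing and st.baseline_count < self._window_steps
        if in_window:
            self._accumulate_baseline()
            inputs = {name: 0.0 for name in self.model.inputs}
        else:
            if normalizing and not st.baseline_ready:
                self._finish_baseline()
            inputs = {name: self._input_value(name)
                      for name in self.model.inputs}
        self.runner.env.update(inputs)   # inputs validated at configuration
        self.runner.step(dt)
        env = self.runner.env
        st.rows.append([env[name] for name in self.recorded])
        st.t += dt

    # -- results -----------------------------------------------------------

    def get_recordings(self, dt: float | None = None) -> TimeSeries:
        rows = self.state.rows
        if not rows:
            raise ValueError("monitor has not recorded anything yet")
        n = len(rows)
        dt = self.state.t / n if dt is None else dt
        return TimeSeries(dt=dt, t0=self.config.start_time + dt,
                          names=list(self.recorded), data=np.asarray(rows))


# --------------------------------------------------------------------------
# the six neurovascular-coupling hypotheses
# --------------------------------------------------------------------------

HYPOTHESIS_IDS = ("A", "B", "C", "D", "E", "F")

#: standard baseline window for the hypothesis monitors, ms
_HYPOTHESIS_WINDOW = 5000.0


def hypothesis_monitor(monitor_id: str, populations,
                       normalize_window: float = _HYPOTHESIS_WINDOW,
                       recorded_variables: list | None = None) -> MonitorConfig:
    """Monitor configuration for one of the six coupling hypotheses.

    Single-input monitors (classic Balloon model, revised non-linear):

    * ``A`` — CBF driven by total synaptic activity (``syn``),
    * ``B`` — CBF driven by excitatory conductance (``g_AMPA``),
    * ``C`` — CBF driven by the windowed firing rate (``r``).

    Two-input monitors (parallel CBF/CMRO2 drive): CBF always driven by
    ``I_AMPA + 1.5 I_GABA``; CMRO2 driven by

    * ``D`` — ``I_AMPA`` in both populations,
    * ``E`` — ``I_AMPA`` in the excitatory population but the firing rate
      ``r`` in the inhibitory one (output-, not input-, coupled energy use
      in interneurons),
    * ``F`` — ``I_AMPA**(1/3)`` (sublinear energy-current relation).

    Baseline normalization is enabled for all six.  Derived source
    expressions are registered on the populations as needed.
    """
    monitor_id = monitor_id.upper()
    if monitor_id not in HYPOTHESIS_IDS:
        raise ValueError(
            f"unknown monitor id {monitor_id!r}; valid ids: "
            f"{', '.join(HYPOTHESIS_IDS)}"
        )
    populations = list(populations)
    recorded = recorded_variables
    if monitor_id in "ABC":
        source = {"A": "syn", "B": "g_AMPA", "C": "r"}[monitor_id]
        return MonitorConfig(
            populations=populations, model="balloon_RN",
            mapping={"I_CBF": source},
            normalize_window=normalize_window,
            recorded_variables=recorded or ["I_CBF", "f_in", "BOLD"],
        )

    for pop in populations:
        pop.register_expression("cbf_drive", "I_AMPA + 1.5 * I_GABA")
    if monitor_id == "D":
        cmro2_source: "str | list" = "I_AMPA"
    elif monitor_id == "E":
        # excitatory population keeps the synaptic current; inhibitory
        # population couples CMRO2 to its output rate instead
        cmro2_source = ["I_AMPA"] + ["r"] * (len(populations) - 1)
    else:  # F
        for pop in populations:
            pop.register_expression("cmro2_drive_cbrt", "I_AMPA**(1/3)")
        cmro2_source = "cmro2_drive_cbrt"
    return MonitorConfig(
        populations=populations, model="balloon_two_inputs",
        mapping={"I_CBF": "cbf_drive", "I_CMRO2": cmro2_source},
        normalize_window=normalize_window,
        recorded_variables=recorded or ["I_CBF", "I_CMRO2", "f_in", "r", "BOLD"],
    )
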