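"""End-to-end experiment drivers.

These reproduce the package's reference simulations:

* :func:`run_artificial_pulse` — a hemodynamic model driven by a manually
  set rectangular input (no network), exposing every model variable;
* :func:`run_simple_demo` — two unconnected 100-neuron Izhikevich
  populations whose noise-driven firing rate feeds the default Balloon
  model, with a noise step mimicking an external input;
* :func:`run_pulse_experiment` — the microcircuit with a brief (100 ms,
  x5) Poisson rate pulse, recorded simultaneously by a baseline-normalized
  and an unnormalized monitor, averaged across seeds;
* :func:`run_hypothesis_comparison` — the six neurovascular-coupling
  monitors attached to one shared microcircuit per seed, under a pulse or a
  sustained (20 s, x1.2) stimulus;
* :func:`scaling_table` — neuron/connection counts of the scaled
  microcircuit.

All experiment schedules share the same clock: a 2 s initialization before
recording starts, a 5 s baseline window, the stimulus onset 10 s into the
recording.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dsl import integrate
from .models import get_model
from .monitor import BoldMonitor, MonitorConfig, hypothesis_monitor
from .network import (IzhikevichSimpleParams, MicrocircuitConfig, Network,
                      SpikingPopulation, build_microcircuit)
from .recording import TimeSeries, average_timeseries

__all__ = [
    "ArtificialInput",
    "ExperimentSpec",
    "run_artificial_pulse",
    "run_simple_demo",
    "run_pulse_experiment",
    "run_hypothesis_comparison",
    "scaling_table",
    "write_recordings",
    "load_recordings",
    "load_config",
    "run_experiment",
]

log = logging.getLogger("boldsim")

#: initialization period before recordings start, ms
INIT_MS = 2000.0
#: baseline window of the normalized monitors, ms
BASELINE_MS = 5000.0
#: stimulus onset on the recording clock, ms
STIM_ONSET_MS = 10_000.0


# --------------------------------------------------------------------------
# artificial (network-free) inputs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ArtificialInput:
    """Piecewise-constant input levels per model input variable.

    ``pieces`` maps an input name to a list of ``(t_start_ms, level)``
    breakpoints with increasing times; the level holds until the next
    breakpoint.
    """

    pieces: dict[str, list[tuple[float, float]]]

    def __post_init__(self) -> None:
        for name, pts in self.pieces.items():
            times = [t for t, _ in pts]
            if times != sorted(times) or len(set(times)) != len(times):
                raise ValueError(f"breakpoint times for {name!r} must increase")
            if not all(np.isfinite(level) for _, level in pts):
                raise ValueError(f"non-finite level for {name!r}")

    def as_array(self, name: str, dt: float, n_steps: int) -> np.ndarray:
        out = np.zeros(n_steps)
        for t_start, level in self.pieces.get(name, []):
            out[int(round(t_start / dt)):] = level
        return out


def run_artificial_pulse(model: str = "classic", dt: float = 1.0,
                         duration: float = 60_000.0,
                         pulse: tuple[float, float] = (5_000.0, 25_000.0),
                         cbf_level: float = 0.2,
                         cmro2_level: float = 0.05) -> TimeSeries:
    """Drive a Balloon model with a rectangular input and record everything.

    ``model`` is ``"classic"`` (single input, level 0.2) or ``"two_input"``
    (I_CBF to 0.2 and I_CMRO2 to 0.05 in parallel).  The pulse is on during
    ``pulse`` (ms).  Returns all model variables plus the inputs.
    """
    if model == "classic":
        definition = get_model("balloon_RN")
        pieces = {"I_CBF": [(pulse[0], cbf_level), (pulse[1], 0.0)]}
    elif model == "two_input":
        definition = get_model("balloon_two_inputs")
        pieces = {
            "I_CBF": [(pulse[0], cbf_level), (pulse[1], 0.0)],
            "I_CMRO2": [(pulse[0], cmro2_level), (pulse[1], 0.0)],
        }
    else:
        raise ValueError(f"model must be 'classic' or 'two_input', got {model!r}")
    art = ArtificialInput(pieces)
    n_steps = int(round(duration / dt))
    inputs = {name: art.as_array(name, dt, n_steps)
              for name in definition.inputs}
    return integrate(definition, inputs, dt=dt, duration=duration)


# --------------------------------------------------------------------------
# the simple two-population demo
# --------------------------------------------------------------------------

def run_simple_demo(seed: int = 0, noise_baseline: float = 5.0,
                    noise_elevated: float = 7.5, dt: float = 1.0,
                    with_step: bool = True) -> TimeSeries:
    """Two 100-neuron Izhikevich populations monitored via their firing rate.

    Schedule: 1 s settling, then recording starts with a 5 s baseline
    window; at 5 s the ``noise`` baseline current of the first population is
    raised for 5 s and then reset; recording ends at 20 s.  The monitor uses
    the default Balloon model with baseline normalization, so the BOLD
    signal rises during the elevated-noise phase and relaxes afterwards.
    """
    rng = np.random.default_rng(seed)
    net = Network(dt=dt)
    params = IzhikevichSimpleParams(noise=noise_baseline)
    rng0, rng1 = rng.spawn(2)
    pop0 = net.add_population(SpikingPopulation("pop0", 100, params, dt, rng=rng0))
    pop1 = net.add_population(SpikingPopulation("pop1", 100, params, dt, rng=rng1))
    monitor = BoldMonitor(MonitorConfig(
        populations=[pop0, pop1], model="balloon_RN",
        mapping={"I_CBF": "r"}, normalize_window=BASELINE_MS,
        recorded_variables=["I_CBF", "f_in", "BOLD"],
    ))
    net.attach_monitor(monitor)

    net.run(1000.0)          # settle
    monitor.start()
    net.run(5000.0)          # baseline window
    if with_step:
        pop0.noise = noise_elevated
        log.info("demo: noise step on at t=%.0f ms", net.time)
    net.run(5000.0)
    pop0.noise = noise_baseline
    log.info("demo: noise step off at t=%.0f ms", net.time)
    net.run(10_000.0)
    return monitor.get_recordings(dt=dt)


# --------------------------------------------------------------------------
# microcircuit experiments
# --------------------------------------------------------------------------

def _seed_for(base_seed: int, i: int) -> int:
    # distinct, stable per-run seeds below 2**31
    return int(np.random.SeedSequence([base_seed, i]).generate_state(1)[0] % (2**31))


def _run_microcircuit_once(seed: int, monitors_factory, total_ms: float,
                           stimulus: tuple[float, float, float] | None,
                           n_recorded: int,
                           config: MicrocircuitConfig | None):
    """Build one microcircuit realization, attach monitors, run the schedule.

    ``monitors_factory(net)`` returns a dict name -> BoldMonitor; the
    stimulus window is given on the recording clock.
    """
    net = build_microcircuit(n_recorded, seed=seed, config=config)
    monitors = monitors_factory(net)
    for mon in monitors.values():
        net.attach_monitor(mon)
    net.run(INIT_MS)
    for mon in monitors.values():
        mon.start()
    log.info("seed %d: recording started at t=%.0f ms", seed, net.time)
    if stimulus is not None:
        t0, t1, mult = stimulus
        net.set_stimulus_schedule([(net.time + t0, net.time + t1, mult)])
    net.run(total_ms)
    return {name: mon.get_recordings(dt=net.dt)
            for name, mon in monitors.items()}


def run_pulse_experiment(n_seeds: int = 40, with_stimulus: bool = True,
                         n_recorded: int = 250, seed: int = 0,
                         total_ms: float = 25_000.0,
                         config: MicrocircuitConfig | None = None,
                         keep_per_seed: bool = False) -> dict:
    """Brief-stimulus experiment with and without baseline normalization.

    Two monitors (source variable ``syn``, default Balloon model) record the
    same microcircuit simultaneously: one normalized against a 5 s baseline,
    one raw.  With ``with_stimulus`` the Poisson rate is multiplied by 5 for
    100 ms, 10 s into the recording; the total recording is 25 s.  Traces
    are averaged across ``n_seeds`` network realizations.

    Returns ``{"normalized": TimeSeries, "raw": TimeSeries}`` (averaged),
    plus per-seed recordings under ``"per_seed"`` if requested.
    """
    def factory(net: Network):
        pops = [net.populations["corE"], net.populations["corI"]]
        recorded = ["I_CBF", "f_in", "BOLD"]
        return {
            "normalized": BoldMonitor(MonitorConfig(
                populations=pops, model="balloon_RN",
                mapping={"I_CBF": "syn"}, normalize_window=BASELINE_MS,
                recorded_variables=recorded)),
            "raw": BoldMonitor(MonitorConfig(
                populations=pops, model="balloon_RN",
                mapping={"I_CBF": "syn"}, normalize_window=0.0,
                recorded_variables=recorded)),
        }

    stimulus = (STIM_ONSET_MS, STIM_ONSET_MS + 100.0, 5.0) if with_stimulus else None
    per_seed = [
        _run_microcircuit_once(_seed_for(seed, i), factory, total_ms,
                               stimulus, n_recorded, config)
        for i in range(n_seeds)
    ]
    out = {
        name: average_timeseries([run[name] for run in per_seed])
        for name in ("normalized", "raw")
    }
    if keep_per_seed:
        out["per_seed"] = per_seed
    return out


def run_hypothesis_comparison(monitor_ids="ABCDEF", stimulus: str = "pulse",
                              n_seeds: int = 40, n_recorded: int = 250,
                              seed: int = 0,
                              config: MicrocircuitConfig | None = None,
                              keep_per_seed: bool = False,
                              total_ms: float | None = None) -> dict:
    """Compare neurovascular-coupling hypotheses on a shared microcircuit.

    All requested monitors attach to the same network instance per seed, so
    differences between their traces reflect only the coupling, not the
    network realization.  ``stimulus`` is ``"pulse"`` (x5 for 100 ms, 25 s
    total) or ``"sustained"`` (x1.2 for 20 s, 45 s total).

    Returns a dict mapping monitor id to the seed-averaged recordings
    (I_CBF, f_in, BOLD — plus I_CMRO2 and r for the two-input monitors).
    """
    monitor_ids = [m.upper() for m in monitor_ids]
    if stimulus == "pulse":
        stim = (STIM_ONSET_MS, STIM_ONSET_MS + 100.0, 5.0)
        total_ms = total_ms or 25_000.0
    elif stimulus == "sustained":
        stim = (STIM_ONSET_MS, STIM_ONSET_MS + 20_000.0, 1.2)
        total_ms = total_ms or 45_000.0
    else:
        raise ValueError(f"stimulus must be 'pulse' or 'sustained', got {stimulus!r}")

    def factory(net: Network):
        pops = [net.populations["corE"], net.populations["corI"]]
        return {mid: BoldMonitor(hypothesis_monitor(mid, pops))
                for mid in monitor_ids}

    per_seed = [
        _run_microcircuit_once(_seed_for(seed, i), factory, total_ms,
                               stim, n_recorded, config)
        for i in range(n_seeds)
    ]
    out = {
        mid: average_timeseries([run[mid] for run in per_seed])
        for mid in monitor_ids
    }
    if keep_per_seed:
        out["per_seed"] = per_seed
    return out


def scaling_table(n_recorded_list, seed: int = 0,
                  config: MicrocircuitConfig | None = None) -> pd.DataFrame:
    """Neuron and connection counts of the microcircuit at each size.

    Each size is actually constructed (populations wired, weights drawn) and
    the counts are read off the built network.
    """
    rows = []
    for n in n_recorded_list:
        net = build_microcircuit(int(n), seed=seed, config=config)
        rows.append({
            "n_recorded": int(n),
            "neurons": net.total_neurons,
            "connections": net.total_connections,
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# persistence and configuration
# --------------------------------------------------------------------------

def write_recordings(recordings, path, fmt: str = "csv",
                     metadata: dict | None = None) -> None:
    """Write one TimeSeries or a dict of them to ``path``.

    CSV writes one file per recording (``<path>/<name>.csv`` for dicts, the
    path itself for a single series); HDF5 writes one file with one group
    per recording.  ``metadata`` (e.g. the seed) goes to a JSON sidecar.
    """
    path = Path(path)
    if fmt not in ("csv", "hdf5"):
        raise ValueError(f"format must be 'csv' or 'hdf5', got {fmt!r}")
    if isinstance(recordings, TimeSeries):
        recordings = {"recording": recordings}
        single = True
    else:
        single = False
    if fmt == "csv":
        if single and path.suffix == ".csv":
            recordings["recording"].to_csv(path)
            meta_path = path.with_suffix(".json")
        else:
            path.mkdir(parents=True, exist_ok=True)
            for name, ts in recordings.items():
                ts.to_csv(path / f"{name}.csv")
            meta_path = path / "metadata.json"
    else:
        path.parent.mkdir(parents=True, exist_ok=True)
        for name, ts in recordings.items():
            ts.to_hdf5(path, group=name)
        meta_path = path.with_suffix(".json")
    if metadata is not None:
        meta_path.write_text(json.dumps(metadata, indent=2))


def load_recordings(path, fmt: str = "csv") -> dict[str, TimeSeries]:
    path = Path(path)
    if fmt == "csv":
        if path.is_dir():
            return {p.stem: TimeSeries.from_csv(p)
                    for p in sorted(path.glob("*.csv"))}
        return {"recording": TimeSeries.from_csv(path)}
    import h5py

    with h5py.File(path, "r") as f:
        groups = list(f.keys())
    return {g: TimeSeries.from_hdf5(path, group=g) for g in groups}


@dataclass
class ExperimentSpec:
    """A config-file description of one experiment run."""

    name: str
    experiment: str                       # artificial | demo | pulse | hypotheses | scale
    seeds: list[int] = field(default_factory=lambda: [0])
    options: dict = field(default_factory=dict)
    output_dir: str = "results"


_EXPERIMENTS = ("artificial", "demo", "pulse", "hypotheses", "scale")


def load_config(path) -> ExperimentSpec:
    """Load and validate a YAML experiment config.

    Required keys: ``name``, ``experiment``.  Errors name the offending key.
    """
    with open(path) as f:
        raw = yaml.safe_load(f)
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    for key in ("name", "experiment"):
        if key not in raw:
            raise ValueError(f"config is missing required key {key!r}")
    if raw["experiment"] not in _EXPERIMENTS:
        raise ValueError(
            f"config key 'experiment': unknown value {raw['experiment']!r} "
            f"(valid: {', '.join(_EXPERIMENTS)})"
        )
    seeds = raw.get("seeds", [0])
    if not isinstance(seeds, list) or not all(isinstance(s, int) for s in seeds):
        raise ValueError("config key 'seeds': must be a list of integers")
    options = raw.get("options", {})
    if not isinstance(options, dict):
        raise ValueError("config key 'options': must be a mapping")
    return ExperimentSpec(
        name=str(raw["name"]), experiment=raw["experiment"],
        seeds=seeds, options=options,
        output_dir=str(raw.get("output_dir", "results")),
    )


def run_experiment(spec: ExperimentSpec) -> dict:
    """Dispatch a loaded :class:`ExperimentSpec`; returns the recordings."""
    opts = dict(spec.options)
    if spec.experiment == "artificial":
        return {"artificial": run_artificial_pulse(**opts)}
    if spec.experiment == "demo":
        return {f"demo_seed{s}": run_simple_demo(seed=s, **opts)
                for s in spec.seeds}
    if spec.experiment == "pulse":
        return run_pulse_experiment(seed=spec.seeds[0], **opts)
    if spec.experiment == "hypotheses":
        return run_hypothesis_comparison(seed=spec.seeds[0], **opts)
    if spec.experiment == "scale":
        sizes = opts.pop("sizes", [250, 500, 1000, 2000])
        table = scaling_table(sizes, **opts)
        return {"scaling": table}
    raise ValueError(f"unknown experiment {spec.experiment!r}")
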