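"""Minimal spiking substrate for exercising the BOLD monitor.

Izhikevich point neurons (the 2003 simple form and the 2007 biophysical
form), Poisson spike sources, conductance-based AMPA/GABA synapses with
exponential decay, fixed in-degree projections with log-normal weights, and
the scalable two-population cortical microcircuit:

* ``corE`` — regular-spiking excitatory neurons (80% of recorded neurons),
* ``corI`` — fast-spiking inhibitory interneurons (20%),
* a Poisson input population the size of ``corE``,

wired by five projections (Poisson->corE, Poisson->corI, corE->corI,
corI->corE, corI->corI), each post-synaptic neuron receiving exactly
``indegree`` (default 10) inputs per projection.

Populations expose per-neuron *source variables* for the monitor: membrane
and recovery variables, conductances, a 100-ms windowed mean firing rate
``r``, the afferent-normalized synaptic activity ``syn``, synaptic current
magnitudes ``I_AMPA``/``I_GABA``, and user-registered arithmetic expressions
over any of these.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .dsl import _EMPTY_GLOBALS, Expression, ParseError, parse_expression

__all__ = [
    "IzhikevichSimpleParams",
    "Izhikevich2007Params",
    "RS_SIMPLE", "RS_2007", "FS_2007",
    "SpikingPopulation",
    "PoissonPopulation",
    "Projection",
    "Network",
    "MicrocircuitConfig",
    "poisson_step",
    "izhikevich_step",
    "synapse_step",
    "synaptic_current",
    "RateWindow",
    "sample_lognormal_weights",
    "sample_fixed_indegree",
    "build_microcircuit",
    "microcircuit_counts",
]

#: synaptic decay time constant, ms
TAU_SYN = 10.0
#: synaptic reversal potentials, mV
E_AMPA = 0.0
E_GABA = -90.0


@dataclass(frozen=True)
class IzhikevichSimpleParams:
    """The 2003 simple Izhikevich model: dv/dt = 0.04 v^2 + 5v + 140 - u + I,
    du/dt = a (b v - u); spike at v >= v_peak with v <- c, u <- u + d.

    Units follow the original dimensionless convention (v in mV, t in ms).
    ``noise`` is the amplitude of an additive per-step standard-normal
    current that sets the baseline drive.
    """

    a: float = 0.02
    b: float = 0.2
    c: float = -65.0
    d: float = 8.0
    v_peak: float = 30.0
    noise: float = 0.0

    def __post_init__(self) -> None:
        if self.c >= self.v_peak:
            raise ValueError("reset c must be below v_peak")


@dataclass(frozen=True)
class Izhikevich2007Params:
    """The 2007 biophysical Izhikevich form:
    C dv/dt = k (v - v_r)(v - v_t) - u + I,  du/dt = a (b (v - v_r) - u).

    ``recovery_cubic`` switches to the fast-spiking interneuron recovery
    nonlinearity: u relaxes toward 0 below ``v_b`` and toward
    ``b (v - v_b)^3`` above it.
    """

    C: float = 100.0     # pF
    k: float = 0.7
    v_r: float = -60.0   # mV
    v_t: float = -40.0
    v_peak: float = 35.0
    a: float = 0.03
    b: float = -2.0
    c: float = -50.0
    d: float = 100.0
    recovery_cubic: bool = False
    v_b: float | None = None
    noise: float = 0.0

    def __post_init__(self) -> None:
        if not (self.v_peak > self.v_t > self.v_r):
            raise ValueError("need v_peak > v_t > v_r")
        if self.c >= self.v_peak:
            raise ValueError("reset c must be below v_peak")
        if self.recovery_cubic and self.v_b is None:
            object.__setattr__(self, "v_b", self.v_r)


#: regular-spiking cortical neuron, simple 2003 form
RS_SIMPLE = IzhikevichSimpleParams(a=0.02, b=0.2, c=-65.0, d=8.0)
#: regular-spiking cortical pyramidal neuron, 2007 form
RS_2007 = Izhikevich2007Params(C=100.0, k=0.7, v_r=-60.0, v_t=-40.0,
                               v_peak=35.0, a=0.03, b=-2.0, c=-50.0, d=100.0)
#: fast-spiking cortical interneuron, 2007 form (cubic recovery)
FS_2007 = Izhikevich2007Params(C=20.0, k=1.0, v_r=-55.0, v_t=-40.0,
                               v_peak=25.0, a=0.2, b=0.025, c=-45.0, d=0.0,
                               recovery_cubic=True, v_b=-55.0)


# --------------------------------------------------------------------------
# elementary update rules
# --------------------------------------------------------------------------

def poisson_step(rates, dt: float, rng: np.random.Generator,
                 multiplier: float = 1.0) -> np.ndarray:
    """One grid step of Poisson spike generation (thinning approximation).

    Each neuron spikes with probability ``rate * multiplier * dt / 1000``.
    Raises if that probability exceeds 1 (grid too coarse for the rate).
    """
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    p = rates * multiplier * dt / 1000.0
    if np.any(p > 1.0):
        raise ValueError(
            f"spike probability per step exceeds 1 (max {p.max():.3f}); "
            "reduce dt or the rate"
        )
    return rng.random(rates.shape) < p


def izhikevich_step(params, v: np.ndarray, u: np.ndarray, I: np.ndarray,
                    dt: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One explicit-Euler step of either Izhikevich form.

    Returns updated (v, u, spikes).  Threshold detection and reset are
    applied after the update: where v >= v_peak, v <- c and u <- u + d.
    """
    v = np.asarray(v, float).copy()
    u = np.asarray(u, float).copy()
    if isinstance(params, IzhikevichSimpleParams):
        dv = 0.04 * v * v + 5.0 * v + 140.0 - u + I
        du = params.a * (params.b * v - u)
    elif isinstance(params, Izhikevich2007Params):
        dv = (params.k * (v - params.v_r) * (v - params.v_t) - u + I) / params.C
        if params.recovery_cubic:
            target = np.where(v < params.v_b, 0.0,
                              params.b * (v - params.v_b) ** 3)
            du = params.a * (target - u)
        else:
            du = params.a * (params.b * (v - params.v_r) - u)
    else:
        raise TypeError(f"unknown parameter type {type(params).__name__}")
    v += dt * dv
    u += dt * du
    if not np.all(np.isfinite(v)):
        raise FloatingPointError("membrane potential became non-finite")
    spikes = v >= params.v_peak
    v[spikes] = params.c
    u[spikes] += params.d
    return v, u, spikes


def synapse_step(g: np.ndarray, weight_increments, dt: float,
                 tau: float = TAU_SYN) -> np.ndarray:
    """Exact exponential conductance decay plus per-spike weight increments:
    ``g <- g * exp(-dt/tau) + sum(incoming weights)``."""
    return g * math.exp(-dt / tau) + weight_increments


def synaptic_current(g: np.ndarray, v: np.ndarray, e_rev: float) -> np.ndarray:
    """Conductance-based synaptic current ``g * (E_rev - v)``."""
    return g * (e_rev - v)


class RateWindow:
    """Incremental windowed mean firing rate (Hz) over the last ``window`` ms.

    Keeps a ring buffer of per-step spike flags; the rate is
    ``1000 * count / window_ms``.
    """

    def __init__(self, n: int, window: float, dt: float):
        steps = window / dt
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("window must be a multiple of dt")
        self.window = window
        self.n_steps = int(round(steps))
        self.buffer = np.zeros((self.n_steps, n), dtype=np.uint8)
        self.counts = np.zeros(n, dtype=np.int64)
        self.pos = 0

    def update(self, spikes: np.ndarray) -> None:
        """Push one step of spike flags."""
        s = spikes.view(np.uint8) if spikes.dtype == np.bool_ \
            else spikes.astype(np.uint8)
        self.counts += s
        self.counts -= self.buffer[self.pos]
        self.buffer[self.pos] = s
        self.pos = (self.pos + 1) % self.n_steps

    @property
    def rate(self) -> np.ndarray:
        return self.counts * (1000.0 / self.window)


def sample_lognormal_weights(mu: float, sigma: float, scale: float, n: int,
                             rng: np.random.Generator) -> np.ndarray:
    """Log-normal synaptic weights scaled by a projection factor.

    The sample median converges to ``scale * exp(mu)`` for large n.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if scale <= 0:
        raise ValueError("scale must be positive")
    return scale * rng.lognormal(mean=mu, sigma=sigma, size=n)


def sample_fixed_indegree(n_pre: int, n_post: int, k: int,
                          rng: np.random.Generator) -> np.ndarray:
    """For each post neuron draw ``k`` distinct pre indices uniformly.

    Returns an (n_post, k) integer array.
    """
    if k > n_pre:
        raise ValueError(f"in-degree {k} exceeds pre-population size {n_pre}")
    if n_pre <= 8 * k:
        # small pre population: rank random keys (duplicate-free by design)
        keys = rng.random((n_post, n_pre))
        return np.argpartition(keys, k - 1, axis=1)[:, :k]
    idx = rng.integers(0, n_pre, size=(n_post, k))
    while True:
        srt = np.sort(idx, axis=1)
        bad = (srt[:, 1:] == srt[:, :-1]).any(axis=1)
        if not bad.any():
            return idx
        idx[bad] = rng.integers(0, n_pre, size=(int(bad.sum()), k))


# --------------------------------------------------------------------------
# populations and projections
# --------------------------------------------------------------------------

class PopulationBase:
    """Shared surface of spiking and Poisson populations."""

    name: str
    size: int

    def __init__(self, name: str, size: int):
        if size <= 0:
            raise ValueError("population size must be positive")
        self.name = name
        self.size = size
        self.spikes = np.zeros(size, dtype=bool)
        self._prev_spike_idx = np.empty(0, dtype=np.int64)

    def commit_spikes(self) -> None:
        """Latch this step's spikes for next-step synaptic transmission."""
        self._prev_spike_idx = np.flatnonzero(self.spikes)


class SpikingPopulation(PopulationBase):
    """A homogeneous population of Izhikevich neurons with AMPA/GABA
    conductances, a windowed firing rate, and derived source variables."""

    def __init__(self, name: str, size: int, params, dt: float,
                 rng: np.random.Generator | None = None,
                 rate_window: float = 100.0, noise: float | None = None):
        super().__init__(name, size)
        self.params = params
        self.dt = dt
        self.rng = rng or np.random.default_rng()
        self.noise = params.noise if noise is None else noise
        self._simple_form = isinstance(params, IzhikevichSimpleParams)
        if not self._simple_form and not isinstance(params, Izhikevich2007Params):
            raise TypeError(f"unknown parameter type {type(params).__name__}")
        if isinstance(params, IzhikevichSimpleParams):
            v0 = params.c
            u0 = params.b * params.c
        else:
            v0 = params.v_r
            u0 = 0.0
        self.v = np.full(size, float(v0))
        self.u = np.full(size, float(u0))
        self.g_ampa = np.zeros(size)
        self.g_gaba = np.zeros(size)
        self._pending_ampa = np.zeros(size)
        self._pending_gaba = np.zeros(size)
        self._I_ampa = np.zeros(size)
        self._I_gaba = np.zeros(size)
        self._decay = math.exp(-dt / TAU_SYN)
        self._rate = RateWindow(size, rate_window, dt)
        self.n_afferent = 0   # total afferent synapses per neuron (set by wiring)
        self._expressions: dict[str, Expression] = {}
        self._var_cache: dict[str, np.ndarray] = {}

    # -- wiring ------------------------------------------------------------

    def add_conductance(self, kind: str, increments: np.ndarray) -> None:
        if kind == "AMPA":
            self._pending_ampa += increments
        elif kind == "GABA":
            self._pending_gaba += increments
        else:
            raise ValueError(f"unknown synapse kind {kind!r}")

    # -- dynamics ----------------------------------------------------------

    def step(self, I_ext: float | np.ndarray = 0.0) -> None:
        self._var_cache.clear()
        g_a = self.g_ampa
        g_g = self.g_gaba
        g_a *= self._decay
        g_a += self._pending_ampa
        g_g *= self._decay
        g_g += self._pending_gaba
        self._pending_ampa[:] = 0.0
        self._pending_gaba[:] = 0.0
        v, u, p, dt = self.v, self.u, self.params, self.dt
        self._I_ampa = g_a * (E_AMPA - v)
        self._I_gaba = g_g * (E_GABA - v)
        I = self._I_ampa + self._I_gaba
        if isinstance(I_ext, np.ndarray) or I_ext != 0.0:
            I = I + I_ext
        if self.noise:
            I += self.noise * self.rng.standard_normal(self.size)
        # inline Euler update (same arithmetic as izhikevich_step; dv and du
        # are both evaluated at the pre-update state)
        if self._simple_form:
            dv = 0.04 * v * v + 5.0 * v + 140.0 - u + I
            du = p.a * (p.b * v - u)
        else:
            dv = (p.k * (v - p.v_r) * (v - p.v_t) - u + I) * (1.0 / p.C)
            if p.recovery_cubic:
                target = np.where(v < p.v_b, 0.0, p.b * (v - p.v_b) ** 3)
                du = p.a * (target - u)
            else:
                du = p.a * (p.b * (v - p.v_r) - u)
        v += dt * dv
        u += dt * du
        if not math.isfinite(float(v.sum())):
            raise FloatingPointError(
                f"membrane potential became non-finite in {self.name!r}")
        spikes = v >= p.v_peak
        if spikes.any():
            v[spikes] = p.c
            if p.d:
                u[spikes] += p.d
        self.spikes = spikes
        self._rate.update(spikes)

    # -- source variables ----------------------------------------------------

    def register_expression(self, name: str, source: str) -> None:
        """Register a derived per-neuron source variable, e.g.
        ``pop.register_expression("drive", "I_AMPA + 1.5 * I_GABA")``."""
        expr = parse_expression(source)
        unknown = expr.names - set(self.variables)
        if unknown:
            raise ParseError(
                f"expression for {name!r} references unknown per-neuron "
                f"variable(s) {sorted(unknown)}"
            )
        self._expressions[name] = expr

    _DIRECT = {"v": "v", "u": "u", "g_AMPA": "g_ampa", "g_GABA": "g_gaba"}

    @property
    def variables(self) -> list[str]:
        base = ["v", "u", "g_AMPA", "g_GABA", "r", "I_AMPA", "I_GABA"]
        if self.n_afferent > 0:
            base.append("syn")
        return base + list(self._expressions)

    def get_variable(self, name: str) -> np.ndarray:
        """Per-neuron values of a source variable.

        Synaptic current magnitudes are exposed (|g (E_rev - v)|) so that
        inhibitory activity contributes positively to flow-driving signals;
        ``syn`` is the total conductance normalized by the afferent synapse
        count.  Derived values are cached within a step, so several monitors
        reading the same variable share one evaluation.
        """
        attr = self._DIRECT.get(name)
        if attr is not None:
            return getattr(self, attr)
        cache = self._var_cache
        val = cache.get(name)
        if val is not None:
            return val
        if name == "r":
            val = self._rate.rate
        elif name == "I_AMPA":
            val = np.abs(self._I_ampa)
        elif name == "I_GABA":
            val = np.abs(self._I_gaba)
        elif name == "syn":
            if self.n_afferent == 0:
                raise ValueError(
                    f"population {self.name!r} has no afferent projections; "
                    "'syn' is undefined"
                )
            val = (self.g_ampa + self.g_gaba) / self.n_afferent
        elif name in self._expressions:
            expr = self._expressions[name]
            env = {n: self.get_variable(n) for n in expr.names}
            # names were validated at registration; plain eval is enough
            val = eval(expr.code, _EMPTY_GLOBALS, env)
        else:
            raise KeyError(f"population {self.name!r} has no variable {name!r}")
        cache[name] = val
        return val

    def get_average(self, name: str) -> float:
        """Population mean of a source variable, cached within a step so
        that several monitors reading the same variable share one
        reduction."""
        key = "\0avg\0" + name
        val = self._var_cache.get(key)
        if val is None:
            arr = self.get_variable(name)
            val = float(np.add.reduce(arr) / arr.size)
            self._var_cache[key] = val
        return val


class PoissonPopulation(PopulationBase):
    """Spike source population with Poisson inter-spike intervals.

    ``rate`` may be a scalar (Hz) or a per-neuron array; a stimulus
    multiplier can be applied per step.
    """

    def __init__(self, name: str, size: int, rate, rng: np.random.Generator):
        super().__init__(name, size)
        self.rate = np.broadcast_to(np.asarray(rate, float), (size,)).copy()
        if np.any(self.rate < 0):
            raise ValueError("rates must be non-negative")
        self.rng = rng
        self.multiplier = 1.0
        self._cached_p: np.ndarray | None = None
        self._cached_key: tuple | None = None

    def step(self, dt: float) -> None:
        key = (dt, self.multiplier)
        if key != self._cached_key:
            p = self.rate * (self.multiplier * dt / 1000.0)
            if np.any(p > 1.0):
                raise ValueError(
                    f"spike probability per step exceeds 1 (max {p.max():.3f});"
                    " reduce dt or the rate"
                )
            self._cached_p = p
            self._cached_key = key
        self.spikes = self.rng.random(self.size) < self._cached_p


@dataclass
class Projection:
    """Fixed in-degree connectivity with per-synapse weights.

    Every post-synaptic neuron receives exactly ``indegree`` synapses from
    distinct pre-synaptic neurons; weights are per-synapse.
    """

    pre: PopulationBase
    post: SpikingPopulation
    kind: str                     # "AMPA" | "GABA"
    pre_indices: np.ndarray       # (n_post, indegree)
    weights: np.ndarray           # (n_post, indegree)
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("AMPA", "GABA"):
            raise ValueError(f"synapse kind must be AMPA or GABA, got {self.kind!r}")
        if self.pre_indices.shape != self.weights.shape:
            raise ValueError("pre_indices and weights shapes differ")
        if np.any(self.weights < 0):
            raise ValueError("synaptic weights must be non-negative")
        srt = np.sort(self.pre_indices, axis=1)
        if (srt[:, 1:] == srt[:, :-1]).any():
            raise ValueError("duplicate pre indices for some post neuron")
        if not self.name:
            self.name = f"{self.pre.name}->{self.post.name}"
        n_post, k = self.pre_indices.shape
        rows = np.repeat(np.arange(n_post), k)
        self._matrix = sparse.csc_matrix(
            (self.weights.ravel(), (rows, self.pre_indices.ravel())),
            shape=(n_post, self.pre.size),
        )
        # column-compressed views for per-spike scatter delivery
        self._indptr = self._matrix.indptr
        self._post_idx = self._matrix.indices
        self._data = self._matrix.data

    @property
    def indegree(self) -> int:
        return self.pre_indices.shape[1]

    @property
    def n_connections(self) -> int:
        return self.pre_indices.size

    def propagate(self) -> None:
        """Deliver last step's pre-synaptic spikes as conductance increments.

        Spiking is sparse on a sub-millisecond grid, so delivery scatters
        each spiking neuron's efferent weights directly (equivalent to a
        sparse matrix-vector product with the spike indicator vector).
        """
        pending = (self.post._pending_ampa if self.kind == "AMPA"
                   else self.post._pending_gaba)
        indptr, post_idx, data = self._indptr, self._post_idx, self._data
        for j in self.pre._prev_spike_idx:
            lo, hi = indptr[j], indptr[j + 1]
            pending[post_idx[lo:hi]] += data[lo:hi]


class Network:
    """A set of populations and projections advanced on a common grid.

    Monitors attached to the network are stepped after every network update;
    they never feed back into the dynamics, so adding a monitor cannot change
    spike trains.
    """

    def __init__(self, dt: float = 0.1):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.dt = dt
        self.time = 0.0
        self.populations: dict[str, PopulationBase] = {}
        self.projections: list[Projection] = []
        self.monitors: list = []
        self.stimulus_schedule: list[tuple[float, float, float]] = []

    def add_population(self, pop: PopulationBase) -> PopulationBase:
        if pop.name in self.populations:
            raise ValueError(f"duplicate population name {pop.name!r}")
        self.populations[pop.name] = pop
        return pop

    def add_projection(self, proj: Projection) -> Projection:
        self.projections.append(proj)
        proj.post.n_afferent += proj.indegree
        return proj

    def attach_monitor(self, monitor) -> None:
        self.monitors.append(monitor)

    def set_stimulus_schedule(
            self, schedule: list[tuple[float, float, float]]) -> None:
        """(t_start ms, t_end ms, rate multiplier) windows, non-overlapping."""
        windows = sorted(schedule)
        for (a0, a1, _), (b0, _, _) in zip(windows, windows[1:]):
            if b0 < a1:
                raise ValueError("stimulus windows overlap")
        for a0, a1, _ in windows:
            if a1 <= a0:
                raise ValueError("stimulus window must have t_end > t_start")
        self.stimulus_schedule = windows

    def _current_multiplier(self) -> float:
        for t0, t1, mult in self.stimulus_schedule:
            if t0 <= self.time < t1:
                return mult
        return 1.0

    @property
    def total_neurons(self) -> int:
        return sum(p.size for p in self.populations.values())

    @property
    def total_connections(self) -> int:
        return sum(p.n_connections for p in self.projections)

    def step(self) -> None:
        mult = self._current_multiplier()
        pops = self.populations.values()
        for pop in pops:
            if isinstance(pop, PoissonPopulation):
                pop.multiplier = mult
                pop.step(self.dt)
        for proj in self.projections:
            proj.propagate()
        for pop in pops:
            if isinstance(pop, SpikingPopulation):
                pop.step()
        for pop in pops:
            pop.commit_spikes()
        self.time += self.dt
        for monitor in self.monitors:
            monitor.step(self.dt)

    def run(self, duration: float) -> None:
        """Advance the network by ``duration`` ms."""
        for _ in range(int(round(duration / self.dt))):
            self.step()


# --------------------------------------------------------------------------
# the scalable microcircuit
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MicrocircuitConfig:
    """Construction parameters of the cortical microcircuit.

    The weight distribution and projection scale factors were calibrated
    once so that the default circuit fires sparsely (corE at a few Hz, corI
    severalfold higher), the regime the monitor's baseline normalization
    expects; they are configuration entries, not fitted claims.
    """

    dt: float = 0.1                       # ms
    indegree: int = 10
    poisson_rate_mean: float = 15.0       # Hz
    poisson_rate_rel_sd: float = 0.05     # per-seed jitter of the mean rate
    rate_window: float = 100.0            # ms
    weight_mu: float = -1.5               # log-normal location (log nS)
    weight_sigma: float = 0.93            # log-normal shape
    scale_poisson_corE: float = 2.0
    scale_poisson_corI: float = 2.0
    scale_corE_corI: float = 1.0
    scale_corI_corE: float = 1.0
    scale_corI_corI: float = 0.5


def microcircuit_counts(n_recorded: int,
                        config: MicrocircuitConfig | None = None
                        ) -> tuple[int, int]:
    """(total neurons, total connections) of the microcircuit without
    building it: corE = 0.8 n, corI = 0.2 n, Poisson = corE, five
    projections of fixed in-degree."""
    cfg = config or MicrocircuitConfig()
    if n_recorded <= 0 or n_recorded % 5:
        raise ValueError(
            f"n_recorded must be a positive multiple of 5 (4:1 split), "
            f"got {n_recorded}"
        )
    n_e = (4 * n_recorded) // 5
    n_i = n_recorded // 5
    neurons = n_e + n_i + n_e
    connections = cfg.indegree * (2 * n_e + 3 * n_i)
    return neurons, connections


def build_microcircuit(n_recorded: int, seed: int | np.random.Generator = 0,
                       config: MicrocircuitConfig | None = None) -> Network:
    """Build the two-population microcircuit with Poisson drive.

    Parameters
    ----------
    n_recorded:
        Number of recorded (cortical) neurons; must be divisible by 5 for
        the 4:1 excitatory:inhibitory split.
    seed:
        Integer seed or a numpy Generator; controls connectivity, weights
        and the per-seed jitter of the Poisson baseline rate.
    """
    cfg = config or MicrocircuitConfig()
    if n_recorded <= 0 or n_recorded % 5:
        raise ValueError(
            f"n_recorded must be a positive multiple of 5 (4:1 split), "
            f"got {n_recorded}"
        )
    if isinstance(seed, np.random.Generator):
        root = seed
    else:
        root = np.random.default_rng(seed)
    # independent streams so monitor count / recording never shifts dynamics
    rng_build, rng_poisson, rng_e, rng_i = root.spawn(4)

    n_e = (4 * n_recorded) // 5
    n_i = n_recorded // 5

    net = Network(dt=cfg.dt)
    rate = cfg.poisson_rate_mean * (
        1.0 + cfg.poisson_rate_rel_sd * rng_build.standard_normal()
    )
    poisson = net.add_population(
        PoissonPopulation("poisson", n_e, max(rate, 0.0), rng_poisson))
    cor_e = net.add_population(SpikingPopulation(
        "corE", n_e, RS_2007, cfg.dt, rng=rng_e, rate_window=cfg.rate_window))
    cor_i = net.add_population(SpikingPopulation(
        "corI", n_i, FS_2007, cfg.dt, rng=rng_i, rate_window=cfg.rate_window))

    def connect(pre, post, kind, scale, name):
        idx = sample_fixed_indegree(pre.size, post.size, cfg.indegree, rng_build)
        w = sample_lognormal_weights(
            cfg.weight_mu, cfg.weight_sigma, scale,
            post.size * cfg.indegree, rng_build,
        ).reshape(post.size, cfg.indegree)
        net.add_projection(Projection(pre, post, kind, idx, w, name=name))

    connect(poisson, cor_e, "AMPA", cfg.scale_poisson_corE, "poisson->corE")
    connect(poisson, cor_i, "AMPA", cfg.scale_poisson_corI, "poisson->corI")
    connect(cor_e, cor_i, "AMPA", cfg.scale_corE_corI, "corE->corI")
    connect(cor_i, cor_e, "GABA", cfg.scale_corI_corE, "corI->corE")
    connect(cor_i, cor_i, "GABA", cfg.scale_corI_corI, "corI->corI")
    return net
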