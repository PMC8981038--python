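"""Built-in hemodynamic models.

The Balloon model treats the venous compartment as an expandable balloon:
inflow f_in (normalized cerebral blood flow, CBF) inflates the venous volume
fraction v, oxygen extraction E(f_in) loads deoxyhemoglobin q, and the BOLD
signal is a non-linear combination of q and v.  Neurovascular coupling enters
through a damped-oscillator flow-driving signal s stimulated by the input
I_CBF.

Four classic variants combine two coefficient sets with two BOLD equations:

* coefficients — classic (k1 = 7 E0, k2 = 2, k3 = 2 E0 - 0.2) or revised
  (k1 = 4.3 nu0 E0 TE, k2 = eps r0 E0 TE, k3 = 1 - eps);
* BOLD equation — non-linear
  ``V0 (k1 (1-q) + k2 (1 - q/v) + k3 (1-v))`` or linearized
  ``V0 ((k1+k2)(1-q) + (k3-k2)(1-v))``.

The naming follows the common C/R (classic/revised) x N/L (non-linear/linear)
convention: ``balloon_CN``, ``balloon_CL``, ``balloon_RN``, ``balloon_RL``.

The two-input variant drives normalized CBF and CMRO2 (oxygen metabolism, r)
in parallel by separate input signals, with a viscoelastic venous outflow
that lets v lag its steady-state relation — enabling an initial dip and a
slower post-stimulus recovery.

A Davis-model extension computes, alongside the Balloon output,
``dBOLD = M (1 - f^a (r/f)^b)`` from the normalized CBF and CMRO2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .dsl import ModelDefinition, ModelError, ModelRunner, ModelState, parse_model

__all__ = [
    "BalloonParameters",
    "TwoInputParameters",
    "DavisParameters",
    "make_balloon",
    "make_two_input_balloon",
    "make_davis_extended_balloon",
    "oxygen_extraction",
    "davis_bold",
    "steady_state",
    "get_model",
    "BUILTIN_MODELS",
]


@dataclass(frozen=True)
class BalloonParameters:
    """Parameters of the classic Balloon model.

    Defaults are standard revised-Balloon literature values.

    Attributes
    ----------
    phi:
        Input gain (dimensionless).
    kappa:
        Flow-signal decay rate, s^-1.
    gamma:
        Flow-signal feedback rate, s^-1; steady-state flow for constant
        input c is ``1 + phi*c/gamma``.
    E_0:
        Resting oxygen extraction fraction.
    tau_0:
        Mean venous transit time, s.
    alpha:
        Grubb flow-volume exponent.
    V_0:
        Resting venous blood volume fraction.
    epsilon, nu_0, r_0, TE:
        Intra/extravascular signal ratio, frequency offset (s^-1), slope
        (s^-1) and echo time (s) entering the revised coefficients.
    """

    phi: float = 1.0
    kappa: float = 1.0 / 1.54
    gamma: float = 1.0 / 2.46
    E_0: float = 0.34
    tau_0: float = 0.98
    alpha: float = 0.33
    V_0: float = 0.02
    epsilon: float = 1.43
    nu_0: float = 40.3
    r_0: float = 25.0
    TE: float = 0.04

    def __post_init__(self) -> None:
        for name in ("phi", "kappa", "gamma", "tau_0", "epsilon",
                     "nu_0", "r_0", "TE"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("E_0", "V_0", "alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


@dataclass(frozen=True)
class TwoInputParameters(BalloonParameters):
    """Balloon parameters plus the CMRO2 oscillator and viscoelastic lag.

    The CMRO2 chain mirrors the CBF damped oscillator but is critically
    damped (``kappa_CMRO2 = 2*sqrt(gamma_CMRO2)`` by default) and stiffer
    (``gamma_CMRO2 = 16*gamma``), so the normalized CMRO2 responds several
    times faster than the CBF and without over/undershoot.  The CMRO2 input
    gain is scaled internally by ``gamma_CMRO2/gamma`` so that equal
    constant inputs still elicit responses with equal steady amplitudes
    (``r - 1 = f_in - 1 = phi*c/gamma``) whatever the speed ratio.  Only a
    CMRO2 chain that is dynamically faster than the CBF chain can produce
    the initial dip: deoxyhemoglobin must accumulate before inflow and
    washout catch up.
    """

    kappa_CMRO2: float | None = None
    gamma_CMRO2: float | None = None
    tau_visc: float = 6.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.gamma_CMRO2 is None:
            object.__setattr__(self, "gamma_CMRO2", 16.0 * self.gamma)
        if self.kappa_CMRO2 is None:
            object.__setattr__(self, "kappa_CMRO2",
                               2.0 * math.sqrt(self.gamma_CMRO2))
        if self.tau_visc < 0:
            raise ValueError("tau_visc must be non-negative")
        if self.kappa_CMRO2 < 2.0 * math.sqrt(self.gamma_CMRO2) - 1e-12:
            warnings.warn(
                "CMRO2 oscillator is underdamped (kappa_CMRO2 < 2*sqrt("
                "gamma_CMRO2)); the CMRO2 response will overshoot",
                UserWarning, stacklevel=2,
            )


@dataclass(frozen=True)
class DavisParameters:
    """Davis-model parameters: scaling M, flow-volume exponent alpha_D and
    deoxyhemoglobin exponent beta_D."""

    M: float = 0.08
    alpha_D: float = 0.38
    beta_D: float = 1.5

    def __post_init__(self) -> None:
        if self.M <= 0 or self.alpha_D <= 0 or self.beta_D <= 0:
            raise ValueError("Davis parameters must be positive")


_VARIANTS = {"CN", "CL", "RN", "RL"}

_CLASSIC_COEFFS = (
    "k_1 = 7 * E_0\n"
    "k_2 = 2\n"
    "k_3 = 2 * E_0 - 0.2\n"
)
_REVISED_COEFFS = (
    "k_1 = 4.3 * nu_0 * E_0 * TE\n"
    "k_2 = epsilon * r_0 * E_0 * TE\n"
    "k_3 = 1 - epsilon\n"
)
_NONLINEAR_BOLD = (
    "BOLD = V_0 * (k_1 * (1 - q) + k_2 * (1 - q / v) + k_3 * (1 - v))"
)
_LINEAR_BOLD = (
    "BOLD = V_0 * ((k_1 + k_2) * (1 - q) + (k_3 - k_2) * (1 - v))"
)


def _balloon_parameter_block(p: BalloonParameters, revised: bool) -> str:
    lines = [
        f"phi = {p.phi!r}",
        f"kappa = {p.kappa!r}",
        f"gamma = {p.gamma!r}",
        f"E_0 = {p.E_0!r}",
        f"tau_0 = {p.tau_0!r}",
        f"alpha = {p.alpha!r}",
        f"V_0 = {p.V_0!r}",
    ]
    if revised:
        lines += [
            f"epsilon = {p.epsilon!r}",
            f"nu_0 = {p.nu_0!r}",
            f"r_0 = {p.r_0!r}",
            f"TE = {p.TE!r}",
        ]
    return "\n".join(lines)


def make_balloon(variant: str = "RN",
                 params: BalloonParameters | None = None) -> ModelDefinition:
    """Build one of the four classic Balloon model variants.

    ``variant`` selects coefficients (C = classic, R = revised) and BOLD
    equation (N = non-linear, L = linear).  The definition has one input
    ``I_CBF`` and output ``BOLD``.
    """
    variant = variant.upper()
    if variant not in _VARIANTS:
        raise ModelError(f"unknown Balloon variant {variant!r} (use CN/CL/RN/RL)")
    p = params or BalloonParameters()
    revised = variant[0] == "R"
    coeffs = _REVISED_COEFFS if revised else _CLASSIC_COEFFS
    bold = _NONLINEAR_BOLD if variant[1] == "N" else _LINEAR_BOLD
    equations = (
        "ds/dt = phi * sum(I_CBF) - kappa * s - gamma * (f_in - 1)\n"
        "df_in/dt = s : init=1.0\n"
        "E = 1 - (1 - E_0)**(1 / f_in)\n"
        "dv/dt = (f_in - v**(1/alpha)) / tau_0 : init=1.0\n"
        "f_out = v**(1/alpha)\n"
        "dq/dt = (f_in * E / E_0 - f_out * q / v) / tau_0 : init=1.0\n"
        + coeffs + bold
    )
    return parse_model(
        _balloon_parameter_block(p, revised), equations,
        inputs=["I_CBF"], output="BOLD", name=f"balloon_{variant}",
    )


def make_two_input_balloon(
        params: TwoInputParameters | None = None) -> ModelDefinition:
    """Build the Balloon model with parallel CBF and CMRO2 drive.

    Inputs ``I_CBF`` and ``I_CMRO2`` feed two damped oscillators for the
    normalized CBF (f_in) and CMRO2 (r).  The deoxyhemoglobin balance is
    driven by r directly, and the venous outflow includes a viscoelastic
    term so the volume fraction lags its steady-state relation:

        dv/dt = (f_in - v^(1/alpha)) / (tau_0 + tau_visc)
        f_out = v^(1/alpha) + tau_visc * dv/dt

    The BOLD output uses the revised non-linear equation.
    """
    p = params or TwoInputParameters()
    parameters = (
        _balloon_parameter_block(p, revised=True)
        + f"\nkappa_CMRO2 = {p.kappa_CMRO2!r}"
        + f"\ngamma_CMRO2 = {p.gamma_CMRO2!r}"
        + f"\ntau_visc = {p.tau_visc!r}"
        + "\nphi_CMRO2 = phi * gamma_CMRO2 / gamma"  # equal steady gain
    )
    equations = (
        "ds/dt = phi * sum(I_CBF) - kappa * s - gamma * (f_in - 1)\n"
        "df_in/dt = s : init=1.0\n"
        "ds_CMRO2/dt = phi_CMRO2 * sum(I_CMRO2) - kappa_CMRO2 * s_CMRO2"
        " - gamma_CMRO2 * (r - 1)\n"
        "dr/dt = s_CMRO2 : init=1.0\n"
        "dv/dt = (f_in - v**(1/alpha)) / (tau_0 + tau_visc) : init=1.0\n"
        "f_out = v**(1/alpha)"
        " + tau_visc * (f_in - v**(1/alpha)) / (tau_0 + tau_visc)\n"
        "dq/dt = (r - f_out * q / v) / tau_0 : init=1.0\n"
        + _REVISED_COEFFS + _NONLINEAR_BOLD
    )
    return parse_model(parameters, equations,
                       inputs=["I_CBF", "I_CMRO2"], output="BOLD",
                       name="balloon_two_inputs")


def make_davis_extended_balloon(
        params: BalloonParameters | None = None,
        davis: DavisParameters | None = None) -> ModelDefinition:
    """Revised non-linear Balloon model that additionally evaluates the
    Davis model.

    The normalized CMRO2 is recovered from the flow chain as
    ``r = f_in * E / E_0`` and fed into the Davis equation; the extra
    recordable variable is ``BOLD_Davis`` (the output stays ``BOLD``).
    """
    p = params or BalloonParameters()
    d = davis or DavisParameters()
    parameters = (
        _balloon_parameter_block(p, revised=True)
        + f"\nM = {d.M!r}\nalpha_D = {d.alpha_D!r}\nbeta_D = {d.beta_D!r}"
    )
    equations = (
        "ds/dt = phi * sum(I_CBF) - kappa * s - gamma * (f_in - 1)\n"
        "df_in/dt = s : init=1.0\n"
        "E = 1 - (1 - E_0)**(1 / f_in)\n"
        "dv/dt = (f_in - v**(1/alpha)) / tau_0 : init=1.0\n"
        "f_out = v**(1/alpha)\n"
        "dq/dt = (f_in * E / E_0 - f_out * q / v) / tau_0 : init=1.0\n"
        + _REVISED_COEFFS + _NONLINEAR_BOLD + "\n"
        "r = f_in * E / E_0 : init=1.0\n"
        "BOLD_Davis = M * (1 - f_in**alpha_D * (r / f_in)**beta_D)"
    )
    return parse_model(parameters, equations,
                       inputs=["I_CBF"], output="BOLD",
                       name="balloon_RN_davis")


def oxygen_extraction(f_in: float, E_0: float = 0.34) -> float:
    """Oxygen extraction fraction under the oxygen-limitation model,
    ``E = 1 - (1 - E_0)**(1/f_in)``.

    Decreasing in f_in: faster flow leaves less time to extract oxygen.
    """
    if f_in <= 0:
        raise ValueError(f"f_in must be positive, got {f_in}")
    if not 0 < E_0 < 1:
        raise ValueError(f"E_0 must lie in (0, 1), got {E_0}")
    return 1.0 - (1.0 - E_0) ** (1.0 / f_in)


def davis_bold(f: float, r: float,
               params: DavisParameters | None = None) -> float:
    """Davis-model relative BOLD change ``M * (1 - f^a * (r/f)^b)`` for
    normalized CBF ``f`` and CMRO2 ``r``."""
    if f <= 0 or r <= 0:
        raise ValueError(f"normalized CBF and CMRO2 must be positive "
                         f"(got f={f}, r={r})")
    p = params or DavisParameters()
    return p.M * (1.0 - f ** p.alpha_D * (r / f) ** p.beta_D)


def steady_state(definition: ModelDefinition,
                 constant_inputs: dict[str, float] | None = None,
                 dt: float = 1.0, tol: float = 1e-10,
                 max_time_s: float = 600.0) -> ModelState:
    """Long-integration fixed point under constant inputs.

    Integrates until every ODE right-hand side is below ``tol`` (s^-1),
    staying faithful to the shipped (Euler) dynamics rather than solving the
    algebraic system directly.
    """
    inputs = dict(constant_inputs or {})
    missing = set(definition.inputs) - inputs.keys()
    if missing:
        raise ModelError(f"missing constant input(s) {sorted(missing)}")
    runner = ModelRunner(definition)
    runner.set_inputs(inputs)
    check_every = max(1, int(round(100.0 / dt)))  # every 100 ms
    n_max = int(round(max_time_s * 1000.0 / dt))
    for i in range(n_max):
        runner.step(dt)
        if (i + 1) % check_every == 0:
            rates = runner.ode_rates()
            if all(abs(v) < tol for v in rates.values()):
                return runner.state
    raise ModelError(
        f"no steady state within {max_time_s} s (max |rhs| = "
        f"{max(abs(v) for v in runner.ode_rates().values()):.3e})"
    )


def _builtin_factories():
    return {
        "balloon_CN": lambda: make_balloon("CN"),
        "balloon_CL": lambda: make_balloon("CL"),
        "balloon_RN": lambda: make_balloon("RN"),
        "balloon_RL": lambda: make_balloon("RL"),
        "balloon_two_inputs": make_two_input_balloon,
        "balloon_RN_davis": make_davis_extended_balloon,
    }


BUILTIN_MODELS = tuple(_builtin_factories())


def get_model(name: str) -> ModelDefinition:
    """Instantiate a built-in model by name (default parameters)."""
    try:
        return _builtin_factories()[name]()
    except KeyError:
        raise ModelError(
            f"unknown model {name!r}; built-ins: {', '.join(BUILTIN_MODELS)}"
        ) from None
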