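"""Equation-based definition and forward-Euler integration of hemodynamic models.

A hemodynamic ("BOLD") model is declared as two text blocks — parameters
(``name = value`` per line) and equations — plus the names of its input
signals and a single output variable.  Equations are either ordinary
differential equations (left-hand side ``d<var>/dt``) integrated with the
explicit Euler method on a fixed millisecond grid, or algebraic assignments
re-evaluated every step in declaration order.  Input signals supplied by a
monitor are read inside equations through the accessor ``sum(NAME)``.

Rate constants and time constants in model definitions are in s^-1 and s
respectively, while the simulation grid is in ms; the Euler update therefore
uses ``dt/1000`` as the effective step.

Expressions use the operators ``+ - * / **`` (power is right-associative),
parentheses and unary minus.  Trailing annotations after a colon set the
initial value and optional clamps, e.g.::

    dv/dt = (f_in - v**(1/alpha)) / tau_0 : init=1.0, min=0.01
"""

from __future__ import annotations

import ast
import json
import math
import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .recording import TimeSeries

__all__ = [
    "ModelError",
    "ParseError",
    "IntegrationError",
    "EquationSpec",
    "ModelDefinition",
    "ModelState",
    "ModelRunner",
    "parse_expression",
    "evaluate_expression",
    "parse_model",
    "step",
    "integrate",
]


class ModelError(Exception):
    """Base class for model definition and evaluation errors."""


class ParseError(ModelError):
    """Raised when a model definition violates the grammar or references
    undefined symbols."""


class IntegrationError(ModelError):
    """Raised when a variable becomes non-finite during integration."""


# --------------------------------------------------------------------------
# expression handling
# --------------------------------------------------------------------------

_ALLOWED_BINOPS = (ast.Add, ast.Sub, ast.Mult, ast.Div, ast.Pow)
_ALLOWED_UNARY = (ast.USub, ast.UAdd)

#: name of the input accessor in definition text
INPUT_ACCESSOR = "sum"


class _InputRewriter(ast.NodeTransformer):
    """Rewrite ``sum(NAME)`` calls into plain reads of the input variable."""

    def __init__(self) -> None:
        self.inputs_used: set[str] = set()

    def visit_Call(self, node: ast.Call) -> ast.AST:
        if not (isinstance(node.func, ast.Name) and node.func.id == INPUT_ACCESSOR):
            raise ParseError(
                f"only the input accessor '{INPUT_ACCESSOR}(NAME)' may be called"
            )
        if len(node.args) != 1 or node.keywords or not isinstance(node.args[0], ast.Name):
            raise ParseError(
                f"input accessor must be '{INPUT_ACCESSOR}(NAME)' with a bare name"
            )
        name = node.args[0].id
        self.inputs_used.add(name)
        return ast.copy_location(ast.Name(id=name, ctx=ast.Load()), node)


def _validate_nodes(tree: ast.AST, source: str) -> None:
    for node in ast.walk(tree):
        if isinstance(node, (ast.Expression, ast.Name, ast.Load, ast.Call)):
            continue
        if isinstance(node, ast.Constant):
            if not isinstance(node.value, (int, float)):
                raise ParseError(f"non-numeric constant in {source!r}")
            continue
        if isinstance(node, ast.BinOp) and isinstance(node.op, _ALLOWED_BINOPS):
            continue
        if isinstance(node, ast.UnaryOp) and isinstance(node.op, _ALLOWED_UNARY):
            continue
        if isinstance(node, (ast.operator, ast.unaryop)):
            continue
        raise ParseError(
            f"unsupported syntax ({type(node).__name__}) in expression {source!r}"
        )


@dataclass(frozen=True)
class Expression:
    """A validated, compiled arithmetic expression."""

    source: str
    names: frozenset[str]          # all names read (inputs already rewritten)
    inputs_used: frozenset[str]    # names read through the input accessor
    code: object = field(compare=False, repr=False, default=None)
    py_source: str = field(compare=False, repr=False, default="")

    def __call__(self, env: dict) -> float:
        return evaluate_expression(self, env)


def parse_expression(source: str) -> Expression:
    """Parse and compile one right-hand side expression."""
    try:
        tree = ast.parse(source.strip(), mode="eval")
    except SyntaxError as exc:
        raise ParseError(f"cannot parse expression {source!r}: {exc.msg}") from None
    _validate_nodes(tree, source)
    rewriter = _InputRewriter()
    tree = ast.fix_missing_locations(rewriter.visit(tree))
    names = frozenset(
        n.id for n in ast.walk(tree) if isinstance(n, ast.Name)
    )
    code = compile(tree, "<model>", "eval")
    return Expression(source=source.strip(), names=names,
                      inputs_used=frozenset(rewriter.inputs_used), code=code,
                      py_source=ast.unparse(tree))


_EMPTY_GLOBALS = {"__builtins__": {}}


def evaluate_expression(expression: Expression | str, environment: dict):
    """Evaluate an expression in ``environment`` (name -> value).

    Values may be floats or numpy arrays (broadcasting applies).  Division by
    zero on scalar floats is flagged with a warning and yields NaN; unbound
    names raise :class:`ParseError` naming the symbol.
    """
    if isinstance(expression, str):
        expression = parse_expression(expression)
    missing = expression.names - environment.keys()
    if missing:
        raise ParseError(
            f"unbound symbol(s) {sorted(missing)} in expression {expression.source!r}"
        )
    try:
        with np.errstate(divide="ignore", invalid="ignore"):
            return eval(expression.code, _EMPTY_GLOBALS, environment)
    except ZeroDivisionError:
        warnings.warn(
            f"division by zero in {expression.source!r}; propagating NaN",
            RuntimeWarning, stacklevel=2,
        )
        return float("nan")


# --------------------------------------------------------------------------
# model definition
# --------------------------------------------------------------------------

ODE = "ode"
ALGEBRAIC = "algebraic"

_ODE_LHS = re.compile(r"^d\s*(\w+)\s*/\s*dt$")
_NAME = re.compile(r"^[A-Za-z_]\w*$")


@dataclass(frozen=True)
class EquationSpec:
    """One line of a model definition.

    ``ode`` targets are advanced by explicit Euler; ``algebraic`` targets are
    assigned the expression value each step.  Clamps are applied after the
    update.
    """

    target: str
    kind: str                      # ODE or ALGEBRAIC
    expression: Expression
    init: float = 0.0
    lower_bound: float | None = None
    upper_bound: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in (ODE, ALGEBRAIC):
            raise ValueError(f"unknown equation kind {self.kind!r}")


@dataclass
class ModelState:
    """Current values of all declared variables plus the model clock (ms)."""

    values: dict[str, float]
    time: float = 0.0

    def copy(self) -> "ModelState":
        return ModelState(dict(self.values), self.time)


@dataclass(frozen=True)
class ModelDefinition:
    """A hemodynamic model: parameters, ordered equations, inputs, output."""

    parameters: dict[str, float]
    equations: tuple[EquationSpec, ...]
    inputs: tuple[str, ...]
    output: str
    name: str = "model"

    @property
    def variables(self) -> list[str]:
        return [eq.target for eq in self.equations]

    def initial_state(self) -> ModelState:
        """Initial values: declared inits for ODE targets; algebraic targets
        are evaluated once (inputs at 0) so the state is self-consistent."""
        env: dict[str, float] = dict(self.parameters)
        for name in self.inputs:
            env[name] = 0.0
        for eq in self.equations:
            env[eq.target] = eq.init
        for eq in self.equations:
            if eq.kind == ALGEBRAIC:
                try:
                    val = evaluate_expression(eq.expression, env)
                except ZeroDivisionError:
                    val = eq.init
                if isinstance(val, float) and not math.isfinite(val):
                    val = eq.init
                env[eq.target] = float(val)
        return ModelState({eq.target: env[eq.target] for eq in self.equations}, 0.0)

    def with_parameters(self, **overrides: float) -> "ModelDefinition":
        """Copy of this definition with some parameter values replaced."""
        unknown = set(overrides) - set(self.parameters)
        if unknown:
            raise ModelError(f"unknown parameter(s) {sorted(unknown)}")
        params = dict(self.parameters)
        params.update({k: float(v) for k, v in overrides.items()})
        return replace(self, parameters=params)

    # -- serialization -----------------------------------------------------

    def parameters_text(self) -> str:
        return "\n".join(f"{k} = {v!r}" for k, v in self.parameters.items())

    def equations_text(self) -> str:
        lines = []
        for eq in self.equations:
            lhs = f"d{eq.target}/dt" if eq.kind == ODE else eq.target
            ann = []
            if eq.init != 0.0:
                ann.append(f"init={eq.init!r}")
            if eq.lower_bound is not None:
                ann.append(f"min={eq.lower_bound!r}")
            if eq.upper_bound is not None:
                ann.append(f"max={eq.upper_bound!r}")
            suffix = f" : {', '.join(ann)}" if ann else ""
            lines.append(f"{lhs} = {eq.expression.source}{suffix}")
        return "\n".join(lines)

    def to_text(self) -> str:
        return (
            f"# model: {self.name}\n"
            f"[parameters]\n{self.parameters_text()}\n"
            f"[equations]\n{self.equations_text()}\n"
            f"[inputs]\n" + "\n".join(self.inputs) + "\n"
            f"[output]\n{self.output}\n"
        )

    @classmethod
    def from_text(cls, text: str) -> "ModelDefinition":
        sections: dict[str, list[str]] = {}
        current: list[str] | None = None
        name = "model"
        for raw in text.splitlines():
            line = raw.strip()
            if line.startswith("# model:"):
                name = line.split(":", 1)[1].strip()
                continue
            if not line or line.startswith("#"):
                continue
            m = re.match(r"^\[(\w+)\]$", line)
            if m:
                current = sections.setdefault(m.group(1), [])
                continue
            if current is None:
                raise ParseError(f"content before any section header: {line!r}")
            current.append(line)
        for key in ("parameters", "equations", "output"):
            if key not in sections:
                raise ParseError(f"missing [{key}] section")
        outputs = sections["output"]
        if len(outputs) != 1:
            raise ParseError("[output] must contain exactly one name")
        return parse_model(
            "\n".join(sections["parameters"]),
            "\n".join(sections["equations"]),
            inputs=sections.get("inputs", []),
            output=outputs[0],
            name=name,
        )

    def to_json(self) -> str:
        return json.dumps({
            "name": self.name,
            "parameters": self.parameters,
            "equations": [
                {
                    "target": eq.target,
                    "kind": eq.kind,
                    "expression": eq.expression.source,
                    "init": eq.init,
                    "lower_bound": eq.lower_bound,
                    "upper_bound": eq.upper_bound,
                }
                for eq in self.equations
            ],
            "inputs": list(self.inputs),
            "output": self.output,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelDefinition":
        obj = json.loads(text)
        equations = tuple(
            EquationSpec(
                target=e["target"], kind=e["kind"],
                expression=parse_expression(e["expression"]),
                init=float(e.get("init", 0.0)),
                lower_bound=e.get("lower_bound"),
                upper_bound=e.get("upper_bound"),
            )
            for e in obj["equations"]
        )
        definition = cls(
            parameters={k: float(v) for k, v in obj["parameters"].items()},
            equations=equations,
            inputs=tuple(obj.get("inputs", [])),
            output=obj["output"],
            name=obj.get("name", "model"),
        )
        _validate_definition(definition)
        return definition


def _parse_annotations(text: str, lineno: int) -> dict[str, float]:
    out: dict[str, float] = {}
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        m = re.match(r"^(init|min|max)\s*=\s*([-+0-9.eE]+)$", part)
        if m is None:
            raise ParseError(
                f"line {lineno}: bad annotation {part!r} (expected init/min/max=value)"
            )
        out[m.group(1)] = float(m.group(2))
    return out


def parse_parameters(parameters_text: str) -> dict[str, float]:
    """Parse a key-value parameter block.

    Right-hand sides may be numeric literals or constant expressions over
    previously defined parameters (e.g. ``k_1 = 7 * E_0``).
    """
    params: dict[str, float] = {}
    for lineno, raw in enumerate(parameters_text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParseError(f"parameter line {lineno}: missing '=' in {line!r}")
        lhs, rhs = (s.strip() for s in line.split("=", 1))
        if not _NAME.match(lhs):
            raise ParseError(f"parameter line {lineno}: bad name {lhs!r}")
        if lhs in params:
            raise ParseError(f"parameter line {lineno}: duplicate parameter {lhs!r}")
        expr = parse_expression(rhs)
        if expr.inputs_used:
            raise ParseError(f"parameter line {lineno}: inputs not allowed here")
        missing = expr.names - params.keys()
        if missing:
            raise ParseError(
                f"parameter line {lineno}: undefined symbol(s) {sorted(missing)}"
            )
        params[lhs] = float(evaluate_expression(expr, params))
    return params


def parse_model(parameters_text: str, equations_text: str,
                inputs: list[str] | tuple[str, ...] | str = (),
                output: str = "BOLD", name: str = "model") -> ModelDefinition:
    """Parse parameter and equation text blocks into a validated definition.

    Parameters
    ----------
    parameters_text:
        One ``name = value`` assignment per line.
    equations_text:
        One equation per line; ODE lines have ``d<var>/dt`` on the left.
        Optional trailing ``: init=..., min=..., max=...`` annotations.
    inputs:
        Names of the input signals readable via ``sum(NAME)``.
    output:
        The variable recorded by default; must be defined by an equation.
    """
    if isinstance(inputs, str):
        inputs = (inputs,)
    inputs = tuple(inputs)
    if len(set(inputs)) != len(inputs):
        raise ParseError(f"duplicate input names in {list(inputs)}")

    params = parse_parameters(parameters_text)

    equations: list[EquationSpec] = []
    targets: set[str] = set()
    for lineno, raw in enumerate(equations_text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" in line:
            line, ann_text = line.split(":", 1)
            ann = _parse_annotations(ann_text, lineno)
        else:
            ann = {}
        if "=" not in line:
            raise ParseError(f"equation line {lineno}: missing '=' in {raw.strip()!r}")
        lhs, rhs = (s.strip() for s in line.split("=", 1))
        m = _ODE_LHS.match(lhs)
        if m:
            target, kind = m.group(1), ODE
        elif _NAME.match(lhs):
            target, kind = lhs, ALGEBRAIC
        else:
            raise ParseError(f"equation line {lineno}: bad left-hand side {lhs!r}")
        if target in targets:
            raise ParseError(f"equation line {lineno}: duplicate variable {target!r}")
        if target in params:
            raise ParseError(
                f"equation line {lineno}: {target!r} already defined as a parameter"
            )
        targets.add(target)
        expr = parse_expression(rhs)
        equations.append(EquationSpec(
            target=target, kind=kind, expression=expr,
            init=ann.get("init", 0.0),
            lower_bound=ann.get("min"), upper_bound=ann.get("max"),
        ))

    definition = ModelDefinition(
        parameters=params, equations=tuple(equations),
        inputs=inputs, output=output, name=name,
    )
    _validate_definition(definition, equations_text=equations_text)
    return definition


def _validate_definition(definition: ModelDefinition,
                         equations_text: str | None = None) -> None:
    params = definition.parameters
    targets = set(definition.variables)
    known = targets | params.keys() | set(definition.inputs)
    for i, eq in enumerate(definition.equations, start=1):
        bad_inputs = eq.expression.inputs_used - set(definition.inputs)
        if bad_inputs:
            raise ParseError(
                f"equation {i} ({eq.target}): accessor reads undeclared "
                f"input(s) {sorted(bad_inputs)}"
            )
        # inputs are only legal through the accessor
        plain = eq.expression.names - eq.expression.inputs_used
        undefined = plain - targets - params.keys()
        if undefined:
            raise ParseError(
                f"equation {i} ({eq.target}): undefined symbol(s) "
                f"{sorted(undefined)}"
            )
    if definition.output not in targets:
        raise ParseError(
            f"output {definition.output!r} is not a declared variable "
            f"(have {sorted(targets)})"
        )


# --------------------------------------------------------------------------
# integration
# --------------------------------------------------------------------------

class ModelRunner:
    """Stateful forward-Euler integrator for one model instance.

    Keeps the evaluation environment (parameters + variables + inputs) alive
    between steps so stepping is cheap inside a simulation loop.
    """

    def __init__(self, definition: ModelDefinition,
                 state: ModelState | None = None):
        self.definition = definition
        state = definition.initial_state() if state is None else state.copy()
        self.env: dict[str, float] = dict(definition.parameters)
        self.env.update(state.values)
        for name in definition.inputs:
            self.env.setdefault(name, 0.0)
        self.time = state.time
        self._eqs = [
            (eq, eq.expression.code, eq.kind == ODE) for eq in definition.equations
        ]
        self._fast_step = self._compile_fast()

    _RESERVED = frozenset({"env", "k", "_tot", "_math"})

    def _compile_fast(self):
        """Generate one specialized function for the whole Euler step.

        Loads the state into locals, evaluates every equation in declaration
        order, applies clamps, verifies finiteness and writes back — one
        function call per step instead of one ``eval`` per equation.  Falls
        back to ``None`` (per-equation path) if any symbol collides with the
        generated scaffolding.
        """
        d = self.definition
        names = set(d.variables) | set(d.parameters) | set(d.inputs)
        if names & self._RESERVED:
            return None
        lines = ["def _model_step(env, k):"]
        for p, v in d.parameters.items():
            lines.append(f"    {p} = {v!r}")
        for name in d.inputs:
            lines.append(f"    {name} = env[{name!r}]")
        for var in d.variables:
            lines.append(f"    {var} = env[{var!r}]")
        for eq in d.equations:
            rhs = eq.expression.py_source
            if eq.kind == ODE:
                lines.append(f"    {eq.target} = {eq.target} + k * ({rhs})")
            else:
                lines.append(f"    {eq.target} = {rhs}")
            if eq.lower_bound is not None:
                lines.append(f"    if {eq.target} < {eq.lower_bound!r}: "
                             f"{eq.target} = {eq.lower_bound!r}")
            if eq.upper_bound is not None:
                lines.append(f"    if {eq.target} > {eq.upper_bound!r}: "
                             f"{eq.target} = {eq.upper_bound!r}")
        total = " + ".join(d.variables)
        lines.append(f"    if not _math.isfinite({total}):")
        lines.append("        raise FloatingPointError")
        for var in d.variables:
            lines.append(f"    env[{var!r}] = {var}")
        namespace = {"_math": math}
        exec("\n".join(lines), namespace)
        return namespace["_model_step"]

    @property
    def state(self) -> ModelState:
        return ModelState(
            {eq.target: self.env[eq.target] for eq in self.definition.equations},
            self.time,
        )

    def set_inputs(self, input_values: dict[str, float]) -> None:
        missing = set(self.definition.inputs) - input_values.keys()
        if missing:
            raise ModelError(f"missing input value(s) {sorted(missing)}")
        self.env.update(input_values)

    def step(self, dt: float) -> None:
        """Advance all equations by one Euler step of dt ms."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        if self._fast_step is not None:
            try:
                self._fast_step(self.env, dt / 1000.0)
                self.time += dt
                return
            except (FloatingPointError, ZeroDivisionError, OverflowError,
                    TypeError, ValueError):
                pass  # re-run the diagnostic path; env not yet written back
        self._step_slow(dt)

    def _step_slow(self, dt: float) -> None:
        env = self.env
        k = dt / 1000.0  # rate constants are per second
        for eq, code, is_ode in self._eqs:
            try:
                val = eval(code, _EMPTY_GLOBALS, env)
            except (ZeroDivisionError, OverflowError):
                val = float("nan")
            if isinstance(val, complex):   # negative base, fractional power
                val = float("nan")
            if is_ode:
                val = env[eq.target] + k * val
            if eq.lower_bound is not None and val < eq.lower_bound:
                val = eq.lower_bound
            if eq.upper_bound is not None and val > eq.upper_bound:
                val = eq.upper_bound
            if not math.isfinite(val):
                raise IntegrationError(
                    f"variable {eq.target!r} became non-finite at "
                    f"t={self.time + dt:.3f} ms"
                )
            env[eq.target] = val
        self.time += dt

    def ode_rates(self) -> dict[str, float]:
        """Current right-hand-side values of all ODE targets (per second)."""
        rates = {}
        for eq, code, is_ode in self._eqs:
            if is_ode:
                try:
                    rates[eq.target] = eval(code, _EMPTY_GLOBALS, self.env)
                except ZeroDivisionError:
                    rates[eq.target] = float("nan")
        return rates


def step(definition: ModelDefinition, state: ModelState,
         input_values: dict[str, float], dt: float) -> ModelState:
    """Advance ``state`` by one Euler step of ``dt`` ms and return the result.

    Equations are evaluated in declaration order against the environment as
    updated so far; ODE targets use ``x <- x + (dt/1000) * rhs``.
    """
    runner = ModelRunner(definition, state)
    runner.set_inputs(input_values)
    runner.step(dt)
    return runner.state


def integrate(definition: ModelDefinition,
              inputs: dict[str, "float | np.ndarray | TimeSeries"] | None = None,
              dt: float = 1.0, duration: float = 1000.0,
              record: list[str] | None = None,
              t0: float = 0.0) -> TimeSeries:
    """Integrate a model over ``duration`` ms with given input series.

    ``inputs`` maps each declared input name to a constant, an array with one
    value per step, or a :class:`TimeSeries` on the same grid.  Recording
    defaults to every declared variable plus the inputs; an explicit
    ``record`` list is augmented with the output variable.
    """
    inputs = dict(inputs or {})
    n_steps = int(round(duration / dt))
    missing = set(definition.inputs) - inputs.keys()
    if missing:
        raise ModelError(f"missing input series for {sorted(missing)}")

    input_arrays: dict[str, np.ndarray] = {}
    for name in definition.inputs:
        val = inputs[name]
        if isinstance(val, TimeSeries):
            if abs(val.dt - dt) > 1e-9:
                raise ModelError(
                    f"input {name!r}: grid mismatch (series dt={val.dt}, need {dt})"
                )
            if val.n_steps < n_steps:
                raise ModelError(
                    f"input {name!r}: series too short ({val.n_steps} < {n_steps})"
                )
            arr = val[name] if name in val.names else val.data[:, 0]
            input_arrays[name] = np.asarray(arr, float)[:n_steps]
        else:
            arr = np.asarray(val, float)
            if arr.ndim == 0:
                arr = np.full(n_steps, float(arr))
            elif arr.shape[0] < n_steps:
                raise ModelError(
                    f"input {name!r}: series too short ({arr.shape[0]} < {n_steps})"
                )
            input_arrays[name] = arr[:n_steps]

    if record is None:
        names = list(definition.inputs) + definition.variables
    else:
        unknown = set(record) - set(definition.variables) - set(definition.inputs)
        if unknown:
            raise ModelError(f"cannot record unknown variable(s) {sorted(unknown)}")
        names = list(record)
        if definition.output not in names:
            names.append(definition.output)

    runner = ModelRunner(definition)
    runner.time = t0
    out = np.empty((n_steps, len(names)))
    env = runner.env
    for i in range(n_steps):
        for name, arr in input_arrays.items():
            env[name] = arr[i]
        runner.step(dt)
        for j, name in enumerate(names):
            out[i, j] = env[name]
    return TimeSeries(dt=dt, t0=t0 + dt, names=names, data=out)
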