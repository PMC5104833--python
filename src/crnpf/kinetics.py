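"""Intensity (propensity) functions and the phi-factorization.

Three kinetics modes are supported:

* ``mass_action`` -- the stochastic falling-factorial rates;
* ``theta_product`` -- rates of the form
  ``kappa_k * prod_i prod_{j<nu_ki} theta_i(x_i - j)``;
* ``alpha_theta_product`` -- the generalized form where species i is
  consumed only in multiples of ``alpha_i`` and theta_i is evaluated on an
  alpha_i-spaced lattice:
  ``kappa_k * prod_i prod_{j<nu_ki/alpha_i} theta_i(x_i - j*alpha_i)``.

The phi-recursion factorizes a window-``alpha`` theta into univariate
factors, ``theta(z) = phi(z) * phi(z-1) * ... * phi(z-alpha+1)``, which is
the device that reduces the generalized product-form measure to the
classical one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .network import AlphaPartition, ReactionNetwork

__all__ = [
    "ThetaFunction",
    "PhiFunction",
    "KineticsSpec",
    "ThetaDomainError",
    "KineticsError",
    "mass_action_intensity",
    "theta_intensity",
    "propensities",
    "validate_assumption1",
    "phi_from_theta",
    "factorization_check",
    "compile_theta_expression",
]

REL_TOL = 1e-9
ABS_TOL = 1e-12


class KineticsError(ValueError):
    """Structural problem with a kinetics specification."""


class ThetaDomainError(KeyError):
    """A tabulated theta was evaluated beyond its last entry."""


def compile_theta_expression(expr: str) -> Callable[[np.ndarray], np.ndarray]:
    """Compile an arithmetic expression in ``x`` to a vectorized callable.

    Supported names: ``ind(cond)`` (0/1 indicator), ``sin``, ``cos``,
    ``sqrt``, ``exp``, ``log``, ``floor``, ``abs``, ``pi``.  Comparison
    operators inside ``ind`` work elementwise.
    """
    code = compile(expr, "<theta>", "eval")
    namespace = {
        "ind": lambda cond: np.asarray(cond, dtype=float),
        "sin": np.sin,
        "cos": np.cos,
        "sqrt": np.sqrt,
        "exp": np.exp,
        "log": np.log,
        "floor": np.floor,
        "abs": np.abs,
        "pi": np.pi,
        "__builtins__": {},
    }
    for name in code.co_names:
        if name not in namespace and name != "x":
            raise KineticsError(f"unknown name {name!r} in theta expression {expr!r}")

    def fn(x: np.ndarray) -> np.ndarray:
        out = eval(code, dict(namespace), {"x": np.asarray(x, dtype=float)})
        return np.broadcast_to(np.asarray(out, dtype=float), np.shape(x)).copy()

    return fn


@dataclass
class ThetaFunction:
    """Per-species rate factor theta_i.

    The rule is either a closed-form expression / callable or a finite
    lookup table.  Tables raise :class:`ThetaDomainError` when evaluated
    past their last entry rather than extrapolating.  Arguments below zero
    evaluate to zero.
    """

    alpha: int = 1
    table: np.ndarray | None = None
    func: Callable[[np.ndarray], np.ndarray] | None = None
    expr: str | None = None
    species: str | None = None

    def __post_init__(self):
        if self.alpha < 1:
            raise KineticsError("alpha must be a positive integer")
        if self.table is None and self.func is None and self.expr is None:
            raise KineticsError("theta needs a table, callable or expression")
        if self.expr is not None and self.func is None:
            self.func = compile_theta_expression(self.expr)
        if self.table is not None:
            self.table = np.asarray(self.table, dtype=float)

    @classmethod
    def from_expression(cls, expr: str, alpha: int = 1, species: str | None = None):
        return cls(alpha=alpha, expr=expr, species=species)

    @classmethod
    def from_table(cls, values: Sequence[float], alpha: int = 1, species: str | None = None):
        return cls(alpha=alpha, table=np.asarray(values, dtype=float), species=species)

    @classmethod
    def from_callable(cls, fn: Callable, alpha: int = 1, species: str | None = None):
        return cls(alpha=alpha, func=fn, species=species)

    def __call__(self, z):
        scalar = np.isscalar(z)
        z = np.atleast_1d(np.asarray(z))
        out = np.zeros(z.shape, dtype=float)
        nonneg = z >= 0
        if self.table is not None:
            if np.any(z[nonneg] >= len(self.table)):
                raise ThetaDomainError(
                    f"theta table of length {len(self.table)} evaluated at "
                    f"z={int(z[nonneg].max())}; extend the table"
                )
            out[nonneg] = self.table[z[nonneg].astype(np.intp)]
        else:
            out[nonneg] = self.func(z[nonneg])
        return float(out[0]) if scalar else out

    def tabulate(self, zmax: int) -> np.ndarray:
        """Values on 0..zmax inclusive."""
        return np.asarray(self(np.arange(zmax + 1)), dtype=float)


@dataclass
class PhiFunction:
    """Univariate factor obtained from the window-product recursion.

    ``values[z]`` holds phi(z) for 0 <= z <= zmax, with phi(0) = 0,
    phi(1) = C, phi(z) = 1 for 2 <= z <= alpha-1 and, for z >= alpha,
    phi(z) = theta(z) / (phi(z-1) ... phi(z-alpha+1)).
    """

    values: np.ndarray
    alpha: int
    C: float = 1.0

    def __call__(self, z):
        scalar = np.isscalar(z)
        z = np.atleast_1d(np.asarray(z))
        out = np.zeros(z.shape, dtype=float)
        ok = (z >= 0) & (z < len(self.values))
        if np.any(z >= len(self.values)):
            raise ThetaDomainError("phi evaluated beyond its tabulated range")
        out[ok] = self.values[z[ok].astype(np.intp)]
        return float(out[0]) if scalar else out

    def to_theta(self, species: str | None = None) -> ThetaFunction:
        """Reinterpret phi as a window-1 theta (phi(z) > 0 for z >= 1)."""
        return ThetaFunction.from_table(self.values, alpha=1, species=species)


@dataclass
class KineticsSpec:
    """Kinetics mode plus per-species theta functions.

    ``thetas`` maps species name to :class:`ThetaFunction`; it is unused
    (and may be empty) for mass action.
    """

    mode: str = "mass_action"
    thetas: Mapping[str, ThetaFunction] = field(default_factory=dict)

    MODES = ("mass_action", "theta_product", "alpha_theta_product")

    def __post_init__(self):
        if self.mode not in self.MODES:
            raise KineticsError(f"unknown kinetics mode {self.mode!r}")

    def theta_for(self, net: ReactionNetwork, i: int) -> ThetaFunction:
        name = net.species[i]
        if name not in self.thetas:
            raise KineticsError(f"no theta function given for species {name!r}")
        return self.thetas[name]

    def effective_alpha(self, net: ReactionNetwork, ap: AlphaPartition | None) -> tuple[int, ...]:
        if self.mode == "alpha_theta_product":
            if ap is None:
                raise KineticsError("alpha_theta_product mode requires an AlphaPartition")
            return ap.alpha
        return (1,) * net.d


def mass_action_intensity(net: ReactionNetwork, k: int, x) -> float:
    """kappa_k * prod_i x_i! / (x_i - nu_ki)!; zero when any x_i < nu_ki."""
    x = np.asarray(x)
    r = net.reactions[k]
    val = r.rate_constant
    for i, nu in enumerate(r.source):
        for j in range(nu):
            val *= x[i] - j
    return float(max(val, 0.0))


def theta_intensity(
    spec: KineticsSpec,
    net: ReactionNetwork,
    ap: AlphaPartition | None,
    k: int,
    x,
) -> float:
    """Generalized product-form intensity of reaction k at state x.

    ``lambda_k(x) = kappa_k prod_i prod_{j=0}^{nu_ki/alpha_i - 1}
    theta_i(x_i - j*alpha_i)``; empty products are one.  Raises
    :class:`KineticsError` when some ``nu_ki`` is not divisible by
    ``alpha_i``.
    """
    if spec.mode == "mass_action":
        return mass_action_intensity(net, k, x)
    x = np.asarray(x)
    alpha = spec.effective_alpha(net, ap)
    r = net.reactions[k]
    val = r.rate_constant
    for i, nu in enumerate(r.source):
        if nu == 0:
            continue
        a = alpha[i]
        if nu % a:
            raise KineticsError(
                f"reaction {k}: source count {nu} for species {net.species[i]!r} "
                f"is not divisible by alpha={a}"
            )
        theta = spec.theta_for(net, i)
        for j in range(nu // a):
            val *= theta(int(x[i]) - j * a)
            if val == 0.0:
                return 0.0
    return float(val)


def propensities(
    net: ReactionNetwork,
    spec: KineticsSpec,
    X: np.ndarray,
    ap: AlphaPartition | None = None,
) -> np.ndarray:
    """Vectorized intensities: (n_states, d) int array -> (n_states, K)."""
    X = np.atleast_2d(np.asarray(X, dtype=np.int64))
    n = X.shape[0]
    out = np.empty((n, net.K), dtype=float)
    if spec.mode == "mass_action":
        for k, r in enumerate(net.reactions):
            lam = np.full(n, r.rate_constant)
            for i, nu in enumerate(r.source):
                col = X[:, i].astype(float)
                for j in range(nu):
                    lam *= col - j
            out[:, k] = np.maximum(lam, 0.0)
        return out
    alpha = spec.effective_alpha(net, ap)
    for k, r in enumerate(net.reactions):
        lam = np.full(n, r.rate_constant)
        for i, nu in enumerate(r.source):
            if nu == 0:
                continue
            a = alpha[i]
            if nu % a:
                raise KineticsError(
                    f"reaction {k}: source count {nu} not divisible by alpha={a}"
                )
            theta = spec.theta_for(net, i)
            for j in range(nu // a):
                lam *= theta(X[:, i] - j * a)
        out[:, k] = lam
    return out


@dataclass
class Assumption1Report:
    """Outcome of checking the zero-pattern and divisibility conditions."""

    ok: bool
    violations: tuple[str, ...]


def validate_assumption1(
    spec: KineticsSpec,
    net: ReactionNetwork,
    ap: AlphaPartition,
    zmax: int,
) -> Assumption1Report:
    """Check theta_i(z) = 0 iff z <= alpha_i - 1 on [0, zmax], and that
    alpha_i divides every source count.  Violations are reported, not
    raised.
    """
    if zmax < max(ap.alpha):
        raise KineticsError("zmax must be at least max(alpha)")
    violations: list[str] = []
    src = net.source_matrix
    for i, name in enumerate(net.species):
        a = ap.alpha[i]
        for k in range(net.K):
            if src[k, i] % a:
                violations.append(
                    f"reaction {k}: source count {int(src[k, i])} for species "
                    f"{name!r} not divisible by alpha={a}"
                )
        if spec.mode == "mass_action":
            continue
        if name not in spec.thetas:
            violations.append(f"species {name!r}: no theta function provided")
            continue
        theta = spec.thetas[name]
        vals = theta.tabulate(zmax)
        for z in range(a):
            if vals[z] != 0.0:
                violations.append(
                    f"species {name!r}: theta({z}) = {vals[z]} but must vanish "
                    f"for z <= alpha-1 = {a - 1}"
                )
        for z in range(a, zmax + 1):
            if not vals[z] > 0.0:
                violations.append(
                    f"species {name!r}: theta({z}) = {vals[z]} but must be "
                    f"positive for z >= alpha = {a}"
                )
    return Assumption1Report(ok=not violations, violations=tuple(violations))


def phi_from_theta(theta: ThetaFunction, zmax: int, C: float = 1.0) -> PhiFunction:
    """Tabulate the recursive factor phi on 0..zmax.

    Initialization: phi(0)=0; phi(1)=C (the proof's choice is C=1); phi=1
    on 2..alpha-1.  For z >= alpha,
    ``phi(z) = theta(z) / (phi(z-1) ... phi(z-alpha+1))``.
    """
    a = theta.alpha
    if zmax < a:
        raise KineticsError("zmax must be at least alpha")
    if not C > 0:
        raise KineticsError("C must be positive")
    tvals = theta.tabulate(zmax)
    phi = np.zeros(zmax + 1)
    if a == 1:
        phi[1:] = tvals[1:]
        return PhiFunction(phi, alpha=1, C=C)
    phi[1] = C
    phi[2:a] = 1.0
    for z in range(a, zmax + 1):
        denom = np.prod(phi[z - a + 1 : z])
        assert denom != 0.0, "zero phi in denominator; theta violates the zero pattern"
        phi[z] = tvals[z] / denom
    return PhiFunction(phi, alpha=a, C=C)


def factorization_check(theta: ThetaFunction, phi: PhiFunction, zmax: int) -> float:
    """Worst relative discrepancy of the telescoped factorization identity.

    Verifies ``prod_{j=0}^{z-1} phi(z-j) = prod_{j=0}^{floor(z/a)-1}
    theta(z - j*a)`` for 0 <= z <= zmax, in log space, and returns the
    maximum absolute relative error.
    """
    a = theta.alpha
    worst = 0.0
    log_phi_cum = 0.0  # sum of log phi(1..z)
    tvals = theta.tabulate(zmax)
    log_theta_cum = np.zeros(zmax + 1)  # log prod_{j} theta(z - j*a)
    for z in range(1, zmax + 1):
        log_theta_cum[z] = log_theta_cum[z - a] + math.log(tvals[z]) if z >= a else 0.0
    for z in range(1, zmax + 1):
        log_phi_cum += math.log(phi.values[z]) if z >= 1 else 0.0
        lhs, rhs = log_phi_cum, log_theta_cum[z]
        worst = max(worst, abs(lhs - rhs) / max(abs(rhs), 1.0))
    return worst


def kinetics_from_dict(
    block: Mapping, net: ReactionNetwork, ap: AlphaPartition | None = None
) -> KineticsSpec:
    """Parse the ``kinetics`` section of a network file."""
    known = {"mode", "thetas"}
    unknown = set(block) - known
    if unknown:
        raise KineticsError(f"unknown kinetics keys: {sorted(unknown)}")
    mode = block.get("mode", "mass_action")
    thetas: dict[str, ThetaFunction] = {}
    alpha_map = {}
    if ap is not None:
        alpha_map = {s: a for s, a in zip(net.species, ap.alpha)}
    for name, rule in block.get("thetas", {}).items():
        if name not in net.species:
            raise KineticsError(f"theta given for unknown species {name!r}")
        a = alpha_map.get(name, 1) if mode == "alpha_theta_product" else 1
        if "expr" in rule:
            theta = ThetaFunction.from_expression(rule["expr"], alpha=a, species=name)
        elif "table" in rule:
            theta = ThetaFunction.from_table(rule["table"], alpha=a, species=name)
        elif "phi_from" in rule:
            sub = rule["phi_from"]
            base = ThetaFunction.from_expression(sub["expr"], alpha=int(sub["window"]))
            phi = phi_from_theta(base, int(sub.get("zmax", 2000)), float(sub.get("C", 1.0)))
            theta = phi.to_theta(species=name)
        else:
            raise KineticsError(f"theta for {name!r} needs 'expr', 'table' or 'phi_from'")
        thetas[name] = theta
    return KineticsSpec(mode=mode, thetas=thetas)
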