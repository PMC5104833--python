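"""Product-form invariant measures on enumerated state classes.

The unnormalized measure assigns state ``x`` the log-weight

    sum_i [ x_i log c_i - sum_{j=0}^{floor(x_i/alpha_i)-1}
            log theta_i(x_i - j alpha_i) ],

which for ``alpha_i = 1`` is the classical form and for ``theta_i(z) = z``
is a product of Poisson weights.  All arithmetic is in log space;
normalization uses log-sum-exp, since the raw weights overflow around
x ~ 1e3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .kinetics import KineticsSpec, ThetaFunction
from .network import AlphaPartition, ReactionNetwork

__all__ = [
    "StateClass",
    "ProductFormMeasure",
    "DiscreteDistribution",
    "enumerate_class",
    "log_measure_thm1",
    "log_measure_thm2",
    "normalize",
    "marginal",
    "expectation",
]

MAX_BOX_STATES = 50_000_000


@dataclass(frozen=True)
class StateClass:
    """A finite lattice class: box plus linear and residue constraints.

    ``linear_invariants`` is a list of ``(w, v)`` pairs enforcing
    ``w . x == v``; ``residue_constraints`` a list of ``(u, m, a)``
    enforcing ``u . x == a (mod m)``.  ``box`` gives inclusive upper
    bounds per coordinate (lower bounds are zero).
    """

    box: tuple[int, ...]
    linear_invariants: tuple[tuple[tuple[int, ...], int], ...] = ()
    residue_constraints: tuple[tuple[tuple[int, ...], int, int], ...] = ()

    @property
    def dimension(self) -> int:
        return len(self.box)


@dataclass
class DiscreteDistribution:
    """A probability distribution on an explicit list of lattice states."""

    states: np.ndarray  # (n, d) int64, lexicographic order
    probs: np.ndarray  # (n,)
    log_norm: float = math.nan  # log of the normalization constant Gamma
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.probs)

    def expectation(self, f) -> float:
        """E[f(X)] for a vectorized f, or E[w.X] for a coefficient vector."""
        return expectation(self, f)


def enumerate_class(cls: StateClass) -> np.ndarray:
    """All states in the box satisfying every constraint, lex order."""
    sizes = [n + 1 for n in cls.box]
    total = math.prod(sizes)
    if total > MAX_BOX_STATES:
        raise ValueError(f"box contains {total} lattice points; refusing to enumerate")
    grids = np.indices(sizes).reshape(len(sizes), -1).T.astype(np.int64)
    mask = np.ones(len(grids), dtype=bool)
    for w, v in cls.linear_invariants:
        mask &= grids @ np.asarray(w, dtype=np.int64) == v
    for u, m, a in cls.residue_constraints:
        mask &= (grids @ np.asarray(u, dtype=np.int64)) % m == a % m
    return grids[mask]


def _cumulative_log_theta(theta: ThetaFunction, alpha: int, zmax: int) -> np.ndarray:
    """L[v] = sum_{j=0}^{floor(v/alpha)-1} log theta(v - j*alpha).

    L[v] = -inf marks states outside the support (a zero denominator
    factor).  L[v] = 0 for v < alpha.
    """
    tvals = theta.tabulate(zmax)
    # extended precision: these sums reach O(1e3) and their rounding is the
    # dominant error in the balance residuals of the normalized measure
    L = np.zeros(zmax + 1, dtype=np.longdouble)
    with np.errstate(divide="ignore"):
        logt = np.log(tvals.astype(np.longdouble))
    for v in range(alpha, zmax + 1):
        L[v] = L[v - alpha] + logt[v]
    return L


@dataclass
class ProductFormMeasure:
    """Evaluable log-measure with per-species cumulative denominators."""

    c: np.ndarray
    thetas: tuple[ThetaFunction, ...]
    alpha: tuple[int, ...]
    _cum: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    @classmethod
    def from_kinetics(
        cls,
        c: Sequence[float],
        spec: KineticsSpec,
        net: ReactionNetwork,
        ap: AlphaPartition | None = None,
    ) -> "ProductFormMeasure":
        alpha = spec.effective_alpha(net, ap)
        thetas = tuple(spec.theta_for(net, i) for i in range(net.d))
        return cls(np.asarray(c, dtype=float), thetas, alpha)

    def _cum_for(self, i: int, zmax: int) -> np.ndarray:
        cached = self._cum.get(i)
        if cached is None or len(cached) <= zmax:
            self._cum[i] = _cumulative_log_theta(self.thetas[i], self.alpha[i], zmax)
        return self._cum[i]

    def log_weights(self, X: np.ndarray) -> np.ndarray:
        """Vectorized log-measure in extended precision; -inf outside support."""
        X = np.atleast_2d(np.asarray(X, dtype=np.int64))
        out = np.zeros(len(X), dtype=np.longdouble)
        logc = np.log(self.c.astype(np.longdouble))
        for i in range(len(self.c)):
            zmax = int(X[:, i].max(initial=0))
            cum = self._cum_for(i, zmax)
            out += X[:, i] * logc[i] - cum[X[:, i]]
        return out

    def log_weight(self, x) -> float:
        return float(self.log_weights(np.asarray(x)[None, :])[0])


def log_measure_thm1(
    c: Sequence[float], thetas: Sequence[ThetaFunction], x: Sequence[int]
) -> float:
    """Classical product-form log-weight (all window lengths equal one)."""
    measure = ProductFormMeasure(np.asarray(c, dtype=float), tuple(thetas),
                                 (1,) * len(tuple(thetas)))
    return measure.log_weight(x)


def log_measure_thm2(
    c: Sequence[float],
    spec: KineticsSpec,
    net: ReactionNetwork,
    ap: AlphaPartition | None,
    x: Sequence[int],
) -> float:
    """Generalized product-form log-weight with alpha-spaced denominators."""
    return ProductFormMeasure.from_kinetics(c, spec, net, ap).log_weight(x)


def normalize(
    measure: ProductFormMeasure,
    cls: StateClass,
    boundary_tol: float = 1e-12,
) -> DiscreteDistribution:
    """Normalize the measure on the enumerated class via log-sum-exp.

    The returned distribution's ``meta`` records the boundary-shell mass
    and a ``truncation_limited`` flag when that mass exceeds
    ``boundary_tol`` (the summability certificate is then unreliable).
    """
    states = enumerate_class(cls)
    if len(states) == 0:
        raise ValueError("state class is empty")
    lw = measure.log_weights(states)
    finite = np.isfinite(lw)
    if not finite.any():
        raise ValueError("every state in the class lies outside the support")
    m = lw[finite].max()
    weights = np.zeros(len(states), dtype=np.longdouble)
    weights[finite] = np.exp(lw[finite] - m)
    total = weights.sum()
    probs = (weights / total).astype(np.float64)
    log_norm = float(m + np.log(total))
    shell = np.zeros(len(states), dtype=bool)
    for i, n in enumerate(cls.box):
        shell |= states[:, i] == n
    boundary_mass = float(probs[shell].sum())
    return DiscreteDistribution(
        states=states,
        probs=probs,
        log_norm=log_norm,
        meta={
            "boundary_mass": boundary_mass,
            "truncation_limited": boundary_mass > boundary_tol,
            "n_outside_support": int((~finite).sum()),
        },
    )


def marginal(dist: DiscreteDistribution, functional) -> DiscreteDistribution:
    """Distribution of ``w . X`` (coefficient vector) or of coordinate i (int)."""
    if np.isscalar(functional):
        vals = dist.states[:, int(functional)]
    else:
        vals = dist.states @ np.asarray(functional, dtype=np.int64)
    support = np.unique(vals)
    probs = np.array([dist.probs[vals == v].sum() for v in support])
    return DiscreteDistribution(states=support[:, None], probs=probs,
                                meta={"marginal_of": functional})


def expectation(dist: DiscreteDistribution, f) -> float:
    """E[f(X)] (vectorized callable on the (n, d) state array) or E[w.X]."""
    if callable(f):
        vals = np.asarray(f(dist.states), dtype=float)
    else:
        vals = dist.states @ np.asarray(f, dtype=float)
    return float(np.dot(dist.probs, vals))
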