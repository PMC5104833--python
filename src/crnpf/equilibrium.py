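"""Complex-balanced equilibria of the associated deterministic system.

The product-form stationary measures are parameterized by a positive
concentration vector ``c`` at which, for every complex, the total
mass-action inflow equals the total outflow.  For weakly reversible
deficiency-zero networks such a ``c`` exists for every choice of rate
constants; the solver here finds one numerically, optionally on an affine
slice ``w . c = b``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .network import ReactionNetwork, structural_report

__all__ = [
    "EquilibriumResult",
    "EquilibriumError",
    "deterministic_rhs",
    "complex_balance_residual",
    "solve_complex_balanced",
]


class EquilibriumError(RuntimeError):
    """Solver failed to converge; carries the best iterate found."""

    def __init__(self, message, best_c=None, residual=None):
        super().__init__(message)
        self.best_c = best_c
        self.residual = residual


@dataclass(frozen=True)
class EquilibriumResult:
    """Positive equilibrium with its complex-balance diagnostics."""

    c: np.ndarray
    complexes: tuple[tuple[int, ...], ...]
    residuals: np.ndarray
    tolerance: float
    constraint: tuple[np.ndarray, float] | None = None
    warnings: tuple[str, ...] = ()
    n_iter: int = 0

    @property
    def max_residual(self) -> float:
        return float(np.max(np.abs(self.residuals)))


def deterministic_rhs(net: ReactionNetwork, x: Sequence[float]) -> np.ndarray:
    """Mass-action ODE right-hand side: sum_k r_k(x) (nu_k' - nu_k)."""
    x = np.asarray(x, dtype=float)
    out = np.zeros(net.d)
    for r in net.reactions:
        rate = r.rate_constant * np.prod(x ** np.asarray(r.source, dtype=float))
        out += rate * np.asarray(r.net_change, dtype=float)
    return out


def _complexes_of(net: ReactionNetwork) -> list[tuple[int, ...]]:
    seen: dict[tuple[int, ...], None] = {}
    for r in net.reactions:
        seen.setdefault(r.source)
        seen.setdefault(r.product)
    return list(seen)


def complex_balance_residual(net: ReactionNetwork, c: Sequence[float]) -> tuple[
    tuple[tuple[int, ...], ...], np.ndarray
]:
    """Per-complex inflow-minus-outflow under mass action at concentrations c.

    Returns the deduplicated complex list (in first-appearance order) and
    the aligned residual vector ``sum_{k: source=eta} r_k(c) -
    sum_{k: product=eta} r_k(c)``.
    """
    c = np.asarray(c, dtype=float)
    complexes = _complexes_of(net)
    index = {cx: i for i, cx in enumerate(complexes)}
    res = np.zeros(len(complexes))
    for r in net.reactions:
        rate = r.rate_constant * np.prod(c ** np.asarray(r.source, dtype=float))
        res[index[r.source]] += rate
        res[index[r.product]] -= rate
    return tuple(complexes), res


def solve_complex_balanced(
    net: ReactionNetwork,
    constraint: tuple[Sequence[float], float] | None = None,
    tol_scale: float = 1e-10,
    max_iter: int = 200,
    polish: int = 3,
) -> EquilibriumResult:
    """Find a positive complex-balanced equilibrium, optionally constrained.

    A damped Newton iteration in log-concentrations ``c = exp(u)`` is run
    on the stacked scale-free residual (per-complex ``log inflow - log
    outflow`` plus the normalized affine constraint), starting from
    ``c = 1``.  The log form has no spurious zero at ``c -> 0`` (where all
    raw rates vanish) and its convergence threshold ``tol_scale`` is a
    relative balance error.  The reported per-complex residuals and the
    ``tolerance`` field (``tol_scale *`` max complex throughput) are on the
    raw inflow-minus-outflow scale.

    Raises :class:`EquilibriumError` on non-convergence.  A warning string
    is attached when the network is not weakly reversible or has positive
    deficiency (existence is then not guaranteed).
    """
    report = structural_report(net)
    warnings: list[str] = []
    if not report.weakly_reversible:
        warnings.append("network is not weakly reversible; a complex-balanced "
                        "equilibrium may not exist")
    elif report.deficiency != 0:
        warnings.append(f"network has deficiency {report.deficiency}; "
                        "complex balance is not guaranteed for all rate constants")

    complexes = _complexes_of(net)
    cx_index = {cx: i for i, cx in enumerate(complexes)}
    ncx = len(complexes)
    d = net.d
    kappa = np.array([r.rate_constant for r in net.reactions])
    src = net.source_matrix.astype(float)  # (K, d)
    sign = np.zeros((ncx, net.K))
    for k, r in enumerate(net.reactions):
        sign[cx_index[r.source], k] += 1.0
        sign[cx_index[r.product], k] -= 1.0

    if constraint is not None:
        w = np.asarray(constraint[0], dtype=float)
        b = float(constraint[1])
    else:
        w, b = None, None

    source_of = np.maximum(sign, 0.0)  # (ncx, K) complex-is-source indicator
    product_of = np.maximum(-sign, 0.0)
    if np.any(source_of.sum(axis=1) == 0) or np.any(product_of.sum(axis=1) == 0):
        missing = [
            complexes[i]
            for i in range(ncx)
            if source_of[i].sum() == 0 or product_of[i].sum() == 0
        ]
        raise EquilibriumError(
            "no positive complex-balanced equilibrium can exist: complexes "
            f"{missing} lack an incoming or outgoing reaction"
        )

    def residual_and_jac(u: np.ndarray):
        """Log-balance residual per complex (scale-free): the difference
        log(inflow) - log(outflow) has no spurious zero at c -> 0."""
        rates = kappa * np.exp(src @ u)  # (K,)
        inflow = product_of @ rates
        outflow = source_of @ rates
        g = np.log(inflow) - np.log(outflow)
        win = (product_of * rates) / inflow[:, None]  # softmax weights
        wout = (source_of * rates) / outflow[:, None]
        jac_g = (win - wout) @ src  # (ncx, d)
        if w is None:
            return g, jac_g
        c = np.exp(u)
        f = np.concatenate([g, [(w @ c - b) / (1.0 + abs(b))]])
        jac = np.vstack([jac_g, (w * c / (1.0 + abs(b)))[None, :]])
        return f, jac

    def raw_residuals(u: np.ndarray):
        rates = kappa * np.exp(src @ u)
        res = sign @ rates
        thr = float((np.abs(sign) @ rates).max(initial=0.0))
        return res, thr

    u = np.zeros(d)
    f, jac = residual_and_jac(u)
    best = (np.linalg.norm(f), u.copy())
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if np.max(np.abs(f)) <= tol_scale:
            break
        step, *_ = np.linalg.lstsq(jac, -f, rcond=None)
        # damped line search; cap the log-step to stay in a trust region
        step_norm = np.linalg.norm(step)
        if step_norm > 5.0:
            step *= 5.0 / step_norm
        norm_f = np.linalg.norm(f)
        lam = 1.0
        for _ in range(40):
            u_new = u + lam * step
            f_new, jac_new = residual_and_jac(u_new)
            if np.linalg.norm(f_new) < norm_f or lam < 1e-8:
                break
            lam *= 0.5
        u, f, jac = u_new, f_new, jac_new
        if np.linalg.norm(f) < best[0]:
            best = (np.linalg.norm(f), u.copy())
    else:
        raise EquilibriumError(
            f"complex-balance solve did not converge in {max_iter} iterations "
            f"(best log-balance residual {best[0]:.3e})",
            best_c=np.exp(best[1]),
            residual=best[0],
        )

    # a few undamped Newton steps to polish to machine precision (the
    # product-form balance identities are only as exact as c)
    for _ in range(polish):
        step, *_ = np.linalg.lstsq(jac, -f, rcond=None)
        u_try = u + step
        f_try, jac_try = residual_and_jac(u_try)
        if np.linalg.norm(f_try) >= np.linalg.norm(f):
            break
        u, f, jac = u_try, f_try, jac_try

    res_cx, thr = raw_residuals(u)
    c = np.exp(u)
    return EquilibriumResult(
        c=c,
        complexes=tuple(complexes),
        residuals=res_cx,
        tolerance=tol_scale * thr,
        constraint=None if w is None else (w, b),
        warnings=tuple(warnings),
        n_iter=n_iter,
    )
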