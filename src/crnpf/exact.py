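"""Ground-truth machinery for truncated chains.

Builds the generator of the continuous-time chain restricted to a finite
state class (transitions that would leave the class are dropped, i.e. the
truncation reflects by removing outflow), solves the stationary balance
equations with a sparse direct method, evaluates stationarity residuals
of arbitrary distributions, and runs the stochastic simulation algorithm
as an independent sampling oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla

from .kinetics import KineticsSpec, propensities, theta_intensity
from .network import AlphaPartition, ReactionNetwork
from .product_form import DiscreteDistribution, StateClass, enumerate_class

__all__ = [
    "TruncatedChain",
    "build_generator",
    "solve_stationary",
    "stationarity_residual",
    "ssa_simulate",
    "distribution_distance",
]


@dataclass
class TruncatedChain:
    """Generator matrix on an enumerated state set.

    ``generator[x, y]`` holds the rate of the jump ``x -> y`` for y != x;
    the diagonal is minus the row sum, so rows sum to zero exactly.
    """

    states: np.ndarray  # (n, d) int64 in enumeration order
    generator: sp.csr_matrix
    net: ReactionNetwork
    kinetics: KineticsSpec
    ap: AlphaPartition | None = None
    index: dict = field(default_factory=dict, repr=False)

    @property
    def n_states(self) -> int:
        return len(self.states)


def _state_index_map(states: np.ndarray, box: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Dense ravel-based lookup: raveled box index -> row, or -1."""
    sizes = np.array([n + 1 for n in box], dtype=np.int64)
    strides = np.concatenate([np.cumprod(sizes[::-1])[::-1][1:], [1]])
    ravel = states @ strides
    lookup = np.full(int(sizes.prod()), -1, dtype=np.int64)
    lookup[ravel] = np.arange(len(states))
    return lookup, strides


def build_generator(
    net: ReactionNetwork,
    kinetics: KineticsSpec,
    cls: StateClass,
    ap: AlphaPartition | None = None,
) -> TruncatedChain:
    """Sparse generator on the enumerated class; off-class jumps dropped."""
    states = enumerate_class(cls)
    if len(states) == 0:
        raise ValueError("state class is empty")
    lookup, strides = _state_index_map(states, cls.box)
    box = np.asarray(cls.box, dtype=np.int64)
    lam = propensities(net, kinetics, states, ap)  # (n, K)
    n = len(states)
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for k, r in enumerate(net.reactions):
        delta = np.asarray(r.net_change, dtype=np.int64)
        targets = states + delta
        inside = np.all((targets >= 0) & (targets <= box), axis=1)
        rates = lam[:, k]
        active = inside & (rates > 0)
        tgt_rows = np.full(n, -1, dtype=np.int64)
        tgt_rows[active] = lookup[targets[active] @ strides]
        active &= tgt_rows >= 0  # drop jumps leaving the class
        rows.append(np.nonzero(active)[0])
        cols.append(tgt_rows[active])
        vals.append(rates[active])
        np.add.at(diag, np.nonzero(active)[0], -rates[active])
    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    A.sum_duplicates()
    return TruncatedChain(states=states, generator=A, net=net, kinetics=kinetics, ap=ap)


def _count_closed_classes(A: sp.csr_matrix) -> int:
    # copy index arrays: setdiag/eliminate_zeros mutate structure in place
    adj = sp.csr_matrix(
        (np.ones_like(A.data), A.indices.copy(), A.indptr.copy()), shape=A.shape
    )
    adj.setdiag(0)
    adj.eliminate_zeros()
    ncomp, labels = csgraph.connected_components(adj, directed=True, connection="strong")
    if ncomp == 1:
        return 1
    # a component is closed iff no edge leaves it
    coo = adj.tocoo()
    has_exit = np.zeros(ncomp, dtype=bool)
    cross = labels[coo.row] != labels[coo.col]
    has_exit[np.unique(labels[coo.row[cross]])] = True
    return int((~has_exit).sum())


def solve_stationary(chain: TruncatedChain, tol: float = 1e-10) -> DiscreteDistribution:
    """Solve pi A = 0, sum(pi) = 1 by sparse LU on the adjoint.

    One balance equation is replaced by the normalization row (the last,
    deterministically).  Raises if the state set contains more than one
    closed communicating class -- restrict the class (conserved quantity,
    parity) in that case.
    """
    A = chain.generator
    n = A.shape[0]
    n_closed = _count_closed_classes(A)
    if n_closed != 1:
        raise ValueError(
            f"state set contains {n_closed} closed communicating classes; "
            "restrict the class (e.g. fix the conserved quantity or parity)"
        )
    M = A.T.tocoo()
    keep = M.row != n - 1
    rows = np.concatenate([M.row[keep], np.full(n, n - 1)])
    cols = np.concatenate([M.col[keep], np.arange(n)])
    vals = np.concatenate([M.data[keep], np.ones(n)])
    M2 = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
    b = np.zeros(n)
    b[-1] = 1.0
    pi = spla.spsolve(M2, b)
    pi = np.maximum(pi, 0.0)
    pi /= pi.sum()
    scale = np.abs(A.diagonal()).max()
    residual = float(np.abs(pi @ A).max())
    if residual > tol * max(scale, 1.0):
        raise RuntimeError(
            f"stationary solve residual {residual:.3e} exceeds tolerance "
            f"{tol * max(scale, 1.0):.3e}"
        )
    return DiscreteDistribution(
        states=chain.states,
        probs=pi,
        meta={"solver": "sparse_lu_adjoint", "residual": residual,
              "residual_scale": scale},
    )


def stationarity_residual(
    dist: DiscreteDistribution,
    net: ReactionNetwork,
    kinetics: KineticsSpec,
    ap: AlphaPartition | None = None,
    box: tuple[int, ...] | None = None,
) -> float:
    """Max master-equation balance violation over interior states.

    For each state the residual is ``sum_k lambda_k(x - delta_k)
    pi(x - delta_k) - sum_k lambda_k(x) pi(x)``, with terms for
    infeasible predecessors dropped.  States with a neighbour outside the
    enumerated set (in either direction, with positive rate) are excluded
    as boundary states.
    """
    states = dist.states
    if box is None:
        box = tuple(int(v) for v in states.max(axis=0))
    lookup, strides = _state_index_map(states, box)
    boxv = np.asarray(box, dtype=np.int64)
    lam = propensities(net, kinetics, states, ap)
    n = len(states)
    outflow = lam.sum(axis=1) * dist.probs
    inflow = np.zeros(n)
    interior = np.ones(n, dtype=bool)
    for k, r in enumerate(net.reactions):
        delta = np.asarray(r.net_change, dtype=np.int64)
        # predecessor x - delta must be in the set, or infeasible (negative)
        pred = states - delta
        pred_feasible = np.all(pred >= 0, axis=1)
        pred_inbox = pred_feasible & np.all(pred <= boxv, axis=1)
        pred_rows = np.full(n, -1, dtype=np.int64)
        pred_rows[pred_inbox] = lookup[pred[pred_inbox] @ strides]
        have_pred = pred_rows >= 0
        inflow[have_pred] += (
            lam[pred_rows[have_pred], k] * dist.probs[pred_rows[have_pred]]
        )
        # feasible predecessor missing from the set -> boundary state
        interior &= have_pred | ~pred_feasible
        # successor with positive rate leaving the set -> boundary state
        succ = states + delta
        succ_inbox = np.all((succ >= 0) & (succ <= boxv), axis=1)
        succ_rows = np.full(n, -1, dtype=np.int64)
        succ_rows[succ_inbox] = lookup[succ[succ_inbox] @ strides]
        interior &= (succ_rows >= 0) | (lam[:, k] == 0)
    res = np.abs(inflow - outflow)
    if not interior.any():
        raise ValueError("no interior states in the enumerated set")
    return float(res[interior].max())


def _ssa_on_class(net, kinetics, cls, x0, t_end, rng, ap, max_jumps):
    """Table-driven direct method on a pre-enumerated class (fast path)."""
    states = enumerate_class(cls)
    lookup, strides = _state_index_map(states, cls.box)
    box = np.asarray(cls.box, dtype=np.int64)
    lam = propensities(net, kinetics, states, ap)  # (n, K)
    n, K = lam.shape
    succ = np.full((n, K), -1, dtype=np.int64)
    for k, r in enumerate(net.reactions):
        delta = np.asarray(r.net_change, dtype=np.int64)
        tgt = states + delta
        inside = np.all((tgt >= 0) & (tgt <= box), axis=1)
        succ[inside, k] = lookup[tgt[inside] @ strides]
    lam = np.where(succ >= 0, lam, 0.0)  # dropped transitions, as in the generator
    cum = np.cumsum(lam, axis=1)
    total = cum[:, -1]
    i = lookup[np.asarray(x0, dtype=np.int64) @ strides]
    if i < 0:
        raise ValueError(f"initial state {tuple(x0)} is not in the class")
    hold = np.zeros(n)
    t = 0.0
    n_jumps = 0
    while t < t_end:
        rate = total[i]
        if rate <= 0.0:
            hold[i] += t_end - t
            break
        dt = rng.exponential(1.0 / rate)
        hold[i] += min(dt, t_end - t)
        t += dt
        if t >= t_end:
            break
        k = int(np.searchsorted(cum[i], rng.random() * rate, side="right"))
        i = succ[i, k]
        n_jumps += 1
        if n_jumps >= max_jumps:
            raise RuntimeError("max_jumps exceeded before t_end")
    hold /= hold.sum()
    occupancy = {tuple(int(v) for v in states[j]): float(hold[j])
                 for j in np.nonzero(hold)[0]}
    return {
        "occupancy": occupancy,
        "occupancy_dist": DiscreteDistribution(states=states, probs=hold,
                                               meta={"seed": None}),
        "final_state": tuple(int(v) for v in states[i]),
        "n_jumps": n_jumps,
        "t_end": t_end,
        "method": "gillespie_direct_tabulated",
    }


def ssa_simulate(
    net: ReactionNetwork,
    kinetics: KineticsSpec,
    x0,
    t_end: float,
    seed: int,
    ap: AlphaPartition | None = None,
    cls: StateClass | None = None,
    max_jumps: int = 100_000_000,
    record_trajectory: bool = False,
):
    """Gillespie direct-method simulation; returns time-weighted occupancy.

    When ``cls`` is given the chain is simulated on the pre-enumerated
    class with tabulated rates (much faster; transitions leaving the class
    are dropped exactly as in :func:`build_generator`).

    Returns a dict with ``occupancy`` (state tuple -> fraction of time),
    ``final_state``, ``n_jumps``, ``seed`` and, if requested, the jump
    ``trajectory`` as (times, states).
    """
    rng = np.random.default_rng(seed)
    if cls is not None:
        if record_trajectory:
            raise ValueError("trajectory recording is not supported on the fast path")
        out = _ssa_on_class(net, kinetics, cls, x0, t_end, rng, ap, max_jumps)
        out["seed"] = seed
        return out
    x = np.asarray(x0, dtype=np.int64).copy()
    deltas = [np.asarray(r.net_change, dtype=np.int64) for r in net.reactions]
    t = 0.0
    occupancy: dict[tuple, float] = {}
    times, path = [0.0], [tuple(x)]
    n_jumps = 0
    K = net.K
    lam = np.empty(K)
    while t < t_end:
        for k in range(K):
            lam[k] = theta_intensity(kinetics, net, ap, k, x)
        total = lam.sum()
        if not math.isfinite(total):
            raise OverflowError(f"propensity overflow at state {tuple(x)}")
        if total <= 0.0:
            occupancy[tuple(x)] = occupancy.get(tuple(x), 0.0) + (t_end - t)
            t = t_end
            break
        dt = rng.exponential(1.0 / total)
        hold = min(dt, t_end - t)
        key = tuple(x)
        occupancy[key] = occupancy.get(key, 0.0) + hold
        t += dt
        if t >= t_end:
            break
        k = rng.choice(K, p=lam / total)
        x = x + deltas[k]
        n_jumps += 1
        if record_trajectory:
            times.append(t)
            path.append(tuple(x))
        if n_jumps >= max_jumps:
            raise RuntimeError("max_jumps exceeded before t_end")
    total_time = sum(occupancy.values())
    occupancy = {k: v / total_time for k, v in occupancy.items()}
    out = {
        "occupancy": occupancy,
        "final_state": tuple(int(v) for v in x),
        "n_jumps": n_jumps,
        "seed": seed,
        "t_end": t_end,
        "method": "gillespie_direct",
    }
    if record_trajectory:
        out["trajectory"] = (np.array(times), np.array(path))
    return out


def distribution_distance(p, q, mode: str = "relative_l2") -> float:
    """``relative_l2`` = ||p - q||_2 / ||q||_2 (q is the reference);
    ``total_variation`` = 0.5 * sum |p - q|.  Supports must align."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"support mismatch: {p.shape} vs {q.shape}")
    if mode == "relative_l2":
        return float(np.linalg.norm(p - q) / np.linalg.norm(q))
    if mode == "total_variation":
        return float(0.5 * np.abs(p - q).sum())
    raise ValueError(f"unknown distance mode {mode!r}")
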