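"""Reaction-network representation and structural analysis.

A network is a list of species and a list of reactions, each reaction a
pair of nonnegative integer stoichiometric vectors (source, product) with
a positive rate constant.  Structural quantities -- complexes, linkage
classes, weak reversibility, deficiency, conservation laws and the
per-species gcd partition -- gate which stationary-distribution theorems
apply.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import sympy

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "StructuralReport",
    "AlphaPartition",
    "NetworkValidationError",
    "build_network",
    "structural_report",
    "alpha_partition",
    "load_network",
    "dump_network",
]


class NetworkValidationError(ValueError):
    """Raised when a network description violates a structural invariant."""


@dataclass(frozen=True)
class Reaction:
    """One reaction channel: ``source -> product`` with rate constant kappa."""

    source: tuple[int, ...]
    product: tuple[int, ...]
    rate_constant: float
    label: str | None = None

    @property
    def net_change(self) -> tuple[int, ...]:
        return tuple(p - s for s, p in zip(self.source, self.product))


@dataclass(frozen=True)
class ReactionNetwork:
    """Validated chemical reaction network.

    Attributes
    ----------
    species : tuple of str
        Ordered species identifiers (length ``d``).
    reactions : tuple of Reaction
        The ``K`` reaction channels.
    """

    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]

    @property
    def d(self) -> int:
        return len(self.species)

    @property
    def K(self) -> int:
        return len(self.reactions)

    def species_index(self, name: str) -> int:
        return self.species.index(name)

    @property
    def source_matrix(self) -> np.ndarray:
        """(K, d) integer matrix of source stoichiometries."""
        return np.array([r.source for r in self.reactions], dtype=np.int64)

    @property
    def product_matrix(self) -> np.ndarray:
        return np.array([r.product for r in self.reactions], dtype=np.int64)

    @property
    def stoichiometric_matrix(self) -> np.ndarray:
        """(d, K) matrix whose k-th column is the net change of reaction k."""
        return (self.product_matrix - self.source_matrix).T

    def complex_label(self, vec: Sequence[int]) -> str:
        terms = []
        for count, name in zip(vec, self.species):
            if count == 1:
                terms.append(name)
            elif count > 1:
                terms.append(f"{count}{name}")
        return " + ".join(terms) if terms else "0"


@dataclass(frozen=True)
class StructuralReport:
    """Graph-theoretic summary of a reaction network."""

    complexes: tuple[tuple[int, ...], ...]
    linkage_classes: tuple[tuple[int, ...], ...]
    weakly_reversible: bool
    stoich_rank: int
    deficiency: int
    conservation_laws: tuple[tuple[int, ...], ...]

    @property
    def n_complexes(self) -> int:
        return len(self.complexes)

    @property
    def n_linkage_classes(self) -> int:
        return len(self.linkage_classes)


@dataclass(frozen=True)
class AlphaPartition:
    """Per-species gcd of source stoichiometries and the induced split.

    ``alpha[i]`` is the gcd of the i-th source column over all reactions,
    with the convention that an all-zero column (a species never consumed)
    yields ``alpha[i] = 1``.  Species with ``alpha[i] > 1`` form the scaled
    set ``S2``; the rest form ``S1``.
    """

    alpha: tuple[int, ...]
    slow_set_S1: tuple[int, ...]
    scaled_set_S2: tuple[int, ...]


def build_network(
    species: Sequence[str],
    reactions: Iterable[Mapping | Reaction],
) -> ReactionNetwork:
    """Validate and construct a :class:`ReactionNetwork`.

    Parameters
    ----------
    species : sequence of str
        Unique species names.
    reactions : iterable
        Either :class:`Reaction` objects or mappings with keys
        ``reactants``/``products`` ({species: count}) and ``rate_constant``.

    Raises
    ------
    NetworkValidationError
        On duplicate species, non-integer or negative stoichiometry,
        non-positive rate constants, or a reaction whose source equals its
        product.
    """
    species = tuple(str(s) for s in species)
    if len(species) == 0:
        raise NetworkValidationError("network must contain at least one species")
    if len(set(species)) != len(species):
        dupes = sorted({s for s in species if species.count(s) > 1})
        raise NetworkValidationError(f"duplicate species names: {dupes}")
    index = {name: i for i, name in enumerate(species)}

    built: list[Reaction] = []
    for pos, r in enumerate(reactions):
        if isinstance(r, Reaction):
            src, prod, kappa, label = r.source, r.product, r.rate_constant, r.label
            if len(src) != len(species) or len(prod) != len(species):
                raise NetworkValidationError(
                    f"reaction {pos}: stoichiometry length does not match species list"
                )
        else:
            src_map = dict(r.get("reactants", {}))
            prod_map = dict(r.get("products", {}))
            for m in (src_map, prod_map):
                unknown = set(m) - set(species)
                if unknown:
                    raise NetworkValidationError(
                        f"reaction {pos}: unknown species {sorted(unknown)}"
                    )
            src = tuple(src_map.get(s, 0) for s in species)
            prod = tuple(prod_map.get(s, 0) for s in species)
            kappa = r["rate_constant"]
            label = r.get("label")
        for vec, side in ((src, "source"), (prod, "product")):
            for v in vec:
                if not float(v).is_integer() or v < 0:
                    raise NetworkValidationError(
                        f"reaction {pos} ({side}): stoichiometries must be "
                        f"nonnegative integers, got {vec}"
                    )
        src = tuple(int(v) for v in src)
        prod = tuple(int(v) for v in prod)
        if src == prod:
            raise NetworkValidationError(
                f"reaction {pos}{'' if label is None else ' (' + label + ')'}: "
                "source and product complexes coincide"
            )
        kappa = float(kappa)
        if not kappa > 0 or not math.isfinite(kappa):
            raise NetworkValidationError(
                f"reaction {pos}: rate constant must be positive, got {kappa}"
            )
        built.append(Reaction(src, prod, kappa, label))
    if not built:
        raise NetworkValidationError("network must contain at least one reaction")
    return ReactionNetwork(species, tuple(built))


def _primitive_integer_rows(vectors: list[list[Fraction]]) -> list[tuple[int, ...]]:
    """Clear denominators, divide by gcd, make first nonzero entry positive."""
    out = []
    for vec in vectors:
        denom = math.lcm(*(f.denominator for f in vec)) if vec else 1
        ints = [int(f * denom) for f in vec]
        g = math.gcd(*(abs(v) for v in ints))
        if g > 1:
            ints = [v // g for v in ints]
        first = next((v for v in ints if v != 0), 0)
        if first < 0:
            ints = [-v for v in ints]
        out.append(tuple(ints))
    out.sort()
    return out


def structural_report(net: ReactionNetwork) -> StructuralReport:
    """Compute complexes, linkage classes, deficiency and conservation laws.

    The deficiency is ``n - l - s`` where ``n`` is the number of distinct
    complexes, ``l`` the number of linkage classes (connected components
    of the complex graph) and ``s`` the rank of the span of the reaction
    vectors.  Conservation laws are an exact rational basis of the left
    null space of the stoichiometric matrix, returned as primitive integer
    vectors in a deterministic order.
    """
    complexes: list[tuple[int, ...]] = []
    cindex: dict[tuple[int, ...], int] = {}
    for r in net.reactions:
        for cx in (r.source, r.product):
            if cx not in cindex:
                cindex[cx] = len(complexes)
                complexes.append(cx)

    g = nx.DiGraph()
    g.add_nodes_from(range(len(complexes)))
    for r in net.reactions:
        g.add_edge(cindex[r.source], cindex[r.product])

    linkage = [tuple(sorted(comp)) for comp in nx.connected_components(g.to_undirected())]
    linkage.sort()
    weakly_reversible = all(
        nx.is_strongly_connected(g.subgraph(comp)) for comp in linkage
    )

    # exact rank and left null space over the rationals
    S = net.stoichiometric_matrix
    sym = sympy.Matrix(S.tolist())
    rank = sym.rank()
    null = sym.T.nullspace()
    laws = _primitive_integer_rows(
        [[Fraction(int(v.p), int(v.q)) for v in vec] for vec in null]
    )
    deficiency = len(complexes) - len(linkage) - rank
    return StructuralReport(
        complexes=tuple(complexes),
        linkage_classes=tuple(linkage),
        weakly_reversible=weakly_reversible,
        stoich_rank=rank,
        deficiency=deficiency,
        conservation_laws=tuple(laws),
    )


def alpha_partition(net: ReactionNetwork) -> AlphaPartition:
    """gcd of each source column; all-zero columns get alpha = 1."""
    src = net.source_matrix
    alpha = []
    for i in range(net.d):
        g = 0
        for k in range(net.K):
            g = math.gcd(g, int(src[k, i]))
        alpha.append(g if g > 1 else 1)
    s1 = tuple(i for i, a in enumerate(alpha) if a == 1)
    s2 = tuple(i for i, a in enumerate(alpha) if a > 1)
    return AlphaPartition(tuple(alpha), s1, s2)


# ---------------------------------------------------------------------------
# network file format (JSON / YAML dialect)
# ---------------------------------------------------------------------------

_TOP_KEYS = {"species", "reactions", "kinetics"}
_REACTION_KEYS = {"reactants", "products", "rate_constant", "label"}


def network_to_dict(net: ReactionNetwork, kinetics_block: dict | None = None) -> dict:
    """Serialize a network (and optional kinetics section) to plain data."""
    reactions = []
    for r in net.reactions:
        entry: dict = {
            "reactants": {s: int(c) for s, c in zip(net.species, r.source) if c},
            "products": {s: int(c) for s, c in zip(net.species, r.product) if c},
            "rate_constant": r.rate_constant,
        }
        if r.label is not None:
            entry["label"] = r.label
        reactions.append(entry)
    out = {"species": list(net.species), "reactions": reactions}
    if kinetics_block is not None:
        out["kinetics"] = kinetics_block
    return out


def network_from_dict(data: Mapping) -> tuple[ReactionNetwork, dict | None]:
    """Parse the network file dialect; rejects unknown keys."""
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise NetworkValidationError(f"unknown top-level keys: {sorted(unknown)}")
    if "species" not in data or "reactions" not in data:
        raise NetworkValidationError("network file requires 'species' and 'reactions'")
    for pos, r in enumerate(data["reactions"]):
        bad = set(r) - _REACTION_KEYS
        if bad:
            raise NetworkValidationError(f"reaction {pos}: unknown keys {sorted(bad)}")
    net = build_network(data["species"], data["reactions"])
    return net, data.get("kinetics")


def load_network(path) -> tuple[ReactionNetwork, dict | None]:
    """Read a network file (YAML superset of JSON)."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise NetworkValidationError(f"{path}: expected a mapping at top level")
    return network_from_dict(data)


def dump_network(net: ReactionNetwork, path, kinetics_block: dict | None = None) -> None:
    """Write a network file as JSON (valid YAML, bit-exact round-trip)."""
    with open(path, "w") as fh:
        json.dump(network_to_dict(net, kinetics_block), fh, indent=2, sort_keys=True)
        fh.write("\n")
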