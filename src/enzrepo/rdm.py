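"""Atom mapping, RDM reaction-center patterns, and reaction similarity.

A reaction (one substrate/product compound pair) is summarised by its RDM
pattern: for every reaction-center atom, the atom-type change at the center
(R), the atom types gained or lost next to it (D, the difference region), and
the type transitions of its conserved neighbors (M, the matched region).
Two reactions are compared by optimally matching their RDM triples; the
score is on [0, 1] and equals 1 exactly when the patterns coincide.

The atom correspondence underlying a pattern is a maximum common connected
subgraph (MCS) between substrate and product under element compatibility.
Bond orders are deliberately not an MCS constraint: an order change at the
reaction center is precisely what the pattern has to capture, so an
order-strict MCS would exclude the center from the mapping.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .reaction_model import (
    AtomMapping,
    CompoundGraph,
    ConfigError,
    ReactantPair,
    VOCABULARY_VERSION,
)

DEFAULT_WEIGHTS = (0.5, 0.25, 0.25)


@dataclass
class RDMConfig:
    """Scoring configuration: R/D/M weights and the exact-MCS size cap."""

    weights: tuple[float, float, float] = DEFAULT_WEIGHTS
    mcs_size_cap: int = 30
    vocabulary: str = VOCABULARY_VERSION

    def __post_init__(self):
        w = self.weights
        if len(w) != 3 or any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
            raise ConfigError(
                f"weights must be 3 nonnegative values summing to 1, got {w}"
            )
        self._pattern_cache: dict[tuple[str, str], "RDMPattern"] = {}


@dataclass(frozen=True, order=True)
class RDMTriple:
    """One reaction-center atom's (R, D, M) description.

    ``r_change`` is the (before, after) atom-type pair at the center;
    ``d_set`` the sorted multiset of atom types unmapped on either side
    adjacent to the center; ``m_set`` the sorted multiset of (before, after)
    type pairs of mapped neighbors.
    """

    r_change: tuple[str, str]
    d_set: tuple[str, ...]
    m_set: tuple[tuple[str, str], ...]


@dataclass(frozen=True)
class RDMPattern:
    triples: tuple[RDMTriple, ...]
    pair_id: str = ""
    vocabulary: str = VOCABULARY_VERSION

    def __post_init__(self):
        object.__setattr__(self, "triples", tuple(sorted(self.triples)))

    def __len__(self) -> int:
        return len(self.triples)

    def to_json(self) -> dict:
        return {
            "vocabulary": self.vocabulary,
            "pair_id": self.pair_id,
            "triples": [
                {
                    "r": list(t.r_change),
                    "d": list(t.d_set),
                    "m": [list(p) for p in t.m_set],
                }
                for t in self.triples
            ],
        }

    @staticmethod
    def from_json(obj: dict) -> "RDMPattern":
        return RDMPattern(
            tuple(
                RDMTriple(
                    tuple(t["r"]),
                    tuple(t["d"]),
                    tuple(tuple(p) for p in t["m"]),
                )
                for t in obj["triples"]
            ),
            obj.get("pair_id", ""),
            obj["vocabulary"],
        )


@dataclass(frozen=True)
class SimilarityScore:
    value: float
    components: tuple[float, ...] = ()


# ---------------------------------------------------------------------------
# Maximum common connected subgraph


def _compatible(g1: CompoundGraph, g2: CompoundGraph, i: int, j: int) -> bool:
    return g1.element(i) == g2.element(j)


def _consistent(g1, g2, mapping: dict[int, int], a: int, b: int) -> bool:
    # induced: bond presence must agree with every already-mapped pair
    for x, y in mapping.items():
        if g1.has_bond(a, x) != g2.has_bond(b, y):
            return False
    return True


def _exact_mcs(g1: CompoundGraph, g2: CompoundGraph) -> list[tuple[int, int]]:
    """Exhaustive connected-MCS search with lexicographic tie-breaking.

    Enumerates connected common induced subgraphs seeded at each substrate
    atom (requiring the seed to be the smallest substrate index in the
    mapping, which makes the enumeration duplicate-free across seeds) and
    keeps the largest mapping; among equal sizes the lexicographically
    smallest sorted (substrate, product) pair sequence wins.
    """
    n1, n2 = len(g1), len(g2)
    best: list[tuple[int, int]] = []

    def grow(mapping: dict[int, int], used2: set[int], frontier_ban: frozenset[int], seed: int):
        nonlocal best
        # frontier: unmapped substrate atoms adjacent to the mapped set
        frontier = sorted(
            {
                nb
                for i in mapping
                for nb in g1.neighbors(i)
                if nb not in mapping and nb not in frontier_ban and nb > seed
            }
        )
        # optimistic bound: everything reachable could still be mapped
        if len(mapping) + len(_reachable(g1, mapping, frontier_ban, seed)) < len(best):
            return
        if not frontier:
            if len(mapping) > len(best) or (
                len(mapping) == len(best)
                and sorted(mapping.items()) < sorted(best)
            ):
                best = list(mapping.items())
            return
        a = frontier[0]
        # branch 1: map a to every consistent product atom
        for b in range(n2):
            if b in used2 or not _compatible(g1, g2, a, b):
                continue
            if not _consistent(g1, g2, mapping, a, b):
                continue
            mapping[a] = b
            used2.add(b)
            grow(mapping, used2, frontier_ban, seed)
            del mapping[a]
            used2.remove(b)
        # branch 2: exclude a permanently from this subtree
        grow(mapping, used2, frontier_ban | {a}, seed)

    for i in range(n1):
        for j in range(n2):
            if not _compatible(g1, g2, i, j):
                continue
            grow({i: j}, {j}, frozenset(), i)
    return sorted(best)


def _reachable(g1, mapping, ban, seed) -> set[int]:
    out = set()
    stack = list(mapping)
    seen = set(mapping)
    while stack:
        i = stack.pop()
        for nb in g1.neighbors(i):
            if nb in seen or nb in ban or nb <= seed and nb not in mapping:
                continue
            seen.add(nb)
            out.add(nb)
            stack.append(nb)
    return out


def _greedy_mcs(g1: CompoundGraph, g2: CompoundGraph) -> list[tuple[int, int]]:
    """Greedy extension from every seed pair; documented fallback beyond the cap.

    From each compatible seed the mapped set is extended by always taking the
    smallest frontier substrate atom and its smallest consistent partner.
    """
    best: list[tuple[int, int]] = []
    for i in range(len(g1)):
        for j in range(len(g2)):
            if not _compatible(g1, g2, i, j):
                continue
            mapping = {i: j}
            used2 = {j}
            progress = True
            while progress:
                progress = False
                frontier = sorted(
                    {
                        nb
                        for x in mapping
                        for nb in g1.neighbors(x)
                        if nb not in mapping
                    }
                )
                for a in frontier:
                    for b in range(len(g2)):
                        if b in used2 or not _compatible(g1, g2, a, b):
                            continue
                        if _consistent(g1, g2, mapping, a, b):
                            mapping[a] = b
                            used2.add(b)
                            progress = True
                            break
                    if progress:
                        break
            cand = sorted(mapping.items())
            if len(cand) > len(best) or (len(cand) == len(best) and cand < best):
                best = cand
    return best


def map_atoms(
    pair: ReactantPair, mode: str = "exact", size_cap: int = 30
) -> AtomMapping:
    """Maximum common connected-subgraph atom mapping for a reactant pair.

    ``mode='exact'`` guarantees optimality up to ``size_cap`` heavy atoms per
    graph and falls back to the greedy heuristic beyond it; the mode actually
    used is recorded on the returned mapping.
    """
    if mode not in ("exact", "greedy-fallback"):
        raise ConfigError(f"unknown mapping mode {mode!r}")
    g1, g2 = pair.substrate, pair.product
    use_exact = mode == "exact" and max(len(g1), len(g2)) <= size_cap
    pairs = _exact_mcs(g1, g2) if use_exact else _greedy_mcs(g1, g2)
    return AtomMapping(
        tuple(pairs), len(pairs), "exact" if use_exact else "greedy-fallback"
    )


# ---------------------------------------------------------------------------
# RDM extraction


def extract_rdm(pair: ReactantPair, mapping: AtomMapping) -> RDMPattern:
    """Extract the RDM pattern of a reactant pair under an atom mapping.

    A mapped atom is a reaction center iff its atom-type code changes, it is
    adjacent to an unmapped atom on either side, or an incident bond within
    the mapped set changes order.
    """
    sub, prod = pair.substrate, pair.product
    fwd = mapping.as_dict()
    rev = {v: k for k, v in fwd.items()}
    for i, j in fwd.items():
        if i >= len(sub) or j >= len(prod):
            raise ValueError("mapping does not fit the given pair")
        if sub.element(i) != prod.element(j):
            raise ValueError("mapping pairs atoms of different elements")

    triples = []
    for i, j in fwd.items():
        t_before, t_after = sub.atom_type(i), prod.atom_type(j)
        sub_unmapped = [nb for nb in sub.neighbors(i) if nb not in fwd]
        prod_unmapped = [nb for nb in prod.neighbors(j) if nb not in rev]
        mapped_nbs = [nb for nb in sub.neighbors(i) if nb in fwd]
        order_change = any(
            sub.bond_order(i, nb) != prod.bond_order(j, fwd[nb])
            for nb in mapped_nbs
            if prod.has_bond(j, fwd[nb])
        )
        is_center = (
            t_before != t_after or sub_unmapped or prod_unmapped or order_change
        )
        if not is_center:
            continue
        d_set = sorted(
            [sub.atom_type(nb) for nb in sub_unmapped]
            + [prod.atom_type(nb) for nb in prod_unmapped]
        )
        m_set = sorted(
            (sub.atom_type(nb), prod.atom_type(fwd[nb])) for nb in mapped_nbs
        )
        triples.append(RDMTriple((t_before, t_after), tuple(d_set), tuple(m_set)))
    return RDMPattern(tuple(triples), pair_id=f"{sub.compound_id}>{prod.compound_id}")


# ---------------------------------------------------------------------------
# Similarity


def multiset_jaccard(a, b) -> float:
    """Jaccard index of two multisets; both empty counts as full agreement."""
    ca, cb = Counter(a), Counter(b)
    if not ca and not cb:
        return 1.0
    inter = sum((ca & cb).values())
    union = sum((ca | cb).values())
    return inter / union


def triple_similarity(
    a: RDMTriple, b: RDMTriple, weights: tuple[float, float, float] = DEFAULT_WEIGHTS
) -> float:
    w_r, w_d, w_m = weights
    if any(w < 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
        raise ConfigError(f"invalid weights {weights}")
    return (
        w_r * (1.0 if a.r_change == b.r_change else 0.0)
        + w_d * multiset_jaccard(a.d_set, b.d_set)
        + w_m * multiset_jaccard(a.m_set, b.m_set)
    )


def pattern_similarity(
    p: RDMPattern, q: RDMPattern, weights: tuple[float, float, float] = DEFAULT_WEIGHTS
) -> SimilarityScore:
    """Maximum-weight bipartite matching of triples, normalised by the larger
    pattern size.  Two empty patterns score 1; exactly one empty scores 0."""
    if p.vocabulary != q.vocabulary:
        raise ConfigError(
            f"vocabulary mismatch: {p.vocabulary!r} vs {q.vocabulary!r}"
        )
    if len(p) == 0 and len(q) == 0:
        return SimilarityScore(1.0)
    if len(p) == 0 or len(q) == 0:
        return SimilarityScore(0.0)
    sims = np.array(
        [[triple_similarity(a, b, weights) for b in q.triples] for a in p.triples]
    )
    rows, cols = linear_sum_assignment(sims, maximize=True)
    matched = sims[rows, cols]
    value = float(matched.sum()) / max(len(p), len(q))
    return SimilarityScore(value, tuple(float(x) for x in matched))


def reaction_pattern(pair: ReactantPair, config: RDMConfig) -> RDMPattern:
    """RDM pattern of a pair, cached on the config by compound content."""
    key = pair.key()
    cache = config._pattern_cache
    if key not in cache:
        mapping = map_atoms(pair, "exact", config.mcs_size_cap)
        pair.mapping = mapping
        cache[key] = extract_rdm(pair, mapping)
    return cache[key]


def score_reaction_pair(
    query: ReactantPair, target: ReactantPair, config: RDMConfig | None = None
) -> SimilarityScore:
    """Similarity of two reactions' RDM patterns on [0, 1]."""
    config = config or RDMConfig()
    p = reaction_pattern(query, config)
    q = reaction_pattern(target, config)
    return pattern_similarity(p, q, config.weights)
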