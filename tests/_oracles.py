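"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: subgraph enumeration
via networkx isomorphism, matching by permutation enumeration, taxon calls by
direct set logic, and local alignment by a cubic gap-scan dynamic program.
"""

from __future__ import annotations

import itertools

import networkx as nx
from Bio.Align import substitution_matrices

from enzrepo.rdm import triple_similarity

_B62 = substitution_matrices.load("BLOSUM62")


def to_nx(graph) -> nx.Graph:
    g = nx.Graph()
    for a in graph.atoms:
        g.add_node(a.index, element=a.element)
    for b in graph.bonds:
        g.add_edge(b.a, b.b)
    return g


def mcs_size_bruteforce(g1, g2) -> int:
    """Largest connected induced common subgraph (element-labeled, orders
    ignored) by exhaustive subset enumeration + isomorphism testing."""
    G1, G2 = to_nx(g1), to_nx(g2)
    node_match = lambda x, y: x["element"] == y["element"]  # noqa: E731
    for k in range(min(len(G1), len(G2)), 0, -1):
        subs2 = [
            s
            for s in itertools.combinations(G2.nodes, k)
            if nx.is_connected(G2.subgraph(s))
        ]
        for s1 in itertools.combinations(G1.nodes, k):
            H1 = G1.subgraph(s1)
            if not nx.is_connected(H1):
                continue
            for s2 in subs2:
                gm = nx.algorithms.isomorphism.GraphMatcher(
                    H1, G2.subgraph(s2), node_match=node_match
                )
                if gm.is_isomorphic():
                    return k
    return 0


def matching_score_bruteforce(p, q, weights=(0.5, 0.25, 0.25)) -> float:
    """Pattern similarity by enumerating every bipartite matching."""
    if not p.triples and not q.triples:
        return 1.0
    if not p.triples or not q.triples:
        return 0.0
    a, b = list(p.triples), list(q.triples)
    if len(a) > len(b):
        a, b = b, a
    best = 0.0
    for perm in itertools.permutations(range(len(b)), len(a)):
        s = sum(triple_similarity(a[i], b[j], weights) for i, j in enumerate(perm))
        best = max(best, s)
    return best / max(len(p.triples), len(q.triples))


def classify_bruteforce(reaction, taxon_group, db) -> str:
    """Direct set-logic re-statement of the taxon specificity definitions."""
    orgs = {
        org
        for cid in reaction.cluster_ids
        for org, _gene in db.clusters[cid].members
    }
    if orgs:
        if all(db.organisms[o].taxon_group == taxon_group for o in orgs):
            return "specific"
        return "shared"
    if set(reaction.pathway_taxa) == {taxon_group}:
        return "orphan-specific"
    return "unassigned"


def sw_bruteforce(a: str, b: str, gap_open: int = 11, gap_extend: int = 1):
    """Smith–Waterman with explicit gap-length scanning (O(nm(n+m))).

    Returns (score, identity, coverage, aligned) with identity over aligned
    columns, coverage over the query span, canonical traceback preferring
    substitution > query-consuming gap > target-consuming gap, shortest gap.
    """
    m, n = len(a), len(b)
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            cands = [0.0, H[i - 1][j - 1] + float(_B62[a[i - 1], b[j - 1]])]
            for k in range(1, i + 1):
                cands.append(H[i - k][j] - gap_open - gap_extend * k)
            for k in range(1, j + 1):
                cands.append(H[i][j - k] - gap_open - gap_extend * k)
            H[i][j] = max(cands)
            if H[i][j] > best:
                best, bi, bj = H[i][j], i, j
    if best <= 0:
        return 0.0, 0.0, 0.0, False
    i, j = bi, bj
    matches = columns = 0
    while H[i][j] > 0:
        if (
            i > 0
            and j > 0
            and H[i][j] == H[i - 1][j - 1] + float(_B62[a[i - 1], b[j - 1]])
        ):
            columns += 1
            matches += a[i - 1] == b[j - 1]
            i, j = i - 1, j - 1
            continue
        moved = False
        for k in range(1, i + 1):
            if H[i][j] == H[i - k][j] - gap_open - gap_extend * k:
                columns += k
                i -= k
                moved = True
                break
        if moved:
            continue
        for k in range(1, j + 1):
            if H[i][j] == H[i][j - k] - gap_open - gap_extend * k:
                columns += k
                j -= k
                moved = True
                break
        assert moved, "traceback stuck"
    identity = 100.0 * matches / columns if columns else 0.0
    coverage = 100.0 * (bi - i) / m
    return best, identity, coverage, True
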