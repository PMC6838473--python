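"""Candidate profiling: per-organism aggregation, tree annotation export, and
the sequence-independence check.

The sequence-independence check asks whether a candidate enzyme could have
been found by ordinary homology search: each candidate protein is locally
aligned (Smith–Waterman, BLOSUM62, affine gaps 11/1) against the known
enzymes for the reaction, reporting score, percent identity over aligned
columns and query coverage.  Low identity/coverage means the candidate sits
outside the reach of sequence-similarity screening.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import Phylo
from Bio.Align import substitution_matrices

from .reaction_model import ReactionDatabase
from .screen import ScreenResult

# ---------------------------------------------------------------------------
# Organism profiles


@dataclass
class TaxonProfile:
    """Binary organism × query-reaction matrix with per-organism marginals."""

    matrix: pd.DataFrame  # index: organism codes, columns: query reaction ids
    marginals: pd.Series  # reactions per organism (row sums)


def aggregate_by_organism(result: ScreenResult, db: ReactionDatabase) -> TaxonProfile:
    """Mark (organism, query) cells where the organism contributes ≥1
    candidate gene; marginals count reactions, not genes."""
    organisms = sorted(
        code
        for code, org in db.organisms.items()
        if org.taxon_group == result.target_taxon
    )
    queries = sorted(result.candidates)
    mat = pd.DataFrame(0, index=organisms, columns=queries, dtype=int)
    for q, hits in result.candidates.items():
        for cand in hits:
            for org, _gene, _cid in cand.candidate_genes:
                mat.loc[org, q] = 1
    return TaxonProfile(mat, mat.sum(axis=1))


def _read_tree(tree):
    if hasattr(tree, "get_terminals"):
        return tree
    s = str(tree)
    text = s if "(" in s else Path(s).read_text()
    return Phylo.read(io.StringIO(text), "newick")


def clade_rollups(profile: TaxonProfile, tree) -> dict[str, float]:
    """Sum of leaf marginals per clade, keyed by clade name or a stable
    ``node<k>`` id for unnamed internal nodes (preorder numbering)."""
    t = _read_tree(tree)
    rollups: dict[str, float] = {}
    counter = [0]

    def walk(clade) -> float:
        if clade.is_terminal():
            val = float(profile.marginals.get(clade.name, 0))
            rollups[clade.name] = val
            return val
        name = clade.name or f"node{counter[0]}"
        counter[0] += 1
        val = sum(walk(c) for c in clade.clades)
        rollups[name] = val
        return val

    walk(t.root)
    return rollups


def export_itol_heatmap(profile: TaxonProfile, tree, path) -> list[str]:
    """Write an iTOL-style heatmap dataset (plain text, tab separated).

    One DATA line per tree leaf; leaves absent from the profile get
    zero-filled rows and are returned in the warning list.  Output is
    byte-stable for fixed input.
    """
    t = _read_tree(tree)
    leaves = [leaf.name for leaf in t.get_terminals()]
    warnings = []
    lines = [
        "DATASET_HEATMAP",
        "SEPARATOR TAB",
        "DATASET_LABEL\tcandidate reactions",
        "FIELD_LABELS\t" + "\t".join(profile.matrix.columns),
        "DATA",
    ]
    for leaf in leaves:
        if leaf in profile.matrix.index:
            row = profile.matrix.loc[leaf]
            lines.append(leaf + "\t" + "\t".join(str(int(v)) for v in row))
        else:
            warnings.append(f"tree leaf {leaf!r} not in profile; zero-filled")
            lines.append(leaf + "\t" + "\t".join("0" for _ in profile.matrix.columns))
    Path(path).write_text("\n".join(lines) + "\n")
    return warnings


# ---------------------------------------------------------------------------
# Local alignment

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
ALLOWED_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class AlignParams:
    gap_open: int = 11  # BLAST-style: a gap of length L costs gap_open + L*gap_extend
    gap_extend: int = 1


@dataclass(frozen=True)
class AlignmentReport:
    query_id: str
    target_id: str
    score: float
    identity: float  # percent over aligned columns (gap columns included)
    coverage: float  # percent of query spanned by the local alignment
    aligned: bool  # False when no positive-scoring local alignment exists


def _check_sequence(seq: str, label: str) -> None:
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    for pos, ch in enumerate(seq):
        if ch not in ALLOWED_RESIDUES:
            raise ValueError(
                f"{label}: illegal character {ch!r} at position {pos}"
            )


def _subst(a: str, b: str) -> float:
    return float(_BLOSUM62[a, b])


def pairwise_identity(
    a: str,
    b: str,
    params: AlignParams = AlignParams(),
    query_id: str = "query",
    target_id: str = "target",
) -> AlignmentReport:
    """Optimal Smith–Waterman local alignment of protein sequences.

    Affine gaps (a gap of length L costs ``gap_open + L*gap_extend``),
    BLOSUM62 scoring.  Canonical optimum: among co-optimal cells the one with
    the smallest (query, target) end position; traceback prefers substitution
    over a query-consuming gap over a target-consuming gap, and the shortest
    optimal gap.
    """
    a, b = a.upper(), b.upper()
    _check_sequence(a, query_id)
    _check_sequence(b, target_id)
    m, n = len(a), len(b)
    go, ge = params.gap_open, params.gap_extend
    NEG = float("-inf")
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in target (consumes a)
    F = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in query (consumes b)
    best, bi, bj = 0.0, 0, 0
    for i in range(1, m + 1):
        Hi, Hi1 = H[i], H[i - 1]
        Ei, Ei1 = E[i], E[i - 1]
        Fi = F[i]
        ai = a[i - 1]
        for j in range(1, n + 1):
            Ei[j] = max(Hi1[j] - go - ge, Ei1[j] - ge)
            Fi[j] = max(Hi[j - 1] - go - ge, Fi[j - 1] - ge)
            h = max(0.0, Hi1[j - 1] + _subst(ai, b[j - 1]), Ei[j], Fi[j])
            Hi[j] = h
            if h > best:
                best, bi, bj = h, i, j
    if best <= 0:
        return AlignmentReport(query_id, target_id, 0.0, 0.0, 0.0, False)

    # canonical traceback
    i, j = bi, bj
    matches = columns = 0
    state = "H"
    while True:
        if state == "H":
            h = H[i][j]
            if h == 0:
                break
            if i > 0 and j > 0 and h == H[i - 1][j - 1] + _subst(a[i - 1], b[j - 1]):
                columns += 1
                if a[i - 1] == b[j - 1]:
                    matches += 1
                i, j = i - 1, j - 1
            elif h == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            columns += 1
            if E[i][j] == H[i - 1][j] - go - ge:
                i, state = i - 1, "H"
            else:
                i = i - 1
        else:  # F
            columns += 1
            if F[i][j] == H[i][j - 1] - go - ge:
                j, state = j - 1, "H"
            else:
                j = j - 1
    identity = 100.0 * matches / columns if columns else 0.0
    coverage = 100.0 * (bi - i) / m
    return AlignmentReport(query_id, target_id, best, identity, coverage, True)


REPORT_COLUMNS = ("query", "target", "score", "coverage", "identity")


def sequence_independence_report(
    candidates: Mapping[str, str | None],
    known_enzymes: Mapping[str, str],
    path=None,
    params: AlignParams = AlignParams(),
) -> tuple[pd.DataFrame, list[str]]:
    """Align every candidate against every known enzyme.

    Pairs without a positive-scoring local alignment get ``N.A.`` cells;
    candidates lacking a sequence get ``missing`` cells plus a warning.
    """
    rows = []
    warnings = []
    for cand_id in candidates:
        seq = candidates[cand_id]
        for known_id in known_enzymes:
            if seq is None:
                warnings.append(f"no sequence for candidate {cand_id!r}")
                rows.append([cand_id, known_id, "missing", "missing", "missing"])
                continue
            rep = pairwise_identity(
                seq, known_enzymes[known_id], params, cand_id, known_id
            )
            if rep.aligned:
                rows.append(
                    [
                        cand_id,
                        known_id,
                        f"{rep.score:.1f}",
                        f"{rep.coverage:.1f}",
                        f"{rep.identity:.1f}",
                    ]
                )
            else:
                rows.append([cand_id, known_id, "N.A.", "N.A.", "N.A."])
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df, warnings
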