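"""The re-positioning screen.

Every taxon-specific query reaction is scored against every reaction that has
at least one gene in the target taxon group; hits at or above the similarity
threshold are reported together with the target-taxon genes of the hit
reaction's ortholog clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .rdm import RDMConfig, pattern_similarity, reaction_pattern
from .reaction_model import ConfigError, ReactionDatabase
from .taxonomy import find_taxon_specific

DEFAULT_TIERS = (0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass(frozen=True)
class RepositionCandidate:
    query_reaction_id: str
    hit_reaction_id: str
    score: float
    candidate_genes: frozenset[tuple[str, str, str]]  # (organism, gene, cluster)
    ec_of_hit: str | None = None


@dataclass
class ScreenConfig:
    threshold: float = 0.4
    weights: tuple[float, float, float] = (0.5, 0.25, 0.25)
    mcs_size_cap: int = 30
    include_orphans: bool = True
    tiers: tuple[float, ...] = DEFAULT_TIERS
    prefilter: bool = False
    seed: int = 0  # recorded for provenance; the screen itself is deterministic


@dataclass
class ScreenResult:
    query_taxon: str
    target_taxon: str
    config: ScreenConfig
    vocabulary: str
    candidates: dict[str, list[RepositionCandidate]]  # query id -> ranked hits
    all_scores: dict[str, list[tuple[str, float]]]
    warnings: list[str] = field(default_factory=list)

    def max_scores(self) -> dict[str, float]:
        return {
            q: (hits[0].score if hits else 0.0)
            for q, hits in self.candidates.items()
        }


def apply_threshold(
    scored: list[tuple[str, float]], threshold: float
) -> list[tuple[str, float]]:
    """Retain hits with score >= threshold, ranked by (-score, hit id)."""
    kept = [(hid, s) for hid, s in scored if s >= threshold]
    kept.sort(key=lambda x: (-x[1], x[0]))
    return kept


def run_screen(
    db: ReactionDatabase,
    query_taxon: str,
    target_taxon: str,
    threshold: float = 0.4,
    config: ScreenConfig | None = None,
) -> ScreenResult:
    """Score all taxon-specific queries against the target-taxon reaction pool."""
    if threshold < 0:
        raise ConfigError(f"threshold must be nonnegative, got {threshold}")
    config = config or ScreenConfig()
    config.threshold = threshold
    rdm_cfg = RDMConfig(weights=config.weights, mcs_size_cap=config.mcs_size_cap)

    queries = find_taxon_specific(db, query_taxon, config.include_orphans)
    targets = []
    for rid in sorted(db.reactions):
        rx = db.reactions[rid]
        genes = _taxon_genes(rx, target_taxon, db)
        if genes:
            targets.append((rx, genes))

    warnings = []
    if not queries:
        warnings.append(f"no {query_taxon}-specific query reactions in database")
    if not targets:
        warnings.append(f"no reactions with {target_taxon} genes in database")
    if threshold > 1.0:
        warnings.append(
            f"threshold {threshold} exceeds the maximum similarity of 1"
        )

    candidates: dict[str, list[RepositionCandidate]] = {}
    all_scores: dict[str, list[tuple[str, float]]] = {}
    for qa in queries:
        q_rx = db.reactions[qa.reaction_id]
        q_pat = reaction_pattern(q_rx.main_pair, rdm_cfg)
        scored = []
        for t_rx, genes in targets:
            if t_rx.reaction_id == q_rx.reaction_id:
                continue  # never self-hit
            t_pat = reaction_pattern(t_rx.main_pair, rdm_cfg)
            if config.prefilter and _score_bound(q_pat, t_pat, config) < threshold:
                # provably below threshold; sub-threshold value not computed
                scored.append((t_rx.reaction_id, 0.0))
                continue
            s = pattern_similarity(q_pat, t_pat, rdm_cfg.weights)
            scored.append((t_rx.reaction_id, s.value))
        all_scores[qa.reaction_id] = scored
        ranked = apply_threshold(scored, threshold)
        gene_map = {t.reaction_id: g for t, g in targets}
        candidates[qa.reaction_id] = [
            RepositionCandidate(
                qa.reaction_id,
                hid,
                s,
                frozenset(gene_map[hid]),
                db.reactions[hid].ec,
            )
            for hid, s in ranked
        ]
    return ScreenResult(
        query_taxon,
        target_taxon,
        config,
        rdm_cfg.vocabulary,
        candidates,
        all_scores,
        warnings,
    )


def _score_bound(p, q, config: ScreenConfig) -> float:
    """Cheap upper bound on pattern similarity (used by the pre-filter).

    If the two patterns share no reaction-center element, every R component
    is 0 and no triple can exceed w_D + w_M.
    """
    if len(p) == 0 and len(q) == 0:
        return 1.0
    if len(p) == 0 or len(q) == 0:
        return 0.0
    elems_p = {t.r_change[0].split(".")[0] for t in p.triples}
    elems_q = {t.r_change[0].split(".")[0] for t in q.triples}
    if elems_p & elems_q:
        return 1.0
    _w_r, w_d, w_m = config.weights
    return w_d + w_m


def _taxon_genes(rx, taxon_group: str, db) -> set[tuple[str, str, str]]:
    out = set()
    for cid in rx.cluster_ids:
        for org, gene in db.clusters[cid].members:
            if db.organisms[org].taxon_group == taxon_group:
                out.add((org, gene, cid))
    return out


def tier_counts(
    result: ScreenResult, tiers: tuple[float, ...] = DEFAULT_TIERS
) -> list[int]:
    """Number of queries with at least one hit at or above each tier.

    Tiers must be ascending; the returned counts are non-increasing, mirroring
    nested similarity-score regions.
    """
    if list(tiers) != sorted(tiers):
        raise ConfigError("tiers must be ascending")
    if any(t < 0 or t > 1 for t in tiers):
        raise ConfigError("tiers must lie in [0, 1]")
    counts = []
    for t in tiers:
        n = sum(
            1
            for scored in result.all_scores.values()
            if any(s >= t for _hid, s in scored)
        )
        counts.append(n)
    return counts


CANDIDATE_COLUMNS = (
    "query_reaction",
    "hit_reaction",
    "organism",
    "gene",
    "score",
    "cluster",
    "definition",
    "ko",
)


def write_candidate_table(result: ScreenResult, path, db=None) -> None:
    """One row per (candidate hit, gene); scores printed with 3 decimals."""
    lines = ["\t".join(CANDIDATE_COLUMNS)]
    for q in sorted(result.candidates):
        for cand in result.candidates[q]:
            for org, gene, cid in sorted(cand.candidate_genes):
                definition, ko = "", ""
                if db is not None and cid in db.clusters:
                    ann = db.clusters[cid].ko_annotation or ""
                    if ann:
                        ko, _, definition = ann.partition(" ")
                lines.append(
                    "\t".join(
                        [
                            cand.query_reaction_id,
                            cand.hit_reaction_id,
                            org,
                            gene,
                            f"{cand.score:.3f}",
                            cid,
                            definition,
                            ko,
                        ]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


def read_candidate_table(path) -> list[dict]:
    rows = []
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    for line in lines[1:]:
        if not line.strip():
            continue
        rows.append(dict(zip(header, line.split("\t"))))
    return rows
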