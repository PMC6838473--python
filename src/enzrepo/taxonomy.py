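"""Taxon-specificity of reactions from ortholog-cluster membership.

A reaction is *specific* to a taxon group (say, plants) when every gene
annotated to it — via its ortholog clusters — belongs to an organism of that
group.  Reactions without any annotated gene are *orphans*; they can still be
called taxon-specific, but only on explicit pathway evidence, never from the
absence of data.
"""

from __future__ import annotations

from dataclasses import dataclass

from .reaction_model import ConfigError, ReactionDatabase, ReactionRecord


@dataclass(frozen=True)
class TaxonAssignment:
    reaction_id: str
    status: str  # specific | shared | orphan-specific | unassigned
    evidence: tuple[tuple[str, tuple[str, ...]], ...]


def organisms_of(reaction: ReactionRecord, db: ReactionDatabase) -> set[str]:
    """Union of member organisms over the reaction's ortholog clusters."""
    out: set[str] = set()
    for cid in reaction.cluster_ids:
        out.update(org for org, _gene in db.clusters[cid].members)
    return out


def classify_reaction(
    reaction: ReactionRecord,
    taxon_group: str,
    db: ReactionDatabase,
    min_group_fraction: float = 1.0,
) -> TaxonAssignment:
    """Classify one reaction relative to a taxon group.

    ``min_group_fraction`` relaxes the all-members rule (e.g. 0.95 tolerates
    5% stray annotations); the default 1.0 is the strict reading.
    """
    if taxon_group not in db.taxon_groups:
        raise ConfigError(
            f"unknown taxon_group {taxon_group!r}"
            f" (configured: {', '.join(db.taxon_groups)})"
        )
    orgs = organisms_of(reaction, db)
    evidence = tuple(
        (cid, tuple(sorted(org for org, _g in db.clusters[cid].members)))
        for cid in sorted(reaction.cluster_ids)
    )
    if orgs:
        in_group = sum(
            1 for o in orgs if db.organisms[o].taxon_group == taxon_group
        )
        frac = in_group / len(orgs)
        status = "specific" if frac >= min_group_fraction and in_group > 0 else "shared"
        return TaxonAssignment(reaction.reaction_id, status, evidence)
    if reaction.pathway_taxa == frozenset({taxon_group}):
        return TaxonAssignment(
            reaction.reaction_id,
            "orphan-specific",
            (("pathway:" + taxon_group, ()),),
        )
    ev = tuple(("pathway:" + t, ()) for t in sorted(reaction.pathway_taxa))
    return TaxonAssignment(reaction.reaction_id, "unassigned", ev)


def find_taxon_specific(
    db: ReactionDatabase,
    taxon_group: str,
    include_orphans: bool = True,
    min_group_fraction: float = 1.0,
) -> list[TaxonAssignment]:
    """All specific (and optionally orphan-specific) reactions, sorted by ID."""
    wanted = {"specific"} | ({"orphan-specific"} if include_orphans else set())
    out = []
    for rid in sorted(db.reactions):
        a = classify_reaction(
            db.reactions[rid], taxon_group, db, min_group_fraction
        )
        if a.status in wanted:
            out.append(a)
    return out


def write_assignments(assignments, path) -> None:
    lines = ["reaction_id\tstatus\tevidence"]
    for a in assignments:
        ev = ";".join(
            f"{tag}({','.join(orgs)})" if orgs else tag for tag, orgs in a.evidence
        )
        lines.append(f"{a.reaction_id}\t{a.status}\t{ev}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
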