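from __future__ import annotations

import numpy as np
import pytest

from enzrepo.reaction_model import (
    CompoundGraph,
    Organism,
    OrthologCluster,
    ReactantPair,
    ReactionDatabase,
    ReactionRecord,
)


def molblock(elements, bonds, title="mol"):
    """Compose a minimal V2000 molblock (independent of the package writer)."""
    lines = [title, "  test", ""]
    lines.append(
        f"{len(elements):3d}{len(bonds):3d}  0  0  0  0  0  0  0  0999 V2000"
    )
    for el in elements:
        lines.append(f"{'0.0000':>10}{'0.0000':>10}{'0.0000':>10} {el:<3} 0  0")
    for a, b, order in bonds:
        lines.append(f"{a + 1:3d}{b + 1:3d}{order:3d}  0")
    lines.append("M  END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def methane_molblock():
    return molblock(["C", "H", "H", "H", "H"], [(0, i, 1) for i in range(1, 5)])


@pytest.fixture
def benzene_molblock():
    bonds = [(i, (i + 1) % 6, 4) for i in range(6)]
    return molblock(["C"] * 6, bonds, title="benzene")


@pytest.fixture
def ethanol_molblock():
    return molblock(["C", "C", "O"], [(0, 1, 1), (1, 2, 1)], title="ethanol")


def one_atom_pair(sub_id="CS", prod_id="CP"):
    s = CompoundGraph.build(sub_id, ["C"], [])
    p = CompoundGraph.build(prod_id, ["C"], [])
    return ReactantPair(s, p)


def tiny_db(
    reactions: dict[str, tuple[set[str], set[str]]],
    clusters: dict[str, set[tuple[str, str]]],
    organisms: dict[str, str],
) -> ReactionDatabase:
    """Assemble a chemistry-free database for taxonomy/screen plumbing tests.

    ``reactions`` maps reaction_id -> (cluster_ids, pathway_taxa);
    ``organisms`` maps code -> taxon_group.
    """
    orgs = {
        code: Organism(code, code.upper(), group) for code, group in organisms.items()
    }
    cls = {
        cid: OrthologCluster(cid, frozenset(members))
        for cid, members in clusters.items()
    }
    compounds = {}
    rxs = {}
    for rid, (cids, taxa) in reactions.items():
        pair = one_atom_pair(f"{rid}_s", f"{rid}_p")
        compounds[pair.substrate.compound_id] = pair.substrate
        compounds[pair.product.compound_id] = pair.product
        rxs[rid] = ReactionRecord(
            rid, [pair], None, frozenset(cids), frozenset(taxa)
        )
    db = ReactionDatabase(compounds, rxs, cls, orgs)
    db.validate()
    return db


def random_graph(rng: np.random.Generator, lo=3, hi=8, compound_id="G"):
    from enzrepo.synthetic import _random_mol

    return _random_mol(rng, lo, hi).graph(compound_id)
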