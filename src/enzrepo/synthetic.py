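"""Seeded generator of toy reaction databases with planted cross-taxon analogs.

The generator emulates the statistical shape of a taxon-specific screen:
plant-specific reactions (some with planted bacterial analog reactions),
background bacterial reactions, mixed-taxon (shared) reactions, and orphan
plant reactions carrying only pathway evidence.

Planted analogs are constructed to be *exact* reaction analogs at
perturbation level 0: query and analog perform the same single-center
transformation (a bond-order change inside a fixed local motif) on different
scaffolds, so their RDM patterns coincide and the similarity score is exactly
1.  Each planted pair draws a distinct transformation signature from a fixed
pool, and background reactions are restricted to single-bond atom
addition/removal, whose patterns can never tie a planted analog — this makes
rank-1 recovery of the planted pairs a structural guarantee, not a
statistical one.  The perturbation ladder decorates the analog's
reaction-center neighborhood with pendant oxygens, degrading the matched
region (and eventually the center code) one step at a time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .reaction_model import (
    CompoundGraph,
    Organism,
    OrthologCluster,
    ReactantPair,
    ReactionDatabase,
    ReactionRecord,
    write_fasta,
)


class GenerationError(ValueError):
    """Raised when a configuration cannot be realised."""


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_plant_reactions: int = 20
    n_bacterial_reactions: int = 30
    n_shared_reactions: int = 5
    n_orphan_plant_reactions: int = 5
    n_planted_analogs: int = 10
    perturbation_level: int = 0
    compound_size: tuple[int, int] = (4, 12)
    n_plant_organisms: int = 5
    n_bacterial_organisms: int = 8

    def validate(self) -> None:
        counts = (
            self.n_plant_reactions,
            self.n_bacterial_reactions,
            self.n_shared_reactions,
            self.n_orphan_plant_reactions,
            self.n_planted_analogs,
        )
        if any(c < 0 for c in counts):
            raise GenerationError("all counts must be >= 0")
        if self.n_planted_analogs > self.n_plant_reactions:
            raise GenerationError(
                "n_planted_analogs exceeds n_plant_reactions"
            )
        if self.n_planted_analogs > len(SIGNATURE_POOL):
            raise GenerationError(
                f"n_planted_analogs exceeds the signature pool"
                f" ({len(SIGNATURE_POOL)} distinct transformations)"
            )
        if self.perturbation_level > 3:
            raise GenerationError("perturbation_level must be <= 3")
        lo, hi = self.compound_size
        if lo < 3 or hi < lo:
            raise GenerationError("compound_size range too small (min 3)")


def _rng(seed: int, component: int) -> np.random.Generator:
    # documented substream scheme: one spawn key per component, so component
    # counts can change without perturbing the other components' draws
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(component,)))


# ---------------------------------------------------------------------------
# Transformation signatures for planted pairs

#: (hetero element, new bond order, motif shape, direction).  Shape "g3" is a
#: 3-neighbor center; "g4c"/"g4h" add a fourth carbon / hetero neighbor.
SIGNATURE_POOL: list[tuple[str, int, str, str]] = [
    (h, b, g, d)
    for h in ("N", "O", "S")
    for b in (2, 3)
    for g in ("g3", "g4c", "g4h")
    for d in ("fwd", "rev")
]


@dataclass
class _Mol:
    """Mutable molecule under construction."""

    elements: list[str]
    bonds: dict[tuple[int, int], object]

    def add_atom(self, element: str) -> int:
        self.elements.append(element)
        return len(self.elements) - 1

    def add_bond(self, a: int, b: int, order=1) -> None:
        self.bonds[(min(a, b), max(a, b))] = order

    def neighbors(self, i: int) -> list[int]:
        out = []
        for (a, b) in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def copy(self) -> "_Mol":
        return _Mol(list(self.elements), dict(self.bonds))

    def graph(self, compound_id: str) -> CompoundGraph:
        return CompoundGraph.build(
            compound_id,
            self.elements,
            [(a, b, o) for (a, b), o in self.bonds.items()],
        )


_BACKGROUND_ELEMENTS = ("C", "C", "C", "C", "C", "N", "O")  # no sulfur


def _random_mol(rng: np.random.Generator, lo: int, hi: int) -> _Mol:
    """Random connected scaffold: a tree plus up to 2 ring-closing edges."""
    n = int(rng.integers(lo, hi + 1))
    mol = _Mol(["C"], {})
    for _ in range(n - 1):
        parent = int(rng.integers(0, len(mol.elements)))
        el = _BACKGROUND_ELEMENTS[int(rng.integers(0, len(_BACKGROUND_ELEMENTS)))]
        idx = mol.add_atom(el)
        mol.add_bond(parent, idx)
    for _ in range(int(rng.integers(0, 3))):
        if len(mol.elements) < 4:
            break
        a, b = rng.choice(len(mol.elements), size=2, replace=False)
        a, b = int(min(a, b)), int(max(a, b))
        if (a, b) not in mol.bonds:
            mol.add_bond(a, b)
    return mol


def _permuted_graph(
    mol: _Mol, compound_id: str, rng: np.random.Generator
) -> CompoundGraph:
    """Renumber atoms with a random permutation before freezing the graph."""
    n = len(mol.elements)
    perm = list(rng.permutation(n))
    inv = {old: new for new, old in enumerate(perm)}
    elements = [mol.elements[perm[i]] for i in range(n)]
    bonds = [(inv[a], inv[b], o) for (a, b), o in mol.bonds.items()]
    return CompoundGraph.build(compound_id, elements, bonds)


def _background_reaction(
    rng: np.random.Generator, lo: int, hi: int, cid_sub: str, cid_prod: str
) -> ReactantPair:
    """Random single-site atom addition or removal (single bonds only)."""
    mol = _random_mol(rng, lo, hi)
    product = mol.copy()
    leaves = [
        i for i in range(len(mol.elements)) if len(mol.neighbors(i)) == 1
    ]
    do_remove = bool(rng.integers(0, 2)) and len(leaves) > 0 and len(mol.elements) > lo
    if do_remove:
        drop = leaves[int(rng.integers(0, len(leaves)))]
        keep = [i for i in range(len(product.elements)) if i != drop]
        remap = {old: new for new, old in enumerate(keep)}
        product = _Mol(
            [product.elements[i] for i in keep],
            {
                (remap[a], remap[b]): o
                for (a, b), o in product.bonds.items()
                if a != drop and b != drop
            },
        )
    else:
        site = int(rng.integers(0, len(product.elements)))
        el = _BACKGROUND_ELEMENTS[int(rng.integers(0, len(_BACKGROUND_ELEMENTS)))]
        idx = product.add_atom(el)
        product.add_bond(site, idx)
    return ReactantPair(
        _permuted_graph(mol, cid_sub, rng), _permuted_graph(product, cid_prod, rng)
    )


def _motif_mol(
    signature: tuple[str, int, str, str],
    rng: np.random.Generator,
    lo: int,
    hi: int,
    pendants: int = 0,
) -> tuple[_Mol, dict[str, int]]:
    """Build a planted substrate: signature motif + random appendage.

    The motif is a center carbon with neighbors n1 (carbon growth point),
    n2 (carbon, the bond-change target), n3 (the hetero flank) and, for g4
    shapes, n4.  The appendage grows from n1 only; its first shell is
    carbon-only and ring closures avoid paths through the motif, so the type
    codes of the center and its neighbors are fully determined by the
    signature alone.
    """
    h, b, g, d = signature
    mol = _Mol(["C"], {})  # 0 = center
    n1 = mol.add_atom("C")
    n2 = mol.add_atom("C")
    n3 = mol.add_atom(h)
    roles = {"c": 0, "n1": n1, "n2": n2, "n3": n3}
    for nb in (n1, n2, n3):
        mol.add_bond(0, nb)
    if g in ("g4c", "g4h"):
        n4 = mol.add_atom("C" if g == "g4c" else h)
        mol.add_bond(0, n4)
        roles["n4"] = n4
    if d == "rev":
        # reverse direction: the substrate already carries the high bond order
        mol.bonds[(min(0, n2), max(0, n2))] = b
    motif_atoms = set(roles.values())

    # appendage from n1: first shell carbon, deeper atoms free, no S
    budget = max(0, int(rng.integers(lo, hi + 1)) - len(mol.elements) - pendants)
    shell1: set[int] = set()
    deep: list[int] = []
    attach_points = [n1]
    for _ in range(budget):
        parent = attach_points[int(rng.integers(0, len(attach_points)))]
        if parent == n1:
            el = "C"
        else:
            el = _BACKGROUND_ELEMENTS[int(rng.integers(0, len(_BACKGROUND_ELEMENTS)))]
        idx = mol.add_atom(el)
        mol.add_bond(parent, idx)
        if parent == n1:
            shell1.add(idx)
        else:
            deep.append(idx)
        attach_points.append(idx)
    # optional ring closure strictly inside the appendage's deep region
    if len(deep) >= 3 and rng.integers(0, 2):
        a, bb = rng.choice(deep, size=2, replace=False)
        a, bb = int(min(a, bb)), int(max(a, bb))
        if (a, bb) not in mol.bonds and not _path_hits(
            mol, a, bb, motif_atoms | shell1
        ):
            mol.add_bond(a, bb)
    return mol, roles


def _path_hits(mol: _Mol, a: int, b: int, forbidden: set[int]) -> bool:
    """Does the (unique pre-closure tree) path a..b pass through forbidden atoms?"""
    import networkx as nx

    g = nx.Graph(list(mol.bonds))
    g.add_nodes_from(range(len(mol.elements)))
    try:
        path = nx.shortest_path(g, a, b)
    except nx.NetworkXNoPath:
        return True
    return any(p in forbidden for p in path[1:-1])


_PERTURBATION_ORDER = ("n1", "n3", "n2")


def _planted_pair(
    signature: tuple[str, int, str, str],
    rng: np.random.Generator,
    lo: int,
    hi: int,
    cid_sub: str,
    cid_prod: str,
    perturbation: int = 0,
) -> ReactantPair:
    """One reaction realising a signature; optional perturbation edits.

    Perturbation edit k attaches a pendant oxygen to the k-th atom of
    (n1, n3, n2), changing one matched-region entry per level (and, at level
    3, the second center's own code).
    """
    mol, roles = _motif_mol(signature, rng, lo, hi, pendants=perturbation)
    for k in range(perturbation):
        target = roles[_PERTURBATION_ORDER[k]]
        o = mol.add_atom("O")
        mol.add_bond(target, o)
    product = mol.copy()
    h, b, g, d = signature
    c, n2 = roles["c"], roles["n2"]
    key = (min(c, n2), max(c, n2))
    product.bonds[key] = 1 if d == "rev" else b
    return ReactantPair(
        _permuted_graph(mol, cid_sub, rng), _permuted_graph(product, cid_prod, rng)
    )


# ---------------------------------------------------------------------------
# Database assembly


def _organisms(config: GeneratorConfig) -> dict[str, Organism]:
    orgs = {}
    families = ("Actinomycetia", "Gammaproteobacteria", "Bacilli")
    for i in range(config.n_plant_organisms):
        code = f"pln{i:02d}"
        orgs[code] = Organism(
            code,
            f"Planta synthetica {i}",
            "plant",
            ("Eukaryota", "Viridiplantae", f"Cladus{i % 2}"),
        )
    for i in range(config.n_bacterial_organisms):
        code = f"bac{i:02d}"
        orgs[code] = Organism(
            code,
            f"Bacterium fictum {i}",
            "bacteria",
            ("Bacteria", families[i % len(families)], f"Genus{i}"),
        )
    return orgs


def generate_database(
    config: GeneratorConfig,
) -> tuple[ReactionDatabase, dict]:
    """Generate a complete toy database plus a ground-truth manifest.

    The manifest lists every planted (query, analog) pair with its signature
    and the perturbation level applied.
    """
    config.validate()
    lo, hi = config.compound_size
    organisms = _organisms(config)
    plant_codes = sorted(c for c, o in organisms.items() if o.taxon_group == "plant")
    bact_codes = sorted(c for c, o in organisms.items() if o.taxon_group == "bacteria")
    if config.n_plant_reactions and not plant_codes:
        raise GenerationError("plant reactions requested but no plant organisms")
    if (config.n_bacterial_reactions or config.n_planted_analogs) and not bact_codes:
        raise GenerationError("bacterial reactions requested but no bacterial organisms")

    compounds: dict[str, CompoundGraph] = {}
    clusters: dict[str, OrthologCluster] = {}
    reactions: dict[str, ReactionRecord] = {}

    def add_reaction(rx: ReactionRecord) -> None:
        if rx.reaction_id in reactions:
            raise GenerationError(f"duplicate reaction id {rx.reaction_id}")
        reactions[rx.reaction_id] = rx

    counters = {"compound": 0, "cluster": 0, "gene": 0}

    def new_cid() -> str:
        counters["compound"] += 1
        return f"C{counters['compound']:04d}"

    def register(pair: ReactantPair) -> ReactantPair:
        compounds[pair.substrate.compound_id] = pair.substrate
        compounds[pair.product.compound_id] = pair.product
        return pair

    def new_cluster(codes, rng, n_genes=2, ko=None) -> str:
        counters["cluster"] += 1
        cid = f"OC{counters['cluster']:04d}"
        members = set()
        for _ in range(n_genes):
            org = codes[int(rng.integers(0, len(codes)))]
            counters["gene"] += 1
            members.add((org, f"{org}_g{counters['gene']:04d}"))
        clusters[cid] = OrthologCluster(cid, frozenset(members), ko)
        return cid

    def random_ec(rng) -> str:
        return f"1.14.{int(rng.integers(11, 20))}.{int(rng.integers(1, 99))}"

    manifest_pairs = []

    # plant-specific reactions; the first n_planted carry planted signatures
    rng_p = _rng(config.seed, 1)
    plant_sigs = []
    sig_order = rng_p.permutation(len(SIGNATURE_POOL))
    for i in range(config.n_plant_reactions):
        rid = f"RP{i:03d}"
        if i < config.n_planted_analogs:
            sig = SIGNATURE_POOL[int(sig_order[i])]
            plant_sigs.append(sig)
            pair = register(
                _planted_pair(sig, rng_p, lo, hi, new_cid(), new_cid())
            )
        else:
            pair = register(_background_reaction(rng_p, lo, hi, new_cid(), new_cid()))
        cid = new_cluster(
            plant_codes,
            rng_p,
            n_genes=int(rng_p.integers(1, 4)),
            ko=f"K{int(rng_p.integers(10000, 20000)):05d} synthetic plant enzyme {i}",
        )
        add_reaction(
            ReactionRecord(rid, [pair], random_ec(rng_p), frozenset({cid}))
        )

    # planted bacterial analogs (same signatures, different scaffolds)
    rng_a = _rng(config.seed, 5)
    for i, sig in enumerate(plant_sigs):
        rid = f"RA{i:03d}"
        pair = register(
            _planted_pair(
                sig,
                rng_a,
                lo,
                hi,
                new_cid(),
                new_cid(),
                perturbation=config.perturbation_level,
            )
        )
        cid = new_cluster(
            bact_codes,
            rng_a,
            n_genes=int(rng_a.integers(1, 4)),
            ko=f"K{int(rng_a.integers(0, 10000)):05d} synthetic monooxygenase {i}",
        )
        add_reaction(
            ReactionRecord(rid, [pair], random_ec(rng_a), frozenset({cid}))
        )
        manifest_pairs.append(
            {
                "query": f"RP{i:03d}",
                "analog": rid,
                "signature": list(sig),
                "perturbation": config.perturbation_level,
            }
        )

    # background bacterial reactions
    rng_b = _rng(config.seed, 2)
    for i in range(config.n_bacterial_reactions):
        rid = f"RB{i:03d}"
        pair = register(_background_reaction(rng_b, lo, hi, new_cid(), new_cid()))
        cid = new_cluster(
            bact_codes,
            rng_b,
            n_genes=int(rng_b.integers(1, 4)),
            ko=f"K{int(rng_b.integers(0, 10000)):05d} synthetic bacterial enzyme {i}",
        )
        add_reaction(
            ReactionRecord(rid, [pair], random_ec(rng_b), frozenset({cid}))
        )

    # shared reactions: clusters spanning both taxa
    rng_s = _rng(config.seed, 3)
    for i in range(config.n_shared_reactions):
        rid = f"RS{i:03d}"
        pair = register(_background_reaction(rng_s, lo, hi, new_cid(), new_cid()))
        counters["cluster"] += 1
        cid = f"OC{counters['cluster']:04d}"
        members = set()
        for codes in (plant_codes, bact_codes):
            org = codes[int(rng_s.integers(0, len(codes)))]
            counters["gene"] += 1
            members.add((org, f"{org}_g{counters['gene']:04d}"))
        clusters[cid] = OrthologCluster(
            cid, frozenset(members), f"K{int(rng_s.integers(0, 10000)):05d} shared enzyme {i}"
        )
        add_reaction(
            ReactionRecord(rid, [pair], random_ec(rng_s), frozenset({cid}))
        )

    # orphan plant reactions: no clusters, pathway evidence only
    rng_o = _rng(config.seed, 4)
    for i in range(config.n_orphan_plant_reactions):
        rid = f"RO{i:03d}"
        pair = register(_background_reaction(rng_o, lo, hi, new_cid(), new_cid()))
        add_reaction(
            ReactionRecord(
                rid,
                [pair],
                random_ec(rng_o),
                frozenset(),
                pathway_taxa=frozenset({"plant"}),
            )
        )

    db = ReactionDatabase(
        compounds,
        reactions,
        clusters,
        organisms,
        provenance=f"synthetic(seed={config.seed})",
    )
    db.validate()
    manifest = {
        "seed": config.seed,
        "config": {k: list(v) if isinstance(v, tuple) else v for k, v in asdict(config).items()},
        "planted": manifest_pairs,
    }
    return db, manifest


def manifest_json(manifest: dict) -> str:
    """Canonical manifest serialisation (stable key order, trailing newline)."""
    return json.dumps(manifest, indent=2, sort_keys=True) + "\n"


def star_newick(organism_codes) -> str:
    """Star tree over the given organisms, unit branch lengths."""
    return "(" + ",".join(f"{c}:1" for c in sorted(organism_codes)) + ")root;"


# ---------------------------------------------------------------------------
# Protein fixtures

_AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(_AA[int(i)] for i in rng.integers(0, len(_AA), size=length))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = []
    for ch in seq:
        if rng.random() < rate:
            choices = _AA.replace(ch, "")
            out.append(choices[int(rng.integers(0, len(choices)))])
        else:
            out.append(ch)
    return "".join(out)


def generate_fasta(
    seed: int,
    n_known: int = 3,
    rates: tuple[float, ...] = (0.0, 0.2, 0.4, None),
    length: int = 300,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], list[dict]]:
    """Known-enzyme and candidate protein sets with controlled identity.

    Each entry in ``rates`` yields one candidate: a mutated copy of a known
    enzyme at that substitution rate (expected identity ≈ 100·(1−rate)), or an
    unrelated random sequence when the rate is None.  Returns (knowns,
    candidates, truth records).
    """
    rng = _rng(seed, 6)
    knowns = [(f"KNOWN{i}", _random_protein(rng, length)) for i in range(n_known)]
    candidates = []
    truth = []
    for i, rate in enumerate(rates):
        cid = f"CAND{i}"
        if rate is None:
            candidates.append((cid, _random_protein(rng, length)))
            truth.append({"candidate": cid, "known": None, "rate": None})
        else:
            src = knowns[i % n_known]
            candidates.append((cid, _mutate(src[1], rate, rng)))
            truth.append({"candidate": cid, "known": src[0], "rate": rate})
    return knowns, candidates, truth


# ---------------------------------------------------------------------------
# On-disk fixture bundles


def write_fixture_bundle(config: GeneratorConfig, out_dir) -> dict:
    """Generate and write a complete fixture directory (SDF, TSVs, FASTA,
    Newick star tree, manifest JSON).  Returns the manifest."""
    from .reaction_model import save_database

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    db, manifest = generate_database(config)
    save_database(db, out)
    (out / "manifest.json").write_text(manifest_json(manifest))
    bact = [c for c, o in db.organisms.items() if o.taxon_group == "bacteria"]
    (out / "tree.nwk").write_text(star_newick(bact) + "\n")
    knowns, cands, _ = generate_fasta(config.seed)
    write_fasta(knowns, out / "known_enzymes.fasta")
    write_fasta(cands, out / "candidates.fasta")
    return manifest
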