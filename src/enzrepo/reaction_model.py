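"""Data model and I/O for compounds, reactions, ortholog clusters and organisms.

Compounds are heavy-atom molecular graphs (hydrogens implicit) whose atoms
carry deterministic KEGG-style environment type codes of the form
``ELEMENT.hyb.ring.het`` — see :func:`atom_type_code`.  Reactions tie a main
substrate/product compound pair to EC numbers and ortholog-cluster IDs, which
in turn tie them to organisms and taxon groups.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

#: Version tag for the atom-type vocabulary.  Similarity scores are only
#: comparable between patterns produced under the same vocabulary.
VOCABULARY_VERSION = "envcode-1"

DEFAULT_TAXON_GROUPS = ("plant", "bacteria", "other")

AROMATIC = "ar"
BondOrder = object  # 1 | 2 | 3 | "ar"


class ParseError(ValueError):
    """Raised when an input file cannot be parsed."""


class IntegrityError(ValueError):
    """Raised when cross-references in a database do not resolve."""


class ConfigError(ValueError):
    """Raised for invalid configuration values."""


# ---------------------------------------------------------------------------
# Compound graphs


@dataclass(frozen=True)
class Atom:
    index: int
    element: str
    atom_type: str | None
    ring_flag: bool


@dataclass(frozen=True)
class Bond:
    a: int
    b: int
    order: object  # 1, 2, 3 or "ar"

    def __post_init__(self):
        if self.a == self.b:
            raise ValueError(f"self-bond on atom {self.a}")
        if self.a > self.b:
            lo, hi = self.b, self.a
            object.__setattr__(self, "a", lo)
            object.__setattr__(self, "b", hi)
        if self.order not in (1, 2, 3, AROMATIC):
            raise ValueError(f"bad bond order {self.order!r}")


def _normalize_bond(a: int, b: int, order) -> Bond:
    lo, hi = (a, b) if a < b else (b, a)
    return Bond(lo, hi, order)


class CompoundGraph:
    """Immutable typed molecular graph over heavy atoms."""

    __slots__ = ("compound_id", "atoms", "bonds", "_adj", "_sig")

    def __init__(self, compound_id: str, atoms: Sequence[Atom], bonds: Iterable[Bond]):
        self.compound_id = compound_id
        self.atoms = tuple(atoms)
        self.bonds = frozenset(bonds)
        n = len(self.atoms)
        if [a.index for a in self.atoms] != list(range(n)):
            raise ValueError("atom indices must be 0..n-1 without gaps")
        seen = set()
        adj: dict[int, dict[int, object]] = {i: {} for i in range(n)}
        for b in self.bonds:
            if not (0 <= b.a < n and 0 <= b.b < n):
                raise ValueError(f"bond {b} references missing atom")
            if (b.a, b.b) in seen:
                raise ValueError(f"duplicate bond {b.a}-{b.b}")
            seen.add((b.a, b.b))
            adj[b.a][b.b] = b.order
            adj[b.b][b.a] = b.order
        self._adj = adj
        self._sig = None

    # -- queries ----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.atoms)

    def neighbors(self, i: int) -> list[int]:
        return sorted(self._adj[i])

    def bond_order(self, i: int, j: int):
        return self._adj[i].get(j)

    def has_bond(self, i: int, j: int) -> bool:
        return j in self._adj[i]

    def element(self, i: int) -> str:
        return self.atoms[i].element

    def atom_type(self, i: int) -> str:
        t = self.atoms[i].atom_type
        if t is None:
            raise ValueError("atom types not assigned; call assign_atom_types")
        return t

    def signature(self) -> str:
        """Content hash over elements, bonds and types (index-order sensitive)."""
        if self._sig is None:
            payload = json.dumps(
                [
                    [(a.element, a.atom_type, a.ring_flag) for a in self.atoms],
                    sorted((b.a, b.b, str(b.order)) for b in self.bonds),
                ],
                separators=(",", ":"),
            )
            self._sig = hashlib.sha1(payload.encode()).hexdigest()
        return self._sig

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"CompoundGraph({self.compound_id!r}, {len(self.atoms)} atoms, {len(self.bonds)} bonds)"

    # -- construction -----------------------------------------------------
    @staticmethod
    def build(
        compound_id: str,
        elements: Sequence[str],
        bonds: Iterable[tuple[int, int, object]],
    ) -> "CompoundGraph":
        """Build from raw element symbols and (a, b, order) bonds.

        Ring flags are perceived (an atom is in a ring iff it lies on some
        cycle) and atom types assigned.
        """
        blist = [_normalize_bond(a, b, o) for a, b, o in bonds]
        ring = _ring_flags(len(elements), blist)
        atoms = [
            Atom(i, el, None, ring[i]) for i, el in enumerate(elements)
        ]
        return assign_atom_types(CompoundGraph(compound_id, atoms, blist))


def _ring_flags(n: int, bonds: Sequence[Bond]) -> list[bool]:
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from((b.a, b.b) for b in bonds)
    bridges = set(frozenset(e) for e in nx.bridges(g))
    flags = [False] * n
    for b in bonds:
        if frozenset((b.a, b.b)) not in bridges:
            flags[b.a] = True
            flags[b.b] = True
    return flags


_HETERO_EXEMPT = {"C", "H"}


def atom_type_code(element: str, hyb: str, in_ring: bool, n_hetero: int) -> str:
    """Compose an ``ELEMENT.hyb.ring.het`` environment code.

    hyb ∈ {sp3, sp2, ar, sp}: ar if any incident aromatic bond; sp for a
    triple bond or cumulated doubles; sp2 for a double bond; else sp3.
    ring ∈ {rg, ac}; het ∈ {h0, h1, h2+} counts non-carbon heavy neighbors.
    """
    het = "h0" if n_hetero == 0 else ("h1" if n_hetero == 1 else "h2+")
    return f"{element}.{hyb}.{'rg' if in_ring else 'ac'}.{het}"


def assign_atom_types(graph: CompoundGraph) -> CompoundGraph:
    """Return a copy with deterministic atom type codes assigned (idempotent)."""
    atoms = []
    for a in graph.atoms:
        orders = [graph.bond_order(a.index, j) for j in graph.neighbors(a.index)]
        if AROMATIC in orders:
            hyb = "ar"
        elif 3 in orders or orders.count(2) >= 2:
            hyb = "sp"
        elif 2 in orders:
            hyb = "sp2"
        else:
            hyb = "sp3"
        n_het = sum(
            1
            for j in graph.neighbors(a.index)
            if graph.element(j) not in _HETERO_EXEMPT
        )
        atoms.append(
            replace(a, atom_type=atom_type_code(a.element, hyb, a.ring_flag, n_het))
        )
    return CompoundGraph(graph.compound_id, atoms, graph.bonds)


# ---------------------------------------------------------------------------
# Molfile / SDF / SMILES

_RDKIT_ORDER = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: AROMATIC,
}
_TO_RDKIT_ORDER = {v: k for k, v in _RDKIT_ORDER.items()}

_PERIODIC = Chem.GetPeriodicTable()


def _precheck_molblock(text: str) -> None:
    lines = text.splitlines()
    if len(lines) < 4:
        raise ParseError("molfile too short: no counts line (line 4)")
    counts = lines[3]
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except (ValueError, IndexError):
        raise ParseError("malformed counts line at line 4") from None
    if len(lines) < 4 + n_atoms + n_bonds:
        raise ParseError(
            f"atom/bond count mismatch: counts line declares {n_atoms} atoms"
            f" and {n_bonds} bonds at line 4, file has {len(lines)} lines"
        )
    for k in range(n_atoms):
        line = lines[4 + k]
        sym = line[31:34].strip() if len(line) > 31 else ""
        try:
            ok = bool(sym) and _PERIODIC.GetAtomicNumber(sym) > 0
        except Exception:
            ok = False
        if not ok:
            raise ParseError(f"unknown element symbol {sym!r} at line {5 + k}")


def _graph_from_rdkit(mol: Chem.Mol, compound_id: str) -> CompoundGraph:
    keep = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() != 1]
    remap = {old: new for new, old in enumerate(keep)}
    elements = [mol.GetAtomWithIdx(i).GetSymbol() for i in keep]
    bonds = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in remap and j in remap:
            bonds.append((remap[i], remap[j], _RDKIT_ORDER[b.GetBondType()]))
    return CompoundGraph.build(compound_id, elements, bonds)


def parse_compound(text: str, compound_id: str) -> CompoundGraph:
    """Parse a V2000 molblock into a typed heavy-atom graph.

    Explicit hydrogens are stripped; coordinates and stereo flags ignored.
    """
    _precheck_molblock(text)
    mol = Chem.MolFromMolBlock(text, sanitize=False, removeHs=False)
    if mol is None:
        raise ParseError("RDKit could not parse molblock")
    return _graph_from_rdkit(mol, compound_id)


def parse_smiles(smiles: str, compound_id: str) -> CompoundGraph:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"invalid SMILES {smiles!r}")
    return _graph_from_rdkit(mol, compound_id)


def read_sdf(path) -> list[CompoundGraph]:
    """Read a multi-record SDF; compound IDs come from the record title line."""
    text = Path(path).read_text()
    graphs = []
    for block in text.split("$$$$"):
        if not block.strip():
            continue
        block = block.lstrip("\n")
        name = block.splitlines()[0].strip()
        mol_end = block.find("M  END")
        molblock = block[: mol_end + 6] if mol_end >= 0 else block
        graphs.append(parse_compound(molblock, name or f"MOL{len(graphs)}"))
    return graphs


def to_molblock(graph: CompoundGraph) -> str:
    mol = Chem.RWMol()
    for a in graph.atoms:
        at = Chem.Atom(a.element)
        at.SetNoImplicit(True)
        mol.AddAtom(at)
    for b in sorted(graph.bonds, key=lambda b: (b.a, b.b)):
        mol.AddBond(b.a, b.b, _TO_RDKIT_ORDER[b.order])
    m = mol.GetMol()
    m.SetProp("_Name", graph.compound_id)
    return Chem.MolToMolBlock(m, kekulize=False)


def write_sdf(graphs: Iterable[CompoundGraph], path) -> None:
    with open(path, "w") as fh:
        for g in graphs:
            fh.write(to_molblock(g))
            fh.write("$$$$\n")


# ---------------------------------------------------------------------------
# Reactions, clusters, organisms


@dataclass(frozen=True)
class AtomMapping:
    """Injective substrate→product atom correspondence."""

    pairs: tuple[tuple[int, int], ...]
    score: int
    mode: str = "exact"

    def __post_init__(self):
        object.__setattr__(self, "pairs", tuple(sorted(self.pairs)))
        s = [p[0] for p in self.pairs]
        t = [p[1] for p in self.pairs]
        if len(set(s)) != len(s) or len(set(t)) != len(t):
            raise ValueError("mapping is not injective")

    def as_dict(self) -> dict[int, int]:
        return dict(self.pairs)


@dataclass
class ReactantPair:
    substrate: CompoundGraph
    product: CompoundGraph
    mapping: AtomMapping | None = None

    def key(self) -> tuple[str, str]:
        return (self.substrate.signature(), self.product.signature())


@dataclass
class ReactionRecord:
    reaction_id: str
    pairs: list[ReactantPair]
    ec: str | None = None
    cluster_ids: frozenset[str] = frozenset()
    pathway_taxa: frozenset[str] = frozenset()
    context_compounds: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.pairs:
            raise ValueError(f"reaction {self.reaction_id} has no reactant pair")
        self.cluster_ids = frozenset(self.cluster_ids)
        self.pathway_taxa = frozenset(self.pathway_taxa)

    @property
    def main_pair(self) -> ReactantPair:
        return self.pairs[0]

    def is_orphan(self) -> bool:
        return not self.cluster_ids


@dataclass(frozen=True)
class OrthologCluster:
    cluster_id: str
    members: frozenset[tuple[str, str]]  # (organism_code, gene_id)
    ko_annotation: str | None = None

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"cluster {self.cluster_id} has no members")


@dataclass(frozen=True)
class Organism:
    code: str
    name: str
    taxon_group: str
    lineage: tuple[str, ...] = ()


class ReactionDatabase:
    """Keyed collections of compounds, reactions, clusters and organisms."""

    def __init__(
        self,
        compounds: Mapping[str, CompoundGraph] | None = None,
        reactions: Mapping[str, ReactionRecord] | None = None,
        clusters: Mapping[str, OrthologCluster] | None = None,
        organisms: Mapping[str, Organism] | None = None,
        taxon_groups: Sequence[str] = DEFAULT_TAXON_GROUPS,
        provenance: str = "",
    ):
        self.compounds = dict(compounds or {})
        self.reactions = dict(reactions or {})
        self.clusters = dict(clusters or {})
        self.organisms = dict(organisms or {})
        self.taxon_groups = tuple(taxon_groups)
        self.provenance = provenance

    def validate(self) -> None:
        """Check referential integrity; raise IntegrityError listing offenders."""
        problems = []
        for org in self.organisms.values():
            if org.taxon_group not in self.taxon_groups:
                problems.append(
                    f"organism {org.code}: unknown taxon_group {org.taxon_group!r}"
                    f" (configured: {', '.join(self.taxon_groups)})"
                )
        for cl in self.clusters.values():
            for org_code, _gene in sorted(cl.members):
                if org_code not in self.organisms:
                    problems.append(
                        f"cluster {cl.cluster_id}: unknown organism {org_code!r}"
                    )
        for rx in self.reactions.values():
            for cid in sorted(rx.cluster_ids):
                if cid not in self.clusters:
                    problems.append(f"reaction {rx.reaction_id}: unknown cluster {cid!r}")
            for pair in rx.pairs:
                for g in (pair.substrate, pair.product):
                    if g.compound_id not in self.compounds:
                        problems.append(
                            f"reaction {rx.reaction_id}: unknown compound"
                            f" {g.compound_id!r}"
                        )
        if problems:
            raise IntegrityError("; ".join(problems))

    def add_reaction(self, rx: ReactionRecord) -> None:
        if rx.reaction_id in self.reactions:
            raise IntegrityError(f"duplicate reaction_id {rx.reaction_id!r}")
        self.reactions[rx.reaction_id] = rx


# ---------------------------------------------------------------------------
# Tabular I/O

REACTION_TSV_COLUMNS = (
    "reaction_id",
    "substrate_id",
    "product_id",
    "ec",
    "cluster_ids",
    "pathway_taxa",
)


@dataclass(frozen=True)
class RawReaction:
    """A reaction table row before compound references are resolved."""

    reaction_id: str
    substrate_id: str
    product_id: str
    ec: str | None
    cluster_ids: frozenset[str]
    pathway_taxa: frozenset[str] = frozenset()
    context_compounds: tuple[str, ...] = ()


def _split_multi(cell: str) -> frozenset[str]:
    cell = cell.strip()
    return frozenset(x for x in cell.split(";") if x) if cell else frozenset()


def read_reaction_table(path, dialect: str = "tsv") -> list[RawReaction]:
    """Read a reaction table in the ``tsv``, ``json`` or ``kegg-flat`` dialect."""
    if dialect not in ("tsv", "json", "kegg-flat"):
        raise ConfigError(f"unsupported dialect {dialect!r}")
    text = Path(path).read_text()
    if dialect == "tsv":
        rows = _parse_reaction_tsv(text)
    elif dialect == "json":
        rows = _parse_reaction_json(text)
    else:
        rows = _parse_kegg_flat(text)
    seen = set()
    for r in rows:
        if r.reaction_id in seen:
            raise ParseError(f"duplicate reaction_id {r.reaction_id!r}")
        seen.add(r.reaction_id)
    return rows


def _parse_reaction_tsv(text: str) -> list[RawReaction]:
    rows = []
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if parts[0] == "reaction_id":
            continue
        if len(parts) < 5:
            raise ParseError(f"line {lineno}: expected ≥5 tab-separated columns")
        rid, sub, prod, ec, clusters = parts[:5]
        taxa = parts[5] if len(parts) > 5 else ""
        rows.append(
            RawReaction(
                rid,
                sub,
                prod,
                ec or None,
                _split_multi(clusters),
                _split_multi(taxa),
            )
        )
    return rows


def _parse_reaction_json(text: str) -> list[RawReaction]:
    data = json.loads(text)
    rows = []
    for obj in data:
        rows.append(
            RawReaction(
                obj["reaction_id"],
                obj["substrate_id"],
                obj["product_id"],
                obj.get("ec"),
                frozenset(obj.get("cluster_ids", [])),
                frozenset(obj.get("pathway_taxa", [])),
                tuple(obj.get("context_compounds", [])),
            )
        )
    return rows


def _parse_kegg_flat(text: str) -> list[RawReaction]:
    """Parse ENTRY/EQUATION/ENZYME/ORTHOLOGY blocks separated by ///."""
    rows = []
    for block in text.split("///"):
        if not block.strip():
            continue
        fields: dict[str, list[str]] = {}
        key = None
        for line in block.splitlines():
            if not line.strip():
                continue
            head = line[:12].strip()
            if head:
                key = head
                fields.setdefault(key, [])
            if key:
                fields[key].append(line[12:].strip())
        if "ENTRY" not in fields or "EQUATION" not in fields:
            raise ParseError("KEGG block missing ENTRY or EQUATION")
        rid = fields["ENTRY"][0].split()[0]
        eq = " ".join(fields["EQUATION"])
        if "<=>" not in eq:
            raise ParseError(f"{rid}: EQUATION lacks '<=>'")
        left, right = eq.split("<=>")

        def _compounds(side: str) -> list[str]:
            out = []
            for term in side.split("+"):
                toks = term.split()
                if toks:
                    out.append(toks[-1])
            return out

        subs, prods = _compounds(left), _compounds(right)
        if not subs or not prods:
            raise ParseError(f"{rid}: empty equation side")
        ec = fields.get("ENZYME", [None])[0]
        clusters = frozenset(
            line.split()[0] for line in fields.get("ORTHOLOGY", []) if line
        )
        rows.append(
            RawReaction(
                rid,
                subs[0],
                prods[0],
                ec,
                clusters,
                frozenset(),
                tuple(subs[1:] + prods[1:]),
            )
        )
    return rows


def write_reaction_table(rows: Iterable[RawReaction | ReactionRecord], path) -> None:
    """Write the canonical TSV form (rows sorted by reaction_id)."""
    out = io.StringIO()
    out.write("\t".join(REACTION_TSV_COLUMNS) + "\n")
    canon = []
    for r in rows:
        if isinstance(r, ReactionRecord):
            canon.append(
                RawReaction(
                    r.reaction_id,
                    r.main_pair.substrate.compound_id,
                    r.main_pair.product.compound_id,
                    r.ec,
                    r.cluster_ids,
                    r.pathway_taxa,
                    r.context_compounds,
                )
            )
        else:
            canon.append(r)
    for r in sorted(canon, key=lambda x: x.reaction_id):
        out.write(
            "\t".join(
                [
                    r.reaction_id,
                    r.substrate_id,
                    r.product_id,
                    r.ec or "",
                    ";".join(sorted(r.cluster_ids)),
                    ";".join(sorted(r.pathway_taxa)),
                ]
            )
            + "\n"
        )
    Path(path).write_text(out.getvalue())


def read_cluster_table(path) -> dict[str, OrthologCluster]:
    """TSV columns: cluster_id, organism_code, gene_id, ko_annotation (optional).

    One row per member gene; the annotation of the first row of a cluster wins.
    """
    members: dict[str, set[tuple[str, str]]] = {}
    annot: dict[str, str | None] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#") or line.startswith("cluster_id\t"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"line {lineno}: expected ≥3 columns")
        cid, org, gene = parts[:3]
        members.setdefault(cid, set()).add((org, gene))
        annot.setdefault(cid, parts[3] if len(parts) > 3 and parts[3] else None)
    return {
        cid: OrthologCluster(cid, frozenset(m), annot[cid])
        for cid, m in members.items()
    }


def write_cluster_table(clusters: Mapping[str, OrthologCluster], path) -> None:
    lines = ["cluster_id\torganism\tgene\tko"]
    for cid in sorted(clusters):
        cl = clusters[cid]
        for org, gene in sorted(cl.members):
            lines.append(f"{cid}\t{org}\t{gene}\t{cl.ko_annotation or ''}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_organism_table(
    path, taxon_groups: Sequence[str] = DEFAULT_TAXON_GROUPS
) -> dict[str, Organism]:
    """TSV columns: code, name, taxon_group, lineage (semicolon-joined)."""
    orgs: dict[str, Organism] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#") or line.startswith("code\t"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"line {lineno}: expected ≥3 columns")
        code, name, group = parts[:3]
        if group not in taxon_groups:
            raise IntegrityError(
                f"line {lineno}: unknown taxon_group {group!r}"
                f" (configured: {', '.join(taxon_groups)})"
            )
        lineage = tuple(x for x in (parts[3].split(";") if len(parts) > 3 else []) if x)
        if code in orgs:
            raise ParseError(f"duplicate organism code {code!r}")
        orgs[code] = Organism(code, name, group, lineage)
    return orgs


def write_organism_table(organisms: Mapping[str, Organism], path) -> None:
    lines = ["code\tname\ttaxon_group\tlineage"]
    for code in sorted(organisms):
        o = organisms[code]
        lines.append(f"{code}\t{o.name}\t{o.taxon_group}\t{';'.join(o.lineage)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fasta(path) -> list[tuple[str, str]]:
    """Read protein FASTA; IDs are the first whitespace token of each header."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"empty FASTA file {path}")
    out = []
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise ParseError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        out.append((rec.id, str(rec.seq).upper()))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Assembly


def assemble_database(
    compounds: Mapping[str, CompoundGraph],
    raw_reactions: Iterable[RawReaction],
    clusters: Mapping[str, OrthologCluster],
    organisms: Mapping[str, Organism],
    taxon_groups: Sequence[str] = DEFAULT_TAXON_GROUPS,
    provenance: str = "",
) -> ReactionDatabase:
    """Resolve raw reaction rows against compounds and validate integrity."""
    db = ReactionDatabase(
        compounds, {}, clusters, organisms, taxon_groups, provenance
    )
    missing = []
    for r in raw_reactions:
        sub = compounds.get(r.substrate_id)
        prod = compounds.get(r.product_id)
        if sub is None or prod is None:
            missing.extend(
                cid
                for cid, g in ((r.substrate_id, sub), (r.product_id, prod))
                if g is None
            )
            continue
        db.add_reaction(
            ReactionRecord(
                r.reaction_id,
                [ReactantPair(sub, prod)],
                r.ec,
                r.cluster_ids,
                r.pathway_taxa,
                r.context_compounds,
            )
        )
    if missing:
        raise IntegrityError(
            "unresolvable compounds: " + ", ".join(sorted(set(missing)))
        )
    db.validate()
    return db


def save_database(db: ReactionDatabase, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_sdf(
        (db.compounds[c] for c in sorted(db.compounds)), out / "compounds.sdf"
    )
    write_reaction_table(db.reactions.values(), out / "reactions.tsv")
    write_cluster_table(db.clusters, out / "clusters.tsv")
    write_organism_table(db.organisms, out / "organisms.tsv")


def load_database(
    in_dir, taxon_groups: Sequence[str] = DEFAULT_TAXON_GROUPS
) -> ReactionDatabase:
    d = Path(in_dir)
    compounds = {g.compound_id: g for g in read_sdf(d / "compounds.sdf")}
    raw = read_reaction_table(d / "reactions.tsv", "tsv")
    clusters = read_cluster_table(d / "clusters.tsv")
    organisms = read_organism_table(d / "organisms.tsv", taxon_groups)
    return assemble_database(
        compounds, raw, clusters, organisms, taxon_groups, provenance=str(d)
    )
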