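"""Molecular structures as labeled graphs, and an exact canonical key.

This module provides the graph layer the scaffold operators are built on:

* :class:`MolecularGraph` — an element/charge/bond-order labeled undirected
  simple graph of one covalent structure (hydrogens implicit, never nodes).
* :class:`AbstractGraph` — the same topology with free-form string labels,
  closed under the label-erasure operators used by the scaffold hierarchy
  (a blank label is a legal label).
* :func:`canonical_key` — an exact canonical form: two graphs receive the
  same key if and only if they are isomorphic under the requested label
  regime.  The key is computed by iterative neighbourhood-invariant
  (colour) refinement followed by individualization of residual tied
  cells, taking the lexicographically minimal adjacency encoding over all
  leaves of the search.  It is exact by construction, not hash-based, so
  there are no collisions.

Structure input goes through RDKit (SMILES and SDF V2000); only element,
formal charge and bond order survive into the graph — stereochemistry and
3D information are deliberately discarded, because every downstream
scaffold level is constitutional.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import networkx as nx
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

#: bond-order label used for aromatic bonds throughout the package
AROMATIC = "ar"

#: default node-count bound for canonical labeling
DEFAULT_MAX_NODES = 256


class StructureParseError(ValueError):
    """Raised when a structure string cannot be parsed.

    Carries the offending input on ``.source`` so batch callers can route
    the row to a rejects report instead of aborting.
    """

    def __init__(self, source: str, reason: str = "unparsable structure"):
        self.source = source
        self.reason = reason
        super().__init__(f"{reason}: {source!r}")


class GraphCapacityError(ValueError):
    """Raised when a graph exceeds the canonical-labeling size bound."""


# ---------------------------------------------------------------------------
# graph types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MolecularGraph:
    """Element-labeled, bond-order-labeled undirected simple graph.

    ``atoms`` holds ``(atom_id, element, formal_charge)`` triples and
    ``bonds`` holds ``(atom_id, atom_id, order)`` with order in
    ``{1, 2, 3, "ar"}``.  The graph may be empty — that is the
    representation of "no framework" for acyclic molecules.
    """

    atoms: tuple[tuple[int, str, int], ...]
    bonds: tuple[tuple[int, int, object], ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [a[0] for a in self.atoms]
        idset = set(ids)
        if len(ids) != len(idset):
            raise ValueError("duplicate atom ids")
        seen: set[frozenset[int]] = set()
        for i, j, _order in self.bonds:
            if i == j:
                raise ValueError(f"self-loop on atom {i}")
            if i not in idset or j not in idset:
                raise ValueError(f"bond ({i},{j}) references undeclared atom")
            key = frozenset((i, j))
            if key in seen:
                raise ValueError(f"parallel bond ({i},{j})")
            seen.add(key)

    # -- basic accessors ---------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def atom_ids(self) -> set[int]:
        return {a[0] for a in self.atoms}

    def adjacency(self) -> dict[int, dict[int, object]]:
        adj: dict[int, dict[int, object]] = {a[0]: {} for a in self.atoms}
        for i, j, order in self.bonds:
            adj[i][j] = order
            adj[j][i] = order
        return adj

    def to_nx(self) -> nx.Graph:
        g = nx.Graph()
        for aid, elem, charge in self.atoms:
            g.add_node(aid, element=elem, charge=charge)
        for i, j, order in self.bonds:
            g.add_edge(i, j, order=order)
        return g

    def subgraph(self, keep: Iterable[int]) -> "MolecularGraph":
        """Induced subgraph on the given atom ids (order preserved)."""
        keep = set(keep)
        return MolecularGraph(
            atoms=tuple(a for a in self.atoms if a[0] in keep),
            bonds=tuple(b for b in self.bonds if b[0] in keep and b[1] in keep),
            provenance=self.provenance,
        )

    def n_components(self) -> int:
        if not self.atoms:
            return 0
        return nx.number_connected_components(self.to_nx())

    def cyclomatic_number(self) -> int:
        """|edges| - |nodes| + |components|: the independent ring count."""
        return self.n_bonds - self.n_atoms + self.n_components()

    def node_label(self, aid: int) -> str:
        """Element label with the formal charge folded in when nonzero."""
        for a, elem, charge in self.atoms:
            if a == aid:
                if charge == 0:
                    return elem
                return f"{elem}{charge:+d}"
        raise KeyError(aid)

    def to_abstract(self) -> "AbstractGraph":
        """Full-label abstract view: element(+charge) nodes, order edges."""
        labels = {}
        nodes = []
        for aid, elem, charge in self.atoms:
            lab = elem if charge == 0 else f"{elem}{charge:+d}"
            labels[aid] = lab
            nodes.append((aid, lab))
        return AbstractGraph(
            nodes=tuple(nodes),
            edges=tuple((i, j, str(order)) for i, j, order in self.bonds),
        )


@dataclass(frozen=True)
class AbstractGraph:
    """Undirected simple graph with string node and edge labels.

    The blank label ``""`` is legal, so the label alphabet is closed under
    the erasure operators (carbon scaffold, atom-type scaffold, graph
    scaffold).
    """

    nodes: tuple[tuple[int, str], ...]
    edges: tuple[tuple[int, int, str], ...]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def erase_node_labels(self) -> "AbstractGraph":
        return AbstractGraph(
            nodes=tuple((i, "") for i, _ in self.nodes), edges=self.edges
        )

    def erase_edge_labels(self) -> "AbstractGraph":
        return AbstractGraph(
            nodes=self.nodes, edges=tuple((i, j, "") for i, j, _ in self.edges)
        )


@dataclass(frozen=True)
class CanonicalKey:
    """A canonical string for one graph at one scaffold level."""

    key: str
    level: str  # one of MF1, MF2, CS, ATS, GS (or COMPOUND for full structures)


# ---------------------------------------------------------------------------
# parsing and normalization (RDKit-backed)
# ---------------------------------------------------------------------------

_BOND_ORDER = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: AROMATIC,
}
_BOND_TYPE = {v: k for k, v in _BOND_ORDER.items()}


def _graph_from_rdkit(mol: Chem.Mol, provenance: str = "") -> MolecularGraph:
    atoms = tuple(
        (a.GetIdx(), a.GetSymbol(), a.GetFormalCharge()) for a in mol.GetAtoms()
    )
    bonds = []
    for b in mol.GetBonds():
        order = _BOND_ORDER.get(b.GetBondType())
        if order is None:
            # dative/other exotic orders collapse to single
            order = max(1, int(round(b.GetBondTypeAsDouble())))
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    return MolecularGraph(atoms=atoms, bonds=tuple(bonds), provenance=provenance)


def _rdkit_from_graph(g: MolecularGraph) -> Chem.Mol:
    """Rebuild an RDKit molecule from a graph.

    Implicit hydrogens are lost in the graph form, so aromatic-NH rings
    (pyrrole-type nitrogens) cannot be kekulized directly; placements of
    one explicit H over the candidate aromatic nitrogens are searched in
    deterministic order until one sanitizes.  The heavy-atom graph is the
    same for every valid placement, so the choice never leaks downstream.
    """

    def build(h_atoms: frozenset[int] = frozenset()) -> Chem.Mol:
        rw = Chem.RWMol()
        index = {}
        for aid, elem, charge in g.atoms:
            atom = Chem.Atom(elem)
            atom.SetFormalCharge(charge)
            index[aid] = rw.AddAtom(atom)
        aromatic_atoms = set()
        for i, j, order in g.bonds:
            rw.AddBond(index[i], index[j], _BOND_TYPE[order])
            if order == AROMATIC:
                aromatic_atoms.update((index[i], index[j]))
        for idx in aromatic_atoms:
            rw.GetAtomWithIdx(idx).SetIsAromatic(True)
        for b in rw.GetBonds():
            if b.GetBondType() == Chem.BondType.AROMATIC:
                b.SetIsAromatic(True)
        for aid in h_atoms:
            rw.GetAtomWithIdx(index[aid]).SetNumExplicitHs(1)
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
        return mol

    pos = {aid: k for k, (aid, _e, _c) in enumerate(g.atoms)}
    expected = {
        (min(pos[i], pos[j]), max(pos[i], pos[j])): order for i, j, order in g.bonds
    }

    def matches(mol: Chem.Mol) -> bool:
        got = {
            (
                min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
                max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
            ): _BOND_ORDER.get(b.GetBondType(), 1)
            for b in mol.GetBonds()
        }
        return got == expected

    try:
        return build()
    except Exception:
        pass
    degree: dict[int, int] = {a[0]: 0 for a in g.atoms}
    for i, j, order in g.bonds:
        degree[i] += 1
        degree[j] += 1
    candidates = sorted(
        aid
        for aid, elem, charge in g.atoms
        if elem == "N"
        and charge == 0
        and degree[aid] == 2
        and any(o == AROMATIC for x, y, o in g.bonds if aid in (x, y))
    )
    fallback: Chem.Mol | None = None
    for size in range(1, min(len(candidates), 4) + 1):
        for combo in itertools.combinations(candidates, size):
            try:
                mol = build(frozenset(combo))
            except Exception:
                continue
            # sanitization can re-perceive aromaticity under a wrong
            # tautomer; only a placement reproducing the input bond
            # orders is faithful
            if matches(mol):
                return mol
            if fallback is None:
                fallback = mol
    if fallback is not None:
        return fallback
    raise StructureParseError(
        g.provenance or f"<graph {g.n_atoms} atoms>", "cannot rebuild molecule"
    )


def parse_structure(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Aromaticity is perceived (RDKit's default model); hydrogens stay
    implicit and never appear as graph nodes.

    Raises
    ------
    StructureParseError
        If the string is not valid SMILES; the error carries the string.
    """
    if smiles is None or not str(smiles).strip():
        raise StructureParseError(str(smiles), "empty structure")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureParseError(smiles)
    return _graph_from_rdkit(mol, provenance=smiles)


_UNCHARGER = rdMolStandardize.Uncharger()


def normalize(mol: MolecularGraph) -> MolecularGraph:
    """Normalize a parsed structure: strip salts, neutralize charges.

    The largest connected component is retained (counter-ions and solvent
    are discarded; ties break deterministically by bond count, then by the
    component's sorted label multiset).  Charges are then neutralized
    wherever a proton can be added or removed without changing heavy-atom
    connectivity (RDKit's uncharger); quaternary centres keep their charge.
    Tautomers are NOT canonicalized.  Idempotent; the empty graph is
    returned unchanged.
    """
    if not mol.atoms:
        return mol
    g = mol.to_nx()
    components = list(nx.connected_components(g))
    if len(components) > 1:
        def _rank(comp: set[int]) -> tuple:
            sub = mol.subgraph(comp)
            labels = tuple(sorted(sub.node_label(a[0]) for a in sub.atoms))
            return (-sub.n_atoms, -sub.n_bonds, labels)

        best = min(components, key=_rank)
        mol = mol.subgraph(best)
    rd = _rdkit_from_graph(mol)
    rd = _UNCHARGER.uncharge(rd)
    return _graph_from_rdkit(rd, provenance=mol.provenance)


def ring_atoms(mol: MolecularGraph) -> set[int]:
    """Atoms lying on at least one cycle.

    Computed as the endpoints of non-bridge edges: an atom is cyclic iff it
    is incident to an edge inside a 2-edge-connected component of size > 1.
    Acyclic graphs give the empty set.
    """
    if not mol.bonds:
        return set()
    g = mol.to_nx()
    bridges = {frozenset(e) for e in nx.bridges(g)}
    cyclic: set[int] = set()
    for i, j, _order in mol.bonds:
        if frozenset((i, j)) not in bridges:
            cyclic.add(i)
            cyclic.add(j)
    return cyclic


# ---------------------------------------------------------------------------
# canonical labeling
# ---------------------------------------------------------------------------


def _refine(
    colors: list[int],
    adj: list[list[tuple[int, str]]],
) -> list[int]:
    """Iterative neighbourhood-invariant (colour) refinement to a fixpoint."""
    n = len(colors)
    while True:
        sigs = [
            (colors[v], tuple(sorted((elab, colors[u]) for u, elab in adj[v])))
            for v in range(n)
        ]
        order = sorted(set(sigs))
        remap = {s: c for c, s in enumerate(order)}
        new = [remap[s] for s in sigs]
        if new == colors:
            return colors
        colors = new


def _encode(
    perm: Sequence[int],
    labels: Sequence[str],
    adj: list[list[tuple[int, str]]],
) -> str:
    """Adjacency encoding of the graph under vertex order ``perm``."""
    pos = {v: k for k, v in enumerate(perm)}
    node_part = ",".join(labels[v] for v in perm)
    edges = []
    for v in perm:
        for u, elab in adj[v]:
            a, b = pos[v], pos[u]
            if a < b:
                edges.append((a, b, elab))
    edge_part = ";".join(f"{a}-{b}:{e}" for a, b, e in sorted(edges))
    return f"{len(perm)}|{node_part}|{edge_part}"


def canonical_key(
    g: AbstractGraph,
    use_node_labels: bool = True,
    use_edge_labels: bool = True,
    max_nodes: int = DEFAULT_MAX_NODES,
) -> str:
    """Exact canonical form of a labeled simple graph.

    Two graphs map to the same string iff they are isomorphic under the
    requested label regime.  Colour refinement partitions the vertices by
    iterated neighbourhood invariants; residual tied cells are resolved by
    individualizing each member of the first non-singleton cell in turn
    and recursing, and the lexicographically minimal adjacency encoding
    over all discrete leaves is returned.  The search is exhaustive, so
    the key is collision-free by construction.

    Raises
    ------
    GraphCapacityError
        If the graph has more than ``max_nodes`` nodes.
    """
    n = g.n_nodes
    if n > max_nodes:
        raise GraphCapacityError(
            f"graph has {n} nodes, exceeding the bound of {max_nodes}"
        )
    if n == 0:
        return "0||"

    ids = [i for i, _ in g.nodes]
    idx = {v: k for k, v in enumerate(ids)}
    labels = [
        (lab if use_node_labels else "") for _, lab in g.nodes
    ]
    adj: list[list[tuple[int, str]]] = [[] for _ in range(n)]
    for i, j, elab in g.edges:
        e = elab if use_edge_labels else ""
        adj[idx[i]].append((idx[j], e))
        adj[idx[j]].append((idx[i], e))

    init_order = sorted(set(labels))
    init_map = {lab: c for c, lab in enumerate(init_order)}
    colors = _refine([init_map[lab] for lab in labels], adj)

    best: list[str | None] = [None]

    def search(colors: list[int]) -> None:
        cells: dict[int, list[int]] = {}
        for v, c in enumerate(colors):
            cells.setdefault(c, []).append(v)
        target = None
        for c in sorted(cells):
            if len(cells[c]) > 1:
                target = cells[c]
                break
        if target is None:
            perm = sorted(range(n), key=lambda v: colors[v])
            enc = _encode(perm, labels, adj)
            if best[0] is None or enc < best[0]:
                best[0] = enc
            return
        for v in target:
            branched = list(colors)
            # individualize v: give it a fresh colour below its cell
            for u in range(n):
                if branched[u] >= branched[v] and u != v:
                    branched[u] += 1
            search(_refine(branched, adj))

    search(colors)
    assert best[0] is not None
    return best[0]


def compound_key(normalized: MolecularGraph) -> str:
    """Unique-structure identifier: canonical key of the normalized graph
    with both node (element+charge) and edge (bond order) labels respected.

    This plays the role a Standard InChIKey plays in registration systems:
    identical structures written as different SMILES get identical keys.
    It is connectivity-level only (no stereochemistry, no tautomer folding).
    """
    return canonical_key(normalized.to_abstract(), True, True)


# ---------------------------------------------------------------------------
# file input
# ---------------------------------------------------------------------------


def read_smiles_file(path: str | Path) -> Iterator[tuple[str, MolecularGraph]]:
    """Yield ``(id, graph)`` from a SMILES file (one structure per line,
    optional tab-separated id; blank lines and ``#`` comments skipped).

    Unparsable lines raise :class:`StructureParseError` carrying the line.
    """
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles = parts[0].strip()
            ident = parts[1].strip() if len(parts) > 1 else f"line{lineno}"
            yield ident, parse_structure(smiles)


def read_sdf_file(path: str | Path) -> Iterator[tuple[str, MolecularGraph]]:
    """Yield ``(id, graph)`` from an SDF (V2000) file.

    Only element, formal charge and bond order are consumed.  Molecules the
    reader cannot sanitize raise :class:`StructureParseError`.
    """
    path = Path(path)
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            raise StructureParseError(f"{path}#{i}", "unreadable SDF record")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i}"
        yield name or f"mol{i}", _graph_from_rdkit(mol, provenance=name)
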