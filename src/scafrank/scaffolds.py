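"""The five-level molecular topology hierarchy (MF1, MF2, CS, ATS, GS).

Frameworks in the Bemis-Murcko sense view a molecule as ring systems
connected by linkers, with acyclic side chains removed.  The hierarchy
implemented here abstracts a normalized structure in five progressive
stages:

1. **MF1** (molecular framework 1) — all terminal side chains removed,
   but atoms attached to the retained core through a double, triple or
   aromatic bond (exocyclic double bonds, and double bonds hanging off the
   linker) are kept.
2. **MF2** (molecular framework 2) — MF1 with those doubly-bonded
   terminal atoms removed as well: the classical Murcko framework of ring
   atoms plus linker atoms only.
3. **CS** (carbon scaffold) — MF2 with every atom treated as carbon;
   bond orders survive, so an aromatic ring stays distinct from its
   saturated counterpart.
4. **ATS** (atom-type scaffold) — MF2 with bond orders erased; elements
   survive, so pyridine stays distinct from benzene.
5. **GS** (graph scaffold) — MF2 with both labels erased: the bare graph
   skeleton.

CS, ATS and GS are always functions of the MF2 graph, never of MF1 or the
full structure.  Acyclic molecules have no framework at any level and are
marked with an explicit ``acyclic`` flag instead of keys.

Every level preserves the cyclomatic number (|edges| − |nodes| +
|components|): abstraction collapses labels and side chains, never rings.
"""

from __future__ import annotations

from dataclasses import dataclass

from .molgraph import (
    AbstractGraph,
    CanonicalKey,
    MolecularGraph,
    canonical_key,
    compound_key,
    ring_atoms,
)

LEVELS = ("MF1", "MF2", "CS", "ATS", "GS")


@dataclass(frozen=True)
class ScaffoldRecord:
    """The five canonical scaffold keys of one compound.

    ``acyclic`` is true iff the compound has no rings, in which case all
    five keys are absent.  ``ring_count`` is the cyclomatic number of the
    full structure (conserved across all five levels).
    """

    compound_key: str
    mf1_key: CanonicalKey | None
    mf2_key: CanonicalKey | None
    cs_key: CanonicalKey | None
    ats_key: CanonicalKey | None
    gs_key: CanonicalKey | None
    acyclic: bool
    ring_count: int = 0

    def key_at(self, level: str) -> CanonicalKey | None:
        return {
            "MF1": self.mf1_key,
            "MF2": self.mf2_key,
            "CS": self.cs_key,
            "ATS": self.ats_key,
            "GS": self.gs_key,
        }[level]


def _is_multiple(order: object) -> bool:
    """Aromatic bonds count as multiple for the MF1 retention rule."""
    return order == "ar" or (isinstance(order, int) and order >= 2)


def _prune_terminals(
    mol: MolecularGraph, keep_multiple_bonded: bool
) -> MolecularGraph:
    """Iteratively delete degree-1 non-ring atoms until fixpoint.

    With ``keep_multiple_bonded`` a terminal atom attached through a bond
    of order ≥ 2 or aromatic survives (the MF1 rule); without it every
    terminal non-ring atom goes (the MF2 rule).  Ring atoms are never
    degree-1 and deleting non-ring atoms cannot open a ring, so ring
    membership is computed once on the input.
    """
    cyclic = ring_atoms(mol)
    adj = mol.adjacency()
    alive = set(adj)
    changed = True
    while changed:
        changed = False
        for v in sorted(alive):
            if v in cyclic:
                continue
            neighbours = [(u, adj[v][u]) for u in adj[v] if u in alive]
            if len(neighbours) != 1:
                continue
            _u, order = neighbours[0]
            if keep_multiple_bonded and _is_multiple(order):
                continue
            alive.discard(v)
            changed = True
        # isolated acyclic atoms (degree 0 after pruning) carry no framework
    alive = {v for v in alive if v in cyclic or any(u in alive for u in adj[v])}
    return mol.subgraph(alive)


def molecular_framework_1(mol: MolecularGraph) -> MolecularGraph:
    """MF1: remove terminal side chains, keep multiply-bonded terminal atoms.

    Deletes, to a fixpoint, every degree-1 atom that is not on a ring and
    is attached through a single bond.  Acyclic input gives the empty
    graph.  Idempotent.
    """
    if not ring_atoms(mol):
        return MolecularGraph(atoms=(), bonds=(), provenance=mol.provenance)
    return _prune_terminals(mol, keep_multiple_bonded=True)


def molecular_framework_2(mf1: MolecularGraph) -> MolecularGraph:
    """MF2: remove the exocyclic / linker-attached double-bonded terminals.

    Applied to an MF1 graph, deletes every degree-1 non-ring atom
    regardless of bond order, to a fixpoint.  The result contains exactly
    the ring atoms and the linker atoms between them; interior bond orders
    are preserved.  Idempotent.
    """
    if not ring_atoms(mf1):
        return MolecularGraph(atoms=(), bonds=(), provenance=mf1.provenance)
    return _prune_terminals(mf1, keep_multiple_bonded=False)


def carbon_scaffold(mf2: MolecularGraph) -> AbstractGraph:
    """CS: erase atom types (every node becomes the uniform symbol);
    bond-order edge labels are preserved."""
    return mf2.to_abstract().erase_node_labels()


def atom_type_scaffold(mf2: MolecularGraph) -> AbstractGraph:
    """ATS: erase bond types (aromatic included); element labels preserved.

    Formal charges are dropped with the bond orders — after erasure the
    nodes carry bare element symbols.
    """
    nodes = tuple((aid, elem) for aid, elem, _charge in mf2.atoms)
    edges = tuple((i, j, "") for i, j, _order in mf2.bonds)
    return AbstractGraph(nodes=nodes, edges=edges)


def graph_scaffold(mf2: MolecularGraph) -> AbstractGraph:
    """GS: erase both labels — the pure graph skeleton."""
    return mf2.to_abstract().erase_node_labels().erase_edge_labels()


def scaffold_record(mol: MolecularGraph) -> ScaffoldRecord:
    """Chain the five operators on a normalized structure and canonicalize.

    Acyclic compounds get an explicit marker and no keys; they still count
    as compounds downstream, just never as scaffolds.
    """
    ckey = compound_key(mol)
    mf1 = molecular_framework_1(mol)
    if not mf1.atoms:
        return ScaffoldRecord(
            compound_key=ckey,
            mf1_key=None,
            mf2_key=None,
            cs_key=None,
            ats_key=None,
            gs_key=None,
            acyclic=True,
            ring_count=0,
        )
    mf2 = molecular_framework_2(mf1)
    return ScaffoldRecord(
        compound_key=ckey,
        mf1_key=CanonicalKey(canonical_key(mf1.to_abstract()), "MF1"),
        mf2_key=CanonicalKey(canonical_key(mf2.to_abstract()), "MF2"),
        cs_key=CanonicalKey(canonical_key(carbon_scaffold(mf2)), "CS"),
        ats_key=CanonicalKey(canonical_key(atom_type_scaffold(mf2)), "ATS"),
        gs_key=CanonicalKey(canonical_key(graph_scaffold(mf2)), "GS"),
        acyclic=False,
        ring_count=mol.cyclomatic_number(),
    )
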