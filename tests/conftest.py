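"""Shared fixtures and oracle helpers for the test suite."""

from __future__ import annotations

import itertools

import networkx as nx
import pytest

from scafrank.molgraph import AbstractGraph, MolecularGraph, normalize, parse_structure

#: a structurally diverse sample: aromatic/saturated, fused/linked rings,
#: exocyclic double bonds, linkers, salts, charges, acyclic molecules
SMILES_SAMPLE = [
    "c1ccccc1",                          # benzene
    "Cc1ccccc1",                         # toluene
    "c1ccncc1",                          # pyridine
    "C1CCCCC1",                          # cyclohexane
    "C=C1CCCCC1",                        # methylenecyclohexane
    "O=C1CCCCC1",                        # cyclohexanone
    "c1ccc2ccccc2c1",                    # naphthalene
    "c1ccc(-c2ccccc2)cc1",               # biphenyl
    "c1ccc(CCc2ccccc2)cc1",              # bibenzyl
    "CCO",                               # ethanol (acyclic)
    "CC(C)CC(=O)O",                      # acyclic acid
    "CC(=O)[O-]",                        # acetate anion
    "c1ccccc1.[Cl-]",                    # benzene + counter-ion
    "Cc1ccc(C(=O)O)cc1",                 # toluic acid
    "C(=C/c1ccccc1)\\c1ccccc1",          # stilbene
    "O=C1NC(=O)c2ccccc21",               # phthalimide
    "CC(C)c1c(C(=O)Nc2ccccc2)c(-c2ccccc2)c(-c2ccc(F)cc2)n1CC[C@@H](O)C[C@@H](O)CC(=O)O",
    "c1ccc2[nH]ccc2c1",                  # indole
    "C1CCN(c2ccccc2)CC1",                # N-phenylpiperidine
    "OCc1ccncc1",                        # pyridinylmethanol
    "N#Cc1ccc(S(C)(=O)=O)cc1",           # nitrile + sulfone decorations
    "c1ncc2[nH]cnc2n1",                  # purine
    "C1CCC2C(C1)CCC1C2CCC2CCCC12",       # gonane
]

ATORVASTATIN = (
    "CC(C)c1c(C(=O)Nc2ccccc2)c(-c2ccccc2)c(-c2ccc(F)cc2)n1"
    "CC[C@@H](O)C[C@@H](O)CC(=O)O"
)


def mol(smiles: str) -> MolecularGraph:
    """Parse and normalize, the way the pipeline does."""
    return normalize(parse_structure(smiles))


def ag(n: int, edges, node_labels=None, edge_labels=None) -> AbstractGraph:
    """Terse AbstractGraph constructor for topology tests."""
    node_labels = node_labels or {}
    edge_labels = edge_labels or {}
    return AbstractGraph(
        nodes=tuple((i, node_labels.get(i, "")) for i in range(n)),
        edges=tuple(
            (i, j, edge_labels.get((i, j), "")) for i, j in edges
        ),
    )


def abstract_to_nx(g: AbstractGraph) -> nx.Graph:
    out = nx.Graph()
    for i, lab in g.nodes:
        out.add_node(i, label=lab)
    for i, j, lab in g.edges:
        out.add_edge(i, j, label=lab)
    return out


def cyclomatic(g) -> int:
    """|E| - |V| + |components| for either graph type."""
    if isinstance(g, AbstractGraph):
        h = abstract_to_nx(g)
        if h.number_of_nodes() == 0:
            return 0
        return (
            h.number_of_edges()
            - h.number_of_nodes()
            + nx.number_connected_components(h)
        )
    return g.cyclomatic_number()


def brute_force_isomorphic(g1: AbstractGraph, g2: AbstractGraph) -> bool:
    """Exhaustive-permutation isomorphism oracle (labels respected).

    Independent of the canonical-key machinery: tries every bijection.
    Only usable for small n.
    """
    if g1.n_nodes != g2.n_nodes or len(g1.edges) != len(g2.edges):
        return False
    ids1 = [i for i, _ in g1.nodes]
    ids2 = [i for i, _ in g2.nodes]
    lab1 = dict(g1.nodes)
    lab2 = dict(g2.nodes)
    e1 = {frozenset((i, j)): lab for i, j, lab in g1.edges}
    e2 = {frozenset((i, j)): lab for i, j, lab in g2.edges}
    if sorted(lab1.values()) != sorted(lab2.values()):
        return False
    for perm in itertools.permutations(ids2):
        mapping = dict(zip(ids1, perm))
        if any(lab1[v] != lab2[mapping[v]] for v in ids1):
            continue
        remapped = {
            frozenset((mapping[i], mapping[j])): lab for i, j, lab in g1.edges
        }
        if remapped == e2:
            return True
    return False


@pytest.fixture(scope="session")
def atorvastatin() -> MolecularGraph:
    return mol(ATORVASTATIN)
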