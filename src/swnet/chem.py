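"""Molecular graphs, r-radius subgraph vocabularies, fingerprints and scaffolds.

SMILES strings are parsed into heavy-atom graphs.  Each atom and bond is then
assigned a discrete *r-radius subgraph* token: the canonical signature of its
neighborhood within graph distance ``r``, obtained by iterative relabeling
(Weisfeiler–Lehman style).  Tokens index learned embedding tables in the GNN
encoder.  Morgan fingerprints, Tanimoto similarity, Bemis–Murcko scaffolds and
UPGMA compound clustering support the drug-similarity attention mechanism and
chemical-diversity analyses.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator
    from rdkit.Chem.Scaffolds import MurckoScaffold

__all__ = [
    "MolecularGraph",
    "SubgraphVocabulary",
    "FingerprintBitSet",
    "DrugSimilarityMatrix",
    "parse_smiles",
    "assign_r_radius_ids",
    "morgan_fingerprint",
    "tanimoto",
    "similarity_matrix",
    "bemis_murcko_scaffold",
    "cluster_compounds",
]

UNKNOWN_ID = 0  # reserved vocabulary id for signatures unseen at training time


class InputError(ValueError):
    """Raised for malformed or inconsistent user input."""


@dataclass
class MolecularGraph:
    """Heavy-atom graph of one compound.

    ``nodes`` holds per-atom descriptors ``(element, aromatic, formal_charge,
    degree)``; ``edges`` holds ``(i, j, bond_label)`` with ``i < j``.  Subgraph
    ids are filled in by :func:`assign_r_radius_ids`.
    """

    nodes: list
    edges: list
    node_subgraph_ids: list | None = None
    edge_subgraph_ids: list | None = None
    smiles: str | None = None
    _mol: object = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        n = len(self.nodes)
        if n < 1:
            raise InputError("molecular graph must have at least one node")
        for i, j, _ in self.edges:
            if i == j or not (0 <= i < n) or not (0 <= j < n):
                raise InputError(f"edge ({i},{j}) references invalid node indices")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self) -> list:
        """Adjacency as ``[(j, edge_idx), ...]`` per node (symmetric)."""
        adj = [[] for _ in self.nodes]
        for e_idx, (i, j, _) in enumerate(self.edges):
            adj[i].append((j, e_idx))
            adj[j].append((i, e_idx))
        return adj


@dataclass
class SubgraphVocabulary:
    """Maps canonical r-radius neighborhood signatures to contiguous ids.

    Id 0 is reserved for unknown signatures; real ids start at 1.  Rebuilding
    on the same compounds in the same order reproduces identical maps.
    """

    radius: int
    node_signature_to_id: dict = field(default_factory=dict)
    edge_signature_to_id: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.radius < 0:
            raise InputError("radius must be non-negative")

    @property
    def n_node_ids(self) -> int:
        return len(self.node_signature_to_id) + 1  # + unknown

    @property
    def n_edge_ids(self) -> int:
        return len(self.edge_signature_to_id) + 1

    def _lookup(self, table: dict, sig: str, grow: bool) -> int:
        if sig in table:
            return table[sig]
        if grow:
            table[sig] = len(table) + 1
            return table[sig]
        return UNKNOWN_ID

    def to_json(self, path):
        payload = {
            "radius": self.radius,
            "node_signature_to_id": self.node_signature_to_id,
            "edge_signature_to_id": self.edge_signature_to_id,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SubgraphVocabulary":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            radius=int(payload["radius"]),
            node_signature_to_id={k: int(v) for k, v in payload["node_signature_to_id"].items()},
            edge_signature_to_id={k: int(v) for k, v in payload["edge_signature_to_id"].items()},
        )


@dataclass
class FingerprintBitSet:
    """Sparse Morgan fingerprint: the set of on bits of an ``n_bits`` vector."""

    on_bits: frozenset
    n_bits: int

    def __post_init__(self):
        self.on_bits = frozenset(self.on_bits)
        if any(b < 0 or b >= self.n_bits for b in self.on_bits):
            raise InputError("fingerprint bit index out of range")


@dataclass
class DrugSimilarityMatrix:
    """Square Tanimoto similarity matrix over an ordered drug list."""

    drug_ids: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.drug_ids)
        if self.values.shape != (n, n):
            raise InputError("similarity matrix shape does not match drug list")
        if not np.allclose(self.values, self.values.T):
            raise InputError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0):
            raise InputError("similarity matrix diagonal must be 1")
        if self.values.min() < 0 or self.values.max() > 1 + 1e-12:
            raise InputError("similarities must lie in [0, 1]")


_BOND_LABELS = {
    Chem.BondType.SINGLE: "-",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "#",
    Chem.BondType.AROMATIC: ":",
}


def parse_smiles(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a heavy-atom :class:`MolecularGraph`."""
    if not smiles or not smiles.strip():
        raise InputError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles, sanitize=True)
    if mol is None:
        raise InputError(f"unparsable SMILES: {smiles!r}")
    nodes = [
        (a.GetSymbol(), a.GetIsAromatic(), a.GetFormalCharge(), a.GetDegree())
        for a in mol.GetAtoms()
    ]
    edges = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        label = _BOND_LABELS.get(b.GetBondType(), str(b.GetBondType()))
        edges.append((min(i, j), max(i, j), label))
    return MolecularGraph(nodes=nodes, edges=edges, smiles=smiles, _mol=mol)


def _relabel_rounds(graph: MolecularGraph, r: int) -> list:
    """Iterative neighborhood relabeling; returns per-round node label lists.

    Round 0 labels are the bare atom descriptors (element, aromatic flag,
    formal charge); round t combines a node's own label with the sorted
    multiset of (neighbor label, bond label) pairs at round t-1.
    """
    labels = [f"{s}|{int(a)}|{c}" for s, a, c, _deg in graph.nodes]
    rounds = [labels]
    adj = graph.neighbors()
    for _ in range(r):
        prev = rounds[-1]
        nxt = []
        for i in range(graph.n_nodes):
            nb = sorted(f"({prev[j]},{graph.edges[e][2]})" for j, e in adj[i])
            nxt.append(prev[i] + "[" + ";".join(nb) + "]")
        rounds.append(nxt)
    return rounds


def assign_r_radius_ids(
    graph: MolecularGraph, vocab: SubgraphVocabulary, grow: bool = False
) -> MolecularGraph:
    """Assign r-radius subgraph ids to every node and edge of ``graph``.

    Node signatures are the relabeling result after ``vocab.radius`` rounds;
    an edge signature combines its bond label with the unordered pair of
    endpoint labels at radius r-1 (bond label alone when r = 0).  With
    ``grow`` unset, unseen signatures map to the reserved unknown id 0.
    """
    r = vocab.radius
    rounds = _relabel_rounds(graph, r)
    node_sigs = rounds[r]
    node_ids = [vocab._lookup(vocab.node_signature_to_id, s, grow) for s in node_sigs]
    edge_ids = []
    for i, j, bond in graph.edges:
        if r == 0:
            sig = bond
        else:
            ends = sorted([rounds[r - 1][i], rounds[r - 1][j]])
            sig = f"{bond}<{ends[0]}|{ends[1]}>"
        edge_ids.append(vocab._lookup(vocab.edge_signature_to_id, sig, grow))
    return replace(graph, node_subgraph_ids=node_ids, edge_subgraph_ids=edge_ids)


def morgan_fingerprint(
    graph: MolecularGraph, radius: int = 2, n_bits: int = 2048
) -> FingerprintBitSet:
    """Circular (Morgan) fingerprint of the compound as a bit set."""
    if radius < 0 or n_bits <= 0:
        raise InputError("radius must be >= 0 and n_bits > 0")
    mol = graph._mol
    if mol is None:
        mol = Chem.MolFromSmiles(graph.smiles) if graph.smiles else None
    if mol is None:
        raise InputError("graph has no underlying molecule for fingerprinting")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bv = gen.GetFingerprint(mol)
    return FingerprintBitSet(on_bits=frozenset(bv.GetOnBits()), n_bits=n_bits)


def tanimoto(a: FingerprintBitSet, b: FingerprintBitSet, empty_value: float = 1.0) -> float:
    """Tanimoto similarity |a∩b| / |a∪b|.

    Two all-zero fingerprints are treated as identical (similarity
    ``empty_value``, default 1), preserving the identity property.
    """
    if a.n_bits != b.n_bits:
        raise InputError(f"fingerprint lengths differ: {a.n_bits} vs {b.n_bits}")
    union = len(a.on_bits | b.on_bits)
    if union == 0:
        return empty_value
    return len(a.on_bits & b.on_bits) / union


def similarity_matrix(
    graphs: list, drug_ids: list | None = None, radius: int = 2, n_bits: int = 2048
) -> DrugSimilarityMatrix:
    """Pairwise Tanimoto similarity of Morgan fingerprints."""
    if not graphs:
        raise InputError("similarity_matrix requires at least one compound")
    if drug_ids is None:
        drug_ids = list(range(len(graphs)))
    fps = [morgan_fingerprint(g, radius=radius, n_bits=n_bits) for g in graphs]
    n = len(fps)
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = tanimoto(fps[i], fps[j])
    return DrugSimilarityMatrix(drug_ids=list(drug_ids), values=values)


def bemis_murcko_scaffold(graph: MolecularGraph) -> str:
    """Bemis–Murcko scaffold SMILES (ring systems + linkers; '' if acyclic)."""
    mol = graph._mol
    if mol is None:
        mol = Chem.MolFromSmiles(graph.smiles) if graph.smiles else None
    if mol is None:
        raise InputError("graph has no underlying molecule")
    return MurckoScaffold.MurckoScaffoldSmiles(mol=mol)


def cluster_compounds(sim: DrugSimilarityMatrix, distance_cutoff: float = 0.6) -> np.ndarray:
    """Average-linkage (UPGMA) clustering on Tanimoto distance 1 - similarity.

    The dendrogram is cut at ``distance_cutoff``; returned labels are
    contiguous integers starting at 0, numbered in order of first appearance.
    """
    if not (0 < distance_cutoff <= 1):
        raise InputError("distance_cutoff must lie in (0, 1]")
    n = len(sim.drug_ids)
    if n == 1:
        return np.array([0])
    dist = 1.0 - sim.values
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    raw = fcluster(Z, t=distance_cutoff, criterion="distance")
    remap, labels = {}, []
    for lab in raw:
        if lab not in remap:
            remap[lab] = len(remap)
        labels.append(remap[lab])
    return np.array(labels)
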