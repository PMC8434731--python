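"""Extended graph neural network over r-radius subgraph tokens.

Each node and edge token drawn from a :class:`~swnet.chem.SubgraphVocabulary`
receives a learned d-dimensional embedding.  T transition steps then propagate
information:

* edge transition:  e_ij <- sigma(e_ij + f(w_e (v_i + v_j + b_e)))
* node transition:  v_i  <- sigma(v_i + sum_{j in N(i)} f(w_n [v_j; e_ij] + b_n))

with sigma the logistic function and f a rectifier by default.  The graph
embedding h_G is the arithmetic mean of the final node states, so after at
least one step every coordinate lies strictly in (0, 1).

Two printed-form ambiguities are exposed as configuration switches rather than
resolved silently: whether the edge update sees the node states from before or
after the same step's node update (``edge_uses_updated_nodes``, default on),
and whether the edge bias sits inside or outside the matrix product
(``bias_outside_product``, default off, i.e. the literal form
``w_e (v_i + v_j + b_e)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, relu, sigmoid
from .chem import MolecularGraph, SubgraphVocabulary

__all__ = [
    "EmbeddingTable",
    "GnnParameters",
    "GraphState",
    "GraphEmbedding",
    "init_state",
    "edge_transition",
    "node_transition",
    "readout",
    "encode",
    "GnnEncoder",
]

_ACTIVATIONS = {"relu": relu, "sigmoid": sigmoid}


@dataclass
class EmbeddingTable:
    """One d-vector per vocabulary id (id 0 = unknown token).

    Initialization is zero-mean uniform scaled by 1/sqrt(d) from a recorded
    seed, so reconstruction with the same seed is bit-identical.
    """

    n_ids: int
    dimension: int
    seed: int
    vectors: Tensor = field(default=None)

    def __post_init__(self):
        if self.vectors is None:
            rng = np.random.default_rng(self.seed)
            scale = 1.0 / np.sqrt(self.dimension)
            data = rng.uniform(-scale, scale, size=(self.n_ids, self.dimension))
            self.vectors = Tensor(data, requires_grad=True)

    def grow_to(self, n_ids: int, seed_offset: int = 1):
        """Extend the table for newly added vocabulary ids."""
        if n_ids <= self.n_ids:
            return
        rng = np.random.default_rng(self.seed + seed_offset)
        scale = 1.0 / np.sqrt(self.dimension)
        extra = rng.uniform(-scale, scale, size=(n_ids - self.n_ids, self.dimension))
        self.vectors = Tensor(np.vstack([self.vectors.data, extra]), requires_grad=True)
        self.n_ids = n_ids


@dataclass
class GnnParameters:
    """Trainable transition parameters, shared across all T steps."""

    dimension: int
    T: int = 2
    activation: str = "relu"
    edge_uses_updated_nodes: bool = True
    bias_outside_product: bool = False
    seed: int = 0
    w_e: Tensor = field(default=None)
    b_e: Tensor = field(default=None)
    w_n: Tensor = field(default=None)
    b_n: Tensor = field(default=None)

    def __post_init__(self):
        if self.T < 1:
            raise ValueError("T must be >= 1")
        d = self.dimension
        if self.w_e is None:
            rng = np.random.default_rng(self.seed)
            self.w_e = Tensor(rng.uniform(-1, 1, (d, d)) / np.sqrt(d), requires_grad=True)
            self.b_e = Tensor(np.zeros(d), requires_grad=True)
            self.w_n = Tensor(rng.uniform(-1, 1, (d, 2 * d)) / np.sqrt(2 * d), requires_grad=True)
            self.b_n = Tensor(np.zeros(d), requires_grad=True)

    @property
    def f(self):
        return _ACTIVATIONS[self.activation]

    def parameters(self) -> list:
        return [self.w_e, self.b_e, self.w_n, self.b_n]


@dataclass
class GraphState:
    """Per-node and per-edge d-vector states plus graph connectivity."""

    node_states: Tensor
    edge_states: Tensor  # (n_edges, d); empty (0, d) when the graph has no edges
    edge_src: np.ndarray  # i of each undirected edge (i, j)
    edge_dst: np.ndarray
    t: int = 0


@dataclass
class GraphEmbedding:
    h_G: Tensor


def init_state(graph: MolecularGraph, node_table: EmbeddingTable, edge_table: EmbeddingTable) -> GraphState:
    """Gather token embeddings into the initial graph state."""
    if graph.node_subgraph_ids is None:
        raise ValueError("graph has no subgraph ids; run assign_r_radius_ids first")
    node_ids = np.asarray(graph.node_subgraph_ids)
    if node_ids.max(initial=0) >= node_table.n_ids:
        raise ValueError("node subgraph id outside embedding table; rebuild tables from vocabulary")
    nodes = node_table.vectors.gather_rows(node_ids)
    if graph.n_edges:
        edge_ids = np.asarray(graph.edge_subgraph_ids)
        if edge_ids.max(initial=0) >= edge_table.n_ids:
            raise ValueError("edge subgraph id outside embedding table; rebuild tables from vocabulary")
        edges = edge_table.vectors.gather_rows(edge_ids)
        src = np.array([e[0] for e in graph.edges])
        dst = np.array([e[1] for e in graph.edges])
    else:
        edges = Tensor(np.zeros((0, node_table.dimension)))
        src = dst = np.zeros(0, dtype=int)
    return GraphState(node_states=nodes, edge_states=edges, edge_src=src, edge_dst=dst, t=0)


def edge_transition(state: GraphState, params: GnnParameters) -> GraphState:
    """e_ij <- sigma(e_ij + f(w_e (v_i + v_j + b_e))); node states untouched."""
    if state.edge_src.size == 0:
        return GraphState(state.node_states, state.edge_states, state.edge_src, state.edge_dst, state.t)
    v = state.node_states
    vsum = v.gather_rows(state.edge_src) + v.gather_rows(state.edge_dst)
    if params.bias_outside_product:
        pre = vsum @ params.w_e.T + params.b_e
    else:
        pre = (vsum + params.b_e) @ params.w_e.T
    g = params.f(pre)
    new_e = sigmoid(state.edge_states + g)
    return GraphState(state.node_states, new_e, state.edge_src, state.edge_dst, state.t)


def node_transition(state: GraphState, params: GnnParameters) -> GraphState:
    """v_i <- sigma(v_i + sum_j f(w_n [v_j; e_ij] + b_n)), synchronous update."""
    from ._autodiff import concat

    v, e = state.node_states, state.edge_states
    n = v.shape[0]
    if state.edge_src.size == 0:
        new_v = sigmoid(v)
        return GraphState(new_v, e, state.edge_src, state.edge_dst, state.t)
    # messages flow in both directions across each undirected edge
    recv = np.concatenate([state.edge_src, state.edge_dst])
    send = np.concatenate([state.edge_dst, state.edge_src])
    edge_idx = np.concatenate([np.arange(state.edge_src.size)] * 2)
    inputs = concat([v.gather_rows(send), e.gather_rows(edge_idx)], axis=1)
    h = params.f(inputs @ params.w_n.T + params.b_n)
    msg = h.segment_sum(recv, n)
    new_v = sigmoid(v + msg)
    return GraphState(new_v, e, state.edge_src, state.edge_dst, state.t)


def readout(state: GraphState) -> GraphEmbedding:
    """Graph-level representation: arithmetic mean of node states."""
    return GraphEmbedding(h_G=state.node_states.mean(axis=0))


def encode(graph: MolecularGraph, node_table: EmbeddingTable, edge_table: EmbeddingTable, params: GnnParameters) -> GraphEmbedding:
    """Run T transition steps from the token embeddings, then read out.

    Per step the node transition runs first; the edge transition then sees the
    just-updated node states when ``edge_uses_updated_nodes`` is on, otherwise
    both transitions read the states from the start of the step (synchronous).
    """
    state = init_state(graph, node_table, edge_table)
    for t in range(params.T):
        if params.edge_uses_updated_nodes:
            state = node_transition(state, params)
            state = edge_transition(state, params)
        else:
            pre = state
            upd_nodes = node_transition(pre, params)
            upd_edges = edge_transition(pre, params)
            state = GraphState(upd_nodes.node_states, upd_edges.edge_states, pre.edge_src, pre.edge_dst, t)
        state.t = t + 1
    return readout(state)


class GnnEncoder:
    """Embedding tables + transition parameters bound to one vocabulary."""

    def __init__(self, vocab: SubgraphVocabulary, dimension: int = 32, T: int | None = None,
                 seed: int = 0, **param_kwargs):
        self.vocab = vocab
        if T is None:
            T = max(vocab.radius, 1)  # default: one step per radius unit
        self.node_table = EmbeddingTable(vocab.n_node_ids, dimension, seed=seed)
        self.edge_table = EmbeddingTable(vocab.n_edge_ids, dimension, seed=seed + 1)
        self.params = GnnParameters(dimension=dimension, T=T, seed=seed + 2, **param_kwargs)

    def sync_tables(self):
        """Grow embedding tables after the vocabulary gained new signatures."""
        self.node_table.grow_to(self.vocab.n_node_ids)
        self.edge_table.grow_to(self.vocab.n_edge_ids)

    def encode(self, graph: MolecularGraph) -> GraphEmbedding:
        return encode(graph, self.node_table, self.edge_table, self.params)

    def parameters(self) -> list:
        return [self.node_table.vectors, self.edge_table.vectors] + self.params.parameters()
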