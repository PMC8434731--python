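"""The dual-convergence response model and its multi-task training loop.

Two branches converge: the GNN encodes the compound's molecular graph into a
d-vector; a 1D-convolutional gene branch encodes the fused genomic profile
geneCom = geneExp + geneVar (*) w', where the mutation weight row w' comes
from the gene weight layer (one shared row, one row per drug, or the
attention-mixed W' = softmax(S) W recomputed every forward pass).  The two
embeddings are concatenated and passed through a prediction subnetwork
(1D convolution, max pooling, batch normalization, fully connected stages) to
a scalar ln IC50.  All drugs are trained jointly with one shared MSE loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .chem import (
    InputError,
    MolecularGraph,
    SubgraphVocabulary,
    assign_r_radius_ids,
    morgan_fingerprint,
    parse_smiles,
    similarity_matrix,
)
from .evaluation import ResponseDataset
from .genomics import GeneFeatureSet, GeneWeightLayer, _softmax_rows, infer_new_drug_weight
from .gnn import GnnEncoder

__all__ = ["TrainingConfig", "SwnetModel", "train", "predict_batch", "forward", "Adam"]


@dataclass
class TrainingConfig:
    """Hyperparameters and mode flags for one training run."""

    learning_rate: float = 1e-3
    weight_layer_lr: float | None = 0.1  # None: use learning_rate for W too
    nonnegative_weights: bool = True  # project W onto [0, inf) after each step
    weight_layer_decay: float = 1e-3  # decoupled L2 decay on W per step
    net_decay: float = 1e-4  # decoupled L2 decay on all other parameters per step
    cosine_lr: bool = False  # cosine-anneal both learning rates to 0 over the run
    weight_init_low: float = 6.0   # W init ~ uniform(low, high); start in the
    weight_init_high: float = 10.0  # separation regime so drivers are visible
    batch_size: int = 64
    epochs: int = 100
    seed: int = 0
    weight_mode: str = "multi"  # "single" | "multi"
    attention: bool = True
    radius: int = 2
    temperature: float = 1.0
    edge_uses_updated_nodes: bool = True
    bias_outside_product: bool = False
    weight_layer_on: str = "mutation"  # "mutation" | "expression" | "both" (ablations)
    # architecture
    gnn_dim: int = 32
    gnn_steps: int | None = None  # default: matched to radius (T = r, min 1)
    gene_channels: tuple = (8, 16, 32)
    gene_kernel: int = 7
    gene_stride: int | tuple = 2  # one stride per conv stage, or a shared scalar
    gene_embedding: int = 128
    fusion_channels: int = 16
    fusion_kernel: int = 5
    pool_width: int = 2
    fusion_hidden: int = 128

    def __post_init__(self):
        if self.learning_rate < 0 or self.batch_size < 1 or self.epochs < 0:
            raise InputError("learning_rate, batch_size, epochs must be non-negative/positive")
        if self.weight_mode not in ("single", "multi"):
            raise InputError(f"unknown weight_mode {self.weight_mode!r}")
        if self.attention and self.weight_mode != "multi":
            raise InputError("self-attention requires the multi weight mode")
        if self.weight_layer_on not in ("mutation", "expression", "both"):
            raise InputError(f"unknown weight_layer_on {self.weight_layer_on!r}")


# ---------------------------------------------------------------------------
# layers


class Dense:
    def __init__(self, n_in, n_out, rng):
        lim = np.sqrt(6.0 / n_in)
        self.W = Tensor(rng.uniform(-lim, lim, (n_out, n_in)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W.T + self.b

    def parameters(self):
        return [self.W, self.b]


class Conv1d:
    def __init__(self, c_in, c_out, kernel, stride, rng):
        lim = np.sqrt(6.0 / (c_in * kernel))
        self.weight = Tensor(rng.uniform(-lim, lim, (c_out, c_in, kernel)), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv1d(x, self.weight, self.bias, stride=self.stride)

    def parameters(self):
        return [self.weight, self.bias]


class BatchNorm1d:
    def __init__(self, channels):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        return ad.batchnorm(x, self.gamma, self.beta, self.running_mean, self.running_var, training)

    def parameters(self):
        return [self.gamma, self.beta]


def _conv_out(L, k, s):
    return (L - k) // s + 1


@dataclass
class GeneBranchParameters:
    """3 conv stages + 1 fully connected stage mapping geneCom to an embedding."""

    convs: list
    fc: Dense
    flat_dim: int

    @classmethod
    def build(cls, n_genes: int, cfg: TrainingConfig, rng) -> "GeneBranchParameters":
        strides = cfg.gene_stride
        if np.isscalar(strides):
            strides = (strides,) * len(cfg.gene_channels)
        convs, c_in, L = [], 1, n_genes
        for c_out, stride in zip(cfg.gene_channels, strides):
            L_next = _conv_out(L, cfg.gene_kernel, stride)
            if L_next < 1:
                raise InputError(
                    f"gene branch: {n_genes} genes too few for kernel {cfg.gene_kernel} "
                    f"strides {strides} over {len(cfg.gene_channels)} stages"
                )
            convs.append(Conv1d(c_in, c_out, cfg.gene_kernel, stride, rng))
            c_in, L = c_out, L_next
        flat = c_in * L
        return cls(convs=convs, fc=Dense(flat, cfg.gene_embedding, rng), flat_dim=flat)

    def __call__(self, genecom: Tensor) -> Tensor:
        """(B, G) geneCom -> (B, gene_embedding)."""
        B = genecom.shape[0]
        x = genecom.reshape(B, 1, genecom.shape[1])
        for conv in self.convs:
            x = ad.relu(conv(x))
        return ad.relu(self.fc(x.reshape(B, self.flat_dim)))

    def parameters(self):
        out = []
        for c in self.convs:
            out += c.parameters()
        return out + self.fc.parameters()


@dataclass
class FusionParameters:
    """Prediction subnetwork: conv, pooling, batch norm, FC stages to a scalar."""

    conv: Conv1d
    bn: BatchNorm1d
    fc1: Dense
    fc2: Dense
    pool_width: int
    flat_dim: int

    @classmethod
    def build(cls, in_dim: int, cfg: TrainingConfig, rng) -> "FusionParameters":
        L1 = _conv_out(in_dim, cfg.fusion_kernel, 1)
        L2 = L1 // cfg.pool_width
        if L2 < 1:
            raise InputError("fusion subnetwork: embedding too short for conv/pool stages")
        conv = Conv1d(1, cfg.fusion_channels, cfg.fusion_kernel, 1, rng)
        flat = cfg.fusion_channels * L2
        return cls(
            conv=conv,
            bn=BatchNorm1d(cfg.fusion_channels),
            fc1=Dense(flat, cfg.fusion_hidden, rng),
            fc2=Dense(cfg.fusion_hidden, 1, rng),
            pool_width=cfg.pool_width,
            flat_dim=flat,
        )

    def __call__(self, fused: Tensor, training: bool) -> Tensor:
        """(B, in_dim) concatenated embeddings -> (B,) predictions."""
        B = fused.shape[0]
        x = fused.reshape(B, 1, fused.shape[1])
        x = ad.relu(self.conv(x))
        x = ad.maxpool1d(x, self.pool_width)
        x = self.bn(x, training)
        x = ad.relu(self.fc1(x.reshape(B, self.flat_dim)))
        return self.fc2(x).reshape(B)

    def parameters(self):
        return self.conv.parameters() + self.bn.parameters() + self.fc1.parameters() + self.fc2.parameters()


class Adam:
    """Adaptive-moment gradient descent."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# the model


class SwnetModel:
    """Vocabulary, GNN encoder, gene branch, fusion subnetwork and gene
    weight layer bound to one set of training drugs."""

    def __init__(self, drug_table, features: GeneFeatureSet, config: TrainingConfig):
        self.config = config
        self.features = features
        self.gene_ids = list(features.gene_ids)
        self.drug_ids = list(drug_table["drug_id"])
        self.smiles = list(drug_table["smiles"])
        self._drug_index = {d: i for i, d in enumerate(self.drug_ids)}
        rng = np.random.default_rng(config.seed)

        self.vocab = SubgraphVocabulary(radius=config.radius)
        graphs = [parse_smiles(s) for s in self.smiles]
        self.graphs = [assign_r_radius_ids(g, self.vocab, grow=True) for g in graphs]

        T = config.gnn_steps if config.gnn_steps is not None else max(config.radius, 1)
        self.encoder = GnnEncoder(
            self.vocab,
            dimension=config.gnn_dim,
            T=T,
            seed=config.seed,
            edge_uses_updated_nodes=config.edge_uses_updated_nodes,
            bias_outside_product=config.bias_outside_product,
        )

        self.fingerprints = [morgan_fingerprint(g) for g in self.graphs]
        self.similarity = similarity_matrix(self.graphs, drug_ids=self.drug_ids)
        if config.attention:
            self.attention_values = _softmax_rows(self.similarity.values, config.temperature)
        else:
            self.attention_values = None

        n_rows = len(self.drug_ids) if config.weight_mode == "multi" else 1
        self.W = Tensor(
            rng.uniform(config.weight_init_low, config.weight_init_high,
                        (n_rows, features.n_genes)),
            requires_grad=True,
        )

        self.gene_branch = GeneBranchParameters.build(features.n_genes, config, rng)
        self.fusion = FusionParameters.build(config.gnn_dim + config.gene_embedding, config, rng)
        self.training = False

    # -- parameter access --------------------------------------------------
    def parameters(self) -> list:
        return (
            self.encoder.parameters()
            + [self.W]
            + self.gene_branch.parameters()
            + self.fusion.parameters()
        )

    def weight_layer(self) -> GeneWeightLayer:
        """Current gene weight layer as plain arrays (raw W, pre-attention)."""
        mode = self.config.weight_mode
        return GeneWeightLayer(
            mode=mode,
            weights=self.W.data.copy(),
            drug_ids=self.drug_ids if mode == "multi" else None,
        )

    def effective_weight_matrix(self) -> np.ndarray:
        """W' = softmax(S) W when attention is on, else W itself."""
        if self.attention_values is not None:
            return self.attention_values @ self.W.data
        return self.W.data

    # -- forward -----------------------------------------------------------
    def _effective_W(self) -> Tensor:
        if self.attention_values is not None:
            return Tensor(self.attention_values) @ self.W
        return self.W

    def _forward_batch(self, drug_idx: np.ndarray, expr: np.ndarray, mut: np.ndarray) -> Tensor:
        """Predictions for a batch of training-drug records."""
        drug_idx = np.asarray(drug_idx)
        uniq, inv = np.unique(drug_idx, return_inverse=True)
        embs = ad.stack([self.encoder.encode(self.graphs[d]).h_G for d in uniq], axis=0)
        graph_emb = embs.gather_rows(inv)

        Wp = self._effective_W()
        if self.config.weight_mode == "multi":
            w_rows = Wp.gather_rows(drug_idx)
        else:
            w_rows = Wp.gather_rows(np.zeros(len(drug_idx), dtype=int))
        genecom = self._combine(Tensor(expr), Tensor(mut), w_rows)
        gene_emb = self.gene_branch(genecom)
        fused = ad.concat([graph_emb, gene_emb], axis=1)
        return self.fusion(fused, self.training)

    def _combine(self, expr: Tensor, mut: Tensor, w_rows: Tensor) -> Tensor:
        on = self.config.weight_layer_on
        if on == "mutation":
            return expr + mut * w_rows
        if on == "expression":
            return expr * w_rows + mut
        return (expr + mut) * w_rows

    def _rows(self, records):
        drug_idx, expr, mut = [], [], []
        unknown = []
        for cell, drug in records:
            if drug not in self._drug_index:
                unknown.append(drug)
                continue
            e, m = self.features.rows_for(cell)
            drug_idx.append(self._drug_index[drug])
            expr.append(e)
            mut.append(m)
        if unknown:
            raise InputError(f"unknown drug ids: {sorted(set(unknown))}")
        return np.array(drug_idx, dtype=int), np.array(expr), np.array(mut)

    def predict(self, records, features: GeneFeatureSet | None = None) -> np.ndarray:
        """Predicted ln IC50 for (cell_id, drug_id) pairs, in input order."""
        if features is not None:
            old, self.features = self.features, features
        try:
            if not records:
                return np.zeros(0)
            self.training = False
            drug_idx, expr, mut = self._rows(records)
            out = []
            bs = self.config.batch_size
            for lo in range(0, len(records), bs):
                sl = slice(lo, lo + bs)
                out.append(self._forward_batch(drug_idx[sl], expr[sl], mut[sl]).data)
            return np.concatenate(out)
        finally:
            if features is not None:
                self.features = old

    def predict_new_drug(self, smiles: str, cells, features: GeneFeatureSet | None = None) -> np.ndarray:
        """Predictions for a compound unseen in training.

        The molecule is tokenized against the frozen vocabulary (unseen
        signatures map to the unknown token) and its mutation weight row is
        inferred by softmax-mixing the trained rows with its Tanimoto
        similarities to the training compounds.
        """
        feats = features if features is not None else self.features
        graph = assign_r_radius_ids(parse_smiles(smiles), self.vocab, grow=False)
        fp = morgan_fingerprint(graph)
        if self.config.weight_mode == "multi":
            w_row = infer_new_drug_weight(
                fp, self.fingerprints, self.weight_layer(), self.config.temperature
            )
        else:
            w_row = self.W.data[0]
        self.training = False
        emb = self.encoder.encode(graph).h_G
        rows = [feats.rows_for(c) for c in cells]
        expr = Tensor(np.array([r[0] for r in rows]))
        mut = Tensor(np.array([r[1] for r in rows]))
        genecom = self._combine(expr, mut, Tensor(np.broadcast_to(w_row, expr.shape).copy()))
        gene_emb = self.gene_branch(genecom)
        B = len(cells)
        graph_emb = ad.stack([emb] * B, axis=0)
        fused = ad.concat([graph_emb, gene_emb], axis=1)
        return self.fusion(fused, False).data


def forward(model: SwnetModel, graph: MolecularGraph, drug_index: int | None,
            expr_row, mut_row) -> float:
    """Single-record prediction.

    ``drug_index`` selects the training drug's weight row; ``None`` triggers
    new-drug weight inference from the graph's own fingerprint.
    """
    expr = np.atleast_2d(np.asarray(expr_row, dtype=float))
    mut = np.atleast_2d(np.asarray(mut_row, dtype=float))
    model.training = False
    if drug_index is not None:
        if not (0 <= drug_index < len(model.drug_ids)):
            raise InputError(f"drug index {drug_index} out of range")
        return float(model._forward_batch(np.array([drug_index]), expr, mut).data[0])
    fp = morgan_fingerprint(graph)
    if model.config.weight_mode == "multi":
        w_row = infer_new_drug_weight(fp, model.fingerprints, model.weight_layer(),
                                      model.config.temperature)
    else:
        w_row = model.W.data[0]
    g = graph if graph.node_subgraph_ids is not None else assign_r_radius_ids(
        graph, model.vocab, grow=False)
    emb = model.encoder.encode(g).h_G
    genecom = model._combine(Tensor(expr), Tensor(mut), Tensor(w_row.reshape(1, -1)))
    gene_emb = model.gene_branch(genecom)
    fused = ad.concat([emb.reshape(1, -1), gene_emb], axis=1)
    return float(model.fusion(fused, False).data[0])


def predict_batch(model: SwnetModel, records, features: GeneFeatureSet | None = None) -> np.ndarray:
    """Vectorized counterpart of :func:`forward` over (cell, drug) records."""
    return model.predict(list(records), features=features)


def train(model: SwnetModel, data: ResponseDataset, cfg: TrainingConfig | None = None,
          features: GeneFeatureSet | None = None, verbose: bool = False):
    """Fit all drugs jointly with one shared MSE loss; returns the loss trace.

    The trace holds one mean training MSE per epoch.  Training is fully
    reproducible given the config seed (it drives batch shuffling; parameter
    initialization is owned by the model's own seed).
    """
    cfg = cfg or model.config
    feats = features if features is not None else model.features
    if len(data) == 0:
        raise InputError("empty training dataset")
    records = [(c, d) for c, d, _y in data.records]
    y = np.array([r[2] for r in data.records])
    old_feats, model.features = model.features, feats
    drug_idx, expr, mut = model._rows(records)
    model.features = old_feats

    # the gene weight layer trains on its own (typically larger) learning rate:
    # attention mixing scales its gradients down by the row-stochastic map
    others = [p for p in model.parameters() if p is not model.W]
    opts = [Adam(others, lr=cfg.learning_rate),
            Adam([model.W], lr=cfg.weight_layer_lr if cfg.weight_layer_lr is not None
                 else cfg.learning_rate)]
    rng = np.random.default_rng(cfg.seed)
    n = len(records)
    trace = []
    base_lrs = [o.lr for o in opts]
    for epoch in range(cfg.epochs):
        if cfg.cosine_lr:
            scale = 0.5 * (1.0 + np.cos(np.pi * epoch / cfg.epochs))
            for o, lr0 in zip(opts, base_lrs):
                o.lr = lr0 * scale
        order = rng.permutation(n)
        model.training = True
        total, count = 0.0, 0
        for b, lo in enumerate(range(0, n, cfg.batch_size)):
            idx = order[lo : lo + cfg.batch_size]
            for opt in opts:
                opt.zero_grad()
            pred = model._forward_batch(drug_idx[idx], expr[idx], mut[idx])
            loss = ((pred - Tensor(y[idx])) ** 2).mean()
            lval = loss.item()
            if not np.isfinite(lval):
                raise RuntimeError(f"non-finite training loss in epoch {epoch}, batch {b}")
            loss.backward()
            for opt in opts:
                opt.step()
            if cfg.net_decay:
                for p in others:
                    p.data *= 1.0 - cfg.net_decay
            if cfg.weight_layer_decay:
                model.W.data *= 1.0 - cfg.weight_layer_decay
            if cfg.nonnegative_weights:
                np.maximum(model.W.data, 0.0, out=model.W.data)
            total += lval * len(idx)
            count += len(idx)
        trace.append(total / count)
        if verbose:
            print(f"epoch {epoch + 1}/{cfg.epochs}  train MSE {trace[-1]:.4f}")
    model.training = False
    return model, trace
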