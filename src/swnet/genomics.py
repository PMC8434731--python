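"""Gene feature construction and the drug-similarity gene weight layer.

Expression is z-scored per cell line; somatic nonsynonymous mutations are
collapsed to a binary cell x gene matrix.  The two are fused per record as

    geneCom = geneExp + geneVar (*) w'

where (*) is the element-wise product and w' is a trainable weight row —
either one shared row (single mode) or one row per drug (multi mode).  In the
self-attention variant the weight matrix W is replaced each forward pass by
W' = softmax(S) W, with S the Morgan/Tanimoto drug-similarity matrix, so
structurally similar drugs share mutation-weight information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import DrugSimilarityMatrix, FingerprintBitSet, InputError, tanimoto

__all__ = [
    "GeneFeatureSet",
    "GeneWeightLayer",
    "AttentionMap",
    "zscore_per_cell",
    "collapse_mutations",
    "merge_gene_lists",
    "combine_gene_features",
    "attention_map",
    "apply_self_attention",
    "infer_new_drug_weight",
    "extract_top_weight_genes",
    "top_k_weight_genes",
    "NONSYNONYMOUS_CONSEQUENCES",
]

#: consequence labels treated as somatic nonsynonymous events
NONSYNONYMOUS_CONSEQUENCES = frozenset(
    {
        "missense",
        "missense_mutation",
        "nonsense",
        "nonsense_mutation",
        "frameshift",
        "frame_shift_del",
        "frame_shift_ins",
        "in_frame_del",
        "in_frame_ins",
        "nonstop",
        "nonstop_mutation",
        "splice_site",
        "start_lost",
        "translation_start_site",
    }
)


@dataclass
class GeneFeatureSet:
    """Paired z-scored expression and binary mutation matrices (cells x genes)."""

    gene_ids: list
    cell_ids: list
    expression: np.ndarray
    mutation: np.ndarray

    def __post_init__(self):
        self.expression = np.asarray(self.expression, dtype=float)
        self.mutation = np.asarray(self.mutation, dtype=float)
        shape = (len(self.cell_ids), len(self.gene_ids))
        if self.expression.shape != shape or self.mutation.shape != shape:
            raise InputError(
                f"feature matrices must both be {shape}; got expression "
                f"{self.expression.shape}, mutation {self.mutation.shape}"
            )
        if not np.isin(self.mutation, (0.0, 1.0)).all():
            raise InputError("mutation matrix entries must be binary 0/1")
        if self.expression.shape[1] >= 2 and self.expression.size:
            mean = self.expression.mean(axis=1)
            sd = self.expression.std(axis=1)
            nonzero = np.abs(self.expression).max(axis=1) > 0
            bad = nonzero & ((np.abs(mean) > 1e-8) | (np.abs(sd - 1) > 1e-6))
            if bad.any():
                raise InputError(
                    f"{int(bad.sum())} expression row(s) are not z-scored "
                    "(per-row mean 0, population sd 1); normalize with zscore_per_cell"
                )
        self._cell_index = {c: i for i, c in enumerate(self.cell_ids)}

    def rows_for(self, cell_id) -> tuple:
        """(expression row, mutation row) for one cell line."""
        try:
            i = self._cell_index[cell_id]
        except KeyError:
            raise InputError(f"unknown cell line id: {cell_id!r}") from None
        return self.expression[i], self.mutation[i]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class GeneWeightLayer:
    """Mutation weight row(s): one shared row (single) or one per drug (multi)."""

    mode: str  # "single" | "multi"
    weights: np.ndarray  # (1, G) or (n_drugs, G)
    drug_ids: list | None = None

    def __post_init__(self):
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        if self.mode not in ("single", "multi"):
            raise InputError(f"unknown weight-layer mode: {self.mode!r}")
        if not np.isfinite(self.weights).all():
            raise InputError("gene weight layer contains non-finite values")
        if self.mode == "single" and self.weights.shape[0] != 1:
            raise InputError("single mode requires exactly one weight row")
        if self.mode == "multi":
            if self.drug_ids is None or len(self.drug_ids) != self.weights.shape[0]:
                raise InputError("multi mode requires drug_ids aligned to weight rows")

    def row_for(self, drug_index: int | None) -> np.ndarray:
        if self.mode == "single":
            return self.weights[0]
        if drug_index is None:
            raise InputError("multi-mode weight layer needs a drug index")
        return self.weights[drug_index]


@dataclass
class AttentionMap:
    """Row-stochastic drug x drug matrix from the softmaxed similarity scores."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if n != m:
            raise InputError("attention map must be square")
        if not np.allclose(self.values.sum(axis=1), 1.0, atol=1e-8):
            raise InputError("attention map rows must sum to 1")
        if (self.values <= 0).any():
            raise InputError("attention map entries must be positive")


def zscore_per_cell(raw_expression: np.ndarray) -> np.ndarray:
    """Z-score each row (cell line) using the population standard deviation.

    Constant rows cannot be scaled and are mapped to all zeros with a warning.
    """
    raw = np.asarray(raw_expression, dtype=float)
    if raw.size == 0:
        raise InputError("empty expression matrix")
    if raw.ndim != 2 or raw.shape[1] < 2:
        raise InputError("expression matrix needs at least 2 genes per cell line")
    mean = raw.mean(axis=1, keepdims=True)
    sd = raw.std(axis=1, keepdims=True)  # population sd (ddof=0)
    constant = sd[:, 0] == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant expression row(s) mapped to zeros",
            stacklevel=2,
        )
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (raw - mean) / sd_safe
    z[constant] = 0.0
    return z


def collapse_mutations(
    variant_records: list,
    cell_ids: list,
    gene_ids: list,
    nonsynonymous: frozenset = NONSYNONYMOUS_CONSEQUENCES,
) -> np.ndarray:
    """Binary cells x genes matrix: 1 iff >= 1 nonsynonymous record for the pair.

    All somatic nonsynonymous events for a gene are collapsed regardless of
    genomic location.  Records naming cells or genes outside the declared
    universe raise an :class:`InputError` listing the offenders.
    """
    cell_index = {c: i for i, c in enumerate(cell_ids)}
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    out = np.zeros((len(cell_ids), len(gene_ids)))
    unknown = []
    for cell, gene, consequence in variant_records:
        if cell not in cell_index or gene not in gene_index:
            unknown.append((cell, gene))
            continue
        if str(consequence).lower() in nonsynonymous:
            out[cell_index[cell], gene_index[gene]] = 1.0
    if unknown:
        raise InputError(f"variant records reference unknown cell/gene ids: {unknown}")
    return out


def merge_gene_lists(cancer_genes, landmark_genes, available) -> list:
    """Union of the two curated lists restricted to measured genes, sorted.

    Lexicographic ordering fixes the convolution axis deterministically.
    """
    avail = set(available)
    merged = sorted((set(cancer_genes) | set(landmark_genes)) & avail)
    if not merged:
        raise InputError("gene-list merge produced an empty gene set")
    return merged


def combine_gene_features(expr_row, mut_row, weight_row) -> np.ndarray:
    """geneCom = geneExp + geneVar (element-wise *) w'."""
    expr_row = np.asarray(expr_row, dtype=float)
    mut_row = np.asarray(mut_row, dtype=float)
    weight_row = np.asarray(weight_row, dtype=float)
    if not (expr_row.shape == mut_row.shape == weight_row.shape):
        raise InputError(
            f"length mismatch: expr {expr_row.shape}, mut {mut_row.shape}, "
            f"weight {weight_row.shape}"
        )
    return expr_row + mut_row * weight_row


def _softmax_rows(x: np.ndarray, temperature: float = 1.0) -> np.ndarray:
    z = x / temperature
    z = z - z.max(axis=-1, keepdims=True)  # numerical stabilization
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def attention_map(sim: DrugSimilarityMatrix, temperature: float = 1.0) -> AttentionMap:
    """Row-wise softmax of the Tanimoto similarity matrix."""
    return AttentionMap(values=_softmax_rows(sim.values, temperature))


def apply_self_attention(W: GeneWeightLayer, amap: AttentionMap) -> GeneWeightLayer:
    """W' = softmax(S) W — every drug's row becomes a convex mixture of rows."""
    if W.mode != "multi":
        raise InputError("self-attention applies to a multi-mode weight layer")
    if amap.values.shape[0] != W.weights.shape[0]:
        raise InputError(
            f"attention map has {amap.values.shape[0]} rows but weight layer "
            f"has {W.weights.shape[0]}"
        )
    return GeneWeightLayer(mode="multi", weights=amap.values @ W.weights, drug_ids=W.drug_ids)


def infer_new_drug_weight(
    new_fp: FingerprintBitSet,
    train_fps: list,
    trained_W: GeneWeightLayer,
    temperature: float = 1.0,
) -> np.ndarray:
    """Weight row for an unseen compound from its similarity to training drugs.

    The softmaxed Tanimoto similarities to the training compounds mix the
    trained weight rows, mirroring how the attention map is built in training.
    """
    if not train_fps:
        raise InputError("infer_new_drug_weight requires a non-empty training set")
    if trained_W.weights.shape[0] != len(train_fps):
        raise InputError("trained weight layer not aligned with training fingerprints")
    sims = np.array([tanimoto(new_fp, fp) for fp in train_fps])
    coeff = _softmax_rows(sims[None, :], temperature)[0]
    return coeff @ trained_W.weights


def _minmax_normalize(row: np.ndarray) -> np.ndarray:
    lo, hi = row.min(), row.max()
    if hi == lo:
        return None
    return (row - lo) / (hi - lo)


def extract_top_weight_genes(weight_row, gene_ids, atol: float = 1e-9) -> list:
    """Genes whose min–max-normalized weight equals 1 (the argmax set).

    Weights are normalized to [0, 1] per drug row before thresholding; a
    constant row carries no information and yields an empty list plus warning.
    """
    row = np.asarray(weight_row, dtype=float)
    if row.size == 0:
        raise InputError("empty weight row")
    norm = _minmax_normalize(row)
    if norm is None:
        warnings.warn("constant weight row: no informative gene", stacklevel=2)
        return []
    return [g for g, v in zip(gene_ids, norm) if v >= 1.0 - atol]


def top_k_weight_genes(weight_row, gene_ids, k: int = 3) -> list:
    """The k genes with the largest min–max-normalized weights, descending."""
    row = np.asarray(weight_row, dtype=float)
    norm = _minmax_normalize(row)
    if norm is None:
        return []
    order = np.argsort(-norm, kind="stable")[:k]
    return [gene_ids[i] for i in order]
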