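"""Readers/writers for the delimited-text input formats and checkpoints.

All tabular inputs are comma-separated UTF-8 with a mandatory header row and
'.' decimal separator.  Formats:

* SMILES table — columns ``drug_id,smiles`` (``.smi`` files: whitespace
  separated ``SMILES id`` lines, no header, per the usual convention);
* expression / mutation — first column ``cell_id``, remaining columns one per
  gene symbol;
* responses — columns ``cell_id,drug_id,ln_ic50``; an empty ``ln_ic50`` field
  marks a missing measurement and the record is dropped (counted);
* gene lists — one symbol per line, ``#`` comments allowed;
* checkpoints — a single NumPy archive holding every parameter array, the
  vocabulary, the training-drug table, the feature matrices and a config echo.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chem import InputError, SubgraphVocabulary
from .evaluation import ResponseDataset
from .genomics import GeneFeatureSet, merge_gene_lists, zscore_per_cell
from .model import SwnetModel, TrainingConfig

__all__ = [
    "RunConfig",
    "load_smiles_table",
    "load_matrix",
    "load_gene_list",
    "load_response_table",
    "build_feature_set",
    "load_inputs",
    "save_checkpoint",
    "load_checkpoint",
]

log = logging.getLogger("swnet")


@dataclass
class RunConfig:
    """Paths plus mode flags for one pipeline run."""

    smiles: str
    expression: str
    mutation: str
    response: str
    cancer_genes: str | None = None
    landmark_genes: str | None = None
    output_dir: str = "swnet_out"
    seed: int = 0
    train_fraction: float = 0.9
    split: str = "instance"  # "instance" | "cell_line"
    training: TrainingConfig = field(default_factory=TrainingConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        tc = TrainingConfig(**raw.pop("training", {}))
        try:
            cfg = cls(training=tc, **raw)
        except TypeError as exc:
            raise InputError(f"bad config key: {exc}") from None
        for role in ("smiles", "expression", "mutation", "response"):
            p = getattr(cfg, role)
            if not Path(p).exists():
                raise InputError(f"{role} file not found: {p}")
        return cfg


def load_smiles_table(path) -> pd.DataFrame:
    """Drug table with columns drug_id, smiles."""
    path = Path(path)
    if path.suffix == ".smi":
        rows = []
        for line in path.read_text().splitlines():
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 2:
                raise InputError(f".smi line needs 'SMILES id': {line!r}")
            rows.append((parts[1], parts[0]))
        df = pd.DataFrame(rows, columns=["drug_id", "smiles"])
    else:
        df = pd.read_csv(path, dtype=str)
        missing = {"drug_id", "smiles"} - set(df.columns)
        if missing:
            raise InputError(f"SMILES table missing columns: {sorted(missing)}")
        df = df[["drug_id", "smiles"]]
    if df["drug_id"].duplicated().any():
        dups = sorted(df.loc[df["drug_id"].duplicated(), "drug_id"].unique())
        raise InputError(f"duplicate drug ids: {dups}")
    return df


def load_matrix(path) -> pd.DataFrame:
    """Cell x gene matrix; first column is the cell id."""
    df = pd.read_csv(path, index_col=0)
    if df.shape[1] == 0:
        raise InputError(f"matrix {path} has no gene columns")
    return df


def load_gene_list(path) -> list:
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.append(line)
    return genes


def load_response_table(path) -> tuple:
    """(ResponseDataset, n_dropped): empty ln_ic50 fields are dropped."""
    df = pd.read_csv(path, dtype={"cell_id": str, "drug_id": str})
    missing = {"cell_id", "drug_id", "ln_ic50"} - set(df.columns)
    if missing:
        raise InputError(f"response table missing columns: {sorted(missing)}")
    n0 = len(df)
    df = df.dropna(subset=["ln_ic50"])
    n_dropped = n0 - len(df)
    if n_dropped:
        log.info("dropped %d record(s) with missing ln_ic50", n_dropped)
    data = ResponseDataset(
        records=list(
            zip(df["cell_id"], df["drug_id"], df["ln_ic50"].astype(float))
        ),
        split=list(df["split"]) if "split" in df.columns else None,
    )
    return data, n_dropped


def build_feature_set(
    expr_df: pd.DataFrame,
    mut_df: pd.DataFrame,
    gene_lists: tuple | None = None,
    already_normalized: bool = False,
) -> GeneFeatureSet:
    """Align expression and mutation, select genes, z-score per cell line.

    Mutation columns are realigned to the expression header order; both
    matrices must cover the same cells and genes.  When curated gene lists
    are supplied the union-restricted-to-available subset is used, and
    z-scoring is applied per cell over the selected genes.
    """
    if set(expr_df.columns) != set(mut_df.columns):
        diff = sorted(set(expr_df.columns) ^ set(mut_df.columns))
        raise InputError(f"expression/mutation gene headers differ, first mismatch: {diff[0]!r}")
    if list(expr_df.index) != list(mut_df.index):
        if set(expr_df.index) != set(mut_df.index):
            diff = sorted(set(expr_df.index) ^ set(mut_df.index))
            raise InputError(f"expression/mutation cell ids differ: {diff[:5]}")
        mut_df = mut_df.loc[expr_df.index]
    mut_df = mut_df[expr_df.columns]  # realign by header

    if gene_lists is not None:
        cancer, landmark = gene_lists
        genes = merge_gene_lists(cancer, landmark, list(expr_df.columns))
    else:
        genes = sorted(expr_df.columns)
    expr = expr_df[genes].to_numpy(dtype=float)
    mut = mut_df[genes].to_numpy(dtype=float)
    if not already_normalized:
        expr = zscore_per_cell(expr)
    return GeneFeatureSet(
        gene_ids=genes, cell_ids=list(expr_df.index), expression=expr, mutation=mut
    )


def load_inputs(config: RunConfig):
    """Load and cross-validate the four inputs.

    Every response record's cell and drug must resolve against the feature
    matrices and the drug table; records with missing ln IC50 are dropped
    with a logged count.
    """
    drug_table = load_smiles_table(config.smiles)
    expr_df = load_matrix(config.expression)
    mut_df = load_matrix(config.mutation)
    gene_lists = None
    if config.cancer_genes or config.landmark_genes:
        cancer = load_gene_list(config.cancer_genes) if config.cancer_genes else []
        landmark = load_gene_list(config.landmark_genes) if config.landmark_genes else []
        gene_lists = (cancer, landmark)
    features = build_feature_set(expr_df, mut_df, gene_lists=gene_lists)
    responses, n_dropped = load_response_table(config.response)

    known_cells = set(features.cell_ids)
    known_drugs = set(drug_table["drug_id"])
    bad_cells = sorted({c for c, _d, _y in responses.records if c not in known_cells})
    bad_drugs = sorted({d for _c, d, _y in responses.records if d not in known_drugs})
    if bad_cells or bad_drugs:
        raise InputError(
            f"unresolvable ids in response table: {len(bad_cells)} cell(s) "
            f"{bad_cells[:5]}, {len(bad_drugs)} drug(s) {bad_drugs[:5]}"
        )
    return drug_table, features, responses, n_dropped


# ---------------------------------------------------------------------------
# checkpointing


def _named_parameters(model: SwnetModel) -> dict:
    params = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    params["bn_running_mean"] = model.fusion.bn.running_mean
    params["bn_running_var"] = model.fusion.bn.running_var
    return params


def save_checkpoint(model: SwnetModel, path) -> None:
    """Serialize the model to one ``.npz`` archive (parameters + provenance)."""
    vocab = {
        "radius": model.vocab.radius,
        "node_signature_to_id": model.vocab.node_signature_to_id,
        "edge_signature_to_id": model.vocab.edge_signature_to_id,
    }
    meta = {
        "config": asdict(model.config),
        "vocab": vocab,
        "drug_ids": model.drug_ids,
        "smiles": model.smiles,
        "gene_ids": model.gene_ids,
        "cell_ids": model.features.cell_ids,
    }
    arrays = _named_parameters(model)
    np.savez(
        path,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        expression=model.features.expression,
        mutation=model.features.mutation,
        **arrays,
    )


def load_checkpoint(path, features: GeneFeatureSet | None = None) -> SwnetModel:
    """Rebuild a model from an archive; predictions round-trip bit-exactly.

    If ``features`` is supplied it replaces the stored feature matrices and
    must have the same gene count and order as at training time.
    """
    try:
        with np.load(path, allow_pickle=False) as npz:
            data = {k: npz[k] for k in npz.files}
    except Exception as exc:
        raise InputError(f"cannot read checkpoint {path}: {exc}") from None
    meta = json.loads(bytes(data["meta"]).decode())
    config = TrainingConfig(**{
        k: tuple(v) if isinstance(v, list) else v for k, v in meta["config"].items()
    })
    stored = GeneFeatureSet(
        gene_ids=meta["gene_ids"],
        cell_ids=meta["cell_ids"],
        expression=data["expression"],
        mutation=data["mutation"],
    )
    if features is not None:
        if list(features.gene_ids) != list(meta["gene_ids"]):
            raise InputError(
                f"checkpoint was trained on {len(meta['gene_ids'])} genes; "
                f"provided features have {features.n_genes} (or a different order)"
            )
        stored = features
    drug_table = pd.DataFrame({"drug_id": meta["drug_ids"], "smiles": meta["smiles"]})
    model = SwnetModel(drug_table, stored, config)
    model.vocab.node_signature_to_id.clear()
    model.vocab.node_signature_to_id.update(
        {k: int(v) for k, v in meta["vocab"]["node_signature_to_id"].items()}
    )
    model.vocab.edge_signature_to_id.clear()
    model.vocab.edge_signature_to_id.update(
        {k: int(v) for k, v in meta["vocab"]["edge_signature_to_id"].items()}
    )
    for i, p in enumerate(model.parameters()):
        saved = data[f"param_{i}"]
        if saved.shape != p.data.shape:
            raise InputError(
                f"checkpoint parameter {i} has shape {saved.shape}, model expects {p.data.shape}"
            )
        p.data = saved
    model.fusion.bn.running_mean = data["bn_running_mean"]
    model.fusion.bn.running_var = data["bn_running_var"]
    return model
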