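"""Regression metrics and train/test splitting protocols.

Two split protocols are provided: a uniform random split of the individual
(cell line, drug) response records, and a cell-line split in which whole cell
lines are held out so their genomic profiles never appear in training — the
harder generalization setting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chem import InputError

__all__ = [
    "ResponseDataset",
    "MetricReport",
    "mse",
    "r_squared",
    "random_instance_split",
    "cell_line_split",
]


@dataclass
class ResponseDataset:
    """(cell_id, drug_id, ln IC50) records with optional train/test tags."""

    records: list  # list of (cell_id, drug_id, float ln_ic50)
    split: list | None = None  # parallel list of "train"/"test", or None

    def __post_init__(self):
        seen = set()
        for cell, drug, y in self.records:
            if not np.isfinite(y):
                raise InputError(f"non-finite ln IC50 for ({cell!r}, {drug!r})")
            if (cell, drug) in seen:
                raise InputError(f"duplicate response record ({cell!r}, {drug!r})")
            seen.add((cell, drug))
        if self.split is not None:
            if len(self.split) != len(self.records):
                raise InputError("split tags must parallel the records")
            bad = set(self.split) - {"train", "test"}
            if bad:
                raise InputError(f"unknown split tags: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, tag: str) -> "ResponseDataset":
        if self.split is None:
            raise InputError("dataset has no split tags")
        recs = [r for r, t in zip(self.records, self.split) if t == tag]
        return ResponseDataset(records=recs)

    @property
    def cell_ids(self) -> list:
        return sorted({r[0] for r in self.records})

    @property
    def drug_ids(self) -> list:
        return sorted({r[1] for r in self.records})

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.records, columns=["cell_id", "drug_id", "ln_ic50"])
        if self.split is not None:
            df["split"] = self.split
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ResponseDataset":
        records = list(df[["cell_id", "drug_id", "ln_ic50"]].itertuples(index=False, name=None))
        split = list(df["split"]) if "split" in df.columns else None
        return cls(records=records, split=split)


@dataclass
class MetricReport:
    mse: float
    r2: float
    n: int


def mse(y, yhat) -> float:
    """Mean squared error (1/N) sum (y_i - yhat_i)^2."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise InputError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise InputError("mse of empty vectors is undefined")
    return float(np.mean((y - yhat) ** 2))


def r_squared(y, yhat) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot (can be negative)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise InputError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size < 2:
        raise InputError("r_squared needs at least 2 observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise InputError("r_squared undefined for constant targets")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def report(y, yhat) -> MetricReport:
    return MetricReport(mse=mse(y, yhat), r2=r_squared(y, yhat), n=len(np.asarray(y)))


def random_instance_split(
    data: ResponseDataset, train_fraction: float = 0.9, seed: int = 0
) -> ResponseDataset:
    """Uniform random record-level split; train size = floor(fraction * N)."""
    if not (0 < train_fraction < 1):
        raise InputError("train_fraction must lie in (0, 1)")
    n = len(data)
    if n < 2:
        raise InputError("need at least 2 records to split")
    n_train = int(np.floor(train_fraction * n))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    tags = np.empty(n, dtype=object)
    tags[perm[:n_train]] = "train"
    tags[perm[n_train:]] = "test"
    return replace(data, split=list(tags))


def cell_line_split(
    data: ResponseDataset, train_fraction: float = 0.9, seed: int = 0
) -> ResponseDataset:
    """Hold out whole cell lines: train cells = floor(fraction * #cells).

    Every record inherits its cell line's tag, so no genomic profile appears
    on both sides of the split.
    """
    if not (0 < train_fraction < 1):
        raise InputError("train_fraction must lie in (0, 1)")
    cells = data.cell_ids
    if len(cells) < 2:
        raise InputError("need at least 2 distinct cell lines to split")
    n_train = int(np.floor(train_fraction * len(cells)))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(cells))
    train_cells = {cells[i] for i in perm[:n_train]}
    tags = ["train" if cell in train_cells else "test" for cell, _, _ in data.records]
    return replace(data, split=tags)
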