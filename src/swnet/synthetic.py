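"""Synthetic fixture datasets with known generative structure.

The generator emits the four standard inputs (SMILES table, expression,
mutation, responses) from an additive ground-truth model

    ln IC50(cell, drug) = offset(drug)
                          + <expr(cell), beta_expr>
                          + <mut(cell), beta_mut(drug)>
                          + Normal(0, noise_sd)

with drug-specific mutation effects (each drug has one dominant "driver" gene
plus a few minor ones), so the multi-row gene weight layer has a true signal
to recover and an ordinary least-squares fit can verify that the signal
exists.  Compounds are drawn from a fixed library of small valid SMILES so
molecular graphs and fingerprints are non-degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import InputError, parse_smiles
from .evaluation import ResponseDataset
from .genomics import GeneFeatureSet, zscore_per_cell

__all__ = ["SMILES_LIBRARY", "SyntheticSpec", "generate"]

#: fixed library of small, chemically diverse, valid SMILES
SMILES_LIBRARY = [
    "C", "CC", "CCC", "CCCC", "CC(C)C", "CCCCC", "CC(C)(C)C",
    "CO", "CCO", "CCCO", "CC(C)O", "OCCO", "CCOCC", "COC",
    "CC=O", "CC(=O)C", "CC(=O)O", "CCN", "NCCO", "CCCl", "CC(N)C(=O)O",
    "c1ccccc1", "Cc1ccccc1", "CCc1ccccc1", "Oc1ccccc1", "Nc1ccccc1",
    "COc1ccccc1", "Clc1ccccc1", "Cc1ccc(C)cc1", "c1ccc2ccccc2c1",
    "N#Cc1ccccc1", "c1ccncc1", "c1ccoc1", "c1ccsc1", "c1cc[nH]c1",
    "c1cnc[nH]1", "c1ccc2[nH]ccc2c1", "C1CCCCC1", "C1CCOC1", "C1CCNCC1",
]


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset; generation is a pure
    function of this object.

    Defaults give ~3000 response records (full cell x drug cross) with a
    moderate noise floor, drug-specific mutation drivers and a dense but
    modest expression effect.
    """

    n_cells: int = 300
    n_genes: int = 50
    n_drugs: int = 10
    seed: int = 0
    noise_sd: float = 0.3
    mutation_rate: float = 0.2
    expr_effect_sd: float = 0.2       # sd of the shared expression coefficients
    driver_effect: tuple = (1.5, 2.5)  # uniform range of each drug's top mutation effect
    minor_effect: tuple = (0.3, 0.8)   # uniform range of secondary mutation effects
    n_minor_genes: int = 3
    offset_sd: float = 1.5             # spread of per-drug baseline potency
    molecular_effect: str = "offset"   # "offset" | "aromatic" (offset from aromatic atom count)

    def __post_init__(self):
        if min(self.n_cells, self.n_genes, self.n_drugs) < 1:
            raise InputError("dimensions must be positive")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be non-negative")
        if not (0 <= self.mutation_rate <= 1):
            raise InputError("mutation_rate must lie in [0, 1]")
        if self.n_drugs > len(SMILES_LIBRARY):
            raise InputError(
                f"n_drugs={self.n_drugs} exceeds the SMILES library size {len(SMILES_LIBRARY)}"
            )


def generate(spec: SyntheticSpec):
    """Generate (drug table, GeneFeatureSet, ResponseDataset, ground truth)."""
    rng = np.random.default_rng(spec.seed)

    drug_ids = [f"D{i:02d}" for i in range(spec.n_drugs)]
    smiles = list(rng.choice(SMILES_LIBRARY, size=spec.n_drugs, replace=False))
    drug_table = pd.DataFrame({"drug_id": drug_ids, "smiles": smiles})

    cell_ids = [f"CL{i:04d}" for i in range(spec.n_cells)]
    gene_ids = [f"G{i:03d}" for i in range(spec.n_genes)]

    raw_expr = rng.normal(size=(spec.n_cells, spec.n_genes))
    expression = zscore_per_cell(raw_expr)
    mutation = (rng.random((spec.n_cells, spec.n_genes)) < spec.mutation_rate).astype(float)
    features = GeneFeatureSet(
        gene_ids=gene_ids, cell_ids=cell_ids, expression=expression, mutation=mutation
    )

    beta_expr = rng.normal(0.0, spec.expr_effect_sd, size=spec.n_genes)

    beta_mut = np.zeros((spec.n_drugs, spec.n_genes))
    top_gene = []
    for d in range(spec.n_drugs):
        n_pick = min(1 + spec.n_minor_genes, spec.n_genes)
        picks = rng.choice(spec.n_genes, size=n_pick, replace=False)
        beta_mut[d, picks[0]] = rng.uniform(*spec.driver_effect)
        for g in picks[1:]:
            beta_mut[d, g] = rng.uniform(*spec.minor_effect)
        top_gene.append(gene_ids[picks[0]])

    if spec.molecular_effect == "aromatic":
        offsets = np.array(
            [0.25 * sum(1 for _s, arom, _c, _d in parse_smiles(s).nodes if arom) for s in smiles],
            dtype=float,
        )
    elif spec.molecular_effect == "offset":
        offsets = rng.normal(0.0, spec.offset_sd, size=spec.n_drugs)
    else:
        raise InputError(f"unknown molecular_effect mode: {spec.molecular_effect!r}")

    records = []
    noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_cells, spec.n_drugs))
    expr_term = expression @ beta_expr  # (n_cells,)
    mut_term = mutation @ beta_mut.T  # (n_cells, n_drugs)
    for c in range(spec.n_cells):
        for d in range(spec.n_drugs):
            y = offsets[d] + expr_term[c] + mut_term[c, d] + noise[c, d]
            records.append((cell_ids[c], drug_ids[d], float(y)))
    responses = ResponseDataset(records=records)

    ground_truth = {
        "beta_expr": beta_expr,
        "beta_mut": beta_mut,
        "offsets": offsets,
        "top_mutation_gene": dict(zip(drug_ids, top_gene)),
        "smiles": dict(zip(drug_ids, smiles)),
    }
    return drug_table, features, responses, ground_truth
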