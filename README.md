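# swnet

Drug-response prediction for cancer cell lines from compound structure and
genomic signatures. The model predicts the natural-log half-maximal inhibitory
concentration, ln IC50, of a (cell line, drug) pair by fusing two branches:

* a **graph neural network** over the drug's molecular graph, where each atom
  and bond is tokenized by its *r-radius subgraph* (the canonical neighborhood
  signature within graph distance *r*) and embedded, then refined by edge and
  node transition functions

  e_ij ← σ(e_ij + f(w_e(v_i + v_j + b_e)))
  v_i ← σ(v_i + Σ_{j∈N(i)} f(w_n [v_j; e_ij] + b_n))

  with mean readout h_G = (1/N) Σ_i v_i;

* a **1D-convolutional gene branch** over the fused genomic profile

  geneCom = geneExp + geneVar ⊙ w′

  where geneExp is z-scored expression, geneVar is the binary somatic
  nonsynonymous mutation indicator, and w′ is a trainable **gene weight
  layer** — one shared row, or one row per drug (multi-task), optionally
  mixed across structurally similar drugs by **self-attention**:
  W′ = softmax(S) W with S the Morgan-fingerprint Tanimoto similarity matrix.

The two embeddings are concatenated and passed through a prediction
subnetwork (convolution, max pooling, batch normalization, fully connected
stages) to the scalar ln IC50. All drugs are trained jointly with one shared
MSE loss. After training, each drug's weight row ranks the mutations most
predictive for that drug, and an unseen compound's weight row is inferred by
softmax-mixing the trained rows with its Tanimoto similarities to the
training drugs.

The package is aimed at computational biologists studying pharmacogenomic
screens (GDSC/CCLE-style data: a SMILES table, expression and mutation
matrices, a response table). A synthetic-data generator with known ground
truth makes every stage testable without external downloads. The neural
components run on a small NumPy reverse-mode autodiff core, so the package
has no deep-learning framework dependency.

## Worked example

```python
import numpy as np
from swnet import SyntheticSpec, generate, SwnetModel, TrainingConfig, train
from swnet import random_instance_split, mse, r_squared
from swnet.genomics import top_k_weight_genes

# reference synthetic study: 300 cell lines x 50 genes x 10 drugs, noise sd 0.3
spec = SyntheticSpec(seed=1)
drug_table, features, responses, truth = generate(spec)

data = random_instance_split(responses, train_fraction=0.9, seed=1)
cfg = TrainingConfig(epochs=50, seed=1)  # multi-weight + self-attention defaults
model = SwnetModel(drug_table, features, cfg)
model, trace = train(model, data.subset("train"))

test = data.subset("test")
y = np.array([r[2] for r in test.records])
yhat = model.predict([(c, d) for c, d, _ in test.records])
print(f"held-out MSE {mse(y, yhat):.4f}  R^2 {r_squared(y, yhat):.4f}  (n={len(y)})")

W = model.weight_layer().weights  # trained mutation weights, one row per drug
for i, d in enumerate(model.drug_ids[:3]):
    top = top_k_weight_genes(W[i], model.gene_ids, k=3)
    print(f"{d} ({truth['smiles'][d]}): top-3 weight genes {top}, "
          f"true driver {truth['top_mutation_gene'][d]}")
```

Output (about two minutes on one CPU):

```
held-out MSE 0.6240  R^2 0.8614  (n=300)
D00 (CCOCC): top-3 weight genes ['G030', 'G029', 'G000'], true driver G030
D01 (CC=O): top-3 weight genes ['G007', 'G039', 'G023'], true driver G007
D02 (N#Cc1ccccc1): top-3 weight genes ['G014', 'G001', 'G005'], true driver G046
```

The held-out R² of 0.86 shows the model recovers most of the generative
signal (drug-specific potency offsets, a dense expression effect, and
drug-specific mutation effects) at noise sd 0.3; for two of the three drugs
shown, the gene carrying the largest true mutation effect tops the trained
weight row (8 of 10 drugs overall in this run).

## Command line

The same pipeline is available as a CLI:

```bash
swnet simulate --out data/ --seed 1                 # write the four input files
swnet featurize --smiles data/smiles.csv --out fz/  # vocabulary, scaffolds, clusters
swnet train --config run.yaml                       # fit; writes checkpoint + weights
swnet predict --checkpoint out/checkpoint.npz --pairs pairs.csv --out pred.csv
swnet evaluate --checkpoint out/checkpoint.npz --response data/response.csv
swnet interpret --checkpoint out/checkpoint.npz --out top_genes.csv
```

`run.yaml` lists the four input paths plus any `training:` overrides
(`weight_mode: single|multi`, `attention: true|false`, `radius`, epochs,
learning rates); `--mode`, `--attention`, `--radius` and `--seed` override it
from the command line. Input formats are plain CSV with headers: a
`drug_id,smiles` table, expression and mutation matrices with a `cell_id`
first column and gene-symbol headers, and a `cell_id,drug_id,ln_ic50`
response table (empty ln_ic50 fields are dropped with a logged count).
Optional cancer-gene and landmark-gene lists (one symbol per line) are merged
and intersected with the measured genes to fix the modeled gene panel.

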