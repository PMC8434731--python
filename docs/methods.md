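# Methods

## Model

The response model predicts ln IC50 for a (cell line, drug) pair with a
dual-convergence architecture: chemistry and genomics are encoded separately
and merged in a prediction subnetwork.

**Molecular branch.** A SMILES string is parsed (RDKit) into its heavy-atom
graph. Every atom and bond is tokenized by its r-radius subgraph signature,
computed by iterative neighborhood relabeling: round 0 labels an atom by
(element, aromaticity, formal charge); round t concatenates the atom's label
with the sorted multiset of (neighbor label, bond label) pairs. The node
signature is the label after r rounds; an edge signature combines the bond
label with the unordered pair of endpoint labels at radius r−1 (bond label
alone at r = 0). Signatures index a vocabulary built over the training
drugs; id 0 is reserved for unseen signatures at inference and carries its
own trainable embedding. Signature canonicalization uses sorted multiset
concatenation with explicit delimiters — exact dictionary lookup, no hashing,
so collisions cannot occur. Atom degree is recorded in the graph but excluded
from the round-0 label since radius-1 relabeling recovers it.

Embeddings (dimension d = 32, zero-mean uniform scaled by 1/√d from a
recorded seed) are refined for T steps (default T = r) by

* edge transition: e_ij ← σ(e_ij + f(w_e(v_i + v_j + b_e)))
* node transition: v_i ← σ(v_i + Σ_{j∈N(i)} f(w_n [v_j; e_ij] + b_n))

with σ the logistic function, f a rectifier, and one shared parameter set
across steps (per-step parameters would multiply the parameter count for no
observed benefit at this scale). Two formulation ambiguities are exposed as
config switches rather than silently resolved: `edge_uses_updated_nodes`
(default on) controls whether the edge update within a step sees the node
states refreshed by that step's node update or the states from the start of
the step; `bias_outside_product` (default off) switches the edge pre-
activation between the literal form w_e(v_i + v_j + b_e) and the
conventional w_e(v_i + v_j) + b_e. Both variants of each are covered by
tests. The graph embedding is the arithmetic mean of the final node states,
so every coordinate lies strictly in (0, 1) after at least one step.

**Gene branch.** Expression is z-scored per cell line (population standard
deviation, so a two-gene row remains valid; constant rows map to zeros with a
warning). Somatic nonsynonymous variants are collapsed per (cell, gene) to a
binary indicator regardless of genomic position. The two are fused per record
as geneCom = geneExp + geneVar ⊙ w′, the Hadamard product keeping geneCom a
G-vector. The weight row w′ comes from the gene weight layer: one shared row
("single"), one row per drug ("multi"), or — with self-attention on — row d
of W′ = softmax(S) W, where S is the Tanimoto similarity matrix of Morgan
fingerprints (radius 2, 2048 bits) over the training drugs. W′ is recomputed
every forward pass (it is one small matrix product), so attention always
reflects the current W. Similarities enter the softmax unscaled; a
temperature option exists (default 1) and drives the attention map to the
identity as it approaches 0 on a diagonal-dominant similarity matrix. The
weight layer applies to the mutation indicator only; applying it to
expression, or to both, is available for ablation (`weight_layer_on`).

geneCom is treated as a length-G single-channel sequence, ordered
lexicographically by gene symbol for reproducibility, and passed through
three 1D convolutions (channels (8, 16, 32), kernel 7, stride 2 — strides may
be given per stage) and one fully connected stage to a 128-dim embedding.

**Fusion.** The concatenated graph and gene embeddings pass through a 1D
convolution (16 channels, kernel 5), max pooling (width 2), batch
normalization (standard train/eval mode switching with running statistics),
and two fully connected stages to the scalar prediction.

**Training.** All drugs are fitted jointly — one MSE loss over all records,
not per-task alternation — with adaptive-moment gradient descent
(learning rate 1e-3, batch 64). For an unseen compound, the weight row is
inferred by softmax-mixing the trained rows with the compound's Tanimoto
similarities to the training drugs, and its graph is tokenized against the
frozen vocabulary with unseen signatures mapping to the unknown token.

## The gene weight layer: constraints and interpretation

The weight layer is the interpretable part of the model: after training,
large entries of a drug's row mark mutations with strong predictive power
for that drug. Three design choices make this interpretation reliable, and
they merit explanation because they are not forced by the architecture:

* **Non-negativity.** W is projected onto [0, ∞) after every optimizer step.
  Without the constraint the downstream network can absorb an arbitrary sign
  flip per entry, so informative genes end up with large weights of
  *arbitrary* sign and a per-row min–max normalization no longer surfaces
  them. With the constraint, mutation contributions express on a positive
  scale and the normalized maximum is meaningful.

* **Initialization inside the separation regime, uniform(6, 10).** geneCom
  adds w to a z-scored expression coordinate when the gene is mutated. For
  small w the mutated and unmutated populations overlap within the ±3 range
  of z-scores and the mutation signal is partially confounded with
  expression; gradient descent then shrinks weights whose gene has a
  negative expression slope, and a weight that reaches 0 receives no further
  signal. Initializing every weight above the overlap region makes mutated
  cells linearly separable from the start, so the network can fit each
  mutation's effect as a level shift and *keep* the weights the data
  supports. Weights the data does not support are pruned by decay.

* **Separate learning rate (0.1) and decoupled decay (1e-3 per step) for W;
  decay 1e-4 for all other parameters.** The row-stochastic attention map
  scales W's gradients down by roughly the number of drugs, so W trains on
  its own, larger rate. The decay on W suppresses spurious weights that fit
  record-level noise (they are the model's main overfitting channel at this
  scale); the mild decay elsewhere regularizes the dense stages.

Driver extraction reads the trained W, not the attention-mixed W′: with a
handful of drugs the softmax rows are close to uniform, so W′ rows are
blurred mixtures, while the drug-specific signal lives in W. The
`extract_top_weight_genes` operation min–max normalizes a row to [0, 1] and
returns the genes at 1 (the argmax set, ties included); `top_k_weight_genes`
returns the k best. A constant row yields an empty list with a warning.

## Synthetic data

The generator emulates a pharmacogenomic screen with a known additive ground
truth:

    ln IC50(c, d) = offset(d) + ⟨expr(c), β_expr⟩ + ⟨mut(c), β_mut(d)⟩ + ε,
    ε ~ Normal(0, noise_sd)

* compounds drawn without replacement from a fixed library of 40 small valid
  SMILES (alkanes, alcohols, aromatics, heterocycles), so graphs and
  fingerprints are non-degenerate;
* expression standard normal, z-scored per cell; mutations Bernoulli(0.2);
* one shared dense expression effect β_expr ~ Normal(0, 0.2²);
* per-drug mutation effects: one driver gene with effect ~ uniform(1.5, 2.5)
  and three minor genes ~ uniform(0.3, 0.8) — drug-specific by construction
  so the multi-row weight layer has a true signal to recover;
* per-drug potency offsets ~ Normal(0, 1.5²); a structure-driven variant
  (offset proportional to aromatic-atom count) is available
  (`molecular_effect="aromatic"`) for tests that need the molecular branch to
  carry signal.

Defaults are 300 cell lines × 50 genes × 10 drugs (3000 records over the
full cross), noise sd 0.3. An ordinary least-squares fit per drug recovers
the generating coefficients within sampling error (tested), establishing
that the signal the network must learn is genuinely present.

What the generator does **not** emulate: tissue-lineage structure among cell
lines, realistic IC50 distributions, linkage between a compound's structure
and which genes it targets, co-mutation patterns, or expression correlation
structure. Passing tests therefore demonstrate that the implementation is
correct and that the architecture can learn signals of this additive form at
this scale — not that it attains any particular accuracy on real screens.

## Splits and metrics

The 90/10 instance split draws a uniformly random permutation and takes
floor(0.9 N) records for training — the only rule consistent with both
published split sizes (177,128 → 159,415/17,713 and 10,853 → 9,767/1,086).
The cell-line split applies the same floor rule to *cell lines* and lets
records inherit their cell's tag, so held-out genomic profiles are never
seen in training. No stratification by drug or tissue is applied. MSE and R²
follow their standard definitions; R² may be negative for poor predictors
and is undefined (an error) for constant targets.

## Numerical choices and degenerate inputs

* Tanimoto similarity of two all-zero fingerprints is defined as 1
  (identical-empty convention, preserving the identity property);
  configurable.
* Softmax rows are stabilized by max subtraction.
* UPGMA compound clustering runs on distance 1 − similarity
  (scipy average linkage) and cuts the dendrogram at 0.6 by default; labels
  are renumbered in order of first appearance.
* The vocabulary is grown only when explicitly requested (`grow=True`);
  inference never mutates it.
* Checkpoints round-trip bit-exactly: every parameter array, the batch-norm
  running statistics, the vocabulary, the training-drug table and the
  feature matrices are stored in one NumPy archive with a config echo.
* Training aborts with a diagnostic naming the epoch and batch if the loss
  becomes non-finite; a learning rate of 0 (with decays 0) provably leaves
  parameters unchanged (tested).

## Problem sizes

The test suite and the acceptance script run the reference study
(300 × 50 × 10, 50 epochs, ≈ 2 minutes per training on one CPU) plus a small
fixture (30 cells, 4 drugs) for unit tests. The architecture defaults were
chosen for the full-screen scale (≈ 1500 genes); all sizes are configurable
and the gene branch computes its shapes from the gene count, rejecting
panels too small for its receptive field (< 43 genes at the default kernel
and strides).

## Known limitations

* The GNN embedding saturates into (0, 1) through the logistic transition;
  with few transition steps the molecular branch mostly distinguishes drugs
  rather than extrapolating structure–activity trends to distant chemistry.
* Attention mixing with few drugs is close to uniform averaging; its benefit
  grows with the number and structural diversity of training compounds.
* The non-negative weight layer cannot represent a mutation that *lowers*
  ln IC50 through a gene whose weight is needed positive by another drug
  sharing the row via attention; at screen scale this is rare, and the
  signed alternative (`nonnegative_weights=False`) is available at the cost
  of interpretable min–max extraction.
* No GPU path; the NumPy autodiff core is adequate for desk-scale studies
  but not for the full 221-drug screen at hundreds of epochs.
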