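# Methods

## Problem and model

The package predicts binary compound–protein interaction (CPI) from
sequence-level inputs only. Three stages:

1. **Token embeddings.** SMILES strings and protein sequences are
   tokenized (atom-level tokens; non-overlapping 3-mers) and a skip-gram
   model with negative sampling (SGNS) is trained per modality from
   scratch. The per-pair objective for center w, true context u and
   negative draws z is log σ(V(w)ᵀθᵘ) + Σ_z log(1 − σ(V(w)ᵀθᶻ)); one SGD
   step updates V(w), θᵘ and the θᶻ simultaneously at the pre-step
   parameters, so each step is exactly one ascent step of the objective
   (this is what the finite-difference tests check). Entity vectors are
   token-vector means.
2. **Pair graph.** Every labeled pair is a node carrying the
   concatenated compound‖protein vectors (2×100 = 200 features by
   default). Adjacency is mutual-max symmetrized cosine kNN (k = 10,
   binary edges by default; weighted mode stores similarities clipped to
   [0, 1]); the propagation operator is S = D̃^(−1/2)(A+I)D̃^(−1/2),
   whose spectrum lies in [−1, 1] so any hop count is numerically
   stable.
3. **Classifier.** Stacks over {GCN, SGCN}: GCN layers apply
   H ← ReLU(S H Θ) with trainable Θ; SGCN layers are the parameter-free
   smoothing H ← S H. A single logistic head closes every stack. A pure
   K-layer SGCN is therefore identical — bit-for-bit, same operation
   order — to σ(S^K X Θ): the smoothing is precomputed once and a
   logistic regression is fit on the smoothed features, so pure-SGCN
   training costs one K-hop propagation regardless of epochs, while
   mixed stacks (full-batch gradient descent on masked binary
   cross-entropy) propagate once per layer per epoch. The propagation
   counters exported in `ModelParams.info` make this efficiency claim a
   testable structural property rather than a wall-clock claim.

Held-out evaluation is transductive: test nodes gain edges only to their
k nearest *training* nodes, never to each other, so no information flows
between held-out pairs and the train block of the adjacency is
unchanged.

## Parameters that matter

| parameter | default | units / range | why |
|---|---|---|---|
| embedding dimension d | 100 per modality | — | concatenated pair features are 200-d |
| window C | 5 | tokens | standard skip-gram context radius |
| negatives per positive | 5 | draws | word2vec convention; distribution ∝ count^0.75 |
| SGNS epochs / lr | 15, 0.025 → 1e-4 linear | — | small corpora converge in ~15 passes; decay stabilizes late epochs |
| IC50 thresholds | < 100 nM positive, > 10000 nM negative | nM, strict | activity-threshold convention for IC50 assays; both configurable |
| redundancy threshold | similarity > 0.8 drops | fraction | strict: exactly 0.8 is retained |
| kNN degree k | 10 | neighbors | sparse but connected at the fixture scales |
| hop count K | 3 (stack `SGCN+SGCN+SGCN`) | layers | 3-hop aggregation; deeper helps little |
| GCN hidden width | 64 | units | Glorot-initialized, seeded |
| stack training | lr 1e-2, 300 epochs, L2 1e-4, patience 30 | — | full-batch descent; early stop on a 10% validation slice |
| decision threshold | 0.5 | probability | ties (exactly 0.5) count positive; AUC/AUPR are threshold-free |

## Synthetic study design

The generator emulates the *shape* of curated bioactivity extracts while
staying fully self-contained:

- **Compounds** are valid SMILES from a guaranteed-valid grammar (chains
  over C/N/O/S, substituents only on tetravalent carbons, one ring
  core). Each of the A archetypes shares a ring scaffold, substituent
  pool and chain-composition bias, so within-archetype Tanimoto
  similarity exceeds cross-archetype similarity — the signal lives in
  the tokens, where the embedding model must find it.
- **Proteins** draw ~60% of their 3-mer blocks from a disjoint
  archetype-specific motif pool, the rest from background.
- **Interactions** follow an additive latent-affinity rule: archetypes
  are ordered by binding propensity and a pair is compatible iff
  compound archetype + protein archetype ≤ A − 2. An additive rule was
  chosen deliberately over "same archetype interacts": an
  equality/XOR-style cell set over concatenated features is not
  representable by any linear head — including the pure-SGCN closed form
  — so it would test the fixture, not the method; graded additive
  affinity is also closer to how potency behaves in real assay data.
  Compatible pairs draw IC50 log-uniformly from 1–99 nM, incompatible
  from 10001–10⁶ nM (both strictly inside the labeling thresholds), and
  a fraction ε = 0.05 of pairs has its range flipped, so the labeling
  rule remains exactly invertible on clean pairs. Pairs are subsampled
  to the requested positive:negative ratio (default 1:10).
- **Splits**: entity-disjoint (held-out compounds *and* proteins; the
  default, and the harder generalization test) or pair-disjoint.

Default study conditions: 150 compounds, 30 proteins, 3 archetypes,
ε = 0.05, 1:10 imbalance, 20% entities held out, seed 7.

What the fixture does *not* emulate: realistic chemistry or docking
plausibility, true protein families, assay heterogeneity (Ki/Kd
mixtures), and database-scale entity counts. Passing tests therefore
demonstrate that the pipeline recovers token-level co-occurrence
structure through embeddings, graph smoothing and the linear head — not
that it matches any published benchmark number on ChEMBL-scale data.

## Problem sizes in tests and the acceptance script

The statistical properties are checked at deliberately reduced scales,
chosen once as the smallest sizes where the effects are stable: the
end-to-end recovery check runs the default 150×30 study (~2000 train
pairs); the imbalance sweep uses 60 compounds × 18 proteins with
pair-disjoint splits (larger, stabler test sets than entity-disjoint at
this scale) over ratios 1:1/1:5/1:10 and 5 seeds, asserting the
seed-mean behavior; the acceptance script adds a 5-fold × 10 repeated
CV summary on the training split. Held-out metrics at the default scale
carry real seed-to-seed variance (only ~11 test positives), which is why
the script reports both the single holdout and the CV means.

## Numerical choices and conventions

- kNN ties broken by lowest node index; node order is the sorted order
  of pair ids — graph construction is fully deterministic.
- Tanimoto of two empty fingerprints is defined as 1 (identical absence
  of features). Sequence identity = identities / alignment length under
  global alignment (match +1, mismatch 0, linear gap −1), gap columns in
  the denominator.
- AUPR is step-wise average precision, never trapezoidal interpolation
  (trapezoids over-estimate PR area). Precision/recall/F1 degenerate
  cases return 0 with a warning — with rare positives an empty
  positive-prediction set is a realistic outcome, not an error.
- ROC AUC equals Mann–Whitney concordance with ties counted ½.
- Zero-degree nodes cannot occur in S: the self-loop guarantees positive
  degree. All-zero feature rows are rejected before cosine similarity.
- One config seed fans out to per-stage seeds by CRC32 of the stage
  name, so stages are independently reproducible; every training path is
  bit-deterministic given its seed (the lbfgs logistic fit is
  deterministic at tol 1e-10).
- Negative draws colliding with the true context token are redrawn.

## Open design points, resolved

- The SGNS likelihood is implemented as the standard product of the
  positive and negative factors (the usual SGNS form).
- Ring/bond/branch symbols are corpus words by default (`atoms_only`
  switches to atom tokens only): keeping them preserves skip-gram
  context around branching and aromaticity.
- Protein 3-mers use frame offset 0 only; trailing residues are dropped,
  not padded — fixed-stride windows should not invent residues.
- "Inorganic" is operationalized as "no carbon atom": simple, logged per
  record, configurable upstream by pre-filtering.
- Mixed stacks read "SGCN" layers as parameter-free smoothing with a
  single shared logistic head — the only reading under which a stack of
  SGCN layers equals the closed form.
- OOV handling defaults to vocabulary-mean replacement; a seeded
  random-vector policy exists solely as the ablation baseline, and an
  `error` policy for strict evaluation.

## Known limitations

- The SGNS trainer is a pure-NumPy loop: ample for fixture-scale corpora
  (seconds to ~1 minute) but not for millions of molecules.
- Similarity search is dense O(n²); fine below ~10⁴ pair nodes.
- The transductive attachment is one design for scoring unseen pairs;
  the package makes no claim it matches any particular published
  protocol, and alternatives (inductive feature-only scoring) reduce to
  K = 0.
- Calibration of predicted probabilities under imbalance is not
  addressed; threshold-free metrics are the intended headline.
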