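# Methods

## Problem and model

Amyloid signaling motifs (ASMs) are short (roughly 11–40 residue)
segments that seed a self-propagating cross-β amyloid fold used for
signal transduction between Nod-like receptors (NLRs) and their effector
proteins in bacteria and fungi. The motif families are highly diverse
beyond recognizable homology, which defeats alignment-based profile
searches; `asmscan` instead trains a discriminative per-window
classifier on a diverse collection of motif families against a broad
negative background and scans whole sequences with it.

The per-window model is a deliberately small bidirectional recurrent
network over a fixed 40-token input:

1. **Embedding** — 26-token vocabulary (PAD at index 0, the 20 canonical
   amino acids plus B, Z, X, U, O) mapped to dense vectors of size 8.
2. **Bidirectional LSTM**, 8 units per direction, tanh activations; the
   final hidden states of the two directions are concatenated into a
   16-dimensional sequence summary.
3. **Unidirectional LSTM**, 4 units, applied to that summary (a
   length-one sequence); this acts as a gated nonlinear refinement of
   the bidirectional summary. Because its initial state is zero and the
   input has length one, the layer's recurrent kernel is inert in the
   forward pass while still being a counted trainable parameter — a
   consequence of the final-state readout, preserved because it is what
   pins the parameter-count contract below.
4. **Sigmoid output unit** giving the probability that the window
   contains an ASM.

Dropout (10%) follows the embedding, the bidirectional layer, and the
unidirectional layer; it is active only during training (inverted
dropout). With the default dimensions the model has exactly

    26·8 + 2·[4·8·(8+8+1)] + 4·4·(2·8+4+1) + (4+1) = 1,637

trainable parameters (single bias per LSTM gate). `count_trainable_params`
implements this closed form and every built model must report the same
total from its actual weight arrays; the tests check the agreement on
random configurations. The 26-row embedding is itself part of this
contract: with the fixed layer dimensions it is the unique vocabulary
size producing 1,637 parameters.

The network is implemented directly in NumPy (`asmscan._nn`): forward
LSTM recursion, backpropagation through time from the final-state
gradient, inverted dropout, and Adam. The model is small enough that
plain float64 NumPy trains it in seconds to minutes on one CPU core,
and a pure-NumPy stack makes runs bit-reproducible for a fixed seed on a
single thread. A finite-difference check of the gradients was part of
development; the training-loop tests assert loss decrease and exact
reproducibility instead, which is what maintenance needs.

## Sequence processing

Inputs are cleaned (uppercased; characters outside the 25 residue
letters mapped to X) and encoded to token indices 1–25; PAD (0) never
appears in a cleaned sequence.

Two different padding rules are used on purpose:

- **Training** sequences shorter than 40 are *prepadded* with residues
  sampled i.i.d. from a background frequency table (bundled Swiss-Prot
  composition; any 2-column TSV can replace it). The pad mimics the
  noise a motif sits in. Pads are sampled once per training run by
  default so runs are reproducible; `TrainConfig(resample_pads_per_epoch=True)`
  resamples each epoch.
- **Scanning** inputs shorter than 40 are *zero-postpadded* with PAD.

Sequences of 40 or more residues are scanned with a sliding window of
size 40 and step 1, so a sequence of length L yields max(1, L−39)
windows. Coordinates are 0-based half-open internally and 1-based
inclusive in output tables.

## Training and the combined model

Training runs 6-fold cross-validation (stratified by class, seeded).
Each fold trains for a fixed number of epochs (default 30; binary
cross-entropy, Adam, learning rate 1e-3, batch size 32, no early
stopping); final-epoch weights are kept, with best-validation-loss
checkpointing available behind `TrainConfig(checkpoint_best=True)`.
Negatives can be subsampled via `neg_per_pos` for quick experiments;
the default uses all negatives with no class weighting.

At inference the six fold models act as one *combined* scorer: each
window receives six probabilities, which are averaged; the per-sequence
score is the maximum window mean (max-pooling). Probabilities, not
logits, are averaged. Ties between equal window means break to the
smallest start. Dropout is disabled at inference, so prediction is a
pure function of the weights and input.

## Evaluation protocol

- **AP** — step-function (non-interpolated) average precision, the
  standard retrieval definition.
- **AUROC** and the ROC curve from a descending-threshold sweep with
  tied scores collapsed; endpoints (0,0) and (1,1) always present.
- **Recall@FPR** — TPR linearly interpolated on the FPR axis; when the
  target falls exactly on a vertical segment of the curve the maximum
  TPR at that FPR is returned (the optimistic convention, matching the
  intent of reporting recall *at* a false-positive budget).
- **Evidenced-set PRF** — for proteome scans where ground truth is a
  fixed set of independently evidenced motifs: recall = true hits /
  evidenced, precision = true hits / hits (defined as 0 for an empty hit
  list), F1 the harmonic mean of the unrounded values. Tables round to
  2 decimals; machine-readable output keeps full precision.
- **Retention rate** — the fraction of a set scoring at or above the
  detection threshold (default 0.5), reported per group next to the
  embedding plots.

## Embedding introspection

For each sequence, the best-scoring window is embedded with every fold's
penultimate layer (the 4-unit unidirectional LSTM output, taken in
inference mode, so identical to the post-dropout representation); the
per-fold vectors are concatenated to a 24-dimensional vector by default
(averaging is available, but concatenation preserves all information and
how the folds' embeddings should be merged is genuinely open). UMAP
(n_neighbors 15, min_dist 0.1, Euclidean; consumed as an established
routine, not reimplemented) projects to 2-D; plots mark detected
sequences with dots and undetected with crosses, colored by group.

## Synthetic benchmark

The generator emulates the *structure* of the real datasets, not their
content:

- **Motif families**: each family has 6 anchor positions at fixed
  relative positions in [0,1), each with a dominant residue (mass 0.9)
  drawn from an amyloid-prone pool (Q, N, G, S, Y); non-anchor positions
  are drawn from a Swiss-Prot background blended with 40% uniform mass
  over that pool. Anchors at relative positions let family identity
  survive the uniform 21–40 length variation, mimicking conserved ASM
  patterns such as Q/N-rich cores. The shared compositional bias is what
  makes *novel* (held-out) families detectable by a model trained on
  other families — the synthetic analogue of bacterial-to-fungal motif
  generalization. Without it, disjoint anchor sets would make remote
  families statistically unrelated and the transfer task meaningless.
- **Negatives**: i.i.d. Swiss-Prot-frequency 40-mers standing in for
  nonredundant protein-space fragments, and motif-free 100-mers standing
  in for non-amyloid NLR N-termini. Negatives are clean by construction;
  the chance that a background 40-mer reproduces a family's six anchor
  residues at the right offsets is below (max residue frequency)^6 per
  alignment ≈ 1e-6 per sequence, far under 1e-3.
- **Test variants**: fresh motifs from the training families ("same"),
  motifs from held-out families ("novel"), each also implanted at a
  uniform feasible offset biased toward the chosen terminus half of a
  100-residue background domain (true coordinates recorded), and cut
  back out with 0/5/10-residue envelopes.

Defaults: 8 training families × 120 motifs, 2 held-out families,
40 test motifs per family, 20,000 training negatives, 2,000 test
negatives, 500 negative domains. All sampling flows from one root seed
through named substreams (families, train motifs, train negatives, test
motifs, implants, test negatives, negative domains), so regeneration is
byte-identical and each component can be re-drawn independently.

**What passing the synthetic tests does and does not show.** The
benchmark verifies the machinery: that the classifier learns conserved
short patterns against realistic background composition, that ensemble
max-pool scanning localizes implanted motifs, and that every metric and
padding rule behaves as specified. It does not certify performance on
real proteomes: real ASM families have correlated positions, indels, and
phylogenetic redundancy that i.i.d. anchor/background sampling does not
model, and real negative sets may contain true amyloid motifs (the
generator's contamination knob defaults to 0).

## Numerical and design choices

- Gate order i, f, g, o with a single bias per gate and forget-gate bias
  initialized to 1; kernels Glorot-uniform, recurrent kernels
  orthogonal, embedding uniform(−0.05, 0.05). A double-bias LSTM variant
  would break the 1,637 contract — the contract test exists to catch
  exactly that.
- Binary cross-entropy is computed from logits (log-sum-exp form) for
  stability; probabilities are produced only at the sigmoid output.
- Adam: β₁ 0.9, β₂ 0.999, ε 1e-7.
- Fold training seeds derive from (run seed, fold index) via
  `numpy.random.SeedSequence`, so folds are independent but reproducible.
- Degenerate inputs error early and specifically: empty sequences,
  over-length training items, single-class folds, inverted intervals,
  out-of-range probabilities.
- Desk-scale defaults used by the test suite: the end-to-end check
  trains the 6-fold ensemble for 10 epochs on the default benchmark
  (960 positives, 20,000 negatives), which reaches held-out same-family
  AP above 0.99 in about five minutes on one core; the package default
  of 30 epochs is for real training runs. The toy separability test uses
  batch size 8, since 40 training examples at batch 32 give too few
  gradient steps in 30 epochs for an LSTM trained from scratch.
- Motif localization is quantified by begin/end shifts of the
  best-scoring window relative to the true motif (negative begin shift =
  window starts before the motif) and by coverage, the fraction of motif
  residues inside the window.

## Known limitations

- The scanner is O(L) windows × 6 folds per sequence of length L; a
  whole proteome is feasible but takes minutes, not seconds.
- No transformer-based scorer ships; `CombinedModel` only requires fold
  objects exposing `predict_proba` on (n, 40) token arrays, which is the
  seam for plugging in an external per-window scorer (e.g. a fine-tuned
  protein language model).
- The probabilistic-grammar baseline that the recurrent model is usually
  compared against is out of scope, as are redundancy reduction of real
  datasets and genomic-neighborhood analysis of hits.
- UMAP coordinates are deterministic only for a fixed seed and library
  version; tests assert structure (blob separation, shape, finiteness),
  not exact coordinates.
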