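# Methods

## Data model and preparation cascade

Input is the VDJdb web-export dialect: a tab-separated table with one
TCR–epitope pair per row (CDR3 amino-acid sequence, chain, V/J gene names,
MHC A/B and class, host species, epitope sequence/parent gene/species, and a
confidence score in 0–3 where 0 means computationally predicted and 1–3 mean
increasing wet-lab support). Rows with an unparseable score or a
non-canonical CDR3 are diverted to a row-level error list rather than
aborting the parse.

The preparation cascade applies, in order, with a count recorded after every
step: (1) drop rows missing mandatory values; (2) keep human and murine
hosts (configurable allowlist); (3) keep confidence score > 0; (4) drop
epitope species of non-infectious origin — the shipped denylist covers
self/tumour antigens, synthetic constructs, a bacterial antigen and a wheat
allergen and is deliberately configuration, since no closed set exists;
(5) deduplicate on the key (CDR3, V, J, MHC A, MHC B), keeping the first
occurrence in file order; (6) keep TRB chains; (7) keep classes with at
least 50 receptors (inclusive bound). The report is monotone non-increasing
by construction. MHC fields participate only in the deduplication key and
are never model features.

Class labels are the space-joined epitope triple. Classes with more than
100 receptors are categorized "easy", all others "hard"; a class of exactly
100 is hard, because "more than 100" excludes it. Splits are 70/15/15,
stratified per class: train gets ⌊0.70·n⌋, validation ⌊0.15·n⌋, test the
remainder, with a seeded uniform shuffle inside each class. Per-class
flooring need not sum to the global floors; the global total is reported,
not enforced.

Gene vocabularies are ordinal encoders over the lexicographically sorted
unique gene names, ordinals starting at 1 so index 0 can serve as the
gene-embedding padding index; the last slot is a special index for names
unseen at fit time. Table size is therefore n + 2 (e.g. 63 V genes → 65,
13 J genes → 15).

## Tokenization

Character vocabulary: the 20 canonical amino acids plus `[PAD]`, `[CLS]`,
`[SEP]`, `[UNK]`; one token per residue, no sub-word merges. Autoencoder
layout is `[CLS] residues [SEP] PAD…` with pooling at the first position;
autoregressive layout is `residues [SEP] [CLS] PAD…` with pooling at the
last non-padding position (the XLNet-family convention). Segment ids are
all zero for this single-sequence task and retained only for interface
completeness.

V/J gene ordinals are broadcast as a constant over residue positions and 0
at special-token and padding positions. Broadcasting (rather than appending
gene tokens) preserves sequence length and gives the gene-embedding tables
their own padding index, so a gene embedding attaches to the protein
sequence and never to special tokens. This alignment is an interpretation —
the alternative of a single extra position would also satisfy the stated
mechanism — and is asserted by the tokenizer invariants.

## Model

The backbone is a standard pre-activation-free (post-layer-norm) encoder:
learned token and position embeddings, embedding layer-norm, then per layer
multi-head self-attention (additive −1e9 mask bias on padded keys) and a
4d GELU feed-forward block, each with residual connection and layer-norm.
Defaults at desk scale: d = 32, 2 layers, 4 heads. All parameters initialize
from N(0, 0.02²) except layer-norm scales (1) and biases (0).

Settings:

* **baseline** — pooled output → linear head `y = xAᵀ + b`.
* **classification** — bilinear head `y_c = x₁ᵀ A_c x₂ + b_c` with
  `x₂ = (v, j)` the raw ordinals as numbers. The head is implemented
  literally, with no extra linear term in `x₁`. Raw ordinal magnitudes are
  arbitrary; an optional flag min–max scales them to [0, 1] and is off by
  default to match the reference protocol.
* **embedding** — V and J embedding tables of shape (table_size, d) with
  row 0 pinned at zero by a gradient mask; rows are added element-wise to
  the token embeddings at residue positions, before the first encoder layer
  and together with (i.e. after) the position embedding. "Merging" by
  addition keeps d unchanged, which is what lets a pre-trained backbone be
  reused without re-shaping. With all gene ids 0 this setting is numerically
  identical to the baseline — the mechanism is a strict superset, and the
  test suite asserts the equivalence to 1e−12.

The V/J-only control is a two-hidden-layer ReLU network with softmax output
on one-hot gene pairs, trained with categorical cross-entropy (implemented
with sklearn's MLPClassifier behind a stable factory).

## Loss

Multi-class focal loss with one-hot targets and natural logarithms;
γ ≥ 0 is a tunable hyperparameter, default 2 for single runs (the original
focal-loss recommendation). Probabilities are clamped at 1e−12 before the
log and clamping events are counted in a diagnostics object rather than
silently absorbed. The differentiable training objective computes the loss
from logits via log-softmax, and the gradient flows through the modulating
factor as well as the log-probability; the analytic probability-space
functions serve as evaluation oracles. Key order properties (0 ≤ FL ≤ CE,
equality iff γ = 0 or p_true = 1; monotone non-increasing in γ) are
property-tested.

## Training

Decoupled-weight-decay Adam with per-group learning rates: in the embedding
setting the gene tables form a separate group at `base_lr × multiplier`
(default 10), mirroring the need to train randomly initialized layers faster
than a pre-trained backbone. Linear warmup runs over `warmup_ratio` of the
planned updates and then holds the base rate constant (the post-warmup decay
schedule is not specified by the reference protocol; constant is the
simplest defensible choice). Gradient accumulation over k micro-batches
performs one update per k; total updates are exposed for auditing.

Early stopping monitors validation loss once per epoch with patience 5 by
default (the reference protocol reports premature stopping under focal-loss
fluctuation but no patience value, so this is an explicit package choice);
the best-validation checkpoint is restored on return. Faithful protocol
defaults are max_epochs 50, train batch 1, eval batch 8; the desk-scale
tests use batch 8 and fewer epochs purely for runtime. A fixed seed drives
one generator for shuffling and dropout, giving bitwise-reproducible
histories on a single device; cross-device bitwise equality is out of
contract.

Hyperparameter search covers the ten tunables (gradient accumulation,
learning rate, weight decay, attention/hidden/classifier dropout, the two
Adam betas, warmup ratio, focal γ). The driver is pluggable: a seeded,
self-contained random sampler is the test surface; a TPE adapter delegates
to Optuna when that optional package is installed (the optimizer itself is
not this package's contribution). Shipped ranges are documented defaults,
not assertions about the reference study's supplementary ranges.

## Evaluation

Weighted F1/precision/recall and balanced accuracy come from sklearn with
`zero_division=0`, so classes absent from predictions contribute 0 rather
than NaN. Per-class one-vs-rest AUROC uses the Mann–Whitney rank identity
with midrank ties (cross-checked against sklearn in tests); classes without
both positives and negatives are flagged undefined and excluded from the
unweighted mean (support-weighting the mean is a defensible alternative;
unweighted is chosen and documented). Model comparison is a two-sided paired
Wilcoxon signed-rank test on per-class AUROC differences, zeros dropped,
exact null for n ≤ 25 without ties in |difference| and normal approximation
otherwise; the implementation is scipy's, validated against brute-force
sign-assignment enumeration for n ≤ 10. The label-permutation control
shuffles evaluation labels with a seeded permutation and recomputes the mean
AUROC, which must sit near 0.5. ROC curves are emitted as FPR/TPR arrays for
external plotting; the core has no plotting dependency.

## Synthetic generator

The generator emulates the *shape* of a curated VDJdb export: default 25
classes (10 above 100 receptors at 150 each, 15 below at 78, ≈ 2,670 pairs
total), 63 V and 13 J gene names in TRBV*/TRBJ* style, CDR3 lengths 10–18,
confidence scores drawn from {1, 2, 3} with probabilities (0.5, 0.3, 0.2),
human host. Class signal has two independent axes: a per-class sequence
motif (length 4) planted at a random offset with probability
`motif_fidelity` (default 0.9), and class-conditional V/J usage —
`none` (uniform, shared), `soft` (per-class Dirichlet draw with
concentration 0.5; a single knob for bias strength), or `deterministic`
(one fixed (V, J) pair per class, which makes the mutual information between
gene pair and class equal the class entropy). Contamination knobs inject
TRA rows, exact duplicates and score-0 rows in known counts so each cascade
step can be tested; with defaults every record passes every filter. CDR3/V/J
keys are rejection-sampled to be unique so the dedup step is exercised only
by the explicit duplicate knob.

What the generator does **not** emulate: V(D)J-recombination statistics,
junctional insertions/deletions, positional residue biases, real epitope or
gene sequences, or cross-reactive TCRs. A green desk-scale test therefore
establishes that the mechanisms work as specified on data with planted
signal — not that full-scale performance on real repertoires is reproduced,
which additionally requires pre-trained protein language-model backbones and
GPU-scale fine-tuning.

## Numerical choices and limitations

* Reverse-mode autodiff on float64 numpy arrays; gradients validated against
  central finite differences for every operation and for the full model
  loss.
* Softmax/log-softmax are computed max-shifted for stability; attention
  probabilities derive from log-softmax so their gradient is exact.
* Adam epsilon 1e−8; weight decay is skipped on masked (frozen) rows.
* Degenerate inputs fail loudly: empty CDR3, over-length sequences, all-zero
  attention masks, gene ordinal 0 at attach time, shape mismatches in heads.
* The desk-scale backbone is randomly initialized; checkpoint hooks accept
  externally trained weights, but no pre-trained protein model ships with
  the package.
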