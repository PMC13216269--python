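# Methods

`glocalmm` implements global–local multimodal representation learning for
paired grayscale images and short clinical reports, together with a
text-guided segmentation decoder, and exercises the whole pipeline on
synthetic lumbar-spine phantoms so that every experiment runs offline on a
single CPU in minutes.

## The alignment model

Each image–report pair is encoded twice:

* **Global**: a visual feature `f_g ∈ R^C` (global average pooling of the
  final convolutional map) and a text feature `g_g ∈ R^d` (the encoder
  output at the CLS position). Affine projections followed by
  ℓ2-normalization map both into a shared space, giving unit vectors
  `v_g, t_g ∈ R^D`.
* **Local**: the `M = h'·w'` spatial positions of the final feature map
  and the `W` word-level text features (token embeddings averaged over
  each word's subword span, after projection), normalized columnwise to
  give `v_l ∈ R^{D×M}`, `t_l ∈ R^{D×W}`.

Training minimizes the sum of four InfoNCE terms over a minibatch of `N`
pairs:

* Global, both directions: `−Σ_i log softmax_k(⟨v_gi, t_gk⟩/t1)` at `k=i`,
  and the transpose. Matched pairs are positives; the other in-batch pairs
  are negatives.
* Local, both directions: a relevance map `s = v_lᵀ t_l` feeds a softmax
  attention over regions per word, `a_ij = softmax_j(s_ji/t2_attn)`;
  context vectors `c_i = Σ_j a_ij v_j` summarize, per word, the image
  evidence for that word; the pairwise match score is the smooth maximum
  `Z = t3·log Σ_i exp(⟨c_i, t_i⟩/t3)`; `Z` then enters an InfoNCE over the
  batch with temperature `t2_local`, with attention recomputed for every
  (image, text) cross pair.

The total loss is `λ1·L_global + λ2·L_local + λ3·L_seg` with all `λ = 1`;
alignment pretraining uses `λ3 = 0`. All four temperatures default to
0.07. A `mean_words` option normalizes `Z` by the word count (removing the
`t3·log W` length bias); it is off by default because it degraded
retrieval in our experiments.

## Desk-scale encoders

The package must train from scratch in a few hundred optimizer steps
(batch 16, Adam 1e-4, ≤30 epochs over 140 training pairs), which drove
every architecture choice below. The guiding principle: the phantom
findings are nearly linearly decodable from pixels, so the encoders are
kept as linear as possible and normalization does the conditioning.

* **Visual encoder (`tiny` preset)**: three stride-2 3×3 convolutions with
  channel-wise LayerNorm, no activation on the main path (an optional
  relu-gated residual mixing branch exists but is off in the tiny preset).
  Two fixed coordinate planes in [−1, 1] are appended to the input so
  region features know where they sit. The final map is multiplied by a
  fixed bank of orthogonal cosine row-basis gates (wavenumbers 0–4 cycled
  over channels): global average pooling of the gated map returns, per
  channel, a Fourier coefficient of the content along image rows, so
  "screws at L2" and "screws at L4" pool to different global vectors.
  Without this, pooling erases the level at which a finding sits and
  report retrieval cannot exceed ~0.4 hit@1. ~18k parameters.
* **Text encoder (`tiny` preset)**: a convolutional n-gram encoder — token
  embeddings (no absolute positions), a 5-tap depth-1 convolution along
  the sequence, LayerNorm, and a pointwise mixing residual. Each token
  summarizes ±2 neighbors, wide enough to bind a finding word to the level
  token it names. The output at the CLS position is defined as the masked
  mean of content-token features. A small transformer encoder is available
  behind the same interface (`text_arch="transformer"`) and is the default
  at the `paper` scale (BioClinicalBERT dimensions, d=768); we found the
  from-scratch transformer does not fit this task inside the step budget.
  ~38k parameters.
* Subword tokenization is deterministic fixed-length chunking (default 6
  characters, lowercased, punctuation stripped); it stands in for a
  trained WordPiece vocabulary while preserving the property the method
  needs — multi-token words whose embeddings are averaged back to word
  level.
* The `paper` preset records ResNet-50-like dimensions (C=2048, stride 32)
  as a hook for external pretrained backbones; nothing in the test suite
  trains it.

## Segmentation

A U-Net-style decoder mirrors the encoder pyramid: bilinear ×2 upsampling,
skip concatenation, 3×3 convolution with channel LayerNorm and relu, and —
when text modulation is on — a cross-modal attention block in which word
embeddings query the stage's spatial positions (keys/values); the per-word
attended summaries are mean-pooled over words, projected to the stage
width, and added residually, so disabling text reduces exactly to a plain
U-Net. A final 1×1 convolution and per-pixel softmax produce probabilities
over {background, vertebra, disc, instrumentation}. The loss is soft Dice
(ε=1 smoothing, mean over classes including background) plus mean
cross-entropy; an auxiliary global-alignment term can be added (off by
default, weight 0.1). The text pipeline supplying word embeddings for
modulation is frozen during segmentation training; with
`init="aligned-checkpoint"` both the encoder weights and the text pipeline
come from an alignment run.

## Synthetic phantoms

`phantom_forge` renders stylized lumbar radiographs: five vertebral bodies
as bright rectangles with cortical edges over a soft-tissue column, disc
spaces as darker bands, pedicle screws as bright bars flanking a vertebra
plus a vertical rod, disc degeneration as a narrowed disc space
(`disc_gap_fraction < 0.6`) bordered by sclerotic endplates, and interbody
fusion as a radiodense bony bridge filling the disc space. Masks label
{background, vertebra, disc, instrumentation}; image-level labels
{degeneration, fusion, instrumentation} derive deterministically from the
spec; every finding word in the templated report maps to its ground-truth
pixel support. Per-patient findings are sampled once and shared across
views, so patient-level splitting (70/10/20, floor rule, remainder to
train, minimum one patient per nonzero split) is what prevents leakage.

Default generation parameters: 64×64 pixels, additive Gaussian noise
σ=0.02, per-vertebra position/width jitter σ=0.5 px, finding prevalences
0.4 (instrumentation), 0.5 (degeneration), 0.25 (fusion), lower lumbar
levels favored for degeneration. Reports are lowercase template sentences
over a ~40-word vocabulary; a disc space is named by its upper vertebra
("the l2 disc space") so reports differing in one degeneration level
differ in exactly one token.

What the phantoms do **not** model: projection physics, soft-tissue
anatomy, exposure variation, overlapping bowel gas, free-text style
variation, or inter-annotator noise. Passing tests therefore demonstrate
that the alignment and segmentation machinery is implemented correctly and
behaves as the method intends on data with the right *structure*; they say
nothing about accuracy on real radiographs.

## Training protocol and study sizes

* Alignment: 200 patients × 1 view with pairwise-distinct findings (so
  reports uniquely identify images), 70/10/20 patient split, batch 16,
  Adam lr 1e-4 (β = 0.9/0.99), 30 epochs, all temperatures 0.07,
  augmentation on (rotation U(−10°, 10°), horizontal flip p=0.5, gain
  U(0.9, 1.1), noise σ=0.02; image only for alignment, synchronized with
  nearest-neighbor mask warping for segmentation). Validation hit@1 every
  2 epochs selects the checkpoint. Three seeds; medians reported.
* Retrieval score: global cosine plus the local match score `Z`, the
  global+local configuration.
* Zero-shot classification: fixed prompt lists per class (one
  instrumentation prompt per lumbar level, and normal/degeneration-only
  negatives); prompt embeddings are averaged then renormalized per class;
  the image score is the cosine difference between the two class
  embeddings.
* Segmentation: 143 patients (≈100 train after the split), batch 4, Adam
  lr 1e-3, 30 epochs, label fractions subset train patients by a seeded
  nested permutation (floor rule; a fraction yielding zero patients is an
  error). Foreground Dice = mean hard Dice over the three non-background
  classes, empty∧empty = 1.
* All randomness descends from one base seed through
  `numpy.random.SeedSequence`; identical seeds give byte-identical
  datasets and epoch-1 losses reproducible to 1e-4 relative.

## Numerical and engineering notes

* All differentiable computation runs on a small in-repo reverse-mode
  autodiff engine over float64 numpy arrays (`glocalmm.nn`): broadcasted
  arithmetic, matmul, reductions, unfold-based convolution, interpolation-
  matrix bilinear upsampling, and a tape-walking backward pass. Every
  primitive's gradient is verified against central finite differences in
  the test suite, as are the composite losses (relative error < 1e-3).
* Softmax/log-sum-exp use detached max-subtraction;
  ℓ2-normalization keeps ε inside the square root so all-zero padding rows
  have exact zero gradients; padded words are masked with −1e9 logits.
* Ranking ties in retrieval metrics break by candidate index; AUROC uses
  exact pair counting below 20 points and midranks otherwise.
* Attention overlays upsample the word's region-attention row with the
  same row-stochastic bilinear matrices used by the decoder, then
  max-normalize; the localization score divides the heat mass inside the
  word's ground-truth pixels by that region's area fraction (enrichment
  over a uniform baseline).

## Known limitations

* Word-level attention does not localize in this regime: with near-uniform
  attention the context vectors all approximate the mean region embedding,
  so the local objective can discriminate pairs without grounding words in
  regions, and the measured enrichment for "screw" stays near 1 (uniform).
  Sharper or softer attention temperatures, alternative gate banks, and
  longer training did not change this; published examples of emergent
  word-region grounding rely on pretrained encoders and far larger
  corpora.
* The retrieval benchmark sits near its threshold; different base seeds
  can move the 3-seed median by a few points in either direction.
* The conv n-gram text encoder cannot represent long-range dependencies
  between sentences; that is irrelevant for the templated reports but
  matters for real clinical text, where the transformer path (ideally
  pretrained) should be used.
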