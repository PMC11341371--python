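# Methods

## Problem setting

An enhancer–promoter interaction (EPI) instance is a pair of genomic
windows — a 3,000-bp enhancer and a 2,000-bp promoter spanning 1,500 bp
upstream to 500 bp downstream of the transcription start site, oriented
with transcription — with a binary label. Real benchmark collections are
heavily imbalanced (non-interacting pairs far outnumber interacting ones)
and cell-type specific. The package predicts the label from sequence
alone and extracts the sequence features that drive the prediction.

Coordinates are 0-based half-open (BED convention) throughout; windows
that overrun a contig are rejected rather than padded, so no artificial
characters enter the k-mer stream. Minus-strand windows are mirrored and
reverse-complemented, because "upstream" is only meaningful in
transcription orientation.

## Tokenization

Sequences are tokenized into overlapping 6-mers at stride 1; 6 balances
vocabulary size (4⁶ = 4,096) against the ability to assemble longer
motifs downstream. Five special tokens (PAD, UNK, CLS, SEP, MASK) occupy
the lowest ids in fixed order so serialized vocabularies are stable.
6-mers containing non-ACGT characters map to UNK rather than growing the
vocabulary. The assembled classification input is
`[CLS] enhancer-6-mers [SEP] promoter-6-mers`; at the full window sizes
this is always 4,992 positions (SEP at index 2,996), independent of
content. PAD exists for variable-length batches and is excluded from
attention targets by masking.

## Architecture

Token embeddings plus learned absolute position embeddings (BERT-style)
feed a stack of post-norm Transformer encoder layers; four layers is the
default. Encoder width, head count and feed-forward size are free
parameters; two presets are provided: `desk_scale` (2 layers, 2 heads,
hidden 32, FF 64 — every experiment in the test suite and acceptance
script uses this) and `paper_scale` (hidden 768, 12 heads — GPU
territory). Per-head attention matrices of every layer are exposed on
each forward pass; they are row-stochastic over non-PAD positions by
construction, and the suite checks this holds after training steps, not
just at initialization.

Three heads share the encoder:

* **TextCNN classifier.** Three parallel 1-D convolutions of distinct
  widths (default 4/5/6, 64 filters each; 16 in the desk preset) slide
  over the encoder output, are max-pooled over positions, concatenated,
  and mapped by one fully connected layer to two logits. All positions
  including the specials are consumed — the SEP position carries
  classification-relevant signal. The "width 6" default matches the
  k-mer span; widths and filter counts are configurable because the
  choice is not structural.
* **MLM head.** A linear map to the vocabulary for masked-language-model
  pre-training; loss is evaluated at masked positions only.
* **Domain discriminator.** A two-layer MLP behind a gradient reversal
  layer (GRL), consuming the CLS-position vector of the final encoder
  layer (mean pooling is a config switch).

The whole stack, including reverse-mode automatic differentiation and the
AdamW optimizer, is implemented in numpy inside the package; evaluation
passes skip tape construction and are bit-reproducible given fixed
weights.

## Training procedures

**Pre-training.** The corpus tiles each contig's N-free segments into
consecutive non-overlapping chunks of at most 5,000 bp (terminal chunks
below 20 bp are dropped; the cap and floor are parameters). Per input,
15% of usable (non-special) tokens are selected — at least one, with
round-half-even arithmetic — and replaced by MASK, a random vocabulary
6-mer, or kept, in the conventional 80/10/10 split. Training stops after
a fixed step budget or on a validation-loss plateau (configurable
patience); a NaN loss aborts with a diagnostic.

**Class balancing.** The minority class is oversampled by re-extracting
both element windows displaced by a uniform offset in ±50 bp (offsets
that would overrun the contig are resampled); originals are always
retained and provenance is tracked. Window-shift oversampling, rather
than plain duplication (also available), adds positional jitter that the
max-pooled TextCNN must become invariant to. Balancing applies to the
training split only.

**Fine-tuning.** Cross-entropy on the balanced training set; AdamW
(lr 10⁻³ at desk scale, 3·10⁻⁴ default for pre-training, linear warmup,
decoupled weight decay 0.01 on matrices only). AUROC/AUPR/F1 are traced
per epoch on the validation split and the best-AUROC checkpoint is kept.

**Domain-adversarial transfer (DANN).** Each step runs the encoder on a
mixed batch: labeled source rows feed the TextCNN head (`L_class`), and
all rows feed the domain discriminator (`L_domain`, binary
source/target). The GRL passes features unchanged forward and multiplies
backward gradients by −λ, so one optimizer step descends
`L_class + L_domain` for the heads while the encoder effectively
descends `L_class − λ·L_domain` — the standard saddle-point objective.
Writing the λ into the total loss *and* reversing in the GRL would count
the reversal twice; the package keeps the flip inside the GRL only and
logs all three terms per step so either bookkeeping convention can be
audited. λ defaults to a constant 0.1; a sigmoid ramp
`λ·(2/(1+e^(−10p))−1)` over training progress p is available. With λ = 0
the encoder receives no domain gradient and training reduces to
source-only fine-tuning. Target labels, when present, are used for
evaluation only.

## Attention interpretation

For each pair, the per-head attention matrices of the last encoder layer
are averaged; each token is scored by the mean of its row (attention
emitted; column means — attention received — are an option, as is
restricting target positions to one element). Token scores are
decomposed onto bases: a base's raw score is the mean score of the ≤ 6
k-mers covering it, which smooths the profile over a 6-base footprint.

Per pair, raw scores over all bases of both elements are normalized as
`(score − min)/max`. This ratio form is reported verbatim (it is bounded
in [0,1] for nonnegative attention and sends the argmin base exactly to
0) but it compresses the profile when attention is diffuse — a nearly
flat profile maps close to 0 everywhere, so a fixed threshold would call
nothing. Region *calling* therefore operates by default on the standard
min–max rescaling, which pins each pair's peak at 1 and makes a 0.5
threshold mean "upper half of the pair's dynamic range"; both
normalizations are exposed. High-attention regions are maximal runs of
≥ 6 bases above the threshold.

**Enrichment.** Candidate strings are all windows of widths 6–12 of a
positive-record region that cover its peak base. Enumerating windows,
rather than taking one trimmed substring, matters: region boundaries
include a few bases of random flank (the per-base smoothing footprint),
so any single cut almost never recurs exactly across records, while one
of the enumerated windows aligns exactly on a recurring motif instance.
Candidates seen in fewer than two distinct regions are dropped before
counting. Each surviving candidate is scored by the hypergeometric upper
tail P(X ≥ k | N, K, n), where N counts all EP pairs analyzed, K the
positive pairs, n the pairs containing the candidate in either element
(exact substring), and k the positive pairs containing it. Because
hundreds of overlapping windows are tested per run, significance is
assessed on Benjamini–Hochberg adjusted p-values (q ≤ 0.005 by default;
raw-p mode is available): an uncorrected 0.005 cutoff admits an expected
~2 false motifs per run even on permuted labels, which the null
calibration in the test suite exposes.

Significant candidates are merged greedily in decreasing-support order:
a candidate joins the first motif whose anchor it matches as a substring
or with an overlap of ≥ 6 bases and ≤ 1 mismatch at the best offset;
otherwise it seeds a new motif. Instances are offset-aligned into a
position frequency matrix (columns sum to 1; consensus = column argmax)
serialized in MEME minimal format.

Regions are labeled **common** when a candidate of theirs is significant
and merges into a motif with support ≥ 3, otherwise **specific**;
positional density histograms of region midpoints and per-record
common/specific counts summarize where the model looks.

**k-mer pair mining.** In each pair's head-averaged matrix, every
(enhancer token, promoter token) cell with attention ≥ 10/L (ten times
the uniform row weight; configurable, cross-segment cells only by
default) contributes one count to that (6-mer, 6-mer) pair. Counts
accumulate separately for positive and negative records; the top-1,000
pairs per class are compared and pairs absent from the negative top list
are flagged exclusive-to-positive.

## Synthetic benchmark

The generator draws i.i.d. backgrounds with a specified GC fraction and
plants, in each positive pair independently with probability 0.9, one
mutated copy (5% per-base substitution by default) of an 8-bp enhancer
motif and an 8-bp promoter motif at uniform interior positions (the
outer 5 bases are avoided so every instance is fully covered by 6-mers).
Negatives are pure background; default counts are 200 positives and
2,000 negatives. Planting uses a consensus string plus i.i.d.
substitution rather than PWM sampling so ground truth is an exact string
and recovery assertions are crisp. The domain-shift variant reuses a
chosen fraction of the source's two motifs (0.5 shares exactly one) and
redraws the rest, optionally shifting background GC (0.4 vs 0.6 in the
transfer benchmark). Everything is byte-deterministic in the spec seed.

What the generator does *not* emulate: genomic distance effects, GC- and
repeat-structured real backgrounds, degenerate/PWM-like motif families,
cooperative or spaced motif grammars, and chromatin context. Passing the
planted-recovery and transfer checks therefore demonstrates that the
architecture, training loop, attention pipeline and statistics are wired
correctly and can extract a genuine sequence signal under class
imbalance and domain shift — not that the model attains benchmark-level
accuracy on real EPI data, which requires full-scale training.

## Problem sizes in the test suite

All trained checks use the desk-scale preset and shortened element
windows so the whole suite runs in minutes on a single core: the
planted-recovery benchmark uses 300/200-bp windows with the default
200/2,000 class counts (one epoch over the balanced ~3,200-sample
training split reaches validation AUROC ≈ 0.96); the transfer and null
benchmarks use 240/160-bp windows with 80/400 and 60/240 counts over
three seeds each. Shorter windows raise the motif-to-background ratio
relative to full-size windows; this is the intended trade of the
desk-scale setting, not a property of the method. The null-calibration
band (mean validation AUROC in [0.4, 0.6] over three seeds) is read on
the final-epoch metric, since best-epoch selection is upward-biased
under the null.

## Numerical notes and limitations

* Float32 throughout; attention rows sum to 1 within 10⁻⁵; PWM columns
  within 10⁻⁹ (exact renormalization on export).
* The hypergeometric tail is computed by `scipy`'s survival function in
  log space; the suite pins it to an exhaustive enumeration oracle for
  all N ≤ 12 at 10⁻¹².
* Max-pool gradients follow the first argmax on exact ties (measure-zero
  under float32 training noise).
* Determinism: identical seeds give identical splits, masks, batches,
  and single-threaded loss traces; BLAS-threaded reductions may differ
  across builds at the last ulp.
* The encoder is O(L²) in memory and time; full 4,992-token inputs are
  practical for single forward passes on CPU but training at that length
  needs a GPU-class budget. Chunked or linear attention is out of scope.
* The domain discriminator sees the CLS vector only; if a domain's
  signature lives entirely in positions the CLS attention ignores, mean
  pooling may work better (config switch).
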