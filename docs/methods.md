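# Methods

## The model

`seq2track` implements a simplified convolution+attention network that maps
a one-hot DNA window to per-bin, per-track Poisson rates. The design follows
the lineage of large sequence-to-track models (convolutional stem and tower
for local context and resolution reduction, self-attention for long-range
interactions, linear per-track heads), reduced to the structural essentials
so that every architectural choice is an explicit, testable configuration
field.

Pipeline for an input of length `L` with bin size `b = 2^p`:

1. **Stem** — a same-padded convolution (kernel 15) from 4 channels to
   `model_width/2`, followed by the first factor-2 pooling stage.
2. **Tower** — `num_conv_blocks − 1` pre-norm convolutional blocks
   (LayerNorm → GELU → conv, kernel 5), residual whenever the width is
   unchanged, with geometric width growth to `model_width`; the first
   `p − 1` tower blocks each end in a factor-2 pooling stage, so after the
   tower there is exactly one position per bin.
3. **Attention stack** — `num_attention_blocks` pre-norm blocks:
   residual multi-head self-attention, then a residual feed-forward
   sub-block. Positional information is a learned bias added to the
   attention logits, symmetric in the distance `|i−j|` by default.
4. **Crop** — central cropping to `output_bins` (margins, where the
   receptive field is truncated, are never scored).
5. **Optional pointwise layer** — LayerNorm → linear (width → 2×width) →
   GELU, present only when `use_final_pointwise` is set.
6. **Head** — one linear layer to `num_tracks` outputs, then softplus.

Pooling is softmax-weighted ("attention") pooling with a learned
per-channel temperature initialized at 2 (max pooling is selectable).
Dropout (rate configurable, default 0) is applied inside attention and
feed-forward sub-blocks during training only.

**Positivity.** Poisson rates must be strictly positive; softplus on the
head output guarantees this structurally, and logarithms in the loss are
additionally floored at 1e-8. This choice is a detail the model family
leaves open; it is fixed here and asserted by tests.

**The two ablation flags.** `use_final_pointwise` removes stage 5 entirely.
`use_attention_linear=False` removes one linear layer from each attention
block; which linear layer is ambiguous in this model family's shorthand, so
both readings are implemented and selectable via `attention_linear_site`:
`output_projection` (default) deletes the post-attention projection, which
forces `num_heads × head_dim = model_width` because the concatenated heads
then feed the residual stream directly; `ffn_second` collapses the
feed-forward expansion to a single width-preserving linear. The adopted
default configuration has both flags off. Ablations remove structure — the
parameters do not exist — rather than zeroing weights, so parameter counts
are comparable across variants. Note a scale effect: removing the per-block
attention linear sheds `~n_attn × width²` parameters versus `~2 × width²`
for the pointwise layer, so the strict count ordering baseline > no-pointwise
> no-attention-linear > both-removed requires at least 3 attention blocks
(at the full-scale 11 it is comfortable); structural checks use a
3-attention-block reduced configuration for this reason.

**Initialization** mirrors the Kaiming-uniform default of mainstream
frameworks (`U(±1/√fan_in)` for weights and biases), drawn from a seeded
NumPy generator in a fixed layer order, so `build_model(config, seed)` is
bit-reproducible.

**Implementation.** The network, its backward passes, and AdamW are written
directly on NumPy arrays (float64). Every layer's gradient is verified
against central finite differences in the test suite. At the desk scales
below, one training step (forward + backward + update) takes ~10 ms on one
CPU core; a full-scale (196,608 bp, 5313 tracks) forward pass takes ~30 s.

## Training protocol

AdamW (β = 0.9/0.999, ε = 1e-8, decoupled weight decay on all parameters) at
batch size 1, 10 epochs, with a per-iteration piecewise-linear learning-rate
schedule: 0 → `peak_lr` across the first (warmup) epoch, then linear decay
to exactly 0 at the final step. Full-scale defaults are `peak_lr` 3e-5 and
weight decay 1e-4. The loss is `mean(λ − y ln λ)` over bins and tracks
(`ln y!` omitted — constant in the parameters, so reported losses are
comparable only within this toolkit). Multi-track mode averages the loss
over all tracks; single-track mode uses one selected track's columns only.
Per-epoch shuffling is seeded from `(shuffle_seed, epoch)`, making loss
trajectories bit-reproducible on a fixed platform.

**Evaluation** pools all bins of all evaluation examples into one
prediction/target vector pair per track and reports the Pearson correlation
(population moments; the normalization cancels), averaged over tracks.
Constant tracks are skipped with a warning and listed. Pooled-versus-
per-example averaging genuinely differ (a test constructs a case where they
disagree); the pooled convention is this package's fixed, documented choice.

## Data handling

Coordinates are 0-based half-open throughout (BED convention). Chromosomes
are tiled into fixed-length windows; windows are randomly partitioned into
train/validation/test with largest-remainder rounding of the requested
fractions (remainder ties resolve in train > validation > test order).

**Homology-aware reassignment** guards against evaluation leakage when a
pretrained model's training data is related to the new dataset: every
region flagged homologous (the table is an input; detection is out of
scope) is moved into train, and an equal number of seeded, non-homologous
originally-train regions are moved out to the labels the homologous regions
vacated. "Equal" is exact up to availability; a shortfall is logged, not
fatal. Provenance flags (`originally_assigned` / `reassigned_in` /
`reassigned_out`) make either audit direction possible, and
`audit_leakage` must return zero after reassignment.

Coverage is binned by **summation** (counts are extensive). Targets are raw
counts; no squashing or clipping transform is applied by default. Sequences
and targets are taken from the forward strand; no reverse-complement
augmentation. The dataset container is a versioned NumPy `.npz` archive
(sequence codes, dense target array, JSON header with the track table and
provenance fingerprint); round trips are exact. FASTA/BED/bedGraph readers
and writers (gzip tolerated) convert external data at the boundary.

## Checkpointing and transfer

A checkpoint stores every named parameter plus the embedded architecture
config (and provenance), so a model rebuilds from the file alone; optimizer
state is deliberately excluded — fine-tuning restarts with a fresh
optimizer. Fine-tuning = load checkpoint → delete the head → install a
freshly seeded head sized to the new track count → optionally freeze the
trunk (only head parameters receive updates; with a fully frozen trunk the
trunk backward pass is skipped) → train under the standard protocol.

The track-count sweep trains, for each (additional-track count, replicate)
cell, a freshly initialized model on the track of interest plus a seeded
sample of additional tracks, then fine-tunes on the single track of
interest for another 10 epochs at a reduced learning rate. Cell seeds are
derived as `SeedSequence([base_seed, count, replicate])`, so extending the
count list never perturbs existing cells. Both the track sample and the
initialization are redrawn per replicate by default (`resample_tracks`
exposes the alternative).

## Synthetic regulatory-grammar benchmark

The generator emulates the statistical structure this model family assumes:
fixed-length windows whose sequence content *causes* per-bin count tracks.

- **Sequence**: i.i.d. background at a configurable GC content; for each
  motif, Poisson-many (mean `mean_plants_per_motif`, default 3) consensus
  instances planted at uniform positions, each position independently
  mutated at `mutation_rate` (default 0); overlapping plants overwrite.
- **Rates**: additive — `baseline` (default 1.0/bin) + per-track motif
  weight × exact-match occurrences overlapping the bin + pairwise
  interaction terms (weight added to both partners' start bins whenever two
  motifs co-occur within a maximum start-to-start distance), floored at
  1e-3. The additive form keeps every expected value hand-enumerable; the
  pair terms give sequence determinants that no per-bin local model can
  capture.
- **Targets**: independent Poisson draws at those rates (or the exact rates
  with noise off, making the generator's ceiling — pooled correlation
  exactly 1 for a rate-profile oracle — testable).
- **Task families**: two grammars over a shared motif vocabulary whose
  supports share an exact, constructed fraction of motifs, emulating a
  conserved regulatory grammar across species; transfer pairs draw
  pretraining data (many tracks) from one member and fine-tuning data (few
  tracks) from the other, with disjoint sequence seeds.
- **Distractor tracks** for the sweep: permuted copies of real tracks,
  tracks from a disjoint-vocabulary grammar evaluated on the same sequences
  (chance matches only), or pure Poisson noise at the base mean rate.

What the generator does **not** emulate: real genomic background
composition and repeats, soft motif matches/PWM energetics, chromatin
biophysics, assay-specific noise (fragment-length effects, GC bias),
strandedness. Passing tests therefore demonstrate that the machinery —
optimization, transfer, freezing, sweep logic — behaves correctly on data
with the assumed causal structure, not that any accuracy level carries over
to real assays.

## Desk-scale reference experiments

`seq2track.experiments` fixes one set of study conditions used by both the
test suite and `scripts/acceptance.py` (the problem sizes are chosen so the
whole battery runs in roughly a quarter hour on one CPU core):

- **Geometry**: 1,024-bp windows, 16-bp bins (4 pooling stages), 56 output
  bins (4 cropped per side); 32-channel trunk, 4 conv blocks, 2 attention
  blocks, 4 heads × 8 dims. ~30k parameters.
- **Optimization**: the 10-epoch protocol with peak learning rate 3e-3 —
  the full-scale 3e-5 is tuned for a model four orders of magnitude larger
  and does not move this small a network measurably in 10 epochs — and
  3e-4 (10× lower, mirroring the full-scale train/fine-tune ratio) for
  post-hoc single-track fine-tuning.
- **Memorization**: 8 examples, single track, 200 epochs, 3 seeds; training
  correlation must reach 0.95 (an optimization-health floor; observed
  ≈ 1.0).
- **Transfer**: 8-motif vocabulary, 75% support overlap; member A supplies
  20 tracks × 256 pretraining windows, member B 1 track × 64 fine-tuning
  windows (validation 96). The fine-tuning set is deliberately scarce:
  transfer matters exactly when downstream data cannot support training
  from scratch to ceiling, and with abundant downstream data this miniature
  saturates and the regimes become indistinguishable. Four regimes per
  paired seed (scratch, fine-tuned, fine-tuned+frozen trunk,
  scratch+frozen trunk control).
- **Sweep**: 4 informative + 64 distractor tracks, counts {1, 4, 16, 64},
  3 replicates, 96/48 train/validation windows. The sweep's distractor
  tracks are driven by a *planted* 12-motif vocabulary disjoint from the
  4 informative motifs: they carry real, learnable sequence signal and so
  compete for trunk capacity and loss weight, which is the mechanism of
  the task-count trade-off (distractors whose motifs never occur in the
  sequences are gradient-inert and produce no trade-off at all — they were
  tried and discarded). The multi-track phase runs at 3e-4 with post-hoc
  single-track fine-tuning at 1e-4: at this scale 3e-3 drives even the
  least-diluted cells to (and past) their small-sample optimum inside the
  fixed 10 epochs, where continued single-track training can only overfit;
  at 3e-4 every cell is still ascending, so the sweep isolates the
  task-count effect and fine-tuning has headroom in every cell, mirroring
  the (far from converged) regime of the full-scale experiments.

## Known limitations

- Batch size is fixed at 1 in spirit and in the inner loop (larger batch
  sizes are gradient accumulation); there is no batch-level vectorization.
- Exact-match motif scanning means mutated plants fall back into the
  background rather than contributing partial signal.
- The relative-position bias is learned per distance; the basis-function
  encodings of the original model family are out of scope.
- Homology detection itself is out of scope; the reassignment consumes a
  precomputed table.
- No mixed precision, no distributed or accelerator execution, no early
  stopping (the protocol trains a fixed number of epochs).
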