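# Methods

## Problem setting

Quantifying blood-vessel density in H&E-stained pathology slides requires
detecting many small, low-contrast objects against a visually dominant,
textured background. `piyolo` implements a single-stage anchor-based
detector for this regime: a standard single-scale YOLOv7 augmented with
three switchable modules — bi-level routing attention (BiFormer) in the
backbone, CARAFE content-aware upsampling in the neck, and GSConv-based
ELAN-GS aggregation blocks in the neck. Each module is a drop-in: every
variant preserves the baseline's inter-block feature shapes, so the
modules can be ablated independently.

The package runs on a self-contained reverse-mode autodiff core
(`piyolo.nn`) over numpy arrays. All primitives the detector needs —
dense/grouped/depthwise convolution, batch and layer normalisation, max
pooling, nearest upsampling, window unfolding, batched matmul/softmax —
carry analytic backward passes that are verified against central finite
differences in the test suite.

## Architecture

The baseline follows the standard single-scale YOLOv7 layer graph: a
4-conv CBS stem; four ELAN stages separated by max-pool transitions, with
feature taps at strides 8/16/32 (512/1024/1024 channels); an SPPCSPC
block; a PAFPN neck with two top-down upsample sites and two bottom-up
strided transitions; RepConv heads feeding 1x1 convs that emit
`3 x (5 + C)` channels per scale over 3 anchors (COCO anchor priors).

**Bi-level routing attention.** A feature map is partitioned into S x S
regions; region-mean queries/keys form the affinity matrix
`Ar = Qr Kr^T` (S^2 x S^2), and each region routes to its top-k most
affine regions (ties break toward the lower region index, for
determinism). Token-to-token scaled-dot-product attention (logits scaled
by `1/sqrt(head_dim)`) then runs only over each region's gathered keys
and values, and a depthwise 5x5 convolution of the value map (local
context enhancement) is added. The full BiFormer block is: depthwise 3x3
positional convolution (residual), LayerNorm -> BRA (residual),
LayerNorm -> 2-layer MLP with SiLU, expansion ratio 3 (residual). Inputs
whose spatial dims are not divisible by S are zero-padded up to the next
multiple and the output is cropped back, which keeps the routing algebra
exact on the padded grid.

Two such blocks are inserted after the final 1x1 convolutions of the
last two backbone ELAN stages, each behind a 1x1 bottleneck
(1024 -> 88 -> 1024, 4 heads). S = 8 at the stride-16 insertion and
S = 4 at stride-32, top-k = 4. The embedding width 88 is the calibrated
value at which the two insertions add the parameter budget reported for
this modification (+0.53 M in the fused graph); the mechanism itself
fixes none of these sizes, so the ablation parameter table is the only
constraint and all of them are exposed in `ModelConfig`.

**CARAFE.** A 1x1 convolution compresses C channels to `Cm`, a 3x3
encoder predicts `sigma^2 * kup^2` channels, which are rearranged
channel-to-space (sigma x sigma sub-pixel blocks in row-major order) and
softmax-normalised over the `kup^2` axis, giving one nonnegative,
unit-sum kernel per output location. Each upsampled pixel is the dot
product of its kernel with the `kup x kup` input window centred at its
source pixel; all channels share the location's kernel. Defaults:
sigma = 2, kup = 5, kenc = 3, Cm = 64 at the operator level; the
detector's two neck instances (256- and 128-channel sites) use Cm = 108,
the calibrated value matching the reported +0.24 M. Windows overhanging
the border read zeros, so a constant field is reproduced exactly on the
interior (and everywhere when kup = 1).

**GSConv / ELAN-GS.** GSConv spends a dense `k x k` convolution on half
its output channels, derives the other half by a depthwise convolution
of the first half, concatenates, and applies a two-group channel
interleave shuffle. In the ELAN-GS neck blocks the four pre-concat 3x3
convolutions are GSConv; the neck's two strided MP-transition 3x3
downsamplers are replaced as well. The depthwise kernel is 3 in the
detector (configurable, default 5 at the operator level): this scope and
kernel were selected by exhaustive search as the closest principled
configuration to the reported parameter reduction, landing at 33.82 M
against a printed 33.80 M — no scope/kernel combination reaches the
printed value exactly, and we do not tune per-instance kernels to force
it.

## Profiling conventions

Parameter counts and GFLOPS are reported for the *deployment* graph, the
form in which such detectors are benchmarked: RepConv's parallel 3x3 and
1x1 conv+BN branches merged into one biased 3x3 (the merge is
implemented and tested for exactness), batch norm folded into conv
biases, implicit add/multiply knowledge folded into the head convs. This
convention reproduces the baseline's published 36.48 M at one class
exactly; counting the raw training graph instead gives 37.20 M, which
matches the official full-width training checkpoint at 80 classes, so we
are confident in the identification. Compute is measured by counting the
multiply-accumulates the forward pass actually executes (each MAC = 2
FLOPs, plus bias adds), via instrumented conv/matmul primitives — so
attention matmuls, LCE and CARAFE reassembly are included; BN,
activations, pooling and nearest upsampling count zero, as in the usual
detector-profiling tools.

Two published numbers cannot be reconciled with any consistent
architecture and are reported as measured:

* the full model's parameter count: the published per-module deltas
  (+0.53, +0.24, -2.68 M) are additive and sum to 34.57 M, not the
  published 34.90 M; our full model measures 34.58 M;
* the full model's 119.70 GFLOPS: +16.5 G over the baseline is
  impossible alongside +0.53 M parameters, because at strides 16/32
  (<= 1600 positions) a convolution contributes at most 2 x 1600 FLOPs
  per parameter and BRA's sparse-attention matmuls are ~0.1 G at the
  calibrated width; our full model measures ~99.7 G (the GSConv neck
  saves more compute than attention and CARAFE add).

## Training and evaluation

The loss is the standard YOLO composite:
`0.05 * (1 - CIoU) + 0.7 * BCE(objectness) + 0.3 * BCE(class)`, with
objectness balanced 4.0/1.0/0.4 across strides 8/16/32 and the detached
CIoU as the objectness target. Assignment gates ground-truth boxes to
anchors within a 4x width/height ratio and places each match at the
box's cell plus its two nearest neighbor cells. The class BCE is trained
even with a single class, because decoded confidence is
objectness x class probability and an untrained class channel would
inject noise into the score ranking. Box decode uses the sigmoid form:
`xy = (2s - 0.5 + grid) * stride`, `wh = (2s)^2 * anchor`.

Head biases follow the prior initialisation of the one-stage detector
literature: the objectness bias starts at the log odds of the expected
object density per grid cell (8 objects per image) and the class biases
near the single-class prior, so that early optimisation refines boxes
instead of first suppressing a half-confident background. Other weights
use scaled-normal (He) initialisation from a single seeded generator.

Anchor priors default to the COCO set of the YOLO family; `train_model`
additionally runs autoanchor — a seeded k-means over the training boxes
in network pixels, nine centres sorted by area, three per scale — which
is the standard YOLO practice and matters whenever the target shapes
(near-square vessel rings spanning an order of magnitude in size) differ
from the COCO statistics. It can be disabled (`auto_anchor=False`), and
is skipped automatically when the dataset has fewer boxes than clusters.

Training defaults mirror the study protocol: 200 epochs, batch 24, Adam
with a maximum learning rate of 1e-3 and "momentum" 0.937 — interpreted
as Adam's beta1, since 0.937 appears alongside the Adam optimizer in the
protocol — step decay x0.1 at 60% and 85% of the run, from scratch, with
mosaic augmentation (four flipped, HSV-jittered, cropped images
composited around a jittered centre; HSV gains 0.015/0.7/0.4; boxes
remapped and dropped below 10% surviving area). Evaluation ranks
detections by confidence, greedily matches them to unmatched same-class
ground truth at IoU >= 0.5, and integrates the all-point interpolated PR
curve (11-point available behind a flag); mAP averages over the classes
present. mAP is reported at IoU 0.5, the community default for
single-threshold comparisons.

## Synthetic data

The generator emulates the target imagery at the level the detector
cares about: 512 x 512 patches with a smooth pink eosin-like background,
scattered dark nuclei-like dots, and ring-shaped vessel cross sections
(lighter lumen inside a darker wall) spanning 8-120 px with random
eccentricity and rotation, each annotated with the tight bounding box of
its rendered mask. It is byte-deterministic given a generator seed. It
does *not* reproduce stain variability, tissue texture continuity,
out-of-focus blur, vessel branching, or the ambiguity of real
annotations — so passing the end-to-end checks demonstrates that the
pipeline (assignment, loss, optimisation, decoding, NMS, evaluation) is
sound, not that real-data accuracy numbers would be reached.

## Problem sizes used in the checks

The repository's own checks are sized for a laptop-class CPU: operator
oracles run on maps up to 8 x 8 against explicit-loop references
(>= 100 seeded instances per operator); profiling builds the five
full-width variants and runs single 640 x 640 forward passes; the
end-to-end trainability check trains the full PI-YOLO configuration at
width multiple 0.1 and 256 px input on 8 synthetic 256 x 256 patches for
300 Adam steps and requires mAP@0.5 >= 0.9 on those same images — a
memorisation test of the whole loop, deliberately small. That check holds
the learning rate at its peak: the step decay points are defined as
fractions of a full-length (200-epoch) schedule and are not meaningful
inside a 300-step run. Width-scaled variants derive
concat widths from their actual inputs, so rounding to units of 8 never
breaks interface shapes.

## Known limitations

* No GPU path; full-width training at realistic dataset sizes is out of
  reach of the numpy core (inference and profiling at 640 are fine).
* Max-pool gradients send ties' gradient to the first maximum
  encountered; exact ties are measure-zero under float noise.
* The BRA routing indices are treated as non-differentiable selections
  (as in the reference designs); gradients flow through everything else.
* Letterboxing uses bilinear resize via PIL; sub-pixel differences from
  other resize kernels are possible when comparing against other stacks.
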