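# Methods

## The activation operator

CroReLU generalises ReLU from a scalar threshold to a learned spatial
condition. For an activation tensor `x` of shape (batch, channel, height,
width), each channel `c` carries a vertical `Kh x 1` kernel `P1[c]` and a
horizontal `1 x Kw` kernel `P2[c]` (both depthwise: channel `c`'s condition
sees only channel `c`). The condition is

    L(x)[c] = x[c] * P1[c] + x[c] * P2[c]        (zero padding, stride 1)

optionally followed by a per-channel batch normalisation with learnable
affine, and the output is `max(x, L(x))` elementwise. Because convolution
is linear in the kernel, the two 1-D branches equal a single 2-D kernel
supported on a cross; the centre coefficient is counted by both branches.
We implement the sum exactly as written — the learned weights absorb the
double-counted centre — and keep the composed-kernel equivalence as a
tested invariant rather than an implementation path.

Design choices where the operator definition leaves room:

- **Depthwise branches.** The per-channel indexing of the kernels makes the
  condition depthwise; this keeps the parameter cost of one site at
  `C * (Kh + Kw + 2)` and preserves channel independence (a tested
  invariant).
- **Condition normalisation.** The summed condition passes through one
  per-channel batch normalisation (batch statistics in training, running
  statistics at inference) so the condition stays on the scale of the
  identity path regardless of the branch-weight magnitude. It can be
  switched off (`normalize=False`), dropping the per-site cost to
  `C * (Kh + Kw)`.
- **No convolution biases.** The normalisation shift subsumes them.
- **Boundary rule.** Zero padding of `(K-1)/2` per side, stride 1, so the
  activation preserves shape at every site.
- **Initialisation.** Branch weights are drawn from N(0, 0.01^2) and the
  affine starts at identity, so a fresh CroReLU behaves almost exactly like
  ReLU and training departs from a known-good operating point. All draws
  are seeded.
- **Tie-breaking.** At `x == L(x)` the forward value is unambiguous; the
  backward pass routes the gradient to the identity branch (mirroring
  ReLU's convention at 0), so a zero-initialised condition receives no
  spurious gradient through the max.

Gradient correctness of the layer (input, branch weights, and affine, in
training mode, i.e. through the batch statistics) is verified against
central finite differences at points sampled away from max ties; at a tie
the subgradient is a convention, not a derivative, so tested instances
enforce `min |x - L(x)| > 1e-2`.

## The numpy network stack

The package runs on a self-contained, CPU-first numpy layer stack
(`crorelu.nn`): im2col/GEMM convolution with stride, zero padding and
channel groups; batch normalisation; max/global-average pooling; linear
heads; squeeze-and-excitation gates; explicit per-layer backward passes;
and the RAdam optimiser (bias-corrected first moment with the rectified
adaptive step, falling back to an un-rectified mean step while the
variance estimate is untractable) with a x0.1-every-20-epochs step decay.
Float32 is the working precision for networks; the layers do not hard-cast,
so the finite-difference tests run the same code in float64.

## Backbones and activation surgery

Two classifier families are built: SE-ResNet-50 (bottlenecks 3-4-6-3 with
squeeze-and-excitation gating, reduction 16) and MobileNet v1 (width 1.0,
13 depthwise-separable blocks partitioned into four stages at the stride-2
boundaries, so the stage-wise sweep is well defined for both families).

A `ReplacementPlan` selects which of the four stages (plus optionally the
stem) swap ReLU for CroReLU. The surgery replaces each activation **in
place** — same site, same channel count — leaving every convolution and
normalisation untouched. Read across unit boundaries the replaced regions
then execute as normalisation -> CroReLU -> convolution
("pre-cross-activation") while unreplaced regions keep
convolution -> normalisation -> ReLU. We deliberately do not re-plumb the
blocks into v2-style pre-activation residuals: that would move
normalisation layers onto different channel counts, changing the parameter
budget of the *unreplaced* network and making the surgery cost ambiguous.
With in-place replacement the delta between any two plans is exactly the
summed `condition_param_count` of the sites that differ — an identity the
tests check against module enumeration. Full 3x3 surgery on the 3-class
SE-ResNet-50 (26.05 M parameters) adds 181,760 parameters (~0.18 M); 7x7
adds ~0.36 M. Both sit inside the published bounds of 0.6 M and 1.7 M; the
per-site accounting behind the published absolute counts is not stated, so
only the deltas are treated as checkable, as upper bounds.

The SE gate's internal scalar nonlinearity stays ReLU even under full
surgery (its input is a pooled vector with no spatial extent); an ablation
flag (`replace_se_internal`) exists but defaults off. The classifier head
is global average pooling plus one linear layer, no dropout.

## Synthetic data

The clinical datasets for infiltration grading are private, so the package
ships a seeded generator of three-class H&E-like texture patches
(`crorelu.synthetic`). A patch is eosin-pink stroma with correlated stain
texture and scattered hematoxylin-purple nuclei; lesion classes add foci of
tubular motifs — curved tubes with dark rims and ring (lumen)
cross-sections, packed into a disc to a sampled area fraction
(default 0.25-0.45), with denser nuclei inside.

The class rule operationalises "maximum lesion diameter" as the Feret
diameter (maximum pairwise pixel distance) of each 8-connected lesion
component, against a configurable pixel threshold (default
`patch_size / 4`, i.e. 56 px at the default 224 px — a stand-in for the
0.5 cm rule; only the relative rule matters for exercising models). The
invariants hold **by construction**, not by rejection sampling:

- *microinfiltration*: every focus is clipped to a disc of diameter
  0.45-0.95 x threshold, and foci are placed with disjoint supporting
  discs, so no component can exceed the threshold;
- *infiltration*: one focus contains a connected tube whose endpoint pixels
  are pinned 1.2-1.6 x threshold apart, so its component always exceeds it;
- *normal*: no lesion at all.

Diameters are sampled up to and just above the threshold, so the two
lesion classes are deliberately confusable near the boundary. What the
generator does **not** emulate: real stain variability, nuclear atypia,
tissue architecture beyond blob/tube motifs, scanner artefacts, or any
photorealism. Passing tests therefore show that the training and surgery
machinery works and that the activation can exploit oriented tubular
context — they say nothing about clinical performance.

## Training and evaluation

Training uses RAdam (batch size 64, initial learning rate 1e-4, x0.1 decay
every 20 epochs, up to 200 epochs — all configurable and scaled down for
desk-scale runs), softmax cross-entropy, seeded shuffling/augmentation,
and best-checkpoint selection on test accuracy. Augmentation applies
random horizontal/vertical flips, rotation and noise overlay, then
rescales to the target size. The "10 decays per 20 steps" schedule is read
as x0.1 every 20 epochs.

Evaluation reduces the K x K confusion matrix to overall accuracy plus
macro one-vs-rest precision, sensitivity and specificity (percentages);
classes with an undefined ratio are excluded from the macro mean with a
warning. ROC curves are one-vs-rest threshold sweeps over the unique
scores with trapezoidal AUC; scikit-learn serves only as an independent
cross-check in the tests.

## Desk-scale problem sizes

The shipped experiments are sized for a single CPU:

- synthetic datasets at 64 px (threshold 16 px) with 300 patches/class,
  split 80/20;
- the paired CroReLU-vs-ReLU comparison uses the 4-stage toy CNN
  (8-16-32-64 channels), 10 epochs, batch 16, learning rate 1e-2, three
  paired seeds — at this scale the larger rate is needed for convergence
  within the epoch budget; the mean best test accuracy of the CroReLU
  variant is required to be at least the ReLU variant's (a directional
  check, not a magnitude claim);
- generator soundness is checked on 300 patches/class at the default
  224 px configuration against a brute-force all-pairs diameter oracle;
- parameter accounting builds the full SE-ResNet-50 (no training).

## Known limitations

- The numpy stack is single-threaded GEMM; training full backbones is
  possible but slow, and no GPU path exists.
- Batch-statistics normalisation inside CroReLU couples outputs within a
  batch during training (as any batch normalisation does); inference uses
  running statistics and is sample-independent.
- MobileNet is the v1 architecture; absolute SE-ResNet-50 parameter counts
  depend on head/reduction conventions, so only surgery deltas are treated
  as meaningful.
- The Feret measurement uses convex-hull acceleration for components above
  100 px (the diameter of a finite point set is attained on its hull); the
  brute-force oracle lives in the tests.
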