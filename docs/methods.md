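# Methods

This note records the modeling assumptions behind `sbmn`, the defaults
that matter, the numerical choices the equations leave open, and what the
synthetic fixtures can and cannot demonstrate.

## Model

The classifier couples three parts:

1. **Embedding network.** Any map from image batches to `B × H` features
   (`H` divisible by 4; 2048 is the conventional full-scale width). The
   package's default is a small seeded strided CNN (three
   patch-convolution stages 4/2/2, relu, global average pooling, linear
   head) so the whole system trains in seconds on one CPU. Large
   pretrained CNNs can be substituted wherever they are available; inputs
   are standardized per image, and grayscale inputs are replicated to
   three channels for RGB backbones. Backbone weights train jointly with
   the rest of the model (nothing is frozen by default).

2. **Category memory.** A bank `CM ∈ R^{M×k×H}` of `M = 16` slots per
   class, initialized i.i.d. N(0, 1). The memory is *state*, not a
   parameter: after every optimizer step the bank is replaced wholesale
   by the modified memory the class modules produced for that batch,
   detached from the autodiff graph. Gradients reach the memory content
   only within the step that produced it. At evaluation time the bank is
   frozen and writes raise an error. An exponential-blend commit
   (`blend_update`, `alpha < 1`) exists but is off by default; full
   replacement is the reference behavior.

3. **Per-class similarity modules and classifier.** Each class owns an
   independent module with four heads. A head projects features and the
   class memory through shared linear maps `E_K : H → H/4` and
   `E_V : H → H/2`, scores every (sample, slot) pair, and normalizes the
   `B × M` score matrix twice: softmax over slots (how much memory flows
   into each sample) and softmax over the batch (how much each sample
   writes into each slot). Raw scores, squashed by a sigmoid and averaged
   over slots, give the per-sample class evidence `sim̄`. The decoder
   mixes `[WV_m ‖ V_x]` and `[WV_x ‖ V_m]` per head through a two-layer
   MLP (`H → H → H`, relu) and fuses heads with linear maps `4H → H`; the
   remake decoder maps the concatenated `WV_m` of all heads (`2H`) back
   to `H`. A module's class score is the mean of its four heads' `sim̄`.
   The classifier applies the same gate with its own lightweight
   projections (shared across classes) to the modified memories — or,
   with `classifier_reuse=True`, reuses the class modules' encoders.
   Ties in the argmax resolve to the smallest class index, which is why
   a zeroed or cloned memory bank collapses all predictions onto class 0.

### Score calibration

The sigmoid-mean evidence branch receives a learnable affine calibration
`σ(e^s · sim + b)` with `s = b = 0` at initialization (identity). Bounded
similarity measures need this: a negative Euclidean distance can never
push a plain sigmoid above 0.5, and cosine/Pearson scores live in
[-1, 1], so without calibration the evidence branch pins near chance and
its gradient vanishes. The softmax weightings always act on the raw
scores. At initialization the calibrated equations coincide exactly with
the uncalibrated ones, which is what the oracle tests check.

### Loss

`L = λ_cls·L_cls + λ_sim·L_sim + λ_remake·L_remake`, all `λ = 1` in
[0, 1]. `L_cls` is cross-entropy on the softmax-normalized class scores,
averaged over the batch. `L_sim` is the binary cross-entropy of each
module's evidence against the one-hot label, summed over samples and
divided by the number of classes (as printed; `normalize=True` divides by
the batch size as well). `L_remake` is the mean squared error between the
remake decoder's output and the input features, averaged over batch and
channels. Probabilities and evidences are clamped at `1e-7` before logs;
clamp events are logged at debug level because saturated sigmoids reach
the clamp routinely late in training.

## Training protocol

SGD with momentum 0.9, weight decay 4e-4, batch size 32, initial learning
rate 5e-3 multiplied by 0.95 every 5 epochs, floored at 1e-5. The
memory is committed exactly once per optimizer step and never during
evaluation. Defaults: 30 epochs for feature-level runs, 100 for image
runs with the fixture backbone (the image pipeline crosses 90% held-out
accuracy around epoch 60–70 and plateaus near 99% by 100; convergence is
visible in the loss log each run writes).

Two numerical safeguards are package choices the equations do not
prescribe:

* **Gradient-norm clipping** (global L2, default 5.0, `grad_clip=0`
  disables). The replacement recursion `m ← f(m, x)` can transiently
  amplify once the gate sharpens; unclipped joint training of backbone
  and modules was observed to overflow. Clipping bounds the step size
  without changing its direction.
* **Near-isometric initialization.** Linear weights are N(0, g²/fan_in)
  with He gain `g = √2` on the hidden (pre-relu) layer of the mix MLP.
  Without the gain each memory commit contracted the bank's norm by
  roughly half, which distance-based gating in particular cannot recover
  from.

Augmentation (horizontal/vertical flips, brightness/contrast jitter 0.5,
saturation 0.5 and hue 0.3 on color inputs, rotation uniform in ±90°) is
implemented for training batches but **off by default for the synthetic
fixture**: a ±90° rotation turns the longitudinal fracture line into a
horizontal band — the bone-loss confounder of the opposite class — so
orientation-destroying augmentation is semantically wrong for this
generator. Real tomographic slices do not have that degeneracy, and the
flag is a single config switch.

Stratified k-fold cross-validation assigns each class's samples
round-robin after a seeded shuffle, making fold membership a pure
function of `(labels, seed)`; per-fold class counts differ by at most
one sample. Every fold trains from fresh initialization, including a
fresh memory bank.

## Synthetic fixtures

* **Tooth slices** (default 64×64, up to 224): a bright two-ellipse
  root silhouette with soft edges and seeded geometric jitter on a dark
  background. The fracture class draws a thin (1–3 px) dark polyline
  roughly parallel to the root axis with a 0.5 relative contrast drop;
  the intact class draws one of {plain root, periapical blob near the
  apex, horizontal darker band} with probabilities (0.34, 0.33, 0.33).
  After drawing, the global mean intensity is re-matched so class labels
  cannot be read off the luminance; Gaussian noise (sd 0.05) is added
  last and values are clipped to [0, 1]. The generator emulates the
  *class structure* of fracture screening — thin longitudinal defect vs.
  compact or banded confounders — not CBCT physics: no beam hardening,
  partial-volume blur, 3-D anatomy or scanner noise statistics. Passing
  the end-to-end tests therefore shows the architecture can learn a
  subtle, shape-selective discrimination under confounders; it does not
  certify clinical performance.

* **Feature clouds**: two isotropic Gaussians in `R^H` (default H=64,
  sd 1, 400 samples per class) whose means are `separation · sd` apart
  (default 4). The Bayes accuracy is `Φ(separation/2)` = 97.7% at the
  default, which calibrates the convergence tests: the trained model's
  ~96–98% held-out accuracy is at the optimum up to sampling noise,
  and the 95% test threshold sits about two binomial standard deviations
  below Bayes on the 160-sample holdout.

## Interpretation analyses

* **Memory manipulation** evaluates the frozen classifier under modified
  banks: zeros, single-class cloning, fresh random draws (10 repeats by
  default, since single draws are uninformative), and a class swap.
  Expected signatures, all reproduced by the acceptance script: constant
  class-0 prediction under zeros/cloning, near-inversion under swap,
  large run-to-run fluctuation under random banks.
* **Channel scatter** pairs channel `c` of an encoded sample (the four
  heads' key projections concatenated, length `H`) with channel `c` of
  the slot-averaged encoded memory and reports the Pearson correlation
  over channels. The slot average is one deliberate reduction among
  several possible; it is configurable at the call site by passing a
  reduced memory. Trained models show strong positive intra-class
  correlation, negative inter-class correlation, and near-zero
  correlation between keys drawn from two different class modules.

## Numerical and implementation notes

* All arithmetic is float64; every source of randomness flows through
  seeded `numpy.random.Generator` instances, and two runs with the same
  seed are bitwise identical on one platform (asserted in the tests).
* The raw score matrix is `B × M` (keys `B × H/4` against `M × H/4`);
  softmax normalizations are numerically stabilized by max subtraction.
* Euclidean gating uses the negative distance with an `1e-12` floor
  inside the square root; cosine/Pearson normalize with the same floor.
  Negative-Euclidean converges noticeably slower than the other three
  measures (the ablation test budgets 100 epochs for that reason) and
  ends a few points lower — the same ordering the similarity ablation
  is expected to show.
* `mod_x` is exposed but not consumed by the default classifier (the
  classification path uses `x` and the modified memories); the remake
  and modified-feature outputs follow each sample's true class during
  training and the predicted class at inference.
* Undefined metric ratios (zero denominators) are reported as NaN with a
  warning, never silently as zero.

## Known limitations

* The memory-replacement dynamic has no fixed-point guarantee; stability
  is empirical (clipping plus near-isometric init) and a sufficiently
  aggressive learning rate can still destabilize it.
* Single-platform determinism only: BLAS reduction order may differ
  across builds, so bitwise reproducibility is not claimed across
  machines.
* `k > 2` is supported by the module stack and classifier, but the swap
  manipulation and the scatter analysis are defined for two classes.
* The fixture backbone is intentionally tiny; nothing in the package
  reproduces clinical-scale results, which require the original private
  imaging data and a full-size pretrained embedding network.
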