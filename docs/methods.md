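# Methods

## The problem being emulated

Clinical ultrasound archives carry burned-in caliper glyphs at the lesions
clinicians measured. A model trained on such images sees a feature that is
bright, high-contrast, and perfectly co-located with the label; in
deployment the images are marker-free. `caliperase` reproduces this
shortcut-learning failure, and the preprocessing defenses against it, on
fully synthetic phantoms so that every stage is testable without patient
data.

## Phantom model

A phantom is `base × noise`, clipped to [0, 1]:

* **base** — a Gaussian-smoothed random field (scale 14 px) rescaled to
  `0.50 ± 0.16`, standing in for smooth echogenicity variation;
* **noise** — unit-mean gamma noise with shape 4 (variance 0.25), smoothed
  by a Gaussian of σ = 1.5 px and therefore spatially correlated. The grain
  matters scientifically: exemplar inpainting copies pixels from
  boundary-matched patches, which only beats a constant fill when
  neighboring speckle is informative about the hidden pixel. With
  uncorrelated per-pixel noise no copy-based method can win; a finite
  resolution-cell size is also what real B-mode speckle looks like. At
  σ = 1.5 texture synthesis beats mean-fill on 20/20 glyph fixtures with a
  mean masked-MSE ratio of ≈ 0.35.
* **nodules** — rotated ellipses darkened by a factor `1 − contrast` with a
  2 px linear feather; contrast is drawn from (0.10, 0.35), near-isoechoic
  to moderately hypoechoic. The tight axis-aligned box of the rotated
  ellipse (half-width `√(a²cos²θ + b²sin²θ)`, analogously for height) is
  the ground-truth detection box; per-image boxes are disjoint.
* **distractors** — 1–3 unannotated darker structures per image (contrast
  0.04–0.12), emulating vessels and shadows. They make the texture task
  realistically imperfect: without them, nodules at any plausible contrast
  are trivially separable from clean speckle and no model has a reason to
  use markers, so the leakage phenomenon cannot arise at all. Contrast and
  distractors were calibrated once to place the texture task in the
  hard-but-learnable regime and then frozen.

Images are 128×128 by default, 1–2 nodules per image, 200 train / 100 test.

## Caliper model

Glyphs are plus-shaped crosses, arm 4 px, thickness 2 px, intensity 1.0,
burned destructively. Thickness 2 is deliberate: after area-average
downsampling to the 16×16 classifier input, a 1 px arm dilutes below the
nodule contrast and the shortcut inverts (markers become *harder* to use
than texture, the opposite of the clinical situation). Groups of 2 sit on
the left/right sides of the nodule's enclosing rectangle, groups of 4 on
all four sides, each glyph at a seeded-uniform position along its side.
Pseudo groups re-use the same geometry on rectangles no larger than the
largest nodule box and with IoU 0 against every real nodule. Mixup keeps 1
of 2 or a uniform 1–3 of 4 glyphs per group, erases the rest by texture
synthesis, and burns the same number of replacements at random positions
whose footprints have IoU 0 with all nodule boxes.

## Marker removal

`locate_markers` runs normalized cross-correlation of each glyph template,
takes local maxima above 0.65 (glyph responses measure 0.71–0.97 on these
phantoms while marker-free speckle peaks near 0.55), stamps glyph
footprints and dilates by 1 px. `inpaint_texture` fills masked pixels
boundary-inward; each pixel is copied from the center of the best
masked-SSD matching patch (9×9 window) among all patches containing no
originally-masked pixel, with a seeded uniform choice among candidates
within 10 % of the minimum SSD. Matching runs in float32; the copied value
is taken from the float64 source so a zero-SSD match reproduces the source
bit-exactly. The optional coarse network (conv 3×3 → dilated conv 3×3 →
conv 3×3, sigmoid output, masked ℓ1 loss, Adam) gives a learned smooth
reconstruction; on held-out fixtures its masked MSE is 0.6–1.1× that of
texture synthesis (it predicts a conditional mean rather than plausible
speckle, so it is competitive on MSE while visually blurrier).

## Classifier and VIB

The encoder maps a 16×16 crop to a 2K vector; the first K entries are μ,
the last K pass through softplus to give σ > 0. The VIB loss is the
variational bound `E[−log softmax(f_d(z))_y] + β·KL(N(μ,diag σ²) ‖ N(0,I))`
with the KL in closed form, `z = μ + σ⊙ε` reparameterized, n_mc = 1 during
training. The baseline trains the identical encoder with plain
cross-entropy at `z = μ`; sampling and the KL term are the only
differences. Defaults: K = 32, β = 0.01 (chosen by a small dev sweep; the
effect of β between 1e-3 and 0.1 is minor at this scale), Adam 1e-3, 60
epochs, batch 32. Two encoder backbones exist: a 2-hidden-layer MLP
(128, 64; ≈ 50k parameters) and a conv–pool–conv–pool–dense CNN (≈ 21k);
both are verified against finite-difference gradients. Evaluation decodes
deterministically at z = μ by default, with Monte-Carlo averaging optional.

## Detector

Training crops are the ground-truth box plus a 6 px context margin
(positives — the margin is what places the calipers inside the crop) and
IoU-0 random windows (negatives, 2:1), area-resized to the classifier
input. Detection slides 24/32/40 px windows at stride 5, scores each with
the classifier, keeps scores ≥ 0.5, and emits the window *minus* the 6 px
margin as the box so detection geometry matches the training-crop geometry.
Greedy NMS at IoU 0.15 follows — aggressive on purpose, since ground-truth
boxes are disjoint by construction and offset duplicate windows are the
dominant false-positive mode.

## Study design

From one phantom dataset: A0 = marker-layered train; A1 = oracle-mask
texture inpainting (emulating careful manual removal); A2 = auto-located
masks + inpainting; A3 = mixup; B1/B2 = marker-layered / marker-free test.
One detector per condition per training seed (3 seeds), evaluated at
IoU 0.3 and 0.4, with recall/F reported at the F-optimal pooled threshold.
At the defaults the marker-layered detector loses ≈ 25–38 mAP points from
B1 to B2 (in every seed), inpainted training shrinks the |gap| to ≤ 10
points and beats marker-layered training on marker-free data in every seed,
and mixup lands between the two — the qualitative ordering of the clinical
study this emulates.

The crop study trains on ~200 marker-layered positive crops and ~200
pseudo-marked negative crops (negatives centered on distractor structures,
mimicking detector proposals; their pseudo groups avoid the local blob per
the IoU-0 rule) and evaluates six cases: baseline/VIB × {negatives
pseudo-marked or as-is} × {positives marker-layered or marker-free}.
Removing the markers from the positives collapses both models to near the
chance floor (case 2 → case 3, ≈ 94 % → ≈ 57 %, all 8 seeds, sign test
p ≈ 0.004) — the annotation-leakage signature.

## Known limitations (what the desk-scale analog does not show)

* **Marked-negative advantage.** In the clinical study the baseline scored
  *higher* when test negatives carried pseudo markers than when they were
  clean. Our small models are monotone under marker removal: fewer bright
  pixels always pushes them toward "negative", which is the correct label
  for unmarked negatives, so this ordering does not reproduce. The clinical
  effect appears to be out-of-distribution brittleness of a very large
  pretrained encoder, which ~50k-parameter models do not exhibit.
* **VIB robustness.** A systematic sweep (β ∈ [1e-3, 0.3], n_mc ∈ {1, 4},
  K ∈ {16, 32}, two benchmark seeds) found no consistent VIB advantage in
  the marker-free drop: the ±2-point margin changes sign with the benchmark
  seed while the drop itself is ≈ 32 points. The marker-free texture
  ceiling on the same crops is ≈ 83 %, so representational headroom exists,
  but the bottleneck objective does not claim it at this scale. The
  corresponding assertion in the acceptance suite is left failing rather
  than weakened.
* The phantoms have no acoustic point-spread function, attenuation, or
  vendor UI chrome; the inpainting stage searches only within the same
  image; and the detector has no box regression, so absolute mAP values are
  not comparable to FPN-scale detectors — only the between-condition
  orderings are meaningful.
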