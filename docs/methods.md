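# Methods

## Scope and assumptions

The pipeline assumes one dominant insect per image, photographed against
a background whose hue distribution is separated from the body's —
the situation of a pest trap photographed from above. It does not handle
multiple insects, hue-camouflaged subjects, or scenes where the insect
touches the image border. All stages run at full double precision.

## Segmentation

RGB→HSV uses the standard hexcone conversion (scikit-image). The hue
band is a configuration value, not a learned quantity: the original
deployment derived a static threshold from hue statistics of its own
trap images, and no universal constant exists. Two usability choices:

- **Wrap-around bands.** H lives on a circle; a band with
  `t_low > t_high` selects `h >= t_low or h < t_high` so reddish bodies
  straddling h = 0 can be captured.
- **`auto` mode** (our construction, off by default): a 32-bin hue
  histogram is assumed bimodal; the band boundary is the
  minimum-frequency valley between the largest bin and the largest bin
  at least three bins away, and the band covers the side of the smaller
  mode (the insect occupies less area than the background). It fails
  loudly on unimodal histograms rather than guessing.

Denoising keeps the largest connected region. Labeling is
scanline/union based (scipy.ndimage.label) rather than recursive flood
fill — identical result, verified exhaustively against a brute-force
flood-fill oracle on all 2^16 4×4 masks for both connectivities, with
no stack-depth hazard on large blobs. Default connectivity is 8
(diagonal steps keep thin legs and antennae attached); 4 is available.
Equal-sized largest regions tie-break to the one whose first pixel
comes earliest in row-major order, which is what label order gives and
is deterministic. Holes inside the body are left unfilled: the
interior of a segmented insect is foreground by thresholding anyway,
and inventing a hole-filling step would change the shape moments.

## Features

Color moments use the masked (foreground) pixels of the H, S and V
channels. Restricting to the mask keeps the features about the insect
rather than the background; the channel choice keeps the whole pipeline
in one color space. Both are configurable points in the code rather
than hard-wired policy. The skew is the *signed* cube root
sign(x)·|x|^(1/3) — skewness must be allowed to be negative, and the
principal complex root would silently discard the sign.

Shape features are binary moments of the mask with pixel centers at
integer coordinates: m_pq = Σ x^p y^q over foreground pixels, central
moments about the centroid, η_pq = μ_pq / μ00^((p+q)/2+1).

- **Eccentricity** EC = √(λ_max/λ_min) of the second-moment matrix
  [[μ20, μ11], [μ11, μ02]]/μ00, i.e. the semi-axis ratio of the
  momental ellipse, oriented so EC ≥ 1. A rasterized 2:1 ellipse
  measures 2.0 within raster error; the value is rotation invariant
  because eigenvalues are. Collinear regions have λ_min = 0; the bare
  function returns +inf (or a configured cap), and the feature
  assembler caps at 100 so a degenerate mask cannot inject non-finite
  values into training.
- **Sphericity** SP = r_i/r_c. r_i is the maximum of the Euclidean
  distance transform over the zero-padded mask (padding makes the
  canvas border count as background). r_c is the exact minimum
  enclosing circle (Welzl's incremental algorithm on convex-hull
  vertices). The circle is taken over *pixel-extent corners* — each
  foreground pixel treated as a unit square — not pixel centers: an
  a×b-pixel rectangle then gives exactly √(a²+b²)/2, consistent with
  the distance-transform inradius, so the analytic values 1/√2 for a
  square and 10/√500 for a 40×20 rectangle are reproduced exactly
  instead of carrying an O(1/size) half-pixel bias.
- **Hu invariants** φ₁, φ₂ from η₂₀, η₀₂, η₁₁. Only the first two are
  used; they are exactly invariant to translation and quarter-turn
  rotation on the lattice, and scale invariant to within raster error
  (≲2 % at region sizes of ~1000 px). φ₂ ≤ φ₁² always (Cauchy–Schwarz
  on η₁₁² ≤ η₂₀η₀₂).

Single-pixel regions define EC = SP = 1 by convention. None of the
shape features encode absolute size, and the color moments don't
either, so the classifier discriminates on hue, brightness, texture
variance and shape ratios only — a deliberate property inherited from
the feature design.

## Classifier

Three layers, logistic sigmoid in both, trained by the online delta
rule on E = ½‖y − t‖² with a fresh seeded shuffle each epoch. Defaults:
learning rate 0.1, max 5000 epochs, stop at mean squared output error
1e-3, hard 0/1 one-hot targets (0.1/0.9 soft targets available). Weight
initialization is uniform in [−0.5, 0.5] from the seeded generator;
training is bit-reproducible given data and seed. Analytic gradients
are checked against central finite differences to 1e-6 in the tests —
the key correctness oracle for the training loop.

Min–max normalization bounds come from the training set only and are
stored in the model file; at test time values are clipped to [0, 1].
Fitting bounds on test data would leak information, and clipping keeps
the sigmoids in range for out-of-distribution inputs. Constant training
features map to 0.

The hidden width heuristic n₁ = round(√(n+m)) + a rounds half up before
adding a (√19 ≈ 4.36 → 4); with 13 features, 6 classes and a = 6 it
yields the default 10-node hidden layer. The model serializes to
versioned JSON (magic string, shapes, weights, thresholds,
normalization bounds, class names); loading validates magic, version
and shape consistency and round-trips bit exactly.

## Protocol

Frame: `0x1B 0x7E`, 16-bit big-endian sequence number, exactly 512
payload bytes, `0xFF` — 517 bytes on the wire, no checksum (corruption
handling lives in the reply path, where an erroneous reply resets the
connection). Big-endian was chosen as the conventional network order.
Short payloads are zero-padded, and a leading length frame (4-byte
big-endian total length, padded to 512) makes reassembly exact while
keeping every frame format identical; the length frame is an explicit
extension of the printed format, which leaves tail handling
unspecified. Sequence numbers wrap at 65536.

The sender is stop-and-wait with one frame in flight: timeout →
retransmit; erroneous reply → reset, resume from the same frame;
correct reply → advance. The simulator's reply bytes (ACK `0x06`, NAK
`0x15`, silence for timeout) are a test convention for the
modem-specific "right reply". `LinkConfig` adds two guards the flow
diagram leaves open: a reset after `max_retries_before_reset`
consecutive timeouts (default 5), and a per-frame `retry_budget`
(default 100) after which delivery fails with the accumulated log
attached. On a channel with any nonzero delivery probability the
default budget makes eventual delivery essentially certain
(P(fail) ≤ drop_prob^100 per frame).

## Synthetic data generator

Real trap photographs for the six target species are not publicly
available, so the generator emulates their relevant statistics: one
rotated filled ellipse (body) with per-pixel Gaussian HSV texture on a
uniform bright background (hue 0.66, far from every body hue), plus
0–4 small noise blobs that *share* the body hue but never touch the
body — they survive thresholding and must be removed by largest-region
denoising, exercising that path. The truth mask is the exact
pixel-center rasterization of the body, so segmentation can be scored
pixel-exactly and every shape feature has an analytic oracle. Bodies
are ellipses, not photorealistic insects, by design: realism would buy
nothing testable.

The six classes differ in hue center (0.06–0.46, spaced 0.08),
brightness (0.45–0.78) and elongation (semi-axis ratios ~1.2–3.5), with
one rounder, brighter class playing the beetle among the moths.
Per-class defaults live in `default_class_specs()`.

Two regimes:

- **easy**: per-pixel hue spread 0.012, no pose or lighting variation.
  Class-conditional feature distributions are separated by ≥3 pooled
  standard deviations in at least one feature for every class pair
  (asserted in tests); an end-to-end run should be near-perfect, so
  any miss indicates a defect.
- **field_like**: per-image hue drift N(0, 0.04), global brightness
  shift U(−0.2, 0.2) emulating uncontrolled lighting, free body
  rotation emulating live-pest pose, widened shape ranges and tripled
  hue spread. These overlaps were fixed once so that neighboring
  classes genuinely confuse the classifier: held-out accuracy across
  seeds falls around 0.75–0.87 — the operating range reported for
  fielded six-class classifiers of this design — rather than
  saturating.

What passing tests on this generator do **not** show: robustness to
real insect texture and wing patterns, shadows, occlusion, background
clutter, or hue-overlapping backgrounds. The generator's separability
is an idealization; field accuracy of the original hardware system is
emulated only in distributional outline.

## Benchmark sizes

The end-to-end benchmark mirrors the original study's composition:
training 70/69/72/70/75/76 images per class (432 total), lab-style
test 23/15/18/21/25/30 (132), field-style test 20/18/20/21/25/23 (127),
on a 96 px canvas. Training uses learning rate 0.2 and at most 300
epochs (the MSE target is typically reached sooner); those sizes keep a
full two-regime run around ten seconds while leaving accuracy
estimates stable to a few percent across seeds. Segmentation failures
on test images count as classification errors, as they would in the
field.

## Known limitations

- The hue-threshold segmenter fails on backgrounds sharing the body's
  hue band; `auto` mode assumes a bimodal histogram.
- Only φ₁ and φ₂ are extracted; shapes differing first in higher-order
  moments are indistinguishable.
- The protocol has no checksum, so a corrupted-but-acknowledged frame
  would go undetected; fidelity to the frame format was preferred.
- Online gradient descent with a fixed learning rate has no momentum
  or adaptive scheduling; convergence on harder feature sets may need
  more epochs.
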