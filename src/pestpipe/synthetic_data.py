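"""Synthetic insect-image generator with pixel-exact ground truth.

The field photographs the pipeline was designed for — live moths and
beetles in a light trap — are emulated by parametric scenes: one
rotated filled ellipse (the body) whose hue distribution is separated
from a uniform background, plus a few small same-hue noise blobs that
exercise the largest-region denoising step.  Bodies are deliberately
simple geometry rather than photorealistic insects so that every shape
feature (eccentricity, sphericity, Hu invariants) has an analytic
oracle on the ground-truth mask.

Six class-conditional parameter sets stand in for the six species the
system was trained on; classes differ in body hue, brightness,
elongation and texture variance.  Two regimes are provided:

``easy``
    Non-overlapping class distributions, fixed pose.  An end-to-end
    pipeline should be near-perfect here; failures indicate bugs, not
    hard data.

``field_like``
    Class distributions overlap: per-image hue drift, a global
    brightness shift emulating uncontrolled field lighting, free body
    rotation emulating live-pest pose, and wider shape ranges.  This
    regime is calibrated so that a correctly built pipeline scores
    well below perfect but far above chance, the operating range
    reported for field deployments of this kind of classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage import color

from .errors import PestPipeError

#: Hue band (non-wrap) containing every class's body hue in both
#: regimes; the background hue lies well outside it.
DEFAULT_BAND = (0.0, 0.55)

SPECIES = (
    "Cnaphalocrocis medinalis Guenee",
    "Chilo suppressalis",
    "Sesamia inferens",
    "Naranga aenescens Moore",
    "Anomala cupripes Hope",
    "Prodenia litura",
)


@dataclass(frozen=True)
class ClassSpec:
    """Class-conditional scene parameters.

    ``major_axis`` / ``minor_axis`` are (low, high) ranges for the body
    ellipse semi-axes in pixels; hue/value parameters are per-pixel
    Gaussian means and spreads in HSV units.
    """

    name: str
    major_axis: tuple[float, float]
    minor_axis: tuple[float, float]
    hue_center: float
    hue_spread: float
    value_mean: float
    value_spread: float
    n_noise_blobs: tuple[int, int] = (0, 3)
    background_hue: float = 0.66
    saturation_mean: float = 0.80


def default_class_specs() -> list[ClassSpec]:
    """The six built-in classes (easy-regime parameterization).

    Hue centers are spaced 0.08 apart in [0.06, 0.46]; brightness and
    elongation give secondary structure (the rounder, brighter class
    emulates a beetle among moths).
    """
    hues = (0.06, 0.14, 0.22, 0.30, 0.38, 0.46)
    majors = ((11, 14), (12, 15), (10, 13), (8, 11), (7, 9), (13, 16))
    minors = ((4, 5), (4, 6), (5, 7), (5, 7), (5, 7), (5, 7))
    values = (0.55, 0.70, 0.45, 0.65, 0.78, 0.50)
    return [
        ClassSpec(
            name=SPECIES[i],
            major_axis=majors[i],
            minor_axis=minors[i],
            hue_center=hues[i],
            hue_spread=0.012,
            value_mean=values[i],
            value_spread=0.03,
        )
        for i in range(6)
    ]


@dataclass(frozen=True)
class LabeledImage:
    image: np.ndarray  # H x W x 3 uint8 RGB
    truth_mask: np.ndarray  # H x W uint8, exact body rasterization
    label: str
    truth_params: dict


def _ellipse_mask(canvas: int, cy, cx, a, b, theta) -> np.ndarray:
    yy, xx = np.mgrid[0:canvas, 0:canvas].astype(float)
    dx = xx - cx
    dy = yy - cy
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(np.uint8)


def make_image(
    spec: ClassSpec,
    seed,
    canvas: int = 96,
    rotate: bool = False,
    hue_shift: float = 0.0,
    value_shift: float = 0.0,
) -> LabeledImage:
    """Render one labeled scene; deterministic given the seed.

    ``hue_shift`` and ``value_shift`` are global per-image offsets used
    by the field-like regime (lighting and hue drift).  The truth mask
    is the exact pixel-center rasterization of the body ellipse; noise
    blobs share the body hue but never touch the body, so they are
    removed by largest-region denoising, not by thresholding.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = rng.uniform(*spec.major_axis)
    b = rng.uniform(*spec.minor_axis)
    if b > a:
        a, b = b, a
    margin = a + 3.0
    if 2 * margin >= canvas:
        raise PestPipeError(
            f"body semi-major axis {a:.1f} does not fit a {canvas}px canvas"
        )
    cy = rng.uniform(margin, canvas - margin)
    cx = rng.uniform(margin, canvas - margin)
    theta = rng.uniform(0.0, np.pi) if rotate else 0.0
    body = _ellipse_mask(canvas, cy, cx, a, b, theta)

    h = np.mod(spec.background_hue + rng.normal(0.0, 0.008, (canvas, canvas)), 1.0)
    s = np.clip(0.35 + rng.normal(0.0, 0.03, (canvas, canvas)), 0.0, 1.0)
    v = np.clip(0.85 + rng.normal(0.0, 0.03, (canvas, canvas)), 0.0, 1.0)

    fg = body.astype(bool)
    n_fg = int(fg.sum())
    fg_hue = spec.hue_center + hue_shift
    h[fg] = np.mod(fg_hue + rng.normal(0.0, spec.hue_spread, n_fg), 1.0)
    s[fg] = np.clip(spec.saturation_mean + rng.normal(0.0, 0.05, n_fg), 0.0, 1.0)
    v[fg] = np.clip(
        spec.value_mean + value_shift + rng.normal(0.0, spec.value_spread, n_fg),
        0.0,
        1.0,
    )

    # noise blobs: small discs sharing the body hue, kept off the body
    lo, hi = spec.n_noise_blobs
    n_blobs = int(rng.integers(lo, hi + 1)) if hi > lo else lo
    placed = 0
    guard = 0
    while placed < n_blobs and guard < 50:
        guard += 1
        r = rng.uniform(1.0, 2.2)
        by = rng.uniform(r + 1, canvas - r - 1)
        bx = rng.uniform(r + 1, canvas - r - 1)
        # keep a 3 px gap to the body so components stay separate
        if np.hypot(by - cy, bx - cx) < (a + r + 4):
            continue
        blob = _ellipse_mask(canvas, by, bx, r, r, 0.0).astype(bool)
        nb = int(blob.sum())
        if nb == 0:
            continue
        h[blob] = np.mod(fg_hue + rng.normal(0.0, spec.hue_spread, nb), 1.0)
        s[blob] = np.clip(spec.saturation_mean + rng.normal(0.0, 0.05, nb), 0.0, 1.0)
        v[blob] = np.clip(spec.value_mean + rng.normal(0.0, 0.05, nb), 0.0, 1.0)
        placed += 1

    hsv = np.dstack([h, s, v])
    rgb = np.clip(np.rint(color.hsv2rgb(hsv) * 255.0), 0, 255).astype(np.uint8)
    params = {
        "major": a, "minor": b, "center": (cy, cx), "theta": theta,
        "hue": fg_hue, "value_shift": value_shift, "n_noise_blobs": placed,
    }
    return LabeledImage(image=rgb, truth_mask=body, label=spec.name, truth_params=params)


def field_like_specs(specs: list[ClassSpec]) -> list[ClassSpec]:
    """Widen per-class distributions for the overlapping regime."""
    out = []
    for sp in specs:
        out.append(
            replace(
                sp,
                hue_spread=max(sp.hue_spread, 0.03),
                value_spread=max(sp.value_spread, 0.06),
                major_axis=(max(4.0, sp.major_axis[0] - 2), sp.major_axis[1] + 2),
                minor_axis=(max(3.0, sp.minor_axis[0] - 1), sp.minor_axis[1] + 1),
                n_noise_blobs=(1, 4),
            )
        )
    return out


def make_dataset(
    specs: list[ClassSpec] | None = None,
    n_per_class=70,
    regime: str = "easy",
    seed: int = 0,
    canvas: int = 96,
) -> list[LabeledImage]:
    """Generate a labeled set, balanced or with explicit per-class sizes.

    ``n_per_class`` may be a single integer or one count per class.
    The field-like regime draws, per image, a hue drift N(0, 0.04) and
    a lighting shift U(-0.2, 0.2), rotates bodies freely, and uses
    the widened class distributions of :func:`field_like_specs`.
    """
    if regime not in ("easy", "field_like"):
        raise ValueError(f"unknown regime {regime!r}")
    if specs is None:
        specs = default_class_specs()
    counts = (
        [int(n_per_class)] * len(specs)
        if np.isscalar(n_per_class)
        else [int(n) for n in n_per_class]
    )
    if len(counts) != len(specs):
        raise ValueError("one count per class required")
    if any(c < 1 for c in counts) or sum(counts) == 0:
        raise ValueError("n_per_class must be >= 1 for every class")
    if regime == "field_like":
        specs = field_like_specs(specs)
    rng = np.random.default_rng(seed)
    images = []
    for sp, n in zip(specs, counts):
        for _ in range(n):
            if regime == "field_like":
                hs = float(rng.normal(0.0, 0.04))
                vs = float(rng.uniform(-0.2, 0.2))
                img = make_image(sp, rng, canvas=canvas, rotate=True,
                                 hue_shift=hs, value_shift=vs)
            else:
                img = make_image(sp, rng, canvas=canvas, rotate=False)
            images.append(img)
    return images
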