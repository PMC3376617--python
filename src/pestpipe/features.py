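"""The 13-dimensional shape/color feature vector.

For a segmented insect region the features are, in order:

==== ======================= ==========================================
 idx  name                    definition
==== ======================= ==========================================
 0-2  h_mean, h_std, h_skew   color moments of the H channel (mean,
                              population std, signed-cube-root skew)
 3-5  s_mean, s_std, s_skew   same for the S channel
 6-8  v_mean, v_std, v_skew   same for the V channel
  9   eccentricity            EC = p/q, semi-axis ratio of the ellipse
                              with the region's second central moments
 10   sphericity              SP = r_i / r_c, inscribed over minimum
                              enclosing circle radius
 11   hu_phi1                 eta20 + eta02
 12   hu_phi2                 (eta20 - eta02)^2 + 4*eta11^2
==== ======================= ==========================================

Color moments are computed over the masked (foreground) pixels of the
HSV channels.  Shape features are binary moments of the mask: pixel
centers sit at integer coordinates and each foreground pixel
contributes weight 1, matching a binarized-image workflow.  phi1/phi2
are invariant to translation, scaling and rotation; EC and SP are
dimensionless shape ratios, so none of the shape features encode
absolute size.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .errors import FeatureError
from .segmentation import rgb_to_hsv

FEATURE_NAMES = (
    "h_mean", "h_std", "h_skew",
    "s_mean", "s_std", "s_skew",
    "v_mean", "v_std", "v_skew",
    "eccentricity", "sphericity", "hu_phi1", "hu_phi2",
)

N_FEATURES = len(FEATURE_NAMES)


def _region_values(channel, mask) -> np.ndarray:
    channel = np.asarray(channel, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if channel.shape != mask.shape:
        raise FeatureError("channel and mask shapes differ")
    vals = channel[mask]
    if vals.size == 0:
        raise FeatureError("empty mask")
    return vals


def color_moments(channel, mask) -> tuple[float, float, float]:
    """Mean, population standard deviation and skew of one channel.

    The skew is the signed cube root of the mean third central moment,
    ``sign(x) * |x|^(1/3)``: the principal complex root would discard
    the sign, but a color distribution skewed toward dark values must
    come out negative.
    """
    vals = _region_values(channel, mask)
    e = float(vals.mean())
    dev = vals - e
    sigma = float(np.sqrt(np.mean(dev**2)))
    m3 = float(np.mean(dev**3))
    s = float(np.sign(m3) * np.abs(m3) ** (1.0 / 3.0))
    return e, sigma, s


@dataclass(frozen=True)
class MomentSet:
    """Raw, central and normalized central binary moments up to order 3.

    ``raw[(p, q)] = sum x^p y^q`` over foreground pixel centers (x =
    column, y = row); ``mu`` are the corresponding central moments and
    ``eta[(p, q)] = mu_pq / mu00^((p+q)/2 + 1)`` for p+q in {2, 3}.
    """

    raw: dict
    mu: dict
    eta: dict

    @property
    def area(self) -> float:
        return self.raw[(0, 0)]


def moments(mask) -> MomentSet:
    """Binary shape moments of a mask, up to third order."""
    mask = np.asarray(mask).astype(bool)
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise FeatureError("empty mask")
    x = xs.astype(float)
    y = ys.astype(float)
    raw = {
        (p, q): float(np.sum(x**p * y**q))
        for p in range(4)
        for q in range(4)
        if p + q <= 3
    }
    m00 = raw[(0, 0)]
    xbar = raw[(1, 0)] / m00
    ybar = raw[(0, 1)] / m00
    xc = x - xbar
    yc = y - ybar
    mu = {
        (p, q): float(np.sum(xc**p * yc**q))
        for p in range(4)
        for q in range(4)
        if p + q <= 3
    }
    eta = {
        (p, q): mu[(p, q)] / m00 ** ((p + q) / 2.0 + 1.0)
        for (p, q) in mu
        if (p + q) in (2, 3)
    }
    return MomentSet(raw=raw, mu=mu, eta=eta)


def hu_features(ms: MomentSet) -> tuple[float, float]:
    """The first two Hu invariants, phi1 and phi2."""
    e20, e02, e11 = ms.eta[(2, 0)], ms.eta[(0, 2)], ms.eta[(1, 1)]
    phi1 = e20 + e02
    phi2 = (e20 - e02) ** 2 + 4.0 * e11**2
    return float(phi1), float(phi2)


def eccentricity(mask, degenerate_cap: float = float("inf")) -> float:
    """Semi-axis ratio EC = p/q >= 1 of the region's momental ellipse.

    p and q are the semi-axes of the ellipse with the same second
    central moments as the region: twice the square roots of the
    eigenvalues of the covariance matrix [[mu20, mu11], [mu11, mu02]] /
    mu00.  A disc gives 1; a 2:1 ellipse gives 2.  Collinear regions
    (zero minor eigenvalue) return ``degenerate_cap`` (+inf by
    default); a single pixel returns 1.0 by convention.
    """
    ms = moments(mask)
    if ms.area < 2:
        return 1.0
    m00 = ms.area
    cov = np.array(
        [
            [ms.mu[(2, 0)], ms.mu[(1, 1)]],
            [ms.mu[(1, 1)], ms.mu[(0, 2)]],
        ]
    ) / m00
    lam = np.linalg.eigvalsh(cov)  # ascending
    lam_min, lam_max = float(lam[0]), float(lam[1])
    if lam_min <= 0 or lam_max <= 0:
        return degenerate_cap
    return float(np.sqrt(lam_max / lam_min))


def _min_enclosing_circle(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact minimum enclosing circle (Welzl, incremental form).

    Expected linear time in the number of points after a seeded
    shuffle; the caller reduces the input to convex-hull vertices so
    the point count is small.
    """
    pts = np.asarray(points, dtype=float)
    rng = np.random.default_rng(0)
    pts = pts[rng.permutation(len(pts))]

    def circle_two(a, b):
        c = (a + b) / 2.0
        return c, float(np.linalg.norm(a - c))

    def circum(a, b, c):
        ax, ay = a
        bx, by = b
        cx, cy = c
        d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
        if abs(d) < 1e-12:
            return None
        ux = (
            (ax**2 + ay**2) * (by - cy)
            + (bx**2 + by**2) * (cy - ay)
            + (cx**2 + cy**2) * (ay - by)
        ) / d
        uy = (
            (ax**2 + ay**2) * (cx - bx)
            + (bx**2 + by**2) * (ax - cx)
            + (cx**2 + cy**2) * (bx - ax)
        ) / d
        center = np.array([ux, uy])
        return center, float(np.linalg.norm(a - center))

    def inside(center, r, p, eps=1e-9):
        return np.linalg.norm(p - center) <= r + eps

    center, r = pts[0].copy(), 0.0
    for i in range(1, len(pts)):
        p = pts[i]
        if inside(center, r, p):
            continue
        center, r = p.copy(), 0.0
        for j in range(i):
            q = pts[j]
            if inside(center, r, q):
                continue
            center, r = circle_two(p, q)
            for k in range(j):
                s = pts[k]
                if inside(center, r, s):
                    continue
                res = circum(p, q, s)
                if res is None:
                    # collinear triple: fall back to the widest pair
                    pair = max(
                        ((p, q), (p, s), (q, s)),
                        key=lambda ab: np.linalg.norm(ab[0] - ab[1]),
                    )
                    center, r = circle_two(*pair)
                else:
                    center, r = res
    return center, r


def sphericity(mask) -> float:
    """SP = inscribed-circle radius over minimum-enclosing-circle radius.

    r_i is the maximum of the Euclidean distance transform over the
    region (the mask is zero-padded so the canvas border counts as
    background); r_c is the radius of the exact minimum enclosing
    circle of the region treating each pixel as a unit square (the
    circle encloses all four corners of every foreground pixel, which
    makes an axis-aligned rectangle of a x b pixels come out exactly
    at sqrt(a^2 + b^2)/2).  A disc gives 1, a square 1/sqrt(2),
    elongated bodies approach 0.  A single pixel returns 1.0 by
    convention.
    """
    mask = np.asarray(mask).astype(bool)
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise FeatureError("empty mask")
    if ys.size == 1:
        return 1.0
    padded = np.pad(mask, 1)
    ri = float(ndimage.distance_transform_edt(padded).max())
    pts = np.column_stack([xs, ys]).astype(float)
    if len(pts) >= 3:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except QhullError:
            pass  # collinear region: Welzl on the raw points
    # expand hull points to pixel corners so the circle encloses the
    # pixel extents, consistent with the distance-transform inradius
    offs = np.array([[0.5, 0.5], [0.5, -0.5], [-0.5, 0.5], [-0.5, -0.5]])
    pts = (pts[:, None, :] + offs[None, :, :]).reshape(-1, 2)
    _, rc = _min_enclosing_circle(pts)
    if rc <= 0:
        return 1.0
    return min(ri / rc, 1.0)


def extract_features(
    img, mask, hsv: np.ndarray | None = None, eccentricity_cap: float = 100.0
) -> np.ndarray:
    """Assemble the 13-feature vector for a segmented image.

    ``hsv`` may be passed to reuse a conversion already done by the
    segmenter.  Degenerate (collinear) regions get their eccentricity
    capped at ``eccentricity_cap`` so the vector stays finite for the
    classifier.  Returns a length-13 float array ordered as
    :data:`FEATURE_NAMES`.
    """
    if hsv is None:
        hsv = rgb_to_hsv(img)
    mask = np.asarray(mask).astype(bool)
    vec = []
    for c in range(3):
        vec.extend(color_moments(hsv[..., c], mask))
    vec.append(min(eccentricity(mask), eccentricity_cap))
    vec.append(sphericity(mask))
    vec.extend(hu_features(moments(mask)))
    out = np.asarray(vec, dtype=float)
    assert out.shape == (N_FEATURES,)
    return out


# ---------------------------------------------------------------------------
# CSV interchange: one row per image, first column an identifier, the 13
# feature columns by name, optional trailing class label.

def write_features_csv(path, ids, X, labels=None) -> None:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != N_FEATURES:
        raise ValueError(f"expected an (n, {N_FEATURES}) feature matrix")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        header = ["id", *FEATURE_NAMES]
        if labels is not None:
            header.append("label")
        w.writerow(header)
        for i, row in enumerate(X):
            out = [ids[i], *(repr(float(v)) for v in row)]
            if labels is not None:
                out.append(labels[i])
            w.writerow(out)


def read_features_csv(path):
    """Returns (ids, X, labels); labels is None if the column is absent."""
    with open(path, newline="") as fh:
        r = csv.reader(fh)
        header = next(r)
        expected = ["id", *FEATURE_NAMES]
        if header[: 1 + N_FEATURES] != expected:
            raise ValueError(f"unexpected feature CSV header: {header}")
        has_label = len(header) > 1 + N_FEATURES
        ids, rows, labels = [], [], []
        for rec in r:
            ids.append(rec[0])
            rows.append([float(v) for v in rec[1 : 1 + N_FEATURES]])
            if has_label:
                labels.append(rec[1 + N_FEATURES])
    X = np.asarray(rows, dtype=float)
    return ids, X, (labels if has_label else None)
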