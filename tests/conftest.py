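import numpy as np
import pytest


def disc_mask(radius: int, pad: int = 5) -> np.ndarray:
    """Rasterized filled disc: pixel centers within `radius` of the center."""
    n = 2 * (radius + pad) + 1
    c = radius + pad
    yy, xx = np.mgrid[0:n, 0:n]
    return (((yy - c) ** 2 + (xx - c) ** 2) <= radius**2).astype(np.uint8)


def ellipse_mask(a: int, b: int, theta: float = 0.0, pad: int = 5) -> np.ndarray:
    """Rasterized filled ellipse with semi-axes a >= b, rotated by theta."""
    n = 2 * (a + pad) + 1
    c = a + pad
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    dx, dy = xx - c, yy - c
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(np.uint8)


def flood_fill_components(mask: np.ndarray, connectivity: int):
    """Brute-force connected components by BFS flood fill.

    Returns a list of pixel-index sets, one per component, in order of
    first (row-major) pixel.
    """
    h, w = mask.shape
    if connectivity == 4:
        nbrs = ((-1, 0), (1, 0), (0, -1), (0, 1))
    else:
        nbrs = tuple(
            (dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)
        )
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for y in range(h):
        for x in range(w):
            if not mask[y, x] or seen[y, x]:
                continue
            comp = set()
            queue = [(y, x)]
            seen[y, x] = True
            while queue:
                cy, cx = queue.pop()
                comp.add((cy, cx))
                for dy, dx in nbrs:
                    ny, nx = cy + dy, cx + dx
                    if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                        seen[ny, nx] = True
                        queue.append((ny, nx))
            comps.append(comp)
    return comps


def largest_component_oracle(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Largest region with the earliest-first-pixel tie rule."""
    comps = flood_fill_components(mask, connectivity)
    best = max(comps, key=len)  # max() keeps the earliest on ties
    out = np.zeros_like(mask, dtype=np.uint8)
    for y, x in best:
        out[y, x] = 1
    return out


def triple_loop_moments(mask: np.ndarray):
    """Naive raw/central/normalized moments, one sum per (p, q)."""
    raw, mu = {}, {}
    pix = [(float(x), float(y)) for y in range(mask.shape[0])
           for x in range(mask.shape[1]) if mask[y, x]]
    for p in range(4):
        for q in range(4):
            if p + q > 3:
                continue
            raw[(p, q)] = sum(x**p * y**q for x, y in pix)
    m00 = raw[(0, 0)]
    xb, yb = raw[(1, 0)] / m00, raw[(0, 1)] / m00
    for p in range(4):
        for q in range(4):
            if p + q > 3:
                continue
            mu[(p, q)] = sum((x - xb) ** p * (y - yb) ** q for x, y in pix)
    eta = {
        k: mu[k] / m00 ** ((k[0] + k[1]) / 2 + 1)
        for k in mu
        if k[0] + k[1] in (2, 3)
    }
    return raw, mu, eta


@pytest.fixture
def rng():
    return np.random.default_rng(42)
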