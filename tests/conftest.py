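"""Shared fixtures and independent brute-force oracles.

The oracle functions here deliberately avoid the code paths (and where
possible the libraries) used by the implementation: explicit Python loops
and padded scipy primitives stand against vectorized scikit-image /
KD-tree code.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from glioseg.phantom import PhantomSpec


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Reduced phantom for fast pipeline-level tests."""
    return PhantomSpec(
        shape=(36, 36, 36),
        brain_half_axes=(15.0, 14.0, 13.0),
        tumor_center=(17.5, 17.5, 17.5),
        tumor_half_axes=(5.0, 4.5, 4.0),
        edema_margin=2.5,
        seed=0,
    )


def make_blobs(seed: int, n_per: int = 20, sigma: float = 0.05):
    """Three tight Gaussian blobs whose centers vary in every dimension.

    After per-dimension z-scoring the centers stay well over 1 apart in
    normalized Manhattan distance, so the generating partition is
    unambiguous.
    """
    rng = np.random.default_rng(seed)
    centers = np.array([[0.0, 0, 0, 0], [2, 2, 0, 0], [0, 0, 2, 2]])
    X = np.vstack([rng.normal(c, sigma, size=(n_per, 4)) for c in centers])
    y = np.repeat([0, 1, 2], n_per)
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    return X, y


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def percentile_oracle(values: np.ndarray, q: float) -> float:
    """Linear-interpolation percentile computed from first principles."""
    v = np.sort(np.asarray(values, dtype=np.float64))
    pos = q / 100.0 * (v.size - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return float(v[lo] * (1 - frac) + v[hi] * frac)


def sauvola_oracle(slice2d: np.ndarray, window: int, k: float, R: float) -> np.ndarray:
    """Windowed mean/population-std threshold map via explicit loops.

    Border handling: symmetric padding (edge value repeated), the same
    semantics as scipy's 'reflect' filter mode.
    """
    slice2d = np.asarray(slice2d, dtype=np.float64)
    r = window // 2
    padded = np.pad(slice2d, r, mode="symmetric")
    out = np.empty_like(slice2d)
    for i in range(slice2d.shape[0]):
        for j in range(slice2d.shape[1]):
            win = padded[i:i + window, j:j + window]
            m = win.mean()
            s = win.std()  # population std
            out[i, j] = m * (1.0 + k * (s / R - 1.0))
    return out


def _disk(radius: int) -> np.ndarray:
    y, x = np.ogrid[-radius:radius + 1, -radius:radius + 1]
    return (x * x + y * y) <= radius * radius


def morphology_oracle(mask: np.ndarray, s_min: int, open_r: int, close_r: int
                      ) -> np.ndarray:
    """Small-object removal + disk opening + disk closing, scipy-composed.

    Erosions treat the outside of the image as foreground, dilations as
    background (finite-grid closing/opening convention).
    """
    mask = np.asarray(mask, dtype=bool)
    out = mask.copy()
    if s_min > 0 and out.any():
        lab, n = ndimage.label(out, structure=np.ones((3, 3), dtype=int))
        sizes = np.bincount(lab.ravel())
        keep = np.zeros(n + 1, dtype=bool)
        keep[1:] = sizes[1:] > s_min
        out = keep[lab]

    def erode(m, fp):
        r = fp.shape[0] // 2
        p = np.pad(m, r, constant_values=True)
        return ndimage.binary_erosion(p, structure=fp, border_value=1)[r:-r, r:-r]

    def dilate(m, fp):
        r = fp.shape[0] // 2
        p = np.pad(m, r, constant_values=False)
        return ndimage.binary_dilation(p, structure=fp, border_value=0)[r:-r, r:-r]

    if open_r > 0:
        fp = _disk(open_r)
        out = dilate(erode(out, fp), fp)
    if close_r > 0:
        fp = _disk(close_r)
        out = erode(dilate(out, fp), fp)
    return out


def confusion_oracle(pred: np.ndarray, gt: np.ndarray) -> tuple[int, int, int]:
    """(tp, fp, fn) by explicit iteration."""
    tp = fp = fn = 0
    for p, g in zip(pred.ravel(), gt.ravel()):
        if p and g:
            tp += 1
        elif p and not g:
            fp += 1
        elif g and not p:
            fn += 1
    return tp, fp, fn


def boundary_oracle(mask: np.ndarray) -> np.ndarray:
    """Boundary voxels: mask voxels with a non-mask 6-neighbor (loops)."""
    coords = []
    nx, ny, nz = mask.shape
    for x, y, z in np.argwhere(mask):
        on_edge = False
        for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            xx, yy, zz = x + dx, y + dy, z + dz
            if not (0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz) \
                    or not mask[xx, yy, zz]:
                on_edge = True
                break
        if on_edge:
            coords.append((x, y, z))
    return np.asarray(coords, dtype=np.int64).reshape(-1, 3)


def hd_oracle(pred: np.ndarray, gt: np.ndarray, spacing=(1.0, 1.0, 1.0),
              q: float = 95.0) -> tuple[float, float]:
    """(qth-percentile, maximum) symmetric surface distance via all pairs."""
    sp = np.asarray(spacing, dtype=np.float64)
    bp = boundary_oracle(pred) * sp
    bg = boundary_oracle(gt) * sp
    d = np.sqrt(((bp[:, None, :] - bg[None, :, :]) ** 2).sum(axis=2))
    d_pg = d.min(axis=1)
    d_gp = d.min(axis=0)
    hq = max(np.percentile(d_pg, q), np.percentile(d_gp, q))
    hmax = max(d_pg.max(), d_gp.max())
    return float(hq), float(hmax)
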