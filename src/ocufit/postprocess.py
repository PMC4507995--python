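"""Post-processing of fitted lifetime maps.

Amplitude-weighted mean lifetime, spatial mean/median filtering, the ETDRS
macular grid (three concentric circles of 500/1500/3000 um radius split by
the 45 degree diagonals into nine subfields) and per-ROI descriptive
statistics and histograms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ETDRS_RADII_UM",
    "ETDRS_LABELS",
    "EtdrsGrid",
    "RoiStats",
    "mean_lifetime",
    "spatial_filter",
    "build_etdrs_grid",
    "roi_statistics",
    "roi_histogram",
]

#: Inner, middle and outer circle radii of the ETDRS grid (micrometers):
#: 1/3, 1 and 2 optic-disc diameters (1500 um).
ETDRS_RADII_UM = (500.0, 1500.0, 3000.0)

ETDRS_LABELS = {
    1: "central",
    2: "inner_superior",
    3: "inner_nasal",
    4: "inner_inferior",
    5: "inner_temporal",
    6: "outer_superior",
    7: "outer_nasal",
    8: "outer_inferior",
    9: "outer_temporal",
}


def mean_lifetime(alpha, tau) -> np.ndarray | float:
    """Amplitude-weighted mean lifetime tau_m = sum(alpha*tau) / sum(alpha).

    Accepts per-pixel vectors or (k, ny, nx) map stacks; the component axis
    is axis 0.  Homogeneous of degree zero in the amplitudes.
    """
    alpha = np.asarray(alpha, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if alpha.shape != tau.shape:
        raise ValueError("alpha and tau must have the same shape")
    if np.any(tau <= 0):
        raise ValueError("lifetimes must be positive")
    denom = alpha.sum(axis=0)
    if np.any(denom <= 0):
        raise ValueError("amplitude sum must be positive")
    out = (alpha * tau).sum(axis=0) / denom
    return float(out) if np.ndim(out) == 0 else out


def spatial_filter(img: np.ndarray, size: int = 3, method: str = "median") -> np.ndarray:
    """Mean- or median-filter a parameter map with a clipped square window.

    Window size must be odd (3 or 5 are the sensible choices); at the image
    border only in-image pixels enter the window.
    """
    if size % 2 == 0 or size < 3:
        raise ValueError("kernel size must be odd and >= 3")
    if method not in ("mean", "median"):
        raise ValueError(f"unknown filter method {method!r}")
    img = np.asarray(img, dtype=float)
    ny, nx = img.shape
    half = size // 2
    out = np.empty_like(img)
    for y in range(ny):
        y0, y1 = max(0, y - half), min(ny, y + half + 1)
        for x in range(nx):
            x0, x1 = max(0, x - half), min(nx, x + half + 1)
            win = img[y0:y1, x0:x1]
            out[y, x] = np.mean(win) if method == "mean" else np.median(win)
    return out


@dataclass
class EtdrsGrid:
    """ETDRS subfield label map on the image lattice.

    ``label_map`` holds 0 for unlabeled pixels (outside the 3000 um circle)
    and 1-9 per ETDRS_LABELS.
    """

    label_map: np.ndarray
    center: tuple[float, float]
    pixel_pitch_um: float
    eye_side: str
    radii_um: tuple[float, float, float] = ETDRS_RADII_UM

    def mask(self, name: str) -> np.ndarray:
        code = {v: k for k, v in ETDRS_LABELS.items()}[name]
        return self.label_map == code

    def subfields(self) -> list[str]:
        return [ETDRS_LABELS[c] for c in sorted(ETDRS_LABELS)]


def build_etdrs_grid(
    center: tuple[float, float],
    pixel_pitch_um: float,
    shape: tuple[int, int],
    eye_side: str = "right",
) -> EtdrsGrid:
    """Label every pixel with its ETDRS subfield.

    Geometry (distances in um from the fovea center, closed inner
    boundaries): distance <= 500 is the central subfield; (500, 1500] the
    inner ring; (1500, 3000] the outer ring.  Rings are split by the
    45/135/225/315 degree diagonals into superior (up), inferior (down),
    nasal and temporal quadrants; a pixel exactly on a diagonal joins the
    counter-clockwise sector.  For a right eye in standard orientation the
    nasal quadrant is image-left; for a left eye image-right.
    """
    ny, nx = shape
    cy, cx = center
    if not (0 <= cy < ny and 0 <= cx < nx):
        raise ValueError("grid center must lie inside the image")
    if pixel_pitch_um <= 0:
        raise ValueError("pixel pitch must be positive")
    if eye_side not in ("left", "right"):
        raise ValueError("eye_side must be 'left' or 'right'")
    r_c, r_i, r_o = ETDRS_RADII_UM

    yy, xx = np.mgrid[0:ny, 0:nx]
    dx = (xx - cx).astype(float)
    dy_up = (cy - yy).astype(float)  # positive = up (towards superior)
    dist = np.hypot(dx, dy_up) * pixel_pitch_um
    ang = np.degrees(np.arctan2(dy_up, dx)) % 360.0

    superior = (ang >= 45.0) & (ang < 135.0)
    left = (ang >= 135.0) & (ang < 225.0)
    inferior = (ang >= 225.0) & (ang < 315.0)
    right = ~(superior | left | inferior)

    nasal = left if eye_side == "right" else right
    temporal = right if eye_side == "right" else left

    labels = np.zeros((ny, nx), dtype=np.int8)
    labels[dist <= r_c] = 1
    inner = (dist > r_c) & (dist <= r_i)
    outer = (dist > r_i) & (dist <= r_o)
    for ring, base in ((inner, 2), (outer, 6)):
        labels[ring & superior] = base
        labels[ring & nasal] = base + 1
        labels[ring & inferior] = base + 2
        labels[ring & temporal] = base + 3
    return EtdrsGrid(
        label_map=labels,
        center=(cy, cx),
        pixel_pitch_um=pixel_pitch_um,
        eye_side=eye_side,
    )


@dataclass
class RoiStats:
    mean: float
    median: float
    mode: float
    std: float
    variance: float
    ci_level: float
    ci_lower: float
    ci_upper: float
    count: int


def roi_statistics(
    img: np.ndarray,
    mask: np.ndarray,
    class_width: float = 10.0,
    ci_level: float = 0.95,
    ci_method: str = "normal",
    n_boot: int = 2000,
    seed: int = 0,
) -> RoiStats:
    """Descriptive statistics of a parameter map over an ROI.

    The mode is the center of the most populated histogram class at the
    given class width (continuous data has no exact mode).  The confidence
    interval for the mean is normal-theory by default or a percentile
    bootstrap (``ci_method='bootstrap'``).
    """
    mask = np.asarray(mask, dtype=bool)
    vals = np.asarray(img, dtype=float)[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("empty ROI")
    mean = float(np.mean(vals))
    std = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    edges, counts = roi_histogram(img, mask, class_width)
    k = int(np.argmax(counts))
    mode = float(0.5 * (edges[k] + edges[k + 1]))
    if vals.size > 1 and std > 0:
        if ci_method == "normal":
            half = sps.t.ppf(0.5 + ci_level / 2, df=vals.size - 1) * std / np.sqrt(vals.size)
            lo, hi = mean - half, mean + half
        elif ci_method == "bootstrap":
            rng = np.random.default_rng(seed)
            boots = np.array(
                [np.mean(rng.choice(vals, size=vals.size)) for _ in range(n_boot)]
            )
            lo, hi = np.percentile(boots, [100 * (0.5 - ci_level / 2), 100 * (0.5 + ci_level / 2)])
        else:
            raise ValueError(f"unknown ci_method {ci_method!r}")
    else:
        lo = hi = mean
    return RoiStats(
        mean=mean,
        median=float(np.median(vals)),
        mode=mode,
        std=std,
        variance=std**2,
        ci_level=ci_level,
        ci_lower=float(lo),
        ci_upper=float(hi),
        count=int(vals.size),
    )


def roi_histogram(
    img: np.ndarray, mask: np.ndarray, class_width: float
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of ROI values in left-closed classes aligned to zero.

    Class k covers [k*w, (k+1)*w); counts sum to the number of finite ROI
    pixels.
    """
    if class_width <= 0:
        raise ValueError("class width must be positive")
    mask = np.asarray(mask, dtype=bool)
    vals = np.asarray(img, dtype=float)[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("empty ROI")
    k0 = int(np.floor(vals.min() / class_width))
    k1 = int(np.floor(vals.max() / class_width)) + 1
    edges = np.arange(k0, k1 + 1) * class_width
    idx = np.floor(vals / class_width).astype(int) - k0
    counts = np.bincount(idx, minlength=k1 - k0)
    return edges, counts
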