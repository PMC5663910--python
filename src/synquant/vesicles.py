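"""Vesicle-scale analyses: particle detection in cell images and
super-resolution vesicle diameter estimation.

Localization microscopy of tracer-loaded synaptic vesicles yields 2-D
point lists (nm).  Clouds are rendered with kernel density estimation at
nanometer pixel size, and the vesicle diameter is estimated by a
least-squares circle fit to the localizations of each ring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .segmentation import SynapseROI, _component_to_roi

__all__ = [
    "VesicleFit",
    "detect_vesicle_particles",
    "render_localizations",
    "fit_vesicle_circle",
    "diameter_summary",
]


@dataclass
class VesicleFit:
    center: tuple[float, float]
    diameter: float
    rms_residual: float
    n_points: int


class CircleFitError(RuntimeError):
    """Raised for degenerate inputs (e.g. collinear localizations)."""


# ---------------------------------------------------------------------------
# particle detection (cell-culture vesicles)

def detect_vesicle_particles(image: np.ndarray,
                             bg_center: tuple[float, float], bg_radius: float,
                             k_sd: float = 2.0,
                             size_range: tuple[int, int] = (2, 200),
                             roundness_min: float = 0.4) -> list[SynapseROI]:
    """Detect fluorescent vesicle particles above a background threshold.

    Background noise is measured inside a circular ROI placed in a
    vesicle-free region; the detection threshold is background mean +
    ``k_sd`` background SDs (default 2).  Connected components above the
    threshold are filtered by area range and minimum roundness.
    """
    if k_sd <= 0:
        raise ValueError("k_sd must be > 0")
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    r0, c0 = bg_center
    if not (0 <= r0 - bg_radius and r0 + bg_radius < h
            and 0 <= c0 - bg_radius and c0 + bg_radius < w):
        raise ValueError("background ROI extends outside the image")
    rr = np.arange(h)[:, None] - r0
    cc = np.arange(w)[None, :] - c0
    bg_mask = rr ** 2 + cc ** 2 <= bg_radius ** 2
    bg_vals = image[bg_mask]
    threshold = bg_vals.mean() + k_sd * bg_vals.std()

    mask = image > threshold
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), int))
    particles = []
    for comp in range(1, n + 1):
        pixels = np.argwhere(labels == comp)
        roi = _component_to_roi(pixels)
        if not (size_range[0] <= roi.area <= size_range[1]):
            continue
        if roi.roundness < roundness_min:
            continue
        roi.mean_gz = float(image[pixels[:, 0], pixels[:, 1]].mean())
        particles.append(roi)
    for i, p in enumerate(particles):
        p.roi_id = i
    return particles


# ---------------------------------------------------------------------------
# localization rendering

def render_localizations(points: np.ndarray, pixel_size: float = 4.12,
                         bandwidth: float | None = None,
                         margin_factor: float = 5.0):
    """Kernel-density rendering of a localization cloud.

    Each point contributes an isotropic Gaussian kernel of SD
    ``bandwidth`` nm (default: the rendering pixel size).  The grid
    covers the cloud's bounding box plus a margin of
    ``margin_factor * bandwidth`` so kernel mass is not clipped; the
    integral of the returned density over the grid equals the number of
    points to within 1%.

    Returns ``(density, (x0, y0))`` — the density grid (points per nm^2,
    indexed [y, x]) and the physical coordinate of its first pixel.
    """
    points = np.asarray(points, dtype=float)
    if points.size == 0:
        raise ValueError("empty localization cloud")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    if bandwidth is None:
        bandwidth = pixel_size
    margin = margin_factor * bandwidth + pixel_size
    x0, y0 = points[:, 0].min() - margin, points[:, 1].min() - margin
    x1, y1 = points[:, 0].max() + margin, points[:, 1].max() + margin
    nx = int(np.ceil((x1 - x0) / pixel_size)) + 1
    ny = int(np.ceil((y1 - y0) / pixel_size)) + 1
    counts, _, _ = np.histogram2d(
        points[:, 1], points[:, 0], bins=(ny, nx),
        range=((y0, y0 + ny * pixel_size), (x0, x0 + nx * pixel_size)))
    density = ndimage.gaussian_filter(counts, sigma=bandwidth / pixel_size,
                                      mode="constant")
    return density / pixel_size ** 2, (x0, y0)


# ---------------------------------------------------------------------------
# circle fitting

def fit_vesicle_circle(points: np.ndarray, refine: bool = True) -> VesicleFit:
    """Least-squares circle through 2-D localizations.

    Algebraic (Kåsa) fit — linear in (center, radius²) — followed by one
    Gauss–Newton step on the geometric residuals.  Collinear points make
    the normal equations singular and raise :class:`CircleFitError`.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need an (n>=3, 2) array of points")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x ** 2 + y ** 2
    sol, residuals, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise CircleFitError("degenerate (collinear) localization set")
    cx, cy = sol[0], sol[1]
    r2 = sol[2] + cx ** 2 + cy ** 2
    if r2 <= 0:
        raise CircleFitError("non-positive fitted radius")
    r = float(np.sqrt(r2))

    if refine:
        for _ in range(1):
            dx, dy = x - cx, y - cy
            di = np.hypot(dx, dy)
            if np.any(di == 0):
                break
            res = di - r
            J = np.column_stack([-dx / di, -dy / di, -np.ones_like(di)])
            try:
                step, *_ = np.linalg.lstsq(J, -res, rcond=None)
            except np.linalg.LinAlgError:  # pragma: no cover
                break
            cx, cy, r = cx + step[0], cy + step[1], r + step[2]
    di = np.hypot(x - cx, y - cy)
    rms = float(np.sqrt(np.mean((di - r) ** 2)))
    if r <= 0:
        raise CircleFitError("non-positive refined radius")
    return VesicleFit(center=(float(cx), float(cy)), diameter=2 * r,
                      rms_residual=rms, n_points=len(pts))


def diameter_summary(fits: list[VesicleFit], bins: int = 20):
    """Mean ± sample SD of fitted diameters plus a histogram.

    Returns ``(mean, sd, (counts, edges), single)`` where ``single`` flags
    an SD reported as 0 because only one fit was supplied.
    """
    if not fits:
        raise ValueError("need at least one fit")
    d = np.array([f.diameter for f in fits])
    single = len(d) == 1
    sd = 0.0 if single else float(d.std(ddof=1))
    counts, edges = np.histogram(d, bins=bins)
    return float(d.mean()), sd, (counts, edges), single
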