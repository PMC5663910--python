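"""Ground-truth data generators for every pipeline stage.

Real acquisitions of the reporter/tracer assay (GZ = eGFP-tagged vesicular
bait, SB = labeled peptide tracer captured by cycling vesicles) are not
publicly deposited, so the package ships generators that emulate their
statistical structure: presynaptic boutons rendered as Gaussian peaks along
smooth axon polylines over a radial tracer-background gradient; per-bouton
reporter amplitude and normalized uptake drawn from configurable
distributions; super-resolution localization clouds on vesicle perimeters;
saturating binding curves; stimulus-locked uptake ramps; and open-field
rat trajectories with scheduled pauses.

Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "SimParams",
    "GroundTruthFOV",
    "generate_fov",
    "generate_sb_gradient",
    "generate_localization_cloud",
    "generate_binding_data",
    "generate_uptake_timeseries",
    "generate_trajectory",
    "write_fov",
]


# ---------------------------------------------------------------------------
# distributions

_DIST_NAMES = {"constant", "normal", "lognormal", "gamma", "uniform"}


def draw_distribution(dist: tuple[str, dict], n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` samples from a named distribution spec ``(name, params)``.

    Supported names: ``constant(value)``, ``normal(mean, sd)``,
    ``lognormal(mean, sigma)`` (parameters of the underlying normal),
    ``gamma(shape, scale)``, ``uniform(low, high)``.
    """
    name, params = dist
    if name not in _DIST_NAMES:
        raise ValueError(f"unknown distribution {name!r}; choose from {sorted(_DIST_NAMES)}")
    if name == "constant":
        return np.full(n, float(params["value"]))
    if name == "normal":
        return rng.normal(params["mean"], params["sd"], size=n)
    if name == "lognormal":
        return rng.lognormal(params["mean"], params["sigma"], size=n)
    if name == "gamma":
        return rng.gamma(params["shape"], params["scale"], size=n)
    return rng.uniform(params["low"], params["high"], size=n)


@dataclass
class SimParams:
    """Parameters of the field-of-view forward model.

    Defaults describe a confocal 63x field: point-spread sigma of 2 px,
    ~50 boutons strung along 6 axons, reporter amplitudes well above the
    noise floor, and a normalized uptake around 0.3 for active boutons.
    """

    n_axons: int = 6
    boutons_per_axon: int = 9
    psf_sigma: float = 2.0
    gz_amplitude_dist: tuple[str, dict] = ("normal", {"mean": 100.0, "sd": 15.0})
    uptake_dist: tuple[str, dict] = ("normal", {"mean": 0.30, "sd": 0.06})
    active_fraction: float = 1.0
    gradient_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.n_axons < 0 or self.boutons_per_axon < 0:
            raise ValueError("counts must be >= 0")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")
        if not 0.0 <= self.active_fraction <= 1.0:
            raise ValueError("active_fraction must lie in [0, 1]")


@dataclass
class GroundTruthFOV:
    """A simulated field of view plus the truth used to render it.

    ``gz_image``/``sb_image`` are the reporter and tracer channels in
    arbitrary linear units.  ``bouton_gz`` is the true peak reporter
    amplitude of each bouton (before gain scaling) and ``bouton_uptake``
    the true normalized uptake, so the tracer peak amplitude of bouton *i*
    is ``bouton_gz[i] * bouton_uptake[i]``.
    """

    gz_image: np.ndarray
    sb_image: np.ndarray
    pixel_size: float
    bouton_centers: np.ndarray          # (n, 2) row/col
    bouton_gz: np.ndarray
    bouton_uptake: np.ndarray
    bouton_axon: np.ndarray             # axon index per bouton
    axon_polylines: list[np.ndarray]
    bg_level: float
    noise_sd: float
    detector_gain: float = 1.0
    laser_power: float = 1.0
    seed: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.gz_image.shape


def _smooth_polyline(rng: np.random.Generator, shape: tuple[int, int],
                     length: float, step: float = 2.0,
                     turn_sd: float = 0.12, margin: float = 8.0) -> np.ndarray:
    """Random smooth path: persistent heading with small turning noise,
    reflected off the image margins."""
    h, w = shape
    pos = np.array([rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)])
    heading = rng.uniform(0, 2 * np.pi)
    pts = [pos.copy()]
    travelled = 0.0
    while travelled < length:
        heading += rng.normal(0.0, turn_sd)
        pos = pos + step * np.array([np.sin(heading), np.cos(heading)])
        # reflect at margins
        for k, lim in enumerate((h, w)):
            if pos[k] < margin:
                pos[k] = 2 * margin - pos[k]
                heading = -heading if k == 0 else np.pi - heading
            elif pos[k] > lim - margin:
                pos[k] = 2 * (lim - margin) - pos[k]
                heading = -heading if k == 0 else np.pi - heading
        pts.append(pos.copy())
        travelled += step
    return np.asarray(pts)


def _arclength_positions(poly: np.ndarray, n: int, jitter: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Uniform arc-length spacing along a polyline, with longitudinal jitter."""
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    targets = (np.arange(n) + 0.5) / n * total
    targets = np.clip(targets + rng.normal(0, jitter, size=n), 0, total)
    rows = np.interp(targets, cum, poly[:, 0])
    cols = np.interp(targets, cum, poly[:, 1])
    return np.column_stack([rows, cols])


def _render_peaks(image: np.ndarray, centers: np.ndarray,
                  amplitudes: np.ndarray, sigma: float) -> None:
    """Add isotropic Gaussian peaks (peak height = amplitude) in place."""
    h, w = image.shape
    half = int(math.ceil(4 * sigma))
    for (r0, c0), amp in zip(centers, amplitudes):
        if amp == 0:
            continue
        r_lo, r_hi = max(0, int(r0) - half), min(h, int(r0) + half + 1)
        c_lo, c_hi = max(0, int(c0) - half), min(w, int(c0) + half + 1)
        rr = np.arange(r_lo, r_hi)[:, None] - r0
        cc = np.arange(c_lo, c_hi)[None, :] - c0
        image[r_lo:r_hi, c_lo:c_hi] += amp * np.exp(-(rr ** 2 + cc ** 2) / (2 * sigma ** 2))


def generate_sb_gradient(shape: tuple[int, int], slope: float,
                         origin: tuple[float, float],
                         base: float = 0.0) -> np.ndarray:
    """Radially symmetric tracer background decreasing linearly with
    distance from ``origin`` (the microperfusion site), floored at zero.

    ``slope = 0`` gives a constant field equal to ``base``.
    """
    if slope < 0:
        raise ValueError("slope must be >= 0")
    h, w = shape
    rr = np.arange(h)[:, None] - origin[0]
    cc = np.arange(w)[None, :] - origin[1]
    dist = np.hypot(rr, cc)
    return np.maximum(base - slope * dist, 0.0)


def generate_fov(params: SimParams, shape: tuple[int, int] = (256, 256),
                 seed: int = 0, *, bg_level: float = 10.0, noise_sd: float = 0.0,
                 sb_bg_level: float = 10.0, pixel_size: float = 0.1,
                 detector_gain: float = 1.0, laser_power: float = 1.0,
                 min_separation: float | None = None,
                 integer_centers: bool = False,
                 gradient_origin: tuple[float, float] | None = None) -> GroundTruthFOV:
    """Simulate one two-channel field of view.

    Boutons are placed along ``n_axons`` random smooth polylines at uniform
    arc-length spacing with jitter; a minimum inter-bouton distance
    (default ``4 * psf_sigma``) keeps ground truth unambiguous — boutons
    violating it are dropped from both the truth list and the images.
    Reporter peaks have height ``bouton_gz``; tracer peaks have height
    ``bouton_gz * bouton_uptake`` on top of the tracer background field.
    A fraction ``1 - active_fraction`` of boutons gets uptake exactly 0.
    Gain and laser power multiply both channels; Gaussian read noise of
    ``noise_sd`` is added last.
    """
    h, w = int(shape[0]), int(shape[1])
    if h < 64 or w < 64:
        raise ValueError("shape must be at least 64 x 64")
    rng = np.random.default_rng(seed)
    if min_separation is None:
        min_separation = 4.0 * params.psf_sigma

    spacing = max(6.0 * params.psf_sigma, min_separation * 1.5)
    polylines: list[np.ndarray] = []
    centers: list[np.ndarray] = []
    axon_of: list[int] = []
    for a in range(params.n_axons):
        poly = _smooth_polyline(rng, (h, w), length=spacing * (params.boutons_per_axon + 1))
        polylines.append(poly)
        pos = _arclength_positions(poly, params.boutons_per_axon,
                                   jitter=0.15 * spacing, rng=rng)
        for p in pos:
            if integer_centers:
                p = np.round(p)
            if all(np.linalg.norm(p - q) >= min_separation for q in centers):
                centers.append(p)
                axon_of.append(a)
    centers_arr = (np.asarray(centers).reshape(-1, 2)
                   if centers else np.empty((0, 2)))

    n = len(centers_arr)
    gz_amp = draw_distribution(params.gz_amplitude_dist, n, rng)
    gz_amp = np.clip(gz_amp, 1e-6, None)
    uptake = np.clip(draw_distribution(params.uptake_dist, n, rng), 0.0, None)
    active = rng.random(n) < params.active_fraction
    uptake = np.where(active, uptake, 0.0)

    gz = np.full((h, w), float(bg_level))
    if gradient_origin is None:
        gradient_origin = (h / 2.0, -0.25 * w)   # perfusion site off-field
    sb = generate_sb_gradient((h, w), params.gradient_slope, gradient_origin,
                              base=sb_bg_level)
    _render_peaks(gz, centers_arr, gz_amp, params.psf_sigma)
    _render_peaks(sb, centers_arr, gz_amp * uptake, params.psf_sigma)

    scale = detector_gain * laser_power
    gz *= scale
    sb *= scale
    if noise_sd > 0:
        gz += rng.normal(0.0, noise_sd, size=gz.shape)
        sb += rng.normal(0.0, noise_sd, size=sb.shape)
    elif noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    return GroundTruthFOV(
        gz_image=gz, sb_image=sb, pixel_size=pixel_size,
        bouton_centers=centers_arr, bouton_gz=gz_amp, bouton_uptake=uptake,
        bouton_axon=np.asarray(axon_of, dtype=int), axon_polylines=polylines,
        bg_level=float(bg_level), noise_sd=float(noise_sd),
        detector_gain=float(detector_gain), laser_power=float(laser_power),
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# localization clouds (super-resolution)

def generate_localization_cloud(diameter: float, precision_sd: float,
                                n_points: int, seed: int = 0,
                                center: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Sample localizations from a vesicle ring of the given diameter (nm).

    Points are uniform on the circle perimeter, then jittered with
    isotropic Gaussian localization noise of ``precision_sd`` nm.
    Returns an (n, 2) array of x/y coordinates in nm.
    """
    if diameter <= 0:
        raise ValueError("diameter must be > 0")
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    if precision_sd < 0:
        raise ValueError("precision_sd must be >= 0")
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, 2 * np.pi, size=n_points)
    r = diameter / 2.0
    pts = np.column_stack([center[0] + r * np.cos(theta),
                           center[1] + r * np.sin(theta)])
    if precision_sd > 0:
        pts += rng.normal(0.0, precision_sd, size=pts.shape)
    return pts


# ---------------------------------------------------------------------------
# binding curves

def generate_binding_data(kd: float, bmax: float, concentrations,
                          noise_sd: float = 0.0, n_rep: int = 1,
                          seed: int = 0) -> pd.DataFrame:
    """Replicate responses around the single-site isotherm b_max*c/(c+kd).

    Returns a tidy frame with columns ``concentration``, ``replicate``,
    ``response``.
    """
    if kd <= 0:
        raise ValueError("kd must be > 0")
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for c in conc:
        mu = bmax * c / (c + kd)
        for rep in range(n_rep):
            y = mu + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append((c, rep, y))
    return pd.DataFrame(rows, columns=["concentration", "replicate", "response"])


# ---------------------------------------------------------------------------
# uptake time series

def generate_uptake_timeseries(n_boutons: int, frame_interval: float,
                               baseline_frames: int, n_frames: int,
                               stim_epochs: list[tuple[int, int]],
                               rate_active: float, noise_sd: float = 0.0,
                               rate_rest: float = 0.0,
                               seed: int = 0) -> pd.DataFrame:
    """Per-bouton cumulative-uptake traces.

    Traces are flat at zero during the ``baseline_frames`` frames before
    tracer wash-in, then ramp with slope ``rate_active`` (a.u./frame)
    inside each stimulation epoch ``(start_frame, end_frame)`` and slope
    ``rate_rest`` outside, plus Gaussian noise.  Epochs are half-open
    frame intervals and must not overlap.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    epochs = sorted(stim_epochs)
    for (s0, e0), (s1, _e1) in zip(epochs, epochs[1:]):
        if s1 < e0:
            raise ValueError("stim epochs must not overlap")
    for s, e in epochs:
        if s < 0 or e > n_frames or e <= s:
            raise ValueError("epoch outside trace or empty")
    rng = np.random.default_rng(seed)
    slope = np.full(n_frames, rate_rest, dtype=float)
    for s, e in epochs:
        slope[s:e] = rate_active
    slope[:baseline_frames] = 0.0
    increments = np.broadcast_to(slope, (n_boutons, n_frames)).copy()
    values = np.cumsum(increments, axis=1)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    frames = np.arange(n_frames)
    recs = {
        "bouton": np.repeat(np.arange(n_boutons), n_frames),
        "frame": np.tile(frames, n_boutons),
        "time_s": np.tile(frames * frame_interval, n_boutons),
        "value": values.ravel(),
    }
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# trajectories

def generate_trajectory(duration: float, fps: float,
                        cage: tuple[float, float] = (38.0, 22.0),
                        pause_schedule: list[tuple[float, float]] | None = None,
                        seed: int = 0, *, speed: float = 8.0,
                        pause_jitter: float = 0.3,
                        turn_sd: float = 0.4) -> pd.DataFrame:
    """Open-field barycenter track with scheduled pauses.

    Between pauses the animal performs a persistent random walk at mean
    ``speed`` cm/s, reflected off the cage walls (default home-cage floor
    38 x 22 cm).  During each scheduled pause ``(start_s, duration_s)``
    the position jitters isotropically (clipped to < 1 cm) around the
    anchor reached at pause onset.  Returns columns ``t_s, x_cm, y_cm``.
    """
    if fps <= 0 or duration <= 0:
        raise ValueError("duration and fps must be > 0")
    schedule = sorted(pause_schedule or [])
    for (s0, d0), (s1, _d1) in zip(schedule, schedule[1:]):
        if s1 < s0 + d0:
            raise ValueError("pause schedule overlaps")
    for s, d in schedule:
        if s < 0 or s + d > duration:
            raise ValueError("pause outside trajectory duration")
    rng = np.random.default_rng(seed)
    w, h = cage
    n = int(round(duration * fps)) + 1
    dt = 1.0 / fps
    pos = np.array([rng.uniform(0.15 * w, 0.85 * w), rng.uniform(0.15 * h, 0.85 * h)])
    heading = rng.uniform(0, 2 * np.pi)
    out = np.empty((n, 2))
    anchor = None
    for i in range(n):
        t = i * dt
        in_pause = next(((s, d) for s, d in schedule if s <= t < s + d), None)
        if in_pause is not None:
            if anchor is None:
                anchor = pos.copy()
                pos = anchor.copy()      # pause onset sits exactly on the anchor
            else:
                jit = rng.normal(0.0, pause_jitter, size=2)
                norm = np.linalg.norm(jit)
                if norm > 0.9:
                    jit *= 0.9 / norm
                pos = anchor + jit
        else:
            if anchor is not None:
                pos = anchor.copy()
                anchor = None
            heading += rng.normal(0.0, turn_sd)
            step = speed * dt
            pos = pos + step * np.array([np.cos(heading), np.sin(heading)])
            for k, lim in enumerate((w, h)):
                if pos[k] < 0:
                    pos[k] = -pos[k]
                    heading = np.pi - heading if k == 0 else -heading
                elif pos[k] > lim:
                    pos[k] = 2 * lim - pos[k]
                    heading = np.pi - heading if k == 0 else -heading
        pos = np.clip(pos, [0, 0], [w, h])
        out[i] = pos
    t = np.arange(n) * dt
    return pd.DataFrame({"t_s": t, "x_cm": out[:, 0], "y_cm": out[:, 1]})


# ---------------------------------------------------------------------------
# file output

def write_fov(fov: GroundTruthFOV, outdir: str | Path, stem: str) -> dict[str, Path]:
    """Write a FOV as two single-plane 16-bit TIFFs plus a JSON sidecar
    carrying ground truth and acquisition metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for suffix, img in (("GZ", fov.gz_image), ("SB", fov.sb_image)):
        p = outdir / f"{stem}_{suffix}.tif"
        tifffile.imwrite(p, np.clip(np.round(img), 0, 65535).astype(np.uint16))
        paths[suffix.lower()] = p
    meta = {
        "pixel_size_um": fov.pixel_size,
        "detector_gain": fov.detector_gain,
        "laser_power": fov.laser_power,
        "bg_level": fov.bg_level,
        "noise_sd": fov.noise_sd,
        "seed": fov.seed,
        "bouton_centers": fov.bouton_centers.tolist(),
        "bouton_gz": fov.bouton_gz.tolist(),
        "bouton_uptake": fov.bouton_uptake.tolist(),
        "bouton_axon": fov.bouton_axon.tolist(),
    }
    sidecar = outdir / f"{stem}_truth.json"
    sidecar.write_text(json.dumps(meta, indent=1))
    paths["truth"] = sidecar
    return paths
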