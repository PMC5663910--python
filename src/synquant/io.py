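"""File I/O: two-channel TIFF fields of view and tabular outputs."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["FOV", "read_fov"]


@dataclass
class FOV:
    """One acquired field: reporter and tracer channel plus metadata."""

    gz_image: np.ndarray
    sb_image: np.ndarray
    fov_id: str = ""
    pixel_size: float = 1.0       # µm / pixel
    detector_gain: float = 1.0
    laser_power: float = 1.0
    animal_id: str = ""
    group_label: str = ""
    metadata: dict = field(default_factory=dict)


def _read_plane(path: str | Path) -> np.ndarray:
    try:
        img = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read TIFF {path}: {exc}") from exc
    img = np.squeeze(img)
    if img.ndim != 2:
        raise IOError(f"{path}: expected a single-plane grayscale image, "
                      f"got shape {img.shape}")
    # bit depth is preserved as linear intensities; no rescaling
    return img.astype(float)


def read_fov(path_gz: str | Path, path_sb: str | Path, *, fov_id: str = "",
             pixel_size: float = 1.0, detector_gain: float = 1.0,
             laser_power: float = 1.0, animal_id: str = "",
             group_label: str = "", **metadata) -> FOV:
    """Load a matched reporter/tracer TIFF pair into an :class:`FOV`.

    Both files must be single-plane grayscale images of identical shape;
    intensities are taken as linear, whatever the bit depth.
    """
    gz = _read_plane(path_gz)
    sb = _read_plane(path_sb)
    if gz.shape != sb.shape:
        raise IOError(f"channel shape mismatch: {path_gz} is {gz.shape}, "
                      f"{path_sb} is {sb.shape}")
    return FOV(gz_image=gz, sb_image=sb, fov_id=fov_id or Path(path_gz).stem,
               pixel_size=pixel_size, detector_gain=detector_gain,
               laser_power=laser_power, animal_id=animal_id,
               group_label=group_label, metadata=metadata)
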