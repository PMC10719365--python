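"""Reading multi-channel confocal z-stacks and the image normalizations the
downstream stages assume.

Images are carried as 4-D float arrays indexed ``(channel, z, y, x)``.
Coordinates are 0-based and bounding boxes half-open. After
:func:`range_normalize` intensities live in ``[0, 1]``; raw integer dtypes are
accepted on read and converted to float.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage.morphology import diamond

__all__ = [
    "AcquisitionSpec",
    "ImageStack",
    "read_stack",
    "write_stack",
    "read_manifest",
    "range_normalize",
    "gamma_adjust",
    "median_denoise",
    "max_z_project",
]

#: metadata columns every manifest must provide
MANIFEST_COLUMNS = ("sample_id", "patient_id", "condition", "timepoint", "path")


@dataclass(frozen=True)
class AcquisitionSpec:
    """Voxel geometry and channel layout of one acquisition.

    Parameters
    ----------
    dx_um, dy_um : float
        Lateral pixel size in micrometres (default 0.09).
    dz_um : float
        Axial step in micrometres (default 0.5).
    channel_map : mapping
        Marker name -> channel index in the voxel array. A ``"DAPI"``
        channel is mandatory; it drives segmentation and all chromatin
        features.
    """

    dx_um: float = 0.09
    dy_um: float = 0.09
    dz_um: float = 0.5
    channel_map: Mapping[str, int] = field(default_factory=lambda: {"DAPI": 0})

    def __post_init__(self):
        for name, v in (("dx_um", self.dx_um), ("dy_um", self.dy_um), ("dz_um", self.dz_um)):
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be a positive finite number, got {v}")
        if "DAPI" not in self.channel_map:
            raise ValueError("channel_map must contain a 'DAPI' channel")
        indices = list(self.channel_map.values())
        if len(set(indices)) != len(indices):
            raise ValueError("channel indices must be unique")
        if len(set(self.channel_map)) != len(self.channel_map):
            raise ValueError("channel names must be unique")

    @property
    def voxel_volume_um3(self) -> float:
        return self.dx_um * self.dy_um * self.dz_um

    @property
    def pixel_area_um2(self) -> float:
        return self.dx_um * self.dy_um

    @property
    def markers(self) -> tuple[str, ...]:
        """Channel names other than DAPI, in channel-index order."""
        return tuple(
            sorted((m for m in self.channel_map if m != "DAPI"), key=self.channel_map.__getitem__)
        )


@dataclass
class ImageStack:
    """One multi-channel 3-D acquisition plus voxel geometry and metadata.

    ``voxels`` is indexed ``(channel, z, y, x)`` with finite non-negative
    intensities; all channels share one ``(z, y, x)`` shape.
    """

    voxels: np.ndarray
    spec: AcquisitionSpec
    sample_id: str = ""
    patient_id: str = ""
    condition: str = ""
    timepoint: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError(f"voxels must be 4-D (channel, z, y, x), got ndim={self.voxels.ndim}")
        if self.voxels.shape[0] < len(self.spec.channel_map):
            raise ValueError(
                f"channel mismatch: stack has {self.voxels.shape[0]} channels, "
                f"manifest names {len(self.spec.channel_map)}"
            )
        if not np.isfinite(self.voxels).all():
            raise ValueError("voxels must be finite")
        if np.issubdtype(self.voxels.dtype, np.floating) and (self.voxels < 0).any():
            raise ValueError("voxels must be non-negative")

    def channel(self, marker: str) -> np.ndarray:
        """Single-channel (z, y, x) view for a named marker."""
        return self.voxels[self.spec.channel_map[marker]]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a sample manifest CSV.

    Required columns: ``sample_id, patient_id, condition, timepoint, path``
    plus one column per marker giving its channel index.
    """
    df = pd.read_csv(path, dtype={c: str for c in MANIFEST_COLUMNS})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing required columns: {missing}")
    marker_cols = [c for c in df.columns if c not in MANIFEST_COLUMNS]
    if "DAPI" not in marker_cols:
        raise ValueError("manifest must contain a DAPI channel column")
    return df


def _spec_from_manifest_row(
    manifest_row: Mapping, dx_um: float = 0.09, dy_um: float = 0.09, dz_um: float = 0.5
) -> AcquisitionSpec:
    channel_map = {
        k: int(v)
        for k, v in dict(manifest_row).items()
        if k not in MANIFEST_COLUMNS and pd.notna(v)
    }
    return AcquisitionSpec(dx_um=dx_um, dy_um=dy_um, dz_um=dz_um, channel_map=channel_map)


def read_stack(
    path: str | Path,
    manifest_row: Mapping,
    dx_um: float = 0.09,
    dy_um: float = 0.09,
    dz_um: float = 0.5,
) -> ImageStack:
    """Read a TIFF z-stack into an :class:`ImageStack`.

    The file stores the array as ``(channel, z, y, x)``; the manifest row
    names every channel present and supplies the sample metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    arr = tifffile.imread(path)
    if arr.ndim == 3:  # single channel stored without a channel axis
        arr = arr[None]
    if arr.ndim != 4:
        raise ValueError(f"expected a (channel, z, y, x) TIFF, got ndim={arr.ndim}")
    spec = _spec_from_manifest_row(manifest_row, dx_um, dy_um, dz_um)
    if arr.shape[0] != len(spec.channel_map):
        raise ValueError(
            f"channel mismatch: file holds {arr.shape[0]} channels, "
            f"manifest names {len(spec.channel_map)}"
        )
    row = dict(manifest_row)
    return ImageStack(
        voxels=np.asarray(arr),
        spec=spec,
        sample_id=str(row.get("sample_id", "")),
        patient_id=str(row.get("patient_id", "")),
        condition=str(row.get("condition", "")),
        timepoint=str(row.get("timepoint", "")),
    )


def write_stack(path: str | Path, stack: ImageStack) -> Path:
    """Write a stack to a plain multi-page TIFF, ``(channel, z, y, x)``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # explicit photometric keeps 3-channel stacks from being stored as RGB
    tifffile.imwrite(path, np.asarray(stack.voxels), photometric="minisblack")
    return path


def range_normalize(image: np.ndarray) -> np.ndarray:
    """Min-max rescale to ``[0, 1]``; a constant image maps to all zeros.

    Applied per image per channel to absorb the variable explored intensity
    range of individual acquisitions.
    """
    image = np.asarray(image, dtype=float)
    if not np.isfinite(image).all():
        raise ValueError("image must be finite")
    lo = image.min()
    hi = image.max()
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def gamma_adjust(image: np.ndarray, gamma: float) -> np.ndarray:
    """Pointwise power-law contrast adjustment ``I**gamma`` on [0, 1] input."""
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    image = np.asarray(image, dtype=float)
    if image.min() < 0 or image.max() > 1:
        raise ValueError("gamma_adjust expects intensities in [0, 1]")
    return image**gamma


def median_denoise(image: np.ndarray, footprint_radius: int = 1) -> np.ndarray:
    """2-D median filter with a cross/diamond footprint and reflective edges."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("median_denoise expects a 2-D image")
    footprint = diamond(footprint_radius)
    return ndi.median_filter(image, footprint=footprint, mode="reflect")


def max_z_project(volume: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection along z of a single-channel (z, y, x) array."""
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("max_z_project expects a (z, y, x) volume")
    if volume.shape[0] < 1:
        raise ValueError("volume must have at least one z-plane")
    return volume.max(axis=0)
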