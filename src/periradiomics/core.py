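"""Shared in-memory containers and NIfTI input/output."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np


@dataclass
class DceSeries:
    """Phase-indexed dynamic contrast-enhanced volume.

    ``data`` has shape ``(n_phases, z, y, x)``; phase 0 is the precontrast
    acquisition and ``phase_times_min`` are minutes relative to contrast
    injection (precontrast first, then the postcontrast times).
    """

    data: np.ndarray
    phase_times_min: tuple[float, ...]
    pixel_spacing_mm: tuple[float, float]
    slice_thickness_mm: float = 1.5

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        times = tuple(float(t) for t in self.phase_times_min)
        if self.data.ndim != 4:
            raise ValueError("series data must be (phase, z, y, x)")
        if len(times) != self.data.shape[0]:
            raise ValueError("one acquisition time per phase is required")
        if np.any(np.diff(times) <= 0):
            raise ValueError("phase times must be strictly increasing")
        self.phase_times_min = times

    @property
    def n_postcontrast(self) -> int:
        return self.data.shape[0] - 1

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]


def _affine(spacing_mm: tuple[float, float], thickness_mm: float) -> np.ndarray:
    return np.diag([thickness_mm, spacing_mm[0], spacing_mm[1], 1.0])


def save_series_nifti(series: DceSeries, path: str | Path) -> None:
    """Write a DCE series as a 4D NIfTI (z, y, x, phase on the last axis)."""
    vol = np.moveaxis(series.data, 0, -1)
    img = nib.Nifti1Image(vol, _affine(series.pixel_spacing_mm, series.slice_thickness_mm))
    img.header["pixdim"][4] = 1.0
    nib.save(img, str(path))


def load_series_nifti(
    path: str | Path,
    phase_times_min,
    pixel_spacing_mm=None,
) -> DceSeries:
    img = nib.load(str(path))
    vol = np.moveaxis(np.asanyarray(img.dataobj, dtype=float), -1, 0)
    zooms = img.header.get_zooms()
    spacing = pixel_spacing_mm or (float(zooms[1]), float(zooms[2]))
    return DceSeries(
        data=vol,
        phase_times_min=tuple(phase_times_min),
        pixel_spacing_mm=tuple(spacing),
        slice_thickness_mm=float(zooms[0]),
    )


def save_mask_nifti(
    mask: np.ndarray,
    path: str | Path,
    pixel_spacing_mm=(1.0, 1.0),
    slice_thickness_mm=1.5,
) -> None:
    img = nib.Nifti1Image(
        np.asarray(mask, dtype=np.uint8), _affine(tuple(pixel_spacing_mm), slice_thickness_mm)
    )
    nib.save(img, str(path))


def load_mask_nifti(path: str | Path) -> np.ndarray:
    return np.asanyarray(nib.load(str(path)).dataobj) > 0
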