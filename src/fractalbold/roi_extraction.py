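"""Spherical ROI masks, mean time-series extraction, linear detrending.

ROIs are spheres specified in millimetre (template/scanner) coordinates; a
voxel belongs to the ROI when its *center* lies at Euclidean mm distance
≤ radius from the sphere center (closed boundary, so ties at exactly the
radius are included).  The regional signal is the arithmetic mean over the
masked voxels, followed by least-squares removal of a straight-line trend —
the slow drifts of fMRI series must go before any spectral or fractal
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .timeseries import TimeSeries

__all__ = [
    "ROISpec",
    "sphere_mask",
    "build_sphere_mask",
    "extract_mean_timeseries",
    "detrend_linear",
    "read_rois_tsv",
]


@dataclass(frozen=True)
class ROISpec:
    """A named sphere in mm coordinates (default radius 10 mm)."""

    name: str
    center_mm: tuple[float, float, float]
    radius_mm: float = 10.0

    def __post_init__(self):
        center = np.asarray(self.center_mm, dtype=float)
        if center.shape != (3,) or not np.all(np.isfinite(center)):
            raise ValueError("center_mm must be a finite 3-vector")
        if not (self.radius_mm > 0):
            raise ValueError("radius_mm must be positive")
        object.__setattr__(self, "center_mm", tuple(center))


def sphere_mask(center_mm, radius_mm: float, affine, shape) -> np.ndarray:
    """Boolean voxel mask of the sphere on a grid with the given affine.

    ``affine`` is the 4x4 voxel-index → mm map of the image; membership is
    decided per voxel center.  An empty result raises (the radius is too
    small to catch any voxel center).
    """
    import nibabel as nib

    affine = np.asarray(affine, dtype=float)
    center = np.asarray(center_mm, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    shape = tuple(int(s) for s in shape[:3])

    idx = np.indices(shape).reshape(3, -1).T
    mm = nib.affines.apply_affine(affine, idx)
    dist2 = np.sum((mm - center) ** 2, axis=1)
    mask = (dist2 <= radius_mm**2).reshape(shape)
    if not mask.any():
        raise ValueError(
            f"sphere of radius {radius_mm:g} mm at {tuple(center)} contains "
            "no voxel centers")
    return mask


def build_sphere_mask(roi: ROISpec, image) -> np.ndarray:
    """Mask for ``roi`` on the geometry of a nibabel image (or (affine, shape))."""
    if hasattr(image, "affine"):
        affine, shape = image.affine, image.shape
    else:
        affine, shape = image
    return sphere_mask(roi.center_mm, roi.radius_mm, affine, shape)


def extract_mean_timeseries(image, mask, sampling_interval: float | None = None,
                            label: str = "") -> TimeSeries:
    """Arithmetic mean over masked voxels at each volume.

    ``image`` is a 4D nibabel image (or a 4D array).  The sampling interval
    is taken from the image header's 4th zoom when available, otherwise
    from the argument (default 2.0 s).
    """
    if hasattr(image, "get_fdata"):
        data = image.get_fdata()
        if sampling_interval is None:
            zooms = image.header.get_zooms()
            if len(zooms) > 3 and zooms[3] > 0:
                sampling_interval = float(zooms[3])
    else:
        data = np.asarray(image, dtype=float)
    if sampling_interval is None:
        sampling_interval = 2.0
    if data.ndim != 4:
        raise ValueError("expected a 4D image")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != data.shape[:3]:
        raise ValueError("mask shape does not match image grid")
    if not mask.any():
        raise ValueError("mask is empty")
    voxels = data[mask]  # (n_voxels, n_volumes)
    if np.isnan(voxels).all(axis=1).any():
        raise ValueError("mask contains all-NaN voxel series")
    return TimeSeries(voxels.mean(axis=0), sampling_interval, label)


def detrend_linear(ts: TimeSeries, mode: str = "least_squares") -> TimeSeries:
    """Remove a straight-line trend over the full series.

    ``mode="least_squares"`` (default) subtracts the ordinary
    least-squares line, leaving a zero-mean, zero-slope residual; a
    constant series comes back as all zeros.  ``mode="endpoints"``
    subtracts the line through the first and last samples instead.
    """
    if ts.n < 3:
        raise ValueError("detrending needs at least 3 samples")
    x = ts.values
    if mode == "least_squares":
        from scipy.signal import detrend as _detrend

        return ts.with_values(_detrend(x, type="linear"))
    if mode == "endpoints":
        t = np.arange(ts.n, dtype=float)
        line = x[0] + (x[-1] - x[0]) * t / (ts.n - 1)
        return ts.with_values(x - line)
    raise ValueError(f"unknown detrend mode {mode!r}")


def read_rois_tsv(path) -> list[ROISpec]:
    """Read an ROI list: TSV with columns name, x, y, z[, radius] (mm)."""
    frame = pd.read_csv(path, sep="\t")
    required = {"name", "x", "y", "z"}
    if not required.issubset(frame.columns):
        raise ValueError(f"ROI table needs columns {sorted(required)}")
    rois = []
    for _, row in frame.iterrows():
        radius = float(row["radius"]) if "radius" in frame.columns else 10.0
        rois.append(ROISpec(str(row["name"]),
                            (float(row["x"]), float(row["y"]), float(row["z"])),
                            radius))
    return rois
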