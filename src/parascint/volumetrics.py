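"""Seed-guided percent-of-max isocontour volumetry on SPECT volumes.

The adenoma volume (Svol, cm^3) is the volume of the connected set of voxels
at or above a stated percentage (default 40%) of a *local* peak — the maximum
within a search sphere around an operator seed, not the global image maximum,
since normal thyroid can out-shine the adenoma. The PTH/Svol composite divides
serum parathormone (ng/L) by Svol, giving a secretory-activity-per-volume
proxy in ng/L/cm^3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import ActivityVolume, Ellipsoid

__all__ = [
    "Voi",
    "VolumetricsResult",
    "locate_peak",
    "segment_isocontour",
    "compute_svol",
    "compute_pth_svol",
    "quantify_patient_spect",
]


@dataclass(frozen=True)
class Voi:
    """Isocontour volume of interest.

    ``voxels`` is an (N, 3) integer index array: the 26-connected component of
    voxels >= threshold_pct/100 * peak_value that contains the peak.
    """

    voxels: np.ndarray
    threshold_pct: float
    peak_value: float
    peak_location: tuple[int, int, int]
    touches_boundary: bool = False

    def __post_init__(self) -> None:
        vx = np.atleast_2d(np.asarray(self.voxels, dtype=int))
        if vx.size == 0:
            raise ValueError("VOI must be non-empty")
        if vx.shape[1] != 3:
            raise ValueError("VOI voxels must be (N, 3) indices")
        object.__setattr__(self, "voxels", np.unique(vx, axis=0))

    def __len__(self) -> int:
        return int(self.voxels.shape[0])


@dataclass(frozen=True)
class VolumetricsResult:
    svol: float  # cm^3
    voi: Voi
    pth_svol: float | None = None  # ng/L per cm^3


def locate_peak(
    volume: ActivityVolume,
    seed_point: tuple[int, int, int],
    search_radius_mm: float = 15.0,
) -> tuple[tuple[int, int, int], float]:
    """Find the hottest voxel within a sphere (mm) around the seed.

    Ties are broken by smallest world distance to the seed, then by
    lexicographic voxel index, so the result is deterministic; on a locally
    uniform volume the seed voxel itself is returned.
    """
    seed = np.asarray(seed_point, dtype=int)
    shape = np.asarray(volume.counts.shape)
    if np.any(seed < 0) or np.any(seed >= shape):
        raise ValueError(f"seed {tuple(seed)} lies outside the volume grid")
    spacing = np.asarray(volume.voxel_spacing)
    half = np.maximum(np.floor(search_radius_mm / spacing).astype(int), 0)
    lo = np.maximum(seed - half, 0)
    hi = np.minimum(seed + half + 1, shape)
    if np.any(lo >= hi):
        raise ValueError("search sphere lies entirely outside the grid")
    idx = np.stack(
        np.meshgrid(*(np.arange(l, h) for l, h in zip(lo, hi)), indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    dist2 = (((idx - seed) * spacing) ** 2).sum(axis=1)
    inside = dist2 <= search_radius_mm**2
    if not inside.any():
        raise ValueError("search sphere lies entirely outside the grid")
    idx, dist2 = idx[inside], dist2[inside]
    vals = volume.counts[idx[:, 0], idx[:, 1], idx[:, 2]]
    # max value, then min distance to seed, then lexicographic index
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], dist2, -vals))
    best = idx[order[0]]
    return tuple(int(v) for v in best), float(volume.counts[tuple(best)])


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def segment_isocontour(
    volume: ActivityVolume,
    peak: tuple[int, int, int],
    threshold_pct: float = 40.0,
    clip_ellipsoid: Ellipsoid | None = None,
    background: float = 0.0,
) -> Voi:
    """Isocontour VOI: the 26-connected component >= pct of the peak value.

    ``clip_ellipsoid`` optionally restricts the thresholded mask to a bounding
    ellipsoid (world mm) before taking the component, mimicking vendor tools
    that draw a spherical/ellipsoid shell first. ``background``, if nonzero,
    is subtracted from both the volume and the peak before thresholding (off
    by default). A component touching the grid boundary is flagged.
    """
    if not (0.0 < threshold_pct <= 100.0):
        raise ValueError("threshold_pct must be in (0, 100]")
    peak = tuple(int(v) for v in peak)
    peak_value = float(volume.counts[peak])
    if peak_value - background <= 0:
        raise ValueError("peak value must be positive (after background subtraction)")
    level = background + (threshold_pct / 100.0) * (peak_value - background)
    mask = volume.counts >= level
    if clip_ellipsoid is not None:
        spacing = np.asarray(volume.voxel_spacing)
        coords = np.stack(
            np.meshgrid(
                *(np.arange(n) * s for n, s in zip(volume.counts.shape, spacing)),
                indexing="ij",
            ),
            axis=-1,
        )
        mask &= clip_ellipsoid.contains(coords)
    labels, _ = ndimage.label(mask, structure=_CONN26)
    lab = labels[peak]
    if lab == 0:
        raise ValueError("peak voxel falls below its own threshold")
    component = np.argwhere(labels == lab)
    touches = bool(
        (component == 0).any()
        or (component == np.asarray(volume.counts.shape) - 1).any()
    )
    return Voi(
        voxels=component,
        threshold_pct=float(threshold_pct),
        peak_value=peak_value,
        peak_location=peak,
        touches_boundary=touches,
    )


def compute_svol(voi: Voi, voxel_spacing: tuple[float, float, float]) -> float:
    """VOI volume in cm^3: voxel count x voxel volume."""
    spacing = np.asarray(voxel_spacing, dtype=float)
    if np.any(spacing <= 0):
        raise ValueError("voxel spacing must be positive")
    return float(len(voi) * np.prod(spacing) / 1000.0)


def compute_pth_svol(pth: float, svol: float) -> float:
    """Parathormone / scintigraphic volume composite (ng/L per cm^3)."""
    if svol <= 0:
        raise ValueError("Svol must be positive")
    if pth < 0:
        raise ValueError("PTH must be non-negative")
    return float(pth / svol)


def quantify_patient_spect(
    volume: ActivityVolume,
    seed_point: tuple[int, int, int],
    threshold_pct: float = 40.0,
    search_radius_mm: float = 15.0,
    pth: float | None = None,
) -> VolumetricsResult:
    """Full per-patient volumetric read-out: peak, VOI, Svol, PTH/Svol."""
    peak, _ = locate_peak(volume, seed_point, search_radius_mm)
    voi = segment_isocontour(volume, peak, threshold_pct)
    svol = compute_svol(voi, volume.voxel_spacing)
    return VolumetricsResult(
        svol=svol,
        voi=voi,
        pth_svol=None if pth is None else compute_pth_svol(pth, svol),
    )
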