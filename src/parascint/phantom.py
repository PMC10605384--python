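"""Digital neck phantom for dual-phase parathyroid scintigraphy.

Generates noise-free 3-D activity maps with a known adenoma ellipsoid and two
thyroid lobes, applies early->delayed tracer washout, PSF blur with Poisson
counting noise, and projects planar views — so every downstream quantification
stage can be tested against analytic ground truth.

Axis convention: volumes are indexed (x: right->left, y: anterior->posterior,
z: inferior->superior), 0-based, with world coordinates in mm at voxel centers
(voxel ``i`` is centered at ``i * spacing``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "Ellipsoid",
    "PhantomSpec",
    "ActivityVolume",
    "PlanarImage",
    "build_activity_volume",
    "apply_noise",
    "project_planar",
    "default_phantom_spec",
]

#: minutes between the early (~10 min p.i.) and delayed (~90 min p.i.) scans
DELAY_MINUTES = 80.0

COMPARTMENTS = ("adenoma", "thyroid", "background")


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in world coordinates (mm)."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    side: str | None = None  # left / right label for thyroid lobes

    def volume_cm3(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c / 1000.0

    def contains(self, coords: np.ndarray) -> np.ndarray:
        """Boolean mask for points (..., 3) in mm inside the ellipsoid."""
        d = (coords - np.asarray(self.center)) / np.asarray(self.semi_axes)
        return (d**2).sum(axis=-1) <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth description of the simulated neck.

    Uptake values are activity concentrations in arbitrary counts/voxel at the
    early time point; the delayed image applies a mono-exponential decay with
    the per-compartment effective half-life (minutes; ``inf`` = fixed uptake).
    """

    grid_shape: tuple[int, int, int] = (80, 80, 80)
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    adenoma: Ellipsoid = field(
        default_factory=lambda: Ellipsoid((64.0, 90.0, 70.0), (7.0, 6.0, 8.0))
    )
    thyroid_lobes: tuple[Ellipsoid, Ellipsoid] = field(
        default_factory=lambda: (
            Ellipsoid((64.0, 70.0, 84.0), (9.0, 11.0, 20.0), side="right"),
            Ellipsoid((96.0, 70.0, 84.0), (9.0, 11.0, 20.0), side="left"),
        )
    )
    compartment_uptake_early: dict[str, float] = field(
        default_factory=lambda: {"adenoma": 6.0, "thyroid": 3.0, "background": 1.0}
    )
    effective_half_life: dict[str, float] = field(
        default_factory=lambda: {"adenoma": 240.0, "thyroid": 60.0, "background": 90.0}
    )
    psf_sigma: float = 4.0  # mm
    count_scale: float = 200.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ValueError("grid_shape must be three positive integers")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be positive")
        for ell in (self.adenoma, *self.thyroid_lobes):
            if any(a <= 0 for a in ell.semi_axes):
                raise ValueError("ellipsoid semi-axes must be positive")
        u = self.compartment_uptake_early
        missing = set(COMPARTMENTS) - set(u)
        if missing:
            raise ValueError(f"missing compartment uptake: {sorted(missing)}")
        if any(v < 0 for v in u.values()):
            raise ValueError("uptake concentrations must be >= 0")
        if not (u["adenoma"] > u["thyroid"] > u["background"]):
            raise ValueError(
                "detectable-lesion convention requires "
                "adenoma > thyroid > background early uptake"
            )
        if any(h <= 0 for h in self.effective_half_life.values()):
            raise ValueError("effective half-lives must be positive (inf allowed)")
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be >= 0")
        if self.count_scale <= 0:
            raise ValueError("count_scale must be positive")
        # the adenoma must fit fully inside the grid
        axes = "xyz"
        for ax in range(3):
            lo = self.adenoma.center[ax] - self.adenoma.semi_axes[ax]
            hi = self.adenoma.center[ax] + self.adenoma.semi_axes[ax]
            extent = (self.grid_shape[ax] - 1) * self.voxel_spacing[ax]
            if lo < 0 or hi > extent:
                raise ValueError(
                    f"adenoma ellipsoid extends outside the grid along axis "
                    f"{axes[ax]} ([{lo:.1f}, {hi:.1f}] mm vs [0, {extent:.1f}] mm)"
                )


@dataclass
class ActivityVolume:
    """3-D count volume with voxel spacing in mm."""

    counts: np.ndarray
    voxel_spacing: tuple[float, float, float]
    time_point: str  # "early" | "delayed"
    truth: PhantomSpec | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 3:
            raise ValueError("ActivityVolume requires a 3-D array")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be positive")

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.voxel_spacing)) / 1000.0


@dataclass
class PlanarImage:
    """2-D planar count image with square pixels (mm)."""

    counts: np.ndarray
    pixel_spacing: float
    time_point: str

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("PlanarImage requires a 2-D array")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")


def _decay_factor(half_life_min: float, dt_min: float) -> float:
    if np.isinf(half_life_min):
        return 1.0
    return float(2.0 ** (-dt_min / half_life_min))


def build_activity_volume(
    spec: PhantomSpec, time_point: str = "early", delay_minutes: float = DELAY_MINUTES
) -> ActivityVolume:
    """Voxelize the phantom into a noise-free activity volume.

    Voxels inside the adenoma ellipsoid carry the adenoma concentration
    (overriding thyroid where they overlap), thyroid-lobe voxels the thyroid
    concentration, all others background. ``time_point="delayed"`` applies the
    per-compartment mono-exponential washout over ``delay_minutes``.
    """
    spec.validate()
    if time_point not in ("early", "delayed"):
        raise ValueError(f"unknown time_point {time_point!r}")
    dt = delay_minutes if time_point == "delayed" else 0.0
    conc = {
        c: spec.compartment_uptake_early[c]
        * _decay_factor(spec.effective_half_life.get(c, np.inf), dt)
        for c in COMPARTMENTS
    }
    grids = np.meshgrid(
        *(np.arange(n) * sp for n, sp in zip(spec.grid_shape, spec.voxel_spacing)),
        indexing="ij",
    )
    coords = np.stack(grids, axis=-1)
    counts = np.full(spec.grid_shape, conc["background"], dtype=float)
    for lobe in spec.thyroid_lobes:
        counts[lobe.contains(coords)] = conc["thyroid"]
    counts[spec.adenoma.contains(coords)] = conc["adenoma"]
    return ActivityVolume(counts, spec.voxel_spacing, time_point, truth=spec)


def apply_noise(
    volume: ActivityVolume,
    seed: int,
    psf_sigma: float | None = None,
    count_scale: float | None = None,
) -> ActivityVolume:
    """Blur with a Gaussian PSF, then draw voxelwise Poisson counts.

    The expected counts are ``blurred * count_scale``; the draw is divided by
    ``count_scale`` again so the output stays on the input concentration scale
    (uptake ratios are scale-free, and replicate means converge to the
    noise-free blurred volume). Reproducible for a fixed seed.
    """
    spec = volume.truth
    if psf_sigma is None:
        psf_sigma = spec.psf_sigma if spec is not None else 0.0
    if count_scale is None:
        count_scale = spec.count_scale if spec is not None else 1.0
    if psf_sigma < 0:
        raise ValueError("psf_sigma must be >= 0")
    if count_scale <= 0:
        raise ValueError("count_scale must be positive")
    blurred = volume.counts
    if psf_sigma > 0:
        sigma_vox = [psf_sigma / sp for sp in volume.voxel_spacing]
        blurred = gaussian_filter(blurred, sigma=sigma_vox, mode="nearest")
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(blurred * count_scale).astype(float) / count_scale
    return replace(volume, counts=noisy)


def blur_only(volume: ActivityVolume, psf_sigma: float) -> ActivityVolume:
    """Gaussian PSF blur without counting noise (noise-free expectation)."""
    if psf_sigma < 0:
        raise ValueError("psf_sigma must be >= 0")
    if psf_sigma == 0:
        return replace(volume, counts=volume.counts.copy())
    sigma_vox = [psf_sigma / sp for sp in volume.voxel_spacing]
    return replace(
        volume, counts=gaussian_filter(volume.counts, sigma=sigma_vox, mode="nearest")
    )


def project_planar(volume: ActivityVolume) -> PlanarImage:
    """Sum counts along the anterior-posterior (y) axis into an anterior view.

    The planar image is indexed (row = z, inferior->superior; column = x,
    right->left) so that the neck midline is a pixel *column* and a caudal
    shift is a negative row offset. Total counts are conserved exactly.
    Requires square in-plane pixels.
    """
    sx, _, sz = volume.voxel_spacing
    if not np.isclose(sx, sz):
        raise ValueError(
            f"anisotropic in-plane spacing ({sx} vs {sz} mm): planar "
            "quantification assumes square pixels"
        )
    return PlanarImage(
        counts=volume.counts.sum(axis=1).T,
        pixel_spacing=float(sx),
        time_point=volume.time_point,
    )


def default_phantom_spec(**overrides) -> PhantomSpec:
    """The default neck phantom used throughout the test-bench."""
    return replace(PhantomSpec(), **overrides) if overrides else PhantomSpec()
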