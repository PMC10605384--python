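"""Dual-phase planar quantification: LBR, LTR and the retention index.

A lesion ROI drawn on the early anterior view is mirrored across the neck
midline to obtain a same-size, same-shape reference ROI over the contralateral
thyroid, and (with a caudal offset) over the contralateral background cervical
region. Uptake ratios are ratios of per-pixel mean counts:

    LBR = mean(lesion) / mean(contralateral background)
    LTR = mean(lesion) / mean(contralateral thyroid)
    RI  = (eLTR - dLTR) / eLTR

with e/d prefixes for the early (~10 min) and delayed (~90 min) views. The
same pixel masks are applied to both time points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import PlanarImage

__all__ = [
    "Roi",
    "PlanarParams",
    "roi_mean",
    "mirror_roi",
    "compute_lbr",
    "compute_ltr",
    "compute_ri",
    "quantify_patient_planar",
]

ROI_LABELS = ("lesion", "thyroid_ref", "background_ref")


@dataclass(frozen=True)
class Roi:
    """Pixel-index region of interest on a planar image.

    ``pixels`` is an (N, 2) integer array of (row, col) indices; rows index
    the z (inferior->superior) axis and columns the x (right->left) axis of
    the anterior projection, so the neck midline is a column.
    """

    pixels: np.ndarray
    label: str = "lesion"
    source: str = "manual"  # manual | mirrored

    def __post_init__(self) -> None:
        px = np.atleast_2d(np.asarray(self.pixels, dtype=int))
        if px.size == 0:
            raise ValueError("ROI must contain at least one pixel")
        if px.shape[1] != 2:
            raise ValueError("ROI pixels must be (N, 2) (row, col) indices")
        # de-duplicate and order deterministically
        px = np.unique(px, axis=0)
        object.__setattr__(self, "pixels", px)
        if self.label not in ROI_LABELS:
            raise ValueError(f"unknown ROI label {self.label!r}")

    def __len__(self) -> int:
        return int(self.pixels.shape[0])

    def validate_on(self, image: PlanarImage) -> None:
        nr, nc = image.counts.shape
        r, c = self.pixels[:, 0], self.pixels[:, 1]
        if r.min() < 0 or c.min() < 0 or r.max() >= nr or c.max() >= nc:
            raise ValueError(
                f"ROI {self.label!r} exceeds the {nr}x{nc} image bounds"
            )


@dataclass(frozen=True)
class PlanarParams:
    """The five dual-phase planar parameters for one patient."""

    elbr: float
    dlbr: float
    eltr: float
    dltr: float
    ri: float

    def as_dict(self) -> dict[str, float]:
        return {
            "eLBR": self.elbr,
            "dLBR": self.dlbr,
            "eLTR": self.eltr,
            "dLTR": self.dltr,
            "RI": self.ri,
        }


def roi_mean(image: PlanarImage, roi: Roi) -> float:
    """Arithmetic mean of counts over the ROI pixels."""
    roi.validate_on(image)
    return float(image.counts[roi.pixels[:, 0], roi.pixels[:, 1]].mean())


def mirror_roi(
    roi: Roi,
    image: PlanarImage,
    midline_column: int,
    row_offset: int = 0,
    label: str = "thyroid_ref",
) -> Roi:
    """Reflect an ROI across the vertical midline (optionally shifting rows).

    Reflection maps column ``c`` to ``2 * midline_column - c``, preserving the
    pixel count and shape (mirrored). ``row_offset`` translates the reflected
    mask along the rows (used to drop the background reference caudally so it
    clears the contralateral thyroid).
    """
    px = roi.pixels.copy()
    px[:, 1] = 2 * midline_column - px[:, 1]
    px[:, 0] += row_offset
    mirrored = Roi(px, label=label, source="mirrored")
    nr, nc = image.counts.shape
    r, c = mirrored.pixels[:, 0], mirrored.pixels[:, 1]
    if r.min() < 0 or c.min() < 0 or r.max() >= nr or c.max() >= nc:
        raise ValueError(
            "mirrored ROI exits the image bounds; pass a row_offset (or adjust "
            "midline_column) to translate the reference region back inside"
        )
    if len(mirrored) != len(roi):
        raise AssertionError("reflection must preserve the pixel count")
    return mirrored


def compute_lbr(lesion_mean: float, background_mean: float) -> float:
    """Lesion/background uptake ratio of mean ROI counts."""
    if background_mean <= 0:
        raise ValueError(
            "background ROI mean must be positive (check ROI placement)"
        )
    return float(lesion_mean / background_mean)


def compute_ltr(lesion_mean: float, thyroid_mean: float) -> float:
    """Lesion/thyroid uptake ratio of mean ROI counts."""
    if thyroid_mean <= 0:
        raise ValueError("thyroid ROI mean must be positive (check ROI placement)")
    return float(lesion_mean / thyroid_mean)


def compute_ri(eltr: float, dltr: float) -> float:
    """Retention index: fractional change of LTR, (eLTR - dLTR) / eLTR.

    Zero when the lesion and thyroid wash out in lockstep; negative when the
    lesion accumulates tracer relative to thyroid on the delayed view.
    """
    if eltr <= 0:
        raise ValueError("eLTR must be positive")
    return float((eltr - dltr) / eltr)


def quantify_patient_planar(
    early: PlanarImage,
    delayed: PlanarImage,
    lesion_roi: Roi,
    midline_column: int,
    background_row_offset: int | None = None,
) -> PlanarParams:
    """Compute eLBR, dLBR, eLTR, dLTR and RI for one early/delayed pair.

    The thyroid reference is the lesion ROI mirrored across ``midline_column``;
    the background reference is the mirrored ROI shifted by
    ``background_row_offset`` rows (default: one ROI height caudally, i.e.
    toward smaller z, to clear the contralateral thyroid). Identical masks are
    applied to both time points.
    """
    if early.counts.shape != delayed.counts.shape:
        raise ValueError("early and delayed images must share a shape")
    if not np.isclose(early.pixel_spacing, delayed.pixel_spacing):
        raise ValueError("early and delayed images must share pixel spacing")
    lesion_roi.validate_on(early)
    if background_row_offset is None:
        rows = lesion_roi.pixels[:, 0]
        background_row_offset = -int(rows.max() - rows.min() + 1)
    thyroid_ref = mirror_roi(lesion_roi, early, midline_column, label="thyroid_ref")
    background_ref = mirror_roi(
        lesion_roi,
        early,
        midline_column,
        row_offset=background_row_offset,
        label="background_ref",
    )
    means = {
        tp: {
            "lesion": roi_mean(img, lesion_roi),
            "thyroid": roi_mean(img, thyroid_ref),
            "background": roi_mean(img, background_ref),
        }
        for tp, img in (("e", early), ("d", delayed))
    }
    eltr = compute_ltr(means["e"]["lesion"], means["e"]["thyroid"])
    dltr = compute_ltr(means["d"]["lesion"], means["d"]["thyroid"])
    return PlanarParams(
        elbr=compute_lbr(means["e"]["lesion"], means["e"]["background"]),
        dlbr=compute_lbr(means["d"]["lesion"], means["d"]["background"]),
        eltr=eltr,
        dltr=dltr,
        ri=compute_ri(eltr, dltr),
    )
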