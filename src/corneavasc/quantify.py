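"""Vessel-density and vessel-growth-density statistics.

Vessel density percentage over a region of interest A is the discrete form
of ``(integral of V dA / integral of dA) * 100`` with V = 1 on vessel (white)
pixels and 0 on background: the vessel pixel count inside the ROI divided by
the ROI pixel count, times 100.

Vessel growth density between consecutive follow-ups subtracts the
registered previous binary map from the new one, removes sub-3-px change
components (misalignment debris), and expresses the surviving new-vessel
pixels as a percentage of the same ROI. The identical computation applied to
two repeat scans of the same time point gives the repeated-scan error floor
against which real weekly growth is judged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .images import BinaryVesselMap, RegionOfInterest
from .registration import RegistrationResult, warp
from .segmentation import remove_small_components


@dataclass
class DensityMeasurement:
    """One vessel-density reading: exact pixel ratio, scaled to percent."""

    density_percent: float
    vessel_px: int
    roi: RegionOfInterest
    modality: str | None = None
    week: int | None = None
    repeat_index: int | None = None


@dataclass
class GrowthMeasurement:
    """New-vessel density between two consecutive follow-ups.

    ``growth_percent`` comes from the subtracted-mask procedure (never
    negative); ``plain_difference_percent`` is the week-to-week density
    difference, reported alongside since the two definitions diverge when
    vessels regress or small components are filtered. Regression is exposed
    separately as ``regressed_px`` (previous-only pixels).
    """

    week_from: int | None
    week_to: int | None
    growth_percent: float
    surviving_new_px: int
    plain_difference_percent: float
    regressed_px: int
    roi: RegionOfInterest


def vessel_density(
    vmap: BinaryVesselMap, roi: RegionOfInterest
) -> DensityMeasurement:
    """Vessel pixel fraction inside the ROI, as a percentage."""
    if vmap.mask.shape != roi.mask.shape:
        raise ValueError(
            f"map shape {vmap.mask.shape} does not match ROI {roi.mask.shape}"
        )
    if roi.area_px == 0:  # unreachable through RegionOfInterest, but explicit
        raise ValueError("ROI has zero area")
    vessel_px = int(np.count_nonzero(vmap.mask & roi.mask))
    return DensityMeasurement(
        density_percent=vessel_px / roi.area_px * 100.0,
        vessel_px=vessel_px,
        roi=roi,
        modality=vmap.modality,
        week=vmap.week,
        repeat_index=vmap.repeat_index,
    )


def growth_density(
    prev: BinaryVesselMap,
    next: BinaryVesselMap,
    transform: RegistrationResult | None,
    roi: RegionOfInterest,
    min_area_px: int = 3,
) -> GrowthMeasurement:
    """New-vessel density from ``prev`` to ``next`` inside a common ROI.

    ``transform`` registers ``prev`` into the ``next`` frame; pass ``None``
    for pairs already in a common frame. Change components smaller than
    ``min_area_px`` (default: area of 2 px and below) are discarded as
    misalignment debris before counting.
    """
    if transform is not None:
        if not transform.converged:
            raise ValueError(
                "registration did not converge; growth cannot be computed"
            )
        prev = warp(prev, transform.transform, next.mask.shape)
    if prev.mask.shape != next.mask.shape:
        raise ValueError("prev and next maps must share a frame")
    new_px_mask = next.mask & ~prev.mask
    if min_area_px > 1:
        new_px_mask = remove_small_components(new_px_mask, min_area_px)
    new_px_mask &= roi.mask
    surviving = int(new_px_mask.sum())
    d_prev = vessel_density(prev, roi).density_percent
    d_next = vessel_density(next, roi).density_percent
    regressed = int(np.count_nonzero(prev.mask & ~next.mask & roi.mask))
    return GrowthMeasurement(
        week_from=prev.week,
        week_to=next.week,
        growth_percent=surviving / roi.area_px * 100.0,
        surviving_new_px=surviving,
        plain_difference_percent=d_next - d_prev,
        regressed_px=regressed,
        roi=roi,
    )


def repeated_scan_error(
    repeat_a: BinaryVesselMap,
    repeat_b: BinaryVesselMap,
    transform: RegistrationResult | None,
    roi: RegionOfInterest,
    min_area_px: int = 3,
    symmetric: bool = False,
) -> float:
    """Density difference between two same-time-point repeat scans (percent).

    Identical computation to :func:`growth_density` applied to the repeat
    pair; with ``symmetric=True`` the mean of the a->b and b->a directions
    is returned.
    """
    ab = growth_density(repeat_a, repeat_b, transform, roi, min_area_px).growth_percent
    if not symmetric:
        return ab
    inv = None
    if transform is not None:
        inv = RegistrationResult(
            transform=np.linalg.inv(transform.transform),
            similarity_score=transform.similarity_score,
            overlap_mask=transform.overlap_mask,
            converged=transform.converged,
        )
    ba = growth_density(repeat_b, repeat_a, inv, roi, min_area_px).growth_percent
    return 0.5 * (ab + ba)


def density_to_area(density_percent: float, field_width_mm: float) -> float:
    """Convert a density percentage of a square field into mm^2.

    E.g. 1.5% of a 3 mm field is 0.135 mm^2.
    """
    if not 0.0 <= density_percent <= 100.0:
        raise ValueError("density_percent must lie in [0, 100]")
    if field_width_mm <= 0:
        raise ValueError("field_width_mm must be positive")
    return density_percent / 100.0 * field_width_mm**2
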