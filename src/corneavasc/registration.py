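"""Intensity-based alignment of modality pairs and follow-up scans.

A global 2-D transform (translation, similarity = translation + rotation +
isotropic scale, or full affine) is estimated by multi-resolution
optimization of an intensity metric: mutual information for cross-modality
pairs (OCTA/ICGA/SLP intensities are non-linearly related) or normalized
cross-correlation for same-modality pairs. The optimizer backend is
SimpleITK with dense metric sampling, so runs are deterministic.

Coordinates: transforms are 3x3 homogeneous matrices acting on ``(x, y, 1)``
with ``x`` = column, ``y`` = row, pixel centers at integer coordinates. The
stored :attr:`RegistrationResult.transform` maps moving-image coordinates
into the fixed-image frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from skimage.transform import AffineTransform, warp as _skimage_warp
from sklearn.base import BaseEstimator

from .images import BinaryVesselMap, RasterImage, RegionOfInterest, DEFAULT_PITCH_MM

MODELS = ("translation", "similarity", "affine")
METRICS = ("mutual_information", "correlation")

#: score floors below which a fit is reported as not converged
_SCORE_FLOOR = {"mutual_information": 0.15, "correlation": 0.3}


@dataclass
class RegistrationResult:
    """Outcome of one pairwise registration."""

    transform: np.ndarray  # 3x3, moving -> fixed pixel coordinates
    similarity_score: float
    overlap_mask: np.ndarray  # boolean, fixed-image frame
    converged: bool
    metric: str = "mutual_information"
    model: str = "similarity"

    def corner_displacement(self, shape: tuple[int, int]) -> float:
        """Max displacement of the image corners under the transform (px)."""
        rows, cols = shape
        corners = np.array(
            [[0, 0, 1], [cols - 1, 0, 1], [0, rows - 1, 1], [cols - 1, rows - 1, 1]],
            dtype=float,
        )
        moved = corners @ self.transform.T
        return float(np.max(np.hypot(moved[:, 0] - corners[:, 0], moved[:, 1] - corners[:, 1])))


def _pixels(img) -> np.ndarray:
    if isinstance(img, RasterImage):
        return img.pixels
    if isinstance(img, BinaryVesselMap):
        return img.mask.astype(np.float64)
    return np.asarray(img, dtype=np.float64)


def _sitk_to_matrix(tx: sitk.Transform) -> np.ndarray:
    """Affine matrix of an sitk transform (maps fixed -> moving points)."""
    # sample the action of the transform on basis points (robust to type)
    p0 = np.array(tx.TransformPoint((0.0, 0.0)))
    px = np.array(tx.TransformPoint((1.0, 0.0)))
    py = np.array(tx.TransformPoint((0.0, 1.0)))
    M = np.eye(3)
    M[:2, 0] = px - p0
    M[:2, 1] = py - p0
    M[:2, 2] = p0
    return M


class IntensityRegistration(BaseEstimator):
    """Fit a global transform aligning a moving image to a fixed image.

    After :meth:`fit`, ``transform_`` holds the 3x3 moving->fixed matrix,
    ``score_`` the similarity (higher is better) and ``converged_`` whether
    the optimizer found usable shared structure. :meth:`transform` then
    resamples moving-frame images into the fixed frame.

    Parameters
    ----------
    model : {'translation', 'similarity', 'affine'}
        Transform family; similarity (translation + rotation + isotropic
        scale) covers magnification and acquisition-angle differences.
    metric : {'mutual_information', 'correlation'}
        Intensity similarity to maximize.
    levels : int
        Multi-resolution pyramid depth.
    iterations : int
        Optimizer iteration cap per level.
    """

    def __init__(
        self,
        model: str = "similarity",
        metric: str = "mutual_information",
        levels: int = 3,
        iterations: int = 300,
    ):
        self.model = model
        self.metric = metric
        self.levels = levels
        self.iterations = iterations

    def fit(self, moving, fixed):
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")
        mov = _pixels(moving)
        fix = _pixels(fixed)
        self._fixed_shape_ = fix.shape
        self._moving_shape_ = mov.shape
        if mov.std() < 1e-8 or fix.std() < 1e-8:
            # constant image: zero shared information, nothing to optimize
            self.transform_ = np.eye(3)
            self.score_ = 0.0
            self.converged_ = False
            self._finish()
            return self

        f_img = sitk.GetImageFromArray(fix.astype(np.float32))
        m_img = sitk.GetImageFromArray(mov.astype(np.float32))

        if self.model == "translation":
            initial = sitk.TranslationTransform(2)
        elif self.model == "similarity":
            initial = sitk.CenteredTransformInitializer(
                f_img, m_img, sitk.Similarity2DTransform(),
                sitk.CenteredTransformInitializerFilter.GEOMETRY,
            )
        else:
            initial = sitk.CenteredTransformInitializer(
                f_img, m_img, sitk.AffineTransform(2),
                sitk.CenteredTransformInitializerFilter.GEOMETRY,
            )

        reg = sitk.ImageRegistrationMethod()
        if self.metric == "mutual_information":
            reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=50)
        else:
            reg.SetMetricAsCorrelation()
        reg.SetMetricSamplingStrategy(reg.NONE)  # dense: deterministic
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=1.0,
            minStep=1e-4,
            numberOfIterations=self.iterations,
            relaxationFactor=0.6,
            gradientMagnitudeTolerance=1e-6,
        )
        reg.SetOptimizerScalesFromPhysicalShift()
        shrink = [2 ** (self.levels - 1 - i) for i in range(self.levels)]
        reg.SetShrinkFactorsPerLevel(shrink)
        reg.SetSmoothingSigmasPerLevel([max(s - 1, 0) for s in shrink])
        reg.SetInitialTransform(initial, inPlace=False)

        try:
            final = reg.Execute(f_img, m_img)
            metric_value = reg.GetMetricValue()
        except RuntimeError:
            self.transform_ = np.eye(3)
            self.score_ = 0.0
            self.converged_ = False
            self._finish()
            return self

        # sitk transforms map fixed -> moving; ours maps moving -> fixed
        fixed_to_moving = _sitk_to_matrix(final)
        if abs(np.linalg.det(fixed_to_moving[:2, :2])) < 1e-12:
            self.transform_ = np.eye(3)
            self.score_ = 0.0
            self.converged_ = False
            self._finish()
            return self
        self.transform_ = np.linalg.inv(fixed_to_moving)
        self.score_ = float(-metric_value)
        self.converged_ = self.score_ >= _SCORE_FLOOR[self.metric]
        self._finish()
        return self

    def _finish(self) -> None:
        ones = np.ones(self._moving_shape_, dtype=float)
        warped = warp(ones, self.transform_, self._fixed_shape_, order=0)
        self.overlap_mask_ = np.asarray(warped) > 0.5
        self.result_ = RegistrationResult(
            transform=self.transform_,
            similarity_score=self.score_,
            overlap_mask=self.overlap_mask_,
            converged=self.converged_,
            metric=self.metric,
            model=self.model,
        )

    def transform(self, X):
        """Warp a moving-frame image or mask into the fixed frame."""
        return warp(X, self.transform_, self._fixed_shape_)


def register_pair(
    moving,
    fixed,
    model: str = "similarity",
    metric: str | None = None,
    levels: int = 3,
    iterations: int = 300,
) -> RegistrationResult:
    """Estimate the transform aligning ``moving`` onto ``fixed``.

    ``metric=None`` picks mutual information when the two images carry
    different modality tags and correlation otherwise.
    """
    if metric is None:
        mod_a = getattr(moving, "modality", None)
        mod_b = getattr(fixed, "modality", None)
        same = mod_a is not None and mod_a == mod_b
        metric = "correlation" if same else "mutual_information"
    est = IntensityRegistration(model, metric, levels, iterations)
    est.fit(moving, fixed)
    return est.result_


def warp(
    img_or_mask,
    transform: np.ndarray,
    target_shape: tuple[int, int] | None = None,
    order: int | None = None,
):
    """Resample an image/mask through a moving->fixed transform.

    Intensity images are linearly interpolated, binary maps use nearest
    neighbor. Out-of-field pixels are filled with 0 (background) and fall
    outside every overlap mask.
    """
    transform = np.asarray(transform, dtype=float)
    if transform.shape != (3, 3) or abs(np.linalg.det(transform[:2, :2])) < 1e-12:
        raise ValueError("transform must be an invertible 3x3 affine matrix")
    if isinstance(img_or_mask, RasterImage):
        data, is_binary = img_or_mask.pixels, False
    elif isinstance(img_or_mask, BinaryVesselMap):
        data, is_binary = img_or_mask.mask.astype(float), True
    else:
        data = np.asarray(img_or_mask, dtype=float)
        is_binary = img_or_mask.dtype == bool if hasattr(img_or_mask, "dtype") else False
    if order is None:
        order = 0 if is_binary else 1
    target_shape = target_shape or data.shape
    inv = AffineTransform(matrix=np.linalg.inv(transform))
    out = _skimage_warp(
        data, inverse_map=inv, output_shape=target_shape, order=order,
        mode="constant", cval=0.0, preserve_range=True,
    )
    if isinstance(img_or_mask, RasterImage):
        return img_or_mask.with_pixels(np.clip(out, 0.0, 1.0))
    if isinstance(img_or_mask, BinaryVesselMap):
        return img_or_mask.with_mask(out > 0.5, warped=True)
    return out > 0.5 if is_binary else out


def identity_result(shape: tuple[int, int]) -> RegistrationResult:
    """Identity registration for image pairs already in a common frame."""
    return RegistrationResult(
        transform=np.eye(3),
        similarity_score=1.0,
        overlap_mask=np.ones(shape, dtype=bool),
        converged=True,
        metric="correlation",
        model="translation",
    )


def matched_roi(
    results: list[RegistrationResult],
    manual_exclusion: np.ndarray | None = None,
    pixel_pitch_mm: float = DEFAULT_PITCH_MM,
) -> RegionOfInterest:
    """ROI = intersection of registration overlaps minus the exclusion mask.

    This is the measurement region in which all downstream densities are
    computed; the optional exclusion mask removes manually flagged iris
    background.
    """
    if not results:
        raise ValueError("at least one RegistrationResult is required")
    for r in results:
        if not r.converged:
            raise ValueError(
                "cannot build an ROI from a non-converged registration; "
                "re-register with a different model/metric"
            )
    mask = results[0].overlap_mask.copy()
    for r in results[1:]:
        if r.overlap_mask.shape != mask.shape:
            raise ValueError("overlap masks must share the fixed-image frame")
        mask &= r.overlap_mask
    if manual_exclusion is not None:
        mask &= ~np.asarray(manual_exclusion, dtype=bool)
    if not mask.any():
        raise ValueError(
            "empty ROI: registration overlaps do not intersect; re-register"
        )
    return RegionOfInterest(mask, pixel_pitch_mm)
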