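"""Synthetic corneal-angiography scene generator.

Ground truth is a vascular tree of straight capsule segments (line segments
with a radius) sprouting from the limbus at one image border and growing over
8 weekly time points, mimicking suture-induced corneal neovascularization in
the superior quadrant. Each scene can be rendered as OCTA, ICGA or SLP with
phenomenological degradations: speckle and additive noise, OCTA horizontal
motion lines, ICGA dye-leakage halos and bright iris-vessel background bands,
SLP dark vessels on a textured background, and contrast attenuation of
small-caliber vessels for the dye/photographic modalities. Repeated scans of
the same scene (taken minutes apart in the emulated study) differ only in
noise realization plus an optional sub-pixel positioning jitter.

All randomness flows through explicitly seeded ``numpy.random.Generator``
instances; identical seeds and parameters reproduce trees, masks and renders
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .images import BinaryVesselMap, RasterImage, save_image, save_mask

CaliberClass = Literal["large", "small"]


@dataclass(frozen=True)
class VesselSegment:
    """A straight vessel segment: a capsule of given half-width (radius)."""

    start_point: tuple[float, float]  # (x, y) in mm
    end_point: tuple[float, float]
    radius: float  # half-width, mm
    appearance_week: int
    caliber_class: CaliberClass = "large"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("segment radius must be positive")
        if self.appearance_week < 1:
            raise ValueError("appearance_week must be >= 1")
        if self.start_point == self.end_point:
            raise ValueError("degenerate segment: start_point == end_point")


@dataclass
class VesselTree:
    """A connected set of segments sprouting from one image border."""

    segments: list[VesselSegment]
    limbus_edge: str = "top"
    field_width_mm: float = 3.0
    rng_seed: int = 0

    def segments_at(
        self, week: int, caliber_filter: CaliberClass | None = None
    ) -> list[VesselSegment]:
        out = [s for s in self.segments if s.appearance_week <= week]
        if caliber_filter is not None:
            out = [s for s in out if s.caliber_class == caliber_filter]
        return out


@dataclass(frozen=True)
class GrowthParams:
    """Weekly-growth parameters for the capsule-tree model.

    Defaults model the emulated study: vessels sprout from the limbus in week
    1 and the network accretes segments weekly for 8 weeks, reaching roughly
    15% area density in a 3 mm field by week 3 and above 30% by week 8, with
    a few percentage points of new density per week across the follow-up.
    """

    weeks: int = 8
    branches_per_week: int = 14
    roots: int = 6  # limbal sprouts in week 1
    segment_length_mm: tuple[float, float] = (0.8, 1.4)
    radius_mm: tuple[float, float] = (0.02, 0.04)
    small_fraction: float = 0.3
    #: segments classed "small" get a radius below this ICGA/SLP detectability
    #: limit (~2 px at the default 9.87 um pitch)
    small_radius_mm: tuple[float, float] = (0.008, 0.018)
    branch_angle_deg: tuple[float, float] = (30.0, 70.0)
    root_spread: float = 0.9  # fraction of the edge over which roots spread

    def __post_init__(self) -> None:
        if self.weeks < 0:
            raise ValueError("weeks must be >= 0")
        if self.weeks > 0 and self.branches_per_week < 1:
            raise ValueError("branches_per_week must be >= 1")
        if self.weeks > 0 and self.roots < 1:
            raise ValueError("roots must be >= 1")
        if not 0.0 <= self.small_fraction <= 1.0:
            raise ValueError("small_fraction must lie in [0, 1]")


_EDGE_SETUP = {
    # edge -> (root point builder, inward growth direction)
    "top": (lambda u, w: (u * w, 0.0), (0.0, 1.0)),
    "bottom": (lambda u, w: (u * w, w), (0.0, -1.0)),
    "left": (lambda u, w: (0.0, u * w), (1.0, 0.0)),
    "right": (lambda u, w: (w, u * w), (-1.0, 0.0)),
}


def _rotate(v: tuple[float, float], deg: float) -> tuple[float, float]:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return (c * v[0] - s * v[1], s * v[0] + c * v[1])


def generate_tree(
    seed: int,
    params: GrowthParams | None = None,
    field_width_mm: float = 3.0,
    limbus_edge: str = "top",
) -> VesselTree:
    """Grow a connected capsule tree over weekly time points.

    Week 1 adds root segments on the limbus edge growing inward; every later
    week attaches new branches to points on existing segments, rotated by a
    random branching angle from the parent direction. Identical
    ``seed``/``params`` yield byte-identical trees.
    """
    params = params or GrowthParams()
    if field_width_mm <= 0:
        raise ValueError("field_width_mm must be positive")
    if limbus_edge not in _EDGE_SETUP:
        raise ValueError(f"limbus_edge must be one of {sorted(_EDGE_SETUP)}")
    rng = np.random.default_rng(seed)
    w = field_width_mm
    root_point, inward = _EDGE_SETUP[limbus_edge]
    segments: list[VesselSegment] = []
    directions: list[tuple[float, float]] = []

    def _clip_end(start, direction, length):
        """Shorten the segment so its end stays inside the field."""
        t = 1.0
        for p, d in ((start[0], direction[0]), (start[1], direction[1])):
            if d > 0:
                t = min(t, (w - p) / (d * length)) if d * length > w - p else t
            elif d < 0:
                t = min(t, (0.0 - p) / (d * length)) if d * length < -p else t
        t = max(t, 0.0)
        return (start[0] + direction[0] * length * t, start[1] + direction[1] * length * t)

    for week in range(1, params.weeks + 1):
        n_new = params.roots if week == 1 else params.branches_per_week
        for _ in range(n_new):
            small = rng.random() < params.small_fraction
            radius = (
                rng.uniform(*params.small_radius_mm)
                if small
                else rng.uniform(*params.radius_mm)
            )
            length = rng.uniform(*params.segment_length_mm)
            if week == 1 or not segments:
                u = 0.5 + params.root_spread * (rng.random() - 0.5)
                start = root_point(u, w)
                direction = _rotate(inward, rng.uniform(-30.0, 30.0))
            else:
                parent_idx = int(rng.integers(len(segments)))
                parent = segments[parent_idx]
                t = rng.uniform(0.4, 1.0)  # attach toward the distal end
                start = (
                    parent.start_point[0]
                    + t * (parent.end_point[0] - parent.start_point[0]),
                    parent.start_point[1]
                    + t * (parent.end_point[1] - parent.start_point[1]),
                )
                angle = rng.uniform(*params.branch_angle_deg)
                flip = rng.random() < 0.5
                # branch to whichever side keeps more of the segment in-field
                candidates = []
                for sign in ((1, -1) if flip else (-1, 1)):
                    d = _rotate(directions[parent_idx], sign * angle)
                    e = _clip_end(start, d, length)
                    extent = np.hypot(e[0] - start[0], e[1] - start[1])
                    candidates.append((extent, d))
                direction = max(candidates, key=lambda c: c[0])[1]
                if not small:
                    radius = min(radius, parent.radius)
            end = _clip_end(start, direction, length)
            if np.hypot(end[0] - start[0], end[1] - start[1]) < 1e-6:
                continue  # fully clipped at the border; skip
            segments.append(
                VesselSegment(
                    start_point=start,
                    end_point=end,
                    radius=radius,
                    appearance_week=week,
                    caliber_class="small" if small else "large",
                )
            )
            directions.append(direction)
    return VesselTree(
        segments=segments,
        limbus_edge=limbus_edge,
        field_width_mm=field_width_mm,
        rng_seed=seed,
    )


def rasterize_truth(
    tree: VesselTree,
    week: int,
    image_size_px: tuple[int, int] = (304, 304),
    caliber_filter: CaliberClass | None = None,
) -> BinaryVesselMap:
    """Rasterize the ground-truth mask for a given week.

    A pixel is vessel iff its center lies within ``radius`` of any segment
    whose ``appearance_week`` is at or before ``week`` (and, optionally, whose
    caliber class matches ``caliber_filter``). Pixel (r, c) has its center at
    ``((c + 0.5) * pitch, (r + 0.5) * pitch)`` mm so the grid tiles the field
    symmetrically.
    """
    if not 1 <= week <= 8:
        raise ValueError(f"week must be in 1..8, got {week}")
    rows, cols = image_size_px
    pitch = tree.field_width_mm / cols
    mask = np.zeros((rows, cols), dtype=bool)
    segs = tree.segments_at(week, caliber_filter)
    if not segs:
        return BinaryVesselMap(mask, week=week, provenance={"source": "truth"})
    xs = (np.arange(cols) + 0.5) * pitch
    ys = (np.arange(rows) + 0.5) * pitch
    X, Y = np.meshgrid(xs, ys)
    for s in segs:
        ax, ay = s.start_point
        bx, by = s.end_point
        dx, dy = bx - ax, by - ay
        L2 = dx * dx + dy * dy
        t = np.clip(((X - ax) * dx + (Y - ay) * dy) / L2, 0.0, 1.0)
        d2 = (X - (ax + t * dx)) ** 2 + (Y - (ay + t * dy)) ** 2
        mask |= d2 <= s.radius**2
    return BinaryVesselMap(
        mask,
        week=week,
        provenance={"source": "truth", "seed": tree.rng_seed, "caliber": caliber_filter},
    )


@dataclass(frozen=True)
class ModalityRenderConfig:
    """Rendering parameters for one imaging modality.

    ``vessel_polarity`` is "bright" for the angiographic modalities (flow /
    dye signal on dark background) and "dark" for slit-lamp photographs
    (blood vessels absorb light on a bright textured cornea).
    ``contrast_floor_small_vessels`` attenuates the contrast of
    small-caliber segments toward background (1 = invisible), emulating the
    detectability limit of ICGA and SLP for vessels near 10-20 um caliber.
    """

    modality: str
    image_size_px: tuple[int, int] = (304, 304)
    background_level: float = 0.15
    vessel_contrast: float = 0.5
    vessel_polarity: Literal["bright", "dark"] = "bright"
    speckle_sigma: float = 0.0
    gaussian_sigma: float = 0.0
    motion_lines: int = 0
    motion_line_gain: float = 0.25
    iris_bands: int = 0
    iris_band_intensity: float = 0.0
    leakage_halo_sigma_px: float = 0.0
    leakage_gain: float = 0.0
    background_texture_sigma: float = 0.0
    contrast_floor_small_vessels: float = 0.0

    def __post_init__(self) -> None:
        if self.modality not in ("OCTA", "ICGA", "SLP"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if min(self.image_size_px) < 1:
            raise ValueError("image_size_px must be positive")
        if not 0.0 <= self.contrast_floor_small_vessels <= 1.0:
            raise ValueError("contrast_floor_small_vessels must lie in [0, 1]")
        expected = "dark" if self.modality == "SLP" else "bright"
        if self.vessel_polarity != expected:
            raise ValueError(
                f"{self.modality} renders must use {expected!r} vessel polarity"
            )

    @classmethod
    def for_modality(cls, modality: str, **overrides) -> "ModalityRenderConfig":
        """Default degradation model per modality."""
        base = {
            "OCTA": dict(
                background_level=0.12,
                vessel_contrast=0.55,
                vessel_polarity="bright",
                speckle_sigma=0.12,
                gaussian_sigma=0.02,
                motion_lines=2,
                motion_line_gain=0.25,
                contrast_floor_small_vessels=0.0,
            ),
            "ICGA": dict(
                background_level=0.2,
                vessel_contrast=0.5,
                vessel_polarity="bright",
                speckle_sigma=0.05,
                gaussian_sigma=0.03,
                iris_bands=2,
                iris_band_intensity=0.3,
                leakage_halo_sigma_px=6.0,
                leakage_gain=0.12,
                contrast_floor_small_vessels=0.9,
            ),
            "SLP": dict(
                background_level=0.7,
                vessel_contrast=0.35,
                vessel_polarity="dark",
                speckle_sigma=0.0,
                gaussian_sigma=0.03,
                background_texture_sigma=0.05,
                contrast_floor_small_vessels=0.9,
            ),
        }[modality]
        base.update(overrides)
        return cls(modality=modality, **base)

    @classmethod
    def clean(cls, modality: str, **overrides) -> "ModalityRenderConfig":
        """A degradation-free configuration (noiseless limit)."""
        polarity = "dark" if modality == "SLP" else "bright"
        background = 0.7 if modality == "SLP" else 0.15
        base = dict(
            background_level=background,
            vessel_contrast=0.5,
            vessel_polarity=polarity,
        )
        base.update(overrides)
        return cls(modality=modality, **base)


def render_modality(
    tree: VesselTree,
    week: int,
    cfg: ModalityRenderConfig,
    noise_seed: int = 0,
    jitter_px: tuple[float, float] = (0.0, 0.0),
) -> RasterImage:
    """Render the scene at ``week`` as one modality-specific image.

    Two calls with the same scene and different ``noise_seed`` (and optional
    sub-pixel ``jitter_px`` = (drow, dcol)) model the study's repeated scans
    taken 1-2 minutes apart.
    """
    rng = np.random.default_rng(noise_seed)
    rows, cols = cfg.image_size_px
    pitch = tree.field_width_mm / cols
    large = rasterize_truth(tree, week, cfg.image_size_px, "large").mask
    small = rasterize_truth(tree, week, cfg.image_size_px, "small").mask

    signal = large.astype(np.float64)
    signal += (1.0 - cfg.contrast_floor_small_vessels) * (small & ~large)
    sign = 1.0 if cfg.vessel_polarity == "bright" else -1.0
    img = cfg.background_level + sign * cfg.vessel_contrast * signal

    if cfg.background_texture_sigma > 0:
        texture = ndimage.gaussian_filter(rng.standard_normal((rows, cols)), 8.0)
        texture /= max(texture.std(), 1e-12)
        img += cfg.background_texture_sigma * texture
    if cfg.iris_bands > 0:
        # bright horizontal iris-vessel bands in the lower (scleral) half
        ys = np.arange(rows)[:, None]
        for _ in range(cfg.iris_bands):
            center = rng.uniform(0.55 * rows, 0.95 * rows)
            width = rng.uniform(4.0, 9.0)
            img += cfg.iris_band_intensity * np.exp(
                -0.5 * ((ys - center) / width) ** 2
            )
    if cfg.leakage_gain > 0 and cfg.leakage_halo_sigma_px > 0:
        # dye leakage intensifies over the follow-up weeks
        halo = ndimage.gaussian_filter(
            (large | small).astype(float), cfg.leakage_halo_sigma_px
        )
        img += cfg.leakage_gain * min(week / 4.0, 1.0) * halo
    if cfg.motion_lines > 0:
        line_rows = rng.integers(0, rows, size=cfg.motion_lines)
        for r in line_rows:
            img[r, :] += cfg.motion_line_gain
    if cfg.speckle_sigma > 0:
        img = img * (1.0 + cfg.speckle_sigma * rng.standard_normal((rows, cols)))
    if cfg.gaussian_sigma > 0:
        img = img + cfg.gaussian_sigma * rng.standard_normal((rows, cols))
    if jitter_px != (0.0, 0.0):
        img = ndimage.shift(img, jitter_px, order=1, mode="nearest")
    img = np.clip(img, 0.0, 1.0)
    return RasterImage(
        img, pixel_pitch_mm=pitch, modality=cfg.modality, week=week
    )


def make_study(
    seed: int,
    weeks: Sequence[int],
    modalities: Sequence[str],
    out_dir: str | Path,
    repeats: int = 2,
    params: GrowthParams | None = None,
    field_width_mm: float = 3.0,
    image_size_px: tuple[int, int] = (304, 304),
    jitter_px: float = 0.5,
) -> pd.DataFrame:
    """Render and write a full longitudinal study to ``out_dir``.

    Writes one PNG per (week, modality, repeat), one truth-mask PNG per week,
    and a ``manifest.csv`` with columns
    ``file,week,modality,repeat,pixel_pitch_mm,seed``. Repeat scans reuse the
    scene with a fresh noise seed and a ``jitter_px`` sub-pixel shift.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out_dir}: {exc}") from exc
    tree = generate_tree(seed, params, field_width_mm)
    pitch = field_width_mm / image_size_px[1]
    seed_rng = np.random.default_rng(seed)
    rows = []
    for week in weeks:
        truth = rasterize_truth(tree, week, image_size_px)
        save_mask(out_dir / f"truth_week{week}.png", truth)
        for modality in modalities:
            cfg = ModalityRenderConfig.for_modality(
                modality, image_size_px=image_size_px
            )
            for rep in range(1, repeats + 1):
                noise_seed = int(seed_rng.integers(0, 2**31 - 1))
                jit = (0.0, 0.0) if rep == 1 else (jitter_px, jitter_px)
                img = render_modality(tree, week, cfg, noise_seed, jitter_px=jit)
                fname = f"{modality.lower()}_week{week}_rep{rep}.png"
                save_image(out_dir / fname, img)
                rows.append(
                    dict(
                        file=fname,
                        week=week,
                        modality=modality,
                        repeat=rep,
                        pixel_pitch_mm=pitch,
                        seed=seed,
                    )
                )
    manifest = pd.DataFrame(
        rows, columns=["file", "week", "modality", "repeat", "pixel_pitch_mm", "seed"]
    )
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
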