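"""Trap (ROI) detection by normalized cross-correlation and per-trap
time-series extraction.

Coordinates are 0-based, row-major, origin top-left. Boxes are half-open
``[r, r+h) x [c, c+w)``. ROI positions are frozen at frame 0: traps are
stationary in the chip, so no per-frame registration is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import match_template


class DegenerateTemplateError(ValueError):
    """Raised for a flat (zero-variance) template."""


class InvalidRoiError(ValueError):
    """Raised when an ROI box falls outside the field of view."""


@dataclass
class TrapMovie:
    """One trap's image time series, shape (T, H, W, C)."""

    frames: np.ndarray
    frame_interval_min: float
    channel_names: list[str] = field(default_factory=lambda: ["brightfield"])
    roi_id: str = "roi"
    origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim == 3:
            self.frames = self.frames[..., None]
        if self.frames.ndim != 4 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a T x H x W x C array with T >= 1")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.frames.shape


@dataclass
class RoiSet:
    """Detected trap boxes: centers plus a common box size."""

    centers: list[tuple[int, int]]
    box_size: tuple[int, int]
    template_id: str = "template"
    scores: list[float] = field(default_factory=list)

    def top_left(self, k: int) -> tuple[int, int]:
        r, c = self.centers[k]
        h, w = self.box_size
        return r - h // 2, c - w // 2


def detect_trap_rois(
    fov_image: np.ndarray,
    template: np.ndarray,
    *,
    threshold: float = 0.5,
    min_distance: int | None = None,
    max_count: int | None = None,
) -> RoiSet:
    """Locate trap centers as local maxima of normalized cross-correlation.

    Maxima scoring >= ``threshold`` are kept greedily in descending score
    order subject to a ``min_distance`` (Chebyshev) exclusion radius
    (non-maximum suppression). Deterministic.
    """
    fov_image = np.asarray(fov_image, dtype=np.float64)
    template = np.asarray(template, dtype=np.float64)
    if fov_image.ndim != 2 or template.ndim != 2:
        raise ValueError("fov_image and template must be 2-D")
    if template.shape[0] >= fov_image.shape[0] or template.shape[1] >= fov_image.shape[1]:
        raise ValueError("template must be strictly smaller than the field of view")
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    if template.std() == 0:
        raise DegenerateTemplateError("template has zero variance")
    if min_distance is None:
        min_distance = template.shape[1]

    ncc = match_template(fov_image, template, pad_input=False)
    th, tw = template.shape
    flat = ncc.ravel()
    order = np.argsort(flat, kind="stable")[::-1]
    order = order[flat[order] >= threshold]
    kept: list[tuple[int, int]] = []
    scores: list[float] = []
    for idx in order:
        r, c = divmod(int(idx), ncc.shape[1])
        center = (r + th // 2, c + tw // 2)
        if any(
            max(abs(center[0] - kr), abs(center[1] - kc)) < min_distance
            for kr, kc in kept
        ):
            continue
        kept.append(center)
        scores.append(float(flat[idx]))
        if max_count is not None and len(kept) >= max_count:
            break
    return RoiSet(centers=kept, box_size=(th, tw), scores=scores)


def extract_roi_timeseries(
    fov_stack: np.ndarray,
    rois: RoiSet,
    *,
    frame_interval_min: float = 5.0,
    channel_names: list[str] | None = None,
) -> list[TrapMovie]:
    """Crop one fixed box per ROI out of every frame of the FOV stack."""
    fov_stack = np.asarray(fov_stack, dtype=np.float64)
    if fov_stack.ndim == 3:
        fov_stack = fov_stack[..., None]
    _, fh, fw, _ = fov_stack.shape
    h, w = rois.box_size
    movies = []
    for k in range(len(rois.centers)):
        r0, c0 = rois.top_left(k)
        if r0 < 0 or c0 < 0 or r0 + h > fh or c0 + w > fw:
            raise InvalidRoiError(f"ROI {k} box [{r0}:{r0+h}, {c0}:{c0+w}] out of bounds")
        crop = fov_stack[:, r0 : r0 + h, c0 : c0 + w, :].copy()
        movies.append(
            TrapMovie(
                frames=crop,
                frame_interval_min=frame_interval_min,
                channel_names=list(channel_names or ["brightfield"]),
                roi_id=f"roi{k:04d}",
                origin=(r0, c0),
            )
        )
    return movies


def compose_zstack_rgb(planes: list[np.ndarray]) -> np.ndarray:
    """Stack 1-3 z-planes into a 3-channel image (channel k = plane k).

    With fewer than 3 planes the last plane is replicated to fill.
    """
    if not 1 <= len(planes) <= 3:
        raise ValueError("expected 1 to 3 planes")
    planes = [np.asarray(p, dtype=np.float64) for p in planes]
    shape = planes[0].shape
    if any(p.shape != shape for p in planes):
        raise ValueError("all planes must share the same shape")
    while len(planes) < 3:
        planes.append(planes[-1])
    return np.stack(planes, axis=-1)
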