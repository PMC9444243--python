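"""Rendering of cell histories into trap image sequences and masks.

Appearance is a deliberately simple surrogate: flat-intensity disks for
cell bodies between trap walls, a contrast inversion plus speckle for
dead cells, near-total disk coverage for clogged traps, and a nuclear
blob in the fluorescence channel whose total intensity rises after the
SEP. Noise is additive Gaussian plus a signal-dependent term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk as draw_disk

from divtrap.roi import TrapMovie
from divtrap.trapsynth.history import CellHistory


@dataclass
class RenderParams:
    height: int = 60
    width: int = 60
    mother_radius: float = 8.0  # nominal; actual radius drawn per cell
    mother_radius_range: tuple[float, float] = (6.5, 9.5)
    mother_growth_per_gen: float = 0.25
    mother_radius_max: float = 11.0
    bud_max_radius: float = 6.0
    daughter_radius: float = 3.5
    max_daughters: int = 2
    bg_level: float = 0.25
    cell_level: float = 0.85
    bud_level_frac: float = 0.9  # bud intensity relative to the mother
    dead_level: float = 0.10
    wall_level: float = 0.60
    wall_width: int = 2
    noise_sigma: float = 0.03
    signal_noise_frac: float = 0.05
    with_fluorescence: bool = True
    fluo_bg: float = 10.0
    nucleus_radius: float = 2.5
    nucleus_base_total: float = 200.0
    nucleus_post_sep_rise: float = 2.0  # per frame after the SEP

    def validate(self) -> None:
        if self.height < 32 or self.width < 32:
            raise ValueError("trap image must be at least 32x32")
        need = 2 * (max(self.mother_radius, self.mother_radius_max) + self.bud_max_radius) + 4
        if min(self.height, self.width) < need:
            raise ValueError("image too small for the trap geometry")


@dataclass
class SynthScene:
    movie: TrapMovie
    truth: CellHistory
    masks: np.ndarray  # (T, H, W) int: 0 bg, 1 mother, 2 other
    nucleus_masks: np.ndarray  # (T, H, W) int: 0 bg, 1 nucleus
    nuclear_intensity_trace: np.ndarray  # (T,)
    render_params: RenderParams = field(default_factory=RenderParams)

    def __post_init__(self) -> None:
        t, h, w, _ = self.movie.frames.shape
        if self.masks.shape != (t, h, w) or self.nucleus_masks.shape != (t, h, w):
            raise ValueError("masks and movie must share T, H, W")


def _disk(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_disk(center, radius, shape=shape)
    mask[rr, cc] = True
    return mask


def trap_template(params: RenderParams | None = None) -> np.ndarray:
    """The empty-trap appearance: two vertical walls on flat background."""
    params = params or RenderParams()
    h, w = params.height, params.width
    img = np.full((h, w), params.bg_level)
    ww = params.wall_width
    r0, r1 = h // 6, h - h // 6
    img[r0:r1, 3 : 3 + ww] = params.wall_level
    img[r0:r1, w - 3 - ww : w - 3] = params.wall_level
    return img


def _cycle_spans(history: CellHistory, t_total: int) -> list[tuple[int, int]]:
    bf = history.budding_frames
    spans = []
    for k, b in enumerate(bf):
        end = bf[k + 1] if k + 1 < len(bf) else (history.death_frame or t_total)
        spans.append((b, min(end, t_total)))
    return spans


def render_trap_movie(
    history: CellHistory, render_params: RenderParams | None = None, seed: int = 0
) -> SynthScene:
    """Render a CellHistory into brightfield (+ fluorescence) frames with masks."""
    params = render_params or RenderParams()
    params.validate()
    rng = np.random.default_rng(seed)
    labels = history.per_frame_labels
    t_total = len(labels)
    h, w = params.height, params.width
    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    base = trap_template(params)

    spans = _cycle_spans(history, t_total)
    cycle_of_frame: dict[int, tuple[int, int, int]] = {}
    bud_angles = []
    daughters_per_cycle = []
    # mother size varies per cell and grows with replicative age
    r0 = rng.uniform(*params.mother_radius_range)
    r_cap = params.mother_radius_max
    min_rad = r_cap + params.bud_max_radius + params.daughter_radius
    for k, (b, e) in enumerate(spans):
        bud_angles.append(rng.uniform(0, 2 * np.pi))
        nd = int(rng.integers(0, params.max_daughters + 1))
        dpos = []
        # daughters stay clearly peripheral so they cannot be mistaken
        # for the mother's bud
        for _ in range(nd):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(max(min_rad, 0.85 * min(h, w) / 2.0), min(h, w) / 2.0)
            dpos.append((center[0] + rad * np.sin(ang), center[1] + rad * np.cos(ang)))
        daughters_per_cycle.append(dpos)
        for t in range(b, e):
            cycle_of_frame[t] = (k, b, e)

    budding = np.asarray(history.budding_frames)

    def mother_radius_at(t: int) -> float:
        gens = int(np.searchsorted(budding, t, side="right"))
        return min(r0 + params.mother_growth_per_gen * gens, r_cap)

    frames = np.empty((t_total, h, w, 2 if params.with_fluorescence else 1))
    masks = np.zeros((t_total, h, w), dtype=int)
    nuc_masks = np.zeros((t_total, h, w), dtype=int)
    nuc_trace = np.zeros(t_total)

    # frozen clog layout so consecutive clog frames look alike
    clog_centers: list[tuple[float, float]] | None = None

    for t in range(t_total):
        lab = labels[t]
        img = base.copy()
        mask = np.zeros((h, w), dtype=int)
        mother_present = lab not in ("empty",)

        if lab == "empty":
            pass
        elif lab == "clog":
            if clog_centers is None:
                clog_centers = []
                cover = np.zeros((h, w), dtype=bool)
                target = 0.55 * h * w
                while cover.sum() < target:
                    c = (rng.uniform(0, h), rng.uniform(0, w))
                    clog_centers.append(c)
                    cover |= _disk((h, w), c, 7.0)
            mother = _disk((h, w), center, mother_radius_at(t))
            img[mother] = params.cell_level
            mask[mother] = 1
            for c in clog_centers:
                d = _disk((h, w), c, 7.0)
                d &= ~mother
                img[d] = params.cell_level * 0.95
                mask[d] = 2
        else:
            r_mother = mother_radius_at(t)
            mother = _disk((h, w), center, r_mother)
            if lab == "dead":
                img[mother] = params.dead_level
                speckle = mother & (rng.random((h, w)) < 0.3)
                img[speckle] = params.dead_level + 0.35
                mask[mother] = 1
            else:
                img[mother] = params.cell_level
                mask[mother] = 1
                if lab in ("small", "large") and t in cycle_of_frame:
                    k, b, e = cycle_of_frame[t]
                    phase = (t - b + 1) / max(e - b, 1)
                    # area grows through the cycle and jumps across the
                    # small/large threshold mid-cycle so the two states
                    # are visually separable at the boundary
                    if lab == "small":
                        frac = 0.35 + 0.20 * min(phase / 0.5, 1.0)
                    else:
                        frac = 0.85 + 0.15 * min(max(phase - 0.5, 0.0) / 0.5, 1.0)
                    r_bud = params.bud_max_radius * frac
                    ang = bud_angles[k]
                    bc = (
                        center[0] + (r_mother + r_bud) * np.sin(ang),
                        center[1] + (r_mother + r_bud) * np.cos(ang),
                    )
                    bud = _disk((h, w), bc, r_bud)
                    bud &= ~mother
                    img[bud] = params.cell_level * params.bud_level_frac
                    mask[bud] = 2
                if t in cycle_of_frame:
                    for dc in daughters_per_cycle[cycle_of_frame[t][0]]:
                        d = _disk((h, w), dc, params.daughter_radius)
                        d &= ~(mask > 0)
                        img[d] = params.cell_level * 0.8
                        mask[d] = 2

        bf_noisy = img
        if params.noise_sigma > 0 or params.signal_noise_frac > 0:
            bf_noisy = (
                img
                + rng.normal(0, params.noise_sigma, size=img.shape)
                + rng.normal(0, 1.0, size=img.shape)
                * params.signal_noise_frac
                * np.sqrt(np.clip(img, 0, None))
            )
        frames[t, :, :, 0] = bf_noisy
        masks[t] = mask

        if params.with_fluorescence:
            fimg = np.full((h, w), params.fluo_bg)
            if mother_present and lab != "clog":
                total = params.nucleus_base_total
                if history.sep_frame is not None and t >= history.sep_frame:
                    total += params.nucleus_post_sep_rise * (t - history.sep_frame)
                nuc = _disk((h, w), (center[0] + 1.5, center[1] - 1.5), params.nucleus_radius)
                npix = nuc.sum()
                if npix:
                    fimg[nuc] += total / npix
                    nuc_masks[t][nuc] = 1
                    nuc_trace[t] = total
            if params.noise_sigma > 0 or params.signal_noise_frac > 0:
                fimg = (
                    fimg
                    + rng.normal(0, params.noise_sigma, size=fimg.shape)
                    + rng.normal(0, 1.0, size=fimg.shape)
                    * params.signal_noise_frac
                    * np.sqrt(np.clip(fimg, 0, None))
                )
            frames[t, :, :, 1] = fimg

    movie = TrapMovie(
        frames=frames,
        frame_interval_min=history.params.frame_interval_min,
        channel_names=["brightfield", "gfp"] if params.with_fluorescence else ["brightfield"],
        roi_id="synth",
    )
    return SynthScene(
        movie=movie,
        truth=history,
        masks=masks,
        nucleus_masks=nuc_masks,
        nuclear_intensity_trace=nuc_trace,
        render_params=params,
    )


def render_field_of_view(
    n_rows: int,
    n_cols: int,
    *,
    spacing: int = 70,
    jitter_sd: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    margin: int = 40,
    render_params: RenderParams | None = None,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """A field of view with identical trap templates on a jittered grid.

    Returns the image and the list of true template centers (row, col).
    """
    params = render_params or RenderParams()
    template = trap_template(params)
    th, tw = template.shape
    if n_rows and n_cols and spacing < max(th, tw):
        raise ValueError("spacing smaller than the trap template")
    rng = np.random.default_rng(seed)
    height = 2 * margin + max(n_rows - 1, 0) * spacing + (th if n_rows else 0)
    width = 2 * margin + max(n_cols - 1, 0) * spacing + (tw if n_cols else 0)
    img = np.full((max(height, 1), max(width, 1)), params.bg_level)
    centers: list[tuple[int, int]] = []
    for i in range(n_rows):
        for j in range(n_cols):
            r = margin + i * spacing + (0 if jitter_sd == 0 else round(rng.normal(0, jitter_sd)))
            c = margin + j * spacing + (0 if jitter_sd == 0 else round(rng.normal(0, jitter_sd)))
            img[r : r + th, c : c + tw] = template
            centers.append((r + th // 2, c + tw // 2))
    if noise_sigma > 0:
        img = img + rng.normal(0, noise_sigma, size=img.shape)
    return img, centers
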