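"""Geometric urine-image phantoms with known ground truth.

Renders the standardized acquisition scene as a flat geometric phantom: a
24-patch colour reference card, a liquid column at a prescribed CIELAB
colour, and a foam band above the liquid whose height follows
``h(t) = h0 * 2^(-t / T1/2)`` across the four capture times, populated at
t = 30 s with non-overlapping bubble disks drawn from a two-component
(micro/macro) log-normal diameter mixture.  A 3x3 colour cast simulates the
acquisition illuminant; the in-frame card allows the extraction pipeline to
undo it.  Ground-truth masks, bubble tables and generative parameters ride
along with the frames, so every extraction operator can be scored against
truth.  No photorealism is attempted — the phantoms exercise the operators'
contracts, not their robustness to real-world imaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.color import lab2rgb
from skimage.draw import disk as draw_disk

from .physicalomics import ImageSeries, Region

__all__ = [
    "ImageSpec",
    "COLORCHECKER_SRGB",
    "sample_bubble_diameters",
    "render_urine_series",
]

#: sRGB values of the classic 24-patch colour reference card
COLORCHECKER_SRGB = np.array(
    [
        (115, 82, 68), (194, 150, 130), (98, 122, 157), (87, 108, 67),
        (133, 128, 177), (103, 189, 170), (214, 126, 44), (80, 91, 166),
        (193, 90, 99), (94, 60, 108), (157, 188, 64), (224, 163, 46),
        (56, 61, 150), (70, 148, 73), (175, 54, 60), (231, 199, 31),
        (187, 86, 149), (8, 133, 161), (243, 243, 242), (200, 200, 200),
        (160, 160, 160), (122, 122, 121), (85, 85, 85), (52, 52, 52),
    ],
    dtype=float,
)

_BG = np.array([25.0, 25.0, 28.0])
_FOAM_MATRIX = np.array([235.0, 235.0, 235.0])
_BUBBLE_INTERIOR = np.array([190.0, 190.0, 195.0])
_BUBBLE_RIM = np.array([90.0, 90.0, 95.0])


@dataclass
class ImageSpec:
    """Generative description of one rendered urine series."""

    lab_color: tuple[float, float, float] = (80.0, 0.0, 35.0)
    foam_half_life_s: float = 10.0
    initial_foam_height_mm: float = 10.0
    bubble_diameters_mm: np.ndarray = field(default_factory=lambda: np.array([]))
    frame_times_s: tuple[float, ...] = (0.0, 30.0, 60.0, 120.0)
    pixel_scale_mm: float = 0.05
    cast: np.ndarray = field(default_factory=lambda: np.eye(3))
    card_colors: np.ndarray = field(default_factory=lambda: COLORCHECKER_SRGB.copy())
    liquid_height_mm: float = 25.0
    headspace_mm: float | None = None  # auto: foam + margin; explicit may error
    noise_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.foam_half_life_s <= 0:
            raise ValueError("foam_half_life_s must be > 0")
        if self.pixel_scale_mm <= 0:
            raise ValueError("pixel_scale_mm must be > 0")
        if self.initial_foam_height_mm <= 0:
            raise ValueError("initial foam height must be > 0")
        times = self.frame_times_s
        if times[0] != 0 or any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must start at 0 and strictly increase")
        self.cast = np.asarray(self.cast, float)
        if self.cast.shape != (3, 3):
            raise ValueError("cast must be a 3x3 matrix")


def sample_bubble_diameters(
    n: int, micro_weight: float, rng: np.random.Generator
) -> np.ndarray:
    """Two-component log-normal diameter mixture (mm).

    Micro component: median 0.30 mm, truncated to [0.18, 0.44]; macro:
    median 1.1 mm, truncated to [0.60, 2.20].  The truncation keeps every
    bubble unambiguously on one side of the 0.5 mm classification cutoff at
    the default 0.05 mm/px raster resolution.  ``micro_weight`` is the
    probability of the micro component (higher in DKD-like samples).
    """
    if not 0 <= micro_weight <= 1:
        raise ValueError("micro_weight must lie in [0, 1]")
    is_micro = rng.random(n) < micro_weight
    d = np.where(
        is_micro,
        np.clip(0.30 * np.exp(0.25 * rng.standard_normal(n)), 0.18, 0.44),
        np.clip(1.10 * np.exp(0.30 * rng.standard_normal(n)), 0.60, 2.20),
    )
    return d


def _foam_height_px(spec: ImageSpec, t: float) -> int:
    h_mm = spec.initial_foam_height_mm * 2.0 ** (-t / spec.foam_half_life_s)
    return int(np.rint(h_mm / spec.pixel_scale_mm))


def render_urine_series(spec: ImageSpec) -> ImageSeries:
    """Render one frame per capture time plus ground-truth masks.

    Raises if an explicit headspace cannot contain the initial foam band.
    """
    s = spec.pixel_scale_mm
    rng = np.random.default_rng(spec.seed)

    headspace_mm = (
        spec.initial_foam_height_mm + 4.0 if spec.headspace_mm is None else spec.headspace_mm
    )
    if spec.initial_foam_height_mm > headspace_mm:
        raise ValueError("foam band taller than the available headspace/frame")

    def px(mm: float) -> int:
        return int(np.rint(mm / s))

    margin = px(3.0)
    cuv_x0, cuv_x1 = px(3.0), px(17.0)
    head_px = px(headspace_mm)
    liq_px = px(spec.liquid_height_mm)
    liq_top = margin + head_px
    liq_bot = liq_top + liq_px
    height = liq_bot + margin

    patch_mm, gap_mm = 3.0, 1.0
    n_cols, n_rows = 4, 6
    card_x0 = px(20.0)
    card_w = px(n_cols * (patch_mm + gap_mm))
    width = card_x0 + card_w + px(2.0)

    liquid_rgb = np.clip(
        lab2rgb(np.asarray(spec.lab_color, float).reshape(1, 1, 3))[0, 0] * 255.0,
        0,
        255,
    )

    base = np.empty((height, width, 3), float)
    base[:] = _BG
    base[liq_top:liq_bot, cuv_x0:cuv_x1] = liquid_rgb

    card_patches = []
    colors = spec.card_colors
    for i in range(min(len(colors), n_rows * n_cols)):
        r, c = divmod(i, n_cols)
        y0 = margin + px(r * (patch_mm + gap_mm))
        x0 = card_x0 + px(c * (patch_mm + gap_mm))
        y1, x1 = y0 + px(patch_mm), x0 + px(patch_mm)
        base[y0:y1, x0:x1] = colors[i]
        card_patches.append((Region(y0, y1, x0, x1), colors[i].copy()))

    foam_roi = Region(margin, liq_top, cuv_x0, cuv_x1)
    liquid_roi = Region(liq_top + 2, liq_bot - 2, cuv_x0 + 2, cuv_x1 - 2)

    frames = []
    foam_masks = {}
    heights_mm = {}
    bubble_labels = np.zeros((height, width), int)
    bubble_rows = []

    for t in spec.frame_times_s:
        img = base.copy()
        h_px = _foam_height_px(spec, t)
        band_y0, band_y1 = liq_top - h_px, liq_top
        mask = np.zeros((height, width), bool)
        if h_px > 0:
            img[band_y0:band_y1, cuv_x0:cuv_x1] = _FOAM_MATRIX
            mask[band_y0:band_y1, cuv_x0:cuv_x1] = True
            if t == 30.0 and spec.bubble_diameters_mm is not None:
                placed: list[tuple[int, int, int]] = []
                label = 0
                for d_mm in np.asarray(spec.bubble_diameters_mm, float):
                    # exact float radius: aggregate rasterized area then tracks
                    # the analytic disk-area sum
                    r_f = max(d_mm / (2 * s), 2.0)
                    r_px = int(np.ceil(r_f))
                    # keep a 1-px matrix ring around every rim so bubbles stay
                    # interior to the band
                    if 2 * r_px + 4 > h_px or 2 * r_px + 4 > (cuv_x1 - cuv_x0):
                        continue  # bubble no longer fits the shrinking band
                    for _ in range(60):
                        cy = rng.integers(band_y0 + r_px + 2, band_y1 - r_px - 1)
                        cx = rng.integers(cuv_x0 + r_px + 2, cuv_x1 - r_px - 1)
                        if all(
                            (cy - py) ** 2 + (cx - px_) ** 2 > (r_px + pr + 2) ** 2
                            for py, px_, pr in placed
                        ):
                            break
                    else:
                        continue  # no room left
                    placed.append((cy, cx, r_px))
                    label += 1
                    rr, cc = draw_disk((cy, cx), r_f, shape=img.shape[:2])
                    img[rr, cc] = _BUBBLE_RIM
                    bubble_labels[rr, cc] = label
                    area_px = rr.size
                    rr_i, cc_i = draw_disk((cy, cx), r_f - 1.0, shape=img.shape[:2])
                    img[rr_i, cc_i] = _BUBBLE_INTERIOR
                    d_eq = 2.0 * np.sqrt(area_px * s**2 / np.pi)
                    bubble_rows.append(
                        {
                            "label": label,
                            "true_diameter_mm": d_mm,
                            "area_px": area_px,
                            "equiv_diameter_mm": d_eq,
                            "micro": d_eq < 0.5,
                        }
                    )
        heights_mm[t] = h_px * s
        foam_masks[t] = mask
        img = img @ spec.cast.T
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
        frames.append((float(t), np.clip(img, 0, 255).astype(np.uint8)))

    bubble_table = pd.DataFrame(bubble_rows)
    band_area = foam_masks.get(30.0, np.zeros(1)).sum()
    if band_area > 0 and len(bubble_table):
        mbi_truth = 100.0 * bubble_table.loc[bubble_table.micro, "area_px"].sum() / band_area
    else:
        mbi_truth = 0.0 if band_area > 0 else float("nan")

    return ImageSeries(
        frames=frames,
        card_patches=card_patches,
        liquid_roi=liquid_roi,
        foam_roi=foam_roi,
        pixel_scale_mm=s,
        truth={
            "t_half_s": spec.foam_half_life_s,
            "heights_mm": heights_mm,
            "foam_masks": foam_masks,
            "bubble_labels": bubble_labels,
            "bubble_table": bubble_table,
            "mbi_pct": float(mbi_truth),
            "lab_color": tuple(spec.lab_color),
        },
    )
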