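"""Procedural wood-grain image generator.

Real sawn-timber imagery is rarely shareable, so this module fabricates a
labelled stand-in: rectangular boards of heterogeneous sizes whose surface
texture is an oriented quasi-periodic grain — a sinusoid along the grain axis,
phase-warped by smoothed low-frequency noise — darkened by Poisson-scattered
knot discs.  Each species style controls base colour, grain period,
orientation, contrast, warp amplitude and knot density, so first- and
second-order image statistics are class-distinctive and tunably separable.

Everything is a pure function of (style, size, seed): one dataset-level seed
spawns per-image seeds through a counter-based scheme, so generation is
reproducible even if images are rendered out of order.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "SpeciesStyle",
    "SyntheticDatasetSpec",
    "default_styles",
    "TABLE_CLASS_COUNTS",
    "render_board",
    "generate_dataset",
]

# Published per-species sample totals for the five-species sawn-timber study
# this generator emulates (beech, ash, birch, cherry, fir).
TABLE_CLASS_COUNTS: tuple[int, ...] = (807, 797, 805, 801, 969)


@dataclass(frozen=True)
class SpeciesStyle:
    """Texture recipe for one species.

    grain_period_px   distance between grain bands, in pixels (> 1)
    grain_orientation_deg   angle of the banding axis; 0 = bands vary along x
    grain_contrast    relative amplitude of the banding, in [0, 1]
    distortion_amp    phase-warp amplitude in pixels (0 = perfectly straight grain)
    knot_density      expected knots per megapixel
    """

    class_label: str
    base_color: tuple[int, int, int]
    grain_period_px: float = 12.0
    grain_orientation_deg: float = 0.0
    grain_contrast: float = 0.35
    distortion_amp: float = 4.0
    knot_density: float = 3.0

    def __post_init__(self):
        if not all(0 <= c <= 255 for c in self.base_color):
            raise ValueError(f"base_color channels must lie in [0, 255], got {self.base_color}")
        if self.grain_period_px <= 1:
            raise ValueError(f"grain_period_px must exceed 1, got {self.grain_period_px}")
        if not 0.0 <= self.grain_contrast <= 1.0:
            raise ValueError(f"grain_contrast must lie in [0, 1], got {self.grain_contrast}")
        if self.distortion_amp < 0:
            raise ValueError("distortion_amp must be non-negative")
        if self.knot_density < 0:
            raise ValueError("knot_density must be non-negative")


def default_styles() -> list[SpeciesStyle]:
    """Five styles loosely evoking beech, ash, birch, cherry and fir boards:
    distinct base colours plus distinct grain periods/orientations."""
    return [
        SpeciesStyle("beech", (205, 160, 115), grain_period_px=14, grain_orientation_deg=0,
                     grain_contrast=0.30, distortion_amp=3.0, knot_density=2.0),
        SpeciesStyle("ash", (215, 195, 160), grain_period_px=22, grain_orientation_deg=5,
                     grain_contrast=0.40, distortion_amp=5.0, knot_density=1.0),
        SpeciesStyle("birch", (230, 210, 180), grain_period_px=9, grain_orientation_deg=-4,
                     grain_contrast=0.22, distortion_amp=2.0, knot_density=4.0),
        SpeciesStyle("cherry", (170, 100, 70), grain_period_px=17, grain_orientation_deg=8,
                     grain_contrast=0.35, distortion_amp=4.0, knot_density=3.0),
        SpeciesStyle("fir", (200, 170, 120), grain_period_px=28, grain_orientation_deg=2,
                     grain_contrast=0.50, distortion_amp=6.0, knot_density=6.0),
    ]


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Recipe for a whole labelled dataset.

    Boards are rectangular: height and width ranges are independent (the
    default aspect leans wide, like sawn boards on a conveyor) and sizes are
    drawn uniformly from the closed integer ranges.
    """

    styles: tuple[SpeciesStyle, ...] = field(default_factory=lambda: tuple(default_styles()))
    counts_per_class: tuple[int, ...] = TABLE_CLASS_COUNTS
    height_range_px: tuple[int, int] = (64, 128)
    width_range_px: tuple[int, int] = (128, 512)
    seed: int = 0

    def __post_init__(self):
        if len(self.counts_per_class) != len(self.styles):
            raise ValueError(
                f"counts_per_class has {len(self.counts_per_class)} entries "
                f"for {len(self.styles)} styles"
            )
        if any(c < 1 for c in self.counts_per_class):
            raise ValueError("all class counts must be positive")
        for name, (lo, hi) in (("height", self.height_range_px), ("width", self.width_range_px)):
            if lo > hi or lo < 1:
                raise ValueError(f"empty or invalid {name} range [{lo}, {hi}]")


def _image_seed(dataset_seed: int, index: int) -> np.random.SeedSequence:
    # counter-based spawning: independent of generation order
    return np.random.SeedSequence([dataset_seed, index])


def render_board(style: SpeciesStyle, height_px: int, width_px: int, seed) -> np.ndarray:
    """Render one (height, width, 3) uint8 board image.

    Deterministic in (style, size, seed).  With zero contrast, warp and knot
    density the output is a constant image equal to ``style.base_color``.
    """
    if height_px <= 0 or width_px <= 0:
        raise ValueError(f"image size must be positive, got {height_px}x{width_px}")
    rng = np.random.default_rng(seed)

    yy, xx = np.mgrid[0:height_px, 0:width_px].astype(np.float64)
    theta = np.deg2rad(style.grain_orientation_deg)
    # coordinate along the banding axis
    t = xx * np.cos(theta) + yy * np.sin(theta)

    shade = np.ones((height_px, width_px))
    if style.grain_contrast > 0:
        if style.distortion_amp > 0:
            noise = rng.uniform(-1.0, 1.0, size=(height_px, width_px))
            warp = gaussian_filter(noise, sigma=style.grain_period_px) * style.distortion_amp * 8.0
        else:
            warp = 0.0
        grain = np.sin(2.0 * np.pi * (t + warp) / style.grain_period_px)
        shade = shade + 0.5 * style.grain_contrast * grain

    if style.knot_density > 0:
        n_knots = rng.poisson(style.knot_density * height_px * width_px / 1e6)
        for _ in range(n_knots):
            cy = rng.uniform(0, height_px)
            cx = rng.uniform(0, width_px)
            radius = rng.uniform(0.02, 0.06) * min(height_px, width_px) + 2.0
            r2 = (yy - cy) ** 2 + (xx - cx) ** 2
            shade = shade * (1.0 - 0.65 * np.exp(-r2 / (2.0 * radius**2)))

    img = np.asarray(style.base_color, dtype=np.float64)[None, None, :] * shade[:, :, None]
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_dataset(spec: SyntheticDatasetSpec, out_dir, force: bool = False) -> Path:
    """Write one PNG per sample plus a ``manifest.csv`` (path,label,height,width).

    Per-class counts equal ``spec.counts_per_class``; sizes are uniform over
    the spec's ranges.  Refuses to overwrite an existing manifest unless
    ``force`` is set.  Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.csv"
    if manifest_path.exists() and not force:
        raise FileExistsError(
            f"{manifest_path} already exists; pass force=True (or --force) to overwrite"
        )

    rows = []
    index = 0
    for style, count in zip(spec.styles, spec.counts_per_class):
        for j in range(count):
            ss = _image_seed(spec.seed, index)
            rng = np.random.default_rng(ss)
            h = int(rng.integers(spec.height_range_px[0], spec.height_range_px[1] + 1))
            w = int(rng.integers(spec.width_range_px[0], spec.width_range_px[1] + 1))
            img = render_board(style, h, w, ss.spawn(1)[0])
            fname = f"{style.class_label}_{j:05d}.png"
            Image.fromarray(img).save(out_dir / fname)
            rows.append((fname, style.class_label, h, w))
            index += 1

    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "label", "height", "width"])
        writer.writerows(rows)
    return manifest_path
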