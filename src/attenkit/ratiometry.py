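"""Pixelwise two-channel fluorescence ratiometry.

Attenuation is measured as the ratio of attenuated GFP to an internal
IRES-driven RFP control, pixel by pixel, over sparsely transfected
cells on a dark background.  The workflow mirrors the imaging pipeline
the measurements come from: a large composite image is tiled into
equal sub-images, a uniform manually chosen background threshold masks
out non-cell pixels, the green/red ratio is averaged over masked
pixels, and replicate composites (each covering > 1,000 transfected
cells) are aggregated into a per-condition mean ± SEM.

A fully seed-deterministic synthetic scene generator provides ground
truth for closed-loop validation: elliptical "cells" with
channel-correlated intensities (green = fraction × red × noise) on a
noisy dark background.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import tifffile
from skimage.draw import ellipse

from .panel import summarize_replicates

__all__ = [
    "ChannelImagePair",
    "RatioMeasurement",
    "SyntheticScene",
    "subdivide_tiles",
    "pixel_mask",
    "pixelwise_ratio",
    "percent_of_control",
    "aggregate_replicates",
    "generate_synthetic_pair",
    "read_pair",
    "write_pair",
]

U16_MAX = 65535


@dataclass
class ChannelImagePair:
    """Matched green (GFP) and red (RFP) intensity images.

    Images are converted to float64 on construction; acquisition is
    16-bit but all arithmetic is floating point.
    """

    green: np.ndarray
    red: np.ndarray
    pixel_size: float = 2.366 / 0.948  # microns per pixel of the source optics
    metadata: dict = field(default_factory=dict)
    tile_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.green = np.asarray(self.green, dtype=np.float64)
        self.red = np.asarray(self.red, dtype=np.float64)
        if self.green.shape != self.red.shape:
            raise ValueError(
                f"channel shapes differ: {self.green.shape} vs {self.red.shape}"
            )
        if self.green.ndim != 2:
            raise ValueError("images must be 2-D single-channel arrays")
        if (self.green < 0).any() or (self.red < 0).any():
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.green.shape


@dataclass(frozen=True)
class RatioMeasurement:
    """Mean green/red ratio over the masked pixels of one (sub-)image."""

    mean_ratio: Optional[float]
    pixel_count: int
    threshold_red: float
    threshold_green: float
    tile_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pixel_count < 0:
            raise ValueError("pixel_count must be >= 0")
        if self.pixel_count == 0 and self.mean_ratio is not None:
            raise ValueError("mean_ratio is undefined for an empty mask")


def subdivide_tiles(pair: ChannelImagePair, grid: int) -> list[ChannelImagePair]:
    """Split both channels into a grid×grid set of equal tiles.

    Tile size is floor(H/grid) × floor(W/grid); remainder rows/columns
    that do not fill a tile are discarded from the bottom/right (a
    948-pixel composite on a 10×10 grid yields 100 tiles of 94×94 with
    8 pixels dropped per axis).
    """
    if grid < 1:
        raise ValueError("grid must be >= 1")
    h, w = pair.shape
    th, tw = h // grid, w // grid
    if th < 1 or tw < 1:
        raise ValueError(f"{h}x{w} image cannot form a {grid}x{grid} grid")
    tiles = []
    for r in range(grid):
        for c in range(grid):
            sl = (slice(r * th, (r + 1) * th), slice(c * tw, (c + 1) * tw))
            tiles.append(
                ChannelImagePair(
                    green=pair.green[sl],
                    red=pair.red[sl],
                    pixel_size=pair.pixel_size,
                    metadata=dict(pair.metadata),
                    tile_id=f"r{r:02d}c{c:02d}",
                )
            )
    return tiles


def pixel_mask(
    pair: ChannelImagePair,
    threshold_red: float,
    threshold_green: float,
    *,
    red_only: bool = False,
) -> np.ndarray:
    """Boolean foreground mask from uniform background thresholds.

    Default: a pixel counts only when both channels clear their
    thresholds (a sub-background green pixel contributes an unreliable
    ratio).  ``red_only=True`` masks on the transfection-control
    channel alone.
    """
    if threshold_red < 0 or threshold_green < 0:
        raise ValueError("thresholds must be >= 0")
    mask = pair.red > threshold_red
    if not red_only:
        mask &= pair.green > threshold_green
    return mask


def pixelwise_ratio(
    pair: ChannelImagePair,
    mask: np.ndarray,
    *,
    threshold_red: float = 0.0,
    threshold_green: float = 0.0,
    estimator: str = "mean_of_ratios",
) -> RatioMeasurement:
    """Aggregate the green/red ratio over masked pixels.

    The primary statistic is the per-pixel mean of green/red
    ("mean_of_ratios"); "ratio_of_sums" (Σgreen / Σred) is offered as
    an alternative estimator.  An empty mask yields a no-signal result
    (pixel_count 0, undefined ratio) rather than an exception.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != pair.shape:
        raise ValueError("mask shape must match the images")
    n = int(mask.sum())
    if n == 0:
        return RatioMeasurement(
            mean_ratio=None,
            pixel_count=0,
            threshold_red=threshold_red,
            threshold_green=threshold_green,
            tile_id=pair.tile_id,
        )
    g = pair.green[mask]
    r = pair.red[mask]
    if estimator == "mean_of_ratios":
        ratio = float(np.mean(g / r))
    elif estimator == "ratio_of_sums":
        ratio = float(g.sum() / r.sum())
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return RatioMeasurement(
        mean_ratio=ratio,
        pixel_count=n,
        threshold_red=threshold_red,
        threshold_green=threshold_green,
        tile_id=pair.tile_id,
    )


def percent_of_control(
    sample: RatioMeasurement, control: RatioMeasurement
) -> float:
    """Sample ratio as a percentage of the un-attenuated control ratio."""
    if control.mean_ratio is None or control.mean_ratio <= 0:
        raise ValueError("control ratio is undefined or non-positive")
    if sample.mean_ratio is None:
        raise ValueError("sample ratio is undefined (empty mask)")
    return 100.0 * sample.mean_ratio / control.mean_ratio


def aggregate_replicates(
    groups: Mapping[str, Sequence[Sequence[RatioMeasurement]]],
    z: float = 1.96,
) -> dict[str, dict]:
    """Per-condition summary across replicate composites.

    ``groups`` maps condition → list of replicates, each replicate a
    list of per-tile measurements.  Tiles within a replicate are pooled
    with pixel weighting (equivalent to measuring the whole composite);
    replicates are then averaged unweighted, with SEM and z·SEM when
    n ≥ 2.
    """
    out: dict[str, dict] = {}
    for condition, replicates in groups.items():
        rep_ratios: list[float] = []
        total_pixels = 0
        for tiles in replicates:
            weights = [m.pixel_count for m in tiles if m.pixel_count > 0]
            ratios = [m.mean_ratio for m in tiles if m.pixel_count > 0]
            total_pixels += sum(weights)
            if not weights:
                continue
            rep_ratios.append(
                sum(w * r for w, r in zip(weights, ratios)) / sum(weights)
            )
        if not rep_ratios:
            out[condition] = {
                "mean_ratio": None,
                "sem": None,
                "ci95_halfwidth": None,
                "n_replicates": 0,
                "total_pixels": 0,
            }
            continue
        if len(rep_ratios) >= 2:
            mean, sem, half = summarize_replicates(rep_ratios, z)
        else:
            mean, sem, half = rep_ratios[0], None, None
        out[condition] = {
            "mean_ratio": mean,
            "sem": sem,
            "ci95_halfwidth": half,
            "n_replicates": len(rep_ratios),
            "total_pixels": total_pixels,
        }
    return out


# ---------------------------------------------------------------------
# synthetic scene generation
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticScene:
    """Parameters of a simulated two-channel transfection field.

    Defaults emulate the acquisition the pipeline was built around:
    sparse bright cells on a dark 16-bit background.  ``true_fraction``
    is the ground-truth GFP/RFP ratio of the simulated construct (1.0
    for an un-attenuated control).  Red per-cell amplitude is drawn
    log-normally (heterogeneous expression); green is
    ``true_fraction × red`` with independent multiplicative noise per
    pixel; both channels sit on Gaussian camera background.
    """

    n_cells: int = 60
    true_fraction: float = 1.0
    shape: tuple[int, int] = (948, 948)
    red_log_mean: float = math.log(18000.0)
    red_log_sd: float = 0.35
    cell_radius: tuple[float, float] = (9.0, 22.0)
    multiplicative_noise_sd: float = 0.08
    background_mean: float = 120.0
    background_noise_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_fraction < 0:
            raise ValueError("true_fraction must be >= 0")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")


def generate_synthetic_pair(
    scene: SyntheticScene,
) -> tuple[ChannelImagePair, dict]:
    """Render a synthetic channel pair plus its ground-truth record.

    Cells are non-overlapping random ellipses; placement retries are
    bounded, and an infeasible packing raises.  Identical scenes
    produce bit-identical images.
    """
    rng = np.random.default_rng(scene.seed)
    h, w = scene.shape
    red = np.zeros((h, w), dtype=np.float64)
    green = np.zeros((h, w), dtype=np.float64)
    occupied = np.zeros((h, w), dtype=bool)
    cells = []
    attempts_left = 200 * max(scene.n_cells, 1)
    placed = 0
    rmin, rmax = scene.cell_radius
    while placed < scene.n_cells:
        if attempts_left <= 0:
            raise RuntimeError(
                f"could not place {scene.n_cells} non-overlapping cells "
                f"in a {h}x{w} field"
            )
        attempts_left -= 1
        ra = rng.uniform(rmin, rmax)
        rb = rng.uniform(rmin, rmax)
        theta = rng.uniform(0, math.pi)
        cy = rng.uniform(rmax, h - rmax)
        cx = rng.uniform(rmax, w - rmax)
        rr, cc = ellipse(cy, cx, ra, rb, shape=(h, w), rotation=theta)
        if occupied[rr, cc].any():
            continue
        amp = float(rng.lognormal(scene.red_log_mean, scene.red_log_sd))
        occupied[rr, cc] = True
        red[rr, cc] = amp
        noise = 1.0 + rng.normal(0.0, scene.multiplicative_noise_sd, rr.size)
        green[rr, cc] = scene.true_fraction * amp * np.clip(noise, 0.0, None)
        cells.append(
            {"cy": cy, "cx": cx, "ra": ra, "rb": rb, "red_amplitude": amp,
             "n_pixels": int(rr.size)}
        )
        placed += 1
    for img in (red, green):
        img += rng.normal(scene.background_mean, scene.background_noise_sd, (h, w))
    red = np.clip(np.rint(red), 0, U16_MAX)
    green = np.clip(np.rint(green), 0, U16_MAX)
    pair = ChannelImagePair(
        green=green,
        red=red,
        metadata={"synthetic": True, "seed": scene.seed},
    )
    truth = {
        "true_fraction": scene.true_fraction,
        "n_cells": placed,
        "foreground_pixels": int(occupied.sum()),
        "background_mean": scene.background_mean,
        "background_noise_sd": scene.background_noise_sd,
        "seed": scene.seed,
        "cells": cells,
    }
    return pair, truth


def suggested_thresholds(scene: SyntheticScene) -> tuple[float, float]:
    """Background mean + 3 SD for both channels (the manual-threshold rule)."""
    t = scene.background_mean + 3.0 * scene.background_noise_sd
    return t, t


# ---------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------

def write_pair(
    pair: ChannelImagePair, green_path, red_path, truth: dict | None = None,
    truth_path=None,
) -> None:
    """Write the two channels as 16-bit single-channel TIFFs."""
    tifffile.imwrite(green_path, pair.green.astype(np.uint16))
    tifffile.imwrite(red_path, pair.red.astype(np.uint16))
    if truth is not None and truth_path is not None:
        with open(truth_path, "w") as fh:
            json.dump(truth, fh, indent=1)


def read_pair(green_path, red_path) -> ChannelImagePair:
    return ChannelImagePair(
        green=tifffile.imread(green_path), red=tifffile.imread(red_path)
    )


def measurements_to_tsv(measurements: Iterable[RatioMeasurement]) -> str:
    lines = ["tile_id\tmean_ratio\tpixel_count\tthreshold_red\tthreshold_green"]
    for m in measurements:
        ratio = "" if m.mean_ratio is None else f"{m.mean_ratio:.6f}"
        lines.append(
            f"{m.tile_id or ''}\t{ratio}\t{m.pixel_count}\t"
            f"{m.threshold_red:g}\t{m.threshold_green:g}"
        )
    return "\n".join(lines) + "\n"
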