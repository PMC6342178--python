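"""Synthetic study systems with known truth, plus downsampling utilities.

Two systems are provided:

* A gradient system: two environmental variables that vary linearly from 0
  to 100 across the study area ("BottomToTop" along y, "LeftToRight" along
  x), truth response curves peaked near 50 (one wide, one narrow), a truth
  habitat map equal to the product of the two curve evaluations, and
  occurrences placed by rejection sampling (a uniform candidate point is
  kept with probability equal to its habitat suitability).

* A canyon system: a sinuous narrow band of optimal habitat (value 255 on a
  0 background) with 1,000 occurrences placed uniformly inside the band,
  together with degraded variants — nearest-neighbor downsampling by a
  factor of 8, three successive factor-2 block averagings ("bilinear"), and
  a per-block standard-deviation raster usable as a spatially varying noise
  field.

All geometry is planar with unit-square pixels; no projections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import ResponseCurve, suitability_many
from .raster import OccurrenceSet, Raster, sample_raster_at_points

__all__ = [
    "WIDE_TRUTH_CURVE",
    "NARROW_TRUTH_CURVE",
    "GradientSystem",
    "CanyonSystem",
    "gradient_raster",
    "truth_habitat",
    "sample_occurrences",
    "make_gradient_system",
    "canyon_habitat",
    "make_canyon_system",
    "downsample",
    "neighborhood_sd",
    "block_sd_raster",
]

#: wide truth response (BottomToTop): good habitat across most of the range
WIDE_TRUTH_CURVE = ResponseCurve([(0, 0), (25, 1), (75, 1), (100, 0)], 0, 100)
#: narrow truth response (LeftToRight): good habitat only near 50
NARROW_TRUTH_CURVE = ResponseCurve([(30, 0), (45, 1), (55, 1), (70, 0)], 0, 100)


@dataclass
class GradientSystem:
    """The gradient study system: variables, truth, and sampled occurrences."""

    rasters: dict[str, Raster]
    truth_curves: dict[str, ResponseCurve]
    habitat: Raster
    occurrences: OccurrenceSet
    n_candidates: int
    seed: int


@dataclass
class CanyonSystem:
    """The narrow-canyon system with its downsampled variants."""

    habitat: Raster
    occurrences: OccurrenceSet
    nearest8: Raster
    bilinear3: Raster
    sd_raster: Raster
    seed: int


def gradient_raster(
    size: int,
    direction: str,
    vmin: float = 0.0,
    vmax: float = 100.0,
    cell_size: float = 1.0,
) -> Raster:
    """Square raster varying linearly along one axis, constant along the other.

    ``bottom_to_top`` runs vmin at the bottom edge to vmax at the top;
    ``left_to_right`` runs vmin in the first column to vmax in the last.
    """
    if size < 2:
        raise ValueError("size must be >= 2")
    ramp = np.linspace(vmin, vmax, size)
    if direction == "left_to_right":
        values = np.tile(ramp, (size, 1))
    elif direction == "bottom_to_top":
        values = np.tile(ramp[::-1, None], (1, size))
    else:
        raise ValueError("direction must be 'bottom_to_top' or 'left_to_right'")
    return Raster(values, origin_x=0.0, origin_y=size * cell_size, cell_size=cell_size)


def _evaluate_curve_on_raster(curve: ResponseCurve, r: Raster) -> np.ndarray:
    """Exact curve evaluation per pixel, deduplicated over unique values."""
    vals = r.values
    flat = vals.ravel()
    finite = np.isfinite(flat)
    uniq, inv = np.unique(flat[finite], return_inverse=True)
    suit = suitability_many(curve, np.clip(uniq, curve.vmin, curve.vmax))
    out = np.full(flat.shape, np.nan)
    out[finite] = suit[inv]
    return out.reshape(vals.shape)


def truth_habitat(
    bt_curve: ResponseCurve,
    lr_curve: ResponseCurve,
    bt: Raster,
    lr: Raster,
) -> Raster:
    """Pixelwise product of the two truth-curve evaluations."""
    if not bt.aligned_with(lr):
        raise ValueError("gradient rasters are not aligned")
    return bt.with_values(
        _evaluate_curve_on_raster(bt_curve, bt) * _evaluate_curve_on_raster(lr_curve, lr)
    )


def sample_occurrences(
    habitat: Raster, n_candidates: int, rng: np.random.Generator
) -> OccurrenceSet:
    """Rejection-sample occurrences from a suitability map.

    n_candidates points are drawn uniformly over the extent; each is kept
    with probability equal to the habitat suitability of its pixel (a
    uniform [0, 1] draw at or below the suitability keeps the point).
    """
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    xmin, ymin, xmax, ymax = habitat.extent
    xs = rng.uniform(xmin, xmax, n_candidates)
    ys = rng.uniform(ymin, ymax, n_candidates)
    u = rng.uniform(0.0, 1.0, n_candidates)
    vals = sample_raster_at_points(habitat, OccurrenceSet(np.column_stack([xs, ys])))
    keep = np.isfinite(vals) & (u <= vals)
    return OccurrenceSet(np.column_stack([xs[keep], ys[keep]]))


def make_gradient_system(
    size: int = 1000,
    n_candidates: int = 20000,
    seed: int = 0,
    wide: ResponseCurve = WIDE_TRUTH_CURVE,
    narrow: ResponseCurve = NARROW_TRUTH_CURVE,
) -> GradientSystem:
    """Build the default gradient system (1 map unit per pixel)."""
    bt = gradient_raster(size, "bottom_to_top")
    lr = gradient_raster(size, "left_to_right")
    habitat = truth_habitat(wide, narrow, bt, lr)
    rng = np.random.default_rng([int(seed), 101])
    occ = sample_occurrences(habitat, n_candidates, rng)
    return GradientSystem(
        rasters={"BottomToTop": bt, "LeftToRight": lr},
        truth_curves={"BottomToTop": wide, "LeftToRight": narrow},
        habitat=habitat,
        occurrences=occ,
        n_candidates=n_candidates,
        seed=int(seed),
    )


def canyon_habitat(
    size: int = 512,
    band_width_fraction: float = 0.06,
    rng: np.random.Generator | None = None,
    n_occurrences: int = 1000,
) -> tuple[Raster, OccurrenceSet]:
    """Sinuous vertical band of optimal habitat (255) on a 0 background.

    The band's horizontal center follows a smooth random sum of sinusoids;
    n_occurrences points are placed uniformly within the 255-valued region.
    """
    if rng is None:
        rng = np.random.default_rng()
    if not 0 < band_width_fraction < 1:
        raise ValueError("band_width_fraction must be in (0, 1)")
    band_px = band_width_fraction * size
    if band_px < 2:
        raise ValueError("band must span at least 2 pixels")
    rows = np.arange(size)
    margin = band_px / 2 + 2
    amp_total = (size / 2 - margin) * 0.8
    center = np.full(size, size / 2.0)
    for k, frac in enumerate((0.55, 0.3, 0.15)):
        phase = rng.uniform(0, 2 * np.pi)
        period = size / rng.uniform(1.0 + k, 2.0 + k)
        center += amp_total * frac * np.sin(2 * np.pi * rows / period + phase)
    cols = np.arange(size)
    inside = np.abs(cols[None, :] - center[:, None]) <= band_px / 2
    values = np.where(inside, 255.0, 0.0)
    habitat = Raster(values, origin_x=0.0, origin_y=float(size), cell_size=1.0)
    rr, cc = np.nonzero(inside)
    pick = rng.integers(0, rr.size, n_occurrences)
    # uniform position within each picked habitat pixel
    x = cc[pick] + rng.uniform(0, 1, n_occurrences)
    y = size - (rr[pick] + rng.uniform(0, 1, n_occurrences))
    return habitat, OccurrenceSet(np.column_stack([x, y]))


def downsample(r: Raster, factor: int, method: str = "nearest") -> Raster:
    """Reduce resolution by an integer factor.

    ``nearest`` takes each block's center sample (ties toward the top-left
    of the two central candidates); ``bilinear`` takes the block mean
    (nodata-aware).  Dimensions not divisible by the factor are padded with
    nodata.  Output cell size is input * factor with the same origin.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if method not in ("nearest", "bilinear"):
        raise ValueError("method must be 'nearest' or 'bilinear'")
    if factor == 1:
        return r.with_values(r.values.copy())
    v = r.values
    ph = (-v.shape[0]) % factor
    pw = (-v.shape[1]) % factor
    if ph or pw:
        v = np.pad(v, ((0, ph), (0, pw)), constant_values=np.nan)
    blocks = v.reshape(v.shape[0] // factor, factor, v.shape[1] // factor, factor)
    if method == "nearest":
        off = (factor - 1) // 2
        out = blocks[:, off, :, off]
    else:
        with np.errstate(invalid="ignore"):
            out = np.nanmean(blocks, axis=(1, 3))
    return Raster(
        out, origin_x=r.origin_x, origin_y=r.origin_y,
        cell_size=r.cell_size * factor, nodata=None,
    )


def neighborhood_sd(r: Raster, window: int = 8) -> Raster:
    """Population sd of each pixel's window x window block (block tiling).

    Every pixel receives the standard deviation of the non-overlapping block
    that contains it, so a factor-``window`` downsample afterwards yields one
    sd value per coarse pixel (see :func:`block_sd_raster`).
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    v = r.values
    ph = (-v.shape[0]) % window
    pw = (-v.shape[1]) % window
    if ph or pw:
        v = np.pad(v, ((0, ph), (0, pw)), constant_values=np.nan)
    blocks = v.reshape(v.shape[0] // window, window, v.shape[1] // window, window)
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(blocks, axis=(1, 3))
    out = np.repeat(np.repeat(sd, window, axis=0), window, axis=1)
    out = out[: r.values.shape[0], : r.values.shape[1]]
    return r.with_values(out)


def block_sd_raster(r: Raster, window: int = 8) -> Raster:
    """Per-block sd at the downsampled resolution (one value per block)."""
    return downsample(neighborhood_sd(r, window), window, "nearest")


def make_canyon_system(
    size: int = 512,
    band_width_fraction: float = 0.06,
    seed: int = 0,
) -> CanyonSystem:
    """Canyon habitat plus its degraded variants.

    nearest8 downsamples by 8 with nearest-neighbor selection; bilinear3
    applies factor-2 block averaging three consecutive times (net factor 8);
    sd_raster is the per-8x8-block population sd at the coarse resolution.
    """
    rng = np.random.default_rng([int(seed), 202])
    habitat, occ = canyon_habitat(size, band_width_fraction, rng)
    nearest8 = downsample(habitat, 8, "nearest")
    bilinear3 = habitat
    for _ in range(3):
        bilinear3 = downsample(bilinear3, 2, "bilinear")
    sd_raster = block_sd_raster(habitat, 8)
    return CanyonSystem(
        habitat=habitat,
        occurrences=occ,
        nearest8=nearest8,
        bilinear3=bilinear3,
        sd_raster=sd_raster,
        seed=int(seed),
    )
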