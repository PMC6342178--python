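"""The three model-graph histograms: f(z), f1(z), and the ratio f1/f.

Each environmental variable is summarized by 256-bin histograms over its
value range: f(z) counts every data pixel, f1(z) counts the pixels under the
occurrence points, and f1/f corrects the occurrence frequencies for how much
of each environmental condition is actually available in the study area.
For display the histograms are rescaled so their maximum is 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import OccurrenceSet, Raster, sample_raster_at_points
from .curves import bin_centers

__all__ = [
    "NBINS",
    "Histogram256",
    "value_to_bin",
    "build_all_histogram",
    "build_occurrence_histogram",
    "ratio_histogram",
    "histograms_to_frame",
]

NBINS = 256


@dataclass
class Histogram256:
    """256 non-negative bin weights over [vmin, vmax].

    kind is one of ``all_pixels`` (f), ``occurrences`` (f1), ``ratio``
    (f1/f).  Weights are stored unrescaled; :meth:`rescaled` divides by the
    maximum so the peak is exactly 1.
    """

    vmin: float
    vmax: float
    weights: np.ndarray
    kind: str = "all_pixels"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (NBINS,):
            raise ValueError(f"histogram needs exactly {NBINS} bins")
        if np.any(w < 0):
            raise ValueError("histogram weights must be non-negative")
        self.weights = w

    @property
    def centers(self) -> np.ndarray:
        return bin_centers(self.vmin, self.vmax, NBINS)

    @property
    def degenerate(self) -> bool:
        """True when the variable range has zero width."""
        return not self.vmax > self.vmin

    def rescaled(self) -> np.ndarray:
        """Weights divided by their maximum (max becomes exactly 1)."""
        m = self.weights.max()
        return self.weights / m if m > 0 else self.weights.copy()

    @property
    def total(self) -> float:
        return float(self.weights.sum())


def value_to_bin(
    values: np.ndarray, vmin: float, vmax: float, clip: bool = False
) -> np.ndarray:
    """Bin index by the floor rule: floor(256 * (v - vmin) / (vmax - vmin)).

    v == vmax maps to bin 255.  With ``clip`` values outside [vmin, vmax]
    clamp to the end bins (used for prediction on noised rasters); without it
    they raise.  A zero-width range puts everything in bin 0.
    """
    v = np.asarray(values, dtype=float)
    if not vmax > vmin:
        return np.zeros(v.shape, dtype=np.int64)
    idx = np.floor(NBINS * (v - vmin) / (vmax - vmin)).astype(np.int64)
    if clip:
        return np.clip(idx, 0, NBINS - 1)
    if np.any((v < vmin) | (v > vmax)):
        raise ValueError("values outside [vmin, vmax]; pass clip=True to clamp")
    return np.minimum(idx, NBINS - 1)


def build_all_histogram(
    r: Raster, vmin: float | None = None, vmax: float | None = None
) -> Histogram256:
    """f(z): frequency of every non-nodata pixel value.

    The bin range defaults to the raster's own min/max; an explicit range may
    be supplied to keep bins fixed across Monte Carlo iterations.
    """
    vals = r.finite_values()
    if vals.size == 0:
        raise ValueError("raster has no data cells")
    lo = float(np.min(vals)) if vmin is None else float(vmin)
    hi = float(np.max(vals)) if vmax is None else float(vmax)
    idx = value_to_bin(vals, lo, hi, clip=True)
    w = np.bincount(idx, minlength=NBINS).astype(float)
    return Histogram256(lo, hi, w, kind="all_pixels")


def build_occurrence_histogram(
    r: Raster, occ: OccurrenceSet, range_from: Histogram256
) -> Histogram256:
    """f1(z): frequency of the variable at the occurrence pixels.

    Shares the bin range of ``range_from`` so f and f1 are comparable.
    Points outside the extent or on nodata pixels are skipped.
    """
    vals = sample_raster_at_points(r, occ)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no usable occurrences (all outside extent or on nodata)")
    idx = value_to_bin(vals, range_from.vmin, range_from.vmax, clip=True)
    w = np.bincount(idx, minlength=NBINS).astype(float)
    return Histogram256(range_from.vmin, range_from.vmax, w, kind="occurrences")


def ratio_histogram(f1: Histogram256, f: Histogram256) -> Histogram256:
    """f1/f per bin (0 where f is 0), rescaled to a maximum of 1."""
    if (f1.vmin, f1.vmax) != (f.vmin, f.vmax):
        raise ValueError("f1 and f must share the same bin range")
    if not np.any(f.weights > 0):
        raise ValueError("f is entirely zero")
    ratio = np.zeros(NBINS)
    nz = f.weights > 0
    ratio[nz] = f1.weights[nz] / f.weights[nz]
    m = ratio.max()
    if m > 0:
        ratio = ratio / m
    return Histogram256(f.vmin, f.vmax, ratio, kind="ratio")


def histograms_to_frame(
    f: Histogram256, f1: Histogram256, ratio: Histogram256
) -> pd.DataFrame:
    """Tidy table (bin, center, f, f1, ratio; all rescaled) for CSV export."""
    return pd.DataFrame(
        {
            "bin": np.arange(NBINS),
            "center": f.centers,
            "f": f.rescaled(),
            "f1": f1.rescaled(),
            "ratio": ratio.rescaled(),
        }
    )
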