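"""Multi-variable habitat suitability models: assembly, prediction, ROC/AUC,
and the jackknife over variable combinations.

A model holds one fitted response curve per environmental variable.  The
suitability map evaluates every variable's curve at each pixel (through the
256-entry lookup) and combines the per-variable suitabilities with a product
(default) or geometric mean.  Model performance is scored presence-vs-
background: occurrence pixels against all data pixels of the study area.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import ResponseCurve, curve_to_lookup
from .fitting import (
    FitResult,
    FitTargetWeights,
    GridSearchConfig,
    aic,
    fit_curve,
    log_likelihood,
)
from .histograms import (
    Histogram256,
    build_all_histogram,
    build_occurrence_histogram,
    ratio_histogram,
    value_to_bin,
)
from .raster import OccurrenceSet, Raster, sample_raster_at_points

__all__ = [
    "HSVariable",
    "HSModel",
    "ROCResult",
    "build_weights",
    "fit_hs_model",
    "predict_map",
    "roc_auc",
    "jackknife",
]


class AlignmentError(ValueError):
    """Variable rasters do not share a common grid."""


@dataclass
class HSVariable:
    """One environmental variable with its data summaries and fitted curve."""

    name: str
    raster: Raster
    curve: ResponseCurve
    hist_all: Histogram256 | None = None
    hist_occ: Histogram256 | None = None
    hist_ratio: Histogram256 | None = None
    weights: FitTargetWeights | None = None
    fit: FitResult | None = None


@dataclass
class HSModel:
    variables: list[HSVariable]
    combiner: str = "product"

    def __post_init__(self) -> None:
        if not self.variables:
            raise ValueError("a model needs at least one variable")
        if self.combiner not in ("product", "geometric_mean"):
            raise ValueError("combiner must be 'product' or 'geometric_mean'")
        ref = self.variables[0].raster
        bad = [v.name for v in self.variables[1:] if not v.raster.aligned_with(ref)]
        if bad:
            raise AlignmentError(f"rasters not aligned with {self.variables[0].name}: {bad}")

    @property
    def loglik(self) -> float:
        return float(sum(v.fit.loglik for v in self.variables if v.fit is not None))

    @property
    def k(self) -> int:
        return 6 * len(self.variables)

    def aic(self, convention: str = "paper") -> float:
        return aic(self.loglik, self.k, convention)


@dataclass
class ROCResult:
    """Presence-background ROC curve and rank-statistic AUC."""

    points: np.ndarray  # (m, 2) (fpr, tpr), monotone from (0,0) to (1,1)
    auc: float
    n_presence: int = 0
    n_background: int = 0


def build_weights(
    r: Raster,
    occ: OccurrenceSet,
    target: str = "ratio",
    vmin: float | None = None,
    vmax: float | None = None,
) -> tuple[FitTargetWeights, Histogram256, Histogram256, Histogram256]:
    """Histograms and fit-target weights for one variable.

    target 'ratio' (default) uses the rescaled f1/f values as pseudo-counts;
    'f1' uses the raw occurrence counts.
    """
    f = build_all_histogram(r, vmin=vmin, vmax=vmax)
    f1 = build_occurrence_histogram(r, occ, f)
    ratio = ratio_histogram(f1, f)
    if target == "ratio":
        # availability-corrected pseudo-counts: ratio shape scaled to carry
        # the same total weight as the occurrences, so likelihood and AIC
        # magnitudes stay on the per-occurrence scale
        w = ratio.rescaled()
        w = FitTargetWeights(w * (f1.total / w.sum()), source="ratio")
    elif target == "f1":
        w = FitTargetWeights(f1.weights, source="f1")
    else:
        raise ValueError("target must be 'ratio' or 'f1'")
    return w, f, f1, ratio


def fit_hs_model(
    rasters: dict[str, Raster],
    occ: OccurrenceSet,
    cfg: GridSearchConfig | None = None,
    target: str = "ratio",
    combiner: str = "product",
    aic_convention: str = "paper",
    ranges: dict[str, tuple[float, float]] | None = None,
) -> HSModel:
    """Fit a response curve per variable and assemble the model.

    ranges optionally fixes each variable's histogram range (used by the
    Monte Carlo loop to keep bins comparable across noise injections).
    """
    if not rasters:
        raise ValueError("no variables given")
    variables = []
    for name, r in rasters.items():
        vmin, vmax = (ranges or {}).get(name, (None, None))
        w, f, f1, ratio = build_weights(r, occ, target=target, vmin=vmin, vmax=vmax)
        fit = fit_curve(w, f.vmin, f.vmax, cfg, aic_convention=aic_convention)
        variables.append(
            HSVariable(
                name=name, raster=r, curve=fit.curve,
                hist_all=f, hist_occ=f1, hist_ratio=ratio,
                weights=w, fit=fit,
            )
        )
    return HSModel(variables, combiner=combiner)


def predict_map(m: HSModel) -> Raster:
    """Suitability raster in [0, 1]; nodata wherever any variable is nodata.

    Each pixel's variable value maps to a histogram bin by the same floor
    rule used when binning (values outside the curve range clamp to the end
    bins) and the curve lookup supplies the suitability.
    """
    ref = m.variables[0].raster
    out = np.ones(ref.values.shape)
    for v in m.variables:
        lut = curve_to_lookup(v.curve)
        vals = v.raster.values
        idx = value_to_bin(
            np.where(np.isfinite(vals), vals, v.curve.vmin),
            v.curve.vmin, v.curve.vmax, clip=True,
        )
        suit = lut[idx]
        suit[~np.isfinite(vals)] = np.nan
        out *= suit
    if m.combiner == "geometric_mean":
        out = out ** (1.0 / len(m.variables))
    return ref.with_values(out)


def _rank_auc(presence: np.ndarray, background: np.ndarray) -> float:
    """(wins + 0.5 * ties) / (n_presence * n_background)."""
    bg = np.sort(background)
    lo = np.searchsorted(bg, presence, side="left")
    hi = np.searchsorted(bg, presence, side="right")
    wins = lo.sum()
    ties = (hi - lo).sum()
    return float((wins + 0.5 * ties) / (presence.size * bg.size))


def roc_auc(suit: Raster, occ: OccurrenceSet, n_thresholds: int = 257) -> ROCResult:
    """Presence-background ROC of a suitability map.

    Presence scores are the map values at the occurrence pixels (points off
    the map or on nodata are dropped); background scores are all data pixels.
    The AUC is the exact rank statistic; the ROC polyline is swept over the
    n_thresholds bin edges of [0, 1] (descending, score >= threshold), with
    the all-negative origin prepended.
    """
    presence = sample_raster_at_points(suit, occ)
    presence = presence[np.isfinite(presence)]
    if presence.size == 0:
        raise ValueError("no usable presence points on the suitability map")
    background = suit.finite_values()
    if background.size == 0:
        raise ValueError("suitability map has no data pixels")
    auc = _rank_auc(presence, background)
    thr = np.linspace(1.0, 0.0, n_thresholds)
    ps = np.sort(presence)
    bs = np.sort(background)
    tpr = 1.0 - np.searchsorted(ps, thr, side="left") / ps.size
    fpr = 1.0 - np.searchsorted(bs, thr, side="left") / bs.size
    points = np.column_stack([np.concatenate([[0.0], fpr]), np.concatenate([[0.0], tpr])])
    return ROCResult(points=points, auc=auc, n_presence=ps.size, n_background=bs.size)


def jackknife(
    rasters: dict[str, Raster],
    occ: OccurrenceSet,
    cfg: GridSearchConfig | None = None,
    mode: str = "leave_one_out_and_single",
    target: str = "ratio",
    combiner: str = "product",
    aic_convention: str = "paper",
    ranges: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Refit the model on subsets of the variables and tabulate lnL/AIC/AUC.

    mode 'leave_one_out_and_single' evaluates each single variable, each
    leave-one-out set, and the full set; 'all_subsets' evaluates every
    nonempty subset (refused above 12 variables).
    """
    names = list(rasters)
    if mode == "all_subsets":
        if len(names) > 12:
            raise ValueError("all_subsets refused for more than 12 variables")
        subsets = [
            list(c)
            for k in range(1, len(names) + 1)
            for c in itertools.combinations(names, k)
        ]
    elif mode == "leave_one_out_and_single":
        subsets = [[n] for n in names]
        if len(names) >= 2:
            subsets += [[m for m in names if m != n] for n in names]
            subsets.append(list(names))
    else:
        raise ValueError("unknown jackknife mode")
    # drop duplicate subsets while preserving order
    seen: set[tuple[str, ...]] = set()
    rows = []
    for sub in subsets:
        key = tuple(sub)
        if key in seen:
            continue
        seen.add(key)
        model = fit_hs_model(
            {n: rasters[n] for n in sub}, occ, cfg,
            target=target, combiner=combiner,
            aic_convention=aic_convention, ranges=ranges,
        )
        suit = predict_map(model)
        roc = roc_auc(suit, occ)
        rows.append(
            {
                "variables": "+".join(sub),
                "n_variables": len(sub),
                "loglik": model.loglik,
                "aic": model.aic(aic_convention),
                "auc": roc.auc,
            }
        )
    return pd.DataFrame(rows)
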