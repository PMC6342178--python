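"""Monte Carlo uncertainty analysis: noise injection, cross-validation,
sensitivity testing, and aggregation into uncertainty maps and envelopes.

Each iteration, in order: (1) Gaussian noise is added to the occurrence
coordinates, (2) Gaussian noise (scalar or per-pixel raster parameters) is
added to the environmental rasters, (3) the occurrences are split into
training and test sets, (4) histograms are rebuilt from the (possibly
noised) data and the response curves refit, (5) the fitted control points
are perturbed (sensitivity testing), (6) the suitability map is predicted,
and (7) log-likelihood and AIC are computed on the training weights and the
presence-background AUC on the test occurrences.  After all iterations the
per-pixel mean/min/max/standard-deviation maps, per-variable response-curve
envelopes (mean, min, max, and a nonparametric 95% interval at the 256 bin
centers), and running cumulative means/sds of AIC and AUC are assembled.

Randomness is fully reproducible: each iteration draws from a generator
seeded by (master seed, iteration index), so results do not depend on
execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import ControlPoint, ResponseCurve, curve_to_lookup
from .fitting import GridSearchConfig, aic, log_likelihood
from .model import fit_hs_model, jackknife, predict_map, roc_auc
from .raster import OccurrenceSet, Raster, sample_raster_at_points

__all__ = [
    "EnvNoise",
    "NoiseSpec",
    "MCConfig",
    "IterationStats",
    "MCResult",
    "perturb_occurrences",
    "perturb_raster",
    "perturb_curve",
    "split_train_test",
    "aggregate_maps",
    "running_stats",
    "run_monte_carlo",
]


@dataclass
class EnvNoise:
    """Additive Gaussian noise for one variable; parameters may be scalars
    or rasters aligned with the variable (spatially varying uncertainty)."""

    mean: float | Raster = 0.0
    sd: float | Raster = 0.0


@dataclass
class NoiseSpec:
    """Which noise stages run and with what parameters.

    occurrence_sd is in map units.  environment maps variable name ->
    EnvNoise.  curve maps variable name -> (sd_x in variable units, sd_y in
    suitability units) applied to fitted control points (sensitivity
    testing).  A stage is enabled when its parameters are present/nonzero.
    """

    occurrence_sd: float = 0.0
    environment: dict[str, EnvNoise] = field(default_factory=dict)
    curve: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.occurrence_sd < 0:
            raise ValueError("occurrence_sd must be >= 0")


@dataclass
class MCConfig:
    iterations: int = 100
    train_fraction: float = 0.7
    split: bool = False
    seed: int = 0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    grid: GridSearchConfig = field(default_factory=GridSearchConfig)
    jackknife: bool = False
    target: str = "ratio"
    combiner: str = "product"
    aic_convention: str = "paper"

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class IterationStats:
    iteration: int
    loglik: float
    aic: float
    auc: float
    dropped: int
    n_train: int
    n_test: int


@dataclass
class MCResult:
    stats: pd.DataFrame
    maps: dict[str, Raster]
    envelopes: dict[str, pd.DataFrame]
    curves: dict[str, list[ResponseCurve]]
    running: pd.DataFrame
    jackknife: pd.DataFrame | None
    config: MCConfig


def perturb_occurrences(
    occ: OccurrenceSet, sd: float, rng: np.random.Generator
) -> OccurrenceSet:
    """Independent Gaussian(0, sd) added to each coordinate of each point."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0 or occ.n == 0:
        return OccurrenceSet(occ.xy.copy())
    return OccurrenceSet(occ.xy + rng.normal(0.0, sd, occ.xy.shape))


def _param_array(p: float | Raster, ref: Raster, what: str) -> np.ndarray:
    if isinstance(p, Raster):
        if not p.aligned_with(ref):
            raise ValueError(f"{what} parameter raster is not aligned with the variable")
        return p.values
    return np.full(ref.values.shape, float(p))


def perturb_raster(
    r: Raster,
    mean: float | Raster,
    sd: float | Raster,
    rng: np.random.Generator,
) -> Raster:
    """Per-pixel Gaussian(mean, sd) added to the raster, clamped to the
    original data range; nodata cells are untouched."""
    m = _param_array(mean, r, "mean")
    s = _param_array(sd, r, "sd")
    if np.any(s[np.isfinite(s)] < 0):
        raise ValueError("sd must be >= 0 everywhere")
    noise = m + rng.standard_normal(r.values.shape) * s
    out = np.clip(r.values + noise, r.vmin, r.vmax)
    return r.with_values(out)


def perturb_curve(
    c: ResponseCurve, sd_x: float, sd_y: float, rng: np.random.Generator
) -> ResponseCurve:
    """Gaussian noise on control-point coordinates, repaired to validity.

    After the perturbation, y is clamped to [0, 1] and x to [vmin, vmax],
    the points are re-sorted by x to restore ordering, and the end points
    are projected onto their nearest feasible edge (cp0: left or bottom;
    cp3: bottom or right).
    """
    if sd_x < 0 or sd_y < 0:
        raise ValueError("sd values must be >= 0")
    xs = np.clip(c.xs + rng.normal(0.0, sd_x, 4) if sd_x > 0 else c.xs.copy(), c.vmin, c.vmax)
    ys = np.clip(c.ys + rng.normal(0.0, sd_y, 4) if sd_y > 0 else c.ys.copy(), 0.0, 1.0)
    order = np.argsort(xs, kind="stable")
    xs, ys = xs[order], ys[order]
    # project end points to the nearest feasible edge (distances compared
    # on the unit square: x scaled by the variable range, y by 1)
    rng_w = max(c.vmax - c.vmin, np.finfo(float).tiny)
    if (xs[0] - c.vmin) / rng_w <= ys[0]:
        xs[0] = c.vmin
    else:
        ys[0] = 0.0
    if (c.vmax - xs[3]) / rng_w <= ys[3]:
        xs[3] = c.vmax
    else:
        ys[3] = 0.0
    return ResponseCurve(
        [ControlPoint(float(x), float(y)) for x, y in zip(xs, ys)], c.vmin, c.vmax
    )


def split_train_test(
    occ: OccurrenceSet, train_fraction: float, rng: np.random.Generator
) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Uniform random partition; |train| = round(n * train_fraction)."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if occ.n < 2:
        raise ValueError("need at least 2 occurrences to split")
    k = int(round(occ.n * train_fraction))
    k = min(max(k, 1), occ.n - 1)
    perm = rng.permutation(occ.n)
    return occ.subset(np.sort(perm[:k])), occ.subset(np.sort(perm[k:]))


def aggregate_maps(maps: list[Raster]) -> dict[str, Raster]:
    """Pixelwise mean/min/max/population-sd of aligned maps; nodata propagates."""
    if not maps:
        raise ValueError("need at least one map")
    ref = maps[0]
    for m in maps[1:]:
        if not m.aligned_with(ref):
            raise ValueError("maps are not aligned")
    stack = np.stack([m.values for m in maps])
    return {
        "mean": ref.with_values(stack.mean(axis=0)),
        "min": ref.with_values(stack.min(axis=0)),
        "max": ref.with_values(stack.max(axis=0)),
        "sd": ref.with_values(stack.std(axis=0)),
    }


def running_stats(series) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative means and population sds: element t summarizes values[:t+1]."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    n = np.arange(1, x.size + 1)
    csum = np.cumsum(x)
    mean = csum / n
    var = np.cumsum(x * x) / n - mean**2
    return mean, np.sqrt(np.maximum(var, 0.0))


class _MapAccumulator:
    """Streaming pixelwise mean/min/max/population sd (Welford update)."""

    def __init__(self, ref: Raster):
        shape = ref.values.shape
        self.ref = ref
        self.n = 0
        self.mean = np.zeros(shape)
        self.m2 = np.zeros(shape)
        self.min = np.full(shape, np.inf)
        self.max = np.full(shape, -np.inf)
        self.anynan = np.zeros(shape, dtype=bool)

    def add(self, r: Raster) -> None:
        v = r.values
        nan = ~np.isfinite(v)
        self.anynan |= nan
        vv = np.where(nan, 0.0, v)
        self.n += 1
        delta = vv - self.mean
        self.mean += delta / self.n
        self.m2 += delta * (vv - self.mean)
        self.min = np.minimum(self.min, np.where(nan, np.inf, v))
        self.max = np.maximum(self.max, np.where(nan, -np.inf, v))

    def result(self) -> dict[str, Raster]:
        mean = self.mean
        sd = np.sqrt(np.maximum(self.m2 / self.n, 0.0))
        out = {}
        for name, arr in (
            ("mean", mean),
            ("min", self.min),
            ("max", self.max),
            ("sd", sd),
        ):
            a = np.where(self.anynan, np.nan, arr)
            out[name] = self.ref.with_values(a)
        return out


def _curve_envelope(lookups: np.ndarray, centers: np.ndarray) -> pd.DataFrame:
    """Pointwise envelope of per-iteration curve lookups (iters x 256)."""
    lo, hi = np.percentile(lookups, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {
            "center": centers,
            "mean": lookups.mean(axis=0),
            "min": lookups.min(axis=0),
            "max": lookups.max(axis=0),
            "lo95": lo,
            "hi95": hi,
        }
    )


def run_monte_carlo(
    rasters: dict[str, Raster],
    occ: OccurrenceSet,
    cfg: MCConfig,
) -> MCResult:
    """Run the full Monte Carlo loop and aggregate the outputs.

    lnL/AIC are computed on the training weights of the iteration's fitted
    (and, when sensitivity testing is on, perturbed) model; AUC uses the
    test occurrences against the iteration's suitability map.
    """
    if occ.n < 1:
        raise ValueError("no occurrences")
    names = list(rasters)
    ranges = {n: (rasters[n].vmin, rasters[n].vmax) for n in names}
    accum: _MapAccumulator | None = None
    lookups: dict[str, list[np.ndarray]] = {n: [] for n in names}
    curves: dict[str, list[ResponseCurve]] = {n: [] for n in names}
    rows = []
    for it in range(cfg.iterations):
        rng = np.random.default_rng([int(cfg.seed), 1000 + it])
        try:
            # (1) occurrence noise
            occ_it = occ
            if cfg.noise.occurrence_sd > 0:
                occ_it = perturb_occurrences(occ_it, cfg.noise.occurrence_sd, rng)
            # (2) environmental noise (fresh draw each iteration)
            rasters_it = dict(rasters)
            for name in names:
                env = cfg.noise.environment.get(name)
                if env is not None:
                    rasters_it[name] = perturb_raster(
                        rasters[name], env.mean, env.sd, rng
                    )
            # (3) train/test split
            if cfg.split:
                train, test = split_train_test(occ_it, cfg.train_fraction, rng)
            else:
                train = test = occ_it
            # (4) fit on training data against the noised rasters
            dropped = int(
                np.sum(
                    ~np.isfinite(
                        sample_raster_at_points(rasters_it[names[0]], train)
                    )
                )
            )
            model = fit_hs_model(
                rasters_it, train, cfg.grid,
                target=cfg.target, combiner=cfg.combiner,
                aic_convention=cfg.aic_convention, ranges=ranges,
            )
            # (5) sensitivity: perturb fitted control points
            for v in model.variables:
                sds = cfg.noise.curve.get(v.name)
                if sds is not None and (sds[0] > 0 or sds[1] > 0):
                    v.curve = perturb_curve(v.curve, sds[0], sds[1], rng)
            # (6) predict
            suit = predict_map(model)
            # (7) statistics (training weights; curves may be perturbed)
            lnl = float(
                sum(log_likelihood(v.curve, v.weights) for v in model.variables)
            )
            aic_val = aic(lnl, 6 * len(names), cfg.aic_convention)
            auc = roc_auc(suit, test).auc
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise RuntimeError(f"Monte Carlo iteration {it} failed: {exc}") from exc
        if accum is None:
            accum = _MapAccumulator(suit)
        accum.add(suit)
        for v in model.variables:
            lookups[v.name].append(curve_to_lookup(v.curve))
            curves[v.name].append(v.curve)
        rows.append(
            IterationStats(
                iteration=it, loglik=lnl, aic=aic_val, auc=auc,
                dropped=dropped, n_train=train.n, n_test=test.n,
            ).__dict__
        )
    stats = pd.DataFrame(rows)
    auc_mean, auc_sd = running_stats(stats["auc"])
    aic_mean, aic_sd = running_stats(stats["aic"])
    running = pd.DataFrame(
        {
            "iteration": stats["iteration"],
            "auc_mean": auc_mean,
            "auc_sd": auc_sd,
            "aic_mean": aic_mean,
            "aic_sd": aic_sd,
        }
    )
    from .curves import bin_centers

    envelopes = {
        n: _curve_envelope(np.stack(lookups[n]), bin_centers(*ranges[n]))
        for n in names
    }
    jk = None
    if cfg.jackknife:
        jk = jackknife(
            rasters, occ, cfg.grid,
            target=cfg.target, combiner=cfg.combiner,
            aic_convention=cfg.aic_convention, ranges=ranges,
        )
    return MCResult(
        stats=stats,
        maps=accum.result(),
        envelopes=envelopes,
        curves=curves,
        running=running,
        jackknife=jk,
        config=cfg,
    )
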