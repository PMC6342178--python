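"""Histogram-accelerated maximum likelihood fitting of response curves.

The model for one variable is a four-control-point Bezier curve.  Its
likelihood against binned data is

    lnL = sum_j w_j * ln p(h_j)        p(h_j) = v_j / sum_k v_k

where h_j are the bin centers, v_j the curve's suitability at h_j, and w_j
either the occurrence counts per bin (f1 target) or the rescaled ratio
histogram values used as pseudo-counts (f1/f target, the default).  The
discrete normalization by sum_k v_k is the "area under the model" on the bin
grid.  Because the sum runs over bins rather than occurrences, fitting time
is independent of the number of occurrences.

Fitting enumerates control-point positions on a grid (10 x 10 by default:
x over [vmin, vmax], y over [0, 1]; the two end points are restricted to
their feasible edges), keeps the maximum-likelihood combination, and
recursively re-grids a +/- one-cell neighborhood around the winner.

Implementation notes
--------------------
For a fixed tuple of control-point x positions, the curve value at every bin
center is *linear* in the four control-point y values: v_j = M_j . y with a
basis matrix M that depends only on the x tuple.  The search therefore
enumerates feasible x tuples, computes M once per tuple (inverting x(t) by a
sampled-interpolation + Newton step), and scores all y combinations with
dense linear algebra.  The normalized likelihood is invariant to uniform
scaling of the y values (and near-identical normalized shapes are realized
by polygons with different absolute peaks), so curve amplitude is not
identified by the data.  Selection therefore follows a profile-likelihood
style rule: among candidates within ``ridge_tolerance`` nats of the
optimum, the one with the largest canonical curve peak wins; remaining
ties go to the first candidate in enumeration order, which runs x
ascending and y *descending* within each control point and so also prefers
large amplitudes.  The reported log-likelihood of the selected curve is
always recomputed with the exact bisection-based curve evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import ResponseCurve, bin_centers, curve_to_lookup, suitability_many

__all__ = [
    "PROB_FLOOR",
    "GridSearchConfig",
    "FitTargetWeights",
    "FitResult",
    "log_likelihood",
    "direct_log_likelihood",
    "aic",
    "fit_curve",
]

#: floor applied to bin probabilities before the log; keeps the search finite
#: while still heavily penalizing curves that zero out occupied bins
PROB_FLOOR = 1e-12

#: relative tolerance under which two candidate scores are treated as tied
#: (ties are then broken by enumeration order); covers the floating-point
#: noise of the vectorized scoring path
TIE_RTOL = 1e-6

_T_SAMPLES = 257  # t-grid used to initialize the x(t) inversion


class DegenerateRangeError(ValueError):
    """vmax == vmin: no variable range to fit over."""


@dataclass
class GridSearchConfig:
    """Geometry of the recursive grid search.

    grid_rows/grid_cols control the candidate grid (y and x node counts),
    levels the number of recursive refinements, and shrink the fraction of
    the previous grid spacing spanned by each refinement window (1.0 means
    +/- one previous cell).
    """

    grid_rows: int = 10
    grid_cols: int = 10
    levels: int = 3
    shrink: float = 1.0
    #: log-likelihood half-width of the amplitude ridge: candidates within
    #: this many nats of the optimum are treated as statistically
    #: indistinguishable in shape and the one with the largest canonical
    #: curve peak is selected (see module docstring); 0 reduces selection to
    #: the plain argmax
    ridge_tolerance: float = 10.0

    def __post_init__(self) -> None:
        if self.grid_rows < 2 or self.grid_cols < 2:
            raise ValueError("grid_rows and grid_cols must be >= 2")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if not 0 < self.shrink <= 2:
            raise ValueError("shrink must be in (0, 2]")
        if self.ridge_tolerance < 0:
            raise ValueError("ridge_tolerance must be >= 0")


@dataclass
class FitTargetWeights:
    """256 non-negative weights the curve is fit to.

    source 'f1' means raw occurrence counts C_j; 'ratio' means the rescaled
    f1/f histogram used as pseudo-counts (the default target).
    """

    weights: np.ndarray
    source: str = "ratio"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1:
            raise ValueError("weights must be a 1D array")
        if np.any(w < 0) or not np.sum(w) > 0:
            raise ValueError("weights must be non-negative with a positive sum")
        if self.source not in ("f1", "ratio"):
            raise ValueError("source must be 'f1' or 'ratio'")
        self.weights = w


@dataclass
class FitResult:
    curve: ResponseCurve
    loglik: float
    aic: float
    k: int = 6
    evaluations: int = 0
    #: (level, running-best exact lnL, candidate evaluations) per level
    levels: list[tuple[int, float, int]] = field(default_factory=list)
    #: True when the selected curve is zero on every bin (floor-dominated fit)
    degenerate: bool = False


def _as_weights(w) -> np.ndarray:
    if isinstance(w, FitTargetWeights):
        return w.weights
    return np.asarray(w, dtype=float)


def log_likelihood(c: ResponseCurve, w) -> float:
    """Binned log-likelihood of curve c under weights w (length = bin count)."""
    w = _as_weights(w)
    v = curve_to_lookup(c, len(w))
    s = v.sum()
    if s <= 0:
        return float(w.sum() * np.log(PROB_FLOOR))
    p = np.maximum(v / s, PROB_FLOOR)
    return float(w @ np.log(p))


def direct_log_likelihood(c: ResponseCurve, values: np.ndarray, nbins: int = 256) -> float:
    """Per-occurrence log-likelihood sum_i ln p(z_i) with the same discrete
    normalization as the histogram path (area = sum of the nbins lookup).

    Used to quantify the quantization error of the histogram acceleration.
    """
    z = np.clip(np.asarray(values, dtype=float), c.vmin, c.vmax)
    v = suitability_many(c, z)
    s = curve_to_lookup(c, nbins).sum()
    if s <= 0:
        return float(len(z) * np.log(PROB_FLOOR))
    p = np.maximum(v / s, PROB_FLOOR)
    return float(np.sum(np.log(p)))


def aic(loglik: float, k: int = 6, convention: str = "paper") -> float:
    """Akaike information criterion.

    convention 'paper' uses AIC = 2k - lnL, matching the printed outputs of
    earlier habitat-modeling software; 'standard' uses the textbook
    AIC = 2k - 2 lnL.  Model ranking is unaffected because k is shared
    across models.
    """
    if convention == "paper":
        return 2.0 * k - loglik
    if convention == "standard":
        return 2.0 * k - 2.0 * loglik
    raise ValueError("convention must be 'paper' or 'standard'")


# ----------------------------------------------------------------------
# candidate axes


class _CandidateAxis:
    """Candidates for one control point, grouped by x.

    Canonical enumeration order: x ascending, y descending within x.  The
    flat index over that order defines tie-breaking ranks.
    """

    __slots__ = ("entries", "xs", "bases", "total", "xflat", "yflat")

    def __init__(self, points: list[tuple[float, float]]):
        by_x: dict[float, set[float]] = {}
        for x, y in points:
            by_x.setdefault(float(x), set()).add(float(y))
        self.entries: list[tuple[float, np.ndarray]] = []
        for x in sorted(by_x):
            ys = np.array(sorted(by_x[x], reverse=True))
            self.entries.append((x, ys))
        self.xs = np.array([e[0] for e in self.entries])
        counts = [len(e[1]) for e in self.entries]
        self.bases = np.concatenate([[0], np.cumsum(counts)])[:-1].astype(np.int64)
        self.total = int(sum(counts))
        self.xflat = np.concatenate([np.full(len(e[1]), e[0]) for e in self.entries])
        self.yflat = np.concatenate([e[1] for e in self.entries])


def _level1_axes(vmin: float, vmax: float, cfg: GridSearchConfig):
    gx = np.linspace(vmin, vmax, cfg.grid_cols)
    gy = np.linspace(0.0, 1.0, cfg.grid_rows)
    cp0 = [(vmin, y) for y in gy] + [(x, 0.0) for x in gx]
    interior = [(x, y) for x in gx for y in gy]
    cp3 = [(x, 0.0) for x in gx] + [(vmax, y) for y in gy]
    return [
        _CandidateAxis(cp0),
        _CandidateAxis(interior),
        _CandidateAxis(interior),
        _CandidateAxis(cp3),
    ]


def _window(center: float, half: float, lo: float, hi: float, n: int) -> np.ndarray:
    a = max(lo, center - half)
    b = min(hi, center + half)
    return np.unique(np.linspace(a, b, n))


def _refine_axes(
    best: ResponseCurve,
    dx: float,
    dy: float,
    vmin: float,
    vmax: float,
    cfg: GridSearchConfig,
):
    """Candidate axes for the next level: each control point re-gridded over
    a +/- shrink * previous-spacing window, intersected with its feasible
    region (interior box for cp1/cp2; left/bottom edges for cp0, bottom/right
    for cp3)."""
    wx = cfg.shrink * dx
    wy = cfg.shrink * dy
    eps = 1e-12 * max(abs(vmax - vmin), 1.0)
    axes = []
    # cp0: left and/or bottom edge segments reachable from the current best
    x0, y0 = best.cp[0].x, best.cp[0].y
    pts0: list[tuple[float, float]] = []
    if x0 - vmin <= wx + eps:
        pts0 += [(vmin, y) for y in _window(y0, wy, 0.0, 1.0, cfg.grid_rows)]
    if y0 <= wy + eps:
        pts0 += [(x, 0.0) for x in _window(x0, wx, vmin, vmax, cfg.grid_cols)]
    axes.append(_CandidateAxis(pts0))
    for p in (best.cp[1], best.cp[2]):
        xs = _window(p.x, wx, vmin, vmax, cfg.grid_cols)
        ys = _window(p.y, wy, 0.0, 1.0, cfg.grid_rows)
        axes.append(_CandidateAxis([(x, y) for x in xs for y in ys]))
    x3, y3 = best.cp[3].x, best.cp[3].y
    pts3: list[tuple[float, float]] = []
    if y3 <= wy + eps:
        pts3 += [(x, 0.0) for x in _window(x3, wx, vmin, vmax, cfg.grid_cols)]
    if vmax - x3 <= wx + eps:
        pts3 += [(vmax, y) for y in _window(y3, wy, 0.0, 1.0, cfg.grid_rows)]
    axes.append(_CandidateAxis(pts3))
    return axes


# ----------------------------------------------------------------------
# basis matrices: curve value at bin centers as a linear map of control y's

_BASIS_CACHE: dict[tuple, np.ndarray] = {}
_BASIS_CACHE_CAP = 20000


def _bernstein_rows(t: np.ndarray) -> np.ndarray:
    u = 1.0 - t
    return np.stack([u * u * u, 3 * u * u * t, 3 * u * t * t, t * t * t], axis=-1)


def _compute_basis(X: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Basis matrices M (B, nbins, 4) with v_j = M[., j, :] @ y for each of
    the B x-tuples in X; rows outside [x0, x3] are zero."""
    B, nbins = X.shape[0], z.shape[0]
    inside = (z[None, :] >= X[:, 0:1]) & (z[None, :] <= X[:, 3:4])
    tg = np.linspace(0.0, 1.0, _T_SAMPLES)
    xt = X @ _bernstein_rows(tg).T  # (B, K) non-decreasing rows
    # batched per-row searchsorted via an offset large enough to separate rows
    off = (np.ptp(xt) + np.ptp(z) + 1.0) * np.arange(B)
    flat = (xt + off[:, None]).ravel()
    q = (np.broadcast_to(z, (B, nbins)) + off[:, None]).ravel()
    k = np.searchsorted(flat, q, side="left") - np.repeat(
        np.arange(B) * _T_SAMPLES, nbins
    )
    k = np.clip(k.reshape(B, nbins), 1, _T_SAMPLES - 1)
    rows = np.arange(B)[:, None]
    x_lo = xt[rows, k - 1]
    x_hi = xt[rows, k]
    dt = tg[1] - tg[0]
    t = tg[k - 1] + (z[None, :] - x_lo) / np.maximum(x_hi - x_lo, 1e-300) * dt
    t = np.clip(t, 0.0, 1.0)
    # two Newton polish steps on x(t) - z (x monotone; guard flat spots)
    d10 = X[:, 1] - X[:, 0]
    d21 = X[:, 2] - X[:, 1]
    d32 = X[:, 3] - X[:, 2]
    scale = np.maximum(np.abs(X[:, 3] - X[:, 0]), 1.0)[:, None]
    for _ in range(2):
        u = 1.0 - t
        xv = (
            u * u * u * X[:, 0:1]
            + 3 * u * u * t * X[:, 1:2]
            + 3 * u * t * t * X[:, 2:3]
            + t * t * t * X[:, 3:4]
        )
        deriv = 3.0 * (
            u * u * d10[:, None] + 2 * u * t * d21[:, None] + t * t * d32[:, None]
        )
        step = np.where(deriv > 1e-12 * scale, (xv - z[None, :]) / np.maximum(deriv, 1e-300), 0.0)
        t = np.clip(t - step, 0.0, 1.0)
    M = _bernstein_rows(t)  # (B, nbins, 4)
    M[~inside] = 0.0
    return M


def _basis_rows(X: np.ndarray, vmin: float, vmax: float, nbins: int) -> np.ndarray:
    """Cached basis matrices for the x-tuples in X (T, 4)."""
    global _BASIS_CACHE
    z = bin_centers(vmin, vmax, nbins)
    out = np.empty((X.shape[0], nbins, 4))
    missing = []
    keys = []
    for i, row in enumerate(X):
        key = (row[0], row[1], row[2], row[3], vmin, vmax, nbins)
        keys.append(key)
        m = _BASIS_CACHE.get(key)
        if m is None:
            missing.append(i)
        else:
            out[i] = m
    if missing:
        M = _compute_basis(X[missing], z)
        if len(_BASIS_CACHE) + len(missing) > _BASIS_CACHE_CAP:
            _BASIS_CACHE = {}
        for j, i in enumerate(missing):
            out[i] = M[j]
            _BASIS_CACHE[keys[i]] = M[j]
    return out


# ----------------------------------------------------------------------
# grid search


def _search_axes(axes, w: np.ndarray, vmin: float, vmax: float, ridge_tol: float = 2.0):
    """Best candidate over the enumerated axes.

    Returns (curve, evaluations).  Selection: among candidates whose
    log-likelihood is within ``ridge_tol`` nats of the maximum (the
    amplitude ridge of the normalized likelihood, plus floating-point
    ties), the one with the largest canonical curve peak wins; remaining
    ties go to the candidate earliest in enumeration order (x ascending,
    y descending per control point).
    """
    nbins = len(w)
    W = float(w.sum())
    ln_floor = np.log(PROB_FLOOR)
    a0, a1, a2, a3 = axes
    # interior axes must share one y-array per entry for the grouped scoring
    for ax in (a1, a2):
        ys0 = ax.entries[0][1]
        for _, ys in ax.entries[1:]:
            if len(ys) != len(ys0) or not np.array_equal(ys, ys0):
                raise ValueError("interior candidate axes must share y grids")
    y1s = a1.entries[0][1]
    y2s = a2.entries[0][1]
    n1, n2 = len(y1s), len(y2s)
    N1, N2, N3 = a1.total, a2.total, a3.total

    # enumerate feasible x-index tuples (ordering; zero-width support skipped)
    tuples: list[tuple[int, int, int, int]] = []
    for a, xa in enumerate(a0.xs):
        for b, xb in enumerate(a1.xs):
            if xb < xa:
                continue
            for c, xc in enumerate(a2.xs):
                if xc < xb:
                    continue
                for d, xd in enumerate(a3.xs):
                    if xd < xc or xd <= xa:
                        continue
                    tuples.append((a, b, c, d))
    if not tuples:
        raise ValueError("no feasible control-point combination")
    tup = np.array(tuples, dtype=np.int64)
    X = np.column_stack(
        [a0.xs[tup[:, 0]], a1.xs[tup[:, 1]], a2.xs[tup[:, 2]], a3.xs[tup[:, 3]]]
    )
    M = _basis_rows(X, vmin, vmax, nbins)
    # single precision for the bulk scoring passes; differences this loses
    # (well under a millinat per candidate) are absorbed by the selection
    # tolerances, and the winner is re-scored in double precision
    M32 = M.astype(np.float32)
    w32 = w.astype(np.float32)

    best_val = -np.inf
    best_arg: tuple[float, float, int] | None = None  # (lnL, peak, rank) of argmax
    res_val: list[np.ndarray] = []
    res_peak: list[np.ndarray] = []
    res_rank: list[np.ndarray] = []
    evaluations = 0
    # group tuples by the y-arrays of their end points; end-point entries
    # carry at most two distinct y-arrays (edge segment vs single bottom
    # node), so this yields at most four large batches
    def _entry_groups(ax: _CandidateAxis) -> dict[bytes, list[int]]:
        groups: dict[bytes, list[int]] = {}
        for i, (_, ys) in enumerate(ax.entries):
            groups.setdefault(ys.tobytes(), []).append(i)
        return groups

    groups0 = _entry_groups(a0)
    groups3 = _entry_groups(a3)
    chunk_elems = 6_000_000
    for key0, set0 in groups0.items():
        for key3, set3 in groups3.items():
            pick = np.isin(tup[:, 0], set0) & np.isin(tup[:, 3], set3)
            idxs = np.nonzero(pick)[0]
            if idxs.size == 0:
                continue
            y0s = a0.entries[set0[0]][1]
            y3s = a3.entries[set3[0]][1]
            m0, m3 = len(y0s), len(y3s)
            nY = m0 * n1 * n2 * m3
            # y-combination block in canonical row order (i0, i1, i2, i3)
            Y = np.stack(
                [g.ravel() for g in np.meshgrid(y0s, y1s, y2s, y3s, indexing="ij")],
                axis=-1,
            )  # (nY, 4)
            Y32 = Y.astype(np.float32)
            ymax = np.maximum(Y.max(axis=1), 1e-300)
            rows_per = max(1, chunk_elems // max(nY * nbins, 1))
            for s in range(0, len(idxs), rows_per):
                sel = idxs[s : s + rows_per]
                Mg = M32[sel]  # (tc, nbins, 4)
                V = np.matmul(Y32, Mg.transpose(0, 2, 1))  # (tc, nY, nbins)
                S = V.sum(axis=2, dtype=np.float32)
                # epsilon-add stands in for the probability floor during the
                # search (identical outside-support behavior, O(1e-12)
                # relative elsewhere); the winner is re-scored exactly
                V += (S * np.float32(PROB_FLOOR) + np.float32(1e-38))[:, :, None]
                np.log(V, out=V)
                lnL = (V @ w32).astype(np.float64) - W * np.log(
                    np.maximum(S.astype(np.float64), 1e-300)
                )
                lnL[S <= 0] = W * ln_floor
                evaluations += lnL.size
                m = float(lnL.max())
                delta = max(ridge_tol, TIE_RTOL * (1.0 + abs(max(m, best_val))))
                if m > best_val:
                    best_val = m
                ti, yi = np.nonzero(lnL >= best_val - delta)
                if ti.size:
                    # canonical curve peaks, computed only for the eligible set
                    Vsub = np.einsum(
                        "cjk,ck->cj", Mg[ti], Y[yi]
                    )  # (n_eligible, nbins)
                    peak_sub = Vsub.max(axis=1) / ymax[yi]
                    tt = tup[np.asarray(sel)[ti]]
                    i3 = yi % m3
                    r = yi // m3
                    i2 = r % n2
                    r //= n2
                    i1 = r % n1
                    i0 = r // n1
                    g0 = a0.bases[tt[:, 0]] + i0
                    g1 = a1.bases[tt[:, 1]] + i1
                    g2 = a2.bases[tt[:, 2]] + i2
                    g3 = a3.bases[tt[:, 3]] + i3
                    rank = ((g0 * N1 + g1) * N2 + g2) * N3 + g3
                    pk = peak_sub
                    lv = lnL[ti, yi]
                    # remember the running argmax so the final reservoir can
                    # never be emptied by a later rise of the threshold
                    j = int(np.argmax(lv))
                    if best_arg is None or lv[j] > best_arg[0]:
                        best_arg = (float(lv[j]), float(pk[j]), int(rank[j]))
                    # keep only the highest-peak eligible candidates per chunk
                    if ti.size > 64:
                        order = np.lexsort((rank, -pk))[:64]
                        lv, pk, rank = lv[order], pk[order], rank[order]
                    res_val.append(lv)
                    res_peak.append(pk)
                    res_rank.append(rank)
                if sum(v.size for v in res_val) > 100_000:
                    kv = np.concatenate(res_val)
                    kp = np.concatenate(res_peak)
                    kr = np.concatenate(res_rank)
                    keep = kv >= best_val - delta
                    res_val, res_peak, res_rank = [kv[keep]], [kp[keep]], [kr[keep]]

    vals = np.concatenate(res_val + [np.array([best_arg[0]])])
    peaks = np.concatenate(res_peak + [np.array([best_arg[1]])])
    ranks = np.concatenate(res_rank + [np.array([best_arg[2]], dtype=np.int64)])
    delta = max(ridge_tol, TIE_RTOL * (1.0 + abs(best_val)))
    ok = vals >= best_val - delta
    peaks, ranks = peaks[ok], ranks[ok]
    rank = int(ranks[np.lexsort((ranks, -peaks))[0]])
    # decompose the winning rank back into per-control-point candidates
    g3 = rank % N3
    rank //= N3
    g2 = rank % N2
    rank //= N2
    g1 = rank % N1
    g0 = rank // N1
    cps = [
        (a0.xflat[g0], a0.yflat[g0]),
        (a1.xflat[g1], a1.yflat[g1]),
        (a2.xflat[g2], a2.yflat[g2]),
        (a3.xflat[g3], a3.yflat[g3]),
    ]
    return ResponseCurve(cps, vmin, vmax), evaluations


def _canonical_amplitude(c: ResponseCurve) -> ResponseCurve:
    """Scale control-point y values so their maximum is 1.

    The normalized likelihood is invariant to uniform scaling of the control
    y values, so curve amplitude is not identified by the fit; the canonical
    representative with peak control weight 1 is reported (matching the
    max-1 rescaling of the fit-target histograms).
    """
    m = float(c.ys.max())
    if m <= 0 or m == 1.0:
        return c
    return ResponseCurve(
        [(p.x, p.y / m) for p in c.cp], c.vmin, c.vmax
    )


def fit_curve(
    w,
    vmin: float,
    vmax: float,
    cfg: GridSearchConfig | None = None,
    aic_convention: str = "paper",
) -> FitResult:
    """Recursive grid-search maximum-likelihood fit of one response curve.

    w is a FitTargetWeights or a plain array of bin weights (its length sets
    the bin count).  Returns the best curve found with its exact
    log-likelihood and AIC (k = 6).
    """
    if cfg is None:
        cfg = GridSearchConfig()
    weights = _as_weights(w)
    if not np.sum(weights) > 0:
        raise ValueError("weights must have a positive sum")
    if not vmax > vmin:
        raise DegenerateRangeError(
            f"cannot fit over a degenerate range [{vmin}, {vmax}]"
        )
    axes = _level1_axes(vmin, vmax, cfg)
    dx = (vmax - vmin) / (cfg.grid_cols - 1)
    dy = 1.0 / (cfg.grid_rows - 1)
    best_curve = None
    best_lnl = -np.inf
    evaluations = 0
    levels: list[tuple[int, float, int]] = []
    for level in range(1, cfg.levels + 1):
        if level > 1:
            axes = _refine_axes(best_curve, dx, dy, vmin, vmax, cfg)
            dx = 2.0 * cfg.shrink * dx / (cfg.grid_cols - 1)
            dy = 2.0 * cfg.shrink * dy / (cfg.grid_rows - 1)
        curve, n_eval = _search_axes(axes, weights, vmin, vmax, cfg.ridge_tolerance)
        curve = _canonical_amplitude(curve)
        evaluations += n_eval
        lnl = log_likelihood(curve, weights)
        if lnl > best_lnl:
            best_lnl = lnl
            best_curve = curve
        levels.append((level, best_lnl, n_eval))
    degenerate = not np.any(curve_to_lookup(best_curve, len(weights)) > 0)
    return FitResult(
        curve=best_curve,
        loglik=best_lnl,
        aic=aic(best_lnl, 6, aic_convention),
        k=6,
        evaluations=evaluations,
        levels=levels,
        degenerate=degenerate,
    )
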