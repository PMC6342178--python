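"""Bezier response curves: the per-variable habitat suitability model.

A response curve maps an environmental value z in [vmin, vmax] to a
suitability in [0, 1].  It is a single cubic Bezier through four control
points whose x coordinates are non-decreasing; the first point must lie on
the left or bottom edge of the graph and the last on the bottom or right
edge.  Those edge constraints give the end points one degree of freedom
each and the interior points two each: six estimated parameters per curve.

Because x(t) is monotone for an x-ordered control polygon, the curve can be
read as a function y(z); values of z left of the first or right of the last
control point are unsuitable (suitability 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ControlPoint",
    "ResponseCurve",
    "validate_curve",
    "bezier_point",
    "suitability_at",
    "suitability_many",
    "curve_to_lookup",
    "curve_to_text",
    "curve_from_text",
]

#: bisection iterations used to invert x(t); 2^-40 in t is far below the
#: 1e-9 * range tolerance on x for any control polygon
_BISECT_ITERS = 40
_EDGE_TOL = 1e-9


@dataclass(frozen=True)
class ControlPoint:
    x: float
    y: float


class ResponseCurve:
    """Four constrained control points over a variable range [vmin, vmax]."""

    __slots__ = ("cp", "vmin", "vmax", "_xs", "_ys")

    def __init__(
        self,
        cp: Sequence[ControlPoint | tuple[float, float]],
        vmin: float,
        vmax: float,
    ) -> None:
        pts = tuple(
            p if isinstance(p, ControlPoint) else ControlPoint(float(p[0]), float(p[1]))
            for p in cp
        )
        if len(pts) != 4:
            raise ValueError("a response curve needs exactly four control points")
        self.cp = pts
        self.vmin = float(vmin)
        self.vmax = float(vmax)
        self._xs = np.array([p.x for p in pts])
        self._ys = np.array([p.y for p in pts])

    @property
    def xs(self) -> np.ndarray:
        return self._xs

    @property
    def ys(self) -> np.ndarray:
        return self._ys

    def __repr__(self) -> str:
        pts = ", ".join(f"({p.x:g}, {p.y:g})" for p in self.cp)
        return f"ResponseCurve([{pts}], vmin={self.vmin:g}, vmax={self.vmax:g})"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ResponseCurve):
            return NotImplemented
        return (
            self.cp == other.cp and self.vmin == other.vmin and self.vmax == other.vmax
        )

    def __hash__(self) -> int:
        return hash((self.cp, self.vmin, self.vmax))


def validate_curve(c: ResponseCurve) -> list[str]:
    """Return descriptions of every violated curve invariant (empty = valid)."""
    out: list[str] = []
    xs, ys = c.xs, c.ys
    rng = c.vmax - c.vmin
    tol = _EDGE_TOL * max(abs(rng), 1.0)
    if c.vmax < c.vmin:
        out.append("vmax < vmin")
    if np.any(ys < -_EDGE_TOL) or np.any(ys > 1 + _EDGE_TOL):
        out.append("control point y outside [0, 1]")
    if np.any(xs < c.vmin - tol) or np.any(xs > c.vmax + tol):
        out.append("control point x outside [vmin, vmax]")
    if np.any(np.diff(xs) < -tol):
        out.append("control point x values not in non-decreasing order")
    cp0, cp3 = c.cp[0], c.cp[3]
    if not (abs(cp0.x - c.vmin) <= tol or abs(cp0.y) <= _EDGE_TOL):
        out.append("cp0 off left/bottom edge")
    if not (abs(cp3.x - c.vmax) <= tol or abs(cp3.y) <= _EDGE_TOL):
        out.append("cp3 off bottom/right edge")
    if rng > tol and abs(xs[3] - xs[0]) <= tol:
        out.append("all control point x values coincide (degenerate spike)")
    return out


def _bernstein(p: np.ndarray, t: np.ndarray | float) -> np.ndarray | float:
    """Cubic Bezier component with control values p[0..3] at parameter t."""
    u = 1.0 - t
    return (
        u * u * u * p[0]
        + 3.0 * u * u * t * p[1]
        + 3.0 * u * t * t * p[2]
        + t * t * t * p[3]
    )


def bezier_point(c: ResponseCurve, t: float) -> tuple[float, float]:
    """Point on the cubic Bezier at parameter t in [0, 1]."""
    if not (0.0 <= t <= 1.0):
        raise ValueError(f"t must be in [0, 1], got {t}")
    return float(_bernstein(c.xs, t)), float(_bernstein(c.ys, t))


def invert_bezier_x(xs: np.ndarray, z: np.ndarray, iters: int = _BISECT_ITERS) -> np.ndarray:
    """Solve x(t) = z by bisection for each z (assumes x-ordered control points).

    z values must lie within [xs[0], xs[3]].  Vectorized over z.
    """
    z = np.asarray(z, dtype=float)
    lo = np.zeros(z.shape)
    hi = np.ones(z.shape)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        below = _bernstein(xs, mid) < z
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return 0.5 * (lo + hi)


def suitability_many(c: ResponseCurve, z: np.ndarray) -> np.ndarray:
    """Vectorized suitability; z outside [cp0.x, cp3.x] gives 0.

    No domain check: callers are expected to pass values within (or clamped
    to) [vmin, vmax].
    """
    z = np.asarray(z, dtype=float)
    xs, ys = c.xs, c.ys
    out = np.zeros(z.shape)
    inside = (z >= xs[0]) & (z <= xs[3])
    if xs[3] - xs[0] <= 0:
        # degenerate spike: all mass at a single x
        out[inside] = np.clip(ys.max(), 0.0, 1.0)
        return out
    if np.any(inside):
        t = invert_bezier_x(xs, z[inside])
        out[inside] = np.clip(_bernstein(ys, t), 0.0, 1.0)
    return out


def suitability_at(c: ResponseCurve, z: float) -> float:
    """Suitability at a single value z in [vmin, vmax].

    For cp0.x <= z <= cp3.x this is y(t*) with x(t*) = z (unique by
    monotonicity, found by bisection); values left of cp0 or right of cp3
    are unsuitable (0).  The result is clamped to [0, 1].
    """
    if not (c.vmin <= z <= c.vmax):
        raise ValueError(f"z={z} outside the variable range [{c.vmin}, {c.vmax}]")
    return float(suitability_many(c, np.array([z]))[0])


def bin_centers(vmin: float, vmax: float, nbins: int = 256) -> np.ndarray:
    """Centers of nbins equal bins over [vmin, vmax]."""
    return vmin + (np.arange(nbins) + 0.5) * (vmax - vmin) / nbins


def curve_to_lookup(c: ResponseCurve, nbins: int = 256) -> np.ndarray:
    """Suitability evaluated at the nbins bin centers of [vmin, vmax].

    This lookup is the curve's interface to histograms and raster prediction.
    """
    return suitability_many(c, bin_centers(c.vmin, c.vmax, nbins))


def curve_to_text(c: ResponseCurve) -> str:
    """Serialize to a plain-text block: range line plus four x y lines."""
    lines = [f"range {c.vmin!r} {c.vmax!r}"]
    lines += [f"{p.x!r} {p.y!r}" for p in c.cp]
    return "\n".join(lines) + "\n"


def curve_from_text(text: str | Iterable[str]) -> ResponseCurve:
    """Parse the output of :func:`curve_to_text`."""
    if isinstance(text, str):
        lines = [ln for ln in text.splitlines() if ln.strip()]
    else:
        lines = [ln for ln in text if ln.strip()]
    if len(lines) != 5 or not lines[0].split()[0] == "range":
        raise ValueError("curve text must be a 'range vmin vmax' line and four 'x y' lines")
    _, vmin, vmax = lines[0].split()
    cps = []
    for ln in lines[1:]:
        x, y = ln.split()
        cps.append(ControlPoint(float(x), float(y)))
    return ResponseCurve(cps, float(vmin), float(vmax))
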