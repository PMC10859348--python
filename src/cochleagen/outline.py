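"""Closed canal outline through the nine boundary landmarks.

The source images give nine boundary landmarks per cross-section; the wall
between them is interpolated with a closed C1 periodic cubic spline in a
chord-length parameter.  The outline supports the queries the landmark
construction needs: ray and axis-line crossings (bisection-refined on the
spline), point containment, and extraction of oriented wall arcs between
two points known to lie on the outline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq
from shapely.geometry import Point, Polygon

__all__ = ["CanalOutline", "OutlineError"]


class OutlineError(ValueError):
    """Degenerate or self-intersecting canal outline."""


@dataclass(frozen=True)
class _Crossing:
    point: np.ndarray     # (2,) crossing location
    s: float              # outline parameter in [0, 1)
    t: float              # parameter along the query line / ray


class CanalOutline:
    """Closed composite cubic curve through an ordered landmark loop.

    Parameters
    ----------
    points:
        (n, 2) array of landmark coordinates in canonical order around the
        wall.  Orientation is normalised to counter-clockwise internally.
    resolution:
        Number of polyline samples used for intersection bracketing and
        polygon queries.
    """

    def __init__(self, points: np.ndarray, resolution: int = 512):
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise OutlineError("outline needs at least three 2D points")
        # signed area (shoelace) to normalise orientation
        x, y = pts[:, 0], pts[:, 1]
        area2 = float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        if area2 == 0:
            raise OutlineError("outline landmarks are collinear")
        if area2 < 0:
            pts = np.vstack([pts[:1], pts[1:][::-1]])
        self._landmarks = pts

        closed = np.vstack([pts, pts[:1]])
        seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        if np.any(seg == 0):
            raise OutlineError("coincident consecutive outline landmarks")
        u = np.concatenate([[0.0], np.cumsum(seg)])
        self._period = float(u[-1])
        self._u = u / self._period  # normalised arc-ish parameter in [0, 1]
        self._spline = CubicSpline(self._u, closed, axis=0, bc_type="periodic")

        self.resolution = int(resolution)
        s = np.linspace(0.0, 1.0, self.resolution, endpoint=False)
        self._s_samples = s
        self._poly_pts = self._spline(s)
        self._polygon = Polygon(self._poly_pts)
        if not self._polygon.is_valid:
            raise OutlineError("sampled outline is self-intersecting")

    # ------------------------------------------------------------------
    @property
    def landmark_points(self) -> np.ndarray:
        return self._landmarks.copy()

    @property
    def polygon(self) -> Polygon:
        """Shapely polygon of the sampled outline (CCW)."""
        return self._polygon

    def point(self, s: float | np.ndarray) -> np.ndarray:
        """Evaluate the spline at parameter ``s`` (wrapped to [0, 1))."""
        return self._spline(np.mod(s, 1.0))

    def sample(self, n: int | None = None) -> np.ndarray:
        """(n, 2) polyline sample of the outline (not closed)."""
        if n is None:
            return self._poly_pts.copy()
        s = np.linspace(0.0, 1.0, int(n), endpoint=False)
        return self._spline(s)

    def contains(self, p, tol: float = 0.0) -> bool:
        pt = Point(float(p[0]), float(p[1]))
        if tol > 0:
            return self._polygon.buffer(tol).contains(pt)
        return self._polygon.covers(pt)

    def distance_to(self, p) -> float:
        """Distance from ``p`` to the sampled outline curve."""
        return float(self._polygon.exterior.distance(Point(float(p[0]), float(p[1]))))

    # ------------------------------------------------------------------
    def _line_crossings(self, origin, direction) -> list[_Crossing]:
        """All crossings of the infinite line origin + t*direction."""
        o = np.asarray(origin, dtype=float)
        d = np.asarray(direction, dtype=float)
        nrm = np.linalg.norm(d)
        if nrm == 0:
            raise ValueError("zero direction vector")
        d = d / nrm
        n = np.array([-d[1], d[0]])  # left normal

        s = self._s_samples
        f = (self._poly_pts - o) @ n  # signed distance of samples to the line
        crossings: list[_Crossing] = []
        fn = np.roll(f, -1)
        idx = np.nonzero((f == 0) | (np.sign(f) != np.sign(fn)))[0]
        for i in idx:
            s0 = s[i]
            s1 = s[(i + 1) % len(s)]
            if s1 <= s0:
                s1 = s0 + 1.0 / self.resolution

            def g(sv):
                return float((self._spline(np.mod(sv, 1.0)) - o) @ n)

            g0, g1 = g(s0), g(s1)
            if g0 == 0.0:
                root = s0
            elif np.sign(g0) == np.sign(g1):
                continue
            else:
                root = brentq(g, s0, s1, xtol=1e-12)
            p = self._spline(np.mod(root, 1.0))
            crossings.append(_Crossing(point=p, s=float(np.mod(root, 1.0)),
                                       t=float((p - o) @ d)))
        # deduplicate near-identical roots from adjacent brackets
        out: list[_Crossing] = []
        for c in sorted(crossings, key=lambda c: c.s):
            if out and (abs(c.s - out[-1].s) < 1e-9 or abs(c.s - out[-1].s) > 1 - 1e-9):
                continue
            out.append(c)
        return out

    def ray_crossings(self, origin, direction, t_min: float = 1e-9) -> list[_Crossing]:
        """Crossings of the ray (t >= t_min), ordered by distance."""
        cs = [c for c in self._line_crossings(origin, direction) if c.t >= t_min]
        return sorted(cs, key=lambda c: c.t)

    def first_ray_hit(self, origin, direction, t_min: float = 1e-9) -> _Crossing:
        cs = self.ray_crossings(origin, direction, t_min=t_min)
        if not cs:
            raise OutlineError("ray does not intersect the outline")
        return cs[0]

    def axis_crossings(self, axis: str, value: float) -> list[_Crossing]:
        """Crossings with the line x = value (axis='x') or y = value.

        Returned ordered by the other coordinate (the line parameter).
        """
        if axis == "x":
            origin, direction = (value, 0.0), (0.0, 1.0)
        elif axis == "y":
            origin, direction = (0.0, value), (1.0, 0.0)
        else:
            raise ValueError("axis must be 'x' or 'y'")
        return sorted(self._line_crossings(origin, direction), key=lambda c: c.t)

    def locate(self, p, tol: float = 1e-6) -> float:
        """Outline parameter of a point known to lie on the outline."""
        from scipy.optimize import minimize_scalar

        p = np.asarray(p, dtype=float)
        d2 = np.sum((self._poly_pts - p) ** 2, axis=1)
        i = int(np.argmin(d2))
        lo = self._s_samples[i] - 1.5 / self.resolution
        hi = self._s_samples[i] + 1.5 / self.resolution
        res = minimize_scalar(
            lambda sv: float(np.sum((self._spline(np.mod(sv, 1.0)) - p) ** 2)),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-13},
        )
        s = float(np.mod(res.x, 1.0))
        if np.linalg.norm(self.point(s) - p) > max(tol, 1e-9) * max(1.0, self._period):
            raise OutlineError("point does not lie on the outline")
        return s

    def arc(self, s0: float, s1: float, n: int = 64, direction: int = +1) -> np.ndarray:
        """Sampled arc from parameter ``s0`` to ``s1``.

        ``direction=+1`` walks in increasing parameter (CCW), ``-1`` CW.
        Endpoints included.
        """
        s0 = float(np.mod(s0, 1.0))
        s1 = float(np.mod(s1, 1.0))
        if direction == +1:
            span = np.mod(s1 - s0, 1.0)
        elif direction == -1:
            span = -np.mod(s0 - s1, 1.0)
        else:
            raise ValueError("direction must be +1 or -1")
        ss = s0 + np.linspace(0.0, span, max(int(n), 2))
        return self._spline(np.mod(ss, 1.0))
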