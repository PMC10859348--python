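"""Construction of the internal cross-section geometry.

Given the nine canal-boundary landmarks and a parameter set in mm, this
module places the internal landmarks (a, b, c, d, e, f, g, h, i, k, l, o,
p), fits the two quartic Bezier curves bounding the spiral ligament, and
assembles the labelled tissue regions and thin-membrane interface layers
of one cross-section.

All constructions happen in a local frame derived from the boundary
landmarks themselves (origin at LS, +x toward the midpoint of MSVS/MSTS,
+y toward the superior landmark SS), which makes the whole pipeline
equivariant under rigid motion, mirroring and uniform scaling of the
input.

Construction sequence (each step names the parameters it consumes):

1.  ``a``   lateral wall point at signed vertical offset Wa from LS.
2.  lamina line through ``a`` at angle alpha to the local horizontal.
3.  ``g``   medial wall intersection of the lamina line.
4.  ``k``   ligament/BM junction at distance Wsl from ``a`` along the line.
5.  ``h``   organ-of-Corti point: distance Wm from LS parallel to the line.
6.  ``i``   ``h`` offset perpendicularly (vestibular side) by the lamina
    thickness Hsg.
7.  ``o``/``p`` lamina extent: chord distances Ft (tympanic edge) and Fv
    (vestibular edge) from ``a``; the bony strip between them and the
    medial wall is emitted as a modiolar-bone wedge.
8.  ``c``/``d`` ligament/wall intersections at horizontal offsets Wc
    (above) and Wd (below) from ``a``.
9.  ``e``/``f`` ligament mid-points from the chords k-c / k-d via
    (Hkn, phi_en) and (Hkm, phi_fm); the along-chord component is capped
    at 75% of the chord and the lateral offset is capped at 50% of the
    free distance to the wall (and shrunk further if needed) so the
    ligament boundary always remains a valid crescent inside the canal.
10. ``l``  Reissner's-membrane root on the lamina's vestibular edge at
    distance Wsm medial of ``i``.
11. ``b``  Reissner's membrane cast up-laterally from ``l`` (rotated by
    pi - beta from the lamina direction) until it meets the ligament
    boundary (or, for apical sections, the vestibular wall).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

from .equations import ParameterSet
from .outline import CanalOutline, OutlineError

__all__ = [
    "BOUNDARY_NAMES",
    "INTERNAL_NAMES",
    "REGION_CONDUCTIVITY",
    "INTERFACE_PROPERTIES",
    "BoundaryLandmarks",
    "InternalLandmarks",
    "BezierCurve",
    "TissueRegion",
    "InterfaceLayer",
    "CrossSectionGeometry",
    "GeometryError",
    "basal_canal_width",
    "bezier_point",
    "line_outline_intersection",
    "construct_internal_landmarks",
    "build_spiral_ligament",
    "assemble_cross_section",
]

BOUNDARY_NAMES = ("LS", "SLS", "SS", "SMS", "MSVS", "MSTS", "IMS", "IS", "ILS")
INTERNAL_NAMES = ("a", "b", "c", "d", "e", "f", "g", "h", "i", "k", "l", "o", "p")

#: Bulk conductivities of the homogeneous tissue regions, S/m.
REGION_CONDUCTIVITY = {
    "scala_tympani": 1.43,
    "scala_vestibuli": 1.43,
    "scala_media": 1.67,
    "spiral_ligament": 1.67,
    "spiral_lamina_nerve": 0.33,
    "modiolar_bone": 0.016,
}

#: Thin layers simulated as contact impedances: (conductivity S/m, thickness mm).
INTERFACE_PROPERTIES = {
    "temporal_bone": (0.0334, 0.02),
    "basilar_membrane": (0.0126, 0.005),
    "reissner_membrane": (0.0001, 0.002),
    "stria_vascularis": (0.005, 0.01),
}


class GeometryError(ValueError):
    """A landmark or region could not be constructed."""


# ----------------------------------------------------------------------
# basic primitives
# ----------------------------------------------------------------------

def bezier_point(control: np.ndarray, t) -> np.ndarray:
    """Evaluate a fourth-order (five-control-point) Bezier curve.

    ``t`` may be scalar or an array in [0, 1]; Bernstein form.
    """
    P = np.asarray(control, dtype=float)
    if P.shape != (5, 2):
        raise ValueError(f"fourth-order Bezier needs 5 control points, got {P.shape}")
    t = np.asarray(t, dtype=float)
    if np.any(t < -1e-12) or np.any(t > 1 + 1e-12):
        raise ValueError("Bezier parameter t must lie in [0, 1]")
    t = np.clip(t, 0.0, 1.0)
    s = 1.0 - t
    w = np.stack([s**4, 4 * s**3 * t, 6 * s**2 * t**2, 4 * s * t**3, t**4], axis=-1)
    out = w @ P
    return out


@dataclass(frozen=True)
class BezierCurve:
    """Quartic Bezier with cached dense sampling."""

    control: np.ndarray

    def __call__(self, t):
        return bezier_point(self.control, t)

    def sample(self, n: int = 200) -> np.ndarray:
        return bezier_point(self.control, np.linspace(0.0, 1.0, n))


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n == 0:
        raise GeometryError("zero-length direction")
    return v / n


def _ray_polyline_hits(origin, direction, polyline) -> list[tuple[float, float, np.ndarray]]:
    """Intersections of a ray with a polyline.

    Returns a list of (t_ray, idx_frac, point) ordered by ``t_ray`` where
    ``idx_frac`` is the fractional vertex index in [0, 1] (for a polyline
    sampled uniformly in a curve parameter this equals that parameter).
    """
    o = np.asarray(origin, float)
    d = _unit(np.asarray(direction, float))
    P = np.asarray(polyline, float)
    A, B = P[:-1], P[1:]
    e = B - A
    denom = d[0] * e[:, 1] - d[1] * e[:, 0]
    w = A - o
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (w[:, 0] * e[:, 1] - w[:, 1] * e[:, 0]) / denom
        u = (w[:, 0] * d[1] - w[:, 1] * d[0]) / -denom
    ok = np.isfinite(t) & np.isfinite(u) & (u >= -1e-12) & (u <= 1 + 1e-12) & (t > 1e-9)
    hits = []
    nseg = len(e)
    for i in np.nonzero(ok)[0]:
        pt = o + t[i] * d
        idx_frac = (i + u[i]) / nseg
        hits.append((float(t[i]), float(np.clip(idx_frac, 0.0, 1.0)), pt))
    hits.sort(key=lambda h: h[0])
    return hits


# ----------------------------------------------------------------------
# boundary landmarks / local frame
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class BoundaryLandmarks:
    """The nine canal-wall landmarks of one cross-section, in mm."""

    points: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        missing = [n for n in BOUNDARY_NAMES if n not in self.points]
        if missing:
            raise GeometryError(f"missing boundary landmarks: {missing}")
        pts = {n: np.asarray(self.points[n], dtype=float) for n in BOUNDARY_NAMES}
        for n, p in pts.items():
            if p.shape != (2,) or not np.all(np.isfinite(p)):
                raise GeometryError(f"landmark {n} must be a finite 2D point")
        object.__setattr__(self, "points", pts)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def array(self) -> np.ndarray:
        return np.array([self.points[n] for n in BOUNDARY_NAMES])

    def outline(self, resolution: int = 512) -> CanalOutline:
        return CanalOutline(self.array(), resolution=resolution)

    def transformed(self, fn) -> "BoundaryLandmarks":
        return BoundaryLandmarks({n: fn(p) for n, p in self.points.items()})


@dataclass(frozen=True)
class LocalFrame:
    """Canonical cross-section frame derived from the boundary landmarks.

    Origin at LS; +x toward the MSVS/MSTS midpoint (medial); +y chosen so
    the superior landmark SS has positive y (handles mirrored inputs).
    """

    origin: np.ndarray
    xhat: np.ndarray
    yhat: np.ndarray

    @classmethod
    def from_boundary(cls, boundary: BoundaryLandmarks) -> "LocalFrame":
        ls = boundary["LS"]
        mid = 0.5 * (boundary["MSVS"] + boundary["MSTS"])
        xhat = _unit(mid - ls)
        yhat = np.array([-xhat[1], xhat[0]])
        if float(np.dot(boundary["SS"] - ls, yhat)) < 0:
            yhat = -yhat
        return cls(origin=ls, xhat=xhat, yhat=yhat)

    def to_local(self, p) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        d = p - self.origin
        return np.stack([d @ self.xhat, d @ self.yhat], axis=-1)

    def to_world(self, p) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        return (
            self.origin
            + np.multiply.outer(p[..., 0], self.xhat)
            + np.multiply.outer(p[..., 1], self.yhat)
        )


def basal_canal_width(boundary: BoundaryLandmarks) -> float:
    """Distance from LS to the midpoint of MSVS and MSTS, in mm."""
    mid = 0.5 * (boundary["MSVS"] + boundary["MSTS"])
    w = float(np.linalg.norm(mid - boundary["LS"]))
    if w <= 0 or not np.isfinite(w):
        raise GeometryError("degenerate canal: LS coincides with the MSVS/MSTS midpoint")
    return w


def line_outline_intersection(
    origin,
    angle: float,
    outline: CanalOutline,
    side_hint: str = "nearest",
):
    """Nearest ray/outline intersection refined by bisection on the spline.

    ``side_hint`` selects among the crossings: "nearest" (default, first
    along the ray), or "farthest".  The origin must lie inside or on the
    outline.
    """
    o = np.asarray(origin, dtype=float)
    if not outline.contains(o, tol=1e-9 * max(1.0, outline.polygon.length)):
        raise GeometryError("ray origin lies outside the canal outline")
    d = np.array([math.cos(angle), math.sin(angle)])
    hits = outline.ray_crossings(o, d)
    if not hits:
        raise GeometryError("ray does not intersect the canal outline")
    if side_hint == "nearest":
        return hits[0].point
    if side_hint == "farthest":
        return hits[-1].point
    raise ValueError(f"unknown side_hint {side_hint!r}")


# ----------------------------------------------------------------------
# internal landmarks
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class InternalLandmarks:
    """Constructed internal landmarks of one cross-section (mm, world frame).

    ``provenance`` maps each landmark to the parameters that produced it;
    ``aux`` carries construction by-products needed for region assembly
    (local frame, wall hits of the lamina band edges, ligament curves,
    warnings).
    """

    points: dict[str, np.ndarray]
    provenance: dict[str, tuple[str, ...]] = field(default_factory=dict, repr=False)
    aux: dict = field(default_factory=dict, repr=False)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def __contains__(self, name: str) -> bool:
        return name in self.points

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.points)

    def transformed(self, fn) -> "InternalLandmarks":
        return InternalLandmarks(
            {n: np.asarray(fn(p), float) for n, p in self.points.items()},
            provenance=dict(self.provenance),
        )


def _axis_pick(outline: CanalOutline, axis: str, value: float, pick, name: str):
    cs = outline.axis_crossings(axis, value)
    if not cs:
        raise GeometryError(f"landmark {name}: no outline crossing at {axis}={value:.4g}")
    c = pick(cs)
    if c is None:
        raise GeometryError(f"landmark {name}: no admissible outline crossing")
    return c


def build_spiral_ligament(
    lm: InternalLandmarks, params: ParameterSet | None = None
) -> tuple[BezierCurve, BezierCurve]:
    """Quartic Bezier boundaries of the spiral ligament.

    Curve 1 runs c -> e -> k (vestibular side), curve 2 k -> f -> d
    (tympanic side); each interpolates its middle landmark exactly at
    t = 0.5.  The inner control points are placed symmetrically: P1/P3 are
    blended halfway from the endpoints toward the middle landmark and P2
    solves the t=0.5 interpolation constraint.
    """
    for n in ("c", "d", "e", "f", "k"):
        if n not in lm:
            raise GeometryError(f"ligament curves need landmark {n!r}")
    return (
        _ligament_curve(lm["c"], lm["e"], lm["k"]),
        _ligament_curve(lm["k"], lm["f"], lm["d"]),
    )


def _ligament_curve(p0, mid, p4) -> BezierCurve:
    p0 = np.asarray(p0, float)
    mid = np.asarray(mid, float)
    p4 = np.asarray(p4, float)
    chord = p4 - p0
    L = np.linalg.norm(chord)
    if L == 0:
        raise GeometryError("coincident ligament curve endpoints")
    u = chord / L
    proj = float(np.dot(mid - p0, u)) / L
    if not (0.0 < proj < 1.0):
        warnings.warn(
            "ligament middle landmark does not project between its "
            f"endpoints (chord fraction {proj:.3f})",
            stacklevel=3,
        )
    p1 = p0 + 0.5 * (mid - p0)
    p3 = p4 + 0.5 * (mid - p4)
    p2 = (16.0 * mid - p0 - 4.0 * p1 - 4.0 * p3 - p4) / 6.0
    return BezierCurve(np.array([p0, p1, p2, p3, p4]))


def construct_internal_landmarks(
    boundary: BoundaryLandmarks,
    params: ParameterSet,
    outline_resolution: int = 512,
) -> InternalLandmarks:
    """Place the internal landmarks from boundary landmarks + mm parameters."""
    if params.units != "mm":
        raise GeometryError(
            "construct_internal_landmarks needs denormalised (mm) parameters; "
            "call equations.denormalize first"
        )
    frame = LocalFrame.from_boundary(boundary)
    local_boundary = boundary.transformed(frame.to_local)
    outline = local_boundary.outline(resolution=outline_resolution)
    width = basal_canal_width(local_boundary)

    pts: dict[str, np.ndarray] = {}
    prov: dict[str, tuple[str, ...]] = {}
    notes: list[str] = []

    # -- 1: a on the lateral wall at vertical offset Wa from LS (origin)
    def nearest_lateral(cs):
        return min(cs, key=lambda c: c.point[0])

    ca = _axis_pick(outline, "y", params.Wa, nearest_lateral, "a")
    a = ca.point
    pts["a"], prov["a"] = a, ("Wa",)

    # -- 2/3: lamina line and medial wall point g
    alpha = params.alpha
    u = np.array([math.cos(alpha), math.sin(alpha)])
    n = np.array([-math.sin(alpha), math.cos(alpha)])
    hit_g = outline.first_ray_hit(a + 1e-9 * width * u, u)
    g = hit_g.point
    pts["g"], prov["g"] = g, ("Wa", "alpha")
    lamina_span = float(np.dot(g - a, u))

    # -- 4: ligament/BM junction k
    if params.Wsl >= lamina_span:
        raise GeometryError("Wsl exceeds the canal width along the lamina line")
    k = a + params.Wsl * u
    pts["k"], prov["k"] = k, ("Wa", "alpha", "Wsl")

    # -- 5: organ of Corti h (distance Wm from LS parallel to the line)
    t_h = params.Wm - float(np.dot(a, u))
    h = a + t_h * u
    if not (0.0 < t_h < lamina_span):
        raise GeometryError("Wm places h outside the canal along the lamina line")
    pts["h"], prov["h"] = h, ("Wa", "alpha", "Wm")

    # -- 6: lamina thickness point i
    i_pt = h + params.Hsg * n
    pts["i"], prov["i"] = i_pt, ("Wa", "alpha", "Wm", "Hsg")

    # -- 7: lamina extent o (tympanic edge) and p (vestibular edge)
    t_o = params.Ft
    if t_o >= 0.95 * lamina_span:
        notes.append("Ft clipped to the medial wall")
        t_o = 0.95 * lamina_span
    if t_o <= t_h:
        raise GeometryError("Ft places o lateral of the organ of Corti")
    o_pt = a + t_o * u
    pts["o"], prov["o"] = o_pt, ("Wa", "alpha", "Ft")

    # the vestibular band edge is the line through i with direction u; cast
    # the wall ray from i (strictly inside) since the lateral wall curves
    # over the band origin near LS
    band_origin = a + params.Hsg * n
    hit_pw = outline.first_ray_hit(i_pt + 1e-9 * width * u, u)
    p_wall = hit_pw.point
    upper_span = float(np.dot(p_wall - band_origin, u))
    t_p = math.sqrt(max(params.Fv**2 - params.Hsg**2, 0.0))
    if t_p >= 0.95 * upper_span:
        notes.append("Fv clipped to the medial wall")
        t_p = 0.95 * upper_span
    if t_p <= float(np.dot(i_pt - band_origin, u)):
        raise GeometryError("Fv places p lateral of the lamina tip")
    p_pt = band_origin + t_p * u
    pts["p"], prov["p"] = p_pt, ("Wa", "alpha", "Hsg", "Fv")

    # -- 8: ligament/wall intersections c (above) and d (below)
    def pick_above(cs):
        above = [c for c in cs if c.point[1] > a[1] + 1e-12]
        return min(above, key=lambda c: c.point[1]) if above else None

    def pick_below(cs):
        below = [c for c in cs if c.point[1] < a[1] - 1e-12]
        return max(below, key=lambda c: c.point[1]) if below else None

    cc = _axis_pick(outline, "x", a[0] + params.Wc, pick_above, "c")
    cd = _axis_pick(outline, "x", a[0] + params.Wd, pick_below, "d")
    c_pt, d_pt = cc.point, cd.point
    pts["c"], prov["c"] = c_pt, ("Wa", "Wc")
    pts["d"], prov["d"] = d_pt, ("Wa", "Wd")

    # -- 9: ligament mid-points e and f (capped, see module docstring)
    # tolerance absorbs the sagitta between the sampled polygon and the
    # true spline (points computed on the spline can sit marginally
    # outside the polyline polygon)
    wall_polygon = outline.polygon.buffer(2e-4 * width)

    def midpoint_from_chord(curve_p0, curve_p4, start, end, along, lateral,
                            who, parnames):
        """Place a ligament mid-landmark and guarantee a valid curve.

        ``along``/``lateral`` are the chord-parallel and lateral components
        measured from ``start`` along the chord start->end.  The along
        component is capped at 75% of the chord and the lateral offset is
        shrunk until the resulting quartic curve (which must interpolate
        the landmark at t=0.5) stays inside the canal.
        """
        from shapely.geometry import LineString

        chord = end - start
        L = float(np.linalg.norm(chord))
        ue = chord / L
        s_along = along
        if s_along > 0.75 * L:
            notes.append(f"{who}: along-chord component capped at 75% of the chord")
            s_along = 0.75 * L
        base = start + s_along * ue
        ne = np.array([-ue[1], ue[0]])
        if ne[0] > 0:  # lateral = -x in the local frame
            ne = -ne
        try:
            wall = outline.first_ray_hit(base, ne)
            free = float(np.dot(wall.point - base, ne))
        except OutlineError:
            free = 0.0
        off = lateral
        if off > 0.5 * free:
            notes.append(f"{who}: lateral offset capped at 50% of the wall distance")
            off = 0.5 * free
        p = base + off * ne
        for shrink in (1.0, 0.75, 0.5, 0.25, 0.1, 0.0):
            p = base + shrink * off * ne
            curve = _ligament_curve(curve_p0, p, curve_p4)
            if wall_polygon.covers(LineString(curve.sample(80))):
                if shrink < 1.0:
                    notes.append(
                        f"{who}: lateral offset shrunk to keep the ligament "
                        "boundary inside the canal"
                    )
                break
        else:
            raise GeometryError(f"no valid ligament boundary through {who}")
        pts[who], prov[who] = p, parnames
        return p

    midpoint_from_chord(c_pt, k, k, c_pt, params.Hkn, params.phi_en, "e",
                        ("Wa", "alpha", "Wsl", "Wc", "Hkn", "phi_en"))
    midpoint_from_chord(k, d_pt, k, d_pt, params.Hkm, params.phi_fm, "f",
                        ("Wa", "alpha", "Wsl", "Wd", "Hkm", "phi_fm"))

    # -- ligament boundary curves (needed for b)
    lm_partial = InternalLandmarks(dict(pts), dict(prov))
    curve_ek, curve_kd = build_spiral_ligament(lm_partial)

    # -- 10: Reissner's membrane root l on the vestibular lamina edge
    l_pt = i_pt + params.Wsm * u
    pts["l"], prov["l"] = l_pt, ("Wa", "alpha", "Wm", "Hsg", "Wsm")

    # -- 11: membrane end b on the ligament boundary (or vestibular wall)
    beta_dir = np.array(
        [math.cos(alpha + math.pi - params.beta), math.sin(alpha + math.pi - params.beta)]
    )
    curve_poly = curve_ek.sample(400)  # runs c -> k
    hits = _ray_polyline_hits(l_pt, beta_dir, curve_poly)
    if hits:
        # grazing intersections make the polyline segment fraction
        # ill-conditioned; snap b onto the true curve at the parameter
        # nearest the hit so curve splits at b stay consistent
        from scipy.optimize import minimize_scalar

        _, t0, b_raw = hits[0]
        res = minimize_scalar(
            lambda t: float(np.sum((curve_ek(t) - b_raw) ** 2)),
            bounds=(max(0.0, t0 - 0.02), min(1.0, t0 + 0.02)),
            method="bounded",
            options={"xatol": 1e-12},
        )
        b_curve_t = float(res.x)
        b_pt = curve_ek(b_curve_t)
        pts["b"], prov["b"] = b_pt, ("beta", "Wsm") + prov["e"]
    else:
        try:
            hit_b = outline.first_ray_hit(l_pt, beta_dir)
        except OutlineError as exc:
            raise GeometryError("Reissner's membrane does not reach a boundary") from exc
        b_curve_t = None
        pts["b"], prov["b"] = hit_b.point, ("beta", "Wsm")
        notes.append("Reissner's membrane terminates on the canal wall (apical form)")

    for msg in notes:
        warnings.warn(msg, stacklevel=2)

    world = frame.to_world
    lm = InternalLandmarks(
        {name: world(p) for name, p in pts.items()},
        provenance=prov,
        aux={
            "frame": frame,
            "outline_local": outline,
            "width": width,
            "lamina_u_local": u,
            "lamina_n_local": n,
            "p_wall": world(p_wall),
            "p_wall_local": p_wall,
            "local_points": pts,
            "b_curve_t": b_curve_t,
            "notes": tuple(notes),
            "params": params,
        },
    )
    return lm


# ----------------------------------------------------------------------
# region assembly
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class TissueRegion:
    """A homogeneous tissue area with its bulk conductivity."""

    name: str
    boundary: np.ndarray          # (n, 2) closed-loop vertices (last != first)
    conductivity: float

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.boundary)


@dataclass(frozen=True)
class InterfaceLayer:
    """A thin membrane simplified to a line with a contact impedance.

    ``surface_resistance`` = thickness / conductivity (Ohm * m^2 after
    unit conversion; stored here in mm / (S/m) consistent with mm-scale
    geometry, conversion is handled by the FEM assembly).
    """

    name: str
    paths: tuple[np.ndarray, ...]
    conductivity: float
    thickness: float

    def __post_init__(self):
        if self.thickness <= 0 or self.conductivity <= 0:
            raise GeometryError(f"interface {self.name}: non-physical layer values")

    @property
    def path(self) -> np.ndarray:
        return self.paths[0]

    @property
    def surface_resistance(self) -> float:
        return self.thickness / self.conductivity


@dataclass(frozen=True)
class CrossSectionGeometry:
    """Labelled 2D cross-section: regions, interfaces and landmarks."""

    regions: tuple[TissueRegion, ...]
    interfaces: tuple[InterfaceLayer, ...]
    internal: InternalLandmarks
    boundary: BoundaryLandmarks
    theta_deg: float

    def region(self, name: str) -> TissueRegion:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)

    def interface(self, name: str) -> InterfaceLayer:
        for f in self.interfaces:
            if f.name == name:
                return f
        raise KeyError(name)


def _dedup(poly: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    keep = [poly[0]]
    for p in poly[1:]:
        if np.linalg.norm(p - keep[-1]) > tol:
            keep.append(p)
    if np.linalg.norm(keep[0] - keep[-1]) <= tol and len(keep) > 1:
        keep = keep[:-1]
    return np.asarray(keep)


def assemble_cross_section(
    boundary: BoundaryLandmarks,
    lm: InternalLandmarks,
    params: ParameterSet,
    theta_deg: float,
    boundary_spacing: float | None = None,
) -> CrossSectionGeometry:
    """Assemble the labelled region/interface decomposition.

    Emits six tissue regions (three scalae, spiral ligament, lamina nerve
    channel, modiolar-bone wedge) and four contact-impedance layers
    (temporal-bone lining, basilar membrane, Reissner's membrane, stria
    vascularis).  Curved boundaries are sampled at approximately
    ``boundary_spacing`` (default: 1/48 of the canal width) so that short
    arcs do not accumulate near-coincident vertices.  Raises
    :class:`GeometryError` naming the offending region if any boundary
    self-intersects or two interiors overlap.
    """
    if "frame" not in lm.aux:
        raise GeometryError("landmarks lack construction context; use "
                            "construct_internal_landmarks")
    frame: LocalFrame = lm.aux["frame"]
    outline: CanalOutline = lm.aux["outline_local"]
    P = lm.aux["local_points"]
    p_wall = lm.aux["p_wall_local"]
    width = lm.aux["width"]

    ds = boundary_spacing if boundary_spacing is not None else width / 48.0

    def _n_samples(polyline) -> int:
        L = float(np.sum(np.linalg.norm(np.diff(polyline, axis=0), axis=1)))
        return int(np.clip(np.ceil(L / ds) + 1, 3, 512))

    curve_ek, curve_kd = build_spiral_ligament(
        InternalLandmarks({n: P[n] for n in ("c", "d", "e", "f", "k")})
    )
    # one shared sampling of each curve: regions on both sides reuse the
    # same vertices bitwise so interiors stay exactly disjoint
    n_ek = _n_samples(curve_ek.sample(24))
    n_kd = _n_samples(curve_kd.sample(24))
    tt = np.linspace(0.0, 1.0, n_ek)
    b_t = lm.aux.get("b_curve_t")
    if b_t is not None:
        tt = np.unique(np.concatenate([tt, [b_t]]))
    poly_ek = curve_ek(tt)                        # c -> k
    poly_kd = curve_kd.sample(n_kd)               # k -> d
    if b_t is not None:
        ib = int(np.searchsorted(tt, b_t))
        poly_ek[ib] = P["b"]

    s = {name: outline.locate(P[name], tol=1e-5) for name in ("a", "c", "d", "g")}
    s["p_wall"] = outline.locate(p_wall, tol=1e-5)
    s_ls = outline.locate(np.zeros(2), tol=1e-5)
    s_top = outline.locate(frame.to_local(boundary["SS"]), tol=1e-5)
    s_bot = outline.locate(frame.to_local(boundary["IS"]), tol=1e-5)

    def arc(s0, s1, avoid, snap0=None, snap1=None):
        """Wall arc s0 -> s1 choosing the direction that skips ``avoid``.

        Endpoints are snapped to the exact landmark coordinates so that
        adjacent boundary pieces share vertices bitwise.
        """
        fwd = np.mod(s1 - s0, 1.0)
        pos = np.mod(avoid - s0, 1.0)
        direction = -1 if pos < fwd else +1
        coarse = outline.arc(s0, s1, n=24, direction=direction)
        pts = outline.arc(s0, s1, n=_n_samples(coarse), direction=direction)
        if snap0 is not None:
            pts[0] = snap0
        if snap1 is not None:
            pts[-1] = snap1
        return pts

    if b_t is not None:
        # split the shared c->k sampling at the b vertex
        poly_cb = poly_ek[: ib + 1]
        poly_bk = poly_ek[ib:]
        chain_bk = poly_bk                 # b -> k, the scala-media lateral wall
    else:
        # b lies on the wall: scala-media lateral chain = wall b->c then curve c->k
        wall_to_b = arc(outline.locate(P["b"], tol=1e-5), s["c"], avoid=s_top,
                        snap0=P["b"], snap1=P["c"])
        chain_bk = np.vstack([wall_to_b, poly_ek[1:]])
        poly_cb = None

    regions: list[TissueRegion] = []

    def add_region(name, *pieces):
        pts = _dedup(np.vstack(pieces))
        poly = Polygon(pts)
        if not poly.is_valid or poly.area <= 0:
            raise GeometryError(f"region {name!r} is degenerate or self-intersecting")
        regions.append(
            TissueRegion(name=name, boundary=pts, conductivity=REGION_CONDUCTIVITY[name])
        )

    # spiral ligament: wall arc d -> c through LS (split at a so the BM
    # attachment is an exact wall vertex), curve c->e->k, curve k->f->d
    A_lig = np.vstack(
        [
            arc(s["d"], s["a"], avoid=s_bot, snap0=P["d"], snap1=P["a"]),
            arc(s["a"], s["c"], avoid=s_bot, snap0=P["a"], snap1=P["c"])[1:],
        ]
    )
    add_region("spiral_ligament", A_lig, poly_ek, poly_kd)

    # scala media: BM k->h, lamina lateral edge h->i, edge i->l, RM l->b, chain b->k
    add_region(
        "scala_media",
        np.array([P["k"], P["h"], P["i"], P["l"], P["b"]]),
        chain_bk,
    )

    # scala vestibuli: RM b->l, upper lamina edge l->p, p->p_wall, wall back to c (or b)
    if b_t is not None:
        sv_lateral = poly_cb[::-1]  # b -> c along the ligament curve
        wall_piece = arc(s["c"], s["p_wall"], avoid=s_ls, snap0=P["c"], snap1=p_wall)
    else:
        sv_lateral = np.array([P["b"]])
        wall_piece = arc(outline.locate(P["b"], tol=1e-5), s["p_wall"], avoid=s_ls,
                         snap0=P["b"], snap1=p_wall)
    add_region(
        "scala_vestibuli",
        sv_lateral,
        wall_piece,
        np.array([P["p"], P["l"]]),
    )

    # scala tympani: BM h->k, ligament curve k->f->d, wall d -> g via the floor,
    # lamina tympanic edge g->o->h
    add_region(
        "scala_tympani",
        np.array([P["h"], P["k"]]),
        poly_kd[1:],
        arc(s["d"], s["g"], avoid=s_ls, snap0=P["d"], snap1=P["g"])[1:],
        np.array([P["o"]]),
    )

    # spiral lamina nerve channel: h->o (tympanic edge), o->p, p->i (vestibular edge)
    add_region(
        "spiral_lamina_nerve",
        np.array([P["h"], P["o"], P["p"], P["i"]]),
    )

    # modiolar-bone wedge between the lamina end and the medial wall
    add_region(
        "modiolar_bone",
        np.array([P["o"]]),
        arc(s["g"], s["p_wall"], avoid=s_ls, snap0=P["g"], snap1=p_wall),
        np.array([P["p"]]),
    )

    # pairwise interior disjointness
    polys = [(r.name, r.polygon) for r in regions]
    for idx, (n1, p1) in enumerate(polys):
        for n2, p2 in polys[idx + 1:]:
            inter = p1.intersection(p2).area
            if inter > 1e-6 * min(p1.area, p2.area):
                raise GeometryError(
                    f"regions {n1!r} and {n2!r} overlap (area {inter:.3g})"
                )

    # ---- interface layers
    # the wall lining reuses the exact region wall arcs so that the lining
    # polyline and the region boundaries are sampled identically (the FEM
    # mesher requires coincident constraints to share vertices)
    if b_t is not None:
        A_sv = wall_piece                      # c -> p_wall over the top
    else:
        A_sv = np.vstack([wall_to_b[::-1], wall_piece[1:]])  # c -> b -> p_wall
    A_bone = arc(s["g"], s["p_wall"], avoid=s_ls, snap0=P["g"], snap1=p_wall)
    A_st = arc(s["d"], s["g"], avoid=s_ls, snap0=P["d"], snap1=P["g"])
    outline_loop = _dedup(
        np.vstack([A_lig, A_sv[1:], A_bone[::-1][1:], A_st[::-1][1:]])
    )
    lining = [
        np.vstack([outline_loop, outline_loop[:1]]),
        np.array([P["h"], P["o"], P["g"]]),          # tympanic bony plate
        np.array([P["i"], P["p"], p_wall]),          # vestibular bony plate
    ]
    stria_path = chain_bk
    interfaces = []
    for name, pathlist in (
        ("temporal_bone", lining),
        ("basilar_membrane", [np.array([P["a"], P["k"], P["h"]])]),
        ("reissner_membrane", [np.array([P["l"], P["b"]])]),
        ("stria_vascularis", [stria_path]),
    ):
        cond, thick = INTERFACE_PROPERTIES[name]
        interfaces.append(
            InterfaceLayer(
                name=name,
                paths=tuple(np.asarray(p, float) for p in pathlist),
                conductivity=cond,
                thickness=thick,
            )
        )

    # map everything back to the world frame
    world_regions = tuple(
        TissueRegion(r.name, frame.to_world(r.boundary), r.conductivity) for r in regions
    )
    world_interfaces = tuple(
        InterfaceLayer(
            f.name,
            tuple(frame.to_world(p) for p in f.paths),
            f.conductivity,
            f.thickness,
        )
        for f in interfaces
    )
    return CrossSectionGeometry(
        regions=world_regions,
        interfaces=world_interfaces,
        internal=lm,
        boundary=boundary,
        theta_deg=float(theta_deg),
    )
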