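"""2D stationary volume-conduction FEM and parameter-sensitivity sweeps.

Solves the purely resistive electrostatics problem div(sigma grad V) = 0
on a labelled triangular mesh with

- per-region bulk conductivities (S/m),
- thin-membrane contact impedances: across duplicated-DOF interface
  edges the potential may jump by [V] = r_s * J_n, implemented as a
  surface conductance 1/r_s coupling the two sides,
- a current source: uniform normal current density along the electrode's
  modiolar-facing arc, integrating to the stimulation current,
- a Dirichlet ground (V = 0) on the lower boundary of the model domain.

Geometry lives in mm; the assembly converts to SI (metres), so the
solution is in volts for a stimulation current interpreted per metre of
out-of-plane depth.

The sensitivity analysis builds a mid-modiolar half-section: cross
sections of the first half-turns stacked along the modiolar axis, a
nerve trunk running down to the domain boundary, and a half-band
electrode in the basal scala tympani.  One parameter at a time is swept
over its admissible range, the potential profile along each nerve fibre
is extracted, and parameters are ranked by the largest potential change
they induce on the basal fibres.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.linalg import spsolve
from shapely.geometry import Point, Polygon

from . import equations as eqmod
from .equations import (
    NormalisationContext,
    default_registry,
    default_sweep_range,
    denormalize,
    parameter_set,
)
from .geometry import (
    GeometryError,
    assemble_cross_section,
    basal_canal_width,
    construct_internal_landmarks,
)
from .meshing import DomainSpec, InterfaceSpec, Mesh, MeshError, RegionSpec, build_mesh
from .synth import canonical_boundary

__all__ = [
    "FemConfig",
    "FemProblem",
    "FemSolution",
    "FibreProfile",
    "SensitivityResult",
    "build_domain",
    "solve_stationary",
    "fibre_potential_profile",
    "sweep_parameter",
    "rank_parameters",
]

MM = 1e-3  # mm -> m


class FemError(RuntimeError):
    """FEM setup or solve failed."""


@dataclass(frozen=True)
class FemConfig:
    """Tunable settings of the sensitivity model.

    Mesh sizes are in mm; ``current_A`` is the stimulation current (2 mA
    by default); the domain is a square ``domain_scale`` times the width
    of the cochlea with the cochlea centred.
    """

    thetas: tuple[float, ...] = (0.0, 180.0, 360.0, 540.0, 720.0)
    basal_width_mm: float = 2.0
    decay: float = 0.85
    canal_gap_mm: float = 0.35
    trunk_width_mm: float = 1.0
    wall_gap_mm: float = 0.15
    electrode_radius_mm: float = 0.2
    current_A: float = 2e-3
    domain_scale: float = 4.0
    h_canal_mm: float = 0.16
    h_trunk_mm: float = 0.35
    h_background_mm: float = 1.0
    n_stations: int = 200
    n_basal_fibres: int = 3
    sweep_steps: int = 5


@dataclass
class FemProblem:
    """A meshed, fully specified conduction problem."""

    mesh: Mesh
    surface_resistance: dict[str, float]      # interface name -> Ohm m^2
    current_A: float
    ground_dofs: np.ndarray
    meta: dict = field(default_factory=dict)


@dataclass
class FemSolution:
    """Nodal potentials with interpolation helpers."""

    problem: FemProblem
    V: np.ndarray                              # (ndof,) volts
    ground_current_A: float

    def potential_at(self, xy) -> float:
        """Potential at a point (piecewise-linear interpolation)."""
        mesh = self.problem.mesh
        xy = np.asarray(xy, float)
        t = mesh.locate(xy)
        if t < 0:
            raise FemError(f"point {xy} lies outside the meshed domain")
        tri = mesh.triangles[t]
        dofs = mesh.tri_dof[t]
        p = mesh.points[tri]
        T = np.array([p[1] - p[0], p[2] - p[0]]).T
        try:
            lam12 = np.linalg.solve(T, xy - p[0])
        except np.linalg.LinAlgError as exc:
            raise FemError("degenerate triangle during interpolation") from exc
        lam = np.array([1.0 - lam12.sum(), lam12[0], lam12[1]])
        return float(lam @ self.V[dofs])


def _ground_dofs(mesh: Mesh, y_min: float, tol: float) -> np.ndarray:
    pts = mesh.points[mesh.dof_point]
    return np.nonzero(pts[:, 1] <= y_min + tol)[0]


def make_problem(
    mesh: Mesh,
    surface_resistance: dict[str, float],
    current_A: float,
    ground: str = "bottom",
    meta: dict | None = None,
) -> FemProblem:
    """Wrap a mesh into a problem with a bottom-edge ground."""
    if ground != "bottom":
        raise ValueError("only the bottom-boundary ground is supported")
    y_min = float(mesh.points[:, 1].min())
    diam = float(np.max(mesh.points.max(axis=0) - mesh.points.min(axis=0)))
    g = _ground_dofs(mesh, y_min, 1e-9 * diam)
    if len(g) == 0:
        raise FemError("no ground nodes found on the lower boundary")
    if not mesh.source_edges:
        raise FemError("problem has no source boundary")
    return FemProblem(
        mesh=mesh,
        surface_resistance=dict(surface_resistance),
        current_A=float(current_A),
        ground_dofs=g,
        meta=dict(meta or {}),
    )


def solve_stationary(problem: FemProblem) -> FemSolution:
    """Assemble and solve the stationary conduction problem."""
    mesh = problem.mesh
    pts = mesh.points * MM
    tris = mesh.triangles
    ndof = mesh.n_dof

    p0 = pts[tris[:, 0]]
    p1 = pts[tris[:, 1]]
    p2 = pts[tris[:, 2]]
    det = (p1[:, 0] - p0[:, 0]) * (p2[:, 1] - p0[:, 1]) - (
        p1[:, 1] - p0[:, 1]
    ) * (p2[:, 0] - p0[:, 0])
    area = 0.5 * np.abs(det)
    if np.any(area <= 0):
        raise FemError("mesh contains degenerate triangles")
    # P1 shape-function gradients
    b = np.stack(
        [p1[:, 1] - p2[:, 1], p2[:, 1] - p0[:, 1], p0[:, 1] - p1[:, 1]], axis=1
    )
    c = np.stack(
        [p2[:, 0] - p1[:, 0], p0[:, 0] - p2[:, 0], p1[:, 0] - p0[:, 0]], axis=1
    )
    sigma = mesh.region_conductivity[mesh.tri_region]
    coef = sigma / (4.0 * area)
    rows, cols, vals = [], [], []
    for i in range(3):
        for j in range(3):
            rows.append(mesh.tri_dof[:, i])
            cols.append(mesh.tri_dof[:, j])
            vals.append(coef * (b[:, i] * b[:, j] + c[:, i] * c[:, j]))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)

    # contact-impedance coupling across split interfaces
    irows, icols, ivals = [], [], []
    for name, edges in mesh.interface_edges.items():
        r_s = problem.surface_resistance.get(name)
        if r_s is None:
            continue
        if r_s <= 0:
            raise FemError(f"interface {name!r}: surface resistance must be > 0")
        g_s = 1.0 / r_s
        for p, q in edges:
            left, right = mesh.edge_side_dofs(p, q)
            if left is None or right is None:
                continue
            L = float(np.linalg.norm(pts[p] - pts[q]))
            m11 = g_s * L / 3.0
            m12 = g_s * L / 6.0
            (pl, ql), (pr, qr) = left, right
            if pl == pr and ql == qr:
                continue  # unsplit edge: no jump possible
            pairs = [
                (pl, pl, m11), (ql, ql, m11), (pl, ql, m12), (ql, pl, m12),
                (pr, pr, m11), (qr, qr, m11), (pr, qr, m12), (qr, pr, m12),
                (pl, pr, -m11), (pr, pl, -m11), (ql, qr, -m11), (qr, ql, -m11),
                (pl, qr, -m12), (qr, pl, -m12), (ql, pr, -m12), (pr, ql, -m12),
            ]
            for r_, c_, v_ in pairs:
                irows.append(r_)
                icols.append(c_)
                ivals.append(v_)
    if irows:
        rows = np.concatenate([rows, np.asarray(irows)])
        cols = np.concatenate([cols, np.asarray(icols)])
        vals = np.concatenate([vals, np.asarray(ivals)])

    K = coo_matrix((vals, (rows, cols)), shape=(ndof, ndof)).tocsr()

    # source: uniform current density along the source arcs
    f = np.zeros(ndof)
    seg = [
        (p, q, float(np.linalg.norm(pts[p] - pts[q])))
        for chain in mesh.source_edges
        for p, q in chain
    ]
    total_len = sum(L for _, _, L in seg)
    if total_len <= 0:
        raise FemError("source boundary has zero length")
    j = problem.current_A / total_len
    for p, q, L in seg:
        f[p] += 0.5 * j * L
        f[q] += 0.5 * j * L

    # Dirichlet ground; DOFs untouched by any triangle (isolated points
    # left over from degenerate-triangle removal) are pinned as well so
    # the reduced system stays non-singular
    diag = K.diagonal()
    isolated = np.nonzero(diag == 0.0)[0]
    g = np.union1d(problem.ground_dofs, isolated)
    free = np.setdiff1d(np.arange(ndof), g, assume_unique=False)
    if len(free) == ndof:
        raise FemError("singular system: no ground boundary")
    Kff = K[free][:, free]
    Vf = spsolve(csr_matrix(Kff), f[free])
    V = np.zeros(ndof)
    V[free] = Vf

    residual = K @ V - f
    ground_current = float(-np.sum(residual[g]))
    return FemSolution(problem=problem, V=V, ground_current_A=ground_current)


@dataclass(frozen=True)
class FibreProfile:
    """Potential along one nerve-fibre path."""

    arc_mm: np.ndarray
    potential_V: np.ndarray
    path: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.arc_mm) <= 0):
            raise FemError("fibre arc length must be strictly increasing")
        if not np.all(np.isfinite(self.potential_V)):
            raise FemError("non-finite fibre potentials")


def fibre_potential_profile(
    solution: FemSolution, path: np.ndarray, n_stations: int = 200
) -> FibreProfile:
    """Interpolate the potential at equally spaced arc-length stations."""
    path = np.asarray(path, float)
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] <= 0:
        raise FemError("fibre path has zero length")
    s = np.linspace(0.0, cum[-1], n_stations)
    xy = np.empty((n_stations, 2))
    for d in range(2):
        xy[:, d] = np.interp(s, cum, path[:, d])
    pot = np.array([solution.potential_at(q) for q in xy])
    return FibreProfile(arc_mm=s, potential_V=pot, path=path)


# ----------------------------------------------------------------------
# sensitivity domain
# ----------------------------------------------------------------------

@dataclass
class SensitivityDomain:
    """Assembled multi-section domain ready for meshing and solving."""

    spec: DomainSpec
    fibres: list[np.ndarray]            # fibre polylines, basal first
    surface_resistance: dict[str, float]
    config: FemConfig
    meta: dict = field(default_factory=dict)

    def solve(self) -> tuple[FemSolution, list[FibreProfile]]:
        mesh = build_mesh(self.spec)
        problem = make_problem(
            mesh, self.surface_resistance, self.config.current_A, meta=self.meta
        )
        sol = solve_stationary(problem)
        profiles = [
            fibre_potential_profile(sol, f, self.config.n_stations)
            for f in self.fibres
        ]
        return sol, profiles


def build_domain(
    config: FemConfig | None = None,
    registry=None,
    overrides: dict[str, float] | None = None,
    mesh_scale: float = 1.0,
) -> SensitivityDomain:
    """Build the mid-modiolar sensitivity domain.

    Cross-sections at ``config.thetas`` (canonical synthetic boundaries,
    scaled by the per-turn decay) are stacked along the modiolar axis
    with the nerve trunk medial of them reaching the lower domain
    boundary.  ``overrides`` pins named parameters to fixed normalised
    values in every section (the sweep mechanism).  ``mesh_scale``
    multiplies all target edge lengths (< 1 refines).
    """
    cfg = config or FemConfig()
    registry = registry if registry is not None else default_registry()
    overrides = dict(overrides or {})

    regions: list[RegionSpec] = []
    interfaces: list[InterfaceSpec] = []
    fibre_paths: list[np.ndarray] = []
    surface_resistance: dict[str, float] = {}

    y_cursor = 0.0
    medial_x = 0.0  # canal medial walls end here; trunk starts at +wall_gap
    canal_info = []

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for idx, theta in enumerate(cfg.thetas):
            width = cfg.basal_width_mm * cfg.decay ** (theta / 360.0)
            bl = canonical_boundary(width)
            ctx = NormalisationContext(basal_canal_width(bl))
            ps = parameter_set(theta, registry=registry)
            for name, value in overrides.items():
                ps = ps.with_value(name, value)
            mm = denormalize(ps, ctx)
            lm = construct_internal_landmarks(bl, mm)
            geom = assemble_cross_section(bl, lm, mm, theta)

            pts_all = np.vstack([np.asarray(r.boundary) for r in geom.regions])
            lo = pts_all.min(axis=0)
            hi = pts_all.max(axis=0)
            shift = np.array([medial_x - hi[0], y_cursor - lo[1]])

            for r in geom.regions:
                regions.append(
                    RegionSpec(
                        name=f"{r.name}@{theta:g}",
                        polygon=np.asarray(r.boundary) + shift,
                        conductivity=r.conductivity,
                        h=cfg.h_canal_mm * mesh_scale,
                    )
                )
            for fc in geom.interfaces:
                surface_resistance[fc.name] = fc.surface_resistance * MM
                for pi, pth in enumerate(fc.paths):
                    interfaces.append(
                        InterfaceSpec(
                            name=fc.name,
                            polyline=np.asarray(pth) + shift,
                            surface_resistance=fc.surface_resistance * MM,
                            closed=bool(
                                np.linalg.norm(pth[0] - pth[-1]) < 1e-9
                            ),
                        )
                    )
            P = {n: np.asarray(p) + shift for n, p in lm.points.items()}
            p_wall = np.asarray(lm.aux["p_wall"]) + shift
            canal_info.append(
                {"theta": theta, "width": width, "landmarks": P,
                 "p_wall": p_wall, "shift": shift,
                 "geom": geom, "lo": lo + shift, "hi": hi + shift}
            )
            y_cursor += (hi[1] - lo[1]) + cfg.canal_gap_mm

    trunk_x0 = medial_x + cfg.wall_gap_mm
    trunk_x1 = trunk_x0 + cfg.trunk_width_mm
    trunk_top = canal_info[-1]["hi"][1] + 0.5

    # overall cochlea bounding box -> square domain
    all_lo = np.min([c["lo"] for c in canal_info], axis=0)
    all_hi = np.max([c["hi"] for c in canal_info], axis=0)
    all_lo = np.minimum(all_lo, [trunk_x0, all_lo[1]])
    all_hi = np.maximum(all_hi, [trunk_x1, trunk_top])
    cochlea_w = all_hi[0] - all_lo[0]
    centre = 0.5 * (all_lo + all_hi)
    side = cfg.domain_scale * cochlea_w
    sq_lo = centre - side / 2
    sq_hi = centre + side / 2
    outer = np.array(
        [[sq_lo[0], sq_lo[1]], [sq_hi[0], sq_lo[1]],
         [sq_hi[0], sq_hi[1]], [sq_lo[0], sq_hi[1]]]
    )

    trunk = np.array(
        [[trunk_x0, sq_lo[1]], [trunk_x1, sq_lo[1]],
         [trunk_x1, trunk_top], [trunk_x0, trunk_top]]
    )

    # electrode in the basal scala tympani
    basal = canal_info[0]
    st_poly = None
    for r in basal["geom"].regions:
        if r.name == "scala_tympani":
            st_poly = Polygon(np.asarray(r.boundary) + basal["shift"])
    if st_poly is None:
        raise FemError("basal section lacks a scala tympani region")
    centre_e = np.asarray(st_poly.representative_point().coords[0])
    r_e = cfg.electrode_radius_mm
    if not st_poly.buffer(-r_e * 1.05).contains(Point(centre_e)):
        # shrink until the contact fits inside the scala
        for shrink in (0.75, 0.5, 0.3):
            if st_poly.buffer(-r_e * shrink * 1.05).contains(Point(centre_e)):
                r_e *= shrink
                break
        else:
            raise FemError("electrode does not fit inside the basal scala tympani")
    ang = np.linspace(0.0, 2 * np.pi, 33)
    circle = centre_e + r_e * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    if not st_poly.contains(Polygon(circle)):
        raise FemError("electrode contact leaves the scala tympani")
    # modiolar-facing half of the contact carries the current
    face = ang[(np.cos(ang) > 0.05)]
    face = np.sort(face)
    source_arc = centre_e + r_e * np.stack([np.cos(face), np.sin(face)], axis=1)

    electrode_region = RegionSpec(
        name="electrode_silicone",
        polygon=circle[:-1],
        conductivity=1e-7,
        h=cfg.h_canal_mm * mesh_scale,
    )
    trunk_region = RegionSpec(
        name="nerve_trunk",
        polygon=trunk,
        conductivity=0.33,
        h=cfg.h_trunk_mm * mesh_scale,
    )

    # fibre polylines: organ of Corti -> lamina channel -> trunk -> down
    trunk_mid = 0.5 * (trunk_x0 + trunk_x1)
    y_end = basal["lo"][1]
    for c in canal_info:
        P = c["landmarks"]
        start = 0.5 * (P["h"] + P["i"])
        band_end = 0.5 * (P["g"] + c["p_wall"])
        entry = np.array([trunk_mid, band_end[1]])
        fibre = np.array([start, band_end, entry, [trunk_mid, y_end]])
        fibre_paths.append(fibre)

    spec = DomainSpec(
        outer=outer,
        background_name="temporal_bone_bulk",
        background_conductivity=0.016,
        background_h=cfg.h_background_mm * mesh_scale,
        regions=[electrode_region] + regions + [trunk_region],
        interfaces=interfaces,
        source_arcs=[source_arc],
    )
    return SensitivityDomain(
        spec=spec,
        fibres=fibre_paths,
        surface_resistance=surface_resistance,
        config=cfg,
        meta={
            "overrides": overrides,
            "cochlea_width_mm": float(cochlea_w),
            "domain_side_mm": float(side),
            "electrode_centre": centre_e.tolist(),
            "electrode_radius_mm": float(r_e),
        },
    )


# ----------------------------------------------------------------------
# parameter sweep
# ----------------------------------------------------------------------

@dataclass
class SensitivityResult:
    """Outcome of sweeping one parameter."""

    parameter: str
    values: np.ndarray
    profiles: list[list[FibreProfile]]      # [sweep value][fibre]
    max_spread_V: float
    argmax_fibre: int
    argmax_station: int
    station_arc_mm: float
    potential_at_max: np.ndarray            # potential vs sweep value
    skipped: list[float] = field(default_factory=list)

    def normalised_values(self) -> np.ndarray:
        lo, hi = self.values.min(), self.values.max()
        if hi == lo:
            return np.zeros_like(self.values)
        return (self.values - lo) / (hi - lo)


def sweep_parameter(
    name: str,
    value_range: tuple[float, float] | None = None,
    n_steps: int | None = None,
    config: FemConfig | None = None,
    registry=None,
    mesh_scale: float = 1.0,
) -> SensitivityResult:
    """Sweep one parameter and measure fibre-potential sensitivity.

    The parameter is pinned to each of ``n_steps`` values spanning its
    range (default: its 20-80 percentile window, see
    :func:`cochleagen.equations.default_sweep_range`), the domain is
    rebuilt and re-solved per value, and the arc-length station with the
    largest potential spread over the sweep is located on the basal
    fibres (the apical fibres are excluded from the ranking).
    """
    cfg = config or FemConfig()
    registry = registry if registry is not None else default_registry()
    if n_steps is None:
        n_steps = cfg.sweep_steps
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if value_range is None:
        ctx = NormalisationContext(cfg.basal_width_mm)
        value_range = default_sweep_range(name, 0.0, registry=registry, ctx=ctx)
    lo, hi = value_range
    values = np.linspace(lo, hi, n_steps)

    all_profiles: list[list[FibreProfile]] = []
    kept_values = []
    skipped = []
    for v in values:
        try:
            dom = build_domain(
                config=cfg, registry=registry, overrides={name: float(v)},
                mesh_scale=mesh_scale,
            )
            _, profiles = dom.solve()
        except (GeometryError, MeshError, FemError) as exc:
            warnings.warn(f"sweep {name}={v:.4g} skipped: {exc}", stacklevel=2)
            skipped.append(float(v))
            continue
        all_profiles.append(profiles)
        kept_values.append(float(v))
    if len(kept_values) < 2:
        raise FemError(f"sweep of {name!r}: fewer than two valid sweep values")

    n_fibres = min(cfg.n_basal_fibres, len(all_profiles[0]))
    best = (0.0, 0, 0)
    for fi in range(n_fibres):
        pots = np.stack(
            [profs[fi].potential_V for profs in all_profiles], axis=0
        )
        spread = pots.max(axis=0) - pots.min(axis=0)
        si = int(np.argmax(spread))
        if spread[si] > best[0]:
            best = (float(spread[si]), fi, si)
    max_spread, fi, si = best
    potential_at_max = np.array(
        [profs[fi].potential_V[si] for profs in all_profiles]
    )
    return SensitivityResult(
        parameter=name,
        values=np.asarray(kept_values),
        profiles=all_profiles,
        max_spread_V=max_spread,
        argmax_fibre=fi,
        argmax_station=si,
        station_arc_mm=float(all_profiles[0][fi].arc_mm[si]),
        potential_at_max=potential_at_max,
        skipped=skipped,
    )


def rank_parameters(results) -> list[str]:
    """Parameter names in descending order of basal-fibre potential spread."""
    results = list(results)
    if not results:
        raise ValueError("rank_parameters needs at least one result")
    return [
        r.parameter
        for r in sorted(results, key=lambda r: r.max_spread_V, reverse=True)
    ]
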