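"""Conforming triangular meshing for the volume-conduction model.

Builds an unstructured triangular mesh of a 2D domain made of labelled
polygonal regions inside an outer boundary, with selected polylines
(thin-membrane interfaces, electrode faces) guaranteed to be resolved by
mesh edges.  The strategy:

1. resample every constraint polyline at the local target edge length,
2. scatter hexagonal-lattice interior points per region (with clearance
   from the constraints),
3. Delaunay-triangulate all points (scipy),
4. enforce constraint conformity by inserting segment midpoints until
   every constraint segment appears as a mesh edge,
5. label triangles by region via point-in-polygon tests on centroids.

Thin resistive membranes are modelled as contact impedances: the degrees
of freedom of nodes interior to an interface polyline are duplicated so
the potential may jump across it, and the FEM assembly couples the two
sides with the layer's surface conductance (1 / r_s per unit length).
The duplication is purely topological — both copies share coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

__all__ = ["MeshError", "RegionSpec", "InterfaceSpec", "DomainSpec", "Mesh",
           "build_mesh"]


class MeshError(RuntimeError):
    """Meshing failed (non-conforming constraints, degenerate input)."""


@dataclass(frozen=True)
class RegionSpec:
    """A labelled polygonal subdomain."""

    name: str
    polygon: np.ndarray           # (n, 2) loop, mm
    conductivity: float           # S/m
    h: float                      # target edge length, mm


@dataclass(frozen=True)
class InterfaceSpec:
    """A thin layer to be modelled as a contact impedance."""

    name: str
    polyline: np.ndarray          # (n, 2), mm
    surface_resistance: float     # Ohm * m^2 (SI)
    closed: bool = False


@dataclass
class DomainSpec:
    """Complete description of a meshable domain.

    ``outer`` is the bounding polygon (typically a rectangle); regions
    are tested in order, first containing polygon wins, and anything not
    covered falls back to the outer background conductivity.
    """

    outer: np.ndarray
    background_name: str
    background_conductivity: float
    background_h: float
    regions: list[RegionSpec] = field(default_factory=list)
    interfaces: list[InterfaceSpec] = field(default_factory=list)
    extra_constraints: list[np.ndarray] = field(default_factory=list)
    source_arcs: list[np.ndarray] = field(default_factory=list)


@dataclass
class Mesh:
    """Triangular mesh with duplicated-DOF interface topology.

    ``triangles`` index geometric points; ``tri_dof`` indexes degrees of
    freedom (equal to ``triangles`` except across split interfaces).
    ``dof_point`` maps every DOF back to its geometric point.
    """

    points: np.ndarray                    # (npts, 2) mm
    triangles: np.ndarray                 # (ntri, 3) point ids
    tri_dof: np.ndarray                   # (ntri, 3) dof ids
    n_dof: int
    dof_point: np.ndarray                 # (ndof,) point ids
    tri_region: np.ndarray                # (ntri,) region index
    region_names: list[str]
    region_conductivity: np.ndarray       # (nregion,) S/m
    interface_edges: dict[str, list[tuple[int, int]]]   # point-id segments
    source_edges: list[list[tuple[int, int]]]
    _delaunay: Delaunay | None = None

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def edge_side_dofs(self, p: int, q: int):
        """DOFs of edge (p, q) on its left and right sides.

        Returns ((pL, qL), (pR, qR)) or None for a side with no adjacent
        triangle (outer-boundary edges).
        """
        tris = self._edge_tris.get(_ekey(p, q))
        if not tris:
            raise MeshError(f"edge ({p}, {q}) not found in mesh")
        left = right = None
        a, b = self.points[p], self.points[q]
        for t in tris:
            cen = self.points[self.triangles[t]].mean(axis=0)
            cross = (b[0] - a[0]) * (cen[1] - a[1]) - (b[1] - a[1]) * (cen[0] - a[0])
            dofs = self.tri_dof[t]
            pt_ids = self.triangles[t]
            dp = int(dofs[list(pt_ids).index(p)])
            dq = int(dofs[list(pt_ids).index(q)])
            if cross > 0:
                left = (dp, dq)
            else:
                right = (dp, dq)
        return left, right

    def locate(self, xy) -> int:
        """Triangle index containing a point (-1 if outside)."""
        if self._delaunay is None:
            raise MeshError("mesh lost its point-location structure")
        s = int(self._delaunay.find_simplex(np.asarray(xy, float)))
        return s

    def __post_init__(self):
        edge_tris: dict[tuple[int, int], list[int]] = {}
        for t, tri in enumerate(self.triangles):
            for i in range(3):
                k = _ekey(int(tri[i]), int(tri[(i + 1) % 3]))
                edge_tris.setdefault(k, []).append(t)
        self._edge_tris = edge_tris


def _ekey(p: int, q: int) -> tuple[int, int]:
    return (p, q) if p < q else (q, p)


class _PointBank:
    """Deduplicating point store with grid-based snapping."""

    def __init__(self, tol: float):
        self.tol = tol
        self.points: list[np.ndarray] = []
        self._grid: dict[tuple[int, int], list[int]] = {}

    def _cells(self, p):
        cx, cy = int(np.floor(p[0] / self.tol)), int(np.floor(p[1] / self.tol))
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                yield (cx + dx, cy + dy)

    def add(self, p) -> int:
        p = np.asarray(p, float)
        for cell in self._cells(p):
            for idx in self._grid.get(cell, ()):
                if np.hypot(*(self.points[idx] - p)) <= self.tol:
                    return idx
        idx = len(self.points)
        self.points.append(p)
        cx, cy = int(np.floor(p[0] / self.tol)), int(np.floor(p[1] / self.tol))
        self._grid.setdefault((cx, cy), []).append(idx)
        return idx

    def array(self) -> np.ndarray:
        return np.asarray(self.points)


def _resample(polyline: np.ndarray, h: float, closed: bool) -> np.ndarray:
    """Subdivide polyline segments longer than ``h`` (keeps vertices)."""
    pts = np.asarray(polyline, float)
    if closed and np.linalg.norm(pts[0] - pts[-1]) > 1e-12:
        pts = np.vstack([pts, pts[:1]])
    out = [pts[0]]
    for a, b in zip(pts[:-1], pts[1:]):
        L = np.linalg.norm(b - a)
        if L == 0:
            continue
        n = max(int(np.ceil(L / h)), 1)
        for j in range(1, n + 1):
            out.append(a + (b - a) * j / n)
    return np.asarray(out)


def build_mesh(spec: DomainSpec, max_conform_iter: int = 12) -> Mesh:
    """Mesh a labelled domain with conforming constraint polylines."""
    outer = np.asarray(spec.outer, float)
    diam = float(np.max(outer.max(axis=0) - outer.min(axis=0)))
    snap = 1e-7 * diam
    bank = _PointBank(snap)

    region_polys = [Polygon(np.asarray(r.polygon, float)) for r in spec.regions]
    for r, poly in zip(spec.regions, region_polys):
        if not poly.is_valid:
            raise MeshError(f"region {r.name!r} polygon is invalid")
    prepared = [prep(p) for p in region_polys]

    def local_h(p) -> float:
        for r, pr in zip(spec.regions, prepared):
            if pr.intersects(Point(p)):
                return r.h
        return spec.background_h

    # --- constraint polylines -> point-id chains
    chains: list[tuple[str, list[int], bool]] = []   # (kind:name, ids, closed)

    def add_chain(kind, polyline, closed):
        pts = np.asarray(polyline, float)
        h = min(local_h(q) for q in pts[:: max(len(pts) // 8, 1)])
        res = _resample(pts, h, closed)
        ids = [bank.add(q) for q in res]
        dedup = [ids[0]]
        for i in ids[1:]:
            if i != dedup[-1]:
                dedup.append(i)
        chains.append((kind, dedup, closed))

    add_chain("outer", outer, True)
    for r in spec.regions:
        add_chain(f"region:{r.name}", r.polygon, True)
    for f in spec.interfaces:
        add_chain(f"interface:{f.name}", f.polyline, f.closed)
    for c in spec.extra_constraints:
        add_chain("constraint", c, False)
    for a in spec.source_arcs:
        add_chain("source", a, False)

    # --- split chain segments at incident vertices: overlapping collinear
    # constraints (shared walls sampled by several chains) must share their
    # subdivision points or no triangulation can conform to all of them
    from scipy.spatial import cKDTree

    pts_now = bank.array()
    inc_tree = cKDTree(pts_now)
    inc_tol = 1e-6 * diam
    split_chains = []
    for kind, ids, closed in chains:
        out_ids = [ids[0]]
        for p, q in zip(ids[:-1], ids[1:]):
            a, b = pts_now[p], pts_now[q]
            L = float(np.linalg.norm(b - a))
            if L > 0:
                u = (b - a) / L
                cand = inc_tree.query_ball_point(0.5 * (a + b), 0.5 * L + inc_tol)
                ins = []
                for idx in cand:
                    if idx == p or idx == q:
                        continue
                    w = pts_now[idx] - a
                    t = float(w @ u)
                    if t <= inc_tol or t >= L - inc_tol:
                        continue
                    if abs(w[0] * u[1] - w[1] * u[0]) <= inc_tol:
                        ins.append((t, idx))
                for _, idx in sorted(ins):
                    if idx != out_ids[-1]:
                        out_ids.append(idx)
            out_ids.append(q)
        split_chains.append((kind, out_ids, closed))
    chains = split_chains

    # --- interior lattice points (clearance from constraints via KD-tree)
    constraint_tree = cKDTree(bank.array())

    def lattice(poly: Polygon, h: float):
        minx, miny, maxx, maxy = poly.bounds
        dy = h * np.sqrt(3) / 2
        rows = int(np.ceil((maxy - miny) / dy)) + 1
        pr = prep(poly)
        cand = []
        for j in range(rows):
            y = miny + j * dy
            x0 = minx + (h / 2 if j % 2 else 0.0)
            for x in np.arange(x0, maxx + h, h):
                cand.append((x, y))
        if not cand:
            return []
        cand = np.asarray(cand)
        d, _ = constraint_tree.query(cand, k=1)
        cand = cand[d > 0.55 * h]
        return [q for q in cand if pr.contains(Point(q))]

    interior = []
    covered = None
    for r, poly in zip(spec.regions, region_polys):
        interior.extend(lattice(poly, r.h))
        covered = poly if covered is None else covered.union(poly)
    outer_poly = Polygon(outer)
    bg = outer_poly if covered is None else outer_poly.difference(covered)
    interior.extend(lattice(bg, spec.background_h))
    for q in interior:
        bank.add(q)

    # --- Delaunay with conformity enforcement
    required: set[tuple[int, int]] = set()
    for _, ids, _ in chains:
        for p, q in zip(ids[:-1], ids[1:]):
            required.add(_ekey(p, q))

    def split_required():
        """Insert midpoints of missing constraint edges; update chains."""
        pts = bank.array()
        tri = Delaunay(pts)
        edges = set()
        for simplex in tri.simplices:
            for i in range(3):
                edges.add(_ekey(int(simplex[i]), int(simplex[(i + 1) % 3])))
        missing = [e for e in required if e not in edges]
        return tri, missing

    for _ in range(max_conform_iter):
        tri, missing = split_required()
        if not missing:
            break
        midpoint_of: dict[tuple[int, int], int] = {}
        for p, q in missing:
            mid = 0.5 * (bank.points[p] + bank.points[q])
            m = bank.add(mid)
            if m == p or m == q:
                raise MeshError("constraint segment collapsed during refinement")
            required.discard(_ekey(p, q))
            required.add(_ekey(p, m))
            required.add(_ekey(m, q))
            midpoint_of[_ekey(p, q)] = m
        for chain in chains:
            ids = chain[1]
            new_ids = [ids[0]]
            for p, q in zip(ids[:-1], ids[1:]):
                m = midpoint_of.get(_ekey(p, q))
                if m is not None:
                    new_ids.append(m)
                new_ids.append(q)
            ids[:] = new_ids
    else:
        pts = bank.array()
        where = [
            tuple(np.round(0.5 * (pts[p] + pts[q]), 4)) for p, q in missing[:8]
        ]
        raise MeshError(
            f"constraint conformity not reached; {len(missing)} segments "
            f"unresolved, e.g. near {where}"
        )

    points = bank.array()
    simplices = tri.simplices.copy()

    # drop zero-area triangles (collinear boundary points)
    p0 = points[simplices[:, 0]]
    p1 = points[simplices[:, 1]]
    p2 = points[simplices[:, 2]]
    area2 = (p1[:, 0] - p0[:, 0]) * (p2[:, 1] - p0[:, 1]) - (
        p1[:, 1] - p0[:, 1]
    ) * (p2[:, 0] - p0[:, 0])
    keep = np.abs(area2) > 1e-14 * diam**2
    simplices = simplices[keep]

    # --- region labelling
    cen = points[simplices].mean(axis=1)
    region_names = [r.name for r in spec.regions] + [spec.background_name]
    sigmas = np.array(
        [r.conductivity for r in spec.regions] + [spec.background_conductivity]
    )
    tri_region = np.full(len(simplices), len(spec.regions), dtype=int)
    unassigned = np.ones(len(simplices), dtype=bool)
    for k, pr in enumerate(prepared):
        if not np.any(unassigned):
            break
        idx = np.nonzero(unassigned)[0]
        hit = np.array([pr.contains(Point(c)) for c in cen[idx]])
        tri_region[idx[hit]] = k
        unassigned[idx[hit]] = False

    # --- interface node splitting
    tri_dof = simplices.astype(np.int64).copy()
    n_dof = len(points)
    dof_point = list(range(len(points)))
    point_tris: dict[int, list[int]] = {}
    for t, tri_pts in enumerate(simplices):
        for v in tri_pts:
            point_tris.setdefault(int(v), []).append(t)

    # nodes with at least one boundary edge (only one adjacent triangle):
    # open-interface endpoints landing there seal against the wall and are
    # split with a half-plane test so no current short-circuits around the
    # membrane's end
    edge_count: dict[tuple[int, int], int] = {}
    for tri_pts in simplices:
        for i in range(3):
            k = _ekey(int(tri_pts[i]), int(tri_pts[(i + 1) % 3]))
            edge_count[k] = edge_count.get(k, 0) + 1
    boundary_nodes = set()
    for (p, q), cnt in edge_count.items():
        if cnt == 1:
            boundary_nodes.add(p)
            boundary_nodes.add(q)

    def split_node(v: int, u: int, w: int | None):
        """Duplicate DOF of node ``v`` on one side of the interface.

        ``u``/``w`` are the neighbouring path nodes (``w`` None at a
        sealed endpoint: half-plane of the single segment u-v is used).
        """
        nonlocal n_dof
        pv = points[v]
        du = points[u] - pv
        au = np.arctan2(du[1], du[0])
        for t in point_tris[v]:
            c = points[simplices[t]].mean(axis=0) - pv
            if w is None:
                cross = du[0] * c[1] - du[1] * c[0]
                dup = cross > 0
            else:
                dw = points[w] - pv
                ac = np.arctan2(c[1], c[0])
                aw = np.arctan2(dw[1], dw[0])
                sector = np.mod(aw - au, 2 * np.pi)
                pos_c = np.mod(ac - au, 2 * np.pi)
                dup = pos_c >= sector
            if not dup:
                continue
            corner = list(simplices[t]).index(v)
            if tri_dof[t, corner] == v:
                tri_dof[t, corner] = -1  # mark for this split
        new_dof = None
        for t in point_tris[v]:
            corner = list(simplices[t]).index(v)
            if tri_dof[t, corner] == -1:
                if new_dof is None:
                    new_dof = n_dof
                    n_dof += 1
                    dof_point.append(int(v))
                tri_dof[t, corner] = new_dof

    interface_edges: dict[str, list[tuple[int, int]]] = {}
    for kind, ids, closed in chains:
        if not kind.startswith("interface:"):
            continue
        name = kind.split(":", 1)[1]
        interface_edges.setdefault(name, []).extend(
            (ids[i], ids[i + 1]) for i in range(len(ids) - 1)
        )
        if closed:
            for pos in range(len(ids) - 1):
                u = ids[pos - 1] if pos > 0 else ids[-2]
                split_node(ids[pos], u, ids[pos + 1])
        else:
            for pos in range(1, len(ids) - 1):
                split_node(ids[pos], ids[pos - 1], ids[pos + 1])
            if ids[0] in boundary_nodes:
                split_node(ids[0], ids[1], None)
            if ids[-1] in boundary_nodes:
                split_node(ids[-1], ids[-2], None)

    source_edges = []
    for kind, ids, closed in chains:
        if kind == "source":
            source_edges.append([(ids[i], ids[i + 1]) for i in range(len(ids) - 1)])

    mesh = Mesh(
        points=points,
        triangles=simplices,
        tri_dof=tri_dof,
        n_dof=n_dof,
        dof_point=np.asarray(dof_point),
        tri_region=tri_region,
        region_names=region_names,
        region_conductivity=sigmas,
        interface_edges=interface_edges,
        source_edges=source_edges,
        _delaunay=tri,
    )
    return mesh
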