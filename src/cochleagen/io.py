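"""CSV/JSON/SVG input and output.

File dialects:

- landmark CSV: columns section_id, theta_deg, landmark, x_mm, y_mm
  (header required, one row per landmark); used for both boundary and
  internal landmarks.
- measurement CSV: columns section_id, theta_deg, parameter, value.
- geometry JSON: regions as named vertex loops in mm, interfaces as
  polylines with conductivity/thickness.
- SVG export of a cross-section for visual inspection.
"""

from __future__ import annotations

import json
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .geometry import (
    BOUNDARY_NAMES,
    BoundaryLandmarks,
    CrossSectionGeometry,
    GeometryError,
    InternalLandmarks,
)

__all__ = [
    "read_landmark_csv",
    "write_landmark_csv",
    "boundaries_from_frame",
    "internal_from_frame",
    "read_measurement_csv",
    "write_measurement_csv",
    "geometry_to_json",
    "geometry_to_svg",
]

_LANDMARK_COLS = ["section_id", "theta_deg", "landmark", "x_mm", "y_mm"]


def read_landmark_csv(path) -> pd.DataFrame:
    """Read a landmark CSV, validating the dialect with line context."""
    df = pd.read_csv(path)
    missing = [c for c in _LANDMARK_COLS if c not in df.columns]
    if missing:
        raise GeometryError(f"landmark CSV {path}: missing columns {missing}")
    bad = df.index[~np.isfinite(df["x_mm"]) | ~np.isfinite(df["y_mm"])]
    if len(bad):
        raise GeometryError(
            f"landmark CSV {path}: non-finite coordinates at data line(s) "
            f"{[int(i) + 2 for i in bad[:5]]}"
        )
    return df[_LANDMARK_COLS]


def write_landmark_csv(path, rows: pd.DataFrame | Iterable[dict]) -> None:
    df = pd.DataFrame(rows)
    df = df[_LANDMARK_COLS]
    df.to_csv(path, index=False)


def landmarks_to_frame(
    section_id: str,
    theta_deg: float,
    landmarks: Mapping[str, np.ndarray] | BoundaryLandmarks | InternalLandmarks,
) -> pd.DataFrame:
    if isinstance(landmarks, (BoundaryLandmarks, InternalLandmarks)):
        landmarks = landmarks.points
    rows = [
        {"section_id": section_id, "theta_deg": float(theta_deg), "landmark": n,
         "x_mm": float(p[0]), "y_mm": float(p[1])}
        for n, p in landmarks.items()
    ]
    return pd.DataFrame(rows)


def boundaries_from_frame(df: pd.DataFrame) -> dict[tuple[str, float], BoundaryLandmarks]:
    """Group a landmark table into BoundaryLandmarks per (section, theta)."""
    out = {}
    for (sid, theta), grp in df.groupby(["section_id", "theta_deg"]):
        pts = {r.landmark: np.array([r.x_mm, r.y_mm]) for r in grp.itertuples()}
        missing = [n for n in BOUNDARY_NAMES if n not in pts]
        if missing:
            raise GeometryError(
                f"section {sid} at theta={theta}: missing boundary landmarks "
                f"{missing}"
            )
        out[(str(sid), float(theta))] = BoundaryLandmarks(
            {n: pts[n] for n in BOUNDARY_NAMES}
        )
    return out


def internal_from_frame(df: pd.DataFrame) -> dict[tuple[str, float], dict[str, np.ndarray]]:
    """Group a landmark table into name->point dicts per (section, theta)."""
    out = {}
    for (sid, theta), grp in df.groupby(["section_id", "theta_deg"]):
        out[(str(sid), float(theta))] = {
            r.landmark: np.array([r.x_mm, r.y_mm]) for r in grp.itertuples()
        }
    return out


def read_measurement_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = ["theta_deg", "parameter", "value"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise GeometryError(f"measurement CSV {path}: missing columns {missing}")
    return df


def write_measurement_csv(path, df: pd.DataFrame) -> None:
    cols = [c for c in ["section_id", "theta_deg", "parameter", "value"]
            if c in df.columns]
    df[cols].to_csv(path, index=False)


def geometry_to_json(geom: CrossSectionGeometry, path=None) -> str:
    data = {
        "theta_deg": geom.theta_deg,
        "regions": [
            {
                "name": r.name,
                "conductivity_S_per_m": r.conductivity,
                "vertices_mm": np.asarray(r.boundary, float).tolist(),
            }
            for r in geom.regions
        ],
        "interfaces": [
            {
                "name": f.name,
                "conductivity_S_per_m": f.conductivity,
                "thickness_mm": f.thickness,
                "paths_mm": [np.asarray(p, float).tolist() for p in f.paths],
            }
            for f in geom.interfaces
        ],
        "landmarks": {
            "internal": {n: np.asarray(p, float).tolist()
                         for n, p in geom.internal.points.items()},
            "boundary": {n: np.asarray(p, float).tolist()
                         for n, p in geom.boundary.points.items()},
        },
    }
    text = json.dumps(data, indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


_REGION_FILL = {
    "scala_tympani": "#bfdbf7",
    "scala_vestibuli": "#cde8d0",
    "scala_media": "#f6e3b4",
    "spiral_ligament": "#e8b4b8",
    "spiral_lamina_nerve": "#d4b4e8",
    "modiolar_bone": "#d9d9d9",
}


def geometry_to_svg(geom: CrossSectionGeometry, path=None, size: int = 640) -> str:
    """Minimal standalone SVG rendering of a cross-section."""
    pts = np.vstack([np.asarray(r.boundary) for r in geom.regions])
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = float(max(hi - lo))
    pad = 0.05 * span
    scale = size / (span + 2 * pad)

    def xy(p):
        x = (p[0] - lo[0] + pad) * scale
        y = size - (p[1] - lo[1] + pad) * scale  # SVG y grows downward
        return f"{x:.2f},{y:.2f}"

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{size}" height="{size}" '
        f'viewBox="0 0 {size} {size}">'
    ]
    for r in geom.regions:
        d = " ".join(xy(p) for p in r.boundary)
        fill = _REGION_FILL.get(r.name, "#eeeeee")
        parts.append(
            f'<polygon points="{d}" fill="{fill}" stroke="#555" '
            f'stroke-width="0.6"><title>{r.name}</title></polygon>'
        )
    for f in geom.interfaces:
        for pth in f.paths:
            d = " ".join(xy(p) for p in pth)
            parts.append(
                f'<polyline points="{d}" fill="none" stroke="#c0392b" '
                f'stroke-width="1.2"><title>{f.name}</title></polyline>'
            )
    for n, p in geom.internal.points.items():
        x, y = xy(p).split(",")
        parts.append(
            f'<circle cx="{x}" cy="{y}" r="2.4" fill="#1a1a1a"/>'
            f'<text x="{float(x) + 4:.1f}" y="{float(y) - 3:.1f}" '
            f'font-size="11">{n}</text>'
        )
    parts.append("</svg>")
    text = "\n".join(parts)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text
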