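"""Seeded synthetic generators standing in for histologic source data.

No public dataset of measured cochlear-duct cross-sections exists, so the
package ships generators that emulate the three kinds of input the
pipeline consumes: series of canal-boundary landmark sets along the
spiral, noisy parameter-measurement tables, and perturbed internal
landmark sets for validating the comparison statistics.

All generators are pure functions of their arguments including the seed;
randomness is confined to this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .equations import EquationRegistry, default_registry
from .geometry import BOUNDARY_NAMES, BoundaryLandmarks, InternalLandmarks

__all__ = [
    "CANONICAL_BOUNDARY",
    "canonical_boundary",
    "SyntheticSeries",
    "synthetic_boundary_series",
    "synthetic_measurement_table",
    "perturb_landmarks",
]

#: Canonical 9-landmark canal outline, version 1.
#:
#: Hand-drawn plausible duct cross-section in the canonical local frame
#: (LS at the origin, +x medial, +y toward the apex), normalised so the
#: basal canal width (LS to the MSVS/MSTS midpoint) is exactly 1.  It is
#: deliberately not traced from any real section; proportions are chosen
#: so that the full Table-of-parameters construction remains valid over
#: the first two turns.
CANONICAL_BOUNDARY: dict[str, tuple[float, float]] = {
    "LS": (0.0, 0.0),
    "SLS": (0.10, 0.32),
    "SS": (0.45, 0.47),
    "SMS": (0.78, 0.38),
    "MSVS": (1.0, 0.17),
    "MSTS": (1.0, -0.17),
    "IMS": (0.80, -0.47),
    "IS": (0.48, -0.66),
    "ILS": (0.15, -0.45),
}
CANONICAL_VERSION = 1


def canonical_boundary(width_mm: float = 1.0) -> BoundaryLandmarks:
    """The canonical outline scaled to a given basal canal width (mm)."""
    if width_mm <= 0:
        raise ValueError("width_mm must be positive")
    return BoundaryLandmarks(
        {n: width_mm * np.asarray(p, float) for n, p in CANONICAL_BOUNDARY.items()}
    )


@dataclass(frozen=True)
class SyntheticSeries:
    """A seeded series of cross-section boundaries along the spiral."""

    sections: tuple[tuple[float, BoundaryLandmarks], ...]
    seed: int
    basal_width_mm: float
    decay: float
    noise_sigma: float

    def __iter__(self):
        return iter(self.sections)

    def __len__(self) -> int:
        return len(self.sections)

    @property
    def thetas(self) -> tuple[float, ...]:
        return tuple(t for t, _ in self.sections)

    def boundary_at(self, theta_deg: float) -> BoundaryLandmarks:
        for t, b in self.sections:
            if abs(t - theta_deg) < 1e-9:
                return b
        raise KeyError(f"no section at theta={theta_deg}")


def synthetic_boundary_series(
    n_sections: int = 9,
    basal_width_mm: float = 2.0,
    decay: float = 0.85,
    noise_sigma: float = 0.0,
    seed: int = 0,
    theta_step_deg: float = 90.0,
) -> SyntheticSeries:
    """Generate a spiral series of boundary-landmark sets.

    The canonical outline is scaled by ``decay**(theta/360)`` (the canal
    narrows toward the apex) and each landmark is jittered with seeded
    Gaussian noise of standard deviation ``noise_sigma`` (mm).  Jitter
    above roughly 2% of the section width may break the outline
    invariants; generated boundaries are validated and a clear error is
    raised rather than returning a corrupt series.
    """
    if n_sections < 1:
        raise ValueError("n_sections must be >= 1")
    if basal_width_mm <= 0:
        raise ValueError("basal_width_mm must be positive")
    if not (0 < decay <= 1):
        raise ValueError("decay must be in (0, 1]")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    template = np.array([CANONICAL_BOUNDARY[n] for n in BOUNDARY_NAMES])
    sections = []
    for j in range(n_sections):
        theta = j * theta_step_deg
        scale = basal_width_mm * decay ** (theta / 360.0)
        pts = template * scale
        pts = pts + rng.normal(0.0, noise_sigma, size=pts.shape)
        bl = BoundaryLandmarks(dict(zip(BOUNDARY_NAMES, pts)))
        bl.outline()  # validate: raises on a self-intersecting outline
        sections.append((float(theta), bl))
    return SyntheticSeries(
        sections=tuple(sections),
        seed=int(seed),
        basal_width_mm=float(basal_width_mm),
        decay=float(decay),
        noise_sigma=float(noise_sigma),
    )


def synthetic_measurement_table(
    equations: EquationRegistry | None = None,
    thetas=None,
    noise_frac: float = 0.05,
    seed: int = 0,
):
    """Noisy parameter measurements drawn around the fitted curves.

    Values are ``equation(theta) * (1 + eps)`` with seeded Gaussian
    relative noise ``eps ~ N(0, noise_frac)``, one row per (section,
    parameter).  Returns a long-format :class:`pandas.DataFrame` with
    columns section_id, theta_deg, parameter, value — the same dialect
    :mod:`cochleagen.fitting` consumes.
    """
    import pandas as pd

    equations = equations if equations is not None else default_registry()
    if thetas is None:
        thetas = np.linspace(0.0, 720.0, 27)
    thetas = np.asarray(thetas, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for eq in equations:
        vals = np.asarray(eq(thetas), dtype=float)
        noisy = vals * (1.0 + rng.normal(0.0, noise_frac, size=vals.shape))
        for sid, (t, v) in enumerate(zip(thetas, noisy)):
            rows.append(
                {"section_id": f"S{sid:02d}", "theta_deg": float(t),
                 "parameter": eq.name, "value": float(v)}
            )
    return pd.DataFrame(rows)


def perturb_landmarks(
    lm: InternalLandmarks, sigma_mm: float, seed: int = 0
) -> InternalLandmarks:
    """Isotropic seeded Gaussian displacement of each landmark (mm)."""
    if sigma_mm < 0:
        raise ValueError("sigma_mm must be >= 0")
    rng = np.random.default_rng(seed)
    return InternalLandmarks(
        {
            name: np.asarray(p, float) + rng.normal(0.0, sigma_mm, size=2)
            for name, p in lm.points.items()
        },
        provenance=dict(lm.provenance),
    )
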