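"""Parametric equations for the internal cochlear-duct geometry.

Sixteen dimensionless parameters describe the internal structures of a
mid-modiolar cochlear-duct cross-section (basilar-membrane angle, spiral
lamina width and thickness, spiral-ligament landmark offsets, Reissner's
membrane angle, ...).  Each parameter is a function of the cochlear angle
``theta`` (degrees along the spiral, 0 at the most basal section) and is
normalised to the width of the most basal cochlear canal, so the model is
independent of the absolute size of an individual cochlea.

Four curve families occur: Gaussian ``a*exp(-c*(theta-b)^2) + d``,
one-term exponential ``a*exp(b*theta) + c``, cubic polynomials in a
centred variable ``theta_n = (theta - c1)/c2``, and straight lines.
Angle-valued parameters (``alpha``, ``beta``) are in radians; all length
parameters are fractions of the basal canal width.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CochlearAngle",
    "ParameterEquation",
    "ParameterSet",
    "NormalisationContext",
    "EquationRegistry",
    "default_registry",
    "evaluate_equation",
    "parameter_set",
    "denormalize",
    "default_sweep_range",
    "PARAMETER_NAMES",
    "ANGLE_PARAMETERS",
    "THETA_MAX",
]

#: Largest cochlear angle covered by the source measurements (two turns).
THETA_MAX = 720.0

#: Parameters whose value is an angle in radians (scale free).
ANGLE_PARAMETERS = ("alpha", "beta")

PARAMETER_NAMES = (
    "alpha", "Wa", "Wm", "Hsg", "Ft", "Fv", "Wsl", "Bm",
    "Wc", "Wd", "Hkm", "phi_fm", "Hkn", "phi_en", "Wsm", "beta",
)


class ExtrapolationError(ValueError):
    """Cochlear angle outside the modelled range without the opt-in flag."""


@dataclass(frozen=True)
class CochlearAngle:
    """Angular position along the cochlear spiral.

    Parameters
    ----------
    theta_deg:
        Angle in degrees, 0 at the most basal cross-section.
    extrapolate:
        Permit angles beyond two full turns (720 degrees).  Apical
        extrapolation is occasionally needed for full-length duct models
        but is outside the fitted range, hence opt-in.
    """

    theta_deg: float
    extrapolate: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.theta_deg):
            raise ValueError("theta_deg must be finite")
        if self.theta_deg < 0:
            raise ValueError(f"theta_deg must be >= 0, got {self.theta_deg}")
        if self.theta_deg > THETA_MAX and not self.extrapolate:
            raise ExtrapolationError(
                f"theta_deg={self.theta_deg} exceeds {THETA_MAX}; pass "
                "extrapolate=True to evaluate beyond the fitted range"
            )
        if self.theta_deg > THETA_MAX:
            warnings.warn(
                f"extrapolating parameter equations to theta={self.theta_deg} deg",
                stacklevel=2,
            )


_FAMILY_ARITY = {"gaussian": 4, "exponential": 3, "polynomial": None, "linear": 2}


@dataclass(frozen=True)
class ParameterEquation:
    """One fitted parameter curve.

    ``coefficients`` ordering by family:

    - ``gaussian``: (a, b, c, d) for ``a*exp(-c*(theta-b)**2) + d``
    - ``exponential``: (a, b, c) for ``a*exp(b*theta) + c``
    - ``polynomial``: highest power first, evaluated in the centred
      variable ``theta_n = (theta - c1)/c2``
    - ``linear``: (slope, intercept)
    """

    name: str
    family: str
    coefficients: tuple[float, ...]
    centring: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILY_ARITY:
            raise ValueError(f"unknown equation family {self.family!r}")
        arity = _FAMILY_ARITY[self.family]
        coeffs = tuple(float(c) for c in self.coefficients)
        object.__setattr__(self, "coefficients", coeffs)
        if arity is not None and len(coeffs) != arity:
            raise ValueError(
                f"{self.family} family takes {arity} coefficients, got {len(coeffs)}"
            )
        if (self.centring is not None) != (self.family == "polynomial"):
            raise ValueError("centring is present iff family == 'polynomial'")
        if self.centring is not None:
            c1, c2 = (float(v) for v in self.centring)
            if c2 == 0:
                raise ValueError("centring scale c2 must be nonzero")
            object.__setattr__(self, "centring", (c1, c2))

    @property
    def n_parameters(self) -> int:
        return len(self.coefficients)

    def __call__(self, theta_deg: float | np.ndarray) -> float | np.ndarray:
        t = np.asarray(theta_deg, dtype=float)
        if self.family == "gaussian":
            a, b, c, d = self.coefficients
            out = a * np.exp(-c * (t - b) ** 2) + d
        elif self.family == "exponential":
            a, b, c = self.coefficients
            out = a * np.exp(b * t) + c
        elif self.family == "linear":
            m, q = self.coefficients
            out = m * t + q
        else:  # polynomial
            c1, c2 = self.centring
            tn = (t - c1) / c2
            out = np.polyval(self.coefficients, tn)
        return out if out.ndim else float(out)

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "family": self.family,
            "coefficients": list(self.coefficients),
        }
        if self.centring is not None:
            d["centring"] = list(self.centring)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParameterEquation":
        centring = d.get("centring")
        return cls(
            name=d["name"],
            family=d["family"],
            coefficients=tuple(d["coefficients"]),
            centring=tuple(centring) if centring is not None else None,
        )


def evaluate_equation(eq: ParameterEquation, theta: CochlearAngle | float) -> float:
    """Evaluate one parameter curve at a cochlear angle."""
    if not isinstance(theta, CochlearAngle):
        theta = CochlearAngle(float(theta))
    return float(eq(theta.theta_deg))


# Fitted curves, coefficients kept to full published precision.
_DEFAULT_EQUATIONS: tuple[ParameterEquation, ...] = (
    ParameterEquation("alpha", "gaussian", (0.11423, 250.0, 34e-6, 0.0977)),
    ParameterEquation("Wa", "gaussian", (-0.09641, 400.0, 2.8e-5, 0.0)),
    ParameterEquation("Wm", "gaussian", (0.4162, -200.0, 0.0001, 0.3524)),
    ParameterEquation("Hsg", "polynomial", (-0.0013, 0.0017, -0.0016, 0.0425),
                      centring=(338.28, 242.26)),
    ParameterEquation("Ft", "polynomial", (-0.01562, 0.0433, -0.0217, 0.759),
                      centring=(339.11, 244.91)),
    ParameterEquation("Fv", "exponential", (0.1391, -8.5e-3, 0.7666)),
    ParameterEquation("Wsl", "exponential", (0.2156, -2.5e-3, 0.01466)),
    ParameterEquation("Bm", "linear", (2.0005e-4, 0.157)),
    ParameterEquation("Wc", "polynomial", (-0.0243, 0.0482, -0.0484, 0.2087),
                      centring=(341.69, 241.6)),
    ParameterEquation("Wd", "gaussian", (0.0727, 400.0, 4.8e-5, 0.1086)),
    ParameterEquation("Hkm", "gaussian", (0.22, -250.0, 1.7e-5, 0.4349)),
    ParameterEquation("phi_fm", "exponential", (0.1996, -2e-3, 0.1344)),
    ParameterEquation("Hkn", "exponential", (-0.0631, -0.01, 0.4128)),
    ParameterEquation("phi_en", "exponential", (0.2011, -0.01, 0.3964)),
    ParameterEquation("Wsm", "linear", (-1.886e-5, 0.074)),
    ParameterEquation("beta", "polynomial", (-0.0321, 0.0582, 0.1567, 0.6729),
                      centring=(341.22, 243.57)),
)


class EquationRegistry:
    """Named collection of parameter equations, JSON round-trippable.

    Users may substitute re-derived curves (see :mod:`cochleagen.fitting`)
    for any subset of the built-in ones.
    """

    def __init__(self, equations: Iterable[ParameterEquation]):
        self._eqs: dict[str, ParameterEquation] = {}
        for eq in equations:
            if eq.name in self._eqs:
                raise ValueError(f"duplicate equation for {eq.name!r}")
            self._eqs[eq.name] = eq

    def __getitem__(self, name: str) -> ParameterEquation:
        try:
            return self._eqs[name]
        except KeyError:
            raise KeyError(f"no equation registered for parameter {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._eqs

    def __iter__(self):
        return iter(self._eqs.values())

    def __len__(self) -> int:
        return len(self._eqs)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._eqs)

    def replace(self, *equations: ParameterEquation) -> "EquationRegistry":
        eqs = dict(self._eqs)
        for eq in equations:
            eqs[eq.name] = eq
        return EquationRegistry(eqs.values())

    def to_json(self, path=None) -> str:
        text = json.dumps([eq.to_dict() for eq in self], indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "EquationRegistry":
        if hasattr(source, "read"):
            data = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("["):
                data = json.loads(text)
            else:
                with open(text) as fh:
                    data = json.load(fh)
        return cls(ParameterEquation.from_dict(d) for d in data)


def default_registry() -> EquationRegistry:
    """Registry of the sixteen built-in parameter curves."""
    return EquationRegistry(_DEFAULT_EQUATIONS)


@dataclass(frozen=True)
class ParameterSet:
    """All sixteen parameters at one cochlear angle.

    Length-like fields are dimensionless (normalised to the basal canal
    width) unless produced by :func:`denormalize`, in which case they are
    in millimetres and ``units == "mm"``.  ``alpha``/``beta`` are radians
    in either case.
    """

    theta_deg: float
    alpha: float
    Wa: float
    Wm: float
    Hsg: float
    Ft: float
    Fv: float
    Wsl: float
    Bm: float
    Wc: float
    Wd: float
    Hkm: float
    phi_fm: float
    Hkn: float
    phi_en: float
    Wsm: float
    beta: float
    units: str = "normalised"
    warnings_: tuple[str, ...] = field(default=(), repr=False)

    def __getitem__(self, name: str) -> float:
        if name not in PARAMETER_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def with_value(self, name: str, value: float) -> "ParameterSet":
        if name not in PARAMETER_NAMES:
            raise KeyError(name)
        return replace(self, **{name: float(value)})

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAMETER_NAMES}

    def validate(self) -> tuple[str, ...]:
        """Return invariant-violation messages (empty when all hold)."""
        problems = []
        for name in PARAMETER_NAMES:
            if not math.isfinite(self[name]):
                problems.append(f"{name} is not finite")
        if self.Hsg <= 0:
            problems.append(f"Hsg must be > 0, got {self.Hsg}")
        if self.Wsl <= 0:
            problems.append(f"Wsl must be > 0, got {self.Wsl}")
        if self.Wm < self.Wsl:
            problems.append(f"Wm={self.Wm} < Wsl={self.Wsl}")
        return tuple(problems)


def parameter_set(
    theta: CochlearAngle | float,
    registry: EquationRegistry | None = None,
) -> ParameterSet:
    """Evaluate every parameter equation at ``theta``.

    Invariant violations (e.g. a substituted registry giving Wm < Wsl) are
    attached to the result as ``warnings_`` and emitted via ``warnings``;
    values are never clamped.
    """
    if not isinstance(theta, CochlearAngle):
        theta = CochlearAngle(float(theta))
    registry = registry if registry is not None else default_registry()
    values = {name: evaluate_equation(registry[name], theta) for name in PARAMETER_NAMES}
    ps = ParameterSet(theta_deg=theta.theta_deg, **values)
    problems = ps.validate()
    if problems:
        for msg in problems:
            warnings.warn(f"parameter set at theta={theta.theta_deg}: {msg}", stacklevel=2)
        ps = replace(ps, warnings_=problems)
    return ps


@dataclass(frozen=True)
class NormalisationContext:
    """Physical scale of one cochlea: basal canal width in mm."""

    basal_canal_width: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.basal_canal_width) and self.basal_canal_width > 0):
            raise ValueError(
                f"basal_canal_width must be positive, got {self.basal_canal_width}"
            )


def denormalize(params: ParameterSet, ctx: NormalisationContext) -> ParameterSet:
    """Scale length parameters to millimetres; angles are unchanged."""
    w = ctx.basal_canal_width
    scaled = {
        name: (params[name] if name in ANGLE_PARAMETERS else params[name] * w)
        for name in PARAMETER_NAMES
    }
    return replace(params, units="mm", **scaled)


def _percentile_range(
    eq: ParameterEquation, lo: float = 20.0, hi: float = 80.0
) -> tuple[float, float]:
    grid = np.linspace(0.0, THETA_MAX, 721)
    vals = np.asarray(eq(grid), dtype=float)
    return float(np.percentile(vals, lo)), float(np.percentile(vals, hi))


def default_sweep_range(
    name: str,
    theta: CochlearAngle | float,
    registry: EquationRegistry | None = None,
    ctx: NormalisationContext | None = None,
    mode: str = "percentile",
    fraction: float = 0.20,
) -> tuple[float, float]:
    """Default (low, high) sweep interval for a parameter, normalised units.

    The interval emulates the 20th-80th percentile window of the original
    measurements: by default the 20th-80th percentile of the fitted curve
    over the whole angular range stands in for the unpublished raw data
    (``mode="percentile"``); ``mode="fraction"`` gives +/- ``fraction`` of
    the value at ``theta`` instead.  Two anatomically anchored overrides
    always apply: ``alpha`` sweeps 0-15 degrees and ``Wm`` sweeps from
    Wsl(theta) up to 0.6 mm (normalised via ``ctx``).
    """
    if name not in PARAMETER_NAMES:
        raise KeyError(f"unknown parameter {name!r}")
    if not isinstance(theta, CochlearAngle):
        theta = CochlearAngle(float(theta))
    registry = registry if registry is not None else default_registry()

    if name == "alpha":
        return (0.0, math.radians(15.0))
    if name == "Wm":
        # Wm = Wsl collapses the scala media to zero width, so the lower
        # bound sits 5% above the anatomical floor
        wsl = 1.05 * evaluate_equation(registry["Wsl"], theta)
        width = ctx.basal_canal_width if ctx is not None else 2.0
        hi = 0.6 / width
        return (wsl, max(hi, wsl))

    if mode == "percentile":
        return _percentile_range(registry[name])
    if mode == "fraction":
        v = evaluate_equation(registry[name], theta)
        lo, hi = v - fraction * abs(v), v + fraction * abs(v)
        return (lo, hi)
    raise ValueError(f"unknown sweep-range mode {mode!r}")


def parameter_table(
    thetas: Sequence[float],
    ctx: NormalisationContext | None = None,
    registry: EquationRegistry | None = None,
) -> pd.DataFrame:
    """Long-format table of parameter values over a set of angles.

    Columns: theta_deg, parameter, value_normalised, value_mm (NaN for
    angles when no context is given).
    """
    rows = []
    for t in thetas:
        ps = parameter_set(t, registry=registry)
        mm = denormalize(ps, ctx) if ctx is not None else None
        for name in PARAMETER_NAMES:
            rows.append(
                {
                    "theta_deg": float(t),
                    "parameter": name,
                    "value_normalised": ps[name],
                    "value_mm": (
                        np.nan
                        if mm is None or name in ANGLE_PARAMETERS
                        else mm[name]
                    ),
                }
            )
    return pd.DataFrame(rows)
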