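"""Template-morphing baseline for internal-structure prediction.

The baseline method against which the parametric landmark prediction is
compared: a generalised internal-structure template (landmarks + outline
of one basal cross-section, normalised to a unit reference box) is fitted
to a target cross-section by anisotropic scaling, translation and an
optional mirror flip.  No elastic warping and no statistical shape model
— the affine box fit is the whole method.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .geometry import (
    BoundaryLandmarks,
    GeometryError,
    InternalLandmarks,
)

__all__ = ["MorphTemplate", "OrientedBox", "target_box", "morph_template",
           "default_template"]


@dataclass(frozen=True)
class OrientedBox:
    """Axis-aligned bounding box (x0, y0) - (x1, y1)."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self):
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise GeometryError("degenerate target box (zero extent)")

    @property
    def extents(self) -> tuple[float, float]:
        return (self.x1 - self.x0, self.y1 - self.y0)

    @property
    def origin(self) -> np.ndarray:
        return np.array([self.x0, self.y0])


@dataclass(frozen=True)
class MorphTemplate:
    """Generalised internal geometry normalised to the unit box.

    ``landmarks`` maps names to 2D points; ``outline`` is the template's
    canal outline polyline.  All coordinates live in (roughly) the unit
    square; small excursions are tolerated since some landmarks may sit
    marginally outside the box that normalised them.
    """

    landmarks: dict[str, np.ndarray]
    outline: np.ndarray
    provenance: str = "unspecified"

    def __post_init__(self):
        lms = {n: np.asarray(p, float) for n, p in self.landmarks.items()}
        object.__setattr__(self, "landmarks", lms)
        object.__setattr__(self, "outline", np.asarray(self.outline, float))
        pts = np.array(list(lms.values()))
        if pts.size and (pts.min() < -0.05 or pts.max() > 1.05):
            raise GeometryError(
                "template landmarks leave the unit reference box by more "
                "than the 5% tolerance"
            )

    def to_json(self, path=None) -> str:
        data = {
            "provenance": self.provenance,
            "landmarks": {n: list(map(float, p)) for n, p in self.landmarks.items()},
            "outline": self.outline.tolist(),
        }
        text = json.dumps(data, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "MorphTemplate":
        if hasattr(source, "read"):
            data = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                data = json.loads(text)
            else:
                with open(text) as fh:
                    data = json.load(fh)
        return cls(
            landmarks={n: np.array(p) for n, p in data["landmarks"].items()},
            outline=np.array(data["outline"]),
            provenance=data.get("provenance", "unspecified"),
        )


def target_box(boundary: BoundaryLandmarks) -> OrientedBox:
    """Bounding box spanned by IS, LS, SS and the MSVS/MSTS midpoint."""
    pts = np.array(
        [
            boundary["IS"],
            boundary["LS"],
            boundary["SS"],
            0.5 * (boundary["MSVS"] + boundary["MSTS"]),
        ]
    )
    x0, y0 = pts.min(axis=0)
    x1, y1 = pts.max(axis=0)
    if np.isclose(x0, x1) or np.isclose(y0, y1):
        raise GeometryError("box-defining landmarks are collinear")
    return OrientedBox(float(x0), float(y0), float(x1), float(y1))


def normalising_box(points: np.ndarray) -> OrientedBox:
    pts = np.asarray(points, float)
    x0, y0 = pts.min(axis=0)
    x1, y1 = pts.max(axis=0)
    return OrientedBox(float(x0), float(y0), float(x1), float(y1))


def make_template(
    landmarks: dict[str, np.ndarray],
    boundary: BoundaryLandmarks,
    outline_samples: int = 128,
    provenance: str = "unspecified",
) -> MorphTemplate:
    """Normalise a measured/predicted section into a morph template.

    The normalising box is the same box construction used for targets
    (IS, LS, SS and the MSVS/MSTS midpoint), so morphing a template back
    onto its own source box is the identity.
    """
    box = target_box(boundary)
    ex, ey = box.extents
    o = box.origin

    def norm(p):
        return (np.asarray(p, float) - o) / np.array([ex, ey])

    outline = boundary.outline().sample(outline_samples)
    return MorphTemplate(
        landmarks={n: norm(p) for n, p in landmarks.items()},
        outline=norm(outline),
        provenance=provenance,
    )


def morph_template(
    tpl: MorphTemplate, box: OrientedBox, mirror: bool = False
) -> InternalLandmarks:
    """Fit the template into a target box by scale/translate (+ mirror).

    Scaling is anisotropic (x and y scaled independently to the box
    extents); ``mirror`` reflects x about the box midline for
    contralateral cochleae.  The map is affine, so collinearity and
    ratios along lines are preserved.
    """
    ex, ey = box.extents
    o = box.origin

    def fit(p):
        p = np.asarray(p, float)
        x = 1.0 - p[0] if mirror else p[0]
        return o + np.array([x * ex, p[1] * ey])

    return InternalLandmarks(
        {n: fit(p) for n, p in tpl.landmarks.items()},
        provenance={n: ("template_morph",) for n in tpl.landmarks},
    )


def default_template() -> MorphTemplate:
    """The shipped generalised template.

    Built from the parametric construction at the most basal angle (0
    degrees) on the canonical synthetic boundary — a stand-in for the
    unpublished histologic section the original baseline used; marked
    synthetic in its provenance.
    """
    from importlib.resources import files

    path = files("cochleagen").joinpath("data/default_template_synthetic.json")
    return MorphTemplate.from_json(path.read_text())
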