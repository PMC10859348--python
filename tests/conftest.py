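import warnings

import numpy as np
import pytest

from cochleagen.equations import NormalisationContext, denormalize, parameter_set
from cochleagen.geometry import (
    assemble_cross_section,
    basal_canal_width,
    construct_internal_landmarks,
)
from cochleagen.synth import canonical_boundary


@pytest.fixture(scope="session")
def basal_boundary():
    """Canonical synthetic boundary scaled to a 2 mm basal canal width."""
    return canonical_boundary(2.0)


@pytest.fixture(scope="session")
def basal_params_mm(basal_boundary):
    ps = parameter_set(0.0)
    return denormalize(ps, NormalisationContext(basal_canal_width(basal_boundary)))


@pytest.fixture(scope="session")
def basal_landmarks(basal_boundary, basal_params_mm):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return construct_internal_landmarks(basal_boundary, basal_params_mm)


@pytest.fixture(scope="session")
def basal_geometry(basal_boundary, basal_params_mm, basal_landmarks):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return assemble_cross_section(
            basal_boundary, basal_landmarks, basal_params_mm, 0.0
        )


def de_casteljau(control, t):
    """Independent Bezier oracle: de Casteljau recursion."""
    pts = [np.asarray(p, float) for p in control]
    while len(pts) > 1:
        pts = [(1 - t) * a + t * b for a, b in zip(pts[:-1], pts[1:])]
    return pts[0]
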