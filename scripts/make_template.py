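"""Regenerate the shipped synthetic morph template.

Builds the parametric geometry at the most basal angle on the canonical
synthetic boundary and normalises it into the unit reference box.  Run
from the repository root:

    python scripts/make_template.py
"""

import warnings

from cochleagen.equations import NormalisationContext, denormalize, parameter_set
from cochleagen.geometry import basal_canal_width, construct_internal_landmarks
from cochleagen.morph import make_template
from cochleagen.synth import canonical_boundary


def build():
    bl = canonical_boundary(2.0)
    ps = parameter_set(0.0)
    mm = denormalize(ps, NormalisationContext(basal_canal_width(bl)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lm = construct_internal_landmarks(bl, mm)
    return make_template(
        dict(lm.points),
        bl,
        provenance="synthetic: parametric construction at 0 deg on the "
                   "canonical boundary (not a histologic section), v1",
    )


if __name__ == "__main__":
    tpl = build()
    path = "src/cochleagen/data/default_template_synthetic.json"
    tpl.to_json(path)
    print(f"wrote {path}")
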