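"""Rule-based fine-tuning and natural-language report generation.

Two lexicon rules adjust the model output after the category regression:

1. a round nodule has no orientation (neither parallel nor anti-parallel) —
   the orientation output is removed;
2. a simple cyst, a complex cyst and a spiculated nodule force the category
   to 2, 4A and 5, respectively.

When rules conflict (e.g. a spiculated nodule typed as a cyst) the
malignancy-dominant order wins: spiculated (5) overrides the tumor type,
which overrides the regression.  Applying the rules twice equals applying
them once.

The narrative is a deterministic template fill; templates are plain text
files with ``{named}`` slots, shipped in English and replaceable by the user.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from .descriptors import DescriptorSet
from .errors import InputError, TemplateError
from .vocab import BIRADS_CATEGORIES

#: Category -> clinical intervention, over the full clinical scale.
INTERVENTIONS = {
    "0": "Additional evaluation",
    "1": "Normal procedure",
    "2": "Normal procedure",
    "3": "Control in 6 months",
    "4A": "Biopsy",
    "4B": "Biopsy",
    "4C": "Biopsy",
    "5": "Biopsy",
    "6": "Treatment",
}

_PHRASES = {
    "shape": {"oval": "an oval shape", "round": "a round shape",
              "irregular": "an irregular shape"},
    "margin": {"circumscribed": "circumscribed margins",
               "indistinct": "indistinct margins",
               "microlobulated": "microlobulated margins",
               "spiculated": "spiculated margins"},
    "orientation": {"parallel": "a parallel orientation",
                    "anti_parallel": "an anti-parallel orientation"},
    "echogenicity": {"anechoic": "an anechoic interior",
                     "hypoechoic": "a hypoechoic interior",
                     "isoechoic": "an isoechoic interior",
                     "hyperechoic": "a hyperechoic interior",
                     "heterogeneous": "a heterogeneous interior"},
    "posterior": {"none": "no posterior acoustic feature",
                  "enhancement": "posterior enhancement",
                  "shadowing": "posterior shadowing"},
    "halo": {"present": "an echogenic halo", "absent": "no echogenic halo"},
    "suggestivity": {"simple_cyst": "a simple cyst",
                     "complex_cyst": "a complex cyst",
                     "fibroadenoma": "a fibroadenoma",
                     "no_clear_suggestivity": "no clear tumor type"},
}

DEFAULT_TEMPLATE = (
    "The nodule presents {shape}, {margin}, {orientation_clause}"
    "{echogenicity}, {posterior}, and {halo}. The finding is suggestive of "
    "{suggestivity}. Estimated probability of malignancy: {malignancy:.1%}. "
    "BI-RADS category {category}. Recommended intervention: {intervention}."
)


@dataclass(frozen=True)
class FinalReport:
    """Descriptor values after rules, final category and the narrative."""

    descriptors: dict[str, str]  # orientation absent when removed by rule 1
    category: str
    malignancy_probability: float
    intervention: str
    narrative: str

    def to_json(self) -> str:
        return json.dumps(
            {"descriptors": self.descriptors, "category": self.category,
             "malignancy_probability": round(self.malignancy_probability, 6),
             "intervention": self.intervention, "narrative": self.narrative},
            indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, payload: str) -> "FinalReport":
        d = json.loads(payload)
        return cls(descriptors=d["descriptors"], category=d["category"],
                   malignancy_probability=d["malignancy_probability"],
                   intervention=d["intervention"], narrative=d["narrative"])


def apply_rules(d: DescriptorSet | dict, category: str) -> tuple[dict, str]:
    """Fine-tune descriptors and category with the two lexicon rules.

    Returns ``(descriptors, category)`` where the descriptor dict omits the
    orientation key for round nodules.  Idempotent: feeding the output back
    in changes nothing.
    """
    desc = dict(d.as_dict()) if isinstance(d, DescriptorSet) else dict(d)
    if category not in BIRADS_CATEGORIES:
        raise InputError(f"category {category!r} outside the descriptor scale")
    if desc.get("shape") == "round":
        desc.pop("orientation", None)
    if desc.get("margin") == "spiculated":
        category = "5"
    elif desc.get("suggestivity") == "simple_cyst":
        category = "2"
    elif desc.get("suggestivity") == "complex_cyst":
        category = "4A"
    return desc, category


def intervention(category: str) -> str:
    """Clinical intervention for a category (full 0-6 scale)."""
    try:
        return INTERVENTIONS[str(category)]
    except KeyError:
        raise InputError(f"unknown BI-RADS category {category!r}") from None


def render_report(descriptors: dict, category: str,
                  malignancy_probability: float,
                  template: str = DEFAULT_TEMPLATE) -> FinalReport:
    """Fill the narrative template; expects rules already applied.

    The orientation clause disappears entirely when the orientation was
    removed (round nodules).  Serialization round-trips byte-identically.
    """
    phrases = {}
    for name, value in descriptors.items():
        if name == "orientation":
            continue
        if name not in _PHRASES or value not in _PHRASES[name]:
            raise InputError(f"cannot phrase descriptor {name}={value!r}")
        phrases[name] = _PHRASES[name][value]
    orientation_clause = ""
    if descriptors.get("orientation") in ("parallel", "anti_parallel"):
        orientation_clause = _PHRASES["orientation"][descriptors["orientation"]] + ", "
    try:
        narrative = template.format(
            orientation_clause=orientation_clause,
            malignancy=malignancy_probability,
            category=category,
            intervention=intervention(category),
            **phrases,
        )
    except (KeyError, IndexError) as exc:
        raise TemplateError(f"template slot missing: {exc}") from exc
    return FinalReport(
        descriptors=descriptors, category=category,
        malignancy_probability=float(malignancy_probability),
        intervention=intervention(category), narrative=narrative)


def describe(d: DescriptorSet | dict, category: str,
             malignancy_probability: float,
             template: str = DEFAULT_TEMPLATE) -> FinalReport:
    """Apply the rules, then render the report (the usual entry point)."""
    desc, cat = apply_rules(d, category)
    return render_report(desc, cat, malignancy_probability, template)
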