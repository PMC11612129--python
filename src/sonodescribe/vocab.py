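"""BI-RADS descriptor vocabularies and the category scale.

The value sets follow the 5th-edition BI-RADS lexicon restricted to the
descriptors a single-image grayscale pipeline can resolve: mixed posterior
features, complex cystic-and-solid echogenicity and calcifications are
excluded, and the "angular" margin is folded into "indistinct".  All
vocabularies are plain tuples so downstream users with richer annotations can
swap in extended sets through :class:`Vocabularies`.
"""

from __future__ import annotations

from dataclasses import dataclass


SHAPES = ("oval", "round", "irregular")
MARGINS = ("circumscribed", "indistinct", "microlobulated", "spiculated")
ORIENTATIONS = ("parallel", "anti_parallel", "none")
ECHOGENICITIES = ("anechoic", "hypoechoic", "isoechoic", "hyperechoic", "heterogeneous")
POSTERIORS = ("none", "enhancement", "shadowing")
HALOS = ("absent", "present")
SUGGESTIVITIES = ("simple_cyst", "complex_cyst", "fibroadenoma", "no_clear_suggestivity")

#: Categories a descriptor-driven model can produce.  The full clinical scale
#: also contains 0 (incomplete study), 1 (no findings) and 6 (biopsy-proven
#: malignancy), which are procedural states, not image findings; they are
#: accepted by the intervention table but never predicted.
BIRADS_CATEGORIES = ("2", "3", "4A", "4B", "4C", "5")

#: Descriptors produced by the six per-descriptor heads, in canonical order.
DESCRIPTOR_NAMES = ("shape", "margin", "orientation", "echogenicity", "posterior", "halo")

#: The seven categorical outputs compared against a reference reading.
ALL_DESCRIPTOR_NAMES = DESCRIPTOR_NAMES + ("suggestivity",)


@dataclass(frozen=True)
class Vocabularies:
    """Configured value sets for every descriptor and for the category scale."""

    shape: tuple[str, ...] = SHAPES
    margin: tuple[str, ...] = MARGINS
    orientation: tuple[str, ...] = ORIENTATIONS
    echogenicity: tuple[str, ...] = ECHOGENICITIES
    posterior: tuple[str, ...] = POSTERIORS
    halo: tuple[str, ...] = HALOS
    suggestivity: tuple[str, ...] = SUGGESTIVITIES
    birads: tuple[str, ...] = BIRADS_CATEGORIES

    def descriptor_values(self, name: str) -> tuple[str, ...]:
        if name not in ALL_DESCRIPTOR_NAMES:
            raise KeyError(f"unknown descriptor {name!r}")
        return getattr(self, name)

    def validate(self, name: str, value: str) -> None:
        if value not in self.descriptor_values(name):
            raise ValueError(
                f"{value!r} is not a configured value for descriptor {name!r}; "
                f"expected one of {self.descriptor_values(name)}"
            )


DEFAULT_VOCABULARIES = Vocabularies()
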