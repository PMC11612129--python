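"""The descriptor bundle passed between network, regression and rules."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .errors import InputError
from .vocab import DEFAULT_VOCABULARIES, Vocabularies, ALL_DESCRIPTOR_NAMES


@dataclass(frozen=True)
class DescriptorSet:
    """One categorical value per descriptor, plus optional per-value probabilities.

    ``orientation`` may be the literal value ``"none"`` (round nodules);
    downstream rules may *remove* the orientation, which is represented by
    :class:`sonodescribe.rules.FinalReport`, not here.
    """

    shape: str
    margin: str
    orientation: str
    echogenicity: str
    posterior: str
    halo: str
    suggestivity: str
    probabilities: dict[str, dict[str, float]] | None = field(
        default=None, compare=False)

    def validate(self, vocab: Vocabularies = DEFAULT_VOCABULARIES) -> "DescriptorSet":
        for name in ALL_DESCRIPTOR_NAMES:
            value = getattr(self, name)
            if value not in vocab.descriptor_values(name):
                raise InputError(
                    f"{value!r} is not in the {name} vocabulary "
                    f"{vocab.descriptor_values(name)}")
        return self

    def as_dict(self) -> dict[str, str]:
        d = asdict(self)
        d.pop("probabilities")
        return d

    @classmethod
    def from_dict(cls, d: dict[str, str]) -> "DescriptorSet":
        return cls(**{k: d[k] for k in ALL_DESCRIPTOR_NAMES})
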