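"""Outcome catalogues for best-worst scaling studies.

An :class:`OutcomeCatalogue` is the ordered set of items respondents trade
off — here, clinical outcomes that may occur under statin therapy for
primary prevention of cardiovascular disease. One outcome is designated the
*reference*: its utility is fixed at 0 for identification of the choice
model, so every estimated coefficient is a log-odds relative to it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

__all__ = ["OutcomeCatalogue", "statin_catalogue"]


@dataclass(frozen=True)
class OutcomeCatalogue:
    """An ordered list of outcome labels with harm flags and a reference.

    Parameters
    ----------
    outcomes
        Unique, non-empty outcome identifiers, in display order.
    harm_flags
        For each outcome, ``True`` if it is a harm of treatment (as opposed
        to an averted benefit event or a neutral endpoint).
    reference
        The outcome whose utility is fixed at 0 for identification.
    """

    outcomes: tuple[str, ...]
    harm_flags: tuple[bool, ...]
    reference: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "outcomes", tuple(self.outcomes))
        object.__setattr__(self, "harm_flags", tuple(bool(h) for h in self.harm_flags))
        if len(self.outcomes) < 2:
            raise ValueError("catalogue needs at least two outcomes")
        if any(not isinstance(o, str) or not o for o in self.outcomes):
            raise ValueError("outcome identifiers must be non-empty strings")
        if len(set(self.outcomes)) != len(self.outcomes):
            raise ValueError("outcome identifiers must be unique")
        if len(self.harm_flags) != len(self.outcomes):
            raise ValueError("harm_flags must align with outcomes")
        if self.reference not in self.outcomes:
            raise ValueError(
                f"reference {self.reference!r} is not a catalogue outcome"
            )

    def __len__(self) -> int:
        return len(self.outcomes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.outcomes)

    def index(self, outcome: str) -> int:
        return self.outcomes.index(outcome)

    @property
    def reference_index(self) -> int:
        return self.outcomes.index(self.reference)

    @property
    def non_reference(self) -> tuple[str, ...]:
        """Outcomes excluding the reference, in catalogue order."""
        return tuple(o for o in self.outcomes if o != self.reference)

    def is_harm(self, outcome: str) -> bool:
        return self.harm_flags[self.index(outcome)]


#: The 13 statin benefit/harm outcomes, ordered from most to least worrisome
#: in the pooled elicitation. Harms of statin therapy itself are flagged;
#: "treatment discontinuation" (due to side effects) is the reference.
_STATIN_OUTCOMES: Sequence[tuple[str, bool]] = (
    ("severe stroke", False),
    ("severe myocardial infarction", False),
    ("cancer", True),
    ("moderate stroke", False),
    ("moderate myocardial infarction", False),
    ("heart failure", False),
    ("type 2 diabetes", True),
    ("liver injury", True),
    ("unstable angina", False),
    ("acute kidney failure", True),
    ("myopathy", True),
    ("nausea/headache", True),
    ("treatment discontinuation", True),
)


def statin_catalogue() -> OutcomeCatalogue:
    """The default 13-outcome statin benefit/harm catalogue.

    Seven outcomes are statin-associated harms; the reference outcome is
    treatment discontinuation due to side effects, whose log-odds is fixed
    at 0 in every model.
    """
    names = tuple(n for n, _ in _STATIN_OUTCOMES)
    harms = tuple(h for _, h in _STATIN_OUTCOMES)
    return OutcomeCatalogue(outcomes=names, harm_flags=harms, reference="treatment discontinuation")
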