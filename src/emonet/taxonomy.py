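"""Emotion taxonomy: the fixed checklist of discrete emotions and their valence.

The default taxonomy is the 18-item checklist adapted from the modified
Differential Emotions Scale (mDES): nine positive and nine negative emotion
terms. The canonical ordering — positive emotions alphabetically, then
negative emotions alphabetically — is used for every vector, matrix and
output table in the package so that results are reproducible and alignable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

POSITIVE_EMOTIONS: tuple[str, ...] = (
    "alertness",
    "amusement",
    "awe",
    "gratitude",
    "hope",
    "joy",
    "love",
    "pride",
    "satisfaction",
)

NEGATIVE_EMOTIONS: tuple[str, ...] = (
    "anger",
    "anxiety",
    "contempt",
    "disgust",
    "embarrassment",
    "fear",
    "guilt",
    "offense",
    "sadness",
)


@dataclass(frozen=True)
class EmotionTaxonomy:
    """An ordered set of emotion names, each tagged positive or negative.

    Parameters
    ----------
    emotions
        Ordered emotion names. The order is canonical: it fixes the meaning
        of every indicator vector and the row/column order of every matrix.
    valence
        Mapping from emotion name to ``"positive"`` or ``"negative"``.
    """

    emotions: tuple[str, ...] = POSITIVE_EMOTIONS + NEGATIVE_EMOTIONS
    valence: Mapping[str, str] = field(
        default_factory=lambda: {
            **{e: "positive" for e in POSITIVE_EMOTIONS},
            **{e: "negative" for e in NEGATIVE_EMOTIONS},
        }
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "emotions", tuple(self.emotions))
        if len(set(self.emotions)) != len(self.emotions):
            raise ValueError("emotion names must be unique")
        missing = [e for e in self.emotions if e not in self.valence]
        if missing:
            raise ValueError(f"emotions without a valence tag: {missing}")
        bad = {v for v in self.valence.values()} - {"positive", "negative"}
        if bad:
            raise ValueError(f"valence must be 'positive' or 'negative', got {bad}")

    # -- basic protocol -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.emotions)

    def __iter__(self):
        return iter(self.emotions)

    def __contains__(self, name: str) -> bool:
        return name in self.emotions

    def index(self, name: str) -> int:
        return self.emotions.index(name)

    # -- valence helpers ----------------------------------------------------

    @property
    def positive(self) -> tuple[str, ...]:
        return tuple(e for e in self.emotions if self.valence[e] == "positive")

    @property
    def negative(self) -> tuple[str, ...]:
        return tuple(e for e in self.emotions if self.valence[e] == "negative")

    def positive_mask(self) -> np.ndarray:
        """Boolean array aligned to the canonical order; True = positive."""
        return np.array([self.valence[e] == "positive" for e in self.emotions])

    def same_valence(self, a: str, b: str) -> bool:
        return self.valence[a] == self.valence[b]


def default_taxonomy() -> EmotionTaxonomy:
    """The 18-emotion mDES-derived taxonomy (9 positive + 9 negative)."""
    tax = EmotionTaxonomy()
    assert len(tax) == 18 and len(tax.positive) == 9 and len(tax.negative) == 9
    return tax


def validate_emotion_names(names: Iterable[str], taxonomy: EmotionTaxonomy) -> None:
    """Raise ``ValueError`` listing any name not in the taxonomy."""
    unknown = sorted(set(names) - set(taxonomy.emotions))
    if unknown:
        raise ValueError(f"unknown emotion name(s): {unknown}")
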