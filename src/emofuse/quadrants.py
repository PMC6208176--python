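"""Arousal-valence plane conventions.

Emotions are labelled by the quadrant of the circumplex (arousal-valence)
plane their self-assessment ratings fall into.  Ratings are on a 1-9 scale;
the plane is cut at the midpoint 5.0, with ratings exactly at the cutoff
assigned to the "low" side.  Quadrant orientation:

    Q1 = high valence / high arousal (HVHA)
    Q2 = low  valence / high arousal (LVHA)
    Q3 = low  valence / low  arousal (LVLA)
    Q4 = high valence / low  arousal (HVLA)
"""

from __future__ import annotations

QUARTERS = ("Q1", "Q2", "Q3", "Q4")

RATING_MIN = 1.0
RATING_MAX = 9.0
DEFAULT_CUTOFF = 5.0


def quarter_of(arousal: float, valence: float, cutoff: float = DEFAULT_CUTOFF) -> str:
    """Map an (arousal, valence) rating pair to its quadrant label.

    Ratings strictly above ``cutoff`` count as "high"; ties go to the low side.
    """
    high_a = arousal > cutoff
    high_v = valence > cutoff
    if high_a and high_v:
        return "Q1"
    if high_a and not high_v:
        return "Q2"
    if not high_a and not high_v:
        return "Q3"
    return "Q4"


def binarize_arousal(arousal: float, cutoff: float = DEFAULT_CUTOFF) -> int:
    """1 for high arousal, 0 for low."""
    return int(arousal > cutoff)


def binarize_valence(valence: float, cutoff: float = DEFAULT_CUTOFF) -> int:
    """1 for high valence, 0 for low."""
    return int(valence > cutoff)
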