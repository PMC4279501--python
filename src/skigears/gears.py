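"""The five-gear vocabulary of ski-skating sub-techniques.

G2 and G4 come in left- and right-dominant variants (which pole side
leads); G3 uses one symmetric poling action per leg push.  The canonical
order below is used everywhere: model files, confusion-matrix rows and
tie-breaking between equal likelihoods.
"""

from __future__ import annotations

from .exceptions import VocabularyError

GEARS: tuple[str, ...] = ("G2L", "G2R", "G3", "G4L", "G4R")

_GEAR_INDEX = {g: i for i, g in enumerate(GEARS)}


def gear_index(gear: str) -> int:
    """Position of *gear* in the canonical order; raises on unknown labels."""
    try:
        return _GEAR_INDEX[gear]
    except KeyError:
        raise VocabularyError(
            f"unknown gear {gear!r}; expected one of {', '.join(GEARS)}"
        ) from None


def check_gear(gear: str) -> str:
    gear_index(gear)
    return gear
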