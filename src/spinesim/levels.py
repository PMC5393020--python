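"""Vertebral level labels (T1..T12, L1..L5, pelvis) and ordering helpers."""
from __future__ import annotations

THORACIC = [f"T{i}" for i in range(1, 13)]
LUMBAR = [f"L{i}" for i in range(1, 6)]
VERTEBRAE = THORACIC + LUMBAR          # cephalad -> caudal
PELVIS = "PELVIS"
ALL_BODIES = VERTEBRAE + [PELVIS]

_INDEX = {lab: i for i, lab in enumerate(ALL_BODIES)}


def index_of(level: str) -> int:
    """0-based cephalad-to-caudal index of a level label."""
    try:
        return _INDEX[level.upper()]
    except KeyError:
        raise ValueError(f"unknown vertebral level label: {level!r}") from None


def is_valid(level: str) -> bool:
    return str(level).upper() in _INDEX


def is_thoracic(level: str) -> bool:
    return level.upper() in THORACIC


def is_lumbar(level: str) -> bool:
    return level.upper() in LUMBAR


def cephalad_of(a: str, b: str) -> bool:
    """True if level ``a`` is strictly cephalad (above) level ``b``."""
    return index_of(a) < index_of(b)


def span(upper: str, lower: str) -> list[str]:
    """Inclusive list of levels from ``upper`` down to ``lower``."""
    iu, il = index_of(upper), index_of(lower)
    if iu > il:
        raise ValueError(f"invalid level pair: {upper} is not cephalad of {lower}")
    return ALL_BODIES[iu:il + 1]


def midpoint(upper: str, lower: str) -> str:
    """Level nearest the midpoint of a span (cephalad-biased for even spans)."""
    iu, il = index_of(upper), index_of(lower)
    return ALL_BODIES[(iu + il) // 2]
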