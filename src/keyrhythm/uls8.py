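"""Scoring of the 8-item short-form UCLA Loneliness Scale (ULS-8).

Items are answered 1-4. Items 1-6 are scored as answered; items 7 and 8 are
reverse-coded (5 - answer), giving a total in [8, 32]. Four loneliness groups
are defined by inclusive score bands: *no* 8-13, *moderate* 14-20,
*severe* 21-25, *very severe* 26-32; the bands partition 8..32.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import pandas as pd

__all__ = [
    "ULS8Response",
    "LonelinessGroup",
    "GROUP_BANDS",
    "GROUP_LABELS",
    "REVERSED_ITEMS",
    "score_uls8",
    "assign_group",
    "reverse_items",
    "score_table",
]

REVERSED_ITEMS = (7, 8)

#: label -> inclusive (low, high) total-score band
GROUP_BANDS: dict[str, tuple[int, int]] = {
    "no": (8, 13),
    "moderate": (14, 20),
    "severe": (21, 25),
    "very_severe": (26, 32),
}

GROUP_LABELS = tuple(GROUP_BANDS)


@dataclasses.dataclass(frozen=True)
class ULS8Response:
    """Raw questionnaire answers: 8 items, each an integer in 1..4."""

    items: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.items) != 8:
            raise ValueError(f"expected 8 items, got {len(self.items)}")
        for i, v in enumerate(self.items, start=1):
            if not isinstance(v, int) or isinstance(v, bool) or not 1 <= v <= 4:
                raise ValueError(f"item q{i} = {v!r} outside 1..4")


@dataclasses.dataclass(frozen=True)
class LonelinessGroup:
    label: str
    band: tuple[int, int]


def reverse_items(r: ULS8Response) -> ULS8Response:
    """Flip the reverse-coded items (7 and 8) with the 4-point reversal 5 - x.

    Applying it twice returns the original response.
    """
    items = list(r.items)
    for i in REVERSED_ITEMS:
        items[i - 1] = 5 - items[i - 1]
    return ULS8Response(tuple(items))


def score_uls8(r: ULS8Response) -> int:
    """Total ULS-8 score: items 1-6 as answered, items 7-8 reversed."""
    return sum(reverse_items(r).items)


def assign_group(total: int) -> LonelinessGroup:
    """Loneliness group for a total score in [8, 32]."""
    if not 8 <= total <= 32:
        raise ValueError(f"ULS-8 total {total} outside the scale range 8..32")
    for label, (lo, hi) in GROUP_BANDS.items():
        if lo <= total <= hi:
            return LonelinessGroup(label, (lo, hi))
    raise AssertionError("bands partition 8..32")  # pragma: no cover


def score_table(responses: Mapping[str, ULS8Response]) -> pd.DataFrame:
    """Scored table: one row per participant with total score and group label."""
    rows = []
    for pid, r in responses.items():
        total = score_uls8(r)
        rows.append(
            {"participant_id": pid, "uls8_total": total, "group": assign_group(total).label}
        )
    return pd.DataFrame(rows, columns=["participant_id", "uls8_total", "group"])
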