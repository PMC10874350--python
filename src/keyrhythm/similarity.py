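"""Cosine similarity between weekday and weekend typing-ratio profiles.

A participant whose weekday and weekend five-bin ratio profiles are close to
proportional scores near 1; diverging weekday/weekend habits pull the score
down. For nonnegative ratio vectors the cosine lies in [0, 1].
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .features import ParticipantProfile

__all__ = ["SimilarityScore", "UndefinedSimilarityError", "cosine_similarity", "weekday_weekend_similarity"]


class UndefinedSimilarityError(ValueError):
    """Cosine similarity is undefined for a zero vector or missing profile."""


@dataclasses.dataclass(frozen=True)
class SimilarityScore:
    participant_id: str
    cosine: float


def cosine_similarity(u: Sequence[float], v: Sequence[float]) -> float:
    """(u·v) / (||u|| ||v||); raises on a zero vector rather than returning 0."""
    ua = np.asarray(u, dtype=float)
    va = np.asarray(v, dtype=float)
    if ua.shape != va.shape:
        raise ValueError(f"shape mismatch {ua.shape} vs {va.shape}")
    if not (np.all(np.isfinite(ua)) and np.all(np.isfinite(va))):
        raise ValueError("vectors must be finite")
    # sqrt of the product (not product of sqrts) keeps e.g. cos((1,2),(2,1)) exact
    denom = math.sqrt(float(ua @ ua) * float(va @ va))
    if float(ua @ ua) == 0.0 or float(va @ va) == 0.0:
        raise UndefinedSimilarityError("cosine similarity undefined for a zero vector")
    return float(ua @ va) / denom


def weekday_weekend_similarity(profile: ParticipantProfile) -> SimilarityScore:
    """Cosine similarity of a participant's weekday vs weekend mean ratio profiles."""
    if profile.weekday_mean_ratios is None or profile.weekend_mean_ratios is None:
        missing = "weekday" if profile.weekday_mean_ratios is None else "weekend"
        raise UndefinedSimilarityError(
            f"participant {profile.participant_id}: no active {missing} day; similarity undefined"
        )
    return SimilarityScore(
        profile.participant_id,
        cosine_similarity(profile.weekday_mean_ratios, profile.weekend_mean_ratios),
    )
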