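"""Group-level inference: one-way ANOVA, Tukey-Kramer post-hoc, Welch's t.

The statistics are computed from the standard formulas (scipy supplies only
the reference distributions for tail areas).  Tukey's multiple comparison
uses the Kramer harmonic adjustment so unbalanced groups — the study design
here has sizes like 18/26/10/5 — are handled exactly.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "AnovaResult",
    "TukeyPair",
    "TukeyResult",
    "WelchResult",
    "DegenerateDataError",
    "one_way_anova",
    "tukey_hsd",
    "welch_t",
]


class DegenerateDataError(ValueError):
    """The requested test is undefined for the given data (e.g. zero variance)."""


@dataclasses.dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    degenerate: bool = False


@dataclasses.dataclass(frozen=True)
class TukeyPair:
    i: int
    j: int
    mean_diff: float  # mean_i - mean_j
    q: float
    p_adjusted: float


@dataclasses.dataclass(frozen=True)
class TukeyResult:
    pairs: tuple[TukeyPair, ...]
    df_within: int
    n_groups: int


@dataclasses.dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def _validate_groups(groups: Sequence[Sequence[float]], min_groups: int = 2) -> list[np.ndarray]:
    if len(groups) < min_groups:
        raise ValueError(f"need at least {min_groups} groups, got {len(groups)}")
    arrays = []
    for g, sample in enumerate(groups):
        a = np.asarray(sample, dtype=float)
        if a.ndim != 1 or len(a) < 2:
            raise ValueError(f"group {g} needs >= 2 observations")
        if not np.all(np.isfinite(a)):
            raise ValueError(f"group {g} contains non-finite values")
        arrays.append(a)
    return arrays


def _anova_decomposition(arrays: list[np.ndarray]) -> tuple[float, float, int, int]:
    """(MS_between, MS_within, df_between, df_within)."""
    k = len(arrays)
    ns = np.array([len(a) for a in arrays])
    n_total = int(ns.sum())
    grand = float(np.concatenate(arrays).mean())
    means = np.array([a.mean() for a in arrays])
    ss_between = float(ns @ (means - grand) ** 2)
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df_between, df_within = k - 1, n_total - k
    return ss_between / df_between, ss_within / df_within, df_between, df_within


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA: F = MS_between / MS_within.

    All within-group variances zero with unequal means is reported as an
    infinite F with p = 0 and ``degenerate=True`` rather than an error.
    """
    arrays = _validate_groups(groups)
    ms_between, ms_within, df_b, df_w = _anova_decomposition(arrays)
    if ms_within == 0.0:
        if ms_between == 0.0:
            # identical constant groups: no evidence either way
            return AnovaResult(0.0, df_b, df_w, 1.0, degenerate=True)
        return AnovaResult(math.inf, df_b, df_w, 0.0, degenerate=True)
    F = ms_between / ms_within
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(F, df_b, df_w, p)


def tukey_hsd(groups: Sequence[Sequence[float]]) -> TukeyResult:
    """Tukey-Kramer all-pairs comparison for (possibly unbalanced) groups.

    For pair (i, j): q = |mean_i - mean_j| / sqrt(MS_within/2 * (1/n_i + 1/n_j)),
    with the adjusted p from the studentized-range distribution at k groups and
    the ANOVA within-group degrees of freedom.
    """
    arrays = _validate_groups(groups)
    k = len(arrays)
    _, ms_within, _, df_w = _anova_decomposition(arrays)
    if ms_within == 0.0:
        raise DegenerateDataError("Tukey-Kramer undefined with zero within-group variance")
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(arrays[i].mean() - arrays[j].mean())
            se = math.sqrt(ms_within / 2.0 * (1.0 / len(arrays[i]) + 1.0 / len(arrays[j])))
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, df_w))
            pairs.append(TukeyPair(i, j, diff, q, min(p, 1.0)))
    return TukeyResult(tuple(pairs), df_w, k)


def welch_t(a: Sequence[float], b: Sequence[float]) -> WelchResult:
    """Welch's two-sample t-test (unequal variances), two-sided.

    t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b) with
    Welch-Satterthwaite degrees of freedom.
    """
    (aa, bb) = _validate_groups([a, b])
    na, nb = len(aa), len(bb)
    va, vb = float(aa.var(ddof=1)), float(bb.var(ddof=1))
    if va == 0.0 and vb == 0.0:
        raise DegenerateDataError("Welch's t undefined: both samples have zero variance")
    sa, sb = va / na, vb / nb
    t = (float(aa.mean()) - float(bb.mean())) / math.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return WelchResult(t, df, min(p, 1.0))
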