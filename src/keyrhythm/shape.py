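"""Quadratic shape statistics for five-bin typing-count profiles.

An ordinary least-squares degree-2 polynomial is fitted to each participant's
five mean typing counts. The quadratic coefficient a2 encodes the diurnal
shape: an evening peak gives a concave profile (a2 < 0), a late-night/U
pattern with high sleep and night activity gives a convex one (a2 > 0).

The default abscissa is the bin index x = 1..5 (the fit-a-vector idiom);
bin-midpoint clock hours (3, 9, 14.5, 19, 22.5) are available via ``x=``.
For the default equally spaced design the solve goes through the discrete
orthogonal (Gram) polynomial basis, which is algebraically the same OLS
solution but exact for polynomial inputs.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "QuadraticFit",
    "DEFAULT_X",
    "BIN_MIDPOINT_HOURS",
    "fit_quadratic",
    "quadratic_coefficients",
    "group_curve",
]

DEFAULT_X = np.arange(1.0, 6.0)
#: clock-hour midpoints of the five bins (alternative abscissa)
BIN_MIDPOINT_HOURS = np.array([3.0, 9.0, 14.5, 19.0, 22.5])

# orthogonal contrasts for 5 equally spaced points centred at x=3
_Z = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])  # linear,   sum z^2  = 10
_Q = np.array([2.0, -1.0, -2.0, -1.0, 2.0])  # quadratic, sum q^2 = 14


@dataclasses.dataclass(frozen=True)
class QuadraticFit:
    """OLS degree-2 fit y ≈ a2·x² + a1·x + a0 at five design points.

    ``r`` is the Pearson correlation between observed and fitted values;
    it is None (undefined, deliberately not 0) when either side has zero
    variance, e.g. for a constant profile.
    """

    a2: float
    a1: float
    a0: float
    x: tuple[float, ...]
    observed: tuple[float, ...]
    fitted: tuple[float, ...]
    r: float | None


def _pearson(a: np.ndarray, b: np.ndarray) -> float | None:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = math.sqrt(float(a @ a)), math.sqrt(float(b @ b))
    if na == 0.0 or nb == 0.0:
        return None
    return float(a @ b) / (na * nb)


def fit_quadratic(profile: Sequence[float], x: Sequence[float] | None = None) -> QuadraticFit:
    """Least-squares quadratic fit to a five-value profile.

    ``x`` defaults to the bin indices 1..5; pass ``BIN_MIDPOINT_HOURS`` to fit
    against clock time instead.
    """
    y = np.asarray(profile, dtype=float)
    if y.shape != (5,) or not np.all(np.isfinite(y)):
        raise ValueError("profile must be 5 finite values")
    if x is None:
        # exact Gram-basis OLS on the equally spaced design
        b0 = float(y.mean())
        b1 = float(_Z @ y) / 10.0
        b2 = float(_Q @ y) / 14.0
        # y = b0 + b1 (x-3) + b2 ((x-3)^2 - 2)
        a2, a1, a0 = b2, b1 - 6.0 * b2, b0 - 3.0 * b1 + 7.0 * b2
        xv = DEFAULT_X
    else:
        xv = np.asarray(x, dtype=float)
        if xv.shape != (5,):
            raise ValueError("x must have 5 design points")
        a2, a1, a0 = np.polyfit(xv, y, 2)
    fitted = a2 * xv**2 + a1 * xv + a0
    return QuadraticFit(
        float(a2),
        float(a1),
        float(a0),
        tuple(xv),
        tuple(y),
        tuple(fitted),
        _pearson(y, fitted),
    )


def quadratic_coefficients(
    profiles: Mapping[str, Sequence[float]], x: Sequence[float] | None = None
) -> dict[str, float]:
    """Per-participant quadratic coefficients a2, keyed by participant id."""
    out: dict[str, float] = {}
    for pid, profile in profiles.items():
        try:
            out[pid] = fit_quadratic(profile, x=x).a2
        except ValueError as exc:
            raise ValueError(f"participant {pid}: {exc}") from exc
    return out


def group_curve(
    profiles: Iterable[Sequence[float]], x: Sequence[float] | None = None
) -> tuple[np.ndarray, np.ndarray, float | None]:
    """Group-level observed and fitted mean curves and their correlation.

    The group fitted curve is the average over participants of per-participant
    fitted curves; r compares the group-mean observed profile with it.
    """
    fits = [fit_quadratic(p, x=x) for p in profiles]
    if not fits:
        raise ValueError("no profiles")
    observed = np.mean([f.observed for f in fits], axis=0)
    fitted = np.mean([f.fitted for f in fits], axis=0)
    return observed, fitted, _pearson(observed, fitted)
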