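"""Starting values for new-item calibration.

Two schemes, both driven only by quantities observable at calibration
time (the examinees' provisional ability estimates and their scores on
the new item):

* **Squeezing average** (``squeeze_initial_b``): boundary t is the
  midpoint of the trimmed mean abilities of the two score groups that
  straddle it (scores t-1 and t), after deleting the top and bottom 5%
  of each group — the "deleting extremum and squeezing average" rule.
* **Polyserial** (``polyserial_initial``): converts the point-polyserial
  correlation between item score and ability into a polyserial
  correlation r_p via the category pass rates, then maps
  a0 = r_p / sqrt(1 - r_p^2) and b0_t = -Z_t / r_p, where Z_t is the
  (approximate) normal deviate of the pass rate P*_t.

``initial_params`` combines them into the two published schemes:
``poly-ini`` (both parameters polyserial) and ``poly-sq-ini``
(polyserial slope, squeezed boundaries).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScoreGroupedAbilities",
    "CategoryPassRates",
    "trimmed_mean",
    "squeeze_initial_b",
    "inverse_normal_approx",
    "polyserial_initial",
    "initial_params",
    "monotonize",
]

logger = logging.getLogger(__name__)

INITIALIZERS = ("poly-ini", "poly-sq-ini")


@dataclass
class ScoreGroupedAbilities:
    """Ability estimates of one item's examinees, grouped by score 0..f."""

    groups: list[np.ndarray]

    @classmethod
    def from_responses(cls, thetas, scores, f: int) -> "ScoreGroupedAbilities":
        thetas = np.asarray(thetas, float)
        scores = np.asarray(scores, int)
        return cls([thetas[scores == s] for s in range(f + 1)])

    @property
    def f(self) -> int:
        return len(self.groups) - 1

    @property
    def n(self) -> int:
        return sum(len(g) for g in self.groups)


@dataclass
class CategoryPassRates:
    """Pass rates P*_t = P(score >= t), score SD and score-ability
    correlation for one new item."""

    pass_rates: np.ndarray      # (f,) for t = 1..f
    sigma: float
    r: float
    n: int

    @classmethod
    def from_responses(cls, thetas, scores, f: int) -> "CategoryPassRates":
        thetas = np.asarray(thetas, float)
        scores = np.asarray(scores, int)
        n = len(scores)
        rates = np.array([(scores >= t).mean() for t in range(1, f + 1)])
        sigma = float(scores.std())
        if sigma > 0 and thetas.std() > 0:
            r = float(np.corrcoef(scores, thetas)[0, 1])
        else:
            r = np.nan
        return cls(rates, sigma, r, n)


def trimmed_mean(values: np.ndarray, trim: float = 0.05) -> float:
    """Mean after deleting floor(trim*n) values from each end (sorted)."""
    v = np.sort(np.asarray(values, float))
    k = int(math.floor(trim * len(v)))
    v = v[k:len(v) - k] if k else v
    if len(v) == 0:
        return float("nan")
    return float(v.mean())


def monotonize(b: np.ndarray, min_gap: float = 1e-3) -> np.ndarray:
    """Sort ascending; separate exact ties by cumulative ``min_gap``."""
    b = np.sort(np.asarray(b, float))
    for t in range(1, len(b)):
        if b[t] <= b[t - 1]:
            b[t] = b[t - 1] + min_gap
    return b


def squeeze_initial_b(
    groups: ScoreGroupedAbilities, trim: float = 0.05
) -> np.ndarray:
    """Deleting-extremum squeezing-average boundary starts.

    Boundary t (t = 1..f) separates scores t-1 and t; its start is the
    midpoint of the two groups' trimmed means.  A boundary whose
    straddling group is empty comes back NaN for the caller to fill
    (``initial_params`` substitutes the polyserial value).
    """
    if groups.n == 0:
        raise ValueError("all score groups empty; cannot squeeze")
    f = groups.f
    b = np.full(f, np.nan)
    for t in range(1, f + 1):
        lo, hi = groups.groups[t - 1], groups.groups[t]
        if len(lo) == 0 or len(hi) == 0:
            logger.debug("squeeze: empty score group at boundary %d", t)
            continue
        b[t - 1] = 0.5 * (trimmed_mean(lo, trim) + trimmed_mean(hi, trim))
    return b


def inverse_normal_approx(P: float) -> float:
    """Rational approximation of the standard normal quantile.

    Z = sign(P - 1/2) * sqrt(y * (2.0611786 - 5.7262204 / (y + 11.640595)))
    with y = -ln(4 P (1 - P)); accurate to about 1e-3 over (0.005, 0.995).
    """
    P = float(P)
    if not 0.0 < P < 1.0:
        raise ValueError(f"P must lie strictly in (0, 1), got {P}")
    y = -math.log(4.0 * P * (1.0 - P))
    z = math.sqrt(y * (2.0611786 - 5.7262204 / (y + 11.640595)))
    return math.copysign(z, P - 0.5) if P != 0.5 else 0.0


def _neutral_start(rates: CategoryPassRates) -> tuple[float, np.ndarray]:
    """Fallback when the polyserial correlation is unusable: unit slope
    and quantile-based boundaries."""
    z = np.array([inverse_normal_approx(_clamp_rate(p, rates.n))
                  for p in rates.pass_rates])
    return 1.0, monotonize(-z)


def _clamp_rate(p: float, n: int) -> float:
    lo = 1.0 / (2.0 * max(n, 1))
    return min(max(p, lo), 1.0 - lo)


def polyserial_initial(
    rates: CategoryPassRates,
    double_conversion: bool = False,
) -> tuple[float, np.ndarray]:
    """Polyserial starting values (a0, b0) for one new item.

    Degenerate pass rates (0 or 1) are clamped to [1/(2N), 1 - 1/(2N)].
    A non-positive polyserial correlation makes the slope map undefined;
    the neutral start (a0 = 1, quantile boundaries) is returned instead.
    ``double_conversion`` reproduces a variant that applies the
    sigma/sum-density factor a second time.
    """
    n = rates.n
    clamped = [_clamp_rate(p, n) for p in rates.pass_rates]
    if any(p != c for p, c in zip(rates.pass_rates, clamped)):
        logger.debug("polyserial: pass rate clamped away from 0/1")
    z = np.array([inverse_normal_approx(p) for p in clamped])
    dens = np.exp(-0.5 * z**2) / math.sqrt(2.0 * math.pi)
    if not np.isfinite(rates.r) or rates.sigma <= 0:
        logger.debug("polyserial: score variance or correlation unusable")
        return _neutral_start(rates)
    factor = rates.sigma / dens.sum()
    r_p = rates.r * factor
    if double_conversion:
        r_p *= factor
    r_p = float(np.clip(r_p, -0.999, 0.999))
    if r_p <= 0:
        logger.debug("polyserial: non-positive r_p, neutral start used")
        return _neutral_start(rates)
    a0 = r_p / math.sqrt(1.0 - r_p**2)
    a0 = float(np.clip(a0, 0.05, 5.0))
    b0 = monotonize(-z / r_p)
    return a0, b0


def initial_params(
    method: str,
    groups: ScoreGroupedAbilities,
    rates: CategoryPassRates,
    trim: float = 0.05,
    double_conversion: bool = False,
) -> tuple[float, np.ndarray]:
    """Starting values by scheme name: "poly-ini" or "poly-sq-ini"."""
    if method not in INITIALIZERS:
        raise ValueError(f"unknown initializer {method!r}; use {INITIALIZERS}")
    a_poly, b_poly = polyserial_initial(rates, double_conversion)
    if method == "poly-ini":
        return a_poly, b_poly
    b = squeeze_initial_b(groups, trim)
    missing = np.isnan(b)
    if missing.any():
        logger.debug("poly-sq-ini: %d boundaries fell back to polyserial",
                     int(missing.sum()))
        b[missing] = b_poly[missing]
    return a_poly, monotonize(b)
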