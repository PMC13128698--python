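"""Noncentral-t power, sample-size and sensitivity calculations.

Connects an effect-size distribution to study planning: given a
standardized effect d, a t-test design and an alpha level, compute power;
invert for the smallest sufficient sample size or for the minimal
reliably detectable effect; and report which share of an empirical ESD a
design can detect at each power level.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import ESDataset, ValidationError
from .benchmarks import sesoi_split

__all__ = [
    "Tails",
    "Design",
    "PowerSpec",
    "power_t",
    "required_n",
    "detectable_d",
    "detectable_proportion",
]


class Tails(str, enum.Enum):
    ONE = "one"
    TWO = "two"


class Design(str, enum.Enum):
    PAIRED = "paired_or_one_sample"
    TWO_SAMPLE = "two_sample_equal_n"


@dataclass(frozen=True)
class PowerSpec:
    """A t-test power scenario.

    ``n`` is the number of pairs (paired/one-sample) or the per-group
    sample size (two-sample equal-n).
    """

    d: float
    n: int
    alpha: float = 0.05
    tails: Tails = Tails.TWO
    design: Design = Design.PAIRED

    def __post_init__(self) -> None:
        if not np.isfinite(self.d):
            raise ValidationError("d must be finite")
        if self.n < 2:
            raise ValidationError("n must be >= 2")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")

    @property
    def df(self) -> int:
        return self.n - 1 if self.design is Design.PAIRED else 2 * self.n - 2

    @property
    def ncp(self) -> float:
        scale = np.sqrt(self.n) if self.design is Design.PAIRED else np.sqrt(self.n / 2)
        return self.d * scale


def power_t(spec: PowerSpec) -> float:
    """Power of a t test under the noncentral-t alternative.

    One-tailed: P(T_{df,ncp} > t_{1-alpha,df}). Two-tailed adds the lower
    rejection region at -t_{1-alpha/2,df} (negligible for the usual
    positive-effect scenarios but included for correctness).
    """
    df, ncp = spec.df, spec.ncp
    if spec.tails is Tails.ONE:
        t_crit = stats.t.ppf(1.0 - spec.alpha, df)
        return _nct_sf(t_crit, df, ncp)
    t_crit = stats.t.ppf(1.0 - spec.alpha / 2.0, df)
    return _nct_sf(t_crit, df, ncp) + _nct_cdf(-t_crit, df, ncp)


def _nct_sf(t: float, df: int, ncp: float) -> float:
    val = float(stats.nct.sf(t, df, ncp))
    if math.isnan(val):
        # the noncentral-t tail underflows for extreme noncentrality;
        # the normal limit of T - ncp is accurate there
        val = float(stats.norm.sf(t - ncp))
    return val


def _nct_cdf(t: float, df: int, ncp: float) -> float:
    val = float(stats.nct.cdf(t, df, ncp))
    if math.isnan(val):
        val = float(stats.norm.cdf(t - ncp))
    return val


def required_n(
    d: float,
    target_power: float,
    alpha: float = 0.05,
    tails: Tails | str = Tails.TWO,
    design: Design | str = Design.PAIRED,
) -> int:
    """Smallest integer n achieving at least ``target_power``.

    Monotone search: double an upper bracket, then bisect on integers.
    """
    if d == 0:
        raise ValidationError("power cannot exceed alpha at d = 0")
    if not 0.0 < target_power < 1.0:
        raise ValidationError("target_power must lie in (0, 1)")
    tails, design = Tails(tails), Design(design)

    def power_at(n: int) -> float:
        return power_t(PowerSpec(d=d, n=n, alpha=alpha, tails=tails, design=design))

    lo, hi = 2, 2
    while power_at(hi) < target_power:
        lo, hi = hi, hi * 2
        if hi > 10**7:
            raise ValidationError("required sample size exceeds 10^7")
    while lo < hi:
        mid = (lo + hi) // 2
        if power_at(mid) >= target_power:
            hi = mid
        else:
            lo = mid + 1
    return lo


def detectable_d(
    n: int,
    target_power: float,
    alpha: float = 0.05,
    tails: Tails | str = Tails.TWO,
    design: Design | str = Design.PAIRED,
    d_max: float = 10.0,
    tol: float = 1e-6,
) -> float:
    """Smallest positive effect detectable with ``target_power`` at fixed n.

    Solves power(d) = target_power by bisection on d in (0, d_max];
    power is strictly increasing in d > 0, so the root is unique.
    """
    tails, design = Tails(tails), Design(design)
    if not 0.0 < target_power < 1.0:
        raise ValidationError("target_power must lie in (0, 1)")
    if target_power <= alpha:  # power(d -> 0) = alpha for either tail setting
        raise ValidationError(
            "target power must exceed the type-I rate alpha; "
            "any effect is 'detectable' at that level"
        )

    def f(d: float) -> float:
        return (
            power_t(PowerSpec(d=d, n=n, alpha=alpha, tails=tails, design=design))
            - target_power
        )

    if f(d_max) < 0:
        raise ValidationError(f"no effect below {d_max} reaches the target power")
    return float(optimize.brentq(f, 1e-6, d_max, xtol=tol))


def detectable_proportion(
    ds: ESDataset,
    n: int,
    power_levels: list[float],
    alpha: float = 0.05,
    tails: Tails | str = Tails.ONE,
    design: Design | str = Design.PAIRED,
) -> pd.DataFrame:
    """Share of the absolute ESD a design of size ``n`` can detect.

    For each power level, finds the minimal detectable effect and the
    proportion of |effects| at or above it. Columns: ``power``,
    ``detectable_d``, ``proportion_detectable``.
    """
    rows = []
    for level in power_levels:
        d = detectable_d(n, level, alpha=alpha, tails=tails, design=design)
        _, at_or_above = sesoi_split(ds.yi, d, absolute=True)
        rows.append(
            {"power": level, "detectable_d": d, "proportion_detectable": at_or_above}
        )
    return pd.DataFrame(rows)
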