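"""Quantile-based effect-size benchmarks with bootstrap CIs and skewness.

Field-specific benchmarks label effects "small", "medium" and "large" by
fixed percentiles of the empirical effect-size distribution — the 25th,
50th and 75th ("quads"), or the 16.65th, 50th and 83.35th ("thirds").
Benchmarks can be computed per group, on absolute values, and weighted by
the inverse variance (1/SE^2) so precise studies count more. Precision of
each benchmark is assessed with a percentile bootstrap, and distributional
asymmetry with Bowley's quartile skewness coefficient.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ESDataset, ValidationError, to_absolute

__all__ = [
    "BenchmarkMethod",
    "BenchmarkEstimate",
    "BenchmarkRow",
    "BenchmarkTable",
    "quantile",
    "bootstrap_quantile_ci",
    "bowley_skewness",
    "sesoi_split",
    "percentile_rank",
    "benchmark_table",
]

OVERALL_LABEL = "All"


class BenchmarkMethod(str, enum.Enum):
    """Percentile triple defining the small/medium/large benchmarks."""

    QUADS = "quads"
    THIRDS = "thirds"

    @property
    def probabilities(self) -> tuple[float, float, float]:
        if self is BenchmarkMethod.QUADS:
            return (0.25, 0.50, 0.75)
        # "thirds" uses the printed 16.65/83.35 percentiles, not 1/6 and 5/6
        return (0.1665, 0.50, 0.8335)


def _as_array(values: Sequence[float], name: str = "values") -> np.ndarray:
    a = np.asarray(values, dtype=float)
    if a.ndim != 1 or a.size == 0:
        raise ValidationError(f"{name} must be a non-empty 1-d sequence")
    if not np.all(np.isfinite(a)):
        raise ValidationError(f"{name} must be finite")
    return a


def _check_weights(weights: Sequence[float], n: int) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValidationError("weights must match values in length")
    if not np.all(np.isfinite(w)) or np.any(w <= 0):
        raise ValidationError("weights must be finite and > 0")
    return w


def quantile(
    values: Sequence[float],
    p: float,
    weights: Sequence[float] | None = None,
) -> float:
    """Quantile of ``values`` at probability ``p``, optionally weighted.

    Unweighted, this is linear interpolation between order statistics at
    position h = p*(n-1) (the common statistical-software default).

    Weighted, values are sorted and assigned interpolation positions

        c_k = S_{k-1} / (S_n - w_k),   S_k = sum of the first k sorted weights,

    and the quantile is the linear interpolation of the sorted values at
    the point where the positions cross ``p`` (clamped to the extremes).
    The grid reduces exactly to (k-1)/(n-1) when all weights are equal, so
    equally weighted data reproduce the unweighted estimator; it is also
    symmetric under negation: Q_p(-x, w) = -Q_{1-p}(x, w).
    """
    a = _as_array(values)
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"p must lie in [0, 1], got {p}")
    if weights is None:
        return float(np.quantile(a, p))
    w = _check_weights(weights, a.size)
    if a.size == 1:
        return float(a[0])
    if np.ptp(w) == 0.0:
        # identical weights: fall through to the unweighted estimator so the
        # equivalence is exact, not merely up to cumsum rounding
        return float(np.quantile(a, p))
    order = np.argsort(a, kind="stable")
    v, w = a[order], w[order]
    s = np.cumsum(w)
    c = np.concatenate(([0.0], s[:-1])) / (s[-1] - w)
    if p <= c[0]:
        return float(v[0])
    if p >= c[-1]:
        return float(v[-1])
    return float(np.interp(p, c, v))


def bootstrap_quantile_ci(
    values: Sequence[float],
    p: float,
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
    level: float = 0.95,
    weights: Sequence[float] | None = None,
) -> tuple[float, float]:
    """Percentile-bootstrap confidence interval for a quantile.

    Resamples n values with replacement ``n_boot`` times (with probability
    proportional to ``weights`` when given), computes the ``p`` quantile of
    each replicate, and returns the (1-level)/2 and 1-(1-level)/2
    percentiles of the replicate distribution. Deterministic given a seed.
    """
    a = _as_array(values)
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    if not 0.0 < level < 1.0:
        raise ValidationError("level must lie in (0, 1)")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = a.size
    if weights is None:
        idx = rng.integers(0, n, size=(n_boot, n))
    else:
        w = _check_weights(weights, n)
        idx = rng.choice(n, size=(n_boot, n), replace=True, p=w / w.sum())
    reps = np.quantile(a[idx], p, axis=1)
    lo, hi = np.quantile(reps, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def bowley_skewness(
    values: Sequence[float], weights: Sequence[float] | None = None
) -> float:
    """Bowley's quartile skewness: (Q1 + Q3 - 2*Q2) / (Q3 - Q1).

    Based on the middle 50% of the distribution; lies in [-1, 1], with 0
    for symmetric samples, negative for left skew, positive for right
    skew. Undefined (raises) when Q1 = Q3.
    """
    q1 = quantile(values, 0.25, weights)
    q2 = quantile(values, 0.50, weights)
    q3 = quantile(values, 0.75, weights)
    if q3 <= q1:
        raise ValidationError(
            "Bowley skewness undefined: the interquartile range is zero"
        )
    return (q1 + q3 - 2.0 * q2) / (q3 - q1)


def sesoi_split(
    values: Sequence[float], sesoi: float, absolute: bool = True
) -> tuple[float, float]:
    """Proportions of the ESD below vs at-or-above a smallest effect of interest.

    Returns ``(prop_below, prop_at_or_above)`` where the second element is
    #{v >= sesoi}/n; with ``absolute`` (default), |v| is compared. The two
    proportions sum to 1.
    """
    a = _as_array(values)
    if absolute:
        a = np.abs(a)
    at_or_above = float(np.count_nonzero(a >= sesoi)) / a.size
    return 1.0 - at_or_above, at_or_above


def percentile_rank(values: Sequence[float], x: float, absolute: bool = True) -> float:
    """Percentage of the ESD strictly smaller than an observed effect ``x``.

    With ``absolute`` (default) the comparison is between |values| and |x|,
    matching the magnitude-only reading of an ESD.
    """
    a = _as_array(values)
    if absolute:
        a, x = np.abs(a), abs(x)
    return 100.0 * float(np.count_nonzero(a < x)) / a.size


@dataclass(frozen=True)
class BenchmarkEstimate:
    """One benchmark: quantile level, value, optional bootstrap CI."""

    level: float
    value: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int | None = None

    def __post_init__(self) -> None:
        if (self.ci_low is None) != (self.ci_high is None):
            raise ValidationError("ci_low and ci_high must be given together")
        if self.ci_low is not None and self.ci_low > self.ci_high:
            raise ValidationError("ci_low must be <= ci_high")


@dataclass(frozen=True)
class BenchmarkRow:
    group: str
    estimates: tuple[BenchmarkEstimate, BenchmarkEstimate, BenchmarkEstimate]
    n_effects: int
    bowley: float | None = None


class BenchmarkTable:
    """Per-group small/medium/large benchmarks plus a pooled overall row."""

    def __init__(
        self,
        rows: Sequence[BenchmarkRow],
        overall_row: BenchmarkRow,
        method: BenchmarkMethod,
    ) -> None:
        self.rows = list(rows)
        self.overall_row = overall_row
        self.method = method

    def __iter__(self):
        return iter([*self.rows, self.overall_row])

    @property
    def levels(self) -> tuple[float, float, float]:
        return self.method.probabilities

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{100 * p:g}%" for p in self.levels]
        data = []
        for row in self:
            rec: dict[str, object] = {"Group": row.group}
            for col, est in zip(cols, row.estimates):
                rec[col] = est.value
                if est.ci_low is not None:
                    rec[f"{col} CI low"] = est.ci_low
                    rec[f"{col} CI high"] = est.ci_high
            rec["Number of effects"] = row.n_effects
            if row.bowley is not None:
                rec["Bowley"] = row.bowley
            data.append(rec)
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = self.to_frame().to_json(orient="records", indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def to_markdown(self, decimals: int = 2) -> str:
        """Fixed-width markdown rendering, values rounded to ``decimals``."""
        df = self.to_frame().copy()
        for c in df.columns:
            if df[c].dtype.kind == "f":
                df[c] = df[c].map(lambda v: f"{v:.{decimals}f}")
        return df.to_markdown(index=False, disable_numparse=True)

    def summary(self) -> str:
        name = self.method.value
        pct = "/".join(f"{100 * p:g}" for p in self.levels)
        header = (
            f"Effect size benchmarks ({name}: {pct} percentiles)\n"
        )
        return header + self.to_markdown()


def _row_for(
    label: str,
    values: np.ndarray,
    weights: np.ndarray | None,
    method: BenchmarkMethod,
    ci: bool,
    n_boot: int,
    rng: np.random.Generator | None,
    bowley: bool,
) -> BenchmarkRow:
    ests = []
    for p in method.probabilities:
        val = quantile(values, p, weights)
        if ci:
            lo, hi = bootstrap_quantile_ci(
                values, p, n_boot=n_boot, seed=rng, weights=weights
            )
            ests.append(BenchmarkEstimate(p, val, lo, hi, n_boot))
        else:
            ests.append(BenchmarkEstimate(p, val))
    bow = None
    if bowley:
        try:
            bow = bowley_skewness(values, weights)
        except ValidationError:
            bow = float("nan")
    return BenchmarkRow(label, tuple(ests), int(values.size), bow)


def benchmark_table(
    ds: ESDataset,
    method: BenchmarkMethod | str = BenchmarkMethod.QUADS,
    grouping: bool = False,
    min_group_n: int = 3,
    absolute: bool = False,
    weighted: bool = False,
    ci: bool = False,
    n_boot: int = 2000,
    seed: int = 0,
    bowley: bool = False,
) -> BenchmarkTable:
    """Compute the benchmark table for a dataset.

    Groups with fewer than ``min_group_n`` effects are omitted (3 is the
    minimum needed to estimate three benchmarks; some published tables use
    4). Inverse-variance weights 1/sei^2 are applied when ``weighted``;
    absolute conversion happens before the quantiles when ``absolute``.
    A pooled "All" row is always appended. Bootstrap resampling is
    per-group and deterministic given ``seed``.
    """
    method = BenchmarkMethod(method)
    work = to_absolute(ds) if absolute else ds
    values = work.yi
    weights = 1.0 / work.sei**2 if weighted else None
    rng = np.random.default_rng(seed) if ci else None

    rows: list[BenchmarkRow] = []
    if grouping:
        glabels = work.group_labels()
        kept = []
        for label in glabels:
            idx = [i for i, g in enumerate(work.groups) if g == label]
            if len(idx) >= min_group_n:
                kept.append((label, np.array(idx)))
        if not kept:
            raise ValidationError(
                f"no group reaches the minimum of {min_group_n} effects"
            )
        for label, idx in kept:
            rows.append(
                _row_for(
                    label,
                    values[idx],
                    None if weights is None else weights[idx],
                    method,
                    ci,
                    n_boot,
                    rng,
                    bowley,
                )
            )
    overall = _row_for(
        OVERALL_LABEL, values, weights, method, ci, n_boot, rng, bowley
    )
    return BenchmarkTable(rows, overall, method)
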