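"""Data model and I/O for effect-size distributions (ESDs).

An ESD is a flat table of study-level standardized effect sizes, one row
per effect, as typically extracted from published meta-analyses: an effect
estimate ``yi``, its standard error ``sei``, and optional metadata (study
identifier, grouping label such as a clinical subpopulation, total sample
size, and the meta-analysis the row came from).

This module provides the validated container (:class:`ESDataset`), CSV
ingestion with row-level validation (:func:`read_effect_table`), the
small-sample Hedges' g correction (:func:`d_to_g`), and the
one-effect-per-study filtering rule (:func:`dedupe_by_study`) that turns a
raw multi-effect extraction into an ESD suitable for benchmarking.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Metric",
    "EffectRecord",
    "ESDataset",
    "ConversionReport",
    "ValidationError",
    "read_effect_table",
    "d_to_g",
    "r_to_d",
    "dedupe_by_study",
    "to_absolute",
    "DEFAULT_COLUMN_MAP",
]


class ValidationError(ValueError):
    """Raised when input data violate the ESD schema."""


class Metric(str, enum.Enum):
    """Effect-size metric of a record."""

    HEDGES_G = "hedges_g"
    COHENS_D = "cohens_d"
    PEARSON_R = "pearson_r"
    OTHER = "other"


#: Default mapping from semantic roles to CSV column names (the layout of
#: typical meta-analytic extraction tables: ``yi``/``sei``/``group``/...).
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "yi": "yi",
    "sei": "sei",
    "group": "group",
    "study_id": "study_id",
    "n_total": "n_total",
    "meta_source": "meta_analysis",
}


@dataclass(frozen=True)
class EffectRecord:
    """One study-level effect: estimate, standard error, and metadata.

    Parameters
    ----------
    yi : float
        Signed effect size, in the units of ``metric``.
    sei : float
        Standard error of ``yi`` (> 0, finite).
    study_id : str, optional
        Identifier of the originating study.
    metric : Metric
        Effect-size metric; ESDs are benchmarked after conversion to a
        common metric (Hedges' g by convention).
    group : str, optional
        Grouping label (e.g. clinical subpopulation).
    n_total : int, optional
        Total sample size of the study (>= 2 when present).
    meta_source : str, optional
        Identifier of the meta-analysis the record was extracted from.
    """

    yi: float
    sei: float
    study_id: str | None = None
    metric: Metric = Metric.HEDGES_G
    group: str | None = None
    n_total: int | None = None
    meta_source: str | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.yi):
            raise ValidationError(f"effect size must be finite, got {self.yi!r}")
        if not math.isfinite(self.sei) or self.sei <= 0:
            raise ValidationError(
                f"standard error must be finite and > 0, got {self.sei!r}"
            )
        if self.n_total is not None and self.n_total < 2:
            raise ValidationError(f"n_total must be >= 2, got {self.n_total!r}")


class ESDataset:
    """An ordered, validated collection of :class:`EffectRecord`.

    The substrate for all benchmark, adjustment, power and plotting
    computations. Iteration order is the input order and is preserved by
    every transformation in the package.
    """

    def __init__(
        self, records: Iterable[EffectRecord], metric: Metric = Metric.HEDGES_G
    ) -> None:
        self._records: tuple[EffectRecord, ...] = tuple(records)
        if not self._records:
            raise ValidationError("ESDataset must contain at least one record")
        self.metric = Metric(metric)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[EffectRecord]:
        return iter(self._records)

    def __getitem__(self, i: int) -> EffectRecord:
        return self._records[i]

    def __repr__(self) -> str:
        return f"ESDataset(n={len(self)}, metric={self.metric.value!r})"

    # -- accessors ----------------------------------------------------------
    @property
    def records(self) -> tuple[EffectRecord, ...]:
        return self._records

    @property
    def yi(self) -> np.ndarray:
        """Effect sizes, in input order."""
        return np.array([r.yi for r in self._records], dtype=float)

    @property
    def sei(self) -> np.ndarray:
        """Standard errors, in input order."""
        return np.array([r.sei for r in self._records], dtype=float)

    @property
    def groups(self) -> list[str | None]:
        return [r.group for r in self._records]

    def group_labels(self) -> list[str]:
        """Distinct non-null group labels, in order of first appearance."""
        seen: dict[str, None] = {}
        for r in self._records:
            if r.group is not None:
                seen.setdefault(r.group, None)
        return list(seen)

    def subset(self, indices: Sequence[int]) -> "ESDataset":
        return ESDataset((self._records[i] for i in indices), metric=self.metric)

    def replace_effects(self, yi: Sequence[float]) -> "ESDataset":
        """Return a copy with effect sizes replaced elementwise."""
        if len(yi) != len(self._records):
            raise ValidationError("replacement length mismatch")
        return ESDataset(
            (dataclasses.replace(r, yi=float(v)) for r, v in zip(self._records, yi)),
            metric=self.metric,
        )

    # -- frame / file round-trips -------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "study_id": [r.study_id for r in self._records],
                "yi": self.yi,
                "sei": self.sei,
                "group": self.groups,
                "n_total": [r.n_total for r in self._records],
                "meta_analysis": [r.meta_source for r in self._records],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        column_map: Mapping[str, str] | None = None,
        metric: Metric = Metric.HEDGES_G,
        skip_invalid: bool = False,
    ) -> tuple["ESDataset", list[str]]:
        """Build a dataset from a data frame; returns (dataset, warnings)."""
        cmap = dict(DEFAULT_COLUMN_MAP)
        if column_map:
            cmap.update(column_map)
        for role in ("yi", "sei"):
            if cmap[role] not in df.columns:
                raise ValidationError(
                    f"required column {cmap[role]!r} (role {role!r}) not found; "
                    f"available: {list(df.columns)}"
                )

        def _opt(row: pd.Series, role: str):
            col = cmap.get(role)
            if col is None or col not in df.columns:
                return None
            v = row[col]
            return None if pd.isna(v) else v

        records: list[EffectRecord] = []
        warnings: list[str] = []
        for pos, (_, row) in enumerate(df.iterrows(), start=1):
            yi, sei = row[cmap["yi"]], row[cmap["sei"]]
            try:
                if pd.isna(yi) or pd.isna(sei):
                    raise ValidationError("missing effect size or standard error")
                yi_f, sei_f = float(yi), float(sei)
                n_total = _opt(row, "n_total")
                records.append(
                    EffectRecord(
                        yi=yi_f,
                        sei=sei_f,
                        study_id=_fmt(_opt(row, "study_id")),
                        metric=metric,
                        group=_fmt(_opt(row, "group")),
                        n_total=int(n_total) if n_total is not None else None,
                        meta_source=_fmt(_opt(row, "meta_source")),
                    )
                )
            except (TypeError, ValueError) as exc:
                msg = f"row {pos}: {exc}"
                if skip_invalid:
                    warnings.append(msg)
                else:
                    raise ValidationError(msg) from exc
        if not records:
            raise ValidationError("no valid rows in input")
        return cls(records, metric=metric), warnings


def _fmt(v) -> str | None:
    if v is None:
        return None
    s = str(v)
    return s if s else None


@dataclass
class ConversionReport:
    """Accounting of a filtering/conversion pass over a raw extraction."""

    n_in: int
    n_out: int
    n_converted: int = 0
    n_deduplicated: int = 0
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_out > self.n_in:
            raise ValidationError("n_out cannot exceed n_in")
        if self.n_out != self.n_in - self.n_deduplicated:
            raise ValidationError("n_out must equal n_in - n_deduplicated")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def read_effect_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    metric: Metric = Metric.HEDGES_G,
    skip_invalid: bool = False,
) -> ESDataset:
    """Read a CSV of study-level effects into an :class:`ESDataset`.

    The CSV must be comma-separated with a header row; default column
    names are ``yi``, ``sei``, ``group``, ``study_id``, ``n_total``.
    Rows with a missing or invalid effect/SE raise a
    :class:`ValidationError` naming the row, unless ``skip_invalid`` is
    set (then they are dropped and counted in the dataset's warnings).
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    df = pd.read_csv(p)
    ds, warnings = ESDataset.from_frame(
        df, column_map=column_map, metric=metric, skip_invalid=skip_invalid
    )
    ds.warnings = warnings  # type: ignore[attr-defined]
    return ds


def d_to_g(
    d: float, df: float, se_d: float | None = None
) -> float | tuple[float, float]:
    """Apply the Hedges small-sample correction to Cohen's d.

    g = d * J with J = 1 - 3/(4*df - 1), the standard approximation to the
    exact gamma-function correction factor; the SE scales by the same J.
    ``df`` is n1+n2-2 for two-sample designs, n-1 for paired/one-sample.

    Returns ``g`` alone, or ``(g, se_g)`` when ``se_d`` is given.
    """
    if df < 2:
        raise ValidationError(f"degrees of freedom must be >= 2, got {df}")
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = d * j
    if se_d is None:
        return g
    return g, se_d * j


def r_to_d(r: float) -> float:
    """Convert a Pearson correlation to Cohen's d: d = 2r/sqrt(1-r^2).

    Explicit opt-in utility; conversions performed on a dataset should be
    recorded in a :class:`ConversionReport`.
    """
    if not -1.0 < r < 1.0:
        raise ValidationError(f"correlation must lie strictly in (-1, 1), got {r}")
    return 2.0 * r / math.sqrt(1.0 - r * r)


def dedupe_by_study(ds: ESDataset) -> tuple[ESDataset, ConversionReport]:
    """Keep one effect per study: the most precise one.

    Within each ``study_id`` the record with the smallest standard error
    is kept; ties on the SE are broken by the effect closest to zero
    regardless of sign; an exact remaining tie keeps the earliest record.
    Records without a ``study_id`` are treated as singleton studies (with
    a warning), so unrelated rows are never merged.
    """
    warnings: list[str] = []
    best: dict[object, int] = {}
    n_anon = 0
    for i, r in enumerate(ds.records):
        if r.study_id is None:
            n_anon += 1
            best[("__anon__", i)] = i
            continue
        j = best.get(r.study_id)
        if j is None:
            best[r.study_id] = i
            continue
        prev = ds.records[j]
        if (r.sei, abs(r.yi), i) < (prev.sei, abs(prev.yi), j):
            best[r.study_id] = i
    if n_anon:
        warnings.append(
            f"{n_anon} record(s) lack a study_id and were kept as singleton studies"
        )
    keep = sorted(best.values())
    out = ds.subset(keep)
    report = ConversionReport(
        n_in=len(ds),
        n_out=len(out),
        n_deduplicated=len(ds) - len(out),
        warnings=warnings,
    )
    return out, report


def to_absolute(ds: ESDataset) -> ESDataset:
    """Replace every effect by its absolute value (order and SEs kept)."""
    return ds.replace_effects(np.abs(ds.yi))
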