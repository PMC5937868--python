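"""C_max: maximum colonization depth, the abundance metric.

C_max is measured per transect; the annual lake value is (by default) the
deepest transect value of that lake-year, and the lake metric is the mean of
the annual values over the years surveyed — the multi-year average damps the
strong year-to-year variation the depth limit shows.  Missing years are
simply absent from the mean, never imputed as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import numpy as np

from .core import DomainError, TransectSurvey

AnnualRule = Literal["max", "p95"]


@dataclass(frozen=True)
class LakeCmax:
    lake_id: str
    annual_values: Mapping[int, float]
    mean_cmax_m: float


def annual_lake_cmax(surveys: Iterable[TransectSurvey], rule: AnnualRule = "max") -> float:
    """Annual lake C_max from the transects of one lake-year."""
    values = [s.c_max_m for s in surveys]
    if not values:
        raise DomainError("annual_lake_cmax needs at least one transect")
    if rule == "max":
        return float(max(values))
    if rule == "p95":
        return float(np.quantile(values, 0.95))
    raise DomainError(f"unknown annual C_max rule {rule!r} (expected 'max' or 'p95')")


def lake_cmax(annual: Mapping[int, float], lake_id: str = "") -> LakeCmax:
    """Multi-year lake C_max: arithmetic mean over the years present."""
    if not annual:
        raise DomainError("lake_cmax needs at least one annual value")
    for year, v in annual.items():
        if v < 0 or not np.isfinite(v):
            raise DomainError(f"annual C_max for year {year} must be finite and >= 0, got {v}")
    mean = float(np.mean(list(annual.values())))
    return LakeCmax(lake_id=lake_id, annual_values=dict(annual), mean_cmax_m=mean)


def lake_cmax_from_surveys(surveys: list[TransectSurvey], rule: AnnualRule = "max") -> LakeCmax:
    """Group one lake's transects by year and aggregate to the lake value."""
    if not surveys:
        raise DomainError("lake_cmax_from_surveys needs at least one transect survey")
    lakes = {s.lake_id for s in surveys}
    if len(lakes) > 1:
        raise DomainError(f"expected transects of a single lake, got {sorted(lakes)}")
    by_year: dict[int, list[TransectSurvey]] = {}
    for s in surveys:
        by_year.setdefault(s.year, []).append(s)
    annual = {year: annual_lake_cmax(group, rule) for year, group in sorted(by_year.items())}
    return lake_cmax(annual, lake_id=surveys[0].lake_id)
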