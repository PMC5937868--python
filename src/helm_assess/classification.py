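"""EQR computation, piecewise-linear normalization, and status assignment.

Raw metric values become ecological quality ratios (EQR) relative to the
type-specific reference value: reference/observed for the trophic index
(lower raw = better) and observed/reference for C_max (higher raw = better),
capped into [0, 1].  Each EQR is then mapped through a piecewise-linear
interpolation whose knots are the metric's class boundaries, so that on the
normalized scale the High/Good, Good/Moderate, Moderate/Poor and Poor/Bad
boundaries sit at 0.8, 0.6, 0.4 and 0.2 for every metric.  The final score is
the equal-weight mean of the two normalized EQRs and sets the status class.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional

import numpy as np

from .abundance import AnnualRule, lake_cmax_from_surveys
from .core import (
    DomainError,
    LakeAssessment,
    LakeMeta,
    Metric,
    MetricBoundaries,
    Orientation,
    StatusClass,
    TaxonRecord,
    TransectSurvey,
)
from .io import select_boundaries
from .trophic_index import (
    DEFAULT_COVER_SPEC,
    DEFAULT_IMPUTATION,
    AggregationRule,
    CoverWeightSpec,
    LtrImputationModel,
    lake_tihelm,
)

logger = logging.getLogger(__name__)

#: Normalized-scale anchors of the class boundaries (H/G, G/M, M/P, P/B).
NORMALIZED_ANCHORS = {"hg": 0.8, "gm": 0.6, "mp": 0.4, "pb": 0.2}


def eqr(raw: float, boundaries: MetricBoundaries) -> float:
    """Ecological quality ratio of a raw metric value, clamped to [0, 1]."""
    if raw < 0:
        raise DomainError(f"raw metric value must be >= 0, got {raw}")
    ref = boundaries.reference_value
    if boundaries.orientation is Orientation.LOWER_IS_BETTER:
        if raw == 0:
            logger.warning("%s raw value 0 with lower-is-better orientation; EQR clamped to 1",
                           boundaries.metric.value)
            return 1.0
        value = ref / raw
    else:
        value = raw / ref
    return float(min(1.0, max(0.0, value)))


def normalize_eqr(e: float, boundaries: MetricBoundaries) -> float:
    """Piecewise-linear normalization of an EQR onto the common class scale.

    Knots: (lower anchor -> 0), (P/B -> 0.2), (M/P -> 0.4), (G/M -> 0.6),
    (H/G -> 0.8), (1 -> 1).  Values below the lower anchor clamp to 0.
    """
    if not (0.0 <= e <= 1.0):
        raise DomainError(f"EQR must lie in [0, 1], got {e}")
    xp = np.array([boundaries.eqr_lower_anchor, boundaries.eqr_pb, boundaries.eqr_mp,
                   boundaries.eqr_gm, boundaries.eqr_hg, 1.0])
    fp = np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])
    return float(np.interp(e, xp, fp))


def final_helm(neqr_tihelm: Optional[float], neqr_cmax: Optional[float]) -> Optional[float]:
    """Equal-weight combination of the two normalized metric EQRs."""
    if neqr_tihelm is None or neqr_cmax is None:
        return None
    for v in (neqr_tihelm, neqr_cmax):
        if not (0.0 <= v <= 1.0):
            raise DomainError(f"normalized EQR must lie in [0, 1], got {v}")
    return (neqr_tihelm + neqr_cmax) / 2.0


def status_class(score: float) -> StatusClass:
    """Five-class status from a normalized-scale score; a score exactly on a
    boundary belongs to the upper class."""
    if not (0.0 <= score <= 1.0):
        raise DomainError(f"score must lie in [0, 1], got {score}")
    if score >= 0.8:
        return StatusClass.HIGH
    if score >= 0.6:
        return StatusClass.GOOD
    if score >= 0.4:
        return StatusClass.MODERATE
    if score >= 0.2:
        return StatusClass.POOR
    return StatusClass.BAD


def assess_from_raw(
    lake_id: str,
    meta: LakeMeta,
    tihelm_raw: Optional[float],
    cmax_raw_m: Optional[float],
    boundaries: list[MetricBoundaries],
) -> LakeAssessment:
    """Assessment from already-aggregated lake metric values."""
    out = LakeAssessment(lake_id=lake_id, lake_type=meta.lake_type,
                         tihelm_raw=tihelm_raw, cmax_raw_m=cmax_raw_m)
    if tihelm_raw is not None:
        b_ti = select_boundaries(boundaries, Metric.TIHELM, meta.lake_type)
        out.eqr_tihelm = eqr(tihelm_raw, b_ti)
        out.neqr_tihelm = normalize_eqr(out.eqr_tihelm, b_ti)
    if cmax_raw_m is not None:
        b_cm = select_boundaries(boundaries, Metric.CMAX, meta.lake_type)
        out.eqr_cmax = eqr(cmax_raw_m, b_cm)
        out.neqr_cmax = normalize_eqr(out.eqr_cmax, b_cm)
    out.helm = final_helm(out.neqr_tihelm, out.neqr_cmax)
    if out.helm is not None:
        out.status = status_class(out.helm)
    else:
        logger.warning("lake %s is only partially assessable (TIHeLM=%s, C_max=%s); no final score",
                       lake_id, tihelm_raw, cmax_raw_m)
    return out


def assess_lake(
    meta: LakeMeta,
    surveys: list[TransectSurvey],
    taxa: Mapping[str, TaxonRecord],
    boundaries: list[MetricBoundaries],
    *,
    cover_spec: CoverWeightSpec = DEFAULT_COVER_SPEC,
    imputation: LtrImputationModel = DEFAULT_IMPUTATION,
    aggregation_rule: AggregationRule = "max",
    annual_cmax_rule: AnnualRule = "max",
) -> LakeAssessment:
    """Full pipeline for one lake: surveys -> metrics -> EQRs -> nEQRs ->
    final score -> status class."""
    mine = [s for s in surveys if s.lake_id == meta.lake_id]
    if not mine:
        raise DomainError(f"no surveys for lake {meta.lake_id}")
    ti, _diags = lake_tihelm(mine, taxa, cover_spec, imputation, aggregation_rule)
    cm = lake_cmax_from_surveys(mine, annual_cmax_rule).mean_cmax_m
    return assess_from_raw(meta.lake_id, meta, ti, cm, boundaries)


def assess_dataset(
    metas: Mapping[str, LakeMeta],
    surveys: list[TransectSurvey],
    taxa: Mapping[str, TaxonRecord],
    boundaries: list[MetricBoundaries],
    **kwargs,
) -> list[LakeAssessment]:
    """Assess every lake that has surveys, in lake_id order."""
    by_lake: dict[str, list[TransectSurvey]] = {}
    for s in surveys:
        by_lake.setdefault(s.lake_id, []).append(s)
    out = []
    for lake_id in sorted(by_lake):
        if lake_id not in metas:
            logger.warning("lake %s has surveys but no metadata; skipped", lake_id)
            continue
        out.append(assess_lake(metas[lake_id], by_lake[lake_id], taxa, boundaries, **kwargs))
    return out


def round_assessment(a: LakeAssessment) -> dict:
    """Reporting row with the published precision: 3 dp for the trophic index
    and all (n)EQR/final values, 2 dp for raw C_max."""
    r3 = lambda v: None if v is None else round(v, 3)
    return {
        "lake_id": a.lake_id,
        "lake_type": a.lake_type.value,
        "tihelm_raw": r3(a.tihelm_raw),
        "neqr_tihelm": r3(a.neqr_tihelm),
        "cmax_raw_m": None if a.cmax_raw_m is None else round(a.cmax_raw_m, 2),
        "neqr_cmax": r3(a.neqr_cmax),
        "helm": r3(a.helm),
        "status": None if a.status is None else a.status.value,
    }
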