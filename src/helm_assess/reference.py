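"""Reference-site screening and class-boundary derivation.

A lake qualifies as a potential reference site only if all seven pressure
criteria hold simultaneously (strict inequalities against the type-specific
limits).  A second filtering step flags transects whose metric values are
outliers among the reference population (sites limited by natural substrate
or slope rather than pressure).  Boundaries then follow the percentile
scheme: the reference value is the median of reference-site values, the
High/Good boundary the 90th percentile of the reference distribution taken in
the direction of degradation, and the Good/Moderate boundary the 75th
degradation-direction percentile among sites in the 20-50 ug/L total
phosphorus band; the remaining boundaries divide the EQR range below
Good/Moderate into three equal classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import (
    BoundaryScope,
    DomainError,
    LakeMeta,
    Metric,
    MetricBoundaries,
    Orientation,
    PressureProfile,
    PressureThresholds,
)
from .io import DEFAULT_PRESSURE_THRESHOLDS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreeningResult:
    lake_id: str
    passed: bool
    failed_criteria: tuple[str, ...] = ()


#: criterion name -> (profile attribute, threshold attribute, direction)
_CRITERIA = (
    ("TP", "tp_ug_l", "tp_max", "<"),
    ("CHLA", "chla_ug_l", "chla_max", "<"),
    ("SD", "sd_m", "sd_min", ">"),
    ("ALU", "alu_pct", "alu_max", "<"),
    ("IA", "ia_pct", "ia_max", "<"),
    ("NASN", "nasn_pct", "nasn_min", ">"),
    ("PD", "pd_h_km2", "pd_max", "<"),
)


def screen_reference(
    profile: PressureProfile,
    meta: LakeMeta,
    thresholds: Optional[PressureThresholds] = None,
) -> ScreeningResult:
    """Conjunctive screening of one lake against its type's pressure limits.

    A missing indicator makes that criterion "not evaluable" and the lake
    cannot pass.  All comparisons are strict.
    """
    if thresholds is None:
        thresholds = DEFAULT_PRESSURE_THRESHOLDS[meta.lake_type]
    if thresholds.lake_type is not meta.lake_type:
        raise DomainError(
            f"thresholds are for {thresholds.lake_type.value} but lake {meta.lake_id} "
            f"is {meta.lake_type.value}"
        )
    failed: list[str] = []
    for name, attr, limit_attr, op in _CRITERIA:
        value = getattr(profile, attr)
        limit = getattr(thresholds, limit_attr)
        if value is None:
            failed.append(f"{name} (not evaluable)")
            continue
        ok = value < limit if op == "<" else value > limit
        if not ok:
            failed.append(name)
    return ScreeningResult(lake_id=profile.lake_id, passed=not failed,
                           failed_criteria=tuple(failed))


def flag_outlier_transects(values: Sequence[float], k: float = 1.5) -> list[bool]:
    """Tukey-fence outlier flags for per-transect metric values.

    A value outside [Q1 - k*IQR, Q3 + k*IQR] is flagged.  Fewer than 4 values
    give no flags (with a warning); a zero IQR (near-constant sample) is
    treated as no-outlier.
    """
    values = list(values)
    if len(values) < 4:
        logger.warning("only %d value(s); too few for outlier screening, none flagged", len(values))
        return [False] * len(values)
    q1, q3 = np.quantile(values, [0.25, 0.75])
    iqr = q3 - q1
    if iqr == 0:
        return [False] * len(values)
    lo, hi = q1 - k * iqr, q3 + k * iqr
    return [bool(v < lo or v > hi) for v in values]


@dataclass(frozen=True)
class TpGroup:
    """The total-phosphorus band whose sites anchor the Good/Moderate boundary."""

    tp_low: float = 20.0
    tp_high: float = 50.0
    member_lake_ids: tuple[str, ...] = ()

    def contains(self, tp_ug_l: Optional[float]) -> bool:
        return tp_ug_l is not None and self.tp_low <= tp_ug_l <= self.tp_high


def _raw_to_eqr(raw: float, reference: float, orientation: Orientation) -> float:
    if orientation is Orientation.LOWER_IS_BETTER:
        value = reference / raw if raw > 0 else 1.0
    else:
        value = raw / reference
    return float(min(1.0, max(0.0, value)))


def derive_boundaries(
    reference_values: Sequence[float],
    tp_group_values: Sequence[float],
    metric: Metric,
    orientation: Orientation,
    scope: BoundaryScope = BoundaryScope.BOTH_TYPES,
    lower_anchor: Optional[float] = None,
) -> MetricBoundaries:
    """Derive a full boundary record from reference-site and TP-group
    per-transect metric values.

    Percentiles are linearly interpolated order statistics and are always
    read in the direction of degradation: for a lower-is-better metric the
    upper tail is degraded (P90 of reference values = 90th percentile), for a
    higher-is-better metric the lower tail is (P90 = 10th percentile).

    The sub-G/M boundaries divide [lower anchor, G/M] into three equal EQR
    classes.  The lower anchor is 0 for higher-is-better metrics; for
    lower-is-better metrics it defaults to the minimum EQR observed across
    both supplied samples (the worst site), or an explicit ``lower_anchor``.
    """
    ref = np.asarray(reference_values, dtype=float)
    tpg = np.asarray(tp_group_values, dtype=float)
    if ref.size == 0:
        raise DomainError("derive_boundaries: reference_values is empty")
    if tpg.size == 0:
        raise DomainError("derive_boundaries: tp_group_values is empty")

    reference = float(np.median(ref))
    if reference <= 0:
        raise DomainError(f"derived reference value must be > 0, got {reference}")

    degraded_tail_hg = 0.90 if orientation is Orientation.LOWER_IS_BETTER else 0.10
    degraded_tail_gm = 0.75 if orientation is Orientation.LOWER_IS_BETTER else 0.25
    raw_hg = float(np.quantile(ref, degraded_tail_hg))
    raw_gm = float(np.quantile(tpg, degraded_tail_gm))

    eqr_hg = _raw_to_eqr(raw_hg, reference, orientation)
    eqr_gm = _raw_to_eqr(raw_gm, reference, orientation)
    if not eqr_hg > eqr_gm:
        raise DomainError(
            f"derived H/G boundary ({eqr_hg:.4f}) is not better than G/M ({eqr_gm:.4f}); "
            "the supplied data are inconsistent with the boundary-setting scheme"
        )

    if orientation is Orientation.HIGHER_IS_BETTER:
        anchor = 0.0 if lower_anchor is None else float(lower_anchor)
    elif lower_anchor is not None:
        anchor = float(lower_anchor)
    else:
        anchor = float(min(_raw_to_eqr(v, reference, orientation)
                           for v in np.concatenate([ref, tpg])))
    if not anchor < eqr_gm:
        raise DomainError(
            f"lower anchor ({anchor:.4f}) must lie below the G/M boundary ({eqr_gm:.4f})"
        )
    step = (eqr_gm - anchor) / 3.0
    eqr_mp = eqr_gm - step
    eqr_pb = eqr_gm - 2.0 * step
    return MetricBoundaries(
        metric=metric, scope=scope, orientation=orientation,
        reference_value=reference, eqr_hg=eqr_hg, eqr_gm=eqr_gm,
        eqr_mp=eqr_mp, eqr_pb=eqr_pb, eqr_lower_anchor=anchor,
    )


def derive_boundary_set(
    metas,
    surveys,
    taxa,
    pressures,
    thresholds: Optional[dict] = None,
    tp_group: TpGroup = TpGroup(),
    outlier_k: float = 1.5,
) -> list[MetricBoundaries]:
    """End-to-end boundary derivation from a full survey dataset.

    Screens every lake with pressure data, pools per-transect metric values
    of the qualifying reference lakes (after Tukey outlier disqualification),
    pools the TP-group transect values, and derives: one trophic-index
    boundary record common to both lake types, and type-specific C_max
    records for each lake type with reference sites.
    """
    from .abundance import annual_lake_cmax  # noqa: F401  (local to avoid cycle)
    from .trophic_index import transect_tihelm

    if thresholds is None:
        thresholds = DEFAULT_PRESSURE_THRESHOLDS
    by_lake: dict[str, list] = {}
    for s in surveys:
        by_lake.setdefault(s.lake_id, []).append(s)

    ref_lakes: list[str] = []
    for lake_id, profile in pressures.items():
        if lake_id not in metas or lake_id not in by_lake:
            continue
        meta = metas[lake_id]
        if screen_reference(profile, meta, thresholds[meta.lake_type]).passed:
            ref_lakes.append(lake_id)
    if not ref_lakes:
        raise DomainError("no lake passed the reference screening; cannot derive boundaries")

    tpg_lakes = [lid for lid, p in pressures.items()
                 if lid in by_lake and tp_group.contains(p.tp_ug_l)]
    if not tpg_lakes:
        raise DomainError(
            f"no lake lies in the {tp_group.tp_low}-{tp_group.tp_high} ug/L TP group; "
            "cannot derive the Good/Moderate boundary"
        )

    def transect_values(lake_ids, metric: Metric, lake_type=None):
        vals = []
        for lid in lake_ids:
            if lake_type is not None and metas[lid].lake_type is not lake_type:
                continue
            for s in by_lake[lid]:
                if metric is Metric.CMAX:
                    vals.append(s.c_max_m)
                else:
                    v, _ = transect_tihelm(s, taxa)
                    if v is not None:
                        vals.append(v)
        return vals

    def filtered(values):
        flags = flag_outlier_transects(values, k=outlier_k)
        return [v for v, f in zip(values, flags) if not f]

    out: list[MetricBoundaries] = []

    # trophic index: common boundaries, lower anchor at the worst observed site
    ref_ti = filtered(transect_values(ref_lakes, Metric.TIHELM))
    tpg_ti = transect_values(tpg_lakes, Metric.TIHELM)
    all_ti = transect_values(list(by_lake), Metric.TIHELM)
    if not ref_ti:
        raise DomainError("no reference transect has a defined trophic index")
    anchor_ti = float(np.median(ref_ti)) / max(all_ti) if all_ti else None
    out.append(derive_boundaries(ref_ti, tpg_ti, Metric.TIHELM,
                                 Orientation.LOWER_IS_BETTER, BoundaryScope.BOTH_TYPES,
                                 lower_anchor=min(1.0, anchor_ti) if anchor_ti else None))

    # C_max: type-specific boundaries
    from .core import LakeType
    for lake_type, scope in ((LakeType.GR_DNL, BoundaryScope.GR_DNL),
                             (LakeType.GR_SNL, BoundaryScope.GR_SNL)):
        ref_cm = filtered(transect_values(ref_lakes, Metric.CMAX, lake_type))
        tpg_cm = transect_values(tpg_lakes, Metric.CMAX, lake_type)
        if not ref_cm:
            logger.warning("no %s reference transects; C_max boundaries for this type not derived",
                           lake_type.value)
            continue
        if not tpg_cm:
            logger.warning("no %s TP-group transects; C_max boundaries for this type not derived",
                           lake_type.value)
            continue
        out.append(derive_boundaries(ref_cm, tpg_cm, Metric.CMAX,
                                     Orientation.HIGHER_IS_BETTER, scope))
    return out


def raw_boundary(eqr_value: float, boundaries: MetricBoundaries) -> float:
    """Raw metric value corresponding to an EQR boundary (inverse of eqr)."""
    ref = boundaries.reference_value
    if boundaries.orientation is Orientation.LOWER_IS_BETTER:
        if eqr_value <= 0:
            raise DomainError("cannot invert a zero EQR for a lower-is-better metric")
        return ref / eqr_value
    return eqr_value * ref
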