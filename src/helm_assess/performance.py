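"""Pressure-response evaluation of the assessment metrics.

The method is validated by regressing (transformed) metric values on
log10-transformed eutrophication pressure indicators — total phosphorus,
chlorophyll a, Secchi depth — with ordinary least squares.  Conventions:
the trophic index is log10-transformed, C_max square-root-transformed, the
final score left untransformed; a metric counts as well-performing when
R^2 > 0.30, |R| > 0.55 and the model F-test gives p < 0.05.  Life-form
relative abundances summarize the community turnover along the trophic
gradient (submerged forms give way to helophytes and free-floating forms).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import statsmodels.api as sm

from .core import DomainError, LifeForm, TaxonRecord, TransectSurvey
from .trophic_index import DEFAULT_COVER_SPEC, AggregationRule, CoverWeightSpec, dafor_to_cover, transect_taxon_abundance

logger = logging.getLogger(__name__)

R2_THRESHOLD = 0.30
R_THRESHOLD = 0.55
P_THRESHOLD = 0.05

_RESPONSE_TRANSFORMS = {
    "log10": (np.log10, "log"),
    "sqrt": (np.sqrt, "sqrt"),
    "none": (lambda x: x, ""),
}

#: default response transforms per metric
DEFAULT_TRANSFORMS = {"TIHeLM": "log10", "Cmax": "sqrt", "HeLM": "none"}


@dataclass(frozen=True)
class RegressionSpec:
    response: str                     # "TIHeLM" | "Cmax" | "HeLM"
    predictors: tuple[str, ...]       # subset of ("TP", "CHLA", "SD")
    response_transform: Optional[str] = None  # default by metric

    def transform_name(self) -> str:
        if self.response_transform is not None:
            return self.response_transform
        return DEFAULT_TRANSFORMS.get(self.response, "none")


@dataclass
class RegressionResult:
    response: str
    predictors: tuple[str, ...]
    slopes: dict[str, float]
    intercept: float
    r2: float
    r: float          # signed Pearson r for simple fits; +multiple-R otherwise
    p: float
    n: int
    equation: str

    @property
    def well_performing(self) -> bool:
        return self.r2 > R2_THRESHOLD and abs(self.r) > R_THRESHOLD and self.p < P_THRESHOLD


def _format_equation(response: str, transform: str, intercept: float,
                     slopes: Mapping[str, float]) -> str:
    lhs = f"{transform}{response}" if transform else response
    if transform == "sqrt":
        lhs = f"sqrt({response})"
    parts = [f"{intercept:.4g}"]
    for name, b in slopes.items():
        parts.append(f"{'-' if b < 0 else '+'} {abs(b):.4g} x log {name}")
    return f"{lhs} = " + " ".join(parts)


def fit_pressure_regression(
    metric_values: Sequence[float],
    pressure_values: Sequence[float],
    spec: RegressionSpec,
) -> RegressionResult:
    """OLS of one transformed metric on one log10-transformed pressure
    indicator, across lakes.

    Lakes whose pressure value is non-positive (undefined under log) are
    excluded with a warning; at least 3 usable lakes are required.
    """
    if len(spec.predictors) != 1:
        raise DomainError("fit_pressure_regression handles a single predictor; "
                          "use fit_multivariate for several")
    y = np.asarray(metric_values, dtype=float)
    x = np.asarray(pressure_values, dtype=float)
    if y.shape != x.shape:
        raise DomainError("metric and pressure vectors must have equal length")
    keep = x > 0
    if not keep.all():
        logger.warning("excluding %d lake(s) with non-positive %s under log transform",
                       int((~keep).sum()), spec.predictors[0])
        y, x = y[keep], x[keep]
    if y.size < 3:
        raise DomainError(f"need >= 3 lakes for regression, got {y.size}")
    tname = spec.transform_name()
    fy, _ = _RESPONSE_TRANSFORMS[tname]
    if tname == "log10" and (y <= 0).any():
        raise DomainError("log10 response transform requires positive metric values")
    if tname == "sqrt" and (y < 0).any():
        raise DomainError("sqrt response transform requires non-negative metric values")
    ty = fy(y)
    tx = np.log10(x)
    if np.ptp(tx) == 0:
        raise DomainError(f"predictor {spec.predictors[0]} has zero variance")

    model = sm.OLS(ty, sm.add_constant(tx)).fit()
    slope = float(model.params[1])
    intercept = float(model.params[0])
    r2 = float(model.rsquared)
    if np.ptp(ty) == 0:
        r2, r, p = 0.0, 0.0, 1.0  # constant response: no explainable variance
    else:
        r = float(math.copysign(math.sqrt(max(r2, 0.0)), slope))
        p = float(model.f_pvalue)
    slopes = {spec.predictors[0]: slope}
    return RegressionResult(
        response=spec.response, predictors=spec.predictors, slopes=slopes,
        intercept=intercept, r2=r2, r=r, p=p, n=int(y.size),
        equation=_format_equation(spec.response, tname, intercept, slopes),
    )


def fit_multivariate(
    helm_values: Sequence[float],
    tp: Sequence[float],
    chla: Sequence[float],
    sd: Sequence[float],
) -> RegressionResult:
    """Multiple OLS of the untransformed final score on log10 TP, CHLA, SD.

    R is reported as the (positive) multiple correlation sqrt(R^2).
    """
    y = np.asarray(helm_values, dtype=float)
    X = np.column_stack([np.asarray(v, dtype=float) for v in (tp, chla, sd)])
    if (X <= 0).any():
        keep = (X > 0).all(axis=1)
        logger.warning("excluding %d lake(s) with non-positive pressure values under log",
                       int((~keep).sum()))
        y, X = y[keep], X[keep]
    if y.size < 5:
        raise DomainError(f"need >= 5 lakes for the multivariate fit, got {y.size}")
    lX = np.log10(X)
    names = ("TP", "CHLA", "SD")
    # collinearity to machine precision
    if np.linalg.matrix_rank(lX - lX.mean(axis=0)) < lX.shape[1]:
        corr = np.corrcoef(lX, rowvar=False)
        bad = [f"{names[i]}~{names[j]}" for i in range(3) for j in range(i + 1, 3)
               if abs(corr[i, j]) > 1 - 1e-12]
        raise DomainError(f"collinear predictors: {', '.join(bad) or 'rank deficiency'}")
    model = sm.OLS(y, sm.add_constant(lX)).fit()
    slopes = {n: float(b) for n, b in zip(names, model.params[1:])}
    r2 = float(model.rsquared)
    return RegressionResult(
        response="HeLM", predictors=names, slopes=slopes,
        intercept=float(model.params[0]), r2=r2, r=float(math.sqrt(max(r2, 0.0))),
        p=float(model.f_pvalue), n=int(y.size),
        equation=_format_equation("HeLM", "", float(model.params[0]), slopes),
    )


@dataclass(frozen=True)
class LifeFormProfile:
    lake_id: str
    relative_abundance: Mapping[LifeForm, float]


def lifeform_profile(
    surveys: Sequence[TransectSurvey],
    taxa: Mapping[str, TaxonRecord],
    spec: CoverWeightSpec = DEFAULT_COVER_SPEC,
    rule: AggregationRule = "max",
) -> LifeFormProfile:
    """Per-lake life-form relative abundances.

    Percent covers (DAFOR-transformed, transect-aggregated) are summed per
    life-form over all transects and divided by the grand total.  Taxa with
    life-form "other" or absent from the table are skipped with a warning.
    """
    if not surveys:
        raise DomainError("lifeform_profile needs at least one survey")
    lake_id = surveys[0].lake_id
    totals: dict[LifeForm, float] = {}
    skipped: set[str] = set()
    for s in surveys:
        for taxon_id, category in transect_taxon_abundance(s, rule=rule).items():
            taxon = taxa.get(taxon_id)
            if taxon is None or taxon.life_form is LifeForm.OTHER:
                skipped.add(taxon_id)
                continue
            totals[taxon.life_form] = totals.get(taxon.life_form, 0.0) + dafor_to_cover(category, spec)
    if skipped:
        logger.warning("lake %s: %d taxon(s) without a known life-form skipped", lake_id, len(skipped))
    grand = sum(totals.values())
    if grand == 0:
        logger.warning("lake %s: no taxa with a known life-form; empty profile", lake_id)
        return LifeFormProfile(lake_id=lake_id, relative_abundance={})
    return LifeFormProfile(lake_id=lake_id,
                           relative_abundance={lf: v / grand for lf, v in totals.items()})


@dataclass(frozen=True)
class LifeFormTrend:
    life_form: LifeForm
    coefficients: tuple[float, ...]   # highest degree first (numpy convention)
    degree: int


def lifeform_trend(
    profiles: Sequence[LifeFormProfile],
    scores: Sequence[float],
    degree: int = 2,
) -> dict[LifeForm, LifeFormTrend]:
    """Least-squares polynomial of sqrt(relative abundance) on a score axis,
    fitted separately per life-form.  Life-forms with fewer points than
    ``degree + 2`` lakes are skipped with a warning."""
    if len(profiles) != len(scores):
        raise DomainError("profiles and scores must align")
    out: dict[LifeForm, LifeFormTrend] = {}
    for lf in LifeForm:
        if lf is LifeForm.OTHER:
            continue
        xs, ys = [], []
        for prof, score in zip(profiles, scores):
            if lf in prof.relative_abundance:
                xs.append(score)
                ys.append(math.sqrt(prof.relative_abundance[lf]))
        if len(xs) < degree + 2:
            if xs:
                logger.warning("life-form %s: only %d point(s); trend skipped", lf.value, len(xs))
            continue
        coeffs = np.polyfit(xs, ys, degree)
        out[lf] = LifeFormTrend(life_form=lf, coefficients=tuple(float(c) for c in coeffs),
                                degree=degree)
    return out
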