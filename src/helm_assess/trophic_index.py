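"""TIHeLM: the cover-weighted trophic index of taxonomic composition.

Per transect, each scored taxon contributes its lake trophic rank (LTR)
weighted by its percentage cover raised to the power 0.2 — the flattening
exponent keeps dominant stands from swamping the index.  DAFOR categories map
to percent cover as dominant 87.5, abundant 50, frequent 17.5, occasional 5.5,
rare 0.5.  Taxa lacking an LTR but carrying an Ellenberg nutrient value N get
one imputed from the calibration regression LTR = 1.395 N - 0.6276.  The lake
value is the unweighted mean of its transect values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional

from .core import Dafor, DomainError, TaxonRecord, TransectSurvey

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LtrImputationModel:
    """Linear map from Ellenberg N (1-9) to LTR, with published defaults."""

    slope: float = 1.395
    intercept: float = -0.6276
    #: imputed values are clamped into (0, ltr_cap]; the regression exceeds
    #: the 10-rank scale at N = 9
    ltr_cap: float = 10.0

    def impute(self, n_value: float) -> float:
        if not (1.0 <= n_value <= 9.0):
            raise DomainError(f"Ellenberg N must lie in [1, 9], got {n_value}")
        ltr = self.slope * n_value + self.intercept
        if ltr > self.ltr_cap:
            logger.warning("imputed LTR %.4f for N=%.2f exceeds the %.0f-rank scale; clamped",
                           ltr, n_value, self.ltr_cap)
            ltr = self.ltr_cap
        if ltr <= 0:
            raise DomainError(f"imputed LTR {ltr:.4f} for N={n_value} is non-positive; "
                              "check the imputation coefficients")
        return ltr


@dataclass(frozen=True)
class CoverWeightSpec:
    """DAFOR -> percent cover mapping and the weighting exponent."""

    dafor_to_pct: Mapping[Dafor, float] = field(default_factory=lambda: {
        Dafor.DOMINANT: 87.5,
        Dafor.ABUNDANT: 50.0,
        Dafor.FREQUENT: 17.5,
        Dafor.OCCASIONAL: 5.5,
        Dafor.RARE: 0.5,
    })
    weight_exponent: float = 0.2

    def __post_init__(self) -> None:
        if set(self.dafor_to_pct) != set(Dafor):
            raise DomainError("dafor_to_pct must map all five DAFOR categories")
        if self.weight_exponent <= 0:
            raise DomainError("weight_exponent must be > 0")


DEFAULT_COVER_SPEC = CoverWeightSpec()
DEFAULT_IMPUTATION = LtrImputationModel()

AggregationRule = Literal["max", "modal"]


def dafor_to_cover(category: Dafor, spec: CoverWeightSpec = DEFAULT_COVER_SPEC) -> float:
    """Percent cover assigned to a DAFOR category."""
    return spec.dafor_to_pct[category]


def impute_ltr(n_value: float, model: LtrImputationModel = DEFAULT_IMPUTATION) -> float:
    """LTR imputed from an Ellenberg N value via the calibration regression."""
    return model.impute(n_value)


def taxon_ltr(taxon: TaxonRecord, model: LtrImputationModel = DEFAULT_IMPUTATION) -> Optional[float]:
    """Effective LTR of a taxon: its own score, else imputed from Ellenberg N,
    else None (unscoreable)."""
    if taxon.ltr is not None:
        return taxon.ltr
    if taxon.ellenberg_n is not None:
        return model.impute(taxon.ellenberg_n)
    return None


def transect_taxon_abundance(survey: TransectSurvey, rule: AggregationRule = "max") -> dict[str, Dafor]:
    """Collapse plot-level DAFOR records to one category per taxon and transect.

    ``max`` (default) takes the highest category the taxon attains in any plot
    of any depth zone; ``modal`` takes the most frequent category across plots
    (ties resolved toward the higher category).
    """
    per_taxon: dict[str, list[Dafor]] = {}
    for obs in survey.observations:
        per_taxon.setdefault(obs.taxon_id, []).append(obs.abundance)
    if rule == "max":
        return {t: max(cats) for t, cats in per_taxon.items()}
    if rule == "modal":
        out = {}
        for t, cats in per_taxon.items():
            counts: dict[Dafor, int] = {}
            for c in cats:
                counts[c] = counts.get(c, 0) + 1
            out[t] = max(counts, key=lambda c: (counts[c], int(c)))
        return out
    raise DomainError(f"unknown aggregation rule {rule!r} (expected 'max' or 'modal')")


@dataclass
class TransectDiagnostics:
    lake_id: str
    transect_id: str
    year: int
    n_taxa: int
    n_scored: int
    n_excluded: int
    excluded_taxa: list[str] = field(default_factory=list)


def transect_tihelm(
    survey: TransectSurvey,
    taxa: Mapping[str, TaxonRecord],
    spec: CoverWeightSpec = DEFAULT_COVER_SPEC,
    imputation: LtrImputationModel = DEFAULT_IMPUTATION,
    rule: AggregationRule = "max",
) -> tuple[Optional[float], TransectDiagnostics]:
    """Cover-weighted mean LTR of one transect.

    Returns ``(value, diagnostics)``; the value is None (not zero) when the
    transect holds no scoreable taxon.  Weights are relative within the
    transect (divided by their sum), so a common cover rescaling cancels.
    """
    abundances = transect_taxon_abundance(survey, rule=rule)
    num = 0.0
    den = 0.0
    n_scored = 0
    excluded: list[str] = []
    for taxon_id, category in abundances.items():
        taxon = taxa.get(taxon_id)
        ltr = taxon_ltr(taxon, imputation) if taxon is not None else None
        if ltr is None:
            excluded.append(taxon_id)
            continue
        w = dafor_to_cover(category, spec) ** spec.weight_exponent
        num += ltr * w
        den += w
        n_scored += 1
    diag = TransectDiagnostics(
        lake_id=survey.lake_id, transect_id=survey.transect_id, year=survey.year,
        n_taxa=len(abundances), n_scored=n_scored, n_excluded=len(excluded),
        excluded_taxa=sorted(excluded),
    )
    if n_scored == 0:
        logger.warning("transect %s/%s/%s has no scoreable taxa; TIHeLM undefined",
                       survey.lake_id, survey.transect_id, survey.year)
        return None, diag
    return num / den, diag


def lake_tihelm(
    surveys: list[TransectSurvey],
    taxa: Mapping[str, TaxonRecord],
    spec: CoverWeightSpec = DEFAULT_COVER_SPEC,
    imputation: LtrImputationModel = DEFAULT_IMPUTATION,
    rule: AggregationRule = "max",
) -> tuple[Optional[float], list[TransectDiagnostics]]:
    """Unweighted mean of the defined transect TIHeLM values of one lake.

    Transects with no scoreable taxa are excluded from the mean (and visible
    in the diagnostics); if none is defined the lake value is None.
    """
    if not surveys:
        raise DomainError("lake_tihelm needs at least one transect survey")
    lakes = {s.lake_id for s in surveys}
    if len(lakes) > 1:
        raise DomainError(f"lake_tihelm expects transects of a single lake, got {sorted(lakes)}")
    values = []
    diags = []
    for s in surveys:
        v, d = transect_tihelm(s, taxa, spec, imputation, rule)
        diags.append(d)
        if v is not None:
            values.append(v)
    if not values:
        return None, diags
    return sum(values) / len(values), diags
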