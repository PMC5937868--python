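"""Domain types for the HeLM lake-macrophyte assessment method.

The method rests on two metrics per lake: a trophic index (TIHeLM), a
cover-weighted mean of taxon lake-trophic-rank (LTR) scores, and the maximum
colonization depth of aquatic vegetation (C_max, metres).  Both are expressed
as ecological quality ratios (EQR) against type-specific reference values,
normalized to a common five-class scale, and averaged into a final score that
maps onto the Water Framework Directive status classes High .. Bad.

Everything here is a plain, validated record; computation lives in the
sibling modules.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional


class HelmError(Exception):
    """Base class for all validation / domain errors raised by the package."""


class SchemaError(HelmError):
    """A tabular input is missing required columns or has malformed rows."""


class DomainError(HelmError):
    """A value violates a domain precondition (range, ordering, emptiness)."""


class LifeForm(enum.Enum):
    """Macrophyte growth forms used for community-turnover summaries."""

    ELODEID = "elodeid"          # submerged, rooted
    HELOPHYTE = "helophyte"      # emergent
    CHARID = "charid"            # charophyte
    CERATOPHYLLID = "ceratophyllid"  # submerged, rootless
    NYMPHAEID = "nymphaeid"      # floating-leaved, rooted
    LEMNID = "lemnid"            # free-floating
    OTHER = "other"


class Dafor(enum.IntEnum):
    """Five-point ordinal abundance scale; larger value = more abundant."""

    RARE = 1
    OCCASIONAL = 2
    FREQUENT = 3
    ABUNDANT = 4
    DOMINANT = 5

    @classmethod
    def from_token(cls, token: str) -> "Dafor":
        t = str(token).strip().lower()
        aliases = {
            "d": cls.DOMINANT, "dominant": cls.DOMINANT,
            "a": cls.ABUNDANT, "abundant": cls.ABUNDANT,
            "f": cls.FREQUENT, "frequent": cls.FREQUENT,
            "o": cls.OCCASIONAL, "occasional": cls.OCCASIONAL,
            "r": cls.RARE, "rare": cls.RARE,
        }
        if t not in aliases:
            raise DomainError(f"unrecognized DAFOR token: {token!r}")
        return aliases[t]


class LakeType(enum.Enum):
    """Greek national lake types: deep (>9 m mean depth) vs shallow (3-9 m)."""

    GR_DNL = "GR-DNL"
    GR_SNL = "GR-SNL"

    @classmethod
    def from_token(cls, token: str) -> "LakeType":
        t = str(token).strip().upper().replace("_", "-")
        for lt in cls:
            if lt.value == t:
                return lt
        raise DomainError(f"unknown lake type: {token!r} (expected GR-DNL or GR-SNL)")


class StatusClass(enum.Enum):
    HIGH = "High"
    GOOD = "Good"
    MODERATE = "Moderate"
    POOR = "Poor"
    BAD = "Bad"


DEPTH_ZONES = ("0-1", "1-2", "2-4", "4-8", ">8")


def canonical_depth_zone(token: str) -> str:
    t = str(token).strip().replace("–", "-").replace("m", "").strip()
    if t not in DEPTH_ZONES:
        raise DomainError(f"unknown depth zone: {token!r} (expected one of {DEPTH_ZONES})")
    return t


@dataclass(frozen=True)
class TaxonRecord:
    """One macrophyte taxon with its trophic scoring information.

    ``ltr`` is the lake trophic rank (sensitivity to nutrient enrichment,
    higher = more tolerant); ``ellenberg_n`` the Ellenberg nutrient indicator
    value on the 1-9 ordinal scale, used to impute a missing LTR.
    """

    taxon_id: str
    name: str
    life_form: LifeForm = LifeForm.OTHER
    ltr: Optional[float] = None
    ellenberg_n: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ltr is not None:
            if not math.isfinite(self.ltr) or self.ltr <= 0:
                raise DomainError(f"taxon {self.taxon_id}: LTR must be finite and > 0, got {self.ltr}")
        if self.ellenberg_n is not None:
            if not (1.0 <= self.ellenberg_n <= 9.0):
                raise DomainError(
                    f"taxon {self.taxon_id}: Ellenberg N must lie in [1, 9], got {self.ellenberg_n}"
                )

    @property
    def scoreable(self) -> bool:
        return self.ltr is not None or self.ellenberg_n is not None


@dataclass(frozen=True)
class PlotObservation:
    """A single taxon-in-plot record from one survey transect."""

    lake_id: str
    transect_id: str
    year: int
    depth_zone: str
    plot_index: int
    taxon_id: str
    abundance: Dafor

    def __post_init__(self) -> None:
        if self.plot_index < 1:
            raise DomainError(f"plot_index must be >= 1, got {self.plot_index}")
        object.__setattr__(self, "depth_zone", canonical_depth_zone(self.depth_zone))


@dataclass
class TransectSurvey:
    """All plot observations of one transect in one year, plus its C_max."""

    lake_id: str
    transect_id: str
    year: int
    observations: list[PlotObservation] = field(default_factory=list)
    c_max_m: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.c_max_m) or self.c_max_m < 0:
            raise DomainError(
                f"transect {self.lake_id}/{self.transect_id}/{self.year}: "
                f"c_max_m must be finite and >= 0, got {self.c_max_m}"
            )
        for obs in self.observations:
            if (obs.lake_id, obs.transect_id, obs.year) != (self.lake_id, self.transect_id, self.year):
                raise DomainError(
                    f"observation {obs} does not belong to transect "
                    f"{self.lake_id}/{self.transect_id}/{self.year}"
                )


@dataclass(frozen=True)
class LakeMeta:
    lake_id: str
    name: str
    lake_type: LakeType


@dataclass(frozen=True)
class PressureProfile:
    """Per-lake eutrophication and catchment pressure indicators.

    TP: mean annual total phosphorus (ug/L); CHLA: mean summer chlorophyll a
    (ug/L); SD: mean summer Secchi depth (m); ALU/IA/NASN: artificial,
    intensive-agriculture and natural/semi-natural land cover (% of
    catchment); PD: population density (inhabitants/km^2).  ``None`` marks an
    indicator that was not measured.
    """

    lake_id: str
    tp_ug_l: Optional[float] = None
    chla_ug_l: Optional[float] = None
    sd_m: Optional[float] = None
    alu_pct: Optional[float] = None
    ia_pct: Optional[float] = None
    nasn_pct: Optional[float] = None
    pd_h_km2: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("tp_ug_l", "chla_ug_l", "sd_m", "alu_pct", "ia_pct", "nasn_pct", "pd_h_km2"):
            v = getattr(self, name)
            if v is None:
                continue
            if not math.isfinite(v) or v < 0:
                raise DomainError(f"lake {self.lake_id}: {name} must be finite and >= 0, got {v}")
            if name.endswith("_pct") and v > 100:
                raise DomainError(f"lake {self.lake_id}: {name} is a percentage, got {v}")


@dataclass(frozen=True)
class PressureThresholds:
    """Reference-site screening limits for one lake type.

    All seven criteria are applied conjunctively with strict inequalities:
    TP < tp_max, CHLA < chla_max, SD > sd_min, ALU < alu_max, IA < ia_max,
    NASN > nasn_min, PD < pd_max.
    """

    lake_type: LakeType
    tp_max: float
    chla_max: float
    sd_min: float
    alu_max: float
    ia_max: float
    nasn_min: float
    pd_max: float


class Metric(enum.Enum):
    TIHELM = "TIHeLM"
    CMAX = "Cmax"


class Orientation(enum.Enum):
    LOWER_IS_BETTER = "lower-is-better"    # TIHeLM: low trophic index = good
    HIGHER_IS_BETTER = "higher-is-better"  # C_max: deep colonization = good


class BoundaryScope(enum.Enum):
    BOTH_TYPES = "both-types"
    GR_DNL = "GR-DNL"
    GR_SNL = "GR-SNL"

    def applies_to(self, lake_type: LakeType) -> bool:
        return self is BoundaryScope.BOTH_TYPES or self.value == lake_type.value


@dataclass(frozen=True)
class MetricBoundaries:
    """Reference value and EQR class boundaries for one metric x type scope.

    The EQR boundaries are the knots of the piecewise-linear normalization;
    they must be strictly ordered 1 >= H/G > G/M > M/P > P/B > lower anchor
    >= 0.
    """

    metric: Metric
    scope: BoundaryScope
    orientation: Orientation
    reference_value: float
    eqr_hg: float
    eqr_gm: float
    eqr_mp: float
    eqr_pb: float
    eqr_lower_anchor: float

    def __post_init__(self) -> None:
        if self.reference_value <= 0:
            raise DomainError(f"{self.metric.value}/{self.scope.value}: reference value must be > 0")
        seq = (1.0, self.eqr_hg, self.eqr_gm, self.eqr_mp, self.eqr_pb, self.eqr_lower_anchor, 0.0)
        names = ("1", "H/G", "G/M", "M/P", "P/B", "lower anchor", "0")
        if not (seq[0] >= seq[1] and seq[-2] >= seq[-1]):
            raise DomainError(f"{self.metric.value}: EQR boundaries must lie in [0, 1]")
        for i in range(1, len(seq) - 2):
            if not seq[i] > seq[i + 1]:
                raise DomainError(
                    f"{self.metric.value}/{self.scope.value}: boundary ordering violated "
                    f"({names[i]}={seq[i]} must be > {names[i + 1]}={seq[i + 1]}); "
                    "required: 1 >= H/G > G/M > M/P > P/B > lower anchor >= 0"
                )


@dataclass
class LakeAssessment:
    """Full per-lake result: raw metrics, EQRs, normalized EQRs, final score.

    ``helm`` is the arithmetic mean of the two normalized EQRs; ``status`` is
    set solely by ``helm`` against the 0.8/0.6/0.4/0.2 class anchors.  A lake
    with only one computable metric carries the other fields as None and no
    final score.
    """

    lake_id: str
    lake_type: LakeType
    tihelm_raw: Optional[float] = None
    cmax_raw_m: Optional[float] = None
    eqr_tihelm: Optional[float] = None
    eqr_cmax: Optional[float] = None
    neqr_tihelm: Optional[float] = None
    neqr_cmax: Optional[float] = None
    helm: Optional[float] = None
    status: Optional[StatusClass] = None

    @property
    def assessable(self) -> bool:
        return self.helm is not None
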