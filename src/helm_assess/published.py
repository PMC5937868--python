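"""Published HeLM application data for the 16 lakes of the Greek National
Water Monitoring Network (surveys 2013-2015).

Two tables ship with the package:

* :data:`GREEK_LAKES_2013_2015` — per-lake raw metric values (trophic index,
  mean C_max), the published normalized EQRs, final scores and status
  classes.  Re-running the classification pipeline on the raw values against
  the ``builtin:helm2018`` boundaries reproduces the published columns.
* :data:`REFERENCE_LAKE_PRESSURES` — pressure-indicator values of the three
  lakes that passed the reference screening (Kourna, Feneos, Paralimni).
  Kourna's total phosphorus was published as a censored "< 10" ug/L and is
  stored here as 10.0 (any value at or below 10 passes the strict < 12
  deep-lake criterion identically).
"""

from __future__ import annotations

from .core import LakeMeta, LakeType, PressureProfile

# lake_id, type, TIHeLM raw, published nEQR(TIHeLM), C_max raw (m),
# published nEQR(C_max), published final score, published status
GREEK_LAKES_2013_2015: list[dict] = [
    {"lake_id": "Kourna", "lake_type": "GR-DNL", "tihelm_raw": 7.163, "neqr_tihelm": 0.989,
     "cmax_raw_m": 13.20, "neqr_cmax": 1.000, "helm": 0.995, "status": "High"},
    {"lake_id": "Feneos", "lake_type": "GR-DNL", "tihelm_raw": 7.322, "neqr_tihelm": 0.917,
     "cmax_raw_m": 12.80, "neqr_cmax": 1.000, "helm": 0.959, "status": "High"},
    {"lake_id": "Megali Prespa", "lake_type": "GR-DNL", "tihelm_raw": 7.483, "neqr_tihelm": 0.847,
     "cmax_raw_m": 7.00, "neqr_cmax": 0.681, "helm": 0.764, "status": "Good"},
    {"lake_id": "Trichonida", "lake_type": "GR-DNL", "tihelm_raw": 7.694, "neqr_tihelm": 0.740,
     "cmax_raw_m": 10.00, "neqr_cmax": 0.773, "helm": 0.757, "status": "Good"},
    {"lake_id": "Amvrakia", "lake_type": "GR-DNL", "tihelm_raw": 7.497, "neqr_tihelm": 0.841,
     "cmax_raw_m": 6.60, "neqr_cmax": 0.668, "helm": 0.755, "status": "Good"},
    {"lake_id": "Vegoritida", "lake_type": "GR-DNL", "tihelm_raw": 7.579, "neqr_tihelm": 0.807,
     "cmax_raw_m": 7.67, "neqr_cmax": 0.701, "helm": 0.754, "status": "Good"},
    {"lake_id": "Volvi", "lake_type": "GR-DNL", "tihelm_raw": 7.444, "neqr_tihelm": 0.864,
     "cmax_raw_m": 3.87, "neqr_cmax": 0.528, "helm": 0.696, "status": "Good"},
    {"lake_id": "Yliki", "lake_type": "GR-DNL", "tihelm_raw": 7.439, "neqr_tihelm": 0.866,
     "cmax_raw_m": 3.80, "neqr_cmax": 0.519, "helm": 0.693, "status": "Good"},
    {"lake_id": "Paralimni", "lake_type": "GR-SNL", "tihelm_raw": 7.141, "neqr_tihelm": 1.000,
     "cmax_raw_m": 6.80, "neqr_cmax": 1.000, "helm": 1.000, "status": "High"},
    {"lake_id": "Doirani", "lake_type": "GR-SNL", "tihelm_raw": 7.783, "neqr_tihelm": 0.687,
     "cmax_raw_m": 4.67, "neqr_cmax": 0.848, "helm": 0.768, "status": "Good"},
    {"lake_id": "Mikri Prespa", "lake_type": "GR-SNL", "tihelm_raw": 8.389, "neqr_tihelm": 0.478,
     "cmax_raw_m": 5.60, "neqr_cmax": 0.947, "helm": 0.712, "status": "Good"},
    {"lake_id": "Kastoria", "lake_type": "GR-SNL", "tihelm_raw": 8.119, "neqr_tihelm": 0.548,
     "cmax_raw_m": 4.40, "neqr_cmax": 0.820, "helm": 0.684, "status": "Good"},
    {"lake_id": "Lysimachia", "lake_type": "GR-SNL", "tihelm_raw": 7.958, "neqr_tihelm": 0.593,
     "cmax_raw_m": 3.40, "neqr_cmax": 0.576, "helm": 0.585, "status": "Moderate"},
    {"lake_id": "Ozeros", "lake_type": "GR-SNL", "tihelm_raw": 8.788, "neqr_tihelm": 0.379,
     "cmax_raw_m": 3.10, "neqr_cmax": 0.524, "helm": 0.452, "status": "Moderate"},
    {"lake_id": "Zazari", "lake_type": "GR-SNL", "tihelm_raw": 8.737, "neqr_tihelm": 0.392,
     "cmax_raw_m": 1.40, "neqr_cmax": 0.240, "helm": 0.316, "status": "Poor"},
    {"lake_id": "Pamvotida", "lake_type": "GR-SNL", "tihelm_raw": 9.068, "neqr_tihelm": 0.307,
     "cmax_raw_m": 0.53, "neqr_cmax": 0.092, "helm": 0.199, "status": "Bad"},
]

#: Pressure indicators of the three screened reference lakes.
REFERENCE_LAKE_PRESSURES: list[PressureProfile] = [
    PressureProfile(lake_id="Kourna", tp_ug_l=10.0, chla_ug_l=1.27, sd_m=7.5,
                    alu_pct=0.00, ia_pct=2.70, nasn_pct=97.30, pd_h_km2=6.68),
    PressureProfile(lake_id="Feneos", tp_ug_l=10.27, chla_ug_l=0.47, sd_m=9.9,
                    alu_pct=0.00, ia_pct=0.00, nasn_pct=95.47, pd_h_km2=0.00),
    PressureProfile(lake_id="Paralimni", tp_ug_l=13.63, chla_ug_l=3.78, sd_m=2.5,
                    alu_pct=0.16, ia_pct=22.24, nasn_pct=77.59, pd_h_km2=9.57),
]

REFERENCE_LAKE_TYPES: dict[str, LakeType] = {
    "Kourna": LakeType.GR_DNL,
    "Feneos": LakeType.GR_DNL,
    "Paralimni": LakeType.GR_SNL,
}

#: Published simple pressure-response relationships: response, predictor,
#: response transform, intercept, slope (on the transformed scales).
PUBLISHED_REGRESSIONS: list[dict] = [
    {"response": "TIHeLM", "predictor": "TP", "transform": "log10", "intercept": 0.821, "slope": 0.049},
    {"response": "TIHeLM", "predictor": "CHLA", "transform": "log10", "intercept": 0.865, "slope": 0.031},
    {"response": "TIHeLM", "predictor": "SD", "transform": "log10", "intercept": 0.912, "slope": -0.051},
    {"response": "Cmax", "predictor": "TP", "transform": "sqrt", "intercept": 4.379, "slope": -1.383},
    {"response": "Cmax", "predictor": "CHLA", "transform": "sqrt", "intercept": 3.247, "slope": -0.994},
    {"response": "Cmax", "predictor": "SD", "transform": "sqrt", "intercept": 1.764, "slope": 1.528},
    {"response": "HeLM", "predictor": "TP", "transform": "none", "intercept": 1.276, "slope": -0.39},
    {"response": "HeLM", "predictor": "CHLA", "transform": "none", "intercept": 0.931, "slope": -0.253},
    {"response": "HeLM", "predictor": "SD", "transform": "none", "intercept": 0.556, "slope": 0.38},
]

#: Published multivariate relationship of the final score on all three
#: log10 pressure indicators: intercept, then slopes for TP, CHLA, SD.
PUBLISHED_MULTIVARIATE = {"intercept": 1.256, "TP": -0.29, "CHLA": -0.112, "SD": -0.068}


def published_metas() -> dict[str, LakeMeta]:
    return {row["lake_id"]: LakeMeta(lake_id=row["lake_id"], name=row["lake_id"],
                                     lake_type=LakeType(row["lake_type"]))
            for row in GREEK_LAKES_2013_2015}
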