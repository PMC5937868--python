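"""Readers and writers for the tabular exchange formats.

All inputs are plain CSV (comma or semicolon separated, auto-detected,
decimal point mandatory):

* survey table — one row per plot observation:
  ``lake_id,transect_id,year,depth_zone,plot_index,taxon_id,dafor,c_max_m``
* taxa table — ``taxon_id,name,life_form,ltr,ellenberg_n`` (empty cell = absent)
* lake metadata — ``lake_id,name,lake_type``
* pressure table — one row per lake, columns as
  :class:`~helm_assess.core.PressureProfile`

Boundary sets load from YAML/JSON, or from the versioned builtin set
``builtin:helm2018`` holding the published class boundaries.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd
import yaml

from .core import (
    BoundaryScope,
    Dafor,
    DomainError,
    LakeMeta,
    LakeType,
    Metric,
    MetricBoundaries,
    Orientation,
    PlotObservation,
    PressureProfile,
    PressureThresholds,
    SchemaError,
    TaxonRecord,
    TransectSurvey,
    LifeForm,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

SURVEY_COLUMNS = ["lake_id", "transect_id", "year", "depth_zone", "plot_index", "taxon_id", "dafor", "c_max_m"]
TAXA_COLUMNS = ["taxon_id", "name", "life_form", "ltr", "ellenberg_n"]
META_COLUMNS = ["lake_id", "name", "lake_type"]
PRESSURE_COLUMNS = ["lake_id", "tp_ug_l", "chla_ug_l", "sd_m", "alu_pct", "ia_pct", "nasn_pct", "pd_h_km2"]

#: Published screening limits per lake type (TP, CHLA in ug/L; SD in m;
#: ALU, IA, NASN in % catchment; PD in inhabitants/km^2).
DEFAULT_PRESSURE_THRESHOLDS: dict[LakeType, PressureThresholds] = {
    LakeType.GR_DNL: PressureThresholds(LakeType.GR_DNL, tp_max=12, chla_max=2, sd_min=6,
                                        alu_max=4, ia_max=25, nasn_min=70, pd_max=30),
    LakeType.GR_SNL: PressureThresholds(LakeType.GR_SNL, tp_max=15, chla_max=5, sd_min=2,
                                        alu_max=4, ia_max=25, nasn_min=70, pd_max=30),
}


def builtin_boundaries_helm2018() -> list[MetricBoundaries]:
    """The published 2018 boundary set: one TIHeLM record common to both lake
    types and type-specific C_max records.  Reference values are medians of
    reference-site transect values; EQR boundaries are the published (2 dp)
    values, so published classifications reproduce exactly."""
    return [
        MetricBoundaries(
            metric=Metric.TIHELM, scope=BoundaryScope.BOTH_TYPES,
            orientation=Orientation.LOWER_IS_BETTER, reference_value=7.141,
            eqr_hg=0.94, eqr_gm=0.90, eqr_mp=0.82, eqr_pb=0.75, eqr_lower_anchor=0.675,
        ),
        MetricBoundaries(
            metric=Metric.CMAX, scope=BoundaryScope.GR_DNL,
            orientation=Orientation.HIGHER_IS_BETTER, reference_value=12.2,
            eqr_hg=0.89, eqr_gm=0.36, eqr_mp=0.24, eqr_pb=0.12, eqr_lower_anchor=0.0,
        ),
        MetricBoundaries(
            metric=Metric.CMAX, scope=BoundaryScope.GR_SNL,
            orientation=Orientation.HIGHER_IS_BETTER, reference_value=6.1,
            eqr_hg=0.69, eqr_gm=0.58, eqr_mp=0.39, eqr_pb=0.19, eqr_lower_anchor=0.0,
        ),
    ]


def _read_csv(path: PathLike, required: list[str], what: str) -> pd.DataFrame:
    try:
        # sep=None sniffs comma vs semicolon; decimal point is mandatory
        df = pd.read_csv(path, sep=None, engine="python", dtype=str, skipinitialspace=True)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise SchemaError(f"{what} table {path}: cannot parse CSV ({exc})") from exc
    df.columns = [str(c).strip() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table {path}: missing required column(s) {missing}")
    return df


def _opt_float(token, where: str) -> Optional[float]:
    if token is None or (isinstance(token, float) and math.isnan(token)):
        return None
    s = str(token).strip()
    if s == "" or s.lower() in ("na", "nan", "none"):
        return None
    try:
        return float(s)
    except ValueError:
        raise SchemaError(f"{where}: cannot parse number {token!r}") from None


def read_taxa(path: PathLike) -> dict[str, TaxonRecord]:
    """Read a taxa table into a mapping taxon_id -> TaxonRecord."""
    df = _read_csv(path, ["taxon_id"], "taxa")
    taxa: dict[str, TaxonRecord] = {}
    for i, row in df.iterrows():
        tid = str(row["taxon_id"]).strip()
        lf_token = str(row.get("life_form", "") or "other").strip().lower()
        try:
            lf = LifeForm(lf_token) if lf_token else LifeForm.OTHER
        except ValueError:
            raise SchemaError(f"taxa row {i + 2}: unknown life form {lf_token!r}") from None
        rec = TaxonRecord(
            taxon_id=tid,
            name=str(row.get("name", tid) or tid),
            life_form=lf,
            ltr=_opt_float(row.get("ltr"), f"taxa row {i + 2} (taxon {tid})"),
            ellenberg_n=_opt_float(row.get("ellenberg_n"), f"taxa row {i + 2} (taxon {tid})"),
        )
        taxa[tid] = rec
    return taxa


def read_surveys(path: PathLike, taxa: Optional[Mapping[str, TaxonRecord]] = None) -> list[TransectSurvey]:
    """Read a plot-level survey table, grouped into per-(lake, transect, year)
    :class:`TransectSurvey` records.

    Unknown taxon ids (when ``taxa`` is given) are reported via a warning but
    kept — they are excluded later, at scoring time.  The per-transect
    ``c_max_m`` must be constant within a transect group.
    """
    df = _read_csv(path, SURVEY_COLUMNS, "survey")
    if df.empty:
        logger.warning("survey table %s contains a header but no rows", path)
        return []

    surveys: dict[tuple[str, str, int], TransectSurvey] = {}
    unknown: set[str] = set()
    for i, row in df.iterrows():
        where = f"survey row {i + 2}"
        try:
            year = int(str(row["year"]).strip())
            plot_index = int(str(row["plot_index"]).strip())
        except ValueError:
            raise SchemaError(f"{where}: year/plot_index must be integers") from None
        try:
            abundance = Dafor.from_token(row["dafor"])
        except DomainError as exc:
            raise SchemaError(f"{where}: {exc}") from None
        cmax = _opt_float(row["c_max_m"], where)
        if cmax is None:
            raise SchemaError(f"{where}: c_max_m is required")
        obs = PlotObservation(
            lake_id=str(row["lake_id"]).strip(),
            transect_id=str(row["transect_id"]).strip(),
            year=year,
            depth_zone=str(row["depth_zone"]),
            plot_index=plot_index,
            taxon_id=str(row["taxon_id"]).strip(),
            abundance=abundance,
        )
        if taxa is not None and obs.taxon_id not in taxa:
            unknown.add(obs.taxon_id)
        key = (obs.lake_id, obs.transect_id, obs.year)
        if key not in surveys:
            surveys[key] = TransectSurvey(*key, observations=[], c_max_m=cmax)
        else:
            if abs(surveys[key].c_max_m - cmax) > 1e-9:
                raise SchemaError(
                    f"{where}: c_max_m={cmax} conflicts with earlier value "
                    f"{surveys[key].c_max_m} for transect {key}"
                )
        surveys[key].observations.append(obs)
    if unknown:
        logger.warning("survey table %s references %d taxon id(s) absent from the taxa table: %s",
                       path, len(unknown), sorted(unknown))
    return list(surveys.values())


def write_surveys(surveys: Iterable[TransectSurvey], path: PathLike) -> None:
    rows = []
    for s in surveys:
        if not s.observations:
            # keep vegetation-free transects representable: emit nothing
            continue
        for o in s.observations:
            rows.append({
                "lake_id": o.lake_id, "transect_id": o.transect_id, "year": o.year,
                "depth_zone": o.depth_zone, "plot_index": o.plot_index,
                "taxon_id": o.taxon_id, "dafor": o.abundance.name.lower(),
                "c_max_m": s.c_max_m,
            })
    pd.DataFrame(rows, columns=SURVEY_COLUMNS).to_csv(path, index=False)


def write_taxa(taxa: Mapping[str, TaxonRecord], path: PathLike) -> None:
    rows = [{
        "taxon_id": t.taxon_id, "name": t.name, "life_form": t.life_form.value,
        "ltr": "" if t.ltr is None else t.ltr,
        "ellenberg_n": "" if t.ellenberg_n is None else t.ellenberg_n,
    } for t in taxa.values()]
    pd.DataFrame(rows, columns=TAXA_COLUMNS).to_csv(path, index=False)


def read_meta(path: PathLike) -> dict[str, LakeMeta]:
    df = _read_csv(path, META_COLUMNS, "lake metadata")
    metas = {}
    for i, row in df.iterrows():
        lid = str(row["lake_id"]).strip()
        metas[lid] = LakeMeta(lake_id=lid, name=str(row["name"]),
                              lake_type=LakeType.from_token(row["lake_type"]))
    return metas


def write_meta(metas: Mapping[str, LakeMeta], path: PathLike) -> None:
    rows = [{"lake_id": m.lake_id, "name": m.name, "lake_type": m.lake_type.value}
            for m in metas.values()]
    pd.DataFrame(rows, columns=META_COLUMNS).to_csv(path, index=False)


def read_pressures(path: PathLike) -> dict[str, PressureProfile]:
    df = _read_csv(path, ["lake_id"], "pressure")
    profiles = {}
    for i, row in df.iterrows():
        lid = str(row["lake_id"]).strip()
        kwargs = {c: _opt_float(row.get(c), f"pressure row {i + 2} ({c})")
                  for c in PRESSURE_COLUMNS[1:]}
        profiles[lid] = PressureProfile(lake_id=lid, **kwargs)
    return profiles


def write_pressures(profiles: Mapping[str, PressureProfile], path: PathLike) -> None:
    rows = []
    for p in profiles.values():
        row = {"lake_id": p.lake_id}
        for c in PRESSURE_COLUMNS[1:]:
            v = getattr(p, c)
            row[c] = "" if v is None else v
        rows.append(row)
    pd.DataFrame(rows, columns=PRESSURE_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# boundary configuration

def _boundaries_from_mapping(entry: Mapping) -> MetricBoundaries:
    try:
        return MetricBoundaries(
            metric=Metric(entry["metric"]),
            scope=BoundaryScope(entry["scope"]),
            orientation=Orientation(entry["orientation"]),
            reference_value=float(entry["reference_value"]),
            eqr_hg=float(entry["eqr_hg"]),
            eqr_gm=float(entry["eqr_gm"]),
            eqr_mp=float(entry["eqr_mp"]),
            eqr_pb=float(entry["eqr_pb"]),
            eqr_lower_anchor=float(entry["eqr_lower_anchor"]),
        )
    except KeyError as exc:
        raise SchemaError(f"boundary entry missing field {exc}") from None
    except ValueError as exc:
        raise SchemaError(f"boundary entry: {exc}") from None


def load_boundaries(source: PathLike) -> list[MetricBoundaries]:
    """Load a boundary set from a YAML/JSON file, or the sentinel
    ``builtin:helm2018`` for the published set."""
    if str(source) == "builtin:helm2018":
        return builtin_boundaries_helm2018()
    if str(source).startswith("builtin:"):
        raise SchemaError(f"unknown builtin boundary set {source!r} (available: builtin:helm2018)")
    path = Path(source)
    text = path.read_text()
    payload = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if isinstance(payload, Mapping) and "boundaries" in payload:
        payload = payload["boundaries"]
    if not isinstance(payload, list):
        raise SchemaError(f"boundary config {source}: expected a list of boundary entries")
    return [_boundaries_from_mapping(e) for e in payload]


def write_boundaries(boundaries: Iterable[MetricBoundaries], path: PathLike) -> None:
    entries = [{
        "metric": b.metric.value, "scope": b.scope.value, "orientation": b.orientation.value,
        "reference_value": float(b.reference_value),
        "eqr_hg": float(b.eqr_hg), "eqr_gm": float(b.eqr_gm),
        "eqr_mp": float(b.eqr_mp), "eqr_pb": float(b.eqr_pb),
        "eqr_lower_anchor": float(b.eqr_lower_anchor),
    } for b in boundaries]
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps({"boundaries": entries}, indent=2))
    else:
        path.write_text(yaml.safe_dump({"boundaries": entries}, sort_keys=False))


def select_boundaries(boundaries: Iterable[MetricBoundaries], metric: Metric,
                      lake_type: LakeType) -> MetricBoundaries:
    """Pick the boundary record applying to a metric and lake type; a
    type-specific record takes precedence over a both-types one."""
    candidates = [b for b in boundaries if b.metric is metric and b.scope.applies_to(lake_type)]
    if not candidates:
        raise DomainError(f"no boundary set for metric {metric.value} and lake type {lake_type.value}")
    specific = [b for b in candidates if b.scope is not BoundaryScope.BOTH_TYPES]
    return specific[0] if specific else candidates[0]
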