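import math

import numpy as np
import pytest

from helm_assess.core import Dafor, DomainError, LifeForm, TaxonRecord
from helm_assess.performance import (
    LifeFormProfile,
    RegressionSpec,
    fit_multivariate,
    fit_pressure_regression,
    lifeform_profile,
    lifeform_trend,
)
from helm_assess.published import PUBLISHED_MULTIVARIATE, PUBLISHED_REGRESSIONS

from conftest import make_survey

TP = np.logspace(np.log10(5), np.log10(150), 16)


def synth_response(reg, x):
    """Raw metric values generated exactly from a published fitted equation."""
    t = reg["intercept"] + reg["slope"] * np.log10(x)
    if reg["transform"] == "log10":
        return 10 ** t
    if reg["transform"] == "sqrt":
        return t ** 2
    return t


@pytest.mark.parametrize("reg", PUBLISHED_REGRESSIONS,
                         ids=lambda r: f"{r['response']}-{r['predictor']}")
def test_noiseless_fit_recovers_generating_equation(reg):
    x = TP if reg["predictor"] != "SD" else np.linspace(0.5, 10, 16)
    y = synth_response(reg, x)
    res = fit_pressure_regression(y, x, RegressionSpec(reg["response"], (reg["predictor"],)))
    assert res.r2 == pytest.approx(1.0, abs=1e-9)
    assert res.slopes[reg["predictor"]] == pytest.approx(reg["slope"], abs=1e-9)
    assert res.intercept == pytest.approx(reg["intercept"], abs=1e-9)
    assert abs(res.r) == pytest.approx(1.0, abs=1e-9)


def test_noisy_fit_recovers_slope_within_tolerance():
    rng = np.random.default_rng(20180101)
    reg = next(r for r in PUBLISHED_REGRESSIONS
               if r["response"] == "Cmax" and r["predictor"] == "CHLA")
    x = np.logspace(np.log10(0.5), np.log10(100), 200)
    t = reg["intercept"] + reg["slope"] * np.log10(x) + rng.normal(0, 0.05, size=200)
    y = np.clip(t, 0, None) ** 2
    res = fit_pressure_regression(y, x, RegressionSpec("Cmax", ("CHLA",)))
    assert res.slopes["CHLA"] == pytest.approx(reg["slope"], abs=0.05)


def test_r_sign_matches_slope_and_r2_equals_squared_pearson():
    rng = np.random.default_rng(3)
    x = np.logspace(0.5, 2, 30)
    y = 2.0 - 0.5 * np.log10(x) + rng.normal(0, 0.02, 30)
    res = fit_pressure_regression(y, x, RegressionSpec("HeLM", ("TP",), "none"))
    pearson = np.corrcoef(np.log10(x), y)[0, 1]
    assert res.r < 0 and np.sign(res.r) == np.sign(res.slopes["TP"])
    assert res.r2 == pytest.approx(pearson ** 2, abs=1e-12)
    assert res.well_performing


def test_constant_response_not_well_performing():
    res = fit_pressure_regression([0.7] * 10, TP[:10], RegressionSpec("HeLM", ("TP",), "none"))
    assert res.r2 == 0.0 and not res.well_performing


def test_too_few_lakes_rejected():
    with pytest.raises(DomainError):
        fit_pressure_regression([1.0, 2.0], [10.0, 20.0], RegressionSpec("HeLM", ("TP",), "none"))


def test_zero_variance_predictor_rejected():
    with pytest.raises(DomainError, match="variance"):
        fit_pressure_regression([1.0, 2.0, 3.0], [10.0, 10.0, 10.0],
                                RegressionSpec("HeLM", ("TP",), "none"))


def test_nonpositive_pressure_rows_excluded(caplog):
    with caplog.at_level("WARNING"):
        res = fit_pressure_regression([1, 2, 3, 4], [10.0, 20.0, 40.0, 0.0],
                                      RegressionSpec("HeLM", ("TP",), "none"))
    assert res.n == 3
    assert any("non-positive" in r.message for r in caplog.records)


def test_multivariate_noiseless_recovery():
    rng = np.random.default_rng(11)
    tp = rng.uniform(5, 150, 16)
    chla = rng.uniform(0.5, 100, 16)
    sd = rng.uniform(0.3, 10, 16)
    m = PUBLISHED_MULTIVARIATE
    y = (m["intercept"] + m["TP"] * np.log10(tp) + m["CHLA"] * np.log10(chla)
         + m["SD"] * np.log10(sd))
    res = fit_multivariate(y, tp, chla, sd)
    assert res.intercept == pytest.approx(m["intercept"], abs=1e-9)
    for name in ("TP", "CHLA", "SD"):
        assert res.slopes[name] == pytest.approx(m[name], abs=1e-9)
    assert res.r2 == pytest.approx(1.0, abs=1e-9)


def test_multivariate_orthogonal_predictor_gets_zero_slope():
    # response built from TP alone: CHLA and SD slopes vanish
    rng = np.random.default_rng(5)
    tp = np.logspace(1, 2, 16)
    chla = rng.permutation(np.logspace(0, 1, 16))
    sd = rng.permutation(np.logspace(-0.5, 1, 16))
    y = 1.0 - 0.4 * np.log10(tp)
    res = fit_multivariate(y, tp, chla, sd)
    assert res.slopes["TP"] == pytest.approx(-0.4, abs=1e-9)
    assert res.slopes["CHLA"] == pytest.approx(0.0, abs=1e-9)
    assert res.slopes["SD"] == pytest.approx(0.0, abs=1e-9)


def test_multivariate_duplicated_predictor_rejected():
    tp = np.logspace(1, 2, 16)
    with pytest.raises(DomainError, match="collinear"):
        fit_multivariate(np.linspace(0, 1, 16), tp, tp, np.logspace(0, 1, 16))


# --- life-form profiles -----------------------------------------------------

ELO = TaxonRecord("elo", "elo", LifeForm.ELODEID, ltr=5.0)
HEL = TaxonRecord("hel", "hel", LifeForm.HELOPHYTE, ltr=9.0)
LEM = TaxonRecord("lem", "lem", LifeForm.LEMNID, ltr=9.5)
TAXA = {"elo": ELO, "hel": HEL, "lem": LEM}


def test_single_lifeform_profile_is_unity():
    p = lifeform_profile([make_survey([("elo", Dafor.FREQUENT)])], TAXA)
    assert p.relative_abundance == {LifeForm.ELODEID: 1.0}


def test_equal_covers_split_evenly():
    p = lifeform_profile([make_survey([("elo", Dafor.ABUNDANT), ("hel", Dafor.ABUNDANT)])], TAXA)
    assert p.relative_abundance[LifeForm.ELODEID] == pytest.approx(0.5)
    assert p.relative_abundance[LifeForm.HELOPHYTE] == pytest.approx(0.5)


def test_profile_hand_computed_shares():
    # dominant elodeid (87.5) + rare lemnid (0.5): shares out of 88.0
    p = lifeform_profile([make_survey([("elo", Dafor.DOMINANT), ("lem", Dafor.RARE)])], TAXA)
    assert p.relative_abundance[LifeForm.ELODEID] == pytest.approx(87.5 / 88.0)
    assert p.relative_abundance[LifeForm.LEMNID] == pytest.approx(0.5 / 88.0)


def test_profile_sums_to_one():
    p = lifeform_profile([make_survey([("elo", Dafor.DOMINANT), ("hel", Dafor.FREQUENT),
                                       ("lem", Dafor.OCCASIONAL)])], TAXA)
    assert sum(p.relative_abundance.values()) == pytest.approx(1.0, abs=1e-9)


def test_profile_all_unknown_lifeforms_empty(caplog):
    taxa = {"x": TaxonRecord("x", "x", LifeForm.OTHER)}
    with caplog.at_level("WARNING"):
        p = lifeform_profile([make_survey([("x", Dafor.DOMINANT)])], taxa)
    assert p.relative_abundance == {}


def test_lifeform_trend_sign_on_monotone_decline():
    scores = np.linspace(0.1, 1.0, 8)
    profiles = [LifeFormProfile(f"L{i}", {LifeForm.ELODEID: a, LifeForm.HELOPHYTE: 1 - a})
                for i, a in enumerate(np.linspace(0.05, 0.95, 8))]
    trends = lifeform_trend(profiles, scores, degree=1)
    # elodeid share rises with the (quality) score; helophyte share falls
    assert trends[LifeForm.ELODEID].coefficients[0] > 0
    assert trends[LifeForm.HELOPHYTE].coefficients[0] < 0


def test_lifeform_trend_degree_zero_is_mean_line():
    profiles = [LifeFormProfile(f"L{i}", {LifeForm.CHARID: 0.25}) for i in range(5)]
    trends = lifeform_trend(profiles, [0.1, 0.3, 0.5, 0.7, 0.9], degree=0)
    assert trends[LifeForm.CHARID].coefficients[0] == pytest.approx(math.sqrt(0.25))


def test_lifeform_trend_constant_data_has_flat_quadratic():
    profiles = [LifeFormProfile(f"L{i}", {LifeForm.CHARID: 0.36}) for i in range(6)]
    trends = lifeform_trend(profiles, np.linspace(0, 1, 6), degree=2)
    quad, lin, _ = trends[LifeForm.CHARID].coefficients
    assert abs(quad) < 1e-8 and abs(lin) < 1e-8


def test_lifeform_trend_insufficient_points_skipped(caplog):
    profiles = [LifeFormProfile("L1", {LifeForm.NYMPHAEID: 0.5}),
                LifeFormProfile("L2", {LifeForm.NYMPHAEID: 0.4})]
    with caplog.at_level("WARNING"):
        trends = lifeform_trend(profiles, [0.2, 0.8], degree=2)
    assert LifeForm.NYMPHAEID not in trends
    assert any("skipped" in r.message for r in caplog.records)
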