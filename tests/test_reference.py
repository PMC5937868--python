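import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from helm_assess.core import (
    BoundaryScope,
    DomainError,
    LakeMeta,
    LakeType,
    Metric,
    Orientation,
    PressureProfile,
)
from helm_assess.published import REFERENCE_LAKE_PRESSURES, REFERENCE_LAKE_TYPES
from helm_assess.reference import (
    derive_boundaries,
    flag_outlier_transects,
    raw_boundary,
    screen_reference,
)

# indicator attribute -> a value violating its criterion (both lake types)
VIOLATIONS = {
    "tp_ug_l": 20.0, "chla_ug_l": 6.0, "sd_m": 1.0, "alu_pct": 5.0,
    "ia_pct": 30.0, "nasn_pct": 50.0, "pd_h_km2": 40.0,
}


def meta_for(lake_id):
    return LakeMeta(lake_id=lake_id, name=lake_id, lake_type=REFERENCE_LAKE_TYPES[lake_id])


@pytest.mark.parametrize("profile", REFERENCE_LAKE_PRESSURES, ids=lambda p: p.lake_id)
def test_published_reference_lakes_pass_screening(profile):
    res = screen_reference(profile, meta_for(profile.lake_id))
    assert res.passed and res.failed_criteria == ()


@pytest.mark.parametrize("attr", sorted(VIOLATIONS))
def test_perturbing_any_single_indicator_fails_screening(attr):
    # conjunctive screening: one bad criterion disqualifies the lake
    for profile in REFERENCE_LAKE_PRESSURES:
        bad = dataclasses.replace(profile, **{attr: VIOLATIONS[attr]})
        res = screen_reference(bad, meta_for(profile.lake_id))
        assert not res.passed
        assert len(res.failed_criteria) == 1


def test_threshold_comparisons_are_strict():
    # a lake sitting exactly on a limit does not pass
    feneos = next(p for p in REFERENCE_LAKE_PRESSURES if p.lake_id == "Feneos")
    on_limit = dataclasses.replace(feneos, pd_h_km2=30.0)
    res = screen_reference(on_limit, meta_for("Feneos"))
    assert not res.passed and res.failed_criteria == ("PD",)


def test_missing_indicator_not_evaluable_blocks_pass():
    profile = PressureProfile(lake_id="X", tp_ug_l=5.0, chla_ug_l=1.0, sd_m=8.0,
                              alu_pct=1.0, ia_pct=1.0, nasn_pct=90.0, pd_h_km2=None)
    meta = LakeMeta(lake_id="X", name="X", lake_type=LakeType.GR_DNL)
    res = screen_reference(profile, meta)
    assert not res.passed
    assert res.failed_criteria == ("PD (not evaluable)",)


def test_type_mismatched_thresholds_rejected():
    from helm_assess.io import DEFAULT_PRESSURE_THRESHOLDS
    feneos = next(p for p in REFERENCE_LAKE_PRESSURES if p.lake_id == "Feneos")
    with pytest.raises(DomainError):
        screen_reference(feneos, meta_for("Feneos"),
                         DEFAULT_PRESSURE_THRESHOLDS[LakeType.GR_SNL])


# --- outlier disqualification ---------------------------------------------

def test_tukey_flags_high_outlier():
    flags = flag_outlier_transects([7.0, 7.1, 7.2, 7.1, 12.0])
    assert flags == [False, False, False, False, True]


def test_tukey_constant_vector_no_flags():
    assert flag_outlier_transects([5.0] * 6) == [False] * 6


def test_tukey_small_symmetric_set_no_flags():
    # Q1=1.75, Q3=3.25, fences [-0.5, 5.5]
    assert flag_outlier_transects([1, 2, 3, 4]) == [False] * 4


def test_tukey_too_few_values_warns_and_passes_all(caplog):
    with caplog.at_level("WARNING"):
        assert flag_outlier_transects([1.0, 99.0]) == [False, False]
    assert any("too few" in r.message for r in caplog.records)


# --- boundary derivation ----------------------------------------------------

def test_derive_boundaries_published_cmax_snl_arithmetic():
    # reference values whose median is 6.1 and lower-tail P90 is 4.21 give
    # the published shallow-lake H/G boundary 4.21/6.1 = 0.69
    ref = [4.0, 4.2333, 5.7, 6.0, 6.1, 6.1, 6.3, 6.8, 7.0, 7.4]
    assert np.median(ref) == pytest.approx(6.1)
    # quantile(ref, 0.10) = 4.0 + 0.9 * 0.2333 = 4.21 under type-7 interpolation
    b = derive_boundaries(ref, [3.0, 3.5, 3.6, 3.8], Metric.CMAX,
                          Orientation.HIGHER_IS_BETTER, BoundaryScope.GR_SNL)
    assert b.reference_value == pytest.approx(6.1)
    assert b.eqr_hg == pytest.approx(4.21 / 6.1, abs=2e-3)


def test_derive_boundaries_equal_trisection_higher_is_better():
    # G/M at 0.58 trisects down to 0: M/P 0.39, P/B 0.19 (2 dp)
    ref = [6.1] * 10
    ref[-1] = 6.2  # avoid zero-variance degeneracy in H/G
    tpg = [3.54] * 5
    b = derive_boundaries(ref, tpg, Metric.CMAX, Orientation.HIGHER_IS_BETTER,
                          BoundaryScope.GR_SNL)
    assert b.eqr_gm == pytest.approx(3.54 / np.median(ref), abs=1e-9)
    assert round(b.eqr_mp, 2) == 0.39
    assert round(b.eqr_pb, 2) == 0.19
    assert b.eqr_lower_anchor == 0.0


def test_derive_boundaries_median_reference():
    b = derive_boundaries([10, 11, 12, 13, 14], [20, 21, 22, 23], Metric.TIHELM,
                          Orientation.LOWER_IS_BETTER)
    assert b.reference_value == 12


def test_derive_boundaries_equal_division_property():
    b = derive_boundaries([7.0, 7.1, 7.2, 7.3, 7.4], [8.0, 8.2, 8.4, 8.6],
                          Metric.TIHELM, Orientation.LOWER_IS_BETTER)
    steps = (b.eqr_gm - b.eqr_mp, b.eqr_mp - b.eqr_pb, b.eqr_pb - b.eqr_lower_anchor)
    assert steps[0] == pytest.approx(steps[1], abs=1e-12)
    assert steps[1] == pytest.approx(steps[2], abs=1e-12)


def test_derive_boundaries_inconsistent_data_raises():
    # TP-group sites better than reference sites: H/G not above G/M
    with pytest.raises(DomainError, match="inconsistent"):
        derive_boundaries([5.0, 5.5, 6.0, 6.5], [1.0, 1.1, 1.2], Metric.TIHELM,
                          Orientation.LOWER_IS_BETTER)


def test_derive_boundaries_empty_inputs_rejected():
    with pytest.raises(DomainError):
        derive_boundaries([], [1.0], Metric.CMAX, Orientation.HIGHER_IS_BETTER)
    with pytest.raises(DomainError):
        derive_boundaries([1.0], [], Metric.CMAX, Orientation.HIGHER_IS_BETTER)


@given(st.lists(st.floats(min_value=5.0, max_value=15.0), min_size=4, max_size=30),
       st.lists(st.floats(min_value=1.0, max_value=4.0), min_size=4, max_size=30))
def test_derived_boundaries_always_satisfy_ordering(ref, tpg):
    # higher-is-better with degraded TP-group: output ordered or a clean error
    try:
        b = derive_boundaries(ref, tpg, Metric.CMAX, Orientation.HIGHER_IS_BETTER)
    except DomainError:
        return
    assert 1 >= b.eqr_hg > b.eqr_gm > b.eqr_mp > b.eqr_pb > b.eqr_lower_anchor >= 0


def test_degraded_site_added_to_tp_group_worsens_gm_boundary():
    ref = [10.0, 11.0, 12.0, 13.0, 14.0]
    tpg = [6.0, 6.5, 7.0, 7.5]
    base = derive_boundaries(ref, tpg, Metric.CMAX, Orientation.HIGHER_IS_BETTER)
    worse = derive_boundaries(ref, tpg + [2.0], Metric.CMAX, Orientation.HIGHER_IS_BETTER)
    assert worse.eqr_gm <= base.eqr_gm + 1e-12


def test_raw_boundary_inverts_eqr():
    from helm_assess.io import builtin_boundaries_helm2018
    for b in builtin_boundaries_helm2018():
        raw = raw_boundary(b.eqr_hg, b)
        if b.orientation is Orientation.HIGHER_IS_BETTER:
            assert raw / b.reference_value == pytest.approx(b.eqr_hg)
        else:
            assert b.reference_value / raw == pytest.approx(b.eqr_hg)
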