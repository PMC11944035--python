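"""Piecewise-linear ligament model: stiffness table, force law, regional
totals and the failure-threshold annotation."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cervdisc import (
    FAILURE_THRESHOLDS_N,
    DomainError,
    Ligament,
    LigamentSpec,
    Region,
    calibrate_uniform_strain,
    failure_margins,
    ligament_force,
    load_ligament_table,
    total_ligament_force,
)
from cervdisc.ligaments import stiffness_at

NBP1G_TOTALS = {Ligament.ALL: 38.46, Ligament.PLL: 59.95, Ligament.LF: 41.86}
NBP0G_TOTALS = {Ligament.ALL: 92.76, Ligament.PLL: 183.26, Ligament.LF: 85.97}


@pytest.fixture(scope="module")
def specs():
    return load_ligament_table()


def test_packaged_table_reproduces_cadaveric_stiffness(specs):
    by_key = {(s.ligament, s.region): s for s in specs}
    assert len(specs) == 6
    assert by_key[(Ligament.ALL, Region.C2C5)].stiffness == 16.0
    assert by_key[(Ligament.ALL, Region.C5T1)].stiffness == 17.9
    assert by_key[(Ligament.PLL, Region.C2C5)].stiffness == 25.4
    assert by_key[(Ligament.PLL, Region.C5T1)].stiffness == 23.0
    assert by_key[(Ligament.LF, Region.C2C5)].stiffness == 25.0
    assert by_key[(Ligament.LF, Region.C5T1)].stiffness == 21.6
    # the LF C5-T1 strain range is stored in ascending order
    lf = by_key[(Ligament.LF, Region.C5T1)]
    assert (lf.strain_lo, lf.strain_hi) == (75.3, 101.5)


def test_spec_rejects_unordered_strain_bounds():
    with pytest.raises(ValueError, match="ordered"):
        LigamentSpec(
            ligament=Ligament.LF, region=Region.C5T1,
            stiffness=21.6, strain_lo=101.5, strain_hi=75.3,
        )


def test_slack_ligament_carries_no_force(specs):
    for spec in specs:
        assert ligament_force(spec.slack_strain, spec) == 0.0


def test_force_at_thirty_percent_strain_hand_oracle(specs):
    # 30% of a 20 mm ligament = 6 mm elongation at 16 N/mm
    all_c2c5 = next(s for s in specs if (s.ligament, s.region) == (Ligament.ALL, Region.C2C5))
    assert ligament_force(30.0, all_c2c5) == pytest.approx(16.0 * 6.0, rel=1e-12)


def test_negative_strain_rejected(specs):
    with pytest.raises(DomainError):
        ligament_force(-1.0, specs[0])


@given(st.floats(0.0, 150.0), st.floats(0.0, 150.0))
def test_force_monotone_in_strain(e1, e2):
    specs = load_ligament_table()
    lo, hi = sorted((e1, e2))
    for spec in specs:
        assert ligament_force(lo, spec) <= ligament_force(hi, spec) + 1e-12


def test_linearity_within_a_segment(specs):
    spec = specs[0]  # slack 0, single segment
    assert ligament_force(20.0, spec) == pytest.approx(2 * ligament_force(10.0, spec), rel=1e-12)


def test_force_continuous_across_multi_segment_gap():
    # synthetic two-segment ligament with a stiffness jump bridged by
    # interpolation over the gap
    segs = [
        LigamentSpec(ligament=Ligament.ALL, region=Region.C2C5,
                     stiffness=10.0, strain_lo=10.0, strain_hi=20.0),
        LigamentSpec(ligament=Ligament.ALL, region=Region.C2C5,
                     stiffness=30.0, strain_lo=30.0, strain_hi=40.0),
    ]
    for boundary in (10.0, 20.0, 30.0, 40.0):
        below = ligament_force(boundary - 1e-7, segs)
        above = ligament_force(boundary + 1e-7, segs)
        assert abs(above - below) < 1e-3  # continuous, slope bounded
    assert stiffness_at(25.0, segs) == pytest.approx(20.0)
    assert stiffness_at(5.0, segs) == 10.0
    assert stiffness_at(50.0, segs) == 30.0


def test_packaged_fixture_force_continuity_at_boundaries(specs):
    for spec in specs:
        for edge in (spec.strain_lo, spec.strain_hi):
            f_lo = ligament_force(edge - 1e-11, spec)
            f_hi = ligament_force(edge + 1e-11, spec)
            assert abs(f_hi - f_lo) < 1e-9


def test_totals_all_slack_are_zero(specs):
    strains = {(s.ligament, s.region): 0.0 for s in specs}
    totals = total_ligament_force(strains, specs)
    assert set(totals.values()) == {0.0}


def test_totals_missing_region_is_validation_error(specs):
    strains = {(s.ligament, s.region): 10.0 for s in specs}
    strains.pop((Ligament.LF, Region.C5T1))
    with pytest.raises(ValueError, match="missing strain"):
        total_ligament_force(strains, specs)


def test_totals_double_elongation_doubles_force(specs):
    s1 = {(s.ligament, s.region): 8.0 for s in specs}
    s2 = {(s.ligament, s.region): 16.0 for s in specs}
    t1 = total_ligament_force(s1, specs)
    t2 = total_ligament_force(s2, specs)
    for lig in t1:
        assert t2[lig] == pytest.approx(2 * t1[lig], rel=1e-12)


def test_calibrated_strains_reproduce_reference_totals(specs):
    # the reported 1 g totals are a calibration target, not a prediction:
    # a uniform regional strain exists that reproduces each total exactly
    for lig, target in NBP1G_TOTALS.items():
        strain = calibrate_uniform_strain(lig, target, specs)
        strains = {(lig, region): strain for region in Region}
        segs = [s for s in specs if s.ligament == lig]
        assert total_ligament_force(strains, segs)[lig] == pytest.approx(target, abs=1e-8)


def test_microgravity_totals_stay_below_failure_thresholds():
    margins = failure_margins(NBP0G_TOTALS)
    assert all(info["below_failure"] for info in margins.values())
    assert margins[Ligament.ALL]["threshold_N"] == FAILURE_THRESHOLDS_N[Ligament.ALL]
    assert margins[Ligament.PLL]["margin_N"] == pytest.approx(462.9 - 183.26)
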