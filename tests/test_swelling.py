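"""Donnan swelling model: dilution, pressure, water-content updates and the
load-height equilibrium solver."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cervdisc import (
    BracketingError,
    DomainError,
    OsmoticConstants,
    attainable_force_range,
    deformed_water_content,
    disc_swelling_stress,
    donnan_pressure,
    fixed_charge_density,
    height_ratio_from_water_content,
    partition_water_content,
    solve_equilibrium,
    solve_equilibrium_many,
)

# Frozen from independent closed-form evaluation of the dilution and
# Donnan expressions (one-line oracles, evaluated before the solver existed).
FCD_AT_R3_1P1 = 221.26436781609195  # 250 * 0.77 / 0.87
P_AT_CF_150 = 91.31266921460052  # kPa, 8.3144 * 310.15 * 150 * (sqrt(5) - 2) / 1e3
PHI_077_R105 = 0.8013173523377606
PHI_NP_R105 = 0.8272324802937049
PHI_AF_R105 = 0.784040600367131


class TestFixedChargeDensity:
    def test_reference_state_has_no_dilution(self):
        assert fixed_charge_density(250.0, 0.77, 1.0) == pytest.approx(250.0, rel=1e-14)

    def test_dilution_at_ten_percent_volume_gain(self):
        r = 1.1 ** (1.0 / 3.0)
        assert fixed_charge_density(250.0, 0.77, r) == pytest.approx(FCD_AT_R3_1P1, rel=1e-12)

    def test_water_volume_doubling_halves_fcd(self):
        phi0 = 0.77
        r = (1.0 + phi0) ** (1.0 / 3.0)  # phi0 + r^3 - 1 = 2 phi0
        assert fixed_charge_density(250.0, phi0, r) == pytest.approx(125.0, rel=1e-12)

    def test_domain_error_names_the_bound(self):
        with pytest.raises(DomainError, match=r"\(1 - phi0\)\^\(1/3\)"):
            fixed_charge_density(250.0, 0.77, 0.5)

    @given(st.floats(0.9, 1.5), st.floats(0.9, 1.5))
    def test_strictly_decreasing_in_height_ratio(self, r1, r2):
        if r1 == r2:
            return
        lo, hi = sorted((r1, r2))
        assert fixed_charge_density(250.0, 0.77, lo) > fixed_charge_density(250.0, 0.77, hi)


class TestDonnanPressure:
    def test_zero_fcd_means_zero_pressure(self, constants):
        assert donnan_pressure(0.0, constants) == 0.0

    def test_pressure_at_bath_concentration(self, constants):
        assert donnan_pressure(150.0, constants) == pytest.approx(P_AT_CF_150, rel=1e-12)

    def test_high_fcd_asymptote_is_ideal_gas_linear(self, constants):
        cF = 1e6
        ratio = donnan_pressure(cF, constants) * 1e3 / (constants.R * constants.T * cF)
        assert ratio == pytest.approx(1.0, abs=1e-3)

    def test_negative_fcd_rejected(self, constants):
        with pytest.raises(DomainError):
            donnan_pressure(-1.0, constants)

    @given(st.floats(1e-3, 500.0), st.floats(1e-3, 500.0))
    def test_positive_and_strictly_increasing(self, c1, c2):
        p1, p2 = donnan_pressure(c1), donnan_pressure(c2)
        assert p1 > 0.0
        if c1 < c2:
            assert p1 < p2


class TestWaterContent:
    @given(st.floats(0.05, 0.95))
    def test_identity_at_reference_height(self, phi0):
        assert deformed_water_content(phi0, 1.0) == pytest.approx(phi0, rel=1e-14)

    def test_swollen_value_against_hand_oracle(self):
        assert deformed_water_content(0.77, 1.05) == pytest.approx(PHI_077_R105, rel=1e-14)

    def test_pure_water_limit(self):
        assert deformed_water_content(0.77, 50.0) == pytest.approx(1.0, abs=1e-4)

    @given(st.floats(0.8, 2.0), st.floats(0.8, 2.0))
    def test_strictly_increasing_in_r(self, r1, r2):
        if r1 == r2:
            return
        lo, hi = sorted((r1, r2))
        assert deformed_water_content(0.77, lo) < deformed_water_content(0.77, hi)

    @given(st.floats(0.85, 1.8))
    def test_inverse_recovers_height_ratio(self, r):
        phi = deformed_water_content(0.77, r)
        assert height_ratio_from_water_content(phi, 0.77) == pytest.approx(r, abs=1e-10)

    def test_domain_violation_raises(self):
        with pytest.raises(DomainError):
            deformed_water_content(0.2, 0.5)


class TestPartition:
    def test_reference_state_partition(self, ref_c2c3):
        phi_np, phi_af, phi = partition_water_content(1.0, ref_c2c3)
        assert (phi_np, phi_af) == pytest.approx((0.80, 0.75), rel=1e-14)
        assert phi == pytest.approx(0.77, rel=1e-14)

    def test_swollen_partition_against_hand_oracle(self, ref_c2c3):
        phi_np, phi_af, _ = partition_water_content(1.05, ref_c2c3)
        assert phi_np == pytest.approx(PHI_NP_R105, rel=1e-14)
        assert phi_af == pytest.approx(PHI_AF_R105, rel=1e-14)

    @given(st.floats(0.75, 2.5))
    def test_mixture_identity_exact(self, r):
        from cervdisc import load_reference_table

        ref = load_reference_table()[0]
        phi_np, phi_af, phi = partition_water_content(r, ref)
        mixed_ref = 0.4 * ref.phi0_NP + 0.6 * ref.phi0_AF
        assert phi == pytest.approx(0.4 * phi_np + 0.6 * phi_af, abs=1e-15)
        assert phi == pytest.approx(deformed_water_content(mixed_ref, r), abs=1e-12)


class TestSwellingStress:
    def test_reference_state_composition(self, ref_c2c3, constants):
        expect = 0.4 * donnan_pressure(250.0, constants) + 0.6 * donnan_pressure(200.0, constants)
        assert disc_swelling_stress(1.0, ref_c2c3, constants) == pytest.approx(expect, rel=1e-12)

    def test_independent_brute_force_oracle_at_reference(self, ref_c2c3, constants):
        # oracle written from the formulas directly, no shared code path
        import math

        def oracle(r):
            total = 0.0
            for frac, phi0, c0 in ((0.4, 0.80, 250.0), (0.6, 0.75, 200.0)):
                cf = c0 * phi0 / (phi0 + r**3 - 1.0)
                pa = 8.3144 * 310.15 * (math.sqrt(cf * cf + 4 * 150.0**2) - 300.0)
                total += frac * pa / 1e3
            return total

        for r in (0.9, 1.0, 1.2, 1.6):
            assert disc_swelling_stress(r, ref_c2c3, constants) == pytest.approx(oracle(r), rel=1e-12)

    def test_dilution_lowers_pressure(self, ref_c2c3):
        assert disc_swelling_stress(1.01, ref_c2c3) < disc_swelling_stress(1.0, ref_c2c3)


class TestEquilibrium:
    def test_self_consistency_at_reference_height(self, ref_c2c3, constants):
        f_at_1 = disc_swelling_stress(1.0, ref_c2c3, constants) * ref_c2c3.A0 * 1e-3
        sol = solve_equilibrium(f_at_1, ref_c2c3, constants)
        assert sol.r == pytest.approx(1.0, abs=1e-9)
        assert sol.residual <= 1e-10 * max(f_at_1, 1.0)

    def test_zero_load_reports_free_swelling_asymptote(self, ref_c2c3):
        with pytest.raises(BracketingError, match="free-swelling asymptote"):
            solve_equilibrium(0.0, ref_c2c3)

    def test_excessive_load_reports_attainable_interval(self, ref_c2c3):
        f_min, f_max = attainable_force_range(ref_c2c3)
        with pytest.raises(BracketingError, match="attainable range"):
            solve_equilibrium(f_max * 10, ref_c2c3)

    def test_unloading_swells_the_disc(self, ref_c2c3, constants):
        # reference loads for this level under 1 g vs microgravity float
        r_loaded = solve_equilibrium(91.83, ref_c2c3, constants).r
        r_unloaded = solve_equilibrium(21.5, ref_c2c3, constants).r
        assert r_unloaded > r_loaded

    def test_batch_solver_matches_scalar(self, ref_c2c3, constants):
        forces = np.array([10.0, 21.5, 50.0, 91.83])
        batch = solve_equilibrium_many(forces, ref_c2c3, constants)
        for f, r in zip(forces, batch):
            assert r == pytest.approx(solve_equilibrium(f, ref_c2c3, constants).r, abs=1e-10)

    def test_solver_agrees_with_grid_scan_oracle(self, refs, constants):
        # brute-force oracle: argmin |residual| on a dense height-ratio grid
        rng = np.random.default_rng(20251201)
        grid_n = 100_000
        for _ in range(10):
            ref = refs[rng.integers(0, len(refs))].model_copy(
                update={"c0F_NP": float(rng.uniform(100.0, 400.0))}
            )
            f_min, f_max = attainable_force_range(ref, constants)
            force = float(rng.uniform(max(f_min * 2, 1.0), min(f_max, 400.0)))
            lo = (1.0 - ref.phi0_AF) ** (1 / 3) * (1 + 1e-6)
            grid = np.linspace(lo, 3.0, grid_n)
            residual = disc_swelling_stress(grid, ref, constants) * ref.A0 * 1e-3 - force
            r_grid = grid[np.argmin(np.abs(residual))]
            r_solved = solve_equilibrium(force, ref, constants).r
            assert abs(r_solved - r_grid) <= (3.0 - lo) / (grid_n - 1)
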