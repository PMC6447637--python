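"""Four-state CaM partition function and competitive CTerm occupancy."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from camnav import (
    EVANS_SHEA,
    LINSE,
    CTermAffinityTable,
    LobeBindingEnergies,
    ThermoConstants,
    cam_fractions,
    cterm_occupancy,
    dominant_species,
    exact_occupancy,
    half_saturation,
    population_surface,
)

CONSTANTS = ThermoConstants()


def boltzmann_fractions(ca, dg_n, dg_c, rt):
    """Independent oracle: the four statistical weights written out directly."""
    kn, kc = math.exp(-dg_n / rt), math.exp(-dg_c / rt)
    w = [1.0, kn * ca**2, kc * ca**2, kn * kc * ca**4]
    z = sum(w)
    return [x / z for x in w]


class TestCamFractions:
    def test_zero_calcium_is_all_apo(self):
        f = cam_fractions(0.0)
        assert f.f_apo == 1.0 and f.f_2n == f.f_2c == f.f_4 == 0.0

    def test_half_saturation_splits_n_lobe_occupancy(self):
        ca_half = half_saturation(EVANS_SHEA.dg_n, CONSTANTS)
        f = cam_fractions(ca_half)
        # lobe independence: total N-lobe-loaded fraction is exactly 1/2
        assert f.f_2n + f.f_4 == pytest.approx(0.5, abs=1e-12)

    def test_c_lobe_loaded_dominates_at_10_uM(self):
        f = cam_fractions(10e-6)
        oracle = boltzmann_fractions(10e-6, EVANS_SHEA.dg_n, EVANS_SHEA.dg_c, CONSTANTS.rt)
        np.testing.assert_allclose(f.as_array(), oracle, rtol=1e-12)
        assert max(f.as_dict(), key=f.as_dict().get) == "2C"

    def test_negative_calcium_rejected(self):
        with pytest.raises(ValueError):
            cam_fractions(-1e-9)

    @given(
        log_ca=st.floats(min_value=-10, max_value=-2),
        dg_n=st.floats(min_value=-20, max_value=-5),
        dg_c=st.floats(min_value=-20, max_value=-5),
    )
    def test_fractions_normalized_and_in_range(self, log_ca, dg_n, dg_c):
        f = cam_fractions(10**log_ca, LobeBindingEnergies(dg_n, dg_c))
        arr = f.as_array()
        assert np.all(arr >= 0) and np.all(arr <= 1)
        assert arr.sum() == pytest.approx(1.0, abs=1e-12)

    def test_limits_and_monotonicity(self):
        grid = np.logspace(-9, -2, 100)
        f4 = np.array([cam_fractions(ca).f_4 for ca in grid])
        fapo = np.array([cam_fractions(ca).f_apo for ca in grid])
        assert np.all(np.diff(f4) >= 0)
        assert np.all(np.diff(fapo) <= 0)
        assert cam_fractions(1e-12).f_apo == pytest.approx(1.0, abs=1e-6)
        assert cam_fractions(1.0).f_4 == pytest.approx(1.0, abs=1e-6)

    @given(log_ca=st.floats(min_value=-9, max_value=-3))
    def test_lobe_independence(self, log_ca):
        ca = 10**log_ca
        f = cam_fractions(ca)
        kn = math.exp(-EVANS_SHEA.dg_n / CONSTANTS.rt)
        one_lobe = kn * ca**2 / (1.0 + kn * ca**2)
        assert f.f_2n + f.f_4 == pytest.approx(one_lobe, rel=1e-10)


class TestCTermOccupancy:
    def test_no_cam_leaves_cterm_free(self, nav14_long):
        occ = cterm_occupancy(10e-6, 0.0, nav14_long)
        assert occ.b_free == 1.0 and occ.bound_array().sum() == 0.0

    def test_skeletal_isoform_prefers_c_lobe_loaded_cam(self, nav14_long):
        occ = cterm_occupancy(10e-6, 10e-6, nav14_long)
        assert dominant_species(occ) == "2C"

    def test_cardiac_isoform_prefers_fully_loaded_cam(self, nav15_long):
        occ = cterm_occupancy(10e-6, 10e-6, nav15_long)
        assert dominant_species(occ) == "4"

    def test_negative_inputs_rejected(self, nav14_long):
        with pytest.raises(ValueError):
            cterm_occupancy(-1.0, 1e-6, nav14_long)
        with pytest.raises(ValueError):
            cterm_occupancy(1e-6, -1.0, nav14_long)

    @given(
        log_ca=st.floats(min_value=-9, max_value=-3),
        log_cam=st.floats(min_value=-8, max_value=-4),
        log_kds=st.lists(
            st.floats(min_value=-9, max_value=-5), min_size=4, max_size=4
        ),
    )
    def test_five_components_normalized(self, log_ca, log_cam, log_kds):
        table = CTermAffinityTable("X", "Y", *(10**k for k in log_kds))
        occ = cterm_occupancy(10**log_ca, 10**log_cam, table)
        arr = occ.as_array()
        assert np.all(arr >= 0) and np.all(arr <= 1)
        assert arr.sum() == pytest.approx(1.0, abs=1e-12)


class TestExactOccupancy:
    def test_zero_receptor_reduces_to_free_ligand_form(self, nav14_long):
        a = cterm_occupancy(10e-6, 10e-6, nav14_long)
        b = exact_occupancy(10e-6, 10e-6, 0.0, nav14_long)
        np.testing.assert_array_equal(a.as_array(), b.as_array())

    def test_dilute_receptor_matches_approximation(self, nav14_long, nav15_long):
        for table in (nav14_long, nav15_long):
            approx = cterm_occupancy(10e-6, 10e-6, table)
            exact = exact_occupancy(10e-6, 10e-6, 1e-8, table)
            assert np.abs(approx.as_array() - exact.as_array()).max() < 0.01

    def test_total_mass_conservation_and_free_speciation(self, nav14_long):
        # Ca2+ is clamped, so free CaM keeps the partition-function species
        # ratios while CTerm binding depletes the shared pool.
        cam_total, cterm_total = 10e-6, 5e-6
        occ = exact_occupancy(10e-6, cam_total, cterm_total, nav14_long)
        # free_X recovered from the binding ratio b_X / b_free = free_X / Kd_X
        free = nav14_long.kds() * occ.bound_array() / occ.b_free
        bound_total = occ.bound_array().sum() * cterm_total
        assert free.sum() + bound_total == pytest.approx(cam_total, abs=1e-9)
        fractions = cam_fractions(10e-6).as_array()
        np.testing.assert_allclose(free / free.sum(), fractions, rtol=1e-9)

    def test_strong_depletion_shifts_occupancy(self, nav14_long):
        # comparable receptor and ligand: the approximation must break down
        approx = cterm_occupancy(1e-7, 1e-7, nav14_long)
        exact = exact_occupancy(1e-7, 1e-7, 1e-7, nav14_long)
        assert np.abs(approx.as_array() - exact.as_array()).max() > 0.05


class TestPopulationSurface:
    def test_single_cell_matches_direct_call(self, nav14_long):
        surf = population_surface([10e-6], [10e-6], nav14_long)
        direct = cterm_occupancy(10e-6, 10e-6, nav14_long)
        np.testing.assert_allclose(
            surf.occupancy_at(0, 0).as_array(), direct.as_array(), rtol=1e-14
        )

    def test_low_calcium_slice_is_apo_dominated(self, nav14_long, nav15_long):
        for table in (nav14_long, nav15_long):
            occ = cterm_occupancy(100e-9, 10e-6, table)
            assert dominant_species(occ) == "apo"

    def test_lobe_swap_symmetry(self, nav14_long):
        swapped_table = CTermAffinityTable(
            "NaV1.4", "Long",
            kd_apo=nav14_long.kd_apo, kd_2n=nav14_long.kd_2c,
            kd_2c=nav14_long.kd_2n, kd_4=nav14_long.kd_4,
        )
        swapped_energies = LobeBindingEnergies(EVANS_SHEA.dg_c, EVANS_SHEA.dg_n)
        ca, cam = np.logspace(-8, -4, 5), np.logspace(-7, -5, 3)
        orig = population_surface(ca, cam, nav14_long, EVANS_SHEA)
        swap = population_surface(ca, cam, swapped_table, swapped_energies)
        np.testing.assert_allclose(swap.fractions["2N"], orig.fractions["2C"], rtol=1e-10)
        np.testing.assert_allclose(swap.fractions["2C"], orig.fractions["2N"], rtol=1e-10)

    @pytest.mark.parametrize(
        "ca_grid, cam_grid",
        [([], [1e-6]), ([1e-6], []), ([2e-6, 1e-6], [1e-6]), ([-1e-6], [1e-6])],
    )
    def test_malformed_grids_rejected(self, ca_grid, cam_grid, nav14_long):
        with pytest.raises(ValueError):
            population_surface(ca_grid, cam_grid, nav14_long)


class TestDominantSpecies:
    def test_largest_component_wins(self):
        assert dominant_species(_make_occ([0.1, 0.1, 0.6, 0.1, 0.1])) == "2C"

    def test_exact_tie_resolves_to_earlier_label(self):
        assert dominant_species(_make_occ([0.3, 0.3, 0.2, 0.1, 0.1])) == "apo"

    def test_free_considered_only_when_flagged(self):
        occ = _make_occ([0.1, 0.1, 0.2, 0.1, 0.5])
        assert dominant_species(occ) == "2C"
        assert dominant_species(occ, include_free=True) == "free"

    def test_high_calcium_cardiac_isoform_is_fully_loaded(self, nav15_long):
        occ = cterm_occupancy(100e-6, 10e-6, nav15_long)
        assert dominant_species(occ) == "4"


def _make_occ(b):
    from camnav import CTermOccupancy

    return CTermOccupancy(1e-6, 1e-6, *b)


def test_input_set_robustness_is_bounded_and_transition_localized(
    nav14_long, nav15_long
):
    """The two published lobe-energy sets give occupancy curves that agree
    closely away from the C-lobe loading transition and never diverge by more
    than ~0.1 anywhere (the 0.16 kcal/mol C-lobe difference shifts the
    transition by ~14% along the Ca axis)."""
    ca_grid = np.logspace(-8, -3, 120)
    for table in (nav14_long, nav15_long):
        diffs = np.array(
            [
                cterm_occupancy(ca, 10e-6, table, EVANS_SHEA).as_array()
                - cterm_occupancy(ca, 10e-6, table, LINSE).as_array()
                for ca in ca_grid
            ]
        )
        assert np.abs(diffs).max() < 0.15
        # away from the 0.5-50 uM transition window agreement is tight
        outside = (ca_grid < 5e-7) | (ca_grid > 5e-5)
        assert np.abs(diffs[outside]).max() < 0.05
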