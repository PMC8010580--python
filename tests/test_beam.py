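import numpy as np
import pytest

from ionarc.beam import (
    BeamLibrary,
    BeamModelOptions,
    build_depth_profile,
    depth_letd,
    energy_for_r80,
    get_table,
    lateral_sigma,
)
from ionarc.ions import CARBON, HELIUM, PROTON
from ionarc.stopping import MEV_PER_MM_TO_GY_MM2, csda_range


@pytest.fixture(scope="module")
def tables():
    return {ion.label: get_table(ion, e)
            for ion, e in ((PROTON, 118.0), (HELIUM, 118.0), (CARBON, 220.0))}


class TestDepthProfile:
    def test_dose_nonnegative_everywhere(self, tables):
        for tab in tables.values():
            assert np.all(tab.dose_per_primary >= 0)

    def test_component_fractions_sum_to_one(self, tables):
        for tab in tables.values():
            total = sum(c.dose for c in tab.components)
            sel = tab.dose_per_primary > 0
            np.testing.assert_allclose(total[sel], tab.dose_per_primary[sel],
                                       rtol=1e-12)

    def test_r80_inside_grid(self, tables):
        for tab in tables.values():
            assert tab.depth[0] < tab.R80 < tab.depth[-1]

    def test_proton_distal_edge_clean(self, tables):
        tab = tables["proton"]
        sigma = tab.options.straggling_coeff * 100**tab.options.straggling_power
        d = np.interp(tab.R80 + 3 * sigma, tab.depth, tab.dose_per_primary)
        assert d < 0.01 * tab.dose_per_primary.max()

    def test_carbon_fragment_tail_beyond_peak(self, tables):
        tab = tables["carbon"]
        assert np.interp(tab.R80 + 20.0, tab.depth, tab.dose_per_primary) > 0
        assert np.interp(tab.R80 + 10.0, tab.depth, tab.dose_per_primary) > 0

    def test_proton_energy_bookkeeping(self, tables):
        # integral of dose per primary ~ beam energy (times A) within 5%
        tab = tables["proton"]
        integral = np.trapezoid(tab.dose_per_primary, tab.depth) / MEV_PER_MM_TO_GY_MM2
        assert integral == pytest.approx(tab.energy * tab.ion.A, rel=0.05)

    def test_proton_entrance_letd(self, tables):
        assert 0.6 < depth_letd(tables["proton"], 0.5) < 0.7

    def test_primary_let_rises_to_its_maximum(self, tables):
        for tab in tables.values():
            let = tab.components[0].track_let
            imax = int(np.argmax(let))
            assert np.all(np.diff(let[: imax + 1]) >= -1e-9)

    def test_invalid_options_rejected(self):
        with pytest.raises(ValueError):
            build_depth_profile(PROTON, 118.0, BeamModelOptions(depth_step=-0.1))
        with pytest.raises(ValueError):
            build_depth_profile(PROTON, 5.0)  # stops inside the beamline


class TestLetd:
    def test_single_component_identity(self, tables):
        tab = tables["proton"]
        comps = tab.components_at(10.0)
        oracle = sum(c.dose_fraction * c.track_LET for c in comps)
        assert depth_letd(tab, 10.0) == pytest.approx(oracle, rel=1e-12)

    def test_two_component_arithmetic(self):
        # (d=1, LET=2) + (d=1, LET=4) -> 3
        d = np.array([1.0, 1.0])
        let = np.array([2.0, 4.0])
        assert np.sum(d * let) / np.sum(d) == 3.0

    def test_matches_bruteforce_on_random_fields(self, tables):
        rng = np.random.default_rng(7)
        tab = tables["carbon"]
        for depth in rng.uniform(5, tab.R80, 10):
            comps = tab.components_at(float(depth))
            num = sum(c.dose_fraction * c.track_LET for c in comps)
            assert depth_letd(tab, float(depth)) == pytest.approx(num, rel=1e-12)

    def test_undefined_where_dose_vanishes(self, tables):
        import copy

        tab = copy.deepcopy(tables["proton"])
        kill = tab.depth > tab.R80 + 30.0
        tab.dose_per_primary[kill] = 0.0
        for c in tab.components:
            c.dose[kill] = 0.0
        assert np.isnan(depth_letd(tab, tab.depth[-1]))

    def test_outside_grid_rejected(self, tables):
        with pytest.raises(ValueError):
            depth_letd(tables["proton"], -1.0)


class TestLateralSpread:
    def test_entrance_sigma_is_focus_sigma(self, tables):
        for ion in (PROTON, HELIUM, CARBON):
            tab = tables[ion.label]
            assert tab.lateral_sigma[0] == pytest.approx(ion.initial_spot_sigma,
                                                         abs=0.01)

    def test_monotone_nondecreasing(self, tables):
        for tab in tables.values():
            assert np.all(np.diff(tab.lateral_sigma) >= -1e-12)

    def test_proton_scatters_more_than_carbon(self, tables):
        p, c = tables["proton"], tables["carbon"]
        assert p.sigma_at(p.R80) > c.sigma_at(c.R80)
        # also the accumulated MCS part alone
        grow_p = p.sigma_at(p.R80) - p.lateral_sigma[0]
        grow_c = c.sigma_at(c.R80) - c.lateral_sigma[0]
        assert grow_p > grow_c

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            lateral_sigma(PROTON, 118.0, -5.0)


class TestEnergyInversion:
    @pytest.mark.parametrize("ion", [PROTON, HELIUM, CARBON])
    def test_round_trip_sweep(self, ion):
        e_lo = 70.0 if ion is not CARBON else 150.0
        e_hi = 200.0 if ion is not CARBON else 330.0
        for e0 in np.linspace(e_lo, e_hi, 7):
            r80 = get_table(ion, float(e0)).R80
            e1 = energy_for_r80(ion, r80)
            assert e1 == pytest.approx(e0, rel=1e-3)

    def test_depth_window_errors(self):
        with pytest.raises(ValueError, match="window"):
            energy_for_r80(PROTON, 5.0)
        with pytest.raises(ValueError, match="window"):
            energy_for_r80(PROTON, 400.0)


class TestBeamLibrary:
    def test_r80_regeneration_invariant(self):
        lib = BeamLibrary()
        lib.add(PROTON, 118.0)
        lib.add(CARBON, 220.0)
        lib.check(tol_mm=0.1)

    def test_nozzle_offset_shortens_range(self):
        tab = get_table(PROTON, 118.0)
        assert tab.R80 < csda_range(PROTON, 118.0)
        assert tab.R80 == pytest.approx(
            csda_range(PROTON, 118.0) - tab.options.nozzle_wet, abs=1.0)
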