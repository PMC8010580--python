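import numpy as np
import pytest

from ionarc.mkm import (
    MKMParams,
    MixedFieldVoxel,
    PhotonLQParams,
    alpha_beta_ion,
    effective_dose,
    effective_dose_from_lq,
    mix_lq,
    z1d_star,
    z1d_star_single,
)
from ionarc.stopping import stopping_power

PHOTON = PhotonLQParams()
MKM = MKMParams()


class TestParams:
    def test_defaults_encode_study_configuration(self):
        assert PHOTON.alpha_x / PHOTON.beta_x == pytest.approx(2.0)
        assert MKM.domain_radius == 0.3 and MKM.nucleus_radius == 3.6

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            MKMParams(domain_radius=4.0, nucleus_radius=3.6)
        with pytest.raises(ValueError):
            PhotonLQParams(alpha_x=-1.0)

    def test_saturation_parameter_scale(self):
        # z0 = (Rn^2/Rd) sqrt(2/(beta_x (Rd^2+Rn^2))): tens-of-Gy regime
        z0 = MKM.saturation_z0(PHOTON)
        assert 50.0 < z0 < 300.0


class TestZ1dStar:
    def test_vanishes_at_low_let(self):
        assert 0.0 < z1d_star("proton", 1000.0) < 0.3

    def test_monotone_over_proton_therapeutic_let(self):
        # proton LET rises 1 -> 10 keV/um as E falls ~ 60 -> 4 MeV
        energies = np.geomspace(60.0, 4.0, 12)
        vals = [z1d_star("proton", float(e)) for e in energies]
        assert np.all(np.diff(vals) > 0)

    def test_overkill_saturation_for_carbon(self):
        # value at very high LET (stopping carbon) below the curve maximum
        es = np.geomspace(1.5, 500, 40)
        vals = np.array([z1d_star("carbon", float(e)) for e in es])
        imax = int(np.argmax(vals))
        assert 0 < imax < es.size - 1
        assert vals[0] < vals.max()
        let_at_max = stopping_power(6, 12, es[imax])
        assert 80.0 < let_at_max < 400.0

    def test_table_interpolation_matches_direct_quadrature(self):
        for label, e in (("proton", 17.3), ("carbon", 53.1)):
            ion_za = {"proton": (1, 1), "carbon": (6, 12)}[label]
            direct = z1d_star_single(*ion_za, e, MKM, PHOTON)
            assert z1d_star(label, e) == pytest.approx(direct, rel=0.02)

    def test_continuity_in_energy(self):
        for e in (3.0, 30.0, 300.0):
            a0 = alpha_beta_ion("carbon", e).alpha_ion
            a1 = alpha_beta_ion("carbon", e * (1 + 1e-9)).alpha_ion
            assert abs(a1 - a0) < 1e-6


class TestAlphaBetaIon:
    def test_linear_in_z1d_star(self):
        lq = alpha_beta_ion("helium", 10.0)
        assert lq.alpha_ion == pytest.approx(
            PHOTON.alpha_x + PHOTON.beta_x * lq.z1d_star, rel=1e-12)
        assert lq.beta_ion == PHOTON.beta_x

    def test_example_value(self):
        # z1d* = 2 Gy -> alpha = 0.05 + 0.025 * 2 = 0.10
        assert PHOTON.alpha_x + PHOTON.beta_x * 2.0 == pytest.approx(0.10)

    def test_low_dose_rbe_above_one(self):
        lq = alpha_beta_ion("carbon", 50.0)
        assert lq.alpha_ion > PHOTON.alpha_x


class TestMixLq:
    def test_single_component_identity(self):
        v = MixedFieldVoxel(doses=[2.0], alphas=[0.07], betas=[0.025])
        a, b = mix_lq(v)
        assert a == pytest.approx(0.07, rel=1e-15)
        assert b == pytest.approx(0.025, rel=1e-15)

    def test_equal_dose_mean(self):
        v = MixedFieldVoxel(doses=[1.0, 1.0], alphas=[0.05, 0.15],
                            betas=[0.025, 0.025])
        a, _ = mix_lq(v)
        assert a == pytest.approx(0.10, rel=1e-15)

    def test_matches_bruteforce_on_random_fields(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            d = rng.uniform(0.01, 2.0, 20)
            al = rng.uniform(0.05, 1.5, 20)
            be = rng.uniform(0.01, 0.05, 20)
            a, b = mix_lq(MixedFieldVoxel(doses=d, alphas=al, betas=be))
            assert a == pytest.approx(np.sum(d * al) / d.sum(), rel=1e-12)
            assert np.sqrt(b) == pytest.approx(
                np.sum(d * np.sqrt(be)) / d.sum(), rel=1e-12)

    def test_zero_dose_undefined(self):
        with pytest.raises(ValueError):
            mix_lq(MixedFieldVoxel(doses=[0.0], alphas=[0.1], betas=[0.025]))


class TestEffectiveDose:
    def test_photon_identical_field_is_identity(self):
        v = MixedFieldVoxel(doses=[2.0], alphas=[PHOTON.alpha_x],
                            betas=[PHOTON.beta_x])
        assert effective_dose(v) == pytest.approx(2.0, rel=1e-12)

    def test_quadratic_root_example(self):
        # alpha_bar=0.1, beta_bar=0.025, D=2 -> -lnS=0.3 -> D_RBE ~ 2.61
        d_rbe = effective_dose_from_lq(0.1, 0.025, 2.0)
        assert d_rbe == pytest.approx(2.6056, abs=2e-3)

    def test_zero_dose(self):
        v = MixedFieldVoxel(doses=[0.0], alphas=[0.1], betas=[0.025])
        assert effective_dose(v) == 0.0

    def test_log_survival_round_trip(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a, b, d = rng.uniform(0.05, 1.0), rng.uniform(0.01, 0.05), rng.uniform(0.1, 5)
            e = a * d + b * d**2
            x = effective_dose_from_lq(a, b, d)
            assert PHOTON.alpha_x * x + PHOTON.beta_x * x**2 == pytest.approx(
                e, rel=1e-12)

    def test_strictly_increasing_in_dose_and_alpha(self):
        d = np.linspace(0.1, 5, 50)
        out = effective_dose_from_lq(0.1, 0.025, d)
        assert np.all(np.diff(out) > 0)
        alphas = np.linspace(0.05, 1.0, 50)
        out2 = [effective_dose_from_lq(a, 0.025, 2.0) for a in alphas]
        assert np.all(np.diff(out2) > 0)
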