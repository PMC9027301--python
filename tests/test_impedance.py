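"""Forward-model unit and property tests, with mpmath as the precision oracle."""

import mpmath as mp
import numpy as np
import pytest

from ecistools import (
    CONFLUENT_BARRIER,
    DEFAULT_ELECTRODE,
    BarrierParameters,
    ElectrodeParameters,
    FrequencyGrid,
    bessel_ratio,
    cell_covered_impedance,
    cpe_interface_impedance,
    extract_series_rc,
    membrane_impedance,
    well_impedance,
)

GRID = FrequencyGrid()
FREQS = GRID.as_array()


def mp_gk_well(f, electrode, rb, alpha, cm, dps=50):
    """Independent arbitrary-precision transcription of the forward model."""
    with mp.workdps(dps):
        w = 2 * mp.pi * f
        zn = 1 / (electrode.cpe_q * mp.power(mp.mpc(0, w), electrode.cpe_n))
        zm = 2 / (mp.mpc(0, 1) * w * cm * mp.mpf("1e-6"))
        s = 1 / zn + 1 / zm
        g = alpha * mp.sqrt(s)
        if g == 0:
            spread = mp.mpf(1)
        else:
            spread = g / 2 * mp.besseli(0, g) / mp.besseli(1, g)
        inv = (1 / zn) * (zn / (zn + zm) + (zm / (zn + zm)) / (spread + rb * s))
        z = electrode.r_solution + (1 / inv) / electrode.area_cm2
        return complex(z)


class TestCPE:
    def test_ideal_capacitor_when_n_is_one(self):
        el = ElectrodeParameters(cpe_q=1e-6, cpe_n=1.0, r_solution=0, area_cm2=1)
        f = 1234.5
        assert cpe_interface_impedance(f, el) == pytest.approx(
            1 / (1j * 2 * np.pi * f * 1e-6))

    def test_resistor_limit_as_n_approaches_zero(self):
        el = ElectrodeParameters(cpe_q=0.01, cpe_n=1e-9, r_solution=0, area_cm2=1)
        z = cpe_interface_impedance(5000.0, el)
        assert z.real == pytest.approx(100.0, rel=1e-6)
        assert abs(np.angle(z)) < 1e-6

    def test_matches_high_precision_oracle(self):
        el = ElectrodeParameters(cpe_q=2e-5, cpe_n=0.9, r_solution=0, area_cm2=1)
        z = cpe_interface_impedance(4000.0, el)
        with mp.workdps(50):
            w = 2 * mp.pi * 4000
            expected = complex(1 / (mp.mpf("2e-5") * mp.power(mp.mpc(0, w), mp.mpf("0.9"))))
        assert z == pytest.approx(expected, rel=1e-14)

    def test_phase_sign_convention(self):
        z = cpe_interface_impedance(FREQS, DEFAULT_ELECTRODE)
        assert np.all(z.real >= 0) and np.all(z.imag <= 0)

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError):
            cpe_interface_impedance(0.0, DEFAULT_ELECTRODE)


class TestMembrane:
    def test_infinite_capacitance_is_a_short(self):
        assert abs(membrane_impedance(4000.0, 1e9)) < 1e-6
        assert abs(membrane_impedance(4000.0, 1e12)) < 1e-9

    def test_one_over_f_scaling(self):
        assert abs(membrane_impedance(8000.0, 1.0)) == pytest.approx(
            abs(membrane_impedance(4000.0, 1.0)) / 2)

    def test_magnitude_at_reference_point(self):
        # two membranes in series at 4 kHz, 1 µF/cm²
        z = membrane_impedance(4000.0, 1.0)
        assert abs(z) == pytest.approx(2 / (2 * np.pi * 4000 * 1e-6))
        assert z.real == 0

    def test_invalid_cm_rejected(self):
        with pytest.raises(ValueError):
            membrane_impedance(4000.0, 0.0)


class TestBesselRatio:
    def test_small_argument_limit(self):
        for x in (1e-6, 1e-6j, 1e-5 * np.exp(0.3j)):
            assert x * bessel_ratio(x) == pytest.approx(2.0, rel=1e-5)

    def test_large_argument_limit(self):
        for x in (1e5, 1e6, 1e5 * np.exp(0.5j)):
            assert bessel_ratio(x) == pytest.approx(1.0, rel=1e-4)

    def test_unit_argument_against_series_oracle(self):
        with mp.workdps(50):
            expected = complex(mp.besseli(0, 1) / mp.besseli(1, 1))
        assert bessel_ratio(1.0) == pytest.approx(expected, rel=1e-12)

    def test_oracle_agreement_on_complex_grid(self):
        """1e-10 relative agreement over |x| in [1e-4, 1e4], arg in [0, pi/4]."""
        mags = np.logspace(-4, 4, 17)
        args = np.linspace(0.0, np.pi / 4, 5)
        for m in mags:
            for a in args:
                x = m * np.exp(1j * a)
                got = bessel_ratio(x)
                with mp.workdps(60):
                    want = complex(mp.besseli(0, mp.mpc(x.real, x.imag))
                                   / mp.besseli(1, mp.mpc(x.real, x.imag)))
                assert abs(got - want) / abs(want) < 1e-10, x

    def test_zero_argument_rejected(self):
        with pytest.raises(ValueError):
            bessel_ratio(0.0)


class TestCellCoveredImpedance:
    def test_no_barrier_collapses_to_cell_free(self):
        """Zc == Zn to machine precision at Rb = alpha = 0, on every grid f."""
        barrier = BarrierParameters(rb=0.0, alpha=0.0, cm=1.8)
        zc = cell_covered_impedance(FREQS, DEFAULT_ELECTRODE, barrier)
        zn = cpe_interface_impedance(FREQS, DEFAULT_ELECTRODE)
        np.testing.assert_allclose(zc, zn, rtol=1e-14)

    def test_infinite_rb_forces_transcellular_path(self):
        """Zc -> Zn + Zm with relative error < 1e-6 at Rb = 1e9."""
        barrier = BarrierParameters(rb=1e9, alpha=8.0, cm=1.8)
        zc = cell_covered_impedance(FREQS, DEFAULT_ELECTRODE, barrier)
        zn = cpe_interface_impedance(FREQS, DEFAULT_ELECTRODE)
        zm = membrane_impedance(FREQS, 1.8)
        np.testing.assert_allclose(zc, zn + zm, rtol=1e-6)

    def test_matches_independent_transcription(self):
        """Spot value against an mpmath re-implementation of the formula."""
        for f in (250.0, 4000.0, 64000.0):
            got = well_impedance(f, DEFAULT_ELECTRODE,
                                 BarrierParameters(rb=4, alpha=8, cm=1.5))
            want = mp_gk_well(f, DEFAULT_ELECTRODE, 4, 8, 1.5)
            assert got == pytest.approx(want, rel=1e-12)

    def test_cells_never_lower_impedance_magnitude(self):
        """|Z_well cells| >= |Z_well cell-free| for random physical barriers."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            barrier = BarrierParameters(rb=rng.uniform(0, 30),
                                        alpha=rng.uniform(0, 30),
                                        cm=rng.uniform(0.3, 5))
            with_cells = np.abs(well_impedance(FREQS, DEFAULT_ELECTRODE, barrier))
            cell_free = np.abs(well_impedance(FREQS, DEFAULT_ELECTRODE, None))
            assert np.all(with_cells >= cell_free * (1 - 1e-12))

    def test_magnitude_monotone_in_rb_at_4khz(self):
        rbs = np.linspace(0, 50, 40)
        mags = [abs(well_impedance(4000.0, DEFAULT_ELECTRODE,
                                   BarrierParameters(rb=rb, alpha=8, cm=1.8)))
                for rb in rbs]
        assert np.all(np.diff(mags) >= -1e-9)


class TestWellImpedance:
    def test_cell_free_is_scaled_interface_plus_series_resistance(self):
        el = ElectrodeParameters(cpe_q=8e-6, cpe_n=0.9, r_solution=0,
                                 area_cm2=0.02)
        z = well_impedance(4000.0, el, None)
        assert z == pytest.approx(cpe_interface_impedance(4000.0, el) / 0.02)

    def test_zero_barrier_well_equals_cell_free_well(self):
        barrier = BarrierParameters(rb=0.0, alpha=0.0, cm=1.8)
        np.testing.assert_allclose(
            well_impedance(FREQS, DEFAULT_ELECTRODE, barrier),
            well_impedance(FREQS, DEFAULT_ELECTRODE, None), rtol=1e-14)

    def test_confluent_series_capacitance_below_cell_free(self):
        z_cell = well_impedance(64000.0, DEFAULT_ELECTRODE, CONFLUENT_BARRIER)
        z_free = well_impedance(64000.0, DEFAULT_ELECTRODE, None)
        _, c_cell = extract_series_rc(z_cell, 64000.0)
        _, c_free = extract_series_rc(z_free, 64000.0)
        assert c_cell < c_free


class TestDomainTypes:
    def test_grid_must_increase(self):
        with pytest.raises(ValueError):
            FrequencyGrid((1000.0, 500.0))

    def test_default_grid_has_nine_frequencies_spanning_250_64k(self):
        assert len(GRID) == 9
        assert GRID.frequencies_hz[0] == 250.0
        assert GRID.frequencies_hz[-1] == 64000.0

    @pytest.mark.parametrize("kwargs", [
        dict(cpe_q=0, cpe_n=0.9, r_solution=0, area_cm2=1),
        dict(cpe_q=1e-6, cpe_n=1.5, r_solution=0, area_cm2=1),
        dict(cpe_q=1e-6, cpe_n=0.9, r_solution=-1, area_cm2=1),
        dict(cpe_q=1e-6, cpe_n=0.9, r_solution=0, area_cm2=0),
    ])
    def test_invalid_electrode_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ElectrodeParameters(**kwargs)

    def test_zero_rb_forces_modelability_flags_off(self):
        b = BarrierParameters(rb=0.0, alpha=5.0, cm=1.0)
        assert not b.alpha_modelable and not b.cm_modelable
        b = BarrierParameters(rb=0.1, alpha=5.0, cm=1.0)
        assert b.alpha_modelable and b.cm_modelable
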