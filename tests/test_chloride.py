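"""Chloride physiology arithmetic: Nernst, driving force, reversal fits."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fetalmn.chloride import (AmbiguousCrossingError, ChlorideContext,
                              IVSeries, NoReversalError, RampPair,
                              cl_in_from_ecl, driving_force, fit_reversal,
                              nernst_ecl, ramp_subtraction_ecl)
from fetalmn.synth import gen_iv_series, gen_ramp_pair

CTX = ChlorideContext()  # 123.5 mM, 303.15 K


class TestNernst:
    def test_equal_concentrations_give_zero(self):
        assert nernst_ecl(CTX.cl_out, CTX) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("cl_in, expected", [
        (12.2, -60.5), (17.87, -50.5),
    ])
    def test_reference_points(self, cl_in, expected):
        # Closed-form values at RT/F = 26.12 mV (30 °C), cl_out 123.5 mM.
        assert nernst_ecl(cl_in, CTX) == pytest.approx(expected, abs=0.05)

    def test_zero_potential_inverts_to_bath(self):
        assert cl_in_from_ecl(0.0, CTX) == pytest.approx(CTX.cl_out)

    @pytest.mark.parametrize("ecl, expected", [
        (-50.5, 17.87), (-60.5, 12.2),
    ])
    def test_inverse_reference_points(self, ecl, expected):
        assert cl_in_from_ecl(ecl, CTX) == pytest.approx(expected, abs=0.02)

    @given(st.floats(min_value=1.0, max_value=150.0))
    def test_round_trip(self, cl_in):
        back = cl_in_from_ecl(nernst_ecl(cl_in, CTX), CTX)
        assert back == pytest.approx(cl_in, rel=1e-12)

    def test_monotone_in_cl_in(self):
        grid = np.linspace(1, 150, 200)
        vals = nernst_ecl(grid, CTX)
        assert np.all(np.diff(vals) > 0)

    def test_rejects_nonpositive_concentration(self):
        with pytest.raises(ValueError):
            nernst_ecl(0.0, CTX)
        with pytest.raises(ValueError):
            nernst_ecl(-5.0, CTX)


class TestDrivingForce:
    @pytest.mark.parametrize("e_gaba, e_m, expected", [
        (-50.5, -73.1, 22.6),   # depolarized fetal SOD-type values
        (-62.0, -74.1, 12.1),   # WT-type values
    ])
    def test_reported_driving_forces(self, e_gaba, e_m, expected):
        assert driving_force(e_gaba, e_m) == pytest.approx(expected)

    def test_zero_for_equal_potentials(self):
        assert driving_force(-60.0, -60.0) == 0.0

    @given(st.floats(-100, 20), st.floats(-100, 20))
    def test_antisymmetry(self, a, b):
        assert driving_force(a, b) == pytest.approx(-driving_force(b, a))


class TestFitReversal:
    def test_two_point_symmetric_line(self):
        iv = IVSeries([-70.0, -50.0], [-20.0, 20.0])
        assert fit_reversal(iv) == pytest.approx(-60.0)

    def test_exact_linear_construction(self):
        iv = gen_iv_series(e_rev=-48.5, slope=2.0,
                           holdings=[-80, -70, -60, -50, -40])
        assert fit_reversal(iv) == pytest.approx(-48.5, abs=1e-9)

    def test_noisy_recovery_within_2mv(self):
        iv = gen_iv_series(e_rev=-61.4, slope=2.0,
                           holdings=[-70, -60, -50, -40],
                           noise_sd=2.0, seed=11)
        assert fit_reversal(iv) == pytest.approx(-61.4, abs=2.0)

    def test_monte_carlo_bias_below_half_mv(self):
        ests = [fit_reversal(gen_iv_series(-61.4, 2.0, [-70, -60, -50, -40],
                                           noise_sd=2.0, seed=s))
                for s in range(100)]
        assert abs(np.mean(ests) - (-61.4)) < 0.5

    def test_flat_iv_has_no_reversal(self):
        iv = gen_iv_series(e_rev=-60.0, slope=0.0, holdings=[-70, -60, -50])
        with pytest.raises(NoReversalError):
            fit_reversal(iv)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            IVSeries([-60.0], [5.0])


class TestRampSubtraction:
    def test_crossing_at_agonist_reversal(self):
        ramp = gen_ramp_pair(e_agonist=-49.0)
        assert ramp_subtraction_ecl(ramp) == pytest.approx(-49.0, abs=1e-9)

    def test_independent_of_conductance(self):
        for g in (0.5, 1.0, 4.0):
            ramp = gen_ramp_pair(e_agonist=-49.0, g_agonist=g)
            assert ramp_subtraction_ecl(ramp) == pytest.approx(-49.0,
                                                               abs=1e-9)

    def test_interpolated_between_samples(self):
        # Crossing forced between 0.5 mV samples: linear interpolation must
        # land within a quarter of the sample spacing.
        grid = np.arange(-100.0, 10.0, 0.5)
        ramp = gen_ramp_pair(e_agonist=-49.27, grid=grid)
        assert ramp_subtraction_ecl(ramp) == pytest.approx(-49.27, abs=0.25)

    def test_invariant_to_common_current(self):
        ramp = gen_ramp_pair(e_agonist=-49.0)
        offset = 35.0 + 0.8 * ramp.voltages
        shifted = RampPair(ramp.voltages, ramp.control_current + offset,
                           ramp.iso_current + offset)
        assert ramp_subtraction_ecl(shifted) == pytest.approx(
            ramp_subtraction_ecl(ramp), abs=1e-9)

    def test_no_sign_change_raises(self):
        grid = np.arange(-100.0, 10.0, 0.5)
        ramp = RampPair(grid, np.zeros(grid.size),
                        np.full(grid.size, 5.0))
        with pytest.raises(NoReversalError):
            ramp_subtraction_ecl(ramp)

    def test_multiple_crossings_reported(self):
        grid = np.arange(-100.0, 10.0, 0.5)
        diff = np.sin((grid + 100) / 10.0)   # many crossings
        ramp = RampPair(grid, np.zeros(grid.size), diff)
        with pytest.raises(AmbiguousCrossingError) as exc:
            ramp_subtraction_ecl(ramp)
        assert len(exc.value.crossings_mv) > 1

    def test_noisy_monte_carlo_recovery(self):
        ests = []
        for s in range(100):
            ramp = gen_ramp_pair(e_agonist=-49.0, noise_sd=5.0, seed=s)
            try:
                ests.append(ramp_subtraction_ecl(ramp))
            except AmbiguousCrossingError as e:
                # Noise can produce spurious crossings; take the median one.
                ests.append(float(np.median(e.crossings_mv)))
        assert abs(np.mean(ests) - (-49.0)) < 1.0
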