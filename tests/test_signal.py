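"""Forward signal models: closed-form values, decay monotonicity, noise."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import renalqmri as rq
from renalqmri.phantom import LABELS


def _uniform_phantom(t2star=10.0, adc=0.7, grid=(64, 32)):
    preset = rq.ConditionPreset(
        condition="CD0h", perfusion="none",
        t2star={c: rq.GaussianParam(t2star, 0) for c in rq.COMPARTMENTS},
        adc={c: rq.GaussianParam(adc, 0) for c in rq.COMPARTMENTS},
    )
    return rq.make_kidney_phantom(grid=grid, fov_mm=(25, 12.5), preset=preset)


class TestGRE:
    def test_closed_form_single_echo(self):
        ph = _uniform_phantom(t2star=10.0)
        stack = rq.simulate_gre(ph, rq.AcquisitionConfig(te_list_ms=(10.0,), matrix=(64, 32), fov_mm=(25, 12.5)))
        kid = ph.kidney_mask
        assert np.allclose(stack.data[0][kid], 1000.0 * np.exp(-1.0))
        assert np.all(stack.data[0][~kid] == 0)

    def test_te_to_zero_recovers_s0(self):
        ph = _uniform_phantom(t2star=50.0)
        acq = rq.AcquisitionConfig(te_list_ms=(1e-9, 10.0), matrix=(64, 32), fov_mm=(25, 12.5))
        stack = rq.simulate_gre(ph, acq)
        kid = ph.kidney_mask
        np.testing.assert_allclose(stack.data[0][kid], ph.s0_map[kid], rtol=1e-9)

    def test_two_compartment_signal_ratio(self):
        """Equal S0, T2* of 42.3 vs 146.1 ms at TE = 10 ms gives signal ratio
        exp(-10/42.3)/exp(-10/146.1) ~= 0.845."""
        ratio = np.exp(-10 / 42.3) / np.exp(-10 / 146.1)
        assert ratio == pytest.approx(0.845, abs=5e-4)
        preset = rq.table_preset("CD1h").with_zero_sd()
        ph1 = rq.make_kidney_phantom(preset=preset, seed=0)
        ph0 = rq.make_kidney_phantom(preset=rq.table_preset("CD0h").with_zero_sd(), seed=0)
        acq = rq.AcquisitionConfig(te_list_ms=(10.0,))
        s1 = rq.simulate_gre(ph1, acq).data[0]
        s0 = rq.simulate_gre(ph0, acq).data[0]
        is_reg = ph1.label_map == LABELS["IS"]
        assert s1[is_reg].mean() / s0[is_reg].mean() == pytest.approx(ratio, rel=1e-12)

    def test_grid_mismatch_rejected(self):
        ph = _uniform_phantom()
        with pytest.raises(ValueError):
            rq.simulate_gre(ph, rq.AcquisitionConfig(matrix=(256, 128)))

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(t2star=st.floats(5.0, 300.0))
    def test_monotone_decay_in_te(self, t2star):
        ph = _uniform_phantom(t2star=t2star, grid=(32, 32))
        acq = rq.AcquisitionConfig(
            te_list_ms=(2.0, 5.0, 15.0, 40.0), matrix=(32, 32), fov_mm=(12.5, 12.5)
        )
        stack = rq.simulate_gre(ph, acq)
        kid = ph.kidney_mask
        for a, b in zip(stack.data[:-1], stack.data[1:]):
            assert np.all(b[kid] < a[kid])


class TestDWI:
    def test_b0_frame_equals_s0(self):
        ph = _uniform_phantom(adc=0.9)
        acq = rq.AcquisitionConfig(matrix=(64, 32), fov_mm=(25, 12.5))
        stack = rq.simulate_dwi(ph, acq)
        np.testing.assert_array_equal(stack.frame_at(0.0), ph.s0_map)

    def test_attenuation_closed_form(self):
        """ADC 0.626e-3 mm^2/s at b = 134 s/mm^2 attenuates to ~0.91954 S0."""
        ph = _uniform_phantom(adc=0.626)
        acq = rq.AcquisitionConfig(matrix=(64, 32), fov_mm=(25, 12.5))
        stack = rq.simulate_dwi(ph, acq)
        kid = ph.kidney_mask
        ratio = stack.frame_at(134.0)[kid] / stack.frame_at(0.0)[kid]
        np.testing.assert_allclose(ratio, np.exp(-0.083884), atol=5e-7)

    def test_zero_adc_identical_frames(self):
        ph = _uniform_phantom(adc=0.0)
        acq = rq.AcquisitionConfig(b_values=(0.0, 134.0, 500.0), matrix=(64, 32), fov_mm=(25, 12.5))
        stack = rq.simulate_dwi(ph, acq)
        np.testing.assert_array_equal(stack.data[0], stack.data[1])
        np.testing.assert_array_equal(stack.data[0], stack.data[2])

    def test_needs_b0_and_rejects_negative_b(self):
        ph = _uniform_phantom()
        with pytest.raises(ValueError):
            rq.simulate_dwi(ph, rq.AcquisitionConfig(b_values=(10.0, 134.0), matrix=(64, 32), fov_mm=(25, 12.5)))
        with pytest.raises(ValueError):
            rq.AcquisitionConfig(b_values=(-1.0, 134.0))

    def test_signal_non_increasing_in_b(self):
        ph = _uniform_phantom(adc=1.2)
        acq = rq.AcquisitionConfig(b_values=(0.0, 50.0, 134.0, 400.0), matrix=(64, 32), fov_mm=(25, 12.5))
        stack = rq.simulate_dwi(ph, acq)
        kid = ph.kidney_mask
        for a, b in zip(stack.data[:-1], stack.data[1:]):
            assert np.all(b[kid] <= a[kid])


class TestNoise:
    def _stack(self, value=0.0, n=(200, 500)):
        data = np.full((1,) + n, value)
        return rq.ImageStack(data=data, contrast_axis=np.array([10.0]), contrast_unit="ms", kind="gre")

    def test_sigma_zero_is_identity(self):
        stack = self._stack(100.0)
        out = rq.add_noise(stack, 0.0, "gaussian", seed=1)
        np.testing.assert_array_equal(out.data, stack.data)

    def test_same_seed_identical(self):
        stack = self._stack(50.0)
        a = rq.add_noise(stack, 5.0, "rician", seed=42)
        b = rq.add_noise(stack, 5.0, "rician", seed=42)
        np.testing.assert_array_equal(a.data, b.data)
        c = rq.add_noise(stack, 5.0, "rician", seed=43)
        assert not np.array_equal(a.data, c.data)

    def test_rician_background_mean_matches_rayleigh_sampling(self):
        """On zero signal the Rician magnitude is Rayleigh; its mean must match
        a direct-sampling oracle (~ sigma*sqrt(pi/2)) at 1e5 pixels."""
        sigma = 10.0
        stack = self._stack(0.0)
        out = rq.add_noise(stack, sigma, "rician", seed=0)
        rng = np.random.default_rng(12345)
        oracle = np.hypot(rng.normal(0, sigma, 100_000), rng.normal(0, sigma, 100_000)).mean()
        assert out.data.mean() == pytest.approx(oracle, rel=0.02)
        assert oracle == pytest.approx(sigma * np.sqrt(np.pi / 2), rel=0.02)

    def test_averaging_halves_sd_at_four_averages(self):
        sigma = 8.0
        stack = self._stack(1000.0)
        out = rq.add_noise(stack, sigma, "gaussian", seed=3, n_averages=4)
        assert out.data.std() == pytest.approx(sigma / 2, rel=0.05)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            rq.add_noise(self._stack(1.0), 1.0, "poisson", seed=0)
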