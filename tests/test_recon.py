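"""Pre-processing, FBP filtering/reconstruction, sweeps and chunking."""

import numpy as np
import pytest

from lamrec.operators import forward_fourier
from lamrec.recon import (
    ReconConfig,
    chunked_execute,
    fbp_filter,
    fbp_reconstruct,
    normalize_minus_log,
    preprocess,
    try_lamino_angle,
    try_rotation_axis,
)
from lamrec.geometry import ProjectionStack
from .conftest import make_geometry, rel_rms


class TestNormalizeMinusLog:
    def test_flat_field_maps_to_zero(self):
        raw = np.full((2, 4, 4), 110.0)
        out = normalize_minus_log(raw, np.full((4, 4), 10.0), np.full((4, 4), 110.0))
        assert np.allclose(out, 0.0)

    def test_known_attenuation(self):
        # raw 60, dark 10, flat 110: -ln(50/100) = ln 2
        out = normalize_minus_log(np.full((1, 1, 1), 60.0),
                                  np.full((1, 1), 10.0), np.full((1, 1), 110.0))
        assert out[0, 0, 0] == pytest.approx(0.6931, abs=1e-4)

    def test_degenerate_raw_clamped(self, caplog):
        import logging

        raw = np.full((1, 2, 2), 10.0)  # equals dark: zero transmission
        with caplog.at_level(logging.WARNING, logger="lamrec.recon"):
            out = normalize_minus_log(raw, np.full((2, 2), 10.0), np.full((2, 2), 110.0))
        assert np.all(np.isfinite(out)) and np.all(out > 10.0)
        assert any("clamped" in r.message for r in caplog.records)

    def test_flat_not_above_dark_reports_pixel_count(self):
        flat = np.full((2, 2), 5.0)
        flat[0, 0] = 20.0
        with pytest.raises(ValueError, match="3 detector pixels"):
            normalize_minus_log(np.ones((1, 2, 2)) * 10, np.full((2, 2), 10.0), flat)

    def test_preprocess_hooks_applied_in_order(self):
        geom = make_geometry(8, 4, 0.0, n3=8)
        stack = ProjectionStack(
            data=np.full(geom.proj_shape, 50.0),
            dark=np.zeros((8, 8)), flat=np.full((8, 8), 100.0),
            angles=geom.thetas,
        )
        out = preprocess(stack, ring_removal_hook=lambda d: d + 1.0,
                         paganin_hook=lambda d: d * 2.0)
        assert np.allclose(out, (np.log(2.0) + 1.0) * 2.0)


class TestFBPFilter:
    def test_constant_row_filters_to_zero(self):
        data = np.full((3, 2, 32), 7.0)
        out = fbp_filter(data, "ramp", None)
        assert np.abs(out).max() < 1e-12

    def test_impulse_response_is_discrete_ramp_kernel(self):
        # oracle: the response to a unit impulse is the band-limited ramp
        # kernel itself (h[0]=1/4, h[odd k]=-1/(pi k)^2), DC removed to
        # match the filter's exact annihilation of constants
        nu = 32
        import scipy.fft as sfft

        npad = sfft.next_fast_len(2 * nu)
        h = np.zeros(npad)
        k = np.arange(1, npad // 2 + 1)
        odd = k[k % 2 == 1]
        h[0] = 0.25
        h[odd] = -1.0 / (np.pi * odd) ** 2
        h[-odd] = -1.0 / (np.pi * odd) ** 2
        h -= h.mean()
        impulse = np.zeros((1, 1, nu))
        impulse[0, 0, 5] = 1.0
        got = fbp_filter(impulse, "ramp", None)[0, 0]
        want = np.array([h[(s - 5) % npad] for s in range(nu)])
        assert np.abs(got - want).max() < 1e-12

    def test_apodisation_orders_noise_power(self, rng):
        rows = rng.standard_normal((8, 4, 64))
        powers = {
            name: float(np.sum(fbp_filter(rows, name, None) ** 2))
            for name in ("ramp", "shepp", "parzen")
        }
        assert powers["parzen"] < powers["shepp"] < powers["ramp"]

    def test_unknown_filter(self):
        with pytest.raises(ValueError):
            fbp_filter(np.zeros((1, 1, 8)), "hann", None)


class TestFBPReconstruct:
    def test_linear_in_data(self, rng, geom32):
        d = rng.standard_normal(geom32.proj_shape)
        a = fbp_reconstruct(d, geom32).values
        b = fbp_reconstruct(3.0 * d, geom32).values
        assert np.abs(b - 3.0 * a).max() < 1e-10 * np.abs(b).max()

    def test_unit_ball_amplitude_calibration(self):
        # a unit-attenuation ball at phi=0 must reconstruct at amplitude 1
        n = 64
        geom = make_geometry(n, 96, 0.0, n3=n)
        zz, yy, xx = np.meshgrid(*(np.arange(n) - n // 2,) * 3, indexing="ij")
        ball = ((xx**2 + yy**2 + zz**2) <= 12**2).astype(np.float64)
        rec = fbp_reconstruct(forward_fourier(ball, geom), geom).values
        core = rec[(xx**2 + yy**2 + zz**2) <= 8**2]
        assert abs(core.mean() - 1.0) < 0.05

    def test_chunk_invariance(self, rng):
        geom = make_geometry(32, 48, 25.0)
        d = rng.standard_normal(geom.proj_shape)
        ref = fbp_reconstruct(d, geom).values
        for ca, cs, cc in [(1, 1, 1), (7, 5, 100), (48, 16, 1024)]:
            out = fbp_reconstruct(
                d, geom, ReconConfig(chunk_angles=ca, chunk_slices=cs, chunk_columns=cc)
            ).values
            assert rel_rms(out, ref) < 1e-6


class TestSweeps:
    def _sim(self, rng, n=128, phi=20.0, center_offset=0.0, ntheta=96):
        from lamrec.phantoms import brain_phantom

        vol = brain_phantom((n, n, n // 4), seed=3)
        geom = make_geometry(n, ntheta, phi, n3=n // 4,
                             center=n / 2 + center_offset)
        return forward_fourier(vol.values.astype(np.float64), geom), geom

    def test_axis_candidate_coverage(self, rng):
        d, geom = self._sim(rng, n=64)
        cfg = ReconConfig(rotation_axis=1616.0, search_width_axis=20.0,
                          search_step_axis=0.5)
        # candidate grid is [axis-20, axis+20) at 0.5 px
        from lamrec.recon import _sweep_candidates

        cands = _sweep_candidates(1616.0, 20.0, 0.5)
        assert len(cands) == 80
        assert cands[0] == 1596.0 and cands[-1] == 1635.5

    def test_angle_candidate_coverage(self):
        from lamrec.recon import _sweep_candidates

        cands = _sweep_candidates(20.0, 2.0, 0.25)
        assert len(cands) == 16
        assert cands[0] == 18.0 and cands[-1] == 21.75

    def test_zero_width_raises(self, rng):
        d, geom = self._sim(rng, n=32, ntheta=16)
        with pytest.raises(ValueError):
            try_lamino_angle(d, geom, ReconConfig(search_width_angle=0.0))

    def test_axis_recovery_within_half_pixel(self, rng):
        d, geom_true = self._sim(rng, n=128, center_offset=3.0)
        geom_guess = geom_true.replace(center=None)
        sweep = try_rotation_axis(
            d, geom_guess, ReconConfig(search_width_axis=8.0, search_step_axis=0.5))
        assert abs(sweep.best - geom_true.center) <= 0.5

    def test_tilt_recovery_within_one_step(self, rng):
        d, geom_true = self._sim(rng, n=128, phi=20.5)
        geom_guess = geom_true.replace(phi=20.0)
        sweep = try_lamino_angle(
            d, geom_guess, ReconConfig(search_width_angle=2.0, search_step_angle=0.25))
        assert abs(sweep.best - 20.5) <= 0.25

    def test_sweep_writes_one_image_per_candidate(self, rng, tmp_path):
        d, geom = self._sim(rng, n=32, ntheta=16)
        sweep = try_rotation_axis(
            d, geom, ReconConfig(search_width_axis=1.0, search_step_axis=0.5),
            out_dir=tmp_path)
        assert len(list(tmp_path.glob("try_center_*.tiff"))) == len(sweep.candidates) == 4


class TestChunkedExecute:
    def test_identity_across_chunk_sizes(self, rng):
        x = rng.standard_normal((24, 8, 8))
        ref = chunked_execute(np.square, x, 0, None)
        for c in (1, 5, 24, 100):
            assert np.array_equal(chunked_execute(np.square, x, 0, c), ref)

    def test_sum_combine(self, rng):
        x = rng.standard_normal((12, 6))
        want = x.sum(axis=0, keepdims=True)
        got = chunked_execute(lambda a: a.sum(axis=0, keepdims=True), x, 0, 5,
                              combine="sum")
        assert np.allclose(got, want, atol=1e-12)

    def test_working_set_shrinks_with_chunk_size(self):
        import tracemalloc

        x = np.zeros((64, 128, 128))

        def work(chunk):
            return (chunk * 2.0) + 1.0  # allocates ~2 chunk-sized temporaries

        peaks = {}
        for c in (64, 8, 1):
            tracemalloc.start()
            chunked_execute(work, x, 0, c, combine="sum")
            _, peak = tracemalloc.get_traced_memory()
            tracemalloc.stop()
            peaks[c] = peak
        assert peaks[1] < peaks[8] < peaks[64]
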