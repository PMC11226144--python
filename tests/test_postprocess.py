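"""FRC resolution estimation and mosaic stitching."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from lamrec.postprocess import (
    RegistrationError,
    TilePlacement,
    blend_stitch,
    estimate_shift,
    frc,
    halfbit_threshold,
    plan_mosaic,
    resolution_estimate,
    resolution_estimate_volume,
)


def bandlimited_image(rng, n=256, cutoff=0.25):
    """White noise hard-limited to |f| < cutoff cycles/px."""
    spec = np.fft.fft2(rng.standard_normal((n, n)))
    fy = np.fft.fftfreq(n)
    fx = np.fft.fftfreq(n)
    mask = np.hypot(fy[:, None], fx[None, :]) < cutoff
    return np.fft.ifft2(spec * mask).real


class TestFRC:
    def test_identical_inputs_give_unit_correlation(self, rng):
        img = gaussian_filter(rng.standard_normal((64, 64)), 2)
        curve = frc(img, img)
        pop = curve.n_per_shell > 0
        assert np.allclose(curve.frc[pop], 1.0, atol=1e-10)

    def test_independent_noise_decorrelates(self, rng):
        a = rng.standard_normal((128, 128))
        b = rng.standard_normal((128, 128))
        curve = frc(a, b)
        hi = curve.freqs > 0.2
        bound = 3.0 / np.sqrt(curve.n_per_shell[hi])
        assert np.all(np.abs(curve.frc[hi]) <= bound)

    def test_halfbit_asymptote(self):
        assert halfbit_threshold(np.array([1e12]))[0] == pytest.approx(
            0.2071 / 1.2071, abs=1e-4)

    def test_symmetric_and_scale_invariant(self, rng):
        a = gaussian_filter(rng.standard_normal((64, 64)), 1.5)
        b = a + 0.3 * rng.standard_normal((64, 64))
        c1 = frc(a, b)
        c2 = frc(b, a)
        c3 = frc(5.0 * a, 0.2 * b)
        assert np.allclose(c1.frc, c2.frc, atol=1e-12)
        assert np.allclose(c1.frc, c3.frc, atol=1e-10)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            frc(np.zeros((8, 8)), np.zeros((9, 8)))


class TestResolutionEstimate:
    def test_no_crossing_returns_nyquist_flagged(self, rng):
        img = gaussian_filter(rng.standard_normal((64, 64)), 2)
        est = resolution_estimate(frc(img, img), pixel_size=0.92)
        assert not est.crossed
        assert est.resolution == pytest.approx(2 * 0.92)

    def test_recovers_imposed_bandlimit(self, rng):
        signal = bandlimited_image(rng, 256, cutoff=0.25)
        sd = signal.std()
        a = signal + 0.7 * sd * rng.standard_normal(signal.shape)
        b = signal + 0.7 * sd * rng.standard_normal(signal.shape)
        est = resolution_estimate(frc(a, b), pixel_size=1.0)
        assert est.crossed
        assert est.resolution == pytest.approx(4.0, rel=0.10)

    def test_resolution_scales_with_pixel_size(self, rng):
        signal = bandlimited_image(rng, 128, cutoff=0.2)
        a = signal + 0.5 * rng.standard_normal(signal.shape)
        b = signal + 0.5 * rng.standard_normal(signal.shape)
        curve = frc(a, b)
        r1 = resolution_estimate(curve, 1.0).resolution
        r2 = resolution_estimate(curve, 0.5).resolution
        assert r2 == pytest.approx(r1 / 2)

    def test_noisier_inputs_never_improve_resolution(self, rng):
        signal = bandlimited_image(rng, 256, cutoff=0.3)
        sd = signal.std()
        res = []
        for noise in (0.5, 2.0, 5.0):
            a = signal + noise * sd * rng.standard_normal(signal.shape)
            b = signal + noise * sd * rng.standard_normal(signal.shape)
            res.append(resolution_estimate(frc(a, b)).resolution)
        assert res[0] <= res[1] * 1.05 <= res[2] * 1.1

    def test_volume_reports_worst_slice(self, rng):
        sharp = bandlimited_image(rng, 64, cutoff=0.4)
        blurred = gaussian_filter(sharp, 3.0)
        noise = lambda: 0.3 * rng.standard_normal((64, 64))
        va = np.stack([sharp + noise(), blurred + noise()])
        vb = np.stack([sharp + noise(), blurred + noise()])
        worst = resolution_estimate_volume(va, vb)
        per_slice = [resolution_estimate(frc(va[i], vb[i])).resolution for i in range(2)]
        assert worst.resolution == pytest.approx(max(per_slice))


class TestEstimateShift:
    def _tiles(self, rng, shift=(0.0, 0.0), n=400, overlap=120):
        """tile_b's field of view is displaced by ``shift`` from nominal."""
        base = gaussian_filter(rng.standard_normal((n, 2 * n)), 2.0)
        a = base[:, :n]
        from scipy.ndimage import shift as ndshift

        # sampling the window at +shift == shifting the content by -shift
        b_full = ndshift(base, (-shift[0], -shift[1]), order=1, prefilter=False)
        b = b_full[:, n - overlap:2 * n - overlap]
        return a, b, overlap

    def test_zero_shift(self, rng):
        a, b, ov = self._tiles(rng)
        dy, dx = estimate_shift(a, b, ov)
        assert abs(dy) < 0.1 and abs(dx) < 0.1

    @pytest.mark.parametrize("shift", [(7.0, -3.0), (2.5, -1.25)])
    def test_known_shift_recovered(self, rng, shift):
        a, b, ov = self._tiles(rng, shift=shift)
        dy, dx = estimate_shift(a, b, ov)
        assert abs(dy - shift[0]) <= 0.5
        assert abs(dx - shift[1]) <= 0.5

    def test_featureless_overlap_raises(self, rng):
        a = rng.standard_normal((64, 64))
        b = rng.standard_normal((64, 64))
        with pytest.raises(RegistrationError):
            estimate_shift(a, b, 32)


class TestBlendStitch:
    def test_constant_tiles_blend_without_seam(self):
        tiles = [np.full((64, 64), 2.5)] * 2
        placements = plan_mosaic((1, 2), (64, 64), 16)
        out = blend_stitch(tiles, placements)
        assert out.shape == (64, 112)
        assert np.allclose(out, 2.5, atol=1e-12)

    def test_weights_partition_unity(self):
        tiles = [np.ones((40, 40))] * 6
        placements = plan_mosaic((2, 3), (40, 40), 12)
        out = blend_stitch(tiles, placements)
        assert np.abs(out - 1.0).max() < 1e-12

    def test_identity_when_tiles_agree(self, rng):
        truth = gaussian_filter(rng.standard_normal((100, 150)), 2.0)
        placements = plan_mosaic((1, 2), (100, 90), 30)
        tiles = [truth[:, :90], truth[:, 60:150]]
        out = blend_stitch(tiles, placements)
        assert np.abs(out - truth).max() < 1e-10

    def test_gap_raises_listing_uncovered(self):
        tiles = [np.ones((20, 20)), np.ones((20, 20))]
        placements = [
            TilePlacement(0, 0, 0.0, 0.0, (0, 0, 0, 0)),
            TilePlacement(0, 1, 0.0, 30.0, (0, 0, 0, 0)),  # 10-px gap
        ]
        with pytest.raises(ValueError, match="covered by no tile"):
            blend_stitch(tiles, placements)

    def test_full_mosaic_registration_and_blend(self, rng):
        """5 x 3 mosaic with 300-px overlaps and known stage errors:
        pairwise registration recovers each relative shift within half a
        pixel, and blending at the known placements reproduces the ground
        truth in the overlap zones."""
        rows, cols, tile, ov = 3, 5, 420, 300
        step = tile - ov
        maxoff = 4
        H = tile + (rows - 1) * step + 2 * maxoff
        W = tile + (cols - 1) * step + 2 * maxoff
        truth = gaussian_filter(rng.standard_normal((H, W)), 2.0)
        true_off = {(0, 0): (0, 0)}
        tiles = {}
        for r in range(rows):
            for c in range(cols):
                if (r, c) != (0, 0):
                    true_off[(r, c)] = tuple(rng.integers(-maxoff, maxoff + 1, 2))
                dy, dx = true_off[(r, c)]
                y0 = r * step + dy + maxoff
                x0 = c * step + dx + maxoff
                tiles[(r, c)] = truth[y0:y0 + tile, x0:x0 + tile]

        # pairwise registration against each left/top neighbour
        for r in range(rows):
            for c in range(cols):
                if (r, c) == (0, 0):
                    continue
                if c > 0:
                    dy, dx = estimate_shift(tiles[(r, c - 1)], tiles[(r, c)], ov, axis=1)
                    ref = (r, c - 1)
                else:
                    dy, dx = estimate_shift(tiles[(r - 1, c)], tiles[(r, c)], ov, axis=0)
                    ref = (r - 1, c)
                want = (true_off[(r, c)][0] - true_off[ref][0],
                        true_off[(r, c)][1] - true_off[ref][1])
                assert abs(dy - want[0]) <= 0.5
                assert abs(dx - want[1]) <= 0.5

        # blend at the known placements: the mosaic must reproduce the truth
        placements = plan_mosaic((rows, cols), (tile, tile), ov, true_off)
        ordered = [tiles[(p.row, p.col)] for p in placements]
        stitched = blend_stitch(ordered, placements)
        # the blend crops to the fully covered rectangle, whose top-left is
        # the innermost top/left tile edge
        y_start = int(np.ceil(max(p.y0 for p in placements if p.row == 0)))
        x_start = int(np.ceil(max(p.x0 for p in placements if p.col == 0)))
        ref = truth[maxoff + y_start:maxoff + y_start + stitched.shape[0],
                    maxoff + x_start:maxoff + x_start + stitched.shape[1]]
        # overlap zones of the first tile row/column junctions
        for sl in (np.s_[:, step:step + ov], np.s_[step:step + ov, :]):
            got = stitched[sl]
            want = ref[sl]
            err = np.linalg.norm(got - want) / np.linalg.norm(want)
            assert err < 0.01
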