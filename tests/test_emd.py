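"""Bidimensional EMD: extrema, envelopes, sifting, full decomposition."""
import numpy as np
import pytest

from _oracles import (
    brute_extrema_2d,
    brute_zero_crossings,
    emd_1d,
    pearson,
)
from imflight.emd import (
    EMDConfig,
    EnvelopePair,
    build_envelopes,
    check_imf,
    count_zero_crossings,
    decompose,
    extract_next_imf,
    find_extrema,
    local_mean,
    sift_step,
)
from imflight.errors import DataError


def sinusoid_grid(n=64, period=8, amp=1.0):
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    return amp * np.sin(2 * np.pi * xx / period) * np.sin(2 * np.pi * yy / period)


class TestFindExtrema:
    def test_constant_has_none(self):
        ex = find_extrema(np.full((16, 16), 3.0))
        assert ex.n_extrema == 0

    def test_single_bright_pixel(self):
        img = np.zeros((9, 9))
        img[4, 5] = 1.0
        ex = find_extrema(img)
        assert len(ex.maxima) == 1
        assert tuple(ex.maxima[0]) == (4.0, 5.0, 1.0)

    def test_sinusoid_matches_brute_force_scan(self):
        img = sinusoid_grid(64, 8)
        ex = find_extrema(img)
        bmax, bmin = brute_extrema_2d(img)
        assert {(int(r), int(c)) for r, c, _ in ex.maxima} == set(bmax)
        assert {(int(r), int(c)) for r, c, _ in ex.minima} == set(bmin)

    def test_plateau_contributes_centroid_only(self):
        img = np.zeros((11, 11))
        img[4:7, 4:7] = 1.0  # 3x3 flat top
        ex = find_extrema(img)
        assert len(ex.maxima) == 1
        assert tuple(ex.maxima[0][:2]) == (5.0, 5.0)

    def test_shoulder_plateau_rejected(self):
        img = np.zeros((8, 8))
        img[:, 4:] = 1.0  # step, flat region touches nothing smaller on its level
        img[0, 0] = -1.0
        ex = find_extrema(img)
        # the high flat side is a plateau bounded by smaller values only at
        # its left edge -> edge pixels are excluded, interior is a plateau
        # adjacent to equal excluded pixels, so no spurious interior maxima
        for r, c, _ in ex.maxima:
            assert c >= 4

    def test_extrema_strictness(self, rng):
        img = rng.random((32, 32))
        ex = find_extrema(img)
        for r, c, v in ex.maxima:
            r, c = int(r), int(c)
            patch = img[max(0, r - 1):r + 2, max(0, c - 1):c + 2]
            assert v == patch.max()


class TestZeroCrossings:
    def test_alternating_row(self):
        img = np.array([[1.0, -1, 1, -1, 1, -1, 1, -1]])
        assert count_zero_crossings(img) == 7

    def test_all_positive(self, rng):
        assert count_zero_crossings(rng.random((10, 10)) + 1.0) == 0

    def test_negation_symmetry(self, rng):
        img = rng.standard_normal((12, 12))
        assert count_zero_crossings(img) == count_zero_crossings(-img)

    def test_matches_brute_force(self, rng):
        img = rng.standard_normal((15, 9))
        img[rng.random((15, 9)) < 0.1] = 0.0  # exercise zero-skipping
        assert count_zero_crossings(img) == brute_zero_crossings(img)


class TestEnvelopes:
    def test_flat_extrema_give_flat_surfaces(self):
        img = sinusoid_grid(48, 8, amp=1.0)
        ex = find_extrema(img)
        env = build_envelopes(ex, img.shape)
        interior = np.s_[8:40, 8:40]
        assert np.allclose(env.upper[interior], 1.0, atol=0.1)
        assert np.allclose(env.lower[interior], -1.0, atol=0.1)

    def test_envelopes_interpolate_extrema_exactly(self):
        img = sinusoid_grid(48, 12, amp=0.7) + 0.1 * sinusoid_grid(48, 5)
        ex = find_extrema(img)
        env = build_envelopes(ex, img.shape)
        for r, c, v in ex.maxima:
            assert abs(env.upper[int(r), int(c)] - v) < 1e-6

    def test_ribbon_envelopes_reach_amplitude(self):
        t = np.arange(200, dtype=float)
        row = (0.8 * np.sin(2 * np.pi * t / 16))[None, :]
        env = build_envelopes(find_extrema(row), row.shape)
        inner = np.s_[0, 30:170]
        assert np.allclose(env.upper[inner], 0.8, atol=0.05)
        assert np.allclose(env.lower[inner], -0.8, atol=0.05)

    def test_upper_dominates_lower_almost_everywhere(self, rng):
        img = rng.standard_normal((40, 40))
        env = build_envelopes(find_extrema(img), img.shape)
        assert np.mean(env.upper >= env.lower) >= 0.99

    def test_insufficient_extrema_signal(self):
        ramp = np.add.outer(np.arange(16.0), np.arange(16.0))
        assert build_envelopes(find_extrema(ramp), ramp.shape) is None


class TestLocalMeanAndSift:
    def test_antisymmetric_envelopes_zero_mean(self, rng):
        u = rng.random((8, 8))
        assert not local_mean(EnvelopePair(upper=u, lower=-u)).any()

    def test_equal_envelopes(self):
        c = np.full((6, 6), 0.3)
        assert np.allclose(local_mean(EnvelopePair(upper=c, lower=c)), 0.3)

    def test_elementwise_oracle(self, rng):
        u, l = rng.random((7, 9)), rng.random((7, 9))
        m = local_mean(EnvelopePair(upper=u, lower=l))
        for i in range(7):
            for j in range(9):
                assert m[i, j] == (u[i, j] + l[i, j]) / 2

    def test_shape_mismatch(self, rng):
        with pytest.raises(DataError):
            local_mean(EnvelopePair(upper=np.zeros((3, 3)), lower=np.zeros((4, 4))))

    def test_sift_preserves_zero_mean_sinusoid(self):
        img = sinusoid_grid(64, 8)
        detail, mean_mag = sift_step(img)
        inner = np.s_[8:56, 8:56]
        assert pearson(detail[inner], img[inner]) > 0.99
        assert mean_mag < 0.2 * img.std()

    def test_sift_removes_constant_offset(self):
        img = sinusoid_grid(64, 8)
        d0, _ = sift_step(img)
        d1, _ = sift_step(img + 5.0)
        inner = np.s_[8:56, 8:56]
        assert np.abs(d0[inner] - d1[inner]).max() < 0.05

    def test_monotone_ramp_signals_no_envelope(self):
        ramp = np.add.outer(np.arange(20.0), np.arange(20.0))
        assert sift_step(ramp) is None


class TestCheckIMF:
    def test_sinusoid_passes(self):
        report = check_imf(sinusoid_grid(64, 8))
        assert report.passes
        # per-line slack: 64 rows + 64 columns
        assert report.extrema_zero_gap <= 128

    def test_strictly_positive_fails(self):
        report = check_imf(sinusoid_grid(64, 8) + 2.0)
        assert not report.passes
        assert report.n_zero_crossings == 0

    def test_constant_passes_vacuously(self):
        report = check_imf(np.full((16, 16), 1.0))
        assert report.passes
        assert report.n_extrema == 0 and report.n_zero_crossings == 0


class TestExtractIMF:
    def test_fast_component_recovered_over_ramp(self):
        yy, xx = np.mgrid[0:64, 0:64].astype(float)
        fast = 0.5 * sinusoid_grid(64, 8)
        slow = 0.01 * (xx + yy)
        imf, _ = extract_next_imf(fast + slow)
        tr = np.s_[6:58, 6:58]
        assert pearson(imf[tr], fast[tr]) > 0.95

    def test_already_imf_is_fixed_point(self):
        img = sinusoid_grid(64, 8)
        imf, n_iter = extract_next_imf(img)
        assert n_iter <= 2
        inner = np.s_[6:58, 6:58]
        assert pearson(imf[inner], img[inner]) > 0.99

    def test_ramp_yields_no_imf(self):
        ramp = np.add.outer(np.arange(24.0), np.arange(24.0))
        assert extract_next_imf(ramp) is None


class TestDecompose:
    def test_constant_and_ramp_terminal(self):
        for img in (np.full((20, 20), 0.4),
                    np.add.outer(np.arange(20.0), np.arange(20.0))):
            stack = decompose(img)
            assert len(stack) == 0
            assert np.array_equal(stack.residual, img)

    def test_reconstruction_identity(self, rng):
        img = rng.random((48, 48))
        stack = decompose(img)
        assert len(stack) >= 1
        err = np.abs(stack.reconstruct() - img).max()
        assert err <= 1e-8 * (img.max() - img.min())

    def test_row_signal_matches_independent_1d_oracle(self):
        t = np.arange(256, dtype=float)
        sig = np.sin(2 * np.pi * t / 10) + 0.7 * np.sin(2 * np.pi * t / 60)
        stack = decompose(sig[None, :])
        imfs, _ = emd_1d(sig)
        assert len(stack) >= 2 and len(imfs) >= 2
        inner = np.s_[26:230]
        for k in range(2):
            assert pearson(stack.components[k][0, inner], imfs[k][inner]) > 0.9

    def test_frequency_ordering_on_phantom(self, small_spec):
        from imflight.phantoms import generate_phantom

        ph = generate_phantom(small_spec, 1, np.random.default_rng(0))
        stack = decompose(ph.composite)
        counts = [find_extrema(c).n_extrema for c in stack.components]
        assert all(b <= 1.1 * a for a, b in zip(counts, counts[1:]))

    def test_idempotence_energy_concentration(self):
        yy, xx = np.mgrid[0:64, 0:64].astype(float)
        img = 0.5 * sinusoid_grid(64, 8) + 0.02 * (xx + yy)
        first = decompose(img).components[0]
        again = decompose(first)
        energies = [float(np.sum(c**2)) for c in again.components]
        total = sum(energies) + float(np.sum(again.residual**2))
        assert energies[0] / total >= 0.9

    def test_deterministic(self, rng):
        img = rng.random((40, 40))
        a, b = decompose(img), decompose(img)
        assert len(a) == len(b)
        for ca, cb in zip(a.components, b.components):
            assert np.array_equal(ca, cb)

    def test_non_2d_rejected(self):
        with pytest.raises(DataError):
            decompose(np.zeros((4, 4, 3)))
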