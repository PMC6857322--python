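"""Time-series preprocessing: discard, nuisance regression, detrend,
framewise displacement / scrubbing, and the ideal band-pass filter."""

import numpy as np
import pytest

from oscnet.bands import SLOW3, SLOW4, SLOW5, BandDefinition, full_partition
from oscnet.preprocess import (
    NuisanceDesign,
    ScrubMask,
    TimeSeriesMatrix,
    apply_scrub,
    bandpass_ideal,
    build_nuisance_design,
    compute_fd_and_scrub,
    detrend_linear,
    discard_initial_volumes,
    framewise_displacement,
    friston24,
    regress_nuisance,
)

from conftest import make_ts


class TestDiscard:
    def test_discards_first_k_columns(self, rng):
        ts = make_ts(rng.standard_normal((4, 205)))
        out = discard_initial_volumes(ts, 10)
        assert out.n_timepoints == 195
        np.testing.assert_array_equal(out.values, ts.values[:, 10:])

    def test_zero_is_identity(self, random_ts):
        out = discard_initial_volumes(random_ts, 0)
        np.testing.assert_array_equal(out.values, random_ts.values)

    @pytest.mark.parametrize("k", [205, 300, -1])
    def test_out_of_range_discard_rejected(self, rng, k):
        ts = make_ts(rng.standard_normal((3, 205)))
        with pytest.raises(ValueError):
            discard_initial_volumes(ts, k)


class TestNuisanceRegression:
    def test_signal_equal_to_design_column_vanishes(self, rng):
        T = 100
        col = rng.standard_normal(T)
        ts = make_ts(np.vstack([col, 2.0 * col]))
        design = NuisanceDesign(col[:, None], ["reg"])
        out = regress_nuisance(ts, design)
        assert np.abs(out.values).max() < 1e-10

    def test_empty_design_demeans(self, rng):
        ts = make_ts(rng.standard_normal((5, 80)) + 3.0)
        out = regress_nuisance(ts, NuisanceDesign(np.zeros((80, 0)), []))
        expected = ts.values - ts.values.mean(axis=1, keepdims=True)
        np.testing.assert_allclose(out.values, expected, atol=1e-10)

    def test_residuals_orthogonal_to_every_column(self, rng):
        T = 120
        X = rng.standard_normal((T, 5))
        ts = make_ts(rng.standard_normal((7, T)))
        out = regress_nuisance(ts, NuisanceDesign(X))
        for j in range(X.shape[1]):
            dots = out.values @ X[:, j]
            scale = np.linalg.norm(out.values, axis=1) * np.linalg.norm(X[:, j])
            assert np.all(np.abs(dots) < 1e-8 * np.maximum(scale, 1.0))

    def test_duplicate_columns_pruned_not_fatal(self, rng):
        T = 60
        col = rng.standard_normal(T)
        design = NuisanceDesign(np.column_stack([col, col]), ["a", "a_copy"])
        ts = make_ts(rng.standard_normal((2, T)))
        out = regress_nuisance(ts, design)  # pruning keeps the fit well posed
        assert np.all(np.abs(out.values @ col) < 1e-8 * T)

    def test_row_mismatch_rejected(self, rng):
        ts = make_ts(rng.standard_normal((2, 50)))
        with pytest.raises(ValueError, match="rows"):
            regress_nuisance(ts, NuisanceDesign(np.ones((40, 1))))


class TestDetrend:
    def test_pure_line_removed(self):
        t = np.arange(100, dtype=float)
        ts = make_ts(np.vstack([3.0 + 0.5 * t, -1.0 - 2.0 * t]))
        out = detrend_linear(ts)
        assert np.abs(out.values).max() < 1e-9

    def test_idempotent(self, random_ts):
        once = detrend_linear(random_ts)
        twice = detrend_linear(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-10)

    def test_line_plus_sinusoid_recovers_detrended_sinusoid(self):
        """Oracle: subtract the known line analytically, then remove the
        sinusoid's own (small) projection on the line; detrending the sum
        must land exactly there."""
        t = np.arange(200, dtype=float)
        sin = np.sin(2 * np.pi * t / 20.0)
        out = detrend_linear(make_ts((2.0 + 0.3 * t + sin)[None, :]))
        X = np.column_stack([np.ones_like(t), t])
        beta = np.linalg.lstsq(X, sin, rcond=None)[0]
        expected = sin - X @ beta
        np.testing.assert_allclose(out.values[0], expected, atol=1e-8)
        # the residual projection is tiny: the sinusoid survives detrending
        assert np.abs(out.values[0] - sin).max() < 0.1


class TestFramewiseDisplacement:
    def test_zero_motion_no_flags(self):
        mask = compute_fd_and_scrub(np.zeros((50, 6)), 0.5)
        assert mask.fraction_bad == 0.0
        assert mask.fd_series[0] == 0.0

    def test_translation_jump_flagged(self):
        P = np.zeros((30, 6))
        P[10:, 0] = 1.0  # 1 mm step in x at frame 10
        mask = compute_fd_and_scrub(P, 0.5)
        assert mask.fd_series[10] == pytest.approx(1.0)
        assert mask.flags[10] and mask.flags.sum() == 1

    def test_rotation_arc_length_on_50mm_sphere(self):
        P = np.zeros((10, 6))
        P[5:, 4] = 0.02  # 0.02 rad step -> 50 * 0.02 = 1.0 mm
        fd = framewise_displacement(P)
        assert fd[5] == pytest.approx(1.0)

    def test_augment_policy_flags_neighbours(self):
        P = np.zeros((30, 6))
        P[10, 0] = 1.0  # single-frame spike: FD spikes at frames 10 and 11
        mask = compute_fd_and_scrub(P, 0.5, augment_policy="1back2fwd")
        assert mask.flags[9] and mask.flags[10] and mask.flags[11]

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            framewise_displacement(np.zeros((1, 6)))


class TestScrub:
    def test_no_flags_identity(self, random_ts):
        mask = ScrubMask(np.zeros(195, bool), np.zeros(195), 0.5)
        out, report = apply_scrub(random_ts, mask)
        np.testing.assert_array_equal(out.values, random_ts.values)
        assert report["fraction_removed"] == 0.0

    @pytest.mark.parametrize(
        "n_bad,expect_over_third", [(65, False), (66, True)]
    )
    def test_one_third_boundary(self, rng, n_bad, expect_over_third):
        # exclusion rule is strictly "> 1/3 of frames removed"
        ts = make_ts(rng.standard_normal((3, 195)))
        flags = np.zeros(195, bool)
        flags[:n_bad] = True
        out, report = apply_scrub(ts, ScrubMask(flags, np.zeros(195), 0.5))
        assert out.n_timepoints == 195 - n_bad
        assert (report["fraction_removed"] > 1 / 3) is expect_over_third

    def test_all_flagged_rejected(self, random_ts):
        mask = ScrubMask(np.ones(195, bool), np.zeros(195), 0.5)
        with pytest.raises(ValueError):
            apply_scrub(random_ts, mask)


def _sinusoid(freq_hz, T=195, tr=2.0):
    t = np.arange(T) * tr
    return np.sin(2 * np.pi * freq_hz * t)


class TestBandpass:
    def test_in_band_sinusoid_preserved(self):
        T, tr = 200, 2.0  # 0.05 Hz is exactly bin 20 of a 200-sample series
        x = _sinusoid(0.05, T, tr)
        out = bandpass_ideal(make_ts(x[None, :], tr), SLOW4)
        assert np.abs(out.values[0] - x).max() < 0.01 * np.abs(x).max()
        assert out.band == "slow-4"

    def test_out_of_band_sinusoid_rejected(self):
        T, tr = 200, 2.0
        x = _sinusoid(0.05, T, tr)
        out = bandpass_ideal(make_ts(x[None, :], tr), SLOW5)
        assert np.sqrt((out.values**2).mean()) < 1e-6 * np.sqrt((x**2).mean())

    def test_mixture_separated_against_fft_oracle(self):
        T, tr = 390, 2.0  # bin-aligned frequencies: k/(T*tr)
        lo = _sinusoid(16 / (T * tr), T, tr)   # ~0.0205 Hz, slow-5
        hi = _sinusoid(117 / (T * tr), T, tr)  # 0.15 Hz, slow-3
        out = bandpass_ideal(make_ts((lo + hi)[None, :], tr), SLOW3)
        # oracle: directly constructed in-band component
        assert np.abs(out.values[0] - hi).max() < 1e-6

    def test_five_band_partition_reconstructs_signal(self, rng):
        ts = make_ts(rng.standard_normal((4, 195)))
        total = np.zeros_like(ts.values)
        for band in full_partition(ts.tr_seconds):
            total = total + bandpass_ideal(ts, band).values
        rms = np.sqrt((ts.values**2).mean())
        assert np.sqrt(((total - ts.values) ** 2).mean()) < 1e-8 * rms

    def test_filter_and_demean_commute_for_ac_bands(self, rng):
        ts = make_ts(rng.standard_normal((3, 195)) + 5.0)
        demeaned = make_ts(ts.values - ts.values.mean(axis=1, keepdims=True))
        a = bandpass_ideal(demeaned, SLOW4).values
        b = bandpass_ideal(ts, SLOW4).values
        b = b - b.mean(axis=1, keepdims=True)
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_band_above_nyquist_rejected(self):
        ts = make_ts(np.random.default_rng(0).standard_normal((2, 50)), tr=2.0)
        with pytest.raises(ValueError):
            bandpass_ideal(ts, BandDefinition("too-high", 0.3, 0.4))


def test_regress_then_detrend_equals_joint_for_detrended_design(rng):
    """Sequential nuisance regression + linear detrend equals the joint
    regression containing a linear term when the nuisance columns carry no
    linear trend themselves (Frisch-Waugh); with trending columns the two
    differ, which is why the pipeline fixes the stage order."""
    T = 150
    t_lin = np.arange(T, dtype=float)
    L = np.column_stack([np.ones(T), t_lin])
    X = rng.standard_normal((T, 4))
    X = X - L @ np.linalg.lstsq(L, X, rcond=None)[0]  # remove trend from design
    ts = make_ts(rng.standard_normal((6, T)))
    seq = detrend_linear(regress_nuisance(ts, NuisanceDesign(X)))
    joint = regress_nuisance(ts, NuisanceDesign(np.column_stack([X, t_lin])))
    assert np.abs(seq.values - joint.values).max() < 1e-8


def test_friston24_layout(rng):
    P = rng.standard_normal((50, 6))
    F = friston24(P)
    assert F.shape == (50, 24)
    np.testing.assert_array_equal(F[:, :6], P)
    np.testing.assert_array_equal(F[1:, 6:12], P[:-1])
    np.testing.assert_array_equal(F[:, 12:18], P**2)
    assert np.all(F[0, 6:12] == 0)


def test_build_nuisance_design_full(rng):
    P = rng.standard_normal((60, 6))
    d = build_nuisance_design(P, wm_signal=rng.standard_normal(60), csf_signal=rng.standard_normal(60))
    assert d.columns.shape == (60, 26)
    assert d.column_names[-2:] == ["wm", "csf"]
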