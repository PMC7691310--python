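import numpy as np
import pytest

from polfoot.annotation import Anchor
from polfoot.matrix import MatrixSpec
from polfoot.peaks import (PeakCall, PeakConfig, call_short_fragment_peak,
                           filter_peaks, loess_smooth)

SPEC = MatrixSpec(1500, 10)
ANCHOR = Anchor("chr1", 100000, "+", "g")


def naive_loess(y, span=0.05, degree=2):
    """Literal point-by-point LOESS: q nearest bins, tricube weights,
    weighted polyfit, evaluated at the bin.  Independent of the
    convolution-based implementation."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    q = int(np.ceil(span * n))
    out = np.empty(n)
    for i in range(n):
        window = np.arange(max(0, i - q), min(n, i + q + 1))
        d = np.abs(window - i)
        idx = window[np.argsort(d, kind="stable")[:q]]
        dd = np.abs(idx - i).astype(float)
        dmax = dd.max()
        u = dd / dmax if dmax > 0 else dd
        w = np.maximum((1 - u**3) ** 3, 1e-12)
        V = np.vander((idx - i).astype(float), degree + 1, increasing=True)
        beta = np.linalg.solve(V.T @ (V * w[:, None]), (V * w[:, None]).T @ y[idx])
        out[i] = beta[0]
    return out


class TestLoess:
    def test_constant_profile_reproduced(self):
        y = np.full(300, 3.25)
        assert np.allclose(loess_smooth(y), y, atol=1e-9)

    def test_linear_profile_reproduced(self):
        y = 0.7 * np.arange(300) - 12.0
        assert np.allclose(loess_smooth(y), y, atol=1e-8)

    def test_matches_naive_pointwise_fit(self):
        rng = np.random.default_rng(8)
        y = rng.normal(5, 1, 240) + 10 * np.exp(-((np.arange(240) - 100) / 12) ** 2)
        smooth = loess_smooth(y, PeakConfig(span=0.06))
        assert np.allclose(smooth, naive_loess(y, span=0.06), atol=1e-8)

    def test_argmax_matches_statsmodels_lowess(self):
        from statsmodels.nonparametric.smoothers_lowess import lowess

        rng = np.random.default_rng(9)
        n = 300
        x = np.arange(n)
        y = 20 * np.exp(-((x - 173) / 8.0) ** 2) + rng.normal(0, 1.0, n)
        ours = loess_smooth(y)
        oracle = lowess(y, x.astype(float), frac=0.05, it=0,
                        return_sorted=False)
        assert abs(int(np.argmax(ours)) - int(np.argmax(oracle))) <= 2

    def test_shift_equivariance_in_the_interior(self):
        rng = np.random.default_rng(10)
        bump = 8 * np.exp(-((np.arange(60) - 30) / 6.0) ** 2)
        base = np.zeros(300)
        base[100:160] += bump
        shifted = np.zeros(300)
        shifted[140:200] += bump
        s1 = loess_smooth(base)
        s2 = loess_smooth(shifted)
        assert np.allclose(s1[80:180], s2[120:220], atol=1e-9)

    def test_too_few_points_error(self):
        with pytest.raises(ValueError, match="span"):
            loess_smooth(np.ones(5))
        with pytest.raises(ValueError, match="span"):
            loess_smooth(np.ones(20), PeakConfig(span=0.05))  # q=1 < degree+1


def gaussian_row(center_offset, height=20.0, width=30.0):
    offs = np.array([SPEC.bin_center_offset(j) for j in range(SPEC.n_bins)])
    return height * np.exp(-((offs - center_offset) / width) ** 2)


class TestPeakCall:
    def test_bump_at_anchor_has_zero_ish_offset(self):
        call = call_short_fragment_peak(gaussian_row(0), ANCHOR, SPEC)
        assert abs(call.tss_offset) <= 5   # bin centres sit at +-5, +-15, ...
        assert call.passes_background and call.passes_distance

    def test_equidistant_tie_broken_upstream(self):
        row = gaussian_row(-255) + gaussian_row(255)  # exactly mirrored
        call = call_short_fragment_peak(row, ANCHOR, SPEC)
        assert call.tss_offset == -255

    def test_nearer_peak_wins_tie_on_magnitude(self):
        # two identical, well-separated bumps; the one closer to the TSS wins
        row = gaussian_row(-35, width=15) + gaussian_row(195, width=15)
        call = call_short_fragment_peak(row, ANCHOR, SPEC)
        assert call.tss_offset == -35

    def test_minus_strand_peak_position_mirrors(self):
        minus = Anchor("chr1", 100000, "-", "g")
        call = call_short_fragment_peak(gaussian_row(205), minus, SPEC)
        assert call.tss_offset == 205
        assert call.peak_position == 100000 - 205

    def test_background_threshold_is_strict(self):
        row = gaussian_row(0, height=20)
        call = call_short_fragment_peak(row, ANCHOR, SPEC)
        at_boundary = PeakConfig(background_threshold=call.fitted_height)
        recall = call_short_fragment_peak(row, ANCHOR, SPEC, at_boundary)
        assert recall.fitted_height == call.fitted_height
        assert not recall.passes_background      # height > threshold is strict
        below = PeakConfig(background_threshold=call.fitted_height - 1e-9)
        assert call_short_fragment_peak(row, ANCHOR, SPEC, below).passes_background

    def test_distance_filter_inclusive_at_500(self):
        near = call_short_fragment_peak(gaussian_row(495, width=15), ANCHOR, SPEC)
        far = call_short_fragment_peak(gaussian_row(595, width=15), ANCHOR, SPEC)
        assert near.passes_distance and abs(near.tss_offset) <= 500
        assert not far.passes_distance

    def test_all_zero_row_fails_both_filters(self):
        call = call_short_fragment_peak(np.zeros(SPEC.n_bins), ANCHOR, SPEC)
        assert call.fitted_height == 0.0
        assert not call.passes_background and not call.passes_distance


class TestFilterPeaks:
    def mk(self, height, offset):
        cfg = PeakConfig()
        return PeakCall("g", "chr1", 0, offset, height, height,
                        height > cfg.background_threshold,
                        abs(offset) <= cfg.max_tss_distance)

    def test_stagewise_counts(self):
        calls = [self.mk(6, -480), self.mk(6, 501), self.mk(4, 0)]
        retained, counts = filter_peaks(calls)
        assert [c.tss_offset for c in retained] == [-480]
        assert counts == {"total": 3, "above_background": 2,
                          "above_background_and_near_tss": 1}
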