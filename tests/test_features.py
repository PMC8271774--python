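"""Delta kinematics, summary features and dominant-frequency extraction."""

import numpy as np
import pytest

from micromotion import (
    DeltaSeries,
    LandmarkStream,
    dominant_peak_frequency,
    feature_table,
    frame_deltas,
    summary_features,
)


def naive_dft_peak(x, fps, low=2.0, high=None):
    """O(n^2) DFT oracle: dominant in-band frequency of a mean-removed series."""
    x = np.asarray(x, float)
    x = x - x.mean()
    n = x.size
    high = fps / 2 if high is None else high
    best_f, best_mag = None, 0.0
    for k in range(n // 2 + 1):
        f = k * fps / n
        if not (low <= f <= high):
            continue
        re = sum(x[j] * np.cos(2 * np.pi * k * j / n) for j in range(n))
        im = sum(-x[j] * np.sin(2 * np.pi * k * j / n) for j in range(n))
        mag = np.hypot(re, im)
        if mag > best_mag + 1e-9:  # strict improvement: ties stay at lower f
            best_f, best_mag = f, mag
    return best_f


def _delta(mag, fps=30.0):
    """DeltaSeries with a prescribed magnitude series (offset keeps it >= 0;
    the spectral path mean-removes, so only the oscillation matters)."""
    mag = np.asarray(mag, float)
    mag = mag - min(0.0, mag.min())
    return DeltaSeries(dx=mag, dy=np.zeros_like(mag), magnitude=mag, fps=fps)


class TestFrameDeltas:
    def test_constant_positions_zero_deltas(self):
        d = frame_deltas(np.tile([3.0, 4.0], (10, 1)))
        assert np.all(d.magnitude == 0)
        assert len(d) == 9

    def test_prev_minus_curr_sign_convention(self):
        pos = np.column_stack([np.arange(6, dtype=float), np.zeros(6)])
        d = frame_deltas(pos)
        np.testing.assert_allclose(d.dx, -1.0)
        np.testing.assert_allclose(d.magnitude, 1.0)

    def test_random_walk_matches_pairwise_oracle(self, rng):
        pos = np.cumsum(rng.normal(size=(40, 2)), axis=0)
        d = frame_deltas(pos)
        for n in range(1, 40):
            assert d.dx[n - 1] == pytest.approx(pos[n - 1, 0] - pos[n, 0])
            assert d.dy[n - 1] == pytest.approx(pos[n - 1, 1] - pos[n, 1])
            assert d.magnitude[n - 1] == pytest.approx(
                np.hypot(pos[n - 1, 0] - pos[n, 0], pos[n - 1, 1] - pos[n, 1])
            )

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            frame_deltas(np.zeros((1, 2)))


class TestSummaryFeatures:
    def test_unit_magnitudes(self):
        assert summary_features(_delta(np.ones(10))) == pytest.approx((1.0, 0.0))

    def test_population_sd_convention(self):
        mean, sd = summary_features(_delta([0.0, 2.0]))
        assert (mean, sd) == pytest.approx((1.0, 1.0))

    def test_matches_two_pass_oracle(self, rng):
        mags = rng.uniform(0, 5, size=50)
        mean, sd = summary_features(_delta(mags))
        mu = sum(mags) / len(mags)
        var = sum((m - mu) ** 2 for m in mags) / len(mags)
        assert mean == pytest.approx(mu, rel=1e-12)
        assert sd == pytest.approx(np.sqrt(var), rel=1e-12)


class TestDominantPeak:
    def test_recovers_pure_sinusoid(self):
        t = np.arange(120) / 30.0
        f = dominant_peak_frequency(_delta(np.sin(2 * np.pi * 6.0 * t)))
        assert f == pytest.approx(6.0, abs=30.0 / 120)

    def test_constant_series_absent(self):
        assert dominant_peak_frequency(_delta(np.full(64, 2.0))) is None

    def test_larger_amplitude_component_wins(self):
        t = np.arange(120) / 30.0
        x = 1.0 * np.sin(2 * np.pi * 4 * t) + 3.0 * np.sin(2 * np.pi * 10 * t)
        f = dominant_peak_frequency(_delta(x))
        assert f == pytest.approx(10.0, abs=30.0 / 120)
        assert f == pytest.approx(naive_dft_peak(x, 30.0), abs=1e-9)

    def test_agrees_with_naive_dft_on_random_series(self, rng):
        for _ in range(20):
            n = int(rng.integers(16, 64))
            x = rng.normal(size=n)
            mine = dominant_peak_frequency(_delta(x))
            assert mine == pytest.approx(naive_dft_peak(x, 30.0), abs=1e-9)

    def test_short_section_absent(self):
        assert dominant_peak_frequency(_delta(np.ones(5))) is None

    def test_band_restriction_excludes_slow_drift(self):
        t = np.arange(120) / 30.0
        # 1 Hz is below the 2 Hz micromovement band edge; 5 Hz must win
        x = 5.0 * np.sin(2 * np.pi * 1.0 * t) + 1.0 * np.sin(2 * np.pi * 5.0 * t)
        assert dominant_peak_frequency(_delta(x)) == pytest.approx(5.0, abs=30.0 / 120)

    def test_within_nyquist(self, rng):
        x = rng.normal(size=60)
        f = dominant_peak_frequency(_delta(x))
        assert 0 < f <= 15.0


@pytest.fixture(scope="module")
def stream():
    from micromotion import ExpressionProfile, generate_stream

    profile = ExpressionProfile("happiness", onset_amplitude=6.0,
                                vibration_amplitude=1.5, vibration_hz=8.0)
    return generate_stream(profile, duration_s=40.0, seed=5,
                           meta={"subject": 0, "emotion": "happiness",
                                 "authenticity": "real"})


class TestFeatureTable:

    def test_44_rows_11_aus_4_sections(self, stream):
        table = feature_table(stream)
        assert len(table) == 44
        assert table["au"].nunique() == 11
        assert set(table["section"]) == {"pre", "t+0.5", "t+1", "t+4"}

    def test_determinism(self, stream):
        a, b = feature_table(stream), feature_table(stream)
        assert a.equals(b)

    def test_translation_invariance(self, stream):
        moved = LandmarkStream(frames=stream.frames + np.array([37.0, -11.0]),
                               fps=stream.fps, meta=stream.meta)
        a, b = feature_table(stream), feature_table(moved)
        for col in ("mean_delta", "sd_delta", "dominant_peak_hz"):
            np.testing.assert_allclose(a[col], b[col], rtol=1e-9)
        assert (a["onset_frame"] == b["onset_frame"]).all()

    def test_scale_equivariance(self, stream):
        c = 2.5
        scaled = LandmarkStream(frames=stream.frames * c, fps=stream.fps, meta=stream.meta)
        a, b = feature_table(stream), feature_table(scaled)
        np.testing.assert_allclose(b["mean_delta"], c * a["mean_delta"], rtol=1e-9)
        np.testing.assert_allclose(b["sd_delta"], c * a["sd_delta"], rtol=1e-9)
        np.testing.assert_allclose(b["dominant_peak_hz"], a["dominant_peak_hz"], rtol=1e-9)
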