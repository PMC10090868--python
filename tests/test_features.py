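"""Feature-bank definitions against closed forms and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ppgsleep.features import (FEATURE_CATALOG, FEATURE_NAMES,
                               basic_stats, cardioresp_features,
                               extract_features, higuchi_fd, hjorth,
                               katz_fd, lyapunov_coeff, morph_features,
                               poincare, spectral_features)
from ppgsleep.pulse import BeatFiducials, PulseSeries


from oracles import higuchi_oracle, poincare_oracle


def _const_series(value, n):
    return PulseSeries(beat_times=np.arange(n + 1, dtype=float),
                       ppi=np.full(n, value), riam=np.ones(n + 1),
                       rifm=1000.0 / np.full(n, value),
                       valid_mask=np.ones(n, dtype=bool))


# --- catalog ------------------------------------------------------------------

class TestCatalog:
    def test_exactly_79_uniquely_named_features(self):
        assert len(FEATURE_CATALOG) == 79
        assert len(set(FEATURE_NAMES)) == 79
        assert [e.index for e in FEATURE_CATALOG] == list(range(1, 80))

    def test_family_cardinalities(self):
        counts = {}
        for e in FEATURE_CATALOG:
            counts[e.family] = counts.get(e.family, 0) + 1
        assert counts == {"BP": 14, "CR": 18, "SND-PPG": 25, "SND-PPI": 22}


# --- morphology ---------------------------------------------------------------

def _beat(a1, a2, t1=0.3, t2=0.7):
    return BeatFiducials(onset_idx=0, peak_idx=10, inflection_idx=40,
                         end_idx=128, A1=a1, A2=a2, T1=t1, T2=t2)


class TestMorphFeatures:
    def test_identical_beats_have_zero_spread(self):
        out = morph_features([_beat(1.0, 2.0)] * 5)
        assert out["meanIPAR"] == pytest.approx(2.0)
        assert out["meanA"] == pytest.approx(3.0)
        for name in ("sdA1", "sdA2", "sdA", "sdT1", "sdT2", "sdIPAR", "sdIPTR"):
            assert out[name] == 0.0

    def test_matches_direct_recomputation(self, rng):
        beats = [_beat(rng.uniform(0.5, 2), rng.uniform(0.5, 2),
                       rng.uniform(0.2, 0.4), rng.uniform(0.5, 0.9))
                 for _ in range(20)]
        out = morph_features(beats)
        a1 = np.array([b.A1 for b in beats])
        assert out["meanA1"] == pytest.approx(a1.mean())
        assert out["sdA1"] == pytest.approx(a1.std(ddof=1))
        iptr = np.array([b.T2 / b.T1 for b in beats])
        assert out["meanIPTR"] == pytest.approx(iptr.mean())


# --- cardio-respiratory -------------------------------------------------------

class TestCardiorespFeatures:
    def test_constant_ppi_has_zero_dispersion(self):
        out = cardioresp_features(_const_series(1000.0, 4))
        assert out["sdPPI"] == 0.0
        assert out["sdsdPPI"] == 0.0
        assert out["rmssdPPI"] == 0.0
        assert out["pPP50"] == 0.0

    def test_ppp50_counts_differences_over_50ms(self):
        # successive differences 10, 60, 70, 20 ms -> 2 of 4 exceed 50
        ppi = 1000.0 + np.cumsum([0.0, 10.0, 60.0, 70.0, 20.0])
        ps = PulseSeries(beat_times=np.arange(6, dtype=float), ppi=ppi,
                         riam=np.ones(6), rifm=1000.0 / ppi,
                         valid_mask=np.ones(5, dtype=bool))
        assert cardioresp_features(ps)["pPP50"] == pytest.approx(50.0)

    def test_rmssd_of_linear_ramp(self):
        ppi = np.array([900.0, 1000.0, 1100.0])
        ps = PulseSeries(beat_times=np.arange(4, dtype=float), ppi=ppi,
                         riam=np.ones(4), rifm=1000.0 / ppi,
                         valid_mask=np.ones(3, dtype=bool))
        assert cardioresp_features(ps)["rmssdPPI"] == pytest.approx(100.0)

    def test_sem_is_sd_over_sqrt_n(self, rng):
        ppi = rng.normal(1000, 40, size=25)
        ps = PulseSeries(beat_times=np.arange(26, dtype=float), ppi=ppi,
                         riam=np.ones(26), rifm=1000.0 / ppi,
                         valid_mask=np.ones(25, dtype=bool))
        out = cardioresp_features(ps)
        assert out["SEM"] == pytest.approx(np.std(ppi, ddof=1) / 5.0)


class TestSpectralFeatures:
    def _modulated(self, freq):
        t = np.cumsum(np.full(60, 1.0))
        ppi = 1000.0 + 50.0 * np.sin(2 * np.pi * freq * t[1:])
        return PulseSeries(beat_times=t, ppi=ppi, riam=np.ones(60),
                           rifm=1000.0 / ppi,
                           valid_mask=np.ones(59, dtype=bool))

    def test_hf_band_modulation_dominates_hf(self):
        out = spectral_features(self._modulated(0.25))
        assert out["HF"] / out["LF"] > 10

    def test_lf_band_modulation_dominates_lf(self):
        out = spectral_features(self._modulated(0.10))
        assert out["LF"] / out["HF"] > 10

    def test_constant_ppi_has_no_band_power(self):
        out = spectral_features(_const_series(1000.0, 30))
        assert out["VLF"] == out["LF"] == out["HF"] == 0.0
        assert not np.isfinite(out["LFHF"])


# --- distribution statistics --------------------------------------------------

class TestBasicStats:
    def test_constant_series_conventions(self):
        out = basic_stats(np.full(20, 3.0))
        assert out["avgAD"] == 0.0
        assert out["SF"] == pytest.approx(1.0)
        assert out["avgCL"] == 0.0
        assert out["avgTE"] == pytest.approx(0.0)
        assert out["GM"] == pytest.approx(3.0)
        assert out["HaM"] == pytest.approx(3.0)

    def test_teager_energy_of_sinusoid_closed_form(self):
        # x_n = A cos(w n)  ->  Teager energy A^2 sin^2(w)
        A, w = 1.7, 0.4
        x = A * np.cos(w * np.arange(5000))
        out = basic_stats(x)
        assert out["avgTE"] == pytest.approx(A ** 2 * np.sin(w) ** 2, rel=1e-3)

    def test_normal_sample_moments(self, rng):
        x = rng.standard_normal(10_000)
        out = basic_stats(x)
        assert abs(out["Skew"]) < 0.1
        assert out["Kurt"] == pytest.approx(3.0, abs=0.2)

    def test_trimmed_means_match_scipy_convention(self, rng):
        from scipy.stats import trim_mean
        x = rng.normal(size=101)
        out = basic_stats(x)
        assert out["TM25"] == pytest.approx(trim_mean(x, 0.125))
        assert out["TM50"] == pytest.approx(trim_mean(x, 0.25))


class TestPoincare:
    def test_constant_series_degenerates_to_zero(self):
        out = poincare(np.full(30, 5.0))
        assert out["SD1"] == 0.0 and out["SD2"] == 0.0
        assert out["CCM"] == 0.0

    @pytest.mark.parametrize("m", [1, 2])
    def test_sd1_squared_equals_half_lag_difference_variance(self, rng, m):
        x = rng.normal(size=200)
        out = poincare(x, m=m)
        assert out["SD1"] ** 2 == pytest.approx(
            np.var(x[m:] - x[:-m], ddof=1) / 2.0, rel=1e-10)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=rng.integers(10, 60))
            out = poincare(x)
            sd1, sd2, ccm = poincare_oracle(x)
            assert out["SD1"] == pytest.approx(sd1, rel=1e-9)
            assert out["SD2"] == pytest.approx(sd2, rel=1e-9)
            assert out["CCM"] == pytest.approx(ccm, rel=1e-9)


class TestHjorth:
    def test_activity_is_variance(self, rng):
        x = rng.normal(size=500)
        assert hjorth(x)["HA"] == pytest.approx(np.var(x, ddof=1))

    def test_mobility_of_slow_sinusoid_small_angle(self):
        f, fs = 1.0, 128.0
        x = np.sin(2 * np.pi * f * np.arange(4000) / fs)
        assert hjorth(x)["HM"] == pytest.approx(2 * np.pi * f / fs, rel=0.01)

    def test_white_noise_complexity_above_one(self, rng):
        assert hjorth(rng.standard_normal(5000))["HC"] > 1.0

    def test_zero_variance_flags_nonfinite(self):
        out = hjorth(np.full(10, 2.0))
        assert not np.isfinite(out["HM"]) and not np.isfinite(out["HC"])


class TestFractal:
    def test_straight_line_dimensions(self):
        x = np.linspace(0.0, 5.0, 512)
        assert higuchi_fd(x) == pytest.approx(1.0, abs=0.05)
        assert katz_fd(x) == pytest.approx(1.0, abs=1e-9)

    def test_white_noise_higuchi_near_two(self, rng):
        vals = [higuchi_fd(rng.standard_normal(3840)) for _ in range(5)]
        assert np.mean(vals) == pytest.approx(2.0, abs=0.1)

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(800)
        assert higuchi_fd(3.0 * x + 1.0) == pytest.approx(higuchi_fd(x), rel=1e-9)
        assert katz_fd(3.0 * x + 1.0) == pytest.approx(katz_fd(x), rel=1e-9)

    def test_higuchi_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            x = rng.standard_normal(rng.integers(100, 400))
            assert higuchi_fd(x) == pytest.approx(higuchi_oracle(x), rel=1e-3)

    def test_katz_constant_and_random_walk(self, rng):
        assert katz_fd(np.full(100, 1.0)) == 1.0
        walk = np.cumsum(rng.standard_normal(1000))
        assert katz_fd(walk) > 1.0


class TestLyapunov:
    def test_periodic_signal_has_near_zero_divergence(self):
        x = np.sin(2 * np.pi * 1.3 * np.arange(2000) / 128.0)
        assert abs(lyapunov_coeff(x)) <= 0.05

    def test_white_noise_diverges(self, rng):
        assert lyapunov_coeff(rng.standard_normal(2000)) > 0.0

    def test_deterministic(self, rng):
        x = rng.standard_normal(1000)
        assert lyapunov_coeff(x) == lyapunov_coeff(x.copy())


# --- full vector --------------------------------------------------------------

class TestExtractFeatures:
    def test_synthetic_epoch_yields_79_finite_values(self, corpus_features):
        valid = corpus_features[corpus_features["valid"]]
        block = valid[list(FEATURE_NAMES)].to_numpy(dtype=float)
        assert block.shape[1] == 79
        assert np.all(np.isfinite(block))

    def test_identical_epochs_identical_vectors(self, clean_epoch):
        a = extract_features(clean_epoch["epoch"], clean_epoch["beats"],
                             clean_epoch["ps"])
        b = extract_features(clean_epoch["epoch"].copy(),
                             clean_epoch["beats"], clean_epoch["ps"])
        assert np.array_equal(a, b, equal_nan=True)

    def test_stage_separability_of_mean_ppi(self, corpus_features):
        valid = corpus_features[corpus_features["valid"]]
        groups = valid.groupby("label")["avgPPI"]
        means, sds = groups.mean(), groups.std()
        stages = list(means.index)
        for i, a in enumerate(stages):
            for b in stages[i + 1:]:
                gap = abs(means[a] - means[b])
                within = max(sds[a], sds[b])
                assert gap > within  # effect size > 1 between every pair


# --- scale behaviour properties -----------------------------------------------

@settings(max_examples=25, deadline=None)
@given(arrays(np.float64, st.integers(50, 200),
              elements=st.floats(-50, 50, allow_nan=False)),
       st.floats(0.1, 20.0))
def test_scale_behaviour_of_descriptors(x, c):
    if np.ptp(x) < 1e-6:
        return
    p1, p2 = poincare(x), poincare(c * x)
    assert p2["SD1"] == pytest.approx(c * p1["SD1"], rel=1e-6)
    assert p2["SD2"] == pytest.approx(c * p1["SD2"], rel=1e-6)
    s1, s2 = basic_stats(x), basic_stats(c * x)
    assert s2["avgCL"] == pytest.approx(c * s1["avgCL"], rel=1e-6)
    if np.mean(np.abs(x)) > 1e-9:
        assert s2["SF"] == pytest.approx(s1["SF"], rel=1e-6)
    assert katz_fd(c * x) == pytest.approx(katz_fd(x), rel=1e-6)
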