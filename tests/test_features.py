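import numpy as np
import pytest

from osanl.features import (
    FEATURE_COLUMNS,
    FeatureVector,
    apen,
    dfa,
    extract_features,
    lle_rosenstein,
    t90,
)
from osanl.signal_io import Series
from osanl.synthetic import generate_reference_series


def brute_force_apen(x: np.ndarray, m: int, r: float) -> float:
    """Direct O(N^2) epoch-counting oracle (Chebyshev distance, self-matches
    included): ApEn = Phi_m - Phi_{m+1}."""
    phis = []
    for mm in (m, m + 1):
        n_t = len(x) - mm + 1
        templates = np.array([x[i : i + mm] for i in range(n_t)])
        logs = []
        for i in range(n_t):
            d = np.max(np.abs(templates - templates[i]), axis=1)
            logs.append(np.log(np.count_nonzero(d <= r) / n_t))
        phis.append(np.mean(logs))
    return phis[0] - phis[1]


class TestDFA:
    def test_constant_series_flagged(self):
        s = Series(values=np.full(4096, 3.0), rate=1.0)
        res = dfa(s)
        assert res.degenerate
        assert np.isnan(res.alpha_fast) and np.isnan(res.alpha_slow)
        assert np.all(res.fluctuations == 0)

    def test_white_noise_alpha_half(self):
        alphas = [
            dfa(generate_reference_series("white_noise", 8192, seed=s)).alpha_overall
            for s in range(5)
        ]
        assert abs(np.mean(alphas) - 0.5) < 0.05

    def test_scale_and_shift_invariance(self):
        s = generate_reference_series("white_noise", 4096, seed=1)
        base = dfa(s)
        scaled = dfa(Series(values=7.5 * s.values, rate=s.rate))
        shifted = dfa(Series(values=s.values + 100.0, rate=s.rate))
        assert scaled.alpha_fast == pytest.approx(base.alpha_fast, abs=1e-10)
        assert scaled.alpha_slow == pytest.approx(base.alpha_slow, abs=1e-10)
        assert np.allclose(shifted.fluctuations, base.fluctuations, atol=1e-8)

    def test_fluctuations_nonnegative_and_boxes_increasing(self):
        res = dfa(generate_reference_series("fgn", 4096, seed=0, hurst=0.7))
        assert np.all(res.fluctuations >= 0)
        assert np.all(np.diff(res.box_samples) > 0)

    def test_too_short_series(self):
        with pytest.raises(ValueError, match="too short"):
            dfa(Series(values=np.ones(100), rate=1.0))


class TestApEn:
    def test_constant_series_zero(self):
        assert apen(Series(values=np.full(200, 5.0), rate=1.0)).apen == 0.0

    def test_period_two_series_near_zero(self):
        # successor fully determined; edge effects are O(1/N)
        s = Series(values=np.tile([0.0, 1.0], 200), rate=1.0)
        assert abs(apen(s).apen) < 1e-4

    @pytest.mark.parametrize("n,seed", [(200, 0), (350, 1), (500, 2)])
    def test_matches_brute_force_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(size=n)
        r = 0.2 * np.std(x)
        got = apen(Series(values=x, rate=1.0)).apen
        assert got == pytest.approx(brute_force_apen(x, 2, r), abs=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(400)
        a = apen(Series(values=x, rate=1.0)).apen
        b = apen(Series(values=3.0 * x - 11.0, rate=1.0)).apen
        assert a == pytest.approx(b, abs=1e-10)

    def test_high_low_ordering_and_signs(self):
        rng = np.random.default_rng(4)
        s = Series(values=rng.standard_normal(3600), rate=1.0)
        res = apen(s, subwindow_seconds=300.0)
        assert res.apen_low <= res.apen_high
        assert res.subwindow_apen.size == 12

    def test_invalid_r_factor(self):
        with pytest.raises(ValueError):
            apen(Series(values=np.ones(100), rate=1.0), r_factor=0.0)


class TestLLE:
    def test_periodic_orbit_no_divergence(self):
        s = generate_reference_series("sine", 2000, seed=0, period=100.0)
        res = lle_rosenstein(s, embed_dim=2)
        assert abs(res.lyapunov / s.rate) <= 0.02  # per sample-step

    def test_logistic_map_ln2(self):
        s = generate_reference_series("logistic_map", 5000, seed=3, r=4.0)
        res = lle_rosenstein(s, embed_dim=2, delay=1, theiler_window=5)
        assert res.lyapunov == pytest.approx(np.log(2), abs=0.05)

    def test_amplitude_scaling_invariance(self):
        s = generate_reference_series("logistic_map", 3000, seed=6, r=4.0)
        a = lle_rosenstein(s, embed_dim=2, delay=1, theiler_window=5)
        s2 = Series(values=40.0 * s.values, rate=s.rate)
        b = lle_rosenstein(s2, embed_dim=2, delay=1, theiler_window=5)
        assert a.lyapunov == pytest.approx(b.lyapunov, abs=1e-9)

    def test_initial_divergence_matches_perturbation(self):
        # duplicate a chaotic orbit with a tiny offset: the first point of
        # the divergence curve sits at the log of the perturbation
        base = generate_reference_series("logistic_map", 600, seed=7, r=4.0).values
        pert = 1e-6
        x = np.concatenate([base, base + pert])
        res = lle_rosenstein(
            Series(values=x, rate=1.0), embed_dim=2, delay=1,
            theiler_window=10, max_steps=5,
        )
        assert res.divergence_curve[0] == pytest.approx(np.log(pert * np.sqrt(2)), abs=0.3)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            lle_rosenstein(Series(values=np.ones(500), rate=1.0), embed_dim=2, delay=1)


class TestT90:
    def test_all_above(self):
        assert t90(Series(values=np.full(100, 95.0), rate=1.0)) == 0.0

    def test_all_below(self):
        assert t90(Series(values=np.full(100, 85.0), rate=1.0)) == 100.0

    def test_count_arithmetic(self):
        v = np.full(3600, 95.0)
        v[:900] = 88.0
        assert t90(Series(values=v, rate=1.0)) == 25.0

    def test_boundary_strictly_below(self):
        v = np.array([90.0, 89.999, 90.001, 95.0])
        assert t90(Series(values=v, rate=1.0)) == 25.0


class TestExtractFeatures:
    def test_feature_vector_contract(self, short_recording):
        rec, events, spec = short_recording
        fv = extract_features(rec, {"age": 50, "sex": "M", "bmi": 30, "epworth": 8})
        d = fv.to_dict()
        assert set(d) == set(FEATURE_COLUMNS)
        assert 0 <= fv.T90 <= 100
        for (dn, mn), (xn, yn) in FeatureVector.DIFF_MEAN_PAIRS.items():
            dv, mv = getattr(fv, dn), getattr(fv, mn)
            assert getattr(fv, xn) == pytest.approx(mv + dv / 2, abs=1e-12)
            assert getattr(fv, yn) == pytest.approx(mv - dv / 2, abs=1e-12)
        # ApEn-derived pair: d = high + low and m = d/2
        assert fv.dAPEN_f == pytest.approx(fv.APEN_high_f + fv.APEN_low_f, abs=1e-12)
        assert fv.mAPEN_f == pytest.approx(fv.dAPEN_f / 2, abs=1e-12)

    def test_deterministic(self, short_recording):
        rec, _, _ = short_recording
        a = extract_features(rec)
        b = extract_features(rec)
        for attr in FEATURE_COLUMNS.values():
            va, vb = getattr(a, attr), getattr(b, attr)
            if isinstance(va, float):
                assert va == vb

    def test_diff_sign_convention_flips(self, short_recording):
        rec, _, _ = short_recording
        a = extract_features(rec, dfa_diff_sign=1)
        b = extract_features(rec, dfa_diff_sign=-1)
        assert a.dDFA_f == pytest.approx(-b.dDFA_f, abs=1e-12)
        assert a.mDFA_f == pytest.approx(b.mDFA_f, abs=1e-12)

    def test_short_recording_names_failing_feature(self):
        from osanl.synthetic import SyntheticSpec, generate_recording

        spec = SyntheticSpec(duration=2 * 3600.0, true_ahi=0.0, seed=0)
        rec, _ = generate_recording(spec)
        with pytest.raises(ValueError, match="cannot compute feature"):
            extract_features(rec)
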