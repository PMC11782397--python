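import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitfatigue.io import ConfigError, ContractError
from gaitfatigue.features import (
    FEATURE_NAMES,
    FORCE_FEATURES,
    IMU_FEATURES,
    ExtractionParams,
    build_dataset,
    coefficient_of_variation,
    correct_angle_drift,
    extract_cycle_features,
    jerk_series,
    make_windows,
    region_contact_features,
    resultant_magnitude,
)
from gaitfatigue.segmentation import GaitCycle, flat_foot_window, segment_recording
from gaitfatigue.simulate import (
    CohortConfig,
    NoiseSpec,
    cohort_to_triples,
    simulate_cohort,
)

FS = 110.0


def _cycle(start, end):
    fl_s, fl_e = flat_foot_window(start, end)
    to = start + int(0.6 * (end - start))
    return GaitCycle(start, to, end, fl_s, fl_e)


class TestCoefficientOfVariation:
    def test_constant_series_is_zero(self):
        assert coefficient_of_variation(np.full(10, 3.7)) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_hand_value(self):
        # sd([1,2,3]) = 1 (n-1 denominator), |mean| = 2
        assert coefficient_of_variation(np.array([1.0, 2.0, 3.0])) == pytest.approx(0.5)

    def test_near_zero_mean_returns_sentinel(self):
        assert coefficient_of_variation(np.array([1.0, -1.0])) == 0.0

    def test_length_one_rejected(self):
        with pytest.raises(ContractError):
            coefficient_of_variation(np.array([1.0]))

    @given(
        st.lists(
            st.floats(min_value=-100, max_value=100, allow_nan=False),
            min_size=2,
            max_size=30,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_sign_flip_symmetry(self, values):
        x = np.asarray(values)
        assert coefficient_of_variation(-x) == pytest.approx(
            coefficient_of_variation(x), rel=1e-12, abs=1e-12
        )


class TestJerkSeries:
    def test_constant_acceleration_gives_zero_jerk(self):
        assert np.all(jerk_series(np.full(50, 2.5), FS) == 0.0)

    def test_linear_acceleration_gives_exact_slope(self):
        k = 3.7
        t = np.arange(40) / FS
        j = jerk_series(k * t, FS)
        np.testing.assert_allclose(j, k, rtol=1e-9)

    def test_linearity_in_sign(self, rng):
        a = rng.normal(size=30)
        np.testing.assert_allclose(jerk_series(-a, FS), -jerk_series(a, FS))

    def test_too_short_rejected(self):
        with pytest.raises(ContractError):
            jerk_series(np.array([1.0, 2.0]), FS)


class TestResultantMagnitude:
    def test_pythagorean_triple(self):
        out = resultant_magnitude(np.array([3.0]), np.array([4.0]), np.array([0.0]))
        assert out == pytest.approx([5.0])

    def test_zeros(self):
        assert np.all(resultant_magnitude(*np.zeros((3, 5))) == 0.0)

    def test_matches_per_sample_oracle(self, rng):
        x, y, z = rng.normal(size=(3, 100))
        expected = np.array(
            [np.sqrt(x[i] ** 2 + y[i] ** 2 + z[i] ** 2) for i in range(100)]
        )
        np.testing.assert_allclose(resultant_magnitude(x, y, z), expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ContractError):
            resultant_magnitude(np.zeros(3), np.zeros(3), np.zeros(4))


class TestCorrectAngleDrift:
    def test_constant_angle_maps_to_zero(self):
        c = _cycle(0, 100)
        out = correct_angle_drift(np.full(100, 8.3), c)
        np.testing.assert_allclose(out, 0.0)

    def test_linear_drift_closed_form(self):
        c = _cycle(0, 100)
        a = 0.37
        theta = a * np.arange(100, dtype=float)
        out = correct_angle_drift(theta, c)
        mean_idx = np.arange(c.flat_start, c.flat_end).mean()
        np.testing.assert_allclose(out, a * (np.arange(100) - mean_idx), rtol=1e-12)

    def test_idempotent(self, rng):
        c = _cycle(0, 121)
        theta = rng.normal(0, 5, 121)
        once = correct_angle_drift(theta, c)
        twice = correct_angle_drift(once, c)
        np.testing.assert_allclose(twice, once, atol=1e-12)

    def test_zero_mean_over_flat_window(self, rng):
        c = _cycle(0, 121)
        out = correct_angle_drift(rng.normal(0, 5, 121), c)
        assert out[c.flat_start : c.flat_end].mean() == pytest.approx(0.0, abs=1e-12)


class TestRegionContactFeatures:
    def test_constant_contact_closed_forms(self):
        # constant 50 N over a fully contacted 0.5-s cycle
        n = 55  # 0.5 s at 110 Hz
        c = _cycle(0, n)
        ct, pf, imp, fcv = region_contact_features(np.full(n, 50.0), c, 1.0, FS)
        assert ct == pytest.approx(0.5)
        assert pf == 50.0
        assert imp == pytest.approx(25.0)
        assert fcv == 0.0

    def test_triangular_pulse_area(self):
        # 0 -> 100 -> 0 N over 0.4 s: area 20 N.s, apex on a sample
        n_up = 22
        f = np.zeros(121)
        f[:n_up + 1] = np.linspace(0, 100, n_up + 1)
        f[n_up : 2 * n_up + 1] = np.linspace(100, 0, n_up + 1)
        c = _cycle(0, 121)
        _, pf, imp, _ = region_contact_features(f, c, 1e-6, FS)
        assert pf == 100.0
        assert imp == pytest.approx(20.0, rel=1e-6)

    def test_region_never_in_contact(self):
        c = _cycle(0, 121)
        ct, pf, imp, fcv = region_contact_features(np.full(121, 0.5), c, 1.0, FS)
        assert (ct, imp, fcv) == (0.0, 0.0, 0.0)
        assert pf == 0.5

    def test_scale_equivariance(self, rng):
        f = np.concatenate([np.zeros(30), rng.uniform(20, 60, 60), np.zeros(31)])
        c = _cycle(0, 121)
        ct1, pf1, imp1, fcv1 = region_contact_features(f, c, 1.0, FS)
        ct2, pf2, imp2, fcv2 = region_contact_features(2 * f, c, 1.0, FS)
        assert ct2 == ct1
        assert pf2 == pytest.approx(2 * pf1)
        assert imp2 == pytest.approx(2 * imp1)
        assert fcv2 == pytest.approx(fcv1)


class TestExtractCycleFeatures:
    def test_exactly_49_features_partitioned_by_source(self):
        assert len(FEATURE_NAMES) == 49
        assert len(FORCE_FEATURES) == 28
        assert len(IMU_FEATURES) == 21
        assert set(FORCE_FEATURES) | set(IMU_FEATURES) == set(FEATURE_NAMES)

    def test_deterministic(self, clean_recording):
        rec, _ = clean_recording
        c = segment_recording(rec)[0]
        assert extract_cycle_features(rec, c) == extract_cycle_features(rec, c)

    def test_force_scaling_homogeneity(self, clean_recording):
        rec, _ = clean_recording
        c = segment_recording(rec)[1]
        # a vanishing contact threshold keeps the contact mask invariant
        # under amplitude scaling, making the homogeneity exact
        params = ExtractionParams(region_threshold_N=1e-9)
        base = extract_cycle_features(rec, c, params)
        rec2 = type(rec)(
            participant_id=rec.participant_id,
            timestamps=rec.timestamps,
            force=2.0 * rec.force,
            acc=rec.acc,
            gyr=rec.gyr,
            ang=rec.ang,
        )
        doubled = extract_cycle_features(rec2, c, params)
        for r in ("Hx", "MM", "POF", "LM", "MA", "LA", "H"):
            assert doubled[f"PF_{r}"] == pytest.approx(2 * base[f"PF_{r}"])
            assert doubled[f"Imp_{r}"] == pytest.approx(2 * base[f"Imp_{r}"])
            assert doubled[f"CT_{r}"] == base[f"CT_{r}"]
            assert doubled[f"FCV_{r}"] == pytest.approx(base[f"FCV_{r}"])

    def test_constant_angle_offset_leaves_angle_features_unchanged(
        self, clean_recording
    ):
        rec, _ = clean_recording
        c = segment_recording(rec)[0]
        base = extract_cycle_features(rec, c)
        rec2 = type(rec)(
            participant_id=rec.participant_id,
            timestamps=rec.timestamps,
            force=rec.force,
            acc=rec.acc,
            gyr=rec.gyr,
            ang=rec.ang + 17.0,
        )
        shifted = extract_cycle_features(rec2, c)
        for name in FEATURE_NAMES:
            if name.startswith("theta_"):
                assert shifted[name] == pytest.approx(base[name], abs=1e-9)


class TestMakeWindows:
    def test_formula_mode_counts_150(self):
        assert len(make_windows(300.0, 10.0, 8.0, "formula")) == 150

    def test_strict_mode_counts_146(self):
        spans = make_windows(300.0, 10.0, 8.0, "strict")
        assert len(spans) == 146
        assert all(e - s == pytest.approx(10.0) for s, e in spans)

    def test_short_segment_covers_full_window(self):
        for mode in ("formula", "strict"):
            spans = make_windows(10.0, 10.0, 8.0, mode)
            assert spans[0] == (0.0, 10.0)

    def test_formula_trailing_windows_truncate_at_clip(self):
        spans = make_windows(20.0, 10.0, 8.0, "formula", clip_s=20.0)
        assert len(spans) == 10
        assert spans[-1] == (18.0, 20.0)

    def test_invalid_overlap_rejected(self):
        with pytest.raises(ConfigError):
            make_windows(100.0, 8.0, 8.0)
        with pytest.raises(ConfigError):
            ExtractionParams(window_s=5.0, overlap_s=8.0)


@pytest.fixture(scope="module")
def tiny_cohort():
    cfg = CohortConfig(
        n_participants=2,
        segment_duration_s=30.0,
        pad_s=10.0,
        seed=42,
        noise=NoiseSpec.zero(),
    )
    return simulate_cohort(cfg)


class TestBuildDataset:
    def test_counts_and_labels(self, tiny_cohort):
        params = ExtractionParams(segment_duration_s=30.0)
        samples = build_dataset(cohort_to_triples(tiny_cohort), params)
        # formula mode: floor(30 / 2) = 15 windows per state segment
        assert len(samples) == 2 * 2 * 15
        for s in samples:
            assert s.state_label in ("non_fatigue", "fatigue")
            assert s.n_cycles >= params.min_cycles_per_window

    def test_single_participant_single_state_strict_10s(self, tiny_cohort):
        p = tiny_cohort[0]
        triple = [(p.participant_id, "non_fatigue", p.recordings["non_fatigue"])]
        params = ExtractionParams(segment_duration_s=10.0, count_mode="strict")
        samples = build_dataset(triple, params)
        assert len(samples) == 1
        assert samples[0].window_start_s == 0.0

    def test_zero_noise_window_equals_mean_of_cycle_truth(self, tiny_cohort):
        p = tiny_cohort[0]
        state = "non_fatigue"
        rec, truth = p.recordings[state], p.truths[state]
        params = ExtractionParams(segment_duration_s=30.0)
        samples = build_dataset([(p.participant_id, state, rec)], params)
        s0 = samples[0]
        hs_t = truth["hs_index"].to_numpy() / rec.fs
        rows = truth[(hs_t >= 0.0) & (hs_t < 10.0)]
        assert len(rows) == s0.n_cycles
        for name in FEATURE_NAMES:
            assert s0.features[name] == pytest.approx(
                rows[name].mean(), rel=1e-9, abs=1e-12
            )
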