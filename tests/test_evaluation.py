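"""Thresholding, resection ratios, group statistics and the power confound."""

import numpy as np
import pytest
from scipy import stats

from plhfo import (
    MeasureMatrix,
    ResectionRatio,
    StudyConfig,
    apply_threshold,
    compare_groups,
    confound_analysis,
    coupled_spec,
    generate_seizure_case,
    planted_config,
    resection_ratio,
    run_study,
    uncoupled_spec,
    zscore_matrix,
)
from plhfo.evaluation import ThresholdResult
from plhfo.synth import SyntheticSeizureConfig, _diversify

from _oracles import mannwhitney_exact_oracle


def make_matrix(values, name="MI"):
    values = np.asarray(values, dtype=float)
    return MeasureMatrix(
        measure_name=name,
        values=values,
        window_starts=np.arange(values.shape[1]) * 170,
        window_length_samples=1536,
        step_samples=170,
        rate=512.0,
    )


class TestZScore:
    def test_pooled_ictal_mean_zero_sd_one(self, rng):
        m = make_matrix(rng.normal(2.0, 3.0, size=(5, 40)))
        z = zscore_matrix(m, (10, 30))
        block = z.values[:, 10:30]
        assert block.mean() == pytest.approx(0.0, abs=1e-12)
        assert block.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_constant_matrix_rejected(self):
        m = make_matrix(np.full((3, 20), 4.0))
        with pytest.raises(ValueError, match="SD"):
            zscore_matrix(m, (0, 20))

    def test_threshold_equivalence_with_z_units(self, rng):
        m = make_matrix(rng.normal(size=(6, 50)))
        span = (5, 45)
        t = apply_threshold(m, span)
        z = zscore_matrix(m, span)
        z_supra = np.any(z.values[:, span[0] : span[1]] > 2.5, axis=1)
        np.testing.assert_array_equal(t.suprathreshold, z_supra)


class TestApplyThreshold:
    def test_single_outlier_channel_flagged(self, rng):
        vals = rng.normal(0.0, 1.0, size=(6, 40)) * 0.01  # tight background
        mean, sd = vals[:, 5:35].mean(), vals[:, 5:35].std(ddof=1)
        vals[3, 20] = mean + 5 * sd
        t = apply_threshold(make_matrix(vals), (5, 35))
        assert set(np.nonzero(t.suprathreshold)[0]) == {3}
        assert t.first_crossing[3] == 20

    def test_threshold_is_pooled_mean_plus_2p5_sd(self, rng):
        vals = rng.normal(size=(4, 30))
        t = apply_threshold(make_matrix(vals), (0, 30))
        assert t.threshold_value == pytest.approx(
            vals.mean() + 2.5 * vals.std(ddof=1), abs=1e-12
        )

    def test_zero_sd_warns_all_subthreshold(self):
        with pytest.warns(UserWarning, match="SD"):
            t = apply_threshold(make_matrix(np.ones((3, 10))), (0, 10))
        assert not t.suprathreshold.any()

    def test_needs_two_ictal_windows(self, rng):
        with pytest.raises(ValueError, match="2 windows"):
            apply_threshold(make_matrix(rng.normal(size=(3, 10))), (4, 5))


def make_threshold_result(first_crossing, crossing_z=None, name="MI"):
    first = np.asarray(first_crossing)
    supra = first >= 0
    z = np.asarray(crossing_z, dtype=float) if crossing_z is not None else np.where(supra, 3.0, np.nan)
    return ThresholdResult(name, 1.0, 0.0, 0.4, supra, first, z, (0, 50))


class TestResectionRatio:
    def test_half_resected(self):
        t = make_threshold_result([2, 5, -1, 7, 9, -1])
        r = resection_ratio(t, [True, False, False, True, False, False])
        assert r.denominator == 4 and r.numerator == 2
        assert r.ratio == pytest.approx(50.0)

    def test_early_k_takes_first_nine_by_crossing(self):
        first = list(range(12))  # 12 suprathreshold channels, crossing in order
        resected = [True, False, False, True, False, False, True, False, False, True, True, True]
        t = make_threshold_result(first)
        r = resection_ratio(t, resected, variant="early_k", k=9)
        assert r.denominator == 9 and r.numerator == 3
        assert r.ratio == pytest.approx(100.0 / 3.0)

    def test_early_k_tie_break_by_z_then_index(self):
        first = [5, 5, 5, -1]
        z = [1.0, 9.0, 9.0, np.nan]
        t = make_threshold_result(first, z)
        r = resection_ratio(t, [False, True, True, False], variant="early_k", k=2)
        # ties at window 5: higher z first (ch1, ch2), then ch0
        assert r.numerator == 2 and r.denominator == 2

    def test_all_resected_gives_100(self):
        t = make_threshold_result([1, 2, -1])
        r = resection_ratio(t, [True, True, True])
        assert r.ratio == pytest.approx(100.0)

    def test_no_suprathreshold_is_undefined(self):
        t = make_threshold_result([-1, -1])
        r = resection_ratio(t, [True, False])
        assert r.denominator == 0 and r.ratio is None


class TestCompareGroups:
    def ratios(self, values, variant="whole_seizure", name="MI"):
        out = []
        for i, v in enumerate(values):
            num = int(v) if v is not None else 0
            denom = 100 if v is not None else 0
            out.append(ResectionRatio(f"s{i}", name, variant, None, num, denom))
        return out

    def test_identical_groups_not_significant(self):
        rr = self.ratios([50, 50, 50, 50])
        outcomes = {"s0": "I", "s1": "II", "s2": "IV", "s3": "IV"}
        c = compare_groups(rr, outcomes)
        assert c.p_value == pytest.approx(1.0)
        assert not c.significant

    def test_exact_p_matches_enumeration_oracle(self):
        good, poor = [90, 95, 92], [5, 8, 10]
        rr = self.ratios(good + poor)
        outcomes = {f"s{i}": ("I" if i < 3 else "IV") for i in range(6)}
        c = compare_groups(rr, outcomes)
        assert c.p_value == pytest.approx(mannwhitney_exact_oracle(good, poor), abs=1e-12)

    def test_exact_p_matches_oracle_on_random_small_groups(self, rng):
        for _ in range(10):
            n, m = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            pool = rng.permutation(100)[: n + m].astype(float)  # tie-free
            good, poor = list(pool[:n]), list(pool[n:])
            rr = self.ratios(good + poor)
            outcomes = {f"s{i}": ("II" if i < n else "IV") for i in range(n + m)}
            c = compare_groups(rr, outcomes)
            assert c.p_value == pytest.approx(
                mannwhitney_exact_oracle(good, poor), abs=1e-12
            )

    def test_single_element_groups(self):
        rr = self.ratios([100, 0])
        c = compare_groups(rr, {"s0": "I", "s1": "IV"})
        assert c.p_value > 0.01 and not c.significant

    def test_undefined_ratios_excluded_by_default(self):
        rr = self.ratios([80, 90, None, 10, 20])
        outcomes = {f"s{i}": ("I" if i < 3 else "IV") for i in range(5)}
        c = compare_groups(rr, outcomes)
        assert len(c.good_group) == 2 and len(c.poor_group) == 2

    def test_empty_group_rejected(self):
        rr = self.ratios([50, 60])
        with pytest.raises(ValueError, match="non-empty"):
            compare_groups(rr, {"s0": "I", "s1": "II"})


class TestConfoundAnalysis:
    def test_measure_equal_power_identity(self, rng):
        power = make_matrix(np.abs(rng.normal(2, 0.5, size=(3, 60))), "HFO_POWER")
        measure = make_matrix(power.values.copy(), "MVL")
        c = confound_analysis(measure, power)
        np.testing.assert_allclose(c.slopes, 1.0, atol=1e-12)
        np.testing.assert_allclose(c.correlations, 1.0, atol=1e-12)

    def test_independent_series_near_zero(self, rng):
        n = 10_000
        power = make_matrix(np.exp(rng.normal(size=(1, n))), "HFO_POWER")
        measure = make_matrix(np.exp(rng.normal(size=(1, n))), "PLV")
        c = confound_analysis(measure, power)
        assert abs(c.slopes[0]) < 0.05
        assert abs(c.correlations[0]) < 0.05

    def test_short_channels_skipped(self, rng):
        power = make_matrix(np.abs(rng.normal(1, 0.1, size=(2, 10))), "HFO_POWER")
        vals = np.abs(rng.normal(1, 0.1, size=(2, 10)))
        vals[1, :8] = -1.0  # only 2 usable windows on channel 1
        c = confound_analysis(make_matrix(vals, "MVL"), power)
        assert c.slopes.size == 1


@pytest.fixture(scope="module")
def batch_result():
    cases = []
    for i, seed in enumerate([31, 32, 33, 34]):
        cfg = planted_config(
            seed=seed,
            ictal_duration=20.0,
            postictal_duration=5.0,
            resect_coupled=i < 2,  # 2 good, 2 poor
        )
        case = generate_seizure_case(cfg)
        case.case_id = f"sz{i}"
        case.subject_id = f"subj{i}"
        cases.append(case)
    return run_study(cases, StudyConfig())


class TestRunStudy:
    def test_good_ratios_dominate_poor_for_mi(self, batch_result):
        comp = next(
            c
            for c in batch_result.comparisons
            if c.measure_name == "MI" and c.variant == "whole_seizure"
        )
        assert min(comp.good_group) >= max(comp.poor_group)

    def test_empty_case_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            run_study([])

    def test_single_case_skips_group_comparison(self):
        case = generate_seizure_case(
            planted_config(seed=41, ictal_duration=20.0, postictal_duration=5.0)
        )
        res = run_study([case], StudyConfig())
        assert res.comparisons == []
        assert any("skipped" in n for n in res.notes)
        assert len(res.seizures) == 1

    def test_seizures_per_subject_cap(self):
        cases = []
        for i in range(3):
            case = generate_seizure_case(
                planted_config(seed=50 + i, ictal_duration=20.0, postictal_duration=5.0)
            )
            case.case_id = f"sz{i}"
            case.subject_id = "same"
            cases.append(case)
        res = run_study(cases, StudyConfig())
        assert len(res.seizures) == 2

    def test_error_carries_case_context(self):
        case = generate_seizure_case(
            planted_config(seed=60, ictal_duration=20.0, postictal_duration=5.0)
        )
        case.case_id = "badcase"
        case.recording.channel_mask[:] = False
        case.recording.channel_mask[0] = True
        with pytest.raises(ValueError, match="badcase"):
            run_study([case])


class TestWholeSeizureVersusEarlyChannels:
    def test_late_coupling_recovered_whole_seizure_but_missed_early(self):
        """Channels that couple only late are found by whole-seizure MI
        thresholding, while early selection driven by an amplitude-biased
        measure picks the early loud channels instead."""
        late = (0.7, 0.98)
        loud = uncoupled_spec(
            hfo_amplitude=100.0,
            noise_scale=50.0,
            interictal_attenuation=0.05,
        )
        specs = _diversify(
            (
                coupled_spec(0.8, coupling_window=late),
                coupled_spec(0.8, coupling_window=late),
                loud,
                loud,
            )
            + tuple(uncoupled_spec() for _ in range(4))
        )
        cfg = SyntheticSeizureConfig(
            channel_specs=specs,
            resected_channels=frozenset({0, 1}),
            outcome="I",
            seed=77,
            ictal_duration=40.0,
            postictal_duration=5.0,
        )
        case = generate_seizure_case(cfg)
        from plhfo import analyze_case

        res = analyze_case(case, StudyConfig(early_k=2))
        mi_whole = res["ratios"]["MI"]["whole_seizure"]
        assert set(np.nonzero(res["thresholds"]["MI"].suprathreshold)[0]) >= {0, 1}
        assert mi_whole.ratio is not None and mi_whole.ratio >= 50.0
        # the amplitude-biased measure crosses on the loud channels first
        mvl_early = res["ratios"]["MVL"]["early_k"]
        t_mvl = res["thresholds"]["MVL"]
        early_two = sorted(
            np.nonzero(t_mvl.suprathreshold)[0],
            key=lambda ch: (t_mvl.first_crossing[ch], -t_mvl.crossing_z[ch], ch),
        )[:2]
        assert set(early_two) <= {2, 3}
        assert mvl_early.ratio == pytest.approx(0.0)
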