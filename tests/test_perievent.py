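"""Peri-event analysis: z-scoring, window extraction, magnitudes, the
2-delta responder rule, specificity categories, and proportion tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_ethogram
from pacedmating import perievent as pe
from pacedmating.simulate import calcium_kernel, simulate_session, simulate_traces
from pacedmating.types import (
    CellSpec,
    ClassKinetics,
    InvalidParameterError,
    SessionParams,
    TraceMatrix,
)


def make_traces(values, frame_rate=10.0, background_window=(0.0, 60.0), **kw):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = values.shape[0]
    return TraceMatrix(
        cell_ids=[f"c{i}" for i in range(n)],
        cell_types=["Vgat"] * n,
        animal_ids=["a0"] * n,
        values=values,
        frame_rate=frame_rate,
        background_window=background_window,
        **kw,
    )


class TestZscore:
    def test_hand_computed_example(self):
        # background {0,1,2,3,4}: mean 2, sample SD sqrt(2.5); value 5 -> 1.8974
        trace = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        traces = make_traces(trace, frame_rate=0.5, background_window=(0.0, 10.0))
        z = pe.zscore_traces(traces)
        assert z.values[0, -1] == pytest.approx((5 - 2) / np.sqrt(2.5), abs=1e-4)
        assert z.values[0, -1] == pytest.approx(1.8974, abs=1e-4)

    def test_background_mean_maps_to_zero_and_sd_to_one(self):
        rng = np.random.default_rng(0)
        bg = rng.normal(3.0, 2.0, 600)
        trace = np.concatenate([bg, [bg.mean(), bg.mean() + bg.std(ddof=1)]])
        z = pe.zscore_traces(make_traces(trace))
        assert z.values[0, -2] == pytest.approx(0.0, abs=1e-12)
        assert z.values[0, -1] == pytest.approx(1.0, abs=1e-12)

    def test_background_window_standardized(self):
        rng = np.random.default_rng(1)
        z = pe.zscore_traces(make_traces(rng.normal(5, 3, (4, 1200))))
        bg = z.values[:, z.background_slice()]
        np.testing.assert_allclose(bg.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(bg.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_zero_variance_cells_reported(self):
        values = np.vstack([np.ones(1200), np.random.default_rng(2).normal(0, 1, 1200)])
        with pytest.raises(InvalidParameterError, match="c0"):
            pe.zscore_traces(make_traces(values))

    def test_short_background_rejected(self):
        with pytest.raises(InvalidParameterError, match="10 s"):
            pe.zscore_traces(make_traces(np.zeros(100), background_window=(0.0, 5.0)))


class TestFilterAppetitiveSniffs:
    def test_no_mounts_leaves_ethogram_unchanged(self):
        etho = make_ethogram([("sniff", 10.0, 12.0), ("sniff", 50.0, 52.0)])
        assert pe.filter_appetitive_sniffs(etho).events == etho.events

    def test_sniffs_after_first_mount_removed(self):
        etho = make_ethogram(
            [("sniff", 10.0, 12.0), ("mount", 30.0, 40.0), ("sniff", 50.0, 52.0)]
        )
        out = pe.filter_appetitive_sniffs(etho)
        assert [e.onset_s for e in out.of("sniff")] == [10.0]
        assert len(out.of("mount")) == 1

    def test_sniff_at_mount_onset_removed(self):
        etho = make_ethogram([("sniff", 30.0, 32.0), ("mount", 30.0, 40.0)])
        assert pe.filter_appetitive_sniffs(etho).of("sniff") == []


class TestExtractPerievent:
    def test_constant_trace_baselines_to_zero(self):
        traces = make_traces(np.full(2000, 7.0), zscored=True)
        etho = make_ethogram([("sniff", 100.0, 102.0)], duration_s=200.0)
        tensor = pe.extract_perievent(traces, etho)
        np.testing.assert_allclose(tensor.traces["sniff"], 0.0, atol=1e-12)
        assert tensor.traces["sniff"].shape == (1, 200)

    def test_two_events_average_to_the_kernel(self):
        # two identical noise-free transients, far enough apart that tails
        # are below float tolerance in each other's windows
        fs, dur = 10.0, 700.0
        t = np.arange(int(dur * fs)) / fs
        kin = dict(amplitude=4.0, rise_tau_s=0.6, decay_tau_s=8.0)
        trace = calcium_kernel(t - 200.0, **kin) + calcium_kernel(t - 450.0, **kin)
        traces = make_traces(trace, zscored=True)
        etho = make_ethogram(
            [("ejaculation", 200.0, 210.0)], duration_s=dur
        )
        etho2 = make_ethogram(
            [("mount", 200.0, 210.0), ("mount", 450.0, 460.0)], duration_s=dur
        )
        tensor = pe.extract_perievent(traces, etho2)
        wt = tensor.window_times()
        expected = calcium_kernel(wt, **kin)
        np.testing.assert_allclose(tensor.traces["mount"][0], expected, atol=1e-9)

    def test_onset_snapped_to_nearest_sample(self):
        values = np.zeros(400)
        values[100] = 5.0  # t = 10.0 s
        traces = make_traces(values, zscored=True)
        etho = make_ethogram([("sniff", 10.04, 11.0)], duration_s=40.0)
        tensor = pe.extract_perievent(traces, etho, baseline_subtract=False)
        onset_col = int(round(5.0 * 10))
        assert tensor.traces["sniff"][0, onset_col] == 5.0

    def test_uncovered_events_dropped_with_warning(self):
        traces = make_traces(np.zeros(400), zscored=True)
        etho = make_ethogram(
            [("sniff", 2.0, 3.0), ("sniff", 20.0, 21.0)], duration_s=40.0
        )
        with pytest.warns(UserWarning, match="dropped 1"):
            tensor = pe.extract_perievent(traces, etho)
        assert tensor.n_events["sniff"] == 1

    def test_behavior_without_covered_events_absent(self):
        traces = make_traces(np.zeros(300), zscored=True)
        etho = make_ethogram([("sniff", 2.0, 3.0)], duration_s=30.0)
        with pytest.warns(UserWarning):
            tensor = pe.extract_perievent(traces, etho)
        assert "sniff" not in tensor.traces

    def test_baseline_window_mean_is_zero(self, short_params, five_class_spec):
        etho, _ = simulate_session(short_params, 0)
        traces, _ = simulate_traces(etho, five_class_spec, 1)
        z = pe.zscore_traces(traces)
        tensor = pe.extract_perievent(z, etho)
        for mat in tensor.traces.values():
            np.testing.assert_allclose(mat[:, :50].mean(axis=1), 0.0, atol=1e-9)


class TestResponseMagnitude:
    def _tensor_from_window(self, window_row):
        tensor = pe.PeriEventTensor(
            cell_ids=["c0"], cell_types=["Vgat"], window_s=(-5.0, 15.0),
            frame_rate=10.0, baseline_subtracted=True,
        )
        tensor.traces["sniff"] = np.atleast_2d(window_row)
        tensor.n_events["sniff"] = 1
        return tensor

    def test_flat_zero_window(self):
        mag = pe.response_magnitude(self._tensor_from_window(np.zeros(200)))
        assert mag["magnitude"].iloc[0] == 0.0

    def test_sustained_step_of_three(self):
        row = np.zeros(200)
        row[50:] = 3.0
        mag = pe.response_magnitude(self._tensor_from_window(row))
        assert mag["magnitude"].iloc[0] == pytest.approx(3.0)

    def test_ramp_pins_half_open_window(self):
        # r(t) = t on [0, 5) sampled at 0.0..4.9 -> mean 2.45
        row = np.zeros(200)
        row[50:] = np.arange(150) / 10.0
        mag = pe.response_magnitude(self._tensor_from_window(row))
        assert mag["magnitude"].iloc[0] == pytest.approx(2.45)


class TestClassifyResponders:
    @pytest.mark.parametrize(
        "magnitude,expected",
        [(2.5, "positive"), (-2.5, "negative"), (2.0, "none"), (-2.0, "none"),
         (0.0, "none"), (2.0000001, "positive")],
    )
    def test_threshold_is_strict(self, magnitude, expected):
        df = pd.DataFrame(
            [{"cell_id": "c0", "cell_type": "Vgat", "behavior": "sniff",
              "magnitude": magnitude}]
        )
        assert pe.classify_responders(df)["responder"].iloc[0] == expected

    @settings(max_examples=100, deadline=None)
    @given(
        magnitude=st.floats(-10, 10, allow_nan=False),
        shift=st.floats(0, 10, allow_nan=False),
    )
    def test_monotone_under_positive_shift(self, magnitude, shift):
        order = {"negative": 0, "none": 1, "positive": 2}
        df = pd.DataFrame(
            [{"cell_id": "c", "cell_type": "Vgat", "behavior": "b",
              "magnitude": magnitude}]
        )
        before = pe.classify_responders(df)["responder"].iloc[0]
        df["magnitude"] += shift
        after = pe.classify_responders(df)["responder"].iloc[0]
        assert order[after] >= order[before]


class TestCategorizeSpecificity:
    def _responses(self, sniff, mount, ejac):
        rows = [
            {"cell_id": "c0", "cell_type": "Vgat", "behavior": b, "magnitude": m}
            for b, m in (("sniff", sniff), ("mount", mount), ("ejaculation", ejac))
        ]
        return pe.classify_responders(pd.DataFrame(rows))

    def test_argmax_category(self):
        cat = pe.categorize_specificity(self._responses(0.5, 1.0, 3.0))
        assert cat["category"].iloc[0] == "ejaculation"
        assert cat["overlap"].iloc[0] == "ejaculation"

    def test_overlap_lists_all_positive_behaviors(self):
        cat = pe.categorize_specificity(self._responses(2.5, 0.0, 2.6))
        assert cat["category"].iloc[0] == "ejaculation"
        assert set(cat["overlap"].iloc[0].split(";")) == {"sniff", "ejaculation"}

    def test_no_positive_behavior_is_none(self):
        cat = pe.categorize_specificity(self._responses(1.0, 1.5, -0.5))
        assert cat["category"].iloc[0] == "none"

    def test_tie_broken_by_behavior_priority(self):
        cat = pe.categorize_specificity(self._responses(3.0, 3.0, 3.0))
        assert cat["category"].iloc[0] == "ejaculation"


def hypergeom_midp(k1, n1, k2, n2) -> float:
    """Two-sided hypergeometric mid-p for a 2x2 table (exact oracle)."""
    K, N = k1 + k2, n1 + n2
    rv = stats.hypergeom(N, K, n1)
    ks = np.arange(max(0, K - n2), min(K, n1) + 1)
    pmf = rv.pmf(ks)
    p0 = rv.pmf(k1)
    return pmf[pmf < p0 * (1 - 1e-12)].sum() + 0.5 * pmf[
        np.isclose(pmf, p0, rtol=1e-9)
    ].sum()


class TestResponderProportionTest:
    @pytest.mark.parametrize(
        "k1,n1,k2,n2,m,expected,tol",
        [
            (184, 522, 35, 271, 6, 1.52e-10, 0.005e-10),
            (37, 184, 0, 35, 5, 0.018, 0.0005),
        ],
    )
    def test_reproduces_published_proportions(self, k1, n1, k2, n2, m, expected, tol):
        res = pe.responder_proportion_test(k1, n1, k2, n2, m=m)
        assert res["p_bonferroni"] == pytest.approx(expected, abs=tol)

    def test_equal_proportions_give_zero_statistic(self):
        res = pe.responder_proportion_test(10, 100, 10, 100, m=4)
        assert res["chi2"] == 0.0 and res["p_bonferroni"] == 1.0

    def test_zero_margin_degenerate(self):
        assert pe.responder_proportion_test(0, 50, 0, 30)["p"] == 1.0
        assert pe.responder_proportion_test(50, 50, 30, 30)["chi2"] == 0.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(InvalidParameterError):
            pe.responder_proportion_test(1, 0, 0, 5)
        with pytest.raises(InvalidParameterError):
            pe.responder_proportion_test(6, 5, 0, 5)

    def test_agrees_with_exact_midp_where_asymptotics_hold(self):
        """Within its validity range (all expected cells >= 5, exact p not in
        the deep tail) the uncorrected chi-square p stays within a factor of
        2 of the exact hypergeometric mid-p."""
        checked = 0
        for n1, n2 in ((15, 15), (12, 14), (10, 20), (15, 12)):
            for k1 in range(n1 + 1):
                for k2 in range(n2 + 1):
                    tab = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
                    if tab.sum(axis=0).min() == 0:
                        continue
                    expected_cells = np.outer(tab.sum(1), tab.sum(0)) / tab.sum()
                    if expected_cells.min() < 5:
                        continue
                    exact = hypergeom_midp(k1, n1, k2, n2)
                    if exact < 0.005:
                        continue
                    p = pe.responder_proportion_test(k1, n1, k2, n2)["p"]
                    assert 0.5 <= p / exact <= 2.0, (k1, n1, k2, n2, p, exact)
                    checked += 1
        assert checked > 100


class TestPlantedClassRecovery:
    def test_planted_responders_and_nonresponders_recovered(self, short_params):
        """At noise SD 0.5 and amplitude 4, >= 99% of planted ejaculation
        responders classify positive and >= 99% of nonresponders classify
        none, over 100 simulated sessions."""
        spec = CellSpec(
            n_cells_per_class={("fast", "Vgat"): 10, ("nonresponder", "Vgat"): 10},
            kinetics={"fast": ClassKinetics(amplitude=4.0, rise_tau_s=0.6,
                                            decay_tau_s=8.0)},
            noise_sd=0.5,
            coupled_behaviors={"fast": ("ejaculation",)},
        )
        hits_pos = hits_non = 0
        for seed in range(100):
            etho, _ = simulate_session(short_params, seed)
            traces, truth = simulate_traces(etho, spec, seed + 10_000)
            z = pe.zscore_traces(traces)
            tensor = pe.extract_perievent(z, etho)
            responses = pe.classify_responders(pe.response_magnitude(tensor))
            ej = responses[responses["behavior"] == "ejaculation"].set_index("cell_id")
            planted = truth.set_index("cell_id")["response_class"]
            for cid, cls in planted.items():
                if cls == "fast":
                    hits_pos += ej.loc[cid, "responder"] == "positive"
                else:
                    hits_non += ej.loc[cid, "responder"] == "none"
        assert hits_pos >= 990
        assert hits_non >= 990
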