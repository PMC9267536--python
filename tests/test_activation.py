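import numpy as np
import pandas as pd
import pytest

from stimscreen import (
    SignalKey,
    call_activations,
    collapse_timepoints,
    filter_matrix,
    sensitivity_curve,
    summarize_hits,
)
from stimscreen.errors import EmptyMatrixError, StimscreenError
from stimscreen.screen_io import FoldChangeMatrix

from _oracles import hit_counts_oracle
from conftest import make_activation


def make_fc(values, stimuli=None, signals=None):
    arr = np.asarray(values, dtype=float)
    n, m = arr.shape
    stimuli = stimuli or [f"s{i}" for i in range(n)]
    signals = signals or [SignalKey(f"a{j}", "secreted", "24h") for j in range(m)]
    return FoldChangeMatrix(
        values=pd.DataFrame(arr, index=stimuli, columns=[str(s) for s in signals]),
        signals=list(signals),
        n_controls={s: 5 for s in signals},
    )


class TestCallActivations:
    @pytest.mark.parametrize("fc_val, expected", [(1.6, 1), (1.4, 0), (1.5, 1)])
    def test_inclusive_threshold(self, fc_val, expected):
        am = call_activations(make_fc([[fc_val]]), threshold=1.5)
        assert am.calls.iloc[0, 0] == expected

    def test_strict_flag_differs_only_at_ties(self):
        fc = make_fc([[1.4, 1.5, 1.6]])
        inclusive = call_activations(fc, 1.5).calls.to_numpy()
        strict = call_activations(fc, 1.5, strict=True).calls.to_numpy()
        diff = inclusive != strict
        assert diff.sum() == 1 and inclusive[0, 1] == 1 and strict[0, 1] == 0

    def test_missing_fc_yields_zero_and_mask(self):
        am = call_activations(make_fc([[np.nan, 2.0]]))
        assert am.calls.iloc[0, 0] == 0
        assert bool(am.mask.iloc[0, 0]) and not bool(am.mask.iloc[0, 1])

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        fc = make_fc(np.exp(rng.normal(0.3, 0.5, (12, 9))))
        prev = None
        for t in (1.1, 1.3, 1.5, 2.0, 2.8):
            calls = call_activations(fc, t).calls.to_numpy()
            if prev is not None:
                assert not ((prev == 0) & (calls == 1)).any()
            prev = calls

    def test_threshold_must_exceed_one(self):
        with pytest.raises(StimscreenError):
            call_activations(make_fc([[2.0]]), threshold=1.0)


class TestCollapseTimepoints:
    def _two_tp(self, call5, call25):
        signals = [SignalKey("JUN", "phospho", "5min"),
                   SignalKey("JUN", "phospho", "25min"),
                   SignalKey("CXCL10", "secreted", "24h")]
        return make_activation([[call5, call25, 1]], signals=signals)

    @pytest.mark.parametrize("c5, c25, expected", [
        (0, 1, 1),   # active at one timepoint counts as active
        (1, 0, 1),
        (0, 0, 0),
        (1, 1, 1),
    ])
    def test_or_rule_per_analyte(self, c5, c25, expected):
        out = collapse_timepoints(self._two_tp(c5, c25))
        assert out.calls.loc["s0", "JUN@phospho@any"] == expected
        assert out.calls.loc["s0", "CXCL10@secreted@24h"] == 1  # passthrough
        assert out.collapse_rule == "any_timepoint"

    def test_idempotent(self):
        once = collapse_timepoints(self._two_tp(0, 1))
        twice = collapse_timepoints(once)
        pd.testing.assert_frame_equal(once.calls, twice.calls)
        assert [str(s) for s in once.signals] == [str(s) for s in twice.signals]

    def test_never_decreases_any_per_analyte_call(self):
        rng = np.random.default_rng(1)
        signals = [SignalKey(f"p{j}", "phospho", t)
                   for j in range(6) for t in ("5min", "25min")]
        am = make_activation(rng.integers(0, 2, (8, 12)), signals=signals)
        out = collapse_timepoints(am)
        for s in am.signals:
            col = out.calls[f"{s.analyte}@phospho@any"]
            assert (col >= am.calls[str(s)]).all()


class TestSensitivityCurve:
    def test_hand_counted_percentages(self):
        fc = make_fc([[1.2, 1.6], [2.0, 3.0]])
        curve = sensitivity_curve(fc, thresholds=[1.1, 1.5, 2.5])
        np.testing.assert_allclose(curve.pct_active, [100.0, 75.0, 25.0])
        np.testing.assert_allclose(curve.derivative,
                                   [(75 - 100) / 0.4, (25 - 75) / 1.0])

    def test_nonincreasing_on_default_grid(self):
        rng = np.random.default_rng(5)
        fc = make_fc(np.exp(rng.normal(0.2, 0.6, (20, 15))))
        curve = sensitivity_curve(fc)
        assert (np.diff(curve.pct_active) <= 0).all()

    def test_threshold_above_max_fc_gives_zero(self):
        curve = sensitivity_curve(make_fc([[1.2, 1.4]]), thresholds=[2.0])
        assert curve.pct_active[0] == 0.0

    def test_consistent_with_call_activations(self):
        rng = np.random.default_rng(9)
        fc = make_fc(np.exp(rng.normal(0.3, 0.5, (10, 7))))
        t = 1.5
        pct = sensitivity_curve(fc, thresholds=[t]).pct_active[0]
        am = call_activations(fc, t)
        assert pct == pytest.approx(100 * am.calls.to_numpy().mean())

    def test_empty_threshold_list_rejected(self):
        with pytest.raises(StimscreenError):
            sensitivity_curve(make_fc([[2.0]]), thresholds=[])


class TestFilterMatrix:
    def test_drops_inactive_rows_then_dead_columns(self):
        am = make_activation([[1, 0], [0, 0], [1, 0]])
        out = filter_matrix(am)
        assert out.calls.shape == (2, 1)
        assert list(out.calls.index) == ["s0", "s2"]

    def test_all_active_matrix_unchanged(self):
        am = make_activation([[1, 1], [1, 1]])
        out = filter_matrix(am)
        pd.testing.assert_frame_equal(out.calls, am.calls)

    def test_idempotent_and_keeps_every_one(self):
        rng = np.random.default_rng(2)
        am = make_activation((rng.random((15, 10)) < 0.2).astype(int))
        once = filter_matrix(am)
        twice = filter_matrix(once)
        pd.testing.assert_frame_equal(once.calls, twice.calls)
        assert once.calls.to_numpy().sum() == am.calls.to_numpy().sum()

    def test_fixpoint_flag_reaches_same_result(self):
        rng = np.random.default_rng(3)
        am = make_activation((rng.random((12, 8)) < 0.15).astype(int))
        pd.testing.assert_frame_equal(
            filter_matrix(am).calls, filter_matrix(am, fixpoint=True).calls)

    def test_planted_inactive_stimuli_removed_from_true_calls(self, default_sim):
        """Filtering the planted truth removes exactly the inactive stimuli."""
        from stimscreen import INACTIVE_LABEL
        _, truth = default_sim
        am = make_activation(
            truth.true_activation.to_numpy(),
            stimuli=list(truth.true_activation.index),
            signals=[SignalKey.parse(c) for c in truth.true_activation.columns],
        )
        out = filter_matrix(am)
        removed = set(am.stimuli) - set(out.stimuli)
        inactive = {s for s, l in truth.cluster_labels.items()
                    if l == INACTIVE_LABEL}
        assert removed == inactive

    def test_empty_result_is_error(self):
        with pytest.raises(EmptyMatrixError):
            filter_matrix(make_activation([[0, 0], [0, 0]]))


class TestSummarizeHits:
    def test_identity_matrix_counts(self):
        summary = summarize_hits(make_activation([[1, 0], [0, 1]]))
        assert list(summary.per_stimulus["total"]) == [1, 1]
        assert list(summary.per_signal["hits"]) == [1, 1]

    def test_counts_match_bruteforce_oracle(self):
        rng = np.random.default_rng(11)
        calls = (rng.random((20, 13)) < 0.3).astype(int)
        am = make_activation(calls)
        rows, cols = hit_counts_oracle(calls.tolist())
        summary = summarize_hits(am)
        assert sorted(summary.per_stimulus["total"]) == sorted(rows)
        assert sorted(summary.per_signal["hits"]) == sorted(cols)
        # per-stimulus counts map back to the right stimulus
        for i, stim in enumerate(am.stimuli):
            assert summary.per_stimulus.loc[stim, "total"] == rows[i]

    def test_sorted_count_desc_then_name_asc(self):
        calls = [[1, 1], [1, 1], [1, 0]]
        summary = summarize_hits(make_activation(calls, stimuli=["b", "a", "c"]))
        assert list(summary.per_stimulus.index) == ["a", "b", "c"]

    def test_per_panel_split(self):
        signals = [SignalKey("JUN", "phospho", "5min"),
                   SignalKey("IL6", "secreted", "24h")]
        summary = summarize_hits(make_activation([[1, 1], [1, 0]], signals=signals))
        assert list(summary.per_stimulus["phospho"]) == [1, 1]
        assert summary.per_stimulus.loc["s0", "secreted"] == 1
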