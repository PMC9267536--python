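"""Activation calling, threshold sensitivity, filtering and hit summaries.

A (stimulus, signal) pair is called *active* when its fold change reaches a
fixed threshold — 1.5 by default, chosen where the percentage of activations
is insensitive to small threshold changes.  The threshold comparison is
inclusive (FC >= t); a strict-inequality flag exists because published
phrasings differ and the two conventions disagree only at exact ties.

For phosphoprotein signals measured at several timepoints, a stimulus counts
as an activator of an analyte when it crosses the threshold at *at least one*
timepoint; :func:`collapse_timepoints` applies that OR rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyMatrixError, StimscreenError
from .screen_io import ActivationMatrix, FoldChangeMatrix, SignalKey

#: Default grid for the threshold sensitivity analysis.
DEFAULT_THRESHOLD_GRID = tuple(np.round(np.arange(1.05, 3.0001, 0.05), 2))

#: Timepoint label given to OR-collapsed multi-timepoint signals.
COLLAPSED_TIMEPOINT = "any"


@dataclass
class SensitivityCurve:
    """Percent of non-missing cells called active at each threshold.

    ``derivative`` holds the discrete slope Delta(pct)/Delta(threshold)
    between consecutive grid points; a flat stretch (small magnitude) marks
    the threshold-insensitive plateau.  No elbow is selected automatically.
    """

    thresholds: np.ndarray
    pct_active: np.ndarray
    derivative: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        d = np.concatenate([[np.nan], self.derivative])
        return pd.DataFrame(
            {"threshold": self.thresholds, "pct_active": self.pct_active,
             "dpct_dthreshold": d}
        )


@dataclass
class HitSummary:
    """Sorted hit counts: activations per stimulus and per signal.

    Both tables are sorted by count descending, then name ascending.
    ``per_stimulus`` reports one column per panel plus a total.
    """

    per_stimulus: pd.DataFrame
    per_signal: pd.DataFrame


def call_activations(
    fc: FoldChangeMatrix, threshold: float = 1.5, strict: bool = False
) -> ActivationMatrix:
    """Binarize a fold-change matrix at ``threshold``.

    MISSING fold changes yield call 0 with the cell recorded in the mask.
    """
    if threshold <= 1:
        raise StimscreenError(f"threshold must be > 1, got {threshold}")
    arr = fc.values.to_numpy(dtype=float)
    mask = np.isnan(arr)
    if strict:
        calls = (arr > threshold) & ~mask
    else:
        calls = (arr >= threshold) & ~mask
    return ActivationMatrix(
        calls=pd.DataFrame(calls.astype("int8"), index=fc.values.index,
                           columns=fc.values.columns),
        mask=pd.DataFrame(mask, index=fc.values.index, columns=fc.values.columns),
        signals=list(fc.signals),
        threshold=float(threshold),
        strict=strict,
    )


def collapse_timepoints(am: ActivationMatrix) -> ActivationMatrix:
    """OR-combine per-timepoint signals of the same (analyte, panel).

    Signals measured at a single timepoint pass through unchanged (their key
    is kept verbatim), so applying the collapse twice is a no-op.  A
    collapsed cell is masked only when *every* contributing timepoint was
    masked.
    """
    groups: dict[tuple[str, str], list[int]] = {}
    for j, s in enumerate(am.signals):
        groups.setdefault((s.analyte, s.panel), []).append(j)

    new_signals: list[SignalKey] = []
    new_calls = {}
    new_mask = {}
    calls = am.calls.to_numpy()
    mask = am.mask.to_numpy()
    seen: set[tuple[str, str]] = set()
    for j, s in enumerate(am.signals):
        key = (s.analyte, s.panel)
        if key in seen:
            continue
        seen.add(key)
        idx = groups[key]
        if len(idx) == 1:
            new_signals.append(am.signals[idx[0]])
            new_calls[str(new_signals[-1])] = calls[:, idx[0]]
            new_mask[str(new_signals[-1])] = mask[:, idx[0]]
        else:
            sig = SignalKey(s.analyte, s.panel, COLLAPSED_TIMEPOINT)
            new_signals.append(sig)
            new_calls[str(sig)] = calls[:, idx].max(axis=1)
            new_mask[str(sig)] = mask[:, idx].all(axis=1)
    return ActivationMatrix(
        calls=pd.DataFrame(new_calls, index=am.calls.index).astype("int8"),
        mask=pd.DataFrame(new_mask, index=am.calls.index),
        signals=new_signals,
        threshold=am.threshold,
        strict=am.strict,
        collapse_rule="any_timepoint",
    )


def sensitivity_curve(
    fc: FoldChangeMatrix, thresholds=None, strict: bool = False
) -> SensitivityCurve:
    """Percent of active calls across a threshold grid.

    ``thresholds`` must be sorted ascending and all > 1; the default grid is
    1.05 to 3.0 in steps of 0.05.
    """
    if thresholds is None:
        thresholds = DEFAULT_THRESHOLD_GRID
    t = np.asarray(list(thresholds), dtype=float)
    if t.size == 0:
        raise StimscreenError("threshold list must not be empty")
    if (t <= 1).any():
        raise StimscreenError("all thresholds must be > 1")
    if (np.diff(t) <= 0).any():
        raise StimscreenError("thresholds must be sorted strictly ascending")
    arr = fc.values.to_numpy(dtype=float)
    vals = arr[~np.isnan(arr)]
    if vals.size == 0:
        raise EmptyMatrixError("fold-change matrix has no non-missing cells")
    if strict:
        counts = (vals[None, :] > t[:, None]).sum(axis=1)
    else:
        counts = (vals[None, :] >= t[:, None]).sum(axis=1)
    pct = 100.0 * counts / vals.size
    deriv = np.diff(pct) / np.diff(t) if t.size > 1 else np.array([])
    return SensitivityCurve(thresholds=t, pct_active=pct, derivative=deriv)


def filter_matrix(am: ActivationMatrix, fixpoint: bool = False) -> ActivationMatrix:
    """Drop inactive stimuli, then globally non-responsive signals.

    The order is fixed: all-zero stimulus rows first, then all-zero signal
    columns over the remaining stimuli, each once.  (Removing an all-zero
    column cannot create a new all-zero row, so a ``fixpoint`` loop reaches
    the same result; the flag exists to make that checkable.)
    """
    calls = am.calls
    mask = am.mask
    while True:
        row_keep = calls.sum(axis=1) > 0
        calls, mask = calls.loc[row_keep], mask.loc[row_keep]
        col_keep = calls.sum(axis=0) > 0
        calls, mask = calls.loc[:, col_keep], mask.loc[:, col_keep]
        if not fixpoint or (row_keep.all() and col_keep.all()):
            break
    if calls.empty or calls.shape[1] == 0:
        raise EmptyMatrixError("activation matrix is empty after filtering")
    kept = set(calls.columns)
    return ActivationMatrix(
        calls=calls,
        mask=mask,
        signals=[s for s in am.signals if str(s) in kept],
        threshold=am.threshold,
        strict=am.strict,
        collapse_rule=am.collapse_rule,
    )


def summarize_hits(am: ActivationMatrix) -> HitSummary:
    """Hit counts: activations per stimulus (split by panel) and per signal."""
    panels = sorted({s.panel for s in am.signals})
    per_stim = pd.DataFrame(index=am.calls.index)
    for p in panels:
        cols = [str(s) for s in am.signals if s.panel == p]
        per_stim[p] = am.calls[cols].sum(axis=1).astype(int)
    per_stim["total"] = per_stim[panels].sum(axis=1)
    # count desc, then name asc: sort name first (stable), then count
    per_stim = per_stim.sort_index(kind="stable").sort_values(
        "total", ascending=False, kind="stable"
    )
    per_sig = am.calls.sum(axis=0).astype(int).rename("hits").to_frame()
    per_sig = per_sig.sort_index(kind="stable").sort_values(
        "hits", ascending=False, kind="stable"
    )
    return HitSummary(per_stimulus=per_stim, per_signal=per_sig)
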