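"""Fold-change normalization against pooled control-well medians.

For each signal (analyte x panel x timepoint), the unstimulated baseline is
the median MFI over all medium-only control wells of that (panel, timepoint)
group, pooled across the plates of the group — the controls of a screen are
deliberately spread over its plates.  The response to a stimulus is the
single stimulated measurement (or the median over replicate wells) divided
by that baseline.  The resulting ratio is the dimensionless fold change (FC);
FC = 1 means no response.

Stimuli without a measurement for a signal receive an explicit MISSING
marker (NaN), never 0, and MISSING values are excluded downstream.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DegenerateBaselineError, LookupError_, MissingMeasurementError
from .screen_io import FoldChangeMatrix, ScreenDataset, SignalKey

logger = logging.getLogger(__name__)


def control_baseline(
    ds: ScreenDataset, per_plate: bool = False
) -> dict[SignalKey, float] | dict[tuple[str, SignalKey], float]:
    """Median control-well MFI per signal.

    With ``per_plate=False`` (the default and the pipeline's convention),
    control wells are pooled across all plates of each (panel, timepoint)
    group; with ``per_plate=True`` the keys become ``(plate_id, signal)``.

    Raises
    ------
    DegenerateBaselineError
        If any baseline is zero (or negative), naming the signal.
    """
    long = ds.to_long()
    ctrl = long[long["is_control"]]
    group_cols = ["analyte", "panel", "timepoint"]
    if per_plate:
        group_cols = ["plate"] + group_cols
    med = ctrl.groupby(group_cols, sort=False)["value"].median()
    out: dict = {}
    for key, v in med.items():
        if per_plate:
            plate, analyte, panel, timepoint = key
            sig_key = (plate, SignalKey(analyte, panel, timepoint))
        else:
            analyte, panel, timepoint = key
            sig_key = SignalKey(analyte, panel, timepoint)
        if v <= 0:
            raise DegenerateBaselineError(
                f"control median for signal {sig_key} is {v} (must be > 0)"
            )
        out[sig_key] = float(v)
    return out


def aggregate_replicates(ds: ScreenDataset, stimulus: str, signal: SignalKey) -> float:
    """Stimulated-state MFI for one (stimulus, signal).

    A single well contributes its value directly; replicate wells are
    collapsed to their median.
    """
    vals = [
        w.values[signal.analyte]
        for w in ds.wells
        if (not w.is_control and w.stimulus == stimulus
            and w.panel == signal.panel and w.timepoint == signal.timepoint)
    ]
    if not vals:
        raise MissingMeasurementError(
            f"no well measures stimulus {stimulus!r} for signal {signal}"
        )
    return float(np.median(vals))


def fold_changes(
    ds: ScreenDataset,
    per_plate: bool = False,
    floor: float | None = None,
) -> FoldChangeMatrix:
    """Compute the stimuli x signals fold-change matrix of a screen.

    Parameters
    ----------
    per_plate
        Normalize each well against the control median of its own plate
        instead of the pooled group median (non-default diagnostic mode).
    floor
        Non-positive stimulated MFI (possible in background-subtracted
        exports) are clamped to this value before division.  Default: the
        smallest strictly positive MFI on the offending well's plate.
    """
    long = ds.to_long().copy()
    stim = long[~long["is_control"]].copy()

    nonpos = stim["value"] <= 0
    if nonpos.any():
        if floor is not None:
            stim.loc[nonpos, "value"] = floor
        else:
            plate_floor = (
                long[long["value"] > 0].groupby("plate")["value"].min()
            )
            stim.loc[nonpos, "value"] = stim.loc[nonpos, "plate"].map(plate_floor)
        logger.warning(
            "clamped %d non-positive stimulated MFI values to the plate floor",
            int(nonpos.sum()),
        )

    # replicate aggregation: median over wells per (stimulus, signal)
    agg = (
        stim.groupby(["stimulus", "analyte", "panel", "timepoint", "plate"]
                     if per_plate else
                     ["stimulus", "analyte", "panel", "timepoint"], sort=False)
        ["value"].median()
    )

    baselines = control_baseline(ds, per_plate=per_plate)
    ctrl = long[long["is_control"]]
    n_ctrl_series = ctrl.groupby(["analyte", "panel", "timepoint"], sort=False)[
        "well"
    ].count()

    stimuli = ds.stimuli()
    signals = ds.signals()
    n_controls = {
        s: int(n_ctrl_series.get((s.analyte, s.panel, s.timepoint), 0))
        for s in signals
    }
    for s in signals:
        if n_controls[s] < 1:
            raise DegenerateBaselineError(f"signal {s} has no control wells")

    values = np.full((len(stimuli), len(signals)), np.nan)
    stim_ix = {s: i for i, s in enumerate(stimuli)}
    sig_ix = {s: j for j, s in enumerate(signals)}
    if per_plate:
        # per-plate FCs; if replicates span plates, their FCs are median-pooled
        acc: dict[tuple[int, int], list[float]] = {}
        for (stimulus, analyte, panel, timepoint, plate), v in agg.items():
            key = (plate, SignalKey(analyte, panel, timepoint))
            base = baselines.get(key)
            if base is None:
                raise DegenerateBaselineError(
                    f"no control wells on plate {plate!r} for per-plate "
                    f"normalization of signal {key[1]}"
                )
            acc.setdefault((stim_ix[stimulus], sig_ix[key[1]]), []).append(v / base)
        for (i, j), fcs in acc.items():
            values[i, j] = float(np.median(fcs))
    else:
        for (stimulus, analyte, panel, timepoint), v in agg.items():
            sig = SignalKey(analyte, panel, timepoint)
            values[stim_ix[stimulus], sig_ix[sig]] = v / baselines[sig]

    frame = pd.DataFrame(values, index=stimuli, columns=[str(s) for s in signals])
    return FoldChangeMatrix(
        values=frame, signals=signals, n_controls=n_controls, aggregation="median"
    )
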