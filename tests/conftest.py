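import numpy as np
import pandas as pd
import pytest

from stimscreen import (
    ActivationMatrix,
    AnalytePanel,
    ScreenDataset,
    SignalKey,
    SimulationConfig,
    WellRecord,
    simulate_screen,
)


def make_activation(calls, stimuli=None, signals=None, threshold=1.5, mask=None):
    """Build an ActivationMatrix from a plain 0/1 array for tests."""
    arr = np.asarray(calls, dtype="int8")
    n, m = arr.shape
    stimuli = stimuli or [f"s{i}" for i in range(n)]
    signals = signals or [SignalKey(f"a{j}", "secreted", "24h") for j in range(m)]
    cols = [str(s) for s in signals]
    mask_arr = np.zeros_like(arr, dtype=bool) if mask is None else np.asarray(mask, bool)
    return ActivationMatrix(
        calls=pd.DataFrame(arr, index=stimuli, columns=cols),
        mask=pd.DataFrame(mask_arr, index=stimuli, columns=cols),
        signals=list(signals),
        threshold=threshold,
    )


def tiny_dataset(control_values, stim_values, analytes=("A", "B"), replicate_wells=None):
    """A one-panel, one-timepoint dataset: explicit control and stimulus MFIs.

    ``control_values``/``stim_values``: dict analyte -> list of well MFIs.
    """
    panel = AnalytePanel("secreted", tuple(analytes), ("24h",))
    wells = []
    n_ctrl = len(next(iter(control_values.values())))
    for i in range(n_ctrl):
        wells.append(WellRecord(
            plate_id=f"P{i % 2 + 1}", well_id=f"C{i:02d}", stimulus="medium",
            is_control=True, replicate=i + 1, panel="secreted", timepoint="24h",
            values={a: control_values[a][i] for a in analytes},
        ))
    n_stim = len(next(iter(stim_values.values())))
    for i in range(n_stim):
        wells.append(WellRecord(
            plate_id="P1", well_id=f"S{i:02d}", stimulus="stimX",
            is_control=False, replicate=i + 1, panel="secreted", timepoint="24h",
            values={a: stim_values[a][i] for a in analytes},
        ))
    for extra in (replicate_wells or []):
        wells.append(extra)
    return ScreenDataset(panels=[panel], wells=wells)


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulated screen shared across tests."""
    return simulate_screen(SimulationConfig(seed=7))


@pytest.fixture
def noiseless_sim():
    cfg = SimulationConfig(seed=3, noise_cv=0.0)
    return simulate_screen(cfg)
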