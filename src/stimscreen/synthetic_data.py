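"""Synthetic screen generator with planted activation structure.

The generator emulates the design of a two-arm bead-immunoassay screen on
96-well plates: a phosphoprotein panel (27 analytes, read at 5 and 25 min)
and a secreted-factor panel (32 analytes, read at 24 h); each stimulus
occupies a single well (or a small number of replicate wells), while
medium-only control wells are spread over at least two plates per
(panel, timepoint) group.

The planted truth is cluster-structured: each of ``n_clusters`` clusters
draws one binary activation profile over all signals; member stimuli inherit
it, plus rare off-profile (background) activations; a set of inactive
stimuli activates nothing.  The true fold change of an active cell is
log-normal around 3, of an inactive cell log-normal tightly around 1, and
the raw MFI of a well is baseline(analyte) x trueFC x multiplicative
log-normal measurement noise — bead-assay readouts are strictly positive
and heteroscedastic, which the log-normal model reflects.  Defaults are
chosen for identifiability of the planted structure, not as estimates of
any real effect-size distribution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import StimscreenError
from .screen_io import (
    CONTROL_STIMULUS,
    AnalytePanel,
    ScreenDataset,
    SignalKey,
    WellRecord,
)

logger = logging.getLogger(__name__)

#: Ground-truth label of stimuli with no planted activation.
INACTIVE_LABEL = "inactive"

# Cosmetic default names so simulated outputs read like a real screen:
# phosphoprotein hubs and secreted immune factors typical of such panels.
PHOSPHO_ANALYTES = (
    "AKT1", "CREB1", "EGFR", "ERK1", "FAK1", "GSK3B", "HSPB1", "IKBA",
    "JUN", "KS6A1", "KS6B1", "MEK1", "MK03", "MK12", "MK14", "MTOR",
    "PLCG1", "PTN11", "RS6", "SRC", "STAT1", "STAT3", "STAT5", "STAT6",
    "TF65", "TP53", "WNK1",
)
SECRETED_ANALYTES = (
    "CCL2", "CCL3", "CCL5", "CNTF", "CXCL10", "CXCL11", "FGF2", "GCSF",
    "GMCSF", "ICAM1", "IFNG", "IL1A", "IL1B", "IL2", "IL3", "IL4", "IL5",
    "IL6", "IL8", "IL10", "IL12", "IL13", "IL15", "IL17A", "PROK1", "TNF10",
    "TNF12", "TNFA", "TSLP", "VEGFA", "VEGFB", "TRAIL_R2",
)

# Printed stimulus names from the screen this generator emulates; used first
# when naming simulated stimuli (purely cosmetic), then generic fillers.
STIMULUS_NAMES = (
    "LPA 18:1", "HGF", "IL-1b", "FSL1", "TNFa", "PMA", "ANG1", "digoxin",
    "IL-1a", "IL-17a", "TNFSF12", "CXCL14", "promethazine", "PolyIC",
    "PDGF-AB", "PDGF-BB", "BMP2", "BDNF", "IL-10", "Cyr61", "Activin A",
    "WISP1", "EGF", "BMP7", "LPA 16:0", "LPA 20:4",
)

PLATE_CAPACITY = 96
_ROWS = "ABCDEFGH"


def default_panels() -> list[AnalytePanel]:
    """The two-panel design: 27 phospho x {5min, 25min}, 32 secreted x {24h}."""
    return [
        AnalytePanel("phospho", PHOSPHO_ANALYTES, ("5min", "25min")),
        AnalytePanel("secreted", SECRETED_ANALYTES, ("24h",)),
    ]


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults define the reference conditions."""

    n_clusters: int = 3
    stimuli_per_cluster: int = 10
    n_inactive_stimuli: int = 5
    panels: list[AnalytePanel] = field(default_factory=default_panels)
    n_control_wells: int = 5      # per (panel, timepoint) group
    replicate_count: int = 1
    p_active_in_profile: float = 0.3
    p_background: float = 0.02    # off-profile activation rate (cluster members)
    active_fc_log_mean: float = math.log(3.0)
    active_fc_log_sd: float = 0.25
    inactive_fc_log_sd: float = 0.08
    noise_cv: float = 0.10
    baseline_range: tuple[float, float] = (100.0, 10000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_active_in_profile, self.p_background):
            if not 0 <= p <= 1:
                raise StimscreenError("probabilities must lie in [0, 1]")
        for s in (self.active_fc_log_sd, self.inactive_fc_log_sd, self.noise_cv):
            if s < 0:
                raise StimscreenError("spread parameters must be >= 0")
        if self.n_clusters < 1 or self.stimuli_per_cluster < 1:
            raise StimscreenError("need >= 1 cluster with >= 1 stimulus")
        if self.n_inactive_stimuli < 0:
            raise StimscreenError("n_inactive_stimuli must be >= 0")
        if self.n_control_wells < 1 or self.replicate_count < 1:
            raise StimscreenError("control and replicate counts must be >= 1")
        if not self.panels or not any(p.analytes for p in self.panels):
            raise StimscreenError("config defines no signals")
        if self.baseline_range[0] <= 0 or self.baseline_range[1] < self.baseline_range[0]:
            raise StimscreenError("baseline_range must be 0 < lo <= hi")

    def to_yaml(self, path) -> None:
        doc = {
            k: getattr(self, k)
            for k in (
                "n_clusters", "stimuli_per_cluster", "n_inactive_stimuli",
                "n_control_wells", "replicate_count", "p_active_in_profile",
                "p_background", "active_fc_log_mean", "active_fc_log_sd",
                "inactive_fc_log_sd", "noise_cv", "seed",
            )
        }
        doc["baseline_range"] = list(self.baseline_range)
        doc["panels"] = [
            {"name": p.name, "analytes": list(p.analytes),
             "timepoints": list(p.timepoints)}
            for p in self.panels
        ]
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        if "panels" in doc:
            doc["panels"] = [
                AnalytePanel(p["name"], tuple(p["analytes"]), tuple(p["timepoints"]))
                for p in doc["panels"]
            ]
        if "baseline_range" in doc:
            doc["baseline_range"] = tuple(doc["baseline_range"])
        return cls(**doc)


@dataclass
class GroundTruth:
    """Planted truth emitted next to each simulated dataset."""

    cluster_labels: dict[str, object]   # stimulus -> 1..K or INACTIVE_LABEL
    true_activation: pd.DataFrame       # stimuli x signals, 0/1
    true_fc: pd.DataFrame               # stimuli x signals, > 0


def _stimulus_names(n: int) -> list[str]:
    names = list(STIMULUS_NAMES[:n])
    names += [f"stimulus_{i + 1:03d}" for i in range(len(names), n)]
    return names


def _lognormal_sigma(cv: float) -> float:
    """Log-space sd of a log-normal with coefficient of variation ``cv``."""
    return math.sqrt(math.log1p(cv * cv))


def _well_id(i: int) -> str:
    return f"{_ROWS[(i // 12) % 8]}{i % 12 + 1:02d}"


def _draw_profiles(rng: np.random.Generator, cfg: SimulationConfig,
                   n_signals: int) -> np.ndarray:
    """Cluster profiles, resampled until pairwise-separated and non-empty."""
    min_hamming = 0.2 * n_signals
    for attempt in range(1000):
        profiles = (rng.random((cfg.n_clusters, n_signals))
                    < cfg.p_active_in_profile).astype(np.int8)
        if (profiles.sum(axis=1) == 0).any():
            continue
        ok = all(
            (profiles[i] != profiles[j]).sum() >= min_hamming
            for i in range(cfg.n_clusters)
            for j in range(i + 1, cfg.n_clusters)
        )
        if ok:
            if attempt:
                logger.info("cluster profiles resampled %d time(s)", attempt)
            return profiles
    raise StimscreenError(
        "could not draw separated cluster profiles; raise p_active_in_profile "
        "or lower n_clusters"
    )


def simulate_screen(cfg: SimulationConfig) -> tuple[ScreenDataset, GroundTruth]:
    """Generate a raw-MFI screen dataset plus its planted ground truth.

    Deterministic for a fixed ``cfg.seed``.  Wells of each (panel, timepoint)
    group are dealt round-robin across ``max(2, ceil(wells / 96))`` plates,
    which also spreads the control wells over at least two plates.
    """
    rng = np.random.default_rng(cfg.seed)
    signals: list[SignalKey] = []
    for p in cfg.panels:
        signals.extend(p.signals())
    n_sig = len(signals)
    sig_cols = [str(s) for s in signals]

    profiles = _draw_profiles(rng, cfg, n_sig)

    n_clustered = cfg.n_clusters * cfg.stimuli_per_cluster
    n_stim = n_clustered + cfg.n_inactive_stimuli
    stimuli = _stimulus_names(n_stim)

    cluster_labels: dict[str, object] = {}
    activation = np.zeros((n_stim, n_sig), dtype=np.int8)
    for s in range(n_clustered):
        k = s // cfg.stimuli_per_cluster
        cluster_labels[stimuli[s]] = k + 1
        spurious = rng.random(n_sig) < cfg.p_background
        activation[s] = profiles[k] | spurious  # off-profile extras only
    for s in range(n_clustered, n_stim):
        cluster_labels[stimuli[s]] = INACTIVE_LABEL

    eps = rng.standard_normal((n_stim, n_sig))
    true_fc = np.where(
        activation == 1,
        np.exp(cfg.active_fc_log_mean + cfg.active_fc_log_sd * eps),
        np.exp(cfg.inactive_fc_log_sd * eps),
    )

    # per-(panel, analyte) baseline MFI, log-uniform
    lo, hi = cfg.baseline_range
    baseline: dict[tuple[str, str], float] = {}
    for p in cfg.panels:
        draws = np.exp(rng.uniform(math.log(lo), math.log(hi), len(p.analytes)))
        for a, b in zip(p.analytes, draws):
            baseline[(p.name, a)] = float(b)

    sigma = _lognormal_sigma(cfg.noise_cv)

    def noise(size: int) -> np.ndarray:
        if sigma == 0.0:
            return np.ones(size)
        return np.exp(rng.normal(0.0, sigma, size))

    sig_index = {s: j for j, s in enumerate(signals)}
    wells: list[WellRecord] = []
    for p in cfg.panels:
        base = np.array([baseline[(p.name, a)] for a in p.analytes])
        for t in p.timepoints:
            cols = [sig_index[SignalKey(a, p.name, t)] for a in p.analytes]
            entries: list[tuple[str, bool, int, np.ndarray]] = []
            for rep in range(1, cfg.replicate_count + 1):
                for s, name in enumerate(stimuli):
                    mfi = base * true_fc[s, cols] * noise(len(cols))
                    entries.append((name, False, rep, mfi))
            for c in range(1, cfg.n_control_wells + 1):
                mfi = base * noise(len(base))
                entries.append((CONTROL_STIMULUS, True, c, mfi))
            n_plates = max(2, math.ceil(len(entries) / PLATE_CAPACITY))
            counters = [0] * n_plates
            for i, (name, is_ctrl, rep, mfi) in enumerate(entries):
                plate = i % n_plates
                wells.append(
                    WellRecord(
                        plate_id=f"{p.name}_{t}_P{plate + 1}",
                        well_id=_well_id(counters[plate]),
                        stimulus=name,
                        is_control=is_ctrl,
                        replicate=rep,
                        panel=p.name,
                        timepoint=t,
                        values=dict(zip(p.analytes, mfi.astype(float))),
                    )
                )
                counters[plate] += 1

    ds = ScreenDataset(panels=list(cfg.panels), wells=wells)
    truth = GroundTruth(
        cluster_labels=cluster_labels,
        true_activation=pd.DataFrame(activation, index=stimuli, columns=sig_cols),
        true_fc=pd.DataFrame(true_fc, index=stimuli, columns=sig_cols),
    )
    return ds, truth
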