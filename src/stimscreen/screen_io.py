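"""Data model and I/O for multiplex bead-immunoassay (Luminex/xMAP) screens.

A screen is a collection of 96-well plates.  Each well holds cells exposed to
one stimulus (or plain medium, the control), and is read out on one analyte
panel — either intracellular phosphoproteins (two timepoints, 5 and 25 min)
or secreted factors (one timepoint, 24 h).  The raw readout is one median
fluorescence intensity (MFI) per analyte per well.

The model is deliberately flat: a :class:`WellRecord` per physical well, a
:class:`SignalKey` naming one measured quantity (analyte at a timepoint on a
panel), and a :class:`ScreenDataset` tying wells to panel declarations.
Well coordinates are opaque strings; no plate-geometry semantics are attached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyMatrixError,
    FormatError,
    LookupError_,
    ValidationError,
)

#: Stimulus name that marks a medium-only control well.  A separate boolean
#: column guards against typos; disagreement between the two is an error.
CONTROL_STIMULUS = "medium"

#: Canonical timepoint spellings.  Unrecognized labels pass through verbatim.
_TIMEPOINT_ALIASES = {
    "5min": "5min", "5 min": "5min", "5m": "5min", "5'": "5min",
    "25min": "25min", "25 min": "25min", "25m": "25min", "25'": "25min",
    "24h": "24h", "24 h": "24h", "24hr": "24h", "24 hr": "24h",
}

_LONG_COLUMNS = (
    "plate", "well", "stimulus", "is_control", "replicate",
    "panel", "timepoint", "analyte", "value",
)
_WIDE_META_COLUMNS = _LONG_COLUMNS[:7]


def normalize_timepoint(label: str) -> str:
    """Map common timepoint spellings onto "5min"/"25min"/"24h"."""
    return _TIMEPOINT_ALIASES.get(str(label).strip().lower(), str(label).strip())


class SignalKey(NamedTuple):
    """One measured quantity: an analyte on a panel at a timepoint."""

    analyte: str
    panel: str
    timepoint: str

    def __str__(self) -> str:  # column header form
        return f"{self.analyte}@{self.panel}@{self.timepoint}"

    @classmethod
    def parse(cls, text: str) -> "SignalKey":
        parts = str(text).split("@")
        if len(parts) != 3:
            raise FormatError(
                f"signal column {text!r} is not of the form analyte@panel@timepoint"
            )
        return cls(*parts)


@dataclass(frozen=True)
class AnalytePanel:
    """An antibody panel: an ordered analyte list and its assay timepoints."""

    name: str
    analytes: tuple[str, ...]
    timepoints: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "analytes", tuple(self.analytes))
        object.__setattr__(
            self, "timepoints", tuple(normalize_timepoint(t) for t in self.timepoints)
        )
        if len(set(self.analytes)) != len(self.analytes):
            raise ValidationError(f"panel {self.name!r}: duplicate analyte identifiers")
        if not self.analytes:
            raise ValidationError(f"panel {self.name!r}: no analytes")
        if not self.timepoints:
            raise ValidationError(f"panel {self.name!r}: no timepoints")
        if self.name == "secreted" and len(self.timepoints) != 1:
            raise ValidationError("secreted panel must have exactly one timepoint")

    def signals(self) -> list[SignalKey]:
        """All SignalKeys of the panel, timepoint-major, in declared order."""
        return [
            SignalKey(a, self.name, t) for t in self.timepoints for a in self.analytes
        ]


@dataclass
class WellRecord:
    """One physical well: metadata plus one MFI per analyte of its panel."""

    plate_id: str
    well_id: str
    stimulus: str
    is_control: bool
    replicate: int
    panel: str
    timepoint: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        self.timepoint = normalize_timepoint(self.timepoint)
        if self.is_control != (self.stimulus == CONTROL_STIMULUS):
            raise ValidationError(
                f"well {self.plate_id}/{self.well_id}: is_control={self.is_control} "
                f"disagrees with stimulus {self.stimulus!r} "
                f"(control sentinel is {CONTROL_STIMULUS!r})"
            )
        if self.replicate < 1:
            raise ValidationError(
                f"well {self.plate_id}/{self.well_id}: replicate must be >= 1"
            )


@dataclass
class ScreenDataset:
    """A validated screen: panel declarations plus all well records."""

    panels: list[AnalytePanel]
    wells: list[WellRecord]
    stimulus_metadata: dict[str, str] | None = None
    _long_cache: pd.DataFrame | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        panel_by_name = {p.name: p for p in self.panels}
        if len(panel_by_name) != len(self.panels):
            raise ValidationError("duplicate panel names")
        seen_wells: set[tuple[str, str]] = set()
        plate_panel: dict[str, str] = {}
        groups_with_controls: set[tuple[str, str]] = set()
        groups_seen: set[tuple[str, str]] = set()
        for w in self.wells:
            key = (w.plate_id, w.well_id)
            if key in seen_wells:
                raise ValidationError(f"duplicate well {w.plate_id}/{w.well_id}")
            seen_wells.add(key)
            panel = panel_by_name.get(w.panel)
            if panel is None:
                raise ValidationError(
                    f"well {w.plate_id}/{w.well_id}: unknown panel {w.panel!r}"
                )
            if w.timepoint not in panel.timepoints:
                raise ValidationError(
                    f"well {w.plate_id}/{w.well_id}: timepoint {w.timepoint!r} "
                    f"not declared for panel {w.panel!r}"
                )
            if set(w.values) != set(panel.analytes):
                missing = set(panel.analytes) - set(w.values)
                extra = set(w.values) - set(panel.analytes)
                raise ValidationError(
                    f"well {w.plate_id}/{w.well_id}: analyte mismatch with panel "
                    f"{w.panel!r} (missing={sorted(missing)}, extra={sorted(extra)})"
                )
            for a, v in w.values.items():
                if not math.isfinite(v) or v < 0:
                    raise ValidationError(
                        f"well {w.plate_id}/{w.well_id}: MFI for {a!r} is {v!r} "
                        "(must be a finite non-negative number)"
                    )
            prev = plate_panel.setdefault(w.plate_id, w.panel)
            if prev != w.panel:
                raise ValidationError(
                    f"plate {w.plate_id!r} mixes panels {prev!r} and {w.panel!r}"
                )
            groups_seen.add((w.panel, w.timepoint))
            if w.is_control:
                groups_with_controls.add((w.panel, w.timepoint))
        missing_ctrl = groups_seen - groups_with_controls
        if missing_ctrl:
            raise ValidationError(
                "no control well in (panel, timepoint) group(s): "
                + ", ".join(map(str, sorted(missing_ctrl)))
            )

    # -- accessors --------------------------------------------------------

    def panel(self, name: str) -> AnalytePanel:
        for p in self.panels:
            if p.name == name:
                return p
        raise LookupError_(f"unknown panel {name!r}")

    def signals(self) -> list[SignalKey]:
        """All SignalKeys of the screen, in panel declaration order."""
        out: list[SignalKey] = []
        for p in self.panels:
            out.extend(p.signals())
        return out

    def stimuli(self) -> list[str]:
        """Non-control stimuli, ordered by first appearance."""
        seen: dict[str, None] = {}
        for w in self.wells:
            if not w.is_control:
                seen.setdefault(w.stimulus, None)
        return list(seen)

    def plate_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for w in self.wells:
            seen.setdefault(w.plate_id, None)
        return list(seen)

    def to_long(self) -> pd.DataFrame:
        """Long-format view (one row per well x analyte), cached."""
        if self._long_cache is None:
            rows = []
            for w in self.wells:
                for a, v in w.values.items():
                    rows.append(
                        (w.plate_id, w.well_id, w.stimulus, w.is_control,
                         w.replicate, w.panel, w.timepoint, a, v)
                    )
            self._long_cache = pd.DataFrame(rows, columns=_LONG_COLUMNS)
        return self._long_cache


# ---------------------------------------------------------------------------
# Derived matrices
# ---------------------------------------------------------------------------

@dataclass
class FoldChangeMatrix:
    """Stimuli x signals fold changes relative to the control-well median.

    ``values`` is a DataFrame indexed by stimulus, with one column per
    ``str(SignalKey)``; NaN marks a MISSING measurement (never imputed).
    """

    values: pd.DataFrame
    signals: list[SignalKey]
    n_controls: dict[SignalKey, int]
    aggregation: str = "median"

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        ok = np.isnan(arr) | (np.isfinite(arr) & (arr > 0))
        if not ok.all():
            raise ValidationError("fold changes must be finite and > 0 (or NaN)")
        for s in self.signals:
            if self.n_controls.get(s, 0) < 1:
                raise ValidationError(f"signal {s} has no control wells")

    @property
    def stimuli(self) -> list[str]:
        return list(self.values.index)


@dataclass
class ActivationMatrix:
    """Binary stimuli x signals activation calls with full provenance.

    ``calls`` holds 0/1; ``mask`` is True where the underlying fold change
    was MISSING (those calls are 0 by convention and excluded from distances
    and sensitivity percentages).
    """

    calls: pd.DataFrame
    mask: pd.DataFrame
    signals: list[SignalKey]
    threshold: float
    strict: bool = False
    collapse_rule: str = "none"

    def __post_init__(self) -> None:
        vals = self.calls.to_numpy()
        if not ((vals == 0) | (vals == 1)).all():
            raise ValidationError("activation calls must be 0 or 1")
        if self.threshold <= 1:
            raise ValidationError("activation threshold must be > 1")
        if self.collapse_rule not in ("none", "any_timepoint"):
            raise ValidationError(f"unknown collapse rule {self.collapse_rule!r}")

    @property
    def stimuli(self) -> list[str]:
        return list(self.calls.index)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        return pd.read_csv(path, sep=sep)
    except Exception as exc:  # malformed CSV
        raise FormatError(f"cannot parse {path}: {exc}") from exc


def _coerce_bool(x) -> bool:
    if isinstance(x, bool):
        return x
    s = str(x).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise FormatError(f"cannot interpret {x!r} as a boolean is_control flag")


def read_screen(
    paths: Sequence[str | Path],
    layout: str = "long",
    stimulus_metadata: Mapping[str, str] | None = None,
) -> ScreenDataset:
    """Read one or more plate tables into a validated :class:`ScreenDataset`.

    Parameters
    ----------
    paths
        CSV (comma) or TSV (tab) files, each with a header row.
    layout
        ``"long"`` — columns plate, well, stimulus, is_control, replicate,
        panel, timepoint, analyte, value (one row per well x analyte);
        ``"wide"`` — the same seven metadata columns plus one column per
        analyte.
    """
    if layout not in ("long", "wide"):
        raise FormatError(f"unknown layout {layout!r} (expected 'long' or 'wide')")
    frames = []
    for p in paths:
        df = _read_table(p)
        required = _LONG_COLUMNS if layout == "long" else _WIDE_META_COLUMNS
        for col in required:
            if col not in df.columns:
                raise FormatError(f"{p}: missing required column {col!r}")
        if layout == "wide":
            analyte_cols = [c for c in df.columns if c not in _WIDE_META_COLUMNS]
            if not analyte_cols:
                raise FormatError(f"{p}: wide layout has no analyte columns")
            df = df.melt(
                id_vars=list(_WIDE_META_COLUMNS),
                value_vars=analyte_cols,
                var_name="analyte",
                value_name="value",
            )
        frames.append(df[list(_LONG_COLUMNS)])
    long = pd.concat(frames, ignore_index=True)

    values = pd.to_numeric(long["value"], errors="coerce")
    bad = values.isna() | (values < 0)
    if bad.any():
        row = long[bad].iloc[0]
        raise ValidationError(
            f"negative or non-numeric MFI {row['value']!r} at plate={row['plate']} "
            f"well={row['well']} analyte={row['analyte']}"
        )
    long = long.assign(value=values,
                       timepoint=long["timepoint"].map(normalize_timepoint),
                       is_control=long["is_control"].map(_coerce_bool))

    # panel declarations inferred from the data, preserving first appearance
    panels = []
    for name, sub in long.groupby("panel", sort=False):
        analytes = tuple(dict.fromkeys(sub["analyte"]))
        timepoints = tuple(dict.fromkeys(sub["timepoint"]))
        panels.append(AnalytePanel(str(name), analytes, timepoints))

    wells = []
    for (plate, well), sub in long.groupby(["plate", "well"], sort=False):
        meta = sub.iloc[0]
        if sub["stimulus"].nunique() > 1 or sub["timepoint"].nunique() > 1:
            raise ValidationError(
                f"well {plate}/{well}: conflicting stimulus/timepoint rows"
            )
        if sub["analyte"].duplicated().any():
            dup = sub.loc[sub["analyte"].duplicated(), "analyte"].iloc[0]
            raise ValidationError(
                f"well {plate}/{well}: analyte {dup!r} appears more than once"
            )
        wells.append(
            WellRecord(
                plate_id=str(plate),
                well_id=str(well),
                stimulus=str(meta["stimulus"]),
                is_control=bool(meta["is_control"]),
                replicate=int(meta["replicate"]),
                panel=str(meta["panel"]),
                timepoint=str(meta["timepoint"]),
                values=dict(zip(sub["analyte"], sub["value"])),
            )
        )
    return ScreenDataset(
        panels=panels,
        wells=wells,
        stimulus_metadata=dict(stimulus_metadata) if stimulus_metadata else None,
    )


def write_screen(ds: ScreenDataset, path: str | Path) -> None:
    """Write a dataset as a long TSV (the only emitted dialect; lossless)."""
    ds.to_long().to_csv(path, sep="\t", index=False)


def count_measurements(ds: ScreenDataset, plate_id: str) -> int:
    """Number of measurement records a plate yields: wells x panel analytes."""
    wells = [w for w in ds.wells if w.plate_id == plate_id]
    if not wells:
        raise LookupError_(f"unknown plate {plate_id!r}")
    panel = ds.panel(wells[0].panel)
    return len(wells) * len(panel.analytes)


def write_matrix(m: FoldChangeMatrix | ActivationMatrix, path: str | Path) -> None:
    """Serialize a derived matrix as TSV (stimuli rows, analyte@panel@timepoint
    columns).  Fold changes keep full float precision; activation calls are
    0/1 integers with masked (MISSING) cells written as NA.  Provenance is
    kept in ``#``-prefixed header lines so the paired reader round-trips."""
    if m.values.empty if isinstance(m, FoldChangeMatrix) else m.calls.empty:
        raise EmptyMatrixError("refusing to write an empty matrix")
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if isinstance(m, FoldChangeMatrix):
            fh.write("# matrix=fold_change\n")
            fh.write(f"# aggregation={m.aggregation}\n")
            fh.write(
                "# n_controls="
                + ",".join(f"{s}:{m.n_controls[s]}" for s in m.signals)
                + "\n"
            )
            body = m.values.copy()
            body.insert(0, "stimulus", body.index)
            body.to_csv(fh, sep="\t", index=False, na_rep="NA",
                        float_format="%.17g")
        else:
            fh.write("# matrix=activation\n")
            fh.write(f"# threshold={m.threshold!r}\n")
            fh.write(f"# strict={m.strict}\n")
            fh.write(f"# collapse_rule={m.collapse_rule}\n")
            body = m.calls.astype(object).where(~m.mask, other=pd.NA)
            body.insert(0, "stimulus", body.index)
            body.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_matrix(path: str | Path) -> FoldChangeMatrix | ActivationMatrix:
    """Read back a matrix written by :func:`write_matrix`."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                k, _, v = line[1:].strip().partition("=")
                meta[k.strip()] = v
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        body = pd.read_csv(fh, sep="\t", na_values=["NA"], keep_default_na=False)
    if "stimulus" not in body.columns:
        raise FormatError(f"{path}: missing 'stimulus' column")
    body = body.set_index("stimulus")
    body.index.name = None
    signals = [SignalKey.parse(c) for c in body.columns]
    kind = meta.get("matrix")
    if kind == "fold_change":
        n_controls = {}
        for entry in meta.get("n_controls", "").split(","):
            if entry:
                key, _, n = entry.rpartition(":")
                n_controls[SignalKey.parse(key)] = int(n)
        return FoldChangeMatrix(
            values=body.astype(float),
            signals=signals,
            n_controls=n_controls,
            aggregation=meta.get("aggregation", "median"),
        )
    if kind == "activation":
        mask = body.isna()
        calls = body.fillna(0).astype("int8")
        return ActivationMatrix(
            calls=calls,
            mask=mask,
            signals=signals,
            threshold=float(meta["threshold"]),
            strict=meta.get("strict", "False") == "True",
            collapse_rule=meta.get("collapse_rule", "none"),
        )
    raise FormatError(f"{path}: unknown or missing '# matrix=' header")
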