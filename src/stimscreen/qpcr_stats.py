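"""Relative quantification for qPCR validation and routed group comparisons.

Quantification cycles (Cq) are normalized per sample against a reference
gene (default *B2M*): dCq = Cq(gene) - Cq(reference).  Two summaries are
supported:

* **ddCq (Livak)** — per treated sample, fold change relative to the mean
  control dCq: FC = 2^-(dCq_treated - mean dCq_control).
* **dCq** — relative abundance 2^-dCq, for comparing expression levels of
  different genes within the same samples.

Both are exact powers of two of their exponents.

Group comparisons follow a normality-routed scheme: Shapiro-Wilk per group
at alpha = 0.05; any non-normal group routes to the nonparametric branch
(Mann-Whitney for two groups, Kruskal-Wallis otherwise); otherwise two
groups are compared by Student's or Welch's t-test depending on an F-test
of variance equality, and several-versus-control designs use Welch's ANOVA
with Dunnett many-to-one comparisons.  Every check performed is recorded in
a routing trace so the decision path is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.oneway import anova_oneway

from .errors import (
    FormatError,
    InsufficientSamplesError,
    LookupError_,
    ValidationError,
)

REFERENCE_GENE_DEFAULT = "B2M"


@dataclass
class QpcrTable:
    """Long-format Cq table: one row per (sample, gene) with a group label."""

    data: pd.DataFrame  # columns: sample_id, group, gene, cq
    reference_gene: str = REFERENCE_GENE_DEFAULT

    def __post_init__(self) -> None:
        required = {"sample_id", "group", "gene", "cq"}
        missing = required - set(self.data.columns)
        if missing:
            raise FormatError(f"Cq table missing column(s): {sorted(missing)}")
        if not np.isfinite(self.data["cq"].to_numpy(dtype=float)).all():
            raise ValidationError("all Cq values must be finite")
        if self.data.duplicated(["sample_id", "gene"]).any():
            raise ValidationError("duplicate (sample, gene) Cq rows")
        ref = self.data[self.data["gene"] == self.reference_gene]
        samples = set(self.data["sample_id"])
        if set(ref["sample_id"]) != samples:
            missing_ref = samples - set(ref["sample_id"])
            raise ValidationError(
                f"sample(s) without reference-gene Cq: {sorted(missing_ref)}"
            )

    @classmethod
    def read_csv(cls, path: str | Path,
                 reference_gene: str = REFERENCE_GENE_DEFAULT) -> "QpcrTable":
        path = Path(path)
        if not path.exists():
            raise FormatError(f"file not found: {path}")
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        return cls(pd.read_csv(path, sep=sep), reference_gene=reference_gene)

    def _cq(self, sample: str, gene: str) -> float:
        sub = self.data[(self.data["sample_id"] == sample)
                        & (self.data["gene"] == gene)]
        if sub.empty:
            raise LookupError_(f"no Cq for sample {sample!r}, gene {gene!r}")
        return float(sub["cq"].iloc[0])


@dataclass
class RelativeExpression:
    """A gene's relative expression with its per-sample values retained."""

    gene: str
    method: str                  # "ddCq" | "dCq"
    value: float                 # summary (mean over the reported samples)
    per_sample: dict[str, float]


@dataclass
class GroupComparisonResult:
    """Outcome of a routed group comparison, including the decision trace."""

    test_used: str
    statistic: float
    p_value: float
    routing_trace: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValidationError("p-value must lie in [0, 1]")


def delta_cq(tbl: QpcrTable, sample: str, gene: str) -> float:
    """dCq = Cq(gene) - Cq(reference gene) for one sample."""
    return tbl._cq(sample, gene) - tbl._cq(sample, tbl.reference_gene)


def livak_fold_change(
    tbl: QpcrTable, gene: str, calibrator: str = "mean"
) -> RelativeExpression:
    """Livak 2^-ddCq fold change of ``gene`` in treated vs control samples.

    The calibrator is the mean (default; ``calibrator="median"`` available)
    dCq over control-group samples.  One fold change is reported per treated
    sample; ``value`` is their arithmetic mean.
    """
    sub = tbl.data[tbl.data["gene"] == gene]
    if sub.empty:
        raise LookupError_(f"gene {gene!r} not in table")
    treated = sub[sub["group"] == "treated"]["sample_id"].tolist()
    control = sub[sub["group"] == "control"]["sample_id"].tolist()
    if not control:
        raise LookupError_(f"no control samples for gene {gene!r}")
    if not treated:
        raise LookupError_(f"no treated samples for gene {gene!r}")
    control_dcq = [delta_cq(tbl, s, gene) for s in control]
    if calibrator == "mean":
        calib = float(np.mean(control_dcq))
    elif calibrator == "median":
        calib = float(np.median(control_dcq))
    else:
        raise ValidationError(f"unknown calibrator {calibrator!r}")
    per_sample = {
        s: 2.0 ** -(delta_cq(tbl, s, gene) - calib) for s in treated
    }
    return RelativeExpression(
        gene=gene, method="ddCq",
        value=float(np.mean(list(per_sample.values()))),
        per_sample=per_sample,
    )


def relative_abundance(tbl: QpcrTable, genes: list[str]) -> list[RelativeExpression]:
    """2^-dCq relative abundance per gene, returned ranked (highest first).

    Ties in the mean abundance keep the caller's gene order.
    """
    out = []
    samples = list(dict.fromkeys(tbl.data["sample_id"]))
    for gene in genes:
        present = [
            s for s in samples
            if not tbl.data[(tbl.data["sample_id"] == s)
                            & (tbl.data["gene"] == gene)].empty
        ]
        if not present:
            raise LookupError_(f"gene {gene!r} not in table")
        per_sample = {s: 2.0 ** -delta_cq(tbl, s, gene) for s in present}
        out.append(
            RelativeExpression(
                gene=gene, method="dCq",
                value=float(np.mean(list(per_sample.values()))),
                per_sample=per_sample,
            )
        )
    out.sort(key=lambda r: -r.value)
    return out


def route_group_test(
    groups: list[np.ndarray],
    design: str = "two_group",
    alpha: float = 0.05,
) -> GroupComparisonResult:
    """Normality-routed comparison of >= 2 groups of measurements.

    ``design="two_group"`` compares exactly two groups; ``"multi_vs_control"``
    treats the *first* group as the control for Dunnett-style many-to-one
    comparisons.  Each group must have n >= 3 so the Shapiro-Wilk check is
    defined; smaller groups raise rather than silently falling back.
    """
    if design not in ("two_group", "multi_vs_control"):
        raise ValidationError(f"unknown design {design!r}")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    if design == "two_group" and len(groups) != 2:
        raise ValidationError("two_group design needs exactly two groups")
    for i, g in enumerate(groups):
        if len(g) < 3:
            raise InsufficientSamplesError(
                f"group {i} has n={len(g)} < 3; normality checking undefined"
            )
    trace: list[dict] = []
    normal = True
    for i, g in enumerate(groups):
        w, p = stats.shapiro(g)
        ok = p >= alpha
        trace.append({"check": "shapiro", "group": i, "W": float(w),
                      "p": float(p), "normal": bool(ok)})
        normal = normal and ok

    if not normal:
        if len(groups) == 2:
            stat, p = stats.mannwhitneyu(groups[0], groups[1],
                                         alternative="two-sided")
            used = "mann_whitney"
        else:
            stat, p = stats.kruskal(*groups)
            used = "kruskal_wallis"
        trace.append({"test": used, "statistic": float(stat), "p": float(p)})
        return GroupComparisonResult(used, float(stat), float(p), trace)

    if design == "two_group":
        a, b = groups
        f = float(np.var(a, ddof=1) / np.var(b, ddof=1))
        df1, df2 = len(a) - 1, len(b) - 1
        p_var = 2 * min(stats.f.cdf(f, df1, df2), stats.f.sf(f, df1, df2))
        p_var = min(1.0, float(p_var))
        equal_var = p_var >= alpha
        trace.append({"check": "f_variance_ratio", "F": f, "p": p_var,
                      "equal_var": bool(equal_var)})
        stat, p = stats.ttest_ind(a, b, equal_var=equal_var)
        used = "t_unpaired" if equal_var else "t_welch"
        trace.append({"test": used, "statistic": float(stat), "p": float(p)})
        return GroupComparisonResult(used, float(stat), float(p), trace)

    # multi_vs_control, all groups normal: Welch ANOVA omnibus + Dunnett
    res = anova_oneway(groups, use_var="unequal", welch_correction=True)
    trace.append({"test": "welch_anova", "statistic": float(res.statistic),
                  "p": float(res.pvalue)})
    dunnett = stats.dunnett(*groups[1:], control=groups[0])
    trace.append({
        "test": "dunnett",
        "statistic": [float(s) for s in np.atleast_1d(dunnett.statistic)],
        "p": [float(p) for p in np.atleast_1d(dunnett.pvalue)],
    })
    return GroupComparisonResult(
        "welch_anova_dunnett", float(res.statistic), float(res.pvalue), trace
    )
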