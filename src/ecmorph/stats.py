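"""Group summaries and unpaired Student t-tests over per-ROI measurements.

Each analyzed ROI contributes one :class:`RoiMeasurement` with four metrics:
ECM surface %, 2-D fractal dimension, erosion cycles and degradation
velocity.  ROIs are pooled per group and treated as independent observations
(the case-level nesting of ROIs within patients is a documented limitation,
not corrected here).  Group pairs are compared metric-by-metric with the
classical pooled-variance two-sided Student t-test, α = 0.05, no
multiple-testing correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, ValidationError
from .imaging import Group

METRICS = ("ecm_percent", "fractal_dimension", "n_cycles", "velocity")


@dataclass(frozen=True)
class RoiMeasurement:
    """One ROI's complete measurement record."""

    roi_id: str
    case_id: str
    group: Group
    ecm_percent: float
    fractal_dimension: float
    n_cycles: float
    velocity: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", Group.parse(self.group))
        for name in METRICS:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValidationError(f"{name} must be finite, got {v!r}")
        if not 0.0 <= self.ecm_percent <= 100.0:
            raise ValidationError(f"ecm_percent {self.ecm_percent} outside [0, 100]")
        if not 0.0 <= self.fractal_dimension <= 2.0:
            raise ValidationError(
                f"fractal_dimension {self.fractal_dimension} outside [0, 2]"
            )
        if self.n_cycles < 0 or self.velocity < 0:
            raise ValidationError("n_cycles and velocity must be nonnegative")


@dataclass(frozen=True)
class GroupSummary:
    """Mean, sample SD (n−1) and SE per metric for one group's pooled ROIs."""

    group: Group
    n_rois: int
    mean: "dict[str, float]"
    sd: "dict[str, float]"
    se: "dict[str, float]"


@dataclass(frozen=True)
class TTestResult:
    group_a: Group
    group_b: Group
    metric: str
    t_statistic: float
    degrees_of_freedom: int
    p_value: float


def summarize_group(
    measurements: "list[RoiMeasurement]", group: "str | Group"
) -> GroupSummary:
    """Pool all ROIs of one group; sample SD uses the n−1 denominator."""
    group = Group.parse(group)
    rows = [m for m in measurements if m.group == group]
    if len(rows) < 2:
        raise InsufficientDataError(
            f"group {group.value} has {len(rows)} ROI(s); need >= 2"
        )
    n = len(rows)
    mean, sd, se = {}, {}, {}
    for metric in METRICS:
        vals = np.array([getattr(m, metric) for m in rows], float)
        mean[metric] = float(vals.mean())
        sd[metric] = float(vals.std(ddof=1))
        se[metric] = sd[metric] / math.sqrt(n)
    return GroupSummary(group=group, n_rois=n, mean=mean, sd=sd, se=se)


def unpaired_t_test(
    a: "list[float] | np.ndarray",
    b: "list[float] | np.ndarray",
    metric: str = "",
    group_a: "str | Group" = Group.OTHER,
    group_b: "str | Group" = Group.OTHER,
    welch: bool = False,
) -> TTestResult:
    """Two-sided unpaired Student t-test (pooled variance by default).

    t = (mean_a − mean_b) / (s_p · sqrt(1/n_a + 1/n_b)), df = n_a + n_b − 2.
    Degenerate zero-variance inputs follow the documented convention:
    equal means → p = 1, unequal means → p = 0.  ``welch=True`` switches to
    the unequal-variance form.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each sample needs >= 2 values")
    df = len(a) + len(b) - 2
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        equal = a.mean() == b.mean()
        return TTestResult(
            group_a=Group.parse(group_a),
            group_b=Group.parse(group_b),
            metric=metric,
            t_statistic=0.0 if equal else math.inf * np.sign(a.mean() - b.mean()),
            degrees_of_freedom=df,
            p_value=1.0 if equal else 0.0,
        )
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df_used = int(df) if not welch else int(res.df)
    return TTestResult(
        group_a=Group.parse(group_a),
        group_b=Group.parse(group_b),
        metric=metric,
        t_statistic=float(res.statistic),
        degrees_of_freedom=df_used,
        p_value=float(res.pvalue),
    )


@dataclass
class ResultsTable:
    """Table-style report: one summary row per group (mean ± SD per metric)
    plus one row per requested (pair, metric) comparison."""

    summaries: pd.DataFrame
    comparisons: pd.DataFrame

    def to_csv(self, path) -> None:
        combined = pd.concat(
            [
                self.summaries.assign(row_type="summary"),
                self.comparisons.assign(row_type="comparison"),
            ],
            ignore_index=True,
        )
        cols = ["row_type"] + [c for c in combined.columns if c != "row_type"]
        combined[cols].to_csv(path, index=False)

    def to_text(self) -> str:
        lines = ["Group summaries (mean ± SD):"]
        for _, row in self.summaries.iterrows():
            parts = [
                f"{m}={row[f'{m}_mean']:.3f}±{row[f'{m}_sd']:.3f}"
                for m in METRICS
            ]
            lines.append(f"  {row['group']} (n={row['n_rois']}): " + ", ".join(parts))
        lines.append("Pairwise unpaired Student t-tests (two-sided):")
        for _, row in self.comparisons.iterrows():
            star = " *" if row["p_value"] < 0.05 else ""
            lines.append(
                f"  {row['group_a']} vs {row['group_b']} [{row['metric']}]: "
                f"t={row['t_statistic']:.3f}, df={row['df']}, "
                f"p={row['p_value']:.3g}{star}"
            )
        return "\n".join(lines)


def build_results_table(
    measurements: "list[RoiMeasurement]",
    comparisons: "list[tuple[str | Group, str | Group]]",
) -> ResultsTable:
    """Summaries for every group present plus t-tests for the requested pairs.

    Every group named in ``comparisons`` must appear in the measurements.
    """
    groups_present = []
    for m in measurements:
        if m.group not in groups_present:
            groups_present.append(m.group)

    summary_rows = []
    for g in groups_present:
        s = summarize_group(measurements, g)
        row: "dict[str, object]" = {"group": g.value, "n_rois": s.n_rois}
        for metric in METRICS:
            row[f"{metric}_mean"] = s.mean[metric]
            row[f"{metric}_sd"] = s.sd[metric]
            row[f"{metric}_se"] = s.se[metric]
        summary_rows.append(row)

    comp_rows = []
    for ga, gb in comparisons:
        ga, gb = Group.parse(ga), Group.parse(gb)
        for g in (ga, gb):
            if g not in groups_present:
                raise ValidationError(f"group {g.value} absent from measurements")
        for metric in METRICS:
            va = [getattr(m, metric) for m in measurements if m.group == ga]
            vb = [getattr(m, metric) for m in measurements if m.group == gb]
            r = unpaired_t_test(va, vb, metric=metric, group_a=ga, group_b=gb)
            comp_rows.append(
                {
                    "group_a": ga.value,
                    "group_b": gb.value,
                    "metric": metric,
                    "t_statistic": r.t_statistic,
                    "df": r.degrees_of_freedom,
                    "p_value": r.p_value,
                }
            )

    return ResultsTable(
        summaries=pd.DataFrame(summary_rows),
        comparisons=pd.DataFrame(
            comp_rows,
            columns=["group_a", "group_b", "metric", "t_statistic", "df", "p_value"],
        ),
    )


def measurements_to_frame(measurements: "list[RoiMeasurement]") -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "roi_id": m.roi_id,
                "case_id": m.case_id,
                "group": m.group.value,
                **{metric: getattr(m, metric) for metric in METRICS},
            }
            for m in measurements
        ]
    )


def frame_to_measurements(df: pd.DataFrame) -> "list[RoiMeasurement]":
    required = {"roi_id", "case_id", "group", *METRICS}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"measurement table missing columns: {sorted(missing)}")
    return [
        RoiMeasurement(
            roi_id=str(row.roi_id),
            case_id=str(row.case_id),
            group=Group.parse(row.group),
            ecm_percent=float(row.ecm_percent),
            fractal_dimension=float(row.fractal_dimension),
            n_cycles=float(row.n_cycles),
            velocity=float(row.velocity),
        )
        for row in df.itertuples(index=False)
    ]
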