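"""Cohort-level statistics: group-vs-control Student's t-tests.

Per-colony scalar measurements are grouped by (metric, day, group) and each
treated group is compared against the control group with a two-sided
pooled-variance (classic Student) two-sample t-test; significance is called
at p < 0.05. No multiple-testing correction is applied: every comparison
cell is reported raw, so p-values across a table are individually, not
family-wise, calibrated. A Welch (unequal-variance) variant is available
behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DegenerateStatisticsError
from .io import MeasurementRecord, records_to_frame

__all__ = ["GroupComparison", "two_sample_ttest", "compare_to_control", "comparison_table"]

ALPHA = 0.05


@dataclass(frozen=True)
class GroupComparison:
    """One cell of a group-vs-control comparison matrix."""

    metric: str
    day: int
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    t_statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of [0, 1]: {self.p_value}")
        if self.n_a < 2 or self.n_b < 2:
            raise ValueError("each group needs >= 2 observations")

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def two_sample_ttest(
    a: Sequence[float], b: Sequence[float], welch: bool = False
) -> tuple[float, float]:
    """Two-sided two-sample t-test; pooled variance unless ``welch``.

    Degenerate samples with zero pooled variance return (0, 1) when the
    means agree (no evidence of a difference) and raise otherwise, since
    the statistic is then infinite and its distribution undefined.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise DegenerateStatisticsError("each sample needs >= 2 values")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise DegenerateStatisticsError(
            "zero variance in both samples with different means"
        )
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def compare_to_control(
    records: Sequence[MeasurementRecord] | pd.DataFrame,
    metrics: Sequence[str] | None = None,
    control_label: str = "control",
    welch: bool = False,
) -> list[GroupComparison]:
    """Compare every (group, day) cell of each metric against control.

    Returns one :class:`GroupComparison` per non-control group × day ×
    metric for which both the group and the control have at least two
    values. A missing control group is a configuration error.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if control_label not in set(df["group"]):
        raise ConfigError(f"control group {control_label!r} not present in records")
    if metrics is None:
        metrics = sorted(df["metric"].unique())
    out: list[GroupComparison] = []
    for metric in metrics:
        dm = df[df["metric"] == metric]
        for day in sorted(dm["day"].unique()):
            dd = dm[dm["day"] == day]
            ctrl = dd[dd["group"] == control_label]["value"].to_numpy()
            if len(ctrl) < 2:
                continue
            for group in sorted(set(dd["group"]) - {control_label}):
                vals = dd[dd["group"] == group]["value"].to_numpy()
                if len(vals) < 2:
                    continue
                t, p = two_sample_ttest(vals, ctrl, welch=welch)
                out.append(
                    GroupComparison(
                        metric=metric, day=int(day),
                        group_a=group, group_b=control_label,
                        n_a=len(vals), n_b=len(ctrl),
                        t_statistic=t, p_value=p,
                    )
                )
    return out


def comparison_table(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    """Tidy comparison frame: one row per comparison, plus significance."""
    return pd.DataFrame(
        [
            {
                "metric": c.metric,
                "day": c.day,
                "group": c.group_a,
                "control": c.group_b,
                "n_group": c.n_a,
                "n_control": c.n_b,
                "t_statistic": c.t_statistic,
                "p_value": c.p_value,
                "significant": c.significant,
            }
            for c in comparisons
        ],
        columns=[
            "metric", "day", "group", "control",
            "n_group", "n_control", "t_statistic", "p_value", "significant",
        ],
    )
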