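"""Chronological-lifespan (CLS) curve statistics.

Viability curves record the percent of colony-forming cells versus day in
stationary phase, per replicate culture.  Treatments are compared by the
trapezoid area under each replicate's curve (percent x days), followed by a
two-sample Student's t-test on the replicate AUCs with a confidence interval
for the difference of the group means.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SurvivalCurve:
    """One replicate's viability trajectory."""

    group: str
    replicate: str
    days: np.ndarray
    viability: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.days.size < 2:
            raise ValueError("a survival curve needs at least 2 days")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(self.viability < 0):
            raise ValueError("viability must be non-negative")


def survival_auc(curve: SurvivalCurve) -> float:
    """Trapezoid area under the viability curve, in percent x days."""
    return float(np.trapezoid(curve.viability, curve.days))


@dataclass
class AucTestResult:
    """Two-group comparison of replicate AUCs."""

    mean_a: float
    mean_b: float
    difference: float          # mean_a - mean_b
    ci_low: float
    ci_high: float
    p: float
    n_a: int
    n_b: int
    degenerate: bool = False   # zero pooled variance


def auc_difference_test(group_a, group_b, conf: float = 0.95,
                        welch: bool = False) -> AucTestResult:
    """Two-tailed two-sample t-test on per-replicate AUCs.

    Pooled-variance (Student) by default; Welch via ``welch=True``.  With
    zero pooled variance the test is degenerate: the CI collapses onto the
    observed difference and p is 1 for a zero difference, 0 otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 replicate AUCs")
    if not 0 < conf < 1:
        raise ValueError("conf must be in (0, 1)")

    diff = float(a.mean() - b.mean())
    if welch:
        se = float(np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size))
        if se > 0:
            df = (a.var(ddof=1) / a.size + b.var(ddof=1) / b.size) ** 2 / (
                (a.var(ddof=1) / a.size) ** 2 / (a.size - 1)
                + (b.var(ddof=1) / b.size) ** 2 / (b.size - 1)
            )
        else:
            df = a.size + b.size - 2
    else:
        df = a.size + b.size - 2
        sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
        se = float(np.sqrt(sp2 * (1 / a.size + 1 / b.size)))

    if se == 0:
        p = 1.0 if diff == 0 else 0.0
        return AucTestResult(float(a.mean()), float(b.mean()), diff, diff, diff,
                             p, a.size, b.size, degenerate=True)

    tstat = diff / se
    p = float(2.0 * stats.t.sf(abs(tstat), df))
    tcrit = float(stats.t.ppf(0.5 + conf / 2.0, df))
    return AucTestResult(float(a.mean()), float(b.mean()), diff,
                         diff - tcrit * se, diff + tcrit * se, p,
                         a.size, b.size)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_curves(path: str | Path) -> list[SurvivalCurve]:
    """Read curves from a TSV with columns group, replicate, day, viability_percent."""
    df = pd.read_csv(path, sep="\t")
    required = {"group", "replicate", "day", "viability_percent"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"curve table lacks columns: {sorted(missing)}")
    curves = []
    for (group, rep), sub in df.groupby(["group", "replicate"], sort=True):
        sub = sub.sort_values("day")
        curves.append(SurvivalCurve(str(group), str(rep),
                                    sub["day"].to_numpy(),
                                    sub["viability_percent"].to_numpy()))
    return curves


def group_aucs(curves: list[SurvivalCurve], group: str) -> list[float]:
    aucs = [survival_auc(c) for c in curves if c.group == group]
    if not aucs:
        raise ValueError(f"no curves for group {group!r}")
    return aucs
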