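"""Per-gene balanced two-way fixed-effects ANOVA and Euler-sector labels.

The design is condition (vehicle vs. drug) x timepoint with equal replication
in every cell.  For each gene the classical balanced decomposition of the
total sum of squares into condition, time, interaction and residual parts is
computed in closed form, vectorised over genes.  Genes significant on at
least one of the three terms are the differentially expressed genes (DEGs);
the combination of significant terms places each gene in a sector of the
Euler diagram (T, D, I and their overlaps).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CONDITIONS, ExpressionMatrix

#: Euler sector labels, from single terms to the triple overlap.
EULER_SECTORS = ("T", "D", "I", "T&D", "T&I", "D&I", "T&D&I", "ns")

# Residual sums of squares at or below this fraction of the total variation
# are treated as exactly zero (degenerate gene).
_DEGENERATE_RTOL = 1e-12


@dataclass
class AnovaRecord:
    """Two-way ANOVA result for one gene.

    ``cell_means`` is a (2, T) array on the analysis (log2) scale with row 0 =
    vehicle, row 1 = drug, columns in timepoint order.
    """

    gene: str
    p_time: float
    p_drug: float
    p_interaction: float
    F_time: float
    F_drug: float
    F_interaction: float
    cell_means: np.ndarray
    mse: float
    df_error: int
    n_replicates: int
    degenerate: bool = False

    @property
    def min_p(self) -> float:
        return min(self.p_time, self.p_drug, self.p_interaction)


def _design_cube(m: ExpressionMatrix, timepoints: list[float]) -> tuple[np.ndarray, int]:
    """Reshape the matrix into (genes, condition, timepoint, replicate).

    Raises with an explicit list of missing cells when the design is not
    balanced over the selected timepoints.
    """
    design = m.design.loc[list(m.samples)]
    cells: dict[tuple[str, float], list[str]] = {}
    for cond in CONDITIONS:
        for t in timepoints:
            sel = design.index[(design["condition"] == cond) & (design["timepoint_h"] == t)]
            # deterministic replicate order
            cells[(cond, t)] = sorted(sel, key=lambda s: design.loc[s, "replicate"])

    sizes = {k: len(v) for k, v in cells.items()}
    missing = [k for k, n in sizes.items() if n == 0]
    if missing:
        raise ValueError(f"unbalanced design; missing cells (condition, hour): {missing}")
    r = min(sizes.values())
    if r != max(sizes.values()):
        raise ValueError(f"unbalanced design; cell sizes vary: {sizes}")
    if r < 2:
        raise ValueError("two-way ANOVA needs >= 2 replicates per cell")

    order = [s for cond in CONDITIONS for t in timepoints for s in cells[(cond, t)]]
    cube = m.values[order].to_numpy(dtype=float).reshape(len(m.genes), 2, len(timepoints), r)
    return cube, r


def fit_twoway_anova(m: ExpressionMatrix, timepoints=None) -> list[AnovaRecord]:
    """Fit the balanced two-way ANOVA to every gene of a log2-scale matrix.

    Parameters
    ----------
    m
        Matrix with ``scale == "log2"``.
    timepoints
        Hours to analyse; defaults to every timepoint except hour 0 (the
        pre-treatment baseline), giving the 6-level time factor of the
        default design.

    Genes with zero residual variation cannot support an F test; they are
    returned with all p-values set to 1 and ``degenerate=True``.
    """
    if m.scale != "log2":
        raise ValueError(f"ANOVA expects a log2-scale matrix, got {m.scale!r}")
    if timepoints is None:
        timepoints = [t for t in m.timepoints if t != 0]
    timepoints = sorted(float(t) for t in timepoints)
    T = len(timepoints)
    if T < 2:
        raise ValueError("need >= 2 timepoints for the time factor")

    cube, r = _design_cube(m, timepoints)
    n = 2 * T * r

    grand = cube.mean(axis=(1, 2, 3))                         # (g,)
    cond_means = cube.mean(axis=(2, 3))                       # (g, 2)
    time_means = cube.mean(axis=(1, 3))                       # (g, T)
    cell_means = cube.mean(axis=3)                            # (g, 2, T)

    g = grand[:, None, None]
    ss_d = r * T * ((cond_means - grand[:, None]) ** 2).sum(axis=1)
    ss_t = r * 2 * ((time_means - grand[:, None]) ** 2).sum(axis=1)
    ss_i = r * ((cell_means - cond_means[:, :, None] - time_means[:, None, :] + g) ** 2).sum(axis=(1, 2))
    ss_e = ((cube - cell_means[:, :, :, None]) ** 2).sum(axis=(1, 2, 3))
    ss_tot = ((cube - g[..., None]) ** 2).sum(axis=(1, 2, 3))

    df_d, df_t, df_i = 1, T - 1, T - 1
    df_e = 2 * T * (r - 1)
    assert df_d + df_t + df_i + df_e == n - 1

    degenerate = ss_e <= _DEGENERATE_RTOL * np.maximum(ss_tot, 1.0)
    mse = np.where(degenerate, 0.0, ss_e / df_e)
    with np.errstate(divide="ignore", invalid="ignore"):
        F_d = np.where(degenerate, 0.0, (ss_d / df_d) / mse)
        F_t = np.where(degenerate, 0.0, (ss_t / df_t) / mse)
        F_i = np.where(degenerate, 0.0, (ss_i / df_i) / mse)
    p_d = np.where(degenerate, 1.0, stats.f.sf(F_d, df_d, df_e))
    p_t = np.where(degenerate, 1.0, stats.f.sf(F_t, df_t, df_e))
    p_i = np.where(degenerate, 1.0, stats.f.sf(F_i, df_i, df_e))

    return [
        AnovaRecord(
            gene=gid,
            p_time=float(p_t[i]), p_drug=float(p_d[i]), p_interaction=float(p_i[i]),
            F_time=float(F_t[i]), F_drug=float(F_d[i]), F_interaction=float(F_i[i]),
            cell_means=cell_means[i], mse=float(mse[i]), df_error=df_e,
            n_replicates=r, degenerate=bool(degenerate[i]),
        )
        for i, gid in enumerate(m.genes)
    ]


def classify_euler_sector(rec: AnovaRecord, alpha: float = 0.01) -> str:
    """Euler-diagram sector of a gene: the set of terms with p <= alpha."""
    parts = []
    if rec.p_time <= alpha:
        parts.append("T")
    if rec.p_drug <= alpha:
        parts.append("D")
    if rec.p_interaction <= alpha:
        parts.append("I")
    return "&".join(parts) if parts else "ns"


def anova_table(records: list[AnovaRecord], alpha: float = 0.01) -> pd.DataFrame:
    """Tabulate records (one row per gene) with their sector labels."""
    rows = []
    for rec in records:
        rows.append({
            "gene_id": rec.gene,
            "p_time": rec.p_time, "p_drug": rec.p_drug, "p_interaction": rec.p_interaction,
            "F_time": rec.F_time, "F_drug": rec.F_drug, "F_interaction": rec.F_interaction,
            "mse": rec.mse, "df_error": rec.df_error,
            "degenerate": rec.degenerate,
            "sector": classify_euler_sector(rec, alpha),
        })
    return pd.DataFrame(rows).set_index("gene_id")
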