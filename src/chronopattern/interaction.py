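"""Interaction-gene analysis: shape-by-shape grids and per-timepoint LSD.

Genes whose time-by-drug interaction term is significant change shape between
conditions, so their vehicle and drug time profiles are matched to temporal
templates independently and tabulated on a (vehicle shape) x (drug shape)
grid; heavily populated cells point at coherent regulatory programs.  A
complementary per-timepoint view classifies each hour's drug effect with
Fisher's protected LSD — pairwise t comparisons that reuse the pooled ANOVA
residual variance and are run only for genes passing the omnibus gate —
paired with the log2 fold change of drug over vehicle abundance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .anova import AnovaRecord
from .io import ExpressionMatrix
from .templates import TemplateLibrary, assign_profiles

logger = logging.getLogger(__name__)


@dataclass
class InteractionGrid:
    """Counts of interaction genes per (vehicle shape, drug shape) cell.

    ``counts`` is a DataFrame with vehicle shapes as rows and drug shapes as
    columns; ``members`` maps each populated (vehicle, drug) shape pair to
    its gene ids; genes whose vehicle or drug profile could not be assigned
    are listed in ``unassigned``.
    """

    counts: pd.DataFrame
    members: dict[tuple[str, str], list[str]]
    unassigned: list[str]
    flag_threshold: int

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def flagged_cells(self) -> list[tuple[str, str]]:
        """Cells with strictly more genes than the flag threshold."""
        out = []
        for v in self.counts.index:
            for d in self.counts.columns:
                if self.counts.loc[v, d] > self.flag_threshold:
                    out.append((v, d))
        return out


def condition_profiles(m: ExpressionMatrix, genes, condition: str,
                       timepoints) -> np.ndarray:
    """(n_genes, T) per-timepoint replicate means for one condition."""
    cols = []
    for t in timepoints:
        sel = m.samples_for(condition=condition, timepoint_h=t)
        if not sel:
            raise ValueError(f"no samples for condition {condition!r} at hour {t}")
        cols.append(m.values.loc[list(genes), sel].mean(axis=1).to_numpy())
    return np.column_stack(cols)


def build_interaction_grid(genes, m: ExpressionMatrix, lib: TemplateLibrary,
                           r_min: float = 0.85,
                           flag_threshold: int = 100) -> InteractionGrid:
    """Assign vehicle and drug profiles of interaction genes to shapes.

    ``genes`` should be the interaction-significant genes (any gene with
    p_interaction at or below the gate).  Each gene's per-condition profile
    is standardized and template-matched on its own; genes failing assignment
    in either condition are counted separately and excluded from the grid.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty interaction gene set")
    tps = lib.timepoints
    veh = condition_profiles(m, genes, "vehicle", tps)
    drug = condition_profiles(m, genes, "drug", tps)
    v_shapes, _ = assign_profiles(veh, lib, r_min)
    d_shapes, _ = assign_profiles(drug, lib, r_min)

    codes = lib.shape_codes
    counts = pd.DataFrame(0, index=pd.Index(codes, name="vehicle_shape"),
                          columns=pd.Index(codes, name="drug_shape"))
    members: dict[tuple[str, str], list[str]] = {}
    unassigned: list[str] = []
    for g, vs, ds in zip(genes, v_shapes, d_shapes):
        if vs is None or ds is None:
            unassigned.append(g)
            continue
        counts.loc[vs, ds] += 1
        members.setdefault((vs, ds), []).append(g)
    grid = InteractionGrid(counts, members, unassigned, flag_threshold)
    logger.info("interaction grid: %d genes placed, %d unassigned, %d flagged cells",
                grid.total, len(unassigned), len(grid.flagged_cells))
    return grid


@dataclass
class TimepointComparison:
    """Drug-vs-vehicle comparison at one hour for one gene."""

    gene: str
    timepoint_h: float
    log2fc: float
    p: float
    cls: str  # up / down / ns


def timepoint_lsd(rec: AnovaRecord, alpha: float = 0.05,
                  abundance_means: np.ndarray | None = None,
                  timepoints=None, gate_alpha: float = 0.01) -> list[TimepointComparison]:
    """Protected LSD drug-vs-vehicle comparisons at every timepoint.

    The t statistic at hour t is (drug mean - vehicle mean) / sqrt(MSE * 2/r)
    with the ANOVA residual df; protection requires the gene to have passed
    the omnibus gate (some ANOVA p <= ``gate_alpha``), otherwise a ValueError
    is raised.  The reported fold change is computed from abundance-scale
    cell means with a +1 pseudocount guard; when ``abundance_means`` (a
    (2, T) array, vehicle row first) is not supplied, abundances are
    reconstructed as 2**(log2 cell mean).
    """
    if rec.min_p > gate_alpha:
        raise ValueError(
            f"gene {rec.gene}: omnibus gate not passed (min p = {rec.min_p:.3g} > "
            f"{gate_alpha}); protected LSD is undefined"
        )
    T = rec.cell_means.shape[1]
    if timepoints is None:
        timepoints = list(range(1, T + 1))
    if abundance_means is None:
        abundance_means = np.exp2(rec.cell_means)
    abundance_means = np.asarray(abundance_means, dtype=float)
    if abundance_means.shape != rec.cell_means.shape:
        raise ValueError("abundance_means must match the (2, T) cell-mean grid")

    se = np.sqrt(rec.mse * 2.0 / rec.n_replicates)
    out = []
    for j, t in enumerate(timepoints):
        diff = rec.cell_means[1, j] - rec.cell_means[0, j]
        lfc = float(np.log2((abundance_means[1, j] + 1.0) / (abundance_means[0, j] + 1.0)))
        if se == 0:
            p = 1.0 if diff == 0 else 0.0
        else:
            tstat = diff / se
            p = float(2.0 * stats.t.sf(abs(tstat), rec.df_error))
        if p <= alpha and lfc > 0:
            cls = "up"
        elif p <= alpha and lfc < 0:
            cls = "down"
        else:
            cls = "ns"
        out.append(TimepointComparison(rec.gene, float(t), lfc, p, cls))
    return out


def lsd_table(comparisons: list[TimepointComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"gene_id": c.gene, "timepoint_h": c.timepoint_h, "log2fc": c.log2fc,
          "p": c.p, "class": c.cls} for c in comparisons]
    )
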