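"""End-to-end orchestration: normalize -> filter -> ANOVA -> templates ->
interaction -> ORA, with every stage's table written as TSV plus a JSON run
summary.  The pipeline is deterministic: the same config and seed produce
byte-identical outputs."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import anova as anova_mod
from . import interaction as inter_mod
from . import io as io_mod
from . import ora as ora_mod
from . import templates as tmpl_mod

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Paths and thresholds for a full pipeline run."""

    matrix: str
    samples: str
    outdir: str
    lengths: str | None = None
    gmt: str | None = None
    scale: str = "counts"
    anova_alpha: float = 0.01
    r_min: float = 0.85
    lsd_alpha: float = 0.05
    flag_threshold: int = 100
    min_expressed_frac: float = 0.5
    min_mean: float = 1.0
    pseudocount: float = 1.0
    min_set: int = 10
    max_set: int = 2000
    timepoints: list[float] | None = None
    seed: int = 0

    def validate(self) -> None:
        for name, lo, hi, v in (
            ("anova_alpha", 0, 1, self.anova_alpha),
            ("lsd_alpha", 0, 1, self.lsd_alpha),
            ("min_expressed_frac", 0, 1, self.min_expressed_frac),
            ("r_min", -1, 1, self.r_min),
        ):
            if not lo <= v <= hi:
                raise ValueError(f"{name} = {v} outside [{lo}, {hi}]")
        if self.flag_threshold < 0 or self.min_mean < 0 or self.pseudocount < 0:
            raise ValueError("flag_threshold, min_mean and pseudocount must be >= 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg


def _f(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return (and write) the machine-readable summary."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # ---- load + normalize ------------------------------------------------
    stage = "load"
    try:
        design = io_mod.read_samples(config.samples)
        m = io_mod.read_matrix(config.matrix, design, scale=config.scale)
        if m.scale == "counts" and config.lengths:
            lengths = io_mod.read_lengths(config.lengths)
            m = io_mod.compute_tpm(m, lengths)
    except Exception as e:  # noqa: BLE001 - stage wrapper
        raise StageError(stage, e) from e

    return analyze(m, config, outdir)


def analyze(m: io_mod.ExpressionMatrix, config: RunConfig,
            outdir: str | Path) -> dict:
    """Run the analysis stages on an in-memory matrix; write tables + summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "filter"
    try:
        filtered, report = io_mod.filter_genes(
            m, config.min_expressed_frac, config.min_mean, return_report=True)
        logm = io_mod.log_transform(filtered, config.pseudocount)
    except Exception as e:
        raise StageError(stage, e) from e

    stage = "anova"
    try:
        tps = config.timepoints or [t for t in logm.timepoints if t != 0]
        records = anova_mod.fit_twoway_anova(logm, tps)
        atab = anova_mod.anova_table(records, config.anova_alpha)
        _f(atab, outdir / "anova.tsv")
        by_gene = {r.gene: r for r in records}
        sectors = atab["sector"]
        sector_counts = sectors.value_counts().to_dict()
    except StageError:
        raise
    except Exception as e:
        raise StageError(stage, e) from e

    stage = "templates"
    try:
        lib = tmpl_mod.build_template_library(tps)
        td_genes = sectors.index[sectors.isin(["T", "D", "T&D"])].tolist()
        assignments: list[tmpl_mod.TemplateAssignment] = []
        if td_genes:
            both = inter_mod.condition_profiles(logm, td_genes, "vehicle", tps)
            both = (both + inter_mod.condition_profiles(logm, td_genes, "drug", tps)) / 2.0
            shapes, rs = tmpl_mod.assign_profiles(both, lib, config.r_min)
            for g, s, r in zip(td_genes, shapes, rs):
                cls = tmpl_mod.classify_drug_effect(by_gene[g], config.anova_alpha)
                assignments.append(tmpl_mod.TemplateAssignment(g, s, float(r), cls,
                                                               sectors.loc[g]))
            tdf = pd.DataFrame(
                [{"gene_id": a.gene, "sector": a.sector,
                  "shape": a.shape or "", "r": a.r,
                  "drug_class": a.drug_class,
                  "pattern": a.pattern or ""} for a in assignments]
            ).set_index("gene_id")
            _f(tdf, outdir / "template_assignments.tsv")
            assigned = [a for a in assignments if a.assigned]
            enr = tmpl_mod.template_enrichment(assignments, lib, config.anova_alpha) \
                if assigned else []
            edf = pd.DataFrame(
                [{"pattern": e.pattern, "observed": e.observed, "expected": e.expected,
                  "p": e.p, "flagged": e.flagged} for e in enr],
                columns=["pattern", "observed", "expected", "p", "flagged"],
            ).set_index("pattern")
            _f(edf, outdir / "pattern_enrichment.tsv")
            flagged_patterns = [e.pattern for e in enr if e.flagged]
            pct_assigned = 100.0 * len(assigned) / len(assignments)
        else:
            assigned, flagged_patterns, pct_assigned = [], [], None
    except Exception as e:
        raise StageError(stage, e) from e

    stage = "interaction"
    try:
        i_genes = atab.index[atab["p_interaction"] <= config.anova_alpha].tolist()
        flagged_cells: list[list[str]] = []
        if i_genes:
            grid = inter_mod.build_interaction_grid(
                i_genes, logm, lib, config.r_min, config.flag_threshold)
            _f(grid.counts, outdir / "interaction_grid.tsv")
            memb = pd.DataFrame(
                [{"vehicle_shape": v, "drug_shape": d, "gene_id": g}
                 for (v, d), gs in sorted(grid.members.items()) for g in gs]
            )
            memb.to_csv(outdir / "interaction_members.tsv", sep="\t", index=False)
            comps = []
            abundance = filtered.values
            for g in i_genes:
                rec = by_gene[g]
                ab_means = np.column_stack([
                    [abundance.loc[g, filtered.samples_for("vehicle", t)].mean(),
                     abundance.loc[g, filtered.samples_for("drug", t)].mean()]
                    for t in tps
                ])
                comps.extend(inter_mod.timepoint_lsd(
                    rec, config.lsd_alpha, ab_means, tps, config.anova_alpha))
            _f(inter_mod.lsd_table(comps).set_index("gene_id"),
               outdir / "timepoint_lsd.tsv")
            flagged_cells = [list(c) for c in grid.flagged_cells]
    except Exception as e:
        raise StageError(stage, e) from e

    stage = "ora"
    try:
        ora_rows = []
        if config.gmt:
            coll = ora_mod.read_gmt(config.gmt)
            universe = coll.universe & frozenset(logm.genes)
            coll = ora_mod.GeneSetCollection(coll.sets, universe)
            queries: dict[str, list[str]] = {}
            for pat in flagged_patterns:
                queries[f"pattern:{pat}"] = [a.gene for a in assigned if a.pattern == pat]
            for v, d in flagged_cells:
                queries[f"cell:{v}|{d}"] = grid.members[(v, d)]
            for qname, qgenes in queries.items():
                try:
                    recs = ora_mod.run_ora(qgenes, coll, config.min_set, config.max_set)
                except ValueError as ve:
                    logger.warning("ORA skipped for %s: %s", qname, ve)
                    continue
                for r in recs:
                    ora_rows.append({"query": qname, "set_id": r.set_id, "Tot": r.tot,
                                     "Sig": r.sig, "Exp": r.exp, "Ratio": r.ratio,
                                     "p": r.p, "FDR": r.fdr})
            pd.DataFrame(ora_rows).to_csv(outdir / "ora.tsv", sep="\t", index=False,
                                          float_format="%.6g")
    except Exception as e:
        raise StageError(stage, e) from e

    n_deg = int((atab[["p_time", "p_drug", "p_interaction"]].min(axis=1)
                 <= config.anova_alpha).sum())
    summary = {
        "n_genes_input": int(len(m.genes)),
        "n_genes_filtered": int(len(logm.genes)),
        "filter": asdict(report),
        "n_deg": n_deg,
        "sector_counts": {s: int(sector_counts.get(s, 0)) for s in anova_mod.EULER_SECTORS},
        "n_template_candidates": len(assignments),
        "pct_assigned": pct_assigned,
        "flagged_patterns": flagged_patterns,
        "n_interaction_genes": len(i_genes),
        "flagged_grid_cells": flagged_cells,
        "n_ora_rows": len(ora_rows),
    }
    (Path(outdir) / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
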