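"""Synthetic two-condition time-course expression data with known truth.

The generator emulates a balanced vehicle-vs-drug design sampled hourly
(default hours 0-6, 3 replicates per cell, ~5000 genes).  A configurable
fraction of genes follows a planted temporal template from the canonical
shape library, optionally shifted up or down in the drug condition; the rest
are flat null genes.  Expression is built on the log2 scale —

    log2 x = baseline + amplitude * z(template)  [+/- drug shift]  + noise

— with i.i.d. normal replicate noise, then exponentiated to abundance-like
values.  Because the abundance matrix is exactly ``2**log2x``, a log2
transform with pseudocount 0 recovers the planted log2 signal exactly, which
the noiseless recovery tests exploit.  Ground truth (shape code, drug-effect
class, amplitude per gene) is returned alongside the matrix, using the same
vocabulary as the template engine so recovery is a direct join.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .ora import GeneSetCollection
from .templates import DRUG_CLASSES, build_template_library


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic time-course generator.

    ``n_timepoints`` counts the sampled hours 0..n_timepoints-1; hour 0 is
    generated as a pre-treatment baseline and excluded from planted temporal
    signal (the analysis default likewise drops hour 0).  ``amplitude`` and
    ``drug_shift`` are log2-scale effect sizes; ``noise_sd`` is the log2-scale
    replicate standard deviation.  When ``drug_effect_hours`` is given, the
    drug shift of affected genes is confined to those hours (producing
    time-by-drug interaction rather than a pure main effect).
    """

    n_genes: int = 5000
    n_timepoints: int = 7
    n_replicates: int = 3
    frac_patterned: float = 0.2
    amplitude: float = 1.5
    drug_shift: float = 1.0
    noise_sd: float = 0.15
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 2.0
    drug_effect_hours: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2 (ANOVA needs within-cell replication)")
        if self.n_timepoints < 4:
            raise ValueError("n_timepoints must be >= 4 (hour 0 plus >= 3 analysis hours)")
        if not 0.0 <= self.frac_patterned <= 1.0:
            raise ValueError("frac_patterned must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def hours(self) -> tuple[float, ...]:
        return tuple(float(h) for h in range(self.n_timepoints))

    @property
    def analysis_hours(self) -> tuple[float, ...]:
        """Hours carrying planted temporal signal (hour 0 excluded)."""
        return self.hours[1:]


def _sample_grid(config: SyntheticConfig) -> pd.DataFrame:
    rows = []
    for cond in ("vehicle", "drug"):
        for h in config.hours:
            for rep in range(1, config.n_replicates + 1):
                rows.append({
                    "sample_id": f"{cond}_t{int(h)}_r{rep}",
                    "condition": cond,
                    "timepoint_h": h,
                    "replicate": rep,
                })
    return pd.DataFrame(rows).set_index("sample_id")


def generate_dataset(config: SyntheticConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate an abundance matrix and its ground-truth table.

    Returns
    -------
    matrix
        :class:`ExpressionMatrix` with ``scale == "counts"`` (continuous
        abundance values ``2**log2x``).
    truth
        DataFrame indexed by gene id with columns ``shape`` (template code,
        empty string for null genes), ``drug_effect`` (up/down/unchanged) and
        ``amplitude``.
    """
    rng = np.random.default_rng(config.seed)
    design = _sample_grid(config)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    lib = build_template_library(config.analysis_hours)
    nonflat = [s for s in lib.shapes if not s.is_flat]

    n_pat = int(round(config.frac_patterned * config.n_genes))
    patterned = np.zeros(config.n_genes, dtype=bool)
    patterned[rng.choice(config.n_genes, size=n_pat, replace=False)] = True

    shape_idx = rng.integers(0, len(nonflat), size=config.n_genes)
    drug_idx = rng.integers(0, len(DRUG_CLASSES), size=config.n_genes)
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                          size=config.n_genes)

    hours = np.array([design.loc[s, "timepoint_h"] for s in design.index])
    is_drug = np.array([design.loc[s, "condition"] == "drug" for s in design.index])
    # per-shape z-scored template value at each sample's hour (0 at hour 0)
    hour_pos = {h: j for j, h in enumerate(config.analysis_hours)}
    zvecs = np.stack([s.zscored() for s in nonflat])            # (n_shapes, T)
    tmpl_at_sample = np.zeros((len(nonflat), len(design)))
    for k, h in enumerate(hours):
        if h in hour_pos:
            tmpl_at_sample[:, k] = zvecs[:, hour_pos[h]]

    shift_mask = np.ones(len(design))
    if config.drug_effect_hours is not None:
        shift_mask = np.array([1.0 if h in set(config.drug_effect_hours) else 0.0
                               for h in hours])

    log2x = np.tile(baseline[:, None], (1, len(design)))
    shape_codes = []
    drug_effects = []
    amplitudes = np.zeros(config.n_genes)
    sign = {"up": 1.0, "down": -1.0, "unchanged": 0.0}
    for i in range(config.n_genes):
        if patterned[i]:
            code = nonflat[shape_idx[i]].code
            cls = DRUG_CLASSES[drug_idx[i]]
            log2x[i] += config.amplitude * tmpl_at_sample[shape_idx[i]]
            log2x[i] += sign[cls] * config.drug_shift * shift_mask * is_drug
            shape_codes.append(code)
            drug_effects.append(cls)
            amplitudes[i] = config.amplitude
        else:
            shape_codes.append("")
            drug_effects.append("unchanged")

    if config.noise_sd > 0:
        log2x = log2x + rng.normal(0.0, config.noise_sd, size=log2x.shape)

    values = pd.DataFrame(np.exp2(log2x), index=pd.Index(genes, name="gene_id"),
                          columns=design.index)
    matrix = ExpressionMatrix(values, design, scale="counts")
    truth = pd.DataFrame({
        "shape": shape_codes,
        "drug_effect": drug_effects,
        "amplitude": amplitudes,
    }, index=pd.Index(genes, name="gene_id"))
    return matrix, truth


def generate_genesets(truth: pd.DataFrame, n_sets: int, seed: int,
                      set_size: int = 50) -> GeneSetCollection:
    """Build a GMT-compatible gene-set fixture from a truth table.

    The first set collects all genes planted with the most common temporal
    shape (so overrepresentation analysis of that pattern's members must flag
    it); the remaining ``n_sets - 1`` sets are uniform random draws from the
    whole gene universe (null sets).
    """
    if len(truth) == 0:
        raise ValueError("truth table is empty")
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    rng = np.random.default_rng(seed)
    genes = list(truth.index)
    planted = truth[truth["shape"] != ""]
    sets: dict[str, frozenset[str]] = {}
    if len(planted):
        top_shape = planted["shape"].value_counts().idxmax()
        sets[f"planted_{top_shape}"] = frozenset(planted.index[planted["shape"] == top_shape])
    k = min(set_size, len(genes))
    i = 0
    while len(sets) < n_sets:
        i += 1
        sets[f"random_{i:03d}"] = frozenset(rng.choice(genes, size=k, replace=False))
    return GeneSetCollection(sets=sets, universe=frozenset(genes))
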