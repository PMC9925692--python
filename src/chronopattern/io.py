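"""Expression matrices, sample designs and the standard normalisation steps.

The central container is :class:`ExpressionMatrix`: a genes x samples table of
non-negative abundances together with the sample design (condition, timepoint
in hours, replicate) and a scale tag saying whether the values are raw counts,
TPM, or log2-transformed abundances.  All downstream stages consume this
container; the readers/writers below round-trip it through plain TSV files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Allowed values of :attr:`ExpressionMatrix.scale`.
SCALES = ("counts", "tpm", "log2")

#: Allowed condition labels, in canonical order (reference first).
CONDITIONS = ("vehicle", "drug")

_TPM_TOTAL = 1_000_000.0
_TPM_RTOL = 1e-6


@dataclass
class ExpressionMatrix:
    """Gene x sample abundance matrix plus its sample design.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, one column per sample id.
    design
        DataFrame indexed by sample id with columns ``condition``
        (``vehicle``/``drug``), ``timepoint_h`` (hours) and ``replicate``.
    scale
        One of ``counts``, ``tpm`` or ``log2``.
    symbols
        Optional gene id -> gene symbol mapping used by :func:`filter_genes`.
        ``None`` means every gene is taken to carry a valid unique symbol.
    """

    values: pd.DataFrame
    design: pd.DataFrame
    scale: str = "counts"
    symbols: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- structural checks ------------------------------------------------
    def validate(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if not self.values.index.is_unique:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"gene ids are not unique: {dupes[:5]}")
        if self.scale != "log2" and (self.values.to_numpy() < 0).any():
            raise ValueError(f"negative abundances are not allowed on scale {self.scale!r}")
        missing = [s for s in self.values.columns if s not in self.design.index]
        if missing:
            raise ValueError(f"samples missing from design: {missing[:5]}")
        for col in ("condition", "timepoint_h", "replicate"):
            if col not in self.design.columns:
                raise ValueError(f"design lacks required column {col!r}")
            if self.design.loc[list(self.values.columns), col].isna().any():
                raise ValueError(f"design column {col!r} has missing entries")
        bad = set(self.design["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels {sorted(bad)}; expected {CONDITIONS}")
        if self.scale == "tpm":
            sums = self.values.sum(axis=0)
            off = sums[np.abs(sums - _TPM_TOTAL) > _TPM_RTOL * _TPM_TOTAL]
            if len(off):
                raise ValueError(
                    f"TPM columns must sum to 1e6; offending samples: {off.index.tolist()[:5]}"
                )

    # -- convenience ------------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def timepoints(self) -> list[float]:
        return sorted(self.design.loc[list(self.samples), "timepoint_h"].unique())

    def subset_genes(self, genes) -> "ExpressionMatrix":
        sym = self.symbols.reindex(genes) if self.symbols is not None else None
        return ExpressionMatrix(self.values.loc[list(genes)], self.design, self.scale, sym)

    def samples_for(self, condition: str | None = None, timepoint_h: float | None = None) -> list[str]:
        d = self.design.loc[list(self.samples)]
        mask = pd.Series(True, index=d.index)
        if condition is not None:
            mask &= d["condition"] == condition
        if timepoint_h is not None:
            mask &= d["timepoint_h"] == timepoint_h
        return d.index[mask].tolist()


# ---------------------------------------------------------------------------
# TPM and transforms
# ---------------------------------------------------------------------------

def compute_tpm(counts: ExpressionMatrix, lengths: pd.Series) -> ExpressionMatrix:
    """Transcripts-per-million normalisation of a count matrix.

    Per sample the count of each gene is divided by its effective length in
    kilobases to give a rate; rates are rescaled so that each sample sums to
    one million.

    Parameters
    ----------
    counts
        Matrix with ``scale == "counts"``.
    lengths
        Gene id -> effective length in bases (> 0); must cover every gene.
    """
    if counts.scale != "counts":
        raise ValueError(f"compute_tpm expects a counts matrix, got scale {counts.scale!r}")
    missing = counts.genes.difference(lengths.index)
    if len(missing):
        raise ValueError(f"gene lengths missing for: {missing.tolist()[:5]}")
    lens = lengths.reindex(counts.genes).astype(float)
    if (lens <= 0).any():
        bad = lens.index[lens <= 0].tolist()
        raise ValueError(f"non-positive gene lengths for: {bad[:5]}")

    rates = counts.values.div(lens / 1000.0, axis=0)
    totals = rates.sum(axis=0)
    dead = totals.index[totals <= 0].tolist()
    if dead:
        raise ValueError(f"zero total rate in sample(s): {dead}")
    tpm = rates.div(totals, axis=1) * _TPM_TOTAL
    return ExpressionMatrix(tpm, counts.design, "tpm", counts.symbols)


def log_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(x + pseudocount) transform; tags the result ``log2``."""
    if m.scale == "log2":
        return m
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    vals = m.values.to_numpy(dtype=float) + pseudocount
    if (vals <= 0).any():
        raise ValueError("log transform undefined: zero abundance with pseudocount 0")
    out = pd.DataFrame(np.log2(vals), index=m.genes, columns=m.samples)
    return ExpressionMatrix(out, m.design, "log2", m.symbols)


# ---------------------------------------------------------------------------
# Gene filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    """Counts of genes removed by each criterion of :func:`filter_genes`."""

    n_input: int
    n_unannotated: int
    n_duplicate_symbol: int
    n_low_signal: int
    n_kept: int


def filter_genes(
    m: ExpressionMatrix,
    min_expressed_frac: float = 0.5,
    min_mean: float = 1.0,
    return_report: bool = False,
):
    """Keep genes with a unique symbol annotation and sufficient signal.

    A gene is retained when (a) it maps to a unique gene symbol (genes whose
    symbol is shared by another gene are all dropped; genes with no symbol are
    dropped) and (b) it is non-zero in at least ``min_expressed_frac`` of
    samples and its mean abundance is at least ``min_mean``.

    The composition of removals is logged and optionally returned.
    """
    if len(m.genes) == 0:
        raise ValueError("empty expression matrix")

    if m.symbols is None:
        annotated = pd.Series(True, index=m.genes)
        n_unannot = n_dup = 0
    else:
        sym = m.symbols.reindex(m.genes)
        has_symbol = sym.notna() & (sym.astype(str).str.len() > 0)
        counts = sym[has_symbol].value_counts()
        unique_sym = has_symbol & sym.map(counts).eq(1)
        annotated = unique_sym.fillna(False)
        n_unannot = int((~has_symbol).sum())
        n_dup = int((has_symbol & ~annotated).sum())

    vals = m.values
    frac_nonzero = (vals > 0).mean(axis=1)
    means = vals.mean(axis=1)
    strong = (frac_nonzero >= min_expressed_frac) & (means >= min_mean)
    n_low = int((annotated & ~strong).sum())

    keep = annotated & strong
    if not keep.any():
        raise ValueError("filter_genes removed every gene; relax the thresholds")
    report = FilterReport(len(m.genes), n_unannot, n_dup, n_low, int(keep.sum()))
    logger.info(
        "filter_genes: %d -> %d genes (%d unannotated, %d duplicate symbols, %d low signal)",
        report.n_input, report.n_kept, report.n_unannotated,
        report.n_duplicate_symbol, report.n_low_signal,
    )
    out = m.subset_genes(m.genes[keep])
    return (out, report) if return_report else out


# ---------------------------------------------------------------------------
# TSV round-trip
# ---------------------------------------------------------------------------

def write_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def read_matrix(path: str | Path, design: pd.DataFrame, scale: str = "counts",
                symbols: pd.Series | None = None) -> ExpressionMatrix:
    vals = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(vals, design, scale, symbols)


def write_samples(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index_label="sample_id")


def read_samples(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_lengths(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].astype(float)
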