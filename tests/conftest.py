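import numpy as np
import pandas as pd
import pytest

from chronopattern import (SyntheticConfig, build_template_library,
                           generate_dataset, log_transform)
from chronopattern.io import ExpressionMatrix


@pytest.fixture(scope="session")
def lib6():
    """Template library for the standard 6-hour analysis grid."""
    return build_template_library([1, 2, 3, 4, 5, 6])


@pytest.fixture(scope="session")
def small_dataset():
    """A small mixed synthetic dataset (patterned + null genes)."""
    cfg = SyntheticConfig(n_genes=120, frac_patterned=0.5, amplitude=1.5,
                          drug_shift=1.0, noise_sd=0.15, seed=11)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_log2(small_dataset):
    m, _ = small_dataset
    return log_transform(m, pseudocount=0.0)


def toy_matrix(values: np.ndarray, conditions, hours, reps, scale="counts",
               genes=None, symbols=None) -> ExpressionMatrix:
    """Build a matrix with an explicit fully crossed design."""
    sample_ids, rows = [], []
    for cond in conditions:
        for h in hours:
            for r in reps:
                sid = f"{cond}_t{h}_r{r}"
                sample_ids.append(sid)
                rows.append({"sample_id": sid, "condition": cond,
                             "timepoint_h": float(h), "replicate": r})
    design = pd.DataFrame(rows).set_index("sample_id")
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    vals = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                        columns=sample_ids)
    sym = pd.Series(symbols, index=genes) if symbols is not None else None
    return ExpressionMatrix(vals, design, scale, sym)
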