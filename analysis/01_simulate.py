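#!/usr/bin/env python
"""Generate the synthetic study datasets used by the downstream drivers.

Two balanced 2-condition x 7-timepoint x 3-replicate datasets are written:

* ``results/synthetic/`` — 5000 genes, 20% following planted temporal
  templates with a whole-course drug shift (main-effect genes dominate).
* ``results/synthetic_interaction/`` — 2000 genes, 30% patterned with the
  drug shift confined to hours 5-6, so the time-by-drug interaction carries
  the drug signal (the late-hour upregulation regime).

Ground truth and a GMT gene-set fixture accompany each dataset.
"""

from pathlib import Path

from chronopattern import SyntheticConfig, generate_dataset, generate_genesets
from chronopattern.io import write_matrix, write_samples
from chronopattern.ora import write_gmt

ROOT = Path(__file__).resolve().parents[1] / "results"


def emit(name: str, cfg: SyntheticConfig) -> None:
    out = ROOT / name
    out.mkdir(parents=True, exist_ok=True)
    m, truth = generate_dataset(cfg)
    write_matrix(m, out / "matrix.tsv")
    write_samples(m.design, out / "samples.tsv")
    truth.to_csv(out / "truth.tsv", sep="\t")
    write_gmt(generate_genesets(truth, n_sets=15, seed=cfg.seed), out / "genesets.gmt")
    n_pat = int((truth["shape"] != "").sum())
    print(f"{name}: {len(m.genes)} genes x {len(m.samples)} samples, "
          f"{n_pat} patterned ({100 * n_pat / len(m.genes):.0f}%)")


def main() -> None:
    emit("synthetic", SyntheticConfig(n_genes=5000, frac_patterned=0.2,
                                      amplitude=1.5, drug_shift=1.0,
                                      noise_sd=0.15, seed=42))
    emit("synthetic_interaction",
         SyntheticConfig(n_genes=2000, frac_patterned=0.3, amplitude=1.5,
                         drug_shift=1.0, noise_sd=0.15,
                         drug_effect_hours=(5.0, 6.0), seed=43))


if __name__ == "__main__":
    main()
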