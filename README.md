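# chronopattern

Temporal-pattern analysis for two-condition time-course RNA-seq.

When a drug is added to a culture and samples are taken every hour under
both vehicle and treatment, the interesting questions are not just *which*
genes move but *when* they move, in *what shape*, and whether the drug bends
the trajectory itself.  `chronopattern` implements that analysis for
balanced designs (condition x timepoint x replicate), as used in studies of
myriocin-induced lifespan extension in budding yeast:

1. **Normalisation & filtering** — TPM from counts and gene lengths
   (columns sum to 10^6); genes kept if uniquely annotated and expressed.
2. **ANOVA gate** — per-gene balanced two-way fixed-effects ANOVA
   (Time x Drug); a gene with p ≤ 0.01 on any of the three terms is a DEG,
   and the combination of significant terms places it in an Euler sector
   (T, D, I, T&D, ...).
3. **Template matching** — each DEG's z-scored hourly profile is assigned
   by Pearson correlation (r > 0.85) to the best of 21 canonical temporal
   shapes (flat, endpoint changes, plateaus, spikes, linear ramp; each with
   a mirrored reflection), crossed with three drug-effect classes
   (↑/↓/↔) for 63 patterns; over-populated patterns are flagged by an
   exact binomial test against a uniform null.
4. **Interaction grid** — interaction-significant genes are shape-matched
   per condition and tabulated on a 21 x 21 vehicle-shape x drug-shape
   grid; per-hour drug effects are classified by Fisher's protected LSD
   (pooled ANOVA MSE) plus log2 fold change.
5. **ORA** — hypergeometric overrepresentation of gene lists against GMT
   collections, reporting Tot/Sig/Exp/Ratio, p, and BH FDR.
6. **Lifespan AUC** — trapezoid area under chronological-lifespan viability
   curves with a pooled-variance t-test and CI between treatment groups.

A synthetic-data generator plants known templates, drug shifts and log2
noise in a balanced design and returns ground truth, so the whole chain is
testable end to end without any downloads.  See `docs/methods.md` for the
model details and design choices.

## Worked example

```python
from chronopattern import (SyntheticConfig, generate_dataset, log_transform,
                           fit_twoway_anova, build_template_library,
                           assign_profiles)
from chronopattern.anova import anova_table
from chronopattern.interaction import condition_profiles

cfg = SyntheticConfig(n_genes=2000, frac_patterned=1.0, amplitude=1.5,
                      noise_sd=0.15, seed=2024)
m, truth = generate_dataset(cfg)                  # 2000 genes x 42 samples
logm = log_transform(m, pseudocount=0.0)

tab = anova_table(fit_twoway_anova(logm), alpha=0.01)
print(tab["sector"].value_counts().head(3))

lib = build_template_library(cfg.analysis_hours)  # 21 shapes, 63 patterns
genes = list(m.genes)
prof = (condition_profiles(logm, genes, "vehicle", cfg.analysis_hours)
        + condition_profiles(logm, genes, "drug", cfg.analysis_hours)) / 2
shapes, r = assign_profiles(prof, lib, r_min=0.85)
n_assigned = sum(s is not None for s in shapes)
n_correct = sum(s == truth.loc[g, "shape"] for g, s in zip(genes, shapes))
print(f"assigned {n_assigned/len(genes):.1%}, correct {n_correct/len(genes):.1%}")
```

prints

```
sector
T&D      1330
T         649
T&D&I      12
Name: count, dtype: int64
assigned 100.0%, correct 100.0%
```

i.e. with every gene carrying a planted template (log2 amplitude 1.5, noise
SD 0.15), the genes land overwhelmingly in the Time and Time&Drug sectors,
every profile clears the r > 0.85 assignment bar and all of them recover
exactly their planted shape code.

The same stages are available as a CLI (`chronopattern simulate / normalize /
anova / patterns / interaction / ora / cls / run`) and as numbered drivers
under `analysis/` (simulate → ANOVA sectors → templates → interaction → ORA
→ lifespan AUC), which write their tables under `results/`.

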