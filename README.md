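# mztkin

Kinetics of maternal mRNA decay and zygotic transcription from metabolically
labeled single-cell RNA-seq of early embryos.

During the maternal-to-zygotic transition (MZT), an embryo clears the mRNAs
deposited in the egg while switching on its own genome. Metabolic labeling
(4sU incorporated into nascent transcripts, read out as T-to-C conversions)
makes the two populations separable within a single experiment: for every
gene and cell, an upstream estimator provides the labeled fraction
NTR ∈ [0, 1] — the share of that gene's transcripts that are newly
transcribed (zygotic). `mztkin` takes a gene × cell UMI matrix, the NTR
table and cell metadata (stage, cluster, pseudotime, trajectory flags,
replicate) and quantifies the regulatory kinetics behind the transition.

It is aimed at computational biologists analyzing labeled scRNA-seq time
courses of early development (zebrafish-style designs with a handful of
stages spanning zygotic genome activation), and at method developers who
need a fully synthetic, ground-truth-controlled test bed for such analyses.

## What it computes

**Decomposition** (per cell, natural-log convention):

    RNA_total(g,c)    = log1p( UMI(g,c) / Σ_g' UMI(g',c) · 10^4 )
    RNA_maternal(g,c) = log1p( UMI(g,c)·(1−NTR(g,c)) / Σ_g' UMI(g',c) · 10^4 )
    RNA_zygotic(g,c)  = log1p( UMI(g,c)·NTR(g,c)     / Σ_g' UMI(g',c) · 10^4 )

Pseudo-bulk profiles use the same split on aggregated counts, log2-transformed
and floored at −4. Pseudotime is rescaled linearly to a 240–360
"pseudo-minute" axis and cells are placed into 11 overlapping bins
(10-minute spacing, 3-minute overlap, undersized last bin merged).

**Kinetic models**, fit per gene to the binned log2 profiles by bounded
multistart nonlinear least squares and selected by nested likelihood-ratio
tests (σ̂_ML = √(RSS/n)):

* maternal: none ⊂ constant x₀ ⊂ exponential decay
  `log2 M(t) = log2 x₀ − β (t − d) log2 e` for t > d (half-life = ln 2 / β);
* zygotic: none ⊂ linear accumulation `log2 Z(t) = log2 α + log2(t − d)` ⊂
  accumulation with first-order decay
  `log2 Z(t) = log2 α − log2 β_z + log2(1 − e^{−β_z (t−d)})`.

Genes are classified (maternal-only / zygotic-only / maternal-zygotic) and
maternal-zygotic genes grouped A–D by fast/slow decay (half-life < 20 or
> 45 pseudo-min) × fast/slow accumulation (log2 α > −11 or < −12).

Around the models: replicate-derived noise SDs per expression group,
chi-square goodness-of-fit at stage-level pseudotimes, a simulation study for
parameter recovery, trajectory-specific vs uniform regulation tests
(two parameter sets vs one, LRT + R² + fold-change gates), zygotic-fraction
quantile classification, cell-type-restriction tests (one-sided KS), and
k-mer (3–8 nt) enrichment of UTR sequences against fitted parameters with
BH-FDR and a standardized-mean-difference effect size θ.

A first-class synthetic-data generator produces binned noisy profiles, full
cell tables (negative-binomial UMIs, Beta-perturbed labeled fractions) and
UTR sets with planted k-mers — all with known ground truth.

## Worked example

```python
import numpy as np
from mztkin import synth, binning, kinetics
from mztkin.datatypes import SynthConfig

truths = synth.default_truth_panel(40, rng_seed=3)
table = synth.simulate_cell_table(truths, SynthConfig(n_genes=40, n_cells=400, seed=3))
profile = binning.binned_profiles(table)          # 11 pseudotime bins
gene = 3                                          # a maternal-zygotic gene
y = profile.maternal.iloc[gene].to_numpy()
sel = kinetics.select_nested_model(profile.centers, y, "maternal", rng_seed=0)
fit = sel.selected
print(fit.model_id, {k: round(v, 4) for k, v in fit.params.items()})
print("half-life:", round(np.log(2) / fit.params["beta"], 1), "pseudo-min",
      " truth:", round(np.log(2) / truths[gene].maternal.beta, 1))
```

prints

```
M_decay {'x0': 351.635, 'beta': 0.026, 'd': 257.7372}
half-life: 26.7 pseudo-min  truth: 28.3
```

i.e. for this gene the exponential-decay model is selected over the constant
and null alternatives, with a fitted degradation onset of ~258 pseudo-min and
a pseudo-half-life of 26.7 pseudo-min against a generating value of 28.3.

The same analysis runs end to end from the shell:

```sh
mztkin all --seed 3 --out run_out    # synthetic data -> fits -> calls -> TSVs
```

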