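# coexpreserve

Differential coexpression **network preservation** analysis for two-condition
bulk RNA-seq designs, with gene-set overrepresentation testing and qPCR
validation statistics.

The motivating use case is a maternal-nutrition study design: two groups of
animals (e.g. 9 offspring of control-fed dams and 9 of gossypol-exposed dams),
testis transcriptomes, and the question of whether the coexpression structure
of a focal gene program — such as the ~145 expressed genes annotated to GO
spermatogenesis — is preserved between conditions, beyond any per-gene
differential expression.

## What it computes

**Per-condition binary coexpression network.** For each condition a Pearson
correlation matrix *R* = (*r*<sub>ij</sub>) over that condition's samples is
thresholded into an adjacency matrix *A* = (*a*<sub>ij</sub>):

> *a*<sub>ij</sub> = 1 iff |*r*<sub>ij</sub>| ≥ 0.5 and *P* ≤ 0.05, else 0,

where *P* is the two-sided p-value from *t* = *r*·√((*n*−2)/(1−*r*²)) on
*n*−2 df. Each gene is summarized by its connectivity
*k*<sub>i</sub> = Σ<sub>j≠i</sub> *a*<sub>ij</sub> and clustering coefficient
*c*<sub>i</sub> = Σ<sub>j≠i</sub>Σ<sub>l≠i</sub> *a*<sub>ij</sub>*a*<sub>jl</sub>*a*<sub>li</sub> /
((Σ<sub>j≠i</sub> *a*<sub>ij</sub>)² − Σ<sub>j≠i</sub> *a*<sub>ij</sub>²),
whose denominator equals *k*<sub>i</sub>(*k*<sub>i</sub>−1) for binary
networks; *c*<sub>i</sub> is undefined when *k*<sub>i</sub> ≤ 1. Preservation
between conditions is assessed by the difference in condition means of *k* and
*c*, with significance from a pooled sample-label permutation test.

**Gene-set overrepresentation.** Differentially expressed genes are selected
by Benjamini–Hochberg FDR (the implied raw-p cutoff (*k*/*m*)·*q* is
reported), then each gene set is tested one-sided against the background of
all tested genes with the cumulative hypergeometric distribution (Fisher's
exact test upper tail).

**qPCR validation.** ΔCt = Ct<sub>target</sub> − Ct<sub>reference</sub>,
relative expression by the 2<sup>−ΔΔCt</sup> method (control-referenced,
geometric group means), and a Gaussian likelihood-ratio test
*n*·ln(RSS₀/RSS₁) ~ χ²₁ for the group effect on ΔCt.

**Synthetic data.** A one-factor-per-module Gaussian latent / negative-binomial
observation model plants coexpression modules with known within-module
correlation ρ inside a focal gene set, and attenuates ρ by a disruption factor
in condition B, so every stage is testable end to end without external data.

## Worked example

```bash
coexpreserve simulate --outdir data --seed 3 \
    --config <(echo '{"n_genes": 2000, "gene_set_size": 60,
                      "modules": [[20, 0.8], [15, 0.75]], "disruption": 0.9}')
coexpreserve network --counts data/counts.tsv --sample-map data/sample_map.tsv \
    --gene-sets data/gene_sets.gmt --outdir results --seed 1 --n-perm 499
```

or equivalently in Python:

```python
from coexpreserve import (SimulationConfig, simulate_expression, cpm_log2,
                          preservation_analysis)

cfg = SimulationConfig(n_genes=60, gene_set_size=60,
                       modules=((20, 0.8), (15, 0.75)), disruption=0.9, seed=25)
a, b, truth = simulate_expression(cfg)
report = preservation_analysis(cpm_log2(a), cpm_log2(b), n_perm=499, seed=8)
print(report.means)
print(report.p_values)
```

which prints

```
{'mean_k_A': 6.7, 'mean_k_B': 3.2, 'mean_c_A': 0.47963526147319907, 'mean_c_B': 0.2093809523809524}
{'p_delta_k': 0.002, 'p_delta_c': 0.006}
```

Condition B's disrupted modules lose half their mean connectivity
(6.7 → 3.2 partners per gene) and more than half their mean clustering
(0.48 → 0.21), and the permutation test calls both losses significant — the
qualitative signature of a disrupted coexpression program.

Input file formats (count TSV, sample map, GMT, p-value TSV, Ct TSV) are
documented in the `coexpreserve.exprio` module docstring.

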