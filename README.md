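# modrank

Rank cell-type-specific transcriptional gene modules by how faithfully they
report the abundance of their annotated cell type.

Dozens of published gene modules ("signatures") claim to mark the same immune
cell type — T cells, B cells, NK cells, monocytes, neutrophils — yet often
share few genes and behave very differently when used to read cell abundance
out of bulk tissue or blood transcriptomes. `modrank` scores each module's
specificity with the **Modular Discrimination Index (MDI)** and provides the
machinery around it: module scoring, content overlap, module derivation,
validation statistics, and a synthetic-data generator with planted ground
truth so the whole pipeline is testable without any downloads.

## The statistic

A module's expression in a sample is summarized by the geometric mean of its
constituent genes — on log2 data, the arithmetic mean of the log2 values. In
a reference dataset of purified cell populations, let

- *X* = the module's mean score in its **target** cell type (activation /
  differentiation states of the target are first averaged with equal weight),
- *Y* = the mean of the per-condition mean scores over all **non-target**
  cell populations (conditions left uncollapsed, equal weight per condition).

Each of the *n* usable reference datasets contributes the relative difference
(X − Y)/X, and

```
MDI = (1/n) · Σᵢ (Xᵢ − Yᵢ) / Xᵢ
```

Higher MDI ⇒ more target-specific module. A module whose cross-dataset target
mean is lower than any non-target population's mean is *excluded* — it cannot
be a marker of its annotated cell type. Reference datasets should offer
breadth: ≥ 4 non-target cell types and the target < 20% of samples.

Also included:

- **Jaccard overlap** (|A∩B|/|A∪B|) between module gene sets;
- **module derivation** by cross-dataset fold-change overlap (genes ≥ 2-fold
  up in the target versus ≥ 90% of other populations, in ≥ 2 datasets) or by
  bait-gene co-correlation (intersection of the top 1% of each bait's Pearson
  correlation ranking);
- **validation statistics**: between-group module enrichment (Mann–Whitney U),
  covariance of module score with measured cell frequency, and the Spearman
  rank correlation of MDI with either metric.

## Worked example

Plant three T-cell modules of increasing specificity (log2 effects 0.25, 1.0,
2.0) in two synthetic purified-cell reference datasets, score their MDI, then
check that MDI predicts the covariance of module score with the true T-cell
fraction across 40 simulated bulk mixtures:

```python
from modrank import mdi_score, score_collection, mdi_correlation, score_frequency_covariance
from modrank.synthetic import generate_purified, generate_mixtures

plan = [
    {"target": "T cell", "n_genes": 8, "log2_effect": e, "name": n}
    for n, e in [("T_weak", 0.25), ("T_medium", 1.0), ("T_strong", 2.0)]
]
cell_types = ["B cell", "NK", "monocyte", "neutrophil", "DC", "T cell"]
refs = []
for k in range(2):
    ds, modules, truth = generate_purified(
        200, cell_types, 5, plan, noise_sd=0.25, seed=10 + k, name=f"ref{k}"
    )
    refs.append(ds)

results = mdi_score(refs, modules, {})
for r in results:
    print(f"{r.module_name:<10} n={r.n_datasets}  MDI={r.mdi:.4f}")

mix, ann, _ = generate_mixtures(truth, 40, [1.0] * 6, "T cell", seed=99)
table = score_collection(mix, modules)
covs = {c.module_name: c.covariance for c in score_frequency_covariance(table, ann)}
cor = mdi_correlation(results, covs)
print(f"Spearman rho (MDI vs covariance) = {cor.rho:.3f}  p = {cor.p_value:.3g}")
```

Output:

```
T_weak     n=2  MDI=0.0252
T_medium   n=2  MDI=0.1171
T_strong   n=2  MDI=0.2155
Spearman rho (MDI vs covariance) = 1.000  p = 0
```

MDI rises monotonically with the planted specificity, and the module ranking
by MDI exactly matches the ranking by empirical sensitivity to T-cell
abundance — the property that makes the index useful for picking deconvolution
modules.

The same analyses are available from the shell via the `modrank` command
(`simulate`, `score`, `mdi`, `derive fold|bait`, `jaccard`, `enrich`,
`covary`, `mdicor`); every run writes a provenance JSON beside its output.

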