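# Methods

## Model and procedure

`modrank` treats a gene module as a fixed set of gene symbols and summarizes
its expression in a sample by the geometric mean of its genes. All matrices
are handled on the log2 scale, where the log2 of the geometric mean of
linear-scale values equals the arithmetic mean of the log2 values; scores are
therefore plain means of log2 rows and inherit translation equivariance
(adding c to every matrix value shifts every score by c). An optional
linear-scale mode converts scores to 2^score before any averaging, which
makes the discrimination terms invariant to multiplicative rescaling of the
linear expression instead.

The Modular Discrimination Index of a module annotated to a target cell type
is computed per purified-cell reference dataset as (X − Y)/X and averaged
across the n datasets in which the module is scoreable:

- **X** — mean module score of the target cell type. If the dataset
  distinguishes activation or differentiation states of the target, the
  per-state means are first computed and then averaged with equal weight, so
  the index reflects the cell type's core program, not a particular state.
- **Y** — the unweighted mean of the per-condition mean scores over all
  non-target populations. Non-target conditions are *not* collapsed: a
  comparator cell type profiled in two states contributes two comparator
  means. Equal weight per condition (rather than pooling samples) prevents
  abundantly sampled populations from dominating Y; a pooled-sample variant
  is available (`pool_samples=True` / `--pool-samples`) because the equation
  itself does not force either reading.

Two gating rules precede the index:

- **Exclusion** — each comparator condition's mean is averaged across the
  datasets where it appears; if the target's cross-dataset mean is strictly
  lower than any comparator's, the module receives no MDI. A module brighter
  elsewhere than in its own target cannot serve as a marker.
- **Breadth** — a reference dataset should contain at least 4 non-target cell
  types with the target making up less than 20% of samples. Failing datasets
  produce a warning by default and are removed from the computation under
  `strict_breadth`.

n counts only datasets where the module met the coverage floor and the target
was present; X = 0 (possible only in linear-scale mode or with pathological
negative-log data) drops that dataset from n with a warning rather than
propagating an infinity.

## Module derivation

*Fold-change overlap*: per dataset, a gene passes when its log2 target mean
(target states collapsed as above; other conditions kept separate) exceeds at
least ⌈other_fraction · K⌉ of the K comparator means by ≥ log2(fold_threshold),
with ties passing ("two-fold **or greater**"). Defaults: fold 2, fraction 0.9,
required in ≥ 2 datasets. Fold changes are differences of log2 means, i.e.
fold changes of geometric means. Raising any of the three parameters can only
shrink the module (anti-monotonicity), which the property suite asserts.

*Bait co-correlation*: for each bait marker gene, Pearson correlations of its
expression row against every other gene row are ranked; the top
⌊top_fraction · G⌋ genes are taken, where G counts candidate genes excluding
the bait itself (a bait correlates perfectly with itself and would waste a
slot; the baits are re-added to the final module). Zero-variance genes are
dropped from candidacy; a zero-variance bait is an error. Boundary ties break
alphabetically for determinism. The module is the intersection of the
per-bait lists plus the baits; a convenience wrapper intersects modules from
several datasets, but the single-dataset operation is the core contract.

## Validation statistics

- *Group enrichment*: per-module difference of mean scores between two sample
  groups (log2 units), with a two-sided Mann–Whitney U p-value (exact when
  sample sizes permit and no ties) by default. The test choice is a package
  convention — box-plot-style group comparisons pair naturally with a rank
  test — with Welch's t available. No multiplicity correction is applied.
- *Score–frequency covariance*: population covariance (divisor n, the legacy
  spreadsheet COVAR convention) between per-sample module score and the
  annotated cell frequency; divisor n−1 is switchable. The frequency scale
  (fraction vs percent) is declared by the caller and echoed, never rescaled,
  since the covariance magnitude depends on it.
- *MDI correlation*: Spearman rho (average ranks for ties) and its two-sided
  p-value between module MDI and either metric, plus an OLS slope/intercept
  for plotting; the squared rho is reported alongside. Excluded modules are
  dropped with a logged count; at least 3 complete pairs are required.

## Synthetic data

The generator emulates processed microarray-style purified-cell datasets:
per-gene baselines from Normal(8, 1.5) log2 units (approximately the
intensity range of processed arrays), planted module genes receiving a fixed
+log2_effect in their target cell type only, and i.i.d. Normal(0, noise_sd)
noise with default noise_sd = 0.25 log2 units. Mixture samples draw cell-type
fractions from a Dirichlet (the concentration vector controls the spread of
frequencies, allowing very rare through dominant cell types) and combine the
cell-type profiles **on the linear scale** before re-logging — the
biophysically correct model for transcript abundance; mixing log values would
silently change the covariance structure the validation relies on. Noise is
then added on the log2 scale. All randomness flows through a single seeded
numpy Generator (PCG64), so fixed seeds reproduce byte-identical outputs.

What the generator does *not* emulate: platform-specific probe effects, batch
effects, RNA-Seq count noise, correlated gene-gene background structure, and
within-cell-type biological heterogeneity. Passing tests therefore show that
the algorithms recover planted structure under log-normal noise — they do not
certify performance on any particular real platform.

Validation problem sizes used by the test suite and the acceptance script —
three reference datasets of 8 cell types × 5 replicates with a 10-module
specificity gradient spanning log2 effects 0–2, and 40 Dirichlet mixtures —
were chosen as a realistic desk-scale emulation of multi-dataset purified-cell
compendia, and are parameters, not constraints.

## Numerical and design choices

- Gene symbols compare case-sensitively; an opt-in upper-casing at load time
  supports cross-platform joins. Matrix preparation sorts rows alphabetically
  (case-insensitive, case-sensitive tie-break) and keeps the first row of any
  duplicated symbol; the procedure is idempotent.
- Missing expression values are a hard error, never imputed; the log2
  transform is applied only on an explicit flag (no magnitude heuristics).
- Module genes absent from a matrix are dropped with coverage reported;
  modules under the coverage floor (default 0.5, a declared convention) are
  flagged and excluded from downstream tables.
- Cross-dataset cell-type labels are aligned by an optional user-supplied
  label map; unmapped labels pass through verbatim. Target assignment is
  declared input — the tool never guesses which label a module "means".
- The geometric-mean score of a module whose genes share one value v is
  exactly v; degenerate inputs (empty gene sets, both-empty Jaccard, < 3
  correlation pairs, X = 0) raise immediately with named errors.

## Known limitations

MDI is an ordinal index: it ranks modules but its magnitude depends on the
score scale (log2 anchors terms to absolute expression; the linear mode
trades that for scale invariance). Y treats every comparator condition
equally regardless of how many cell types a dataset profiles, so indices are
comparable across modules within a dataset panel, less so across panels of
very different breadth. The derivation algorithms assume the reference
matrices are already symbol-keyed and normalized; probe summarization and
batch correction are upstream of this tool.
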