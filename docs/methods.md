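# Methods

## Model

`fpcam` annotates transcriptomic clusters by comparing each cluster's
marker-gene profile against a voting dictionary of cell types.

**Dictionary weights.** A dictionary record is a (cell type `m`, gene `g`)
pair with a vote count `V(m, g)` — the number of curated sources listing
`g` as a marker of `m` — and the type's total votes. The weight
`W(m, g) = V(m, g) / Σ_g' V(m, g')` normalizes votes within each type, so a
type with many weakly-attested markers does not outscore a type with a few
strongly-attested ones merely by having more rows. Weights are stored as
floats; the voting ratio is also kept as an exact rational (`fractions.
Fraction`) so that round-tripping the dictionary file is bit-exact (the
`percent` column is written as a reduced fraction such as `4/21`).

Totals are *defined* as the per-type vote sum: the two invariants "weight =
votes/total" and "per-type weights sum to 1" force this, so the reader
reconciles any stated total that disagrees (with a warning) rather than
propagating an inconsistent file.

**Expression proportions.** The input is the long-format cluster-level
differential-expression table emitted by standard single-cell toolkits
(`p_val, avg_log2FC, pct.1, pct.2, p_val_adj, cluster, gene`). Rows at or
above the adjusted-p screen (default 0.05) are dropped; the value column
(default `avg_log2FC`, which is nonnegative under positive-only marker
calling; negatives are clipped to 0 and counted) is pivoted to a gene ×
cluster matrix `A` with 0 for unreported pairs — marker callers only
report detected markers, so absence is treated as no evidence. Each gene's
row is then divided by its total across clusters, giving the proportion
matrix `E`. Rows summing to zero stay zero rather than becoming NaN.
Per-gene (row) normalization is the default; per-cluster (column)
normalization is available as `normalize_axis="cluster"` for sensitivity
checks, since the two readings are both plausible descriptions of the
procedure and the row-wise one matches the defining formula.

**Similarity and the λ rule.** `S(j, m) = Σ_g E(g, j) · W(m, g)` over genes
present on both sides; the matrix is dense over all dictionary types, zero
where a cluster shares no gene with a type. Per cluster:

* `S_max` — row maximum; `S_median` — median over the *full* row, maximum
  included; `S_secmax` — largest value after removing one occurrence of the
  maximum (multiset semantics: a tied maximum yields `S_secmax = S_max`).
* `λ₁ = S_max − S_median`. Since max ≥ median, λ₁ ≥ 0 always, and the
  cluster is left `Unannotated` exactly when the maximum equals the median
  (e.g. an all-zero or all-equal row) — a zero or negative λ carries no
  information.
* `λ₂ = S_secmax − S_median`, attached as a secondary label only when the
  top-two gap `S_max − S_secmax` exceeds ε (default 1e-5, configurable) and
  λ₂ > 0. The gap-based trigger follows the method's stated rule as
  printed; the alternative reading, triggering on `λ₁ > ε`, is selectable
  via `lambda2_trigger="median"` for comparison studies. That a *large* gap
  (not a small one) triggers the secondary label is counterintuitive but
  implemented as specified.

Argmax ties are broken lexicographically and logged, for determinism.

**Evaluation harness.** With no expert ground truth, a pseudo-reference is
built per cluster by majority vote over the annotators' primary labels:
a hand-written Boyer–Moore candidate/counter pass followed by a
verification count (the algorithm guarantees correctness only for strict
majorities); when no strict majority exists the plurality label wins with
a lexicographic tie-break, logged as `NO_STRICT_MAJORITY`. Accuracy is
matched clusters over all reference clusters — a mismatch is a single
error event, which makes every accuracy an integer multiple of
1/n_clusters; clusters an annotator skipped or left `Unannotated` count as
errors (default; configurable reading). By default a cluster with two
labels matches if *either* equals the reference (`match_mode="either"`),
since subtype-capable annotators are credited for secondary labels;
`"primary"` mode restricts to the first label. The range statistic
`R = |Acc₁ − Acc₂|` compares two runs of one tool under different
reference files.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `epsilon` | 1e-5 | top-two gap that triggers the secondary label (score units, same scale as S) |
| `p_adj_threshold` | 0.05 | adjusted-p screen on the marker table |
| `value_column` | `avg_log2FC` | which marker-table column feeds `A` (`pct.1` or a mean-expression column also work) |
| `normalize_axis` | `gene` | proportion axis for `E` |
| `lambda2_trigger` | `secmax` | gap-based (printed rule) vs median-based λ₂ trigger |
| `match_mode` | `either` | whether secondary labels earn accuracy credit |
| `case_fold` | true | upper-case gene symbols (reconciles human/mouse conventions); no alias or orthology mapping is attempted |

## Synthetic studies

The generator plants full ground truth: a dictionary whose per-type marker
sets are known (`genes_per_type` genes each, adjacent types sharing
`ceil(marker_overlap × genes_per_type)` genes, vote counts uniform on
1..`n_sources` or a supplied profile), cluster marker tables whose values
are proportional to the dictionary weights under multiplicative log-normal
noise (`noise_sd`) and row dropout, and annotator panels whose labels equal
the truth with probability 1 − error_rate (wrong labels drawn uniformly
from the other types, so expected accuracy is exactly 1 − error_rate). All
randomness flows from the spec's `seed` through per-operation substreams;
no global state.

Two presets: `small` (6 types × 6 clusters, noiseless) and `paper` (75
types, 29 clusters, 10 genes/type, 6 sources, overlap 0.2, noise 0.3,
dropout 0.05), the latter sized to the curated lung-fibrosis dictionary
scale (~600 unique genes over 75 subtypes) to exercise realistic sparsity.

What the generator emulates: the marker-caller output format, literature
vote profiles, shared markers between related types, measurement noise and
marker dropout. What it does not: per-cell counts, library-size and batch
effects, correlated annotator errors, or biologically structured marker
overlap. Passing the planted-recovery tests therefore demonstrates the
scoring and thresholding machinery, not performance on real tissue.

A note on stress conditions: with fully disjoint marker sets a cluster's
similarity to any wrong type is structurally zero, so label recovery is
immune to expression noise by construction. The noise-degradation tests
therefore run at `marker_overlap = 0.4`; even there the method is robust,
because a cluster's own type always scores over its full marker set while
competitors score only over the shared subset.

## Numerical choices and degenerate inputs

* Zero-sum gene rows of `A` produce zero rows of `E` (no NaN); an empty
  gene intersection between markers and dictionary produces an all-zero
  similarity matrix with a warning, and every cluster `Unannotated`.
* A score row of length 1 has `λ₁ = 0` (its median is itself) and no λ₂.
* Duplicate (type, gene) dictionary rows are summed with a warning;
  duplicate (gene, cluster) marker rows are an error by default
  (`on_duplicate="max"` keeps the larger value).
* Top-10 selection when building a dictionary from source tables ranks by
  votes (desc), then the best rank the gene achieved in any source, then
  gene symbol — deterministic under source reordering.
* Label comparison in evaluation trims and case-folds; no ontology mapping.
* All file outputs are plain TSV/CSV/JSON; the `annotate` and `evaluate`
  commands write a manifest (sha256 of inputs, configuration echo, library
  versions, counts of logged warnings) sufficient to reproduce a run.

## Problem sizes used in the checks

The automated checks run the similarity oracle on 100 random fixtures of
up to 50 genes × 10 clusters × 10 types; planted recovery on 50 seeds per
condition with 8 types × 8 clusters; majority-vote verification on 1,000
random 6-vote instances; and panel calibration on 500 seeds × 6 annotators
× 29 clusters. These sizes give binomial standard errors small enough for
3-σ checks while keeping a full run near a minute.

## Limitations

* Annotation is per cluster, not per cell; a mixed cluster gets at most
  two labels and no mixture proportions.
* Scores are not calibrated probabilities; λ thresholds are heuristic gaps.
* The quality of annotation is bounded by the dictionary: rare types
  missing from it can only surface as `Unannotated`.
* The packaged example dictionaries are synthetic fixtures, not curated
  scholarship; users supply their own curated dictionary for real studies.
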