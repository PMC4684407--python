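# Methods

## The data model

A pathway map is a directed graph whose nodes carry exactly one of seven
entity classes (drug, extracellular protein, physiological condition,
receptor, intracellular protein, gene expression, phenotype) and whose
edges are "activates"/"inhibits" relations, each backed by at least one
evidence record: a positive PubMed ID plus free categorical labels for
organism, technique and disease model. Unknown category values are kept
verbatim rather than coerced — the categories describe a literature, not a
closed vocabulary.

Entity identifiers are normalised by casefolding and stripping whitespace
and hyphens, so "MMP-2", "Mmp2" and "mmp 2" are one node. This canonical
key is deliberately aggressive: cross-map comparison (the main consumer)
needs symbol-style variants from different curation efforts to collide.
The cost — rare distinct symbols that differ only in hyphenation would
merge — is acceptable for symbol-level overlap analysis and is documented
at the API boundary.

Design choices where the domain left room:

- **One relation per (source, target, type) triple.** Additional citations
  of the same claim merge into the evidence list; exact duplicate evidence
  tuples are dropped (one article = one citation). Bidirectional claims
  (A activates B and B activates A) are two relations.
- **Self-loops are legal but warned** — autocrine signalling exists, but a
  loop is often a curation slip, so construction emits a warning rather
  than an error.
- **Curation format.** A plain two-section TSV ( `[entities]`,
  `[relations]`, one evidence record per relation row) rather than any
  spreadsheet-add-in syntax; it is diffable, round-trips exactly, and
  parse errors name the file and line.

## The concentric-ring layout

The layout encodes cellular topology: radius is a pure function of entity
class (phenotypes innermost at r=2, then gene expressions at 3,
intracellular proteins spread across rings 4–7, receptors at 8,
physiological conditions at 9, drugs and extracellular proteins outermost
at 10), and each integer radius is treated as its own ring. Within ring
*r* holding S(r) nodes, node *i* (0-based) sits at angle 360/S(r)·i
degrees; angles are stored in degrees and converted to radians only inside
the trigonometry.

Determinism contract: nodes are ordered lexicographically by id within
each ring before angle assignment, and the random stream for the
intracellular radii (uniform integers on [4,7]) is consumed in
within-class lexicographic order. Consequently the layout is a pure
function of (map, seed), and inserting entities of *other* classes never
moves an existing intracellular protein. The 0-based angle index keeps all
angles in [0, 360).

## Filters and neighbourhoods

A filter is a conjunction over evidence facets, evaluated **per article**:
a relation survives iff at least one single evidence record satisfies
every requested constraint simultaneously (an article that is mouse and a
different article that is in-vivo do not together satisfy
mouse ∧ in-vivo). Kept relations retain only the matching evidence, and
entities with no surviving incident relation are dropped — whether a
renderer should instead fade them is a presentation decision outside this
layer. This makes filtering idempotent and composable: filtering by
organism then technique equals the combined filter.

Neighbourhoods are breadth-first balls ignoring edge direction (signalling
context matters in both directions when reading a map), inducing all
relations among the kept entities.

## Comparison

Overlap is symbol-level after normalisation — no topology alignment and no
ortholog mapping. Node overlap is reported relative to a *named reference*
(|shared| / |reference| × 100) because "what fraction of my curated map is
also elsewhere" is the question of interest and the percentage is
asymmetric; a symmetric Jaccard is emitted alongside. Edge overlap
requires the full (source, target, relation type) triple to match — an
activation in one map and an inhibition of the same pair in another are
evidence of disagreement, not overlap. Merging is a set union with origin
labels (`a_only` / `b_only` / `both`) for highlight rendering; a shared id
with conflicting classes is an error listing the ids, since silently
picking a class would corrupt both maps.

## The expression pipeline

Inputs are features × samples matrices with a two-level group factor and
at least two samples per group. Preprocessing mirrors the standard
single-channel microarray chain: average duplicate probe rows, log2
(requiring strictly positive linear signals), then quantile normalisation
— each column's k-th order statistic is replaced by the across-column mean
of k-th order statistics, with ties receiving the mean of their tied
positions' values. An optional minimum-signal filter (drop features whose
linear signal is below 1.0 in every sample) emulates upstream array QC; it
is off by default because the package accepts already-filtered matrices.

### Ordinary t

Per feature, the unpaired pooled-variance two-sample t statistic with
d = n₁+n₂−2 degrees of freedom, two-sided p from the t distribution, and
log2 fold-change defined as mean(group 1) − mean(group 2), group order
being first appearance in the group file. Features with zero pooled
variance yield NaN statistic and p — the test is undefined there and the
package says so rather than inventing a value.

### Moderated t

The empirical-Bayes moderated test treats the per-feature variance s² as
drawn from a scaled inverse-chi-square prior with hyperparameters
(d₀, s₀²), giving the posterior (shrunken) variance

    s̃²_g = (d₀·s₀² + d·s²_g) / (d₀ + d)

and the moderated statistic t_g = logFC_g / (s̃_g·√(1/n₁+1/n₂)) referred
to a t distribution on d + d₀ degrees of freedom. The hyperparameters are
fitted by moment-matching on z = log s²: under the marginal scaled-F
distribution of s², E[z] and Var[z] are closed forms in digamma/trigamma
functions, so

    e_g   = z_g − ψ(d/2) + log(d/2)
    d₀    solves  ψ′(d₀/2) = Var(e) − ψ′(d/2)      (Newton on the trigamma)
    s₀²   = exp( mean(e) + ψ(d₀/2) − log(d₀/2) ).

When the observed spread of log-variances does not exceed pure chi-square
sampling noise (Var(e) ≤ ψ′(d/2)), the prior is infinitely informative:
d₀ = ∞, every posterior variance equals s₀² = mean(s²), and the reference
distribution is normal. With fewer than 10 usable variances the fit is not
meaningful and the function falls back to the ordinary t with a warning.

The implementation is verified two independent ways in the test suite: a
literal transcription of the formulas above using bracketed root-finding
instead of Newton iteration (agreement to 1e-6), and Bioconductor limma's
`lmFit`/`eBayes` run through `Rscript` on the same matrix (agreement to
1e-8 on t and p, 1e-6 relative on the hyperparameters).

### Overlay and candidate selection

Fold-changes paint nodes on a linear red→yellow scale over a symmetric
domain [−max|logFC|, +max|logFC|] (up-regulated red, down-regulated
yellow, zero the midpoint; out-of-domain values clamp). Only entity
classes a transcript can speak for — receptors, intracellular and
extracellular proteins, gene expressions — are annotated; drugs,
phenotypes and physiological conditions are excluded even when a feature
symbol happens to collide with them.

Candidates are features passing p < 0.05 and |log2FC| > 2 (both
configurable) **and** resolving to an allowed-class map entity, sorted by
|log2FC| descending. Thresholding is on raw p-values by default, matching
the conventional use of this workflow; Benjamini–Hochberg adjustment is
available behind a flag. Selection is antitone in both thresholds and
invariant to feature order.

## The synthetic-data generators

The map generator draws the requested number of entities per class,
samples relation triples uniformly without replacement from the
2·n² possible (source, target, type) combinations, and gives each relation
1–4 evidence records (probabilities 0.6/0.25/0.1/0.05) whose facets are
drawn independently per record from categorical distributions defaulting
to the published literature profile of the target corpus: organisms
rat 0.66 / mouse 0.22 / human 0.12, techniques cell-culture 0.60 /
in-vivo 0.30 / in-vitro 0.10, disease models homeostasis 0.45 /
fibrosis 0.35 / other 0.20. Real articles correlate facets (an in-vivo
study is likelier to be a disease model); the independence assumption is
acceptable for exercising filters and summaries but means joint-facet
frequencies are not realistic.

The expression generator produces log2-scale values
baseline_g + effect_g·1[sample ∈ group 1] + N(0, σ²), with per-feature
baselines N(7, 2²) (log-normal linear signals) and σ = 0.5 by default — a
typical post-normalisation microarray noise level — at 3 samples per
group, the design of the study this pipeline emulates. Planted features
carry a stated log2 fold-change; everything else is null. The generator is
Gaussian and homoscedastic across features, so it does not reproduce
real arrays' mean–variance trend, probe-level artefacts, or correlated
genes; passing tests demonstrate correctness of the computations and
calibration under the stated model, not robustness to those real-data
features.

## Numerical and testing choices

- Trigamma inversion uses Newton iteration with the standard 0.5 + 1/y
  start, 50-iteration cap, 1e-10 relative tolerance; the test oracle uses
  Brent root-finding on [1e-6, 1e8] instead, keeping the two code paths
  independent.
- Quantile normalisation interpolates average ranks against the mean order
  statistics, making it exact for tie-free columns and idempotent.
- Layout coordinates are checked to 1e-9 against closed forms and a
  step-by-step brute-force recomputation on maps of ≤ 20 nodes.
- Null calibration (fraction of p < 0.05 within [0.035, 0.065] for both
  tests at 5000 features), planted-logFC recovery (MAE < 0.5 at n=3 vs 3,
  σ=0.5, 200 features at logFC 3) and the end-to-end recovery property
  (≥5 of 6 planted in-map genes with ≤1 false positive in ≥18 of 20
  seeded runs at |logFC| ∈ [2.5, 4] among 1000 features) run on these
  problem sizes as the package's standing acceptance suite;
  `scripts/acceptance.py` recomputes the same quantities from any seed.

## Known limitations

- Symbol normalisation cannot distinguish genuinely different symbols that
  collide after hyphen/case stripping.
- SIF import cannot carry entity classes or evidence; imported comparison
  maps default to intracellular protein and placeholder evidence, which is
  adequate for symbol-level overlap but not for evidence filtering.
- The moderated test assumes a common two-group design across features and
  does not implement robust prior estimation, variance trends, or
  array-quality weights.
- Percentages in literature summaries use distinct articles as the
  denominator; with multi-protocol articles the per-facet percentages
  intentionally sum to more than 100.
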