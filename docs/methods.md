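# Methods

## Scope and data model

`mgcascade` operates entirely downstream of differential-expression
testing: its inputs are per-dataset DEG tables (gene symbol, signed fold
change or log2FC, raw/adjusted p, dataset id, species) and curated gene
lists, and its outputs are tiered gene sets with per-gene provenance. Raw
read alignment, DE model fitting, pathway enrichment, and literature
curation are out of scope; the lists they produce are consumed as inputs.

The universal currency is the *regulated gene set*: a named, species-tagged
map `symbol -> (direction, average fold change, supporting sources)`.
Curated lists are direction-free but may carry per-symbol annotations from
the declared vocabulary `methylation_direction ∈ {hyper, hypo}`,
`expression_direction ∈ {up, down}`, `promoter_dm ∈ {true, false}`.

## Selection and consensus rules

- DEG filter: |FC| ≥ `fc_threshold` (default 1.5, **inclusive**) and
  p < `p_threshold` (default 0.05, **strict**). The p-value consulted is
  configurable per input (`adjusted` for the published AD MG datasets,
  `raw` for the Cbs-knockout bulk table). Records lacking the configured
  p-value or a fold-change magnitude cannot demonstrate the criteria and
  are dropped, with counts recorded in a load report.
- Within one table, duplicate symbols collapse to the smallest-p record
  (ties: larger magnitude, then input order); duplicates with conflicting
  directions drop the gene from that table and are reported. This keeps
  per-table direction unambiguous, which the conflict rule requires.
- Consensus: membership requires calls in ≥ `min_support` datasets, all
  concordant; any cross-dataset direction conflict excludes the gene.
  Human rule `min_support=1` (union minus conflicts), mouse rule
  `min_support=2`. The human rule is a deliberate reading of an ambiguous
  protocol description: a strict 4-way intersection would be far smaller
  than the published 409-gene set, whereas union-minus-conflicts reproduces
  its arithmetic; the rule is configurable for users who want stricter
  support.
- Average FC is the arithmetic mean of *signed linear* fold changes over
  supporting datasets with a magnitude (direction-only rows support
  membership but are excluded from averaging). Averaging signed log2FCs
  and converting back (a geometric mean of magnitudes) is available via
  `fc_average_scale="log2"`; the linear scale is the default because the
  source protocol states only "average FC".

## Overlay semantics

Direction comparison uses the categorical up/down label, never FC
magnitude. Genes lacking a direction on either side are excluded from both
the concordant and discordant intersections and reported separately, so
`|concordant| + |discordant| + |undirected| = |symbol intersection|` holds
exactly. Unions keep conflicting-direction genes flagged `ambiguous` with
per-source directions rather than dropping them — the combined phagocytic
tier legitimately contains genes whose human and mouse directions differ.
All outputs are sorted lexicographically by symbol, making serialization
byte-deterministic.

Cross-species matching is case-insensitive symbol equality after
normalization (trim, uppercase, strip internal whitespace). An optional
two-column ortholog table can rename symbols before matching
(`harmonize.apply_ortholog_map`); symbol matching suffices for the cascade
itself because every curated list is symbol-keyed.

Methylation–expression association is consumed strictly as an annotation
from the source methylome study and never re-inferred: the DM/EG overlay
requires both annotation directions on every member and derives the
hypomethylated and promoter-hypomethylated subsets from them.

The HHcy stage overlaps the Cbs-knockout MG DEG set with five category
sets: (A) phagocytic AD MG DEGs, (B) the Aβ⁺ MG signature list, (C) the
CRISPR modifier list, (D) hypomethylated phagocytic DM/EGs, (E) GWAS-mapped
phagocytic DEGs. Which tier plays category A is genuinely underdetermined
in the source protocol; the default is the endocytosis-related tier, the
only reading under which the published per-category hit counts are disjoint
apart from the two stated duplicates, and `category_a="combined"` selects
the broader 326-gene union (the deduplicated 10-gene total is identical
under both readings in the planted geometry). The final curated
"HHcy-suppressed" subset of 5 genes in the source study is
literature-derived; the cascade emits the 10-gene tier with per-category
provenance and leaves manual curation to annotation pass-through, it does
not compute the 5.

## Synthetic compendium

The simulator plants a gene universe realizing a configured tier geometry
and only then emits noisy per-dataset tables, so every expected tier is
known by construction. Defaults are the study conditions: 4 human + 7 mouse
datasets and the published tier sizes (409, 777, 37/23, 377-gene Aβ⁺ list
with 184 up / 193 down, 20/110/9/14, 286/15, 2172/66/165/16, 326, 559 with
16/14/10/36/23/7, 431 with 17/30/4/20, 353 Cbs DEGs, 10 HHcy-altered, and
a planted −1.79 fold change on the Igf1-analog Cbs hit). The allocation is
generic arithmetic over the `TierSizes` fields with explicit feasibility
checks, so scaled-down geometries (used throughout the tests) are first-
class; an infeasible geometry raises instead of silently adjusting.

Emission details:

- Fold-change magnitudes: lognormal(μ=log 2.5, σ=0.6) truncated at 1.5 by
  rejection; per-dataset draws are independent, so consensus averages vary
  around the planted effect while signs stay fixed.
- Planted p-values: Beta(0.1, 1) rescaled strictly below the significance
  threshold. Rescaling (rather than raw Beta draws) makes planted calls
  pass the p filter deterministically — the design choice that makes
  noiseless recovery *exact* rather than merely probable, which is what
  the recovery tests assert. Decoy p-values are uniform above threshold.
- Decoys exercise each rejection path: sub-threshold calls (low FC or high
  p), cross-dataset direction conflicts, and single-dataset mouse calls
  below the support rule.
- Mouse records are written title-case ("Gn00042") and human records
  uppercase, exercising the case-insensitive matcher; a fraction
  (default 10%) of mouse-only genes get names with no human-style
  counterpart.
- `degrade(tables, detect_prob, direction_flip_prob, seed)` thins and
  perturbs call tables for robustness tests; consensus size shrinks in
  expectation as either noise parameter grows.

What the simulator does **not** emulate: count-level RNA-seq noise,
batch effects, scRNA-seq dropout structure beyond call-level detection,
realistic gene-symbol vocabularies, or correlated membership between
curated lists beyond the planted overlaps. Passing tests therefore
demonstrate correctness of the *set machinery and its rules* on inputs
with the study's overlap geometry — not robustness of the upstream DE
calling, and not that real supplementary tables would yield the same
counts, although loading them through `io_tables` and entering the cascade
mid-stage is exactly what the per-stage API is for.

## Numerical and degenerate-input choices

- Ties in duplicate collapse resolve by (p, −|FC|, input order);
  missing p ranks last.
- Empty tables and empty lists raise explicit empty-input errors at load
  time; empty *sets* flow through the algebra (intersections and unions of
  empties are empty, tier TSVs are written headers-only).
- JSON provenance serializes floats via `repr`, so write→read→write is
  byte-stable; all mappings are emitted with sorted keys.
- Seeds: one `numpy.random.Generator` per simulation, seeded from
  `SimParams.seed`; identical parameters give byte-identical files.

## Problem sizes

The test suite runs the full study-scale geometry (≈6,400 planted genes,
11 datasets, ≈13,000 calls) once as a session fixture and a ~4× smaller
consistent geometry everywhere else; the whole suite completes in a few
seconds on one CPU, and `scripts/acceptance.py` runs the study-scale
simulation plus the full cascade in well under a second.

## Known limitations

- The human `min_support=1` reading and the category-A default are
  documented interpretations of ambiguous protocol text, configurable but
  not resolvable from the text alone.
- Symbol-string orthology ignores one-to-many homology; the ortholog-table
  hook exists but ships empty.
- Overlap significance (hypergeometric or permutation p-values) is
  deliberately absent: the cascade reports raw counts only.
- XLSX reading addresses one sheet at a time; multi-sheet workbooks need
  one `read_deg_table` call per sheet.
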