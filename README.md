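# mgcascade

Cross-species consensus of microglial differential-expression calls and a
direction-aware, provenance-tracking gene-list overlay cascade — the kind of
multi-stage meta-analysis used to nominate genes through which
hyperhomocysteinemia (HHcy) may suppress microglial amyloid-β (Aβ)
phagocytosis in Alzheimer's disease (AD).

## The problem

Microglia (MG) clear Aβ fibrils by receptor-mediated phagocytosis, and their
dysfunction worsens AD. Evidence about which genes matter is scattered
across heterogeneous resources: single-nucleus and bulk RNA-seq of MG from
AD patients and mouse AD models, a functional signature comparing
plaque-engulfing (Aβ⁺) versus non-engulfing MG, a CRISPR knockout screen for
phagocytosis modifiers, curated endocytosis gene sets, an AD-cortex
methylome (differentially methylated/expressed genes, DM/EGs), GWAS-mapped
AD genes, and MG transcriptomes from HHcy (*Cbs*⁻/⁻) mice. None of these
alone identifies methylation-regulated phagocytosis genes altered by HHcy;
their *intersection structure* does. `mgcascade` implements that
intersection machinery as a tested, reusable pipeline that consumes
per-dataset DEG tables and curated lists — no raw reads, no external
downloads.

## The method

**Per-dataset filter.** A gene is a DEG in one dataset when
|FC| ≥ 1.5 (inclusive) and p < 0.05 (strict; raw or adjusted p,
configurable per input). Signed fold change encodes direction
(FC = −2 means halved expression).

**Per-species consensus.** Gene *g* enters the species consensus set iff it
is called in at least *k* datasets and every call agrees in direction;
any cross-dataset direction conflict excludes *g* outright. Human AD MG use
*k* = 1 over four patient datasets (union minus conflicts); mouse AD MG use
*k* = 2 over seven model datasets. Each retained gene is assigned the
arithmetic mean of its signed FCs over supporting datasets and the list of
supporting dataset ids.

**Direction-aware overlays.** For regulated sets *A*, *B* with direction
maps d_A, d_B:

- concordant intersection: { g ∈ A ∩ B : d_A(g) = d_B(g) }
- discordant intersection: { g ∈ A ∩ B : d_A(g) ≠ d_B(g) }
- list overlap: { g ∈ A : g ∈ L } for a direction-free curated list L
- provenance-keeping union, retaining genes whose input directions
  conflict with an explicit `ambiguous` flag.

Concordant + discordant always partition the plain symbol intersection.
Human/mouse symbols match case-insensitively ("TREM2" ↔ "Trem2"); an
explicit two-column ortholog table can override string matching.

**The cascade** chains these primitives: species consensus → cross-species
common tiers → Aβ⁺-signature overlay (concordant = functional-validated
phagocytic DEGs; human discordant = impaired-phagocytosis signature) →
CRISPR-modifier and endocytosis overlays → combined phagocytic union →
DM/EG overlays with hypomethylated and promoter-hypomethylated subsets →
GWAS overlays → overlay of the *Cbs*⁻/⁻ MG DEGs on five phagocytosis
categories. Every tier records complete per-gene provenance back to source
dataset ids and list names.

**Synthetic compendium.** Because the real supplementary tables are
external artifacts, the package ships a simulator that plants a gene
universe with a configured tier geometry (the default reproduces the
published study: 409/777 consensus genes, 37 common, 20/110 Aβ-phagocytic,
15 modifiers, 215 endocytosis, 326 combined, 36 DM/EGs, 43/20 GWAS,
10 HHcy-altered) and emits structurally realistic per-dataset tables,
curated lists, and decoys. With perfect detection and no direction flips
the cascade recovers every planted tier exactly; dropout and flip
probabilities let tests degrade the signal in controlled ways.

## Worked example

```sh
mgcascade simulate --out demo --seed 1
mgcascade cascade --config demo/config.yaml --out demo/results
mgcascade report --results demo/results
```

prints (abridged):

```
tier                           genes    up  down
ab_phago_human                    20    12     8
ab_phago_mouse                   110    69    41
common_concordant                 37    22    15
common_discordant                 23    12    11
dmeg_hypomethylated               23    20     3
endocytosis                      215   112    99
gwas_mg                           43    30    13
gwas_phagocytic                   20    18     2
hhcy_phagocytic                   10     3     7
human_ad                         409   232   177
mouse_ad                         777   498   279
phagocytic_combined              326   183   139
```

Reading: from 409 human and 777 mouse consensus AD MG DEGs, 37 agree in
direction across species (22 up / 15 down) and 23 oppose; 20 human and 110
mouse DEGs move with the Aβ-engulfment signature; modifiers, endocytosis
genes and these functional tiers combine into 326 phagocytic AD MG DEGs; 23
of the 36 methylation-regulated phagocytic genes are hypomethylated; and 10
of the *Cbs*⁻/⁻ (HHcy) MG DEGs hit at least one phagocytosis category
(`demo/results/hhcy_phagocytic.tsv` lists them with fold changes and the
categories each hit; `provenance.json` mirrors every membership decision).
The same stages are available as library functions
(`mgcascade.run_cascade`, `mgcascade.cascade.stage_*`) for entering the
cascade mid-way with your own intermediate lists.

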