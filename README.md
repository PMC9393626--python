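# wsyrnet

A tested, reusable implementation of the dry + wet computational
pipeline used to dissect how the Wenshenyang recipe (WSYR) — a
three-herb traditional Chinese medicine combining Gusuibu (*Drynaria
fortunei*), Roucongrong (*Cistanche deserticola*) and Yinyanghuo
(*Epimedium brevicornu*) — acts on infertility. It is aimed at
network-pharmacology practitioners who want each step of that style of
analysis as an auditable, scriptable function rather than a chain of
web tools.

## What the pipeline computes

1. **ADME compound screen** — retain herb compounds with oral
   bioavailability OB ≥ 30 % and drug-likeness DL ≥ 0.18 (inclusive);
   report per-herb counts, the deduplicated recipe-wide set, and
   compounds shared between herbs.
2. **Therapeutic targets** — union disease-gene lists from named
   sources (Entrez id preferred, case-folded symbol as fallback) and
   intersect each herb's compound-target set with the disease set.
3. **Enrichment** — upper-tail hypergeometric over-representation,
   p = P(X ≥ k) for X ~ Hypergeom(N, K, n), with Benjamini–Hochberg
   q-values and common/unique pathway comparison across herbs.
4. **PPI hub ranking** — build interaction networks from
   confidence-weighted edge lists (edges kept when confidence strictly
   exceeds the threshold, e.g. > 0.9), compute degree, unnormalized
   betweenness and harmonic closeness per node, z-standardize each
   metric (sample SD) and rank by the composite z_deg + z_betw + z_clo.
5. **DEG calling** — classify per-gene statistics with the strict rule
   log2FC > log2 1.5 (up) or < log2 0.67 (down) and p < 0.05, or
   compute the statistics from a count matrix with a conditional
   negative-binomial exact test (median-of-ratios size factors,
   common method-of-moments dispersion); merge per-herb calls with
   direction provenance.
6. **Docking screen** — retain compounds whose docking score strictly
   exceeds fraction × positive-control score (e.g. 75 % of 65.414 for
   estrogen receptor α, 90 % of 52.8724 for β); no-pose rows never
   participate; RMSD < 2 Å validates a redocking model.
7. **qPCR quantification** — relative expression by 2^−ΔΔCt with
   replicate averaging on the Ct scale.
8. **Network assembly** — typed herbs–compounds–targets–pathways
   networks exported to GraphML / SIF / node-link JSON.

A `synthetic` module provides seeded generators with planted ground
truth (active fractions, hub nodes, fold changes, enriched terms,
docking hits, ΔΔCt) so every stage is testable offline, and the
package ships the published compound, target, DEG and docking tables
as plain-text fixtures.

## Worked example

```sh
wsyrnet run-all -o out/
```

runs every stage on the packaged tables. The report (abridged):

```json
"compounds": {"per_herb": {"Gusuibu": 18, "Roucongrong": 6, "Yinyanghuo": 23},
              "unique_active": 43, "n_shared": 4},
"targets":   {"per_herb": {"Gusuibu": 25, "Roucongrong": 22, "Yinyanghuo": 25},
              "union": 44},
"degs":      {"per_herb": {"Gusuibu":    {"total": 22, "up": 19, "down": 3},
                           "Roucongrong": {"total": 26, "up": 15, "down": 11},
                           "Yinyanghuo":  {"total": 54, "up": 30, "down": 24}},
              "union": 92},
"docking":   {"ESR1": {"n_hits": 7, "max_score": 54.53, "min_score": 49.776},
              "ESR2": {"n_hits": 5, "max_score": 50.993, "min_score": 49.054}}
```

Reading: 43 distinct compounds pass the ADME screen (4 of them present
in two herbs); 44 distinct genes are therapeutic targets; 92 distinct
genes are differentially expressed across the three herb treatments;
7 compounds beat 75 % of the ERα control score and 5 beat 90 % of the
ERβ control, with xanthogalenol, davallioside A_qt and linoleyl acetate
passing both receptors. The same numbers are available from Python via
`wsyrnet.run_pipeline(wsyrnet.PipelineConfig())`.

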