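# Methods

This note documents the models, conventions and numerical choices
behind each pipeline stage, what the synthetic-data generators emulate,
and the known limitations.

## ADME compound screen

Compounds are screened on TCMSP-style descriptors: oral bioavailability
(OB, percent ≥ 0) and drug-likeness (DL, unitless in [0, 1]). Both
thresholds are **inclusive** (OB ≥ 30, DL ≥ 0.18): the packaged
reference table contains boundary values (Liquiritigenin at DL = 0.18)
that the published screen retains, which fixes the convention.
Compound identity is the molecule accession (`mol_id`), never the
display name — names vary in case and spelling across tables, and a
compound present in two herbs appears as one accession under two herb
labels. The partition identity
`sum(per-herb counts) = |unique ids| + sum over shared compounds of
(herbs − 1)` is enforced as a property test.

## Gene identity and target intersection

Gene records carry a symbol and optionally an Entrez id. Identity is
the Entrez id when present, else the upper-cased symbol; Entrez wins on
conflict, and a symbol observed with two different Entrez ids across
sources is surfaced as a reconciliation warning rather than silently
merged. Intersection of herb-target sets with the disease universe is
plain set arithmetic; an empty disease set is valid and yields empty
results.

## Over-representation analysis

The test is the one-sided upper-tail hypergeometric:
`p = P(X >= k)`, `X ~ Hypergeom(N, K, n)` with N the universe, K the
term size, n the query size and k the overlap (`scipy.stats.hypergeom`
backs the computation; tests check it against exhaustive enumeration of
all C(N, n) draws for every parameter combination with N ≤ 12). The
universe is the set of genes the annotation carries, not the genome —
the appropriate choice for targeted panels, and explicit in the
report. Benjamini–Hochberg q-values (statsmodels) are emitted
alongside, but the enrichment flag applies to the raw p, matching the
p ≤ 1e−3 / 1e−5 filter convention of the original analysis. Ties in p
are broken by term id so output order is deterministic. Kappa-score
term grouping (as performed by ClueGO-style tools) is deliberately not
reproduced: enriched-pathway counts from such tools depend on the
annotation snapshot, so they are validated here by planted-truth
recovery and null calibration, not by headline counts.

## Interaction-network hub ranking

Edges are kept when confidence is **strictly** greater than the
threshold (matching the "> 0.9" / "> 0.4" convention); duplicate
undirected pairs collapse to their maximum confidence and self-loops
are dropped with a log message. STRING-style 0–1000 integer scores are
auto-detected and rescaled to [0, 1].

Per node, three centralities are computed on the unweighted graph:

* degree — incident edge count;
* betweenness — unnormalized, summed over unordered pairs
  (normalization is affine and cancels in the z-scoring);
* closeness — harmonic centrality (sum of reciprocal distances,
  1/∞ = 0), chosen because high-confidence interaction subgraphs are
  commonly disconnected, where classic closeness degenerates; classic
  closeness remains available as an option.

"Standardization of deviation" is interpreted as the z-score with the
**sample** standard deviation (ddof = 1); a constant metric gets z ≡ 0
(the convention that makes regular graphs a clean total tie). The SD
is treated as zero when it is below 1e−12 relative to the metric's
magnitude, guarding against float jitter on vertex-transitive graphs.
The composite hub score is the sum of the three z-scores; ranking is
composite-descending with node-id tie-breaks. Standardization is
always performed within the analyzed graph (also for pathway-restricted
subnetworks). Published key-target identities depend on the
interaction-database snapshot; they are reproducible only from a
user-supplied edge list, so the packaged validation is planted-hub
recovery on synthetic graphs plus exact equivalence with a brute-force
shortest-path-enumeration oracle on small graphs.

## Differential expression

Classification applies strict inequalities in log2 space:
up iff log2FC > log2 1.5 ≈ 0.58496 and p < 0.05; down iff
log2FC < log2 0.67 ≈ −0.57793 and p < 0.05. The reference table's
smallest-magnitude entries (TXN at 0.615, EGFR at −0.593) pass under
this convention, which confirms it. Raw p-values are thresholded (an
optional BH column is available to users); the merge unions calls by
gene id and records each calling herb with its direction.

`count_test` is a transparent count-based stand-in for shrinkage-based
DE frameworks, not a reimplementation of one:

* **Normalization** — DESeq-style median-of-ratios size factors
  (median across always-expressed genes of the ratio to the per-gene
  geometric mean), falling back to total-count scaling when no gene is
  expressed in every sample. Plain total-count scaling is biased by
  composition: with 10 % of genes planted 4-fold up it shifts every
  null gene's apparent log2FC by about −0.4, which wrecks both type-I
  error and false-discovery control.
* **Dispersion** — a common α shared across genes, the mean of
  per-gene within-group method-of-moments estimates
  (α = (s² − m)/m²), floored at 1e−12. With hundreds of genes this is
  a tight estimate of a shared dispersion, which is exactly the
  generator's regime; per-gene estimation from 5 replicates would be
  far noisier.
* **Test** — the conditional (edgeR-style) exact test: group sums of
  rounded normalized counts are compared against the negative-binomial
  conditional distribution given the gene's total (sum of n iid
  NB(μ, α) is NB(nμ, α/n)); two-sided by the minimum-likelihood rule.
  When α is at the floor the conditional law reduces to the binomial
  (Poisson limit) and is computed directly. Degenerate all-zero genes
  report log2FC = 0, p = 1. Fold changes use a 0.5 pseudocount on the
  normalized group means.

Calibration: across seeds, the null rejection rate at p < 0.05 is
0.05 within binomial error, and planted 4-fold genes at 5
replicates/group are recovered essentially completely.

**A note on fold-change screens and false discoveries.** The null
sampling sd of the estimated log2FC is approximately
√(2(α + 1/μ)/n)/ln 2; at α = 0.1 and n = 5 that is ≈ 0.3, so the
1.5-fold cutoff sits < 2 sd from zero and ~4–5 % of null genes pass
both the FC and the p cut (the two events nearly coincide). With 10 %
of genes truly changed, the false-discovery proportion of the combined
rule is therefore ≈ 0.3 *regardless of the test statistic* — a
property of the thresholding rule, not a defect of the test. At
α = 0.01 the noise floor (≈ 0.09) is far below the cutoff and the rule
controls FDP near zero; the suite tests FDP control in that regime and
recovery in the noisy one.

## Docking screen

Scores are used exactly as printed (higher = stronger affinity;
negative values are legal). Retention is **strict**:
score > fraction × control score, with exactly one control row
required per table; the control itself and rows flagged as having no
refined pose never appear in retention or rankings. The retention
fractions are per-receptor configuration (0.75 for the α receptor,
0.90 for β) with no shared default. Where the source text and table
disagree in the fourth decimal, the fixture stores the table value and
comparisons use a 5e−4 tolerance. RMSD is computed without
superposition (redocked poses share the receptor frame); the
reliability flag is strict (< 2 Å). A Kabsch-superposed variant is out
of scope.

## qPCR quantification

The Livak 2^−ΔΔCt convention: replicates averaged on the Ct scale,
ΔCt = Ct_target − Ct_reference within condition,
ΔΔCt = ΔCt_treated − ΔCt_control, fold = 2^−ΔΔCt. Plate-shift
invariance (a constant added to every Ct cancels) and condition-swap
reciprocity are property-tested. Amplification-efficiency correction
(Pfaffl) is not implemented.

## Synthetic data

One global seed feeds a named `SeedSequence` substream per generator,
so adding a generator never perturbs existing draws and identical
(seed, parameters) give byte-identical tables. Defaults are chosen to
mimic the study's regime:

* compound tables — planted actives drawn with margins (OB ≥ 30.5,
  DL ≥ 0.185) so float comparisons are unambiguous; failures miss at
  least one cutoff; optional cross-herb shared compounds carry
  identical OB/DL everywhere;
* interaction graphs — G(n, p) background with p = base_degree/(n−1),
  hubs connected with 5× that probability plus a hub clique, giving
  hubs ≥ 3× the background expected degree; confidences uniform (0, 1);
* count matrices — NB(μ, μ + αμ²) with α defaulting to 0.1 (a typical
  bulk RNA-seq biological CV of ~0.3), baseline means log-uniform over
  ~20–200 (targeted-panel depth), 5 replicates per group;
* annotations — term sizes uniform 10–50 in a universe of a few
  hundred; the planted term contributes a set fraction of a 40-gene
  query;
* docking tables — planted hits placed strictly above the relative
  threshold with a 1 % margin, non-hits strictly below;
* Ct tables — reference gene at Ct 18, target at ΔCt 4, Gaussian well
  noise.

These generators emulate distributional structure, not real-data
pathologies: no batch effects, no outlier libraries, no correlated
genes, no annotation redundancy, no multi-reference qPCR. Passing the
planted-truth suites therefore demonstrates algorithmic correctness
and calibration under the assumed models, not robustness to violations
of them.

## Problem sizes

The packaged analyses are desk-scale and run in seconds. Simulation
checks use 50-node graphs over 20 seeds for hub recovery, exhaustive
hypergeometric enumeration up to a 12-gene universe, 100–200 null
annotation draws, and 1000-gene count matrices over a handful of seeds
— sizes at which the binomial error of the estimated rates is a few
tenths of a percent, sufficient for the calibration bands tested.

## Known limitations

* Live database queries (compound databases, disease-gene sources,
  interaction databases) are out of scope by design; all such inputs
  are files, so published results that depend on a database snapshot
  (pathway counts, key-target identities) are checked by property, not
  by value.
* `count_test` does not implement dispersion shrinkage, Wald/LRT
  machinery or outlier handling; with strongly gene-specific
  dispersions the common-α assumption is misspecified.
* The enrichment module performs no ontology-graph reasoning
  (no term redundancy reduction, no parent propagation).
* Docking is score-table analysis only; no pose generation, protein
  preparation or PDB parsing.
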