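# Methods

## The distance model

Candidate genes are scored on an undirected, simple gene-symbol graph
built from STRING-dialect edges (`protein1 protein2 combined_score`,
integer scores 0–999). Protein IDs are mapped to gene symbols through an
alias table; endpoints without a mapping are dropped and counted, and
duplicate undirected pairs (including reversed order) collapse to a single
edge keeping the **maximum** score — conservative under a high-confidence
filter, since the strongest evidence for the gene pair survives. Edges
are retained at `combined_score >= min_score` with a default of 700
(STRING's conventional "high confidence" 0.7). The threshold is
non-strict and configurable; either convention can be selected via
`min_score`.

Distances are **unweighted hop counts**: the selection rule distinguishes
only membership (0) from direct interaction (1), so edge scores act as an
inclusion filter rather than a length. The distance from a gene to an
omics level is the minimum over that level's signature genes, computed
with a multi-source BFS. Signature genes absent from the interactome are
still at distance 0 to their own level — membership is definitional,
interaction is evidential — but contribute no paths, so an isolated
signature gene is unreachable from the other levels.

The three per-level minima (transcriptome d_T, genome d_G, protein-level
d_P) are summed into d_sum. The protein term's source set is the union of
the proteome signature and the metabolome-derived gene set. Unreachable
components propagate: d_sum is infinite when any component is, and an
unreachable component disqualifies a gene from selection, since no
interaction evidence links it to that level.

**Selection rule.** A candidate is selected when every component is ≤ 1
and at least one component is 0. Both thresholds are configurable
(`max_component`, `min_zero_levels`) for sensitivity analysis. Note the
rule does not bound d_sum separately; profiles such as (0, 1, 1) and
(0, 0, 1) both qualify, and all selected genes automatically have
d_sum ≤ 2.

**Ranking.** Candidates are ordered by ascending d_sum, ties broken by
the number of zero components (more levels of direct membership first),
then gene symbol. The tie-break is a package convention chosen to make
the output a deterministic total order; nothing downstream depends on the
order among tied profiles.

## Differential expression

Two-group comparisons use an unequal-variance (Welch) two-sample t test
on log2 intensities, with log2FC = mean(case) − mean(control). A
moderated linear-model test (limma-style empirical Bayes) would shrink
per-gene variances toward a common prior; the plain Welch test was chosen
because moderation is a library internal rather than part of the
integration method, and at the sample sizes the pipeline targets (≥ 20
per group) the two agree closely. Genes with zero variance in both
groups get a 1e-12 floor on each variance term (with a warning) so the
statistic stays defined on degenerate fixtures. Multiple testing uses
Benjamini–Hochberg step-up adjustment — the field default where the
choice of "adjusted p" is otherwise open. DEG classification applies
adjusted p < alpha (default 0.05) and |log2FC| ≥ lfc_threshold (default
1, i.e. fold change > 2 or < 0.5 on natural scale, applied on the log
scale for all stages).

Cohort balance checks are Pearson chi-square without continuity
correction (df = (r−1)(c−1); a zero margin is an error) and a one-way
ANOVA reconstructed from group summary statistics: between-group SS from
means and sizes, within-group SS = Σ(nᵢ−1)sᵢ², which reproduces the
full-data F exactly for any per-group summaries.

## Signature assembly

Gene symbols are the integration key: all symbols are uppercased and
deduplicated on load, since mixed-case symbols are the dominant
cross-source failure mode. Metabolite signatures convert to genes through
a scored metabolite–reaction–protein table: proteins with confidence
score **strictly greater than** `min_score` (default 4) for any query
metabolite are kept and collapsed to unique gene symbols. Metabolites
absent from the table are logged, not fatal; high-scoring proteins
without a gene mapping are flagged and dropped.

## Connectivity scoring

Perturbation profiles are complete rankings of a gene universe (rank 1 =
most up-regulated). The enrichment score of a query set is the classic
unweighted Kolmogorov–Smirnov running sum: +1/|Q| at each query gene,
−1/(N−|Q|) otherwise, taking the deviation of largest magnitude (exact
ties resolve positive). The unweighted form was chosen because profiles
carry rankings, not z-scores; a score-weighted variant is a natural
extension hook. The combined score follows the L1000 WTCS convention:
(ES_up − ES_down)/2 when the two enrichment scores have opposite signs,
else 0. Percentile normalization is a signed percentile against a seeded
ensemble of uniform-permutation null profiles (≥ 100 required, 1000 by
default): the percentage of null |WTCS| values strictly below the
observed |WTCS|, carrying the observed sign. Flags are positive above
+90 and negative below −90. This is a faithful-in-spirit reimplementation
of connectivity-map scoring, not a bit-identical one: the reference
ensemble is a permutation null rather than a touchstone-compound library,
and no cross-cell-line tau aggregation is performed, so percentiles are
calibrated within a run, not against an external catalog. Note that by
construction a truly null profile has a uniform percentile, so ~10% of
null profiles exceed ±90 by chance — the thresholds flag extremity, they
do not control a false-discovery rate.

## Synthetic data

The generators emulate the study design at desk scale with exact ground
truth; all are pure functions of their seed.

- **Expression**: two groups (control vs. one case stage), i.i.d.
  Gaussian noise on the log2 scale — the two-group microarray setting
  without probe-level artifacts, batch effects, or correlation structure.
  Planted genes shift the case mean by ±lfc. Defaults for the controlled
  recovery simulation follow the discovery design scaled to its severe-
  stage contrast: 125 up / 43 down planted at |log2FC| = 3 with residual
  SD 0.25 and 20 samples per group over 2000 background genes. At these
  settings the mean-difference SD is 0.25·√(2/20) ≈ 0.079, so planted
  genes sit ≈ 38 SD from 0 and background genes ≈ 12.6 SD below the
  |log2FC| ≥ 1 threshold: recovery is exact with overwhelming
  probability, which is the point — the simulation validates the calling
  machinery, not the test's power at realistic effect sizes.
- **Network**: signature sets per level (auto-named or caller-supplied),
  candidates planted at requested hop distances via dedicated paths of
  above-threshold edges with fresh intermediate nodes and
  per-(candidate, level) anchors. Decoy edges are high-score only among
  background nodes and low-score (< 700) anywhere, so the confidence
  filter removes them and cannot create shortcuts. After construction the
  generator re-derives every truth distance by BFS on the filtered graph
  and raises if any requested geometry is not realized exactly —
  construction is verified, never trusted. The topology is deliberately
  minimal: no scale-free degree structure, so tests validate distance
  logic, not robustness to hub-dominated graphs.
- **Perturbation profiles**: planted-positive profiles place the query
  up-set uniformly within the top `band` fraction of the ranking (default
  0.08) and the down-set within the bottom fraction; negative profiles
  swap the two; null profiles are uniform permutations. The band keeps
  planted WTCS strong (≈ 0.9) without degenerate ±1 scores.
- **Reaction table / target tables**: flat scored rows and
  probability-assigned tiers, exercising the strict score cutoff, the
  unmapped-protein flag, and the tier-join mechanics.

What passing tests on these fixtures show: the calling, distance,
selection, and scoring machinery is correct on inputs whose truth is
known exactly. What they do not show: performance on real cohorts with
correlated expression, incomplete and biased interactomes, or annotation
noise — those depend on external data snapshots outside the package's
scope.

## Pipeline determinism

All thresholds live in one configuration (alpha, lfc_threshold,
min_score, magi_min_score, max_component, min_zero_levels,
connectivity_cutoff, n_null, seed). Outputs contain no timestamps; stage
timings go to the logger only. The manifest records the seed, every
threshold, and SHA-256 checksums of all inputs and outputs, so a rerun
from the same config is byte-identical and verifiable against the
manifest. Any stage failure aborts with the stage name and cause.

## Problem sizes

Test fixtures use 50–80-node networks, 300–2168-gene expression studies,
and 150–1000-permutation null ensembles — sizes chosen so the exact
oracles (Floyd–Warshall, per-source BFS, brute-force running sums,
combinatorial enumeration) remain trivially computable while every code
path, including unreachable components and degenerate variances, is
exercised.

## Known limitations

- Connectivity percentiles are permutation-null based and not comparable
  to touchstone-referenced scores from external services.
- The Welch substitution for moderated DE will differ from
  empirical-Bayes results at very small sample sizes (n < 5 per group).
- Symbol harmonization is uppercase-normalization only; no alias
  resolution against nomenclature services.
- The heat-diffusion comparison ranker is out of scope; the distance
  model favors well-connected candidates by design, relying on the
  high-confidence edge filter to control for interactome noise.
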