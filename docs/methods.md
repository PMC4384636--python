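# Methods

This note records the models, conventions and design choices behind
`locaset`, in the order the pipeline applies them.

## Coordinates, identifiers, inputs

All internal coordinates are 0-based half-open. GFF3 (1-based inclusive)
and bedGraph (0-based half-open) are converted at the boundary, so interval
arithmetic lives in one convention. A 3'UTR form's *end position* is its
strand-aware 3'-most bound: the half-open end on `+`, the start on `-`.
Gene identifiers are opaque FlyBase-style strings.

When a gene has several transcripts, exonic features use the union of all
exons while the intron structure follows a policy switch
(`intron_policy="longest"` by default, the transcript with the longest
genomic span; `"union"` merges all transcripts). The underlying annotation
convention is genuinely ambiguous in screens of this kind, so the choice is
explicit and configurable rather than implied.

All readers validate eagerly: malformed rows fail with the line number,
overlapping conservation intervals are rejected, CV terms outside the
vocabulary are rejected by name, and partial files are never silently
truncated. Conservation queries return exactly one score per base with NaN
(never 0) for uncovered bases.

## Count normalization and stage comparison

Size factors are median-of-ratios: for stage $s$,
$f_s = \mathrm{median}_g\, c_{gs} / \tilde c_g$ where
$\tilde c_g$ is the gene's geometric mean across stages and genes with any
zero are excluded from the reference. This is the standard tag-count
normalization for libraries whose majority of genes are unchanged; full
differential-expression machinery (dispersion shrinkage, Wald tests) is
deliberately out of scope — only the normalization is needed downstream.

Stage similarity is Pearson correlation on $\log_2(x+1)$ of normalized
counts over genes detected in at least one of the two stages. Whether the
original analyses correlated raw, normalized or log counts is not
recoverable, so the transform is a documented default (`log_transform`,
`detection_threshold` arguments).

## pn-status and the binary matrix

Detection thresholds are 70 normalized counts for RNAseq and 50 for 3Pseq.
"Expressed above cut-off" means the maximum normalized count across sampled
stages reaches the cutoff (inclusive, `>=`) in **at least one** assay;
"below" means below in **both**. This reading makes TP/FP/TN/FN a partition
of the (above/below × signal/no-signal) grid; the alternative reading of
"below cut-off in either assay" would double-count. The comparison with
FISH uses the broad class: any specific CV term at any stage makes a probe
*specific*; homogeneous signal at every annotated stage is *ubiquitous*;
no signal at every stage is *no_signal*.

Genes probed more than once with conflicting broad classes are
*not_reliable*, with the conflict typed as no-signal-vs-other (a probe
presumed non-functional) or ubiquitous-vs-specific (probes possibly
isoform-specific). CV term values are summed over probes, so counts above
one only arise from multiply-probed genes. Subclass membership (cellular /
subcellular / nuclear) is a set, not a single label — one mRNA can fall
into several subgroups.

## 3'UTR usage, mean-weighted length, APA

A 3'-end tag is assigned to the annotated form whose strand-aware end is
nearest, provided the absolute genomic distance is at most 200 nt
(`end_window`); exact ties go to the shorter form — conservative toward
proximal ends — then to the lexicographically smaller form id. The window
is symmetric around the annotated end by default with a one-sided option,
since the original description does not fix the sidedness. Usage weights
are assigned tag counts from the same stage's library (normalized weights
are a config option; the mean-weighted length is invariant to rescaling all
weights, so the two only differ when weights are pooled across libraries).

Mean-weighted length is $\bar L = \sum_i w_i L_i / \sum_i w_i$ over forms
with positive weight; APA is called between two stages when
$|\bar L_B - \bar L_A| \ge 200$ nt, inclusive at the boundary (a difference
of exactly 200 qualifies). A stage with no assigned tags yields `no_call`
with a reason rather than a fabricated delta.

3'UTR conservation is the median per-base phyloP-style score over the most
used form (the maximal-weight form, same tie rule). Uncovered bases are
excluded from the median, never imputed as 0; results with more than 50%
missing bases (configurable) carry a low-coverage flag.

## Resampling tests

**Bootstrap median test.** Both groups are resampled with replacement to
their own sizes $B$ times. The group with the lower *observed* median is
determined first; the exceedance count is
$k = \#\{b : \mathrm{med}(low^{*b}) \ge \mathrm{med}(high^{*b})\}$ and
$p = k/B$. Two conventions are supported: `zero_allowed` (default,
$p = 0$ representable, resolution $1/B$) and `add_one`
($(k+1)/(B+1)$, strictly positive). Pairing is within-iteration by
default; comparing the low group's bootstrap medians against the high
group's *observed* median is available as `bootstrap_pairing =
"fixed_reference"` — published p-values of this family of screens cannot
discriminate the two readings.

*Calibration.* Because the orientation (which group is "low") is chosen
from the data and no factor-2 correction is applied, the null distribution
of $p$ is uniform on $(0, \tfrac12)$, not $(0,1)$: unconditionally
$P^*(\mathrm{med}_A^* \ge \mathrm{med}_B^*) \approx \Phi(Z)$ with $Z$
standard normal under the null, and conditioning on the observed direction
restricts $Z \le 0$. The doubled p-value $2k/B$ is uniform on $(0,1)$
(verified by simulation in the test suite). Practically: the test as
defined is anti-conservative by a factor of two, and a nominal level
$\alpha$ corresponds to an actual level $2\alpha$; users who need a
calibrated two-sided test should halve their threshold or double the
reported $p$. The package reports $k/B$ as defined.

**Network permutation test.** The observed statistic is the induced-subgraph
edge count of the gene set, excluding self-loops ("minus loops"; loops are
retained in storage but flagged). The null draws $m$ nodes *without
replacement* from all interactome nodes, where $m$ is the number of set
members participating in at least one interaction; $p$ is the fraction of
draws with as many or more within-sample edges. Sampling from all network
nodes (rather than degree-matched sampling) follows the original design;
the test is therefore sensitive to degree composition as well as to
clustering, which is part of what it measures.

**RNG stream contract.** Each test builds a single
`numpy.random.default_rng(seed)`. The bootstrap draws one uniform-integer
block of shape $(B, n_{low})$ then one of shape $(B, n_{high})$, row-major;
the network test makes $B$ successive `choice(n, m, replace=False)` calls
over the sorted node list. numpy's generator fills arrays sequentially in C
order, so a naive implementation drawing one iteration at a time from the
same seed consumes an identical stream — the test suite exploits this to
compare exceedance counts against independent oracles *exactly*.

**Enrichment z-score** uses the binomial normal approximation
$z = (O - np)/\sqrt{np(1-p)}$ with an optional hypergeometric
finite-population variance correction
($\times (N-n)/(N-1)$) for sets that are a large fraction of the
background.

## Trajectories

The stage axis is `st2_7, st8, st9, st10`, extendable with `emb1_3,
emb4_5`. Categories are minus / plus / ubiquitous / absent; unprobed stages
are *absent*, never ubiquitous. The term→category map ships as editable
YAML per cell-type context; pole-cell annotation is excluded from the plus
category by construction (it is cell-specific expression, not subcellular
localization), embryonic body-axis terms are not auto-mapped, and a term
mapped only in another context carries no polarity (apical enrichment means
nothing in the germline) while a term the map has never seen raises an
error, forcing explicit map maintenance.

Simultaneous minus and plus terms at one stage are recorded as a conflict
and resolve to minus for the code: de-novo minus localization never arises
late in these screens, and a plus-precedence rule would fabricate it.

Clustering is average-linkage agglomerative on the Hamming distance over
stages where both codes are non-absent (normalized by compared positions;
1.0 when none are comparable). Categorical codes produce heavy distance
ties, so codes are first canonicalized (sorted by category string, then
gene id), making memberships invariant to input order. Clusters are
summarized by the majority archetype of their members (stay-minus,
minus→ubiquitous, minus→plus, ubiquitous→plus, …); archetype recovery, not
dendrogram topology, is the meaningful surface.

Cross-cell-type overlap restricts to genes probed in all contexts and
counts exact Venn regions, plus the genes that are minus-category in every
context. Each gene is evaluated independently per context, so one gene can
be localized in several cell types.

## The synthetic cohort

The generator emulates the statistical structure of a real screen; its
defaults are the study conditions of the analyses and tests.

* **Gene sets** (fractions of genes): ubiquitous 0.40, cellular 0.08,
  nuclear 0.05, oocyte-enriched 0.08, anterior 0.035, posterior 0.045,
  epithelial-apical 0.04; the remainder shows no signal. (The analysis
  scripts use a variant with 0.125 anterior/posterior to obtain ~150 genes
  per set.)
* **Counts**: negative binomial, $\mathrm{var} = \mu + \alpha\mu^2$ with
  $\alpha = 0.1$; per-gene means lognormal (log-mean 5.8, log-sd 1.0);
  88% of genes stage-stable, the rest with 1–2 stages knocked down 50-fold.
  The mean level is calibrated so that the planted stable transcriptome is
  *detectable* as stable at the 50/70 noise cutoffs (≥85% of ever-detected
  genes detected at every stage by at least one assay) — emulating a deeply
  sequenced screen whose noise thresholds sit at the expressed/noise
  antimode. No-signal genes carry 5% of a normal mean, populating the
  TN/FP cells of pn-status.
* **Planted posterior effects**: ×2 expression, ×2 3'UTR length, +1
  phyloP-unit conservation shift inside posterior 3'UTRs, and a
  deterministic within-set interaction excess (6% of posterior pairs,
  against an Erdős–Rényi background of density 0.002 with a few self-loops
  to exercise the minus-loops rule). Planted effect sizes are applied
  deterministically — they are conditions, not draws.
* **APA**: 10% of genes carry two 3'UTR forms 320–460 nt apart whose usage
  weights shift 0.9/0.1 → 0.1/0.9 between early and late, planting
  mean-weighted-length differences of ≥256 nt (mean ≈ 310), comfortably
  above the 200 nt call threshold at the default tag depth (Poisson mean 60
  per gene per stage).
* **Read ends**: Gaussian jitter (sd 30 nt) around the used form's
  annotated end, plus 2% background tags 300–1000 nt away that exercise the
  ±200 nt window without saturating it.
* **Conservation**: per-base standard normal scores over all 3'UTR regions
  (phyloP-like, negative values possible), 2% of bases left uncovered to
  exercise missing-data handling.
* **Trajectories**: archetypes consistent with the planted sets
  (oocyte: 70% minus→ubiquitous with a random switch stage, 30%
  stay-minus; posterior: 60% minus→plus, 40% ubiquitous→plus with pole
  plasm in the early embryo; epithelial: apical, partially persisting into
  the embryo). Three or more epithelial genes are additionally localized in
  germline and embryo contexts to populate the triple Venn overlap and the
  minus-consistent count. 3% of genes get a duplicate probe (exercising CV
  summing) and 1% a conflicting probe (exercising both reliability
  conflict types).
* **Determinism**: one `numpy.random.default_rng(seed)` with a fixed,
  documented draw order (sets → APA selection → structures →
  annotations/probes → 3Pseq counts → RNAseq counts → read ends →
  conservation → network); identical (config, seed) produces byte-identical
  files. The manifest records the config and its SHA-256 hash.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sequence content (only coordinates, counts and
scores are simulated); mapping and counting artifacts upstream of the count
tables; correlated biological noise between assays and stages (draws are
independent given the mean); realistic PPI degree distributions (the
background is Erdős–Rényi, so the network test's degree-composition
sensitivity is untested against scale-free structure); annotation noise
(planted trajectories are clean apart from the explicit conflict probes);
and isoform-level RNAseq structure.

## Problem sizes

The shipped analyses use 1,200-gene cohorts with $B = 10^4$ resamples —
enough for ~150-gene sets, p-value resolution of $10^{-4}$, and
second-scale runtimes; production use on a full screen would raise
$B$ to $10^5$ (the default of `ResamplingConfig`). The test suite uses
300-gene cohorts and $B$ between $10^3$ and $10^4$.

## Known limitations

* The bootstrap median test reports the screen's own $k/B$ convention,
  which is anti-conservative by a factor of 2 (see above); no
  multiple-testing correction is applied across set pairs, and the KS
  comparison grid reports raw p-values with a p < 0.01 significance mark.
* The network null is not degree-matched.
* `ConservationTrack` stores scored intervals in memory; chromosome-scale
  tracks would need a different backend (e.g. bigWig), which the reader
  boundary isolates.
* Whether bootstrap resampling should preserve each group's own size
  (implemented) or pool sizes is not decidable from published descriptions;
  group-size preservation is the natural reading of resampling "from
  selected annotation sets".
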