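# locaset

Analysis pipeline for genome-scale mRNA-localization screens of *Drosophila*
oogenesis that combine stage-resolved sequencing (whole-mRNA RNAseq and
3'-end tag 3Pseq) with systematic fluorescent in situ hybridization (FISH)
annotated against a controlled vocabulary (CV).

Such screens ask how thousands of mRNAs distribute inside the egg-chamber —
the oocyte, its nurse cells, and the somatic follicle epithelium — and what
distinguishes localized transcripts from ubiquitous ones. `locaset`
implements the computational layer: fusing FISH annotations with expression
into a per-gene binary matrix, calling 3'UTR usage and alternative
polyadenylation (APA) from 3'-end tags, testing gene-set features with
bespoke resampling nulls, and encoding how localization changes across
developmental stages and cell types. A synthetic-cohort generator plants
all of these effects so the whole pipeline is testable end to end without
any external download.

## The statistics at the core

**Mean-weighted 3'UTR length and APA.** 3'-end tags are assigned to an
annotated 3'UTR form when they fall within ±200 nt of its annotated end.
With usage weights $w_i$ over forms of length $L_i$, the per-stage
mean-weighted length is

$$\bar L = \frac{\sum_i w_i L_i}{\sum_i w_i},$$

and a gene undergoes APA between stages $A, B$ when
$|\bar L_B - \bar L_A| \ge 200$ nt.

**Bootstrap median test.** To compare a feature (3'UTR length, median
phyloP conservation) between annotation gene sets, each set is resampled
with replacement to its own size $B$ times (default $B = 10^5$); with the
lower-median set labelled *low*,

$$p = \frac{1}{B}\,\#\{b : \mathrm{med}(low^{*b}) \ge \mathrm{med}(high^{*b})\}.$$

$p = 0$ is representable at resolution $1/B$; a $(k+1)/(B+1)$ convention is
available. Because the orientation is chosen from the observed medians, the
null distribution of $p$ is uniform on $(0, \tfrac12)$ — see
`docs/methods.md`.

**Protein-interaction permutation test.** For a gene set with $m$ members
participating in the interactome, the observed within-set interaction count
(self-loops excluded) is compared against $B$ random draws of $m$ nodes
from the whole network; $p$ is the fraction of draws with as many or more
within-sample interactions.

**Term enrichment z-score.** CV-term over/under-representation in a set of
size $n$ against background frequency $p$:
$z = (O - np)/\sqrt{np(1-p)}$, with an optional hypergeometric
finite-population correction.

**Normalization and stability.** Libraries are normalized with
median-of-ratios size factors (ratio to the per-gene geometric-mean
pseudo-reference); stage similarity is Pearson $r$ on
$\log_2(\text{normalized}+1)$; FISH-vs-sequencing agreement (pn-status:
TP/FP/TN/FN) uses noise thresholds of 70 (RNAseq) and 50 (3Pseq)
normalized counts.

**Trajectories.** Localization destinations are grouped by microtubule
polarity (minus ends: oocyte enrichment, anterior, apical; plus ends:
posterior, pole plasm, basal). Each gene gets one category per stage
(minus / plus / ubiquitous / absent); trajectories are clustered by
average-linkage on an absent-aware Hamming distance, and cross-cell-type
overlap is counted over genes probed in germline, epithelial and embryonic
contexts.

## Worked example

Run the numbered analysis scripts in order (each writes tables under
`results/`):

```sh
python analysis/01_simulate.py
python analysis/02_expression.py
python analysis/03_utr_apa.py
python analysis/04_feature_stats.py
python analysis/05_binary_matrix.py
python analysis/06_trajectories.py
```

`01` generates a 1,200-gene cohort with ~150 anterior and ~150 posterior
genes, a 2× posterior shift in expression, 3'UTR length and conservation,
a planted excess of posterior-set protein interactions, and ~10% APA genes.
The downstream scripts then print, among other lines:

```
early/late 3Pseq Pearson r = 0.807 over 1199 genes
83.0% of the 1013 detected genes are detectable at every stage -> the transcriptome is stable
set posterior: n=144, median normalized expression 637.6
APA called for 126 genes (126 planted); sensitivity 1.000, false-call rate 0.0000
utr3_length anterior vs posterior: p = 0
PPI within-set excess, posterior: observed 633 interactions, p = 0
PPI within-set excess, anterior: observed 24 interactions, p = 0.5529
of 1200 genes probed in all contexts, 3 localize in all three cell types,
170 in at least two; 3 are minus-category in every cell type
```

Reading these: expression is stable across oogenesis (high stage-to-stage
correlation, most detected genes detectable at every stage) while
localization changes; the posterior gene set is more highly expressed,
has ~2× longer and more conserved 3'UTRs (bootstrap $p = 0$ at
$B = 10^4$, i.e. $p < 10^{-4}$), and shows a within-set interaction excess
that the anterior set lacks; APA is rare and the planted events are
recovered; and only a handful of mRNAs localize congruently across cell
types.

The same steps are available as a CLI:

```sh
locaset simulate --config sim.yaml --out cohort/
locaset validate cohort/
locaset pipeline cohort/ --out results/ --seed 1
```

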