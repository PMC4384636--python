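"""Synthetic ovary-screen cohort generator.

Emits all six input families the pipeline consumes — gene models (GFF3), a
per-base conservation track (bedGraph), stage count tables for 3Pseq and
RNAseq, 3Pseq read 3'-end positions, a controlled-vocabulary FISH annotation
table, and a protein-protein interaction network — together with a truth
table of what was planted, so every downstream analysis can be tested
without any download.

The generator emulates the statistical structure of the real screen:

* a stable transcriptome — negative-binomial counts with stage-stable means
  for most (default 88%) genes, matching the observation that ~85% of
  expressed transcripts are detectable at every time point;
* a posterior gene set with higher expression, longer and more conserved
  3'UTRs, longer gene bodies with more introns, and an excess of
  protein-protein interactions among its members;
* localization trajectories that switch polarity category over stages
  (stay-minus, minus-to-ubiquitous, minus-to-plus, ubiquitous-to-plus);
* a subset of genes undergoing alternative polyadenylation, expressing two
  3'UTR forms whose usage weights shift between early and late stages.

Determinism: a single ``numpy.random.default_rng(seed)`` drives generation.
The draw order is fixed and documented in ``generate_cohort``; identical
(config, seed) pairs produce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import vocabulary as cv
from .io_core import (
    AnnotationTable,
    ConservationTrack,
    CountTable,
    GeneModel,
    InteractionNetwork,
    UTRForm,
    read_annotations,
    read_conservation,
    read_counts,
    read_gene_models,
    read_interactome,
    read_read_ends,
    write_annotations,
    write_conservation,
    write_counts,
    write_gene_models,
    write_interactome,
    write_read_ends,
)

logger = logging.getLogger("locaset")

SEQ_STAGES = ("early", "late", "full", "embryo_0_2h")
ANNOT_STAGES = ("st2_7", "st8", "st9", "st10", "emb1_3", "emb4_5")
OVARY_STAGES = ("st2_7", "st8", "st9", "st10")
EMBRYO_STAGES = ("emb1_3", "emb4_5")

GENE_SETS = ("ubiquitous", "cellular", "nuclear", "oocyte", "anterior",
             "posterior", "other", "no_signal")


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 2000
    seq_stages: tuple[str, ...] = SEQ_STAGES
    annotation_stages: tuple[str, ...] = ANNOT_STAGES
    # gene-set proportions (remainder is the no-signal class)
    proportions: dict = field(default_factory=lambda: {
        "ubiquitous": 0.40,
        "cellular": 0.08,
        "nuclear": 0.05,
        "oocyte": 0.08,
        "anterior": 0.035,
        "posterior": 0.045,
        "other": 0.04,   # apical/basal in the somatic epithelium
    })
    # planted effects on the posterior set
    expression_shift: float = 2.0          # multiplicative mean-count shift
    utr_length_multiplier: float = 2.0     # 3'UTR length multiplier
    conservation_shift: float = 1.0        # additive phyloP-scale shift
    ppi_within_p: float = 0.06             # within-set edge probability
    ppi_excess_edges: int | None = None    # fixed planted edge count override
    # APA
    apa_fraction: float = 0.10
    # counts
    nb_dispersion: float = 0.1             # var = mu + alpha mu^2
    stage_stable_fraction: float = 0.88
    # lognormal(log-mean, log-sd) of per-gene mean counts.  Calibrated so
    # expressed genes sit well above the 50/70 noise cutoffs and the planted
    # stage-stable transcriptome (~88% of genes) is detectable as stable at
    # every stage by at least one assay, mirroring a deeply sequenced screen
    # whose noise thresholds were chosen at the expressed/noise antimode.
    base_mean_log: float = 5.8
    base_mean_sd: float = 1.0
    # 3Pseq read ends
    read_depth: float = 60.0               # mean tags per gene per stage
    read_end_jitter: float = 30.0          # sd (nt) around the annotated end
    background_read_fraction: float = 0.02
    # conservation track
    conservation_missing_fraction: float = 0.02
    # PPI background
    ppi_background_p: float = 0.002
    ppi_loop_rate: float = 0.003
    # probes
    duplicate_probe_fraction: float = 0.03
    conflicting_probe_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if total > 1.0 + 1e-9:
            raise ValueError(f"gene-set proportions sum to {total} > 1")
        for name in ("expression_shift", "utr_length_multiplier"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.apa_fraction <= 1:
            raise ValueError("apa_fraction must lie in [0, 1]")
        if self.n_genes < 10:
            raise ValueError("n_genes must be at least 10")
        if not 0 <= self.ppi_within_p <= 1:
            raise ValueError("ppi_within_p must lie in [0, 1]")
        if self.ppi_excess_edges is not None:
            n_post = int(round(self.n_genes * self.proportions.get("posterior", 0.0)))
            max_edges = n_post * (n_post - 1) // 2
            if self.ppi_excess_edges > max_edges:
                raise ValueError(
                    f"ppi_excess_edges={self.ppi_excess_edges} exceeds the "
                    f"{max_edges} possible pairs within a posterior set of {n_post}"
                )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["seq_stages"] = list(self.seq_stages)
        d["annotation_stages"] = list(self.annotation_stages)
        return d

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    truth: pd.DataFrame
    gene_models: dict[str, GeneModel]
    conservation: ConservationTrack
    counts_3pseq: CountTable
    counts_rnaseq: CountTable
    read_ends: pd.DataFrame
    annotations: AnnotationTable
    network: InteractionNetwork


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate the full cohort.

    Draw order (fixed; all randomness flows through one seeded generator):
    1. gene-set labels, 2. APA/second-form gene selection, 3. gene
    structures, 4. trajectories/annotations and probes, 5. 3Pseq counts,
    6. RNAseq counts, 7. 3Pseq read ends, 8. conservation scores,
    9. interaction network.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = [f"FBgn{i:07d}" for i in range(1, n + 1)]

    # 1. gene sets -----------------------------------------------------------
    labels = list(config.proportions)
    probs = [config.proportions[l] for l in labels]
    labels.append("no_signal")
    probs.append(max(0.0, 1.0 - sum(probs)))
    probs = np.asarray(probs) / np.sum(probs)
    gene_set = rng.choice(labels, size=n, p=probs)

    # 2. APA genes and constitutive two-form genes ---------------------------
    is_apa = rng.random(n) < config.apa_fraction
    two_form_static = (~is_apa) & (rng.random(n) < 0.05)

    # 3. gene structures -----------------------------------------------------
    models: dict[str, GeneModel] = {}
    utr3_main_len = np.zeros(n, dtype=int)
    utr3_delta = np.zeros(n, dtype=int)
    cursor = 1000
    chrom = "chr2L"
    for i, gid in enumerate(gene_ids):
        posterior = gene_set[i] == "posterior"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 6)) + (2 if posterior else 0)
        exon_lens = rng.integers(100, 400, size=n_exons)
        intron_lens = rng.integers(60, 250, size=max(n_exons - 1, 1))[: n_exons - 1]
        utr5_len = int(rng.integers(50, 300))
        L1 = int(np.exp(rng.normal(np.log(300.0), 0.4)))
        if posterior:
            L1 = int(round(L1 * config.utr_length_multiplier))
        L1 = max(L1, 30)
        delta = int(rng.integers(320, 460)) if (is_apa[i] or two_form_static[i]) else 0
        utr3_main_len[i], utr3_delta[i] = L1, delta

        body = int(exon_lens.sum() + intron_lens.sum())
        span_len = body + max(L1 + delta, L1)
        start = cursor
        end = start + span_len
        cursor = end + 500

        # exon chain over the body, with the 3'UTR region appended to the
        # strandwise last exon so UTR forms stay inside the span
        exons: list[tuple[int, int]] = []
        pos = start
        for j in range(n_exons):
            exons.append((pos, pos + int(exon_lens[j])))
            if j < n_exons - 1:
                pos = exons[-1][1] + int(intron_lens[j])
        max_utr3 = max(L1 + delta, L1)
        if strand == "+":
            exons[-1] = (exons[-1][0], end)
            utr_anchor = end - max_utr3  # 5' boundary of the 3'UTR region
            forms = [UTRForm(f"{gid}.utr3_1", (utr_anchor, utr_anchor + L1), strand)]
            if delta:
                forms.append(UTRForm(f"{gid}.utr3_2", (utr_anchor, utr_anchor + L1 + delta), strand))
            utr5 = ((start, start + utr5_len),) if utr5_len else ()
        else:
            # mirror: the 3' end lives at low coordinates; rebuild the exon
            # chain from the high end downward
            exons = []
            pos = end
            for j in range(n_exons):
                exons.append((pos - int(exon_lens[j]), pos))
                if j < n_exons - 1:
                    pos = exons[-1][0] - int(intron_lens[j])
            exons = sorted(exons)
            exons[0] = (start, exons[0][1])
            anchor = start + max_utr3  # 5' boundary (3' end extends down)
            forms = [UTRForm(f"{gid}.utr3_1", (anchor - L1, anchor), strand)]
            if delta:
                forms.append(UTRForm(f"{gid}.utr3_2", (anchor - L1 - delta, anchor), strand))
            utr5 = ((end - utr5_len, end),) if utr5_len else ()
        models[gid] = GeneModel(
            gene_id=gid, chrom=chrom, strand=strand, gene_span=(start, end),
            exons=tuple(exons), utr5=utr5,
            utr3_forms=tuple(sorted(forms, key=lambda f: (f.interval, f.form_id))),
        )

    # 4. trajectories, annotations, probes -----------------------------------
    ann_records, truth_rows = _plant_annotations(rng, gene_ids, gene_set, config)

    # 5-6. counts ------------------------------------------------------------
    mu = np.exp(rng.normal(config.base_mean_log, config.base_mean_sd, size=n))
    mu = np.where(gene_set == "posterior", mu * config.expression_shift, mu)
    mu = np.where(gene_set == "no_signal", mu * 0.05, mu)
    stable = rng.random(n) < config.stage_stable_fraction
    n_stages = len(config.seq_stages)
    stage_mu = np.tile(mu[:, None], (1, n_stages))
    for i in range(n):
        if not stable[i]:
            off = rng.choice(n_stages, size=int(rng.integers(1, 3)), replace=False)
            stage_mu[i, off] *= 0.02
    counts_3p = _nb_draw(rng, stage_mu, config.nb_dispersion)
    mu_rna = stage_mu * 1.4 * np.exp(rng.normal(0.0, 0.1, size=stage_mu.shape))
    counts_rna = _nb_draw(rng, mu_rna, config.nb_dispersion)

    df3 = pd.DataFrame(counts_3p, index=pd.Index(gene_ids, name="gene_id"),
                       columns=list(config.seq_stages))
    dfr = pd.DataFrame(counts_rna, index=pd.Index(gene_ids, name="gene_id"),
                       columns=list(config.seq_stages))
    counts_3pseq = CountTable("3Pseq", config.seq_stages, df3)
    counts_rnaseq = CountTable("RNAseq", config.seq_stages, dfr)

    # 7. 3Pseq read ends -----------------------------------------------------
    read_rows = _plant_read_ends(rng, gene_ids, models, is_apa, two_form_static, config)
    read_ends = pd.DataFrame(read_rows, columns=["chrom", "position", "strand", "gene_id", "stage"])

    # 8. conservation --------------------------------------------------------
    conservation = _plant_conservation(rng, gene_ids, models, gene_set, config)

    # 9. interaction network -------------------------------------------------
    network = _plant_network(rng, gene_ids, gene_set, config)

    truth = pd.DataFrame(truth_rows)
    truth["apa"] = is_apa
    truth["utr3_main_length"] = utr3_main_len
    truth["utr3_form_delta"] = utr3_delta
    truth["planted_mean_count"] = np.round(mu, 4)
    truth["stage_stable"] = stable
    truth = truth.set_index("gene_id")

    return SyntheticCohort(
        config=config, truth=truth, gene_models=models, conservation=conservation,
        counts_3pseq=counts_3pseq, counts_rnaseq=counts_rnaseq,
        read_ends=read_ends, annotations=AnnotationTable(ann_records, cv.VOCABULARY),
        network=network,
    )


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + alpha mu^2."""
    size = 1.0 / alpha
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def _plant_annotations(rng, gene_ids, gene_set, config):
    """Per-gene CV annotation rows and trajectory truth, per gene set.

    Germline-context polarity archetypes: the oocyte set splits into
    minus-to-ubiquitous (70%) and stay-minus; the posterior set into
    minus-to-plus (60%) and ubiquitous-to-plus.  A small slice of the
    epithelial ("other") set is additionally localized in the germline and
    embryo contexts to populate the cross-cell-type Venn overlap.
    """
    records: list[tuple[str, str, str, str]] = []  # gene, probe, stage, term
    truth_rows: list[dict] = []
    n = len(gene_ids)
    n_triple = max(3, n // 400)
    other_idx = [i for i in range(n) if gene_set[i] == "other"]
    triple_set = set(other_idx[:n_triple])

    for i, gid in enumerate(gene_ids):
        s = gene_set[i]
        probe = f"{gid}_p1"
        stage_terms: dict[str, set[str]] = {}
        context = "germline"
        archetype = "other"

        if s == "no_signal":
            for st in config.annotation_stages:
                stage_terms[st] = {cv.NO_SIGNAL}
            archetype = "none"
        elif s == "ubiquitous":
            for st in config.annotation_stages:
                stage_terms[st] = {cv.UBIQUITOUS}
            archetype = "stay_ubiquitous"
        elif s == "cellular":
            for st in OVARY_STAGES:
                stage_terms[st] = {"follicle_cell_restricted"}
            for st in EMBRYO_STAGES:
                stage_terms[st] = {cv.UBIQUITOUS}
            archetype = "cellular"
        elif s == "nuclear":
            stage_terms["st2_7"] = {cv.UBIQUITOUS}
            stage_terms["st8"] = {cv.UBIQUITOUS}
            stage_terms["st9"] = {"nurse_cell_nuclear"}
            stage_terms["st10"] = {"nurse_cell_nuclear"}
            for st in EMBRYO_STAGES:
                stage_terms[st] = {cv.UBIQUITOUS}
            archetype = "nuclear"
        elif s == "oocyte":
            if rng.random() < 0.7:
                archetype = "minus_to_ubiquitous"
                switch = rng.choice(["st8", "st9", "st10"])
                seen = False
                for st in OVARY_STAGES:
                    if st == switch:
                        seen = True
                    stage_terms[st] = {cv.UBIQUITOUS} if seen else {"oocyte_enrichment"}
            else:
                archetype = "stay_minus"
                stage_terms["st2_7"] = {"oocyte_enrichment"}
                for st in ("st8", "st9", "st10"):
                    stage_terms[st] = {"anterior_enrichment"}
            for st in EMBRYO_STAGES:
                stage_terms[st] = {cv.UBIQUITOUS}
        elif s == "anterior":
            archetype = "stay_minus"
            stage_terms["st2_7"] = {"oocyte_enrichment"}
            for st in ("st8", "st9", "st10"):
                stage_terms[st] = {"anterior_enrichment"}
            for st in EMBRYO_STAGES:
                stage_terms[st] = {cv.UBIQUITOUS}
        elif s == "posterior":
            if rng.random() < 0.6:
                archetype = "minus_to_plus"
                stage_terms["st2_7"] = {"oocyte_enrichment"}
                stage_terms["st8"] = {cv.UBIQUITOUS}
            else:
                archetype = "ubiquitous_to_plus"
                stage_terms["st2_7"] = {cv.UBIQUITOUS}
                stage_terms["st8"] = {cv.UBIQUITOUS}
            stage_terms["st9"] = {"posterior_enrichment"}
            stage_terms["st10"] = {"posterior_enrichment"}
            stage_terms["emb1_3"] = {"pole_plasm"}
            stage_terms["emb4_5"] = {cv.UBIQUITOUS}
            if rng.random() < 0.2:  # cell-specific pole-cell signal, not polarity
                stage_terms["emb4_5"] = {"pole_cell"}
        elif s == "other":
            context = "epithelial"
            archetype = "epithelial_apical"
            for st in OVARY_STAGES:
                stage_terms[st] = {"apical_enrichment"}
            stage_terms["emb1_3"] = {cv.UBIQUITOUS}
            stage_terms["emb4_5"] = (
                {"apical_enrichment"} if rng.random() < 0.4 else {cv.UBIQUITOUS}
            )
            if i in triple_set:
                # germline + epithelial + embryo localized, minus-consistent
                stage_terms["st2_7"] = {"oocyte_enrichment", "apical_enrichment"}
                stage_terms["emb4_5"] = {"apical_enrichment"}

        for st, terms in stage_terms.items():
            for term in sorted(terms):
                records.append((gid, probe, st, term))

        # duplicate / conflicting second probes
        r = rng.random()
        if r < config.duplicate_probe_fraction:
            probe2 = f"{gid}_p2"
            for st, terms in stage_terms.items():
                for term in sorted(terms):
                    records.append((gid, probe2, st, term))
        elif r < config.duplicate_probe_fraction + config.conflicting_probe_fraction:
            probe2 = f"{gid}_p2"
            if s in ("no_signal", "ubiquitous") or rng.random() < 0.5:
                conflict_terms = {cv.NO_SIGNAL} if s != "no_signal" else {cv.UBIQUITOUS}
            else:
                conflict_terms = {cv.UBIQUITOUS}
            for st in config.annotation_stages:
                records.append((gid, probe2, st, sorted(conflict_terms)[0]))

        germline_polar = any(
            t in ("oocyte_enrichment", "anterior_enrichment", "posterior_enrichment")
            for terms in stage_terms.values() for t in terms
        )
        epithelial_polar = any(
            t in ("apical_enrichment", "basal_enrichment")
            for st in OVARY_STAGES for t in stage_terms.get(st, ())
        )
        embryo_polar = any(
            t in ("apical_enrichment", "basal_enrichment", "pole_plasm")
            for st in EMBRYO_STAGES for t in stage_terms.get(st, ())
        )
        truth_rows.append({
            "gene_id": gid,
            "gene_set": s,
            "context": context,
            "archetype": archetype,
            "localized_germline": germline_polar,
            "localized_epithelial": epithelial_polar,
            "localized_embryo": embryo_polar,
        })

    df = pd.DataFrame(records, columns=list(AnnotationTable.COLUMNS))
    return df, truth_rows


def _plant_read_ends(rng, gene_ids, models, is_apa, two_form_static, config):
    """3'-end tags jittered around annotated form ends, with usage weights
    shifting between early and later stages for APA genes."""
    rows = []
    early = config.seq_stages[0]
    for i, gid in enumerate(gene_ids):
        gene = models[gid]
        forms = gene.utr3_forms
        if not forms:
            continue
        for stage in config.seq_stages:
            n_reads = int(rng.poisson(config.read_depth))
            if n_reads == 0:
                continue
            if len(forms) == 1:
                weights = np.array([1.0])
            elif is_apa[i]:
                weights = np.array([0.9, 0.1]) if stage == early else np.array([0.1, 0.9])
            else:  # constitutive two-form usage
                weights = np.array([0.6, 0.4])
            picks = rng.choice(len(forms), size=n_reads, p=weights)
            jitter = np.rint(rng.normal(0.0, config.read_end_jitter, size=n_reads)).astype(int)
            background = rng.random(n_reads) < config.background_read_fraction
            for k in range(n_reads):
                end = forms[picks[k]].end_position
                if background[k]:
                    pos = end + int(rng.integers(300, 1000)) * (1 if gene.strand == "+" else -1)
                else:
                    pos = end + int(jitter[k])
                rows.append((gene.chrom, max(pos, 0), gene.strand, gid, stage))
    return rows


def _plant_conservation(rng, gene_ids, models, gene_set, config):
    """Per-base Gaussian scores over every 3'UTR region; the posterior set's
    UTRs are shifted up by the configured amount.  A small fraction of bases
    is left uncovered to exercise missing-data handling."""
    starts_all, ends_all, scores_all = [], [], []
    for i, gid in enumerate(gene_ids):
        gene = models[gid]
        if not gene.utr3_forms:
            continue
        lo = min(f.interval[0] for f in gene.utr3_forms)
        hi = max(f.interval[1] for f in gene.utr3_forms)
        size = hi - lo
        scores = rng.normal(0.0, 1.0, size=size)
        if gene_set[i] == "posterior":
            scores = scores + config.conservation_shift
        covered = rng.random(size) >= config.conservation_missing_fraction
        pos = np.arange(lo, hi)[covered]
        starts_all.append(pos)
        ends_all.append(pos + 1)
        scores_all.append(np.round(scores[covered], 3))
    chrom = next(iter(models.values())).chrom if models else "chr2L"
    data = {
        chrom: (
            np.concatenate(starts_all) if starts_all else np.array([], dtype=int),
            np.concatenate(ends_all) if ends_all else np.array([], dtype=int),
            np.concatenate(scores_all) if scores_all else np.array([]),
        )
    }
    return ConservationTrack(data)


def _plant_network(rng, gene_ids, gene_set, config):
    """Erdos-Renyi background over all genes, a planted excess of edges
    within the posterior set, and a few self-loops."""
    n = len(gene_ids)
    n_pairs = n * (n - 1) // 2
    n_bg = int(rng.binomial(n_pairs, config.ppi_background_p))
    bg_idx = rng.choice(n_pairs, size=n_bg, replace=False)
    edges = [_pair_from_index(int(k), n) for k in bg_idx]

    post = [i for i in range(n) if gene_set[i] == "posterior"]
    m = len(post)
    if m >= 2:
        m_pairs = m * (m - 1) // 2
        if config.ppi_excess_edges is not None:
            k_excess = min(config.ppi_excess_edges, m_pairs)
        else:
            # deterministic planted density: the effect size is a study
            # condition, not a random draw
            k_excess = int(round(m_pairs * config.ppi_within_p))
        if k_excess:
            idx = rng.choice(m_pairs, size=k_excess, replace=False)
            edges.extend((post[a], post[b])
                         for a, b in (_pair_from_index(int(k), m) for k in idx))

    n_loops = int(round(n * config.ppi_loop_rate))
    if n_loops:
        loop_nodes = rng.choice(n, size=n_loops, replace=False)
        edges.extend((int(v), int(v)) for v in loop_nodes)

    return InteractionNetwork((gene_ids[a], gene_ids[b]) for a, b in edges)


def _pair_from_index(k: int, n: int) -> tuple[int, int]:
    """Decode linear index k in [0, C(n,2)) to an (i, j) pair with i < j."""
    i = int(n - 2 - np.floor(np.sqrt(-8 * k + 4 * n * (n - 1) - 7) / 2.0 - 0.5))
    j = int(k + i + 1 - n * (n - 1) // 2 + (n - i) * (n - i - 1) // 2)
    return i, j


# ---------------------------------------------------------------------------
# writing / reading
# ---------------------------------------------------------------------------

COHORT_FILES = {
    "gene_models": "genes.gff3",
    "conservation": "conservation.bedgraph",
    "counts_3pseq": "counts_3pseq.tsv",
    "counts_rnaseq": "counts_rnaseq.tsv",
    "read_ends": "read_ends.tsv",
    "annotations": "annotations.tsv",
    "interactome": "interactome.tsv",
    "truth": "truth.tsv",
    "manifest": "manifest.json",
}


def write_cohort(cohort: SyntheticCohort, directory: str | Path, force: bool = False) -> dict[str, Path]:
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not force:
        raise FileExistsError(f"{directory} is not empty; pass force=True to overwrite")
    directory.mkdir(parents=True, exist_ok=True)
    paths = {key: directory / name for key, name in COHORT_FILES.items()}
    write_gene_models(cohort.gene_models, paths["gene_models"])
    write_conservation(cohort.conservation, paths["conservation"])
    write_counts(cohort.counts_3pseq, paths["counts_3pseq"])
    write_counts(cohort.counts_rnaseq, paths["counts_rnaseq"])
    write_read_ends(cohort.read_ends, paths["read_ends"])
    write_annotations(cohort.annotations, paths["annotations"])
    write_interactome(cohort.network, paths["interactome"])
    cohort.truth.sort_index().to_csv(paths["truth"], sep="\t", lineterminator="\n")
    manifest = {
        "seed": cohort.config.seed,
        "config": cohort.config.to_dict(),
        "config_hash": cohort.config.content_hash(),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("wrote cohort (%d genes) to %s", cohort.config.n_genes, directory)
    return paths


@dataclass
class CohortOnDisk:
    directory: Path
    gene_models: dict[str, GeneModel]
    conservation: ConservationTrack
    counts_3pseq: CountTable
    counts_rnaseq: CountTable
    read_ends: pd.DataFrame
    annotations: AnnotationTable
    network: InteractionNetwork
    truth: pd.DataFrame | None
    manifest: dict | None


def read_cohort(directory: str | Path) -> CohortOnDisk:
    """Load a written cohort back through the io_core readers."""
    d = Path(directory)
    truth_path = d / COHORT_FILES["truth"]
    manifest_path = d / COHORT_FILES["manifest"]
    return CohortOnDisk(
        directory=d,
        gene_models=read_gene_models(d / COHORT_FILES["gene_models"]),
        conservation=read_conservation(d / COHORT_FILES["conservation"]),
        counts_3pseq=read_counts(d / COHORT_FILES["counts_3pseq"]),
        counts_rnaseq=read_counts(d / COHORT_FILES["counts_rnaseq"]),
        read_ends=read_read_ends(d / COHORT_FILES["read_ends"]),
        annotations=read_annotations(d / COHORT_FILES["annotations"], cv.VOCABULARY),
        network=read_interactome(d / COHORT_FILES["interactome"]),
        truth=pd.read_csv(truth_path, sep="\t", index_col="gene_id") if truth_path.exists() else None,
        manifest=json.loads(manifest_path.read_text()) if manifest_path.exists() else None,
    )
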