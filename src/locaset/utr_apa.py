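"""3'UTR form usage, mean-weighted 3'UTR length, APA calling and
gene-architecture features.

3'-end tag reads (one tag per polyadenylated molecule) are assigned to
annotated 3'UTR forms when their mapped 3' end lies within ``end_window``
(default 200 nt) of a form's strand-aware annotated end.  Usage-weighted
("mean-weighted") 3'UTR length per stage is then

    L_bar = sum_i w_i * L_i / sum_i w_i

over forms with positive weight, and a gene is called as undergoing
alternative polyadenylation (APA) between two stages when the mean-weighted
lengths differ by at least ``apa_delta`` (default 200 nt, inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_core import ConservationTrack, GeneModel, UTRForm

logger = logging.getLogger("locaset")


@dataclass(frozen=True)
class APAConfig:
    end_window: int = 200   # nt, read end to annotated form end
    apa_delta: int = 200    # nt, mean-weighted length difference threshold
    one_sided_window: bool = False  # restrict window to one side of the end

    def __post_init__(self) -> None:
        if self.end_window <= 0 or self.apa_delta <= 0:
            raise ValueError("end_window and apa_delta must be positive")


@dataclass
class UTRUsageProfile:
    gene_id: str
    stage: str
    weights: dict[str, float]            # form_id -> assigned weight
    form_lengths: dict[str, int]         # form_id -> length (bp)
    unassigned_reads: int = 0

    @property
    def total_weight(self) -> float:
        return float(sum(self.weights.values()))


def assign_utr_forms(
    read_ends: Sequence[int],
    gene: GeneModel,
    cfg: APAConfig | None = None,
) -> UTRUsageProfile:
    """Assign read 3'-end positions to the gene's annotated 3'UTR forms.

    A read is assigned to the form whose strand-aware annotated end is
    nearest, provided that distance is <= ``end_window``; exact distance ties
    go to the shorter form (conservative toward proximal ends), then to the
    lexicographically smaller form id.  Reads outside the window of every
    form are counted as unassigned.
    """
    cfg = cfg or APAConfig()
    forms = gene.utr3_forms
    lengths = {f.form_id: f.length for f in forms}
    weights = {f.form_id: 0.0 for f in forms}
    if not forms:
        logger.warning("%s: no annotated 3'UTR forms; all reads unassigned", gene.gene_id)
        return UTRUsageProfile(gene.gene_id, "", weights, lengths, unassigned_reads=len(read_ends))
    # downstream-of-end sign convention for the optional one-sided window
    downstream_sign = 1 if gene.strand == "+" else -1
    unassigned = 0
    order = sorted(forms, key=lambda f: (f.length, f.form_id))
    for pos in read_ends:
        best: UTRForm | None = None
        best_d = cfg.end_window + 1
        for form in order:  # shorter-first ordering implements the tie rule
            d = pos - form.end_position
            if cfg.one_sided_window and d * downstream_sign < 0:
                continue
            d = abs(d)
            if d <= cfg.end_window and d < best_d:
                best, best_d = form, d
        if best is None:
            unassigned += 1
        else:
            weights[best.form_id] += 1.0
    return UTRUsageProfile(gene.gene_id, "", weights, lengths, unassigned_reads=unassigned)


def most_used_form(profile: UTRUsageProfile, gene: GeneModel) -> UTRForm:
    """The maximal-weight form; ties break by shorter length, then form id."""
    positive = {fid: w for fid, w in profile.weights.items() if w > 0}
    if not positive:
        raise ValueError(f"{profile.gene_id}: all form weights are zero")
    by_id = {f.form_id: f for f in gene.utr3_forms}
    best_id = min(positive, key=lambda fid: (-positive[fid], by_id[fid].length, fid))
    return by_id[best_id]


def mean_weighted_length(profile: UTRUsageProfile) -> float:
    """Usage-weighted mean of the form lengths with positive weight."""
    total = profile.total_weight
    if total <= 0:
        raise ValueError(f"{profile.gene_id}: zero total weight")
    return sum(w * profile.form_lengths[fid] for fid, w in profile.weights.items()) / total


@dataclass(frozen=True)
class APACall:
    gene_id: str
    decision: str            # "APA" or "no_call"
    delta: float | None      # mean-weighted length difference, stage B - A
    reason: str = ""


def call_apa(
    profile_a: UTRUsageProfile,
    profile_b: UTRUsageProfile,
    cfg: APAConfig | None = None,
) -> APACall:
    """Call APA between two stages when |L_bar_B - L_bar_A| >= apa_delta."""
    cfg = cfg or APAConfig()
    gene_id = profile_a.gene_id or profile_b.gene_id
    for prof, which in ((profile_a, "A"), (profile_b, "B")):
        if prof.total_weight <= 0:
            return APACall(gene_id, "no_call", None, reason=f"no assigned reads in stage {which}")
    delta = mean_weighted_length(profile_b) - mean_weighted_length(profile_a)
    decision = "APA" if abs(delta) >= cfg.apa_delta else "no_call"
    return APACall(gene_id, decision, delta)


@dataclass(frozen=True)
class ConservationSummary:
    median: float
    missing_fraction: float
    low_coverage: bool


def utr_conservation(
    form: UTRForm,
    chrom: str,
    track: ConservationTrack,
    low_coverage_threshold: float = 0.5,
) -> ConservationSummary:
    """Median per-base conservation over the form; uncovered bases are
    excluded from the median (never imputed), and a result whose missing
    fraction exceeds ``low_coverage_threshold`` is flagged."""
    scores = track.query(chrom, *form.interval)
    covered = scores[~np.isnan(scores)]
    if covered.size == 0:
        raise ValueError(f"{form.form_id}: no covered bases in conservation track")
    missing = 1.0 - covered.size / scores.size
    return ConservationSummary(
        median=float(np.median(covered)),
        missing_fraction=missing,
        low_coverage=missing > low_coverage_threshold,
    )


def extract_gene_architecture(gene: GeneModel) -> dict[str, float]:
    """The eight gene-architecture features: gene length, exon count and
    total length, intron count and total length, 5'UTR length, and exon and
    intron proportions of gene length."""
    if not gene.exons:
        raise ValueError(f"{gene.gene_id}: gene without exons")
    exon_len = sum(e - s for s, e in gene.exons)
    introns = gene.introns
    intron_len = sum(e - s for s, e in introns)
    utr5_len = sum(e - s for s, e in gene.utr5)
    if utr5_len == 0:
        logger.debug("%s: no annotated 5'UTR", gene.gene_id)
    return {
        "gene_length": float(gene.length),
        "exon_count": float(len(gene.exons)),
        "exon_length": float(exon_len),
        "intron_count": float(len(introns)),
        "intron_length": float(intron_len),
        "utr5_length": float(utr5_len),
        "exon_proportion": exon_len / gene.length,
        "intron_proportion": intron_len / gene.length,
    }
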