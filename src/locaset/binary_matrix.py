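"""The per-gene binary matrix: controlled-vocabulary term counts, broad
expression class, subclasses, probe reliability, and pn-status.

Broad classes follow the screen's rules: a probe showing no signal at every
stage is ``no_signal``; homogeneous signal at every annotated stage is
``ubiquitous``; any specific term at any stage makes it ``specific``.  Genes
probed more than once with conflicting broad classes are ``not_reliable``,
with the conflict recorded as either no-signal-vs-other (a probe presumed
non-functional) or ubiquitous-vs-specific (probes possibly isoform
specific).

pn-status compares FISH detection with sequencing detection at fixed
normalized-count noise thresholds (70 for RNAseq, 50 for 3Pseq, derived
from the normalized count distributions).  "Expressed above cut-off" means
the maximum normalized count across sampled stages reaches the cutoff in at
least one assay; "below" means below in both assays, so the four statuses
partition the (above/below x signal/no-signal) grid:

    above + signal    -> TP        above + no_signal -> FP
    below + signal    -> FN        below + no_signal -> TN
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import vocabulary as cv
from .io_core import AnnotationTable, CountTable, ValidationError

logger = logging.getLogger("locaset")

BROAD_CLASSES = ("no_signal", "ubiquitous", "specific")
_CLASS_RANK = {c: i for i, c in enumerate(BROAD_CLASSES)}


@dataclass(frozen=True)
class NoiseThresholds:
    rnaseq_cutoff: float = 70.0
    threeP_cutoff: float = 50.0

    def __post_init__(self) -> None:
        if self.rnaseq_cutoff <= 0 or self.threeP_cutoff <= 0:
            raise ValueError("noise thresholds must be positive")

    def cutoff_for(self, assay: str) -> float:
        key = assay.lower()
        if key == "rnaseq":
            return self.rnaseq_cutoff
        if key in ("3pseq", "threep", "threepseq"):
            return self.threeP_cutoff
        raise KeyError(f"unknown assay {assay!r}")


def classify_stage(terms: set[str]) -> str:
    """Broad class of a single annotated stage."""
    if not terms:
        raise ValueError("stage without annotation terms")
    if any(cv.is_specific(t) for t in terms):
        return "specific"
    if cv.UBIQUITOUS in terms:
        return "ubiquitous"
    return "no_signal"


def assign_broad_class(stage_terms: Mapping[str, set[str]]) -> str:
    """Broad class of one probe given its per-stage CV terms."""
    if not stage_terms:
        raise ValueError("probe with no annotated stages")
    stage_classes = {stage: classify_stage(terms) for stage, terms in stage_terms.items()}
    if any(c == "specific" for c in stage_classes.values()):
        return "specific"
    if all(c == "no_signal" for c in stage_classes.values()):
        return "no_signal"
    return "ubiquitous"


@dataclass(frozen=True)
class ReliabilityCall:
    reliability: str                 # "reliable" | "not_reliable"
    conflict_type: str | None = None  # "no_signal_vs_other" | "ubiquitous_vs_specific"


def assess_reliability(probe_classes: Mapping[str, str]) -> ReliabilityCall:
    """Conflicting broad classes across a gene's probes mark it unreliable."""
    if not probe_classes:
        raise ValueError("gene with no probes")
    classes = set(probe_classes.values())
    if len(classes) <= 1:
        return ReliabilityCall("reliable")
    if "no_signal" in classes:
        return ReliabilityCall("not_reliable", "no_signal_vs_other")
    return ReliabilityCall("not_reliable", "ubiquitous_vs_specific")


def assign_pn_status(
    max_normalized: Mapping[str, float],
    broad_class: str,
    thresholds: NoiseThresholds | None = None,
) -> str:
    """TP/FP/TN/FN from sequencing detection vs FISH broad class.

    ``max_normalized`` maps assay name -> maximum normalized count over the
    sampled stages; detection is inclusive (>= cutoff) in at least one assay.
    """
    thresholds = thresholds or NoiseThresholds()
    if not max_normalized:
        raise ValueError("no sequencing data for either assay")
    above = any(
        value >= thresholds.cutoff_for(assay) for assay, value in max_normalized.items()
    )
    signal = broad_class != "no_signal"
    if above:
        return "TP" if signal else "FP"
    return "FN" if signal else "TN"


@dataclass
class BinaryMatrixRow:
    gene_id: str
    cv_counts: dict[str, int]
    broad_class: str
    subclasses: frozenset[str]
    reliability: str
    conflict_type: str | None
    pn_status: str
    max_normalized: dict[str, float]
    mean_weighted_lengths: dict[str, float] = field(default_factory=dict)


def build_binary_matrix(
    annotations: AnnotationTable,
    count_tables: Mapping[str, CountTable],
    mean_weighted_lengths: pd.DataFrame | None = None,
    thresholds: NoiseThresholds | None = None,
) -> list[BinaryMatrixRow]:
    """Fuse annotations, normalized expression and 3'UTR usage into one row
    per annotated gene.

    Genes present in the count tables but never probed are excluded (and
    logged).  A gene annotated by several probes sums its CV term values, so
    counts above 1 only arise from multiple probes.  The broad class of an
    unreliable gene is the highest-severity probe class (specific >
    ubiquitous > no_signal), with the conflict retained in its own columns.
    """
    thresholds = thresholds or NoiseThresholds()
    for assay, table in count_tables.items():
        if table.normalized is None:
            raise ValueError(f"{assay}: normalize counts before building the matrix")

    probed = set(annotations.records["gene_id"])
    for assay, table in count_tables.items():
        skipped = sorted(set(table.genes) - probed)
        if skipped:
            logger.info("%s: %d genes with counts but never probed are excluded",
                        assay, len(skipped))

    rows: list[BinaryMatrixRow] = []
    seen: set[str] = set()
    grouped = annotations.records.groupby("gene_id", sort=True)
    for gene_id, sub in grouped:
        if gene_id in seen:
            raise ValidationError(f"duplicate gene rows for {gene_id}")
        seen.add(gene_id)

        # per-probe stage->terms, broad class per probe
        probe_classes: dict[str, str] = {}
        cv_counts: dict[str, int] = {}
        for probe_id, probe_sub in sub.groupby("probe_id", sort=True):
            stage_terms: dict[str, set[str]] = {}
            for _, rec in probe_sub.iterrows():
                stage_terms.setdefault(rec["stage"], set()).add(rec["term"])
            probe_classes[probe_id] = assign_broad_class(stage_terms)
            for term in {t for terms in stage_terms.values() for t in terms}:
                cv_counts[term] = cv_counts.get(term, 0) + 1

        rel = assess_reliability(probe_classes)
        broad = max(probe_classes.values(), key=_CLASS_RANK.__getitem__)
        subclasses = frozenset(
            cv.subclass_of(t) for t in cv_counts if cv.is_specific(t)
        ) if broad == "specific" else frozenset()

        max_norm = {
            assay: float(table.normalized.loc[gene_id].max())
            for assay, table in count_tables.items()
            if gene_id in table.normalized.index
        }
        pn = assign_pn_status(max_norm, broad, thresholds) if max_norm else "NA"

        mwl: dict[str, float] = {}
        if mean_weighted_lengths is not None and gene_id in mean_weighted_lengths.index:
            mwl = {
                stage: float(v)
                for stage, v in mean_weighted_lengths.loc[gene_id].items()
                if pd.notna(v)
            }

        rows.append(BinaryMatrixRow(
            gene_id=gene_id,
            cv_counts=cv_counts,
            broad_class=broad,
            subclasses=subclasses,
            reliability=rel.reliability,
            conflict_type=rel.conflict_type,
            pn_status=pn,
            max_normalized=max_norm,
            mean_weighted_lengths=mwl,
        ))
    return rows


# ---------------------------------------------------------------------------
# flat-file dump
# ---------------------------------------------------------------------------


def matrix_to_frame(rows: Sequence[BinaryMatrixRow]) -> pd.DataFrame:
    terms = sorted(cv.VOCABULARY)
    records = []
    for row in rows:
        rec: dict[str, object] = {"gene_id": row.gene_id}
        for term in terms:
            rec[f"cv:{term}"] = row.cv_counts.get(term, 0)
        rec["broad_class"] = row.broad_class
        rec["subclasses"] = ",".join(sorted(row.subclasses)) or "-"
        rec["reliability"] = row.reliability
        rec["conflict_type"] = row.conflict_type or "-"
        rec["pn_status"] = row.pn_status
        for assay in sorted(row.max_normalized):
            rec[f"max_norm:{assay}"] = round(row.max_normalized[assay], 4)
        for stage in sorted(row.mean_weighted_lengths):
            rec[f"mwl:{stage}"] = round(row.mean_weighted_lengths[stage], 4)
        records.append(rec)
    return pd.DataFrame.from_records(records).set_index("gene_id").sort_index()


def write_matrix(rows: Sequence[BinaryMatrixRow], path: str | Path) -> None:
    matrix_to_frame(rows).to_csv(path, sep="\t", lineterminator="\n")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
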