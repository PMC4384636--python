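"""Readers, writers and shared domain types for the screen's six input families.

All genomic coordinates are kept internally as 0-based half-open intervals.
GFF3 (1-based, closed) and bedGraph (0-based, half-open) are converted at the
boundary, so every other module does interval arithmetic in one convention.

Identifier space is FlyBase-style opaque strings; nothing is coerced to int.
All readers validate eagerly and reject malformed or partial files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("locaset")

Interval = tuple[int, int]  # 0-based half-open


class ParseError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """A file parses but violates a semantic contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UTRForm:
    """One annotated 3'UTR terminus of a gene.

    ``end_position`` is the strand-aware 3'-most coordinate bound: the
    half-open end of the interval on the + strand, the start on the - strand.
    """

    form_id: str
    interval: Interval
    strand: str

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]

    @property
    def end_position(self) -> int:
        return self.interval[1] if self.strand == "+" else self.interval[0]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    gene_span: Interval
    exons: tuple[Interval, ...]
    utr5: tuple[Interval, ...] = ()
    utr3_forms: tuple[UTRForm, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be '+' or '-'")
        exons = tuple(sorted(self.exons))
        for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
            if s1 < e0:
                raise ValidationError(f"{self.gene_id}: overlapping exons {((s0, e0), (s1, e1))}")
        object.__setattr__(self, "exons", exons)
        lo, hi = self.gene_span
        for form in self.utr3_forms:
            if form.interval[0] < lo or form.interval[1] > hi:
                raise ValidationError(
                    f"{self.gene_id}: 3'UTR form {form.form_id} {form.interval} "
                    f"outside gene span {self.gene_span}"
                )

    @property
    def introns(self) -> tuple[Interval, ...]:
        """Gaps between consecutive exons of the chosen transcript structure."""
        return tuple(
            (e0[1], e1[0]) for e0, e1 in zip(self.exons, self.exons[1:]) if e1[0] > e0[1]
        )

    @property
    def length(self) -> int:
        return self.gene_span[1] - self.gene_span[0]


class ConservationTrack:
    """Per-base conservation scores (phyloP-like, may be negative).

    Backed by sorted non-overlapping scored intervals per chromosome; a query
    over an interval returns exactly one float per base, NaN where the track
    has no score (missing is never silently 0).
    """

    def __init__(self, intervals: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # chrom -> (starts, ends, scores), sorted by start, non-overlapping
        self._data = {}
        for chrom, (starts, ends, scores) in intervals.items():
            order = np.argsort(starts, kind="stable")
            starts, ends, scores = starts[order], ends[order], scores[order]
            if np.any(ends[:-1] > starts[1:]):
                i = int(np.argmax(ends[:-1] > starts[1:]))
                raise ValidationError(
                    f"overlapping conservation intervals on {chrom} near "
                    f"[{starts[i]},{ends[i]}) and [{starts[i + 1]},{ends[i + 1]})"
                )
            self._data[chrom] = (starts, ends, scores)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._data)

    def query(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Scores for every base of [start, end); NaN marks uncovered bases."""
        if end < start:
            raise ValueError(f"negative interval [{start},{end})")
        out = np.full(end - start, np.nan)
        if chrom not in self._data:
            return out
        starts, ends, scores = self._data[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for s, e, sc in zip(starts[lo:hi], ends[lo:hi], scores[lo:hi]):
            a, b = max(s, start), min(e, end)
            if a < b:
                out[a - start : b - start] = sc
        return out


@dataclass
class CountTable:
    """Raw (and optionally normalized) per-gene per-stage counts for one assay."""

    assay: str
    stages: tuple[str, ...]
    counts: pd.DataFrame  # genes x stages, integer
    normalized: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(set(self.stages)) != len(self.stages):
            raise ValidationError(f"{self.assay}: duplicate stage labels")
        if list(self.counts.columns) != list(self.stages):
            raise ValidationError(f"{self.assay}: count columns do not match stages")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError(f"{self.assay}: negative raw counts")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index


@dataclass
class AnnotationTable:
    """Long-form controlled-vocabulary FISH annotations: one row per
    (gene, probe, stage, term)."""

    records: pd.DataFrame  # columns gene_id, probe_id, stage, term
    vocabulary: frozenset[str]

    COLUMNS = ("gene_id", "probe_id", "stage", "term")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.records.columns]
        if missing:
            raise ValidationError(f"annotation table missing columns {missing}")
        unknown = set(self.records["term"]) - self.vocabulary
        if unknown:
            raise ValidationError(
                "annotation terms outside the controlled vocabulary: "
                + ", ".join(sorted(unknown))
            )

    def terms_for(self, gene_id: str) -> pd.DataFrame:
        return self.records[self.records["gene_id"] == gene_id]


class InteractionNetwork:
    """Undirected PPI graph; self-loops are stored but flagged and excluded
    from within-group edge counts (the screen's "minus loops" rule)."""

    def __init__(self, edges: Iterable[tuple[str, str]]):
        self.graph = nx.Graph()
        for a, b in edges:
            self.graph.add_edge(a, b)
        self.loops = sorted(a for a, b in nx.selfloop_edges(self.graph) for a in (a,))

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def has_interaction(self, gene: str) -> bool:
        """Does this gene participate in at least one interaction?"""
        return gene in self.graph and self.graph.degree(gene) > 0

    def induced_edge_count(self, group: Iterable[str], exclude_loops: bool = True) -> int:
        sub = self.graph.subgraph(set(group))
        n = sub.number_of_edges()
        if exclude_loops:
            n -= nx.number_of_selfloops(sub)
        return n


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF_UTR3_TYPES = ("three_prime_UTR", "three_prime_utr")
_GFF_UTR5_TYPES = ("five_prime_UTR", "five_prime_utr")


def _prevalidate_gff3(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated fields")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 1 or end < start:
                raise ParseError(f"{path}:{lineno}: invalid coordinate range {start}-{end}")


def read_gene_models(path: str | Path, intron_policy: str = "longest") -> dict[str, GeneModel]:
    """Parse gene/mRNA/exon/UTR features from a GFF3 file into GeneModels.

    When a gene has several transcripts, exonic features use the union of all
    exons while the intron structure follows ``intron_policy``:
    ``"longest"`` (default) takes the transcript with the longest genomic
    span, ``"union"`` uses the exon union of all transcripts.
    """
    path = Path(path)
    _prevalidate_gff3(path)
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        gene_id = gene.id
        span = (gene.start - 1, gene.end)
        transcripts = list(db.children(gene, featuretype="mRNA"))
        exon_union = sorted(
            {(ex.start - 1, ex.end) for ex in db.children(gene, featuretype="exon")}
        )
        if transcripts and intron_policy == "longest":
            chosen = max(transcripts, key=lambda t: (t.end - t.start, t.id))
            structure = sorted(
                (ex.start - 1, ex.end) for ex in db.children(chosen, featuretype="exon")
            )
        else:
            structure = _merge_intervals(exon_union)
        utr5 = tuple(
            sorted((u.start - 1, u.end) for t in _GFF_UTR5_TYPES for u in db.children(gene, featuretype=t))
        )
        utr3 = []
        for t in _GFF_UTR3_TYPES:
            for u in db.children(gene, featuretype=t):
                utr3.append(UTRForm(form_id=u.id, interval=(u.start - 1, u.end), strand=gene.strand))
        utr3.sort(key=lambda f: (f.interval, f.form_id))
        models[gene_id] = GeneModel(
            gene_id=gene_id,
            chrom=gene.seqid,
            strand=gene.strand,
            gene_span=span,
            exons=tuple(structure),
            utr5=utr5,
            utr3_forms=tuple(utr3),
        )
    logger.info("read %d gene models from %s", len(models), path)
    return models


def _merge_intervals(intervals: Sequence[Interval]) -> list[Interval]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def write_gene_models(models: Mapping[str, GeneModel], path: str | Path) -> None:
    """Emit a canonical GFF3 (genes sorted by chrom, start, id)."""
    lines = ["##gff-version 3"]
    for gene in sorted(models.values(), key=lambda g: (g.chrom, g.gene_span, g.gene_id)):
        s, e = gene.gene_span
        base = [gene.chrom, "locaset", None, None, None, ".", gene.strand, ".", None]

        def row(ftype: str, iv: Interval, attrs: str) -> str:
            f = list(base)
            f[2], f[3], f[4] = ftype, str(iv[0] + 1), str(iv[1])
            f[8] = attrs
            return "\t".join(f)

        lines.append(row("gene", gene.gene_span, f"ID={gene.gene_id}"))
        tid = f"{gene.gene_id}.t1"
        lines.append(row("mRNA", gene.gene_span, f"ID={tid};Parent={gene.gene_id}"))
        for i, ex in enumerate(gene.exons, 1):
            lines.append(row("exon", ex, f"ID={tid}.exon{i};Parent={tid}"))
        for i, u in enumerate(gene.utr5, 1):
            lines.append(row("five_prime_UTR", u, f"ID={tid}.utr5_{i};Parent={tid}"))
        for form in gene.utr3_forms:
            lines.append(row("three_prime_UTR", form.interval, f"ID={form.form_id};Parent={tid}"))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# bedGraph conservation
# ---------------------------------------------------------------------------


def read_conservation(path: str | Path) -> ConservationTrack:
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "score"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "score": float},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: not a valid bedGraph: {exc}") from exc
    if ((df["end"] - df["start"]) <= 0).any() or (df["start"] < 0).any():
        bad = df[(df["end"] - df["start"] <= 0) | (df["start"] < 0)].index[0]
        raise ParseError(f"{path}: non-positive or negative interval at data row {bad}")
    data = {
        chrom: (
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
            sub["score"].to_numpy(),
        )
        for chrom, sub in df.groupby("chrom", sort=True)
    }
    return ConservationTrack(data)


def write_conservation(track: ConservationTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            starts, ends, scores = track._data[chrom]
            for s, e, sc in zip(starts, ends, scores):
                fh.write(f"{chrom}\t{s}\t{e}\t{sc:g}\n")


# ---------------------------------------------------------------------------
# TSV tables: counts, annotations, interactome, read ends
# ---------------------------------------------------------------------------


def read_counts(path: str | Path) -> CountTable:
    """Counts TSV: a ``#assay=<name>`` header line, then gene_id + one column
    per stage of raw integer counts."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    if not first.startswith("#assay="):
        raise ParseError(f"{path}: missing '#assay=' header line")
    assay = first.split("=", 1)[1]
    df = pd.read_csv(path, sep="\t", skiprows=1, index_col="gene_id")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise ValidationError(f"{path}: non-integer raw counts")
        df = df.astype(np.int64)
    if df.index.duplicated().any():
        raise ValidationError(f"{path}: duplicate gene rows")
    return CountTable(assay=assay, stages=tuple(df.columns), counts=df)


def write_counts(table: CountTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#assay={table.assay}\n")
        table.counts.sort_index().to_csv(fh, sep="\t", index_label="gene_id", lineterminator="\n")


def read_annotations(path: str | Path, vocabulary: Iterable[str]) -> AnnotationTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return AnnotationTable(records=df, vocabulary=frozenset(vocabulary))


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    cols = list(AnnotationTable.COLUMNS)
    table.records[cols].sort_values(cols, kind="stable").to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_interactome(path: str | Path) -> InteractionNetwork:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("protein_a", "protein_b"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col}")
    net = InteractionNetwork(zip(df["protein_a"], df["protein_b"]))
    logger.info(
        "read interactome: %d nodes, %d edges (%d loops flagged)",
        len(net.nodes), net.n_edges, len(net.loops),
    )
    return net


def write_interactome(net: InteractionNetwork, path: str | Path) -> None:
    rows = sorted(tuple(sorted((a, b))) for a, b in net.graph.edges)
    pd.DataFrame(rows, columns=["protein_a", "protein_b"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_read_ends(path: str | Path) -> pd.DataFrame:
    """BED-like TSV of 3Pseq read 3'-end positions:
    columns chrom, position, strand, gene_id, stage."""
    df = pd.read_csv(
        path, sep="\t",
        dtype={"chrom": str, "position": np.int64, "strand": str, "gene_id": str, "stage": str},
    )
    required = {"chrom", "position", "strand", "gene_id", "stage"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_read_ends(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["chrom", "position", "strand", "gene_id", "stage"]
    df[cols].sort_values(cols, kind="stable").to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )
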