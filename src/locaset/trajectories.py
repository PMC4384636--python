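"""Localization trajectories: polarity categories per stage, trajectory
encoding, clustering, and cross-cell-type overlap.

Localization destinations are grouped by microtubule polarity — "minus"
where microtubule minus ends are enriched (oocyte enrichment early,
anterior, apical), "plus" near plus ends (posterior, pole plasm, basal) —
so that localization can be compared across stages and cell types.  Each
gene's trajectory is the ordered tuple of categories over a stage axis;
unprobed stages carry "absent", which is excluded (not counted as a
mismatch) from the Hamming distance used for clustering.
"""

from __future__ import annotations

import importlib.resources
import itertools
import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger("locaset")

MINUS, PLUS, UBIQ, ABSENT = "minus", "plus", "ubiquitous", "absent"
CATEGORIES = (MINUS, PLUS, UBIQ, ABSENT)

OVARY_STAGES = ("st2_7", "st8", "st9", "st10")
EMBRYO_STAGES = ("emb1_3", "emb4_5")
DEFAULT_STAGE_AXIS = OVARY_STAGES


class UnmappedTermError(KeyError):
    """A specific localization term has no entry in the category map."""


class CategoryMap:
    """Mapping (CV term, cell-type context) -> polarity category.

    The shipped default covers the ovary germline and epithelial contexts
    plus the embryo; pole-cell annotation is excluded from the plus category
    by construction, and terms with no polarity meaning are listed as
    explicitly unmapped (they yield no category but are not errors).
    """

    def __init__(self, mappings: Mapping[tuple[str, str], str],
                 excluded: Iterable[str], unmapped: Iterable[str]):
        self._map = dict(mappings)
        self.excluded = frozenset(excluded)
        self.unmapped = frozenset(unmapped)
        for (term, _), cat in self._map.items():
            if term in self.excluded and cat == PLUS:
                raise ValueError(f"excluded term {term!r} may not map to plus")

    @classmethod
    def default(cls) -> "CategoryMap":
        text = (importlib.resources.files("locaset") / "data" / "category_map.yaml").read_text()
        return cls.from_yaml_text(text)

    @classmethod
    def from_yaml(cls, path: str) -> "CategoryMap":
        with open(path) as fh:
            return cls.from_yaml_text(fh.read())

    @classmethod
    def from_yaml_text(cls, text: str) -> "CategoryMap":
        doc = yaml.safe_load(text)
        mappings = {
            (m["term"], m["context"]): m["category"] for m in doc.get("mappings", [])
        }
        return cls(mappings, doc.get("excluded", []), doc.get("unmapped", []))

    def lookup(self, term: str, context: str) -> str | None:
        """Category for a specific term, None if polarity-free here.

        A term mapped only in another context carries no polarity in this
        one (apical enrichment means nothing in the germline); a term the
        map has never heard of raises, forcing explicit map maintenance.
        """
        if term in self.excluded or term in self.unmapped:
            return None
        if (term, context) in self._map:
            return self._map[(term, context)]
        if any(t == term for t, _ in self._map):
            return None
        raise UnmappedTermError(
            f"term {term!r} has no category mapping in context {context!r}; "
            "add it to the category map or its unmapped list"
        )


@dataclass(frozen=True)
class CategoryCall:
    category: str
    conflict: bool = False
    categories_seen: frozenset[str] = frozenset()


def assign_polarity_category(
    terms: Iterable[str],
    context: str,
    cmap: CategoryMap | None = None,
) -> CategoryCall:
    """Polarity category of one (gene, stage) annotation term set.

    Specific mapped terms vote; simultaneous minus and plus terms are
    recorded as a conflict resolved with minus precedence (de-novo minus
    localization never arises late, which a plus-precedence rule would
    fabricate).  With no polar term, a ubiquitous term yields "ubiquitous";
    no signal or nothing annotated yields "absent".
    """
    from . import vocabulary as cv

    cmap = cmap or CategoryMap.default()
    terms = set(terms)
    cats = set()
    for term in terms:
        if cv.is_specific(term):
            cat = cmap.lookup(term, context)
            if cat is not None:
                cats.add(cat)
    if MINUS in cats and PLUS in cats:
        return CategoryCall(MINUS, conflict=True, categories_seen=frozenset(cats))
    if MINUS in cats:
        return CategoryCall(MINUS, categories_seen=frozenset(cats))
    if PLUS in cats:
        return CategoryCall(PLUS, categories_seen=frozenset(cats))
    if cv.UBIQUITOUS in terms or (terms - {cv.NO_SIGNAL}):
        # ubiquitous signal, or specific-but-polarity-free terms: the mRNA is
        # present without polar enrichment
        return CategoryCall(UBIQ)
    return CategoryCall(ABSENT)


@dataclass(frozen=True)
class TrajectoryCode:
    gene_id: str
    stages: tuple[str, ...]
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.categories) != len(self.stages):
            raise ValueError(f"{self.gene_id}: trajectory length != stage axis length")


def encode_trajectory(
    gene_id: str,
    stage_terms: Mapping[str, Iterable[str]],
    context: str = "germline",
    cmap: CategoryMap | None = None,
    stage_axis: Sequence[str] = DEFAULT_STAGE_AXIS,
) -> TrajectoryCode:
    """One polarity category per stage of the axis; unprobed stages are
    absent (never ubiquitous)."""
    cmap = cmap or CategoryMap.default()
    cats = []
    for stage in stage_axis:
        if stage in stage_terms:
            cats.append(assign_polarity_category(stage_terms[stage], context, cmap).category)
        else:
            cats.append(ABSENT)
    return TrajectoryCode(gene_id, tuple(stage_axis), tuple(cats))


def hamming_distance(a: TrajectoryCode, b: TrajectoryCode) -> float:
    """Fraction of mismatching stages among stages where both codes are
    non-absent; 1.0 when no stage is comparable."""
    pairs = [
        (x, y) for x, y in zip(a.categories, b.categories)
        if x != ABSENT and y != ABSENT
    ]
    if not pairs:
        return 1.0
    return sum(x != y for x, y in pairs) / len(pairs)


ARCHETYPES = ("stay_minus", "minus_to_ubiquitous", "minus_to_plus",
              "ubiquitous_to_plus", "stay_ubiquitous", "other")


def classify_archetype(code: TrajectoryCode) -> str:
    """Named trajectory archetype from first and last non-absent categories."""
    present = [c for c in code.categories if c != ABSENT]
    if not present:
        return "other"
    first, last = present[0], present[-1]
    if first == MINUS and last == MINUS:
        return "stay_minus"
    if first == MINUS and last == UBIQ:
        return "minus_to_ubiquitous"
    if first == MINUS and last == PLUS:
        return "minus_to_plus"
    if first == UBIQ and last == PLUS:
        return "ubiquitous_to_plus"
    if first == UBIQ and last == UBIQ:
        return "stay_ubiquitous"
    return "other"


@dataclass
class ClusteringResult:
    codes: list[TrajectoryCode]          # canonical order used for clustering
    labels: np.ndarray                   # cluster id per code (1..n_clusters)
    linkage: np.ndarray
    cluster_archetypes: dict[int, str]   # cluster id -> majority archetype

    def label_of(self, gene_id: str) -> int:
        for code, lab in zip(self.codes, self.labels):
            if code.gene_id == gene_id:
                return int(lab)
        raise KeyError(gene_id)


def cluster_trajectories(
    codes: Sequence[TrajectoryCode],
    n_clusters: int | None = None,
    distance_threshold: float = 0.5,
) -> ClusteringResult:
    """Average-linkage agglomerative clustering of trajectory codes on the
    absent-aware Hamming distance.

    Codes are first put in a canonical order (by category string, then gene
    id), which makes memberships invariant to input ordering despite the
    heavy distance ties categorical codes produce.  Clusters are cut at
    ``n_clusters`` when given, else at ``distance_threshold``.
    """
    if len(codes) < 2:
        raise ValueError("need at least two trajectory codes")
    ordered = sorted(codes, key=lambda c: (c.categories, c.gene_id))
    n = len(ordered)
    dist = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = hamming_distance(ordered[i], ordered[j])
        dist[i, j] = dist[j, i] = d
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    if n_clusters is not None:
        labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    else:
        labels = hierarchy.fcluster(Z, t=distance_threshold, criterion="distance")
    archetypes: dict[int, str] = {}
    for lab in sorted(set(labels)):
        members = [classify_archetype(c) for c, l in zip(ordered, labels) if l == lab]
        archetypes[int(lab)] = Counter(members).most_common(1)[0][0]
    return ClusteringResult(list(ordered), labels, Z, archetypes)


def per_stage_category_counts(codes: Sequence[TrajectoryCode]) -> dict[str, Counter]:
    """How many genes fall in each polarity category at each stage."""
    if not codes:
        return {}
    axis = codes[0].stages
    out = {stage: Counter() for stage in axis}
    for code in codes:
        for stage, cat in zip(code.stages, code.categories):
            out[stage][cat] += 1
    return out


@dataclass(frozen=True)
class OverlapCounts:
    celltypes: tuple[str, ...]
    universe_size: int
    by_k: dict[int, int]                  # localized in exactly k cell types
    region_counts: dict[frozenset, int]   # exact Venn region -> count
    minus_consistent: int | None = None


def cross_celltype_overlap(
    localized: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    minus_sets: Mapping[str, Iterable[str]] | None = None,
) -> OverlapCounts:
    """Exact Venn counts of localized genes across cell types, restricted to
    genes assayed in every context; optionally the count of genes whose
    localization is minus-category in every context."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe: no gene probed in all contexts")
    celltypes = tuple(sorted(localized))
    if len(celltypes) < 2:
        raise ValueError("need at least two cell-type sets")
    sets = {ct: set(localized[ct]) & universe for ct in celltypes}
    union = set().union(*sets.values())
    region_counts: dict[frozenset, int] = {}
    by_k: dict[int, int] = {k: 0 for k in range(1, len(celltypes) + 1)}
    for gene in union:
        members = frozenset(ct for ct in celltypes if gene in sets[ct])
        region_counts[members] = region_counts.get(members, 0) + 1
        by_k[len(members)] += 1
    minus_consistent = None
    if minus_sets is not None:
        minus_all = universe.intersection(*(set(minus_sets[ct]) for ct in celltypes))
        minus_consistent = len(minus_all)
    return OverlapCounts(celltypes, len(universe), by_k, region_counts, minus_consistent)
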