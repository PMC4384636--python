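import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from locaset import trajectories as tj
from locaset.trajectories import (
    CategoryMap,
    TrajectoryCode,
    UnmappedTermError,
    assign_polarity_category,
    classify_archetype,
    cluster_trajectories,
    cross_celltype_overlap,
    encode_trajectory,
    hamming_distance,
)


class TestCategoryAssignment:
    def test_oocyte_enrichment_is_minus_in_germline(self):
        call = assign_polarity_category({"oocyte_enrichment"}, "germline")
        assert call.category == tj.MINUS

    def test_pole_plasm_plus_but_pole_cell_excluded(self):
        assert assign_polarity_category({"pole_plasm"}, "embryo").category == tj.PLUS
        # pole-cell is cell-specific expression, not subcellular localization
        assert assign_polarity_category({"pole_cell"}, "embryo").category == tj.UBIQ

    def test_ubiquitous_term_gives_ubiquitous(self):
        assert assign_polarity_category({"ubiquitous"}, "germline").category == tj.UBIQ

    def test_no_signal_gives_absent(self):
        assert assign_polarity_category({"no_signal"}, "germline").category == tj.ABSENT

    def test_minus_plus_conflict_resolved_with_minus_precedence(self):
        call = assign_polarity_category(
            {"anterior_enrichment", "posterior_enrichment"}, "germline")
        assert call.category == tj.MINUS
        assert call.conflict
        assert call.categories_seen == frozenset({tj.MINUS, tj.PLUS})

    def test_unknown_term_raises(self):
        cmap = CategoryMap.default()
        with pytest.raises(UnmappedTermError):
            cmap.lookup("made_up_term", "germline")

    def test_cross_context_term_is_polarity_free(self):
        # apical means minus only in epithelial/embryo contexts
        cmap = CategoryMap.default()
        assert cmap.lookup("apical_enrichment", "germline") is None
        assert cmap.lookup("apical_enrichment", "epithelial") == tj.MINUS


class TestEncoding:
    def test_posterior_switcher_minus_to_plus(self):
        # early oocyte enrichment then posterior localization
        terms = {"st2_7": {"oocyte_enrichment"}, "st8": {"ubiquitous"},
                 "st9": {"posterior_enrichment"}, "st10": {"posterior_enrichment"}}
        code = encode_trajectory("znt35c_like", terms)
        assert code.categories == (tj.MINUS, tj.UBIQ, tj.PLUS, tj.PLUS)
        assert classify_archetype(code) == "minus_to_plus"

    def test_release_to_ubiquitous(self):
        terms = {"st2_7": {"oocyte_enrichment"}, "st8": {"ubiquitous"},
                 "st9": {"ubiquitous"}, "st10": {"ubiquitous"}}
        code = encode_trajectory("exu_like", terms)
        assert code.categories == (tj.MINUS, tj.UBIQ, tj.UBIQ, tj.UBIQ)
        assert classify_archetype(code) == "minus_to_ubiquitous"

    def test_de_novo_posterior_from_ubiquitous(self):
        terms = {"st2_7": {"ubiquitous"}, "st8": {"ubiquitous"},
                 "st9": {"ubiquitous"}, "st10": {"posterior_enrichment"}}
        code = encode_trajectory("aret_like", terms)
        assert classify_archetype(code) == "ubiquitous_to_plus"

    def test_unprobed_stage_is_absent_not_ubiquitous(self):
        code = encode_trajectory("g", {"st9": {"posterior_enrichment"}})
        assert code.categories == (tj.ABSENT, tj.ABSENT, tj.PLUS, tj.ABSENT)


class TestHammingAndClustering:
    @staticmethod
    def _code(gid, cats):
        return TrajectoryCode(gid, ("s1", "s2", "s3", "s4", "s5")[: len(cats)], tuple(cats))

    def test_identical_codes_distance_zero(self):
        a = self._code("a", [tj.MINUS] * 5)
        assert hamming_distance(a, a) == 0.0

    def test_one_mismatch_of_five(self):
        a = self._code("a", [tj.MINUS] * 5)
        b = self._code("b", [tj.MINUS] * 4 + [tj.PLUS])
        assert hamming_distance(a, b) == pytest.approx(1 / 5)

    def test_absent_positions_excluded(self):
        a = self._code("a", [tj.MINUS, tj.ABSENT, tj.PLUS])
        b = self._code("b", [tj.MINUS, tj.UBIQ, tj.PLUS])
        assert hamming_distance(a, b) == 0.0

    def test_no_comparable_positions_max_distance(self):
        a = self._code("a", [tj.ABSENT, tj.MINUS])
        b = self._code("b", [tj.PLUS, tj.ABSENT])
        assert hamming_distance(a, b) == 1.0

    @staticmethod
    def _archetype_codes(n_per=25):
        patterns = {
            "stay_minus": (tj.MINUS, tj.MINUS, tj.MINUS, tj.MINUS),
            "minus_to_ubiquitous": (tj.MINUS, tj.UBIQ, tj.UBIQ, tj.UBIQ),
            "minus_to_plus": (tj.MINUS, tj.UBIQ, tj.PLUS, tj.PLUS),
            "ubiquitous_to_plus": (tj.UBIQ, tj.UBIQ, tj.UBIQ, tj.PLUS),
        }
        codes, truth = [], []
        for name, cats in patterns.items():
            for i in range(n_per):
                codes.append(TrajectoryCode(f"{name}_{i:02d}",
                                            ("st2_7", "st8", "st9", "st10"), cats))
                truth.append(name)
        return codes, truth

    def test_planted_archetypes_recovered_exactly(self):
        codes, truth = self._archetype_codes()
        result = cluster_trajectories(codes, n_clusters=4)
        labels = [result.label_of(c.gene_id) for c in codes]
        assert adjusted_rand_score(truth, labels) == 1.0
        assert set(result.cluster_archetypes.values()) == set(truth)

    def test_clustering_invariant_to_input_order(self):
        codes, _ = self._archetype_codes(10)
        rng = np.random.default_rng(0)
        shuffled = list(codes)
        rng.shuffle(shuffled)
        r1 = cluster_trajectories(codes, n_clusters=4)
        r2 = cluster_trajectories(shuffled, n_clusters=4)
        for code in codes:
            members1 = {c.gene_id for c, l in zip(r1.codes, r1.labels)
                        if l == r1.label_of(code.gene_id)}
            members2 = {c.gene_id for c, l in zip(r2.codes, r2.labels)
                        if l == r2.label_of(code.gene_id)}
            assert members1 == members2


class TestOverlap:
    def test_disjoint_sets_no_triple(self):
        ov = cross_celltype_overlap(
            {"a": {"1"}, "b": {"2"}, "c": {"3"}}, universe={"1", "2", "3"})
        assert ov.by_k[3] == 0
        assert ov.by_k[1] == 3

    def test_identical_sets_all_triple(self):
        genes = {f"g{i}" for i in range(7)}
        ov = cross_celltype_overlap({"a": genes, "b": genes, "c": genes}, universe=genes)
        assert ov.by_k[3] == 7

    def test_hand_enumerated_example(self):
        ov = cross_celltype_overlap(
            {"A": {"1", "2", "3"}, "B": {"2", "3", "4"}, "C": {"3", "5"}},
            universe={"1", "2", "3", "4", "5"})
        assert ov.region_counts[frozenset({"A", "B", "C"})] == 1   # gene 3
        assert ov.region_counts[frozenset({"A", "B"})] == 1        # gene 2
        assert ov.by_k == {1: 3, 2: 1, 3: 1}

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i:02d}" for i in range(20)]
        sets = {ct: {g for g in genes if rng.random() < 0.4}
                for ct in ("germline", "epithelial", "embryo")}
        universe = set(genes)
        ov = cross_celltype_overlap(sets, universe)
        for k in (1, 2, 3):
            brute = sum(
                1 for g in genes
                if sum(g in s for s in sets.values()) == k
            )
            assert ov.by_k[k] == brute

    def test_permutation_invariant_in_set_order(self):
        sets = {"a": {"1", "2"}, "b": {"2", "3"}, "c": {"1", "3"}}
        u = {"1", "2", "3"}
        ov1 = cross_celltype_overlap(sets, u)
        ov2 = cross_celltype_overlap(dict(reversed(list(sets.items()))), u)
        assert ov1.by_k == ov2.by_k

    def test_minus_consistent_count(self):
        sets = {"a": {"1", "2"}, "b": {"1", "2"}, "c": {"1"}}
        minus = {"a": {"1"}, "b": {"1", "2"}, "c": {"1"}}
        ov = cross_celltype_overlap(sets, {"1", "2"}, minus_sets=minus)
        assert ov.minus_consistent == 1

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            cross_celltype_overlap({"a": {"1"}, "b": {"2"}}, universe=set())

    def test_per_stage_counts_sum_to_polar_genes(self, small_cohort):
        from locaset.trajectories import per_stage_category_counts
        from locaset.synthetic import OVARY_STAGES
        cmap = CategoryMap.default()
        ann = small_cohort.annotations.records
        codes = []
        for gid, sub in ann.groupby("gene_id"):
            stage_terms = {}
            for _, rec in sub.iterrows():
                if rec["stage"] in OVARY_STAGES:
                    stage_terms.setdefault(rec["stage"], set()).add(rec["term"])
            codes.append(encode_trajectory(gid, stage_terms, "germline", cmap, OVARY_STAGES))
        counts = per_stage_category_counts(codes)
        for stage in OVARY_STAGES:
            polar = sum(1 for c in codes
                        if c.categories[c.stages.index(stage)] in (tj.MINUS, tj.PLUS))
            assert counts[stage][tj.MINUS] + counts[stage][tj.PLUS] == polar
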