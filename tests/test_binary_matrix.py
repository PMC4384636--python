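import numpy as np
import pandas as pd
import pytest

from locaset import binary_matrix as bm
from locaset.io_core import AnnotationTable, CountTable
from locaset.vocabulary import VOCABULARY


class TestBroadClass:
    def test_no_signal_at_all_stages(self):
        terms = {s: {"no_signal"} for s in ("st2_7", "st8", "st9", "st10")}
        assert bm.assign_broad_class(terms) == "no_signal"

    def test_ubiquitous_at_all_stages(self):
        terms = {s: {"ubiquitous"} for s in ("st2_7", "st8", "st9", "st10")}
        assert bm.assign_broad_class(terms) == "ubiquitous"

    def test_any_specific_term_forces_specific(self):
        terms = {"st2_7": {"ubiquitous"}, "st9": {"posterior_enrichment"}}
        assert bm.assign_broad_class(terms) == "specific"

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError):
            bm.assign_broad_class({})


class TestReliability:
    def test_no_signal_vs_other_conflict(self):
        call = bm.assess_reliability({"p1": "no_signal", "p2": "specific"})
        assert call.reliability == "not_reliable"
        assert call.conflict_type == "no_signal_vs_other"

    def test_ubiquitous_vs_specific_conflict(self):
        call = bm.assess_reliability({"p1": "ubiquitous", "p2": "specific"})
        assert call.reliability == "not_reliable"
        assert call.conflict_type == "ubiquitous_vs_specific"

    def test_single_probe_reliable(self):
        assert bm.assess_reliability({"p1": "specific"}).reliability == "reliable"

    def test_symmetric_in_probe_order(self):
        a = bm.assess_reliability({"p1": "ubiquitous", "p2": "specific"})
        b = bm.assess_reliability({"p1": "specific", "p2": "ubiquitous"})
        assert (a.reliability, a.conflict_type) == (b.reliability, b.conflict_type)


class TestPnStatus:
    def test_threeP_above_with_signal_is_tp(self):
        assert bm.assign_pn_status({"3Pseq": 60.0, "RNAseq": 10.0}, "specific") == "TP"

    def test_rnaseq_above_no_signal_is_fp(self):
        assert bm.assign_pn_status({"RNAseq": 80.0, "3Pseq": 5.0}, "no_signal") == "FP"

    def test_below_both_with_signal_is_fn(self):
        assert bm.assign_pn_status({"RNAseq": 10.0, "3Pseq": 5.0}, "ubiquitous") == "FN"

    def test_below_both_no_signal_is_tn(self):
        assert bm.assign_pn_status({"RNAseq": 10.0, "3Pseq": 5.0}, "no_signal") == "TN"

    def test_missing_both_assays_rejected(self):
        with pytest.raises(ValueError):
            bm.assign_pn_status({}, "specific")

    def test_cutoff_is_inclusive(self):
        assert bm.assign_pn_status({"3Pseq": 50.0}, "specific") == "TP"
        assert bm.assign_pn_status({"3Pseq": 49.999}, "specific") == "FN"

    def test_partition_matches_brute_force_grid(self):
        # the four statuses are a total function over (above x signal)
        rng = np.random.default_rng(12)
        for _ in range(20):
            th = bm.NoiseThresholds(
                rnaseq_cutoff=float(rng.uniform(1, 200)),
                threeP_cutoff=float(rng.uniform(1, 200)),
            )
            for above in (True, False):
                for signal_class in ("specific", "ubiquitous", "no_signal"):
                    if above:
                        values = {"RNAseq": th.rnaseq_cutoff + 1, "3Pseq": 0.0}
                    else:
                        values = {"RNAseq": th.rnaseq_cutoff - 1,
                                  "3Pseq": th.threeP_cutoff - 1}
                    status = bm.assign_pn_status(values, signal_class, th)
                    signal = signal_class != "no_signal"
                    expected = {(True, True): "TP", (True, False): "FP",
                                (False, True): "FN", (False, False): "TN"}[(above, signal)]
                    assert status == expected

    def test_raising_cutoffs_only_demotes(self):
        rng = np.random.default_rng(3)
        low = bm.NoiseThresholds(50, 40)
        high = bm.NoiseThresholds(90, 80)
        for _ in range(200):
            values = {"RNAseq": float(rng.uniform(0, 150)),
                      "3Pseq": float(rng.uniform(0, 150))}
            for cls in ("specific", "no_signal"):
                s_low = bm.assign_pn_status(values, cls, low)
                s_high = bm.assign_pn_status(values, cls, high)
                if s_low in ("FN", "TN"):
                    assert s_high in ("FN", "TN")


def _count_table(genes, values, assay="3Pseq"):
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                      columns=["early", "late"])
    table = CountTable(assay, ("early", "late"), df)
    table.normalized = df.astype(float)
    return table


class TestBuildMatrix:
    def _annotations(self, rows):
        return AnnotationTable(
            pd.DataFrame(rows, columns=["gene_id", "probe_id", "stage", "term"]),
            VOCABULARY,
        )

    def test_unprobed_genes_excluded(self):
        ann = self._annotations([
            ("g1", "p1", "st8", "ubiquitous"),
            ("g2", "p1", "st8", "no_signal"),
        ])
        counts = _count_table(["g1", "g2", "g3"], [[100, 100], [5, 5], [50, 50]])
        rows = bm.build_binary_matrix(ann, {"3Pseq": counts})
        assert [r.gene_id for r in rows] == ["g1", "g2"]

    def test_cv_counts_summed_over_probes(self):
        ann = self._annotations([
            ("g1", "p1", "st8", "posterior_enrichment"),
            ("g1", "p2", "st8", "posterior_enrichment"),
        ])
        counts = _count_table(["g1"], [[100, 100]])
        row = bm.build_binary_matrix(ann, {"3Pseq": counts})[0]
        assert row.cv_counts["posterior_enrichment"] == 2
        assert row.subclasses == frozenset({"subcellular"})

    def test_dump_reload_round_trip(self, tmp_path):
        ann = self._annotations([
            ("g1", "p1", "st8", "ubiquitous"),
            ("g2", "p1", "st9", "oocyte_enrichment"),
        ])
        counts = _count_table(["g1", "g2"], [[100, 100], [60, 60]])
        rows = bm.build_binary_matrix(ann, {"3Pseq": counts})
        p = tmp_path / "matrix.tsv"
        bm.write_matrix(rows, p)
        reloaded = bm.read_matrix(p)
        original = bm.matrix_to_frame(rows)
        pd.testing.assert_frame_equal(reloaded, original, check_dtype=False)

    def test_conflicting_probes_flagged(self):
        ann = self._annotations(
            [("g1", "p1", s, "no_signal") for s in ("st8", "st9")]
            + [("g1", "p2", s, "posterior_enrichment") for s in ("st8", "st9")]
        )
        counts = _count_table(["g1"], [[100, 100]])
        row = bm.build_binary_matrix(ann, {"3Pseq": counts})[0]
        assert row.reliability == "not_reliable"
        assert row.conflict_type == "no_signal_vs_other"
        assert row.broad_class == "specific"
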