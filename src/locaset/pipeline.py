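"""End-to-end pipeline: read a cohort directory, run every analysis stage,
and write canonical TSV outputs.

The pipeline is deterministic: given a cohort directory and a seed it
produces byte-identical outputs across runs.  Resampling seeds for the
individual tests are derived from the pipeline seed through one seeded
generator, in a fixed order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import binary_matrix as bm
from . import expression as expr
from . import resampling as rs
from . import trajectories as tj
from . import utr_apa as ua
from .synthetic import CohortOnDisk, EMBRYO_STAGES, OVARY_STAGES, read_cohort

logger = logging.getLogger("locaset")


@dataclass(frozen=True)
class PipelineConfig:
    n_resamples: int = 10_000
    apa_stage_pair: tuple[str, str] = ("early", "late")
    correlation_stage_pair: tuple[str, str] = ("early", "late")
    thresholds: bm.NoiseThresholds = field(default_factory=bm.NoiseThresholds)
    apa: ua.APAConfig = field(default_factory=ua.APAConfig)


@dataclass
class PipelineResult:
    size_factors: dict[str, pd.Series]
    stage_correlation: expr.StageCorrelation
    utr_features: pd.DataFrame          # per gene: most-used length, conservation, architecture
    mean_weighted_lengths: pd.DataFrame  # gene x stage
    apa_calls: pd.DataFrame
    matrix_rows: list[bm.BinaryMatrixRow]
    gene_sets: dict[str, list[str]]
    set_summaries: dict[str, expr.SetExpressionSummary]
    ks_grid: pd.DataFrame
    resampling_results: pd.DataFrame
    trajectory_codes: list[tj.TrajectoryCode]
    clustering: tj.ClusteringResult | None
    overlap: tj.OverlapCounts | None


def _usage_profiles(cohort: CohortOnDisk, cfg: PipelineConfig):
    """Per-gene per-stage 3'UTR usage profiles from the read-end table."""
    profiles: dict[tuple[str, str], ua.UTRUsageProfile] = {}
    grouped = cohort.read_ends.groupby(["gene_id", "stage"], sort=True)
    for (gid, stage), sub in grouped:
        gene = cohort.gene_models.get(gid)
        if gene is None:
            continue
        prof = ua.assign_utr_forms(sub["position"].to_numpy(), gene, cfg.apa)
        prof.stage = stage
        profiles[(gid, stage)] = prof
    return profiles


def _gene_sets_from_matrix(rows: list[bm.BinaryMatrixRow]) -> dict[str, list[str]]:
    """Annotation gene sets used throughout the feature analyses."""
    sets: dict[str, list[str]] = {
        "ubiquitous": [], "subcellular": [], "anterior": [], "posterior": [],
    }
    for row in rows:
        if row.reliability != "reliable":
            continue
        if row.broad_class == "ubiquitous":
            sets["ubiquitous"].append(row.gene_id)
        elif row.broad_class == "specific" and "subcellular" in row.subclasses:
            sets["subcellular"].append(row.gene_id)
            if row.cv_counts.get("anterior_enrichment", 0):
                sets["anterior"].append(row.gene_id)
            if row.cv_counts.get("posterior_enrichment", 0):
                sets["posterior"].append(row.gene_id)
    return sets


def run_pipeline(
    cohort_dir: str | Path,
    out_dir: str | Path | None = None,
    seed: int = 0,
    cfg: PipelineConfig | None = None,
) -> PipelineResult:
    cfg = cfg or PipelineConfig()
    cohort = read_cohort(cohort_dir)
    seed_rng = np.random.default_rng(seed)

    def next_seed() -> int:
        return int(seed_rng.integers(0, 2**31 - 1))

    # normalization and stage correlation -----------------------------------
    expr.normalize(cohort.counts_3pseq)
    expr.normalize(cohort.counts_rnaseq)
    size_factors = {
        "3Pseq": expr.compute_size_factors(cohort.counts_3pseq),
        "RNAseq": expr.compute_size_factors(cohort.counts_rnaseq),
    }
    corr = expr.stage_correlation(cohort.counts_3pseq, *cfg.correlation_stage_pair)

    # 3'UTR usage, mean-weighted lengths, APA --------------------------------
    profiles = _usage_profiles(cohort, cfg)
    stages = list(cohort.counts_3pseq.stages)
    mwl = pd.DataFrame(index=sorted(cohort.gene_models), columns=stages, dtype=float)
    mwl.index.name = "gene_id"
    for (gid, stage), prof in profiles.items():
        if prof.total_weight > 0:
            mwl.loc[gid, stage] = ua.mean_weighted_length(prof)
    apa_records = []
    sa, sb = cfg.apa_stage_pair
    for gid in sorted(cohort.gene_models):
        pa, pb = profiles.get((gid, sa)), profiles.get((gid, sb))
        if pa is None or pb is None:
            continue
        call = ua.call_apa(pa, pb, cfg.apa)
        apa_records.append({
            "gene_id": gid, "decision": call.decision,
            "delta": round(call.delta, 4) if call.delta is not None else "",
            "reason": call.reason,
        })
    apa_calls = pd.DataFrame(apa_records).set_index("gene_id")

    # per-gene UTR features --------------------------------------------------
    feat_records = []
    for gid in sorted(cohort.gene_models):
        gene = cohort.gene_models[gid]
        rec: dict[str, object] = {"gene_id": gid}
        rec.update(ua.extract_gene_architecture(gene))
        prof = profiles.get((gid, sa)) or profiles.get((gid, sb))
        if prof is not None and prof.total_weight > 0:
            form = ua.most_used_form(prof, gene)
            rec["utr3_length"] = float(form.length)
            cons = ua.utr_conservation(form, gene.chrom, cohort.conservation)
            rec["utr3_conservation"] = cons.median
            rec["conservation_low_coverage"] = cons.low_coverage
        feat_records.append(rec)
    utr_features = pd.DataFrame(feat_records).set_index("gene_id")

    # binary matrix ----------------------------------------------------------
    matrix_rows = bm.build_binary_matrix(
        cohort.annotations,
        {"3Pseq": cohort.counts_3pseq, "RNAseq": cohort.counts_rnaseq},
        mean_weighted_lengths=mwl,
        thresholds=cfg.thresholds,
    )
    gene_sets = _gene_sets_from_matrix(matrix_rows)

    # set expression + KS grid ----------------------------------------------
    summaries, ks_grid, _ = expr.set_expression_summary(
        cohort.counts_3pseq, gene_sets, stage=None
    )

    # resampling tests -------------------------------------------------------
    res_records = []
    rcfg = lambda: rs.ResamplingConfig(n_resamples=cfg.n_resamples, seed=next_seed())
    for feature in ("utr3_length", "utr3_conservation"):
        for pair in (("ubiquitous", "subcellular"), ("anterior", "posterior")):
            va = utr_features.loc[utr_features.index.isin(gene_sets[pair[0]]), feature].dropna()
            vb = utr_features.loc[utr_features.index.isin(gene_sets[pair[1]]), feature].dropna()
            if len(va) < 2 or len(vb) < 2:
                continue
            res = rs.bootstrap_median_test(va, vb, rcfg(), labels=pair)
            res_records.append({
                "test": f"bootstrap_median:{feature}", "groups": "/".join(pair),
                "observed": round(res.observed, 4), "k": res.exceedance_count,
                "B": res.n_resamples, "p_value": res.p_value, "seed": res.seed,
            })
    for label in ("posterior", "anterior"):
        group = gene_sets[label]
        if any(cohort.network.has_interaction(g) for g in group):
            res = rs.network_permutation_test(cohort.network, group, rcfg(), label=label)
            res_records.append({
                "test": "network_permutation", "groups": label,
                "observed": res.observed, "k": res.exceedance_count,
                "B": res.n_resamples, "p_value": res.p_value, "seed": res.seed,
            })
    resampling_results = pd.DataFrame(res_records)

    # trajectories -----------------------------------------------------------
    cmap = tj.CategoryMap.default()
    ann = cohort.annotations.records
    codes = []
    loc_by_ct: dict[str, set[str]] = {"germline": set(), "epithelial": set(), "embryo": set()}
    minus_by_ct: dict[str, set[str]] = {"germline": set(), "epithelial": set(), "embryo": set()}
    for gid, sub in ann.groupby("gene_id", sort=True):
        stage_terms: dict[str, set[str]] = {}
        for _, rec in sub.iterrows():
            stage_terms.setdefault(rec["stage"], set()).add(rec["term"])
        ovary_terms = {s: t for s, t in stage_terms.items() if s in OVARY_STAGES}
        # the oocyte time-course (germline context) drives the dendrogram;
        # epithelial and embryonic polarity are evaluated independently so a
        # gene can be localized in several cell types at once
        code = tj.encode_trajectory(gid, ovary_terms, context="germline", cmap=cmap,
                                    stage_axis=OVARY_STAGES)
        codes.append(code)
        polar = {c for c in code.categories if c in (tj.MINUS, tj.PLUS)}
        if polar:
            loc_by_ct["germline"].add(gid)
            if tj.MINUS in polar:
                minus_by_ct["germline"].add(gid)
        epi_cats = {
            tj.assign_polarity_category(terms, "epithelial", cmap).category
            for terms in ovary_terms.values()
        }
        if epi_cats & {tj.MINUS, tj.PLUS}:
            loc_by_ct["epithelial"].add(gid)
            if tj.MINUS in epi_cats:
                minus_by_ct["epithelial"].add(gid)
        emb_cats = {
            tj.assign_polarity_category(stage_terms[s], "embryo", cmap).category
            for s in EMBRYO_STAGES if s in stage_terms
        }
        if emb_cats & {tj.MINUS, tj.PLUS}:
            loc_by_ct["embryo"].add(gid)
            if tj.MINUS in emb_cats:
                minus_by_ct["embryo"].add(gid)

    clustering = None
    polar_codes = [c for c in codes
                   if any(cat in (tj.MINUS, tj.PLUS) for cat in c.categories)]
    if len(polar_codes) >= 2:
        clustering = tj.cluster_trajectories(polar_codes, distance_threshold=0.5)

    overlap = None
    universe = set(ann["gene_id"])
    if any(loc_by_ct.values()):
        overlap = tj.cross_celltype_overlap(loc_by_ct, universe=universe,
                                            minus_sets=minus_by_ct)

    result = PipelineResult(
        size_factors=size_factors, stage_correlation=corr,
        utr_features=utr_features, mean_weighted_lengths=mwl, apa_calls=apa_calls,
        matrix_rows=matrix_rows, gene_sets=gene_sets, set_summaries=summaries,
        ks_grid=ks_grid, resampling_results=resampling_results,
        trajectory_codes=codes, clustering=clustering, overlap=overlap,
    )
    if out_dir is not None:
        write_pipeline_outputs(result, out_dir)
    return result


def write_pipeline_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sf = pd.DataFrame({assay: s for assay, s in result.size_factors.items()})
    sf.round(6).to_csv(out / "size_factors.tsv", sep="\t", index_label="stage",
                       lineterminator="\n")
    corr = result.stage_correlation
    (out / "stage_correlation.tsv").write_text(
        "stage_a\tstage_b\tpearson_r\tn_genes\n"
        f"{corr.stage_a}\t{corr.stage_b}\t{corr.pearson_r:.6f}\t{corr.n_genes}\n"
    )
    result.utr_features.round(4).to_csv(out / "utr_features.tsv", sep="\t",
                                        lineterminator="\n")
    result.mean_weighted_lengths.round(4).to_csv(out / "mean_weighted_lengths.tsv",
                                                 sep="\t", lineterminator="\n")
    result.apa_calls.to_csv(out / "apa_calls.tsv", sep="\t", lineterminator="\n")
    bm.write_matrix(result.matrix_rows, out / "binary_matrix.tsv")
    result.ks_grid.round(8).to_csv(out / "ks_grid.tsv", sep="\t",
                                   index_label="gene_set", lineterminator="\n")
    result.resampling_results.to_csv(out / "resampling.tsv", sep="\t", index=False,
                                     lineterminator="\n")
    rows = [{"gene_id": c.gene_id,
             "trajectory": "-".join(c.categories)} for c in result.trajectory_codes]
    pd.DataFrame(rows).sort_values("gene_id").to_csv(
        out / "trajectories.tsv", sep="\t", index=False, lineterminator="\n")
    if result.clustering is not None:
        cl = result.clustering
        rows = [{"gene_id": c.gene_id, "cluster": int(l),
                 "cluster_archetype": cl.cluster_archetypes[int(l)]}
                for c, l in zip(cl.codes, cl.labels)]
        pd.DataFrame(rows).sort_values("gene_id").to_csv(
            out / "clusters.tsv", sep="\t", index=False, lineterminator="\n")
    if result.overlap is not None:
        ov = result.overlap
        lines = ["quantity\tvalue"]
        lines.append(f"universe_size\t{ov.universe_size}")
        for k in sorted(ov.by_k):
            lines.append(f"localized_in_exactly_{k}\t{ov.by_k[k]}")
        if ov.minus_consistent is not None:
            lines.append(f"minus_consistent_all_celltypes\t{ov.minus_consistent}")
        for region in sorted(ov.region_counts, key=lambda r: (len(r), sorted(r))):
            lines.append(f"region_{'+'.join(sorted(region))}\t{ov.region_counts[region]}")
        (out / "venn.tsv").write_text("\n".join(lines) + "\n")
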