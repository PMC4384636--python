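"""Gene-set feature statistics: bootstrap median tests for 3'UTR length and
conservation, the protein-interaction permutation test, and CV-term
enrichment z-scores.

The bootstrap test resamples each set to its own size 10,000 times and
reports the exceedance fraction; the network test scores interactions among
set members (minus loops) against random draws of equally many interacting
genes from the whole interactome.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from locaset import vocabulary as cv
from locaset.resampling import (
    ResamplingConfig,
    bootstrap_median_test,
    network_permutation_test,
    term_zscore,
)
from locaset.synthetic import read_cohort
from locaset.utr_apa import assign_utr_forms, most_used_form, utr_conservation

ROOT = Path(__file__).resolve().parent.parent
COHORT = ROOT / "results" / "cohort"
OUT = ROOT / "results" / "feature_stats"

B = 10_000
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = read_cohort(COHORT)
    truth = cohort.truth

    # most-used-form length and conservation per gene (late-stage usage)
    late = cohort.read_ends.query("stage == 'late'")
    length, cons = {}, {}
    for gid, sub in late.groupby("gene_id"):
        gene = cohort.gene_models[gid]
        prof = assign_utr_forms(sub["position"].to_numpy(), gene)
        if prof.total_weight == 0:
            continue
        form = most_used_form(prof, gene)
        length[gid] = form.length
        cons[gid] = utr_conservation(form, gene.chrom, cohort.conservation).median

    sets = {label: [g for g in truth.query("gene_set == @label").index]
            for label in ("ubiquitous", "anterior", "posterior")}
    sets["subcellular"] = [g for g in truth.index
                           if truth.loc[g, "gene_set"] in
                           ("oocyte", "anterior", "posterior", "other")]

    rows = []
    seed_rng = np.random.default_rng(SEED)
    for feature, values in (("utr3_length", length), ("utr3_conservation", cons)):
        for pair in (("ubiquitous", "subcellular"), ("anterior", "posterior")):
            va = np.array([values[g] for g in sets[pair[0]] if g in values], float)
            vb = np.array([values[g] for g in sets[pair[1]] if g in values], float)
            cfg = ResamplingConfig(B, seed=int(seed_rng.integers(0, 2**31 - 1)))
            res = bootstrap_median_test(va, vb, cfg, labels=pair)
            rows.append({"test": feature, "groups": "/".join(pair),
                         "observed_median_diff": round(res.observed, 3),
                         "k": res.exceedance_count, "B": B, "p": res.p_value})
            print(f"{feature} {pair[0]} vs {pair[1]}: p = {res.p_value:.4g}")

    for label in ("posterior", "anterior"):
        cfg = ResamplingConfig(B, seed=int(seed_rng.integers(0, 2**31 - 1)))
        res = network_permutation_test(cohort.network, sets[label], cfg, label=label)
        rows.append({"test": "ppi_permutation", "groups": label,
                     "observed_median_diff": res.observed,
                     "k": res.exceedance_count, "B": B, "p": res.p_value})
        print(f"PPI within-set excess, {label}: observed {res.observed:.0f} "
              f"interactions, p = {res.p_value:.4g}")

    pd.DataFrame(rows).to_csv(OUT / "resampling.tsv", sep="\t", index=False,
                              lineterminator="\n")

    # CV-term over/under-representation in the subcellular set
    ann = cohort.annotations.records
    term_by_gene = ann.groupby("gene_id")["term"].agg(set)
    universe = list(term_by_gene.index)
    sub = [g for g in sets["subcellular"] if g in term_by_gene.index]
    zrows = []
    for term in sorted(cv.SPECIFIC_TERMS):
        bg = sum(term in term_by_gene[g] for g in universe) / len(universe)
        if not 0 < bg < 1:
            continue
        obs = sum(term in term_by_gene[g] for g in sub)
        z = term_zscore(obs, len(sub), bg, term=term, population_size=len(universe))
        zrows.append({"term": term, "observed": obs,
                      "expected": round(z.expected, 2), "z": round(z.z_score, 3)})
    zdf = pd.DataFrame(zrows).sort_values("z", ascending=False)
    zdf.to_csv(OUT / "term_zscores.tsv", sep="\t", index=False, lineterminator="\n")
    print("top over-represented terms in the subcellular set:")
    print(zdf.head(4).to_string(index=False))


if __name__ == "__main__":
    main()
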