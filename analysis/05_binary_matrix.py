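"""Fuse annotations and expression into the per-gene binary matrix and
summarize broad classes, probe reliability and pn-status.

pn-status compares FISH detection with sequencing detection at the noise
thresholds (70 normalized counts for RNAseq, 50 for 3Pseq).
"""

from collections import Counter
from pathlib import Path

from locaset import binary_matrix as bm
from locaset.expression import normalize
from locaset.synthetic import read_cohort

ROOT = Path(__file__).resolve().parent.parent
COHORT = ROOT / "results" / "cohort"
OUT = ROOT / "results" / "binary_matrix.tsv"


def main() -> None:
    cohort = read_cohort(COHORT)
    normalize(cohort.counts_3pseq)
    normalize(cohort.counts_rnaseq)
    rows = bm.build_binary_matrix(
        cohort.annotations,
        {"3Pseq": cohort.counts_3pseq, "RNAseq": cohort.counts_rnaseq},
    )
    bm.write_matrix(rows, OUT)
    print(f"wrote {len(rows)} gene rows to {OUT}")
    print("broad classes:", dict(Counter(r.broad_class for r in rows)))
    print("pn-status:", dict(Counter(r.pn_status for r in rows)))
    unreliable = [r for r in rows if r.reliability == "not_reliable"]
    print(f"{len(unreliable)} genes with conflicting probes:",
          dict(Counter(r.conflict_type for r in unreliable)))


if __name__ == "__main__":
    main()
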