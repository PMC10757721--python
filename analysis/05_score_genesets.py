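"""Per-sample gene-set scoring of the subtype programs.

Scores the C1-up and C2-up halves of the signature with the rank-weighted
single-sample statistic and contrasts them across discovered subtypes with
the Wilcoxon rank-sum test; also runs preranked GSEA of the C1 program on
the C1-vs-C2 mean log2 difference ranking.

Reads scratch/analysis/cohort/ and subtype_labels.tsv; writes scores and
tests under results/analysis/.
"""
from pathlib import Path

import numpy as np
import pandas as pd

from efferotype.datatypes import ExpressionMatrix
from efferotype.scoring import compare_group_scores, preranked_gsea, score_collection
from efferotype.synthetic import read_cohort

COHORT = Path("scratch/analysis/cohort")
OUT = Path("results/analysis")
SEED = 7


def main() -> None:
    cohort = read_cohort(COHORT)
    expr = ExpressionMatrix(np.log2(cohort.expression.values + 1.0), "log2tpm")
    labels = pd.read_csv(OUT / "subtype_labels.tsv", sep="\t", index_col=0)["subtype"]

    collection = {"c1_program": cohort.c1_program, "c2_program": cohort.c2_program}
    scores = score_collection(expr, collection)
    scores.to_csv(OUT / "geneset_scores.tsv", sep="\t", index_label="set")
    tests = compare_group_scores(scores, labels, adjust=True)
    tests.to_csv(OUT / "geneset_group_tests.tsv", sep="\t")
    for name, row in tests.iterrows():
        print(f"{name}: Wilcoxon p = {row['p_value']:.3g} (BH {row['p_adjusted']:.3g})")

    c1 = labels.index[labels == "C1"]
    c2 = labels.index[labels == "C2"]
    ranked = (expr.values[c1].mean(axis=1) - expr.values[c2].mean(axis=1))
    res = preranked_gsea(ranked, set(cohort.c1_program), n_perm=1000, seed=SEED)
    print(f"preranked GSEA of the C1 program on the C1-vs-C2 ranking: "
          f"ES {res.es:.3f}  NES {res.nes:.2f}  p {res.p_value:.3g}")


if __name__ == "__main__":
    main()
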