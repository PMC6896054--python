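#!/usr/bin/env python
"""Between-group statistics on the per-sample summaries.

Wilcoxon rank-sum comparisons of every count and strength metric between
the two lesion groups, Spearman/OLS association of mutation burden with
neoantigen counts, and (when supplied) regressions of cell-type scores
against the adjusted maximum fitness cost with Bonferroni correction.
The headline contrast is adjusted vs unadjusted maximum fitness cost.
"""
import argparse
from pathlib import Path

import pandas as pd

from neofit import io as nio
from neofit.config import RunConfig
from neofit.stats import compare_groups


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--summaries", type=Path, default=Path("results/summaries.tsv"))
    ap.add_argument("--groups", type=Path, default=Path("results/cohort/groups.tsv"))
    ap.add_argument("--cell-scores", type=Path, default=None)
    ap.add_argument("--out", type=Path, default=Path("results/cohort_comparison"))
    args = ap.parse_args()

    summaries = nio.read_table(args.summaries)
    groups = nio.read_groups(args.groups)
    scores = None
    if args.cell_scores is not None:
        scores = pd.read_csv(args.cell_scores, sep="\t").set_index("sample_id")
    res = compare_groups(summaries, groups, RunConfig(), cell_scores=scores)

    args.out.parent.mkdir(parents=True, exist_ok=True)
    nio.write_table(res.metric_tests, f"{args.out}_tests.tsv")
    nio.write_table(res.correlations, f"{args.out}_correlations.tsv")
    nio.write_table(res.regressions, f"{args.out}_regressions.tsv")

    show = res.metric_tests[res.metric_tests["computed"]][
        ["metric", "mean_a", "mean_b", "p_value"]
    ]
    print(show.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    print(res.correlations.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    print(f"wrote {args.out}_tests/_correlations/_regressions.tsv")


if __name__ == "__main__":
    main()
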