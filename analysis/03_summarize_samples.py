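#!/usr/bin/env python
"""Reduce scored records to one summary row per sample.

Reports, per sample: somatic mutations, 21-mer peptides, possible 9-mers,
binding and immunogenic neoantigen counts, immunogenic:binding ratios,
mean Kd/amplitude/recognition, mean and max fitness cost, and the
expression-adjusted versions; flags samples eligible for the between-group
strength comparison (more than one immunogenic neoantigen).
"""
import argparse
from pathlib import Path

from neofit import io as nio
from neofit.config import RunConfig
from neofit.pipeline import summarize_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--scored", type=Path, default=Path("results/scored"))
    ap.add_argument("--out", type=Path, default=Path("results/summaries.tsv"))
    args = ap.parse_args()

    records = nio.read_table(args.scored / "scored.tsv")
    counts = nio.read_table(args.scored / "counts.tsv")
    summaries = summarize_cohort(records, counts, RunConfig())
    args.out.parent.mkdir(parents=True, exist_ok=True)
    nio.write_table(summaries, args.out)

    cols = ["sample_id", "n_somatic_mutations", "n_peptides_21mer",
            "n_possible_9mers", "n_binding", "n_immunogenic", "max_fitness",
            "max_adjusted_fitness", "eligible"]
    print(summaries[cols].to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
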