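#!/usr/bin/env python
"""Score every candidate neoepitope of the simulated cohort.

Reads the bundle written by 01_simulate_cohort.py back through the
file-format layer (the same path external variant tables would take),
enumerates all 9-mer windows, assigns best-allele dissociation constants,
applies the 500 nM binding filter, computes amplitude, TCR recognition
potential, fitness cost and the RPKM expression adjustment. Writes
results/scored/scored.tsv and counts.tsv.
"""
import argparse
from pathlib import Path

from neofit import io as nio
from neofit.config import RunConfig, SimConfig
from neofit.pipeline import attach_expression, score_cohort
from neofit.simulate import SyntheticKdPredictor


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results/scored"))
    args = ap.parse_args()

    variants = nio.read_variants(args.cohort / "variants.tsv", dialect="tsv")
    proteome = nio.read_protein_fasta(args.cohort / "proteins.fasta")
    alleles = nio.read_alleles(args.cohort / "alleles.txt")
    epitopes = nio.read_epitope_reference(args.cohort / "epitopes.fasta")
    expression = nio.read_expression(args.cohort / "expression.tsv")
    sim_cfg = SimConfig.from_yaml(args.cohort / "sim_config.yaml")
    predictor = SyntheticKdPredictor(sim_cfg, role="mt")

    cfg = RunConfig()
    records, counts = score_cohort(
        variants, proteome, alleles, epitopes, cfg,
        kd_source_mt=predictor, kd_source_wt=predictor.for_role("wt"),
    )
    records = attach_expression(records, expression)

    args.out.mkdir(parents=True, exist_ok=True)
    nio.write_table(records, args.out / "scored.tsv")
    nio.write_table(counts, args.out / "counts.tsv")
    n_bind = int(records["is_binding"].sum())
    n_imm = int(records["is_immunogenic"].sum())
    print(f"scored {len(records)} candidate 9-mer windows in {len(counts)} samples")
    print(f"  binding (<500 nM): {n_bind}  immunogenic (binding, R > 0): {n_imm}")
    print(f"wrote {args.out}/scored.tsv and counts.tsv")


if __name__ == "__main__":
    main()
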