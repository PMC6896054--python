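"""End-to-end scoring pipeline: variants -> 9-mer records -> summaries.

`score_cohort` performs the full per-record computation: near-indel SNV
filtering, 21-mer pair construction, 9-mer enumeration, best-allele Kd for
mutant and wild-type windows, the 500 nM binding gate, amplitude, TCR
recognition potential (computed for binding windows, which are the
neoantigens the analysis considers), fitness cost, and classification.
`attach_expression` adds RPKM fractions and adjusted fitness;
`summarize_cohort` reduces to per-sample summaries with eligibility flags.
"""
from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import RunConfig
from .fitness import (
    RECORD_COLUMNS,
    classify,
    expression_fractions,
    select_eligible_samples,
    summaries_to_frame,
    summarize_sample,
)
from .mhc import KdSource, best_kd
from .peptides import (
    SomaticVariant,
    build_peptide_pair,
    enumerate_nine_mers,
    filter_snvs_near_indels,
)
from .tcr import TcrParams, encode_peptides, recognition_potential_batch

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ["sample_id", "n_somatic_mutations", "n_peptides_21mer"]


def _best_kd_many(
    peptides: Sequence[str], alleles: Sequence[str], kd_source: KdSource
) -> Tuple[np.ndarray, List[str]]:
    """Best-allele Kd for many peptides, vectorized when the source supports it."""
    if hasattr(kd_source, "best_kd_batch"):
        enc = encode_peptides(list(peptides))
        kd, idx = kd_source.best_kd_batch(enc, alleles)
        return kd, [alleles[i] for i in idx]
    kds, names = [], []
    for p in peptides:
        kd, allele = best_kd(p, alleles, kd_source)
        kds.append(kd)
        names.append(allele)
    return np.array(kds), names


def score_cohort(
    variants: Sequence[SomaticVariant],
    proteome: Dict[str, str],
    alleles: Sequence[str],
    epitopes: Sequence[str],
    config: RunConfig,
    kd_source_mt: KdSource,
    kd_source_wt: Optional[KdSource] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Score every candidate 9-mer of every sample.

    Returns (records, counts): one row per enumerated 9-mer window with all
    scores and flags, and one row per sample with its post-filter somatic
    mutation and 21-mer peptide counts. Recognition potential and fitness
    are filled only for binding windows; non-binding windows keep NaN and
    are never immunogenic.
    """
    if kd_source_wt is None:
        kd_source_wt = kd_source_mt
    kept = filter_snvs_near_indels(list(variants))
    samples: Dict[str, List[SomaticVariant]] = {}
    for v in kept:
        samples.setdefault(v.sample_id, []).append(v)

    count_rows = []
    record_rows = []
    for sample_id in sorted(samples):
        svars = samples[sample_id]
        n_peptides = 0
        for v in svars:
            if not v.is_nonsynonymous:
                continue
            if v.transcript_id not in proteome:
                raise KeyError(f"transcript {v.transcript_id!r} absent from the proteome FASTA")
            pair = build_peptide_pair(proteome[v.transcript_id], v)
            windows = enumerate_nine_mers(pair)
            if windows:
                n_peptides += 1
            for w in windows:
                record_rows.append(
                    {
                        "sample_id": sample_id,
                        "gene": v.gene,
                        "transcript_id": v.transcript_id,
                        "protein_pos": v.protein_pos,
                        "window_start": w.window_start,
                        "mutant_9mer": w.mutant_9mer,
                        "wildtype_9mer": w.wildtype_9mer,
                        "contains_mutation": w.contains_mutation,
                    }
                )
        count_rows.append(
            {
                "sample_id": sample_id,
                "n_somatic_mutations": len(svars),
                "n_peptides_21mer": n_peptides,
            }
        )
    counts = pd.DataFrame(count_rows, columns=COUNT_COLUMNS)
    records = pd.DataFrame(record_rows)
    if records.empty:
        records = pd.DataFrame(columns=RECORD_COLUMNS)
        return records, counts

    kd_mt, allele_mt = _best_kd_many(records["mutant_9mer"], alleles, kd_source_mt)
    kd_wt, allele_wt = _best_kd_many(records["wildtype_9mer"], alleles, kd_source_wt)
    records["kd_mt_nM"] = kd_mt
    records["kd_wt_nM"] = kd_wt
    records["best_allele_mt"] = allele_mt
    records["best_allele_wt"] = allele_wt
    wt_eff = np.minimum(kd_wt, config.wt_kd_cap_nM) if config.wt_kd_cap_nM else kd_wt
    records["amplitude"] = wt_eff / kd_mt
    records["is_binding"] = kd_mt < config.kd_binding_threshold_nM

    records["recognition"] = np.nan
    records["fitness"] = np.nan
    binding_idx = records.index[records["is_binding"]]
    if len(binding_idx):
        params = TcrParams(a=config.tcr_a, k=config.tcr_k)
        r = recognition_potential_batch(
            records.loc[binding_idx, "mutant_9mer"].tolist(), list(epitopes), params
        )
        records.loc[binding_idx, "recognition"] = r
        records.loc[binding_idx, "fitness"] = (
            records.loc[binding_idx, "amplitude"].to_numpy() * r
        )
    records = classify(records, config)
    records["rpkm"] = np.nan
    records["expression_fraction"] = np.nan
    records["adjusted_fitness"] = np.nan
    return records[RECORD_COLUMNS], counts


def attach_expression(records: pd.DataFrame, expression: pd.DataFrame) -> pd.DataFrame:
    """Per-sample RPKM fractions and adjusted fitness from an expression table."""
    parts = []
    for sample_id, sub in records.groupby("sample_id", sort=True):
        if sample_id not in expression.columns:
            raise KeyError(f"sample {sample_id!r} absent from the expression table")
        parts.append(expression_fractions(sub, expression[sample_id].to_dict()))
    if not parts:
        return records.copy()
    return pd.concat(parts).sort_index()


def summarize_cohort(
    records: pd.DataFrame, counts: pd.DataFrame, config: RunConfig
) -> pd.DataFrame:
    """Per-sample summaries with eligibility flags, one row per sample."""
    summaries = []
    for row in counts.itertuples(index=False):
        sub = records[records["sample_id"] == row.sample_id]
        s = summarize_sample(sub, row.n_somatic_mutations, row.n_peptides_21mer, config)
        s.sample_id = row.sample_id
        summaries.append(s)
    frame = summaries_to_frame(summaries)
    return select_eligible_samples(frame, config)
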