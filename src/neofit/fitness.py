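"""Fitness cost, expression adjustment, and per-sample summaries.

The fitness cost F = A * R combines the MHC-binding amplitude with the TCR
recognition potential; larger F predicts stronger immune recognition (the
sign convention is positive). Because a neoantigen is invisible unless
expressed, F is adjusted by the neoantigen's share of RPKM expression among
the sample's non-zero-fitness neoantigens:

    fraction_i = rpkm_i / sum_j rpkm_j   (j over records with F > 0)
    F_adj_i    = A_i * R_i * fraction_i

Per-sample reductions produce the counts, ratios, means and maxima that the
between-group comparison consumes.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .config import RunConfig

logger = logging.getLogger(__name__)

#: Column order of the scored-records table (one row per 9-mer window).
RECORD_COLUMNS = [
    "sample_id",
    "gene",
    "transcript_id",
    "protein_pos",
    "window_start",
    "mutant_9mer",
    "wildtype_9mer",
    "contains_mutation",
    "kd_mt_nM",
    "kd_wt_nM",
    "best_allele_mt",
    "best_allele_wt",
    "amplitude",
    "is_binding",
    "recognition",
    "fitness",
    "is_immunogenic",
    "is_stringent",
    "rpkm",
    "expression_fraction",
    "adjusted_fitness",
]


def fitness_cost(amplitude: float, recognition: float) -> float:
    """F = A * R."""
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if not 0.0 <= recognition < 1.0:
        raise ValueError("recognition must lie in [0, 1)")
    return amplitude * recognition


def classify(records: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Add is_immunogenic / is_stringent flags from the binding gate and R.

    A record is *immunogenic* when it binds (mutant Kd below threshold) and
    has non-zero recognition potential; *stringent* when it binds and
    R >= the stringent threshold.
    """
    out = records.copy()
    r = out["recognition"].fillna(0.0)
    out["is_immunogenic"] = out["is_binding"] & (r > 0.0)
    out["is_stringent"] = out["is_binding"] & (r >= config.r_stringent_threshold)
    return out


def expression_fractions(
    records: pd.DataFrame, rpkm_by_transcript: Mapping[str, float]
) -> pd.DataFrame:
    """Attach RPKM, expression fractions and adjusted fitness for one sample.

    Only records with F > 0 receive a fraction (their RPKM over the summed
    RPKM of all F > 0 records in the sample); F = 0 (or unscored) records
    keep NaN. Transcripts absent from the expression table count as RPKM 0
    and are logged. If every F > 0 record has zero RPKM the adjustment is
    undefined for the sample and all fractions stay NaN.
    """
    out = records.copy()
    rpkm = np.array(
        [float(rpkm_by_transcript.get(t, np.nan)) for t in out["transcript_id"]]
    )
    missing = np.isnan(rpkm)
    if missing.any():
        logger.warning(
            "%d records map to transcripts absent from the expression table; RPKM set to 0",
            int(missing.sum()),
        )
        rpkm[missing] = 0.0
    if (rpkm < 0).any():
        raise ValueError("negative RPKM encountered")
    out["rpkm"] = rpkm
    out["expression_fraction"] = np.nan
    out["adjusted_fitness"] = np.nan
    f = out["fitness"].to_numpy(dtype=float)
    pos = np.nan_to_num(f, nan=0.0) > 0.0
    if pos.any():
        total = rpkm[pos].sum()
        if total > 0:
            frac = np.full(len(out), np.nan)
            frac[pos] = rpkm[pos] / total
            out["expression_fraction"] = frac
            out["adjusted_fitness"] = f * frac
        else:
            logger.warning(
                "sample %s: all non-zero-fitness records have zero RPKM; adjustment undefined",
                out["sample_id"].iloc[0] if len(out) else "?",
            )
    return out


@dataclass
class SampleSummary:
    """Per-sample counts, ratios and fitness statistics."""

    sample_id: str
    n_somatic_mutations: int
    n_peptides_21mer: int
    n_possible_9mers: int
    n_binding: int
    n_immunogenic: int
    n_stringent: int
    ratio_immunogenic_binding: Optional[float]
    ratio_stringent_binding: Optional[float]
    mean_kd_mt: Optional[float]
    mean_amplitude: Optional[float]
    mean_recognition: Optional[float]
    mean_fitness: Optional[float]
    max_fitness: Optional[float]
    mean_adjusted_fitness: Optional[float]
    max_adjusted_fitness: Optional[float]
    eligible: bool = False

    def __post_init__(self) -> None:
        if not (
            self.n_stringent <= self.n_binding
            and self.n_immunogenic <= self.n_binding
            and self.n_binding <= self.n_possible_9mers
        ):
            raise ValueError("count invariants violated")


def _mean(series: pd.Series) -> Optional[float]:
    return float(series.mean()) if len(series) else None


def summarize_sample(
    records: pd.DataFrame,
    n_somatic_mutations: int,
    n_peptides_21mer: int,
    config: RunConfig,
) -> SampleSummary:
    """Reduce one sample's classified records to its summary row.

    Means of Kd, A, R and F are taken over the configured averaging set
    (immunogenic records by default, optionally all binding records);
    max F over immunogenic records; adjusted statistics over records whose
    adjustment is defined.
    """
    sample_id = str(records["sample_id"].iloc[0]) if len(records) else ""
    binding = records[records["is_binding"].fillna(False).astype(bool)] if len(records) else records
    immunogenic = binding[binding["is_immunogenic"]] if len(binding) else binding
    stringent = binding[binding["is_stringent"]] if len(binding) else binding
    n_binding, n_immuno, n_stringent = len(binding), len(immunogenic), len(stringent)

    avg_set = immunogenic if config.averaging_set == "immunogenic" else binding
    adj = records["adjusted_fitness"].dropna() if len(records) else pd.Series(dtype=float)

    return SampleSummary(
        sample_id=sample_id,
        n_somatic_mutations=n_somatic_mutations,
        n_peptides_21mer=n_peptides_21mer,
        n_possible_9mers=len(records),
        n_binding=n_binding,
        n_immunogenic=n_immuno,
        n_stringent=n_stringent,
        ratio_immunogenic_binding=(n_immuno / n_binding) if n_binding else None,
        ratio_stringent_binding=(n_stringent / n_binding) if n_binding else None,
        mean_kd_mt=_mean(avg_set["kd_mt_nM"]) if len(avg_set) else None,
        mean_amplitude=_mean(avg_set["amplitude"]) if len(avg_set) else None,
        mean_recognition=_mean(avg_set["recognition"]) if len(avg_set) else None,
        mean_fitness=_mean(avg_set["fitness"]) if len(avg_set) else None,
        max_fitness=float(immunogenic["fitness"].max()) if n_immuno else None,
        mean_adjusted_fitness=float(adj.mean()) if len(adj) else None,
        max_adjusted_fitness=float(adj.max()) if len(adj) else None,
    )


def summaries_to_frame(summaries) -> pd.DataFrame:
    """Stack :class:`SampleSummary` objects into a DataFrame."""
    return pd.DataFrame([vars(s) for s in summaries])


def select_eligible_samples(
    summaries: pd.DataFrame, config: RunConfig
) -> pd.DataFrame:
    """Flag samples entering the between-group strength comparisons.

    A sample is eligible when it has at least
    ``config.min_immunogenic_for_eligibility`` immunogenic neoantigens.
    With ``drop_magnitude_outliers`` on, eligible samples whose max fitness
    sits ``outlier_fold``-or-more below the mean max fitness of the other
    eligible samples are additionally dropped.
    """
    out = summaries.copy()
    out["eligible"] = out["n_immunogenic"] >= config.min_immunogenic_for_eligibility
    if config.drop_magnitude_outliers:
        elig = out[out["eligible"] & out["max_fitness"].notna()]
        if len(elig) >= 2:
            for idx in elig.index:
                others = elig.drop(index=idx)["max_fitness"]
                m = float(others.mean())
                v = float(elig.loc[idx, "max_fitness"])
                if m > 0 and v > 0 and v * config.outlier_fold <= m:
                    out.loc[idx, "eligible"] = False
                    logger.info(
                        "sample %s dropped as magnitude outlier (max F %.3g vs cohort mean %.3g)",
                        out.loc[idx, "sample_id"],
                        v,
                        m,
                    )
    return out
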