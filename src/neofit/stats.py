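"""Cohort statistics: rank-sum tests, correlations, regressions, QC checks.

Small-cohort comparisons use the Wilcoxon rank-sum test. The exact mode
enumerates every assignment of ranks to the first group; the normal mode
uses the large-sample z approximation with tie-corrected variance and no
continuity correction (the convention of the classical rank-sum test as
implemented in mainstream statistics packages). Correlation is Spearman's
rho; simple linear regressions report the slope with a t-based confidence
interval; families of regressions are Bonferroni-corrected.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import RunConfig
from .peptides import SomaticVariant

logger = logging.getLogger(__name__)

EXACT_MAX_N = 12  # combined size below which 'auto' enumerates


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum W of x, p).

    exact   : enumerate all C(nx+ny, nx) rank assignments of the observed
              (mid)ranks; p doubles the smaller tail, capped at 1.
    normal  : z = (W - E[W]) / sd with tie-corrected variance, no
              continuity correction.
    auto    : exact when nx+ny <= 12 and the data have no ties, else normal.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if mode not in ("exact", "normal", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    nx, ny = x.size, y.size
    n = nx + ny
    w = float(ranks[:nx].sum())
    has_ties = np.unique(pooled).size < n
    if mode == "auto":
        mode = "exact" if (n <= EXACT_MAX_N and not has_ties) else "normal"
    if mode == "exact":
        sums = np.array([sum(c) for c in combinations(ranks, nx)])
        tol = 1e-9
        lo = np.mean(sums <= w + tol)
        hi = np.mean(sums >= w - tol)
        p = min(1.0, 2.0 * min(lo, hi))
        return w, float(p)
    mean_w = nx * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var_w = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        logger.warning("degenerate rank-sum variance (all values tied); p = 1")
        return w, 1.0
    z = (w - mean_w) / math.sqrt(var_w)
    return w, float(2.0 * sps.norm.sf(abs(z)))


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    """Tie-aware Spearman correlation; None (with a warning) for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        logger.warning("constant vector: Spearman rho undefined")
        return None
    return float(sps.spearmanr(x, y).statistic)


def ols_slope_ci(
    x: Sequence[float], y: Sequence[float], level: float = 0.95
) -> Tuple[float, float, float, float]:
    """Least-squares slope with a t-based CI; returns (slope, lo, hi, p).

    Zero-residual data collapse the CI onto the slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.unique(x).size == 1:
        raise ValueError("constant predictor: degenerate design")
    res = sps.linregress(x, y)
    tq = sps.t.ppf(0.5 + level / 2.0, x.size - 2)
    half = tq * res.stderr
    return float(res.slope), float(res.slope - half), float(res.slope + half), float(res.pvalue)


def bonferroni(pvals: Sequence[float]) -> List[float]:
    """Family-wise correction: p -> min(1, m * p)."""
    m = len(pvals)
    out = []
    for p in pvals:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
        out.append(min(1.0, m * p))
    return out


@dataclass(frozen=True)
class GrooveAnnotation:
    """Exon intervals of one HLA class I gene, 1-based closed coordinates.

    Exons 2 and 3 encode the peptide-binding groove.
    """

    gene: str
    chrom: str
    exons: Mapping[int, Tuple[int, int]]
    groove_exons: Tuple[int, ...] = (2, 3)

    def __post_init__(self) -> None:
        for num, (s, e) in self.exons.items():
            if s > e:
                raise ValueError(f"{self.gene} exon {num}: start > end")
        if not set(self.groove_exons) <= set(self.exons):
            raise ValueError("groove exons must be a subset of the exon set")


def flag_groove_mutations(
    variants: Sequence[SomaticVariant], annotations: Sequence[GrooveAnnotation]
) -> pd.DataFrame:
    """Per-variant flags: inside any HLA exon, inside a groove (exon 2/3) interval."""
    rows = []
    for v in variants:
        in_coding = in_groove = False
        hit_gene = ""
        for ann in annotations:
            if v.chrom != ann.chrom:
                continue
            for num, (s, e) in ann.exons.items():
                if s <= v.pos <= e:
                    in_coding = True
                    hit_gene = ann.gene
                    if num in ann.groove_exons:
                        in_groove = True
        rows.append(
            {
                "sample_id": v.sample_id,
                "chrom": v.chrom,
                "pos": v.pos,
                "hla_gene": hit_gene,
                "in_coding": in_coding,
                "in_groove": in_groove,
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "pos", "hla_gene", "in_coding", "in_groove"])


def expression_outlier_check(
    value: float, cohort: Sequence[float], n_sd: float = 2.0
) -> bool:
    """True when ``value`` lies within ``n_sd`` sample SDs of the cohort mean."""
    cohort = np.asarray(cohort, dtype=float)
    if cohort.size < 2:
        raise ValueError("cohort must contain at least 2 values")
    mean = float(cohort.mean())
    sd = float(cohort.std(ddof=1))
    if sd == 0:
        logger.warning("zero cohort SD in expression check")
        return value == mean
    return abs(value - mean) <= n_sd * sd


# Summary metrics compared between groups over *all* samples (count scale)
COUNT_METRICS = ["n_somatic_mutations", "n_binding", "n_immunogenic"]
# Metrics compared over eligible samples only (strength scale)
STRENGTH_METRICS = [
    "ratio_immunogenic_binding",
    "ratio_stringent_binding",
    "mean_kd_mt",
    "mean_amplitude",
    "mean_recognition",
    "mean_fitness",
    "max_fitness",
    "mean_adjusted_fitness",
    "max_adjusted_fitness",
]


@dataclass
class CohortResult:
    """All between-group statistics of one cohort comparison."""

    group_a: str
    group_b: str
    metric_tests: pd.DataFrame = field(default_factory=pd.DataFrame)
    correlations: pd.DataFrame = field(default_factory=pd.DataFrame)
    regressions: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frames(self) -> Dict[str, pd.DataFrame]:
        return {
            "metric_tests": self.metric_tests,
            "correlations": self.correlations,
            "regressions": self.regressions,
        }


def _metric_row(metric, xa, xb, ga, gb, mode):
    row = {
        "metric": metric,
        "group_a": ga,
        "group_b": gb,
        "n_a": len(xa),
        "n_b": len(xb),
        "mean_a": float(np.mean(xa)) if len(xa) else np.nan,
        "mean_b": float(np.mean(xb)) if len(xb) else np.nan,
        "w_statistic": np.nan,
        "p_value": np.nan,
        "computed": False,
    }
    if len(xa) >= 2 and len(xb) >= 2:
        w, p = wilcoxon_rank_sum(xa, xb, mode=mode)
        row.update(w_statistic=w, p_value=p, computed=True)
    return row


def compare_groups(
    summaries: pd.DataFrame,
    groups: Mapping[str, str],
    config: RunConfig,
    cell_scores: Optional[pd.DataFrame] = None,
    expression_levels: Optional[pd.DataFrame] = None,
) -> CohortResult:
    """Between-group tests, count correlations, and fitness regressions.

    Count metrics are compared across all samples; strength metrics across
    eligible samples only. Mutation-count vs neoantigen-count association
    is reported as Spearman rho plus the OLS slope with 95% CI. When
    per-sample cell-type scores (or pathway-gene expression levels) are
    supplied, each column is regressed against the adjusted maximum fitness
    cost over eligible samples, with Bonferroni correction over the
    cell-score family.
    """
    df = summaries.copy()
    df["group"] = df["sample_id"].map(dict(groups))
    if df["group"].isna().any():
        missing = df.loc[df["group"].isna(), "sample_id"].tolist()
        raise ValueError(f"samples without group labels: {missing}")
    labels = sorted(df["group"].unique())
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, found {labels}")
    ga, gb = labels
    if "eligible" not in df.columns:
        df["eligible"] = True
    elig = df[df["eligible"]]
    mode = config.wilcoxon_mode

    rows = []
    for metric in COUNT_METRICS:
        sub = df[df[metric].notna()]
        rows.append(
            _metric_row(
                metric,
                sub.loc[sub["group"] == ga, metric].to_numpy(float),
                sub.loc[sub["group"] == gb, metric].to_numpy(float),
                ga,
                gb,
                mode,
            )
        )
    for metric in STRENGTH_METRICS:
        sub = elig[elig[metric].notna()]
        rows.append(
            _metric_row(
                metric,
                sub.loc[sub["group"] == ga, metric].to_numpy(float),
                sub.loc[sub["group"] == gb, metric].to_numpy(float),
                ga,
                gb,
                mode,
            )
        )
    metric_tests = pd.DataFrame(rows)

    corr_rows, reg_rows = [], []
    for target in ("n_binding", "n_immunogenic"):
        x = df["n_somatic_mutations"].to_numpy(float)
        y = df[target].to_numpy(float)
        if len(df) >= 3 and np.unique(x).size > 1 and np.unique(y).size > 1:
            rho = spearman_rho(x, y)
            slope, lo, hi, p = ols_slope_ci(x, y)
            corr_rows.append({"pair": f"n_somatic_mutations~{target}", "spearman_rho": rho})
            reg_rows.append(
                {
                    "family": "mutation_counts",
                    "predictor": "n_somatic_mutations",
                    "response": target,
                    "slope": slope,
                    "ci_low": lo,
                    "ci_high": hi,
                    "p_value": p,
                    "p_adjusted": np.nan,
                    "computed": True,
                }
            )
        else:
            corr_rows.append({"pair": f"n_somatic_mutations~{target}", "spearman_rho": np.nan})
            reg_rows.append(
                {
                    "family": "mutation_counts",
                    "predictor": "n_somatic_mutations",
                    "response": target,
                    "slope": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p_value": np.nan,
                    "p_adjusted": np.nan,
                    "computed": False,
                }
            )

    for family, table in (("pathway_expression", expression_levels), ("cell_scores", cell_scores)):
        if table is None:
            continue
        fam_rows = []
        merged = elig.merge(table, left_on="sample_id", right_index=True, how="inner")
        for col in table.columns:
            sub = merged[merged["max_adjusted_fitness"].notna() & merged[col].notna()]
            x = sub["max_adjusted_fitness"].to_numpy(float)
            y = sub[col].to_numpy(float)
            if len(sub) >= 3 and np.unique(x).size > 1:
                slope, lo, hi, p = ols_slope_ci(x, y)
                fam_rows.append(
                    {
                        "family": family,
                        "predictor": "max_adjusted_fitness",
                        "response": col,
                        "slope": slope,
                        "ci_low": lo,
                        "ci_high": hi,
                        "p_value": p,
                        "p_adjusted": np.nan,
                        "computed": True,
                    }
                )
            else:
                fam_rows.append(
                    {
                        "family": family,
                        "predictor": "max_adjusted_fitness",
                        "response": col,
                        "slope": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "p_value": np.nan,
                        "p_adjusted": np.nan,
                        "computed": False,
                    }
                )
        if family == "cell_scores":
            done = [r for r in fam_rows if r["computed"]]
            if done:
                adj = bonferroni([r["p_value"] for r in done])
                for r, pa in zip(done, adj):
                    r["p_adjusted"] = pa
        reg_rows.extend(fam_rows)

    return CohortResult(
        group_a=ga,
        group_b=gb,
        metric_tests=metric_tests,
        correlations=pd.DataFrame(corr_rows),
        regressions=pd.DataFrame(reg_rows),
    )
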