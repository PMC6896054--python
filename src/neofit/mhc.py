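"""MHC class I binding: best-allele Kd selection, binding filter, amplitude.

The binding amplitude A = Kd_WT / Kd_MT captures both how well the mutant
peptide binds MHC class I and how poorly its wild-type counterpart does
(tolerance: T cells recognizing a strongly presented self peptide are
deleted during development). An optional cap on the wild-type Kd is exposed
as a hook for down-weighting dissociation constants predicted far outside a
predictor's trained range.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence, Tuple, Union

KdSource = Union[Mapping[Tuple[str, str], float], Callable[[str, str], float]]


class KdLookupError(KeyError):
    """A (peptide, allele) pair is absent from the Kd source."""


def _lookup(kd_source: KdSource, peptide: str, allele: str) -> float:
    if callable(kd_source):
        return float(kd_source(peptide, allele))
    try:
        return float(kd_source[(peptide, allele)])
    except KeyError as exc:
        raise KdLookupError(f"no Kd for peptide {peptide!r}, allele {allele!r}") from exc


def best_kd(
    peptide: str, alleles: Sequence[str], kd_source: KdSource
) -> Tuple[float, str]:
    """Minimum dissociation constant over the sample's alleles.

    The lowest Kd (strongest binder) wins; ties resolve to the first allele
    in the given order. Applied independently to mutant and wild-type
    peptides.
    """
    if not alleles:
        raise ValueError("at least one HLA allele is required")
    best_val: Optional[float] = None
    best_allele = ""
    for allele in alleles:
        kd = _lookup(kd_source, peptide, allele)
        if kd <= 0:
            raise ValueError(f"non-positive Kd {kd} for ({peptide}, {allele})")
        if best_val is None or kd < best_val:
            best_val, best_allele = kd, allele
    assert best_val is not None
    return best_val, best_allele


def is_binding(kd_mt_nM: float, threshold_nM: float = 500.0) -> bool:
    """Strictly-below-threshold binding test on the mutant 9-mer's Kd."""
    if kd_mt_nM <= 0:
        raise ValueError("kd_mt_nM must be > 0")
    return kd_mt_nM < threshold_nM


def amplitude(
    kd_wt_nM: float, kd_mt_nM: float, wt_kd_cap_nM: Optional[float] = None
) -> float:
    """MHC-binding amplitude A = Kd_WT / Kd_MT (wild-type Kd optionally capped)."""
    if kd_wt_nM <= 0 or kd_mt_nM <= 0:
        raise ValueError("dissociation constants must be > 0")
    if wt_kd_cap_nM is not None:
        if wt_kd_cap_nM <= 0:
            raise ValueError("wt_kd_cap_nM must be > 0")
        kd_wt_nM = min(kd_wt_nM, wt_kd_cap_nM)
    return kd_wt_nM / kd_mt_nM


@dataclass(frozen=True)
class BindingScore:
    """Per-9-mer MHC binding summary."""

    kd_mt_nM: float
    kd_wt_nM: float
    best_allele_mt: str
    best_allele_wt: str
    amplitude: float
    is_binding: bool


def score_binding(
    mutant_9mer: str,
    wildtype_9mer: str,
    alleles: Sequence[str],
    kd_source_mt: KdSource,
    kd_source_wt: Optional[KdSource] = None,
    threshold_nM: float = 500.0,
    wt_kd_cap_nM: Optional[float] = None,
) -> BindingScore:
    """Best-allele Kd for both peptides, the binding flag, and A."""
    if kd_source_wt is None:
        kd_source_wt = kd_source_mt
    kd_mt, allele_mt = best_kd(mutant_9mer, alleles, kd_source_mt)
    kd_wt, allele_wt = best_kd(wildtype_9mer, alleles, kd_source_wt)
    return BindingScore(
        kd_mt_nM=kd_mt,
        kd_wt_nM=kd_wt,
        best_allele_mt=allele_mt,
        best_allele_wt=allele_wt,
        amplitude=amplitude(kd_wt, kd_mt, wt_kd_cap_nM),
        is_binding=is_binding(kd_mt, threshold_nM),
    )
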