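"""Peptide construction around somatic amino-acid changes.

Each nonsynonymous variant yields a mutant/wild-type peptide pair of up to
21 residues (10 on each flank of the changed residue, truncated at the
protein termini), from which every contiguous 9-mer window is enumerated as
a candidate neoepitope. SNVs falling within 1 bp of an indel call are
removed first, as likely alignment artifacts.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

FLANK = 10  # residues kept on each side of the variant position
NINE = 9


class VariantConsistencyError(ValueError):
    """Protein sequence disagrees with the variant annotation."""


@dataclass(frozen=True)
class SomaticVariant:
    """One annotated somatic mutation in one sample.

    Genomic and protein coordinates are both 1-based. ``protein_pos``,
    ``ref_aa`` and ``alt_aa`` are meaningful only for nonsynonymous SNVs.
    """

    sample_id: str
    chrom: str
    pos: int
    variant_class: str  # "snv" | "indel"
    gene: str = ""
    transcript_id: str = ""
    protein_pos: int = 0
    ref_aa: str = ""
    alt_aa: str = ""
    is_nonsynonymous: bool = False

    def __post_init__(self) -> None:
        if self.variant_class not in ("snv", "indel"):
            raise ValueError(f"variant_class must be 'snv' or 'indel', got {self.variant_class!r}")
        if self.is_nonsynonymous:
            if self.protein_pos < 1:
                raise ValueError("protein_pos must be >= 1 for nonsynonymous variants")
            if self.ref_aa == self.alt_aa:
                raise ValueError("ref_aa must differ from alt_aa for nonsynonymous variants")


@dataclass(frozen=True)
class PeptidePair:
    """Mutant/wild-type peptide window around a single substitution."""

    mutant_seq: str
    wildtype_seq: str
    mutant_offset: int  # 1-based index of the changed residue within the window
    source_variant: SomaticVariant

    def __post_init__(self) -> None:
        if len(self.mutant_seq) != len(self.wildtype_seq):
            raise ValueError("mutant and wild-type windows must have equal length")
        if not 1 <= self.mutant_offset <= len(self.mutant_seq):
            raise ValueError("mutant_offset out of range")
        if len(self.mutant_seq) > 2 * FLANK + 1:
            raise ValueError("peptide window longer than 21 residues")
        diffs = [i for i, (m, w) in enumerate(zip(self.mutant_seq, self.wildtype_seq), start=1) if m != w]
        if diffs != [self.mutant_offset]:
            raise ValueError(f"sequences must differ exactly at mutant_offset; differ at {diffs}")


@dataclass(frozen=True)
class NineMerPair:
    """One 9-residue window of a peptide pair, at identical coordinates."""

    mutant_9mer: str
    wildtype_9mer: str
    window_start: int  # 1-based start within the peptide window
    contains_mutation: bool

    def __post_init__(self) -> None:
        if len(self.mutant_9mer) != NINE or len(self.wildtype_9mer) != NINE:
            raise ValueError("both windows must be exactly 9 residues")


def filter_snvs_near_indels(
    variants: Sequence[SomaticVariant], window_bp: int = 1
) -> List[SomaticVariant]:
    """Drop SNVs within ``window_bp`` of an indel in the same sample/chromosome.

    Indel records themselves are retained and input order is preserved.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    indel_pos: Dict[tuple, List[int]] = {}
    for v in variants:
        if v.variant_class == "indel":
            indel_pos.setdefault((v.sample_id, v.chrom), []).append(v.pos)
    kept: List[SomaticVariant] = []
    for v in variants:
        if v.variant_class == "snv":
            near = indel_pos.get((v.sample_id, v.chrom), ())
            if any(abs(v.pos - p) <= window_bp for p in near):
                continue
        kept.append(v)
    return kept


def build_peptide_pair(protein_seq: str, variant: SomaticVariant) -> PeptidePair:
    """Extract the <=21-residue window around the substitution.

    The window spans up to :data:`FLANK` residues on each side of
    ``variant.protein_pos`` and is truncated at the protein termini. Raises
    :class:`VariantConsistencyError` if the protein disagrees with the
    annotated reference residue.
    """
    if not variant.is_nonsynonymous:
        raise ValueError("build_peptide_pair requires a nonsynonymous variant")
    p = variant.protein_pos
    if p > len(protein_seq):
        raise VariantConsistencyError(
            f"{variant.transcript_id}: protein_pos {p} beyond protein length {len(protein_seq)}"
        )
    if protein_seq[p - 1] != variant.ref_aa:
        raise VariantConsistencyError(
            f"{variant.transcript_id} position {p}: protein has "
            f"{protein_seq[p - 1]!r}, variant annotated ref {variant.ref_aa!r}"
        )
    start = max(1, p - FLANK)
    end = min(len(protein_seq), p + FLANK)
    wt = protein_seq[start - 1 : end]
    offset = p - start + 1
    mt = wt[: offset - 1] + variant.alt_aa + wt[offset:]
    return PeptidePair(mutant_seq=mt, wildtype_seq=wt, mutant_offset=offset, source_variant=variant)


def enumerate_nine_mers(pair: PeptidePair) -> List[NineMerPair]:
    """All contiguous 9-mer windows of the pair, at shared coordinates.

    A length-L window yields L-8 pairs (13 for a full 21-mer). Windows that
    do not overlap the mutated residue are flagged ``contains_mutation=False``
    and have identical mutant and wild-type sequences. Peptides shorter
    than 9 residues yield no windows.
    """
    L = len(pair.mutant_seq)
    if L < NINE:
        logger.warning(
            "peptide of length %d (<9) for %s yields no 9-mer windows",
            L,
            pair.source_variant.transcript_id,
        )
        return []
    out: List[NineMerPair] = []
    for start in range(1, L - NINE + 2):
        out.append(
            NineMerPair(
                mutant_9mer=pair.mutant_seq[start - 1 : start + NINE - 1],
                wildtype_9mer=pair.wildtype_seq[start - 1 : start + NINE - 1],
                window_start=start,
                contains_mutation=start <= pair.mutant_offset <= start + NINE - 1,
            )
        )
    return out
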