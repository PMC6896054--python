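"""Readers and writers for the pipeline's external formats.

Variant tables arrive as annotated TSV or VCF 4.2 (INFO keys carrying the
protein-level annotation); protein sequences and epitope references as
FASTA (epitopes alternatively as one-sequence-per-line CSV); expression and
Kd tables as TSV; HLA allele lists as plain text; groove annotations as
BED (0-based half-open on disk, 1-based closed in memory). Output tables
are TSV with fixed column order and floats at 6 significant digits, so
reruns diff cleanly.
"""
from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

from .peptides import AMINO_ACIDS, SomaticVariant
from .stats import GrooveAnnotation

logger = logging.getLogger(__name__)

_AA_SET = set(AMINO_ACIDS)

VARIANT_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "variant_class",
    "gene",
    "transcript_id",
    "protein_pos",
    "ref_aa",
    "alt_aa",
    "is_nonsynonymous",
]

#: INFO keys expected in the VCF dialect.
VCF_INFO_KEYS = ("GENE", "TRANSCRIPT", "PPOS", "RAA", "AAA", "VCLASS", "NONSYN")

FLOAT_FORMAT = "%.6g"


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


# ---------------------------------------------------------------- variants


def _variant_from_fields(fields: dict, where: str) -> SomaticVariant:
    try:
        nonsyn = str(fields["is_nonsynonymous"]).strip().lower() in ("1", "true", "yes")
        return SomaticVariant(
            sample_id=str(fields["sample_id"]),
            chrom=str(fields["chrom"]),
            pos=int(fields["pos"]),
            variant_class=str(fields["variant_class"]).lower(),
            gene=str(fields.get("gene", "") or ""),
            transcript_id=str(fields.get("transcript_id", "") or ""),
            protein_pos=int(fields["protein_pos"]) if nonsyn else 0,
            ref_aa=str(fields.get("ref_aa", "") or "") if nonsyn else "",
            alt_aa=str(fields.get("alt_aa", "") or "") if nonsyn else "",
            is_nonsynonymous=nonsyn,
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"{where}: bad or missing variant annotation ({exc})") from exc


def read_variants(path: str | Path, dialect: str = "tsv") -> List[SomaticVariant]:
    """Read annotated somatic variants from TSV or VCF.

    Returns one record per (sample, variant); genomic and protein positions
    are 1-based. The VCF dialect assigns each record to every sample whose
    genotype carries the alternate allele (or to the single sample of a
    one-sample VCF).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return _read_variants_tsv(path)
    if dialect == "vcf":
        return _read_variants_vcf(path)
    raise ValueError(f"unknown variant dialect {dialect!r} (expected 'tsv' or 'vcf')")


def _read_variants_tsv(path: Path) -> List[SomaticVariant]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    out = []
    for i, row in enumerate(df.to_dict("records"), start=2):  # header is line 1
        out.append(_variant_from_fields(row, f"{path} line {i}"))
    return out


def _read_variants_vcf(path: Path) -> List[SomaticVariant]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    out = []
    for i, rec in enumerate(vcf, start=1):
        where = f"{path} record {i} ({rec.CHROM}:{rec.POS})"
        info = {k: rec.INFO.get(k) for k in VCF_INFO_KEYS}
        if info["VCLASS"] is None:
            raise FormatError(f"{where}: missing INFO/VCLASS annotation")
        nonsyn = str(info["NONSYN"]) in ("1", "True", "true")
        if nonsyn and (info["PPOS"] is None or info["RAA"] is None or info["AAA"] is None):
            raise FormatError(f"{where}: nonsynonymous record lacks PPOS/RAA/AAA annotation")
        if samples:
            gts = rec.genotype.array()
            carriers = [
                s for s, gt in zip(samples, gts) if any(int(a) > 0 for a in gt[:-1] if int(a) >= 0)
            ]
        else:
            carriers = []
        if not carriers:
            sample_field = rec.INFO.get("SAMPLE")
            if sample_field is None:
                raise FormatError(f"{where}: no carrier sample (genotypes or INFO/SAMPLE)")
            carriers = [str(sample_field)]
        for sample in carriers:
            out.append(
                _variant_from_fields(
                    {
                        "sample_id": sample,
                        "chrom": rec.CHROM,
                        "pos": rec.POS,
                        "variant_class": info["VCLASS"],
                        "gene": info["GENE"],
                        "transcript_id": info["TRANSCRIPT"],
                        "protein_pos": info["PPOS"],
                        "ref_aa": info["RAA"],
                        "alt_aa": info["AAA"],
                        "is_nonsynonymous": nonsyn,
                    },
                    where,
                )
            )
    return out


def write_variants_tsv(variants: Sequence[SomaticVariant], path: str | Path) -> None:
    df = pd.DataFrame([vars(v) for v in variants], columns=VARIANT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- expression


def read_expression(path: str | Path) -> pd.DataFrame:
    """Transcript x sample RPKM table (transcript_id index, one column per sample)."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "transcript_id":
        raise FormatError(f"{path}: first column must be 'transcript_id'")
    if df["transcript_id"].duplicated().any():
        dups = df.loc[df["transcript_id"].duplicated(), "transcript_id"].tolist()
        raise FormatError(f"{path}: duplicate transcript ids {dups[:5]}")
    df = df.set_index("transcript_id")
    vals = df.to_numpy()
    if np.isnan(vals.astype(float)).any():
        raise FormatError(f"{path}: missing expression cells")
    if (vals < 0).any():
        raise FormatError(f"{path}: negative RPKM values")
    return df.astype(float)


def write_expression(expression: pd.DataFrame, path: str | Path) -> None:
    expression.to_csv(path, sep="\t", index_label="transcript_id", float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------- sequences


def read_protein_fasta(path: str | Path) -> Dict[str, str]:
    """Protein sequences keyed by transcript id (first token of the header)."""
    seqs: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _AA_SET
        if bad:
            raise FormatError(f"{path}: {rec.id}: non-amino-acid characters {sorted(bad)}")
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate sequence id {rec.id}")
        seqs[rec.id] = seq
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_epitope_reference(path: str | Path) -> List[str]:
    """Known T-cell epitope sequences: uppercased, deduplicated, order-stable.

    Accepts FASTA (.fa/.fasta/.faa) or CSV/plain text with one sequence per
    row. Sequences shorter than 9 residues or containing letters outside
    the 20-letter alphabet are rejected.
    """
    path = Path(path)
    if path.suffix.lower() in (".fa", ".fasta", ".faa"):
        raw = [str(r.seq) for r in SeqIO.parse(str(path), "fasta")]
    else:
        raw = []
        for line in path.read_text().splitlines():
            token = line.strip().split(",")[0].strip()
            if token and token.lower() not in ("sequence", "epitope", "peptide"):
                raw.append(token)
    seen: Dict[str, None] = {}
    for seq in raw:
        seq = seq.upper()
        bad = set(seq) - _AA_SET
        if bad:
            raise FormatError(f"{path}: epitope {seq!r} has non-amino-acid characters {sorted(bad)}")
        if len(seq) < 9:
            raise FormatError(f"{path}: epitope {seq!r} shorter than 9 residues")
        seen.setdefault(seq)
    return list(seen)


def write_epitope_fasta(epitopes: Sequence[str], path: str | Path) -> None:
    write_fasta({f"epitope_{i + 1}": e for i, e in enumerate(epitopes)}, path)


# ---------------------------------------------------------------- misc inputs

_ALLELE_RE = re.compile(r"^HLA-[A-C]\*\d{2}:\d{2}$")


def read_alleles(path: str | Path) -> List[str]:
    """One HLA class I allele per line, e.g. ``HLA-A*02:01``."""
    alleles = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if not _ALLELE_RE.match(line):
            logger.warning("allele %r does not match the HLA-X*NN:NN pattern", line)
        alleles.append(line)
    if not alleles:
        raise FormatError(f"{path}: no alleles found")
    return alleles


def write_alleles(alleles: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(a + "\n" for a in alleles))


def read_kd_table(path: str | Path) -> Dict[Tuple[str, str], float]:
    """Predictor output: columns peptide, allele, kd_nM."""
    df = pd.read_csv(path, sep="\t")
    for col in ("peptide", "allele", "kd_nM"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    table: Dict[Tuple[str, str], float] = {}
    for row in df.itertuples(index=False):
        kd = float(row.kd_nM)
        if kd <= 0:
            raise FormatError(f"{path}: non-positive Kd for ({row.peptide}, {row.allele})")
        table[(str(row.peptide), str(row.allele))] = kd
    return table


def write_kd_table(table: Mapping[Tuple[str, str], float], path: str | Path) -> None:
    rows = [
        {"peptide": p, "allele": a, "kd_nM": kd} for (p, a), kd in sorted(table.items())
    ]
    pd.DataFrame(rows, columns=["peptide", "allele", "kd_nM"]).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT
    )


def read_groups(path: str | Path) -> Dict[str, str]:
    """Sample-to-group mapping from a two-column TSV (sample_id, group)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids")
    return dict(zip(df["sample_id"], df["group"]))


def write_groups(groups: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        [{"sample_id": s, "group": g} for s, g in groups.items()],
        columns=["sample_id", "group"],
    ).to_csv(path, sep="\t", index=False)


def read_groove_bed(path: str | Path) -> List[GrooveAnnotation]:
    """HLA exon intervals from BED: chrom, start (0-based), end, ``GENE|exonN``.

    Converted to 1-based closed intervals in memory.
    """
    per_gene: Dict[str, dict] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise FormatError(f"{path} line {lineno}: expected 4 BED columns")
        chrom, start, end, name = parts[:4]
        m = re.match(r"^([^|]+)\|exon(\d+)$", name)
        if not m:
            raise FormatError(f"{path} line {lineno}: name must look like 'HLA-A|exon2'")
        gene, exon = m.group(1), int(m.group(2))
        entry = per_gene.setdefault(gene, {"chrom": chrom, "exons": {}})
        if entry["chrom"] != chrom:
            raise FormatError(f"{path}: gene {gene} spans multiple chromosomes")
        entry["exons"][exon] = (int(start) + 1, int(end))
    return [
        GrooveAnnotation(
            gene=g,
            chrom=d["chrom"],
            exons=d["exons"],
            groove_exons=tuple(e for e in (2, 3) if e in d["exons"]),
        )
        for g, d in per_gene.items()
    ]


# ---------------------------------------------------------------- results


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Diff-stable TSV output: fixed column order, 6 significant digits."""
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
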