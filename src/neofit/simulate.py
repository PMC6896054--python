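"""Seeded synthetic cohorts: variants, proteome, Kd, epitopes, expression.

The exome data behind this kind of study is typically not shareable, so the
generator produces complete input bundles with the statistical structure
the analysis assumes: per-sample somatic burdens spanning orders of
magnitude, lognormal peptide:MHC dissociation constants calibrated to a
target binding fraction, a small reference set of epitopes, lognormal
per-transcript RPKM, and a group-B immune-escape effect that suppresses
expression of each sample's strongest-fitness neoantigens. Everything is a
pure function of (config, seed); a manifest records the planted ground
truth (near-indel SNVs, suppressed transcripts).

Kd values come from a hash-to-quantile predictor: a stable 64-bit mix of
(peptide, allele, seed) mapped through the lognormal quantile function.
Mutant and wild-type 9-mers differing at one residue share a positional
hash component, which induces the Kd correlation real predictors show for
near-identical peptides. The wild-type role shifts log-Kd down by a
configurable constant, emulating the empirically observed regime in which
wild-type counterparts tend to out-bind their mutant peptides (amplitude
mostly below 1).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.special import ndtri

from . import io as nio
from .config import RunConfig, SimConfig
from .peptides import AMINO_ACIDS, SomaticVariant
from .tcr import encode_peptide, encode_peptides

logger = logging.getLogger(__name__)

_U64 = np.uint64
_P1 = _U64(0x9E3779B97F4A7C15)
_P2 = _U64(0xC2B2AE3D27D4EB4F)
_P3 = _U64(0x165667B19E3779F9)
_P4 = _U64(0xD6E8FEB86659FD93)


def _mix(h: np.ndarray) -> np.ndarray:
    """splitmix64 finalizer (vectorized; uint64 arithmetic wraps by design)."""
    h = np.asarray(h, dtype=_U64)
    with np.errstate(over="ignore"):
        h = (h ^ (h >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
        h = (h ^ (h >> _U64(27))) * _U64(0x94D049BB133111EB)
    return h ^ (h >> _U64(31))


def _hash_str(s: str) -> np.ndarray:
    # 0-d uint64 array: numpy array arithmetic wraps silently on overflow
    h = np.array(1469598103934665603, dtype=_U64)
    for ch in s.encode():
        h = _mix(h ^ _U64(ch))
    return h


def _to_normal(h: np.ndarray) -> np.ndarray:
    """uint64 hash -> standard normal via the 53-bit uniform quantile."""
    u = (np.asarray(h, dtype=_U64) >> _U64(11)).astype(np.float64) * 2.0**-53
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    return ndtri(u)


def calibrate_kd_mu(
    binding_fraction_target: float, sigma: float, n_alleles: int, threshold_nM: float = 500.0
) -> float:
    """log-Kd location putting the best-over-alleles binding fraction on target.

    With independent per-allele draws, P(min Kd < t) = 1 - (1 - p1)^m, so
    the per-allele quantile p1 is solved first and mu follows from the
    lognormal quantile at the threshold.
    """
    p1 = 1.0 - (1.0 - binding_fraction_target) ** (1.0 / n_alleles)
    return float(np.log(threshold_nM) - sigma * ndtri(p1))


class SyntheticKdPredictor:
    """Deterministic stand-in for an MHC class I affinity predictor.

    Kd(peptide, allele) = exp(mu + shift + sigma * z) where z blends a
    full-peptide hash with a per-position hash (weight ``correlation``),
    all seeded. Pure in (peptide, allele, role, seed).
    """

    def __init__(self, config: SimConfig, role: str = "mt") -> None:
        if role not in ("mt", "wt"):
            raise ValueError("role must be 'mt' or 'wt'")
        self.config = config
        self.role = role
        self.sigma = config.kd_sigma
        self.mu = (
            config.kd_mu
            if config.kd_mu is not None
            else calibrate_kd_mu(
                config.binding_fraction_target, config.kd_sigma, len(config.alleles)
            )
        )
        self.shift = config.wt_log_kd_shift if role == "wt" else 0.0
        self.rho = config.kd_mt_wt_correlation
        self._seed = _mix(np.array(config.seed & 0x7FFFFFFF, dtype=_U64) ^ _P1)
        self._allele_h = {a: _hash_str(a) for a in config.alleles}

    def for_role(self, role: str) -> "SyntheticKdPredictor":
        return self if role == self.role else SyntheticKdPredictor(self.config, role)

    def _z(self, enc: np.ndarray, allele: str) -> np.ndarray:
        ah = self._allele_h.get(allele, _hash_str(allele))
        n, L = enc.shape
        codes = enc.astype(_U64)
        pos_salt = np.arange(1, L + 1, dtype=_U64) * _P3  # wrapping array product
        # full-peptide component
        h = np.full(n, self._seed ^ ah, dtype=_U64)
        for i in range(L):
            h = _mix(h ^ (codes[:, i] + _U64(1)) * _P2 ^ pos_salt[i])
        z_full = _to_normal(h)
        # positional component, shared between peptides agreeing at a position
        base = _mix(self._seed ^ ah ^ _P4)
        z_pos = np.zeros(n)
        for i in range(L):
            hp = _mix(base ^ (codes[:, i] + _U64(1)) * _P2 ^ pos_salt[i])
            z_pos += _to_normal(hp)
        z_pos /= np.sqrt(L)
        return np.sqrt(1.0 - self.rho) * z_full + np.sqrt(self.rho) * z_pos

    def kd_batch(self, enc: np.ndarray, allele: str) -> np.ndarray:
        """(n,) Kd in nM for an (n, 9) encoded peptide array under one allele."""
        return np.exp(self.mu + self.shift + self.sigma * self._z(enc, allele))

    def best_kd_batch(
        self, enc: np.ndarray, alleles: Sequence[str]
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Minimum Kd over alleles; returns (kd, winning allele index)."""
        all_kd = np.stack([self.kd_batch(enc, a) for a in alleles])
        idx = np.argmin(all_kd, axis=0)
        return all_kd[idx, np.arange(enc.shape[0])], idx

    def __call__(self, peptide: str, allele: str) -> float:
        return float(self.kd_batch(encode_peptide(peptide)[None, :], allele)[0])


# ---------------------------------------------------------------- generators


#: Approximate amino-acid frequencies of vertebrate proteomes (percent).
#: Uniform composition would overweight rare high-scoring residues (W, C)
#: and fatten the tail of chance BLOSUM62 matches.
AA_FREQUENCIES = {
    "A": 8.3, "C": 1.4, "D": 5.5, "E": 6.7, "F": 3.9, "G": 7.1, "H": 2.3,
    "I": 5.9, "K": 5.8, "L": 9.7, "M": 2.4, "N": 4.1, "P": 4.7, "Q": 3.9,
    "R": 5.5, "S": 6.6, "T": 5.4, "V": 6.9, "W": 1.1, "Y": 2.9,
}

_AA_PROBS = np.array([AA_FREQUENCIES[a] for a in AMINO_ACIDS])
_AA_PROBS = _AA_PROBS / _AA_PROBS.sum()


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length, p=_AA_PROBS))


def generate_proteome(config: SimConfig, rng: np.random.Generator) -> Dict[str, str]:
    """Random protein sequences keyed TX0001.. with realistic residue frequencies."""
    lo, hi = config.protein_length_range
    out: Dict[str, str] = {}
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        out[f"TX{i + 1:04d}"] = _random_peptide(rng, length)
    return out


def generate_epitopes(
    config: SimConfig,
    rng: np.random.Generator,
    proteome: Optional[Dict[str, str]] = None,
    predictor: Optional["SyntheticKdPredictor"] = None,
) -> List[str]:
    """Reference T-cell epitopes (deduplicated, order-stable 9-mers).

    With a proteome and Kd predictor, epitopes are the strongest-binding
    9-mer windows of the first ``epitope_source_proteins`` proteins: real
    epitope databases are dominated by peptides that were actually
    presented (strong MHC binders) and cluster on a handful of
    immunodominant antigens. Somatic mutations landing in or next to these
    source windows then yield high-similarity, often binding-competent
    neoantigens, concentrated on few transcripts -- the regime in which an
    expression-escape effect on the strongest neoantigens is observable.
    Without a proteome, epitopes are composition-matched random 9-mers.
    """
    if proteome is None or predictor is None or config.n_proteins == 0:
        seen: Dict[str, None] = {}
        while len(seen) < config.n_epitopes:
            seen.setdefault(_random_peptide(rng, 9))
        return list(seen)
    source_ids = list(proteome)[: config.epitope_source_proteins]
    windows: List[str] = []
    for tx in source_ids:
        seq = proteome[tx]
        windows.extend(seq[i : i + 9] for i in range(len(seq) - 8))
    windows = list(dict.fromkeys(windows))
    enc = encode_peptides(windows)
    kd, _ = predictor.best_kd_batch(enc, list(config.alleles))
    order = np.argsort(kd, kind="stable")
    chosen = [windows[i] for i in order[: config.n_epitopes]]
    n_binders = int((kd[order[: config.n_epitopes]] < 500.0).sum())
    if n_binders < config.n_epitopes:
        logger.info(
            "epitope reference: %d of %d selected windows are <500 nM binders",
            n_binders,
            config.n_epitopes,
        )
    return chosen


def _sample_ids(config: SimConfig) -> Tuple[List[str], Dict[str, str]]:
    ids = [f"A{i + 1}" for i in range(config.n_samples_group_a)] + [
        f"B{i + 1}" for i in range(config.n_samples_group_b)
    ]
    groups = {s: s[0] for s in ids}
    return ids, groups


# genomic layout of the synthetic proteome: each protein occupies its own
# band so nonsynonymous SNVs, indels and noncoding SNVs never collide
_BAND = 10_000_000
_INDEL_OFFSET = 5_000_000
_NONCODING_OFFSET = 7_000_000


def _protein_band(i: int) -> Tuple[str, int]:
    return f"chr{(i % 22) + 1}", (i // 22 + 1) * _BAND


def generate_variants(
    config: SimConfig, proteome: Dict[str, str], rng: np.random.Generator
) -> Tuple[List[SomaticVariant], Set[Tuple[str, str, int]]]:
    """Per-sample somatic variant tables with planted near-indel SNVs.

    Burdens are uniform over ``mutation_burden_range``. Each nonsynonymous
    SNV picks a random protein/position/alternate residue consistent with
    the proteome. A small fraction of indels plus SNVs placed 1 bp from
    them exercises the proximity filter; the planted SNV keys
    (sample, chrom, pos) are returned for ground-truth checks.
    """
    if not proteome:
        raise ValueError("proteome must be non-empty")
    tx_ids = list(proteome)
    sample_ids, _ = _sample_ids(config)
    lo, hi = config.mutation_burden_range
    variants: List[SomaticVariant] = []
    planted: Set[Tuple[str, str, int]] = set()
    aa_list = list(AMINO_ACIDS)
    for sample in sample_ids:
        burden = int(rng.integers(lo, hi + 1))
        n_indel = int(round(config.indel_fraction * burden))
        n_near = min(int(round(config.near_indel_snv_fraction * burden)), n_indel)
        n_rest = burden - n_indel - n_near
        n_nonsyn = int(round(config.fraction_nonsynonymous * n_rest))
        n_noncoding = n_rest - n_nonsyn

        indel_pos: List[Tuple[str, int]] = []
        for j in range(n_indel):
            pi = int(rng.integers(0, len(tx_ids)))
            chrom, base = _protein_band(pi)
            pos = base + _INDEL_OFFSET + j * 10
            indel_pos.append((chrom, pos))
            variants.append(
                SomaticVariant(sample_id=sample, chrom=chrom, pos=pos, variant_class="indel")
            )
        for j in range(n_near):
            chrom, pos = indel_pos[j]
            near = pos + (1 if rng.random() < 0.5 else -1)
            variants.append(
                SomaticVariant(sample_id=sample, chrom=chrom, pos=near, variant_class="snv")
            )
            planted.add((sample, chrom, near))
        for _ in range(n_nonsyn):
            pi = int(rng.integers(0, len(tx_ids)))
            tx = tx_ids[pi]
            seq = proteome[tx]
            ppos = int(rng.integers(1, len(seq) + 1))
            ref = seq[ppos - 1]
            alt = aa_list[int(rng.integers(0, 20))]
            while alt == ref:
                alt = aa_list[int(rng.integers(0, 20))]
            chrom, base = _protein_band(pi)
            variants.append(
                SomaticVariant(
                    sample_id=sample,
                    chrom=chrom,
                    pos=base + 3 * (ppos - 1),
                    variant_class="snv",
                    gene=f"GENE{pi + 1:04d}",
                    transcript_id=tx,
                    protein_pos=ppos,
                    ref_aa=ref,
                    alt_aa=alt,
                    is_nonsynonymous=True,
                )
            )
        for j in range(n_noncoding):
            pi = int(rng.integers(0, len(tx_ids)))
            chrom, base = _protein_band(pi)
            variants.append(
                SomaticVariant(
                    sample_id=sample,
                    chrom=chrom,
                    pos=base + _NONCODING_OFFSET + j * 10,
                    variant_class="snv",
                )
            )
    return variants, planted


def generate_expression(
    config: SimConfig,
    records: pd.DataFrame,
    groups: Dict[str, str],
    transcripts: Sequence[str],
    rng: np.random.Generator,
) -> Tuple[pd.DataFrame, List[Tuple[str, str]]]:
    """Transcript x sample RPKM with the group-B suppression effect applied.

    Baseline RPKM is lognormal per cell. In each group-B sample, the
    transcripts carrying that sample's top ``suppression_top_k`` records by
    fitness cost are multiplied by ``suppression_effect``. Returns the
    table and the (sample, transcript) pairs actually suppressed.
    """
    samples = sorted(groups)
    vals = rng.lognormal(
        mean=config.expression_mu,
        sigma=config.expression_sigma,
        size=(len(transcripts), len(samples)),
    )
    expr = pd.DataFrame(vals, index=list(transcripts), columns=samples)
    suppressed: List[Tuple[str, str]] = []
    if config.suppression_top_k > 0 and config.suppression_effect < 1.0:
        for sample in samples:
            if groups[sample] != "B":
                continue
            sub = records[
                (records["sample_id"] == sample) & (records["fitness"].fillna(0) > 0)
            ]
            if sub.empty:
                continue
            # rank distinct transcripts by their best record's fitness: the
            # 9-mer windows of one variant share a transcript, so the unit
            # of expression escape is the transcript, not the window
            ranked = sub.sort_values("fitness", ascending=False, kind="mergesort")
            top_tx = list(dict.fromkeys(ranked["transcript_id"]))[: config.suppression_top_k]
            for tx in top_tx:
                if tx in expr.index:
                    expr.loc[tx, sample] *= config.suppression_effect
                    suppressed.append((sample, tx))
    return expr, suppressed


@dataclass
class CohortBundle:
    """In-memory synthetic cohort plus its planted ground truth."""

    sim_config: SimConfig
    proteome: Dict[str, str]
    epitopes: List[str]
    alleles: List[str]
    variants: List[SomaticVariant]
    groups: Dict[str, str]
    expression: pd.DataFrame
    records: pd.DataFrame
    counts: pd.DataFrame
    planted_near_indel_snvs: Set[Tuple[str, str, int]]
    suppressed: List[Tuple[str, str]] = field(default_factory=list)


def generate_cohort(
    sim_config: SimConfig,
    run_config: Optional[RunConfig] = None,
    outdir: Optional[str | Path] = None,
) -> CohortBundle:
    """Generate a full input bundle; optionally write it in pipeline formats.

    The scoring stage runs once internally so the expression effect can
    target each sample's strongest neoantigens. With an ``outdir`` the
    bundle is written as variants.tsv, proteins.fasta, alleles.txt,
    epitopes.fasta, expression.tsv, groups.tsv, sim_config.yaml and
    manifest.tsv (planted ground truth).
    """
    from .pipeline import attach_expression, score_cohort

    run_config = run_config or RunConfig()
    rng = np.random.default_rng(sim_config.seed)
    proteome = generate_proteome(sim_config, rng)
    predictor = SyntheticKdPredictor(sim_config, role="mt")
    epitopes = generate_epitopes(sim_config, rng, proteome, predictor)
    variants, planted = generate_variants(sim_config, proteome, rng)
    _, groups = _sample_ids(sim_config)
    records, counts = score_cohort(
        variants,
        proteome,
        list(sim_config.alleles),
        epitopes,
        run_config,
        kd_source_mt=predictor,
        kd_source_wt=predictor.for_role("wt"),
    )
    expression, suppressed = generate_expression(
        sim_config, records, groups, list(proteome), rng
    )
    records = attach_expression(records, expression)
    bundle = CohortBundle(
        sim_config=sim_config,
        proteome=proteome,
        epitopes=epitopes,
        alleles=list(sim_config.alleles),
        variants=variants,
        groups=groups,
        expression=expression,
        records=records,
        counts=counts,
        planted_near_indel_snvs=planted,
        suppressed=suppressed,
    )
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def write_bundle(bundle: CohortBundle, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nio.write_variants_tsv(bundle.variants, outdir / "variants.tsv")
    nio.write_fasta(bundle.proteome, outdir / "proteins.fasta")
    nio.write_alleles(bundle.alleles, outdir / "alleles.txt")
    nio.write_epitope_fasta(bundle.epitopes, outdir / "epitopes.fasta")
    nio.write_expression(bundle.expression, outdir / "expression.tsv")
    nio.write_groups(bundle.groups, outdir / "groups.tsv")
    bundle.sim_config.to_yaml(outdir / "sim_config.yaml")
    manifest = [
        {"kind": "planted_near_indel_snv", "sample_id": s, "key": f"{c}:{p}"}
        for s, c, p in sorted(bundle.planted_near_indel_snvs)
    ] + [
        {"kind": "suppressed_transcript", "sample_id": s, "key": t}
        for s, t in sorted(bundle.suppressed)
    ]
    pd.DataFrame(manifest, columns=["kind", "sample_id", "key"]).to_csv(
        outdir / "manifest.tsv", sep="\t", index=False
    )
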