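"""TCR recognition potential from sequence similarity to known epitopes.

A candidate neoantigen s is compared with every epitope e in a reference
set of experimentally characterized linear T-cell epitopes. The similarity
|s,e| is the best-scoring ungapped local alignment under BLOSUM62 (maximum,
over all equal-length contiguous substring pairs of s and e, of the summed
substitution scores). The similarities act as binding energies in a
two-state partition function:

    R = Z(k)^-1 * sum_e exp[-k (a - |s,e|)],   Z(k) = 1 + sum_e exp[-k (a - |s,e|)]

where ``a`` shifts and ``k`` steepens the binding curve. R lies in [0, 1):
the '1' in Z is the unbound state, so R is the equilibrium probability that
the neoantigen is TCR-bound. Exponents of magnitude ~1e2 arise at the
default k, so the sum is evaluated in log space.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, List, Sequence

import numpy as np
from scipy.special import expit, logsumexp

from .peptides import AMINO_ACIDS

logger = logging.getLogger(__name__)

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

_ONE_MINUS = float(np.nextafter(1.0, 0.0))  # largest double strictly below 1


@dataclass(frozen=True)
class TcrParams:
    """Binding-curve parameters: horizontal displacement ``a``, steepness ``k``."""

    a: float = 26.0
    k: float = 4.87

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be > 0")


@lru_cache(maxsize=1)
def blosum62_matrix() -> np.ndarray:
    """Canonical NCBI BLOSUM62 as a 20x20 int array over :data:`AMINO_ACIDS` order."""
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    out = np.zeros((20, 20), dtype=np.int64)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            out[i, j] = int(mat[a, b])
    return out


def encode_peptide(seq: str) -> np.ndarray:
    """Map a peptide to integer residue codes; rejects non-standard letters."""
    try:
        return np.array([_AA_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"residue {exc.args[0]!r} outside the 20-letter alphabet in {seq!r}") from None


def encode_peptides(seqs: Sequence[str]) -> np.ndarray:
    """Stack equal-length peptides into an (n, L) code array."""
    if not seqs:
        return np.zeros((0, 0), dtype=np.int64)
    return np.stack([encode_peptide(s) for s in seqs])


def gapless_alignment_score(s: str, e: str, matrix: np.ndarray | None = None) -> int:
    """Maximal ungapped local alignment score |s,e| under a substitution matrix.

    Considers every pair of equal-length contiguous substrings (length >= 1)
    of ``s`` and ``e``; equivalently, the best contiguous run along any
    diagonal of the position-score grid.
    """
    if matrix is None:
        matrix = blosum62_matrix()
    sc = encode_peptide(s)
    ec = encode_peptide(e)
    if sc.size == 0 or ec.size == 0:
        raise ValueError("sequences must be non-empty")
    best = None
    for d in range(-(len(sc) - 1), len(ec)):
        i0 = max(0, -d)
        i1 = min(len(sc), len(ec) - d)
        run = 0
        for i in range(i0, i1):
            x = int(matrix[sc[i], ec[i + d]])
            run = max(run + x, x)
            best = x if best is None else max(best, run)
    assert best is not None
    return best


def alignment_scores_batch(
    queries: np.ndarray, epitope: np.ndarray, matrix: np.ndarray | None = None
) -> np.ndarray:
    """Vectorized |s,e| of many equal-length queries against one epitope.

    ``queries`` is an (n, Lq) code array, ``epitope`` a (Le,) code array.
    Returns an (n,) integer array. Same semantics as
    :func:`gapless_alignment_score`, batched over diagonals with a running
    best-suffix (Kadane) recurrence.
    """
    if matrix is None:
        matrix = blosum62_matrix()
    n, Lq = queries.shape
    Le = epitope.shape[0]
    S = matrix[queries[:, :, None], epitope[None, None, :]]  # (n, Lq, Le)
    best = np.full(n, np.iinfo(np.int64).min, dtype=np.int64)
    for d in range(-(Lq - 1), Le):
        i0 = max(0, -d)
        i1 = min(Lq, Le - d)
        idx = np.arange(i0, i1)
        diag = S[:, idx, idx + d]  # (n, run length)
        run = np.zeros(n, dtype=np.int64)
        for t in range(diag.shape[1]):
            x = diag[:, t]
            run = np.maximum(run + x, x)
            np.maximum(best, run, out=best)
    return best


def recognition_potential(
    s: str,
    epitopes: Iterable[str],
    params: TcrParams = TcrParams(),
    matrix: np.ndarray | None = None,
) -> float:
    """TCR recognition potential R = S/(1+S), S = sum_e exp[-k (a - |s,e|)]."""
    eps = list(epitopes)
    if not eps:
        logger.warning("empty epitope reference: R = 0 for all peptides")
        return 0.0
    scores = np.array(
        [gapless_alignment_score(s, e, matrix) for e in eps], dtype=float
    )
    log_s = logsumexp(-params.k * (params.a - scores))
    # S/(1+S) = sigmoid(log S); clamp to the largest double below 1 so the
    # strict R < 1 bound survives rounding at huge S
    return float(min(expit(log_s), _ONE_MINUS))


def recognition_potential_batch(
    queries: Sequence[str] | np.ndarray,
    epitopes: Sequence[str],
    params: TcrParams = TcrParams(),
    matrix: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorized :func:`recognition_potential` over many 9-mers."""
    enc = queries if isinstance(queries, np.ndarray) else encode_peptides(queries)
    n = enc.shape[0]
    if n == 0:
        return np.zeros(0)
    if not epitopes:
        logger.warning("empty epitope reference: R = 0 for all peptides")
        return np.zeros(n)
    if matrix is None:
        matrix = blosum62_matrix()
    log_terms = np.empty((len(epitopes), n))
    for j, e in enumerate(epitopes):
        sc = alignment_scores_batch(enc, encode_peptide(e), matrix)
        log_terms[j] = -params.k * (params.a - sc.astype(float))
    log_s = logsumexp(log_terms, axis=0)
    return np.minimum(expit(log_s), _ONE_MINUS)


def export_similarity_table(
    queries: Sequence[str], epitopes: Sequence[str], matrix: np.ndarray | None = None
) -> "pd.DataFrame":  # noqa: F821 - imported lazily
    """Per-(neoantigen, epitope) alignment scores, for audit."""
    import pandas as pd

    rows: List[dict] = []
    for s in queries:
        for e in epitopes:
            rows.append(
                {"neoantigen": s, "epitope": e, "score": gapless_alignment_score(s, e, matrix)}
            )
    return pd.DataFrame(rows, columns=["neoantigen", "epitope", "score"])
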