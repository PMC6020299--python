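"""Optimal affine-gap pairwise protein alignment (Gotoh dynamic programming).

Local mode returns the maximal-scoring segment pair (Smith-Waterman);
global mode is Needleman-Wunsch. A gap of length L costs
``gap_open + gap_extend * L`` (BLAST convention: existence 11, extension 1).
Ties are broken deterministically: diagonal over up over left, and in local
mode the end cell with the smallest (query, subject) coordinates.

The scoring alphabet is the 20 standard residues plus X; any pair involving
X scores 0 regardless of the matrix. B, Z, U, J and ``*`` are mapped to X.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

ALPHABET = "ARNDCQEGHILKMFPSTWYVX"
_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
_X = _AA_INDEX["X"]

NEG_INF = -10 ** 9


@lru_cache(maxsize=4)
def score_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """21x21 integer substitution-score matrix over ``ALPHABET``; X scores 0."""
    m = substitution_matrices.load(name)
    out = np.zeros((len(ALPHABET), len(ALPHABET)), dtype=np.int32)
    for i, a in enumerate(ALPHABET[:-1]):
        for j, b in enumerate(ALPHABET[:-1]):
            out[i, j] = int(m[a, b])
    out[_X, :] = 0
    out[:, _X] = 0
    return out


def encode(seq: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(c, _X) for c in seq.upper()], dtype=np.int8)


@dataclass
class ProteinAlignment:
    """Best-path summary of one pairwise protein alignment.

    Spans are 1-based residue coordinates on the ungapped sequences.
    n_aligned_columns counts columns with a residue in both rows;
    n_similar counts aligned columns with a positive substitution score.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    score: float
    n_identical: int
    n_similar: int
    n_aligned_columns: int
    query_aln: str = ""
    subject_aln: str = ""

    def __post_init__(self):
        if not (self.n_identical <= self.n_similar <= self.n_aligned_columns):
            raise ValueError("identical <= similar <= aligned violated")

    @property
    def identity_frac(self) -> float:
        return self.n_identical / self.n_aligned_columns if self.n_aligned_columns else 0.0

    @property
    def similarity_frac(self) -> float:
        return self.n_similar / self.n_aligned_columns if self.n_aligned_columns else 0.0


@njit(cache=True)
def _gotoh(q, s, sub, gap_open, gap_extend, local):
    """Fill H/E/F and pointer matrices; return (best_i, best_j, best_score).

    Pointers: 0 stop, 1 diagonal (from H), 2 up/from F, 3 left/from E.
    E = gap in query (consume subject), F = gap in subject (consume query).
    """
    n, m = len(q), len(s)
    H = np.empty((n + 1, m + 1), dtype=np.int64)
    E = np.empty((n + 1, m + 1), dtype=np.int64)
    F = np.empty((n + 1, m + 1), dtype=np.int64)
    ptrH = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrE = np.zeros((n + 1, m + 1), dtype=np.int8)  # 1 = opened here, 0 = extended
    ptrF = np.zeros((n + 1, m + 1), dtype=np.int8)
    go = gap_open + gap_extend  # cost of a length-1 gap
    H[0, 0] = 0
    E[0, 0] = NEG_INF
    F[0, 0] = NEG_INF
    for j in range(1, m + 1):
        E[0, j] = -(gap_open + gap_extend * j)
        F[0, j] = NEG_INF
        H[0, j] = 0 if local else E[0, j]
        ptrH[0, j] = 0 if local else 3
        ptrE[0, j] = 1 if j == 1 else 0
    for i in range(1, n + 1):
        F[i, 0] = -(gap_open + gap_extend * i)
        E[i, 0] = NEG_INF
        H[i, 0] = 0 if local else F[i, 0]
        ptrH[i, 0] = 0 if local else 2
        ptrF[i, 0] = 1 if i == 1 else 0
    best_i, best_j, best = 0, 0, 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e_open = H[i, j - 1] - go
            e_ext = E[i, j - 1] - gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                ptrE[i, j] = 1
            else:
                E[i, j] = e_ext
                ptrE[i, j] = 0
            f_open = H[i - 1, j] - go
            f_ext = F[i - 1, j] - gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                ptrF[i, j] = 1
            else:
                F[i, j] = f_ext
                ptrF[i, j] = 0
            diag = H[i - 1, j - 1] + sub[qi, s[j - 1]]
            h = diag
            p = 1
            if F[i, j] > h:
                h = F[i, j]
                p = 2
            if E[i, j] > h:
                h = E[i, j]
                p = 3
            if local and h <= 0:
                h = 0
                p = 0
            H[i, j] = h
            ptrH[i, j] = p
            if local and h > best:
                best, best_i, best_j = h, i, j
    if not local:
        best_i, best_j, best = n, m, H[n, m]
    return best_i, best_j, best, ptrH, ptrE, ptrF, H


def align_proteins(query_seq: str, subject_seq: str,
                   substitution_matrix: str | np.ndarray = "BLOSUM62",
                   gap_open: int = 11, gap_extend: int = 1,
                   mode: str = "local",
                   query_id: str = "query", subject_id: str = "subject",
                   ) -> ProteinAlignment:
    """Optimal affine-gap alignment of two protein sequences.

    Raises ValueError on an empty sequence or unknown mode.
    """
    if not query_seq or not subject_seq:
        raise ValueError("empty sequence in align_proteins")
    if mode not in ("local", "global"):
        raise ValueError(f"unknown mode {mode!r}")
    sub = (score_matrix(substitution_matrix)
           if isinstance(substitution_matrix, str) else
           np.asarray(substitution_matrix, dtype=np.int32))
    q = encode(query_seq)
    s = encode(subject_seq)
    bi, bj, score, ptrH, ptrE, ptrF, _H = _gotoh(
        q, s, sub, gap_open, gap_extend, mode == "local")
    # traceback
    i, j = bi, bj
    qa, sa = [], []
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                qa.append(query_seq[i - 1])
                sa.append(subject_seq[j - 1])
                i, j = i - 1, j - 1
            elif p == 2:
                state = "F"
            else:
                state = "E"
        elif state == "F":  # gap in subject, consume query
            opened = ptrF[i, j]
            qa.append(query_seq[i - 1])
            sa.append("-")
            i -= 1
            state = "H" if opened else "F"
        else:  # E: gap in query, consume subject
            opened = ptrE[i, j]
            qa.append("-")
            sa.append(subject_seq[j - 1])
            j -= 1
            state = "H" if opened else "E"
    qa.reverse()
    sa.reverse()
    q_start, s_start = i + 1, j + 1
    n_cols = n_id = n_sim = 0
    for a, b in zip(qa, sa):
        if a != "-" and b != "-":
            n_cols += 1
            ia, ib = _AA_INDEX.get(a, _X), _AA_INDEX.get(b, _X)
            if a == b:
                n_id += 1
            if sub[ia, ib] > 0:
                n_sim += 1
    return ProteinAlignment(
        query_id=query_id, subject_id=subject_id,
        q_start=q_start if bi else 1, q_end=bi if bi else 0,
        s_start=s_start if bj else 1, s_end=bj if bj else 0,
        score=float(score), n_identical=n_id, n_similar=n_sim,
        n_aligned_columns=n_cols,
        query_aln="".join(qa), subject_aln="".join(sa))


def alignment_score(query_seq: str, subject_seq: str, **kw) -> float:
    """Score only (same parameters as align_proteins)."""
    return align_proteins(query_seq, subject_seq, **kw).score
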