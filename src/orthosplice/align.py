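"""Exact affine-gap local alignment (Gotoh) kernels.

These numba kernels are the scoring engine shared by the heuristic search
and by :func:`orthosplice.search.smith_waterman_oracle`. Gap convention: a
gap of length L costs ``gap_open + gap_extend * L`` (the first gapped
column pays open + extend).

Sequences are encoded to small integer alphabets; ``N`` (nt) and ``X``
(protein) score as mismatches against everything, including themselves, so
ambiguous positions never count as identical.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NT_ALPHABET = "ACGTN"
# BLOSUM62 order used by NCBI, with X/*/gap handled explicitly.
AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"

_NT_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate(NT_ALPHABET):
    _NT_CODE[ord(_c)] = _i
    _NT_CODE[ord(_c.lower())] = _i

_AA_CODE = np.full(256, 22, dtype=np.uint8)  # unknowns -> X
for _i, _c in enumerate(AA_ALPHABET):
    _AA_CODE[ord(_c)] = _i
    _AA_CODE[ord(_c.lower())] = _i


def encode_nt(seq: str) -> np.ndarray:
    return _NT_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]

def encode_aa(seq: str) -> np.ndarray:
    return _AA_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def nt_matrix(match: int, mismatch: int) -> np.ndarray:
    """5x5 nucleotide scoring matrix; N scores `mismatch` against all."""
    m = np.full((5, 5), mismatch, dtype=np.int64)
    for i in range(4):
        m[i, i] = match
    m[4, :] = mismatch
    m[:, 4] = mismatch
    return m


_blosum_cache: dict[str, np.ndarray] = {}


def protein_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """Protein scoring matrix in AA_ALPHABET order (from Biopython's tables)."""
    if name not in _blosum_cache:
        from Bio.Align import substitution_matrices

        raw = substitution_matrices.load(name)
        k = len(AA_ALPHABET)
        m = np.full((k, k), -4, dtype=np.int64)
        for i, a in enumerate(AA_ALPHABET):
            for j, b in enumerate(AA_ALPHABET):
                try:
                    m[i, j] = int(raw[a, b])
                except (KeyError, IndexError):
                    pass
        # X and * never count toward identity and never score positively
        m[22, :] = np.minimum(m[22, :], -1)
        m[:, 22] = np.minimum(m[:, 22], -1)
        _blosum_cache[name] = m
    return _blosum_cache[name]


NEG = -(10**9)


@njit(cache=True)
def sw_score(a, b, sub, gap_open, gap_extend):
    """Optimal local alignment score (score-only, linear memory)."""
    la, lb = a.shape[0], b.shape[0]
    H = np.zeros(lb + 1, np.int64)
    E = np.full(lb + 1, NEG, np.int64)
    best = 0
    for i in range(1, la + 1):
        diag = 0
        F = NEG
        ai = a[i - 1]
        for j in range(1, lb + 1):
            e = E[j] - gap_extend
            eo = H[j] - gap_open - gap_extend
            if eo > e:
                e = eo
            E[j] = e
            f = F - gap_extend
            fo = H[j - 1] - gap_open - gap_extend
            if fo > f:
                f = fo
            F = f
            h = diag + sub[ai, b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            diag = H[j]
            H[j] = h
            if h > best:
                best = h
    return best


@njit(cache=True)
def _sw_fill(a, b, sub, gap_open, gap_extend):
    la, lb = a.shape[0], b.shape[0]
    H = np.zeros((la + 1, lb + 1), np.int64)
    ptrH = np.zeros((la + 1, lb + 1), np.uint8)  # 0 stop, 1 diag, 2 E(gap in a), 3 F(gap in b)
    ptrE = np.zeros((la + 1, lb + 1), np.uint8)  # 1 = extend
    ptrF = np.zeros((la + 1, lb + 1), np.uint8)
    E = np.full(lb + 1, NEG, np.int64)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, la + 1):
        F = NEG
        ai = a[i - 1]
        for j in range(1, lb + 1):
            e = E[j] - gap_extend
            eo = H[i - 1][j] - gap_open - gap_extend
            if eo >= e:
                e = eo
                ptrE[i, j] = 0
            else:
                ptrE[i, j] = 1
            E[j] = e
            f = F - gap_extend
            fo = H[i][j - 1] - gap_open - gap_extend
            if fo >= f:
                f = fo
                ptrF[i, j] = 0
            else:
                ptrF[i, j] = 1
            F = f
            d = H[i - 1][j - 1] + sub[ai, b[j - 1]]
            h = 0
            p = 0
            if d > h:
                h = d
                p = 1
            if e > h:
                h = e
                p = 2
            if f > h:
                h = f
                p = 3
            H[i, j] = h
            ptrH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, ptrH, ptrE, ptrF


@njit(cache=True)
def _sw_traceback(a, b, bi, bj, ptrH, ptrE, ptrF):
    # returns column lists (qpos, spos), -1 marking a gap; reversed order
    n = bi + bj
    qcol = np.empty(n, np.int64)
    scol = np.empty(n, np.int64)
    k = 0
    i, j = bi, bj
    state = 0  # 0 = H
    while i > 0 and j > 0:
        if state == 0:
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                qcol[k] = i - 1
                scol[k] = j - 1
                k += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 3
        elif state == 2:  # E: gap in b-direction? E consumes a[i-1] (gap in b)
            qcol[k] = i - 1
            scol[k] = -1
            k += 1
            if ptrE[i, j] == 0:
                state = 0
            i -= 1
        else:  # F consumes b[j-1] (gap in a)
            qcol[k] = -1
            scol[k] = j - 1
            k += 1
            if ptrF[i, j] == 0:
                state = 0
            j -= 1
    return qcol[:k][::-1].copy(), scol[:k][::-1].copy()


def sw_align(a: np.ndarray, b: np.ndarray, sub: np.ndarray,
             gap_open: int, gap_extend: int):
    """Optimal local alignment with traceback.

    Returns (score, qcols, scols): aligned column index arrays into a and b,
    with -1 for gap positions. Empty arrays when the best score is 0.
    """
    score, bi, bj, ptrH, ptrE, ptrF = _sw_fill(a, b, sub, gap_open, gap_extend)
    if score <= 0:
        return 0, np.empty(0, np.int64), np.empty(0, np.int64)
    qcols, scols = _sw_traceback(a, b, bi, bj, ptrH, ptrE, ptrF)
    return int(score), qcols, scols


@njit(cache=True)
def ungapped_xdrop(a, b, qpos, spos, k, sub, xdrop):
    """X-drop ungapped extension of a length-k seed; returns the best score."""
    score = 0
    for t in range(k):
        score += sub[a[qpos + t], b[spos + t]]
    best = score
    # extend right
    i = qpos + k
    j = spos + k
    cur = score
    while i < a.shape[0] and j < b.shape[0]:
        cur += sub[a[i], b[j]]
        if cur > best:
            best = cur
        if cur < best - xdrop:
            break
        i += 1
        j += 1
    # extend left
    cur = best
    i = qpos - 1
    j = spos - 1
    while i >= 0 and j >= 0:
        cur += sub[a[i], b[j]]
        if cur > best:
            best = cur
        if cur < best - xdrop:
            break
        i -= 1
        j -= 1
    return best
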