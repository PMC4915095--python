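"""Pedigree and genomic relationship matrices for single-step evaluation.

The single-step mixed model replaces the inverse of the pedigree
numerator relationship matrix A with the inverse of H, which augments
A with marker information for the genotyped subset:

    H^-1 = A^-1 + [0 0; 0  Gb^-1 - A22^-1]

where A22 is the pedigree relationship block of the genotyped animals
and Gb is the (slightly pedigree-blended, for invertibility) genomic
relationship matrix of VanRaden's method 1.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

__all__ = [
    "build_A",
    "inbreeding",
    "build_Ainv",
    "extract_A22",
    "observed_freqs",
    "build_G",
    "build_Hinv",
    "save_matrix",
]


def _check_pedigree(sire: np.ndarray, dam: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sire = np.asarray(sire, dtype=np.int64)
    dam = np.asarray(dam, dtype=np.int64)
    n = len(sire)
    ids = np.arange(1, n + 1)
    if np.any(sire < 0) or np.any(dam < 0):
        raise ValueError("parent codes must be >= 0 (0 = unknown)")
    if np.any(sire >= ids) or np.any(dam >= ids):
        raise ValueError("pedigree must be sorted so parents precede offspring "
                         "(this also rules out cycles)")
    return sire, dam


def build_A(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Numerator relationship matrix by the tabular method (dense).

    a_ij = (a_{j,s(i)} + a_{j,d(i)}) / 2 for j < i and
    a_ii = 1 + a_{s(i),d(i)} / 2; unknown parents contribute zero.
    """
    sire, dam = _check_pedigree(sire, dam)
    n = len(sire)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i] - 1, dam[i] - 1
        row = np.zeros(n)
        if s >= 0:
            row += 0.5 * A[s]
        if d >= 0:
            row += 0.5 * A[d]
        A[i, :i] = row[:i]
        A[:i, i] = row[:i]
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return A


def inbreeding(sire: np.ndarray, dam: np.ndarray,
               known: np.ndarray | None = None) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen & Luo recursion.

    Writes A = T D T' and uses a_ii = sum_j L_ij^2 D_j over the traced
    ancestors j of i, so the dense tabular matrix is never formed.  The
    Mendelian-sampling variance D_j uses F = -1 for unknown parents,
    which reproduces the usual 1 / 0.75-adjusted variants.

    ``known`` may carry the coefficients of a previously processed
    pedigree prefix (parents precede offspring, so a prefix is closed
    under ancestry and its values are final).
    """
    import heapq

    sire, dam = _check_pedigree(sire, dam)
    n = len(sire)
    F = np.zeros(n)
    start = 0
    if known is not None:
        start = len(known)
        F[:start] = known
    for i in range(start, n):
        if sire[i] == 0 and dam[i] == 0:
            F[i] = 0.0
            continue
        L = {i: 1.0}
        heap = [-i]
        aii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            lj = L.pop(j)
            sj, dj = sire[j] - 1, dam[j] - 1
            Fs = F[sj] if sj >= 0 else -1.0
            Fd = F[dj] if dj >= 0 else -1.0
            aii += lj * lj * (0.5 - 0.25 * (Fs + Fd))
            for p in (sj, dj):
                if p >= 0:
                    if p in L:
                        L[p] += 0.5 * lj
                    else:
                        L[p] = 0.5 * lj
                        heapq.heappush(heap, -p)
        F[i] = aii - 1.0
    return F


def build_Ainv(sire: np.ndarray, dam: np.ndarray,
               F: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse inverse of A by Henderson's rules, accounting for
    inbreeding through the Mendelian-sampling variances.

    Precomputed inbreeding coefficients may be passed as ``F``.
    """
    sire, dam = _check_pedigree(sire, dam)
    n = len(sire)
    if F is None:
        F = inbreeding(sire, dam)
    Fpad = np.concatenate([[-1.0], F])  # F of "unknown parent 0" = -1
    d = 0.5 - 0.25 * (Fpad[sire] + Fpad[dam])
    # unknown parents: their F enters as -1 which reproduces the 3/4 and 1 rules
    alpha = 1.0 / d
    rows, cols, vals = [], [], []
    ids = np.arange(n)
    s = sire - 1
    m = dam - 1
    has_s = s >= 0
    has_d = m >= 0
    # animal-animal
    rows.append(ids); cols.append(ids); vals.append(alpha)
    # animal-parent and parent-parent contributions
    for hp, p in ((has_s, s), (has_d, m)):
        rows.append(ids[hp]); cols.append(p[hp]); vals.append(-0.5 * alpha[hp])
        rows.append(p[hp]); cols.append(ids[hp]); vals.append(-0.5 * alpha[hp])
        rows.append(p[hp]); cols.append(p[hp]); vals.append(0.25 * alpha[hp])
    both = has_s & has_d
    rows.append(s[both]); cols.append(m[both]); vals.append(0.25 * alpha[both])
    rows.append(m[both]); cols.append(s[both]); vals.append(0.25 * alpha[both])
    Ainv = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    return Ainv


def extract_A22(Ainv: sp.spmatrix, geno_idx: np.ndarray) -> np.ndarray:
    """Pedigree relationships among the genotyped animals.

    Solves A^-1 X = E for the genotyped unit vectors, i.e. columns of A,
    and keeps the genotyped rows; avoids forming dense A for the whole
    pedigree.
    """
    geno_idx = np.asarray(geno_idx)
    n = Ainv.shape[0]
    lu = splu(Ainv.tocsc(), permc_spec="MMD_AT_PLUS_A")
    E = np.zeros((n, len(geno_idx)))
    E[geno_idx, np.arange(len(geno_idx))] = 1.0
    cols = lu.solve(E)
    A22 = cols[geno_idx, :]
    return 0.5 * (A22 + A22.T)


def observed_freqs(dosages: np.ndarray) -> np.ndarray:
    """Allele frequencies of the counted allele, from 0/1/2 dosages."""
    return np.asarray(dosages, dtype=float).mean(axis=0) / 2.0


def build_G(dosages: np.ndarray, freqs: np.ndarray | None = None,
            weights: np.ndarray | None = None) -> np.ndarray:
    """VanRaden genomic relationship matrix, optionally SNP-weighted.

    G = P D P' / sum(2 p_i (1 - p_i)), with P the column-centered dosage
    matrix (dosage - 2 p_i) and D = diag(weights).  Monomorphic SNPs
    (freq 0 or 1) are excluded with a warning.
    """
    Z = np.asarray(dosages, dtype=float)
    if freqs is None:
        freqs = observed_freqs(Z)
    freqs = np.asarray(freqs, dtype=float)
    mono = (freqs <= 0.0) | (freqs >= 1.0)
    if mono.any():
        warnings.warn(f"excluding {mono.sum()} monomorphic SNPs from G")
        Z = Z[:, ~mono]
        freqs = freqs[~mono]
        if weights is not None:
            weights = np.asarray(weights, dtype=float)[~mono]
    P = Z - 2.0 * freqs
    denom = float(np.sum(2.0 * freqs * (1.0 - freqs)))
    if denom == 0.0:
        raise ValueError("no polymorphic SNPs: G undefined")
    if weights is None:
        G = P @ P.T / denom
    else:
        G = (P * np.asarray(weights, dtype=float)) @ P.T / denom
    return 0.5 * (G + G.T)


def build_Hinv(Ainv: sp.spmatrix, G: np.ndarray, A22: np.ndarray,
               geno_idx: np.ndarray, blend: float = 0.05) -> sp.csr_matrix:
    """Single-step H inverse.

    Gb = (1 - blend) G + blend A22 guards against a singular genomic
    matrix; the genotyped block receives Gb^-1 - A22^-1.
    """
    geno_idx = np.asarray(geno_idx)
    if len(geno_idx) == 0:
        return Ainv.tocsr().copy()
    Gb = (1.0 - blend) * G + blend * A22
    try:
        Gbinv = np.linalg.inv(Gb)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            f"blended genomic matrix is singular ({e}); increase blend") from e
    A22inv = np.linalg.inv(A22)
    block = Gbinv - A22inv
    r = np.repeat(geno_idx, len(geno_idx))
    c = np.tile(geno_idx, len(geno_idx))
    H = Ainv.tocsr() + sp.coo_matrix((block.ravel(), (r, c)), shape=Ainv.shape).tocsr()
    return H


def save_matrix(path, M) -> None:
    """Export a matrix in MatrixMarket coordinate format."""
    from scipy.io import mmwrite

    mmwrite(path, sp.coo_matrix(M))
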