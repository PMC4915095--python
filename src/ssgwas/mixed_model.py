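"""Henderson mixed-model equations, single-step GBLUP and iterative SNP
weighting (WssGBLUP).

The animal model is y = X b + Z a + e with Var(a) = K sigma2_a and
Var(e) = I sigma2_e, where K is either the pedigree relationship matrix
A or the single-step matrix H.  Solutions come from

    [ X'X      X'Z          ] [b]   [X'y]
    [ Z'X  Z'Z + K^-1 lambda] [a] = [Z'y],   lambda = sigma2_e / sigma2_a.

SNP effects are recovered from the genomic breeding values of the
genotyped animals by u = D P' (P D P')^-1 a_g, and the SNP weights of
the next WssGBLUP iteration are d_i proportional to u_i^2 2 p_i (1-p_i).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import cg, splu

from .relmat import build_G, build_Hinv, observed_freqs

__all__ = [
    "MMEResult",
    "SNPWeightState",
    "GwasData",
    "solve_mme",
    "preadjust_phenotypes",
    "backsolve_snp_effects",
    "update_snp_weights",
    "run_wssgblup",
]

# above this number of equations the direct sparse factorization is
# abandoned for Jacobi-preconditioned conjugate gradients
DIRECT_SOLVE_LIMIT = 150_000


@dataclass
class MMEResult:
    """Solutions of one mixed-model solve."""

    beta_hat: np.ndarray
    a_hat: np.ndarray
    converged: bool
    residual_norm: float
    geno_idx: np.ndarray | None = None

    @property
    def a_g(self) -> np.ndarray:
        """Breeding values of the genotyped animals."""
        if self.geno_idx is None:
            raise ValueError("no genotyped-animal index attached to this solve")
        return self.a_hat[self.geno_idx]


@dataclass
class SNPWeightState:
    """Per-SNP weights (diagonal of D) plus the previous back-solved
    effects that generated them."""

    d: np.ndarray
    iteration: int
    u_hat: np.ndarray | None = None
    p: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.d < 0):
            raise ValueError("SNP weights must be non-negative")


def solve_mme(y: np.ndarray, X: np.ndarray, rec_animal: np.ndarray,
              Kinv: sp.spmatrix, lam: float,
              geno_idx: np.ndarray | None = None,
              tol: float = 1e-10) -> MMEResult:
    """Solve Henderson's MME.

    Parameters
    ----------
    y, X : records and fixed-effect incidence (one row per record).
    rec_animal : 0-based animal index of each record.
    Kinv : inverse relationship matrix over all animals (A^-1 or H^-1).
    lam : variance ratio sigma2_e / sigma2_a (> 0).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    rec_animal = np.asarray(rec_animal, dtype=np.int64)
    nrec = len(y)
    if X.shape[0] != nrec or len(rec_animal) != nrec:
        raise ValueError("X and rec_animal must have one row per record")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    n = Kinv.shape[0]
    p_orig = X.shape[1]

    # drop dependent fixed-effect columns (their solutions constrained to 0)
    rank = np.linalg.matrix_rank(X.T @ X)
    keep = np.arange(p_orig)
    if rank < p_orig:
        warnings.warn(f"fixed effects rank-deficient ({rank}/{p_orig}); "
                      "dropping dependent columns (solution constrained to 0)")
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        keep = np.nonzero(diag > 1e-8 * diag.max())[0]
        X = X[:, keep]
    p = X.shape[1]

    Z = sp.coo_matrix((np.ones(nrec), (np.arange(nrec), rec_animal)),
                      shape=(nrec, n)).tocsr()
    top = sp.hstack([sp.csr_matrix(X.T @ X), sp.csr_matrix(X.T @ Z)])
    bottom = sp.hstack([sp.csr_matrix(Z.T @ sp.csr_matrix(X)),
                        (Z.T @ Z + lam * Kinv)])
    C = sp.vstack([top, bottom]).tocsc()
    rhs = np.concatenate([X.T @ y, Z.T @ y])

    if C.shape[0] <= DIRECT_SOLVE_LIMIT:
        sol = splu(C, permc_spec="MMD_AT_PLUS_A").solve(rhs)
        converged = True
    else:
        M = sp.diags(1.0 / C.diagonal())
        sol, info = cg(C, rhs, rtol=tol, maxiter=10 * C.shape[0], M=M)
        converged = info == 0

    res = float(np.linalg.norm(C @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300))
    full_beta = np.zeros(p_orig)
    full_beta[keep] = sol[:p]
    return MMEResult(beta_hat=full_beta, a_hat=sol[p:], converged=converged,
                     residual_norm=res, geno_idx=geno_idx)


def preadjust_phenotypes(y: np.ndarray, X: np.ndarray,
                         beta_full: np.ndarray) -> np.ndarray:
    """y_adj = y - X beta, with beta taken from a BLUP fit on the full
    record set; downstream genotyped-only models then fit only a mean."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    beta_full = np.asarray(beta_full, dtype=float)
    if X.shape[1] != len(beta_full):
        raise ValueError(
            f"fixed-effect mismatch: X has {X.shape[1]} columns but "
            f"beta_full has {len(beta_full)} entries")
    return y - X @ beta_full


def backsolve_snp_effects(a_g: np.ndarray, P: np.ndarray, d: np.ndarray,
                          freqs: np.ndarray, A22: np.ndarray | None = None,
                          blend: float = 0.0) -> np.ndarray:
    """SNP allele-substitution effects from genomic breeding values:
    u = D P' (P D P')^-1 a_g.

    P is the column-centered dosage matrix of the genotyped animals.
    P D P' is expressed through the (weighted) VanRaden G so the same
    pedigree blend used in the single-step solve keeps it invertible:
    P D P' = c Gb with c = sum 2 p (1 - p).
    """
    a_g = np.asarray(a_g, dtype=float)
    P = np.asarray(P, dtype=float)
    d = np.asarray(d, dtype=float)
    if P.shape[0] != len(a_g) or P.shape[1] != len(d):
        raise ValueError("dimension mismatch between a_g, P and d")
    c = float(np.sum(2.0 * freqs * (1.0 - freqs)))
    G = (P * d) @ P.T / c
    if blend > 0:
        if A22 is None:
            raise ValueError("A22 required when blending")
        G = (1.0 - blend) * G + blend * A22
    rhs = np.linalg.solve(c * G, a_g)
    return d * (P.T @ rhs)


def update_snp_weights(state: SNPWeightState) -> SNPWeightState:
    """Next WssGBLUP weights: d_i proportional to u_i^2 2 p_i (1 - p_i),
    normalized so sum(d) equals the number of SNPs (constant total
    genetic variance across iterations)."""
    if state.u_hat is None or state.p is None:
        raise ValueError("state needs u_hat and p from the previous iteration")
    raw = state.u_hat**2 * 2.0 * state.p * (1.0 - state.p)
    total = raw.sum()
    if total == 0:
        raise ValueError("all SNP effects are zero: weights degenerate")
    m = len(raw)
    return SNPWeightState(d=raw * (m / total), iteration=state.iteration + 1,
                          u_hat=None, p=state.p)


@dataclass
class GwasData:
    """Inputs shared by the SI / SII analyses of one replicate.

    SI uses all records; SII restricts the records to the genotyped
    animals (pre-adjusting for fixed effects estimated in a regular BLUP
    on everything, when there is more than an overall mean).
    """

    y: np.ndarray                # all available records (SI set)
    rec_animal: np.ndarray       # 0-based animal row per record
    X: np.ndarray
    Ainv: sp.spmatrix
    A22: np.ndarray
    geno_idx: np.ndarray         # 0-based rows of the genotyped animals
    dosages: np.ndarray          # (n_geno, m) 0/1/2
    lam: float
    blend: float = 0.05
    freqs: np.ndarray = None

    def __post_init__(self) -> None:
        if self.freqs is None:
            self.freqs = observed_freqs(self.dosages)


def _scenario_records(data: GwasData, scenario: str):
    scenario = scenario.upper()
    if scenario == "SI":
        return data.y, data.rec_animal, data.X
    if scenario != "SII":
        raise ValueError(f"unknown scenario {scenario!r}")
    geno = np.isin(data.rec_animal, data.geno_idx)
    y, rec, X = data.y[geno], data.rec_animal[geno], data.X[geno]
    if data.X.shape[1] > 1:
        # fixed effects are poorly estimable from the genotyped subset:
        # pre-adjust with estimates from a regular BLUP on all records
        full = solve_mme(data.y, data.X, data.rec_animal, data.Ainv, data.lam)
        y = preadjust_phenotypes(y, X, full.beta_hat)
        X = np.ones((len(y), 1))
    return y, rec, X


def run_wssgblup(data: GwasData, scenario: str = "SI",
                 n_iterations: int = 3) -> list[dict]:
    """Weighted single-step GBLUP with iterative SNP reweighting.

    Iteration w1 uses D = I; each following iteration rebuilds G (and
    H^-1) from the weights derived from the previous back-solved SNP
    effects.  Returns one dict per iteration with keys ``u_hat``, ``d``,
    ``a_hat``, ``a_g``, ``beta_hat``.
    """
    y, rec, X = _scenario_records(data, scenario)
    m = data.dosages.shape[1]
    freqs = data.freqs
    P = np.asarray(data.dosages, dtype=float) - 2.0 * freqs
    state = SNPWeightState(d=np.ones(m), iteration=1, p=freqs)
    out = []
    for it in range(1, n_iterations + 1):
        G = build_G(data.dosages, freqs=freqs, weights=state.d)
        Hinv = build_Hinv(data.Ainv, G, data.A22, data.geno_idx,
                          blend=data.blend)
        res = solve_mme(y, X, rec, Hinv, data.lam, geno_idx=data.geno_idx)
        u = backsolve_snp_effects(res.a_g, P, state.d, freqs,
                                  A22=data.A22, blend=data.blend)
        out.append({"iteration": it, "u_hat": u, "d": state.d.copy(),
                    "a_hat": res.a_hat, "a_g": res.a_g,
                    "beta_hat": res.beta_hat})
        if it < n_iterations:
            state = update_snp_weights(
                SNPWeightState(d=state.d, iteration=it, u_hat=u, p=freqs))
    return out
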