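"""Bayes C Gibbs sampler for marker-based GWAS.

Model: y = 1 mu + sum_i g_i b_i delta_i + e, with delta_i a per-SNP
inclusion indicator, P(delta_i = 1) = 1 - pi.  The exclusion fraction pi
is held essentially fixed (0.99 or 0.999) through overwhelming beta
pseudo-counts rather than being estimated (Bayes C, not Bayes Cpi):
fixing pi has been reported to behave better for QTL detection than
estimating it.  Effect and residual variances carry scaled
inverse-chi-squared priors and are updated from their full
conditionals.

The sampler is a single-site Gibbs scheme over SNPs in fixed index
order (reproducible given a seed), with the usual residual-update
trick so each SNP costs O(n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["BayesCConfig", "BayesCPosterior", "run_bayesc"]


@dataclass
class BayesCConfig:
    """Chain settings and priors.

    The full-scale chain of the study design is 550,000 iterations,
    50,000 burn-in, thinning 50 (10,000 kept samples); smaller chains
    are used for desk-scale work.  ``pi_excluded`` is the prior fraction
    of SNPs excluded from the model; the beta pseudo-counts are oriented
    so the prior mean equals it, which pins pi for any realistic number
    of SNPs.
    """

    pi_excluded: float = 0.99
    chain_length: int = 550_000
    burn_in: int = 50_000
    thin: int = 50
    pi_pseudo_count: float = 1e8
    nu_g: float = 4.2
    nu_e: float = 4.2
    s2_g: float | None = None     # derived from var_a if None
    s2_e: float | None = None     # derived from var_e if None
    var_a: float = 0.14
    var_e: float = 0.86
    update_variances: bool = True
    update_pi: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi_excluded <= 1.0:
            raise ValueError("pi_excluded must be in [0, 1]")
        if self.burn_in >= self.chain_length:
            raise ValueError("burn_in must be smaller than chain_length")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_kept(self) -> int:
        return (self.chain_length - self.burn_in) // self.thin

    def prior_scales(self, genotypes: np.ndarray) -> tuple[float, float]:
        """Scaled-inverse-chi-squared scales matching the expected SNP and
        residual variances (E[sigma2] = nu S^2 / (nu - 2))."""
        if self.s2_g is not None and self.s2_e is not None:
            return self.s2_g, self.s2_e
        p = genotypes.mean(axis=0) / 2.0
        het = float(np.mean(2.0 * p * (1.0 - p)))
        m = genotypes.shape[1]
        frac_in = max(1.0 - self.pi_excluded, 1.0 / m)
        target_g = self.var_a / (frac_in * m * max(het, 1e-12))
        s2_g = self.s2_g if self.s2_g is not None else target_g * (self.nu_g - 2.0) / self.nu_g
        s2_e = self.s2_e if self.s2_e is not None else self.var_e * (self.nu_e - 2.0) / self.nu_e
        return s2_g, s2_e


@dataclass
class BayesCPosterior:
    """Thinned posterior summaries."""

    effect_mean: np.ndarray        # posterior mean of b_i delta_i
    inclusion_freq: np.ndarray
    mu_mean: float
    var_g_mean: float
    var_e_mean: float
    pi_mean: float
    n_kept: int
    var_e_sd: float = float("nan")

    def __post_init__(self) -> None:
        if np.any((self.inclusion_freq < 0) | (self.inclusion_freq > 1)):
            raise ValueError("inclusion frequencies must lie in [0, 1]")


@njit(cache=True)
def _gibbs(X, y, chain, burn_in, thin, pi0, alpha0, beta0, nu_g, s2_g,
           nu_e, s2_e, var_g0, var_e0, update_var, update_pi, seed):
    n, m = X.shape
    np.random.seed(seed)
    xtx = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        xtx[j] = s
    b = np.zeros(m)
    delta = np.zeros(m, np.int8)
    mu = 0.0
    for i in range(n):
        mu += y[i]
    mu /= n
    e = y - mu
    var_g = var_g0
    var_e = var_e0
    pi = pi0

    sum_b = np.zeros(m)
    sum_d = np.zeros(m)
    s_mu = 0.0
    s_vg = 0.0
    s_ve = 0.0
    s_ve2 = 0.0
    s_pi = 0.0
    kept = 0

    for it in range(chain):
        # overall mean: mu | rest ~ N(mu + mean(e), var_e / n)
        emean = 0.0
        for i in range(n):
            emean += e[i]
        emean /= n
        mu_new = mu + emean + np.random.normal() * np.sqrt(var_e / n)
        shift = mu_new - mu
        for i in range(n):
            e[i] -= shift
        mu = mu_new

        # SNP effects
        for j in range(m):
            if xtx[j] <= 0.0:
                continue
            # residual excluding SNP j
            r = 0.0
            if delta[j] == 1:
                for i in range(n):
                    r += X[i, j] * (e[i] + X[i, j] * b[j])
            else:
                for i in range(n):
                    r += X[i, j] * e[i]
            if pi >= 1.0 - 1e-12:
                new_d = 0
            else:
                lam_g = var_e / var_g
                v = xtx[j] + lam_g
                # log Bayes factor for inclusion (b_j marginalized)
                log_bf = 0.5 * (np.log(lam_g) - np.log(v) + r * r / (v * var_e))
                log_odds = np.log(1.0 - pi) - np.log(pi) + log_bf
                if log_odds > 35.0:
                    p1 = 1.0
                elif log_odds < -35.0:
                    p1 = 0.0
                else:
                    p1 = 1.0 / (1.0 + np.exp(-log_odds))
                new_d = 1 if np.random.random() < p1 else 0
            old_contrib = b[j] if delta[j] == 1 else 0.0
            if new_d == 1:
                lam_g = var_e / var_g
                v = xtx[j] + lam_g
                bj = r / v + np.random.normal() * np.sqrt(var_e / v)
            else:
                bj = 0.0
            diff = bj - old_contrib
            if diff != 0.0:
                for i in range(n):
                    e[i] -= X[i, j] * diff
            b[j] = bj
            delta[j] = new_d

        # variances
        k = 0
        ssb = 0.0
        for j in range(m):
            if delta[j] == 1:
                k += 1
                ssb += b[j] * b[j]
        if update_var:
            # chi2(df) with fractional df via 2 * Gamma(df / 2)
            df_g = nu_g + k
            chi_g = 2.0 * np.random.gamma(df_g / 2.0, 1.0)
            var_g = (nu_g * s2_g + ssb) / chi_g
            sse = 0.0
            for i in range(n):
                sse += e[i] * e[i]
            df_e = nu_e + n
            chi_e = 2.0 * np.random.gamma(df_e / 2.0, 1.0)
            var_e = (nu_e * s2_e + sse) / chi_e
        if update_pi:
            pi = np.random.beta(alpha0 + (m - k), beta0 + k)

        if it >= burn_in and (it - burn_in) % thin == 0:
            kept += 1
            for j in range(m):
                if delta[j] == 1:
                    sum_b[j] += b[j]
                    sum_d[j] += 1.0
            s_mu += mu
            s_vg += var_g
            s_ve += var_e
            s_ve2 += var_e * var_e
            s_pi += pi

    return sum_b, sum_d, s_mu, s_vg, s_ve, s_ve2, s_pi, kept, var_e


def run_bayesc(y: np.ndarray, genotypes: np.ndarray, config: BayesCConfig,
               seed: int) -> BayesCPosterior:
    """Run the Bayes C Gibbs sampler.

    ``y`` should be pre-adjusted phenotypes (or raw records when only an
    overall mean applies); ``genotypes`` are 0/1/2 dosages of the
    genotyped animals.  Genotype columns are centered internally, which
    only re-parameterizes mu.
    """
    y = np.asarray(y, dtype=np.float64)
    X = np.asarray(genotypes, dtype=np.float64)
    if X.shape[0] != len(y):
        raise ValueError("genotypes and phenotypes disagree on the number of animals")
    X = X - X.mean(axis=0)
    s2_g, s2_e = config.prior_scales(genotypes)
    alpha0 = config.pi_excluded * config.pi_pseudo_count
    beta0 = (1.0 - config.pi_excluded) * config.pi_pseudo_count
    # a beta draw needs both parameters positive
    alpha0 = max(alpha0, 1e-6)
    beta0 = max(beta0, 1e-6)
    var_g0 = s2_g * config.nu_g / max(config.nu_g - 2.0, 0.1)
    var_e0 = s2_e * config.nu_e / max(config.nu_e - 2.0, 0.1)

    (sum_b, sum_d, s_mu, s_vg, s_ve, s_ve2, s_pi, kept, last_ve) = _gibbs(
        X, y, config.chain_length, config.burn_in, config.thin,
        config.pi_excluded, alpha0, beta0,
        config.nu_g, s2_g, config.nu_e, s2_e, var_g0, var_e0,
        config.update_variances, config.update_pi, seed & 0x7FFFFFFF)

    if kept == 0:
        raise RuntimeError("chain produced no kept samples")
    if not np.isfinite(last_ve) or last_ve <= 0:
        raise FloatingPointError(
            f"sampler diverged: residual variance = {last_ve}")
    eff = sum_b / kept
    if not np.all(np.isfinite(eff)):
        raise FloatingPointError("non-finite posterior means; check inputs")
    ve_mean = s_ve / kept
    ve_var = max(s_ve2 / kept - ve_mean**2, 0.0)
    return BayesCPosterior(
        effect_mean=eff,
        inclusion_freq=sum_d / kept,
        mu_mean=s_mu / kept,
        var_g_mean=s_vg / kept,
        var_e_mean=ve_mean,
        pi_mean=s_pi / kept,
        n_kept=kept,
        var_e_sd=float(np.sqrt(ve_var)),
    )
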