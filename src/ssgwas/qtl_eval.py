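"""Linkage-disequilibrium measurement and QTL-detection scoring.

GWAS signals are summarized as the share of genomic variance captured
by consecutive 1-Mb marker windows (1 cM = 1 Mb on simulated maps).
Truth is summarized by each QTL's share of genetic variance; QTLs at
>= 1% are the "topQTL" set, the equally many best windows are the
"topMRKw" set, and a topQTL counts as detected (NtrueQTL) when a top
window midpoint lies within 1 Mb of it under a one-to-one greedy
matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "compute_r2",
    "r2_from_dosages",
    "ld_decay_profile",
    "qtl_variance_shares",
    "hwe_variance_shares",
    "window_variances",
    "top_windows",
    "match_true_qtl",
    "EvalStats",
    "aggregate_replicates",
    "TABLE_ROW_ORDER",
]


def compute_r2(hap_a: np.ndarray, hap_b: np.ndarray) -> float:
    """r^2 between two biallelic loci from phased haplotypes.

    r^2 = D^2 / (pA qA pB qB) with D the haplotype-frequency
    disequilibrium.  Returns NaN for a monomorphic locus.
    """
    a = np.asarray(hap_a).ravel().astype(float)
    b = np.asarray(hap_b).ravel().astype(float)
    if a.shape != b.shape:
        raise ValueError("haplotype vectors must align")
    pa = a.mean()
    pb = b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return float("nan")
    pab = (a * b).mean()
    D = pab - pa * pb
    return float(D * D / (pa * (1 - pa) * pb * (1 - pb)))


def r2_from_dosages(dos_a: np.ndarray, dos_b: np.ndarray) -> float:
    """Squared genotype-dosage correlation; fallback for unphased input."""
    c = np.corrcoef(dos_a, dos_b)[0, 1]
    return float(c * c)


def ld_decay_profile(haps: np.ndarray, chrom: np.ndarray, pos_cm: np.ndarray,
                     bin_edges: np.ndarray,
                     max_pairs: int = 1_000_000,
                     seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Mean r^2 of same-chromosome marker pairs, binned by distance.

    ``haps`` has shape (n, 2, M); pairs beyond ``max_pairs`` are
    subsampled (seeded).  Distances use the 1 cM = 1 Mb convention, so
    ``bin_edges`` can be read as Mb.
    """
    rng = np.random.default_rng(seed)
    chrom = np.asarray(chrom)
    pos_cm = np.asarray(pos_cm)
    H = haps.reshape(-1, haps.shape[-1]).astype(float)  # gametes x loci
    p = H.mean(axis=0)
    poly = (p > 0) & (p < 1)

    pairs_i, pairs_j = [], []
    for c in np.unique(chrom):
        idx = np.nonzero((chrom == c) & poly)[0]
        if len(idx) < 2:
            continue
        i, j = np.triu_indices(len(idx), k=1)
        pairs_i.append(idx[i])
        pairs_j.append(idx[j])
    if not pairs_i:
        raise ValueError("no polymorphic same-chromosome pairs")
    pi = np.concatenate(pairs_i)
    pj = np.concatenate(pairs_j)
    if len(pi) > max_pairs:
        sub = rng.choice(len(pi), size=max_pairs, replace=False)
        pi, pj = pi[sub], pj[sub]

    d = np.abs(pos_cm[pi] - pos_cm[pj])
    # vectorized r2 over pairs
    pa, pb = p[pi], p[pj]
    pab = (H[:, pi] * H[:, pj]).mean(axis=0)
    D = pab - pa * pb
    r2 = D**2 / (pa * (1 - pa) * pb * (1 - pb))

    which = np.digitize(d, bin_edges) - 1
    rows = []
    for b in range(len(bin_edges) - 1):
        sel = which == b
        rows.append({
            "bin_lo": bin_edges[b],
            "bin_hi": bin_edges[b + 1],
            "mean_r2": float(r2[sel].mean()) if sel.any() else np.nan,
            "n_pairs": int(sel.sum()),
        })
    return pd.DataFrame(rows)


def qtl_variance_shares(qtl_values: np.ndarray,
                        tbv: np.ndarray | None = None) -> np.ndarray:
    """Percent of genetic variance explained by each QTL.

    ``qtl_values`` is the (n_animals, Q) matrix of per-QTL genotypic
    values over the reference cohort.  The denominator is Var(TBV) when
    ``tbv`` is given (shares then need not sum to 100 under LD),
    otherwise the sum of per-QTL variances.
    """
    qtl_values = np.asarray(qtl_values, dtype=float)
    v = qtl_values.var(axis=0)
    denom = float(np.var(tbv)) if tbv is not None else float(v.sum())
    if denom <= 0:
        raise ValueError("zero total genetic variance")
    return 100.0 * v / denom


def hwe_variance_shares(freqs: np.ndarray, effects: np.ndarray) -> np.ndarray:
    """Variance shares from allele frequencies and additive allele effects
    under Hardy-Weinberg and linkage equilibrium.

    Per locus: V = 2 (sum_k p_k e_k^2 - (sum_k p_k e_k)^2); shares are
    V / sum(V) * 100.
    """
    freqs = np.asarray(freqs, dtype=float)
    effects = np.asarray(effects, dtype=float)
    m1 = (freqs * effects).sum(axis=1)
    m2 = (freqs * effects**2).sum(axis=1)
    v = 2.0 * (m2 - m1**2)
    total = v.sum()
    if total <= 0:
        raise ValueError("zero total genetic variance")
    return 100.0 * v / total


def window_variances(u_hat: np.ndarray, dosages: np.ndarray,
                     chrom: np.ndarray, pos_cm: np.ndarray,
                     chrom_lengths: np.ndarray,
                     window_size: float = 1.0) -> pd.DataFrame:
    """Share of genomic variance captured by consecutive 1-Mb windows.

    Window value of an animal = sum of dosage * u over the window's
    SNPs; pvar = Var(window value) / Var(total genomic value) * 100
    across the genotyped animals.  Windows partition every chromosome;
    empty windows get pvar 0.
    """
    u_hat = np.asarray(u_hat, dtype=float)
    Z = np.asarray(dosages, dtype=float)
    chrom = np.asarray(chrom)
    pos_cm = np.asarray(pos_cm)
    total = Z @ u_hat
    vtot = total.var()
    rows = []
    for ci, clen in enumerate(chrom_lengths, start=1):
        n_win = int(np.ceil(clen / window_size))
        on_c = chrom == ci
        widx = np.floor(pos_cm / window_size).astype(int)
        for w in range(n_win):
            sel = on_c & (widx == w)
            if sel.any() and vtot > 0:
                wv = Z[:, sel] @ u_hat[sel]
                pvar = 100.0 * wv.var() / vtot
            else:
                pvar = 0.0
            rows.append({"chrom": ci, "window": w,
                         "start": w * window_size,
                         "end": min((w + 1) * window_size, float(clen)),
                         "n_snps": int(sel.sum()), "pvar": pvar})
    return pd.DataFrame(rows)


def top_windows(windows: pd.DataFrame, k: int) -> pd.DataFrame:
    """The k windows with the highest pvar; ties broken by genomic order."""
    return (windows.sort_values(["pvar", "chrom", "window"],
                                ascending=[False, True, True], kind="mergesort")
            .head(k))


def match_true_qtl(qtl_chrom: np.ndarray, qtl_pos: np.ndarray,
                   windows: pd.DataFrame, tolerance: float = 1.0) -> int:
    """One-to-one matching of top windows (midpoint) to topQTL positions;
    a pair counts when within ``tolerance`` (Mb) on the same chromosome.

    The count is the maximum bipartite matching of the within-tolerance
    adjacency, so two windows flanking one QTL contribute a single
    detection and no admissible pairing is left uncounted.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import maximum_bipartite_matching

    qtl_chrom = np.asarray(qtl_chrom)
    qtl_pos = np.asarray(qtl_pos, dtype=float)
    if len(qtl_pos) == 0 or len(windows) == 0:
        return 0
    mid = ((windows["start"] + windows["end"]) / 2.0).to_numpy()
    wch = windows["chrom"].to_numpy()
    ok = (np.abs(mid[:, None] - qtl_pos[None, :]) <= tolerance) & \
         (wch[:, None] == qtl_chrom[None, :])
    if not ok.any():
        return 0
    match = maximum_bipartite_matching(csr_matrix(ok), perm_type="column")
    return int((match >= 0).sum())


@dataclass
class EvalStats:
    """Replicate-level detection statistics for one analysis cell."""

    topQTL: int
    pvar_topQTL: float
    pvar_1stQTL: float
    topMRKw: int
    pvar_topMRKw: float
    pvar_1stMRKw: float
    n_trueQTL: int

    def __post_init__(self) -> None:
        if self.n_trueQTL > min(self.topQTL, self.topMRKw):
            raise ValueError("NtrueQTL cannot exceed the matched set sizes")


def evaluate_cell(u_hat: np.ndarray, dosages: np.ndarray,
                  marker_chrom: np.ndarray, marker_pos: np.ndarray,
                  chrom_lengths: np.ndarray,
                  qtl_shares: np.ndarray, qtl_chrom: np.ndarray,
                  qtl_pos: np.ndarray, share_threshold: float = 1.0,
                  tolerance: float = 1.0) -> EvalStats:
    """Score one method/scenario against the true QTL shares."""
    top_q = qtl_shares >= share_threshold
    k = int(top_q.sum())
    win = window_variances(u_hat, dosages, marker_chrom, marker_pos,
                           chrom_lengths)
    tw = top_windows(win, k)
    n_true = match_true_qtl(qtl_chrom[top_q], qtl_pos[top_q], tw, tolerance)
    return EvalStats(
        topQTL=k,
        pvar_topQTL=float(qtl_shares[top_q].sum()),
        pvar_1stQTL=float(qtl_shares.max()) if len(qtl_shares) else 0.0,
        topMRKw=k,
        pvar_topMRKw=float(tw["pvar"].sum()),
        pvar_1stMRKw=float(tw["pvar"].max()) if len(tw) else 0.0,
        n_trueQTL=n_true,
    )


TABLE_ROW_ORDER = [
    "BayesC_pi0.99", "BayesC_pi0.999",
    "SIw1", "SIw2", "SIw3",
    "SIIw1", "SIIw2", "SIIw3",
]


def aggregate_replicates(stats: list[dict[str, EvalStats]]) -> pd.DataFrame:
    """Mean (SD) table over replicates, one row per analysis cell plus a
    true-values row, mirroring the study's summary layout."""
    if len(stats) < 1:
        raise ValueError("need at least one replicate")
    cells = list(stats[0].keys())
    for i, rep in enumerate(stats):
        if list(rep.keys()) != cells:
            raise ValueError(f"replicate {i} has an inconsistent cell set")

    def ms(vals):
        vals = np.asarray(vals, dtype=float)
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
        return float(vals.mean()), sd

    rows = []
    ordered = [c for c in TABLE_ROW_ORDER if c in cells]
    ordered += [c for c in cells if c not in ordered]
    for cell in ordered:
        pm, psd = ms([r[cell].pvar_topMRKw for r in stats])
        fm, fsd = ms([r[cell].pvar_1stMRKw for r in stats])
        nm, nsd = ms([r[cell].n_trueQTL for r in stats])
        rows.append({"row": cell, "pvar_topMRKw_mean": pm, "pvar_topMRKw_sd": psd,
                     "pvar_1stMRKw_mean": fm, "pvar_1stMRKw_sd": fsd,
                     "n_trueQTL_mean": nm, "n_trueQTL_sd": nsd})
    any_cell = ordered[0]
    tm, tsd = ms([r[any_cell].pvar_topQTL for r in stats])
    fm, fsd = ms([r[any_cell].pvar_1stQTL for r in stats])
    km, ksd = ms([r[any_cell].topQTL for r in stats])
    rows.append({"row": "true_values", "pvar_topMRKw_mean": tm,
                 "pvar_topMRKw_sd": tsd, "pvar_1stMRKw_mean": fm,
                 "pvar_1stMRKw_sd": fsd, "n_trueQTL_mean": km,
                 "n_trueQTL_sd": ksd})
    return pd.DataFrame(rows)
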