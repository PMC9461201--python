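"""Two-group differential expression with an empirical-Bayes moderated t.

Per gene, a pooled two-sample comparison on log2-normalized expression is
moderated by shrinking the sample variance toward a prior estimated across
genes.  The prior (d0, s0^2) is fitted by moment matching on log sample
variances: if s^2 ~ s0^2 * F(d, d0), then

    E[ln s^2]   = ln s0^2 + psi(d/2) - ln(d/2) - psi(d0/2) + ln(d0/2)
    Var[ln s^2] = psi'(d/2) + psi'(d0/2)

so d0 is recovered by inverting the trigamma function on the excess variance
of ln s^2, and s0^2 from the mean.  The moderated statistic is

    t = log2FC / sqrt(s2_post * (1/n1 + 1/n2)),
    s2_post = (d0*s0^2 + d*s^2) / (d0 + d),

referred to a t distribution with d + d0 degrees of freedom (normal when
d0 is infinite).  Significance calls use BH-adjusted q < 0.05 with
|log2FC| > 0.2; ranked lists (by log2FC, descending) feed preranked GSEA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import special, stats
from sklearn.base import BaseEstimator

__all__ = [
    "EBayesPrior",
    "GeneStats",
    "fit_gene_stats",
    "estimate_prior",
    "moderated_t",
    "bh_adjust",
    "call_de",
    "ModeratedTTest",
    "de_table",
    "ranked_list",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class EBayesPrior:
    """Variance prior: d0 prior degrees of freedom (may be inf), s0_sq prior variance."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError("d0 must be positive")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be positive")


@dataclass
class GeneStats:
    """Per-gene two-group summary on the log2 scale."""

    mean_carrier: np.ndarray
    mean_control: np.ndarray
    log2fc: np.ndarray
    s2: np.ndarray
    df: int
    n1: int
    n2: int


def _group_masks(groups: np.ndarray, carrier: str, control: str) -> tuple[np.ndarray, np.ndarray]:
    groups = np.asarray(groups)
    m1 = groups == carrier
    m2 = groups == control
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("each group needs at least 2 cells")
    return m1, m2


def fit_gene_stats(
    norm_matrix_log2: sp.spmatrix | np.ndarray,
    groups: np.ndarray,
    carrier: str = "carrier",
    control: str = "control",
) -> GeneStats:
    """Group means, log2FC (carrier - control) and pooled variance per gene.

    Expects genes x cells values on the log2 scale.  The pooled variance has
    n1 + n2 - 2 residual degrees of freedom.
    """
    m1, m2 = _group_masks(groups, carrier, control)
    X = sp.csr_matrix(norm_matrix_log2) if sp.issparse(norm_matrix_log2) else np.asarray(norm_matrix_log2, dtype=float)
    n1, n2 = int(m1.sum()), int(m2.sum())

    if sp.issparse(X):
        X1, X2 = X[:, np.flatnonzero(m1)], X[:, np.flatnonzero(m2)]
        mu1 = np.asarray(X1.mean(axis=1)).ravel()
        mu2 = np.asarray(X2.mean(axis=1)).ravel()
        sq1 = np.asarray(X1.multiply(X1).sum(axis=1)).ravel()
        sq2 = np.asarray(X2.multiply(X2).sum(axis=1)).ravel()
    else:
        X1, X2 = X[:, m1], X[:, m2]
        mu1, mu2 = X1.mean(axis=1), X2.mean(axis=1)
        sq1, sq2 = (X1**2).sum(axis=1), (X2**2).sum(axis=1)

    ss1 = np.maximum(sq1 - n1 * mu1**2, 0.0)
    ss2 = np.maximum(sq2 - n2 * mu2**2, 0.0)
    df = n1 + n2 - 2
    s2 = (ss1 + ss2) / df
    return GeneStats(
        mean_carrier=mu1,
        mean_control=mu2,
        log2fc=mu1 - mu2,
        s2=s2,
        df=df,
        n1=n1,
        n2=n2,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration (rel. tol 1e-8)."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    # large y -> x ~ 1/y; small y -> x ~ 1/sqrt(y) asymptotics; this start
    # converges over the whole range
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = special.polygamma(1, x)
        tetra = special.polygamma(2, x)
        delta = tri * (1.0 - tri / y) / tetra
        x += delta
        if abs(delta) < 1e-8 * abs(x):
            return float(x)
    raise RuntimeError("trigamma inversion did not converge in 100 iterations")


def estimate_prior(s2: np.ndarray, df: int, min_genes: int = 10) -> EBayesPrior:
    """Moment-matching fit of the variance prior from per-gene sample variances.

    Only genes with positive s2 inform the fit.  If the empirical variance of
    ln(s2) does not exceed the theoretical trigamma(df/2) contribution of the
    residual degrees of freedom alone, there is no evidence of gene-to-gene
    variance heterogeneity and d0 is infinite.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size < min_genes:
        raise ValueError(f"need at least {min_genes} genes with positive variance")
    z = np.log(pos)
    e_mean = z.mean()
    e_var = z.var(ddof=1)
    half_df = df / 2.0
    resid_var = float(special.polygamma(1, half_df))
    excess = e_var - resid_var
    base = e_mean - float(special.digamma(half_df)) + math.log(half_df)
    if excess <= 0:
        return EBayesPrior(d0=math.inf, s0_sq=float(math.exp(base)))
    half_d0 = _trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    s0_sq = math.exp(base + float(special.digamma(half_d0)) - math.log(half_d0))
    return EBayesPrior(d0=d0, s0_sq=float(s0_sq))


def moderated_t(
    gene_stats: GeneStats, prior: EBayesPrior
) -> tuple[np.ndarray, float, np.ndarray]:
    """Moderated t, total degrees of freedom and two-sided p per gene."""
    d, n1, n2 = gene_stats.df, gene_stats.n1, gene_stats.n2
    if math.isinf(prior.d0):
        s2_post = np.full_like(gene_stats.s2, prior.s0_sq)
        df_total = math.inf
    else:
        s2_post = (prior.d0 * prior.s0_sq + d * gene_stats.s2) / (prior.d0 + d)
        df_total = d + prior.d0
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, gene_stats.log2fc / se, 0.0)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return t, df_total, p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, ties preserved)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    log2fc: np.ndarray,
    q: np.ndarray,
    q_thresh: float = 0.05,
    lfc_thresh: float = 0.2,
) -> np.ndarray:
    """Significance calls: up if q < q_thresh and log2FC > lfc_thresh,
    down if q < q_thresh and log2FC < -lfc_thresh, else ns."""
    call = np.full(len(log2fc), "ns", dtype=object)
    sig = q < q_thresh
    call[sig & (log2fc > lfc_thresh)] = "up"
    call[sig & (log2fc < -lfc_thresh)] = "down"
    return call


class ModeratedTTest(BaseEstimator):
    """Empirical-Bayes moderated two-group t-test, sklearn-style.

    Parameters
    ----------
    q_thresh, lfc_thresh : call thresholds (defaults q < 0.05, |log2FC| > 0.2).
    carrier, control : group labels; log2FC is carrier minus control.

    Fitted attributes (per gene): ``log2fc_``, ``s2_``, ``t_``, ``p_``,
    ``q_``, ``call_``, plus ``prior_`` and ``df_total_``.
    """

    def __init__(
        self,
        q_thresh: float = 0.05,
        lfc_thresh: float = 0.2,
        carrier: str = "carrier",
        control: str = "control",
    ):
        self.q_thresh = q_thresh
        self.lfc_thresh = lfc_thresh
        self.carrier = carrier
        self.control = control

    def fit(self, X, y):
        """Fit on X = cells x genes log2-normalized values, y = group labels."""
        Xg = X.T if sp.issparse(X) else np.asarray(X, dtype=float).T  # genes x cells
        gs = fit_gene_stats(Xg, np.asarray(y), self.carrier, self.control)
        prior = estimate_prior(gs.s2, gs.df)
        t, df_total, p = moderated_t(gs, prior)
        q = bh_adjust(p)
        self.n_features_in_ = Xg.shape[0]
        self.stats_ = gs
        self.prior_ = prior
        self.log2fc_ = gs.log2fc
        self.s2_ = gs.s2
        self.t_ = t
        self.df_total_ = df_total
        self.p_ = p
        self.q_ = q
        self.call_ = call_de(gs.log2fc, q, self.q_thresh, self.lfc_thresh)
        return self


def de_table(est: ModeratedTTest, gene_symbols: list[str]) -> pd.DataFrame:
    """Tidy DE result table, ranked by log2FC descending (gene-symbol ties
    broken lexicographically for determinism)."""
    df = pd.DataFrame(
        {
            "gene": gene_symbols,
            "mean_carrier": est.stats_.mean_carrier,
            "mean_control": est.stats_.mean_control,
            "log2FC": est.log2fc_,
            "t_mod": est.t_,
            "p": est.p_,
            "q": est.q_,
            "call": est.call_,
        }
    )
    return df.sort_values(["log2FC", "gene"], ascending=[False, True], kind="mergesort").reset_index(
        drop=True
    )


def ranked_list(de: pd.DataFrame) -> pd.DataFrame:
    """RNK-style two-column ranking (gene, log2FC) for preranked GSEA."""
    return de[["gene", "log2FC"]].copy()
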