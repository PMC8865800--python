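"""Likelihood-ratio differential expression between fitted clusters.

For gene ``j`` and clusters ``g1``, ``g2`` the null hypothesis ties the
two cluster rate parameters, ``Z[j,g1] = Z[j,g2]``, against the free
alternative.  Both hypotheses condition on the fitted nuisance profiles
``X`` and the hard memberships: under H1 each group's rate entry is the
1-D maximum-likelihood value on that group's cells, under H0 a single
pooled entry is fitted on the union.  The statistic

    LRT_j = sum_{i in I1 u I2} (Y log mu_hat - mu_hat)
          - sum_{i in I1 u I2} (Y log mu_bar - mu_bar)

is nonnegative by construction, and 2 * LRT_j is compared against the
chi-squared distribution with 1 degree of freedom (one parameter tied).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix
from .model import PrimusModel, poisson_loglik
from .preprocessing import NuisanceDesign

__all__ = ["lrt_test", "adjust_fdr", "pairwise_scan", "PairwiseScan"]


def lrt_test(
    Y: CountMatrix | np.ndarray,
    design: NuisanceDesign,
    model: PrimusModel,
    g1: int,
    g2: int,
) -> pd.DataFrame:
    """Per-gene LRT between clusters ``g1`` and ``g2``.

    Returns a frame indexed by gene with columns ``lrt_stat``,
    ``p_value``, ``fdr``, ``direction`` (sign of the g1 rate minus the
    g2 rate) and the three fitted rates.
    """
    if g1 == g2:
        raise ValueError("g1 and g2 must differ")
    gene_ids = Y.gene_ids if isinstance(Y, CountMatrix) else None
    Yv = np.asarray(Y.values if isinstance(Y, CountMatrix) else Y, dtype=float)
    members = model.memberships
    i1 = np.flatnonzero(members == g1)
    i2 = np.flatnonzero(members == g2)
    if i1.size == 0 or i2.size == 0:
        raise ValueError("both clusters need at least one cell")

    base = model.X @ design.design if model.r else np.zeros_like(Yv)
    G = design.size_factors

    a1 = base[:, i1]
    a2 = base[:, i2]
    z1 = _solve_rate_pergene(Yv[:, i1], a1, G[i1])
    z2 = _solve_rate_pergene(Yv[:, i2], a2, G[i2])
    iu = np.concatenate([i1, i2])
    z0 = _solve_rate_pergene(Yv[:, iu], base[:, iu], G[iu])

    ll1 = _loglik_pergene(Yv[:, i1], a1, G[i1], z1) + _loglik_pergene(Yv[:, i2], a2, G[i2], z2)
    ll0 = _loglik_pergene(Yv[:, iu], base[:, iu], G[iu], z0)
    stat = np.maximum(0.0, ll1 - ll0)
    p = scipy.stats.chi2.sf(2.0 * stat, df=1)
    direction = np.sign(z1 - z2)
    out = pd.DataFrame(
        {
            "lrt_stat": stat,
            "p_value": p,
            "fdr": adjust_fdr(p),
            "direction": direction,
            "rate_g1": z1,
            "rate_g2": z2,
            "rate_pooled": z0,
        }
    )
    if gene_ids is not None:
        out.index = pd.Index(gene_ids, name="gene")
    return out


def _solve_rate_pergene(Y: np.ndarray, A: np.ndarray, G: np.ndarray, n_bisect: int = 90) -> np.ndarray:
    """Vectorized 1-D MLE of z >= 0 in mu = (A + z) * G, per gene row.

    ``A`` holds the per-gene, per-cell nuisance contribution.  The score
    f(z) = sum_i [Y_i / (A_i + z) - G_i] is strictly decreasing in z and
    its root lies in [0, sum(Y)/sum(G)], so safeguarded bisection is
    unconditionally convergent; 90 halvings reach full double precision.
    """
    tot_y = Y.sum(axis=1)
    tot_g = G.sum()
    hi = np.where(tot_y > 0, tot_y / tot_g, 0.0)

    def score(z):
        denom = A + z[:, None]
        ratio = np.divide(Y, denom, out=np.full_like(Y, np.inf), where=denom > 0)
        ratio = np.where(Y == 0, 0.0, ratio)
        return ratio.sum(axis=1) - tot_g

    lo = np.zeros_like(hi)
    at_zero = score(lo) <= 0
    hi = np.where(at_zero, 0.0, hi)
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        pos = score(mid) > 0
        lo = np.where(pos, mid, lo)
        hi = np.where(pos, hi, mid)
    return 0.5 * (lo + hi)


def _loglik_pergene(Y, A, G, z) -> np.ndarray:
    mu = (A + z[:, None]) * G[None, :]
    return poisson_loglik(Y, mu, axis=1)


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)):
        raise ValueError("NaN p-values")
    return multipletests(p, method="fdr_bh")[1]


class PairwiseScan:
    """All-pairs DE scan results.

    Attributes
    ----------
    tables
        ``{(g1, g2): DataFrame}`` per ordered pair ``g1 < g2``.
    union_genes
        Union over pairs of the top genes passing the FDR cut.
    signed_stats
        genes x comparisons frame of ``direction * lrt_stat``.
    """

    def __init__(self, tables, union_genes, signed_stats):
        self.tables = tables
        self.union_genes = union_genes
        self.signed_stats = signed_stats

    @property
    def n_comparisons(self) -> int:
        return len(self.tables)


def pairwise_scan(
    Y: CountMatrix | np.ndarray,
    design: NuisanceDesign,
    model: PrimusModel,
    top_n: int = 1000,
    fdr_cut: float = 0.01,
) -> PairwiseScan:
    """Run the LRT for all k(k-1)/2 cluster pairs.

    Per pair, the ``top_n`` genes by statistic among those with
    FDR < ``fdr_cut`` are retained; the union of survivors feeds the
    coexpression-network pipeline.
    """
    if model.k < 2:
        raise ValueError("pairwise scan needs k >= 2")
    tables = {}
    union: set[str] = set()
    cols = {}
    for g1 in range(model.k):
        for g2 in range(g1 + 1, model.k):
            t = lrt_test(Y, design, model, g1, g2)
            tables[(g1, g2)] = t
            passing = t[t["fdr"] < fdr_cut]
            top = passing.sort_values("lrt_stat", ascending=False).head(top_n)
            union.update(top.index.astype(str))
            cols[f"{g1}|{g2}"] = t["direction"] * t["lrt_stat"]
    signed = pd.DataFrame(cols)
    order = [g for g in signed.index.astype(str) if g in union]
    return PairwiseScan(tables=tables, union_genes=order, signed_stats=signed)
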