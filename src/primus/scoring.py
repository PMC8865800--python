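"""Gene-set scoring: ssGSEA stress/proliferation scores and the CCA-based
RNA-ISH stress score.

The stress score of a cell or sample is the single-sample gene-set
enrichment (ssGSEA) score of a stress-associated signature; samples are
called stress-high when the permutation p-value (against size-matched
random gene sets) is below 0.05 and stress-low above 0.5.  For RNA-ISH
panels, a per-sample stress score is the first canonical variate of the
probed expression levels against the treatment phase and a reference
(scRNA-seq derived) stress score, with permutation p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ssgsea",
    "permutation_p",
    "classify_stress",
    "CcaScore",
    "cca_stress_score",
]


def _ssgsea_single(order_w: np.ndarray, in_set: np.ndarray, denom_out: float) -> float:
    """Enrichment score given weights in ranked order and the in-set mask."""
    w_in = np.where(in_set, order_w, 0.0)
    tot_in = w_in.sum()
    if tot_in == 0:
        return float(-np.cumsum((~in_set) / denom_out).sum())
    ecdf_in = np.cumsum(w_in) / tot_in
    ecdf_out = np.cumsum(~in_set) / denom_out
    return float((ecdf_in - ecdf_out).sum())


def _prepare(expression: pd.DataFrame):
    genes = expression.index.astype(str)
    vals = expression.to_numpy(dtype=float)
    # ranked positions, highest expression first; stable order on ties
    orders = np.argsort(-vals, axis=0, kind="stable")
    return genes, vals, orders


def ssgsea(
    expression: pd.DataFrame,
    gene_set: list[str],
    alpha: float = 0.25,
    normalize: bool = True,
) -> pd.Series:
    """Single-sample gene-set enrichment scores per unit (cell or sample).

    Per unit, genes are ranked by expression (descending) and the score
    accumulates the gap between the weighted in-set ECDF and the uniform
    out-of-set ECDF along the ranking; weights are the rank-normalized
    positions raised to ``alpha``.  Using ranks (not raw values) makes
    the unnormalized score invariant to any strictly increasing per-unit
    transform.  With ``normalize=True`` scores are rescaled by their
    range across units, as customary when comparing units.
    """
    genes, vals, orders = _prepare(expression)
    n, m = vals.shape
    members = np.asarray([g in set(gene_set) for g in genes])
    n_in = int(members.sum())
    if n_in < 2 or n - n_in < 2:
        raise ValueError(
            f"need >=2 genes inside and outside the set; got {n_in} of {n}"
        )
    rank_weight = ((np.arange(n, 0, -1)) / n) ** alpha  # position 0 = top rank
    scores = np.empty(m)
    for u in range(m):
        in_set = members[orders[:, u]]
        scores[u] = _ssgsea_single(rank_weight, in_set, float(n - n_in))
    out = pd.Series(scores, index=expression.columns, name="ssgsea")
    if normalize:
        rng = out.max() - out.min()
        if rng > 0:
            out = out / rng
    return out


def permutation_p(
    expression: pd.DataFrame,
    gene_set: list[str],
    alpha: float = 0.25,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.Series:
    """Per-unit permutation p-value of the ssGSEA score.

    The null distribution is the scores of ``n_perm`` random gene sets of
    the same effective size drawn from the measured genes;
    p = (1 + #{null >= observed}) / (n_perm + 1), so p is never zero.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    genes, vals, orders = _prepare(expression)
    n, m = vals.shape
    eff = len(set(gene_set) & set(genes))
    if eff > n:
        raise ValueError("gene set larger than the measured universe")
    obs = ssgsea(expression, gene_set, alpha=alpha, normalize=False).to_numpy()
    rng = np.random.default_rng(seed)
    rank_weight = ((np.arange(n, 0, -1)) / n) ** alpha
    exceed = np.zeros(m)
    for _ in range(n_perm):
        idx = rng.choice(n, size=eff, replace=False)
        members = np.zeros(n, dtype=bool)
        members[idx] = True
        for u in range(m):
            in_set = members[orders[:, u]]
            s = _ssgsea_single(rank_weight, in_set, float(n - eff))
            if s >= obs[u]:
                exceed[u] += 1
    p = (1.0 + exceed) / (n_perm + 1.0)
    return pd.Series(p, index=expression.columns, name="p_value")


def classify_stress(p_values: pd.Series, high_max: float = 0.05, low_min: float = 0.5) -> pd.Series:
    """Stress-high iff p < 0.05; stress-low iff p > 0.5; else indeterminate."""
    def label(p: float) -> str:
        if p < high_max:
            return "high"
        if p > low_min:
            return "low"
        return "indeterminate"

    return p_values.map(label).rename("stress_label")


# ---------------------------------------------------------------------------
# CCA stress score for RNA-ISH panels


@dataclass
class CcaScore:
    scores: pd.Series  # per-sample first canonical variate of the ISH block
    coefficients: pd.Series  # per probed gene
    correlation: float  # first canonical correlation, in [0, 1]
    p_correlation: float | None = None
    p_phase: float | None = None


def _standardize(M: np.ndarray):
    mu = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    keep = sd > 0
    return (M[:, keep] - mu[keep]) / sd[keep], keep


def _inv_sqrt(S: np.ndarray, ridge_tol: float = 1e-10):
    vals, vecs = np.linalg.eigh(S)
    vmax = vals.max()
    if vals.min() <= ridge_tol * vmax:
        warnings.warn("rank-deficient covariance; ridge-regularized whitening")
        vals = vals + ridge_tol * vmax
    return vecs @ np.diag(1.0 / np.sqrt(vals)) @ vecs.T


def _first_canonical(Xs: np.ndarray, Ys: np.ndarray):
    n = Xs.shape[0]
    Sxx = Xs.T @ Xs / (n - 1)
    Syy = Ys.T @ Ys / (n - 1)
    Sxy = Xs.T @ Ys / (n - 1)
    Wx = _inv_sqrt(Sxx)
    Wy = _inv_sqrt(Syy)
    U, s, _ = np.linalg.svd(Wx @ Sxy @ Wy)
    rho = float(np.clip(s[0], 0.0, 1.0))
    a = Wx @ U[:, 0]
    return rho, a


def cca_stress_score(
    ish: pd.DataFrame,
    targets: pd.DataFrame,
    n_perm: int = 100_000,
    seed: int = 0,
) -> CcaScore:
    """First-canonical-component stress score from RNA-ISH quantifications.

    Parameters
    ----------
    ish
        Probed genes x samples expression levels.
    targets
        Samples x 2 frame: a treatment-phase indicator column and a
        reference stress score column (in that order).
    n_perm
        Sample-label permutations for the empirical p-values of (a) the
        correlation between the ISH score and the reference score and
        (b) the phase difference of the ISH score.

    The per-sample score is the first canonical variate of the ISH block;
    its per-gene coefficients are the score's linear weights.  The sign
    is fixed so the score correlates nonnegatively with the reference.
    """
    samples = ish.columns
    if not np.array_equal(np.asarray(targets.index), np.asarray(samples)):
        targets = targets.loc[samples]
    X = ish.T.to_numpy(dtype=float)
    Yt = targets.to_numpy(dtype=float)
    Xs, keep_x = _standardize(X)
    Ys, keep_y = _standardize(Yt)
    if not np.all(keep_y):
        dropped = targets.columns[~keep_y].tolist()
        warnings.warn(f"constant target columns dropped: {dropped}")
    if Ys.shape[1] == 0:
        raise ValueError("all target columns are constant")
    rho, a = _first_canonical(Xs, Ys)
    scores = Xs @ a
    ref = Yt[:, -1]
    if np.std(ref) > 0 and np.corrcoef(scores, ref)[0, 1] < 0:
        a, scores = -a, -scores
    coef = np.zeros(X.shape[1])
    coef[keep_x] = a
    phase = Yt[:, 0]
    levels = np.unique(phase)
    obs_corr = abs(np.corrcoef(scores, ref)[0, 1]) if np.std(ref) > 0 else None
    obs_phase = (
        abs(scores[phase == levels[1]].mean() - scores[phase == levels[0]].mean())
        if len(levels) == 2
        else None
    )

    p_corr = p_phase = None
    if n_perm > 0 and (obs_corr is not None or obs_phase is not None):
        rng = np.random.default_rng(seed)
        n = Xs.shape[0]
        hits_corr = hits_phase = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Yp = Ys[perm]
            rho_p, a_p = _first_canonical(Xs, Yp)
            s_p = Xs @ a_p
            if obs_corr is not None:
                c = abs(np.corrcoef(s_p, ref[perm])[0, 1])
                if c >= obs_corr:
                    hits_corr += 1
            if obs_phase is not None:
                pp = phase[perm]
                d = abs(s_p[pp == levels[1]].mean() - s_p[pp == levels[0]].mean())
                if d >= obs_phase:
                    hits_phase += 1
        if obs_corr is not None:
            p_corr = (1 + hits_corr) / (n_perm + 1)
        if obs_phase is not None:
            p_phase = (1 + hits_phase) / (n_perm + 1)

    return CcaScore(
        scores=pd.Series(scores, index=samples, name="ish_stress_score"),
        coefficients=pd.Series(coef, index=ish.index, name="coefficient"),
        correlation=rho,
        p_correlation=p_corr,
        p_phase=p_phase,
    )
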