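"""Bilinear Poisson mixture model for clustering cells across patients.

Observed UMI counts are modeled as

    Y[j, i] ~ Poisson( (sum_l X[j, l] D[l, i] + Z[j, c(i)]) * G[i] )

where ``D`` is a known nuisance design (patient one-hot blocks plus scaled
technical covariates), ``G`` are known per-cell size factors, ``X`` holds
nonnegative nuisance expression profiles, ``Z`` holds nonnegative cluster
profiles, and ``c(i)`` is the hard cluster membership of cell ``i``.  The
nuisance and phenotypic signals are additive, so patient-specific
expression is absorbed by ``X`` while shared cell states land in ``Z``.

Fitting is classification (hard) EM: given memberships, ``X`` and ``Z``
are the per-gene maximum-likelihood nonnegative Poisson-rate regression
against the stacked design [D; one-hot(C)] with exposure ``G``; given
profiles, each cell is reassigned to the cluster maximizing its Poisson
log-likelihood.  The M-step uses multiplicative (KL-divergence) updates,
which never decrease the likelihood, so the whole EM trace is monotone.

Log-likelihoods everywhere omit the constant ``log Y!`` terms; reported
values are therefore comparable only within this implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix
from .preprocessing import NuisanceDesign

__all__ = [
    "PrimusModel",
    "KScan",
    "log_likelihood",
    "poisson_loglik",
    "update_profiles",
    "update_memberships",
    "fit",
    "bic",
    "select_k",
    "denoise",
]


@dataclass
class PrimusModel:
    """A fitted bilinear Poisson mixture.

    ``X`` is genes x r (nuisance profiles), ``Z`` genes x k (cluster
    profiles), ``memberships`` the per-cell hard cluster index in 0..k-1.
    ``ll_trace`` records the log-likelihood after every EM iteration of
    the winning restart.
    """

    X: np.ndarray
    Z: np.ndarray
    memberships: np.ndarray
    k: int
    log_likelihood: float
    bic: float
    n_iter: int
    converged: bool
    seed: int | None = None
    ll_trace: list[float] = field(default_factory=list)

    @property
    def r(self) -> int:
        return self.X.shape[1]

    @property
    def n_genes(self) -> int:
        return self.Z.shape[0]


@dataclass
class KScan:
    """Result of a BIC scan over cluster counts."""

    table: pd.DataFrame  # columns: k, log_likelihood, bic, n_restarts
    selected_k: int
    models: dict[int, PrimusModel] | None = None


def _as_counts_array(Y: CountMatrix | np.ndarray) -> np.ndarray:
    if isinstance(Y, CountMatrix):
        return np.asarray(Y.values, dtype=float)
    return np.asarray(Y, dtype=float)


def poisson_loglik(Y: np.ndarray, mu: np.ndarray, axis=None):
    """sum(Y log mu - mu) with 0*log(0) = 0; -inf where mu = 0 but Y > 0.

    Constant ``log Y!`` terms are omitted.
    """
    Y = np.asarray(Y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    safe = np.where(mu > 0, mu, 1.0)
    terms = np.where(Y > 0, Y * np.log(safe), 0.0) - mu
    terms = np.where((mu == 0) & (Y > 0), -np.inf, terms)
    return terms.sum(axis=axis)


def _rates(X: np.ndarray, Z: np.ndarray, design: NuisanceDesign, memberships: np.ndarray) -> np.ndarray:
    base = X @ design.design if X.shape[1] else np.zeros((Z.shape[0], design.n_cells))
    return (base + Z[:, memberships]) * design.size_factors


def log_likelihood(
    Y: CountMatrix | np.ndarray,
    design: NuisanceDesign,
    model: PrimusModel,
) -> float:
    """Model log-likelihood of the counts (without log Y! constants)."""
    Yv = _as_counts_array(Y)
    mu = _rates(model.X, model.Z, design, model.memberships)
    return float(poisson_loglik(Yv, mu))


def _onehot(memberships: np.ndarray, k: int) -> np.ndarray:
    C = np.zeros((k, memberships.size))
    C[memberships, np.arange(memberships.size)] = 1.0
    return C


def update_profiles(
    Y: CountMatrix | np.ndarray,
    design: NuisanceDesign,
    memberships: np.ndarray,
    k: int,
    init: tuple[np.ndarray, np.ndarray] | None = None,
    max_inner: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """M-step: per-gene nonnegative Poisson regression on [D; one-hot(C)].

    Multiplicative KL updates; warm-startable via ``init`` so repeated
    calls inside EM never decrease the likelihood.  Rows of all-zero genes
    go to exactly zero.  A currently empty cluster's profile column is
    left unchanged (there is no data to update it with).
    """
    Yv = _as_counts_array(Y)
    n_genes, n_cells = Yv.shape
    r = design.r
    A = np.vstack([design.design, _onehot(np.asarray(memberships), k)])
    W = A * design.size_factors  # (r + k) x cells
    row_tot = W.sum(axis=1)  # exposure mass per factor
    active = row_tot > 0

    if init is None:
        # Flat positive start: distribute each gene's mean rate over factors.
        gene_rate = Yv.sum(axis=1) / max(design.size_factors.sum(), 1e-12)
        B = np.tile((gene_rate / max(r + k, 1))[:, None], (1, r + k)) + 1e-8
    else:
        B = np.hstack([init[0], init[1]]).astype(float).copy()

    denom = np.where(active, row_tot, 1.0)
    for _ in range(max_inner):
        M = B @ W
        ratio = np.divide(Yv, M, out=np.zeros_like(Yv), where=M > 0)
        B_new = B * ((ratio @ W.T) / denom)
        B_new[:, ~active] = B[:, ~active]
        # parameter-change stopping: cheap and avoids an extra likelihood pass
        delta = np.max(np.abs(B_new - B) / (np.abs(B) + 1.0))
        B = B_new
        if delta <= tol:
            break
    return B[:, :r], B[:, r:]


def update_memberships(
    Y: CountMatrix | np.ndarray,
    design: NuisanceDesign,
    X: np.ndarray,
    Z: np.ndarray,
) -> np.ndarray:
    """E-step: assign each cell to its maximum-likelihood cluster.

    Ties break to the lowest cluster index.
    """
    Yv = _as_counts_array(Y)
    k = Z.shape[1]
    base = X @ design.design if X.shape[1] else np.zeros((Yv.shape[0], Yv.shape[1]))
    G = design.size_factors
    ll = np.empty((k, Yv.shape[1]))
    for c in range(k):
        mu = (base + Z[:, c][:, None]) * G
        ll[c] = poisson_loglik(Yv, mu, axis=0)
    return np.argmax(ll, axis=0)


def _per_cell_loglik(Yv, design, X, Z, memberships) -> np.ndarray:
    mu = _rates(X, Z, design, memberships)
    return poisson_loglik(Yv, mu, axis=0)


def _reseed_empty_clusters(Yv, design, X, Z, memberships, k) -> np.ndarray:
    """Give empty clusters a chance: reseed their profile from the
    worst-fitting cells' denoised profiles.

    No cell is reassigned here, so the likelihood is unchanged; the next
    membership update adopts the reseeded cluster only if it improves a
    cell's likelihood, preserving EM monotonicity.
    """
    counts = np.bincount(memberships, minlength=k)
    empty = np.flatnonzero(counts == 0)
    if empty.size == 0:
        return Z
    Z = Z.copy()
    percell = _per_cell_loglik(Yv, design, X, Z, memberships)
    worst = np.argsort(percell)
    base = X @ design.design if X.shape[1] else np.zeros_like(Yv)
    for j, c in enumerate(empty):
        i = worst[j % worst.size]
        Z[:, c] = np.maximum(0.0, Yv[:, i] / design.size_factors[i] - base[:, i])
    return Z


def bic(log_likelihood: float, n_genes: int, r: int, k: int, n_cells: int) -> float:
    """-2 log L + p ln(n_cells) with p = n_genes * (r + k) free rates.

    Hard memberships are not counted as parameters.
    """
    p = n_genes * (r + k)
    return -2.0 * log_likelihood + p * np.log(n_cells)


def _kmeanspp_exemplars(L, k, rng):
    """D^2-weighted exemplar cells (k-means++ seeding) in the given
    feature space; small distant cell groups get seeded with high
    probability."""
    n_cells = L.shape[1]
    seeds = [int(rng.integers(n_cells))]
    sq = np.sum((L - L[:, seeds[0]][:, None]) ** 2, axis=0)
    for _ in range(1, k):
        tot = sq.sum()
        if tot <= 0:
            seeds.append(int(rng.integers(n_cells)))
            continue
        nxt = int(rng.choice(n_cells, p=sq / tot))
        seeds.append(nxt)
        sq = np.minimum(sq, np.sum((L - L[:, nxt][:, None]) ** 2, axis=0))
    return np.array(seeds)


def _seeding_spaces(Yv, design):
    """Feature spaces for exemplar seeding, cycled across restarts.

    The raw view is log1p depth-normalized expression.  When a nuisance
    design is present, a second view subtracts a quick nuisance-only
    profile fit (single cluster) so seeding distances reflect cell-state
    structure rather than which patient a cell came from; which view
    separates the cell groups better is data-dependent, so restarts
    alternate between them.
    """
    raw = np.log1p(Yv / design.size_factors)
    if design.r == 0:
        return [raw]
    ones = np.zeros(Yv.shape[1], dtype=int)
    X1, _ = update_profiles(Yv, design, ones, 1, max_inner=60)
    resid = np.maximum(0.0, Yv / design.size_factors - X1 @ design.design)
    return [raw, np.log1p(resid)]


def _init_parameters(Yv, design, k, rng, seed_space):
    """Random initial parameter set: cluster profiles seeded from k
    exemplar cells' depth-normalized counts, nuisance profiles flat.

    Exemplar seeding keeps the initial centroids spread out; uniform
    random memberships would average every centroid to the global mean
    and hard EM could not break the symmetry.
    """
    n_genes, n_cells = Yv.shape
    r = design.r
    seeds = _kmeanspp_exemplars(seed_space, k, rng)
    Z0 = Yv[:, seeds] / design.size_factors[seeds] + 1e-8
    gene_rate = Yv.sum(axis=1) / max(design.size_factors.sum(), 1e-12)
    X0 = np.tile((gene_rate / max(r + k, 1))[:, None], (1, r)) + 1e-8
    return X0, Z0


def _em_loop(Yv, design, k, X, Z, memberships, max_iter, tol):
    """Alternate profile and membership updates from a given state."""
    trace: list[float] = []
    prev_ll = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        inner = 100 if n_iter == 1 else 10
        X, Z = update_profiles(Yv, design, memberships, k, init=(X, Z), max_inner=inner)
        new_members = update_memberships(Yv, design, X, Z)
        unchanged = np.array_equal(new_members, memberships)
        memberships = new_members
        Z = _reseed_empty_clusters(Yv, design, X, Z, memberships, k)
        ll = float(poisson_loglik(Yv, _rates(X, Z, design, memberships)))
        trace.append(ll)
        if unchanged or (np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * (abs(prev_ll) + 1.0)):
            converged = True
            break
        prev_ll = ll
    return X, Z, memberships, trace, n_iter, converged


def _fit_single(Yv, design, k, rng, max_iter, tol, seed_space):
    X, Z = _init_parameters(Yv, design, k, rng, seed_space)
    memberships = update_memberships(Yv, design, X, Z)
    return _em_loop(Yv, design, k, X, Z, memberships, max_iter, tol)


def fit(
    Y: CountMatrix | np.ndarray,
    design: NuisanceDesign | None = None,
    k: int = 1,
    n_init: int = 10,
    max_iter: int = 200,
    tol: float = 1e-8,
    seed: int = 0,
) -> PrimusModel:
    """Fit the model for a fixed cluster count ``k``.

    Runs ``n_init`` random membership initializations and keeps the
    restart with the highest log-likelihood.  Deterministic given
    ``seed``.
    """
    Yv = _as_counts_array(Y)
    if design is None:
        design = NuisanceDesign.empty(Yv.shape[1])
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > Yv.shape[1]:
        raise ValueError(f"k={k} exceeds the number of cells ({Yv.shape[1]})")
    if Yv.shape[1] != design.n_cells:
        raise ValueError("counts and design disagree on the number of cells")

    ss = np.random.SeedSequence(seed)
    spaces = _seeding_spaces(Yv, design)
    best = None
    for i, child in enumerate(ss.spawn(n_init)):
        rng = np.random.default_rng(child)
        X, Z, members, trace, n_iter, converged = _fit_single(
            Yv, design, k, rng, max_iter, tol, spaces[i % len(spaces)]
        )
        ll = trace[-1]
        if best is None or ll > best[3][-1]:
            best = (X, Z, members, trace, n_iter, converged)
    X, Z, members, trace, n_iter, converged = best
    ll = trace[-1]
    return PrimusModel(
        X=X,
        Z=Z,
        memberships=members,
        k=k,
        log_likelihood=ll,
        bic=bic(ll, Yv.shape[0], design.r, k, Yv.shape[1]),
        n_iter=n_iter,
        converged=converged,
        seed=seed,
        ll_trace=trace,
    )


def select_k(
    Y: CountMatrix | np.ndarray,
    design: NuisanceDesign | None = None,
    k_range: range | list[int] = range(1, 26),
    n_init: int = 10,
    max_iter: int = 200,
    tol: float = 1e-8,
    seed: int = 0,
    keep_models: bool = False,
) -> KScan:
    """Scan cluster counts and select the BIC minimizer.

    Defaults scan k = 1..25 with 10 random restarts per k.  The BIC
    penalty grows with k, so clusters that only mirror nuisance factors
    already explained by the design are penalized away.
    """
    k_list = list(k_range)
    if not k_list:
        raise ValueError("empty k range")
    rows = []
    models: dict[int, PrimusModel] = {}
    ss = np.random.SeedSequence(seed)
    for k, child in zip(k_list, ss.spawn(len(k_list))):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        m = fit(Y, design, k=k, n_init=n_init, max_iter=max_iter, tol=tol, seed=sub_seed)
        rows.append({"k": k, "log_likelihood": m.log_likelihood, "bic": m.bic, "n_restarts": n_init})
        if keep_models:
            models[k] = m
    table = pd.DataFrame(rows)
    selected = int(table.loc[table["bic"].idxmin(), "k"])
    return KScan(table=table, selected_k=selected, models=models if keep_models else None)


def denoise(
    Y: CountMatrix | np.ndarray,
    design: NuisanceDesign,
    X: np.ndarray,
) -> np.ndarray:
    """Per-entry MLE of the nuisance-free expression rate.

    Solving ``Y[j,i] ~ Poisson((sum_l X[j,l] D[l,i] + Ztilde) * G[i])``
    for ``Ztilde >= 0`` gives the closed form
    ``max(0, Y/G - sum_l X D)``: observed depth-normalized expression
    minus the nuisance contribution, clipped at zero.
    """
    Yv = _as_counts_array(Y)
    base = X @ design.design if X.shape[1] else np.zeros_like(Yv)
    return np.maximum(0.0, Yv / design.size_factors - base)
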