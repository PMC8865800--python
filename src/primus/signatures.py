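"""Coexpressed gene-community discovery from differential-expression scans.

Genes that move together across cluster-pair comparisons form candidate
transcriptional programs.  The pipeline: (i) all-pairs LRT scan and gene
selection, (ii) a gene network from Pearson correlations of the signed
LRT statistics across comparisons (edges at rho > 0.8, P < 0.01),
(iii) Walktrap community detection with walk length 3, (iv) a coreness
filter trimming peripheral genes, (v) gene-set overrepresentation plus a
biclustering presence filter removing genes weakly supported by the
enriched sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
import scipy.stats
from sklearn.cluster import KMeans

from .de import PairwiseScan, adjust_fdr

__all__ = [
    "GeneCommunity",
    "Signature",
    "signed_lrt_matrix",
    "build_network",
    "walktrap_communities",
    "coreness_filter",
    "ora",
    "presence_filter",
    "discover_signatures",
]


@dataclass
class GeneCommunity:
    community_id: int
    genes: list[str]
    coreness: dict[str, int]

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class Signature:
    """A named gene list with provenance of the filters that produced it."""

    name: str
    genes: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("empty signature")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in signature")


def signed_lrt_matrix(scan: PairwiseScan, genes: list[str] | None = None) -> pd.DataFrame:
    """Genes x comparisons matrix of direction * LRT statistic.

    The sign is taken from the lower-index cluster minus the higher-index
    cluster rate, so up- and down-coregulation stay distinguishable when
    correlating genes.  Defaults to the scan's union gene list.
    """
    if genes is None:
        genes = scan.union_genes
    return scan.signed_stats.loc[genes]


def build_network(
    matrix: pd.DataFrame,
    rho_min: float = 0.8,
    p_max: float = 0.01,
) -> ig.Graph:
    """Pearson-correlation gene network over the signed statistics.

    An edge joins two genes iff rho > ``rho_min`` (strict) and the
    t-based correlation p-value is below ``p_max``, with
    t = rho * sqrt((n - 2) / (1 - rho^2)) on n = number of comparisons.
    Zero-variance rows carry no correlation information and are dropped
    with a warning.
    """
    n = matrix.shape[1]
    if n < 3:
        raise ValueError("need at least 3 comparisons to test correlations")
    vals = matrix.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    keep = sd > 0
    if not np.all(keep):
        dropped = matrix.index[~keep].tolist()
        warnings.warn(f"dropping {len(dropped)} zero-variance genes from network")
    genes = matrix.index[keep].astype(str).tolist()
    vals = vals[keep]
    if len(genes) == 0:
        return ig.Graph()
    rho = np.corrcoef(vals)
    np.fill_diagonal(rho, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - rho**2))
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 2)
    iu, ju = np.triu_indices(len(genes), k=1)
    mask = (rho[iu, ju] > rho_min) & (p[iu, ju] < p_max)
    edges = list(zip(iu[mask].tolist(), ju[mask].tolist()))
    g = ig.Graph(n=len(genes), edges=edges)
    g.vs["name"] = genes
    g.es["rho"] = rho[iu[mask], ju[mask]].tolist()
    g.es["p"] = p[iu[mask], ju[mask]].tolist()
    return g


def walktrap_communities(network: ig.Graph, steps: int = 3) -> list[GeneCommunity]:
    """Walktrap communities (walk length ``steps``), cut at max modularity.

    Deterministic given the vertex order; isolated vertices come back as
    singleton communities.  Coreness is computed on each community's
    induced subgraph.
    """
    if network.vcount() == 0:
        return []
    clustering = network.community_walktrap(steps=steps).as_clustering()
    out = []
    for cid, members in enumerate(clustering):
        sub = network.induced_subgraph(members)
        names = sub.vs["name"]
        core = dict(zip(names, sub.coreness()))
        out.append(GeneCommunity(community_id=cid, genes=list(names), coreness=core))
    return out


def coreness_filter(
    community: GeneCommunity,
    core_quorum: int = 30,
    top_n: int = 30,
) -> Signature:
    """Trim a community to its structural core.

    Let ``n_max`` be the number of genes at the maximum coreness
    (degeneracy) of the community subgraph.  If ``n_max`` exceeds
    ``core_quorum``, exactly those genes are kept; otherwise the top
    ``top_n`` genes ranked by coreness are kept (ties broken
    lexicographically by gene id).
    """
    core = community.coreness
    c_max = max(core.values())
    at_max = sorted(g for g, c in core.items() if c == c_max)
    if len(at_max) > core_quorum:
        kept = at_max
        rule = "max-coreness"
    else:
        ranked = sorted(core.items(), key=lambda gc: (-gc[1], gc[0]))
        kept = [g for g, _ in ranked[:top_n]]
        rule = f"top-{top_n}-coreness"
    return Signature(
        name=f"community_{community.community_id}",
        genes=kept,
        provenance={"community_id": community.community_id, "coreness_rule": rule},
    )


def ora(
    genes: list[str],
    gene_sets: dict[str, list[str]],
    background: list[str],
    fdr_max: float = 0.05,
    max_set: int = 500,
) -> pd.DataFrame:
    """Hypergeometric gene-set overrepresentation analysis.

    Upper-tail p-value per set against the ``background`` universe,
    BH-adjusted; a set is ``retained`` iff FDR < ``fdr_max`` and the set
    has fewer than ``max_set`` genes.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background universe")
    query = set(genes) & bg
    rows = []
    for name, members in gene_sets.items():
        in_bg = set(members) & bg
        overlap = len(query & in_bg)
        p = scipy.stats.hypergeom.sf(overlap - 1, len(bg), len(in_bg), len(query))
        rows.append({"set": name, "set_size": len(members), "overlap": overlap, "p_value": p})
    out = pd.DataFrame(rows).set_index("set")
    out["fdr"] = adjust_fdr(out["p_value"].to_numpy())
    out["retained"] = (out["fdr"] < fdr_max) & (out["set_size"] < max_set)
    return out


def _alternating_bicluster(B: np.ndarray, row_blocks: int, col_blocks: int, seed: int, n_sweeps: int = 5):
    """Co-cluster a binary matrix by alternating two-way k-means.

    Rows are clustered on column-block average profiles and vice versa,
    refining both partitions for a few sweeps.
    """
    rng_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))
    n_r, n_c = B.shape
    # duplicate rows/columns are common in binary membership matrices;
    # cap the block counts at the number of distinct profiles
    row_blocks = min(row_blocks, n_r, len(np.unique(B, axis=0)))
    col_blocks = min(col_blocks, n_c, len(np.unique(B.T, axis=0)))
    row_lab = KMeans(row_blocks, n_init=10, random_state=rng_seed).fit_predict(B)
    col_lab = KMeans(col_blocks, n_init=10, random_state=rng_seed + 1).fit_predict(B.T)
    for sweep in range(n_sweeps):
        col_means = np.stack(
            [B[:, col_lab == c].mean(axis=1) if np.any(col_lab == c) else np.zeros(n_r) for c in range(col_blocks)],
            axis=1,
        )
        row_lab = KMeans(row_blocks, n_init=5, random_state=rng_seed + 2 + sweep).fit_predict(col_means)
        row_means = np.stack(
            [B[row_lab == r].mean(axis=0) if np.any(row_lab == r) else np.zeros(n_c) for r in range(row_blocks)],
            axis=0,
        )  # row_blocks x n_c: each column described by its per-row-block mean
        col_lab = KMeans(col_blocks, n_init=5, random_state=rng_seed + 100 + sweep).fit_predict(row_means.T)
    return row_lab, col_lab


def presence_filter(
    genes: list[str],
    enriched_sets: dict[str, list[str]],
    presence_min: float = 0.03,
    row_blocks: int = 3,
    col_blocks: int = 3,
    seed: int = 0,
    name: str = "signature",
) -> Signature | None:
    """Redundancy filter on the gene x enriched-set membership matrix.

    Genes absent from every enriched set are dropped first.  The binary
    presence matrix is then co-clustered, and every gene block whose
    presence fraction falls below ``presence_min`` in any gene-set block
    is excluded.  Returns ``None`` (with a warning) if nothing survives.
    """
    if not enriched_sets:
        raise ValueError("no enriched sets supplied")
    set_names = list(enriched_sets)
    covered = [g for g in genes if any(g in enriched_sets[s] for s in set_names)]
    if not covered:
        warnings.warn("no gene overlaps any enriched set; empty signature")
        return None
    B = np.array([[1.0 if g in enriched_sets[s] else 0.0 for s in set_names] for g in covered])
    if not B.any():
        warnings.warn("degenerate all-zero presence matrix; empty signature")
        return None
    row_lab, col_lab = _alternating_bicluster(B, row_blocks, col_blocks, seed)
    keep_rows = np.zeros(len(covered), dtype=bool)
    for r in np.unique(row_lab):
        rows = row_lab == r
        ok = True
        for c in np.unique(col_lab):
            block = B[np.ix_(rows, col_lab == c)]
            if block.size and block.mean() < presence_min:
                ok = False
                break
        keep_rows |= rows & ok
    kept = [g for g, k in zip(covered, keep_rows) if k]
    if not kept:
        warnings.warn("presence filter removed all genes")
        return None
    return Signature(
        name=name,
        genes=kept,
        provenance={"filter": "presence", "presence_min": presence_min},
    )


def discover_signatures(
    scan: PairwiseScan,
    gene_sets: dict[str, list[str]] | None = None,
    background: list[str] | None = None,
    rho_min: float = 0.8,
    p_max: float = 0.01,
    steps: int = 3,
    min_community_size: int = 30,
    presence_gate: int = 20,
    seed: int = 0,
) -> list[Signature]:
    """End-to-end signature discovery from a pairwise DE scan.

    Communities larger than ``min_community_size`` genes survive; each is
    trimmed by the coreness filter, and — when ``gene_sets`` are supplied
    and the trimmed community still has more than ``presence_gate``
    genes — by overrepresentation plus the biclustering presence filter.
    """
    matrix = signed_lrt_matrix(scan)
    network = build_network(matrix, rho_min=rho_min, p_max=p_max)
    communities = [c for c in walktrap_communities(network, steps=steps) if len(c) > min_community_size]
    signatures: list[Signature] = []
    for comm in communities:
        sig = coreness_filter(comm)
        if gene_sets is not None and len(sig.genes) > presence_gate:
            bg = background if background is not None else scan.signed_stats.index.astype(str).tolist()
            enrich = ora(sig.genes, gene_sets, bg)
            retained = {s: gene_sets[s] for s in enrich.index[enrich["retained"]]}
            if retained:
                filtered = presence_filter(sig.genes, retained, seed=seed, name=sig.name)
                if filtered is not None:
                    filtered.provenance.update(sig.provenance)
                    sig = filtered
        signatures.append(sig)
    return signatures
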