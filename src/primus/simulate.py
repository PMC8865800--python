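"""Ground-truthed synthetic scRNA-seq datasets.

Two generators are provided:

* :func:`simulate_primus` draws data directly from the bilinear Poisson
  model (gamma-prior profiles, lognormal size factors, hard uniform
  memberships), recording the full truth — the oracle for parameter- and
  membership-recovery experiments.

* :func:`simulate_population` emulates a splatter/splatPop-style
  population simulation: gamma gene means, per-sample lognormal
  multipliers standing in for individual (eQTL-like) effects, per-group
  multiplicative differential-expression effects on a random gene
  subset, lognormal library sizes, Poisson (optionally negative
  binomial) observation noise.  Three compositional scenarios over six
  samples and five cell groups are preset: (i) every group in every
  sample, (ii) three sample pairs sharing no groups plus one
  sample-private group, (iii) scenario ii with unbalanced per-sample
  cell counts from 20 to 2000.  Desk-scale presets shrink genes and
  cells fivefold while preserving the composition structure.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
splitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix
from .preprocessing import NuisanceDesign, build_design, compute_size_factors

__all__ = [
    "SyntheticDataset",
    "ScenarioSpec",
    "simulate_primus",
    "simulate_population",
    "scenario_presets",
]


@dataclass
class SyntheticDataset:
    counts: CountMatrix
    sample_labels: np.ndarray
    group_labels: np.ndarray
    design: NuisanceDesign
    truth: dict | None = None
    scenario: str = ""
    seed: int | None = None


def simulate_primus(
    n_genes: int = 200,
    n_cells: int = 1000,
    r: int = 4,
    k: int = 4,
    seed: int = 0,
    separation: float = 1.0,
    base_shape: float = 2.0,
    base_scale: float = 0.5,
    nuisance_shape: float = 2.0,
    nuisance_scale: float = 0.25,
    size_factor_sigma: float = 0.2,
) -> SyntheticDataset:
    """Draw a dataset from the bilinear Poisson generative model.

    ``separation`` scales the log-spread of cluster profiles around a
    shared gamma-distributed baseline: at 0 all cluster profiles are
    identical (no phenotypic signal); around 1 clusters are well
    separated.  Nuisance profiles are gamma draws per (gene, sample).
    The recorded truth is gauge-fixed: the per-gene minimum over
    nuisance profiles is shifted into ``Z`` so the (X, Z) split is the
    canonical identifiable one.
    """
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    base = rng.gamma(base_shape, base_scale, size=n_genes)
    Z = base[:, None] * np.exp(separation * rng.standard_normal((n_genes, k)))
    if separation == 0:
        Z = np.tile(base[:, None], (1, k))
    X = rng.gamma(nuisance_shape, nuisance_scale, size=(n_genes, r)) if r else np.zeros((n_genes, 0))
    # canonical gauge: per-gene nuisance minimum belongs to the shared part
    if r:
        shift = X.min(axis=1)
        X = X - shift[:, None]
        Z = Z + shift[:, None]
    samples = rng.integers(0, r, size=n_cells) if r else np.zeros(n_cells, dtype=int)
    members = rng.integers(0, k, size=n_cells)
    G = np.exp(size_factor_sigma * rng.standard_normal(n_cells))
    D = np.zeros((r, n_cells))
    if r:
        D[samples, np.arange(n_cells)] = 1.0
    mu = ((X @ D) + Z[:, members]) * G
    Y = rng.poisson(mu)
    counts = CountMatrix(Y.astype(np.int64))
    design = NuisanceDesign(D, [f"sample={s}" for s in range(r)], G)
    return SyntheticDataset(
        counts=counts,
        sample_labels=np.array([f"sample_{s}" for s in samples]),
        group_labels=members,
        design=design,
        truth={"X": X, "Z": Z, "memberships": members, "G": G},
        scenario="primus",
        seed=seed,
    )


@dataclass
class ScenarioSpec:
    """Structure and effect sizes of a population simulation.

    ``composition`` is samples x groups inclusion weights; cells of a
    sample draw their group proportionally to its row.  Effect-size
    defaults describe strongly modular tumor-state programs: 10% of
    genes per group shifted by lognormal fold changes (meanlog 1.0,
    sdlog 0.5, half up / half down), mild per-sample individual effects
    (sdlog 0.3) on all genes, and lognormal library sizes (sdlog 0.2).
    Gene means follow the gamma(0.6, rate 0.3) convention of splatter.
    """

    name: str
    n_genes: int
    cells_per_sample: list[int]
    composition: np.ndarray  # n_samples x n_groups weights
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    sample_effect_sigma: float = 0.3
    de_prob: float = 0.1
    de_loc: float = 1.0
    de_scale: float = 0.5
    lib_sigma: float = 0.2
    nb_dispersion: float | None = None  # optional overdispersion (1/size); off by default

    def __post_init__(self) -> None:
        self.composition = np.asarray(self.composition, dtype=float)
        if np.any(self.composition < 0):
            raise ValueError("composition weights must be nonnegative")
        if len(self.cells_per_sample) != self.composition.shape[0]:
            raise ValueError("cells_per_sample length must match composition rows")
        if any(c < 1 for c in self.cells_per_sample):
            raise ValueError("each sample needs at least one cell")
        if np.any(self.composition.sum(axis=1) == 0):
            raise ValueError("every sample must contain at least one group")

    @property
    def n_samples(self) -> int:
        return self.composition.shape[0]

    @property
    def n_groups(self) -> int:
        return self.composition.shape[1]

    @property
    def n_cells(self) -> int:
        return int(sum(self.cells_per_sample))


def simulate_population(spec: ScenarioSpec, seed: int = 0) -> SyntheticDataset:
    """Simulate counts under a compositional scenario; see module docstring."""
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    n_genes = spec.n_genes
    gene_mean = rng.gamma(spec.mean_shape, 1.0 / spec.mean_rate, size=n_genes)
    sample_eff = np.exp(
        spec.sample_effect_sigma * rng.standard_normal((spec.n_samples, n_genes))
    )
    group_eff = np.ones((spec.n_groups, n_genes))
    de_truth = {}
    for g in range(spec.n_groups):
        n_de = int(round(spec.de_prob * n_genes))
        idx = rng.choice(n_genes, size=n_de, replace=False)
        lfc = rng.normal(spec.de_loc, spec.de_scale, size=n_de)
        sign = rng.choice([-1.0, 1.0], size=n_de)
        group_eff[g, idx] = np.exp(sign * np.abs(lfc))
        de_truth[g] = idx
    sample_labels = []
    group_labels = []
    for s, n_c in enumerate(spec.cells_per_sample):
        w = spec.composition[s] / spec.composition[s].sum()
        groups = rng.choice(spec.n_groups, size=n_c, p=w)
        sample_labels.extend([s] * n_c)
        group_labels.extend(groups.tolist())
    sample_labels = np.array(sample_labels)
    group_labels = np.array(group_labels)
    lib = np.exp(spec.lib_sigma * rng.standard_normal(len(sample_labels)))
    rate = gene_mean[:, None] * sample_eff[sample_labels].T * group_eff[group_labels].T * lib
    if spec.nb_dispersion:
        shape = 1.0 / spec.nb_dispersion
        rate = rate * rng.gamma(shape, 1.0 / shape, size=rate.shape)
    Y = rng.poisson(rate)
    counts = CountMatrix(Y.astype(np.int64))
    meta = pd.DataFrame(
        {"sample": [f"sample_{s}" for s in sample_labels]},
        index=counts.cell_ids,
    )
    design = build_design(meta, categorical=["sample"], size_factors=compute_size_factors(counts))
    return SyntheticDataset(
        counts=counts,
        sample_labels=np.array([f"sample_{s}" for s in sample_labels]),
        group_labels=group_labels,
        design=design,
        truth={
            "gene_mean": gene_mean,
            "de_genes": de_truth,
            "library": lib,
            "sample_effects": sample_eff,
            "group_effects": group_eff,
        },
        scenario=spec.name,
        seed=seed,
    )


# Scenario ii/iii composition over 6 samples x 5 groups: three sample
# pairs (s0,s1), (s2,s3), (s4,s5) share no groups within a pair, and
# group 4 is private to sample 5.
_COMPOSITION_DISJOINT = np.array(
    [
        [1, 1, 0, 0, 0],
        [0, 0, 1, 1, 0],
        [1, 0, 1, 0, 0],
        [0, 1, 0, 1, 0],
        [1, 0, 0, 1, 0],
        [0, 1, 1, 0, 1],
    ],
    dtype=float,
)


def scenario_presets(scale: str = "full") -> dict[str, ScenarioSpec]:
    """The three compositional scenario presets.

    Full scale: (i) 6 x 5 all-present, 3000 cells x 5000 genes;
    (ii) disjoint pairs + one private group, 1400 cells x 5000 genes;
    (iii) composition of ii with per-sample cell counts 20..2000.
    ``scale="desk"`` divides genes and cells by 5, preserving structure.
    """
    if scale not in ("full", "desk"):
        raise ValueError("scale must be 'full' or 'desk'")
    f = 1 if scale == "full" else 5
    presets = {
        "i": ScenarioSpec(
            name="i",
            n_genes=5000 // f,
            cells_per_sample=[3000 // 6 // f] * 6,
            composition=np.ones((6, 5)),
        ),
        "ii": ScenarioSpec(
            name="ii",
            n_genes=5000 // f,
            cells_per_sample=_split_total(1400 // f, 6),
            composition=_COMPOSITION_DISJOINT.copy(),
        ),
        "iii": ScenarioSpec(
            name="iii",
            n_genes=5000 // f,
            cells_per_sample=[max(2, c // f) for c in (20, 50, 100, 500, 1000, 2000)],
            composition=_COMPOSITION_DISJOINT.copy(),
        ),
    }
    return presets


def _split_total(total: int, parts: int) -> list[int]:
    base = total // parts
    rem = total - base * parts
    return [base + (1 if i < rem else 0) for i in range(parts)]
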