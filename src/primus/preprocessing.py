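"""Nuisance designs, size factors, and cell quality-control filtering.

The clustering model treats known unwanted variation — patient identity,
technical covariates such as the mitochondrial fraction — as a design
matrix ``D`` (nuisance factors x cells) whose expression profiles are
absorbed separately from the phenotypic cluster profiles.  Per-cell size
factors ``G`` capture sequencing depth and scale the Poisson rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix


@dataclass
class NuisanceDesign:
    """Known nuisance design ``D`` (r x cells) with per-cell size factors ``G``.

    Categorical factors occupy one-hot blocks (exactly one 1 per cell per
    block); continuous covariates are min-max scaled to [0, 1] so the
    Poisson rate stays nonnegative under nonnegative profiles.
    """

    design: np.ndarray
    factor_names: list[str] = field(default_factory=list)
    size_factors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.design = np.atleast_2d(np.asarray(self.design, dtype=float))
        if not self.factor_names:
            self.factor_names = [f"factor_{l}" for l in range(self.design.shape[0])]
        if len(self.factor_names) != self.design.shape[0]:
            raise ValueError("factor_names length does not match design rows")
        if np.any(self.design < 0):
            raise ValueError("design entries must be nonnegative")
        if self.size_factors is None:
            self.size_factors = np.ones(self.design.shape[1])
        self.size_factors = np.asarray(self.size_factors, dtype=float)
        if self.size_factors.shape != (self.design.shape[1],):
            raise ValueError("size_factors length does not match cells")
        if np.any(self.size_factors <= 0):
            raise ValueError("size factors must be positive")

    @property
    def r(self) -> int:
        return self.design.shape[0]

    @property
    def n_cells(self) -> int:
        return self.design.shape[1]

    @classmethod
    def empty(cls, n_cells: int, size_factors: np.ndarray | None = None) -> "NuisanceDesign":
        """A design with no nuisance factors (r = 0)."""
        return cls(np.zeros((0, n_cells)), [], size_factors)


def build_design(
    meta: pd.DataFrame,
    categorical: list[str] = (),
    continuous: list[str] = (),
    size_factors: np.ndarray | None = None,
) -> NuisanceDesign:
    """Build a nuisance design from per-cell metadata.

    Row order is the categorical one-hot blocks (levels in first-appearance
    order) followed by the min-max scaled continuous covariates.  A
    continuous covariate with no variation carries no information and is
    dropped with a warning.
    """
    rows: list[np.ndarray] = []
    names: list[str] = []
    for col in categorical:
        vals = meta[col]
        if vals.isna().any():
            bad = meta.index[vals.isna()].tolist()
            raise ValueError(f"missing values for {col!r} in cells: {bad}")
        levels = list(dict.fromkeys(vals))
        for lev in levels:
            rows.append((vals == lev).to_numpy(dtype=float))
            names.append(f"{col}={lev}")
    for col in continuous:
        vals = meta[col]
        if vals.isna().any():
            bad = meta.index[vals.isna()].tolist()
            raise ValueError(f"missing values for {col!r} in cells: {bad}")
        x = vals.to_numpy(dtype=float)
        lo, hi = x.min(), x.max()
        if hi == lo:
            warnings.warn(f"continuous covariate {col!r} is constant; dropped")
            continue
        rows.append((x - lo) / (hi - lo))
        names.append(col)
    design = np.array(rows) if rows else np.zeros((0, len(meta)))
    return NuisanceDesign(design, names, size_factors)


def compute_size_factors(counts: CountMatrix) -> np.ndarray:
    """Total-count size factors: per-cell total over the median total.

    Any positive per-cell vector (for example scran/scater pooled factors)
    may be supplied to the model instead; this is the default.
    """
    totals = counts.total_counts().astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = [counts.cell_ids[i] for i in zero[:10]]
        raise ValueError(f"cells with zero total count: {names}")
    return totals / np.median(totals)


# ---------------------------------------------------------------------------
# Quality control

#: Per-class QC cutoffs: min reads, min UMIs, min detected genes, max mito %.
DEFAULT_QC_THRESHOLDS: dict[str, dict[str, float]] = {
    "cancer": {"min_reads": 8192, "min_umis": 4075, "min_genes": 1552, "max_mito_pct": 12.0},
    "stromal": {"min_reads": 4096, "min_umis": 2048, "min_genes": 1024, "max_mito_pct": 7.5},
    "immune": {"min_reads": 2896, "min_umis": 1024, "min_genes": 512, "max_mito_pct": 7.5},
}

#: First-pass cutoff applied to every cell regardless of class.
GLOBAL_MAX_MITO_PCT = 15.0


def qc_filter(
    meta: pd.DataFrame,
    thresholds: dict[str, dict[str, float]] | None = None,
    global_max_mito_pct: float = GLOBAL_MAX_MITO_PCT,
) -> list[str]:
    """Return ids of cells passing quality control.

    ``meta`` needs columns ``cell_class`` (cancer / stromal / immune),
    ``reads``, ``umis``, ``genes`` and ``mito_pct``.  A cell is retained
    iff it passes the global mitochondrial cutoff and all four
    class-specific criteria (strictly above the minimums, strictly below
    the mitochondrial maximum, mirroring how the cutoffs are stated).
    """
    if thresholds is None:
        thresholds = DEFAULT_QC_THRESHOLDS
    retained: list[str] = []
    for cell_id, row in meta.iterrows():
        cls = row["cell_class"]
        if cls not in thresholds:
            raise ValueError(f"unknown cell class {cls!r} for cell {cell_id!r}")
        th = thresholds[cls]
        ok = (
            row["mito_pct"] <= global_max_mito_pct
            and row["reads"] > th["min_reads"]
            and row["umis"] > th["min_umis"]
            and row["genes"] > th["min_genes"]
            and row["mito_pct"] < th["max_mito_pct"]
        )
        if ok:
            retained.append(str(cell_id))
    return retained


def flag_marker_doublets(
    counts: CountMatrix,
    markers: tuple[str, str, str] = ("PAX8", "DCN", "PTPRC"),
    min_count: int = 1,
) -> list[str]:
    """Cells co-expressing lineage-exclusive markers (likely doublets).

    A cell is flagged when two or more of the marker genes (epithelial,
    stromal, immune by default) are detected at ``min_count`` or more.
    The detection threshold is configurable; count >= 1 is the default
    notion of "expressing".
    """
    present = [m for m in markers if m in counts.gene_ids]
    if len(present) < 2:
        return []
    idx = [counts.gene_ids.index(m) for m in present]
    expressed = (counts.values[idx, :] >= min_count).sum(axis=0)
    return [counts.cell_ids[i] for i in np.flatnonzero(expressed >= 2)]
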