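"""Reading and writing count matrices, gene sets, and clinical tables.

Counts are kept genes x cells everywhere: rows are genes, columns are
cells, matching the orientation of 10x-style MatrixMarket exports.  Two
on-disk formats are supported: an MTX coordinate triplet with
``genes.tsv``/``barcodes.tsv`` sidecars, and a dense TSV with gene ids in
the first column and cell ids in the header row.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class FormatError(ValueError):
    """A file violated the expected on-disk format."""


@dataclass
class CountMatrix:
    """UMI counts for genes x cells.

    Attributes
    ----------
    values
        Nonnegative integer matrix, shape ``(n_genes, n_cells)``.
    gene_ids, cell_ids
        Unique row and column labels.
    """

    values: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if not self.gene_ids:
            self.gene_ids = [f"gene_{j}" for j in range(self.values.shape[0])]
        if not self.cell_ids:
            self.cell_ids = [f"cell_{i}" for i in range(self.values.shape[1])]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {self.values.shape[0]} rows"
            )
        if len(self.cell_ids) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {self.values.shape[1]} columns"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        if np.any(self.values < 0):
            raise ValueError("negative counts")
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.all(self.values == np.floor(self.values)):
                raise ValueError("non-integer counts")
            self.values = self.values.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def total_counts(self) -> np.ndarray:
        """Per-cell total UMI count."""
        return self.values.sum(axis=0)


def read_counts(path: str | Path, format: str = "auto") -> CountMatrix:
    """Read a count matrix from disk.

    Parameters
    ----------
    path
        For ``mtx-triplet``, either the ``matrix.mtx`` file or its
        directory (expects ``genes.tsv`` and ``barcodes.tsv`` alongside).
        For ``dense-tsv``, the TSV file.
    format
        ``"mtx-triplet"``, ``"dense-tsv"`` or ``"auto"`` (by extension).
    """
    path = Path(path)
    if format == "auto":
        if path.is_dir() or path.suffix == ".mtx":
            format = "mtx-triplet"
        else:
            format = "dense-tsv"
    if format == "mtx-triplet":
        return _read_mtx_triplet(path)
    if format == "dense-tsv":
        return _read_dense_tsv(path)
    raise ValueError(f"unknown format {format!r}")


def _read_mtx_triplet(path: Path) -> CountMatrix:
    if path.is_dir():
        mtx = path / "matrix.mtx"
    else:
        mtx = path
    folder = mtx.parent
    genes_f = folder / "genes.tsv"
    barcodes_f = folder / "barcodes.tsv"
    for f in (mtx, genes_f, barcodes_f):
        if not f.exists():
            raise FormatError(f"missing file: {f}")
    try:
        mat = scipy.io.mmread(mtx)
    except Exception as exc:  # noqa: BLE001 - surface as a format error
        raise FormatError(f"malformed MatrixMarket file {mtx}: {exc}") from exc
    dense = np.asarray(scipy.sparse.coo_matrix(mat).todense())
    genes = pd.read_csv(genes_f, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
    cells = pd.read_csv(barcodes_f, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
    if dense.shape != (len(genes), len(cells)):
        raise FormatError(
            f"{mtx}: matrix is {dense.shape} but sidecars list "
            f"{len(genes)} genes and {len(cells)} barcodes"
        )
    if np.any(dense < 0) or not np.all(dense == np.floor(dense)):
        raise FormatError(f"{mtx}: counts must be nonnegative integers")
    return CountMatrix(dense.astype(np.int64), genes, cells)


def _read_dense_tsv(path: Path) -> CountMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    vals = df.to_numpy()
    if vals.size and (np.any(pd.isna(vals)) or np.any(vals < 0)):
        bad = int(np.argwhere(pd.isna(vals) | (vals < 0))[0][0]) + 2
        raise FormatError(f"{path}, line {bad}: counts must be nonnegative")
    if vals.size and not np.all(vals == np.floor(vals.astype(float))):
        raise FormatError(f"{path}: non-integer counts")
    return CountMatrix(
        vals.astype(np.int64), df.index.astype(str).tolist(), df.columns.astype(str).tolist()
    )


def write_counts(counts: CountMatrix, path: str | Path, format: str = "mtx-triplet") -> None:
    """Write a count matrix; round-trips bit-exactly with :func:`read_counts`."""
    path = Path(path)
    if format == "mtx-triplet":
        path.mkdir(parents=True, exist_ok=True)
        sp = scipy.sparse.coo_matrix(counts.values)
        scipy.io.mmwrite(path / "matrix.mtx", sp, field="integer")
        pd.Series(counts.gene_ids).to_csv(
            path / "genes.tsv", sep="\t", header=False, index=False
        )
        pd.Series(counts.cell_ids).to_csv(
            path / "barcodes.tsv", sep="\t", header=False, index=False
        )
    elif format == "dense-tsv":
        path.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            counts.values, index=counts.gene_ids, columns=counts.cell_ids
        ).to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Gene sets (GMT)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}, line {lineno}: expected name, description, genes")
        name, genes = parts[0], [g for g in parts[2:] if g]
        if name in sets:
            raise FormatError(f"{path}, line {lineno}: duplicate set {name!r}")
        sets[name] = genes
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *genes]) for name, genes in gene_sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Clinical table


def load_clinical_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load a clinical table (default: the packaged HGSOC NACT cohort).

    The packaged fixture describes 29 patients with high-grade serous
    ovarian cancer treated with neoadjuvant chemotherapy: platinum-free
    interval (PFI, days), treatment, stage, chemotherapy response score,
    CA125 levels, and the anatomical locations sampled for scRNA-seq and
    bulk RNA-seq before and after treatment.
    """
    if path is None:
        ref = importlib.resources.files("primus.data") / "hgsoc_cohort_clinical.tsv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    if df["patient_id"].duplicated().any():
        raise FormatError("duplicate patient ids in clinical table")
    if (df["pfi_days"].dropna() < 0).any():
        raise FormatError("negative PFI")
    return df.set_index("patient_id")


def scrnaseq_patients(clinical: pd.DataFrame) -> list[str]:
    """Patients with at least one scRNA-seq sample recorded."""
    has = clinical[["scrnaseq_tn", "scrnaseq_pn"]].notna().any(axis=1)
    return clinical.index[has].tolist()


def cohort_summary(clinical: pd.DataFrame, patient_ids: list[str] | None = None) -> dict:
    """Summarize a patient subset: median PFI in months (days / 30, one decimal).

    Raises on an empty subset or unknown patient ids.
    """
    if patient_ids is None:
        patient_ids = clinical.index.tolist()
    if len(patient_ids) == 0:
        raise ValueError("empty patient subset")
    missing = sorted(set(patient_ids) - set(clinical.index))
    if missing:
        raise KeyError(f"unknown patients: {missing}")
    sub = clinical.loc[patient_ids]
    median_days = float(sub["pfi_days"].median())
    return {
        "n_patients": len(patient_ids),
        "median_pfi_days": median_days,
        "median_pfi_months": round(median_days / 30.0, 1),
    }
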