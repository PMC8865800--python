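"""Model archives: matrices as TSV plus a JSON manifest.

A fitted model is stored as a directory holding ``X.tsv`` (genes x
nuisance factors), ``Z.tsv`` (genes x clusters), ``memberships.tsv``
and ``manifest.json`` with k, seed, log-likelihood, BIC, iteration
count and package version, so runs are auditable and reloadable.
"""

from __future__ import annotations

import hashlib
import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from .model import PrimusModel

__all__ = ["save_model", "load_model", "write_manifest"]


def _pkg_version() -> str:
    try:
        return version("primus-sc")
    except PackageNotFoundError:
        return "unknown"


def save_model(model: PrimusModel, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(model.X).to_csv(path / "X.tsv", sep="\t", header=False, index=False)
    pd.DataFrame(model.Z).to_csv(path / "Z.tsv", sep="\t", header=False, index=False)
    pd.Series(model.memberships).to_csv(
        path / "memberships.tsv", sep="\t", header=False, index=False
    )
    manifest = {
        "k": model.k,
        "r": model.r,
        "seed": model.seed,
        "log_likelihood": model.log_likelihood,
        "bic": model.bic,
        "n_iter": model.n_iter,
        "converged": model.converged,
        "version": _pkg_version(),
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_model(path: str | Path) -> PrimusModel:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    Z = pd.read_csv(path / "Z.tsv", sep="\t", header=None).to_numpy(dtype=float)
    if manifest["r"] == 0:
        X = np.zeros((Z.shape[0], 0))
    else:
        X = pd.read_csv(path / "X.tsv", sep="\t", header=None).to_numpy(dtype=float)
    members = (
        pd.read_csv(path / "memberships.tsv", sep="\t", header=None)
        .to_numpy(dtype=int)
        .ravel()
    )
    return PrimusModel(
        X=X,
        Z=Z,
        memberships=members,
        k=manifest["k"],
        log_likelihood=manifest["log_likelihood"],
        bic=manifest["bic"],
        n_iter=manifest["n_iter"],
        converged=manifest["converged"],
        seed=manifest["seed"],
    )


def write_manifest(out_dir: str | Path, config: dict, artifacts: list[str | Path]) -> Path:
    """Record a run: config, seed, artifact checksums, package version."""
    out_dir = Path(out_dir)
    entries = {}
    for art in artifacts:
        p = Path(art)
        if p.is_file():
            entries[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {"config": config, "artifacts": entries, "version": _pkg_version()}
    dest = out_dir / "run_manifest.json"
    dest.write_text(json.dumps(manifest, indent=2, default=str))
    return dest
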