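"""Readers and writers for the on-disk formats.

Counts travel as MatrixMarket (.mtx) with sidecar ``<stem>.genes.txt`` /
``<stem>.cells.txt`` id files, or as dense CSV/TSV with gene ids in the
first column and cell ids in the header. Pseudotimes, lineage weights,
covariates and offsets are CSV/TSV tables with cell ids in the first column.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger("trajde")

__all__ = [
    "read_counts",
    "write_counts",
    "read_cell_table",
    "write_cell_table",
    "save_fit",
    "load_fit",
]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def _check_integer(mat: np.ndarray):
    if np.max(np.abs(mat - np.round(mat))) > 1e-9:
        raise ValueError("counts must be integers (entry deviates by more than 1e-9)")


def read_counts(path, genes_path=None, cells_path=None):
    """Read a genes x cells integer count matrix.

    Returns ``(counts, gene_ids, cell_ids)``. An MTX whose sidecar dimensions
    imply a cells x genes orientation is transposed automatically (logged).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"count matrix not found: {path}")
    if path.suffix.lower() == ".mtx":
        stem = path.with_suffix("")
        genes_path = Path(genes_path) if genes_path else Path(f"{stem}.genes.txt")
        cells_path = Path(cells_path) if cells_path else Path(f"{stem}.cells.txt")
        for p, what in ((genes_path, "gene"), (cells_path, "cell")):
            if not p.exists():
                raise FileNotFoundError(f"missing {what} id sidecar file: {p}")
        genes = np.loadtxt(genes_path, dtype=str, ndmin=1)
        cells = np.loadtxt(cells_path, dtype=str, ndmin=1)
        mat = spio.mmread(path).toarray()
        if mat.shape == (len(cells), len(genes)) and mat.shape[0] != mat.shape[1]:
            logger.info("MTX stored as cells x genes; transposing to genes x cells")
            mat = mat.T
        if mat.shape != (len(genes), len(cells)):
            raise ValueError(
                f"matrix shape {mat.shape} does not match {len(genes)} genes x {len(cells)} cells"
            )
        _check_integer(mat)
        return mat.astype(np.int64), genes.astype(object), cells.astype(object)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    mat = df.to_numpy(dtype=float)
    _check_integer(mat)
    return (
        np.round(mat).astype(np.int64),
        df.index.to_numpy(dtype=object),
        df.columns.to_numpy(dtype=object),
    )


def write_counts(path, counts, gene_ids, cell_ids):
    """Write counts as MTX (+ id sidecars) or dense CSV/TSV by extension."""
    path = Path(path)
    counts = np.asarray(counts)
    if path.suffix.lower() == ".mtx":
        stem = path.with_suffix("")
        spio.mmwrite(path, sparse.coo_matrix(counts), field="integer")
        np.savetxt(f"{stem}.genes.txt", np.asarray(gene_ids, dtype=str), fmt="%s")
        np.savetxt(f"{stem}.cells.txt", np.asarray(cell_ids, dtype=str), fmt="%s")
    else:
        pd.DataFrame(counts, index=gene_ids, columns=cell_ids).to_csv(
            path, sep=_sep_for(path)
        )
    return path


def read_cell_table(path):
    """Read a cells x columns table (pseudotimes, weights, covariates...).

    Returns ``(matrix, cell_ids, column_names)``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"table not found: {path}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    return (
        df.to_numpy(dtype=float),
        df.index.to_numpy(dtype=object),
        df.columns.to_numpy(dtype=object),
    )


def write_cell_table(path, matrix, cell_ids, column_names):
    path = Path(path)
    pd.DataFrame(np.asarray(matrix), index=cell_ids, columns=column_names).to_csv(
        path, sep=_sep_for(path)
    )
    return path


# ----------------------------------------------------------- fit persistence
def save_fit(model, out_dir):
    """Persist a fitted model (arrays to .npz, metadata to JSON)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        out_dir / "fit.npz",
        beta=model.beta_,
        Sigma=model.Sigma_,
        phi=model.phi_,
        lam=model.lambda_,
        edf=model.edf_,
        loglik=model.loglik_,
        aic=model.aic_,
        converged=model.converged_,
        knots=model.knots_,
        Z=model.assignment_.Z,
        offsets=model.offsets_,
        lineage_ranges=model.lineage_ranges_,
        gene_ids=np.asarray(model.gene_ids_, dtype=str),
    )
    model.report_.to_json(out_dir / "fit_report.json")
    return out_dir


def load_fit(fit_dir):
    """Reload a fitted model persisted by :func:`save_fit`."""
    from .basis import SplineBasis
    from .data import LineageAssignment
    from .model import FitReport, NBSplineGAM

    fit_dir = Path(fit_dir)
    npz = np.load(fit_dir / "fit.npz", allow_pickle=False)
    with open(fit_dir / "fit_report.json") as fh:
        report = json.load(fh)
    model = NBSplineGAM(n_knots=len(npz["knots"]), seed=report["settings"].get("seed", 0))
    model.beta_ = npz["beta"]
    model.Sigma_ = npz["Sigma"]
    model.phi_ = npz["phi"]
    model.lambda_ = npz["lam"]
    model.edf_ = npz["edf"]
    model.loglik_ = npz["loglik"]
    model.aic_ = npz["aic"]
    model.converged_ = npz["converged"]
    model.knots_ = npz["knots"]
    model.basis_ = SplineBasis(model.knots_)
    model.assignment_ = LineageAssignment(Z=npz["Z"], seed=report["settings"].get("seed", 0))
    model.offsets_ = npz["offsets"]
    model.lineage_ranges_ = npz["lineage_ranges"]
    model.n_lineages_ = npz["Z"].shape[1]
    model.gene_ids_ = npz["gene_ids"].astype(object)
    model.report_ = FitReport(
        n_genes=report["n_genes"],
        n_non_converged=report["n_non_converged"],
        non_converged_ids=report["non_converged_ids"],
        knots=report["knots"],
        settings=report["settings"],
    )
    return model
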