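"""Validated input containers for trajectory-based differential expression.

The model inputs are a genes x cells matrix of raw counts, a cells x L matrix
of lineage pseudotimes, and a cells x L matrix of non-negative lineage weights
(hard or soft cell-to-lineage assignments, as produced by any trajectory
inference method), plus optional cell-level covariates, log-scale offsets and
observation-level weights in [0, 1] used to absorb excess zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TrajectoryData",
    "LineageAssignment",
    "ValidationError",
    "DimensionError",
    "validate_trajectory_data",
    "assign_lineages",
    "compute_offsets",
]


class ValidationError(ValueError):
    """Raised when an input matrix violates a model invariant."""


class DimensionError(ValidationError):
    """Raised when input matrices disagree on a shared axis."""


@dataclass
class TrajectoryData:
    """Validated bundle of model inputs.

    Attributes
    ----------
    counts : (G, n) int array
        Raw non-negative counts, genes x cells.
    pseudotimes : (n, L) float array
        Per-lineage pseudotimes; entries are meaningful only where the
        corresponding lineage weight is positive.
    lineage_weights : (n, L) float array
        Non-negative soft assignment weights; every cell has at least one
        strictly positive entry.
    covariates : (n, p) float array
        Optional fixed-effect covariates (p may be 0).
    offsets : (n,) float array or None
        Log-scale cell-specific offsets; computed from library sizes when
        absent.
    obs_weights : (G, n) float array or None
        Observation-level weights in [0, 1] (1 = fully trusted count).
    """

    counts: np.ndarray
    pseudotimes: np.ndarray
    lineage_weights: np.ndarray
    covariates: np.ndarray
    offsets: np.ndarray | None
    obs_weights: np.ndarray | None
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    all_zero_genes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def n_lineages(self) -> int:
        return self.pseudotimes.shape[1]

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]


@dataclass
class LineageAssignment:
    """Hard cell-to-lineage assignment drawn from the soft weights.

    ``Z`` is a cells x L binary matrix with exactly one 1 per row; ``seed``
    records the RNG seed used for the categorical draws.
    """

    Z: np.ndarray
    seed: int

    @property
    def n_lineages(self) -> int:
        return self.Z.shape[1]

    def cells_in(self, lineage: int) -> np.ndarray:
        """Indices of cells assigned to ``lineage`` (0-based)."""
        return np.flatnonzero(self.Z[:, lineage] == 1)


def _as_2d(name: str, x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2:
        raise DimensionError(f"{name} must be 2-dimensional, got shape {arr.shape}")
    return arr


def validate_trajectory_data(
    counts,
    pseudotimes,
    weights,
    covariates=None,
    offsets=None,
    obs_weights=None,
    gene_ids=None,
    cell_ids=None,
) -> TrajectoryData:
    """Validate raw input matrices and bundle them into a :class:`TrajectoryData`.

    Genes whose counts are all zero are flagged (``all_zero_genes``) but kept,
    so gene indexing stays stable; downstream results for them are NA.

    Raises
    ------
    DimensionError
        If matrices disagree on the cell axis (the message names the axis).
    ValidationError
        For negative counts, cells with all-zero lineage weights (listed by
        id), non-finite pseudotimes where weights are positive, or
        observation weights outside [0, 1].
    """
    counts = np.asarray(counts)
    if counts.ndim != 2:
        raise DimensionError(f"counts must be genes x cells, got shape {counts.shape}")
    if np.any(counts < 0):
        raise ValidationError("counts contains negative entries")
    G, n = counts.shape

    T = _as_2d("pseudotimes", pseudotimes)
    W = _as_2d("lineage_weights", weights)
    if T.shape[0] != n:
        raise DimensionError(
            f"cell axis mismatch: counts has {n} cells but pseudotimes has {T.shape[0]} rows"
        )
    if W.shape != T.shape:
        raise DimensionError(
            f"lineage axis mismatch: pseudotimes is {T.shape} but lineage_weights is {W.shape}"
        )
    if np.any(W < 0):
        raise ValidationError("lineage_weights contains negative entries")

    cell_ids = (
        np.asarray(cell_ids, dtype=object)
        if cell_ids is not None
        else np.array([f"cell{i}" for i in range(n)], dtype=object)
    )
    gene_ids = (
        np.asarray(gene_ids, dtype=object)
        if gene_ids is not None
        else np.array([f"gene{g}" for g in range(G)], dtype=object)
    )
    if len(cell_ids) != n:
        raise DimensionError(f"cell axis mismatch: {len(cell_ids)} cell ids for {n} cells")
    if len(gene_ids) != G:
        raise DimensionError(f"gene axis mismatch: {len(gene_ids)} gene ids for {G} genes")

    dead = np.flatnonzero(W.sum(axis=1) <= 0)
    if dead.size:
        names = ", ".join(str(cell_ids[i]) for i in dead[:10])
        raise ValidationError(
            f"{dead.size} cell(s) have all-zero lineage weights: {names}"
        )
    bad_t = (W > 0) & ~np.isfinite(T)
    if np.any(bad_t):
        idx = np.flatnonzero(bad_t.any(axis=1))
        names = ", ".join(str(cell_ids[i]) for i in idx[:10])
        raise ValidationError(f"non-finite pseudotimes where lineage weight > 0: {names}")

    if covariates is not None:
        U = _as_2d("covariates", covariates)
        if U.shape[0] != n:
            raise DimensionError(
                f"cell axis mismatch: covariates has {U.shape[0]} rows for {n} cells"
            )
    else:
        U = np.zeros((n, 0))

    if offsets is not None:
        offsets = np.asarray(offsets, dtype=float).ravel()
        if offsets.shape[0] != n:
            raise DimensionError(
                f"cell axis mismatch: offsets has length {offsets.shape[0]} for {n} cells"
            )
        if not np.all(np.isfinite(offsets)):
            raise ValidationError("offsets must be finite")

    if obs_weights is not None:
        obs_weights = _as_2d("obs_weights", obs_weights)
        if obs_weights.shape != counts.shape:
            raise DimensionError(
                f"obs_weights shape {obs_weights.shape} does not match counts shape {counts.shape}"
            )
        if np.any(obs_weights < 0) or np.any(obs_weights > 1):
            raise ValidationError("obs_weights must lie in [0, 1]")

    all_zero = np.flatnonzero(counts.sum(axis=1) == 0)
    if all_zero.size:
        warnings.warn(
            f"{all_zero.size} gene(s) have all-zero counts; they are kept and "
            "will carry NA results",
            stacklevel=2,
        )

    return TrajectoryData(
        counts=counts,
        pseudotimes=T,
        lineage_weights=W,
        covariates=U,
        offsets=offsets,
        obs_weights=obs_weights,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        all_zero_genes=all_zero,
    )


def assign_lineages(weights, seed: int = 0) -> LineageAssignment:
    """Assign every cell to exactly one lineage.

    Each cell's lineage is drawn from a categorical distribution with
    probabilities equal to its row-normalized weights; cells with a single
    positive weight are assigned deterministically. The draw is a
    deterministic function of ``(weights, seed)``.
    """
    W = _as_2d("lineage_weights", weights)
    if np.any(W < 0):
        raise ValidationError("lineage_weights contains negative entries")
    row_sums = W.sum(axis=1)
    if np.any(row_sums <= 0):
        bad = np.flatnonzero(row_sums <= 0)
        raise ValidationError(f"cells with all-zero lineage weights: {bad[:10].tolist()}")
    probs = W / row_sums[:, None]
    # per-purpose stream key so identical user seeds in other components
    # (e.g. the simulator) cannot replay the same uniforms
    rng = np.random.default_rng([int(seed), 0x5A11])
    u = rng.random(W.shape[0])
    cum = np.cumsum(probs, axis=1)
    choice = (u[:, None] >= cum).sum(axis=1)
    choice = np.minimum(choice, W.shape[1] - 1)
    # never land on a zero-weight lineage (possible only through float round-off)
    choice = np.where(probs[np.arange(W.shape[0]), choice] > 0, choice,
                      np.argmax(probs, axis=1))
    Z = np.zeros_like(W, dtype=int)
    Z[np.arange(W.shape[0]), choice] = 1
    return LineageAssignment(Z=Z, seed=int(seed))


def compute_offsets(counts, method: str = "libsize") -> np.ndarray:
    """Log-scale cell offsets, centred on the geometric mean.

    ``method="libsize"`` gives ``offset_i = log(libsize_i) - mean_j
    log(libsize_j)``, invariant to a global rescaling of all library sizes.
    ``method="ratio"`` gives median-of-ratios size factors computed on
    positive counts (DESeq-style "poscounts"), which stay unbiased when a
    sizable fraction of genes is differential and would otherwise distort
    the library totals.
    """
    counts = np.asarray(counts)
    lib = counts.sum(axis=0).astype(float)
    if np.any(lib <= 0):
        bad = np.flatnonzero(lib <= 0)
        raise ValidationError(
            f"cells with zero total count (remove them before fitting): {bad[:10].tolist()}"
        )
    if method == "libsize":
        log_lib = np.log(lib)
        return log_lib - log_lib.mean()
    if method != "ratio":
        raise ValueError(f"unknown offset method {method!r}")
    Y = counts.astype(float)
    n = Y.shape[1]
    with np.errstate(divide="ignore"):
        logY = np.where(Y > 0, np.log(Y), 0.0)
    # geometric mean over all cells, zeros contributing log 1
    log_ref = logY.sum(axis=1) / n
    usable = (Y > 0).any(axis=1)
    log_sf = np.empty(n)
    for i in range(n):
        pos = (Y[:, i] > 0) & usable
        if not pos.any():  # pragma: no cover - excluded by the lib check
            raise ValidationError(f"cell {i} has no positive counts")
        log_sf[i] = np.median(np.log(Y[pos, i]) - log_ref[pos])
    return log_sf - log_sf.mean()
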