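"""Network construction: partial correlations, Fisher-z association matrices,
weighted networks and equi-density binary networks.

The association strength between two nodes is the absolute value of the
variance-stabilized Fisher z of their partial correlation,

    z_ij = |atanh(rho_ij)| * sqrt(n - p - 1),

where n is the number of time points and p the number of nodes (the partial
correlation conditions on the remaining p-2 nodes, so the usual n-3 degrees of
freedom lose a further p-2).  Weights follow the monotone map

    w_ij = 2*Phi(z_ij) - 1,

the unique affine-in-Phi transform sending z=0 to 0 and z->inf to 1, so weights
live in [0,1] and preserve the edge ranking of the association matrix.  Binary
networks retain the top round(d * n(n-1)/2) edges at density d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr

__all__ = [
    "AssociationMatrix",
    "WeightedNetwork",
    "BinaryNetwork",
    "partial_correlation",
    "fisher_z",
    "association_from_partial",
    "to_weighted",
    "threshold_to_density",
    "group_average",
    "write_matrix_tsv",
    "read_matrix_tsv",
]


def _check_square_symmetric(mat: np.ndarray, name: str) -> None:
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise ValueError(f"{name} must be symmetric")


@dataclass(frozen=True)
class AssociationMatrix:
    """Symmetric nonnegative matrix of absolute Fisher z-scores, zero diagonal."""

    strength: np.ndarray
    n_timepoints_used: int
    node_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        _check_square_symmetric(self.strength, "strength")
        if not np.isfinite(self.strength).all():
            raise ValueError("strength must be finite")
        if (self.strength < 0).any():
            raise ValueError("strength must be nonnegative")
        if np.diag(self.strength).any():
            raise ValueError("strength diagonal must be zero")
        if self.node_labels is not None and len(self.node_labels) != self.n_nodes:
            raise ValueError("node_labels length mismatch")

    @property
    def n_nodes(self) -> int:
        return self.strength.shape[0]


@dataclass(frozen=True)
class WeightedNetwork:
    weights: np.ndarray
    node_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        _check_square_symmetric(self.weights, "weights")
        if (self.weights < 0).any() or (self.weights > 1).any():
            raise ValueError("weights must lie in [0, 1]")
        if np.diag(self.weights).any():
            raise ValueError("weight diagonal must be zero")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class BinaryNetwork:
    adjacency: np.ndarray
    density: float
    node_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        _check_square_symmetric(self.adjacency, "adjacency")
        if not np.isin(self.adjacency, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")
        if np.diag(self.adjacency).any():
            raise ValueError("adjacency diagonal must be zero")
        n = self.n_nodes
        if n > 1:
            realized = self.adjacency.sum() / 2 / (n * (n - 1) / 2)
            if not math.isclose(realized, self.density, abs_tol=1e-12):
                raise ValueError("stored density does not match adjacency")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)


def partial_correlation(series: np.ndarray, regularization: float = 0.0) -> np.ndarray:
    """Partial correlations from a time x node table via inverse covariance.

    rho_ij = -Omega_ij / sqrt(Omega_ii * Omega_jj) with Omega = inv(cov + reg*I).
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("series must be a 2-D time x node table")
    t, p = series.shape
    if (series.std(axis=0) == 0).any():
        raise ValueError("every node series must have nonzero variance")
    if t <= p and regularization <= 0:
        raise np.linalg.LinAlgError(
            f"covariance is singular with t={t} <= p={p}; increase the number "
            "of samples or use regularization > 0"
        )
    cov = np.cov(series, rowvar=False)
    if regularization > 0:
        cov = cov + regularization * np.eye(p)
    try:
        omega = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "sample covariance is singular; increase the number of samples "
            "or the regularization"
        ) from exc
    d = np.sqrt(np.diag(omega))
    rho = -omega / np.outer(d, d)
    rho = (rho + rho.T) / 2.0
    np.fill_diagonal(rho, 1.0)
    return rho


def fisher_z(rho, n_timepoints: int, n_nodes: int):
    """Absolute variance-stabilized Fisher z: |atanh(rho)| * sqrt(n - p - 1)."""
    dof = n_timepoints - n_nodes - 1
    if dof <= 0:
        raise ValueError(
            f"non-positive degrees of freedom (n_timepoints={n_timepoints}, "
            f"n_nodes={n_nodes})"
        )
    rho = np.asarray(rho, dtype=float)
    if (np.abs(rho) >= 1).any():
        raise ValueError("|rho| must be < 1 (degenerate series)")
    return np.abs(np.arctanh(rho)) * np.sqrt(dof)


def association_from_partial(
    partial: np.ndarray,
    n_timepoints: int,
    n_nodes: int | None = None,
    node_labels: tuple[str, ...] | None = None,
) -> AssociationMatrix:
    """Association matrix of absolute Fisher z-scores from a partial-correlation matrix."""
    partial = np.asarray(partial, dtype=float)
    _check_square_symmetric(partial, "partial")
    p = partial.shape[0] if n_nodes is None else n_nodes
    off = partial.copy()
    np.fill_diagonal(off, 0.0)
    strength = fisher_z(off, n_timepoints, p)
    np.fill_diagonal(strength, 0.0)
    strength = (strength + strength.T) / 2.0
    return AssociationMatrix(
        strength=strength, n_timepoints_used=n_timepoints, node_labels=node_labels
    )


def to_weighted(assoc: AssociationMatrix) -> WeightedNetwork:
    """Map association strengths to weights in [0,1]: w = 2*Phi(z) - 1."""
    w = 2.0 * ndtr(assoc.strength) - 1.0
    np.fill_diagonal(w, 0.0)
    return WeightedNetwork(weights=w, node_labels=assoc.node_labels)


def threshold_to_density(assoc: AssociationMatrix, density: float) -> BinaryNetwork:
    """Retain the round(density * n(n-1)/2) strongest edges (round-half-up).

    Ties at the cut are broken deterministically by ascending (i, j) node-pair
    order so that repeated runs produce identical networks.
    """
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    n = assoc.n_nodes
    m = n * (n - 1) // 2
    n_edges = int(math.floor(density * m + 0.5))
    if n_edges == 0:
        raise ValueError(f"density {density} keeps zero edges: network too sparse")
    ii, jj = np.triu_indices(n, 1)
    strengths = assoc.strength[ii, jj]
    # primary key: strength descending; then i, j ascending
    order = np.lexsort((jj, ii, -strengths))
    keep = order[:n_edges]
    adj = np.zeros((n, n))
    adj[ii[keep], jj[keep]] = 1.0
    adj = adj + adj.T
    return BinaryNetwork(
        adjacency=adj, density=n_edges / m, node_labels=assoc.node_labels
    )


def group_average(assocs: list[AssociationMatrix]) -> AssociationMatrix:
    """Entrywise mean of association matrices (the group association matrix).

    Group weighted/binary networks are always derived from this averaged
    matrix, not by averaging per-subject networks: the z-to-weight map is
    nonlinear, so the two orders of operation differ.
    """
    if not assocs:
        raise ValueError("need at least one association matrix")
    n = assocs[0].n_nodes
    labels = assocs[0].node_labels
    for a in assocs[1:]:
        if a.n_nodes != n:
            raise ValueError("mismatched node counts across association matrices")
    strength = np.mean([a.strength for a in assocs], axis=0)
    np.fill_diagonal(strength, 0.0)
    t_mean = int(round(float(np.mean([a.n_timepoints_used for a in assocs]))))
    return AssociationMatrix(
        strength=strength, n_timepoints_used=t_mean, node_labels=labels
    )


def write_matrix_tsv(mat: np.ndarray, path: str | Path, labels=None) -> None:
    labels = list(labels) if labels is not None else [f"n{i:02d}" for i in range(mat.shape[0])]
    pd.DataFrame(mat, index=labels, columns=labels).to_csv(
        path, sep="\t", float_format="%.17g"
    )


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return frame.to_numpy(dtype=float), list(frame.columns)
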