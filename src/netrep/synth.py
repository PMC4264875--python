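"""Synthetic multi-subject, multi-run node time-series panels with planted structure.

This module plays the role of the data-acquisition stage: it emulates a task-fMRI
style dataset (~54 subjects, 5 runs each, 57 network nodes) by drawing Gaussian
time series whose inverse covariance (precision matrix) encodes a known modular,
hubbed network.  Because the generating partial-correlation matrix is known
exactly, every downstream stage — association matrices, thresholded networks,
graph measures, reliability and robustness analyses — can be validated against
ground truth.

The temporal model is i.i.d. Gaussian by default (prewhitened time series carry
no autocorrelation worth modelling); an optional AR(1) coefficient is available
for sensitivity analyses.  Between-subject variability enters as symmetric
zero-mean jitter on the precision matrix, repaired to positive definiteness by
diagonal loading.

All randomness derives from a single integer seed through a fixed hierarchical
scheme (seed, subject index, run index), so identical calls are bit-identical.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

__all__ = [
    "GroundTruthNetwork",
    "TimeSeriesPanel",
    "ConstructionError",
    "PanelFormatError",
    "build_ground_truth",
    "sample_panel",
    "write_panel",
    "read_panel",
    "write_ground_truth",
    "read_ground_truth",
    "partial_corr_from_precision",
]


class ConstructionError(RuntimeError):
    """Raised when a planted precision matrix cannot be made positive definite."""


class PanelFormatError(ValueError):
    """Raised when panel files on disk are inconsistent or unreadable."""


_EIG_FLOOR = 1e-8
_DELTA_START = 1e-6
_DELTA_MAX = 1.0
_JITTER_RETRIES = 5


def partial_corr_from_precision(precision: np.ndarray) -> np.ndarray:
    """Partial correlations rho_ij = -P_ij / sqrt(P_ii * P_jj), unit diagonal."""
    d = np.sqrt(np.diag(precision))
    rho = -precision / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    return rho


def _min_eig(mat: np.ndarray) -> float:
    return float(np.linalg.eigvalsh(mat)[0])


def _load_positive_definite(mat: np.ndarray) -> tuple[np.ndarray, float]:
    """Repair symmetry/definiteness by adding delta*I, delta grown geometrically.

    delta starts at 1e-6 and is multiplied by 10 until the smallest eigenvalue
    exceeds 1e-8, giving up at delta = 1.
    """
    mat = (mat + mat.T) / 2.0
    if _min_eig(mat) > _EIG_FLOOR:
        return mat, 0.0
    delta = _DELTA_START
    n = mat.shape[0]
    while delta <= _DELTA_MAX:
        loaded = mat + delta * np.eye(n)
        if _min_eig(loaded) > _EIG_FLOOR:
            return loaded, delta
        delta *= 10.0
    raise ConstructionError(
        "precision matrix is not positive definite even after diagonal "
        f"loading up to delta={_DELTA_MAX}"
    )


@dataclass(frozen=True)
class GroundTruthNetwork:
    """Planted generating network: precision matrix plus its derived structure.

    node_importance orders nodes for targeted-removal robustness analyses
    (a stand-in for any externally supplied per-node statistic); hubs carry
    the largest values.
    """

    n_nodes: int
    precision: np.ndarray
    partial_corr: np.ndarray
    module_labels: np.ndarray
    hub_nodes: frozenset[int]
    node_importance: np.ndarray

    def __post_init__(self) -> None:
        p = self.precision
        if p.shape != (self.n_nodes, self.n_nodes):
            raise ValueError("precision shape mismatch")
        if not np.allclose(p, p.T):
            raise ValueError("precision must be symmetric")
        if _min_eig(p) <= 0:
            raise ValueError("precision must be positive definite")
        if self.module_labels.shape != (self.n_nodes,):
            raise ValueError("module_labels must cover all nodes")
        if not set(self.hub_nodes) <= set(range(self.n_nodes)):
            raise ValueError("hub_nodes must be a subset of node indices")


@dataclass
class TimeSeriesPanel:
    """Per (subject, run) time x node signal tables with shared node order."""

    subjects: list[str]
    n_runs: int
    node_labels: list[str]
    series: dict[tuple[str, int], np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        p = len(self.node_labels)
        for key, table in self.series.items():
            if table.ndim != 2 or table.shape[1] != p:
                raise PanelFormatError(f"series {key} has wrong node count")
            if not np.isfinite(table).all():
                raise PanelFormatError(f"series {key} contains missing values")

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def concatenated(self, subject: str, runs: list[int] | None = None) -> np.ndarray:
        """Time series of the given runs (default: all), concatenated in time."""
        runs = list(range(1, self.n_runs + 1)) if runs is None else sorted(runs)
        return np.vstack([self.series[(subject, r)] for r in runs])


def build_ground_truth(
    n_nodes: int,
    n_modules: int,
    within_strength: float,
    between_strength: float,
    n_hubs: int,
    seed: int,
    between_prob: float = 0.15,
    hub_prob: float = 0.4,
) -> GroundTruthNetwork:
    """Assemble a block-structured precision matrix with optional hub nodes.

    Modules are contiguous, near-equal blocks.  Off-diagonal precision entries
    have magnitude ``within_strength`` inside modules; a sparse fraction
    (``between_prob``) of cross-module pairs get magnitude ``between_strength``;
    hub nodes additionally connect to a random ``hub_prob`` fraction of
    out-of-module nodes at magnitude ``within_strength``.  The diagonal is
    loaded (delta*I) until the matrix is positive definite.
    """
    if n_modules < 1:
        raise ValueError("n_modules must be >= 1")
    if n_nodes < n_modules:
        raise ValueError("n_nodes must be >= n_modules")
    if n_hubs < 0 or n_hubs > n_nodes:
        raise ValueError("invalid n_hubs")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))

    labels = np.concatenate(
        [np.full(len(block), m) for m, block in enumerate(np.array_split(np.arange(n_nodes), n_modules))]
    )
    prec = np.eye(n_nodes)
    for m in range(n_modules):
        idx = np.where(labels == m)[0]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                prec[idx[a], idx[b]] = prec[idx[b], idx[a]] = within_strength

    # sparse weak cross-module background
    if between_strength != 0.0:
        for i in range(n_nodes):
            for j in range(i + 1, n_nodes):
                if labels[i] != labels[j] and rng.random() < between_prob:
                    prec[i, j] = prec[j, i] = between_strength

    # hubs: one per module in round-robin order, extra strong cross-module entries
    hubs: list[int] = []
    for h in range(n_hubs):
        module = h % n_modules
        candidates = [i for i in np.where(labels == module)[0] if i not in hubs]
        hubs.append(int(candidates[0]))
    for h in hubs:
        others = np.where(labels != labels[h])[0]
        chosen = others[rng.random(len(others)) < hub_prob]
        for j in chosen:
            prec[h, j] = prec[j, h] = within_strength

    prec, _ = _load_positive_definite(prec)

    # importance: hubs ranked first, then remaining nodes by index, with jitter
    order = hubs + [i for i in range(n_nodes) if i not in hubs]
    importance = np.empty(n_nodes)
    base = np.linspace(1.0, 0.1, n_nodes) if n_nodes > 1 else np.array([1.0])
    for rank, node in enumerate(order):
        importance[node] = base[rank]
    importance += rng.normal(0.0, 0.02, size=n_nodes)

    return GroundTruthNetwork(
        n_nodes=n_nodes,
        precision=prec,
        partial_corr=partial_corr_from_precision(prec),
        module_labels=labels,
        hub_nodes=frozenset(hubs),
        node_importance=importance,
    )


def _subject_precision(
    gt: GroundTruthNetwork,
    subject_index: int,
    jitter_sd: float,
    seed: int,
    scale_sd: float = 0.0,
) -> np.ndarray:
    if jitter_sd == 0.0 and scale_sd == 0.0:
        return gt.precision
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101, subject_index]))
    n = gt.n_nodes
    base = gt.precision
    if scale_sd > 0.0:
        # subject-specific global coupling strength: scale all off-diagonal
        # precision entries by a common positive factor
        factor = float(np.exp(rng.normal(0.0, scale_sd)))
        off = base - np.diag(np.diag(base))
        base = np.diag(np.diag(gt.precision)) + factor * off
    if jitter_sd == 0.0:
        loaded, _ = _load_positive_definite(base)
        return loaded
    for _ in range(_JITTER_RETRIES):
        noise = rng.normal(0.0, jitter_sd, size=(n, n))
        jitter = np.triu(noise, 1)
        jitter = jitter + jitter.T
        try:
            loaded, _ = _load_positive_definite(base + jitter)
            return loaded
        except ConstructionError:
            continue
    raise ConstructionError(
        f"could not repair jittered precision for subject {subject_index} "
        f"after {_JITTER_RETRIES} retries (jitter_sd={jitter_sd})"
    )


def sample_panel(
    gt: GroundTruthNetwork,
    n_subjects: int,
    n_runs: int,
    t_per_run: int,
    subject_jitter_sd: float,
    seed: int,
    ar_coef: float = 0.0,
    subject_scale_sd: float = 0.0,
) -> TimeSeriesPanel:
    """Draw a multi-subject, multi-run panel of Gaussian node time series.

    Each subject gets a jittered copy of the ground-truth precision; each run
    is an independent draw of ``t_per_run`` samples from N(0, inv(precision)).
    With ``ar_coef`` = phi != 0, samples are AR(1)-filtered with innovation
    scaling sqrt(1-phi^2) so the stationary marginal covariance is preserved.
    ``subject_scale_sd`` adds a second, structured source of between-subject
    variability: a log-normal subject factor multiplying every off-diagonal
    precision entry (individual differences in overall coupling strength).
    """
    if t_per_run * n_runs <= gt.n_nodes + 10:
        raise ValueError(
            "t_per_run * n_runs must exceed n_nodes + 10 for the partial "
            "correlation to be estimable after concatenation"
        )
    if not -1.0 < ar_coef < 1.0:
        raise ValueError("ar_coef must lie in (-1, 1)")

    subjects = [f"sub-{s + 1:02d}" for s in range(n_subjects)]
    node_labels = [f"n{i:02d}" for i in range(gt.n_nodes)]
    series: dict[tuple[str, int], np.ndarray] = {}
    for s, subject in enumerate(subjects):
        prec_s = _subject_precision(gt, s, subject_jitter_sd, seed, subject_scale_sd)
        chol = np.linalg.cholesky(np.linalg.inv(prec_s))
        for r in range(1, n_runs + 1):
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), 202, s, r]))
            draws = rng.standard_normal((t_per_run, gt.n_nodes)) @ chol.T
            if ar_coef != 0.0:
                draws = lfilter(
                    [np.sqrt(1.0 - ar_coef**2)], [1.0, -ar_coef], draws, axis=0
                )
            series[(subject, r)] = draws
    return TimeSeriesPanel(
        subjects=subjects, n_runs=n_runs, node_labels=node_labels, series=series
    )


# ---------------------------------------------------------------------------
# panel and ground-truth serialization

_RUN_FILE = re.compile(r"^(?P<subject>sub-.+)_run-(?P<run>\d+)\.tsv$")


def write_panel(panel: TimeSeriesPanel, directory: str | Path) -> list[Path]:
    """Write one TSV per (subject, run): `sub-<id>_run-<k>.tsv`, header = node labels."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for (subject, run), table in sorted(panel.series.items()):
        path = directory / f"{subject}_run-{run}.tsv"
        pd.DataFrame(table, columns=panel.node_labels).to_csv(
            path, sep="\t", index=False, float_format="%.17g"
        )
        written.append(path)
    return written


def read_panel(directory: str | Path) -> TimeSeriesPanel:
    directory = Path(directory)
    files = sorted(directory.glob("sub-*_run-*.tsv"))
    if not files:
        raise PanelFormatError(f"no panel files found in {directory}")
    series: dict[tuple[str, int], np.ndarray] = {}
    node_labels: list[str] | None = None
    runs_seen: dict[str, set[int]] = {}
    for path in files:
        match = _RUN_FILE.match(path.name)
        if match is None:
            continue
        subject, run = match["subject"], int(match["run"])
        frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
        labels = list(frame.columns)
        if node_labels is None:
            node_labels = labels
        elif labels != node_labels:
            raise PanelFormatError(f"inconsistent node header in {path.name}")
        if frame.isna().any().any():
            raise PanelFormatError(f"missing values in {path.name}")
        series[(subject, run)] = frame.to_numpy(dtype=float)
        runs_seen.setdefault(subject, set()).add(run)
    assert node_labels is not None
    run_sets = {frozenset(v) for v in runs_seen.values()}
    if len(run_sets) != 1:
        raise PanelFormatError("subjects have differing run sets")
    n_runs = len(next(iter(run_sets)))
    return TimeSeriesPanel(
        subjects=sorted(runs_seen),
        n_runs=n_runs,
        node_labels=node_labels,
        series=series,
    )


def write_ground_truth(gt: GroundTruthNetwork, path: str | Path) -> None:
    payload = {
        "n_nodes": gt.n_nodes,
        "precision": gt.precision.tolist(),
        "module_labels": gt.module_labels.tolist(),
        "hub_nodes": sorted(gt.hub_nodes),
        "node_importance": gt.node_importance.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path: str | Path) -> GroundTruthNetwork:
    payload = json.loads(Path(path).read_text())
    prec = np.asarray(payload["precision"], dtype=float)
    return GroundTruthNetwork(
        n_nodes=int(payload["n_nodes"]),
        precision=prec,
        partial_corr=partial_corr_from_precision(prec),
        module_labels=np.asarray(payload["module_labels"], dtype=int),
        hub_nodes=frozenset(int(h) for h in payload["hub_nodes"]),
        node_importance=np.asarray(payload["node_importance"], dtype=float),
    )
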