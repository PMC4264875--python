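"""Robustness of graph measures: group-size bootstrapping and targeted node removal.

Group-size curves subsample subjects without replacement, rebuild the group
network per subsample (averaging the per-subject association matrices, then
weighting/thresholding), and express every global measure as the relative
change (%) against the full-group reference.  An individual-level variant
averages per-subject weighted measures over the subsample instead.

Node-removal curves threshold/weight the intact network once, then delete
nodes one by one in ascending order of an externally supplied importance
score (least important first), recomputing all global measures on the
surviving subgraph without re-thresholding, so the realized density drifts as
nodes leave.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import netbuild
from .measures import GLOBAL_MEASURE_NAMES, global_from_network
from .netbuild import AssociationMatrix, BinaryNetwork, WeightedNetwork
from .repro import _subject_association, measure_association
from .synth import TimeSeriesPanel

__all__ = ["RobustnessCurve", "group_size_curve", "node_removal_curve"]


@dataclass
class RobustnessCurve:
    """Relative-change curves: one row per (x, network, measure)."""

    table: pd.DataFrame
    reference: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _relative_change(value: float, reference: float) -> float:
    if reference == 0:
        return float("nan")
    return (value - reference) / abs(reference) * 100.0


def group_size_curve(
    panel: TimeSeriesPanel,
    densities: list[float],
    sizes: list[int],
    n_boot: int = 100,
    seed: int = 0,
    regularization: float = 0.0,
    rel_threshold: float = 10.0,
    alpha: float = 0.05,
) -> RobustnessCurve:
    """Bootstrapped (without replacement) group-size dependence of graph measures.

    Returns mean and sd of the relative change per (size, network, measure) at
    both the group level (group network per subsample) and the individual
    level (subsample mean of per-subject weighted measures), plus, per
    condition, the smallest size whose absolute relative change is
    significantly below ``rel_threshold`` percent (one-sample t-test).
    """
    n_subjects = len(panel.subjects)
    sizes = sorted(sizes)
    if max(sizes) >= n_subjects:
        raise ValueError("sizes must be smaller than the total subject count")
    if min(sizes) < 2:
        raise ValueError("sizes must be >= 2")

    per_subject_assoc = [
        _subject_association(panel, s, None, regularization) for s in panel.subjects
    ]
    full_group = netbuild.group_average(per_subject_assoc)
    ref_group, _ = measure_association(full_group, densities)

    per_subject_weighted = []
    for assoc in per_subject_assoc:
        gm = global_from_network(netbuild.to_weighted(assoc))
        per_subject_weighted.append(gm.as_dict())
    ref_individual = {
        measure: float(np.mean([d[measure] for d in per_subject_weighted]))
        for measure in GLOBAL_MEASURE_NAMES
    }

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 606]))
    records: list[tuple] = []
    for b in range(n_boot):
        for size in sizes:
            chosen = rng.choice(n_subjects, size=size, replace=False)
            sub_assoc = [per_subject_assoc[i] for i in chosen]
            glob, _ = measure_association(
                netbuild.group_average(sub_assoc), densities
            )
            for (label, measure), value in glob.items():
                records.append(
                    (b, size, "group", label, measure,
                     _relative_change(value, ref_group[(label, measure)]))
                )
            for measure in GLOBAL_MEASURE_NAMES:
                value = float(np.mean([per_subject_weighted[i][measure] for i in chosen]))
                records.append(
                    (b, size, "individual", "w", measure,
                     _relative_change(value, ref_individual[measure]))
                )
    raw = pd.DataFrame(
        records, columns=["boot", "x", "level", "network", "measure", "rel_change"]
    )
    table = (
        raw.groupby(["x", "level", "network", "measure"])
        .agg(mean_rel_change=("rel_change", "mean"), sd_rel_change=("rel_change", "std"))
        .reset_index()
    )

    # smallest size at which |relative change| is significantly < rel_threshold
    min_sizes = []
    for (level, label, measure), grp in raw.groupby(["level", "network", "measure"]):
        found = np.nan
        for size in sizes:
            vals = np.abs(grp.loc[grp["x"] == size, "rel_change"].dropna().to_numpy())
            if len(vals) >= 2 and vals.std(ddof=1) > 0:
                _, p = stats.ttest_1samp(vals, rel_threshold, alternative="less")
                if p < alpha:
                    found = size
                    break
        min_sizes.append((level, label, measure, found))
    min_size = pd.DataFrame(
        min_sizes, columns=["level", "network", "measure", "min_size"]
    )

    ref_rows = [("group", label, measure, value)
                for (label, measure), value in ref_group.items()]
    ref_rows += [("individual", "w", measure, value)
                 for measure, value in ref_individual.items()]
    reference = pd.DataFrame(
        ref_rows, columns=["level", "network", "measure", "reference"]
    )
    return RobustnessCurve(
        table=table,
        reference=reference,
        meta={"raw": raw, "min_size": min_size, "sizes": sizes,
              "n_boot": n_boot, "seed": seed},
    )


def _subnetwork(net: BinaryNetwork | WeightedNetwork, keep: np.ndarray):
    if isinstance(net, BinaryNetwork):
        sub = net.adjacency[np.ix_(keep, keep)]
        m = len(keep)
        density = sub.sum() / 2 / (m * (m - 1) / 2) if m > 1 else 0.0
        return BinaryNetwork(adjacency=sub, density=density)
    return WeightedNetwork(weights=net.weights[np.ix_(keep, keep)])


def node_removal_curve(
    assoc: AssociationMatrix,
    importance: np.ndarray,
    densities: list[float],
    max_removed: int,
) -> RobustnessCurve:
    """Targeted-removal robustness: delete lowest-importance nodes first.

    The intact association matrix is weighted/thresholded once at each initial
    density; removal then extracts subgraphs without re-thresholding.  Ties in
    importance break by ascending node index.  If at some step a network has
    fewer than 2 connected nodes left, its curve is truncated and flagged.
    """
    n = assoc.n_nodes
    importance = np.asarray(importance, dtype=float)
    if importance.shape != (n,):
        raise ValueError("importance must have one value per node")
    if max_removed > n - 2:
        raise ValueError("max_removed must leave at least 2 nodes")
    order = np.lexsort((np.arange(n), importance))  # ascending importance, ties by index

    nets: dict[str, BinaryNetwork | WeightedNetwork] = {
        f"{d:g}": netbuild.threshold_to_density(assoc, d) for d in densities
    }
    nets["w"] = netbuild.to_weighted(assoc)

    reference: dict[tuple[str, str], float] = {}
    rows = []
    truncated: dict[str, int] = {}
    for label, net in nets.items():
        for k in range(max_removed + 1):
            keep = np.setdiff1d(np.arange(n), order[:k])
            sub = _subnetwork(net, keep)
            try:
                gm = global_from_network(sub)
            except ValueError:
                truncated[label] = k
                break
            for measure, value in gm.as_dict().items():
                if k == 0:
                    reference[(label, measure)] = value
                rows.append(
                    (k, label, measure,
                     _relative_change(value, reference[(label, measure)]))
                )
    table = pd.DataFrame(rows, columns=["x", "network", "measure", "rel_change"])
    table["mean_rel_change"] = table["rel_change"]
    table["sd_rel_change"] = 0.0
    ref_frame = pd.DataFrame(
        [(label, measure, value) for (label, measure), value in reference.items()],
        columns=["network", "measure", "reference"],
    )
    return RobustnessCurve(
        table=table,
        reference=ref_frame,
        meta={"removal_order": order[:max_removed].tolist(), "truncated": truncated},
    )
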