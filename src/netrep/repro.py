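"""Split-half reliability: ICC, test-retest variability, group-based and
between-independent-groups comparisons, and significance summaries.

Each subject's runs are split into two matched halves, each half is carried
through the full network-construction pipeline, and every graph measure is
treated as a pair of repeated measurements.  Reliability is quantified by

* the one-way random-effects intraclass correlation (ICC(1,1), k = 2):
  ICC = (BMS - EMS) / (BMS + (k-1) EMS), where BMS and EMS are the between-
  subject and residual mean squares of the 2 x S measurement table; and
* the test-retest variability TRT = |v1 - v2| / ((v1 + v2)/2) * 100 (percent).

Repeating the split over many seeded realizations yields means and variances
of both quantities.  Group-based analyses average per-subject association
matrices within each half before network construction (the z-to-weight map is
nonlinear, so this order matters).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import netbuild
from .measures import GLOBAL_MEASURE_NAMES, global_measures, node_measures
from .synth import TimeSeriesPanel

__all__ = [
    "SplitHalfDesign",
    "ReliabilityReport",
    "make_split_half",
    "icc",
    "trt",
    "network_labels",
    "measure_networks",
    "subject_level_reliability",
    "group_level_reliability",
    "compare_independent_groups",
    "significance_summary",
]


@dataclass(frozen=True)
class SplitHalfDesign:
    """Per-subject assignment of runs to two disjoint, equally sized halves."""

    halves: dict[str, tuple[tuple[int, ...], tuple[int, ...]]]
    realization: int
    seed: int

    def __post_init__(self) -> None:
        for subject, (h1, h2) in self.halves.items():
            if set(h1) & set(h2):
                raise ValueError(f"overlapping halves for {subject}")
            if len(h1) != len(h2):
                raise ValueError(f"unequal halves for {subject}")


@dataclass
class ReliabilityReport:
    """Per-(measure, network) reliability summary plus raw per-realization values."""

    global_summary: pd.DataFrame
    global_realizations: pd.DataFrame
    local_summary: pd.DataFrame | None = None
    local_realizations: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)


def make_split_half(
    panel: TimeSeriesPanel, n_realizations: int, seed: int
) -> list[SplitHalfDesign]:
    """Randomized split-half designs: each subject's runs split 50/50.

    With an odd run count (e.g. 5 runs), one run per subject per realization
    is left unused so the halves stay even; the unused run is redrawn every
    realization.  Assignments are drawn independently per subject.
    """
    if panel.n_runs < 2:
        raise ValueError("need at least 2 runs to split")
    half_size = panel.n_runs // 2
    designs = []
    for r in range(n_realizations):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 505, r]))
        halves = {}
        for subject in panel.subjects:
            perm = rng.permutation(np.arange(1, panel.n_runs + 1))
            halves[subject] = (
                tuple(sorted(int(x) for x in perm[:half_size])),
                tuple(sorted(int(x) for x in perm[half_size : 2 * half_size])),
            )
        designs.append(SplitHalfDesign(halves=halves, realization=r, seed=seed))
    return designs


def icc(values: np.ndarray) -> float:
    """One-way random-effects ICC(1,1) of a k x S measurement table (k = 2 here).

    The total variance is split into the between-subject (BMS) and residual
    (EMS) mean squares; ICC = (BMS - EMS) / (BMS + (k-1) EMS).  A table with
    zero total variance is defined as ICC = 0 (with a warning).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be a k x S table")
    k, s = values.shape
    if s < 2:
        raise ValueError("need at least 2 subjects for ICC")
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    grand = values.mean()
    subject_means = values.mean(axis=0)
    bms = k * ((subject_means - grand) ** 2).sum() / (s - 1)
    ems = ((values - subject_means) ** 2).sum() / (s * (k - 1))
    denom = bms + (k - 1) * ems
    if denom == 0:
        warnings.warn("zero total variance; ICC defined as 0", RuntimeWarning)
        return 0.0
    return float((bms - ems) / denom)


def trt(v1: float, v2: float) -> float:
    """Test-retest variability in percent: |v1 - v2| / ((v1 + v2)/2) * 100."""
    mean = (v1 + v2) / 2.0
    if mean == 0:
        return float("nan")
    return float(abs(v1 - v2) / abs(mean) * 100.0)


def network_labels(densities: list[float]) -> list[str]:
    """Stable string ids for the network conditions: one per density plus 'w'."""
    return [f"{d:g}" for d in densities] + ["w"]


def measure_networks(
    series: np.ndarray,
    densities: list[float],
    regularization: float = 0.0,
    local: bool = False,
):
    """Build all networks from one concatenated series and measure them.

    Returns ``(globals, locals)`` where ``globals`` maps (network label,
    measure) -> value and ``locals`` (if requested) maps network label -> the
    per-node measure table.
    """
    rho = netbuild.partial_correlation(series, regularization=regularization)
    assoc = netbuild.association_from_partial(rho, n_timepoints=series.shape[0])
    return measure_association(assoc, densities, local=local)


def measure_association(
    assoc: netbuild.AssociationMatrix, densities: list[float], local: bool = False
):
    nets = {f"{d:g}": netbuild.threshold_to_density(assoc, d) for d in densities}
    nets["w"] = netbuild.to_weighted(assoc)
    glob: dict[tuple[str, str], float] = {}
    loc: dict[str, pd.DataFrame] = {}
    for label, net in nets.items():
        nm = node_measures(net)
        gm = global_measures(nm)
        for measure, value in gm.as_dict().items():
            glob[(label, measure)] = value
        if local:
            loc[label] = nm.table
    return glob, loc


def _subject_association(
    panel: TimeSeriesPanel, subject: str, runs: list[int] | None, regularization: float
) -> netbuild.AssociationMatrix:
    series = panel.concatenated(subject, runs)
    rho = netbuild.partial_correlation(series, regularization=regularization)
    return netbuild.association_from_partial(rho, n_timepoints=series.shape[0])


def subject_level_reliability(
    panel: TimeSeriesPanel,
    densities: list[float],
    n_realizations: int,
    seed: int,
    regularization: float = 0.0,
    local: bool = False,
) -> ReliabilityReport:
    """Split-half ICC and TRT of subject-specific networks.

    Per realization and subject, each half of the runs yields its own network
    and graph measures; ICC is computed over the 2 x S table per measure, and
    TRT per subject is averaged over subjects.  Results are aggregated over
    realizations.
    """
    if len(panel.subjects) < 2:
        raise ValueError("need at least 2 subjects")
    designs = make_split_half(panel, n_realizations, seed)
    labels = network_labels(densities)
    rows = []
    local_rows = []
    for design in designs:
        values: dict[tuple[str, str], list[tuple[float, float]]] = {}
        local_values: dict[tuple[str, str, int], list[tuple[float, float]]] = {}
        for subject in panel.subjects:
            h1, h2 = design.halves[subject]
            try:
                g1, l1 = measure_networks(
                    panel.concatenated(subject, list(h1)), densities,
                    regularization, local,
                )
                g2, l2 = measure_networks(
                    panel.concatenated(subject, list(h2)), densities,
                    regularization, local,
                )
            except (ValueError, np.linalg.LinAlgError) as exc:
                raise RuntimeError(
                    f"network construction failed for subject {subject}, "
                    f"realization {design.realization}: {exc}"
                ) from exc
            for key in g1:
                values.setdefault(key, []).append((g1[key], g2[key]))
            if local:
                for label in l1:
                    for measure in ("degree", "path_length", "clustering",
                                    "local_efficiency", "nodal_efficiency", "betweenness"):
                        a = l1[label][measure].to_numpy()
                        b = l2[label][measure].to_numpy()
                        for node in range(len(a)):
                            if np.isfinite(a[node]) and np.isfinite(b[node]):
                                local_values.setdefault(
                                    (label, measure, node), []
                                ).append((a[node], b[node]))
        for (label, measure), pairs in values.items():
            table = np.array(pairs).T  # 2 x S
            trts = [trt(v1, v2) for v1, v2 in pairs]
            rows.append(
                (design.realization, label, measure, icc(table), float(np.nanmean(trts)))
            )
        for (label, measure, node), pairs in local_values.items():
            if len(pairs) < 2:
                continue
            table = np.array(pairs).T
            trts = [trt(v1, v2) for v1, v2 in pairs]
            local_rows.append(
                (design.realization, label, measure, node, icc(table),
                 float(np.nanmean(trts)))
            )
    realizations = pd.DataFrame(
        rows, columns=["realization", "network", "measure", "icc", "trt"]
    )
    summary = (
        realizations.groupby(["network", "measure"])
        .agg(
            icc_mean=("icc", "mean"),
            icc_var=("icc", "var"),
            trt_mean=("trt", "mean"),
            trt_sd=("trt", "std"),
        )
        .reset_index()
    )
    report = ReliabilityReport(
        global_summary=summary,
        global_realizations=realizations,
        meta={"level": "subject", "densities": list(densities),
              "n_realizations": n_realizations, "seed": seed,
              "labels": labels},
    )
    if local:
        local_realizations = pd.DataFrame(
            local_rows,
            columns=["realization", "network", "measure", "node", "icc", "trt"],
        )
        report.local_realizations = local_realizations
        report.local_summary = (
            local_realizations.groupby(["network", "measure", "node"])
            .agg(
                icc_mean=("icc", "mean"),
                icc_var=("icc", "var"),
                trt_mean=("trt", "mean"),
                trt_sd=("trt", "std"),
            )
            .reset_index()
        )
    return report


def group_level_reliability(
    panel: TimeSeriesPanel,
    densities: list[float],
    n_realizations: int,
    seed: int,
    regularization: float = 0.0,
) -> ReliabilityReport:
    """Split-half TRT of group networks built from half-averaged association matrices."""
    if len(panel.subjects) < 2:
        raise ValueError("need at least 2 subjects")
    designs = make_split_half(panel, n_realizations, seed)
    rows = []
    for design in designs:
        assoc_halves = []
        for half in (0, 1):
            per_subject = [
                _subject_association(
                    panel, subject, list(design.halves[subject][half]), regularization
                )
                for subject in panel.subjects
            ]
            assoc_halves.append(netbuild.group_average(per_subject))
        g1, _ = measure_association(assoc_halves[0], densities)
        g2, _ = measure_association(assoc_halves[1], densities)
        for key in g1:
            label, measure = key
            rows.append((design.realization, label, measure, np.nan, trt(g1[key], g2[key])))
    realizations = pd.DataFrame(
        rows, columns=["realization", "network", "measure", "icc", "trt"]
    )
    summary = (
        realizations.groupby(["network", "measure"])
        .agg(trt_mean=("trt", "mean"), trt_sd=("trt", "std"))
        .reset_index()
    )
    return ReliabilityReport(
        global_summary=summary,
        global_realizations=realizations,
        meta={"level": "group", "densities": list(densities),
              "n_realizations": n_realizations, "seed": seed},
    )


def compare_independent_groups(
    panel_a: TimeSeriesPanel,
    panel_b: TimeSeriesPanel,
    densities: list[float],
    regularization: float = 0.0,
) -> pd.DataFrame:
    """Between-independent-groups comparison of two cohorts.

    Returns one row per (network, measure) with the TRT between the two
    group-based values and, for the weighted network, a two-sample t-test on
    the subject-specific weighted global measures of the two cohorts.
    """
    if panel_a.n_nodes != panel_b.n_nodes:
        raise ValueError("panels must share the node set")
    group_vals = []
    subject_weighted = []
    for panel in (panel_a, panel_b):
        assocs = [
            _subject_association(panel, s, None, regularization) for s in panel.subjects
        ]
        group_assoc = netbuild.group_average(assocs)
        glob, _ = measure_association(group_assoc, densities)
        group_vals.append(glob)
        per_subject = {measure: [] for measure in GLOBAL_MEASURE_NAMES}
        for a in assocs:
            gm = global_measures(node_measures(netbuild.to_weighted(a)))
            for measure, value in gm.as_dict().items():
                per_subject[measure].append(value)
        subject_weighted.append(per_subject)
    rows = []
    for key in group_vals[0]:
        label, measure = key
        t_stat = p_val = np.nan
        if label == "w":
            va = subject_weighted[0][measure]
            vb = subject_weighted[1][measure]
            if np.std(va) > 0 or np.std(vb) > 0:
                t_stat, p_val = stats.ttest_ind(va, vb)
        rows.append(
            (label, measure, trt(group_vals[0][key], group_vals[1][key]), t_stat, p_val)
        )
    return pd.DataFrame(
        rows, columns=["network", "measure", "trt", "t_stat", "t_pvalue"]
    )


def significance_summary(
    report: ReliabilityReport,
    icc_cutoff: float = 0.4,
    trt_cutoffs: tuple[float, float] = (5.0, 10.0),
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """One-sample t-tests of ICC > cutoff and TRT < cutoffs, plus a log-TRT
    versus density regression, Bonferroni-corrected.

    Global measures are corrected for the number of network conditions;
    local measures additionally for the number of nodes.  Conditions with
    degenerate (zero) variance across realizations are flagged and skipped.
    """
    real = report.global_realizations
    if real["realization"].nunique() < 2:
        raise ValueError("need at least 2 realizations")
    n_networks = real["network"].nunique()
    alpha_global = alpha / n_networks
    rows = []
    for (label, measure), grp in real.groupby(["network", "measure"]):
        iccs = grp["icc"].dropna().to_numpy()
        trts = grp["trt"].dropna().to_numpy()
        row = {
            "network": label, "measure": measure,
            "icc_mean": iccs.mean() if len(iccs) else np.nan,
            "trt_mean": trts.mean() if len(trts) else np.nan,
            "degenerate": False,
        }
        if len(iccs) >= 2 and iccs.std(ddof=1) > 0:
            _, p = stats.ttest_1samp(iccs, icc_cutoff, alternative="greater")
            row["icc_gt_cutoff_p"] = p
            row["icc_significant"] = p < alpha_global
        else:
            row["icc_gt_cutoff_p"] = np.nan
            row["icc_significant"] = False
            if len(iccs) >= 2:
                row["degenerate"] = True
        for cutoff in trt_cutoffs:
            key = f"trt_lt_{cutoff:g}"
            if len(trts) >= 2 and trts.std(ddof=1) > 0:
                _, p = stats.ttest_1samp(trts, cutoff, alternative="less")
                row[f"{key}_p"] = p
                row[f"{key}_significant"] = p < alpha_global
            else:
                row[f"{key}_p"] = np.nan
                row[f"{key}_significant"] = False
                if len(trts) >= 2:
                    row["degenerate"] = True
        rows.append(row)
    flags = pd.DataFrame(rows)

    # log-TRT vs density regression over the binary-density conditions
    reg_rows = []
    binary = real[real["network"] != "w"].copy()
    if not binary.empty:
        binary["density"] = binary["network"].astype(float)
        for measure, grp in binary.groupby("measure"):
            ok = grp["trt"] > 0
            if ok.sum() >= 3 and grp.loc[ok, "density"].nunique() >= 2:
                res = stats.linregress(
                    grp.loc[ok, "density"], np.log(grp.loc[ok, "trt"])
                )
                reg_rows.append(
                    (measure, res.slope, res.pvalue, res.pvalue < alpha_global)
                )
            else:
                reg_rows.append((measure, np.nan, np.nan, False))
    regression = pd.DataFrame(
        reg_rows, columns=["measure", "log_trt_slope", "slope_p", "slope_significant"]
    )

    out = {"global": flags, "regression": regression}
    if report.local_realizations is not None and not report.local_realizations.empty:
        n_nodes = report.local_realizations["node"].nunique()
        alpha_local = alpha_global / max(n_nodes, 1)
        loc_rows = []
        for (label, measure, node), grp in report.local_realizations.groupby(
            ["network", "measure", "node"]
        ):
            iccs = grp["icc"].dropna().to_numpy()
            trts = grp["trt"].dropna().to_numpy()
            row = {"network": label, "measure": measure, "node": node}
            if len(iccs) >= 2 and iccs.std(ddof=1) > 0:
                _, p = stats.ttest_1samp(iccs, icc_cutoff, alternative="greater")
                row["icc_significant"] = p < alpha_local
            else:
                row["icc_significant"] = False
            for cutoff in trt_cutoffs:
                if len(trts) >= 2 and trts.std(ddof=1) > 0:
                    _, p = stats.ttest_1samp(trts, cutoff, alternative="less")
                    row[f"trt_lt_{cutoff:g}_significant"] = p < alpha_local
                else:
                    row[f"trt_lt_{cutoff:g}_significant"] = False
            loc_rows.append(row)
        out["local"] = pd.DataFrame(loc_rows)
    return out
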