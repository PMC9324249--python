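"""Cohort-level statistical designs over per-subject graph metrics.

Three designs mirror the study workflow:

* whole-brain / hemispheric analysis — per-subject *network means* of the
  seven metrics are compared across groups (LGG vs HC, HGG vs HC, LGG vs
  HGG) for the whole-brain, left- and right-hemisphere networks, plus a
  paired left-vs-right contrast within each group;
* lobar analysis — patients are restricted to one tumor-location label and
  every node of that lobe (both hemispheres) is compared across groups on
  the whole-brain network, with BH-FDR applied within each
  (lobe, metric, pairing) family of nodes;
* connectograms — for a seed ROI, a one-sample t-test of each target's
  Fisher z across a group's subjects, BH-FDR over targets, and a count of
  significant connections.

A confound screen reports correlation / covariance / regression slope of
each network-mean metric against age and tumor size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .connectivity import ConnectivityMatrix, FilterSpec, connectivity_pipeline
from .exceptions import InvalidArgumentError
from .graph import METRICS, SCOPES, ThresholdSpec, subject_graph_metrics
from .parcellation import LOBES, ParcellationTable
from .stats import TestResult, compare_groups, compare_paired, fdr_correct
from .synthetic import SubjectTimeseries

logger = logging.getLogger(__name__)

PAIRINGS = (("LGG", "HC"), ("HGG", "HC"), ("LGG", "HGG"))

COMPARISON_COLUMNS = [
    "scope", "node", "metric", "group_a", "group_b", "test_used",
    "statistic", "p_raw", "p_fdr", "direction", "n_a", "n_b",
]


@dataclass
class CohortData:
    """Everything the statistical designs need about one cohort."""

    parcellation: ParcellationTable
    manifest: pd.DataFrame = field(repr=False)
    connectivity: dict[str, ConnectivityMatrix] = field(repr=False)
    metrics: dict[str, dict[str, pd.DataFrame]] = field(repr=False)
    network_means: pd.DataFrame = field(repr=False)

    def subjects_in(self, group: str, tumor_location: str | None = None) -> list[str]:
        m = self.manifest
        mask = m["group"] == group
        if tumor_location is not None:
            mask &= m["tumor_location"] == tumor_location
        return m.loc[mask, "subject_id"].tolist()


def compute_cohort(
    subjects: list[SubjectTimeseries],
    parcellation: ParcellationTable,
    TR: float = 2.5,
    filter_spec: FilterSpec | None = None,
    threshold: ThresholdSpec | None = None,
) -> CohortData:
    """Run connectivity + graph metrics for every subject of a cohort."""
    manifest_rows, conns, metrics, mean_rows = [], {}, {}, []
    for s in subjects:
        manifest_rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "tumor_location": s.tumor_location,
                "age": s.age,
                "tumor_size": s.tumor_size,
                "seed": s.seed,
            }
        )
        conn = connectivity_pipeline(s.data, TR, filter_spec, subject_id=s.subject_id)
        conns[s.subject_id] = conn
        tables = subject_graph_metrics(conn, parcellation, threshold)
        metrics[s.subject_id] = tables
        for scope in SCOPES:
            means = tables[scope].mean()
            for metric in METRICS:
                mean_rows.append(
                    {
                        "subject_id": s.subject_id,
                        "group": s.group,
                        "scope": scope,
                        "metric": metric,
                        "value": float(means[metric]),
                    }
                )
    return CohortData(
        parcellation=parcellation,
        manifest=pd.DataFrame(manifest_rows),
        connectivity=conns,
        metrics=metrics,
        network_means=pd.DataFrame(mean_rows),
    )


def _result_row(scope, node, metric, group_a, group_b, res: TestResult,
                n_a: int, n_b: int, alpha_normality: float) -> dict:
    assert res.gate_consistent(alpha_normality), "normality gate / test mismatch"
    return {
        "scope": scope, "node": node, "metric": metric,
        "group_a": group_a, "group_b": group_b,
        "test_used": res.test_used, "statistic": res.statistic,
        "p_raw": res.p, "p_fdr": np.nan, "direction": res.direction,
        "n_a": n_a, "n_b": n_b,
    }


def _apply_family_fdr(df: pd.DataFrame, family_cols: list[str]) -> pd.DataFrame:
    if df.empty:
        return df
    df = df.copy()
    for _, idx in df.groupby(family_cols, dropna=False).groups.items():
        df.loc[idx, "p_fdr"] = fdr_correct(df.loc[idx, "p_raw"].to_numpy())
    return df


def hemispheric_analysis(
    cohort: CohortData,
    alpha_normality: float = 0.05,
    paired_lr: bool = True,
) -> pd.DataFrame:
    """Whole-brain and hemispheric network-mean comparisons.

    For each scope and metric the three group pairings are tested with the
    gated t / Mann-Whitney procedure; BH-FDR runs within each
    (scope, pairing) family across the seven metrics.  The left-vs-right
    contrast within each group is paired per subject by default.
    """
    nm = cohort.network_means
    rows = []
    wide = nm.pivot_table(index=["subject_id", "group"], columns=["scope", "metric"],
                          values="value")
    groups_present = set(cohort.manifest["group"])
    for scope in SCOPES:
        for group_a, group_b in PAIRINGS:
            if group_a not in groups_present or group_b not in groups_present:
                logger.info("hemispheric: skipping %s vs %s (group missing)",
                            group_a, group_b)
                continue
            for metric in METRICS:
                a = wide.loc[wide.index.get_level_values("group") == group_a,
                             (scope, metric)].to_numpy()
                b = wide.loc[wide.index.get_level_values("group") == group_b,
                             (scope, metric)].to_numpy()
                res = compare_groups(a, b, alpha_normality)
                rows.append(_result_row(scope, "network-mean", metric,
                                        group_a, group_b, res, a.size, b.size,
                                        alpha_normality))
    # Within-group left-vs-right contrast.
    for group in ("HC", "LGG", "HGG"):
        if group not in groups_present:
            continue
        sel = wide.index.get_level_values("group") == group
        for metric in METRICS:
            left = wide.loc[sel, ("L", metric)].to_numpy()
            right = wide.loc[sel, ("R", metric)].to_numpy()
            if paired_lr:
                res = compare_paired(left, right, alpha_normality)
            else:
                res = compare_groups(left, right, alpha_normality)
            rows.append(_result_row("left_vs_right", "network-mean", metric,
                                    group, group, res, left.size, right.size,
                                    alpha_normality))
    df = pd.DataFrame(rows, columns=COMPARISON_COLUMNS)
    return _apply_family_fdr(df, ["scope", "group_a", "group_b"])


def lobar_analysis(
    cohort: CohortData,
    alpha_normality: float = 0.05,
    min_n: int = 3,
) -> pd.DataFrame:
    """Node-level comparisons within each tumor-location subgroup.

    For every lobe carrying at least one patient, patient groups are
    restricted to subjects with that tumor-location label and every node of
    the lobe (both hemispheres) is compared on the whole-brain network.
    BH-FDR runs within each (lobe, metric, pairing) family across nodes.
    """
    parc = cohort.parcellation
    rows = []
    for lobe in LOBES:
        nodes = parc.lobe_ids(lobe)
        for group_a, group_b in PAIRINGS:
            ids_a = cohort.subjects_in(group_a, None if group_a == "HC" else lobe)
            ids_b = cohort.subjects_in(group_b, None if group_b == "HC" else lobe)
            if group_a != "HC" and not ids_a or group_b != "HC" and not ids_b:
                continue  # no patients with this location in the pairing
            if len(ids_a) < min_n or len(ids_b) < min_n:
                logger.info("lobar %s: skipping %s (n=%d) vs %s (n=%d)",
                            lobe, group_a, len(ids_a), group_b, len(ids_b))
                continue
            for metric in METRICS:
                mat_a = np.array([
                    cohort.metrics[sid]["whole_brain"].loc[nodes, metric].to_numpy()
                    for sid in ids_a
                ])
                mat_b = np.array([
                    cohort.metrics[sid]["whole_brain"].loc[nodes, metric].to_numpy()
                    for sid in ids_b
                ])
                for j, node in enumerate(nodes):
                    res = compare_groups(mat_a[:, j], mat_b[:, j], alpha_normality)
                    rows.append(_result_row(f"lobe:{lobe}", int(node), metric,
                                            group_a, group_b, res,
                                            len(ids_a), len(ids_b),
                                            alpha_normality))
    df = pd.DataFrame(rows, columns=COMPARISON_COLUMNS)
    return _apply_family_fdr(df, ["scope", "metric", "group_a", "group_b"])


def direction_matrix(lobar: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Increase/decrease table of FDR-significant lobar results."""
    sig = lobar[lobar["p_fdr"] < alpha].copy()
    if sig.empty:
        return pd.DataFrame(columns=["node", "metric", "comparison", "direction"])
    sig["comparison"] = sig["group_a"] + "/" + sig["group_b"]
    sig["direction"] = np.where(sig["direction"] > 0, "increase", "decrease")
    return sig[["node", "metric", "comparison", "direction", "p_fdr"]].reset_index(drop=True)


@dataclass(frozen=True)
class ConnectogramResult:
    """Group-level significant connections of one seed ROI."""

    seed_roi: int
    group: str
    target_ids: np.ndarray = field(repr=False)
    p_fdr: np.ndarray = field(repr=False)
    significant_targets: tuple[int, ...] = ()

    @property
    def count(self) -> int:
        return len(self.significant_targets)


def connectogram(
    cohort: CohortData,
    seed_roi: int,
    group: str,
    alpha: float = 0.05,
) -> ConnectogramResult:
    """Seed-to-ROI connectivity diagram for one group.

    Second level: one-sample two-sided t-test of the subjects' Fisher z
    against zero per target, BH-FDR across the N - 1 targets.
    """
    sids = cohort.subjects_in(group)
    if len(sids) < 3:
        raise InvalidArgumentError(f"group {group} needs >= 3 subjects")
    n = cohort.parcellation.n_roi
    targets = np.array([j for j in range(n) if j != seed_roi])
    stack = np.array([cohort.connectivity[sid].z[seed_roi, targets] for sid in sids])
    p = np.ones(targets.size)
    varying = stack.std(axis=0) > 0
    if varying.any():
        res = sps.ttest_1samp(stack[:, varying], 0.0, axis=0)
        p[varying] = res.pvalue
    # A column of exact zeros (e.g. an all-zero cohort) carries no evidence.
    zero_mean = ~varying & (stack.mean(axis=0) == 0)
    p[zero_mean] = 1.0
    p[~varying & ~zero_mean] = 0.0
    p_fdr = fdr_correct(p)
    significant = tuple(int(t) for t, q in zip(targets, p_fdr) if q < alpha)
    return ConnectogramResult(seed_roi=int(seed_roi), group=group,
                              target_ids=targets, p_fdr=p_fdr,
                              significant_targets=significant)


def compare_connection_counts(counts_a, counts_b) -> TestResult:
    """Two-tailed Student t-test on total significant-connection counts."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if np.all(np.concatenate([a, b]) == np.concatenate([a, b])[0]):
        return TestResult("t", 0.0, 1.0, 0, True, True)
    stat, p = sps.ttest_ind(a, b, equal_var=True)
    return TestResult("t", float(stat), float(p),
                      int(np.sign(a.mean() - b.mean())), True, True)


def confound_screen(
    cohort: CohortData,
    corr_bound: float = 0.4,
    cov_bound: float = 0.2,
) -> pd.DataFrame:
    """Correlation / covariance / slope of network-mean metrics vs covariates.

    Screens patients only (tumor size is undefined for controls; age is
    screened on the same subjects for comparability).  Covariance is
    computed on range-normalized variables so it is bounded and unit-free;
    correlation is plain Pearson.  Rows are flagged when |corr| or |cov|
    exceeds the configured bounds, or when a covariate is constant.
    """
    m = cohort.manifest
    patients = m[m["group"].isin(["LGG", "HGG"])]
    nm = cohort.network_means
    rows = []
    for covariate in ("age", "tumor_size"):
        cov_values = patients.set_index("subject_id")[covariate]
        for scope in SCOPES:
            for metric in METRICS:
                sel = nm[(nm["scope"] == scope) & (nm["metric"] == metric)]
                sel = sel[sel["subject_id"].isin(cov_values.index)]
                y = sel.set_index("subject_id")["value"].reindex(cov_values.index)
                x = cov_values.to_numpy(dtype=float)
                yv = y.to_numpy(dtype=float)
                flag = ""
                if np.ptp(x) == 0:
                    corr = cov = slope = np.nan
                    flag = "constant-covariate"
                elif np.ptp(yv) == 0:
                    corr = cov = np.nan
                    slope = 0.0
                    flag = "constant-metric"
                else:
                    corr = float(sps.pearsonr(x, yv).statistic)
                    xs = (x - x.min()) / np.ptp(x)
                    ys = (yv - yv.min()) / np.ptp(yv)
                    cov = float(np.cov(xs, ys, ddof=1)[0, 1])
                    z = (yv - yv.mean()) / yv.std(ddof=1)
                    slope = float(sps.linregress(x, z).slope)
                    if abs(corr) > corr_bound or abs(cov) > cov_bound:
                        flag = "exceeds-bound"
                rows.append(
                    {
                        "scope": scope, "metric": metric, "covariate": covariate,
                        "n": int(x.size), "correlation": corr,
                        "covariance": cov, "slope": slope, "flag": flag,
                    }
                )
    return pd.DataFrame(rows)
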