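"""Survival-linked clustering of exon-usage profiles.

Patients are grouped by k-means on their relative exon-usage vectors
(initially 4 clusters), clusters whose survival curves are statistically
indistinguishable are merged greedily by pairwise log-rank p-value, and
the final grouping is summarized with Kaplan-Meier curves and a k-sample
log-rank test on (k - 1) degrees of freedom.

Kaplan-Meier estimation and the log-rank tests are delegated to lifelines;
this module owns the cluster/merge logic and the bookkeeping types.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterAssignment",
    "SurvivalCurve",
    "LogRankResult",
    "kmeans_usage",
    "km_curve",
    "logrank",
    "merge_similar_clusters",
    "cluster_usage_summary",
]


@dataclass
class ClusterAssignment:
    """Patient -> cluster labels (contiguous, starting at 1)."""

    labels: pd.Series  # index: barcode, values: int labels 1..k
    k_initial: int
    merge_map: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        uniq = sorted(int(x) for x in self.labels.unique())
        if uniq != list(range(1, len(uniq) + 1)):
            raise ValueError(f"labels must be contiguous from 1, got {uniq}")
        if not self.merge_map:
            self.merge_map = {c: c for c in uniq}

    @property
    def k_final(self) -> int:
        return int(self.labels.nunique())


@dataclass
class SurvivalCurve:
    """Product-limit estimate with at-risk/event bookkeeping.

    ``event_times`` are the distinct times with >= 1 event; ``at_risk`` and
    ``events`` the n_i and d_i at those times; ``survival`` the step values
    S(t_i) = prod_{t_j <= t_i} (1 - d_j / n_j).
    """

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray

    def at(self, t: float) -> float:
        """S(t): right-continuous step function, S = 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p_value: float


def kmeans_usage(
    usage: pd.DataFrame,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
    standardize: bool = False,
) -> ClusterAssignment:
    """K-means (Lloyd, Euclidean) on raw usage percentages.

    Rows with any missing usage value are dropped with a logged count.
    Best of ``n_restarts`` initializations by within-cluster sum of
    squares; deterministic under ``seed``. Labels are renumbered 1..k in
    order of first appearance so the numbering is input-order stable.
    ``standardize`` switches to per-exon z-scores (off by default: the
    usage transform already removes the dominant scale effects).
    """
    complete = usage.dropna(axis=0)
    dropped = len(usage) - len(complete)
    if dropped:
        logger.info("kmeans: dropped %d rows with missing usage values", dropped)
    if k > len(complete):
        raise ValueError(f"k={k} exceeds {len(complete)} complete patients")
    x = complete.to_numpy(dtype=float)
    if standardize:
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed, algorithm="lloyd")
    raw = km.fit_predict(x)
    relabel: dict[int, int] = {}
    out = np.empty(raw.shape, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        out[i] = relabel[lab]
    return ClusterAssignment(
        labels=pd.Series(out, index=complete.index, name="cluster"), k_initial=k
    )


def km_curve(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate of one group's survival.

    Subjects censored at an event time stay at risk for the events at that
    time (the standard convention).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty group")
    if np.any(times <= 0):
        raise ValueError("survival times must be > 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    with_events = table[table["observed"] > 0]
    event_times = with_events.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(event_times).to_numpy(dtype=float)
    return SurvivalCurve(
        event_times=event_times,
        at_risk=with_events["at_risk"].to_numpy(dtype=int),
        events=with_events["observed"].to_numpy(dtype=int),
        survival=surv,
    )


def logrank(groups: list[tuple[np.ndarray, np.ndarray]]) -> LogRankResult:
    """K-sample log-rank test; chi-squared on (k - 1) degrees of freedom."""
    if len(groups) < 2:
        raise ValueError("log-rank needs >= 2 groups")
    times, events, labels = [], [], []
    for g, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=bool)
        if t.size == 0:
            raise ValueError(f"group {g} is empty")
        times.append(t)
        events.append(e)
        labels.append(np.full(t.size, g))
    times = np.concatenate(times)
    events = np.concatenate(events)
    labels = np.concatenate(labels)
    df = len(groups) - 1
    if not events.any():
        return LogRankResult(statistic=0.0, df=df, p_value=1.0)
    res = multivariate_logrank_test(times, labels, events)
    return LogRankResult(
        statistic=float(res.test_statistic), df=df, p_value=float(res.p_value)
    )


def merge_similar_clusters(
    assignment: ClusterAssignment,
    survival: pd.DataFrame,
    p_merge: float = 0.2,
    k_target: int = 3,
) -> ClusterAssignment:
    """Greedily merge the cluster pair with the largest pairwise log-rank p.

    The pair with the largest pairwise p (most similar survival) is merged
    first. Merging is mandatory while more than ``k_target`` clusters
    remain, and continues past ``k_target`` only while the largest pairwise
    p still exceeds ``p_merge`` (curves "nearly identical"). ``survival``
    must carry ``survival_time`` and ``event`` indexed by barcode; patients
    missing from it are ignored for the merge decision but keep their
    labels.
    """
    labels = assignment.labels.copy()
    if assignment.k_final < k_target:
        raise ValueError("k_target exceeds current cluster count")
    current = {int(c): int(c) for c in sorted(labels.unique())}  # initial -> surviving label
    surv = survival.loc[survival.index.intersection(labels.index)]

    def group_data(cluster):
        idx = labels.index[labels == cluster].intersection(surv.index)
        sub = surv.loc[idx]
        return sub["survival_time"].to_numpy(), sub["event"].to_numpy(dtype=bool)

    while labels.nunique() > 1:
        clusters = sorted(labels.unique())
        best_pair, best_p = None, -1.0
        for i, a in enumerate(clusters):
            for b in clusters[i + 1 :]:
                ga, gb = group_data(a), group_data(b)
                if ga[0].size == 0 or gb[0].size == 0:
                    p = 1.0
                else:
                    p = logrank([ga, gb]).p_value
                if p > best_p:
                    best_pair, best_p = (a, b), p
        if labels.nunique() <= k_target and best_p <= p_merge:
            break  # at target and no pair is "nearly identical" any more
        a, b = best_pair
        labels[labels == b] = a
        for init, cur in current.items():
            if cur == b:
                current[init] = a
    # renumber contiguously from 1, in order of first appearance
    relabel: dict[int, int] = {}
    new = labels.copy()
    for bc, lab in labels.items():
        if int(lab) not in relabel:
            relabel[int(lab)] = len(relabel) + 1
        new[bc] = relabel[int(lab)]
    merge_map = {int(init): relabel[int(cur)] for init, cur in current.items()}
    return ClusterAssignment(
        labels=new.astype(int), k_initial=assignment.k_initial, merge_map=merge_map
    )


def ward_order(usage: pd.DataFrame) -> list:
    """Patient ordering from Ward hierarchical clustering, for heatmap export.

    Survival classification uses k-means; this ordering only arranges rows
    so that similar usage profiles sit together in a heatmap.
    """
    from scipy.cluster.hierarchy import leaves_list, linkage

    complete = usage.dropna(axis=0)
    if len(complete) < 2:
        return list(complete.index)
    z = linkage(complete.to_numpy(dtype=float), method="ward")
    return [complete.index[i] for i in leaves_list(z)]


def cluster_usage_summary(
    usage: pd.DataFrame, assignment: ClusterAssignment
) -> pd.DataFrame:
    """Median and quartiles (type-7, linear interpolation) per exon per cluster.

    Returns a long table: cluster, exon, q1, median, q3 — boxplot-ready.
    """
    rows = []
    common = usage.index.intersection(assignment.labels.index)
    lab = assignment.labels.loc[common]
    for cluster in sorted(lab.unique()):
        sub = usage.loc[lab.index[lab == cluster]]
        q = sub.quantile([0.25, 0.5, 0.75], interpolation="linear")
        for exon in usage.columns:
            rows.append(
                {
                    "cluster": cluster,
                    "exon": exon,
                    "q1": q.loc[0.25, exon],
                    "median": q.loc[0.5, exon],
                    "q3": q.loc[0.75, exon],
                }
            )
    return pd.DataFrame(rows)
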