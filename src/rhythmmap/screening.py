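"""ECG-level screening from snippet responsibilities.

A new ECG is screened by (1) projecting each of its snippets through the
trained GTM to get node responsibilities, (2) averaging those rows into a
single per-ECG probability distribution over the latent nodes, (3) totalling
that distribution per macrocluster, and (4) assigning the ECG to the
macrocluster with the largest total. Each macrocluster carries a diagnosis
label estimated from the training snippets that mode-project into it, so the
cluster assignment translates directly into a screening call
(normal / possible_af / af).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rhythmmap.gtm import GTMResults, mode_project
from rhythmmap.macrocluster import MacroclusterPartition

__all__ = [
    "DIAGNOSES",
    "ScreeningResult",
    "ClusterDiagnosisMap",
    "Screener",
    "aggregate_responsibilities",
    "cluster_totals",
    "label_clusters",
    "evaluate",
]

#: diagnosis vocabulary, ordered by increasing risk
DIAGNOSES = ("normal", "possible_af", "af")
_RISK = {d: i for i, d in enumerate(DIAGNOSES)}


@dataclass
class ScreeningResult:
    """Screening output for one ECG."""

    ecg_id: str
    node_distribution: np.ndarray  # length K, sums to 1
    cluster_totals: np.ndarray  # length M, sums to 1
    assigned_cluster: int  # 1..M
    assigned_diagnosis: str
    trajectory: np.ndarray  # chronological node index per snippet
    unscreenable: bool = False


@dataclass
class ClusterDiagnosisMap:
    """Majority diagnosis per macrocluster plus the supporting composition."""

    labels: dict[int, str]
    composition: pd.DataFrame  # rows = clusters, columns = DIAGNOSES, fractions

    def __getitem__(self, m: int) -> str:
        return self.labels[m]


def aggregate_responsibilities(R_snippets: np.ndarray) -> np.ndarray:
    """Arithmetic column mean of one ECG's snippet responsibility rows."""
    R = np.atleast_2d(np.asarray(R_snippets, dtype=float))
    if R.shape[0] < 1 or R.size == 0:
        raise ValueError("need at least one snippet responsibility row")
    return R.mean(axis=0)


def cluster_totals(
    node_distribution: np.ndarray, partition: MacroclusterPartition
) -> np.ndarray:
    """Total responsibility per macrocluster (length M, sums to 1)."""
    dist = np.asarray(node_distribution, dtype=float)
    if dist.size != partition.K:
        raise ValueError("distribution length does not match the partition")
    totals = np.zeros(partition.M)
    for m in range(1, partition.M + 1):
        totals[m - 1] = dist[partition.labels == m].sum()
    return totals


def label_clusters(
    R_train: np.ndarray,
    partition: MacroclusterPartition,
    diagnoses,
) -> ClusterDiagnosisMap:
    """Assign each macrocluster the majority diagnosis of its member snippets.

    Training snippets are mode-projected to nodes; a cluster's members are
    the snippets landing on its nodes. Ties break toward the higher-risk
    label (af > possible_af > normal). Empty clusters are labeled
    ``unassigned`` with a warning.
    """
    diagnoses = np.asarray(list(diagnoses), dtype=object)
    unknown = set(diagnoses) - set(DIAGNOSES)
    if unknown:
        raise ValueError(f"unknown diagnosis labels: {sorted(unknown)}")
    nodes = mode_project(np.asarray(R_train, dtype=float))
    snippet_cluster = partition.labels[nodes]

    labels: dict[int, str] = {}
    comp_rows = []
    for m in range(1, partition.M + 1):
        member_dx = diagnoses[snippet_cluster == m]
        if member_dx.size == 0:
            warnings.warn(f"macrocluster {m} has no training snippets", stacklevel=2)
            labels[m] = "unassigned"
            comp_rows.append({d: np.nan for d in DIAGNOSES})
            continue
        counts = {d: int(np.sum(member_dx == d)) for d in DIAGNOSES}
        best = max(counts, key=lambda d: (counts[d], _RISK[d]))
        labels[m] = best
        total = member_dx.size
        comp_rows.append({d: counts[d] / total for d in DIAGNOSES})
    composition = pd.DataFrame(comp_rows, index=pd.RangeIndex(1, partition.M + 1, name="macrocluster"))
    return ClusterDiagnosisMap(labels=labels, composition=composition)


class Screener:
    """Bundle of trained model, macrocluster partition and diagnosis map."""

    def __init__(
        self,
        results: GTMResults,
        partition: MacroclusterPartition,
        cmap: ClusterDiagnosisMap,
    ):
        self.results = results
        self.partition = partition
        self.cmap = cmap

    def screen_responsibilities(self, ecg_id: str, R_snippets: np.ndarray) -> ScreeningResult:
        """Screen one ECG from its snippet responsibility rows (chronological)."""
        R = np.atleast_2d(np.asarray(R_snippets, dtype=float))
        if R.size == 0 or R.shape[0] == 0:
            return ScreeningResult(
                ecg_id=ecg_id,
                node_distribution=np.zeros(self.partition.K),
                cluster_totals=np.zeros(self.partition.M),
                assigned_cluster=0,
                assigned_diagnosis="unscreenable",
                trajectory=np.array([], dtype=int),
                unscreenable=True,
            )
        dist = aggregate_responsibilities(R)
        totals = cluster_totals(dist, self.partition)
        assigned = int(np.argmax(totals)) + 1  # argmax ties -> lowest cluster id
        return ScreeningResult(
            ecg_id=ecg_id,
            node_distribution=dist,
            cluster_totals=totals,
            assigned_cluster=assigned,
            assigned_diagnosis=self.cmap[assigned],
            trajectory=mode_project(R),
        )

    def screen_table(self, feature_table: pd.DataFrame) -> list[ScreeningResult]:
        """Screen every ECG in a raw (unstandardized) snippet feature table.

        The table must carry ``ecg_id`` and ``snippet_index`` columns; rows
        are standardized with the model's stored parameters. ECGs whose
        snippets all failed quality (no rows) never appear here — use
        :meth:`screen_responsibilities` with an empty matrix to represent
        them explicitly.
        """
        out = []
        for ecg_id, group in feature_table.groupby("ecg_id", sort=False):
            group = group.sort_values("snippet_index")
            R = self.results.transform_new(group)
            out.append(self.screen_responsibilities(str(ecg_id), R))
        return out

    def report_frame(self, results: list[ScreeningResult]) -> pd.DataFrame:
        """One CSV-ready row per ECG: node probabilities, cluster totals,
        assignment and diagnosis."""
        rows = []
        for r in results:
            row = {"ecg_id": r.ecg_id}
            row.update({f"node_{k}": v for k, v in enumerate(r.node_distribution)})
            row.update({f"cluster_{m+1}": v for m, v in enumerate(r.cluster_totals)})
            row["assigned_cluster"] = r.assigned_cluster
            row["diagnosis"] = r.assigned_diagnosis
            rows.append(row)
        return pd.DataFrame(rows)


def evaluate(y_true, y_pred) -> tuple[pd.DataFrame, float]:
    """3x3 confusion matrix (rows = truth, ordered normal/possible_af/af)
    and overall accuracy."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label lists differ in length")
    bad = [lab for lab in set(y_true) | set(y_pred) if lab not in DIAGNOSES]
    if bad:
        raise ValueError(f"labels outside vocabulary {DIAGNOSES}: {sorted(bad)}")
    mat = pd.DataFrame(0, index=list(DIAGNOSES), columns=list(DIAGNOSES))
    for t, p in zip(y_true, y_pred):
        mat.loc[t, p] += 1
    acc = float(np.trace(mat.to_numpy())) / len(y_true)
    return mat, acc
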