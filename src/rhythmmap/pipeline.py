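"""High-level glue: simulate a corpus, train the full model stack, screen.

These helpers chain the library stages with the study configuration as
defaults (8 x 8 latent grid, 3 x 3 RBFs, width 0.8, alpha 1, KNN k = 5,
M = 5 macroclusters). The CLI, the test suite and the acceptance script all
drive the pipeline through this module so they cannot drift apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rhythmmap.gtm import GTM, GTMResults
from rhythmmap.macrocluster import MacroclusterPartition, macrocluster_pipeline
from rhythmmap.preprocessing import featurize_recordings, filter_features, standardize
from rhythmmap.screening import ClusterDiagnosisMap, Screener, evaluate, label_clusters
from rhythmmap.synthetic import RhythmSpec, simulate_rr_series

__all__ = ["PipelineConfig", "simulate_corpus", "train_pipeline", "screen_corpus"]


@dataclass
class PipelineConfig:
    """Knobs of the full pipeline, defaulting to the study configuration."""

    window: float = 20.0
    stride: float = 5.0
    cap: float = 60.0
    quality_backend: str = "template_correlation"
    corr_thresh: float = 0.9
    miss_thresh: float = 0.30
    grid_shape: tuple[int, int] = (8, 8)
    rbf_shape: tuple[int, int] = (3, 3)
    width: float = 0.8
    alpha: float = 1.0
    tol: float = 1e-5
    max_iter: int = 200
    knn_k: int = 5
    n_macroclusters: int = 5
    knn_scaling: str = "minmax"
    seed: int = 0

    def to_dict(self) -> dict:
        import dataclasses

        d = dataclasses.asdict(self)
        d["grid_shape"] = list(d["grid_shape"])
        d["rbf_shape"] = list(d["rbf_shape"])
        return d


def simulate_corpus(
    n_per_class: int = 40,
    duration: float = 60.0,
    seed: int = 0,
    classes: tuple[str, ...] = ("normal", "af", "paroxysmal"),
) -> list:
    """Simulate ``n_per_class`` recordings per rhythm class at the defaults."""
    recordings = []
    for ci, cls in enumerate(classes):
        for i in range(n_per_class):
            spec = RhythmSpec(
                rhythm_class=cls, duration=duration, seed=seed + ci * 100_003 + i
            )
            rec = simulate_rr_series(spec)
            rec.ecg_id = f"{cls}-{i:03d}"
            recordings.append(rec)
    return recordings


def train_pipeline(
    recordings, config: PipelineConfig | None = None
) -> tuple[Screener, pd.DataFrame, list]:
    """Featurize, filter, standardize, fit the GTM, macrocluster and label.

    Returns the ready :class:`Screener`, the raw (pre-standardization but
    post-filtering) feature table, and the column-filter audit log.
    """
    cfg = config or PipelineConfig()
    table = featurize_recordings(
        recordings,
        window=cfg.window,
        stride=cfg.stride,
        cap=cfg.cap,
        quality_backend=cfg.quality_backend,
    )
    if table.empty:
        raise ValueError("no snippets survived featurization")
    filtered, audit = filter_features(
        table, corr_thresh=cfg.corr_thresh, miss_thresh=cfg.miss_thresh
    )
    ztable, scaler = standardize(filtered)
    model = GTM.from_dataframe(
        ztable,
        standardizer=scaler,
        grid_shape=cfg.grid_shape,
        rbf_shape=cfg.rbf_shape,
        width=cfg.width,
        alpha=cfg.alpha,
    )
    results = model.fit(max_iter=cfg.max_iter, tol=cfg.tol)
    results.attach_magnification()
    partition = macrocluster_pipeline(
        results, k=cfg.knn_k, M=cfg.n_macroclusters, scaling=cfg.knn_scaling
    )
    cmap = label_clusters(results.responsibilities_, partition, filtered["diagnosis"])
    partition.diagnosis = dict(cmap.labels)
    return Screener(results, partition, cmap), filtered, audit


def screen_corpus(screener: Screener, recordings, config: PipelineConfig | None = None):
    """Featurize and screen recordings; returns (results, confusion, accuracy).

    The confusion matrix and accuracy are None when any recording lacks a
    ground-truth diagnosis.
    """
    cfg = config or PipelineConfig()
    table = featurize_recordings(
        recordings,
        window=cfg.window,
        stride=cfg.stride,
        cap=cfg.cap,
        quality_backend=cfg.quality_backend,
    )
    results = screener.screen_table(table)
    truth = {rec.ecg_id: rec.diagnosis for rec in recordings}
    if any(truth.get(r.ecg_id) is None for r in results):
        return results, None, None
    y_true = [truth[r.ecg_id] for r in results]
    y_pred = [r.assigned_diagnosis for r in results]
    confusion, accuracy = evaluate(y_true, y_pred)
    return results, confusion, accuracy
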