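"""Scoring: detection matching, CSR, robustness study and the benchmark grid.

The classification success rate (CSR) is the fraction of spikes receiving
the correct classification, under the best one-to-one assignment of
predicted clusters to true classes (solved optimally over the confusion
matrix, so any relabeling permutation of the predictions scores the same).
Detected spikes are matched to ground-truth events greedily,
nearest-in-time first, within a sample tolerance; unmatched detections
(false alarms) are reported separately and excluded from CSR, which scores
classification of true spikes only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import clustering, features
from .clustering import Codebook, TrainingConfig
from .detection import ChannelConfig, process_multichannel

__all__ = [
    "CSRReport",
    "match_detections",
    "csr",
    "robustness_study",
    "benchmark_grid",
    "score_detection",
]


@dataclass
class CSRReport:
    csr: float
    confusion: np.ndarray  # true x predicted counts
    assignment: dict[int, int]  # predicted cluster -> true class
    n_spikes: int


def match_detections(detected_peaks, truth_samples, tolerance_samples: int
                     ) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Greedy nearest-in-time one-to-one matching within a tolerance.

    Candidate (detection, truth) pairs are considered in order of
    increasing time difference; each side is matched at most once.
    Returns (matched index pairs, missed truth indices, false-alarm
    detection indices).
    """
    if tolerance_samples < 0:
        raise ValueError("tolerance must be >= 0")
    det = np.asarray(detected_peaks)
    tru = np.asarray(truth_samples)
    if det.size == 0 or tru.size == 0:
        return [], list(range(tru.size)), list(range(det.size))
    diff = np.abs(det[:, None] - tru[None, :])
    order = np.argsort(diff, axis=None, kind="stable")
    det_used = np.zeros(det.size, bool)
    tru_used = np.zeros(tru.size, bool)
    pairs: list[tuple[int, int]] = []
    for flat in order:
        i, j = divmod(int(flat), tru.size)
        if diff[i, j] > tolerance_samples:
            break
        if det_used[i] or tru_used[j]:
            continue
        det_used[i] = tru_used[j] = True
        pairs.append((i, j))
    misses = [j for j in range(tru.size) if not tru_used[j]]
    false_alarms = [i for i in range(det.size) if not det_used[i]]
    return pairs, misses, false_alarms


def csr(labels_pred, labels_true) -> CSRReport:
    """CSR under the optimal predicted-cluster -> true-class assignment."""
    pred = np.asarray(labels_pred)
    true = np.asarray(labels_true)
    if pred.size == 0 or pred.size != true.size:
        raise ValueError("labels_pred and labels_true must be equal-length "
                         "and non-empty")
    true_ids = np.unique(true)
    pred_ids = np.unique(pred)
    conf = np.zeros((true_ids.size, pred_ids.size), dtype=int)
    t_index = {v: i for i, v in enumerate(true_ids)}
    p_index = {v: i for i, v in enumerate(pred_ids)}
    for p, t in zip(pred, true):
        conf[t_index[t], p_index[p]] += 1
    rows, cols = linear_sum_assignment(conf, maximize=True)
    correct = int(conf[rows, cols].sum())
    assignment = {int(pred_ids[c]): int(true_ids[r])
                  for r, c in zip(rows, cols)}
    return CSRReport(csr=correct / pred.size, confusion=conf,
                     assignment=assignment, n_spikes=int(pred.size))


def score_detection(detected_peaks, truth_samples, tolerance_samples: int
                    ) -> dict:
    """Sensitivity and false-alarm rate of a detection run vs ground truth."""
    pairs, misses, fas = match_detections(detected_peaks, truth_samples,
                                          tolerance_samples)
    n_truth = len(truth_samples)
    return {
        "n_truth": n_truth,
        "n_detected": len(detected_peaks),
        "n_matched": len(pairs),
        "sensitivity": len(pairs) / n_truth if n_truth else float("nan"),
        "false_alarm_rate": len(fas) / n_truth if n_truth else float("nan"),
    }


def robustness_study(features_arr: np.ndarray, labels_true, k: int,
                     r: int = 300, base_seed: int = 0,
                     config: TrainingConfig | None = None) -> pd.DataFrame:
    """CSR of ``r`` independent CL trainings with different random inits.

    Run ``i`` is seeded ``base_seed + i``; every run initializes its
    centers by random selection from the same feature set and then makes
    one training pass (per the config).  Returns a DataFrame with columns
    (seed, csr); the spread (max - min) measures sensitivity to
    initialization.
    """
    if r < 2:
        raise ValueError("need at least 2 runs")
    x = np.atleast_2d(np.asarray(features_arr, dtype=float))
    base = config or TrainingConfig(k=k)
    rows = []
    for i in range(r):
        seed = base_seed + i
        cfg = replace(base, k=k, seed=seed)
        cb = clustering.init_codebook({0: x}, k=k, seed=seed,
                                      eta=cfg.resolved_eta,
                                      eta_exponent=cfg.resolved_exponent,
                                      shift_mode=cfg.shift_mode)
        clustering.cl_train({0: x}, cb, cfg)
        pred = clustering.cl_classify_batch(cb, 0, x)
        rows.append((seed, csr(pred, labels_true).csr))
    return pd.DataFrame(rows, columns=["seed", "csr"])


def osort_threshold(waveforms: np.ndarray, subsample: int = 200) -> float:
    """Data-driven OSORT create/merge threshold from pairwise distances.

    The 10th percentile of pairwise squared distances tracks the
    within-unit (noise) spread; 1.5x that sits above it while staying
    below the between-unit separation.  On near-noiseless data, where
    the within-unit distances vanish, a small fraction of the 95th
    percentile provides the floor.
    """
    wf = np.atleast_2d(np.asarray(waveforms, dtype=float))
    sample = wf[:: max(1, len(wf) // subsample)]
    d2 = ((sample[:, None, :] - sample[None, :, :]) ** 2).sum(-1)
    dv = d2[np.triu_indices(len(sample), 1)]
    return float(max(1.5 * np.quantile(dv, 0.10),
                     0.05 * np.quantile(dv, 0.95)))


def _train_classify_cl(feats: np.ndarray, k: int, seed: int) -> np.ndarray:
    cb = clustering.init_codebook({0: feats}, k=k, seed=seed)
    clustering.cl_train({0: feats}, cb, TrainingConfig(k=k, seed=seed))
    return clustering.cl_classify_batch(cb, 0, feats)


def benchmark_grid(recording, truth, config: ChannelConfig | None = None,
                   k: int | None = None, seed: int = 0,
                   tolerance_samples: int | None = None) -> pd.DataFrame:
    """The feature-method x clusterer CSR grid on one recording.

    Pipeline: detect -> match detections to ground truth (carrying true
    labels) -> extract {PDAC, PCA, GHA} features -> cluster with
    {CL, K-means, FCM}, plus OSORT directly on the raw waveforms.  Cells
    that fail at any stage are reported as NaN and the run continues.
    Rows are feature methods plus 'waveform' (OSORT); columns clusterers.
    """
    config = config or ChannelConfig(
        sampling_rate_hz=recording.sampling_rate_hz,
        n_channels=recording.n_channels)
    if tolerance_samples is None:
        tolerance_samples = config.m // 2
    spikes = process_multichannel(recording, config)
    waveforms, true_labels = [], []
    for q in range(recording.n_channels):
        ch_spikes = [s for s in spikes if s.channel == q]
        tdf = truth.for_channel(q)
        pairs, _, _ = match_detections(
            [s.peak_index for s in ch_spikes],
            tdf["sample_index"].to_numpy(), tolerance_samples)
        for i, j in pairs:
            waveforms.append(ch_spikes[i].waveform)
            true_labels.append(int(tdf["label"].iloc[j]))
    if not waveforms:
        raise ValueError("no detected spike matched the ground truth")
    wf = np.vstack(waveforms)
    true_labels = np.asarray(true_labels)
    if k is None:
        k = len(np.unique(true_labels))

    extractors = {
        "PCA": lambda w: features.pca_features(w, 2),
        "GHA": lambda w: features.gha_features(w, 2, seed=seed),
        "PDAC": lambda w: features.pdac_feature_matrix(w),
    }
    clusterers = {
        "CL": lambda f: _train_classify_cl(f, k, seed),
        "K-means": lambda f: clustering.kmeans_train(f, k, seed=seed)[1],
        "FCM": lambda f: clustering.fcm_train(f, k, seed=seed)[1].argmax(1),
    }
    grid = pd.DataFrame(index=[*extractors, "waveform"],
                        columns=[*clusterers, "OSORT"], dtype=float)
    for fname, extract in extractors.items():
        try:
            feats = extract(wf)
        except Exception:
            continue
        for cname, cluster in clusterers.items():
            try:
                pred = cluster(feats)
                grid.loc[fname, cname] = csr(pred, true_labels).csr
            except Exception:
                pass
    try:
        _, pred = clustering.osort_train(wf, osort_threshold(wf))
        grid.loc["waveform", "OSORT"] = csr(pred, true_labels).csr
    except Exception:
        pass
    return grid
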