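"""Competitive-learning (CL) clustering plus K-means, FCM and OSORT baselines.

CL is an online winner-take-all vector quantizer.  Each channel q keeps K
centers C(p, q).  For every incoming feature vector X the winner

    k = argmin_p d(C(p, q), X)        (squared Euclidean distance)

moves a fraction eta toward X,

    C(k, q) <- C(k, q) + eta * (X - C(k, q)),

and every other center stays put.  With eta restricted to a power of two
(default 2**-5) the multiply reduces to an arithmetic right shift on
scaled integers, which this module reproduces bit-faithfully in its
``shift_mode``.  Training is a single pass over the stream; only the
winner search is needed at classification time.  An adaptive variant
grows K online: starting from K=2, a vector farther than a threshold
from every center seeds a new cluster (up to ``k_max``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Codebook",
    "TrainingConfig",
    "init_codebook",
    "find_winner",
    "update_winner",
    "cl_train",
    "cl_classify",
    "cl_classify_batch",
    "cl_train_adaptive",
    "kmeans_train",
    "fcm_train",
    "osort_train",
]

logger = logging.getLogger(__name__)

#: fixed-point scale for the shift-based (hardware-style) update path
SHIFT_SCALE_BITS = 15


@dataclass
class Codebook:
    """Per-channel cluster centers plus the learning-rate configuration.

    ``centers`` maps channel -> (K, d) array.  ``eta_exponent`` b (with
    eta = 2**-b) enables the shift-based integer update when
    ``shift_mode`` is set.  ``distance_evals`` counts every squared
    distance computed during winner competition, supporting the O(2KT)
    complexity accounting (2 multiplies per distance at d=2).
    """

    eta: float = 2.0 ** -5
    eta_exponent: int | None = 5
    shift_mode: bool = False
    centers: dict[int, np.ndarray] = field(default_factory=dict)
    update_count: dict[int, int] = field(default_factory=dict)
    distance_evals: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.eta <= 1:
            raise ValueError("eta must be in (0, 1]")
        if self.eta_exponent is not None and not np.isclose(
                self.eta, 2.0 ** -self.eta_exponent):
            raise ValueError("eta and eta_exponent are inconsistent")
        if self.shift_mode and self.eta_exponent is None:
            raise ValueError("shift_mode requires a power-of-two eta")

    def k(self, channel: int) -> int:
        return self.centers[channel].shape[0]

    @property
    def channels(self) -> list[int]:
        return sorted(self.centers)

    def copy(self) -> "Codebook":
        cb = Codebook(eta=self.eta, eta_exponent=self.eta_exponent,
                      shift_mode=self.shift_mode)
        cb.centers = {q: c.copy() for q, c in self.centers.items()}
        cb.update_count = dict(self.update_count)
        cb.distance_evals = self.distance_evals
        return cb


@dataclass(frozen=True)
class TrainingConfig:
    """CL training options; eta = 2**-eta_exponent unless ``eta`` is given."""

    k: int = 2
    eta_exponent: int = 5
    eta: float | None = None
    epochs: int = 1
    seed: int = 0
    shift_mode: bool = False
    adaptive: bool = False
    new_cluster_threshold: float | None = None
    k_max: int = 8

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.k_max < 2:
            raise ValueError("k_max must be >= 2")

    @property
    def resolved_eta(self) -> float:
        return 2.0 ** -self.eta_exponent if self.eta is None else self.eta

    @property
    def resolved_exponent(self) -> int | None:
        return self.eta_exponent if self.eta is None else None


def init_codebook(features_by_channel: dict[int, np.ndarray], k: int,
                  seed: int = 0, eta: float = 2.0 ** -5,
                  eta_exponent: int | None = 5,
                  shift_mode: bool = False) -> Codebook:
    """Initial centers: K distinct training vectors drawn per channel.

    Sampling is uniform without replacement, the standard random-selection
    initialization for CL.
    """
    rng = np.random.default_rng(seed)
    cb = Codebook(eta=eta, eta_exponent=eta_exponent, shift_mode=shift_mode)
    for q in sorted(features_by_channel):
        x = np.atleast_2d(np.asarray(features_by_channel[q], dtype=float))
        if x.shape[0] < k:
            raise ValueError(
                f"channel {q} has {x.shape[0]} vectors, fewer than K={k}"
            )
        idx = rng.choice(x.shape[0], size=k, replace=False)
        cb.centers[q] = x[idx].copy()
        cb.update_count[q] = 0
    return cb


def _squared_distances(centers: np.ndarray, x: np.ndarray) -> np.ndarray:
    return ((centers - x) ** 2).sum(axis=1)


def find_winner(codebook: Codebook, channel: int, x: np.ndarray
                ) -> tuple[int, float]:
    """Index and squared distance of the nearest center (ties: smallest p).

    Increments the codebook's distance-evaluation counter by K.
    """
    x = np.asarray(x, dtype=float)
    centers = codebook.centers[channel]
    if x.shape != centers.shape[1:]:
        raise ValueError(
            f"feature dimension {x.shape} does not match centers "
            f"{centers.shape[1:]}"
        )
    d = _squared_distances(centers, x)
    codebook.distance_evals += len(d)
    k = int(np.argmin(d))  # argmin returns the first minimum: smallest p
    return k, float(d[k])


def _shift_update(center: np.ndarray, x: np.ndarray, exponent: int
                  ) -> np.ndarray:
    """Winner update via arithmetic right shift on 2**15-scaled integers.

    Matches the float update exactly whenever the scaled difference is
    divisible by 2**exponent, and within one LSB (2**-15) otherwise.
    """
    scale = 1 << SHIFT_SCALE_BITS
    c_i = np.round(center * scale).astype(np.int64)
    x_i = np.round(x * scale).astype(np.int64)
    delta = (x_i - c_i) >> exponent  # arithmetic shift: floors toward -inf
    return (c_i + delta) / scale


def update_winner(codebook: Codebook, channel: int, k: int, x: np.ndarray
                  ) -> np.ndarray:
    """Move the winning center toward x by eta; all other centers unchanged."""
    x = np.asarray(x, dtype=float)
    centers = codebook.centers[channel]
    if not 0 <= k < centers.shape[0]:
        raise ValueError(f"cluster index {k} out of range")
    if codebook.shift_mode:
        centers[k] = _shift_update(centers[k], x, codebook.eta_exponent)
    else:
        centers[k] = centers[k] + codebook.eta * (x - centers[k])
    codebook.update_count[channel] = codebook.update_count.get(channel, 0) + 1
    return centers[k].copy()


def _as_stream(features) -> dict[int, np.ndarray]:
    if isinstance(features, dict):
        return {q: np.atleast_2d(np.asarray(v, dtype=float))
                for q, v in features.items()}
    return {0: np.atleast_2d(np.asarray(features, dtype=float))}


def cl_train(features_stream, codebook: Codebook,
             config: TrainingConfig | None = None) -> Codebook:
    """Sequential winner-find + winner-update over the training stream.

    ``features_stream`` is either an (n, d) array (single channel 0) or a
    dict channel -> (n, d) array.  One pass per epoch, in stream order.
    The codebook is updated in place and returned.
    """
    config = config or TrainingConfig()
    stream = _as_stream(features_stream)
    for q, x in stream.items():
        if q not in codebook.centers:
            raise ValueError(f"codebook has no centers for channel {q}")
        if x.shape[0] == 0:
            raise ValueError(f"empty training stream for channel {q}")
        for _ in range(config.epochs):
            for xi in x:
                k, _ = find_winner(codebook, q, xi)
                update_winner(codebook, q, k, xi)
    return codebook


def cl_classify(codebook: Codebook, channel: int, x: np.ndarray) -> int:
    """Label of the nearest center; never mutates the codebook."""
    x = np.asarray(x, dtype=float)
    return int(np.argmin(_squared_distances(codebook.centers[channel], x)))


def cl_classify_batch(codebook: Codebook, channel: int, x: np.ndarray
                      ) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    centers = codebook.centers[channel]
    d = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return d.argmin(axis=1)


def _adaptive_threshold(x: np.ndarray, codebook: Codebook, channel: int,
                        n_probe: int = 50) -> float:
    """Heuristic: 9x the median winning distance over the first vectors."""
    probe = x[:n_probe]
    d = [min(_squared_distances(codebook.centers[channel], xi))
         for xi in probe]
    return 9.0 * float(np.median(d))


def cl_train_adaptive(features_stream, config: TrainingConfig | None = None
                      ) -> Codebook:
    """CL training with online cluster creation (OSORT-like K growth).

    Starts from K=2 centers randomly selected per channel.  When the
    winning squared distance exceeds ``new_cluster_threshold`` and the
    channel still has fewer than ``k_max`` clusters, the current vector
    is appended as a new center; otherwise the standard winner update
    applies.  Attempts beyond ``k_max`` are logged and ignored.
    """
    config = config or TrainingConfig(adaptive=True)
    stream = _as_stream(features_stream)
    codebook = init_codebook(stream, k=2, seed=config.seed,
                             eta=config.resolved_eta,
                             eta_exponent=config.resolved_exponent,
                             shift_mode=config.shift_mode)
    for q, x in stream.items():
        threshold = config.new_cluster_threshold
        if threshold is None:
            threshold = _adaptive_threshold(x, codebook, q)
        if threshold <= 0 and config.new_cluster_threshold is not None:
            if config.new_cluster_threshold < 0:
                raise ValueError("new_cluster_threshold must be > 0")
        for _ in range(config.epochs):
            for xi in x:
                k, dist = find_winner(codebook, q, xi)
                if dist > threshold:
                    if codebook.k(q) < config.k_max:
                        codebook.centers[q] = np.vstack(
                            [codebook.centers[q], xi])
                        continue
                    logger.debug(
                        "channel %d: cluster creation suppressed at "
                        "k_max=%d", q, config.k_max)
                update_winner(codebook, q, k, xi)
    return codebook


# ---------------------------------------------------------------------------
# Batch baselines
# ---------------------------------------------------------------------------

def kmeans_train(features: np.ndarray, k: int, max_iter: int = 100,
                 seed: int = 0) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Batch Lloyd iterations until the assignment fixpoint or max_iter.

    Initial centers are drawn from the data without replacement.  Returns
    (centers, labels, per-iteration within-cluster SSE history); the SSE
    is non-increasing by construction of the Lloyd steps.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[0] < k:
        raise ValueError("fewer data points than clusters")
    rng = np.random.default_rng(seed)
    centers = x[rng.choice(x.shape[0], size=k, replace=False)].copy()
    labels = np.full(x.shape[0], -1)
    sse_history: list[float] = []
    for _ in range(max_iter):
        d = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = d.argmin(axis=1)
        sse_history.append(float(d[np.arange(len(x)), new_labels].sum()))
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for p in range(k):
            mask = labels == p
            if mask.any():
                centers[p] = x[mask].mean(axis=0)
    return centers, labels, sse_history


def fcm_train(features: np.ndarray, k: int, fuzzifier: float = 2.0,
              max_iter: int = 100, tol: float = 1e-5, seed: int = 0
              ) -> tuple[np.ndarray, np.ndarray]:
    """Fuzzy C-means: alternating membership / center updates.

    Memberships u_ip are row-normalized to 1; centers are the
    membership**fuzzifier weighted means.  Stops when the maximum
    membership change drops below ``tol``.
    """
    if fuzzifier <= 1:
        raise ValueError("fuzzifier must be > 1")
    x = np.atleast_2d(np.asarray(features, dtype=float))
    rng = np.random.default_rng(seed)
    u = rng.dirichlet(np.ones(k), size=x.shape[0])
    power = 2.0 / (fuzzifier - 1.0)
    centers = np.empty((k, x.shape[1]))
    for _ in range(max_iter):
        um = u ** fuzzifier
        centers = (um.T @ x) / um.sum(axis=0)[:, None]
        d = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        d = np.maximum(d, 1e-300)
        inv = d ** (-power / 2.0)
        new_u = inv / inv.sum(axis=1, keepdims=True)
        # points exactly on a center get a crisp membership
        exact = d < 1e-200
        if exact.any():
            rows = exact.any(axis=1)
            new_u[rows] = exact[rows] / exact[rows].sum(axis=1, keepdims=True)
        if np.max(np.abs(new_u - u)) < tol:
            u = new_u
            break
        u = new_u
    return centers, u


def osort_train(waveforms: np.ndarray, merge_threshold: float
                ) -> tuple[np.ndarray, np.ndarray]:
    """Simplified OSORT on full m-sample waveforms (no feature reduction).

    Each waveform joins the nearest running cluster mean if its squared
    distance is below ``merge_threshold``, else it seeds a new cluster;
    after every assignment, cluster means closer than the threshold are
    merged.  Returns the final means and per-waveform labels (labels of
    merged clusters are remapped to the surviving cluster).
    """
    if merge_threshold <= 0:
        raise ValueError("merge_threshold must be > 0")
    x = np.atleast_2d(np.asarray(waveforms, dtype=float))
    means: list[np.ndarray] = []
    counts: list[int] = []
    ids: list[int] = []
    alias: dict[int, int] = {}  # merged cluster id -> absorbing id
    labels = np.zeros(x.shape[0], dtype=int)
    next_id = 0
    for i, xi in enumerate(x):
        if means:
            d = np.array([((mu - xi) ** 2).sum() for mu in means])
            j = int(d.argmin())
        if not means or d[j] > merge_threshold:
            means.append(xi.copy())
            counts.append(1)
            ids.append(next_id)
            labels[i] = next_id
            next_id += 1
            continue
        counts[j] += 1
        means[j] = means[j] + (xi - means[j]) / counts[j]
        labels[i] = ids[j]
        # absorb any cluster whose mean drifted within the threshold
        for a in range(len(means) - 1, -1, -1):
            if a == j:
                continue
            if ((means[a] - means[j]) ** 2).sum() <= merge_threshold:
                tot = counts[a] + counts[j]
                means[j] = (counts[a] * means[a] + counts[j] * means[j]) / tot
                counts[j] = tot
                alias[ids[a]] = ids[j]
                del means[a], counts[a], ids[a]
                if a < j:
                    j -= 1

    def resolve(c: int) -> int:
        while c in alias:
            c = alias[c]
        return c

    final = [resolve(int(c)) for c in labels]
    remap: dict[int, int] = {}
    out = np.empty(len(final), dtype=int)
    for i, c in enumerate(final):
        out[i] = remap.setdefault(c, len(remap))
    mean_arr = np.vstack(means) if means else np.empty((0, x.shape[1]))
    return mean_arr, out
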