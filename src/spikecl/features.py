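"""Feature extraction: PDAC (main path) plus PCA and GHA baselines.

PDAC (peak detection with area computation) reduces an m-sample spike
x = [x_1, ..., x_m] to two numbers.  With imin/imax the arg-extrema of x,

    a1 = sum_{i <= imin} (x_i - x_imin)      (area left of the minimum)
    a2 = sum_{i >  imin} (x_i - x_imin)      (area right of the minimum)
    f_i = a_i / (imin - imax),  i = 1, 2

The two areas partition the total area of x above its minimum, and the
denominator is the (signed) trough-to-peak index distance, so a taller,
faster spike yields larger-|f| features.  The signed denominator follows
the printed formula; clustering is indifferent to the global sign, and an
``abs_denominator`` switch is provided for the unsigned variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

__all__ = [
    "DegenerateWaveformError",
    "PDACIntermediate",
    "pdac_intermediate",
    "pdac_features",
    "pdac_feature_matrix",
    "pca_features",
    "gha_fit",
    "gha_features",
]


class DegenerateWaveformError(ValueError):
    """Raised when imin == imax (constant waveform): Eq. denominator is 0."""


@dataclass(frozen=True)
class PDACIntermediate:
    imin: int
    imax: int
    a1: float
    a2: float


def pdac_intermediate(waveform: np.ndarray) -> PDACIntermediate:
    """Arg-extrema and the two areas above the minimum, split at imin.

    Ties in the extrema are broken by first occurrence (matching a
    sequential hardware scan); indices are 0-based.  The hardware insight
    mirrored here is that the running min/max search and the area
    accumulation need only a single pass over the samples.
    """
    x = np.asarray(waveform, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("waveform must be 1-D with at least 2 samples")
    imin = int(np.argmin(x))
    imax = int(np.argmax(x))
    xmin = x[imin]
    a1 = float(np.sum(x[:imin + 1] - xmin))
    a2 = float(np.sum(x[imin + 1:] - xmin))
    return PDACIntermediate(imin=imin, imax=imax, a1=a1, a2=a2)


def pdac_features(waveform: np.ndarray,
                  abs_denominator: bool = False) -> np.ndarray:
    """The 2-D PDAC feature vector [f1, f2] = [a1, a2] / (imin - imax)."""
    inter = pdac_intermediate(waveform)
    if inter.imin == inter.imax:
        raise DegenerateWaveformError(
            "waveform minimum and maximum coincide (constant input); "
            "the PDAC denominator imin - imax is zero"
        )
    denom = inter.imin - inter.imax
    if abs_denominator:
        denom = abs(denom)
    return np.array([inter.a1 / denom, inter.a2 / denom])


def pdac_feature_matrix(waveforms: np.ndarray,
                        abs_denominator: bool = False) -> np.ndarray:
    """Row-wise PDAC features for an (n_spikes, m) waveform matrix."""
    return np.vstack([pdac_features(w, abs_denominator=abs_denominator)
                      for w in np.atleast_2d(waveforms)])


# ---------------------------------------------------------------------------
# PCA baseline
# ---------------------------------------------------------------------------

def pca_features(waveform_matrix: np.ndarray,
                 n_components: int = 2) -> np.ndarray:
    """Mean-centered projections onto the top principal axes."""
    x = np.atleast_2d(np.asarray(waveform_matrix, dtype=float))
    if x.shape[0] < n_components:
        raise ValueError("need at least n_components waveforms")
    rank = np.linalg.matrix_rank(x)
    if rank < n_components:
        raise ValueError(
            f"data rank {rank} is below n_components={n_components}"
        )
    return PCA(n_components=n_components, svd_solver="full").fit_transform(x)


# ---------------------------------------------------------------------------
# GHA baseline (Sanger's rule)
# ---------------------------------------------------------------------------

def gha_fit(waveform_matrix: np.ndarray, n_components: int = 2,
            lr: float = 1e-3, epochs: int = 20, seed: int = 0) -> np.ndarray:
    """Streaming estimation of the leading principal axes by Sanger's rule.

    Weight update per sample x (y = W x):

        W <- W + lr_e * (y x^T - LT(y y^T) W)

    with LT the lower-triangular part and lr_e = lr / (1 + epoch).
    Returns the (n_components, m) weight matrix, rows approximately
    orthonormal and aligned with the PCA axes up to sign.
    """
    if lr < 0:
        raise ValueError("lr must be >= 0")
    x = np.atleast_2d(np.asarray(waveform_matrix, dtype=float))
    mean = x.mean(axis=0)
    xc = x - mean
    rng = np.random.default_rng(seed)
    w = rng.normal(0.0, 0.1, size=(n_components, x.shape[1]))
    for epoch in range(epochs):
        lr_e = lr / (1.0 + epoch)
        for xi in xc:
            y = w @ xi
            w += lr_e * (np.outer(y, xi) - np.tril(np.outer(y, y)) @ w)
            if np.linalg.norm(w) > 1e3:
                raise FloatingPointError(
                    "GHA weights diverged; use a smaller lr"
                )
    return w


def gha_features(waveform_matrix: np.ndarray, n_components: int = 2,
                 lr: float = 1e-3, epochs: int = 20,
                 seed: int = 0) -> np.ndarray:
    """Projections of mean-centered waveforms onto the GHA weight vectors."""
    x = np.atleast_2d(np.asarray(waveform_matrix, dtype=float))
    w = gha_fit(x, n_components=n_components, lr=lr, epochs=epochs, seed=seed)
    return (x - x.mean(axis=0)) @ w.T
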