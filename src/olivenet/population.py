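"""Population metrics: zero-lag synchrony and PCA dimensionality.

Synchrony of two neurons is the correlation coefficient of their 10-ms
binarized spike trains at zero lag,

    C_xy = sum X~(i) Y~(i) / sqrt(sum X~(i)^2 * sum Y~(i)^2),

with X~ the mean-subtracted binary train.  Dimensionality is the
participation ratio of the eigenvalue spectrum of the covariance of
per-neuron firing rates sampled in sliding windows,

    d = 1 / sum_i lam~_i^2,   lam~_i = lam_i / sum_j lam_j,

ranging from 1 (all variance in one component, fully co-modulated ensemble)
to N (isotropic spectrum).  The normalized value d/N compensates for the
ensemble-size dependence of the raw estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dataset import SpikeDataset

__all__ = [
    "BinnedTrains",
    "bin_trains",
    "pairwise_synchrony",
    "neuron_synchrony",
    "dataset_synchrony",
    "participation_ratio",
    "dimensionality",
    "sliding_sync_dim",
]


@dataclass
class BinnedTrains:
    """Binary spike matrix: 1 if the neuron fired at least once in the bin."""

    matrix: np.ndarray           # (n_neurons, n_bins) of 0/1
    bin_width: float             # s
    neuron_ids: list[int]

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]


def bin_trains(dataset: SpikeDataset, bin_width: float = 0.01) -> BinnedTrains:
    """Binarize at ``bin_width`` seconds (multiple spikes per bin clip to 1)."""
    n_bins = int(np.floor(dataset.duration / bin_width))
    ids = dataset.neuron_ids
    X = np.zeros((len(ids), n_bins), dtype=np.int8)
    for row, nid in enumerate(ids):
        idx = (dataset.trains[nid] / bin_width).astype(int)
        idx = idx[idx < n_bins]
        X[row, idx] = 1
    return BinnedTrains(X, bin_width, ids)


def pairwise_synchrony(x: np.ndarray, y: np.ndarray) -> float:
    """Zero-lag correlation coefficient of two binary trains.

    Returns the NaN sentinel (with a warning) if either train has zero
    variance (empty or saturated).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("trains must have equal length")
    xm = x - x.mean()
    ym = y - y.mean()
    den = np.sqrt((xm ** 2).sum() * (ym ** 2).sum())
    if den == 0:
        warnings.warn("zero-variance train in synchrony computation")
        return np.nan
    return float((xm * ym).sum() / den)


def neuron_synchrony(dataset: SpikeDataset, neuron: int,
                     bin_width: float = 0.01) -> float:
    """Mean pairwise synchrony of one neuron with all others in the ensemble."""
    if dataset.n_neurons < 2:
        raise ValueError("need at least 2 neurons")
    bt = bin_trains(dataset, bin_width)
    row = bt.neuron_ids.index(neuron)
    vals = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j in range(len(bt.neuron_ids)):
            if j == row:
                continue
            vals.append(pairwise_synchrony(bt.matrix[row], bt.matrix[j]))
    vals = [v for v in vals if np.isfinite(v)]
    return float(np.mean(vals)) if vals else np.nan


def dataset_synchrony(dataset: SpikeDataset, bin_width: float = 0.01) -> float:
    """Mean synchrony over all neuron pairs (sentinel pairs skipped)."""
    bt = bin_trains(dataset, bin_width)
    n = len(bt.neuron_ids)
    if n < 2:
        raise ValueError("need at least 2 neurons")
    vals = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for a in range(n):
            for b in range(a + 1, n):
                v = pairwise_synchrony(bt.matrix[a], bt.matrix[b])
                if np.isfinite(v):
                    vals.append(v)
    return float(np.mean(vals)) if vals else np.nan


def participation_ratio(eigenvalues: np.ndarray) -> float:
    """d = 1 / sum(lam~^2) with lam~ the eigenvalue shares."""
    lam = np.asarray(eigenvalues, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0:
        return np.nan
    shares = lam / lam.sum()
    return float(1.0 / (shares ** 2).sum())


def _rate_windows(dataset: SpikeDataset, window: float, step: float) -> np.ndarray:
    """Per-neuron mean rates in sliding windows (observations x neurons)."""
    bin_w = min(step, 0.01)
    bt = bin_trains(dataset, bin_w)
    counts = np.cumsum(bt.matrix, axis=1)
    w = int(round(window / bin_w))
    s = max(int(round(step / bin_w)), 1)
    n_bins = counts.shape[1]
    if n_bins <= w:
        raise ValueError("duration must exceed the window length")
    starts = np.arange(0, n_bins - w, s)
    obs = (counts[:, starts + w] - counts[:, starts]) / window
    return obs.T  # (n_windows, n_neurons)


def dimensionality(
    dataset: SpikeDataset, window: float = 50.0, step: float = 0.01,
    normalized: bool = False,
) -> float:
    """Participation-ratio dimensionality of population rate covariance.

    Rates are sampled in ``window``-second windows slid by ``step`` seconds
    (heavily overlapping by default); d is the participation ratio of the
    covariance eigenvalues, in [1, N].  With ``normalized=True`` the value is
    divided by the number of neurons.
    """
    if dataset.n_neurons < 2:
        raise ValueError("need at least 2 neurons")
    obs = _rate_windows(dataset, window, step)
    cov = np.cov(obs.T)
    if not np.any(np.diag(cov) > 0):
        warnings.warn("zero-variance covariance; dimensionality undefined")
        return np.nan
    lam = np.linalg.eigvalsh(cov)
    d = participation_ratio(lam)
    return d / dataset.n_neurons if normalized else d


def sliding_sync_dim(
    dataset: SpikeDataset, window: float = 10.0, step: float = 1.0,
    bin_width: float = 0.01,
) -> dict:
    """Time-resolved synchrony and dimensionality in a moving window.

    Within each window both metrics use the 10-ms timescale: synchrony is the
    pair-averaged zero-lag correlation, and d is the participation ratio of
    the covariance of the 10-ms binned trains.  Windows containing silent
    neurons yield sentinel entries, excluded from the reported correlation.

    Returns dict with 'starts', 'synchrony', 'dimensionality', 'correlation'.
    """
    if dataset.duration <= window:
        raise ValueError("duration must exceed the window")
    starts = np.arange(0.0, dataset.duration - window + 1e-9, step)
    sync = np.full(starts.size, np.nan)
    dim = np.full(starts.size, np.nan)
    for i, t0 in enumerate(starts):
        sub = dataset.window(t0, t0 + window)
        bt = bin_trains(sub, bin_width)
        if (bt.matrix.sum(axis=1) == 0).any():
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sync[i] = dataset_synchrony(sub, bin_width)
        cov = np.cov(bt.matrix.astype(float))
        lam = np.linalg.eigvalsh(cov)
        dim[i] = participation_ratio(lam)
    ok = np.isfinite(sync) & np.isfinite(dim)
    corr = float(np.corrcoef(sync[ok], dim[ok])[0, 1]) if ok.sum() >= 3 else np.nan
    return {"starts": starts, "synchrony": sync, "dimensionality": dim,
            "correlation": corr}
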