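"""Spatiotemporal spike-train features and the PCA embedding used for
simulator-backed inference.

The default feature vector has 67 entries per neuron:

====================  ====  ==========================================
block                 size  definition
====================  ====  ==========================================
firing rate              1  spikes/s over the segment
local variation          1  LV of consecutive inter-spike intervals
auto-correlogram        25  50-ms bins, lags 0-1.25 s, P(partner spike)
cross-correlogram       20  10-ms bins, lags -100..100 ms, pair-averaged
minimal distance        20  50-ms bins of the nearest-partner-spike
                            distance distribution, pair-averaged
====================  ====  ==========================================

Correlogram bins hold the probability that another spike (auto) or a spike of
the partner neuron (cross) falls in the lag bin, given a reference spike; the
same estimator is applied to simulated and recorded data.  The library of
feature vectors over the (g_i, g_c) conductance grid is summarized by the top
three principal components of the z-scored features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dataset import SpikeDataset

__all__ = [
    "FeatureSpec",
    "FeatureLibrary",
    "local_variation",
    "correlogram",
    "minimal_distance_distribution",
    "extract_feature_vector",
    "extract_feature_matrix",
    "fit_feature_pca",
    "FeaturePCA",
]

#: sentinel for features undefined on degenerate (near-silent) trains
SENTINEL = np.nan


@dataclass
class FeatureSpec:
    """Composition of the feature vector (sizes must total ``length``)."""

    acg_bin: float = 0.05        # s
    acg_n: int = 25
    ccg_bin: float = 0.01        # s
    ccg_n: int = 20              # total bins covering +-100 ms
    md_bin: float = 0.05         # s
    md_n: int = 20

    def __post_init__(self) -> None:
        for name in ("acg_bin", "ccg_bin", "md_bin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def length(self) -> int:
        return 2 + self.acg_n + self.ccg_n + self.md_n


def local_variation(train: np.ndarray) -> float:
    """Local variation of inter-spike intervals.

    LV = (1/(n-1)) * sum 3 (I_k - I_{k+1})^2 / (I_k + I_{k+1})^2 over
    consecutive ISI pairs; 0 for regular trains, ~1 for Poisson.  Returns the
    NaN sentinel for trains with fewer than 3 spikes.
    """
    t = np.asarray(train, dtype=float)
    if t.size < 3:
        return SENTINEL
    isi = np.diff(t)
    a, b = isi[:-1], isi[1:]
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = 3.0 * (a - b) ** 2 / (a + b) ** 2
    terms = terms[np.isfinite(terms)]
    if terms.size == 0:
        return SENTINEL
    return float(terms.mean())


def correlogram(
    train_a: np.ndarray,
    train_b: np.ndarray | None = None,
    bin_width: float = 0.05,
    max_lag: float = 1.25,
    mode: str = "auto",
    start_lag: float = 0.0,
) -> np.ndarray:
    """Spike-count correlogram normalized per reference spike.

    mode='auto': histogram of forward lags t_j - t_i > 0 of a train against
    itself (zero-lag self pairs excluded), bins [start_lag, max_lag).
    mode='cross': histogram of all lags t_b - t_a in [-max_lag, max_lag).
    Counts are divided by the number of reference spikes, yielding the
    probability of a (partner) spike in each lag bin.
    """
    a = np.asarray(train_a, dtype=float)
    if mode == "auto":
        b = a
    elif mode == "cross":
        if train_b is None:
            raise ValueError("cross mode requires train_b")
        b = np.asarray(train_b, dtype=float)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    nbins = int(round((max_lag - start_lag) / bin_width)) if mode == "auto" \
        else int(round(2 * max_lag / bin_width))
    if a.size == 0 or b.size == 0:
        warnings.warn("correlogram of an empty train is all-zero")
        return np.zeros(nbins)
    if mode == "auto":
        edges = start_lag + bin_width * np.arange(nbins + 1)
        lags = []
        # forward lags only; the max_lag break keeps this O(n * k)
        for i, ti in enumerate(a):
            for tj in a[i + 1:]:
                d = tj - ti
                if d >= max_lag:
                    break
                lags.append(d)
        h, _ = np.histogram(lags, bins=edges)
    else:
        edges = -max_lag + bin_width * np.arange(nbins + 1)
        lags = []
        lo = 0
        for ti in a:
            while lo < b.size and b[lo] < ti - max_lag:
                lo += 1
            j = lo
            while j < b.size and b[j] < ti + max_lag:
                lags.append(b[j] - ti)
                j += 1
        h, _ = np.histogram(lags, bins=edges)
    return h / a.size


def minimal_distance_distribution(
    train_a: np.ndarray, train_b: np.ndarray,
    bin_width: float = 0.05, n_bins: int = 20,
) -> np.ndarray:
    """Histogram fractions of the nearest-partner-spike distance.

    For every spike of ``train_a`` the minimum |dt| to any spike of
    ``train_b`` is computed and histogrammed in ``n_bins`` bins of
    ``bin_width`` seconds (last bin absorbs the overflow); fractions sum to 1.
    Returns the sentinel vector if either train is empty.
    """
    a = np.asarray(train_a, dtype=float)
    b = np.asarray(train_b, dtype=float)
    if a.size == 0 or b.size == 0:
        return np.full(n_bins, SENTINEL)
    idx = np.searchsorted(b, a)
    left = np.clip(idx - 1, 0, b.size - 1)
    right = np.clip(idx, 0, b.size - 1)
    d = np.minimum(np.abs(a - b[left]), np.abs(a - b[right]))
    binned = np.minimum((d / bin_width).astype(int), n_bins - 1)
    h = np.bincount(binned, minlength=n_bins).astype(float)
    return h / h.sum()


def extract_feature_vector(
    dataset: SpikeDataset, neuron: int, spec: FeatureSpec | None = None,
) -> np.ndarray:
    """Feature vector of one neuron within its ensemble.

    Cross-correlogram and minimal-distance blocks are averaged over all
    partner neurons.  Undefined entries carry the NaN sentinel (imputed with
    the library median before PCA).
    """
    spec = spec or FeatureSpec()
    if neuron not in dataset.trains:
        raise KeyError(f"neuron {neuron} not in dataset")
    t = dataset.trains[neuron]
    partners = [i for i in dataset.neuron_ids if i != neuron]
    rate = len(t) / dataset.duration
    lv = local_variation(t)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        acg = correlogram(t, bin_width=spec.acg_bin,
                          max_lag=spec.acg_n * spec.acg_bin, mode="auto")
        ccgs, mds = [], []
        for p in partners:
            tp = dataset.trains[p]
            if t.size and tp.size:
                ccgs.append(correlogram(t, tp, bin_width=spec.ccg_bin,
                                        max_lag=spec.ccg_n * spec.ccg_bin / 2,
                                        mode="cross"))
                mds.append(minimal_distance_distribution(
                    t, tp, bin_width=spec.md_bin, n_bins=spec.md_n))
    ccg = np.mean(ccgs, axis=0) if ccgs else np.full(spec.ccg_n, SENTINEL)
    md = np.mean(mds, axis=0) if mds else np.full(spec.md_n, SENTINEL)
    vec = np.concatenate([[rate, lv], acg, ccg, md])
    assert vec.size == spec.length
    return vec


def extract_feature_matrix(dataset: SpikeDataset, spec: FeatureSpec | None = None) -> np.ndarray:
    """(n_neurons, n_features) matrix, rows ordered by neuron id."""
    spec = spec or FeatureSpec()
    return np.vstack([extract_feature_vector(dataset, i, spec)
                      for i in dataset.neuron_ids])


@dataclass
class FeaturePCA:
    """Z-scored PCA basis retaining the top components of a feature library."""

    mean: np.ndarray
    scale: np.ndarray
    components: np.ndarray       # (k, n_features)
    explained_variance_ratio: np.ndarray
    impute: np.ndarray           # library medians for sentinel imputation

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def project(self, vec: np.ndarray) -> np.ndarray:
        v = np.asarray(vec, dtype=float)
        one = v.ndim == 1
        v = np.atleast_2d(v).copy()
        nanmask = ~np.isfinite(v)
        if nanmask.any():
            v[nanmask] = np.broadcast_to(self.impute, v.shape)[nanmask]
        z = (v - self.mean) / self.scale
        out = z @ self.components.T
        return out[0] if one else out


def fit_feature_pca(vectors: np.ndarray, n_components: int = 3) -> FeaturePCA:
    """Fit the z-scored PCA of a library of feature vectors.

    Sentinel (NaN) entries are imputed with the per-feature median.
    Components are ordered by decreasing eigenvalue; if the library is
    rank-deficient only the available components are retained (with warning).
    """
    from sklearn.decomposition import PCA

    X = np.asarray(vectors, dtype=float)
    if X.shape[0] < n_components:
        raise ValueError("need at least as many library vectors as components")
    impute = np.nanmedian(X, axis=0)
    impute = np.where(np.isfinite(impute), impute, 0.0)
    X = X.copy()
    mask = ~np.isfinite(X)
    X[mask] = np.broadcast_to(impute, X.shape)[mask]
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - mean) / scale
    rank = np.linalg.matrix_rank(Z)
    k = min(n_components, rank)
    if k < n_components:
        warnings.warn(f"library rank {rank} < {n_components}; retaining {k}")
    p = PCA(n_components=k, svd_solver="full").fit(Z)
    return FeaturePCA(mean=mean, scale=scale, components=p.components_,
                      explained_variance_ratio=p.explained_variance_ratio_,
                      impute=impute)


def pca_error(pca: FeaturePCA, vec_a: np.ndarray, vec_b: np.ndarray) -> float:
    """Euclidean distance between two vectors in the retained PCA space."""
    return float(np.linalg.norm(pca.project(vec_a) - pca.project(vec_b)))


@dataclass
class FeatureLibrary:
    """Grid of (g_i, g_c, noise rate) -> feature vectors with a PCA basis."""

    coords: np.ndarray           # (n_points, 3): g_i, g_c, noise rate
    vectors: np.ndarray          # (n_points, n_features)
    spec: FeatureSpec
    g_i_axis: np.ndarray
    g_c_axis: np.ndarray
    noise_rate: float
    pca: FeaturePCA | None = None
    projections: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.coords.shape[0] != self.vectors.shape[0]:
            raise ValueError("coords/vectors length mismatch")

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    def fit_pca(self, n_components: int = 3) -> "FeatureLibrary":
        self.pca = fit_feature_pca(self.vectors, n_components)
        self.projections = self.pca.project(self.vectors)
        return self

    def grid_shape(self) -> tuple[int, int]:
        return len(self.g_i_axis), len(self.g_c_axis)

    def projection_grid(self) -> np.ndarray:
        """Projections reshaped to (n_g_i, n_g_c, k); row-major in (g_i, g_c)."""
        if self.projections is None:
            raise RuntimeError("call fit_pca() first")
        ni, nc = self.grid_shape()
        return self.projections.reshape(ni, nc, -1)

    # ---- persistence ---------------------------------------------------
    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f["coords"] = self.coords
            f["vectors"] = self.vectors
            f["g_i_axis"] = self.g_i_axis
            f["g_c_axis"] = self.g_c_axis
            f.attrs["noise_rate"] = self.noise_rate
            for name in ("acg_bin", "acg_n", "ccg_bin", "ccg_n", "md_bin", "md_n"):
                f.attrs[name] = getattr(self.spec, name)
            if self.pca is not None:
                g = f.create_group("pca")
                g["mean"] = self.pca.mean
                g["scale"] = self.pca.scale
                g["components"] = self.pca.components
                g["explained_variance_ratio"] = self.pca.explained_variance_ratio
                g["impute"] = self.pca.impute

    @classmethod
    def load(cls, path) -> "FeatureLibrary":
        import h5py

        with h5py.File(path, "r") as f:
            spec = FeatureSpec(
                acg_bin=float(f.attrs["acg_bin"]), acg_n=int(f.attrs["acg_n"]),
                ccg_bin=float(f.attrs["ccg_bin"]), ccg_n=int(f.attrs["ccg_n"]),
                md_bin=float(f.attrs["md_bin"]), md_n=int(f.attrs["md_n"]))
            lib = cls(coords=f["coords"][...], vectors=f["vectors"][...],
                      spec=spec, g_i_axis=f["g_i_axis"][...],
                      g_c_axis=f["g_c_axis"][...],
                      noise_rate=float(f.attrs["noise_rate"]))
            if "pca" in f:
                g = f["pca"]
                lib.pca = FeaturePCA(
                    mean=g["mean"][...], scale=g["scale"][...],
                    components=g["components"][...],
                    explained_variance_ratio=g["explained_variance_ratio"][...],
                    impute=g["impute"][...])
                lib.projections = lib.pca.project(lib.vectors)
        return lib
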