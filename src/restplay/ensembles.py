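"""Resting-state ensemble detection and cue/trajectory classification.

Synchronously co-activating groups of neurons are found by average-
linkage agglomerative clustering of the distance matrix d = 1 - r,
where r is the Pearson correlation of Gaussian-smoothed (sigma =
200 ms), z-scored rest traces with movement epochs removed.  The
dendrogram is cut at d = 0.75 (average within-cluster correlation
0.25) and clusters with fewer than 5 members are dropped.

Classification scans the normalized tuning curves of an ensemble's
spatially-selective members for contiguous supra-0.5 spatial segments
(circularly wrapped across the reward line).  An ensemble carrying a
segment shorter than 30 cm that spans a cue centre is a *cue* ensemble;
one that still carries any segment is a *trajectory* ensemble; the rest
are unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import minimize
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom
from sklearn.base import BaseEstimator, ClusterMixin

from .spatial import SpatialCellResult, TuningCurve

__all__ = [
    "DistanceMatrix", "Ensemble", "EncodingBias",
    "correlation_to_distance", "correlation_distance", "detect_ensembles",
    "extract_trajectory_segments", "segment_length_cm",
    "classify_ensemble", "label_ensembles",
    "encoding_bias", "hypergeometric_enrichment", "EnsembleDetector",
]


@dataclass
class DistanceMatrix:
    d: np.ndarray            # n x n, d = 1 - r
    valid: np.ndarray        # neurons with defined (non-constant) traces

    @property
    def n(self) -> int:
        return self.d.shape[0]


@dataclass
class Ensemble:
    members: list            # neuron indices, sorted
    label: str = "none"      # cue | trajectory | none
    segments: list = field(default_factory=list)  # (start_cm, end_cm, wrapped)
    block: str = ""

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class EncodingBias:
    ll_place: float
    ll_cue: float

    @property
    def ratio(self) -> float:
        """Positive favours the cue-rate model, negative the Gaussian
        place model."""
        return self.ll_cue - self.ll_place


def correlation_to_distance(r):
    """The clustering metric d = 1 - r (r = 0.25 maps to the 0.75
    dendrogram cut-off, i.e. an average within-cluster correlation of
    0.25)."""
    return 1.0 - np.asarray(r, dtype=float)


def smooth_traces(activity: np.ndarray, sigma_ms: float = 200.0,
                  frame_rate_hz: float = 19.0) -> np.ndarray:
    """Gaussian temporal smoothing of frames x neurons activity."""
    sigma_frames = sigma_ms / 1000.0 * frame_rate_hz
    return gaussian_filter1d(np.asarray(activity, float), sigma_frames, axis=0)


def correlation_distance(rest_activity: np.ndarray,
                         movement_mask: np.ndarray | None = None,
                         sigma_ms: float = 200.0,
                         frame_rate_hz: float = 19.0) -> DistanceMatrix:
    """Pairwise distance d = 1 - Pearson r of smoothed, z-scored traces."""
    X = np.asarray(rest_activity, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a frames x neurons matrix with >= 2 neurons")
    X = smooth_traces(X, sigma_ms, frame_rate_hz)
    if movement_mask is not None:
        X = X[~np.asarray(movement_mask, bool)]
    sd = X.std(axis=0)
    valid = sd > 0
    n = X.shape[1]
    d = np.ones((n, n))
    if valid.sum() >= 2:
        r = np.corrcoef(X[:, valid], rowvar=False)
        sub = 1.0 - r
        d[np.ix_(valid, valid)] = sub
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d=d, valid=valid)


def detect_ensembles(dm: DistanceMatrix, cutoff: float = 0.75,
                     min_size: int = 5, block: str = "") -> list[Ensemble]:
    """Average-linkage clustering cut at ``cutoff``; small clusters dropped."""
    ids = np.where(dm.valid)[0]
    if len(ids) < min_size:
        return []
    sub = dm.d[np.ix_(ids, ids)]
    sub = (sub + sub.T) / 2.0
    np.fill_diagonal(sub, 0.0)
    Z = linkage(squareform(sub, checks=False), method="average")
    labels = fcluster(Z, t=cutoff, criterion="distance")
    ensembles = []
    for lab in np.unique(labels):
        members = ids[labels == lab]
        if len(members) >= min_size:
            ensembles.append(Ensemble(members=sorted(int(i) for i in members),
                                      block=block))
    ensembles.sort(key=lambda e: e.members[0])
    return ensembles


# ---------------------------------------------------------------------------
# trajectory segments and labels
# ---------------------------------------------------------------------------

def _circular_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a circular boolean array, as (start, stop)
    bin index pairs with stop inclusive (stop < start means wrapped)."""
    n = len(mask)
    if mask.all():
        return [(0, n - 1)]
    if not mask.any():
        return []
    ext = np.concatenate([mask, mask])
    runs = []
    i = 0
    while i < n:
        if ext[i] and not ext[i - 1 if i > 0 else n - 1]:
            j = i
            while ext[j + 1] if j + 1 < 2 * n else False:
                j += 1
            runs.append((i, j % n))
            i = j + 1
        else:
            i += 1
    return runs


def extract_trajectory_segments(members: list[int],
                                spatial_results: list[SpatialCellResult],
                                tuning_curves: list[TuningCurve],
                                belt_length_cm: float = 150.0,
                                threshold: float = 0.5,
                                min_cells: int = 3) -> list[tuple]:
    """Supra-threshold spatial segments shared by an ensemble.

    Each spatially-selective member's trial-averaged tuning curve is
    min-max normalized to [0, 1]; bins where any member exceeds
    ``threshold`` are unioned and split into circular contiguous
    segments.  Segments supported by fewer than ``min_cells``
    spatially-selective members are discarded; ensembles with fewer
    than ``min_cells`` spatially-selective members yield no segments.

    Returns a list of ``(start_cm, end_cm, wrapped)`` tuples.
    """
    spatial_members = [i for i in members if spatial_results[i].is_spatial]
    if len(spatial_members) < min_cells:
        return []
    n_bins = tuning_curves[spatial_members[0]].n_bins
    bin_cm = belt_length_cm / n_bins

    supra = np.zeros((len(spatial_members), n_bins), dtype=bool)
    for k, i in enumerate(spatial_members):
        v = tuning_curves[i].values
        rng_v = v.max() - v.min()
        if rng_v <= 0:
            continue
        norm = (v - v.min()) / rng_v
        supra[k] = norm > threshold
    union = supra.any(axis=0)

    segments = []
    for lo, hi in _circular_runs(union):
        bins = (list(range(lo, hi + 1)) if lo <= hi
                else list(range(lo, n_bins)) + list(range(0, hi + 1)))
        n_contrib = int(np.sum(supra[:, bins].any(axis=1)))
        if n_contrib < min_cells:
            continue
        wrapped = lo > hi
        segments.append((lo * bin_cm, (hi + 1) * bin_cm, wrapped))
    return segments


def segment_length_cm(seg: tuple, belt_length_cm: float) -> float:
    start, end, wrapped = seg
    if wrapped:
        return (belt_length_cm - start) + end
    return end - start


def _segment_contains(seg: tuple, x: float, belt_length_cm: float) -> bool:
    start, end, wrapped = seg
    if wrapped:
        return x >= start or x <= end
    return start <= x <= end


def classify_ensemble(segments: list[tuple], cue_centers_cm,
                      belt_length_cm: float = 150.0,
                      cue_max_len_cm: float = 30.0) -> str:
    """Cue if any segment < 30 cm spans a cue centre, else trajectory if
    any segment remains, else none."""
    for seg in segments:
        if segment_length_cm(seg, belt_length_cm) < cue_max_len_cm:
            if any(_segment_contains(seg, c, belt_length_cm)
                   for c in cue_centers_cm):
                return "cue"
    return "trajectory" if segments else "none"


def label_ensembles(ensembles: list[Ensemble],
                    spatial_results: list[SpatialCellResult],
                    tuning_curves: list[TuningCurve],
                    cue_centers_cm, belt_length_cm: float = 150.0
                    ) -> list[Ensemble]:
    """Fill ``segments`` and ``label`` of each detected ensemble in place."""
    for e in ensembles:
        e.segments = extract_trajectory_segments(
            e.members, spatial_results, tuning_curves, belt_length_cm)
        e.label = classify_ensemble(e.segments, cue_centers_cm,
                                    belt_length_cm)
    return ensembles


# ---------------------------------------------------------------------------
# encoding bias (Gaussian place model vs per-cue rate model)
# ---------------------------------------------------------------------------

def _poisson_ll(y: np.ndarray, n: np.ndarray, rate: np.ndarray) -> float:
    rate = np.clip(rate, 1e-12, None)
    return float(np.sum(y * np.log(rate) - n * rate))


def encoding_bias(activity: np.ndarray, position_cm: np.ndarray,
                  cue_centers_cm, cue_width_cm: float = 10.0,
                  n_bins: int = 50, belt_length_cm: float = 150.0,
                  n_starts: int = 8, seed: int = 0) -> EncodingBias:
    """Likelihood ratio between a Gaussian spatial-tuning model and a
    per-cue rate model for one neuron.

    Both models are maximum-likelihood fits under a Poisson observation
    law on 3 cm bins (bin exposure = occupancy frames).  The Gaussian
    model has baseline, amplitude, circular centre and width; the cue
    model fits one rate per cue window plus a baseline in closed form.
    A positive ``ratio`` favours the cue model.
    """
    from .spatial import bin_index
    activity = np.asarray(activity, dtype=float)
    if not np.any(activity > 0):
        raise ValueError("silent neuron: encoding bias undefined")
    idx = bin_index(np.asarray(position_cm, float), n_bins, belt_length_cm)
    n = np.bincount(idx, minlength=n_bins).astype(float)
    y = np.bincount(idx, weights=activity, minlength=n_bins)
    centers = (np.arange(n_bins) + 0.5) * belt_length_cm / n_bins

    def circ_d(a, b):
        d = np.abs(a - b) % belt_length_cm
        return np.minimum(d, belt_length_cm - d)

    # Gaussian place model: rate(x) = b + A exp(-d(x, mu)^2 / (2 s^2))
    def negll(theta):
        b, A, mu, s = theta
        rate = b + A * np.exp(-0.5 * (circ_d(centers, mu) / s) ** 2)
        return -_poisson_ll(y, n, rate)

    base_rate = y.sum() / n.sum()
    best = np.inf
    starts = np.linspace(0, belt_length_cm, n_starts, endpoint=False)
    for mu0 in starts:
        res = minimize(
            negll, x0=[base_rate, max(base_rate, 1e-3), mu0, 10.0],
            method="L-BFGS-B",
            bounds=[(1e-9, None), (0, None), (0, belt_length_cm),
                    (1.0, belt_length_cm)])
        if res.fun < best:
            best = res.fun
    ll_place = -best

    # cue model: closed-form MLE per region (baseline + one rate per cue)
    region = np.full(n_bins, -1)
    half = cue_width_cm / 2
    for k, c in enumerate(cue_centers_cm):
        region[circ_d(centers, c) <= half] = k
    ll_cue = 0.0
    for k in range(-1, len(cue_centers_cm)):
        m = region == k
        if not m.any() or n[m].sum() == 0:
            continue
        rate = y[m].sum() / n[m].sum()
        ll_cue += _poisson_ll(y[m], n[m], np.full(int(m.sum()), rate))
    return EncodingBias(ll_place=ll_place, ll_cue=ll_cue)


def hypergeometric_enrichment(k_spatial_in_ensemble: int, ensemble_size: int,
                              n_spatial_total: int,
                              n_neurons_total: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k) of drawing at
    least ``k`` spatially-selective cells in an ensemble by chance."""
    k, m = k_spatial_in_ensemble, ensemble_size
    K, N = n_spatial_total, n_neurons_total
    if not (0 <= k <= min(m, K)) or m > N or K > N:
        raise ValueError("inconsistent counts for hypergeometric test")
    return float(hypergeom.sf(k - 1, N, K, m))


class EnsembleDetector(ClusterMixin, BaseEstimator):
    """Scikit-learn style ensemble detector.

    ``fit(X)`` on a frames x neurons rest-activity matrix computes the
    smoothed correlation distance, clusters it, and exposes
    ``ensembles_`` (list of :class:`Ensemble`) plus per-neuron
    ``labels_`` (ensemble index, -1 for unassigned).
    """

    def __init__(self, cutoff: float = 0.75, min_size: int = 5,
                 sigma_ms: float = 200.0, frame_rate_hz: float = 19.0):
        self.cutoff = cutoff
        self.min_size = min_size
        self.sigma_ms = sigma_ms
        self.frame_rate_hz = frame_rate_hz

    def fit(self, X, y=None, *, movement_mask=None, block: str = ""):
        X = np.asarray(X, dtype=float)
        self.distance_ = correlation_distance(
            X, movement_mask, self.sigma_ms, self.frame_rate_hz)
        self.ensembles_ = detect_ensembles(
            self.distance_, self.cutoff, self.min_size, block=block)
        self.labels_ = np.full(X.shape[1], -1)
        for m, e in enumerate(self.ensembles_):
            self.labels_[e.members] = m
        return self

    def fit_predict(self, X, y=None, **kwargs):
        return self.fit(X, y, **kwargs).labels_
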