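"""Spatial tuning, spatial information, and wavelet place-field detection.

A neuron is called spatially selective when two criteria hold:

1. its spatial information :math:`I = \\sum_i p_i (f_i/f) \\log_2(f_i/f)`
   (occupancy :math:`p_i`, mean in-bin activity :math:`f_i`, overall
   mean :math:`f`, over 50 bins) exceeds the 95th percentile of a
   circular-shuffle null distribution, and
2. it supports at least one place field found by a continuous wavelet
   transform (Ricker / Mexican-hat, scales 1..50) of its tuning curve,
   subject to width, in/out-field contrast and per-lap reliability
   constraints.

The belt is a loop, so tuning curves and the CWT are treated as
circular throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from sklearn.base import BaseEstimator

__all__ = [
    "TuningCurve", "PlaceField", "SpatialCellResult",
    "compute_tuning_curve", "per_lap_tuning", "spatial_information",
    "shuffle_test", "detect_place_fields", "classify_spatial_cells",
    "SpatialCellDetector",
]

N_BINS_DEFAULT = 50


@dataclass
class TuningCurve:
    values: np.ndarray       # mean activity per bin (f_i); NaN-free
    occupancy: np.ndarray    # fraction of frames per bin (p_i), sums to 1
    overall_mean: float      # occupancy-weighted mean activity (f)
    empty: np.ndarray        # bins with zero occupancy (excluded from SI)

    @property
    def n_bins(self) -> int:
        return len(self.values)


@dataclass
class PlaceField:
    center_bin: int
    width_bins: float
    scale: int
    bins: tuple = ()         # member bin indices (circular)

    def contains_bin(self, b: int) -> bool:
        return b in self.bins


@dataclass
class SpatialCellResult:
    neuron: int
    si_bits: float
    si_p: float
    fields: list = field(default_factory=list)

    @property
    def is_spatial(self) -> bool:
        return self.si_p < 0.05 and len(self.fields) > 0


def bin_index(position_cm: np.ndarray, n_bins: int,
              belt_length_cm: float) -> np.ndarray:
    """Half-open spatial bins: bin b covers [b*L/N, (b+1)*L/N)."""
    idx = np.floor(position_cm / belt_length_cm * n_bins).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def compute_tuning_curve(activity: np.ndarray, position_cm: np.ndarray,
                         n_bins: int = N_BINS_DEFAULT,
                         belt_length_cm: float = 150.0) -> TuningCurve:
    """Occupancy and occupancy-weighted mean activity per spatial bin."""
    activity = np.asarray(activity, dtype=float)
    position_cm = np.asarray(position_cm, dtype=float)
    if activity.shape[0] != position_cm.shape[0]:
        raise ValueError("activity and position must have equal length")
    if np.any((position_cm < 0) | (position_cm >= belt_length_cm)):
        raise ValueError("positions outside [0, belt_length)")
    idx = bin_index(position_cm, n_bins, belt_length_cm)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    sums = np.bincount(idx, weights=activity, minlength=n_bins)
    empty = counts == 0
    values = np.zeros(n_bins)
    np.divide(sums, counts, out=values, where=~empty)
    occupancy = counts / counts.sum()
    overall = float(np.dot(occupancy, values))
    return TuningCurve(values=values, occupancy=occupancy,
                       overall_mean=overall, empty=empty)


def per_lap_tuning(activity: np.ndarray, position_cm: np.ndarray,
                   n_bins: int = N_BINS_DEFAULT,
                   belt_length_cm: float = 150.0) -> np.ndarray:
    """Laps x bins matrix of mean activity (NaN where a lap missed a bin)."""
    pos = np.asarray(position_cm, dtype=float)
    wraps = np.where(np.diff(pos) < -belt_length_cm / 2)[0] + 1
    bounds = np.concatenate([[0], wraps, [len(pos)]])
    idx = bin_index(pos, n_bins, belt_length_cm)
    rows = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        if e - s < 2:
            continue
        counts = np.bincount(idx[s:e], minlength=n_bins).astype(float)
        sums = np.bincount(idx[s:e], weights=activity[s:e], minlength=n_bins)
        row = np.full(n_bins, np.nan)
        np.divide(sums, counts, out=row, where=counts > 0)
        rows.append(row)
    return np.array(rows) if rows else np.empty((0, n_bins))


def spatial_information(t: TuningCurve) -> float:
    """Skaggs spatial information (bits), zero-rate bins contribute 0."""
    f = t.overall_mean
    if f <= 0:
        raise ValueError("overall mean activity is zero; SI undefined")
    occ = ~t.empty
    fi = t.values[occ]
    pi = t.occupancy[occ]
    ratio = fi / f
    pos = ratio > 0
    return float(np.sum(pi[pos] * ratio[pos] * np.log2(ratio[pos])))


def _si_from_binned(F: np.ndarray, occupancy: np.ndarray) -> np.ndarray:
    """Vectorized SI for rows of pre-binned mean activity F."""
    f = F @ occupancy
    out = np.zeros(F.shape[0])
    ok = f > 0
    ratio = np.divide(F[ok], f[ok, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = occupancy[None, :] * ratio * np.log2(ratio)
    terms[~np.isfinite(terms)] = 0.0
    out[ok] = terms.sum(axis=1)
    return out


def shuffle_test(activity: np.ndarray, position_cm: np.ndarray,
                 n_shuffles: int = 1000, seed: int | None = 0,
                 n_bins: int = N_BINS_DEFAULT, belt_length_cm: float = 150.0,
                 min_shift_s: float = 1.0,
                 frame_rate_hz: float = 19.0) -> tuple[float, float]:
    """Circular-shift significance test for spatial information.

    Each shuffle circularly rotates the activity trace by a uniform
    random offset (at least ``min_shift_s`` away from zero in either
    direction, keeping the null conservative) and recomputes SI against
    the fixed occupancy.  Returns ``(si_bits, p)`` with
    ``p = fraction of shuffles >= observed``.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be at least 100")
    activity = np.asarray(activity, dtype=float)
    T = len(activity)
    if not np.any(activity > 0):
        return 0.0, 1.0  # silent neuron: not significant by convention
    tc = compute_tuning_curve(activity, position_cm, n_bins, belt_length_cm)
    obs = spatial_information(tc)

    rng = np.random.default_rng(seed)
    min_shift = min(int(round(min_shift_s * frame_rate_hz)), max(1, T // 4))
    offsets = rng.integers(min_shift, T - min_shift, size=n_shuffles)

    idx = bin_index(np.asarray(position_cm, float), n_bins, belt_length_cm)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    shifted = activity[(np.arange(T)[None, :] + offsets[:, None]) % T]
    # mean in-bin activity per shuffle: sum into bins then divide
    B = np.zeros((T, n_bins))
    B[np.arange(T), idx] = 1.0
    sums = shifted @ B
    with np.errstate(invalid="ignore"):
        F = np.divide(sums, counts[None, :],
                      out=np.zeros_like(sums), where=counts[None, :] > 0)
    null = _si_from_binned(F, tc.occupancy)
    p = float(np.mean(null >= obs))
    return obs, p


# ---------------------------------------------------------------------------
# place-field detection
# ---------------------------------------------------------------------------

def _circular_cwt(values: np.ndarray, scales: np.ndarray) -> np.ndarray:
    """Ricker CWT of a circular signal: transform a 3x tiling, keep centre."""
    n = len(values)
    ext = np.tile(values, 3)
    coef, _ = pywt.cwt(ext, scales, "mexh")
    return coef[:, n:2 * n]


def _local_maxima_circ(row: np.ndarray) -> np.ndarray:
    n = len(row)
    left = np.roll(row, 1)
    right = np.roll(row, -1)
    return np.where((row > left) & (row >= right))[0]


def _field_bounds(row: np.ndarray, peak: int) -> tuple[int, int]:
    """Bins spanned between the zero crossings of the CWT response
    around ``peak`` (circular)."""
    n = len(row)
    lo = peak
    for step in range(1, n):
        j = (peak - step) % n
        if row[j] <= 0:
            break
        lo = j
    hi = peak
    for step in range(1, n):
        j = (peak + step) % n
        if row[j] <= 0:
            break
        hi = j
    return lo, hi


def _bins_between(lo: int, hi: int, n: int) -> tuple:
    if lo <= hi:
        return tuple(range(lo, hi + 1))
    return tuple(list(range(lo, n)) + list(range(0, hi + 1)))


def detect_place_fields(t: TuningCurve, per_lap: np.ndarray,
                        scales: np.ndarray | None = None,
                        min_width_frac: float = 0.05,
                        max_width_frac: float = 0.80,
                        in_out_ratio: float = 2.5,
                        lap_frac: float = 1 / 3,
                        min_laps: int = 10) -> list[PlaceField]:
    """Ricker-wavelet place-field detection on a circular tuning curve.

    Candidate fields are CWT ridge peaks exceeding 3 median absolute
    deviations of the scale-1 coefficients; overlapping candidates
    compete and the stronger wavelet response wins.  Retained fields
    must have width within ``[min_width_frac, max_width_frac]`` of the
    track, in-field mean activity at least ``in_out_ratio`` times the
    out-of-field mean, and the per-lap activity peak inside the field in
    at least ``lap_frac`` of laps.
    """
    n = t.n_bins
    if per_lap.shape[0] < min_laps:
        raise ValueError(
            f"need at least {min_laps} laps, got {per_lap.shape[0]}")
    if scales is None:
        scales = np.arange(1, n + 1)
    coef = _circular_cwt(t.values, scales)

    base = coef[0]
    mad = np.median(np.abs(base - np.median(base)))
    thresh = np.median(base) + 3 * mad
    if mad == 0 and np.allclose(base, base[0]):
        return []

    # all supra-threshold local maxima with a valid width; candidates of
    # invalid width cannot be fields and must not suppress nested ones
    lo_w, hi_w = min_width_frac * n, max_width_frac * n
    raw: list[tuple[float, PlaceField]] = []
    n_scales = len(scales)
    for si in range(n_scales - 1, -1, -1):
        row = coef[si]
        for peak in _local_maxima_circ(row):
            if row[peak] <= thresh:
                continue
            # ridge peak: also a local maximum along the scale axis, so a
            # bump is detected at the scale its wavelet response prefers
            if si > 0 and coef[si - 1, peak] > row[peak]:
                continue
            if si < n_scales - 1 and coef[si + 1, peak] > row[peak]:
                continue
            lo, hi = _field_bounds(row, peak)
            bins = _bins_between(lo, hi, n)
            if lo_w <= len(bins) <= hi_w:
                raw.append((float(row[peak]),
                            PlaceField(center_bin=int(peak),
                                       width_bins=float(len(bins)),
                                       scale=int(scales[si]), bins=bins)))

    # overlapping candidates compete; the one with the stronger wavelet
    # response wins (a bump's matched scale beats both its coarse-scale
    # echo and a merged envelope over separate bumps)
    raw.sort(key=lambda cf: -cf[0])
    candidates = []
    for _, f in raw:
        if any(f.center_bin in g.bins or g.center_bin in f.bins
               for g in candidates):
            continue
        candidates.append(f)
    if not candidates:
        return []

    in_all = np.zeros(n, dtype=bool)
    for f in candidates:
        in_all[list(f.bins)] = True
    out_bins = ~in_all & ~t.empty
    out_mean = float(t.values[out_bins].mean()) if out_bins.any() else 0.0

    lap_peaks = np.nanargmax(np.where(np.isnan(per_lap), -np.inf, per_lap),
                             axis=1)
    fields = []
    for f in candidates:
        in_mean = float(t.values[list(f.bins)].mean())
        if out_mean > 0 and in_mean < in_out_ratio * out_mean:
            continue
        frac = np.mean([p in f.bins for p in lap_peaks])
        if frac < lap_frac:
            continue
        fields.append(f)
    return fields


def classify_spatial_cells(run_activity: np.ndarray, position_cm: np.ndarray,
                           n_bins: int = N_BINS_DEFAULT,
                           belt_length_cm: float = 150.0,
                           n_shuffles: int = 1000, seed: int = 0,
                           frame_rate_hz: float = 19.0,
                           min_laps: int = 10) -> list[SpatialCellResult]:
    """Per-neuron spatial-selectivity classification over a RUN block."""
    run_activity = np.asarray(run_activity, dtype=float)
    if run_activity.size == 0:
        return []
    results = []
    for i in range(run_activity.shape[1]):
        a = run_activity[:, i]
        if not np.any(a > 0):
            results.append(SpatialCellResult(neuron=i, si_bits=0.0, si_p=1.0))
            continue
        si, p = shuffle_test(a, position_cm, n_shuffles=n_shuffles,
                             seed=seed + i, n_bins=n_bins,
                             belt_length_cm=belt_length_cm,
                             frame_rate_hz=frame_rate_hz)
        fields: list[PlaceField] = []
        if p < 0.05:  # fields only needed when the SI criterion passes
            tc = compute_tuning_curve(a, position_cm, n_bins, belt_length_cm)
            laps = per_lap_tuning(a, position_cm, n_bins, belt_length_cm)
            fields = detect_place_fields(tc, laps, min_laps=min_laps)
        results.append(SpatialCellResult(neuron=i, si_bits=si, si_p=p,
                                         fields=fields))
    return results


class SpatialCellDetector(BaseEstimator):
    """Scikit-learn style wrapper around :func:`classify_spatial_cells`.

    Parameters mirror the functional interface; after ``fit`` the
    attributes ``results_`` (list of :class:`SpatialCellResult`) and
    ``is_spatial_`` (boolean array) are available.
    """

    def __init__(self, n_bins: int = N_BINS_DEFAULT,
                 belt_length_cm: float = 150.0, n_shuffles: int = 1000,
                 frame_rate_hz: float = 19.0, min_laps: int = 10,
                 seed: int = 0):
        self.n_bins = n_bins
        self.belt_length_cm = belt_length_cm
        self.n_shuffles = n_shuffles
        self.frame_rate_hz = frame_rate_hz
        self.min_laps = min_laps
        self.seed = seed

    def fit(self, X, y=None, *, position_cm):
        X = np.asarray(X, dtype=float)
        self.results_ = classify_spatial_cells(
            X, position_cm, n_bins=self.n_bins,
            belt_length_cm=self.belt_length_cm, n_shuffles=self.n_shuffles,
            seed=self.seed, frame_rate_hz=self.frame_rate_hz,
            min_laps=self.min_laps)
        self.is_spatial_ = np.array([r.is_spatial for r in self.results_])
        return self
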