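"""Temporal coordination of reactivations with SWRs and between ensembles.

Covers peri-event averages of reactivation strength around SWR onsets,
unbiased cross-correlation with a Gaussian peak fit for lag estimation,
onset cross-correlograms with bootstrap confidence bands, detection of
temporally coupled cue-trajectory ensemble pairs against a
circular-shift null, similarity of reactivated features, the fraction
of reactivation events associated with an SWR, explained variance
(ev/rev) between RUN and rest pair-correlation structure, and Jaccard
persistence of ensembles with a Fisher exact significance rule.

Lag sign convention: a positive lag means the second series (or event
train) lags the first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import fisher_exact, pearsonr

__all__ = [
    "PeriEventAverage", "LagEstimate", "CoupledPair",
    "peri_event_average", "xcorr_unbiased", "xcorr_gaussian_lag",
    "onset_crosscorrelogram", "find_coupled_pairs", "feature_similarity",
    "swr_association_fraction", "explained_variance",
    "jaccard_persistence", "max_jaccard", "persistence_significance",
]


@dataclass
class PeriEventAverage:
    lags_s: np.ndarray
    mean_z: np.ndarray
    sem: np.ndarray
    n_events: int


@dataclass
class LagEstimate:
    lag_s: float
    coeff_peak: float
    ci_halfwidth_s: float
    fit_ok: bool


@dataclass
class CoupledPair:
    cue_id: int
    traj_id: int
    lag_s: float
    coupled: bool
    peak_coeff: float
    null_bound: float
    feature_r: float | None = None
    feature_z: float | None = None   # atanh-transformed r


def galvo_dwell_ci_ms(frame_dwell_ms: float = 50.0) -> float:
    """Timing confidence half-width from resonant-galvo scanning.

    Two neurons at random positions along the slow scan axis are imaged
    on average a third of the frame dwell time apart, so lags carry an
    irreducible ±dwell/3 uncertainty (~±17 ms at a ~50 ms dwell)."""
    return frame_dwell_ms / 3.0


def peri_event_average(series: np.ndarray, event_times_s,
                       rate_hz: float, window_s: float = 2.0
                       ) -> PeriEventAverage:
    """Average of the z-scored series in windows centred on events.

    Events whose window crosses a block edge are dropped; raises if no
    usable event remains.
    """
    s = np.asarray(series, dtype=float)
    sd = s.std()
    if sd == 0:
        raise ValueError("constant series")
    z = (s - s.mean()) / sd
    half = int(round(window_s * rate_hz))
    frames = np.round(np.asarray(event_times_s, float) * rate_hz).astype(int)
    frames = frames[(frames - half >= 0) & (frames + half < len(z))]
    if len(frames) == 0:
        raise ValueError("no events with a full window inside the block")
    wins = np.stack([z[f - half:f + half + 1] for f in frames])
    mean = wins.mean(axis=0)
    sem = wins.std(axis=0, ddof=1) / np.sqrt(len(frames)) \
        if len(frames) > 1 else np.zeros_like(mean)
    lags = np.arange(-half, half + 1) / rate_hz
    return PeriEventAverage(lags_s=lags, mean_z=mean, sem=sem,
                            n_events=len(frames))


def xcorr_unbiased(a: np.ndarray, b: np.ndarray, max_lag: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Unbiased-normalized cross-correlation coefficients over
    lags -max_lag..max_lag (positive lag: b lags a)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    T = len(a)
    za = (a - a.mean())
    zb = (b - b.mean())
    denom = a.std() * b.std()
    if denom == 0:
        raise ValueError("zero-variance series")
    lags = np.arange(-max_lag, max_lag + 1)
    c = np.empty(len(lags))
    for i, l in enumerate(lags):
        if l >= 0:
            prod = za[: T - l] @ zb[l:]
        else:
            prod = za[-l:] @ zb[: T + l]
        c[i] = prod / ((T - abs(l)) * denom)
    return lags, c


def xcorr_gaussian_lag(a: np.ndarray, b: np.ndarray, rate_hz: float,
                       max_lag_s: float = 1.0) -> LagEstimate:
    """Lag of the Gaussian fitted to the unbiased cross-correlation.

    Falls back to the argmax lag (``fit_ok=False``) when the fit fails.
    """
    max_lag = int(round(max_lag_s * rate_hz))
    lags, c = xcorr_unbiased(a, b, max_lag)
    lags_s = lags / rate_hz
    i0 = int(np.argmax(c))

    def gauss(x, A, mu, sigma, C):
        return A * np.exp(-0.5 * ((x - mu) / sigma) ** 2) + C

    try:
        p0 = [c[i0] - c.min(), lags_s[i0], max(2.0 / rate_hz, 0.05),
              float(c.min())]
        popt, _ = curve_fit(gauss, lags_s, c, p0=p0, maxfev=5000)
        mu = float(popt[1])
        if abs(mu) > max_lag_s:
            raise RuntimeError("fitted mean outside window")
        return LagEstimate(lag_s=mu, coeff_peak=float(c[i0]),
                           ci_halfwidth_s=1.0 / rate_hz, fit_ok=True)
    except Exception:
        return LagEstimate(lag_s=float(lags_s[i0]), coeff_peak=float(c[i0]),
                           ci_halfwidth_s=1.0 / rate_hz, fit_ok=False)


def onset_crosscorrelogram(onsets_a, onsets_b, bin_ms: float = 100.0,
                           window_s: float = 1.0, n_boot: int = 1000,
                           seed: int = 0):
    """Histogram of a-onset minus b-onset lags with bootstrap 95 % CI.

    Returns ``(bin_centers_s, counts, ci_low, ci_high)``.
    """
    a = np.asarray(onsets_a, dtype=float)
    b = np.asarray(onsets_b, dtype=float)
    if len(a) < 5 or len(b) < 5:
        raise ValueError("need at least 5 events in each train")
    width = bin_ms / 1000.0
    edges = np.arange(-window_s, window_s + width / 2, width)

    def hist(aa, bb):
        d = aa[:, None] - bb[None, :]
        d = d[np.abs(d) <= window_s]
        return np.histogram(d, bins=edges)[0]

    counts = hist(a, b)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, len(counts)))
    for i in range(n_boot):
        aa = rng.choice(a, size=len(a), replace=True)
        bb = rng.choice(b, size=len(b), replace=True)
        boots[i] = hist(aa, bb)
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    centers = (edges[:-1] + edges[1:]) / 2
    return centers, counts, lo, hi


def _weighted_lag(lags_s: np.ndarray, c: np.ndarray) -> float:
    """Mean lag weighted by the (positive part of the) coefficients."""
    w = np.clip(c, 0, None)
    if w.sum() == 0:
        return float(lags_s[np.argmax(c)])
    return float(np.sum(lags_s * w) / w.sum())


def find_coupled_pairs(strengths_cue: np.ndarray, strengths_traj: np.ndarray,
                       rate_hz: float, window_s: float = 1.0,
                       alpha: float = 0.05, n_null: int = 500,
                       min_shift_s: float = 1.0, seed: int = 0
                       ) -> list[CoupledPair]:
    """Temporally coupled cue-trajectory ensemble pairs.

    A pair is coupled when the peak |cross-correlation| within
    ±``window_s`` exceeds the one-tailed (1 - alpha) bound of a
    circular-shift surrogate null of the trajectory series.  The
    reported lag is the coefficient-weighted mean lag (positive:
    trajectory lags cue).
    """
    Sc = np.atleast_2d(np.asarray(strengths_cue, float).T).T
    St = np.atleast_2d(np.asarray(strengths_traj, float).T).T
    T = Sc.shape[0]
    max_lag = int(round(window_s * rate_hz))
    if T < 4 * max_lag:
        raise ValueError("series too short for the requested lag window")
    rng = np.random.default_rng(seed)
    min_shift = int(round(min_shift_s * rate_hz))
    shifts = rng.integers(min_shift, T - min_shift, size=n_null)

    pairs = []
    for i in range(Sc.shape[1]):
        for j in range(St.shape[1]):
            lags, c = xcorr_unbiased(Sc[:, i], St[:, j], max_lag)
            peak = float(np.max(np.abs(c)))
            null_peaks = np.empty(n_null)
            for s_idx, sh in enumerate(shifts):
                rolled = np.roll(St[:, j], int(sh))
                _, cn = xcorr_unbiased(Sc[:, i], rolled, max_lag)
                null_peaks[s_idx] = np.max(np.abs(cn))
            bound = float(np.quantile(null_peaks, 1 - alpha))
            pairs.append(CoupledPair(
                cue_id=i, traj_id=j,
                lag_s=_weighted_lag(lags / rate_hz, c),
                coupled=peak > bound, peak_coeff=peak, null_bound=bound))
    return pairs


def feature_similarity(f_a: np.ndarray, f_b: np.ndarray
                       ) -> tuple[float, float]:
    """Pearson r between two reactivated features and its Fisher
    transform atanh(r)."""
    f_a = np.asarray(f_a, dtype=float)
    f_b = np.asarray(f_b, dtype=float)
    if f_a.shape != f_b.shape:
        raise ValueError("features must have equal length")
    if f_a.std() == 0 or f_b.std() == 0:
        raise ValueError("zero-variance feature")
    r = float(pearsonr(f_a, f_b)[0])
    r_clip = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    return r, float(np.arctanh(r_clip))


def swr_association_fraction(event_onsets, swr_onsets,
                             window_s: float = 0.5) -> float:
    """Percentage of reactivation events whose onset lies within
    ±``window_s`` of any SWR onset."""
    ev = np.asarray(event_onsets, dtype=float)
    sw = np.asarray(swr_onsets, dtype=float)
    if len(ev) == 0:
        return 0.0
    if len(sw) == 0:
        return 0.0
    d = np.min(np.abs(ev[:, None] - sw[None, :]), axis=1)
    return float(100.0 * np.mean(d <= window_s))


def _pair_correlations(X: np.ndarray) -> np.ndarray:
    C = np.corrcoef(X, rowvar=False)
    iu = np.triu_indices(C.shape[0], k=1)
    return C[iu]


def explained_variance(X_rest1: np.ndarray, X_run: np.ndarray,
                       X_rest2: np.ndarray) -> tuple[float, float]:
    """Explained variance (ev) and reverse explained variance (rev), %.

    ev is the squared partial correlation between the RUN and REST2
    pairwise-correlation matrices controlling for REST1; rev swaps the
    roles of REST1 and REST2.  Neurons with zero variance in any block
    are excluded.
    """
    blocks = [np.asarray(b, float) for b in (X_rest1, X_run, X_rest2)]
    ok = np.ones(blocks[0].shape[1], dtype=bool)
    for b in blocks:
        ok &= b.std(axis=0) > 0
    if ok.sum() < 5:
        raise ValueError("need at least 5 neurons with variance in all blocks")
    r1, run, r2 = (_pair_correlations(b[:, ok]) for b in blocks)

    def pcorr(x, y, z):
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        return (rxy - rxz * ryz) / np.sqrt((1 - rxz ** 2) * (1 - ryz ** 2))

    ev = pcorr(run, r2, r1) ** 2 * 100.0
    rev = pcorr(run, r1, r2) ** 2 * 100.0
    return float(ev), float(rev)


def jaccard_persistence(members_a, members_b) -> float:
    """Jaccard index J = O / (A + B - O) between two member sets."""
    a, b = set(members_a), set(members_b)
    if not a and not b:
        raise ValueError("both sets empty: Jaccard undefined")
    o = len(a & b)
    return o / (len(a) + len(b) - o)


def max_jaccard(members: list, others: list[list]) -> float:
    """Maximum Jaccard index of one ensemble against a list of others."""
    if not others:
        return 0.0
    return max(jaccard_persistence(members, o) for o in others)


def persistence_significance(O: int, A: int, B: int, n_total: int,
                             alpha: float = 0.001) -> tuple[float, bool]:
    """One-tailed Fisher exact test that the overlap O between sets of
    sizes A and B from ``n_total`` neurons exceeds chance.

    Returns ``(p, significant)``.
    """
    if not (0 <= O <= min(A, B)) or A > n_total or B > n_total \
            or n_total - A - B + O < 0:
        raise ValueError("inconsistent counts")
    table = [[O, A - O], [B - O, n_total - A - B + O]]
    _, p = fisher_exact(table, alternative="greater")
    return float(p), bool(p < alpha)
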