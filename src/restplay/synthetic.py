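"""Synthetic session generator with planted ground truth.

Emulates a head-fixed treadmill experiment: a REST1 block of quiet
wakefulness, a RUN block of laps on a 150 cm circular belt lined with
visuo-tactile cues, and a REST2 block in which planted ensembles of
neurons spontaneously co-activate, optionally time-locked to planted
hippocampal sharp-wave ripples (SWRs) in a simulated LFP channel.

Activity is emitted directly as non-negative deconvolved event-rate
traces (the form consumed by all downstream analyses).  Every planted
quantity — cell type, place-field centre, ensemble membership,
reactivation onset, SWR time, cue/trajectory onset lag — is recorded in
a :class:`GroundTruth` object so each analysis stage can be validated by
parameter recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import filtfilt, firwin

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SessionBundle",
    "simulate_run",
    "simulate_rest",
    "simulate_lfp",
    "simulate_full_experiment",
]


@dataclass
class SimConfig:
    """Parameters of a simulated session.

    Defaults mirror the experimental conditions the pipeline targets:
    ~19 Hz two-photon frame rate, 2.6 kHz LFP, a 150 cm belt with four
    cues, 10 min rest blocks flanking an 8 min run.
    """

    n_neurons: int = 100
    frac_place: float = 0.3
    frac_cue: float = 0.1
    belt_length_cm: float = 150.0
    cue_centers_cm: tuple = (20.0, 55.0, 100.0, 120.0)
    cue_width_cm: float = 10.0
    frame_rate_hz: float = 19.0
    lfp_rate_hz: float = 2600.0
    run_duration_s: float = 480.0
    rest_duration_s: float = 600.0
    n_ensembles: int = 3
    n_cue_ensembles: int = 1
    ensemble_size_range: tuple = (6, 10)
    reactivation_rate_hz: float = 0.05
    swr_rate_hz: float = 0.1
    p_swr_coupled: float = 0.2
    cue_lag_ms: float = 50.0
    traj_lag_ms: float = 180.0
    noise_sd: float = 0.05
    seed: int = 0

    # Secondary knobs (not stated by the experimental protocol; exposed
    # rather than hard-coded).
    run_speed_cm_s: float = 15.0
    reward_pause_s: float = 1.0
    field_sigma_cm: float = 6.0
    transient_amplitude: float = 3.0
    transient_duration_ms: float = 180.0
    background_rate_hz: float = 0.1
    movement_frac: float = 0.1
    rest1_ensemble_frac: float = 0.5
    swr_amplitude_sd: float = 5.0
    swr_duration_ms: float = 50.0
    ripple_freq_hz: float = 200.0

    def validate(self) -> None:
        if self.n_neurons <= 0:
            raise ValueError("n_neurons must be positive")
        if self.run_duration_s <= 0 or self.rest_duration_s <= 0:
            raise ValueError("durations must be positive")
        if not (0 <= self.frac_place <= 1 and 0 <= self.frac_cue <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.frac_place + self.frac_cue > 1:
            raise ValueError("frac_place + frac_cue must not exceed 1")
        for c in self.cue_centers_cm:
            if not (0 <= c < self.belt_length_cm):
                raise ValueError("cue centers must lie within the belt")
        for name in ("reactivation_rate_hz", "swr_rate_hz", "noise_sd",
                     "frame_rate_hz", "lfp_rate_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 <= self.p_swr_coupled <= 1):
            raise ValueError("p_swr_coupled must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cue_centers_cm"] = list(self.cue_centers_cm)
        d["ensemble_size_range"] = list(self.ensemble_size_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "cue_centers_cm" in d:
            d["cue_centers_cm"] = tuple(d["cue_centers_cm"])
        if "ensemble_size_range" in d:
            d["ensemble_size_range"] = tuple(d["ensemble_size_range"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted parameters of a simulated session."""

    cell_labels: list = field(default_factory=list)  # per neuron: place|cue|none
    field_centers_cm: dict = field(default_factory=dict)  # neuron -> centre
    cue_assignments: dict = field(default_factory=dict)  # cue neuron -> cue idx
    ensemble_members: list = field(default_factory=list)  # list of sorted lists
    ensemble_labels: list = field(default_factory=list)  # cue | trajectory
    ensemble_segments_cm: list = field(default_factory=list)  # (start, end)
    reactivation_times_s: dict = field(default_factory=dict)  # block -> [per ens]
    swr_times_s: dict = field(default_factory=dict)  # block -> list
    planted_lags_ms: dict = field(default_factory=dict)  # class -> lag

    def to_dict(self) -> dict:
        return {
            "cell_labels": list(self.cell_labels),
            "field_centers_cm": {str(k): float(v)
                                 for k, v in self.field_centers_cm.items()},
            "cue_assignments": {str(k): int(v)
                                for k, v in self.cue_assignments.items()},
            "ensemble_members": [[int(i) for i in m]
                                 for m in self.ensemble_members],
            "ensemble_labels": list(self.ensemble_labels),
            "ensemble_segments_cm": [list(map(float, s))
                                     for s in self.ensemble_segments_cm],
            "reactivation_times_s": {
                b: [[float(t) for t in ts] for ts in per_ens]
                for b, per_ens in self.reactivation_times_s.items()},
            "swr_times_s": {b: [float(t) for t in ts]
                            for b, ts in self.swr_times_s.items()},
            "planted_lags_ms": {k: float(v)
                                for k, v in self.planted_lags_ms.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        gt = cls()
        gt.cell_labels = list(d["cell_labels"])
        gt.field_centers_cm = {int(k): float(v)
                               for k, v in d["field_centers_cm"].items()}
        gt.cue_assignments = {int(k): int(v)
                              for k, v in d.get("cue_assignments", {}).items()}
        gt.ensemble_members = [list(map(int, m)) for m in d["ensemble_members"]]
        gt.ensemble_labels = list(d["ensemble_labels"])
        gt.ensemble_segments_cm = [tuple(s)
                                   for s in d.get("ensemble_segments_cm", [])]
        gt.reactivation_times_s = {
            b: [list(map(float, ts)) for ts in per_ens]
            for b, per_ens in d["reactivation_times_s"].items()}
        gt.swr_times_s = {b: list(map(float, ts))
                          for b, ts in d["swr_times_s"].items()}
        gt.planted_lags_ms = dict(d["planted_lags_ms"])
        return gt


@dataclass
class SessionBundle:
    """One simulated (or loaded) session: REST1 / RUN / REST2."""

    rest1: np.ndarray  # frames x neurons, deconvolved rates
    run: np.ndarray
    rest2: np.ndarray
    position_cm: np.ndarray  # per RUN frame
    velocity_cm_s: np.ndarray
    rest1_movement_mask: np.ndarray  # True where the animal moved
    rest2_movement_mask: np.ndarray
    lfp_rest1: np.ndarray | None = None
    lfp_rest2: np.ndarray | None = None
    meta: SimConfig | None = None

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty if valid)."""
        v = []
        for name in ("rest1", "run", "rest2"):
            a = getattr(self, name)
            if np.any(a < 0):
                v.append(f"{name}: negative activity values")
        ncols = {self.rest1.shape[1], self.run.shape[1], self.rest2.shape[1]}
        if len(ncols) != 1:
            v.append("blocks disagree on neuron count")
        if self.meta is not None:
            L = self.meta.belt_length_cm
            if np.any((self.position_cm < 0) | (self.position_cm >= L)):
                v.append("position outside [0, belt_length)")
            laps = count_laps(self.position_cm, L)
            if laps < 10:
                v.append(f"RUN contains only {laps} laps (minimum 10)")
        if len(self.position_cm) != self.run.shape[0]:
            v.append("position length does not match RUN frames")
        return v


def count_laps(position_cm: np.ndarray, belt_length_cm: float) -> int:
    """Number of completed laps, counted as wrap-arounds of position."""
    d = np.diff(position_cm)
    return int(np.sum(d < -belt_length_cm / 2))


# ---------------------------------------------------------------------------
# cell-type assignment and tuning
# ---------------------------------------------------------------------------

def _circ_dist(a, b, L):
    d = np.abs(a - b) % L
    return np.minimum(d, L - d)


def _assign_cells(config: SimConfig, rng: np.random.Generator) -> GroundTruth:
    """Assign cell types, field centres and planted ensembles."""
    n = config.n_neurons
    n_place = int(round(config.frac_place * n))
    n_cue = int(round(config.frac_cue * n))
    truth = GroundTruth()
    truth.cell_labels = (["place"] * n_place + ["cue"] * n_cue
                         + ["none"] * (n - n_place - n_cue))
    place_ids = list(range(n_place))
    cue_ids = list(range(n_place, n_place + n_cue))

    lo, hi = config.ensemble_size_range
    n_cue_ens = min(config.n_cue_ensembles, config.n_ensembles)
    labels = ["cue"] * n_cue_ens + ["trajectory"] * (config.n_ensembles - n_cue_ens)
    free_place = list(place_ids)
    free_cue = list(cue_ids)

    for m, label in enumerate(labels):
        size = int(rng.integers(lo, hi + 1))
        if label == "cue":
            if size > len(free_cue):
                raise ValueError(
                    "not enough cue cells for the requested cue ensembles; "
                    "increase frac_cue or n_neurons")
            members = [free_cue.pop(0) for _ in range(size)]
            cue_idx = m % len(config.cue_centers_cm)
            c = config.cue_centers_cm[cue_idx]
            for i in members:
                truth.cue_assignments[i] = cue_idx
                # members share a nearly identical narrow tuning at the cue
                truth.field_centers_cm[i] = float(
                    (c + rng.normal(0, 1.0)) % config.belt_length_cm)
            half = config.cue_width_cm / 2
            truth.ensemble_segments_cm.append(
                ((c - half) % config.belt_length_cm,
                 (c + half) % config.belt_length_cm))
        else:
            if size > len(free_place):
                raise ValueError(
                    "not enough place cells for the requested trajectory "
                    "ensembles; increase frac_place or n_neurons")
            members = [free_place.pop(0) for _ in range(size)]
            seg_len = float(rng.uniform(32.0, 42.0))
            traj_rank = m - n_cue_ens
            if traj_rank < n_cue_ens:
                # paired with cue ensemble traj_rank: the trajectory
                # spans that cue's location (coupled pairs reactivate
                # overlapping features)
                c_pair = config.cue_centers_cm[
                    traj_rank % len(config.cue_centers_cm)]
                start = float(c_pair - seg_len / 2.0)
            else:
                start = float(rng.uniform(0, config.belt_length_cm))
            # members' fields tile the segment contiguously
            offsets = np.linspace(0, seg_len, size)
            for i, off in zip(members, offsets):
                truth.field_centers_cm[i] = float(
                    (start + off) % config.belt_length_cm)
            truth.ensemble_segments_cm.append(
                (start % config.belt_length_cm,
                 (start + seg_len) % config.belt_length_cm))
        truth.ensemble_members.append(sorted(members))
        truth.ensemble_labels.append(label)

    # remaining tuned cells get independent random fields / cues
    for i in free_place:
        truth.field_centers_cm[i] = float(rng.uniform(0, config.belt_length_cm))
    for i in free_cue:
        cue_idx = int(rng.integers(len(config.cue_centers_cm)))
        truth.cue_assignments[i] = cue_idx
        truth.field_centers_cm[i] = float(
            (config.cue_centers_cm[cue_idx] + rng.normal(0, 1.0))
            % config.belt_length_cm)

    truth.planted_lags_ms = {"cue": config.cue_lag_ms,
                             "trajectory": config.traj_lag_ms}
    return truth


def _tuned_rates(config: SimConfig, truth: GroundTruth,
                 position: np.ndarray) -> np.ndarray:
    """Per-frame noiseless tuned rate for every neuron (frames x neurons)."""
    n = config.n_neurons
    L = config.belt_length_cm
    rates = np.zeros((len(position), n))
    for i, label in enumerate(truth.cell_labels):
        if label == "none":
            continue
        c = truth.field_centers_cm[i]
        sigma = (config.field_sigma_cm if label == "place"
                 else config.cue_width_cm / 3.0)
        d = _circ_dist(position, c, L)
        rates[:, i] = np.exp(-0.5 * (d / sigma) ** 2)
    return rates


def _background(config: SimConfig, n_frames: int,
                rng: np.random.Generator) -> np.ndarray:
    """Sparse independent event noise plus Gaussian jitter, clipped at 0."""
    p = config.background_rate_hz / config.frame_rate_hz
    events = (rng.random((n_frames, config.n_neurons)) < p)
    amp = rng.exponential(1.0, size=events.shape)
    x = events * amp + rng.normal(0, config.noise_sd,
                                  size=(n_frames, config.n_neurons))
    return np.clip(x, 0, None)


# ---------------------------------------------------------------------------
# RUN block
# ---------------------------------------------------------------------------

def simulate_run(config: SimConfig, truth: GroundTruth | None = None,
                 rng: np.random.Generator | None = None):
    """Simulate the RUN block.

    Returns ``(activity, position_cm, velocity_cm_s, truth)``.  The
    animal runs laps at roughly constant speed with Gaussian speed
    jitter and a reward pause at the lap line; tuned cells emit
    Gaussian spatial rates, cue cells narrow rates at their cue.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if truth is None:
        truth = _assign_cells(config, rng)

    dt = 1.0 / config.frame_rate_hz
    n_frames = int(round(config.run_duration_s * config.frame_rate_hz))
    position = np.empty(n_frames)
    velocity = np.empty(n_frames)
    pos = 0.0
    pause_left = 0.0
    for t in range(n_frames):
        if pause_left > 0:
            v = 0.0
            pause_left -= dt
        else:
            v = max(0.0, config.run_speed_cm_s + rng.normal(0, 2.0))
        new = pos + v * dt
        if new >= config.belt_length_cm:  # lap completed: reward pause
            new -= config.belt_length_cm
            pause_left = config.reward_pause_s
        position[t] = new
        velocity[t] = v
        pos = new

    activity = (_tuned_rates(config, truth, position)
                + _background(config, n_frames, rng))
    return activity, position, velocity, truth


# ---------------------------------------------------------------------------
# REST blocks
# ---------------------------------------------------------------------------

def _movement_mask(config: SimConfig, n_frames: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Contiguous movement epochs covering ~movement_frac of the block."""
    mask = np.zeros(n_frames, dtype=bool)
    epoch = max(1, int(round(2.0 * config.frame_rate_hz)))  # ~2 s epochs
    n_epochs = int(round(config.movement_frac * n_frames / epoch))
    for _ in range(n_epochs):
        s = int(rng.integers(0, max(1, n_frames - epoch)))
        mask[s:s + epoch] = True
    return mask


def _transient_kernel(config: SimConfig) -> np.ndarray:
    """Half-Gaussian rise / half-Gaussian decay envelope, ~180 ms total."""
    dt = 1.0 / config.frame_rate_hz
    total = config.transient_duration_ms / 1000.0
    t = np.arange(0, total + dt / 2, dt)
    t_peak = total / 3.0
    sigma_r, sigma_d = t_peak / 1.5, (total - t_peak) / 2.0
    env = np.where(t <= t_peak,
                   np.exp(-0.5 * ((t - t_peak) / sigma_r) ** 2),
                   np.exp(-0.5 * ((t - t_peak) / sigma_d) ** 2))
    return env


def _draw_swr_times(config: SimConfig, duration: float,
                    rng: np.random.Generator) -> list[float]:
    """Poisson SWR times with a 300 ms minimum separation."""
    n = rng.poisson(config.swr_rate_hz * duration)
    times = np.sort(rng.uniform(1.0, duration - 1.0, size=n))
    kept: list[float] = []
    for t in times:
        if not kept or t - kept[-1] >= 0.3:
            kept.append(float(t))
    return kept


def simulate_rest(config: SimConfig, truth: GroundTruth, block: str,
                  rng: np.random.Generator | None = None,
                  active_ensembles: list[int] | None = None):
    """Simulate one rest block.

    Plants SWR times, movement epochs, and per-ensemble reactivation
    events whose member neurons emit a shared ~180 ms transient (member
    amplitudes jittered ±20 %).  A fraction ``p_swr_coupled`` of
    reactivations onset at a fixed class-specific lag after an SWR
    onset; the rest are placed uniformly in quiet periods.

    Returns ``(activity, movement_mask, reactivation_times, swr_times)``
    where ``reactivation_times`` is a list (one entry per ensemble, in
    ensemble order; empty for inactive ensembles) of onset times in
    seconds.
    """
    if block not in ("rest1", "rest2"):
        raise ValueError("block must be 'rest1' or 'rest2'")
    if rng is None:
        rng = np.random.default_rng(config.seed + (1 if block == "rest1" else 2))
    config.validate()

    fr = config.frame_rate_hz
    n_frames = int(round(config.rest_duration_s * fr))
    duration = n_frames / fr
    mask = _movement_mask(config, n_frames, rng)
    swr_times = _draw_swr_times(config, duration, rng)

    n_ens = len(truth.ensemble_members)
    if active_ensembles is None:
        if block == "rest2":
            active_ensembles = list(range(n_ens))
        else:
            k = int(round(config.rest1_ensemble_frac * n_ens))
            active_ensembles = list(range(k))

    kernel = _transient_kernel(config)
    klen = len(kernel)
    event_sep = max(klen + 1, int(round(0.5 * fr)))  # min event separation

    activity = _background(config, n_frames, rng)
    react_times: list[list[float]] = [[] for _ in range(n_ens)]

    quiet_frames = np.where(~mask)[0]
    quiet_frames = quiet_frames[(quiet_frames > fr)
                                & (quiet_frames < n_frames - klen - 1)]

    # paired cue/trajectory ensembles couple to the same SWR subset so
    # their reactivations are temporally coordinated (cue first, then
    # trajectory at the planted lag); unpaired ensembles draw their own
    n_cue_ens = sum(1 for lab in truth.ensemble_labels if lab == "cue")
    pair_pools: dict = {}
    cue_rank = traj_rank = 0
    pair_keys = []
    for m, lab in enumerate(truth.ensemble_labels):
        if lab == "cue":
            key = ("pair", cue_rank)
            cue_rank += 1
        else:
            key = (("pair", traj_rank) if traj_rank < n_cue_ens
                   else ("solo", m))
            traj_rank += 1
        pair_keys.append(key)
        if key not in pair_pools:
            pool = list(swr_times)
            rng.shuffle(pool)
            pair_pools[key] = pool

    for m in active_ensembles:
        # separation is enforced within an ensemble only: different
        # ensembles may co-reactivate around the same SWR (that is the
        # planted cue->trajectory coupling)
        occupied = np.zeros(n_frames, dtype=bool)

        def try_place(frame: int) -> bool:
            lo = max(0, frame - event_sep)
            hi = min(n_frames, frame + event_sep)
            if frame < 0 or frame + klen >= n_frames or mask[frame] \
                    or occupied[lo:hi].any():
                return False
            occupied[frame:frame + klen] = True
            return True

        label = truth.ensemble_labels[m]
        lag_s = truth.planted_lags_ms[label] / 1000.0
        n_events = rng.poisson(config.reactivation_rate_hz * duration)
        n_coupled = int(round(config.p_swr_coupled * n_events))
        placed = 0
        swr_pool = pair_pools[pair_keys[m]]
        for t_swr in swr_pool:
            if placed >= n_coupled:
                break
            frame = int(round((t_swr + lag_s) * fr))
            if try_place(frame):
                react_times[m].append(frame / fr)
                placed += 1
        attempts = 0
        while placed < n_events:
            attempts += 1
            if attempts > 50 * n_events + 100:
                raise ValueError(
                    "reactivation_rate_hz too high to place "
                    "non-overlapping events in the rest block")
            frame = int(rng.choice(quiet_frames))
            if try_place(frame):
                react_times[m].append(frame / fr)
                placed += 1
        react_times[m].sort()

        members = truth.ensemble_members[m]
        for t0 in react_times[m]:
            f0 = int(round(t0 * fr))
            amps = config.transient_amplitude * rng.uniform(
                0.8, 1.2, size=len(members))
            seg = slice(f0, f0 + klen)
            activity[seg, members] += kernel[:, None] * amps[None, :]

    return activity, mask, react_times, swr_times


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------

def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude-shaped Gaussian noise, unit variance."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec = spec / np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _ripple_band_envelope(x: np.ndarray, rate: float) -> np.ndarray:
    taps = firwin(401, [150.0, 250.0], pass_zero=False, fs=rate)
    filt = filtfilt(taps, [1.0], x)
    win = max(2, int(round(0.008 * rate)))
    from scipy.ndimage import uniform_filter1d
    return np.sqrt(uniform_filter1d(filt ** 2, size=win))


def simulate_lfp(config: SimConfig, swr_times: list[float],
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Pink-noise LFP with amplitude-modulated ~200 Hz bursts at SWR times.

    Each burst is a Hann-windowed sinusoid whose peak ripple-band RMS
    envelope sits ``swr_amplitude_sd`` standard deviations above the
    mean of the background envelope, so detectability is planted in SD
    units exactly as the detector thresholds it.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    rate = config.lfp_rate_hz
    n = int(round(config.rest_duration_s * rate))
    lfp = _pink_noise(n, rng)

    env = _ripple_band_envelope(lfp, rate)
    mu, sd = float(env.mean()), float(env.std())
    target_peak_env = mu + config.swr_amplitude_sd * sd

    dur = config.swr_duration_ms / 1000.0
    blen = int(round(dur * rate))
    t = np.arange(blen) / rate
    # flat-topped (Tukey) amplitude modulation: ripple envelopes plateau
    # rather than peak sharply
    from scipy.signal.windows import tukey
    window = tukey(blen, alpha=0.5)
    taps = firwin(401, [150.0, 250.0], pass_zero=False, fs=rate)
    band_bg = filtfilt(taps, [1.0], lfp)
    for t0 in swr_times:
        s = int(round(t0 * rate))
        if s < 0 or s + blen > n:
            continue
        phase = rng.uniform(0, 2 * np.pi)
        burst = window * np.sin(2 * np.pi * config.ripple_freq_hz * t + phase)
        # the burst replaces the local ripple-band background (during a
        # ripple the band content *is* the event), so the planted SD
        # multiple is realized in the combined envelope; peak RMS
        # envelope of a unit-amplitude windowed sinusoid ~ 1/sqrt(2)
        lfp[s:s + blen] += (burst * target_peak_env * np.sqrt(2.0)
                            - window * band_bg[s:s + blen])
    return lfp


# ---------------------------------------------------------------------------
# full session
# ---------------------------------------------------------------------------

def simulate_full_experiment(config: SimConfig):
    """Compose REST1 / RUN / REST2 (+ LFP) into a full session.

    Returns ``(SessionBundle, GroundTruth)``.  Deterministic for a
    fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = _assign_cells(config, rng)

    run_act, position, velocity, _ = simulate_run(config, truth, rng)

    r1_act, r1_mask, r1_times, r1_swr = simulate_rest(
        config, truth, "rest1", rng)
    r2_act, r2_mask, r2_times, r2_swr = simulate_rest(
        config, truth, "rest2", rng)

    truth.reactivation_times_s = {"rest1": r1_times, "rest2": r2_times}
    truth.swr_times_s = {"rest1": r1_swr, "rest2": r2_swr}

    lfp1 = simulate_lfp(config, r1_swr, rng)
    lfp2 = simulate_lfp(config, r2_swr, rng)

    bundle = SessionBundle(
        rest1=r1_act, run=run_act, rest2=r2_act,
        position_cm=position, velocity_cm_s=velocity,
        rest1_movement_mask=r1_mask, rest2_movement_mask=r2_mask,
        lfp_rest1=lfp1, lfp_rest2=lfp2, meta=config)
    return bundle, truth
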