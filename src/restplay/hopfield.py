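"""Hopfield pattern-completion test on reactivated features.

The network stores two binarized trajectory features (one from an
ensemble pair with significant temporal coupling to a cue ensemble,
one from an uncoupled pair) with the Hebbian outer-product rule, is
probed with the coupled pair's binarized cue feature, and retrieval is
scored by which stored pattern the settled state is nearer to in
Hamming distance.  Patterns are ±1 vectors over the spatial bins;
updates are asynchronous in fixed index order (ties at zero local
field keep the current bit), which guarantees energy descent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

__all__ = ["BinaryPattern", "HopfieldNetwork", "binarize_feature",
           "train", "retrieve", "hamming", "energy",
           "coupled_retrieval_experiment"]


@dataclass
class BinaryPattern:
    bits: np.ndarray         # entries in {-1, +1}
    source: str = ""         # cue_feature | traj_feature

    def __post_init__(self):
        self.bits = np.asarray(self.bits)
        if not np.all(np.isin(self.bits, (-1, 1))):
            raise ValueError("pattern bits must be -1 or +1")


def binarize_feature(feature: np.ndarray, threshold_frac: float = 0.5,
                     source: str = "") -> BinaryPattern:
    """+1 where the min-max-normalized feature exceeds
    ``threshold_frac``, else -1."""
    f = np.asarray(feature, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("feature contains non-finite values")
    rng = f.max() - f.min()
    if rng == 0:
        raise ValueError("flat feature cannot be binarized")
    norm = (f - f.min()) / rng
    bits = np.where(norm > threshold_frac, 1, -1)
    return BinaryPattern(bits=bits, source=source)


def train(patterns: list[BinaryPattern]) -> "HopfieldNetwork":
    net = HopfieldNetwork()
    net.fit(np.stack([p.bits for p in patterns]))
    net.stored_patterns_ = list(patterns)
    return net


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    return int(np.sum(np.asarray(a) != np.asarray(b)))


def energy(weights: np.ndarray, state: np.ndarray) -> float:
    s = np.asarray(state, dtype=float)
    return float(-0.5 * s @ weights @ s)


def retrieve(net: "HopfieldNetwork", probe: BinaryPattern,
             max_sweeps: int = 100) -> tuple[BinaryPattern, bool]:
    """Asynchronous updates until a fixed point (or ``max_sweeps``).

    Returns ``(settled pattern, converged flag)``.
    """
    state, converged = net._settle(probe.bits, max_sweeps)
    return BinaryPattern(bits=state, source=probe.source), converged


class HopfieldNetwork(BaseEstimator):
    """Hebbian Hopfield network with a fit/predict surface.

    ``fit(P)`` stores the rows of a patterns x bits ±1 matrix with the
    outer-product rule (symmetric weights, zero diagonal);
    ``predict(P)`` settles each probe row to its attractor.
    """

    def __init__(self, max_sweeps: int = 100):
        self.max_sweeps = max_sweeps

    def fit(self, X, y=None):
        P = np.asarray(X, dtype=float)
        if P.ndim != 2 or not np.all(np.isin(P, (-1, 1))):
            raise ValueError("patterns must be a 2-D ±1 array")
        n = P.shape[1]
        W = P.T @ P / n
        np.fill_diagonal(W, 0.0)
        self.weights_ = W
        self.stored_patterns_ = [BinaryPattern(bits=row.astype(int))
                                 for row in P]
        return self

    def _settle(self, bits: np.ndarray, max_sweeps: int | None = None
                ) -> tuple[np.ndarray, bool]:
        if max_sweeps is None:
            max_sweeps = self.max_sweeps
        state = np.asarray(bits, dtype=float).copy()
        n = len(state)
        if n != self.weights_.shape[0]:
            raise ValueError("probe length does not match network size")
        for _ in range(max_sweeps):
            changed = False
            for i in range(n):   # fixed scan order; h == 0 keeps the bit
                h = self.weights_[i] @ state
                new = state[i] if h == 0 else (1.0 if h > 0 else -1.0)
                if new != state[i]:
                    state[i] = new
                    changed = True
            if not changed:
                return state.astype(int), True
        return state.astype(int), False

    def predict(self, X):
        P = np.atleast_2d(np.asarray(X))
        return np.stack([self._settle(row)[0] for row in P])


def coupled_retrieval_experiment(cue_features: dict, traj_features: dict,
                                 coupled_pairs: list[tuple[int, int]],
                                 threshold_frac: float = 0.5,
                                 max_sweeps: int = 100) -> dict:
    """Pattern-completion score over all (coupled, uncoupled) storage
    combinations.

    ``cue_features`` / ``traj_features`` map ensemble ids to 50-bin
    reactivated features; ``coupled_pairs`` lists (cue_id, traj_id)
    pairs with significant temporal coupling.  For every coupled pair
    and every trajectory feature not coupled to that cue, the network
    stores the two binarized trajectory features, is probed with the
    coupled cue feature, and the trial succeeds when the settled state
    is strictly nearer (Hamming) to the coupled trajectory pattern.
    Ties (including identical stored patterns) are counted as
    indeterminate.

    Returns a dict with per-trial outcomes, the success fraction among
    determinate trials, and cue-to-trajectory Hamming distances for
    coupled vs uncoupled pairs.
    """
    coupled_set = set(coupled_pairs)
    trials = []
    d_coupled, d_uncoupled = [], []

    for (ci, ti) in coupled_pairs:
        try:
            p_cue = binarize_feature(cue_features[ci], threshold_frac, "cue")
            p_traj = binarize_feature(traj_features[ti], threshold_frac,
                                      "traj")
        except ValueError:
            continue
        d_coupled.append(hamming(p_cue.bits, p_traj.bits))
        uncoupled_ids = [tj for tj in traj_features
                         if (ci, tj) not in coupled_set]
        for tj in uncoupled_ids:
            try:
                p_unc = binarize_feature(traj_features[tj], threshold_frac,
                                         "traj")
            except ValueError:
                continue
            d_uncoupled.append(hamming(p_cue.bits, p_unc.bits))
            if np.array_equal(p_traj.bits, p_unc.bits):
                trials.append({"cue": ci, "coupled_traj": ti,
                               "uncoupled_traj": tj, "outcome": "tie"})
                continue
            net = train([p_traj, p_unc])
            settled, _ = retrieve(net, p_cue, max_sweeps)
            dc = hamming(settled.bits, p_traj.bits)
            du = hamming(settled.bits, p_unc.bits)
            outcome = ("coupled" if dc < du
                       else "uncoupled" if du < dc else "tie")
            trials.append({"cue": ci, "coupled_traj": ti,
                           "uncoupled_traj": tj, "outcome": outcome})

    determinate = [t for t in trials if t["outcome"] != "tie"]
    n_ok = sum(t["outcome"] == "coupled" for t in determinate)
    frac = n_ok / len(determinate) if determinate else float("nan")
    return {
        "trials": trials,
        "n_trials": len(trials),
        "success_fraction": frac,
        "hamming_coupled": d_coupled,
        "hamming_uncoupled": d_uncoupled,
    }
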