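"""Seeded PCA-ICA estimation of per-ensemble reactivation strength.

The detected ensembles provide a seed basis W-tilde whose column m is
the unit indicator vector of ensemble m's members (entries
1/sqrt(|members|)); disjoint memberships make the basis orthonormal.
The z-scored rest matrix X is de-noised by removing the seeded
subspace, X-hat = X - X W W^T, PCA on the residual correlation matrix
keeps the L eigenvectors above the Marcenko-Pastur bound
lambda_+ = (1 + sqrt(N/T))^2, and the concatenated orthonormal basis
W' = [W-tilde | Sigma_lambda+] defines a k = M + L dimensional
subspace.  Projecting X onto W' and running reconstruction ICA

    minimize_W  (1/T) sum_i ||x_i - x_i W W^T||^2
                + beta * sum_i sum_j g(x_i W_j),    g(x) = 0.5 log cosh(2x)

from W = identity refines the within-subspace rotation; the first M
columns of W' W^T are the final ensemble components.  Projecting any
standardized block onto a component gives that ensemble's reactivation
strength over time; supra-(mean + 3 SD) excursions, extended to 25 % of
that threshold, are reactivation events.  Projecting the RUN block and
averaging by spatial bin gives the reactivated feature of an ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .spatial import bin_index

__all__ = [
    "SeedBasis", "PcaSelection", "IcaModel", "ReactivationEvent",
    "build_seed_basis", "standardize", "denoise_residual",
    "select_components", "fit_reconstruction_ica", "reactivation_strength",
    "detect_reactivation_events", "extract_run_features",
    "ReactivationModel",
]


@dataclass
class SeedBasis:
    W: np.ndarray            # neurons x M, unit indicator columns

    @property
    def n_ensembles(self) -> int:
        return self.W.shape[1]


@dataclass
class PcaSelection:
    eigvals: np.ndarray
    eigvecs: np.ndarray
    lambda_plus: float
    kept: np.ndarray         # neurons x L


@dataclass
class IcaModel:
    W_prime: np.ndarray      # neurons x k concatenated basis
    W: np.ndarray            # k x k rotation
    components: np.ndarray   # neurons x M final, unit-norm
    objective_trace: list = field(default_factory=list)
    converged: bool = True


@dataclass
class ReactivationEvent:
    ensemble_id: int
    onset_s: float
    offset_s: float
    peak_s: float
    peak_strength: float


def build_seed_basis(member_sets: list[list[int]], n_neurons: int) -> SeedBasis:
    """Unit indicator columns for disjoint ensemble member sets."""
    seen: set[int] = set()
    for members in member_sets:
        s = set(members)
        if s & seen:
            raise ValueError("ensemble member sets must be disjoint")
        seen |= s
    W = np.zeros((n_neurons, len(member_sets)))
    for m, members in enumerate(member_sets):
        if len(members) == 0:
            raise ValueError("empty ensemble")
        W[list(members), m] = 1.0 / np.sqrt(len(members))
    return SeedBasis(W=W)


def standardize(X: np.ndarray, mean: np.ndarray | None = None,
                sd: np.ndarray | None = None):
    """Z-score columns; returns (Z, mean, sd).  Zero-variance columns
    are left centred at zero."""
    X = np.asarray(X, dtype=float)
    if mean is None:
        mean = X.mean(axis=0)
    if sd is None:
        sd = X.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / safe, mean, sd


def denoise_residual(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Residual after removing the seeded subspace: X - X W W^T."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != W.shape[0]:
        raise ValueError("X columns must match seed basis rows")
    return X - (X @ W) @ W.T


def select_components(X_hat: np.ndarray, use_correlation: bool = True
                      ) -> PcaSelection:
    """Eigen-decomposition of the residual correlation matrix, keeping
    eigenvectors above the Marcenko-Pastur bound (1 + sqrt(N/T))^2.

    Degenerate (zero-variance) residual columns are excluded from the
    correlation and re-inserted as zero rows in the kept eigenvectors.
    """
    X_hat = np.asarray(X_hat, dtype=float)
    T, N = X_hat.shape
    lam_plus = (1.0 + np.sqrt(N / T)) ** 2
    sd = X_hat.std(axis=0)
    ok = sd > 1e-12
    if ok.sum() == 0:
        return PcaSelection(eigvals=np.zeros(N), eigvecs=np.zeros((N, N)),
                            lambda_plus=lam_plus, kept=np.zeros((N, 0)))
    sub = X_hat[:, ok]
    C = np.corrcoef(sub, rowvar=False) if use_correlation \
        else np.cov(sub, rowvar=False)
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > lam_plus
    kept = np.zeros((N, int(keep.sum())))
    kept[ok] = vecs[:, keep]
    full_vals = np.zeros(N)
    full_vals[: len(vals)] = vals
    full_vecs = np.zeros((N, N))
    full_vecs[np.ix_(ok, np.arange(len(vals)))] = vecs
    return PcaSelection(eigvals=full_vals, eigvecs=full_vecs,
                        lambda_plus=lam_plus, kept=kept)


# ---------------------------------------------------------------------------
# reconstruction ICA
# ---------------------------------------------------------------------------

def _rica_objective_grad(Xp: np.ndarray, W: np.ndarray, beta: float):
    """Objective (mean reconstruction error + log-cosh penalty) and its
    gradient in the projected space."""
    T = Xp.shape[0]
    C = Xp.T @ Xp               # k x k
    Y = Xp @ W                  # T x k
    # reconstruction term: (1/T) ||Xp - Y W^T||_F^2
    R = Xp - Y @ W.T
    j1 = float(np.sum(R * R)) / T
    g1 = (2.0 / T) * (C @ W @ (W.T @ W) + W @ (W.T @ C @ W) - 2.0 * C @ W)
    # penalty: beta * mean_i sum_j 0.5 log cosh(2 y_ij)
    j2 = beta * float(np.sum(0.5 * np.log(np.cosh(2.0 * Y)))) / T
    g2 = beta * (Xp.T @ np.tanh(2.0 * Y)) / T
    return j1 + j2, g1 + g2


def fit_reconstruction_ica(X: np.ndarray, W_prime: np.ndarray,
                           penalty_weight: float = 1.0,
                           max_iter: int = 500, tol: float = 1e-6,
                           n_ensembles: int | None = None) -> IcaModel:
    """Reconstruction ICA on the projection of X onto W'.

    Gradient descent with backtracking line search from W = identity
    (deterministic).  Returns the rotation, the unit-norm final
    components (first M columns of W' W^T, sign-fixed so the largest-
    magnitude weight is positive) and the per-iteration objective.
    """
    X = np.asarray(X, dtype=float)
    k = W_prime.shape[1]
    if n_ensembles is None:
        n_ensembles = k
    Xp = X @ W_prime
    scale = np.sqrt(np.mean(Xp ** 2))
    if scale > 0:            # global scaling so the penalty is data-size free
        Xp = Xp / scale

    W = np.eye(k)
    obj, grad = _rica_objective_grad(Xp, W, penalty_weight)
    trace = [obj]
    step = 1.0
    converged = False
    for _ in range(max_iter):
        gnorm2 = float(np.sum(grad * grad))
        # gradient-norm convergence: a relative-objective rule stalls in
        # the slow rotation phase long before the separating optimum
        if np.sqrt(gnorm2) < tol * max(1.0, abs(obj)):
            converged = True
            break
        # backtracking (Armijo) line search
        accepted = False
        for _ in range(40):
            W_new = W - step * grad
            obj_new, grad_new = _rica_objective_grad(Xp, W_new, penalty_weight)
            if obj_new <= obj - 1e-4 * step * gnorm2:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        W, obj, grad = W_new, obj_new, grad_new
        trace.append(obj)
        step = min(step * 2.0, 1e3)

    # In the row-vector convention of the objective (x_i W_j are the
    # separated coordinates) the neuron-space filters are W'W; the
    # transpose form seen with column-vector conventions would apply
    # the inverse rotation and re-mix the sources.
    comps = (W_prime @ W)[:, :n_ensembles]
    norms = np.linalg.norm(comps, axis=0)
    norms[norms == 0] = 1.0
    comps = comps / norms
    for j in range(comps.shape[1]):           # sign convention
        i = np.argmax(np.abs(comps[:, j]))
        if comps[i, j] < 0:
            comps[:, j] *= -1.0
    return IcaModel(W_prime=W_prime, W=W, components=comps,
                    objective_trace=trace, converged=converged)


def reactivation_strength(X_block: np.ndarray,
                          components: np.ndarray) -> np.ndarray:
    """Projection of a standardized block onto the ensemble components
    (frames x M)."""
    X_block = np.asarray(X_block, dtype=float)
    if X_block.shape[1] != components.shape[0]:
        raise ValueError("block and components disagree on neuron count")
    return X_block @ components


def detect_reactivation_events(strength: np.ndarray, frame_rate_hz: float,
                               ensemble_id: int = 0,
                               n_sd: float = 3.0,
                               boundary_frac: float = 0.25
                               ) -> list[ReactivationEvent]:
    """Supra-threshold excursions of one ensemble's strength series.

    The threshold is mean + ``n_sd`` SD of the series; event bounds are
    extended outward to the first crossing of ``boundary_frac`` of that
    threshold, and events whose extended bounds overlap are merged.
    """
    s = np.asarray(strength, dtype=float)
    mu, sd = s.mean(), s.std()
    if sd == 0:
        return []
    theta = mu + n_sd * sd
    low = boundary_frac * theta
    core = s > theta
    if not core.any():
        return []
    events = []
    T = len(s)
    i = 0
    while i < T:
        if core[i]:
            j = i
            while j + 1 < T and core[j + 1]:
                j += 1
            on = i
            while on > 0 and s[on - 1] > low:
                on -= 1
            off = j
            while off + 1 < T and s[off + 1] > low:
                off += 1
            seg = slice(on, off + 1)
            peak = on + int(np.argmax(s[seg]))
            events.append([on, off, peak])
            i = off + 1
        else:
            i += 1
    # merge overlapping extended events
    merged = [events[0]]
    for on, off, peak in events[1:]:
        if on <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], off)
            if s[peak] > s[merged[-1][2]]:
                merged[-1][2] = peak
        else:
            merged.append([on, off, peak])
    out = []
    for on, off, peak in merged:
        if peak <= on:
            # no rising flank: a single-frame spike that never leaves
            # the boundary threshold is not a transient event
            continue
        out.append(ReactivationEvent(
            ensemble_id=ensemble_id, onset_s=on / frame_rate_hz,
            offset_s=off / frame_rate_hz, peak_s=peak / frame_rate_hz,
            peak_strength=float((s[peak] - mu) / sd)))
    return out


def extract_run_features(X_run_std: np.ndarray, components: np.ndarray,
                         position_cm: np.ndarray, n_bins: int = 50,
                         belt_length_cm: float = 150.0) -> np.ndarray:
    """Per-ensemble mean projected RUN activity by spatial bin
    (M x n_bins)."""
    proj = reactivation_strength(X_run_std, components)  # frames x M
    idx = bin_index(np.asarray(position_cm, float), n_bins, belt_length_cm)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    feats = np.zeros((components.shape[1], n_bins))
    for m in range(components.shape[1]):
        sums = np.bincount(idx, weights=proj[:, m], minlength=n_bins)
        np.divide(sums, counts, out=feats[m], where=counts > 0)
    return feats


class ReactivationModel(TransformerMixin, BaseEstimator):
    """Seeded PCA-ICA reactivation model with a sklearn fit/transform
    surface.

    ``fit(X, member_sets=...)`` standardizes the rest block (excluding
    movement frames when a mask is given), builds the seed basis,
    removes its subspace, keeps supra-Marcenko-Pastur residual
    eigenvectors, and refines the rotation by reconstruction ICA.
    ``transform(X)`` returns per-frame reactivation strengths of any
    block standardized with the rest-fit statistics.
    """

    def __init__(self, penalty_weight: float = 1.0, max_iter: int = 500,
                 tol: float = 1e-6, frame_rate_hz: float = 19.0,
                 use_ica: bool = True):
        self.penalty_weight = penalty_weight
        self.max_iter = max_iter
        self.tol = tol
        self.frame_rate_hz = frame_rate_hz
        self.use_ica = use_ica

    def fit(self, X, y=None, *, member_sets, movement_mask=None):
        X = np.asarray(X, dtype=float)
        fit_X = X[~np.asarray(movement_mask, bool)] \
            if movement_mask is not None else X
        Z, self.mean_, self.sd_ = standardize(fit_X)
        self.seed_ = build_seed_basis(member_sets, X.shape[1])
        X_hat = denoise_residual(Z, self.seed_.W)
        self.pca_ = select_components(X_hat)
        kept = self.pca_.kept
        if kept.size:
            # correlation-matrix eigenvectors are only approximately
            # orthogonal to the seed subspace (exactly so for the
            # covariance); re-orthonormalize to keep W' an orthonormal
            # basis as the concatenation requires
            kept = kept - self.seed_.W @ (self.seed_.W.T @ kept)
            kept, _ = np.linalg.qr(kept)
        self.W_prime_ = np.concatenate([self.seed_.W, kept], axis=1)
        if self.use_ica:
            self.ica_ = fit_reconstruction_ica(
                Z, self.W_prime_, penalty_weight=self.penalty_weight,
                max_iter=self.max_iter, tol=self.tol,
                n_ensembles=self.seed_.n_ensembles)
            self.components_ = self.ica_.components
        else:
            self.components_ = self.seed_.W.copy()
        return self

    def transform(self, X):
        Z, _, _ = standardize(np.asarray(X, float), self.mean_, self.sd_)
        return reactivation_strength(Z, self.components_)

    def detect_events(self, X, zscore_strength: bool = True
                      ) -> list[ReactivationEvent]:
        """Reactivation events for every ensemble in a block."""
        S = self.transform(X)
        events = []
        for m in range(S.shape[1]):
            events.extend(detect_reactivation_events(
                S[:, m], self.frame_rate_hz, ensemble_id=m))
        return events

    def run_features(self, X_run, position_cm, n_bins: int = 50,
                     belt_length_cm: float = 150.0) -> np.ndarray:
        Z, _, _ = standardize(np.asarray(X_run, float), self.mean_, self.sd_)
        return extract_run_features(Z, self.components_, position_cm,
                                    n_bins, belt_length_cm)
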