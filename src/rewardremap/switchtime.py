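"""Trial-resolved remap-time detection.

Population activity (trials x bins x neurons, each neuron min-max scaled
over the session) is factorized by k-means with k = 2: U assigns each trial
to a cluster (one-hot) and V holds the two bins x neurons centroid "maps".
Model quality is validated with a speckled (element-wise) 10% holdout
against a trial-rotation null.  A signed distance score locates each trial's
population vector along the inter-centroid axis (-1 at the first map of the
session, +1 at the second); the inflection point of a sigmoid fit to the
distance-score time course is the *remap trial*.  Running licking and speed
maps through the identical pipeline gives behavioral remap trials, and the
neural-behavioral differences are the remap lags.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit


@dataclass
class ClusterModel:
    U: np.ndarray          # (n_trials, k) one-hot assignments
    V: np.ndarray          # (k, n_bins, n_neurons) centroids
    objective: float       # within-cluster SSE
    restarts: int

    @property
    def labels(self):
        return self.U.argmax(axis=1)


def normalize_01(values):
    """Min-max scale each neuron over the session; constant neurons -> 0.

    ``values`` is trials x bins x neurons (or trials x bins for a single
    behavioral channel).  Returns (scaled, constant_mask).
    """
    v = np.asarray(values, dtype=float)
    squeeze = v.ndim == 2
    if squeeze:
        v = v[:, :, None]
    lo = np.nanmin(v, axis=(0, 1), keepdims=True)
    hi = np.nanmax(v, axis=(0, 1), keepdims=True)
    rng_ = hi - lo
    constant = (rng_ == 0)[0, 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (v - lo) / rng_
    out[np.broadcast_to(constant[None, None, :], out.shape)] = 0.0
    out = np.nan_to_num(out, nan=0.0)
    if squeeze:
        return out[:, :, 0], constant
    return out, constant


def _lloyd(X, k, rng, max_iter=100, weights=None):
    """One Lloyd run on rows of X; returns (labels, centers, sse).

    ``weights`` is an optional observation mask (same shape as X) for
    speckled-holdout fitting: masked-out entries are ignored in both the
    assignment distances and the centroid means.
    """
    n = X.shape[0]
    W = np.ones_like(X) if weights is None else weights
    centers = X[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    for _ in range(max_iter):
        d = np.zeros((n, k))
        for j in range(k):
            diff = (X - centers[j]) ** 2 * W
            d[:, j] = diff.sum(axis=1)
        new = d.argmin(axis=1)
        if np.array_equal(new, labels):
            break
        labels = new
        for j in range(k):
            sel = labels == j
            if not sel.any():
                centers[j] = X[rng.integers(n)]
                continue
            wsum = W[sel].sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                c = (X[sel] * W[sel]).sum(axis=0) / wsum
            centers[j] = np.where(wsum > 0, c, centers[j])
    sse = sum(((X[labels == j] - centers[j]) ** 2 * W[labels == j]).sum()
              for j in range(k))
    return labels, centers, sse


def factorized_kmeans(X, k=2, restarts=100, rng=None, weights=None
                      ) -> ClusterModel:
    """k-means on trials (rows = flattened bins x neurons vectors).

    Best of ``restarts`` Lloyd runs by within-cluster SSE.  Cluster 1 is
    standardized to the cluster of the first trial in the session.
    """
    v = np.asarray(X, dtype=float)
    if v.ndim == 2:
        v = v[:, :, None]
    n_trials, n_bins, n_neurons = v.shape
    if k > n_trials:
        raise ValueError("k exceeds the number of trials")
    flat = v.reshape(n_trials, -1)
    wflat = None if weights is None else np.asarray(weights, float).reshape(n_trials, -1)
    rng = np.random.default_rng(rng)
    best = None
    for _ in range(restarts):
        labels, centers, sse = _lloyd(flat, k, rng, weights=wflat)
        if best is None or sse < best[2]:
            best = (labels, centers, sse)
    labels, centers, sse = best
    # first cluster appearing in the session gets index 0
    order = []
    for lab in labels:
        if lab not in order:
            order.append(lab)
    order += [j for j in range(k) if j not in order]
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[l] for l in labels])
    centers = centers[order]
    U = np.zeros((n_trials, k))
    U[np.arange(n_trials), labels] = 1.0
    V = centers.reshape(k, n_bins, n_neurons)
    return ClusterModel(U=U, V=V, objective=float(sse), restarts=restarts)


def _uncentered_r2(x_true, x_hat):
    ss = np.sum(x_true**2)
    if ss == 0:
        return np.nan
    return 1.0 - np.sum((x_true - x_hat) ** 2) / ss


def _random_rotation(n, rng):
    """Haar-random orthogonal matrix (QR of a Gaussian matrix)."""
    A = rng.standard_normal((n, n))
    Q, R = np.linalg.qr(A)
    return Q * np.sign(np.diag(R))


def kmeans_significance(X, k=2, holdout=0.10, reps=50, restarts=10,
                        rng=None, p_threshold=0.05):
    """Speckled-holdout test of the k = 2 factorization vs a rotation null.

    For each repetition, 10% of the entries are held out; the model is fit
    on the rest and scored by uncentered R^2 on the held-out entries.  The
    null applies a random orthogonal rotation across the trial axis before
    the same procedure.  Returns (include, p, real_r2, null_r2): ``include``
    is True when real beats null (one-sided Wilcoxon signed-rank P <
    ``p_threshold``).
    """
    if holdout <= 0:
        raise ValueError("holdout must be > 0")
    v = np.asarray(X, dtype=float)
    if v.ndim == 2:
        v = v[:, :, None]
    rng = np.random.default_rng(rng)
    flat = v.reshape(v.shape[0], -1)
    n_trials = flat.shape[0]

    def score(mat, rep_rng):
        mask = rep_rng.random(mat.shape) >= holdout   # observed entries
        model = factorized_kmeans(
            mat[:, :, None], k=k, restarts=restarts, rng=rep_rng,
            weights=mask[:, :, None].astype(float))
        recon = model.V.reshape(k, -1)[model.labels]
        held = ~mask
        return _uncentered_r2(mat[held], recon[held])

    real = np.empty(reps)
    null = np.empty(reps)
    for r in range(reps):
        rep_rng = np.random.default_rng(rng.integers(2**31))
        real[r] = score(flat, rep_rng)
        Q = _random_rotation(n_trials, rep_rng)
        null[r] = score(Q @ flat, rep_rng)
    diff = real - null
    if np.allclose(diff, 0):
        return False, 1.0, real, null
    stat = stats.wilcoxon(real, null, alternative="greater")
    include = bool(stat.pvalue < p_threshold)
    return include, float(stat.pvalue), real, null


def silhouette_by_k(X, ks=(2, 3, 4), restarts=20, rng=None):
    """Silhouette score of the trial clustering for each k (diagnostic).

    Supports checking that the two-map description (k = 2) is not beaten by
    a finer partition.  Returns {k: score}.
    """
    from sklearn.metrics import silhouette_score

    v = np.asarray(X, dtype=float)
    if v.ndim == 2:
        v = v[:, :, None]
    flat = v.reshape(v.shape[0], -1)
    rng = np.random.default_rng(rng)
    out = {}
    for k in ks:
        model = factorized_kmeans(v, k=k, restarts=restarts,
                                  rng=np.random.default_rng(rng.integers(2**31)))
        labels = model.labels
        if len(np.unique(labels)) < 2:
            out[k] = np.nan
            continue
        out[k] = float(silhouette_score(flat, labels))
    return out


@dataclass
class DistanceScoreSeries:
    P: np.ndarray                 # per-trial distance score
    params: Optional[dict]        # sigmoid fit: floor, ceiling, slope, inflection
    remap_trial: float            # inflection (NaN if not converged)
    converged: bool


def distance_score(X, V1, V2):
    """Signed position of each trial along the inter-centroid axis.

    -1 at the first centroid, +1 at the second, 0 at the midpoint: the
    normalized projection of (X_i - midpoint) onto (V2 - V1).
    """
    v = np.asarray(X, dtype=float)
    if v.ndim == 2:
        v = v[:, :, None]
    flat = v.reshape(v.shape[0], -1)
    v1 = np.asarray(V1, dtype=float).ravel()
    v2 = np.asarray(V2, dtype=float).ravel()
    axis = v2 - v1
    denom = np.sum(axis**2)
    if denom == 0:
        return np.full(flat.shape[0], np.nan)
    mid = (v1 + v2) / 2
    return 2.0 * (flat - mid) @ axis / denom


def _sigmoid(t, a, b, s, t0):
    z = np.clip(-s * (t - t0), -500, 500)
    return a + (b - a) / (1.0 + np.exp(z))


def fit_remap_sigmoid(P, rng=None) -> DistanceScoreSeries:
    """4-parameter logistic fit to a distance-score series.

    The remap trial is the inflection t0.  Initialization at the trial of
    the largest score step; bounds keep t0 within the session and the slope
    positive.  Flat or non-sigmoidal series are flagged unconverged.
    """
    P = np.asarray(P, dtype=float)
    t = np.arange(len(P), dtype=float)
    ok = np.isfinite(P)
    if ok.sum() < 5 or np.nanstd(P) == 0:
        return DistanceScoreSeries(P=P, params=None, remap_trial=np.nan,
                                   converged=False)
    dP = np.abs(np.diff(P[ok]))
    t0_init = t[ok][np.argmax(dP)] + 0.5 if len(dP) else len(P) / 2
    p0 = [np.nanmin(P), np.nanmax(P), 1.0, t0_init]
    bounds = ([-2.0, -2.0, 1e-3, 0.0], [2.0, 2.0, 50.0, len(P) - 1.0])
    try:
        popt, _ = curve_fit(_sigmoid, t[ok], P[ok], p0=p0, bounds=bounds,
                            maxfev=5000)
    except RuntimeError:
        return DistanceScoreSeries(P=P, params=None, remap_trial=np.nan,
                                   converged=False)
    a, b, s, t0 = popt
    # a flat "sigmoid" (negligible step) carries no transition information
    converged = abs(b - a) > 0.2 and np.nanstd(P) > 0.05
    params = dict(floor=float(a), ceiling=float(b), slope=float(s),
                  inflection=float(t0))
    return DistanceScoreSeries(P=P, params=params,
                               remap_trial=float(t0) if converged else np.nan,
                               converged=converged)


def remap_trial_pipeline(values, k=2, restarts=100, rng=None
                         ) -> tuple[DistanceScoreSeries, ClusterModel]:
    """Scale -> k-means -> distance score -> sigmoid, for one input tensor.

    ``values`` is trials x bins x neurons (population) or trials x bins
    (licking or speed map).
    """
    scaled, _ = normalize_01(values)
    if scaled.ndim == 2:
        scaled = scaled[:, :, None]
    model = factorized_kmeans(scaled, k=k, restarts=restarts, rng=rng)
    P = distance_score(scaled, model.V[0], model.V[1])
    series = fit_remap_sigmoid(P)
    return series, model


def lag_table(remap_trials: dict, session_id=0) -> pd.DataFrame:
    """Neural-vs-behavioral remap lags for one session.

    ``remap_trials`` maps domain name ('neural_PV', 'licking', 'speed') to
    the fitted remap trial (NaN when the sigmoid did not converge).  The lag
    is expressed as the neural *lead*: behavioral remap trial minus neural
    remap trial, positive when the population map updates first.  Sessions
    with any missing domain are excluded, matching the convergence rule for
    lag comparisons.
    """
    needed = ("neural_PV", "licking", "speed")
    if any(not np.isfinite(remap_trials.get(d, np.nan)) for d in needed):
        return pd.DataFrame(columns=["session", "neural_lead_over_lick",
                                     "neural_lead_over_speed"])
    return pd.DataFrame([dict(
        session=session_id,
        neural_lead_over_lick=remap_trials["licking"] - remap_trials["neural_PV"],
        neural_lead_over_speed=remap_trials["speed"] - remap_trials["neural_PV"],
    )])
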