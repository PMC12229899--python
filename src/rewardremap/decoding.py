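"""Circular-linear decoding of reward-relative position.

A linear decoder maps population event rates to the unit-circle embedding
(cos y, sin y) of the animal's reward-relative phase y; the prediction is
read out as atan2(sin-part, cos-part).  The per-sample decode score is
cos(y - y_hat): 1 for perfect prediction, ~0 for random prediction.
Performance is z-scored against shuffles in which each cell's time series is
independently circularly shifted, destroying its tuning while preserving its
autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .remapping import align_to_reward, to_periodic, wrap_phase
from .signals import SPEED_MIN_CMS, valid_frame_mask


@dataclass
class CircularDecoder:
    weights: np.ndarray   # (n_neurons + 1, 2) for [cos, sin]; last row = bias
    ridge: float

    def predict(self, X):
        Xb = np.column_stack([X, np.ones(len(X))])
        cs = Xb @ self.weights
        return np.arctan2(cs[:, 1], cs[:, 0])


def fit_circular_decoder(activity, phases, ridge=1e-3) -> CircularDecoder:
    """Ridge-regularized linear maps from activity onto (cos y, sin y)."""
    X = np.asarray(activity, dtype=float)
    y = np.asarray(phases, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a samples x neurons matrix with >= 2 neurons")
    if X.shape[0] < 100:
        raise ValueError("need at least 100 samples")
    Xb = np.column_stack([X, np.ones(len(X))])
    T = np.column_stack([np.cos(y), np.sin(y)])
    pen = np.full(Xb.shape[1], ridge)
    pen[-1] = 0.0  # no penalty on the bias
    W = np.linalg.solve(Xb.T @ Xb + np.diag(pen), Xb.T @ T)
    return CircularDecoder(weights=W, ridge=ridge)


def decode_score(y_true, y_pred):
    """Per-sample cos(y - y_hat)."""
    return np.cos(wrap_phase(np.asarray(y_true) - np.asarray(y_pred)))


@dataclass
class DecodeResult:
    mean_score: float
    fold_scores: np.ndarray
    shuffle_scores: np.ndarray    # mean score of each shuffled dataset
    z: float
    z_per_bin: np.ndarray         # z-scored score per RR-position bin
    y_true: np.ndarray
    y_pred: np.ndarray


def _rr_samples(session, cells, speed_min=SPEED_MIN_CMS):
    """(activity samples x cells, rr phase, trial id) at running samples."""
    fr = session.frames
    pos = fr["position_cm"].to_numpy()
    ok = valid_frame_mask(pos, fr["speed_cms"].to_numpy(),
                          fr["teleport"].to_numpy(), speed_min)
    trial = fr["trial"].to_numpy()
    zone_phase = to_periodic(
        session.trials["zone_start_cm"].to_numpy(), session.track_length_cm)
    y = align_to_reward(to_periodic(pos[ok], session.track_length_cm),
                        zone_phase[trial[ok]])
    X = session.events[np.asarray(cells)][:, ok].T.astype(float)
    return X, y, trial[ok]


def _match_occupancy(y, n_bins, rng):
    """Indices downsampled (without replacement) to equal RR-bin occupancy."""
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    bi = np.clip(np.digitize(y, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(bi, minlength=n_bins)
    m = counts[counts > 0].min()
    keep = []
    for b in range(n_bins):
        idx = np.nonzero(bi == b)[0]
        if len(idx) > 0:
            keep.append(rng.choice(idx, size=m, replace=False))
    return np.sort(np.concatenate(keep))


def _mean_scores(Xtr, ytr, Xte, yte, n_folds, rng, ridge):
    """Mean decode score; K-fold within one set when Xte is None."""
    if Xte is None:
        order = rng.permutation(len(ytr))
        folds = np.array_split(order, n_folds)
        scores = []
        preds = np.full(len(ytr), np.nan)
        for k in range(n_folds):
            te = folds[k]
            tr = np.concatenate([folds[j] for j in range(n_folds) if j != k])
            dec = fit_circular_decoder(Xtr[tr], ytr[tr], ridge)
            preds[te] = dec.predict(Xtr[te])
            scores.append(decode_score(ytr[te], preds[te]).mean())
        return np.array(scores), ytr, preds
    dec = fit_circular_decoder(Xtr, ytr, ridge)
    preds = dec.predict(Xte)
    return np.array([decode_score(yte, preds).mean()]), yte, preds


def decode_protocol(session, cells, mode="within_before", n_folds=10,
                    n_shuffles=100, rng=None, ridge=1e-3,
                    last_n_post=30) -> DecodeResult:
    """Cross-validated RR-position decoding with occupancy matching.

    ``mode`` is ``within_before`` (10-fold CV on pre-switch trials) or
    ``before_after`` (train on pre-switch, test on the last ``last_n_post``
    post-switch trials).  Occupancy is equalized across the 45 RR-phase bins
    by seeded downsampling.  ``n_shuffles`` shuffled datasets (independent
    circular shifts of each cell's time series) give the null score
    distribution used for z-scoring, overall and per RR bin.
    """
    cells = np.asarray(cells)
    if len(cells) == 0:
        raise ValueError("empty subpopulation")
    rng = np.random.default_rng(rng)
    n_bins = session.n_bins
    X, y, trial = _rr_samples(session, cells)
    pre, post = session.trial_sets()
    post_use = post[-last_n_post:]
    in_pre = np.isin(trial, pre)
    in_post = np.isin(trial, post_use)

    def run(Xall):
        tr_idx = np.nonzero(in_pre)[0]
        tr_idx = tr_idx[_match_occupancy(y[in_pre], n_bins, rng)]
        if mode == "within_before":
            return _mean_scores(Xall[tr_idx], y[tr_idx], None, None,
                                n_folds, rng, ridge)
        te_idx = np.nonzero(in_post)[0]
        te_idx = te_idx[_match_occupancy(y[in_post], n_bins, rng)]
        return _mean_scores(Xall[tr_idx], y[tr_idx], Xall[te_idx], y[te_idx],
                            n_folds, rng, ridge)

    fold_scores, y_eval, y_pred = run(X)
    real = fold_scores.mean()
    per_sample = decode_score(y_eval, y_pred)

    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    bi = np.clip(np.digitize(y_eval, edges) - 1, 0, n_bins - 1)
    real_bin = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = bi == b
        if sel.any():
            real_bin[b] = per_sample[sel].mean()

    n_samples = X.shape[0]
    shuffle_scores = np.empty(n_shuffles)
    shuffle_bins = np.full((n_shuffles, n_bins), np.nan)
    for s in range(n_shuffles):
        shifts = rng.integers(1, n_samples, size=X.shape[1])
        Xs = np.empty_like(X)
        for j in range(X.shape[1]):
            Xs[:, j] = np.roll(X[:, j], shifts[j])
        fs, ys, ps = run(Xs)
        shuffle_scores[s] = fs.mean()
        sc = decode_score(ys, ps)
        bs = np.clip(np.digitize(ys, edges) - 1, 0, n_bins - 1)
        for b in range(n_bins):
            sel = bs == b
            if sel.any():
                shuffle_bins[s, b] = sc[sel].mean()

    sd = shuffle_scores.std(ddof=1)
    z = (real - shuffle_scores.mean()) / sd if sd > 0 else np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        bin_sd = np.nanstd(shuffle_bins, axis=0, ddof=1)
        z_bin = (real_bin - np.nanmean(shuffle_bins, axis=0)) / bin_sd
    return DecodeResult(
        mean_score=float(real), fold_scores=fold_scores,
        shuffle_scores=shuffle_scores, z=float(z), z_per_bin=z_bin,
        y_true=y_eval, y_pred=y_pred,
    )
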