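"""Spatial information, shuffle significance, and spatial peaks.

Spatial information (SI) of a neuron over binned positions:

    SI = sum_i p_i (f_i / f) log2(f_i / f)

with p_i the session-wide occupancy probability of bin i, f_i the
trial-averaged activity in bin i, and f = sum_i f_i p_i.  Significance is
assessed against a null built by circularly shifting each trial's activity
relative to position by an independent random offset (at least ~1 s), with
the null pooled across all simultaneously recorded cells: a cell is
significant when its true SI exceeds the 95th percentile of the pooled null.

Place cells are cells with significant SI in either the pre-switch or the
post-switch trial set (session halves on non-switch days).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signals import SPEED_MIN_CMS, _bin_indices, valid_frame_mask


@dataclass
class SpatialInfoResult:
    si: np.ndarray            # (n_neurons,) true SI, bits
    null: np.ndarray          # (n_shuffles, n_neurons) shuffle SI
    significant: np.ndarray   # (n_neurons,) bool
    threshold: float          # pooled-null 95th percentile
    p_occupancy: np.ndarray   # (n_bins,)
    tuning: np.ndarray        # (n_neurons, n_bins) trial-averaged f_i


def occupancy_probability(position, speed, trial_ids, bin_edges,
                          teleport=None, speed_min=SPEED_MIN_CMS):
    """Session occupancy probability per bin.

    Per-trial occupancy probabilities (samples in bin / samples in trial)
    are summed over trials and renormalized, so every trial contributes
    equally regardless of its duration.
    """
    position = np.asarray(position, dtype=float)
    trial_ids = np.asarray(trial_ids)
    n_bins = len(bin_edges) - 1
    ok = valid_frame_mask(position, speed, teleport, speed_min)
    acc = np.zeros(n_bins)
    for tr in np.unique(trial_ids):
        sel = ok & (trial_ids == tr)
        n = sel.sum()
        if n == 0:
            continue
        bi = _bin_indices(position[sel], bin_edges, bin_edges[-1])
        acc += np.bincount(bi, minlength=n_bins) / n
    total = acc.sum()
    return acc / total if total > 0 else acc


def spatial_information(tuning, p):
    """SI in bits from trial-averaged tuning f_i and occupancy p_i.

    ``tuning`` may be (n_bins,) or (..., n_bins).  Bins with NaN tuning
    (never occupied) are dropped and p renormalized over the rest.  Terms
    with f_i = 0 contribute 0; silent cells (f = 0) have SI 0.
    """
    f_i = np.atleast_2d(np.asarray(tuning, dtype=float))
    p = np.asarray(p, dtype=float)
    valid = np.isfinite(f_i)
    pv = np.where(valid, p, 0.0)
    pv = pv / np.maximum(pv.sum(axis=-1, keepdims=True), np.finfo(float).tiny)
    fv = np.where(valid, f_i, 0.0)
    f = (fv * pv).sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = fv / f
        terms = pv * ratio * np.log2(ratio)
    terms[~np.isfinite(terms)] = 0.0
    si = terms.sum(axis=-1)
    si[f[..., 0] == 0] = 0.0
    out = si if np.asarray(tuning).ndim > 1 else si[0]
    return out


class _TrialFrames:
    """Pre-indexed on-track frames of each trial, for fast shuffled binning."""

    def __init__(self, position, speed, trial_ids, bin_edges, teleport,
                 speed_min=SPEED_MIN_CMS):
        position = np.asarray(position, dtype=float)
        trial_ids = np.asarray(trial_ids)
        on_track = np.isfinite(position)
        if teleport is not None:
            on_track &= ~np.asarray(teleport, dtype=bool)
        run = np.asarray(speed) >= speed_min
        self.n_bins = len(bin_edges) - 1
        self.trials = []
        for tr in np.unique(trial_ids):
            idx = np.nonzero(on_track & (trial_ids == tr))[0]
            if len(idx) == 0:
                continue
            valid = run[idx]
            bi = _bin_indices(position[idx], bin_edges, bin_edges[-1])
            counts = np.bincount(bi[valid], minlength=self.n_bins)
            # one-hot (n_frames x n_bins) binning matrix over valid frames
            M = np.zeros((len(idx), self.n_bins))
            M[np.nonzero(valid)[0], bi[valid]] = 1.0
            self.trials.append(dict(tr=tr, idx=idx, M=M, counts=counts))

    def tuning(self, traces, trial_subset=None, offsets=None):
        """Trial-averaged f_i, optionally with per-trial circular offsets.

        ``offsets`` is None (no shuffle) or (n_shuffles, n_trials) integer
        shifts of each trial's activity relative to position.  Returns
        (n_shuffles, n_neurons, n_bins) or (n_neurons, n_bins).
        """
        traces = np.atleast_2d(traces)
        n_neurons = traces.shape[0]
        use = [t for t in self.trials
               if trial_subset is None or t["tr"] in set(np.asarray(trial_subset))]
        S = 1 if offsets is None else offsets.shape[0]
        acc = np.zeros((S, n_neurons, self.n_bins))
        ntr = np.zeros((S, 1, self.n_bins))
        for j, t in enumerate(use):
            A = traces[:, t["idx"]]                        # (N, L)
            L = A.shape[1]
            if offsets is None:
                sums = A @ t["M"]                           # (N, bins)
                sums = sums[None]
            else:
                cols = (np.arange(L)[None, :] - offsets[:, j, None]) % L
                G = A[:, cols]                              # (N, S, L)
                G = np.ascontiguousarray(np.swapaxes(G, 0, 1))
                sums = G.reshape(S * n_neurons, L) @ t["M"]
                sums = sums.reshape(S, n_neurons, self.n_bins)
            c = t["counts"]
            occ = c > 0
            with np.errstate(invalid="ignore", divide="ignore"):
                means = sums[..., occ] / c[occ]
            acc[..., occ] += means
            ntr[..., occ] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            f = acc / ntr
        f[np.broadcast_to(ntr == 0, f.shape)] = np.nan
        return f if offsets is not None else f[0]

    def shuffle_offsets(self, rng, n_shuffles, frame_rate_hz, trial_subset=None):
        """Per-trial circular offsets, uniform between ~1 s and trial length."""
        use = [t for t in self.trials
               if trial_subset is None or t["tr"] in set(np.asarray(trial_subset))]
        lo = int(np.ceil(frame_rate_hz))
        out = np.empty((n_shuffles, len(use)), dtype=int)
        for j, t in enumerate(use):
            L = len(t["idx"])
            a = min(lo, max(L - 1, 1))
            out[:, j] = rng.integers(a, max(L, a + 1), size=n_shuffles)
        return out


def si_significance(session, trial_set, n_shuffles=100, rng=None,
                    signal="events", percentile=95.0) -> SpatialInfoResult:
    """SI and pooled-shuffle significance for every neuron over a trial set."""
    trial_set = np.asarray(trial_set)
    if len(trial_set) < 2:
        raise ValueError("need at least 2 trials in the set")
    rng = np.random.default_rng(rng)
    fr = session.frames
    tf = _TrialFrames(fr["position_cm"].to_numpy(), fr["speed_cms"].to_numpy(),
                      fr["trial"].to_numpy(), session.bin_edges,
                      fr["teleport"].to_numpy())
    p = occupancy_probability(
        fr["position_cm"].to_numpy(), fr["speed_cms"].to_numpy(),
        fr["trial"].to_numpy(), session.bin_edges, fr["teleport"].to_numpy(),
    )
    traces = session.events if signal == "events" else session.dff
    tuning = tf.tuning(traces, trial_subset=trial_set)
    si = np.atleast_1d(spatial_information(tuning, p))
    offs = tf.shuffle_offsets(rng, n_shuffles, session.frame_rate_hz, trial_set)
    null_tuning = tf.tuning(traces, trial_subset=trial_set, offsets=offs)
    null = spatial_information(
        null_tuning.reshape(-1, tf.n_bins), p
    ).reshape(n_shuffles, -1)
    thr = float(np.percentile(null, percentile))
    return SpatialInfoResult(si=si, null=null, significant=si > thr,
                             threshold=thr, p_occupancy=p, tuning=tuning)


def find_place_cells(session, n_shuffles=100, rng=None,
                     signal="events") -> pd.DataFrame:
    """Per-neuron SI and significance flags for both trial sets.

    A place cell has significant SI in the pre-switch OR post-switch set.
    """
    rng = np.random.default_rng(rng)
    pre, post = session.trial_sets()
    before = si_significance(session, pre, n_shuffles, rng, signal)
    after = si_significance(session, post, n_shuffles, rng, signal)
    return pd.DataFrame(dict(
        si_before=before.si, si_after=after.si,
        sig_before=before.significant, sig_after=after.significant,
        place_cell=before.significant | after.significant,
    ))


def spatial_peak(values, trials=None):
    """Peak bin of the trial-averaged unsmoothed tuning (ties -> lowest bin).

    ``values`` is a trials x bins matrix (typically unsmoothed binned ΔF/F).
    Raises on an all-NaN average.
    """
    v = np.asarray(values, dtype=float)
    if trials is not None:
        v = v[np.asarray(trials)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        avg = np.nanmean(v, axis=0)
    if not np.isfinite(avg).any():
        raise ValueError("tuning is all-NaN; cannot locate a peak")
    return int(np.nanargmax(avg))


def population_peaks(tensor_values, trials=None):
    """Per-neuron peak bins from a trials x bins x neurons tensor (NaN-safe)."""
    v = np.asarray(tensor_values, dtype=float)
    if trials is not None:
        v = v[np.asarray(trials)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        avg = np.nanmean(v, axis=0)           # (bins, neurons)
    peaks = np.full(avg.shape[1], np.nan)
    ok = np.isfinite(avg).any(axis=0)
    filled = np.where(np.isfinite(avg), avg, -np.inf)
    peaks[ok] = np.argmax(filled[:, ok], axis=0)
    return peaks
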