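"""Trace preprocessing and spatial binning.

ΔF/F is computed per trial with a maximin (rolling-min then rolling-max)
baseline over a 20-s window, then lightly smoothed.  Spatial binning averages
activity over the imaging samples falling in each 10-cm position bin while
the animal runs faster than 2 cm/s — the mean over samples is equivalent to
occupancy normalization within a trial.  Trial-by-trial similarity matrices
are Pearson correlations of z-scored spatial profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.ndimage import gaussian_filter1d

SPEED_MIN_CMS = 2.0


@dataclass
class TrialPositionMatrix:
    """trials x position-bins activity for one neuron (occupancy normalized)."""

    values: np.ndarray           # (n_trials, n_bins); NaN where unoccupied
    bin_edges: np.ndarray        # half-open [lo, hi) bins spanning the track
    trial_ids: np.ndarray
    signal_kind: str = "events"  # "dff" or "events"


@dataclass
class PopulationTensor:
    """trials x position-bins x neurons activity; neuron order is stable."""

    values: np.ndarray
    bin_edges: np.ndarray
    trial_ids: np.ndarray
    signal_kind: str = "events"


def compute_dff(fluorescence: np.ndarray, trial_ids: np.ndarray,
                frame_rate_hz: float, window_s: float = 20.0,
                smooth_sd_samples: float = 2.0):
    """Per-trial maximin ΔF/F.

    Baseline is computed within each trial independently: a centered rolling
    minimum followed by a centered rolling maximum over a ``window_s`` window
    (truncated at trial edges).  ΔF/F = (F - baseline)/|baseline|, smoothed
    with a ``smooth_sd_samples``-s.d. Gaussian.  Returns ``(dff, zero_mask)``
    where ``zero_mask`` flags samples whose baseline was 0 (ΔF/F set to 0).
    """
    f = np.atleast_2d(np.asarray(fluorescence, dtype=float))
    trial_ids = np.asarray(trial_ids)
    if f.shape[1] != trial_ids.shape[0]:
        raise ValueError("fluorescence and trial_ids are not aligned")
    w = max(int(round(window_s * frame_rate_hz)), 1)
    out = np.empty_like(f)
    zero_mask = np.zeros(f.shape, dtype=bool)
    for tr in np.unique(trial_ids):
        sel = trial_ids == tr
        seg = pd.DataFrame(f[:, sel].T)
        roll = dict(window=w, center=True, min_periods=1)
        base = seg.rolling(**roll).min().rolling(**roll).max().to_numpy().T
        zero = base == 0
        denom = np.where(zero, 1.0, np.abs(base))
        d = (f[:, sel] - base) / denom
        d[zero] = 0.0
        zero_mask[:, sel] = zero
        if smooth_sd_samples > 0:
            d = gaussian_filter1d(d, smooth_sd_samples, axis=1, mode="nearest")
        out[:, sel] = d
    if np.asarray(fluorescence).ndim == 1:
        return out[0], zero_mask[0]
    return out, zero_mask


def _bin_indices(position, bin_edges, track_length):
    """Half-open [lo, hi) bin index per frame; position == track end wraps to 0."""
    pos = np.mod(np.asarray(position, dtype=float), track_length)
    idx = np.floor(pos / (bin_edges[1] - bin_edges[0])).astype(int)
    return np.clip(idx, 0, len(bin_edges) - 2)


def valid_frame_mask(position, speed, teleport=None, speed_min=SPEED_MIN_CMS):
    """Frames usable for spatial analysis: on-track and running >= speed_min."""
    pos = np.asarray(position, dtype=float)
    ok = np.isfinite(pos) & (np.asarray(speed) >= speed_min)
    if teleport is not None:
        ok &= ~np.asarray(teleport, dtype=bool)
    return ok


def bin_by_position(trace, position, speed, trial_ids, bin_edges,
                    speed_min=SPEED_MIN_CMS, teleport=None,
                    signal_kind="events") -> TrialPositionMatrix:
    """Occupancy-normalized trials x bins matrix for one neuron.

    Each entry is the mean of the included samples (speed >= ``speed_min``,
    on-track) in that trial and bin; unoccupied bins are NaN.
    """
    tensor = bin_population(
        np.atleast_2d(trace), position, speed, trial_ids, bin_edges,
        speed_min=speed_min, teleport=teleport, signal_kind=signal_kind,
    )
    return TrialPositionMatrix(
        values=tensor.values[:, :, 0],
        bin_edges=tensor.bin_edges,
        trial_ids=tensor.trial_ids,
        signal_kind=signal_kind,
    )


def bin_population(traces, position, speed, trial_ids, bin_edges,
                   speed_min=SPEED_MIN_CMS, teleport=None,
                   signal_kind="events") -> PopulationTensor:
    """Vectorized trials x bins x neurons binning (see :func:`bin_by_position`)."""
    traces = np.asarray(traces)
    position = np.asarray(position, dtype=float)
    trial_ids = np.asarray(trial_ids)
    n_bins = len(bin_edges) - 1
    track_length = bin_edges[-1]
    uniq = np.unique(trial_ids)
    trial_pos = {t: i for i, t in enumerate(uniq)}
    ok = valid_frame_mask(position, speed, teleport, speed_min)

    bi = _bin_indices(position[ok], bin_edges, track_length)
    ti = np.array([trial_pos[t] for t in trial_ids[ok]])
    flat = ti * n_bins + bi
    ind = sparse.csr_matrix(
        (np.ones(len(flat)), (flat, np.arange(len(flat)))),
        shape=(len(uniq) * n_bins, len(flat)),
    )
    sums = ind @ traces[:, ok].T            # (trials*bins, neurons)
    counts = np.asarray(ind.sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts[:, None]
    means[counts == 0] = np.nan
    values = means.reshape(len(uniq), n_bins, traces.shape[0])
    return PopulationTensor(values=values, bin_edges=np.asarray(bin_edges),
                            trial_ids=uniq, signal_kind=signal_kind)


def bin_session(session, signal="events", speed_min=SPEED_MIN_CMS) -> PopulationTensor:
    """Bin every neuron of a session into a trials x bins x neurons tensor."""
    traces = session.events if signal == "events" else session.dff
    fr = session.frames
    return bin_population(
        traces, fr["position_cm"].to_numpy(), fr["speed_cms"].to_numpy(),
        fr["trial"].to_numpy(), session.bin_edges,
        speed_min=speed_min, teleport=fr["teleport"].to_numpy(),
        signal_kind=signal,
    )


def smooth_tuning(values, sd_cm, bin_width_cm, axis=-2):
    """Gaussian-smooth along the position axis with circular wrap-around."""
    if sd_cm <= 0:
        return values
    nan = ~np.isfinite(values)
    if nan.any():
        filled = np.where(nan, 0.0, values)
        norm = gaussian_filter1d((~nan).astype(float), sd_cm / bin_width_cm,
                                 axis=axis, mode="wrap")
        sm = gaussian_filter1d(filled, sd_cm / bin_width_cm, axis=axis, mode="wrap")
        with np.errstate(invalid="ignore", divide="ignore"):
            out = sm / norm
        out[nan & (norm == 0)] = np.nan
        return out
    return gaussian_filter1d(values, sd_cm / bin_width_cm, axis=axis, mode="wrap")


def correlation_matrix(A, smooth_sd_cm=None, bin_width_cm=10.0):
    """Trial-by-trial Pearson correlation matrix.

    ``A`` is trials x bins (single cell; default smoothing 20 cm s.d.) or
    trials x bins x neurons (population; default 10 cm s.d., neurons
    concatenated after smoothing).  Each trial is z-scored across its spatial
    (or spatial x neuron) profile and C = AAᵀ/(m-1).  Profiles containing
    NaNs fall back to pairwise-complete correlation; zero-variance trials
    yield NaN rows/columns.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim == 2:
        sd = 20.0 if smooth_sd_cm is None else smooth_sd_cm
        sm = smooth_tuning(A, sd, bin_width_cm, axis=1)
        flat = sm
    elif A.ndim == 3:
        sd = 10.0 if smooth_sd_cm is None else smooth_sd_cm
        sm = smooth_tuning(A, sd, bin_width_cm, axis=1)
        flat = sm.reshape(sm.shape[0], -1)
    else:
        raise ValueError("A must be 2-D or 3-D")
    if flat.shape[0] < 2:
        raise ValueError("need at least 2 trials")
    if np.isnan(flat).any():
        return pd.DataFrame(flat.T).corr(min_periods=2).to_numpy()
    m = flat.shape[1]
    mu = flat.mean(axis=1, keepdims=True)
    sdev = flat.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (flat - mu) / sdev
    z[np.broadcast_to(sdev == 0, z.shape)] = np.nan
    C = z @ z.T / (m - 1)
    C[~np.isfinite(sdev[:, 0]) | (sdev[:, 0] == 0)] = np.nan
    C[:, sdev[:, 0] == 0] = np.nan
    return C


def exclude_putative_interneurons(dff, speed, threshold=0.5):
    """Flag neurons whose ΔF/F tracks running speed (Pearson r > threshold).

    Returns ``(keep, r)``: constant traces (undefined r) are kept and have
    NaN in ``r``.
    """
    dff = np.atleast_2d(np.asarray(dff, dtype=float))
    speed = np.asarray(speed, dtype=float)
    sd_d = dff.std(axis=1)
    sd_s = speed.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = ((dff - dff.mean(axis=1, keepdims=True))
               * (speed - speed.mean())).mean(axis=1)
        r = cov / (sd_d * sd_s)
    r[sd_d == 0] = np.nan
    keep = ~(r > threshold)
    return keep, r
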