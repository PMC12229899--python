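"""Licking and running-speed analysis.

The anticipatory lick ratio quantifies licking precision over blocks of
trials:

    ratio = (Lick_in - Lick_out) / (Lick_in + Lick_out)

where ``Lick_in`` is the mean lick rate in the 50-cm anticipatory window
before the reward-zone start and ``Lick_out`` the mean rate everywhere else
outside the reward zone (the zone itself is excluded to drop consummatory
licks).  A ratio of 1 means licking only in the anticipatory window, -1 only
elsewhere, 0 spatially unselective licking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signals import _bin_indices


@dataclass
class LickMap:
    """trials x bins lick rate (licks/s) with per-trial zone metadata."""

    rate: np.ndarray            # (n_trials, n_bins), NaN rows for removed trials
    bin_edges: np.ndarray
    trial_ids: np.ndarray
    zone_start_cm: np.ndarray   # per trial
    zone_length_cm: float


def remove_erroneous_lick_trials(lick_counts, trial_ids, max_count=2,
                                 frac_threshold=0.30):
    """Mask of trials with physically implausible sustained lick detection.

    A trial is removed (mask False) when more than ``frac_threshold`` of its
    frames carry a cumulative lick count above ``max_count`` — at the imaging
    frame duration that would be a sustained rate >= 20 Hz.
    """
    lick_counts = np.asarray(lick_counts)
    trial_ids = np.asarray(trial_ids)
    keep = {}
    for tr in np.unique(trial_ids):
        sel = trial_ids == tr
        frac = np.mean(lick_counts[sel] > max_count)
        keep[tr] = frac <= frac_threshold
    return keep


def lick_rate_map(lick, position, trial_ids, bin_edges, frame_rate_hz,
                  zone_start_cm, zone_length_cm=50.0, teleport=None,
                  lick_counts=None) -> LickMap:
    """Per-trial spatially binned lick rate (licks / s occupancy).

    ``lick`` is the binary per-frame lick vector; if raw ``lick_counts`` are
    given, erroneous trials are removed first (set to NaN rows).  Bins the
    animal never occupied in a trial are NaN.
    """
    lick = np.asarray(lick, dtype=float)
    position = np.asarray(position, dtype=float)
    trial_ids = np.asarray(trial_ids)
    n_bins = len(bin_edges) - 1
    track_length = bin_edges[-1]
    uniq = np.unique(trial_ids)
    ok = np.isfinite(position)
    if teleport is not None:
        ok &= ~np.asarray(teleport, dtype=bool)
    keep = (remove_erroneous_lick_trials(lick_counts, trial_ids)
            if lick_counts is not None else {tr: True for tr in uniq})

    rate = np.full((len(uniq), n_bins), np.nan)
    dt = 1.0 / frame_rate_hz
    for i, tr in enumerate(uniq):
        if not keep[tr]:
            continue
        sel = ok & (trial_ids == tr)
        bi = _bin_indices(position[sel], bin_edges, track_length)
        counts = np.bincount(bi, weights=lick[sel], minlength=n_bins)
        occ_s = np.bincount(bi, minlength=n_bins) * dt
        with np.errstate(invalid="ignore", divide="ignore"):
            r = counts / occ_s
        r[occ_s == 0] = np.nan
        rate[i] = r
    zs = np.asarray(zone_start_cm, dtype=float)
    if zs.ndim == 0:
        zs = np.full(len(uniq), float(zs))
    return LickMap(rate=rate, bin_edges=np.asarray(bin_edges), trial_ids=uniq,
                   zone_start_cm=zs, zone_length_cm=zone_length_cm)


def _window_masks(bin_edges, zone_start, zone_length, anticipatory_cm=50.0):
    """(anticipatory, outside) bin masks; the reward zone belongs to neither."""
    centers = (bin_edges[:-1] + bin_edges[1:]) / 2
    track = bin_edges[-1]
    rel = np.mod(centers - zone_start, track)
    in_zone = rel < zone_length
    antic = np.mod(zone_start - centers, track) <= anticipatory_cm
    antic &= ~in_zone
    outside = ~in_zone & ~antic
    return antic, outside


def anticipatory_lick_ratio(lick_map: LickMap, trials=None,
                            anticipatory_cm=50.0) -> float:
    """Anticipatory lick ratio over a set of trials (default: all).

    NaN when no licks fall outside the reward zone at all.
    """
    idx = (np.arange(len(lick_map.trial_ids)) if trials is None
           else np.asarray(trials))
    lick_in, lick_out = [], []
    for i in idx:
        row = lick_map.rate[i]
        if not np.isfinite(row).any():
            continue
        antic, outside = _window_masks(
            lick_map.bin_edges, lick_map.zone_start_cm[i],
            lick_map.zone_length_cm, anticipatory_cm,
        )
        lick_in.append(np.nanmean(row[antic]) if np.isfinite(row[antic]).any()
                       else np.nan)
        lick_out.append(np.nanmean(row[outside]) if np.isfinite(row[outside]).any()
                        else np.nan)
    li = np.nanmean(lick_in) if len(lick_in) else np.nan
    lo = np.nanmean(lick_out) if len(lick_out) else np.nan
    if not np.isfinite(li) or not np.isfinite(lo) or (li + lo) == 0:
        return np.nan
    return (li - lo) / (li + lo)


def lick_ratio_blocks(lick_map: LickMap, switch_trial=None, block_size=10,
                      min_block=5) -> pd.DataFrame:
    """Lick-ratio time course over blocks of ``block_size`` trials.

    Blocks never straddle the reward switch; a final partial block is kept
    only if it has at least ``min_block`` trials.
    """
    n = len(lick_map.trial_ids)
    bounds = [0, n] if switch_trial is None else [0, switch_trial, n]
    rows = []
    block = 0
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        for start in range(lo, hi, block_size):
            stop = min(start + block_size, hi)
            if stop - start < min_block:
                continue
            rows.append(dict(
                block=block, first_trial=int(lick_map.trial_ids[start]),
                n_trials=stop - start,
                ratio=anticipatory_lick_ratio(lick_map, np.arange(start, stop)),
            ))
            block += 1
    return pd.DataFrame(rows)


def speed_map(speed, position, trial_ids, bin_edges, teleport=None):
    """trials x bins mean running speed (cm/s); unoccupied bins NaN."""
    speed = np.asarray(speed, dtype=float)
    position = np.asarray(position, dtype=float)
    trial_ids = np.asarray(trial_ids)
    n_bins = len(bin_edges) - 1
    track = bin_edges[-1]
    uniq = np.unique(trial_ids)
    ok = np.isfinite(position)
    if teleport is not None:
        ok &= ~np.asarray(teleport, dtype=bool)
    out = np.full((len(uniq), n_bins), np.nan)
    for i, tr in enumerate(uniq):
        sel = ok & (trial_ids == tr)
        bi = _bin_indices(position[sel], bin_edges, track)
        s = np.bincount(bi, weights=speed[sel], minlength=n_bins)
        c = np.bincount(bi, minlength=n_bins)
        with np.errstate(invalid="ignore", divide="ignore"):
            m = s / c
        m[c == 0] = np.nan
        out[i] = m
    return out


def session_lick_map(session, signal_bins=None) -> LickMap:
    """Convenience: LickMap for a session using its trial zone metadata."""
    fr = session.frames
    edges = session.bin_edges if signal_bins is None else signal_bins
    zone_starts = session.trials["zone_start_cm"].to_numpy()
    return lick_rate_map(
        fr["lick"].to_numpy(), fr["position_cm"].to_numpy(),
        fr["trial"].to_numpy(), edges, session.frame_rate_hz,
        zone_starts, session.zone_length_cm, teleport=fr["teleport"].to_numpy(),
    )
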