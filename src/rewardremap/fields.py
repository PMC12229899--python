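"""Individual place-field detection and dynamics.

Candidate fields are contiguous regions of the trial-averaged, 10-cm-s.d.
smoothed deconvolved tuning exceeding 20% of its maximum and spanning at
least 20 cm.  A field is kept when the cell is significantly active within
the field in at least 8 of the 30 trials of the set (raw in-field activity
exceeding its pooled mean + 1 s.d.).  The formation lap is the first active
trial of the first 5-trial window containing at least 3 active trials; field
shift is the center-of-mass displacement from the formation lap to the mean
of the last 30 trials (negative = backward, toward earlier positions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .sequences import circ_circ_corr


@dataclass
class PlaceField:
    start_bin: int
    end_bin: int               # inclusive
    width_cm: float
    in_field_rate: float       # mean raw event rate inside the field
    n_active_trials: int
    edge_overlap: bool         # touches first/last bin (excluded from width/rate)
    formation_lap: Optional[float] = None
    com_formation_cm: Optional[float] = None
    com_last30_cm: Optional[float] = None
    shift_cm: Optional[float] = None


def _supra_regions(avg, threshold):
    """(start, end-inclusive) runs of bins with avg > threshold."""
    above = avg > threshold
    regions = []
    start = None
    for i, a in enumerate(above):
        if a and start is None:
            start = i
        elif not a and start is not None:
            regions.append((start, i - 1))
            start = None
    if start is not None:
        regions.append((start, len(avg) - 1))
    return regions


def detect_fields(trial_avg_smoothed, per_trial_raw, bin_width_cm=10.0,
                  threshold_frac=0.20, min_width_cm=20.0,
                  min_active_trials=8) -> list[PlaceField]:
    """Detect place fields of one cell within a 30-trial set.

    ``trial_avg_smoothed`` is the smoothed trial-averaged binned event
    tuning; ``per_trial_raw`` the unsmoothed trials x bins event matrix used
    for the reliability test.  All-zero cells yield no fields.
    """
    avg = np.asarray(trial_avg_smoothed, dtype=float)
    raw = np.asarray(per_trial_raw, dtype=float)
    mx = np.nanmax(avg) if np.isfinite(avg).any() else 0.0
    if not mx > 0:
        return []
    thr = threshold_frac * mx
    fields = []
    for lo, hi in _supra_regions(np.nan_to_num(avg, nan=-np.inf), thr):
        width = (hi - lo + 1) * bin_width_cm
        if width < min_width_cm:
            continue
        infield = raw[:, lo:hi + 1]
        samples = infield[np.isfinite(infield)]
        if samples.size == 0:
            continue
        act_thr = samples.mean() + samples.std()
        with np.errstate(invalid="ignore"):
            trial_max = np.nanmax(infield, axis=1)
        n_active = int(np.nansum(trial_max > act_thr))
        if n_active < min_active_trials:
            continue
        fields.append(PlaceField(
            start_bin=lo, end_bin=hi, width_cm=width,
            in_field_rate=float(np.nanmean(infield)),
            n_active_trials=n_active,
            edge_overlap=(lo == 0 or hi == raw.shape[1] - 1),
        ))
    return fields


def formation_lap(field: PlaceField, per_trial_binned, bin_width_cm=10.0,
                  margin_cm=10.0, window=5, min_in_window=3):
    """Formation lap of a field from post-switch per-trial binned activity.

    Activity is averaged over the field bounds ±``margin_cm``; trials above
    the across-trial mean + 1 s.d. are 'active'.  Returns the first active
    trial in the first ``window``-trial span holding >= ``min_in_window``
    active trials, or NaN if none exists.
    """
    v = np.asarray(per_trial_binned, dtype=float)
    pad = int(round(margin_cm / bin_width_cm))
    lo = max(field.start_bin - pad, 0)
    hi = min(field.end_bin + pad, v.shape[1] - 1)
    with np.errstate(invalid="ignore"):
        per_trial = np.nanmean(v[:, lo:hi + 1], axis=1)
    mu = np.nanmean(per_trial)
    sd = np.nanstd(per_trial)
    active = per_trial > mu + sd
    n = len(active)
    for start in range(0, n - window + 1):
        w = active[start:start + window]
        if w.sum() >= min_in_window:
            return int(start + np.argmax(w))
    return np.nan


def _com(activity, positions):
    a = np.asarray(activity, dtype=float)
    x = np.asarray(positions, dtype=float)
    ok = np.isfinite(a) & np.isfinite(x)
    total = a[ok].sum()
    if total <= 0:
        return np.nan
    return float((a[ok] * x[ok]).sum() / total)


def field_com(field: PlaceField, raw_activity, positions, trial_ids, trials,
              bin_width_cm=10.0):
    """Center of mass from raw sample-level activity within the field bounds,
    pooled over ``trials``."""
    pos = np.asarray(positions, dtype=float)
    act = np.asarray(raw_activity, dtype=float)
    tid = np.asarray(trial_ids)
    lo_cm = field.start_bin * bin_width_cm
    hi_cm = (field.end_bin + 1) * bin_width_cm
    sel = np.isin(tid, np.asarray(trials)) & (pos >= lo_cm) & (pos < hi_cm)
    return _com(act[sel], pos[sel])


def field_shift(field: PlaceField, raw_activity, positions, trial_ids,
                formation_trial, last_trials, bin_width_cm=10.0):
    """COM(last trials) - COM(formation lap); negative = backward shift."""
    c_form = field_com(field, raw_activity, positions, trial_ids,
                       [formation_trial], bin_width_cm)
    c_last = field_com(field, raw_activity, positions, trial_ids,
                       last_trials, bin_width_cm)
    if not (np.isfinite(c_form) and np.isfinite(c_last)):
        return np.nan
    return float(c_last - c_form)


def two_field_coordination(offsets_before, offsets_after, min_cells=5):
    """Circular-circular correlation of between-field offsets across a switch.

    ``offsets_*`` hold, per cell with exactly two fields in both epochs, the
    circular offset (radians) between its two field positions.  Returns
    (rho, low_n).
    """
    a = np.asarray(offsets_before, dtype=float)
    b = np.asarray(offsets_after, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < min_cells:
        return np.nan, True
    return circ_circ_corr(a[ok], b[ok]), False
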