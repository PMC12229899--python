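"""Reward-relative (RR) remapping analysis.

Track position is mapped to periodic coordinates with 0 cm at -pi and the
track end at +pi; rotating so the reward-zone start sits at phase 0 gives
reward-relative coordinates.  A cell is *reward-relative* when its field
keeps a fixed circular distance from the zone start across a reward switch:

* criterion 1 — reward-aligned spatial peaks before vs after the switch fall
  within ~0.698 rad (50 cm on a 450-cm track) of each other;
* criterion 2 — the circular cross-correlogram of the reward-aligned
  trial-averaged tuning (pre vs post) peaks above the 97.5th percentile of a
  trial-shift null, at a lag within 5 bins of zero.

Track-relative (TR) cells instead keep their track-coordinate peak (<= 50 cm
shift) with significant spatial information in both trial sets.  A
population-level excess of near-zero reward-relative peak shifts is tested
against a random-remapping null that circularly permutes each cell's
post-switch tuning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .placecells import population_peaks
from .synthetic import wrap_phase

#: 50 cm on the 450-cm circularized track
RAD_PER_50CM = 50.0 / 450.0 * 2 * np.pi  # ~0.698132

CATEGORIES = (
    "TR", "disappearing", "appearing", "remap_near_reward",
    "remap_far_from_reward", "RR", "nonRR_remap", "unclassified", "nonplace",
)


def to_periodic(position_cm, track_length_cm=450.0):
    """Track position -> phase in [-pi, pi); 0 cm -> -pi, track end -> pi."""
    pos = np.asarray(position_cm, dtype=float)
    return wrap_phase(pos / track_length_cm * 2 * np.pi - np.pi)


def from_periodic(phase, track_length_cm=450.0):
    """Inverse of :func:`to_periodic` (phase -> cm in [0, track_length))."""
    ph = wrap_phase(phase)
    return np.mod((ph + np.pi) / (2 * np.pi) * track_length_cm, track_length_cm)


def align_to_reward(phase, zone_start_phase):
    """Rotate phases so the reward-zone start lies at 0."""
    return wrap_phase(np.asarray(phase) - zone_start_phase)


def phase_to_cm(phase, track_length_cm=450.0):
    """Signed circular distance in cm corresponding to a phase difference."""
    return np.asarray(phase) * track_length_cm / (2 * np.pi)


def bin_phase(bin_index, n_bins=45):
    """Phase of a spatial bin center."""
    return wrap_phase((np.asarray(bin_index, dtype=float) + 0.5)
                      / n_bins * 2 * np.pi - np.pi)


def reward_align_tensor(values, zone_bins):
    """Circularly roll each trial's bins so the zone-start bin maps to bin 0.

    ``values`` is trials x bins (x neurons); ``zone_bins`` the per-trial
    zone-start bin index.  Bin b of the output holds activity at track bin
    (b + zone_bin) — i.e. position relative to the reward-zone start.
    """
    v = np.asarray(values, dtype=float)
    zone_bins = np.asarray(zone_bins, dtype=int)
    n_bins = v.shape[1]
    out = np.empty_like(v)
    cols = np.arange(n_bins)
    for t in range(v.shape[0]):
        out[t] = v[t, (cols + zone_bins[t]) % n_bins]
    return out


def _circular_xcorr(pre, post_stack, n_bins=None):
    """Pearson correlation of ``pre`` vs circular shifts of each post curve.

    Returns (corr, lags): corr has shape post_stack.shape[:-1] + (n_bins,)
    where corr[..., k] is the correlation with ``post`` rolled by lags[k];
    lags span [-n_bins//2, n_bins//2].
    """
    pre = np.asarray(pre, dtype=float)
    post = np.atleast_2d(np.asarray(post_stack, dtype=float))
    m = pre.shape[-1]
    lags = np.arange(m) - m // 2
    idx = (np.arange(m)[None, :] - lags[:, None]) % m   # (lags, bins)

    def _z(x):
        mu = x.mean(axis=-1, keepdims=True)
        sd = x.std(axis=-1, ddof=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sd > 0, (x - mu) / sd, np.nan)

    zp = _z(pre)
    zq = _z(post)
    rolled = zq[..., idx]                               # (..., lags, bins)
    corr = rolled @ zp / (m - 1)
    return corr, lags


@dataclass
class RRCellResult:
    is_rr: bool
    rel_peak_pre: float       # reward-relative peak phase, pre-switch
    rel_peak_post: float
    rel_peak_diff: float      # wrapped post - pre, radians
    peak_within: bool         # criterion 1
    xcorr_peak: float
    xcorr_lag_bins: int
    xcorr_null_975: float
    xcorr_pass: bool          # criterion 2


def rr_cell_criteria(pre_rr, post_rr, n_shuffles=500, rng=None,
                     max_diff_rad=RAD_PER_50CM, max_lag_bins=5) -> RRCellResult:
    """Test one place cell for reward-relative remapping.

    ``pre_rr``/``post_rr`` are trials x bins matrices of reward-aligned
    (zone start at bin 0) unsmoothed binned ΔF/F for the pre- and post-switch
    trial sets.
    """
    rng = np.random.default_rng(rng)
    pre_rr = np.asarray(pre_rr, dtype=float)
    post_rr = np.asarray(post_rr, dtype=float)
    n_bins = pre_rr.shape[1]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        pre_avg = np.nanmean(pre_rr, axis=0)
        post_avg = np.nanmean(post_rr, axis=0)
    pre_avg = np.where(np.isfinite(pre_avg), pre_avg, np.nanmean(pre_avg))
    post_avg = np.where(np.isfinite(post_avg), post_avg, np.nanmean(post_avg))

    pk_pre = int(np.argmax(pre_avg))
    pk_post = int(np.argmax(post_avg))
    rel_pre = bin_phase(pk_pre, n_bins)
    rel_post = bin_phase(pk_post, n_bins)
    diff = float(wrap_phase(rel_post - rel_pre))
    peak_within = abs(diff) <= max_diff_rad

    corr, lags = _circular_xcorr(pre_avg, post_avg[None])
    corr = corr[0]
    if np.isfinite(corr).any():
        k = int(np.nanargmax(corr))
        real_peak, real_lag = float(corr[k]), int(lags[k])
    else:
        real_peak, real_lag = np.nan, 0

    # null: circularly shift each post-switch trial independently
    filled = np.where(np.isfinite(post_rr), post_rr,
                      np.nanmean(post_avg))
    shifts = rng.integers(1, n_bins, size=(n_shuffles, post_rr.shape[0]))
    cols = np.arange(n_bins)
    null_avgs = np.empty((n_shuffles, n_bins))
    for s in range(n_shuffles):
        idx = (cols[None, :] - shifts[s][:, None]) % n_bins
        null_avgs[s] = np.take_along_axis(filled, idx, axis=1).mean(axis=0)
    null_corr, _ = _circular_xcorr(pre_avg, null_avgs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        null_peaks = np.nanmax(null_corr, axis=-1)
        thr = (float(np.nanpercentile(null_peaks, 97.5))
               if np.isfinite(null_peaks).any() else np.nan)
    xcorr_pass = bool(np.isfinite(real_peak) and real_peak > thr
                      and abs(real_lag) <= max_lag_bins)

    return RRCellResult(
        is_rr=bool(peak_within and xcorr_pass),
        rel_peak_pre=float(rel_pre), rel_peak_post=float(rel_post),
        rel_peak_diff=diff, peak_within=bool(peak_within),
        xcorr_peak=real_peak, xcorr_lag_bins=real_lag,
        xcorr_null_975=thr, xcorr_pass=xcorr_pass,
    )


def classify_remapping(sig_before, sig_after, peak_before_bin, peak_after_bin,
                       zone_bin_before, zone_bin_after,
                       mean_post_dff, pre_trial_means,
                       n_bins=45, track_length_cm=450.0) -> str:
    """Pre-RR remapping taxonomy for one cell.

    ``pre_trial_means`` are the per-trial mean binned ΔF/F values before the
    switch; ``mean_post_dff`` the mean binned ΔF/F after.
    """
    pre_trial_means = np.asarray(pre_trial_means, dtype=float)
    if not sig_before and not sig_after:
        return "nonplace"
    if sig_before and sig_after:
        d_track = abs(phase_to_cm(
            wrap_phase(bin_phase(peak_after_bin, n_bins)
                       - bin_phase(peak_before_bin, n_bins)),
            track_length_cm))
        if d_track <= 50.0:
            return "TR"
        d_pre = abs(phase_to_cm(wrap_phase(
            bin_phase(peak_before_bin, n_bins) - bin_phase(zone_bin_before, n_bins)
            + np.pi / n_bins), track_length_cm))
        d_post = abs(phase_to_cm(wrap_phase(
            bin_phase(peak_after_bin, n_bins) - bin_phase(zone_bin_after, n_bins)
            + np.pi / n_bins), track_length_cm))
        if d_pre <= 50.0 and d_post <= 50.0:
            return "remap_near_reward"
        return "remap_far_from_reward"
    if sig_before:
        pre_med = np.nanpercentile(pre_trial_means, 50)
        if np.isfinite(mean_post_dff) and mean_post_dff < pre_med:
            return "disappearing"
        return "unclassified"
    # significant after only
    mu, sd = np.nanmean(pre_trial_means), np.nanstd(pre_trial_means)
    if np.isfinite(mean_post_dff) and mean_post_dff > mu + sd:
        return "appearing"
    return "unclassified"


def classify_session(session, place_table, dff_tensor, rr_shuffles=500,
                     rng=None) -> pd.DataFrame:
    """Full per-neuron remapping classification for a switch session.

    ``place_table`` comes from :func:`rewardremap.placecells.find_place_cells`
    and ``dff_tensor`` is the unsmoothed binned ΔF/F
    :class:`~rewardremap.signals.PopulationTensor`.  RR takes precedence over
    remap-near/far and appearing/disappearing; TR cells are never reassigned.
    """
    rng = np.random.default_rng(rng)
    pre, post = session.trial_sets()
    vals = dff_tensor.values
    n_bins = vals.shape[1]
    bin_w = session.track_length_cm / n_bins
    zone_bins = (session.trials["zone_start_cm"].to_numpy() / bin_w).round().astype(int)
    rr_vals = reward_align_tensor(vals, zone_bins)

    peaks_pre = population_peaks(vals, pre)
    peaks_post = population_peaks(vals, post)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        trial_means = np.nanmean(vals, axis=1)      # (trials, neurons)
    rows = []
    for n in range(session.n_neurons):
        sig_b = bool(place_table["sig_before"].iloc[n])
        sig_a = bool(place_table["sig_after"].iloc[n])
        cat = classify_remapping(
            sig_b, sig_a,
            0 if np.isnan(peaks_pre[n]) else int(peaks_pre[n]),
            0 if np.isnan(peaks_post[n]) else int(peaks_post[n]),
            zone_bins[pre[0]], zone_bins[post[0]],
            np.nanmean(trial_means[post, n]), trial_means[pre, n],
            n_bins=n_bins, track_length_cm=session.track_length_cm,
        )
        rr = None
        if cat not in ("nonplace", "TR"):
            rr = rr_cell_criteria(rr_vals[pre][:, :, n], rr_vals[post][:, :, n],
                                  n_shuffles=rr_shuffles, rng=rng)
            if rr.is_rr:
                cat = "RR"
        rows.append(dict(
            category=cat,
            peak_before=peaks_pre[n], peak_after=peaks_post[n],
            rel_peak_diff=rr.rel_peak_diff if rr else np.nan,
            xcorr_peak=rr.xcorr_peak if rr else np.nan,
            xcorr_lag_bins=rr.xcorr_lag_bins if rr else np.nan,
            xcorr_pass=rr.xcorr_pass if rr else False,
        ))
    out = pd.DataFrame(rows)
    out["place_cell"] = place_table["place_cell"].to_numpy()
    out["nonRR_remap"] = (out["place_cell"]
                          & ~out["category"].isin(["RR", "TR", "nonplace"]))
    return out


@dataclass
class RRPopulationResult:
    diffs: np.ndarray            # wrapped reward-relative peak shifts, radians
    hist: np.ndarray             # counts per phase bin
    shuffle_band: np.ndarray     # per-bin 95th percentile of shuffle counts
    bin_edges: np.ndarray
    n_eligible: int
    n_in_window: int
    shuffle_window_counts: np.ndarray
    above_chance_fraction: float
    significant: bool
    low_n: bool = False


def rr_population_test(dff_tensor_values, zone_bins, pre, post,
                       sig_before, sig_after, n_place,
                       n_shuffles=1000, exclusion_radius_cm=0.0,
                       rng=None, track_length_cm=450.0) -> RRPopulationResult:
    """Population test of reward-relative remapping against a random null.

    Restricted to cells with significant SI in both trial sets, with putative
    TR cells (track-phase peaks within ~0.698 rad) removed.  The null keeps
    each cell's pre-switch reward-relative peak and circularly shifts its
    post-switch tuning by a uniform 0..n_bins-1 bin offset.  The above-chance
    fraction is (true count in the |diff| <= 0.698 rad window minus the mean
    shuffle count there) / ``n_place``.
    """
    rng = np.random.default_rng(rng)
    vals = np.asarray(dff_tensor_values, dtype=float)
    n_bins = vals.shape[1]
    rr_vals = reward_align_tensor(vals, zone_bins)

    eligible = np.asarray(sig_before) & np.asarray(sig_after)
    tr_pk_pre = population_peaks(vals, pre)
    tr_pk_post = population_peaks(vals, post)
    track_diff = wrap_phase(bin_phase(tr_pk_post, n_bins)
                            - bin_phase(tr_pk_pre, n_bins))
    eligible &= np.abs(track_diff) > RAD_PER_50CM      # remove putative TR
    rel_pre = bin_phase(population_peaks(rr_vals, pre), n_bins)
    rel_post = bin_phase(population_peaks(rr_vals, post), n_bins)
    if exclusion_radius_cm > 0:
        rad = exclusion_radius_cm / track_length_cm * 2 * np.pi
        near_both = (np.abs(rel_pre) <= rad) & (np.abs(rel_post) <= rad)
        eligible &= ~near_both
    eligible &= np.isfinite(rel_pre) & np.isfinite(rel_post)
    idx = np.nonzero(eligible)[0]
    diffs = wrap_phase(rel_post[idx] - rel_pre[idx])

    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    hist = np.histogram(diffs, bins=edges)[0]
    # null: shift each cell's post tuning by a uniform offset; the peak moves
    # with the shift, so the null post peak is the true peak plus the offset
    offs = rng.integers(0, n_bins, size=(n_shuffles, len(idx)))
    null_post = bin_phase(
        (np.round((rel_post[idx] + np.pi) / (2 * np.pi) * n_bins - 0.5).astype(int)
         [None, :] + offs) % n_bins, n_bins)
    null_diffs = wrap_phase(null_post - rel_pre[idx][None, :])
    null_hist = np.stack([np.histogram(d, bins=edges)[0] for d in null_diffs])
    band = np.percentile(null_hist, 95, axis=0)

    in_window = int(np.sum(np.abs(diffs) <= RAD_PER_50CM))
    null_window = np.sum(np.abs(null_diffs) <= RAD_PER_50CM, axis=1)
    frac = (in_window - null_window.mean()) / max(n_place, 1)
    significant = in_window > np.percentile(null_window, 95)
    return RRPopulationResult(
        diffs=diffs, hist=hist, shuffle_band=band, bin_edges=edges,
        n_eligible=len(idx), n_in_window=in_window,
        shuffle_window_counts=null_window,
        above_chance_fraction=float(frac), significant=bool(significant),
        low_n=len(idx) < 10,
    )


def trial_peak_errors(trial_matrix, trials, track_length_cm=450.0):
    """Per-trial circular distance (cm) from each trial's peak to the set mean.

    ``trial_matrix`` is trials x bins binned activity for one cell.
    """
    v = np.asarray(trial_matrix, dtype=float)[np.asarray(trials)]
    n_bins = v.shape[1]
    pk = np.full(len(v), np.nan)
    for i, row in enumerate(v):
        if np.isfinite(row).any():
            pk[i] = np.nanargmax(row)
    ph = bin_phase(pk, n_bins)
    ok = np.isfinite(ph)
    if ok.sum() == 0:
        return np.full(len(v), np.nan)
    mean_ph = np.arctan2(np.nanmean(np.sin(ph[ok])), np.nanmean(np.cos(ph[ok])))
    err = np.abs(phase_to_cm(wrap_phase(ph - mean_ph), track_length_cm))
    err[~ok] = np.nan
    return err


def teleport_distance_control(peak_errors, teleport_distances):
    """Spearman correlation of a cell's trial peak error with the distance
    run in the preceding teleport period.

    ``peak_errors[i]`` is the error on trial i; ``teleport_distances[i]`` the
    distance run in the teleport *ending* trial i (i.e. after trial i-1).
    Returns (rho, p); NaN when either series is constant.
    """
    e = np.asarray(peak_errors, dtype=float)
    d = np.asarray(teleport_distances, dtype=float)
    ok = np.isfinite(e) & np.isfinite(d)
    if ok.sum() < 3 or np.nanstd(e[ok]) == 0 or np.nanstd(d[ok]) == 0:
        return np.nan, np.nan
    rho, p = stats.spearmanr(d[ok], e[ok])
    return float(rho), float(p)
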