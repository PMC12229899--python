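"""Piecewise-linear trial warping and the reward-versus-omission index.

Trials are aligned on the position-bin axis by monotone warping functions of
increasing complexity — shift, linear, and piecewise-linear with 1-3 interior
knots — fit by alternating coordinate descent on per-trial knot values and a
template update (the mean of the warped trials).  Each model family warm
starts from the previous one's solution, so the minimized mean squared error
is non-increasing from shift to piecewise-3.  The fitted (behavior-derived)
warps are then applied to the neural activity of the same trials.

The reward-versus-omission index of a cell compares its warped activity
averaged over rewarded vs omission trials over the position bins from the
reward-zone start to the track end:

    RO = sum_j (r_j - o_j) / sum_j (r_j + o_j)

1 means firing only on rewarded trials, -1 only on omissions, 0 no
preference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MODEL_TYPES = ("shift", "linear", "piecewise-1", "piecewise-2", "piecewise-3")

#: number of interior knots per model (shift/linear handled specially)
_N_KNOTS = {"shift": 0, "linear": 0, "piecewise-1": 1, "piecewise-2": 2,
            "piecewise-3": 3}


@dataclass
class WarpModel:
    model_type: str
    knots_x: np.ndarray        # shared x positions of warp control points
    knots_y: np.ndarray        # (n_trials, n_points) per-trial control values
    template: np.ndarray       # (n_bins,) mean warped profile
    mse: float
    trial_mask: np.ndarray     # finite (included) trials
    n_bins: int

    def warp_positions(self, trial):
        """w_t(x) evaluated on the bin axis for one trial."""
        x = np.arange(self.n_bins, dtype=float)
        if self.model_type == "shift":
            return x + self.knots_y[trial, 0]
        return np.interp(x, self.knots_x, self.knots_y[trial])


def _warp_trial(profile, wx):
    """Resample a profile at warped positions (edge values outside)."""
    x = np.arange(len(profile), dtype=float)
    return np.interp(np.clip(wx, 0, len(profile) - 1), x, profile)


def _eval_warp(model_type, params, knots_x, n_bins):
    x = np.arange(n_bins, dtype=float)
    if model_type == "shift":
        return x + params[0]
    return np.interp(x, knots_x, params)


def _trial_mse(profile, template, model_type, params, knots_x, n_bins):
    wx = _eval_warp(model_type, params, knots_x, n_bins)
    return np.mean((_warp_trial(profile, wx) - template) ** 2)


def _descend_trial(profile, template, model_type, params, knots_x, n_bins,
                   span, n_candidates=21, sweeps=6):
    """Coordinate descent on one trial's warp parameters (monotone in y).

    Each sweep searches a grid of candidates around the current value of
    every parameter; the search range halves per sweep (multi-scale), so the
    final resolution is far below one bin.  Only improving moves are
    accepted, which preserves warm-start monotonicity of the MSE.
    """
    params = params.copy()
    best = _trial_mse(profile, template, model_type, params, knots_x, n_bins)
    r0 = span if model_type == "shift" else 0.75 * n_bins
    for sweep in range(sweeps):
        r = r0 / (2**sweep)
        for i in range(len(params)):
            if model_type == "shift":
                lo_b, hi_b = -span, span
            else:
                lo_b = params[i - 1] if i > 0 else -0.25 * n_bins
                hi_b = params[i + 1] if i < len(params) - 1 else 1.25 * n_bins
            lo = max(params[i] - r, lo_b)
            hi = min(params[i] + r, hi_b)
            cand = np.linspace(lo, hi, n_candidates)
            for c in cand:
                trial = params.copy()
                trial[i] = c
                m = _trial_mse(profile, template, model_type, trial,
                               knots_x, n_bins)
                if m < best - 1e-15:
                    best = m
                    params = trial
    return params, best


def _init_params(model_type, n_bins, rng=None, warm=None, warm_type=None,
                 warm_x=None):
    """Identity, random, or warm-start parameters for one trial."""
    k = _N_KNOTS[model_type]
    if model_type == "shift":
        if warm is not None and warm_type == "shift":
            return warm.copy()
        return np.zeros(1)
    kx = np.linspace(0, n_bins - 1, k + 2)
    if warm is not None:
        prev = _eval_warp(warm_type, warm, warm_x, n_bins)
        return np.interp(kx, np.arange(n_bins, dtype=float), prev)
    if rng is not None:
        y = np.sort(rng.uniform(-0.25 * n_bins, 1.25 * n_bins, k + 2))
        return y
    return kx.copy()


def fit_timewarp(profiles, model_type="piecewise-3", restarts=10, rng=None,
                 max_iter=15, tol=1e-10, return_chain=False):
    """Fit one warp-model family to trials x bins (x 1) speed profiles.

    Rewarded and omission trials are fit jointly; trials containing
    non-finite values are excluded (flagged in ``trial_mask``).  Families up
    to ``model_type`` are fit in sequence with warm starting, which makes
    the final MSE non-increasing in model complexity.
    """
    if model_type not in MODEL_TYPES:
        raise ValueError(f"unknown model type {model_type!r}")
    prof = np.asarray(profiles, dtype=float)
    if prof.ndim == 3:
        prof = prof[:, :, 0]
    mask = np.isfinite(prof).all(axis=1)
    if mask.sum() < 5:
        raise ValueError("need at least 5 finite trials")
    data = prof[mask]
    n_trials, n_bins = data.shape
    rng = np.random.default_rng(rng)
    span = 0.25 * n_bins

    chain = MODEL_TYPES[:MODEL_TYPES.index(model_type) + 1]
    prev_params = None
    prev_type = prev_x = None
    model = None
    chain_models = {}
    for mt in chain:
        k = _N_KNOTS[mt]
        kx = (np.linspace(0, n_bins - 1, k + 2) if mt != "shift"
              else np.array([0.0]))
        inits = []
        if prev_params is not None:
            inits.append([
                _init_params(mt, n_bins, warm=prev_params[t],
                             warm_type=prev_type, warm_x=prev_x)
                for t in range(n_trials)
            ])
        inits.append([_init_params(mt, n_bins) for _ in range(n_trials)])
        for _ in range(max(restarts - len(inits), 0)):
            inits.append([_init_params(mt, n_bins, rng=rng)
                          for _ in range(n_trials)])

        best = None
        for init in inits:
            params = [p.copy() for p in init]
            template = np.mean(
                [_warp_trial(data[t],
                             _eval_warp(mt, params[t], kx, n_bins))
                 for t in range(n_trials)], axis=0)
            mse_prev = np.inf
            for _ in range(max_iter):
                total = 0.0
                for t in range(n_trials):
                    params[t], m = _descend_trial(
                        data[t], template, mt, params[t], kx, n_bins, span)
                    total += m
                total /= n_trials
                template = np.mean(
                    [_warp_trial(data[t],
                                 _eval_warp(mt, params[t], kx, n_bins))
                     for t in range(n_trials)], axis=0)
                if mse_prev - total < tol:
                    break
                mse_prev = total
            mse = np.mean([
                _trial_mse(data[t], template, mt, params[t], kx, n_bins)
                for t in range(n_trials)])
            if best is None or mse < best[0]:
                best = (mse, [p.copy() for p in params], template.copy())
        mse, params, template = best
        prev_params, prev_type, prev_x = params, mt, kx
        model = WarpModel(
            model_type=mt, knots_x=kx,
            knots_y=np.array(params), template=template,
            mse=float(mse), trial_mask=mask, n_bins=n_bins,
        )
        chain_models[mt] = model
    if return_chain:
        return chain_models
    return model


def fit_warp_family(profiles, restarts=10, rng=None) -> dict:
    """Fit all five model types in one warm-start chain; returns {type: model}."""
    return fit_timewarp(profiles, MODEL_TYPES[-1], restarts=restarts,
                        rng=rng, return_chain=True)


def apply_warp(model: WarpModel, neural, inverse=False):
    """Resample trials x bins (x neurons) activity through the fitted warps.

    The warp was fit on behavior only; it is blind to the neural content.
    With ``inverse=True`` the (strictly monotone) warp is inverted.
    """
    v = np.asarray(neural, dtype=float)
    squeeze = v.ndim == 2
    if squeeze:
        v = v[:, :, None]
    included = np.nonzero(model.trial_mask)[0]
    if v.shape[0] == model.trial_mask.shape[0]:
        v = v[included]
    out = np.empty_like(v)
    x = np.arange(model.n_bins, dtype=float)
    for i in range(v.shape[0]):
        wx = model.warp_positions(i)
        if inverse:
            wxc = np.clip(wx, 0, model.n_bins - 1)
            for n in range(v.shape[2]):
                out[i, :, n] = np.interp(x, wxc, v[i, :, n])
        else:
            for n in range(v.shape[2]):
                out[i, :, n] = _warp_trial(v[i, :, n], wx)
    return out[:, :, 0] if squeeze else out


@dataclass
class ROResult:
    ro_index: np.ndarray      # per cell, in [-1, 1] (NaN if ineligible)
    eligible: np.ndarray      # per cell bool
    n_omissions: int


def reward_omission_index(warped, rewarded, zone_start_bin, peaks=None,
                          min_omissions=3) -> ROResult:
    """Reward-versus-omission index per cell.

    ``warped`` is trials x bins (x cells) warped activity; ``rewarded`` the
    per-trial rewarded flags (the rest are omissions).  Bins from
    ``zone_start_bin`` to the track end are summed.  Cells are eligible only
    when their spatial ``peaks`` (if given) fall in that span and the set has
    >= ``min_omissions`` omission trials.
    """
    v = np.asarray(warped, dtype=float)
    if v.ndim == 2:
        v = v[:, :, None]
    rewarded = np.asarray(rewarded, dtype=bool)
    n_om = int((~rewarded).sum())
    n_cells = v.shape[2]
    with np.errstate(invalid="ignore"):
        r_mean = np.nanmean(v[rewarded], axis=0)     # (bins, cells)
        o_mean = (np.nanmean(v[~rewarded], axis=0) if n_om > 0
                  else np.full(r_mean.shape, np.nan))
    span = slice(int(zone_start_bin), v.shape[1])
    num = np.nansum(r_mean[span] - o_mean[span], axis=0)
    den = np.nansum(r_mean[span] + o_mean[span], axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ro = num / den
    ro[den == 0] = np.nan

    eligible = np.full(n_cells, n_om >= min_omissions)
    if peaks is not None:
        pk = np.asarray(peaks, dtype=float)
        eligible &= np.isfinite(pk) & (pk >= zone_start_bin)
    ro = np.where(eligible, ro, np.nan)
    return ROResult(ro_index=ro, eligible=eligible, n_omissions=n_om)
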