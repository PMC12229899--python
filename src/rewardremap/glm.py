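"""Poisson encoding model with variable-group ablation.

The design matrix holds three task variables — track position and
reward-relative position, each expanded into 45 raised-cosine bases (one per
10-cm bin), and a rewarded-by-position interaction (the binary 'rewarded'
regressor switches to 1 at reward delivery and stays 1 to trial end, 0
throughout omission trials) — plus three movement variables (speed,
acceleration, lick rate), each quantile-transformed and expanded with cubic
B-splines with five knots (7 bases each): 156 columns in total.

Neurons are fit with a ridge-penalized Poisson regression (log link).  The
penalty is selected by fivefold cross-validated deviance inside an
85%/15% trial-grouped train/test split stratified over rewarded-before,
rewarded-after and omission trials.  Test performance is the fraction
deviance explained, FDE = 1 - dev_model/dev_null (null = constant mean
rate).  The contribution of a variable group is measured by zeroing its
coefficients and re-evaluating on the cross-validation data:

    relative contribution = (dev_ablated - dev_full) / (dev_null - dev_full).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import xlogy
from sklearn.preprocessing import QuantileTransformer, SplineTransformer

from .remapping import align_to_reward, to_periodic, wrap_phase
from .signals import _bin_indices
from scipy.ndimage import gaussian_filter1d

GROUP_NAMES = ("position", "rr_position", "rewarded_position",
               "speed", "acceleration", "licking")


@dataclass
class DesignMatrix:
    values: np.ndarray          # (n_samples, 156), unscaled
    groups: dict                # name -> column index array
    trial: np.ndarray           # per-sample trial id
    strata: np.ndarray          # per-sample stratum label
    frame_index: np.ndarray     # indices into the session frame table
    position_bin: np.ndarray    # per-sample 10-cm track bin

    @property
    def n_columns(self):
        return self.values.shape[1]


def raised_cosine_basis(phases, n_bases=45, half_width_bins=1.5):
    """Circular raised-cosine bases, one per phase bin, unit-sum per sample."""
    ph = np.asarray(phases, dtype=float)
    width = half_width_bins * 2 * np.pi / n_bases
    centers = wrap_phase((np.arange(n_bases) + 0.5) / n_bases * 2 * np.pi - np.pi)
    d = wrap_phase(ph[:, None] - centers[None, :])
    B = np.where(np.abs(d) < width, 0.5 * (1 + np.cos(np.pi * d / width)), 0.0)
    s = B.sum(axis=1, keepdims=True)
    return B / np.maximum(s, np.finfo(float).tiny)


def _movement_bases(x):
    """Quantile transform then cubic B-spline expansion (5 knots -> 7 bases)."""
    x = np.asarray(x, dtype=float).reshape(-1, 1)
    if np.std(x) == 0:
        raise ValueError("constant movement variable; quantile transform degenerate")
    qt = QuantileTransformer(
        n_quantiles=min(1000, len(x)), output_distribution="uniform",
        subsample=len(x), random_state=0)
    q = qt.fit_transform(x)
    st = SplineTransformer(n_knots=5, degree=3, include_bias=True)
    return st.fit_transform(q)


def _rewarded_flag(session):
    """Per-frame binary: 1 from reward delivery to trial end (0 on omissions)."""
    fr = session.frames
    pos = fr["position_cm"].to_numpy()
    trial = fr["trial"].to_numpy()
    flag = np.zeros(len(fr))
    for tr, row in session.trials.iterrows():
        if not row["rewarded"] or not np.isfinite(row["reward_pos_cm"]):
            continue
        sel = trial == tr
        after = np.zeros(sel.sum(), dtype=bool)
        on = np.isfinite(pos[sel]) & (pos[sel] >= row["reward_pos_cm"])
        if on.any():
            after[np.argmax(on):] = True
        flag[np.nonzero(sel)[0][after]] = 1.0
    return flag


def build_design_matrix(session) -> DesignMatrix:
    """156-column design matrix over the session's on-track frames."""
    fr = session.frames
    pos = fr["position_cm"].to_numpy()
    teleport = fr["teleport"].to_numpy().astype(bool)
    use = np.isfinite(pos) & ~teleport
    idx = np.nonzero(use)[0]
    trial = fr["trial"].to_numpy()[idx]

    theta = to_periodic(pos[idx], session.track_length_cm)
    zone_phase = to_periodic(session.trials["zone_start_cm"].to_numpy(),
                             session.track_length_cm)
    rr = align_to_reward(theta, zone_phase[trial])
    B_pos = raised_cosine_basis(theta, session.n_bins)
    B_rr = raised_cosine_basis(rr, session.n_bins)
    rewarded = _rewarded_flag(session)[idx]
    B_rew = rewarded[:, None] * B_pos

    speed = gaussian_filter1d(fr["speed_cms"].to_numpy().astype(float), 5.0)
    accel = gaussian_filter1d(
        np.gradient(fr["speed_cms"].to_numpy().astype(float))
        * session.frame_rate_hz, 5.0)
    lick = gaussian_filter1d(fr["lick"].to_numpy().astype(float), 2.0)
    B_speed = _movement_bases(speed[idx])
    B_acc = _movement_bases(accel[idx])
    B_lick = _movement_bases(lick[idx])

    blocks = [B_pos, B_rr, B_rew, B_speed, B_acc, B_lick]
    X = np.hstack(blocks)
    groups = {}
    start = 0
    for name, b in zip(GROUP_NAMES, blocks):
        groups[name] = np.arange(start, start + b.shape[1])
        start += b.shape[1]

    om = session.trials["omission"].to_numpy()
    sw = session.switch_trial or session.n_trials // 2
    strata_by_trial = np.where(
        om, "omission", np.where(np.arange(session.n_trials) < sw,
                                 "rewarded_before", "rewarded_after"))
    pbin = _bin_indices(pos[idx], session.bin_edges, session.track_length_cm)
    return DesignMatrix(values=X, groups=groups, trial=trial,
                        strata=strata_by_trial[trial], frame_index=idx,
                        position_bin=pbin)


def stratified_trial_split(design: DesignMatrix, test_frac=0.15, rng=None):
    """Trial-grouped train/test split stratified over reward strata."""
    rng = np.random.default_rng(rng)
    trials = np.unique(design.trial)
    stratum = {t: design.strata[design.trial == t][0] for t in trials}
    train, test = [], []
    for s in np.unique(list(stratum.values())):
        ts = np.array([t for t in trials if stratum[t] == s])
        ts = rng.permutation(ts)
        n_test = max(int(round(test_frac * len(ts))), 1)
        test.extend(ts[:n_test])
        train.extend(ts[n_test:])
    return np.sort(np.array(train)), np.sort(np.array(test))


def poisson_deviance(y, mu):
    """Poisson deviance 2*sum(y log(y/mu) - (y - mu))."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-12)
    return float(2.0 * np.sum(xlogy(y, y / mu) - (y - mu)))


def _fit_poisson_ridge(X, Y, alpha, W0=None, b0=None, tol=1e-7, maxiter=400):
    """Joint ridge Poisson fits for all response columns of Y.

    Returns (W (p x N), b (N,)).  The intercept is unpenalized.
    """
    n, p = X.shape
    Y = np.atleast_2d(Y.T).T
    N = Y.shape[1]
    if W0 is None:
        W0 = np.zeros((p, N))
    if b0 is None:
        b0 = np.log(np.maximum(Y.mean(axis=0), 1e-4))

    def unpack(z):
        W = z[: p * N].reshape(p, N)
        b = z[p * N:]
        return W, b

    def fun(z):
        W, b = unpack(z)
        eta = np.clip(X @ W + b, -30, 30)
        mu = np.exp(eta)
        loss = np.sum(mu - Y * eta) + 0.5 * alpha * np.sum(W * W)
        r = mu - Y
        gW = X.T @ r + alpha * W
        gb = r.sum(axis=0)
        return loss / n, np.concatenate([gW.ravel(), gb]) / n

    z0 = np.concatenate([W0.ravel(), b0])
    res = minimize(fun, z0, jac=True, method="L-BFGS-B",
                   options=dict(maxiter=maxiter, ftol=tol, gtol=1e-6))
    W, b = unpack(res.x)
    return W, b, bool(res.success)


@dataclass
class GLMFit:
    coef: np.ndarray            # (p, n_neurons) final model on all train data
    intercept: np.ndarray
    alpha: np.ndarray           # selected penalty per neuron
    fde_test: np.ndarray
    fde_train: np.ndarray
    converged: np.ndarray
    groups: dict
    col_mean: np.ndarray        # train-fold standardization
    col_sd: np.ndarray
    cv_coef: list = field(default_factory=list)      # per fold (p, N)
    cv_intercept: list = field(default_factory=list)
    cv_val_rows: list = field(default_factory=list)  # per fold sample indices


def _standardize(X, mean, sd):
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (X - mean) / sd
    Z[:, sd == 0] = 0.0
    return Z


def fit_poisson_glm(design: DesignMatrix, Y, rng=None, test_frac=0.15,
                    n_folds=5, alphas=(0.03, 0.3, 3.0, 30.0)) -> GLMFit:
    """Fit the encoding model to one or more neurons (columns of Y).

    Columns are z-scored with training-set statistics.  The ridge penalty is
    chosen per neuron by fivefold cross-validated deviance on the training
    trials; FDE is reported on the held-out test trials.
    """
    rng = np.random.default_rng(rng)
    Y = np.atleast_2d(np.asarray(Y, dtype=float).T).T
    N = Y.shape[1]
    train_tr, test_tr = stratified_trial_split(design, test_frac, rng)
    in_train = np.isin(design.trial, train_tr)
    in_test = np.isin(design.trial, test_tr)
    mean = design.values[in_train].mean(axis=0)
    sd = design.values[in_train].std(axis=0)
    Z = _standardize(design.values, mean, sd)
    Ztr, Ytr = Z[in_train], Y[in_train]

    # fivefold CV over training trials
    perm = rng.permutation(train_tr)
    folds = np.array_split(perm, n_folds)
    cv_dev = np.zeros((len(alphas), n_folds, N))
    fold_rows = []
    fold_models = {}
    for k, val_trials in enumerate(folds):
        val = np.isin(design.trial, val_trials) & in_train
        fit = in_train & ~val
        fold_rows.append(np.nonzero(val)[0])
        W, b = None, None
        for a_i, alpha in enumerate(alphas):
            W, b, _ = _fit_poisson_ridge(Z[fit], Y[fit], alpha, W0=W, b0=b)
            mu = np.exp(np.clip(Z[val] @ W + b, -30, 30))
            for j in range(N):
                cv_dev[a_i, k, j] = poisson_deviance(Y[val][:, j], mu[:, j])
            fold_models[(a_i, k)] = (W.copy(), b.copy())

    best_alpha_idx = cv_dev.sum(axis=1).argmin(axis=0)   # per neuron
    # final fit on all training data at each selected alpha
    coef = np.zeros((Z.shape[1], N))
    intercept = np.zeros(N)
    converged = np.zeros(N, dtype=bool)
    for a_i in np.unique(best_alpha_idx):
        cols = np.nonzero(best_alpha_idx == a_i)[0]
        W, b, ok = _fit_poisson_ridge(Ztr, Ytr[:, cols], alphas[a_i])
        coef[:, cols] = W
        intercept[cols] = b
        converged[cols] = ok

    def _fde(rows):
        mu = np.exp(np.clip(Z[rows] @ coef + intercept, -30, 30))
        out = np.empty(N)
        for j in range(N):
            dev = poisson_deviance(Y[rows][:, j], mu[:, j])
            null = poisson_deviance(Y[rows][:, j],
                                    np.full(rows.sum(), Ytr[:, j].mean()))
            out[j] = 0.0 if null == 0 else 1.0 - dev / null
        return out

    # keep per-fold models at the selected alpha for ablation analyses
    cv_coef, cv_int = [], []
    for k in range(n_folds):
        Wk = np.zeros_like(coef)
        bk = np.zeros(N)
        for a_i in np.unique(best_alpha_idx):
            cols = np.nonzero(best_alpha_idx == a_i)[0]
            W, b = fold_models[(a_i, k)]
            Wk[:, cols] = W[:, cols]
            bk[cols] = b[cols]
        cv_coef.append(Wk)
        cv_int.append(bk)

    return GLMFit(
        coef=coef, intercept=intercept,
        alpha=np.array([alphas[i] for i in best_alpha_idx]),
        fde_test=_fde(in_test), fde_train=_fde(in_train),
        converged=converged, groups=design.groups,
        col_mean=mean, col_sd=sd,
        cv_coef=cv_coef, cv_intercept=cv_int, cv_val_rows=fold_rows,
    )


def relative_contribution(fit: GLMFit, design: DesignMatrix, Y, group,
                          per_bin=False):
    """Ablation contribution of one variable group on the CV data.

    Returns per-neuron scores, or a (n_bins, n_neurons) array when
    ``per_bin`` (contribution restricted to samples in each 10-cm bin).
    NaN where dev_null == dev_full.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float).T).T
    N = Y.shape[1]
    Z = _standardize(design.values, fit.col_mean, fit.col_sd)
    cols = fit.groups[group]
    n_bins = design.position_bin.max() + 1
    shape = (n_bins, N) if per_bin else (N,)
    dev_full = np.zeros(shape)
    dev_abl = np.zeros(shape)
    dev_null = np.zeros(shape)
    for Wk, bk, rows in zip(fit.cv_coef, fit.cv_intercept, fit.cv_val_rows):
        Wa = Wk.copy()
        Wa[cols] = 0.0
        mu_f = np.exp(np.clip(Z[rows] @ Wk + bk, -30, 30))
        mu_a = np.exp(np.clip(Z[rows] @ Wa + bk, -30, 30))
        ybar = Y.mean(axis=0)
        if per_bin:
            pb = design.position_bin[rows]
            for b in range(n_bins):
                sel = pb == b
                if not sel.any():
                    continue
                for j in range(N):
                    dev_full[b, j] += poisson_deviance(Y[rows][sel, j], mu_f[sel, j])
                    dev_abl[b, j] += poisson_deviance(Y[rows][sel, j], mu_a[sel, j])
                    dev_null[b, j] += poisson_deviance(
                        Y[rows][sel, j], np.full(sel.sum(), ybar[j]))
        else:
            for j in range(N):
                dev_full[j] += poisson_deviance(Y[rows][:, j], mu_f[:, j])
                dev_abl[j] += poisson_deviance(Y[rows][:, j], mu_a[:, j])
                dev_null[j] += poisson_deviance(
                    Y[rows][:, j], np.full(len(rows), ybar[j]))
    with np.errstate(invalid="ignore", divide="ignore"):
        rc = (dev_abl - dev_full) / (dev_null - dev_full)
    rc = np.where(dev_null == dev_full, np.nan, rc)
    return rc


def contribution_table(fit: GLMFit, design: DesignMatrix, Y) -> pd.DataFrame:
    """Per-neuron relative contribution of every variable group."""
    out = {g: relative_contribution(fit, design, Y, g) for g in fit.groups}
    df = pd.DataFrame(out)
    df["fde_test"] = fit.fde_test
    df["top_predictor"] = df[list(fit.groups)].idxmax(axis=1)
    return df


def top_predictor_table(contribs: pd.DataFrame, labels, fde_min=0.15
                        ) -> pd.DataFrame:
    """Distribution of argmax-contribution variables per cell subpopulation.

    Only cells with FDE above ``fde_min`` are counted.
    """
    labels = pd.Series(np.asarray(labels), index=contribs.index)
    keep = contribs["fde_test"] > fde_min
    rows = []
    for lab in labels[keep].unique():
        sub = contribs[keep & (labels == lab)]
        counts = sub["top_predictor"].value_counts(normalize=True)
        for var, frac in counts.items():
            rows.append(dict(subpop=lab, variable=var, fraction=frac,
                             n_cells=len(sub)))
    return pd.DataFrame(rows, columns=["subpop", "variable", "fraction", "n_cells"])
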