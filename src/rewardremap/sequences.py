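"""Behavioral-timescale sequence analysis and cross-day tracking.

Neurons are sorted by peak position on odd pre-switch trials; the sort is
cross-validated on even pre-switch trials and applied to post-switch (or
next-day) trials.  Preservation of sequence order is the circular-circular
correlation (Jammalamadaka-SenGupta estimator)

    rho = sum sin(a - a_bar) sin(b - b_bar)
          / sqrt(sum sin^2(a - a_bar) * sum sin^2(b - b_bar))

with circular means a_bar, b_bar, validated by a cell-identity permutation
test with P = (n_{|rho_shuf| >= |rho_obs|} + 1)/(N_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

from .placecells import population_peaks
from .remapping import bin_phase

MIN_CELLS_CROSS_DAY = 5


@dataclass
class SequenceResult:
    sort_order: np.ndarray        # neuron indices sorted by odd-pre peaks
    positions_before: np.ndarray  # even-pre trial-averaged peak phases
    positions_after: np.ndarray
    rho: float
    p_perm: float
    n_cells: int
    low_n: bool = False


def circular_mean(phases):
    phases = np.asarray(phases, dtype=float)
    return float(np.arctan2(np.sin(phases).mean(), np.cos(phases).mean()))


def circ_circ_corr(a, b) -> float:
    """Jammalamadaka-SenGupta circular-circular correlation coefficient.

    NaN when either sample has zero circular dispersion.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    sa = np.sin(a - circular_mean(a))
    sb = np.sin(b - circular_mean(b))
    denom = np.sqrt((sa**2).sum() * (sb**2).sum())
    if denom == 0:
        return np.nan
    return float((sa * sb).sum() / denom)


def sequence_permutation_test(positions_before, positions_after,
                              n_perm=1000, rng=None, exhaustive=False):
    """Two-tailed cell-identity permutation test of the sequence correlation.

    Returns (rho, p).  With ``exhaustive=True`` all n! relabelings of
    ``positions_after`` are enumerated instead of sampled (small n only).
    """
    rng = np.random.default_rng(rng)
    a = np.asarray(positions_before, dtype=float)
    b = np.asarray(positions_after, dtype=float)
    obs = circ_circ_corr(a, b)
    if exhaustive:
        shufs = np.array([circ_circ_corr(a, b[list(p)])
                          for p in permutations(range(len(b)))])
        # exclude the identity arrangement count convention: keep all
        n_ge = np.sum(np.abs(shufs) >= abs(obs))
        return obs, float(n_ge / len(shufs))
    n_ge = 0
    for _ in range(n_perm):
        n_ge += abs(circ_circ_corr(a, rng.permutation(b))) >= abs(obs)
    return obs, float((n_ge + 1) / (n_perm + 1))


def cross_validated_sequence(dff_tensor_values, pre_trials, post_trials,
                             cells=None, n_perm=1000, rng=None,
                             min_cells=MIN_CELLS_CROSS_DAY) -> SequenceResult:
    """Cross-validated sequence of a cell subpopulation across a switch.

    ``dff_tensor_values`` is trials x bins x neurons unsmoothed binned ΔF/F
    in circular *track* coordinates.  The sort comes from odd pre-switch
    trials; sequence positions are the peak phases of the even-pre and
    post-switch trial averages.
    """
    rng = np.random.default_rng(rng)
    v = np.asarray(dff_tensor_values, dtype=float)
    if cells is not None:
        v = v[:, :, np.asarray(cells)]
    n_cells = v.shape[2]
    n_bins = v.shape[1]
    pre = np.asarray(pre_trials)
    post = np.asarray(post_trials)
    low_n = n_cells < min_cells

    odd = pre[1::2]
    even = pre[0::2]
    pk_sort = population_peaks(v, odd)
    order = np.argsort(pk_sort, kind="stable")
    pos_before = bin_phase(population_peaks(v, even), n_bins)
    pos_after = bin_phase(population_peaks(v, post), n_bins)
    if low_n:
        return SequenceResult(order, pos_before, pos_after,
                              np.nan, np.nan, n_cells, low_n=True)
    ok = np.isfinite(pos_before) & np.isfinite(pos_after)
    rho, p = sequence_permutation_test(pos_before[ok], pos_after[ok],
                                       n_perm=n_perm, rng=rng)
    return SequenceResult(order, pos_before, pos_after, rho, p,
                          int(ok.sum()), low_n=False)


def sequence_density(peak_phases, n_place_cells, n_bins=45):
    """Fraction of place cells with peaks in each 2*pi/n_bins phase bin."""
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    ph = np.asarray(peak_phases, dtype=float)
    counts = np.histogram(ph[np.isfinite(ph)], bins=edges)[0]
    return counts / max(n_place_cells, 1)


def circular_variance(phases):
    """1 - mean resultant length, in [0, 1] (0 = concentrated, 1 = uniform)."""
    ph = np.asarray(phases, dtype=float)
    ph = ph[np.isfinite(ph)]
    if len(ph) == 0:
        return np.nan
    R = np.hypot(np.sin(ph).mean(), np.cos(ph).mean())
    return float(np.clip(1.0 - R, 0.0, 1.0))


def bootstrap_circular_mean_ci(phases, n_boot=10000, ci=95.0, rng=None):
    """Bootstrap confidence interval of the circular mean.

    Used to test for a directional bias of a phase distribution (e.g. an
    over-representation of peaks just after the reward-zone start): the
    bias is supported when the CI excludes the null direction.  Returns
    (mean, lo, hi) in radians; lo/hi are quantiles of the wrapped
    differences from the point estimate, re-centered.
    """
    rng = np.random.default_rng(rng)
    ph = np.asarray(phases, dtype=float)
    ph = ph[np.isfinite(ph)]
    if len(ph) == 0:
        return np.nan, np.nan, np.nan
    m = circular_mean(ph)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = circular_mean(rng.choice(ph, size=len(ph), replace=True))
    d = np.mod(boots - m + np.pi, 2 * np.pi) - np.pi
    alpha = (100.0 - ci) / 2
    lo, hi = np.percentile(d, [alpha, 100 - alpha])
    return m, m + lo, m + hi


def iou(mask_a, mask_b) -> float:
    """Intersection over union of two boolean pixel masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def match_rois_across_days(masks_day1, masks_day2) -> pd.DataFrame:
    """Greedy cross-day ROI matching by pixel intersection-over-union.

    Empty masks are excluded.  The acceptance threshold is chosen as the
    largest IoU such that every accepted best match exceeds that pair's
    second-best IoU — matches whose best IoU does not beat the runner-up for
    either ROI are rejected.  Returns a table (roi_day1, roi_day2, iou).
    """
    m1 = [np.asarray(m, dtype=bool) for m in masks_day1]
    m2 = [np.asarray(m, dtype=bool) for m in masks_day2]
    ok1 = [i for i, m in enumerate(m1) if m.any()]
    ok2 = [j for j, m in enumerate(m2) if m.any()]
    if not ok1 or not ok2:
        return pd.DataFrame(columns=["roi_day1", "roi_day2", "iou"])
    M = np.zeros((len(ok1), len(ok2)))
    for a, i in enumerate(ok1):
        for b, j in enumerate(ok2):
            M[a, b] = iou(m1[i], m2[j])

    def second_best(row):
        if len(row) < 2:
            return 0.0
        return float(np.sort(row)[-2])

    pairs = []
    used1, used2 = set(), set()
    order = np.argsort(M, axis=None)[::-1]
    for flat in order:
        a, b = np.unravel_index(flat, M.shape)
        if M[a, b] <= 0 or a in used1 or b in used2:
            continue
        if M[a, b] <= second_best(M[a, :]) or M[a, b] <= second_best(M[:, b]):
            continue
        used1.add(a)
        used2.add(b)
        pairs.append(dict(roi_day1=ok1[a], roi_day2=ok2[b], iou=float(M[a, b])))
    return pd.DataFrame(pairs, columns=["roi_day1", "roi_day2", "iou"])


def recruitment_table(labels_day_a, labels_day_b, matching: pd.DataFrame
                      ) -> pd.DataFrame:
    """Label-conversion fractions among cells followed across a day pair.

    ``labels_day_*`` map neuron index -> category; ``matching`` is the ROI
    matching table.  Returns rows (from_label, to_label, n, fraction) where
    fraction is normalized within each from_label.
    """
    if len(matching) == 0:
        return pd.DataFrame(columns=["from_label", "to_label", "n", "fraction"])
    la = pd.Series(labels_day_a)
    lb = pd.Series(labels_day_b)
    rows = []
    pairs = [(la[r.roi_day1], lb[r.roi_day2]) for r in matching.itertuples()]
    df = pd.DataFrame(pairs, columns=["from_label", "to_label"])
    for (fr, to), grp in df.groupby(["from_label", "to_label"]):
        n_from = (df["from_label"] == fr).sum()
        rows.append(dict(from_label=fr, to_label=to, n=len(grp),
                         fraction=len(grp) / n_from))
    return pd.DataFrame(rows)
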