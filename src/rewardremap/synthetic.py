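"""Synthetic VR reward-switch sessions with ground-truth tuning classes.

Emulates head-fixed mice running a 450-cm virtual track with a hidden 50-cm
reward zone at one of three locations (A: 80 cm, B: 200 cm, C: 320 cm).  After
a fixed number of trials the zone moves.  Rewards are randomly omitted on a
fraction of trials.  Behavior shows anticipatory licking and slowing before
the active zone; each lap ends in a "teleport" period of jittered duration.

Neurons are drawn from ground-truth tuning classes:

``TR``
    track-relative: field fixed in track coordinates across the switch.
``RR``
    reward-relative: field at a fixed circular distance from the reward-zone
    start, so it translates with the zone; anchors are biased to positions
    just after the zone start (post-reward over-representation).
``appearing`` / ``disappearing``
    spatially tuned only after / only before the switch.
``random_remap``
    tuned in both epochs at unrelated track positions.
``untuned``
    position-independent low-rate activity.
``speed_coupled``
    rate proportional to running speed (putative interneuron).

Event rates are Poisson samples of the underlying rate; ``dff`` traces are the
event train convolved with a single-exponential calcium kernel plus Gaussian
noise.  All randomness derives from a single seed via per-neuron substreams,
so adding neurons does not perturb the simulated behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import lfilter

TUNING_CLASSES = (
    "TR",
    "RR",
    "appearing",
    "disappearing",
    "random_remap",
    "untuned",
    "speed_coupled",
)

#: per-class default counts and parameters for a default session
DEFAULT_POPULATION = {
    "TR": {"n": 100},
    "RR": {"n": 100, "post_reward_bias": 0.6},
    "appearing": {"n": 40},
    "disappearing": {"n": 40},
    "random_remap": {"n": 60},
    "untuned": {"n": 50},
    "speed_coupled": {"n": 10},
}


@dataclass
class SimConfig:
    """Parameters of a simulated switch session.

    Defaults mirror the task geometry: a 450-cm circular-trial track binned at
    10 cm, hidden 50-cm reward zones starting at 80/200/320 cm, a reward
    switch after 30 trials, ~15% random reward omissions, and behavior/imaging
    sampled at 15.5 Hz.
    """

    track_length_cm: float = 450.0
    n_bins: int = 45
    zone_starts_cm: dict = field(
        default_factory=lambda: {"A": 80.0, "B": 200.0, "C": 320.0}
    )
    zone_length_cm: float = 50.0
    n_trials: int = 80
    switch_trial: int = 30
    zone_sequence: tuple = ("A", "B")
    omission_prob: float = 0.15
    frame_rate_hz: float = 15.5
    population_spec: dict = field(default_factory=lambda: dict(DEFAULT_POPULATION))
    seed: int = 0

    # neural response parameters
    calcium_tau_s: float = 0.7
    dff_per_event: float = 0.25
    dff_noise_sd: float = 0.05
    peak_rate_hz: float = 8.0
    baseline_rate_hz: float = 0.05
    field_sd_cm: float = 20.0
    field_jitter_sd_cm: float = 10.0
    gain_sigma: float = 0.3

    # behavioral parameters
    base_speed_cms: float = 45.0
    slowdown_depth: float = 0.7
    slowdown_sd_cm: float = 25.0

    # trial at which the neural map / overt behavior adopts the new zone
    # (defaults to the actual reward switch)
    neural_remap_trial: Optional[int] = None
    behavior_remap_trial: Optional[int] = None

    def __post_init__(self):
        if not 0 <= self.omission_prob < 1:
            raise ValueError("omission_prob must be in [0, 1)")
        if self.switch_trial >= self.n_trials:
            raise ValueError("switch_trial must be < n_trials")
        for name, start in self.zone_starts_cm.items():
            if start + self.zone_length_cm > self.track_length_cm:
                raise ValueError(f"zone {name} extends past the track end")
        for cls in self.population_spec:
            if cls not in TUNING_CLASSES:
                raise ValueError(f"unknown tuning class {cls!r}")
        for z in self.zone_sequence:
            if z not in self.zone_starts_cm:
                raise ValueError(f"unknown zone {z!r} in zone_sequence")

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(0.0, self.track_length_cm, self.n_bins + 1)


@dataclass
class GroundTruth:
    """Simulator-side per-neuron tuning class and parameters.

    ``anchor_phase`` is the field center: a reward-relative phase for RR
    cells, a track phase for all other tuned classes.  ``anchor_phase_post``
    holds the independent post-switch anchor of random-remap cells (NaN
    elsewhere).  ``gains`` is the (neurons x trials) multiplicative per-trial
    gain; ``jitter_phase`` the (neurons x trials) per-trial field jitter.
    """

    table: pd.DataFrame
    gains: np.ndarray
    jitter_phase: np.ndarray

    def neurons_of_class(self, cls: str) -> np.ndarray:
        return self.table.index[self.table["tuning_class"] == cls].to_numpy()


@dataclass
class Session:
    """One simulated (or loaded) imaging session.

    ``frames`` has one row per imaging frame: time_s, trial, position_cm
    (NaN during teleport), speed_cms, lick (0/1), teleport (bool).
    ``trials`` has one row per trial: zone, zone_start_cm, rewarded,
    omission, reward_pos_cm (NaN on omissions), teleport_distance_cm.
    ``dff`` and ``events`` are (neurons x frames) float32 arrays.
    """

    frames: pd.DataFrame
    trials: pd.DataFrame
    dff: np.ndarray
    events: np.ndarray
    frame_rate_hz: float
    track_length_cm: float = 450.0
    n_bins: int = 45
    zone_length_cm: float = 50.0
    meta: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return self.dff.shape[0]

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(0.0, self.track_length_cm, self.n_bins + 1)

    @property
    def switch_trial(self) -> Optional[int]:
        """First trial of the new reward zone, or None on non-switch days."""
        zones = self.trials["zone"].to_numpy()
        change = np.nonzero(zones[1:] != zones[:-1])[0]
        if len(change) == 0:
            return None
        return int(change[0]) + 1

    def trial_sets(self) -> tuple[np.ndarray, np.ndarray]:
        """(pre-switch, post-switch) trial indices; session halves if no switch."""
        sw = self.switch_trial
        if sw is None:
            sw = self.n_trials // 2
        t = np.arange(self.n_trials)
        return t[:sw], t[sw:]


def wrap_phase(phase):
    """Wrap angles to [-pi, pi)."""
    return np.mod(np.asarray(phase) + np.pi, 2 * np.pi) - np.pi


def _position_to_phase(position_cm, track_length_cm):
    return wrap_phase(np.asarray(position_cm) / track_length_cm * 2 * np.pi - np.pi)


def _simulate_behavior(cfg: SimConfig, rng: np.random.Generator):
    """Frame-by-frame behavior for every trial, including teleports."""
    dt = 1.0 / cfg.frame_rate_hz
    omission = rng.random(cfg.n_trials) < cfg.omission_prob
    behav_switch = (
        cfg.behavior_remap_trial
        if cfg.behavior_remap_trial is not None
        else cfg.switch_trial
    )

    rows_f = {k: [] for k in ("time_s", "trial", "position_cm", "speed_cms", "lick", "teleport")}
    rows_t = []
    t_now = 0.0
    for tr in range(cfg.n_trials):
        zone = cfg.zone_sequence[0] if tr < cfg.switch_trial else cfg.zone_sequence[1]
        bzone = cfg.zone_sequence[0] if tr < behav_switch else cfg.zone_sequence[1]
        z0 = cfg.zone_starts_cm[zone]
        bz0 = cfg.zone_starts_cm[bzone]
        z1 = z0 + cfg.zone_length_cm

        v0 = max(rng.normal(cfg.base_speed_cms, 4.0), 20.0)
        x = 0.0
        reward_pos = np.nan
        rewarded = False
        consume_until = -1.0  # time until which the mouse pauses/licks post-reward
        while x < cfg.track_length_cm:
            # anticipatory slowing centered shortly after the behavioral zone start
            d = x - (bz0 + 10.0)
            slow = cfg.slowdown_depth * np.exp(-(d * d) / (2 * cfg.slowdown_sd_cm**2))
            v = v0 * (1.0 - slow) + rng.normal(0.0, 3.0)
            if t_now < consume_until:
                v = rng.uniform(0.0, 1.5)  # consummatory pause
            v = max(v, 0.0)

            # licking probability by position relative to the behavioral zone
            if t_now < consume_until:
                p_lick = 0.8
            elif bz0 - cfg.zone_length_cm <= x < bz0:
                p_lick = 0.08 + 0.5 * (x - (bz0 - cfg.zone_length_cm)) / cfg.zone_length_cm
            elif bz0 <= x < bz0 + cfg.zone_length_cm and not rewarded:
                p_lick = 0.55
            else:
                p_lick = 0.015
            lick = int(rng.random() < p_lick)

            # reward delivery at first lick inside the *actual* zone
            if (not rewarded) and (not omission[tr]) and z0 <= x < z1 and lick:
                rewarded = True
                reward_pos = x
                consume_until = t_now + 1.0
            rows_f["time_s"].append(t_now)
            rows_f["trial"].append(tr)
            rows_f["position_cm"].append(x)
            rows_f["speed_cms"].append(v)
            rows_f["lick"].append(lick)
            rows_f["teleport"].append(False)
            x += v * dt
            t_now += dt

        # auto-delivery at zone end if the mouse never licked in the zone
        if not rewarded and not omission[tr]:
            rewarded = True
            reward_pos = z1

        # teleport period: longer after omissions
        dur = rng.uniform(5.0, 10.0) if omission[tr] else rng.uniform(1.0, 5.0)
        n_tp = max(int(round(dur * cfg.frame_rate_hz)), 1)
        tp_dist = 0.0
        for _ in range(n_tp):
            v = max(v0 + rng.normal(0.0, 5.0), 0.0)
            tp_dist += v * dt
            rows_f["time_s"].append(t_now)
            rows_f["trial"].append(tr)
            rows_f["position_cm"].append(np.nan)
            rows_f["speed_cms"].append(v)
            rows_f["lick"].append(0)
            rows_f["teleport"].append(True)
            t_now += dt

        rows_t.append(
            dict(
                trial=tr,
                zone=zone,
                zone_start_cm=z0,
                rewarded=bool(rewarded),
                omission=bool(omission[tr]),
                reward_pos_cm=reward_pos,
                teleport_distance_cm=tp_dist,
            )
        )

    frames = pd.DataFrame(rows_f)
    frames["trial"] = frames["trial"].astype(np.int64)
    frames["lick"] = frames["lick"].astype(np.int64)
    trials = pd.DataFrame(rows_t).set_index("trial")
    return frames, trials


def _assign_population(cfg: SimConfig, rng: np.random.Generator):
    """Draw per-neuron classes, anchors and amplitudes."""
    rows = []
    for cls, spec in cfg.population_spec.items():
        n = int(spec["n"])
        bias = float(spec.get("post_reward_bias", 0.6))
        for _ in range(n):
            amp = cfg.peak_rate_hz * rng.lognormal(0.0, 0.25)
            sd = cfg.field_sd_cm
            if cls == "RR":
                # over-represent reward-relative phases just after the zone start
                if rng.random() < bias:
                    anchor = rng.uniform(0.0, 1.5)
                else:
                    anchor = rng.uniform(-np.pi, np.pi)
            else:
                anchor = rng.uniform(-np.pi, np.pi)
            anchor_post = (
                rng.uniform(-np.pi, np.pi) if cls == "random_remap" else np.nan
            )
            rows.append(
                dict(
                    tuning_class=cls,
                    anchor_phase=wrap_phase(anchor),
                    anchor_phase_post=anchor_post,
                    field_sd_cm=sd,
                    amplitude=amp,
                )
            )
    table = pd.DataFrame(rows)
    table.index.name = "neuron"
    return table


def _neuron_rate(cfg: SimConfig, cls, anchor, anchor_post, sd_cm, amp,
                 gains, jitter, phase, speed, trial_idx, zone_phase_by_trial,
                 neural_switch):
    """Underlying event rate (Hz) for one neuron over all frames."""
    n_frames = phase.shape[0]
    rate = np.full(n_frames, cfg.baseline_rate_hz)
    if cls == "untuned":
        return rate + 0.45
    if cls == "speed_coupled":
        return rate + 0.15 * speed

    sd_phase = sd_cm / cfg.track_length_cm * 2 * np.pi
    post = trial_idx >= neural_switch
    centers = np.empty(cfg.n_trials)
    for tr in range(cfg.n_trials):
        if cls == "RR":
            c = anchor + zone_phase_by_trial[tr]
        elif cls == "random_remap":
            c = anchor_post if tr >= neural_switch else anchor
        else:
            c = anchor
        centers[tr] = c + jitter[tr]
    d = wrap_phase(phase - centers[trial_idx])
    bump = np.exp(-(d * d) / (2 * sd_phase**2))
    g = gains[trial_idx]
    if cls == "appearing":
        g = np.where(post, g, 0.0)
    elif cls == "disappearing":
        g = np.where(post, 0.0, g)
    rate = rate + amp * g * bump
    rate[~np.isfinite(phase)] = cfg.baseline_rate_hz  # teleport: no spatial drive
    return rate


def simulate_session(config: SimConfig) -> tuple[Session, GroundTruth]:
    """Simulate one reward-switch session with known per-neuron ground truth.

    Returns the session (behavior frames, trial table, dff and event-rate
    traces) and the :class:`GroundTruth` used to generate it.  Bit-identical
    for a fixed config.
    """
    root = np.random.SeedSequence(config.seed)
    ss_behavior, ss_pop, ss_neurons = root.spawn(3)
    behavior_rng = np.random.default_rng(ss_behavior)
    pop_rng = np.random.default_rng(ss_pop)

    frames, trials = _simulate_behavior(config, behavior_rng)
    table = _assign_population(config, pop_rng)
    n_neurons = len(table)
    n_frames = len(frames)
    dt = 1.0 / config.frame_rate_hz

    neural_switch = (
        config.neural_remap_trial
        if config.neural_remap_trial is not None
        else config.switch_trial
    )
    # zone phase as seen by the neural map on each trial
    zone_phase_by_trial = np.empty(config.n_trials)
    for tr in range(config.n_trials):
        z = config.zone_sequence[0] if tr < neural_switch else config.zone_sequence[1]
        zone_phase_by_trial[tr] = _position_to_phase(
            config.zone_starts_cm[z], config.track_length_cm
        )

    phase = _position_to_phase(frames["position_cm"].to_numpy(), config.track_length_cm)
    speed = frames["speed_cms"].to_numpy()
    trial_idx = frames["trial"].to_numpy()

    jitter_sd_phase = config.field_jitter_sd_cm / config.track_length_cm * 2 * np.pi
    gains = np.empty((n_neurons, config.n_trials))
    jitters = np.empty((n_neurons, config.n_trials))
    events = np.empty((n_neurons, n_frames), dtype=np.float32)
    dff = np.empty((n_neurons, n_frames), dtype=np.float32)
    decay = np.exp(-dt / config.calcium_tau_s)

    child_seeds = ss_neurons.spawn(n_neurons)
    for i, (row, ss) in enumerate(zip(table.itertuples(), child_seeds)):
        nrng = np.random.default_rng(ss)
        gains[i] = nrng.lognormal(0.0, config.gain_sigma, config.n_trials)
        jitters[i] = nrng.normal(0.0, jitter_sd_phase, config.n_trials)
        rate = _neuron_rate(
            config, row.tuning_class, row.anchor_phase, row.anchor_phase_post,
            row.field_sd_cm, row.amplitude, gains[i], jitters[i],
            phase, speed, trial_idx, zone_phase_by_trial, neural_switch,
        )
        ev = nrng.poisson(rate * dt).astype(np.float32)
        events[i] = ev
        ca = lfilter([config.dff_per_event], [1.0, -decay], ev)
        dff[i] = ca + nrng.normal(0.0, config.dff_noise_sd, n_frames)

    session = Session(
        frames=frames,
        trials=trials,
        dff=dff,
        events=events,
        frame_rate_hz=config.frame_rate_hz,
        track_length_cm=config.track_length_cm,
        n_bins=config.n_bins,
        zone_length_cm=config.zone_length_cm,
        meta=dict(seed=config.seed, switch_trial=config.switch_trial,
                  zone_sequence=list(config.zone_sequence)),
    )
    gt = GroundTruth(table=table, gains=gains, jitter_phase=jitters)
    return session, gt


def tuning_curve(gt: GroundTruth, neuron: int, zone_start_cm: float,
                 track_length_cm: float = 450.0, n_bins: int = 45,
                 post: bool = False) -> np.ndarray:
    """Expected spatial tuning of one simulated neuron for a given zone.

    Returns the noiseless rate profile over ``n_bins`` equal track bins,
    normalized so the curve integrates (over cm) to the neuron's amplitude.
    RR cells produce a circular Gaussian bump at anchor + zone phase; TR-like
    classes a bump at their fixed track anchor; untuned cells a flat curve.
    """
    row = gt.table.loc[neuron]
    cls = row["tuning_class"]
    centers_cm = (np.arange(n_bins) + 0.5) * track_length_cm / n_bins
    theta = _position_to_phase(centers_cm, track_length_cm)
    if cls in ("untuned", "speed_coupled"):
        return np.full(n_bins, row["amplitude"] / track_length_cm)
    if cls == "RR":
        center = wrap_phase(
            row["anchor_phase"]
            + _position_to_phase(zone_start_cm, track_length_cm)
        )
    elif cls == "random_remap" and post:
        center = row["anchor_phase_post"]
    else:
        center = row["anchor_phase"]
    sd_phase = row["field_sd_cm"] / track_length_cm * 2 * np.pi
    bump = np.exp(-(wrap_phase(theta - center) ** 2) / (2 * sd_phase**2))
    bin_w = track_length_cm / n_bins
    integral = bump.sum() * bin_w
    return row["amplitude"] * bump / integral
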