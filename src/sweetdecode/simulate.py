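"""Synthetic sessions of the sucrose intensity discrimination task.

The generator produces the statistical structure the analyses assume:
rhythmic ~6.5 Hz licking, cue-locked rate modulations of the five evoked
profile classes, intensity tuning and graded concentration tracking,
choice/direction/outcome coding, trial-to-trial shared-gain noise
correlations, and sigmoidal psychometric behavior over the concentration
set {0, 3, 4.75, 7.5, 11.75, 18} wt%.

Spikes are drawn from an inhomogeneous Poisson process by thinning: the
per-trial rate function is an additive combination of baseline, cue-locked,
and label-dependent terms, multiplied by a lick-phase factor and a per-trial
shared gain, rectified at zero.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import expit

from .core import CONCENTRATIONS, LickTrain, Session, SpikeTrain, Trial, ValidationError

PROFILES = ("phasic", "tonic_active", "tonic_inactive",
            "coh_active", "coh_inactive", "non_evoked")


@dataclass
class NeuronSpec:
    """Generative parameters for one synthetic neuron.

    ``evoked_delta`` is the signed cue-locked rate change (spikes/s) applied
    from ``evoked_onset`` for ``evoked_duration`` after cue delivery.  The
    remaining terms inject the coding properties the detectors look for;
    ``noise_group`` couples neurons through a per-trial shared gain.
    """

    profile: str = "non_evoked"
    baseline_rate: float = 10.0
    evoked_delta: float = 0.0
    evoked_onset: float = 0.02
    evoked_duration: float = 0.5
    intensity_selectivity: str = "none"  # none | low_pref | high_pref
    intensity_effect: float = 0.0
    concentration_slope: float = 0.0  # spikes/s per wt%
    lick_coupling_depth: float = 0.0  # in [0, 1]
    lick_coupling_phase: float = 0.0
    lick_coupling_epochs: tuple | None = None  # None = wherever licking occurs
    choice_effect: float = 0.0  # signed, + = higher rate on High-port choices
    direction_pref: str = "none"  # none | left | right
    direction_effect: float = 0.0
    outcome_coding: str = "none"  # none | active | inactive
    outcome_effect: float = 0.0
    noise_group: int | None = None

    def __post_init__(self) -> None:
        if self.profile not in PROFILES:
            raise ValidationError(f"unknown profile {self.profile!r}")
        if not 0.0 <= self.lick_coupling_depth <= 1.0:
            raise ValidationError("lick_coupling_depth must lie in [0, 1]")
        if self.baseline_rate < 0:
            raise ValidationError("baseline_rate must be non-negative")
        if self.intensity_selectivity not in ("none", "low_pref", "high_pref"):
            raise ValidationError(
                f"unknown intensity_selectivity {self.intensity_selectivity!r}")
        if self.direction_pref not in ("none", "left", "right"):
            raise ValidationError(f"unknown direction_pref {self.direction_pref!r}")
        if self.outcome_coding not in ("none", "active", "inactive"):
            raise ValidationError(f"unknown outcome_coding {self.outcome_coding!r}")

    @classmethod
    def preset(cls, profile: str, **overrides) -> "NeuronSpec":
        """Strong-effect archetype of each modulation profile class."""
        base = {
            "phasic": dict(baseline_rate=8.0, evoked_delta=30.0,
                           evoked_onset=0.05, evoked_duration=0.10),
            "tonic_active": dict(baseline_rate=8.0, evoked_delta=10.0,
                                 evoked_onset=0.02, evoked_duration=0.50),
            "tonic_inactive": dict(baseline_rate=15.0, evoked_delta=-11.0,
                                   evoked_onset=0.02, evoked_duration=0.50),
            "coh_active": dict(baseline_rate=10.0, evoked_delta=10.0,
                               evoked_onset=0.02, evoked_duration=0.50,
                               lick_coupling_depth=0.9),
            "coh_inactive": dict(baseline_rate=16.0, evoked_delta=-11.0,
                                 evoked_onset=0.02, evoked_duration=0.50,
                                 lick_coupling_depth=0.9),
            "non_evoked": dict(baseline_rate=10.0, evoked_delta=0.0),
        }[profile]
        base.update(overrides)
        return cls(profile=profile, **base)


@dataclass
class PsychometricParams:
    """Logistic choice model p(High) = floor + (ceil - floor) * expit(slope*(c - midpoint))."""

    floor: float = 0.05
    ceiling: float = 0.95
    midpoint_wt_pct: float = 7.5
    slope: float = 0.6  # 1/wt%

    def p_high(self, concentration: float | np.ndarray) -> np.ndarray:
        return self.floor + (self.ceiling - self.floor) * expit(
            self.slope * (np.asarray(concentration, dtype=float) - self.midpoint_wt_pct))


@dataclass
class SimConfig:
    """Session-level generative parameters; defaults are the task conditions."""

    n_trials: int = 200
    cue_g_fraction: float = 0.20
    concentrations: tuple = CONCENTRATIONS
    psychometric: PsychometricParams = field(default_factory=PsychometricParams)
    lick_rate_hz: float = 6.5
    lick_jitter: float = 0.08  # lognormal sigma on inter-lick intervals
    n_dry_licks: tuple = (3, 5)  # pre-cue central licks required (range)
    return_median_s: float = 1.2
    return_sigma: float = 0.20
    response_median_s: float = 1.1
    response_sigma: float = 0.25
    stop_latency_base_s: float = 0.55  # latency to stop central licking at 0 wt%
    stop_latency_per_wt: float = 0.011  # palatability: longer licking for sweeter cues
    stop_latency_sigma: float = 0.15
    outcome_rewarded_s: float = 3.0  # lateral licking duration when rewarded
    outcome_omitted_s: float = 1.2
    iti_median_s: float = 2.0
    iti_sigma: float = 0.3
    high_port: str = "right"
    neurons: list = field(default_factory=lambda: [NeuronSpec()])
    noise_gain_sd: dict = field(default_factory=dict)  # noise_group -> gain SD

    def __post_init__(self) -> None:
        if not 0.0 <= self.cue_g_fraction <= 1.0:
            raise ValidationError("cue_g_fraction must lie in [0, 1]")
        for name in ("return_median_s", "response_median_s", "outcome_rewarded_s",
                     "outcome_omitted_s", "iti_median_s", "lick_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not self.neurons:
            raise ValidationError("config must define at least one neuron")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.md5(payload.encode()).hexdigest()


# -- behavior ------------------------------------------------------------------


def _lognormal(rng: np.random.Generator, median: float, sigma: float) -> float:
    return float(median * np.exp(sigma * rng.standard_normal()))


def _lick_bout(rng: np.random.Generator, start: float, stop: float,
               rate: float, jitter: float) -> np.ndarray:
    """Rhythmic lick onsets from ``start`` until ``stop`` (jittered intervals)."""
    times = [start]
    while True:
        isi = np.exp(jitter * rng.standard_normal()) / rate
        t = times[-1] + isi
        if t > stop:
            break
        times.append(t)
    return np.asarray(times)


def simulate_behavior(
    config: SimConfig, seed: int | np.random.Generator
) -> tuple[list[Trial], dict[str, np.ndarray]]:
    """Generate trials and lick trains for one session.

    Choices are Bernoulli with p(High) given by the configured psychometric;
    Cue-D trials are correct iff the choice matches the cue's intensity label
    and are rewarded iff correct; Cue-G trials are never rewarded.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cfg = config
    low_port = "left" if cfg.high_port == "right" else "right"
    cue_d_set = (3.0, 18.0)

    trials: list[Trial] = []
    licks: dict[str, list] = {"central": [], "left": [], "right": []}
    t = 1.0
    prev_choice = "left" if rng.random() < 0.5 else "right"
    for trial_id in range(cfg.n_trials):
        is_g = rng.random() < cfg.cue_g_fraction
        if is_g:
            conc = float(rng.choice(cfg.concentrations))
        else:
            conc = float(rng.choice(cue_d_set))
        label = "High" if conc >= 7.5 else "Low"
        cue_kind = "Cue-G" if is_g else "Cue-D"

        t_return_onset = t
        return_dur = _lognormal(rng, cfg.return_median_s, cfg.return_sigma)
        t_entry = t_return_onset + return_dur

        # pre-cue dry licking at the central spout; cue on the n-th lick
        isi = 1.0 / cfg.lick_rate_hz
        n_dry = int(rng.integers(cfg.n_dry_licks[0], cfg.n_dry_licks[1] + 1))
        pre = _lick_bout(rng, t_entry + 0.15, t_entry + 0.15 + (n_dry + 0.5) * isi,
                         cfg.lick_rate_hz, cfg.lick_jitter)[: n_dry + 1]
        t_cue = pre[-1]

        stop_lat = _lognormal(
            rng, cfg.stop_latency_base_s + cfg.stop_latency_per_wt * conc,
            cfg.stop_latency_sigma)
        stop_lat = max(stop_lat, 1.5 * isi)
        post = _lick_bout(rng, t_cue + isi * np.exp(cfg.lick_jitter * rng.standard_normal()),
                          t_cue + stop_lat, cfg.lick_rate_hz, cfg.lick_jitter)
        if post.size == 0:  # the Stimulus epoch needs at least one post-cue lick
            post = np.asarray([t_cue + isi])
        central = np.concatenate([pre, post])
        licks["central"].append(central)
        t_response_onset = float(central[-1])

        p_high = float(cfg.psychometric.p_high(conc))
        chose_high = rng.random() < p_high
        choice = cfg.high_port if chose_high else low_port
        correct = (label == "High") == chose_high
        rewarded = correct and not is_g

        move_dur = _lognormal(rng, cfg.response_median_s, cfg.response_sigma)
        move_dur = max(move_dur, 0.85)  # decision-window analyses need 0.8 s post-onset
        t_first_lat = t_response_onset + move_dur
        out_dur = cfg.outcome_rewarded_s if rewarded else cfg.outcome_omitted_s
        out_dur = _lognormal(rng, out_dur, 0.15)
        lat = _lick_bout(rng, t_first_lat, t_first_lat + max(out_dur, 3.0 * isi),
                         cfg.lick_rate_hz, cfg.lick_jitter)
        while lat.size < 2:  # analyses align on the second lateral lick
            lat = np.append(lat, lat[-1] + isi)
        licks[choice].append(lat)
        t_second_lat = float(lat[1])
        t_outcome_end = float(lat[-1]) + 0.1

        epochs = {
            "Return": (t_return_onset, t_entry),
            "Stimulus": (t_cue, t_response_onset),
            "Response": (t_response_onset, t_first_lat),
            "Outcome": (t_first_lat, t_outcome_end),
        }
        return_side = "right" if prev_choice == "left" else "left"
        trials.append(Trial(
            trial_id=trial_id, cue_kind=cue_kind, concentration_wt_pct=conc,
            intensity_label=label, choice=choice, correct=correct, rewarded=rewarded,
            t_cue=t_cue, t_response_onset=t_response_onset,
            t_second_lateral_lick=t_second_lat, t_return_onset=t_return_onset,
            epochs=epochs, return_side=return_side, high_port=cfg.high_port,
        ))
        prev_choice = choice
        t = t_outcome_end + max(t_second_lat + 0.7 - t_outcome_end, 0.0) \
            + _lognormal(rng, cfg.iti_median_s, cfg.iti_sigma)

    lick_arrays = {sp: (np.sort(np.concatenate(v)) if v else np.empty(0))
                   for sp, v in licks.items()}
    return trials, lick_arrays


# -- spikes --------------------------------------------------------------------


def _lick_factor(t: np.ndarray, lick_times: np.ndarray, depth: float,
                 phase0: float, max_gap: float = 0.4) -> np.ndarray:
    """Multiplicative lick-phase modulation 1 + depth*cos(phase).

    Phase advances linearly through each inter-lick cycle; outside licking
    bouts (gaps longer than ``max_gap``) the factor is 1.
    """
    if depth == 0.0 or lick_times.size < 2:
        return np.ones_like(t)
    idx = np.searchsorted(lick_times, t) - 1
    inside = (idx >= 0) & (idx < lick_times.size - 1)
    factor = np.ones_like(t)
    if np.any(inside):
        prev = lick_times[idx[inside]]
        nxt = lick_times[idx[inside] + 1]
        gap = nxt - prev
        ok = gap <= max_gap
        phase = 2.0 * np.pi * (t[inside] - prev) / gap + phase0
        mod = 1.0 + depth * np.cos(phase)
        mod[~ok] = 1.0
        factor[inside] = mod
    return factor


def _in(t: np.ndarray, a: float, b: float) -> np.ndarray:
    return (t >= a) & (t <= b)


def _trial_rate(spec: NeuronSpec, trial: Trial, t: np.ndarray,
                lick_times: np.ndarray, gain: float) -> np.ndarray:
    """Evaluate the neuron's rate function at session times ``t`` within a trial."""
    rate = np.full_like(t, spec.baseline_rate, dtype=float)

    cue = trial.t_cue
    if spec.evoked_delta != 0.0:
        rate += spec.evoked_delta * _in(t, cue + spec.evoked_onset,
                                        cue + spec.evoked_onset + spec.evoked_duration)
    stim_win = _in(t, cue, cue + 0.6)
    if spec.intensity_selectivity != "none" and spec.intensity_effect != 0.0:
        pref_label = "High" if spec.intensity_selectivity == "high_pref" else "Low"
        if trial.intensity_label == pref_label:
            rate += spec.intensity_effect * stim_win
    if spec.concentration_slope != 0.0:
        rate += spec.concentration_slope * trial.concentration_wt_pct * stim_win
    if spec.choice_effect != 0.0 and trial.choice == trial.high_port:
        rate += spec.choice_effect * _in(t, trial.t_response_onset - 0.4,
                                         trial.t_response_onset + 0.8)
    if spec.direction_pref != "none" and spec.direction_effect != 0.0:
        if trial.choice == spec.direction_pref:
            rate += spec.direction_effect * _in(t, trial.t_response_onset,
                                                trial.t_response_onset + 0.7)
        if trial.return_side == spec.direction_pref:
            rate += spec.direction_effect * _in(t, trial.t_return_onset,
                                                trial.t_return_onset + 0.7)
    if spec.outcome_coding != "none" and spec.outcome_effect != 0.0:
        out_win = _in(t, trial.t_second_lateral_lick, trial.t_second_lateral_lick + 0.6)
        if spec.outcome_coding == "active" and not trial.rewarded:
            rate += spec.outcome_effect * out_win
        elif spec.outcome_coding == "inactive" and trial.rewarded:
            rate += spec.outcome_effect * out_win

    if spec.lick_coupling_depth > 0.0:
        if spec.lick_coupling_epochs is None:
            mod_licks = lick_times
        else:
            segs = [trial.epochs[e] for e in spec.lick_coupling_epochs if e in trial.epochs]
            # pre-Stimulus licking = central licks between Return end and cue
            if "pre-Stimulus" in spec.lick_coupling_epochs:
                segs.append((trial.epochs["Return"][1], trial.t_cue))
            keep = np.zeros(lick_times.size, dtype=bool)
            for a, b in segs:
                keep |= (lick_times >= a) & (lick_times <= b)
            mod_licks = lick_times[keep]
        rate *= _lick_factor(t, mod_licks, spec.lick_coupling_depth,
                             spec.lick_coupling_phase)

    return np.maximum(rate * gain, 0.0)


def simulate_neuron(
    spec: NeuronSpec,
    trials: Sequence[Trial],
    licks: dict[str, np.ndarray],
    seed: int | np.random.Generator,
    gains: np.ndarray | None = None,
    neuron_id: str = "n0",
    channel: int = 0,
) -> SpikeTrain:
    """Sample a spike train by thinning the spec's rate function, trial by trial.

    ``gains`` is the per-trial shared multiplicative gain (1.0 if omitted);
    the session generator fills it from the neuron's noise group.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if gains is None:
        gains = np.ones(len(trials))
    if len(gains) != len(trials):
        raise ValidationError("gains must have one entry per trial")
    all_licks = np.sort(np.concatenate([licks.get(sp, np.empty(0))
                                        for sp in ("central", "left", "right")]))
    pos = [spec.evoked_delta, spec.intensity_effect, abs(spec.choice_effect),
           spec.direction_effect, spec.outcome_effect,
           spec.concentration_slope * 18.0]
    headroom = spec.baseline_rate + sum(p for p in pos if p > 0)
    spikes: list[np.ndarray] = []
    prev_end = -np.inf
    for trial, gain in zip(trials, gains):
        a = max(trial.t_return_onset - 0.5, prev_end)
        b = trial.epochs["Outcome"][1] + 0.7
        prev_end = b
        rmax = headroom * (1.0 + spec.lick_coupling_depth) * max(gain, 1e-12)
        if rmax <= 0:
            continue
        n_cand = rng.poisson(rmax * (b - a))
        if n_cand == 0:
            continue
        cand = np.sort(a + (b - a) * rng.random(n_cand))
        r = _trial_rate(spec, trial, cand, all_licks, gain)
        keep = rng.random(n_cand) * rmax < r
        spikes.append(cand[keep])
    ts = np.concatenate(spikes) if spikes else np.empty(0)
    ts = np.sort(ts)
    if ts.size > 1:  # enforce the strict-ordering invariant
        keep = np.concatenate([[True], np.diff(ts) >= 1e-6])
        ts = ts[keep]
    return SpikeTrain(neuron_id, ts, channel=channel)


def simulate_session(config: SimConfig, seed: int) -> Session:
    """Generate a full session; identical (seed, config) gives identical output."""
    ss = np.random.SeedSequence(seed)
    behav_rng, gain_rng, *neuron_seeds = [
        np.random.default_rng(s) for s in ss.spawn(2 + len(config.neurons))]
    trials, licks = simulate_behavior(config, behav_rng)

    groups = sorted({s.noise_group for s in config.neurons if s.noise_group is not None})
    group_z = {g: gain_rng.standard_normal(len(trials)) for g in groups}
    spikes = []
    for i, (spec, nrng) in enumerate(zip(config.neurons, neuron_seeds)):
        if spec.noise_group is not None:
            sd = config.noise_gain_sd.get(spec.noise_group, 0.2)
            gains = np.maximum(1.0 + sd * group_z[spec.noise_group], 0.0)
        else:
            gains = np.ones(len(trials))
        spikes.append(simulate_neuron(spec, trials, licks, nrng, gains,
                                      neuron_id=f"n{i:03d}", channel=i))

    lick_trains = [LickTrain(sp, arr) for sp, arr in licks.items()]
    n_g = sum(t.cue_kind == "Cue-G" for t in trials)
    meta = {
        "seed": int(seed),
        "config_hash": config.config_hash(),
        "cue_g_fraction_config": config.cue_g_fraction,
        "cue_g_fraction_observed": n_g / max(len(trials), 1),
        "generalization_session": n_g > 0,
    }
    return Session(f"synthetic-{seed}", trials, spikes, lick_trains,
                   region_label="synthetic", meta=meta)


def cohort(profile_counts: dict[str, int], seed: int, n_trials: int = 220,
           **spec_overrides) -> Session:
    """Convenience: one session with ``profile_counts[p]`` preset neurons per class."""
    specs = []
    for profile, n in profile_counts.items():
        specs.extend(NeuronSpec.preset(profile, **spec_overrides.get(profile, {}))
                     for _ in range(n))
    cfg = SimConfig(n_trials=n_trials, neurons=specs)
    return simulate_session(cfg, seed)
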