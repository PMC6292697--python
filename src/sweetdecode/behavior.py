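"""Behavioral summaries: task performance, psychometric fits, lick statistics."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import expit

from .core import AlignedRaster, Trial, align_spikes, bin_counts

logger = logging.getLogger(__name__)

_SLOPE_MAX = 50.0  # 1/wt%; optimizer bound flagging separable (step-like) data


@dataclass
class PsychometricFit:
    """Four-parameter logistic fit to percent-High responses vs concentration.

    percent(c) = floor + (ceiling - floor) * expit(slope * (c - midpoint)),
    all on the 0-100 scale, slope in 1/wt%.
    """

    concentrations: np.ndarray
    percent_high: np.ndarray
    n_trials: np.ndarray
    floor: float
    ceiling: float
    midpoint: float
    slope: float
    slope_ci: tuple[float, float]
    converged: bool = True
    at_bound: bool = False

    def predict(self, c: np.ndarray) -> np.ndarray:
        return _logistic4(np.asarray(c, dtype=float),
                          self.floor, self.ceiling, self.midpoint, self.slope)


@dataclass
class BehaviorSummary:
    percent_correct: float
    stop_licking_latency: dict = field(default_factory=dict)  # concentration -> [s]
    movement_times: dict = field(default_factory=dict)  # (epoch, side) -> [s]
    outcome_lick_duration: dict = field(default_factory=dict)  # rewarded/omitted -> [s]
    n_excluded: int = 0


def _logistic4(c, floor, ceiling, midpoint, slope):
    return floor + (ceiling - floor) * expit(slope * (c - midpoint))


def percent_correct(trials: Sequence[Trial]) -> float:
    """Percent of Cue-D trials answered at the correct spout (Cue-G excluded)."""
    cue_d = [t for t in trials if t.cue_kind == "Cue-D"]
    if not cue_d:
        raise ValueError("no Cue-D trials")
    return 100.0 * sum(t.correct for t in cue_d) / len(cue_d)


def percent_high_by_concentration(
    trials: Sequence[Trial],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw percent of High-port choices per concentration, with trial counts."""
    concs = sorted({t.concentration_wt_pct for t in trials})
    pct, n = [], []
    for c in concs:
        sub = [t for t in trials if np.isclose(t.concentration_wt_pct, c)]
        n.append(len(sub))
        pct.append(100.0 * sum(t.choice == t.high_port for t in sub) / len(sub))
    return np.asarray(concs), np.asarray(pct), np.asarray(n)


def _fit_logistic4(concs: np.ndarray, pct: np.ndarray,
                   p0=None) -> tuple[np.ndarray, bool]:
    if p0 is None:
        p0 = [max(pct.min(), 1.0), min(pct.max(), 99.0),
              float(np.median(concs)), 0.5]
    bounds = ([0.0, 0.0, concs.min() - 5.0, 1e-4],
              [100.0, 100.0, concs.max() + 5.0, _SLOPE_MAX])
    try:
        popt, _ = curve_fit(_logistic4, concs, pct, p0=p0, bounds=bounds,
                            maxfev=5000)
        return popt, True
    except RuntimeError:
        return np.asarray(p0), False


def fit_psychometric(
    trials: Sequence[Trial],
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> PsychometricFit:
    """Fit a sigmoid to percent-High choices; slope CI by trial bootstrap.

    The 95% slope confidence interval comes from a nonparametric bootstrap
    over trials (refit per resample); non-convergence is flagged, not silent.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    trials = list(trials)
    concs, pct, n = percent_high_by_concentration(trials)
    if concs.size < 2:
        raise ValueError("need at least two distinct concentrations")
    popt, ok = _fit_logistic4(concs, pct)

    # vectorized trial bootstrap: resample (concentration, choice) codes
    codes = np.argmin(np.abs(np.asarray([t.concentration_wt_pct for t in trials])[:, None]
                             - concs[None, :]), axis=1)
    high = np.asarray([t.choice == t.high_port for t in trials], dtype=float)
    slopes = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(trials), len(trials))
        cnt = np.bincount(codes[idx], minlength=concs.size)
        hits = np.bincount(codes[idx], weights=high[idx], minlength=concs.size)
        present = cnt > 0
        if present.sum() < 2:
            continue
        bp = 100.0 * hits[present] / cnt[present]
        bopt, bok = _fit_logistic4(concs[present], bp, p0=popt if ok else None)
        if bok:
            slopes.append(bopt[3])
    if slopes:
        lo, hi = np.percentile(slopes, [2.5, 97.5])
    else:
        lo = hi = float("nan")
    at_bound = popt[3] >= 0.98 * _SLOPE_MAX
    if at_bound:
        logger.info("psychometric slope at optimizer bound (step-like data)")
    return PsychometricFit(concs, pct, n, floor=float(popt[0]), ceiling=float(popt[1]),
                           midpoint=float(popt[2]), slope=float(popt[3]),
                           slope_ci=(float(lo), float(hi)), converged=ok,
                           at_bound=at_bound)


def lick_psth(
    lick_times: np.ndarray,
    events: Sequence[float],
    window: tuple[float, float],
    bin_size: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged lick rate (licks/s) on a regular grid around each event."""
    raster = align_spikes(np.asarray(lick_times, dtype=float), events, window,
                          alignment_event="lick_psth")
    counts, edges = bin_counts(raster, bin_size)
    rate = counts.mean(axis=0) / bin_size
    return rate, edges


def epoch_timing_summary(trials: Sequence[Trial],
                         licks: dict[str, np.ndarray]) -> BehaviorSummary:
    """Latency to stop licking, movement times per direction, outcome lick time.

    Trials with no central lick after the cue are excluded (counted in
    ``n_excluded``).  Outcome lick duration = last minus first lateral lick of
    the chosen spout within the Outcome epoch, split by reward delivery.
    """
    stop: dict[float, list] = {}
    move: dict[tuple, list] = {}
    out: dict[str, list] = {"rewarded": [], "omitted": []}
    central = np.asarray(licks.get("central", np.empty(0)))
    n_excluded = 0
    for t in trials:
        post = central[(central > t.t_cue) & (central <= t.epochs["Stimulus"][1] + 1e-9)]
        if post.size == 0:
            n_excluded += 1
            logger.debug("trial %d: no central lick after cue; excluded", t.trial_id)
            continue
        stop.setdefault(t.concentration_wt_pct, []).append(post[-1] - t.t_cue)
        move.setdefault(("Response", t.choice), []).append(
            t.epochs["Response"][1] - t.epochs["Response"][0])
        move.setdefault(("Return", t.return_side), []).append(
            t.epochs["Return"][1] - t.epochs["Return"][0])
        lat = np.asarray(licks.get(t.choice, np.empty(0)))
        a, b = t.epochs["Outcome"]
        lat = lat[(lat >= a) & (lat <= b)]
        if lat.size >= 2:
            out["rewarded" if t.rewarded else "omitted"].append(lat[-1] - lat[0])
    return BehaviorSummary(
        percent_correct=percent_correct(trials),
        stop_licking_latency={k: np.asarray(v) for k, v in stop.items()},
        movement_times={k: np.asarray(v) for k, v in move.items()},
        outcome_lick_duration={k: np.asarray(v) for k, v in out.items()},
        n_excluded=n_excluded,
    )
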