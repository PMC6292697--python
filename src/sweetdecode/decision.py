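"""Decision-variable coding: Choice neurons with neurometric-psychometric
comparison, Direction selectivity via the preference index, and reward
omission (Outcome) coding.

The preference index scales the auROC to a signed value,
P_index = 2 (auROC - 0.5) in [-1, 1]; 0 means the two firing-rate
distributions are indistinguishable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .behavior import PsychometricFit, _fit_logistic4
from .core import AlignedRaster, bin_counts, firing_rate
from .stats import auroc, auroc_bootstrap_ci, auroc_permutation_test

logger = logging.getLogger(__name__)

LOW_GROUP = (0.0, 3.0, 4.75)
HIGH_GROUP = (7.5, 11.75, 18.0)

CHOICE_INTERVAL_CUE = (0.0, 0.6)  # from cue delivery (Stimulus epoch)
CHOICE_INTERVAL_RESPONSE = (-0.4, 0.8)  # around Response onset
ROC_WINDOW = 0.2
ROC_STEP = 0.1


@dataclass
class PreferenceResult:
    auroc: float
    ci: tuple[float, float]
    p_index: float
    p_value: float
    epoch: str = ""

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass
class SlidingRoc:
    centers: np.ndarray
    auroc: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray

    @property
    def significant(self) -> np.ndarray:
        """Two-sided at the CI level: either bound clear of 0.5."""
        return (self.ci_lo > 0.5) | (self.ci_hi < 0.5)


@dataclass
class NeurometricResult:
    best_window: tuple[float, float]
    threshold: float
    preference: str  # "Low-preferred" | "High-preferred"
    low_hits: int
    high_hits: int
    n_trials: int
    percent_correct: float
    concentrations: np.ndarray
    percent_high_classified: np.ndarray
    slope: float = float("nan")
    slope_ci: tuple[float, float] = (float("nan"), float("nan"))
    is_choice_neuron: bool = False
    matches_behavior: bool | None = None
    degenerate: bool = False


@dataclass
class OutcomeCoding:
    auroc: float
    p_index: float
    sign_class: str  # "Active" (fires more on omission) | "Inactive"
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass
class DirectionResult:
    classification: str  # "Left-selective" | "Right-selective" | "none"
    response: PreferenceResult
    ret: PreferenceResult | None = None


def intensity_group(concentration: float) -> str:
    """Choice-analysis grouping: Low = {0, 3, 4.75}, High = {7.5, 11.75, 18} wt%."""
    return "High" if concentration >= 7.5 else "Low"


# -- sliding ROC ---------------------------------------------------------------


def sliding_roc(
    raster: AlignedRaster,
    interval: tuple[float, float],
    window: float = ROC_WINDOW,
    step: float = ROC_STEP,
    positive_label: str = "High",
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> SlidingRoc:
    """auROC (positive vs other label) with bootstrap CI at sliding centers.

    Centers step by 0.1 s so every 0.2 s window lies inside ``interval``.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    if raster.labels is None:
        raise ValueError("raster must carry group labels")
    labels = np.asarray(raster.labels)
    pos = labels == positive_label
    if not pos.any() or pos.all():
        raise ValueError("both label groups must be present")
    if min(pos.sum(), (~pos).sum()) < 5:
        raise ValueError("each group needs at least 5 trials")
    a, b = interval
    centers = np.round(np.arange(a + window / 2, b - window / 2 + 1e-9, step), 10)
    aur = np.empty(centers.size)
    lo = np.empty(centers.size)
    hi = np.empty(centers.size)
    for i, c in enumerate(centers):
        rates = firing_rate(raster, (c - window / 2, c + window / 2))
        aur[i] = auroc(rates[pos], rates[~pos])
        lo[i], hi[i] = auroc_bootstrap_ci(rates[pos], rates[~pos],
                                          n_boot=n_boot, rng=rng)
    return SlidingRoc(centers, aur, lo, hi)


def _has_consecutive(mask: np.ndarray, n: int) -> bool:
    run = 0
    for s in mask:
        run = run + 1 if s else 0
        if run >= n:
            return True
    return False


def detect_choice_neuron(
    cue_raster: AlignedRaster,
    response_raster: AlignedRaster,
    n_boot: int = 1000,
    min_consecutive: int = 5,
    rng: np.random.Generator | None = None,
) -> dict:
    """ROC stage of Choice-neuron detection over the two decision intervals.

    Requires at least ``min_consecutive`` consecutive significant ROC centers
    in either the cue interval (0-0.6 s) or the Response-onset interval
    (-0.4 to 0.8 s).  Rasters carry "Low"/"High" concentration-group labels
    from generalization-session trials.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    roc_cue = sliding_roc(cue_raster, CHOICE_INTERVAL_CUE, n_boot=n_boot, rng=rng)
    roc_resp = sliding_roc(response_raster, CHOICE_INTERVAL_RESPONSE,
                           n_boot=n_boot, rng=rng)
    in_cue = _has_consecutive(roc_cue.significant, min_consecutive)
    in_resp = _has_consecutive(roc_resp.significant, min_consecutive)
    return {
        "detected": in_cue or in_resp,
        "in_cue_interval": in_cue,
        "in_response_interval": in_resp,
        "roc_cue": roc_cue,
        "roc_response": roc_resp,
    }


# -- neurometric ---------------------------------------------------------------


def _threshold_grid(rates: np.ndarray) -> np.ndarray:
    u = np.unique(rates)
    if u.size == 1:
        return np.asarray([u[0] - 1.0])
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate([[u[0] - 1.0], mids])


def neurometric(
    raster: AlignedRaster,
    interval: tuple[float, float],
    concentrations: np.ndarray,
    psychometric: PsychometricFit | None = None,
    window: float = ROC_WINDOW,
    step: float = ROC_STEP,
    choice_criterion: float = 70.0,
    n_boot: int = 500,
    rng: np.random.Generator | None = None,
) -> NeurometricResult:
    """Best decision window and firing-rate threshold classifying Low vs High.

    For a High-preferred neuron, High Hits are High trials with rate above
    the threshold and Low Hits are Low trials below it (reversed for
    Low-preferred); percent correct = 100 (Low Hits + High Hits) / trials.
    The best (window, threshold) maximizes that percent; >= 70% qualifies as
    a Choice neuron.  The neurometric curve is the per-concentration percent
    of trials classified High, fitted with the same sigmoid as the behavior,
    and matches behavior when the slope CIs overlap.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    labels = np.asarray(raster.labels)
    concentrations = np.asarray(concentrations, dtype=float)
    is_high = labels == "High"
    n = labels.size
    a, b = interval
    centers = np.round(np.arange(a + window / 2, b - window / 2 + 1e-9, step), 10)

    best = None  # (percent, -center, -thr) maximized
    for c in centers:
        win = (c - window / 2, c + window / 2)
        rates = firing_rate(raster, win)
        high_pref = rates[is_high].mean() >= rates[~is_high].mean()
        for thr in _threshold_grid(rates):
            above = rates > thr
            if high_pref:
                hh = int(np.sum(above & is_high))
                lh = int(np.sum(~above & ~is_high))
            else:
                lh = int(np.sum(above & ~is_high))
                hh = int(np.sum(~above & is_high))
            pct = 100.0 * (lh + hh) / n
            key = (pct, -c, -thr)
            if best is None or key > best[0]:
                best = (key, win, float(thr), high_pref, lh, hh, rates)
    _, win, thr, high_pref, lh, hh, rates = best
    pct = 100.0 * (lh + hh) / n
    degenerate = np.unique(rates).size == 1

    def curve(rates_v, concs_v):
        classified_high = (rates_v > thr) if high_pref else (rates_v <= thr)
        cs = np.unique(concs_v)
        return cs, np.asarray([
            100.0 * classified_high[np.isclose(concs_v, c)].mean() for c in cs])

    cs, pct_high = curve(rates, concentrations)
    popt, _ = _fit_logistic4(cs, pct_high)
    slopes = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        bcs, bp = curve(rates[idx], concentrations[idx])
        if bcs.size < 2:
            continue
        bopt, ok = _fit_logistic4(bcs, bp)
        if ok:
            slopes.append(bopt[3])
    ci = tuple(np.percentile(slopes, [2.5, 97.5])) if slopes else (np.nan, np.nan)

    matches = None
    if psychometric is not None and np.isfinite(ci[0]):
        p_lo, p_hi = psychometric.slope_ci
        matches = bool(max(ci[0], p_lo) <= min(ci[1], p_hi))
    return NeurometricResult(
        best_window=win, threshold=thr,
        preference="High-preferred" if high_pref else "Low-preferred",
        low_hits=lh, high_hits=hh, n_trials=n, percent_correct=pct,
        concentrations=cs, percent_high_classified=pct_high,
        slope=float(popt[3]), slope_ci=(float(ci[0]), float(ci[1])),
        is_choice_neuron=pct >= choice_criterion,
        matches_behavior=matches, degenerate=degenerate,
    )


# -- preference index ----------------------------------------------------------


def preference_index(
    rates_a: np.ndarray,
    rates_b: np.ndarray,
    epoch: str = "",
    n_perm: int = 10_000,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> PreferenceResult:
    """P_index = 2 (auROC - 0.5) of condition A vs B, with permutation p.

    Positive values prefer condition A (e.g., rightward movement); the
    permutation shuffles condition labels without replacement 10,000 times,
    p = (k+1)/(n+1) on |auROC - 0.5|.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    rates_a = np.asarray(rates_a, dtype=float)
    rates_b = np.asarray(rates_b, dtype=float)
    if rates_a.size == 0 or rates_b.size == 0:
        raise ValueError("both conditions must be present")
    a, p = auroc_permutation_test(rates_a, rates_b, n_perm=n_perm, rng=rng)
    ci = auroc_bootstrap_ci(rates_a, rates_b, n_boot=n_boot, rng=rng)
    return PreferenceResult(a, ci, 2.0 * (a - 0.5), p, epoch)


def detect_direction_neuron(
    response_raster: AlignedRaster,
    return_raster: AlignedRaster,
    interval: tuple[float, float] = (0.0, 0.7),
    alpha: float = 0.05,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
) -> DirectionResult:
    """Sequential direction-selectivity test over Response then Return epochs.

    All trials (correct and error) enter; rasters carry "left"/"right"
    movement-direction labels per epoch.  Selective iff the Response-epoch
    permutation is significant and the Return epoch is significant with the
    same sign; the side follows the P_index sign (positive = Right).
    """
    rng = np.random.default_rng(0) if rng is None else rng

    def epoch_pref(raster: AlignedRaster, name: str) -> PreferenceResult:
        labels = np.asarray(raster.labels)
        rates = firing_rate(raster, interval)
        right, left = rates[labels == "right"], rates[labels == "left"]
        if right.size == 0 or left.size == 0:
            raise ValueError(f"{name}: both directions required")
        return preference_index(right, left, epoch=name, n_perm=n_perm, rng=rng)

    resp = epoch_pref(response_raster, "Response")
    if resp.p_value >= alpha or resp.p_index == 0:
        return DirectionResult("none", resp)
    ret = epoch_pref(return_raster, "Return")
    same_sign = np.sign(ret.p_index) == np.sign(resp.p_index)
    if ret.p_value < alpha and same_sign:
        side = "Right-selective" if resp.p_index > 0 else "Left-selective"
        return DirectionResult(side, resp, ret)
    return DirectionResult("none", resp, ret)


def detect_outcome_neuron(
    raster: AlignedRaster,
    interval: tuple[float, float] = (0.0, 0.6),
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
) -> OutcomeCoding:
    """Reward-omission coding in the Outcome epoch (second lateral lick + 0.6 s).

    Rasters carry "RW"/"RWO" labels; positive P_index (higher rate on
    omission) is the Active class, negative the Inactive class.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    labels = np.asarray(raster.labels)
    rates = firing_rate(raster, interval)
    rwo, rw = rates[labels == "RWO"], rates[labels == "RW"]
    if rwo.size == 0 or rw.size == 0:
        raise ValueError("both outcome classes required")
    pref = preference_index(rwo, rw, epoch="Outcome", n_perm=n_perm, rng=rng)
    sign_class = "Active" if pref.p_index > 0 else "Inactive"
    return OutcomeCoding(pref.auroc, pref.p_index, sign_class, pref.p_value)


# -- population traces ---------------------------------------------------------


def population_zscore(
    rasters: list[AlignedRaster],
    baseline: tuple[float, float],
    bin_size: float = 0.02,
) -> dict:
    """Group mean +/- SEM of per-neuron z-scored PSTHs.

    Each neuron's trial-averaged binned rate is z-scored against the mean and
    SD of its own per-trial baseline rates; zero-variance baselines exclude
    the neuron (logged).
    """
    traces = []
    excluded = 0
    edges = None
    for raster in rasters:
        base = firing_rate(raster, baseline)
        mu, sd = base.mean(), base.std(ddof=1)
        if sd == 0:
            excluded += 1
            logger.info("neuron %s excluded from z-score: zero baseline variance",
                        raster.neuron_id)
            continue
        counts, edges = bin_counts(raster, bin_size)
        rate = counts.mean(axis=0) / bin_size
        traces.append((rate - mu) / sd)
    if not traces:
        raise ValueError("no neurons with non-degenerate baseline")
    arr = np.vstack(traces)
    sem = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0]) if arr.shape[0] > 1 \
        else np.zeros(arr.shape[1])
    return {"mean": arr.mean(axis=0), "sem": sem, "edges": edges,
            "n_neurons": arr.shape[0], "n_excluded": excluded}
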