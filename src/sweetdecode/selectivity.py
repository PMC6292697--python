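"""Intensity selectivity, the lick-rate confound control, and concentration
tracking (Sensory) analysis on generalization trials."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AlignedRaster, align_spikes, firing_rate, NONZERO_CONCENTRATIONS
from .modulation import BestWindow, best_window_scan, grid_windows
from .stats import auroc, auroc_bootstrap_ci, pearson_r, permutation_pvalue


@dataclass
class IntensitySelectivity:
    is_selective: bool
    preferred: str | None = None  # "Low" | "High"
    best_window: BestWindow | None = None
    p_value: float = float("nan")
    lick_confound_overlap: float = float("nan")  # fraction of best window


@dataclass
class SensoryTuning:
    """Concentration tracking in the best window of a selective neuron."""

    best_window: tuple[float, float]
    r: float
    sign: str  # "positive" | "negative"
    p_uncorrected: float
    p_corrected: float
    mean_rates: dict  # concentration -> mean rate in window
    normalized_profile: np.ndarray  # z-scored rates anchored at 3 wt%


def intensity_selective(raster: AlignedRaster, alpha: float = 0.05) -> IntensitySelectivity:
    """Low-vs-High contrast over the best-window grid on correct Cue-D trials.

    ``raster.labels`` must hold "Low"/"High" per trial; the preferred label is
    the one with the higher rate in the best window.
    """
    if raster.labels is None:
        raise ValueError("raster must carry Low/High labels")
    labels = np.asarray(raster.labels)
    for lab in ("Low", "High"):
        if np.sum(labels == lab) < 5:
            raise ValueError(f"need at least 5 trials of label {lab}")
    bw = best_window_scan(raster, alpha=alpha, contrast="two_group",
                          group_mask=(labels == "High"))
    if bw is None:
        return IntensitySelectivity(False)
    preferred = "High" if bw.delta > 0 else "Low"  # delta = mean(High) - mean(Low)
    return IntensitySelectivity(True, preferred, bw, bw.p_value)


def lick_confound_roc(
    lick_raster_low: AlignedRaster,
    lick_raster_high: AlignedRaster,
    best_window: tuple[float, float] | None = None,
    bin_size: float = 0.1,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-bin auROC of Low-vs-High lick rates over 0-0.6 s post cue.

    A bin counts as significant when the lower bootstrap CI of its auROC is
    above 0.5.  Returns (bin_starts, significant_mask, overlap), where overlap
    is the fraction of ``best_window`` covered by significant bins.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    starts = np.round(np.arange(0.0, 0.6 - bin_size / 2, bin_size), 10)
    sig = np.zeros(starts.size, dtype=bool)
    for i, a in enumerate(starts):
        b = a + bin_size
        lo_rates = firing_rate(lick_raster_low, (a, b))
        hi_rates = firing_rate(lick_raster_high, (a, b))
        if np.ptp(np.concatenate([lo_rates, hi_rates])) == 0:
            continue
        # orient toward the larger group so the test is two-sided in effect
        x, y = (hi_rates, lo_rates) if hi_rates.mean() >= lo_rates.mean() else (lo_rates, hi_rates)
        ci_lo, _ = auroc_bootstrap_ci(x, y, n_boot=n_boot, rng=rng)
        sig[i] = ci_lo > 0.5
    overlap = float("nan")
    if best_window is not None:
        a, b = best_window
        covered = 0.0
        for i, s in enumerate(starts):
            if sig[i]:
                covered += max(0.0, min(s + bin_size, b) - max(s, a))
        overlap = covered / (b - a) if b > a else float("nan")
    return starts, sig, overlap


def sensory_tuning(
    raster: AlignedRaster,
    alpha: float = 0.05,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
) -> SensoryTuning | None:
    """Best-window Pearson correlation of Cue-G rates with concentration.

    ``raster`` must be aligned to Cue-G delivery with per-trial concentration
    labels restricted to the five non-zero concentrations.  The scan keeps the
    significant window with the highest |r|; a 10,000-shuffle permutation of
    the concentration labels corrects for the scan (p = (k+1)/(n+1)).
    Returns None when nothing survives.
    """
    from scipy.stats import pearsonr

    rng = np.random.default_rng(0) if rng is None else rng
    if raster.labels is None:
        raise ValueError("raster must carry concentration labels")
    concs = np.asarray(raster.labels, dtype=float)
    if np.unique(concs).size < 2:
        raise ValueError("need at least two distinct concentrations")

    best = None  # (|r|, -size, -center, r, interval, p)
    for center, size, (a, b) in grid_windows():
        rates = firing_rate(raster, (a, b))
        if rates.std() == 0:
            continue
        r, p = pearsonr(rates, concs)
        if p >= alpha:
            continue
        key = (abs(r), -size, -center)
        if best is None or key > best[0]:
            best = (key, float(r), (a, b), float(p))
    if best is None:
        return None
    _, r_obs, interval, p_unc = best
    rates = firing_rate(raster, interval)

    k = 0
    thr = abs(r_obs) - 1e-12
    for _ in range(n_perm):
        r_perm = pearson_r(rates, rng.permutation(concs))
        if not np.isnan(r_perm) and abs(r_perm) >= thr:
            k += 1
    p_corr = permutation_pvalue(k, n_perm)
    if p_corr >= alpha:
        return None

    mean_rates = {c: float(rates[np.isclose(concs, c)].mean())
                  for c in sorted(np.unique(concs))}
    profile = _normalized_profile(mean_rates)
    return SensoryTuning(interval, r_obs, "positive" if r_obs > 0 else "negative",
                         p_unc, p_corr, mean_rates, profile)


def _normalized_profile(mean_rates: dict) -> np.ndarray:
    """Z-score the per-concentration rates, then anchor the curve at 3 wt%."""
    concs = sorted(mean_rates)
    vals = np.asarray([mean_rates[c] for c in concs])
    sd = vals.std(ddof=1)
    z = (vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals)
    anchor_idx = int(np.argmin(np.abs(np.asarray(concs) - 3.0)))
    return z - z[anchor_idx]


def sensory_population_profile(
    tunings: list[SensoryTuning],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-sign mean +/- SEM of the normalized concentration profiles."""
    out = {}
    for sign in ("positive", "negative"):
        group = [t.normalized_profile for t in tunings if t.sign == sign]
        if not group:
            continue
        arr = np.vstack(group)
        sem = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0]) if arr.shape[0] > 1 \
            else np.zeros(arr.shape[1])
        out[sign] = (arr.mean(axis=0), sem)
    return out


def cue_g_raster(session, train, window=(-0.3, 0.6)) -> AlignedRaster:
    """Raster of Cue-G trials at non-zero concentrations, labeled by wt%."""
    trials = [t for t in session.cue_g_trials()
              if any(np.isclose(t.concentration_wt_pct, c) for c in NONZERO_CONCENTRATIONS)]
    return align_spikes(train, [t.t_cue for t in trials], window,
                        labels=[t.concentration_wt_pct for t in trials],
                        alignment_event="cue_g")
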