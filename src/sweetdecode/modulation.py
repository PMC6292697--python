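"""Cue-evoked modulation-profile classification.

Each neuron's response in the Stimulus epoch (0-0.6 s after cue delivery,
baseline -0.3-0 s of dry licking) is assigned exactly one of seven labels:
Phasic, Tonic-Active, Tonic-Inactive, Coh-Active, Coh-Inactive,
Coherent-Non-evoked, or Non-modulated.  Lick-coherent labels take precedence,
then the phasic criterion, then the tonic best-window criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coherence import CoherenceResult, bout_segments, lick_spike_coherence
from .core import AlignedRaster, Session, align_spikes, firing_rate
from .stats import ranksum_pvalue

BASELINE = (-0.3, 0.0)
STIMULUS_SPAN = (0.0, 0.6)
#: best-window grid: sizes 0.05..0.6 and centers 0.05..0.5, in 0.05 s steps
GRID_STEP = 0.05
WINDOW_SIZES = tuple(np.round(np.arange(1, 13) * GRID_STEP, 10))
WINDOW_CENTERS = tuple(np.round(np.arange(1, 11) * GRID_STEP, 10))

LABELS = ("Phasic", "Tonic-Active", "Tonic-Inactive", "Coh-Active",
          "Coh-Inactive", "Coherent-Non-evoked", "Non-modulated")
NON_EVOKED = ("Non-modulated", "Coherent-Non-evoked")


@dataclass
class BestWindow:
    """Window on the scan grid maximizing |delta| among significant windows."""

    center: float
    size: float
    interval: tuple[float, float]
    window_rate: float
    baseline_rate_mean: float
    delta: float
    p_value: float


@dataclass
class PhasicResult:
    is_phasic: bool
    p_value: float
    onset: float | None = None
    offset: float | None = None
    insufficient_data: bool = False


@dataclass
class ModulationLabel:
    neuron_id: str
    label: str
    best_window: BestWindow | None = None
    phasic: PhasicResult | None = None
    coherence: CoherenceResult | None = None

    @property
    def is_non_evoked(self) -> bool:
        return self.label in NON_EVOKED


def grid_windows() -> list[tuple[float, float, tuple[float, float]]]:
    """All (center, size, interval) with center +/- size/2 inside [0, 0.6]."""
    out = []
    for size in WINDOW_SIZES:
        for center in WINDOW_CENTERS:
            a = round(center - size / 2.0, 10)
            b = round(center + size / 2.0, 10)
            if a >= -1e-9 and b <= STIMULUS_SPAN[1] + 1e-9:
                out.append((center, size, (max(a, 0.0), min(b, STIMULUS_SPAN[1]))))
    return out


def baseline_rate(raster: AlignedRaster) -> np.ndarray:
    """Per-trial firing rate in the pre-cue dry-licking baseline (-0.3 to 0 s)."""
    if raster.window[0] > BASELINE[0] + 1e-9:
        raise ValueError("raster window must include the -0.3 s baseline")
    return firing_rate(raster, BASELINE)


def _runs(mask: np.ndarray, merge_gap: int = 1) -> list[tuple[int, int]]:
    """Maximal runs of True, merging runs separated by <= merge_gap bins."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    runs = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev <= merge_gap + 1:
            prev = i
        else:
            runs.append((start, prev + 1))
            start = prev = i
    runs.append((start, prev + 1))
    return runs


def phasic_detect(raster: AlignedRaster, alpha: float = 0.05,
                  bin_size: float = 0.005) -> PhasicResult:
    """Detect a brief excitatory cue-locked bout.

    A Wilcoxon rank-sum first compares per-trial rates in 0-0.2 s against the
    baseline.  If significant, the trial-averaged PSTH (5 ms bins, lightly
    smoothed) is thresholded at baseline mean + 2 SD of the baseline bins;
    the dominant suprathreshold run must start within 0.1 s of the cue and
    last 0.04-0.2 s to qualify as Phasic.
    """
    if raster.n_trials < 5:
        return PhasicResult(False, float("nan"), insufficient_data=True)
    base = firing_rate(raster, (-0.2, 0.0))  # duration-matched to the 0.2 s test window
    early = firing_rate(raster, (0.0, 0.2))
    p = ranksum_pvalue(early, base)
    if p >= alpha:
        return PhasicResult(False, p)

    rel = np.concatenate(raster.trials) if raster.trials else np.empty(0)
    n_trials = raster.n_trials

    def psth(a: float, b: float) -> np.ndarray:
        edges = np.arange(a, b + bin_size / 2, bin_size)
        counts, _ = np.histogram(rel, bins=edges)
        return counts / (n_trials * bin_size)

    kernel = np.ones(5) / 5.0  # 25 ms boxcar; tames single-bin Poisson noise
    base_smooth = np.convolve(psth(*BASELINE), kernel, mode="same")
    stim_smooth = np.convolve(psth(*STIMULUS_SPAN), kernel, mode="same")
    thr = base_smooth.mean() + 2.0 * base_smooth.std(ddof=1)
    runs = [(i0, i1) for i0, i1 in _runs(stim_smooth > thr, merge_gap=3)
            if i1 - i0 >= 2]
    if not runs:
        return PhasicResult(False, p)
    # dominant bout: largest integrated excess above threshold
    excess = [float(np.sum(stim_smooth[i0:i1] - thr)) for i0, i1 in runs]
    i0, i1 = runs[int(np.argmax(excess))]
    onset, offset = i0 * bin_size, i1 * bin_size
    duration = offset - onset
    ok = (onset <= 0.1 + 1e-9) and (0.04 - 1e-9 <= duration <= 0.2 + 1e-9)
    return PhasicResult(ok, p, onset=onset, offset=offset)


_HALF_STEP = GRID_STEP / 2  # window edges (center +/- size/2) lie on this grid


def _cell_counts(raster: AlignedRaster) -> np.ndarray:
    """Per-trial spike counts in the 36 grid cells of 0.025 s tiling [-0.3, 0.6]."""
    edges = np.round(-0.3 + _HALF_STEP * np.arange(37), 10)
    out = np.empty((raster.n_trials, 36), dtype=np.int64)
    for i, rel in enumerate(raster.trials):
        out[i], _ = np.histogram(rel, bins=edges)
    return out


def _window_rates(cells: np.ndarray, a: float, b: float) -> np.ndarray:
    i0 = int(round((a + 0.3) / _HALF_STEP))
    i1 = int(round((b + 0.3) / _HALF_STEP))
    # round the exposure so equal-duration intervals divide by the identical
    # float, preserving cross-sample rate ties for the rank-sum test
    return cells[:, i0:i1].sum(axis=1) / np.round(b - a, 10)


def best_window_scan(
    raster: AlignedRaster,
    alpha: float = 0.05,
    contrast: str = "vs_baseline",
    group_mask: np.ndarray | None = None,
) -> BestWindow | None:
    """Scan the (center, size) grid over 0-0.6 s for the largest significant delta.

    ``vs_baseline`` compares each window's per-trial rates against baseline
    rates measured over a duration-matched pre-cue interval (capped at the
    0.3 s of available baseline), which keeps the rank-sum test calibrated
    despite the discreteness of short-window counts; the reported delta is
    relative to the full-baseline mean.  ``two_group`` compares the two trial
    groups given by ``group_mask`` (True = group A) within each window, with
    delta = mean(A) - mean(B).  Ties in |delta| break toward the smaller
    window, then the earlier center.
    """
    cells = _cell_counts(raster)
    if contrast == "vs_baseline":
        ref_full_mean = float(_window_rates(cells, *BASELINE).mean())
    elif contrast == "two_group":
        if group_mask is None:
            raise ValueError("two_group contrast requires group_mask")
        group_mask = np.asarray(group_mask, dtype=bool)
        if group_mask.all() or not group_mask.any():
            raise ValueError("two_group contrast requires both groups present")
    else:
        raise ValueError(f"unknown contrast {contrast!r}")

    best: BestWindow | None = None
    for center, size, (a, b) in grid_windows():
        rates = _window_rates(cells, a, b)
        if contrast == "vs_baseline":
            x = rates
            y = _window_rates(cells, -min(size, 0.3), 0.0)
            base_mean = ref_full_mean
        else:
            x, y = rates[group_mask], rates[~group_mask]
            base_mean = float(y.mean())
        if np.ptp(np.concatenate([x, y])) == 0:
            continue  # flat data carries no evidence either way
        p = ranksum_pvalue(x, y)
        if p >= alpha:
            continue
        delta = float(x.mean() - base_mean)
        cand = BestWindow(center, size, (a, b), float(x.mean()), base_mean,
                          delta, p)
        if best is None or (abs(delta), -size, -center) > (abs(best.delta), -best.size, -best.center):
            best = cand
    return best


def _max_significant_size(raster: AlignedRaster, alpha: float,
                          best: BestWindow) -> float:
    """Modulation duration: longest significant window of the same response.

    Considers only windows that overlap the best window and whose delta has
    the same sign, so the duration describes the detected modulation rather
    than an unrelated fluctuation elsewhere in the scan span.
    """
    cells = _cell_counts(raster)
    ref_full_mean = float(_window_rates(cells, *BASELINE).mean())
    sign = np.sign(best.delta)
    longest = best.size
    for _center, size, (a, b) in grid_windows():
        if size <= longest:
            continue
        if b <= best.interval[0] + 1e-9 or a >= best.interval[1] - 1e-9:
            continue
        rates = _window_rates(cells, a, b)
        ref = _window_rates(cells, -min(size, 0.3), 0.0)
        if np.ptp(np.concatenate([rates, ref])) == 0:
            continue
        if (rates.mean() - ref_full_mean) * sign <= 0:
            continue
        if ranksum_pvalue(rates, ref) < alpha:
            longest = size
    return longest


def classify_modulation(
    raster: AlignedRaster,
    coherence: CoherenceResult,
    alpha: float = 0.05,
) -> ModulationLabel:
    """Assign one of the seven modulation-profile labels to a neuron.

    Decision tree: lick-coherent neurons become Coh-Active/Coh-Inactive by the
    sign of their best-window delta (Coherent-Non-evoked if no significant
    window); otherwise the phasic criterion applies; otherwise a significant
    modulation lasting >= 0.2 s is Tonic (Active/Inactive by sign); anything
    left is Non-modulated.
    """
    bw = best_window_scan(raster, alpha=alpha)
    if coherence.is_coherent:
        if bw is None:
            label = "Coherent-Non-evoked"
        else:
            label = "Coh-Active" if bw.delta > 0 else "Coh-Inactive"
        return ModulationLabel(raster.neuron_id, label, bw, None, coherence)
    ph = phasic_detect(raster, alpha=alpha)
    if ph.is_phasic:
        return ModulationLabel(raster.neuron_id, "Phasic", bw, ph, coherence)
    if bw is not None:
        duration = _max_significant_size(raster, alpha, bw)
        if duration >= 0.2 - 1e-9:
            label = "Tonic-Active" if bw.delta > 0 else "Tonic-Inactive"
            return ModulationLabel(raster.neuron_id, label, bw, ph, coherence)
    return ModulationLabel(raster.neuron_id, "Non-modulated", bw, ph, coherence)


def coherence_by_epoch(
    spike_times: np.ndarray,
    session: Session,
    epochs: tuple = ("pre-Stimulus", "Stimulus", "Outcome"),
    seg_len: float = 0.512,
    **kwargs,
) -> dict[str, CoherenceResult]:
    """Lick-spike coherence restricted to each task epoch's licks.

    pre-Stimulus uses central licks before cue delivery, Stimulus the central
    licks after it, and Outcome the lateral (reinforced) licks; epochs without
    enough licking segments come back flagged insufficient.
    """
    central = session.lick_times("central")
    lateral = session.lateral_lick_times()
    out = {}
    for epoch in epochs:
        keep = np.zeros(central.size, dtype=bool)
        if epoch == "pre-Stimulus":
            src = central
            for t in session.trials:
                keep |= (src >= t.epochs["Return"][1]) & (src <= t.t_cue)
        elif epoch == "Stimulus":
            src = central
            for t in session.trials:
                keep |= (src > t.t_cue) & (src <= t.epochs["Stimulus"][1])
        elif epoch == "Outcome":
            src = lateral
            keep = np.zeros(src.size, dtype=bool)
            for t in session.trials:
                a, b = t.epochs["Outcome"]
                keep |= (src >= a) & (src <= b)
        else:
            raise ValueError(f"unknown epoch {epoch!r}")
        out[epoch] = lick_spike_coherence(spike_times, src[keep],
                                          seg_len=seg_len, **kwargs)
    return out


def dry_lick_segments(session: Session, seg_len: float = 0.512,
                      correct_only: bool = True) -> np.ndarray:
    """Coherence segments from the pre-cue dry-licking bout, ending at the cue.

    Anchoring segments before cue delivery keeps cue-evoked transients (which
    are themselves lick-triggered) from masquerading as lick coherence.
    """
    central = session.lick_times("central")
    starts = []
    for t in session.cue_d_trials(correct_only=correct_only):
        start = t.t_cue - seg_len
        bout = central[(central >= t.epochs["Return"][1]) & (central <= t.t_cue)]
        if bout.size and bout[0] <= start + 1e-9:
            starts.append(start)
    return np.asarray(starts)


def classify_session(
    session: Session,
    alpha: float = 0.05,
    coherence_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Classify every neuron in a session; one row per neuron.

    Uses correct Cue-D trials only (error trials are reserved for the
    direction analysis); coherence is estimated on pre-cue dry-licking
    segments of the central-lick bout.
    """
    trials = session.cue_d_trials(correct_only=True)
    cues = [t.t_cue for t in trials]
    central = session.lick_times("central")
    ckw = dict(coherence_kwargs or {})
    seg_len = ckw.pop("seg_len", 0.512)
    segs = dry_lick_segments(session, seg_len=seg_len)
    rows = []
    labels = {}
    for train in session.spikes:
        raster = align_spikes(train, cues, (-0.3, 0.6), alignment_event="cue")
        coh = lick_spike_coherence(train.timestamps, central,
                                   seg_len=seg_len, seg_starts=segs, **ckw)
        ml = classify_modulation(raster, coh, alpha=alpha)
        labels[train.neuron_id] = ml
        bw = ml.best_window
        rows.append({
            "neuron_id": train.neuron_id,
            "label": ml.label,
            "window_a": bw.interval[0] if bw else np.nan,
            "window_b": bw.interval[1] if bw else np.nan,
            "delta": bw.delta if bw else np.nan,
            "p": bw.p_value if bw else np.nan,
            "coherence": coh.coherence,
            "is_coherent": coh.is_coherent,
        })
    df = pd.DataFrame(rows)
    df.attrs["labels"] = labels
    return df
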