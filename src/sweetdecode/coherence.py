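"""Multitaper spike-lick coherence with jackknife confidence intervals.

Spike and lick trains are binned within fixed-length segments taken from
licking bouts, tapered with DPSS (Slepian) windows, and the magnitude
coherence |S_xy| / sqrt(S_xx S_yy) is averaged over tapers and segments.
The band summary (default 4-12 Hz, spanning the ~6.5 Hz lick rhythm and its
first harmonic region) gets a leave-one-segment-out jackknife CI on the
atanh scale; a neuron counts as lick-coherent only when the lower CI
exceeds the analytic significance threshold for the available degrees of
freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import dpss

__all__ = ["CoherenceResult", "bout_segments", "multitaper_coherence",
           "lick_spike_coherence", "coherence_threshold"]

MIN_SEGMENTS = 20


@dataclass
class CoherenceResult:
    """Band-averaged lick-spike coherence and its significance call."""

    band: tuple[float, float]
    coherence: float  # band-average |coherency|
    ci: tuple[float, float]  # jackknife CI on the band average
    threshold: float  # alpha-level significance threshold for |coherency|
    is_coherent: bool
    n_segments: int = 0
    insufficient_data: bool = False
    freqs: np.ndarray | None = field(default=None, repr=False)
    spectrum: np.ndarray | None = field(default=None, repr=False)  # |C(f)|


def coherence_threshold(n_estimates: int, alpha: float = 0.05) -> float:
    """Significance level for |coherency| averaged over ``n_estimates`` spectra.

    Under independence the null distribution of coherence-squared from m
    averaged estimates gives P(|C| > c) = (1 - c^2)^(m-1), hence the
    threshold c = sqrt(1 - alpha^(1/(m-1))).
    """
    if n_estimates < 2:
        return 1.0
    return float(np.sqrt(1.0 - alpha ** (1.0 / (n_estimates - 1))))


def bout_segments(lick_times: np.ndarray, seg_len: float,
                  max_gap: float = 0.4) -> np.ndarray:
    """Segment start times tiling continuous licking bouts.

    A bout is a maximal run of licks with inter-lick gaps below ``max_gap``;
    each bout contributes consecutive non-overlapping segments of length
    ``seg_len`` as long as they fit inside the bout span.
    """
    lick_times = np.sort(np.asarray(lick_times, dtype=float))
    if lick_times.size < 2:
        return np.empty(0)
    gaps = np.diff(lick_times)
    breaks = np.flatnonzero(gaps > max_gap)
    bout_bounds = zip(np.concatenate([[0], breaks + 1]),
                      np.concatenate([breaks, [lick_times.size - 1]]))
    starts = []
    for i0, i1 in bout_bounds:
        a, b = lick_times[i0], lick_times[i1]
        n = int(np.floor((b - a) / seg_len))
        starts.extend(a + k * seg_len for k in range(n))
    return np.asarray(starts)


def _binned(times: np.ndarray, start: float, n: int, dt: float) -> np.ndarray:
    idx = np.floor((times - start) / dt).astype(int)
    idx = idx[(idx >= 0) & (idx < n)]
    out = np.zeros(n)
    np.add.at(out, idx, 1.0)
    return out


def multitaper_coherence(
    x_times: np.ndarray,
    y_times: np.ndarray,
    seg_starts: np.ndarray,
    seg_len: float = 1.024,
    fs: float = 250.0,
    nw: float = 3.0,
    n_tapers: int = 5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Magnitude coherence between two point processes over tapered segments.

    Returns (freqs, |C(f)|, per-segment complex cross/auto triplets) where the
    last element is an (n_seg, 3, n_freq) array of (Sxy, Sxx, Syy) per segment
    for jackknifing.
    """
    n = int(round(seg_len * fs))
    dt = 1.0 / fs
    tapers = dpss(n, nw, n_tapers)
    freqs = np.fft.rfftfreq(n, dt)
    per_seg = np.zeros((len(seg_starts), 3, freqs.size), dtype=complex)
    for s, start in enumerate(np.asarray(seg_starts, dtype=float)):
        x = _binned(np.asarray(x_times, dtype=float), start, n, dt)
        y = _binned(np.asarray(y_times, dtype=float), start, n, dt)
        x = x - x.mean()
        y = y - y.mean()
        X = np.fft.rfft(tapers * x, axis=1)
        Y = np.fft.rfft(tapers * y, axis=1)
        per_seg[s, 0] = (X * np.conj(Y)).mean(axis=0)
        per_seg[s, 1] = (np.abs(X) ** 2).mean(axis=0)
        per_seg[s, 2] = (np.abs(Y) ** 2).mean(axis=0)
    sxy, sxx, syy = per_seg.mean(axis=0)
    denom = np.sqrt(np.abs(sxx) * np.abs(syy))
    coh = np.divide(np.abs(sxy), denom, out=np.zeros_like(denom, dtype=float),
                    where=denom > 0)
    return freqs, coh, per_seg


def _band_mean(per_seg_sum: np.ndarray, band_mask: np.ndarray) -> float:
    sxy, sxx, syy = per_seg_sum
    denom = np.sqrt(np.abs(sxx[band_mask]) * np.abs(syy[band_mask]))
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.abs(sxy[band_mask]) / denom
    return float(np.nanmean(np.where(denom > 0, c, np.nan)))


def lick_spike_coherence(
    spike_times: np.ndarray,
    lick_times: np.ndarray,
    band: tuple[float, float] = (4.0, 12.0),
    seg_len: float = 1.024,
    fs: float = 250.0,
    nw: float = 3.0,
    n_tapers: int = 5,
    alpha: float = 0.05,
    seg_starts: np.ndarray | None = None,
    min_segments: int = MIN_SEGMENTS,
) -> CoherenceResult:
    """Band-average spike-lick coherence with jackknife CI and significance.

    Segments default to tilings of licking bouts; fewer than ``min_segments``
    of them yields an insufficient-data flag rather than a classification.
    """
    if seg_starts is None:
        seg_starts = bout_segments(np.asarray(lick_times, dtype=float), seg_len)
    seg_starts = np.asarray(seg_starts, dtype=float)
    if seg_starts.size < min_segments:
        return CoherenceResult(band, float("nan"), (float("nan"), float("nan")),
                               1.0, False, n_segments=int(seg_starts.size),
                               insufficient_data=True)
    freqs, coh, per_seg = multitaper_coherence(
        spike_times, lick_times, seg_starts, seg_len, fs, nw, n_tapers)
    band_mask = (freqs >= band[0]) & (freqs <= band[1])
    total = per_seg.sum(axis=0)
    c_hat = _band_mean(total, band_mask)

    n_seg = per_seg.shape[0]
    loo = np.array([_band_mean(total - per_seg[s], band_mask) for s in range(n_seg)])
    z = np.arctanh(np.clip(loo, 0.0, 1.0 - 1e-12))
    z_hat = np.arctanh(min(max(c_hat, 0.0), 1.0 - 1e-12))
    se = np.sqrt((n_seg - 1) / n_seg * np.sum((z - z.mean()) ** 2))
    lo, hi = np.tanh(z_hat - 1.96 * se), np.tanh(z_hat + 1.96 * se)

    thr = coherence_threshold(n_seg * n_tapers, alpha)
    return CoherenceResult(band, c_hat, (float(lo), float(hi)), thr,
                           is_coherent=bool(lo > thr), n_segments=n_seg,
                           freqs=freqs, spectrum=coh)
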