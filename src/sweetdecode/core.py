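"""Domain types for recorded sessions and peri-event spike alignment.

A :class:`Session` bundles trial metadata, per-neuron spike trains and
per-spout lick trains for one behavioral recording of the sucrose intensity
discrimination task.  Times are double-precision seconds from session start;
event-relative times are computed on demand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

CONCENTRATIONS = (0.0, 3.0, 4.75, 7.5, 11.75, 18.0)
#: Cue-G concentrations used for concentration-tracking (Sensory) analysis.
NONZERO_CONCENTRATIONS = (3.0, 4.75, 7.5, 11.75, 18.0)

EPOCHS = ("Return", "Stimulus", "Response", "Outcome")

_MIN_SPIKE_SEPARATION = 1e-6


class ValidationError(ValueError):
    """A domain-type invariant was violated."""


class FormatError(ValueError):
    """A session file did not match the expected format."""


@dataclass
class SpikeTrain:
    """Timestamps of one sorted unit, in seconds from session start."""

    neuron_id: str
    timestamps: np.ndarray
    channel: int = 0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        t = self.timestamps
        if t.size and (not np.all(np.isfinite(t)) or t[0] < 0):
            raise ValidationError(f"neuron {self.neuron_id}: non-finite or negative timestamps")
        if t.size > 1:
            dt = np.diff(t)
            # tolerance: times serialized on the 1 us grid give diffs like 9.9999e-7
            if np.any(dt < _MIN_SPIKE_SEPARATION * (1 - 1e-6)):
                raise ValidationError(
                    f"neuron {self.neuron_id}: timestamps must be strictly increasing "
                    f"(min separation {_MIN_SPIKE_SEPARATION} s)"
                )


@dataclass
class LickTrain:
    """Lick-onset timestamps registered at one spout."""

    spout: str  # central | left | right
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        if self.spout not in ("central", "left", "right"):
            raise ValidationError(f"unknown spout {self.spout!r}")
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        t = self.timestamps
        if t.size and not np.all(np.isfinite(t)):
            raise ValidationError(f"{self.spout} licks: non-finite timestamps")
        if t.size > 1 and np.any(np.diff(t) < 0):
            raise ValidationError(f"{self.spout} licks: timestamps must be sorted")


@dataclass
class Trial:
    """One trial of the two-alternative sucrose intensity task.

    Cue-D trials deliver 3 (Low) or 18 wt% (High) sucrose and are rewarded on
    correct choices; Cue-G (generalization) trials sample the full
    concentration set and are never rewarded.
    """

    trial_id: int
    cue_kind: str  # "Cue-D" | "Cue-G"
    concentration_wt_pct: float
    intensity_label: str  # "Low" | "High"
    choice: str  # "left" | "right"
    correct: bool
    rewarded: bool
    t_cue: float
    t_response_onset: float  # last central lick
    t_second_lateral_lick: float
    t_return_onset: float
    epochs: dict = field(default_factory=dict)  # name -> (t0, t1)
    return_side: str = "left"  # direction of the Return movement this trial
    high_port: str = "right"  # lateral port associated with High

    def __post_init__(self) -> None:
        if self.cue_kind not in ("Cue-D", "Cue-G"):
            raise ValidationError(f"trial {self.trial_id}: bad cue_kind {self.cue_kind!r}")
        if not any(np.isclose(self.concentration_wt_pct, c) for c in CONCENTRATIONS):
            raise ValidationError(
                f"trial {self.trial_id}: concentration {self.concentration_wt_pct} not in task set"
            )
        if self.cue_kind == "Cue-G" and self.rewarded:
            raise ValidationError(f"trial {self.trial_id}: Cue-G trials are unrewarded")
        if self.cue_kind == "Cue-D" and self.rewarded != self.correct:
            raise ValidationError(f"trial {self.trial_id}: Cue-D reward must equal correctness")
        bounds = [self.epochs[name] for name in EPOCHS if name in self.epochs]
        for (a0, a1) in bounds:
            if a1 <= a0:
                raise ValidationError(f"trial {self.trial_id}: empty epoch interval")
        for (_a0, a1), (b0, _b1) in zip(bounds[:-1], bounds[1:]):
            if b0 < a1 - 1e-9:
                raise ValidationError(f"trial {self.trial_id}: overlapping epochs")


@dataclass
class Session:
    """Container for one recording: trials, spike trains and lick trains."""

    session_id: str
    trials: list[Trial]
    spikes: list[SpikeTrain]
    licks: list[LickTrain]
    region_label: str = "synthetic"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.spikes:
            raise ValidationError(f"session {self.session_id}: at least one neuron required")
        if self.region_label not in ("pIC", "aIC", "OFC", "synthetic"):
            raise ValidationError(f"unknown region {self.region_label!r}")

    # -- convenience accessors -------------------------------------------------

    def neuron(self, neuron_id: str) -> SpikeTrain:
        for s in self.spikes:
            if s.neuron_id == neuron_id:
                return s
        raise KeyError(neuron_id)

    def lick_times(self, spout: str) -> np.ndarray:
        for l in self.licks:
            if l.spout == spout:
                return l.timestamps
        return np.empty(0)

    def lateral_lick_times(self) -> np.ndarray:
        return np.sort(np.concatenate([self.lick_times("left"), self.lick_times("right")]))

    def cue_d_trials(self, correct_only: bool = False) -> list[Trial]:
        out = [t for t in self.trials if t.cue_kind == "Cue-D"]
        if correct_only:
            out = [t for t in out if t.correct]
        return out

    def cue_g_trials(self) -> list[Trial]:
        return [t for t in self.trials if t.cue_kind == "Cue-G"]


@dataclass
class AlignedRaster:
    """Per-trial spike times relative to an alignment event."""

    neuron_id: str
    alignment_event: str
    window: tuple[float, float]
    trials: list[np.ndarray]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        t0, t1 = self.window
        for rel in self.trials:
            if rel.size and (rel.min() < t0 - 1e-9 or rel.max() > t1 + 1e-9):
                raise ValidationError("relative spike time outside raster window")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(self.trials):
                raise ValidationError("label count must equal trial count")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def subset(self, mask: np.ndarray) -> "AlignedRaster":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return AlignedRaster(
            self.neuron_id,
            self.alignment_event,
            self.window,
            [self.trials[i] for i in idx],
            None if self.labels is None else self.labels[idx],
        )


# -- alignment / binning -------------------------------------------------------


def align_spikes(
    spikes: SpikeTrain | np.ndarray,
    events: Sequence[float],
    window: tuple[float, float],
    labels: Sequence | None = None,
    alignment_event: str = "event",
) -> AlignedRaster:
    """Extract event-relative spike times for each event.

    Trial *i* contains exactly the spikes with ``t0 <= s - event_i <= t1``.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window t0 must precede t1")
    events = np.asarray(events, dtype=float)
    if events.size == 0:
        raise ValueError("align_spikes requires at least one event")
    if isinstance(spikes, SpikeTrain):
        ts, nid = spikes.timestamps, spikes.neuron_id
    else:
        ts, nid = np.asarray(spikes, dtype=float), "unnamed"
    trials = []
    for ev in events:
        lo = np.searchsorted(ts, ev + t0, side="left")
        hi = np.searchsorted(ts, ev + t1, side="right")
        trials.append(ts[lo:hi] - ev)
    return AlignedRaster(nid, alignment_event, (t0, t1), trials,
                         None if labels is None else np.asarray(labels))


def bin_counts(raster: AlignedRaster, bin_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial spike-count matrix on a regular grid over the raster window.

    Bins are half-open ``[edge_i, edge_{i+1})`` with the final bin closed, so
    each in-window spike is counted exactly once.  A trailing partial bin
    (when ``bin_size`` does not divide the window) is dropped and the spikes
    falling in it are excluded from the matrix.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    t0, t1 = raster.window
    n_bins = int(np.floor((t1 - t0) / bin_size + 1e-9))
    if n_bins < 1:
        raise ValueError("window shorter than one bin")
    if abs(t0 + n_bins * bin_size - t1) > 1e-9:
        logger.debug("bin_counts: dropping partial trailing bin (window %s, bin %s)",
                     raster.window, bin_size)
    edges = t0 + bin_size * np.arange(n_bins + 1)
    counts = np.zeros((raster.n_trials, n_bins), dtype=np.int64)
    for i, rel in enumerate(raster.trials):
        if rel.size == 0:
            continue
        idx = np.floor((rel - t0) / bin_size).astype(int)
        idx[np.isclose(rel, edges[-1])] = n_bins - 1  # final bin closed
        idx = idx[(idx >= 0) & (idx < n_bins)]
        np.add.at(counts[i], idx, 1)
    return counts, edges


def firing_rate(raster: AlignedRaster, interval: tuple[float, float]) -> np.ndarray:
    """Per-trial firing rate (spikes/s) in ``interval`` within the raster window."""
    a, b = interval
    if b <= a:
        raise ValueError("interval must have positive length")
    t0, t1 = raster.window
    if a < t0 - 1e-9 or b > t1 + 1e-9:
        raise ValueError(f"interval {interval} outside raster window {raster.window}")
    rates = np.empty(raster.n_trials)
    for i, rel in enumerate(raster.trials):
        rates[i] = np.count_nonzero((rel >= a) & (rel <= b)) / (b - a)
    return rates
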