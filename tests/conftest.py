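"""Shared fixtures: deterministic rasters and a small simulated session."""

from __future__ import annotations

import numpy as np
import pytest

from sweetdecode.core import AlignedRaster
from sweetdecode.simulate import NeuronSpec, SimConfig, simulate_session


def poisson_raster(
    rate_fn,
    n_trials: int,
    window: tuple[float, float],
    rng: np.random.Generator,
    labels=None,
    neuron_id: str = "n0",
) -> AlignedRaster:
    """Raster of inhomogeneous-Poisson trials with rate ``rate_fn(t)`` (Hz)."""
    rates = [float(rate_fn(t)) for t in np.arange(window[0], window[1], 1e-3)]
    rmax = max(max(rates), 1e-9)
    trials = []
    for _ in range(n_trials):
        n = rng.poisson(rmax * (window[1] - window[0]))
        t = np.sort(rng.uniform(window[0], window[1], n))
        keep = rng.uniform(0, rmax, n) < np.array([rate_fn(ti) for ti in t])
        trials.append(t[keep])
    return AlignedRaster(
        neuron_id=neuron_id, alignment_event="event", window=window,
        trials=trials,
        labels=None if labels is None else np.asarray(labels))


def rate_raster(rates, labels=None, window=(0.0, 1.0)) -> AlignedRaster:
    """Raster whose per-trial spike count equals round(rate * duration),
    spikes evenly spaced, so ``firing_rate`` returns ``rates`` exactly."""
    dur = window[1] - window[0]
    trials = []
    for r in np.asarray(rates, dtype=float):
        n = int(round(r * dur))
        trials.append(window[0] + (np.arange(n) + 0.5) * dur / max(n, 1))
    return AlignedRaster(
        neuron_id="n0", alignment_event="event", window=window, trials=trials,
        labels=None if labels is None else np.asarray(labels))


@pytest.fixture(scope="session")
def small_session():
    """A 80-trial session with one neuron of each archetype (seed 7)."""
    neurons = [NeuronSpec.preset(p) for p in
               ("phasic", "tonic_active", "coh_active", "non_evoked")]
    return simulate_session(SimConfig(n_trials=80, neurons=neurons), seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
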