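"""Pseudo-population decoding of sucrose intensity and reward omission.

The classifier is maximum-correlation template matching: class templates are
mean z-scored feature vectors over training trials, and a test trial is
assigned the class whose template correlates best with its feature vector.
Features are spike counts in 20 ms bins over 0-0.6 s after cue delivery
(or -0.2 to 0.6 s around the second lateral lick for outcome decoding).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import AlignedRaster, Session, SpikeTrain, align_spikes, bin_counts
from .stats import permutation_pvalue

logger = logging.getLogger(__name__)

DECODE_WINDOW = (0.0, 0.6)
BIN_SIZE = 0.02

#: inclusion/dropping population names -> modulation labels they comprise
POPULATIONS = {
    "All": None,
    "Non-Evo": ("Non-modulated", "Coherent-Non-evoked"),
    "Phasic": ("Phasic",),
    "Inactive": ("Tonic-Inactive",),
    "Active": ("Tonic-Active",),
    "Coh-Inac": ("Coh-Inactive",),
    "Coh-Act": ("Coh-Active",),
    "All-Tonic": ("Tonic-Active", "Tonic-Inactive"),
    "All-Coh": ("Coh-Active", "Coh-Inactive"),
}


@dataclass
class PseudoPopulation:
    """Per-neuron, per-class binned count matrices ready for decoding."""

    neuron_ids: list[str]
    counts: dict  # class label -> list of (n_trials, n_bins) arrays, one per neuron
    n_trials_per_class: int
    bin_size: float = BIN_SIZE
    window: tuple[float, float] = DECODE_WINDOW
    variant: str = "raw"

    @property
    def classes(self) -> list[str]:
        return list(self.counts)

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_ids)


@dataclass
class DecodeResult:
    variant: str
    accuracy: float  # mean percent correct over folds and runs
    sem: float
    run_accuracies: np.ndarray = field(repr=False, default=None)
    n_ties: int = 0


@dataclass
class NoiseCorrelationResult:
    pair: tuple[str, str]
    r_sc: float
    p_value: float
    window_s: float = 0.6
    undefined: bool = False

    @property
    def significant(self) -> bool:
        return (not self.undefined) and self.p_value < 0.05


# -- population building -------------------------------------------------------


def build_pseudopopulation(
    sessions: Session | list[Session],
    n_trials_per_class: int,
    neuron_filter: set | None = None,
    classes: tuple = ("Low", "High"),
    window: tuple[float, float] = DECODE_WINDOW,
    bin_size: float = BIN_SIZE,
    correct_only: bool = True,
) -> PseudoPopulation:
    """Collect per-neuron Low/High count matrices across sessions.

    Neurons lacking ``n_trials_per_class`` trials of either class are
    excluded (logged).  ``neuron_filter`` restricts to a named subset, e.g. a
    modulation-profile population.
    """
    if isinstance(sessions, Session):
        sessions = [sessions]
    ids: list[str] = []
    counts: dict = {c: [] for c in classes}
    for sess in sessions:
        trials = sess.cue_d_trials(correct_only=correct_only)
        cues = np.asarray([t.t_cue for t in trials])
        labels = np.asarray([t.intensity_label for t in trials])
        for train in sess.spikes:
            nid = f"{sess.session_id}/{train.neuron_id}"
            if neuron_filter is not None and train.neuron_id not in neuron_filter \
                    and nid not in neuron_filter:
                continue
            raster = align_spikes(train, cues, window, alignment_event="cue")
            mat, _ = bin_counts(raster, bin_size)
            per_class = {c: mat[labels == c] for c in classes}
            if any(len(per_class[c]) < n_trials_per_class for c in classes):
                logger.info("neuron %s excluded: fewer than %d trials per class",
                            nid, n_trials_per_class)
                continue
            ids.append(nid)
            for c in classes:
                counts[c].append(per_class[c])
    return PseudoPopulation(ids, counts, n_trials_per_class, bin_size, window)


# -- classifier ----------------------------------------------------------------


def _zscore_train(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0  # constant features carry no information either way
    return (train - mu) / sd, (test - mu) / sd


def _corr_rows(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of x with template vector t."""
    xc = x - x.mean(axis=1, keepdims=True)
    tc = t - t.mean()
    denom = np.linalg.norm(xc, axis=1) * np.linalg.norm(tc)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, xc @ tc / denom, np.nan)


def _fold_accuracy(train_mats: dict, test_mats: dict,
                   rng: np.random.Generator) -> tuple[float, int]:
    classes = list(train_mats)
    all_train = np.vstack([train_mats[c] for c in classes])
    mu = all_train.mean(axis=0)
    sd = all_train.std(axis=0)
    sd[sd == 0] = 1.0
    templates = {c: ((train_mats[c] - mu) / sd).mean(axis=0) for c in classes}
    correct = 0
    total = 0
    ties = 0
    for c in classes:
        z = (test_mats[c] - mu) / sd
        scores = np.column_stack([_corr_rows(z, templates[k]) for k in classes])
        for row in scores:
            if np.all(np.isnan(row)) or np.isclose(np.nanmax(row), np.nanmin(row)):
                pick = rng.integers(len(classes))
                ties += 1
            else:
                pick = int(np.nanargmax(row))
            correct += classes[pick] == c
            total += 1
    return 100.0 * correct / total, ties


def _cv_accuracy(class_mats: dict, k_splits: int,
                 rng: np.random.Generator) -> tuple[float, int]:
    """One cross-validation pass: mean accuracy over k folds."""
    n = min(len(m) for m in class_mats.values())
    fold_ids = {c: np.array_split(rng.permutation(len(class_mats[c]))[:n], k_splits)
                for c in class_mats}
    accs = []
    ties = 0
    for f in range(k_splits):
        train_mats, test_mats = {}, {}
        for c, mat in class_mats.items():
            test_idx = fold_ids[c][f]
            train_idx = np.concatenate([fold_ids[c][g] for g in range(k_splits) if g != f])
            train_mats[c] = mat[train_idx]
            test_mats[c] = mat[test_idx]
        a, t = _fold_accuracy(train_mats, test_mats, rng)
        accs.append(a)
        ties += t
    return float(np.mean(accs)), ties


def decode(
    pop: PseudoPopulation,
    k_splits: int = 5,
    n_runs: int = 50,
    seed: int | np.random.Generator = 0,
) -> DecodeResult:
    """Cross-validated template-matching accuracy of a pseudo-population.

    Each run independently resamples ``n_trials_per_class`` trials per class
    per neuron (pseudo-trials are aligned by sampling position) and performs
    a fresh k-fold split; the result averages over folds and runs.
    """
    if k_splits < 2:
        raise ValueError("k_splits must be >= 2")
    if pop.n_neurons == 0:
        raise ValueError("empty pseudo-population")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = pop.n_trials_per_class
    run_accs = np.empty(n_runs)
    ties = 0
    for r in range(n_runs):
        class_mats = {}
        for c in pop.classes:
            cols = []
            for mat in pop.counts[c]:
                idx = rng.choice(len(mat), size=n, replace=False)
                cols.append(mat[idx])
            class_mats[c] = np.hstack(cols).astype(float)
        run_accs[r], t = _cv_accuracy(class_mats, k_splits, rng)
        ties += t
    sem = run_accs.std(ddof=1) / np.sqrt(n_runs) if n_runs > 1 else 0.0
    return DecodeResult(pop.variant, float(run_accs.mean()), float(sem), run_accs, ties)


# -- controls ------------------------------------------------------------------


def shuffle_spike_timing(
    train: SpikeTrain,
    events: np.ndarray,
    window: tuple[float, float] = DECODE_WINDOW,
    seed: int | np.random.Generator = 0,
) -> SpikeTrain:
    """Redraw in-window spike times uniformly, preserving per-trial counts exactly.

    For each event, the spikes falling in ``window`` are replaced by the same
    number of timestamps sampled uniformly in that interval; spikes outside
    every window are untouched.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ts = train.timestamps
    t0, t1 = window
    keep_mask = np.ones(ts.size, dtype=bool)
    new_chunks = []
    for ev in np.asarray(events, dtype=float):
        lo = np.searchsorted(ts, ev + t0, side="left")
        hi = np.searchsorted(ts, ev + t1, side="right")
        n = hi - lo
        keep_mask[lo:hi] = False
        if n == 0:
            continue
        while True:  # reject draws violating the 1 us separation invariant
            new = np.sort(ev + t0 + (t1 - t0) * rng.random(n))
            if n < 2 or np.min(np.diff(new)) >= 1e-6:
                break
        new_chunks.append(new)
    parts = [ts[keep_mask]] + new_chunks
    return SpikeTrain(train.neuron_id, np.sort(np.concatenate(parts)),
                      channel=train.channel)


def noise_correlation(
    a_low: np.ndarray, a_high: np.ndarray,
    b_low: np.ndarray, b_high: np.ndarray,
    pair: tuple[str, str] = ("A", "B"),
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
    window_s: float = 0.6,
) -> NoiseCorrelationResult:
    """Noise correlation r_sc of a simultaneously recorded pair.

    Per neuron and per stimulus the trial firing rates are z-normalized,
    (FR_k - mean)/sigma, Low and High blocks are concatenated, and r_sc is
    the Pearson correlation of the two normalized vectors.  Significance by
    shuffling trial positions within each stimulus block for each neuron
    independently, p = (k+1)/(n+1) on |r|.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    blocks = [np.asarray(v, dtype=float) for v in (a_low, a_high, b_low, b_high)]
    if any(b.std(ddof=1) == 0 for b in blocks):
        return NoiseCorrelationResult(pair, float("nan"), float("nan"),
                                      window_s, undefined=True)

    def z(v):
        return (v - v.mean()) / v.std(ddof=1)

    za = np.concatenate([z(blocks[0]), z(blocks[1])])
    zb = np.concatenate([z(blocks[2]), z(blocks[3])])
    r_obs = float(np.corrcoef(za, zb)[0, 1])
    n_lo = blocks[0].size
    k = 0
    thr = abs(r_obs) - 1e-12
    for _ in range(n_perm):
        pa = np.concatenate([rng.permutation(za[:n_lo]), rng.permutation(za[n_lo:])])
        pb = np.concatenate([rng.permutation(zb[:n_lo]), rng.permutation(zb[n_lo:])])
        if abs(np.corrcoef(pa, pb)[0, 1]) >= thr:
            k += 1
    return NoiseCorrelationResult(pair, r_obs, permutation_pvalue(k, n_perm), window_s)


def session_noise_correlations(
    session: Session,
    window_s: float = 0.6,
    n_perm: int = 2_000,
    seed: int = 0,
) -> list[NoiseCorrelationResult]:
    """r_sc for every different-channel pair in a session (correct Cue-D trials)."""
    trials = session.cue_d_trials(correct_only=True)
    cues = np.asarray([t.t_cue for t in trials])
    labels = np.asarray([t.intensity_label for t in trials])
    rates = {}
    for train in session.spikes:
        raster = align_spikes(train, cues, (0.0, window_s))
        r = np.asarray([len(rel) / window_s for rel in raster.trials])
        rates[train.neuron_id] = r
    rng = np.random.default_rng(seed)
    out = []
    neurons = session.spikes
    for i in range(len(neurons)):
        for j in range(i + 1, len(neurons)):
            if neurons[i].channel == neurons[j].channel:
                continue
            a, b = rates[neurons[i].neuron_id], rates[neurons[j].neuron_id]
            out.append(noise_correlation(
                a[labels == "Low"], a[labels == "High"],
                b[labels == "Low"], b[labels == "High"],
                pair=(neurons[i].neuron_id, neurons[j].neuron_id),
                n_perm=n_perm, seed=rng, window_s=window_s))
    return out


def decorrelate_trials(
    pop: PseudoPopulation,
    correlated_neurons: set,
    seed: int | np.random.Generator = 0,
) -> PseudoPopulation:
    """Shuffle trial order within class for noise-correlated neurons.

    Destroys pairwise trial alignment while leaving every neuron's per-class
    count distribution exactly unchanged; unflagged neurons are untouched.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = {c: [] for c in pop.classes}
    for c in pop.classes:
        for nid, mat in zip(pop.neuron_ids, pop.counts[c]):
            if nid in correlated_neurons or nid.split("/")[-1] in correlated_neurons:
                counts[c].append(mat[rng.permutation(len(mat))])
            else:
                counts[c].append(mat)
    return PseudoPopulation(pop.neuron_ids, counts, pop.n_trials_per_class,
                            pop.bin_size, pop.window, variant="decorrelated")


# -- population inclusion / dropping ------------------------------------------


def _filter_ids(labels: dict, wanted: tuple | None, invert: bool = False) -> set:
    if wanted is None:
        return set(labels)
    sel = {nid for nid, lab in labels.items() if (lab in wanted) != invert}
    return sel


def population_inclusion(
    sessions: Session | list[Session],
    labels: dict,
    n_trials_per_class: int,
    populations: tuple = tuple(POPULATIONS),
    k_splits: int = 5,
    n_runs: int = 50,
    seed: int = 0,
) -> dict[str, DecodeResult]:
    """Decode with only one modulation-profile population included at a time.

    ``labels`` maps neuron_id -> modulation label.  Empty populations are
    reported as missing (absent key).
    """
    out = {}
    for name in populations:
        ids = _filter_ids(labels, POPULATIONS[name])
        pop = build_pseudopopulation(sessions, n_trials_per_class, neuron_filter=ids)
        if pop.n_neurons == 0:
            logger.info("population %s empty; skipped", name)
            continue
        pop.variant = f"include:{name}"
        out[name] = decode(pop, k_splits, n_runs, seed)
    return out


def population_dropping(
    sessions: Session | list[Session],
    labels: dict,
    n_trials_per_class: int,
    populations: tuple = tuple(n for n in POPULATIONS if n not in ("All", "Non-Evo")),
    k_splits: int = 5,
    n_runs: int = 50,
    seed: int = 0,
) -> dict[str, DecodeResult]:
    """Decode All-minus-one-population, for each population in turn."""
    out = {}
    for name in populations:
        ids = _filter_ids(labels, POPULATIONS[name], invert=True)
        pop = build_pseudopopulation(sessions, n_trials_per_class, neuron_filter=ids)
        if pop.n_neurons == 0:
            logger.info("dropping %s leaves no neurons; skipped", name)
            continue
        pop.variant = f"drop:{name}"
        out[name] = decode(pop, k_splits, n_runs, seed)
    return out


# -- outcome decoding ----------------------------------------------------------


def decode_outcome(
    session: Session,
    source: str = "spikes",
    window: tuple[float, float] = (-0.2, 0.6),
    bin_size: float = BIN_SIZE,
    k_splits: int = 5,
    n_runs: int = 20,
    seed: int = 0,
    min_consecutive: int = 5,
) -> dict:
    """Cumulative-bin decoding of rewarded vs omitted outcomes.

    Aligns ``source`` events (spike trains of all neurons, or the lick train)
    to the second lateral lick, and for each prefix of 20 ms bins decodes
    RW vs RWO; a time point is significant when the lower CI of accuracy over
    runs stays above 50% for at least ``min_consecutive`` bins.  Returns the
    accuracy trace, per-bin CI, significance mask and first significant time.
    """
    rw = [t for t in session.trials if t.rewarded]
    rwo = [t for t in session.trials if not t.rewarded]
    if not rw or not rwo:
        raise ValueError("both rewarded and omitted trials are required")
    rng = np.random.default_rng(seed)

    def mats_for(trials):
        events = [t.t_second_lateral_lick for t in trials]
        cols = []
        if source == "spikes":
            for train in session.spikes:
                raster = align_spikes(train, events, window)
                m, _ = bin_counts(raster, bin_size)
                cols.append(m)
        elif source == "licks":
            all_licks = session.lateral_lick_times()
            raster = align_spikes(all_licks, events, window)
            m, _ = bin_counts(raster, bin_size)
            cols.append(m)
        else:
            raise ValueError(f"unknown source {source!r}")
        return np.hstack(cols).astype(float)

    mats = {"RW": mats_for(rw), "RWO": mats_for(rwo)}
    n = min(len(mats["RW"]), len(mats["RWO"]))
    n_neurons = len(session.spikes) if source == "spikes" else 1
    n_bins = mats["RW"].shape[1] // n_neurons

    trace = np.zeros(n_bins)
    ci = np.zeros((n_bins, 2))
    for b in range(1, n_bins + 1):
        cols = np.concatenate([np.arange(u * n_bins, u * n_bins + b)
                               for u in range(n_neurons)])
        run_accs = np.empty(n_runs)
        for r in range(n_runs):
            sub = {c: m[rng.choice(len(m), n, replace=False)][:, cols]
                   for c, m in mats.items()}
            run_accs[r], _ = _cv_accuracy(sub, k_splits, rng)
        trace[b - 1] = run_accs.mean()
        ci[b - 1] = np.percentile(run_accs, [2.5, 97.5])

    sig = ci[:, 0] > 50.0
    first = None
    run = 0
    for i, s in enumerate(sig):
        run = run + 1 if s else 0
        if run >= min_consecutive:
            first = i - min_consecutive + 1
            break
    times = window[0] + bin_size * (np.arange(n_bins) + 1)
    return {
        "source": source,
        "times": times,
        "accuracy": trace,
        "ci": ci,
        "significant": sig,
        "first_significant_time": None if first is None else float(times[first]),
    }
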