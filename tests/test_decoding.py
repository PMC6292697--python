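"""Pseudo-population decoding, timing/correlation controls, outcome decoding."""

import numpy as np
import pytest

from sweetdecode.core import SpikeTrain, align_spikes
from sweetdecode.decoding import (PseudoPopulation, build_pseudopopulation,
                                  decode, decorrelate_trials, decode_outcome,
                                  noise_correlation, population_dropping,
                                  population_inclusion,
                                  session_noise_correlations,
                                  shuffle_spike_timing)
from sweetdecode.simulate import NeuronSpec, SimConfig, simulate_session


def make_pop(rng, n_neurons=10, n_trials=40, n_bins=30, delta=0.0, base=3.0):
    """Poisson count pseudo-population; even-indexed neurons get +delta counts
    per bin on High trials (the correlation classifier is blind to offsets
    that are uniform across the whole feature vector, so the signal must be
    structured across neurons)."""
    counts = {
        "Low": [rng.poisson(base, (n_trials, n_bins)) for _ in range(n_neurons)],
        "High": [rng.poisson(base + (delta if i % 2 == 0 else 0.0),
                             (n_trials, n_bins)) for i in range(n_neurons)],
    }
    return PseudoPopulation([f"n{i}" for i in range(n_neurons)], counts,
                            n_trials_per_class=n_trials)


class TestDecoder:
    def test_separable_population_decodes_perfectly(self, rng):
        pop = make_pop(rng, delta=4.0)
        res = decode(pop, n_runs=5, seed=0)
        assert res.accuracy > 95.0

    def test_label_free_population_is_at_chance(self, rng):
        # average over fresh population draws: a single finite sample has
        # dataset-level accuracy variance of several percent on its own
        accs = [decode(make_pop(rng, n_neurons=20, n_trials=60, delta=0.0),
                       n_runs=10, seed=s).accuracy for s in range(6)]
        assert np.mean(accs) == pytest.approx(50.0, abs=4.0)

    def test_empty_population_raises(self):
        pop = PseudoPopulation([], {"Low": [], "High": []}, 10)
        with pytest.raises(ValueError):
            decode(pop)

    def test_build_excludes_undersampled_neurons(self, small_session):
        pop = build_pseudopopulation(small_session, n_trials_per_class=10)
        assert pop.n_neurons == len(small_session.spikes)
        huge = build_pseudopopulation(small_session, n_trials_per_class=10_000)
        assert huge.n_neurons == 0


class TestTimingShuffle:
    def test_counts_conserved_exactly(self, small_session):
        train = small_session.spikes[0]
        cues = np.asarray([t.t_cue for t in small_session.trials])
        shuffled = shuffle_spike_timing(train, cues, (0.0, 0.6), seed=3)
        assert shuffled.timestamps.size == train.timestamps.size
        for ev in cues:
            orig = np.sum((train.timestamps >= ev) & (train.timestamps <= ev + 0.6))
            new = np.sum((shuffled.timestamps >= ev) & (shuffled.timestamps <= ev + 0.6))
            assert new == orig

    def test_out_of_window_spikes_untouched(self, small_session):
        train = small_session.spikes[0]
        cues = np.asarray([t.t_cue for t in small_session.trials])
        shuffled = shuffle_spike_timing(train, cues, (0.0, 0.6), seed=3)
        in_any = np.zeros(train.timestamps.size, dtype=bool)
        for ev in cues:
            in_any |= (train.timestamps >= ev) & (train.timestamps <= ev + 0.6)
        np.testing.assert_array_equal(
            np.sort(train.timestamps[~in_any]),
            np.sort(shuffled.timestamps)[np.isin(
                np.sort(shuffled.timestamps), train.timestamps[~in_any])])
        assert np.intersect1d(shuffled.timestamps, train.timestamps[~in_any]).size \
            == np.unique(train.timestamps[~in_any]).size


class TestNoiseCorrelation:
    def test_hand_oracle_zscore_and_pearson(self):
        a_low, a_high = np.array([1.0, 2, 3, 4]), np.array([2.0, 4, 6, 8])
        b_low, b_high = np.array([2.0, 4, 6, 8]), np.array([1.0, 2, 3, 4])
        res = noise_correlation(a_low, a_high, b_low, b_high, n_perm=200)
        # both z-vectors are identical after per-stimulus normalization
        assert res.r_sc == pytest.approx(1.0, abs=1e-12)
        assert res.significant

    def test_matches_definition_on_random_data(self, rng):
        blocks = [rng.normal(10, 2, 25) for _ in range(4)]
        res = noise_correlation(*blocks, n_perm=50)

        def z(v):
            return (v - v.mean()) / v.std(ddof=1)
        za = np.concatenate([z(blocks[0]), z(blocks[1])])
        zb = np.concatenate([z(blocks[2]), z(blocks[3])])
        expected = np.corrcoef(za, zb)[0, 1]
        assert res.r_sc == pytest.approx(expected, abs=1e-12)

    def test_constant_rates_undefined(self):
        res = noise_correlation(np.ones(10), np.ones(10), np.ones(10),
                                np.ones(10), n_perm=10)
        assert res.undefined
        assert not res.significant

    def test_shared_gain_pair_detected_in_session(self):
        specs = [NeuronSpec.preset("non_evoked", noise_group=0)
                 for _ in range(2)]
        sess = simulate_session(
            SimConfig(n_trials=200, neurons=specs, noise_gain_sd={0: 0.4}),
            seed=6)
        results = session_noise_correlations(sess, n_perm=500)
        assert len(results) == 1
        assert results[0].r_sc > 0
        assert results[0].significant


class TestDecorrelate:
    def test_marginals_exactly_invariant(self, rng):
        pop = make_pop(rng, n_neurons=4, delta=1.0)
        out = decorrelate_trials(pop, {"n1", "n3"}, seed=5)
        for c in pop.classes:
            for i in range(pop.n_neurons):
                orig = np.sort(pop.counts[c][i], axis=0)
                new = np.sort(out.counts[c][i], axis=0)
                np.testing.assert_array_equal(orig, new)
        # untouched neurons keep row order
        np.testing.assert_array_equal(pop.counts["Low"][0], out.counts["Low"][0])

    def test_variant_marked(self, rng):
        pop = make_pop(rng, n_neurons=2)
        assert decorrelate_trials(pop, set()).variant == "decorrelated"


class TestPopulations:
    def test_inclusion_and_dropping_run_on_session(self, small_session):
        labels = {s.neuron_id: lab for s, lab in
                  zip(small_session.spikes,
                      ["Phasic", "Tonic-Active", "Coh-Active", "Non-modulated"])}
        inc = population_inclusion(small_session, labels, n_trials_per_class=8,
                                   populations=("All", "Phasic"), n_runs=2)
        assert set(inc) == {"All", "Phasic"}
        assert inc["All"].variant == "include:All"
        drop = population_dropping(small_session, labels, n_trials_per_class=8,
                                   populations=("Phasic",), n_runs=2)
        assert drop["Phasic"].variant == "drop:Phasic"

    def test_empty_population_skipped(self, small_session):
        labels = {s.neuron_id: "Non-modulated" for s in small_session.spikes}
        inc = population_inclusion(small_session, labels, n_trials_per_class=8,
                                   populations=("Phasic",), n_runs=2)
        assert inc == {}


class TestOutcomeDecode:
    def test_outcome_decoding_from_spikes(self):
        # heterogeneous outcome effects: a uniform offset on a single neuron
        # is invisible to the correlation classifier
        specs = [NeuronSpec.preset("non_evoked", outcome_coding="active",
                                   outcome_effect=15.0),
                 NeuronSpec.preset("non_evoked", outcome_coding="inactive",
                                   outcome_effect=8.0),
                 NeuronSpec.preset("non_evoked")]
        sess = simulate_session(SimConfig(n_trials=120, neurons=specs), seed=8)
        out = decode_outcome(sess, source="spikes", n_runs=5)
        assert out["accuracy"].shape == out["times"].shape
        assert out["accuracy"][-5:].mean() > 60.0
        assert out["first_significant_time"] is not None

    def test_unknown_source_raises(self, small_session):
        with pytest.raises(ValueError):
            decode_outcome(small_session, source="emg")
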