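"""Choice, neurometric, direction and outcome coding analyses."""

import numpy as np
import pytest

from sweetdecode.core import AlignedRaster
from sweetdecode.decision import (detect_choice_neuron, detect_direction_neuron,
                                  detect_outcome_neuron, intensity_group,
                                  neurometric, population_zscore,
                                  preference_index, sliding_roc)
from tests.conftest import poisson_raster, rate_raster


def labeled_raster(rates, labels, window=(0.0, 1.0)):
    r = rate_raster(rates, window=window)
    r.labels = np.asarray(labels)
    return r


def test_intensity_group_boundaries():
    assert [intensity_group(c) for c in (0.0, 3.0, 4.75)] == ["Low"] * 3
    assert [intensity_group(c) for c in (7.5, 11.75, 18.0)] == ["High"] * 3


class TestPreferenceIndex:
    def test_perfect_separation_is_one(self, rng):
        res = preference_index(np.full(20, 10.0), np.zeros(20), rng=rng)
        assert res.p_index == 1.0
        assert res.auroc == 1.0
        assert res.p_value < 0.05

    def test_identical_rates_is_zero(self, rng):
        res = preference_index(np.full(20, 5.0), np.full(20, 5.0), rng=rng)
        assert res.p_index == 0.0
        assert res.p_value == 1.0
        assert not res.significant

    def test_antisymmetry(self, rng):
        a = rng.poisson(8, 30).astype(float)
        b = rng.poisson(12, 30).astype(float)
        assert (preference_index(a, b, rng=rng, n_perm=100).p_index
                == pytest.approx(-preference_index(b, a, rng=rng, n_perm=100).p_index,
                                 abs=1e-12))


class TestSlidingRoc:
    def test_centers_inset_by_half_window(self, rng):
        raster = poisson_raster(lambda t: 10.0, 24, (0.0, 0.6), rng)
        raster.labels = np.array(["High", "Low"] * 12)
        roc = sliding_roc(raster, (0.0, 0.6), n_boot=100, rng=rng)
        assert roc.centers[0] == pytest.approx(0.1)
        assert roc.centers[-1] == pytest.approx(0.5)
        assert roc.auroc.shape == roc.centers.shape

    def test_low_preferring_neuron_flagged_significant(self):
        # Low trials fire, High trials silent: auROC(High vs Low) = 0
        raster = labeled_raster([0.0] * 12 + [20.0] * 12,
                                ["High"] * 12 + ["Low"] * 12,
                                window=(0.0, 0.6))
        roc = sliding_roc(raster, (0.0, 0.6), n_boot=100)
        assert np.all(roc.auroc == 0.0)
        assert roc.significant.all()  # via ci_hi < 0.5


class TestChoiceNeuron:
    def test_strong_choice_signal_detected(self, rng):
        n = 30
        cue = AlignedRaster(
            "n0", "cue", (0.0, 0.6),
            poisson_raster(lambda t: 18.0, n, (0.0, 0.6), rng).trials
            + poisson_raster(lambda t: 4.0, n, (0.0, 0.6), rng).trials,
            labels=np.array(["High"] * n + ["Low"] * n))
        resp = AlignedRaster(
            "n0", "response", (-0.4, 0.8),
            poisson_raster(lambda t: 18.0, n, (-0.4, 0.8), rng).trials
            + poisson_raster(lambda t: 4.0, n, (-0.4, 0.8), rng).trials,
            labels=np.array(["High"] * n + ["Low"] * n))
        out = detect_choice_neuron(cue, resp, n_boot=200, rng=rng)
        assert out["detected"]

    def test_four_consecutive_not_enough(self):
        # centers in (0, 0.6): 5 total; make exactly 4 significant
        mask = np.array([True, True, True, True, False])
        from sweetdecode.decision import _has_consecutive
        assert not _has_consecutive(mask, 5)
        assert _has_consecutive(np.ones(5, dtype=bool), 5)


class TestNeurometric:
    def test_perfect_separation_hits_100(self):
        # 10 Hz on all High, 0 Hz on all Low -> 100% correct, criterion met
        concs = np.array([3.0] * 10 + [18.0] * 10)
        raster = labeled_raster([0.0] * 10 + [10.0] * 10,
                                ["Low"] * 10 + ["High"] * 10,
                                window=(0.0, 0.6))
        res = neurometric(raster, (0.0, 0.6), concs, n_boot=50)
        assert res.percent_correct == pytest.approx(100.0)
        assert res.is_choice_neuron
        assert res.preference == "High-preferred"
        assert res.low_hits == 10 and res.high_hits == 10

    def test_known_hit_rates_give_85_percent(self):
        # High-preferred; threshold separates all but 3 of 20 trials -> 85%
        rates = [0.0] * 8 + [10.0] * 2 + [10.0] * 9 + [0.0] * 1
        labels = ["Low"] * 10 + ["High"] * 10
        concs = np.array([3.0] * 10 + [18.0] * 10)
        res = neurometric(labeled_raster(rates, labels, window=(0.0, 0.6)),
                          (0.0, 0.6), concs, n_boot=50)
        assert res.percent_correct == pytest.approx(100 * (8 + 9) / 20)

    def test_uninformative_neuron_fails_criterion(self, rng):
        n = 40
        raster = poisson_raster(lambda t: 8.0, 2 * n, (0.0, 0.6), rng)
        raster.labels = np.array(["High", "Low"] * n)
        concs = np.array([18.0, 3.0] * n)
        res = neurometric(raster, (0.0, 0.6), concs, n_boot=50, rng=rng)
        assert res.percent_correct < 70.0
        assert not res.is_choice_neuron


class TestDirection:
    def test_right_selective_same_sign_both_epochs(self, rng):
        n = 25
        def make(window):
            return AlignedRaster(
                "n0", "move", window,
                poisson_raster(lambda t: 20.0, n, window, rng).trials
                + poisson_raster(lambda t: 5.0, n, window, rng).trials,
                labels=np.array(["right"] * n + ["left"] * n))
        res = detect_direction_neuron(make((0.0, 0.7)), make((0.0, 0.7)),
                                      n_perm=500, rng=rng)
        assert res.classification == "Right-selective"
        assert res.response.p_index > 0 and res.ret.p_index > 0

    def test_opposite_signs_not_selective(self):
        n = 20
        resp = labeled_raster([20.0] * n + [0.0] * n,
                              ["right"] * n + ["left"] * n, window=(0.0, 0.7))
        ret = labeled_raster([0.0] * n + [20.0] * n,
                             ["right"] * n + ["left"] * n, window=(0.0, 0.7))
        res = detect_direction_neuron(resp, ret, n_perm=200)
        assert res.classification == "none"


class TestOutcome:
    def test_omission_firing_is_active_endpoint(self):
        raster = labeled_raster([15.0] * 15 + [0.0] * 15,
                                ["RWO"] * 15 + ["RW"] * 15, window=(0.0, 0.6))
        res = detect_outcome_neuron(raster, n_perm=500)
        assert res.sign_class == "Active"
        assert res.p_index == 1.0
        assert res.significant

    def test_suppressed_on_omission_is_inactive(self):
        raster = labeled_raster([0.0] * 15 + [15.0] * 15,
                                ["RWO"] * 15 + ["RW"] * 15, window=(0.0, 0.6))
        res = detect_outcome_neuron(raster, n_perm=500)
        assert res.sign_class == "Inactive"
        assert res.p_index == -1.0


class TestPopulationZscore:
    def test_zscore_uses_own_baseline(self, rng):
        rasters = [poisson_raster(lambda t: 10.0 + (20.0 if t >= 0 else 0.0),
                                  60, (-0.3, 0.6), rng, neuron_id=f"n{i}")
                   for i in range(4)]
        out = population_zscore(rasters, (-0.3, 0.0))
        assert out["n_neurons"] == 4
        # post-cue z well above pre-cue z
        edges = out["edges"]
        post = out["mean"][edges[:-1] >= 0]
        pre = out["mean"][edges[:-1] < -0.02]
        assert post.mean() > pre.mean() + 1.0

    def test_zero_variance_baseline_excluded(self, rng):
        good = poisson_raster(lambda t: 10.0, 40, (-0.3, 0.6), rng)
        silent = rate_raster(np.zeros(40), window=(-0.3, 0.6))
        out = population_zscore([good, silent], (-0.3, 0.0))
        assert out["n_neurons"] == 1
        assert out["n_excluded"] == 1
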