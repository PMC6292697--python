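"""Intensity selectivity, lick confound control, and Sensory tuning."""

import numpy as np
import pytest

from sweetdecode.core import AlignedRaster
from sweetdecode.selectivity import (intensity_selective, lick_confound_roc,
                                     sensory_tuning, sensory_population_profile,
                                     _normalized_profile)
from tests.conftest import poisson_raster, rate_raster


def two_group_raster(rng, delta_high=10.0, span=(0.0, 0.4), n_per=50, base=10.0):
    def rate_low(t):
        return base

    def rate_high(t):
        return base + (delta_high if span[0] <= t < span[1] else 0.0)

    low = poisson_raster(rate_low, n_per, (-0.3, 0.6), rng)
    high = poisson_raster(rate_high, n_per, (-0.3, 0.6), rng)
    return AlignedRaster(
        "n0", "cue", (-0.3, 0.6), low.trials + high.trials,
        labels=np.array(["Low"] * n_per + ["High"] * n_per))


class TestIntensitySelective:
    def test_detects_high_preference(self, rng):
        raster = two_group_raster(rng)
        res = intensity_selective(raster)
        assert res.is_selective
        assert res.preferred == "High"
        assert res.p_value < 0.05

    def test_detects_low_preference(self, rng):
        raster = two_group_raster(rng, delta_high=-8.0, base=14.0)
        res = intensity_selective(raster)
        assert res.is_selective
        assert res.preferred == "Low"

    def test_requires_labels_and_minimum_trials(self, rng):
        raster = poisson_raster(lambda t: 10.0, 20, (-0.3, 0.6), rng)
        with pytest.raises(ValueError):
            intensity_selective(raster)
        small = two_group_raster(rng, n_per=4)
        with pytest.raises(ValueError):
            intensity_selective(small)

    def test_all_zero_not_selective(self):
        n = 20
        raster = rate_raster(np.zeros(2 * n), window=(-0.3, 0.6))
        raster.labels = np.array(["Low"] * n + ["High"] * n)
        assert not intensity_selective(raster).is_selective


class TestLickConfound:
    def test_identical_lick_trains_zero_overlap(self, rng):
        licks = poisson_raster(lambda t: 6.5, 40, (0.0, 0.6), rng)
        starts, sig, overlap = lick_confound_roc(licks, licks, (0.0, 0.4))
        assert not sig.any()
        assert overlap == 0.0

    def test_everywhere_different_gives_full_overlap(self, rng):
        slow = rate_raster(np.zeros(30), window=(0.0, 0.6))
        fast = rate_raster(np.full(30, 10.0), window=(0.0, 0.6))
        starts, sig, overlap = lick_confound_roc(slow, fast, (0.1, 0.5),
                                                 rng=rng)
        assert sig.all()
        assert overlap == pytest.approx(1.0)

    def test_confined_difference_misses_early_window(self, rng):
        def late_only(t):
            return 7.0 if t >= 0.4 else 3.0
        low = poisson_raster(lambda t: 3.0, 60, (0.0, 0.6), rng)
        high = poisson_raster(late_only, 60, (0.0, 0.6), rng)
        _, sig, overlap = lick_confound_roc(low, high, (0.0, 0.3), rng=rng)
        assert overlap == pytest.approx(0.0)


class TestSensoryTuning:
    def test_recovers_positive_concentration_slope(self, rng):
        concs = np.repeat([3.0, 4.75, 7.5, 11.75, 18.0], 16)
        trials = []
        for c in concs:
            r = poisson_raster(lambda t, c=c: 8.0 + (1.0 * c if t >= 0 else 0.0),
                               1, (-0.3, 0.6), rng)
            trials.append(r.trials[0])
        raster = AlignedRaster("n0", "cue_g", (-0.3, 0.6), trials, labels=concs)
        tuning = sensory_tuning(raster, n_perm=2000, rng=rng)
        assert tuning is not None
        assert tuning.sign == "positive"
        assert tuning.r > 0.4
        assert tuning.p_corrected < 0.05
        assert list(tuning.mean_rates) == [3.0, 4.75, 7.5, 11.75, 18.0]

    def test_unrelated_rates_return_none(self, rng):
        concs = np.repeat([3.0, 4.75, 7.5, 11.75, 18.0], 16)
        raster = poisson_raster(lambda t: 10.0, concs.size, (-0.3, 0.6), rng)
        raster.labels = concs
        assert sensory_tuning(raster, n_perm=500, rng=rng) is None

    def test_normalized_profile_anchored_at_3pct(self):
        prof = _normalized_profile({3.0: 5.0, 4.75: 6.0, 7.5: 7.0,
                                    11.75: 8.0, 18.0: 9.0})
        assert prof[0] == pytest.approx(0.0)
        assert np.all(np.diff(prof) > 0)

    def test_population_profile_grouped_by_sign(self):
        from sweetdecode.selectivity import SensoryTuning
        up = SensoryTuning((0, 0.2), 0.9, "positive", 0.01, 0.01, {},
                           np.array([0.0, 1.0]))
        down = SensoryTuning((0, 0.2), -0.9, "negative", 0.01, 0.01, {},
                             np.array([0.0, -1.0]))
        out = sensory_population_profile([up, up, down])
        np.testing.assert_allclose(out["positive"][0], [0.0, 1.0])
        np.testing.assert_allclose(out["negative"][0], [0.0, -1.0])
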