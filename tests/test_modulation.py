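"""Best-window scan, phasic criterion, and profile classification."""

import numpy as np
import pytest

from sweetdecode.coherence import CoherenceResult
from sweetdecode.modulation import (BASELINE, STIMULUS_SPAN, best_window_scan,
                                    classify_modulation, dry_lick_segments,
                                    grid_windows, phasic_detect)
from tests.conftest import poisson_raster


def fake_coherence(is_coherent: bool) -> CoherenceResult:
    return CoherenceResult(band=(4.0, 12.0), coherence=0.4 if is_coherent else 0.01,
                           ci=(0.3, 0.5) if is_coherent else (0.0, 0.02),
                           threshold=0.06, is_coherent=is_coherent, n_segments=50)


class TestGrid:
    def test_enumeration_matches_brute_force_oracle(self):
        # independent re-derivation: all center +/- size/2 inside [0, 0.6]
        expected = set()
        for i in range(1, 13):
            for j in range(1, 11):
                size, center = i * 0.05, j * 0.05
                a, b = center - size / 2, center + size / 2
                if a >= -1e-9 and b <= 0.6 + 1e-9:
                    expected.add((round(center, 10), round(size, 10)))
        got = {(c, s) for c, s, _ in grid_windows()}
        assert got == expected
        assert len(got) == 70

    def test_intervals_inside_stimulus_span(self):
        for _c, _s, (a, b) in grid_windows():
            assert a >= -1e-9 and b <= STIMULUS_SPAN[1] + 1e-9


class TestBestWindow:
    def test_recovers_step_modulation(self, rng):
        def rate(t):
            return 10.0 + (20.0 if 0.1 <= t < 0.5 else 0.0)
        raster = poisson_raster(rate, 60, (-0.3, 0.6), rng)
        bw = best_window_scan(raster)
        assert bw is not None
        # the best window lies inside (or equals) the modulated span
        assert bw.interval[0] >= 0.1 - 0.101 and bw.interval[1] <= 0.5 + 0.101
        assert bw.delta == pytest.approx(20.0, abs=7.0)
        assert bw.p_value < 0.05

    def test_inhibition_gives_negative_delta(self, rng):
        def rate(t):
            return 15.0 - (11.0 if 0.0 <= t < 0.6 else 0.0)
        raster = poisson_raster(rate, 60, (-0.3, 0.6), rng)
        bw = best_window_scan(raster)
        assert bw is not None and bw.delta < 0

    def test_flat_zero_rate_yields_none(self):
        from tests.conftest import rate_raster
        raster = rate_raster(np.zeros(30), window=(-0.3, 0.6))
        assert best_window_scan(raster) is None

    def test_single_window_null_calibrated(self):
        """Duration-matched rank-sum keeps per-window level ~ alpha."""
        rng = np.random.default_rng(8)
        n_rep, n = 300, 120
        for size, bl in [(0.05, 0.05), (0.3, 0.3)]:
            rej = 0
            for _ in range(n_rep):
                from sweetdecode.stats import ranksum_pvalue
                x = rng.poisson(10.0 * size, n) / size
                y = rng.poisson(10.0 * bl, n) / bl
                rej += ranksum_pvalue(x, y) < 0.05
            se = np.sqrt(0.05 * 0.95 / n_rep)
            assert rej / n_rep <= 0.05 + 3 * se


class TestPhasic:
    def test_detects_injected_bump(self, rng):
        def rate(t):
            return 8.0 + (30.0 if 0.05 <= t < 0.15 else 0.0)
        hits = 0
        for _ in range(10):
            raster = poisson_raster(rate, 80, (-0.3, 0.6), rng)
            res = phasic_detect(raster)
            hits += res.is_phasic
        assert hits >= 9

    def test_long_step_is_not_phasic(self, rng):
        def rate(t):
            return 8.0 + (20.0 if 0.0 <= t < 0.4 else 0.0)
        raster = poisson_raster(rate, 80, (-0.3, 0.6), rng)
        assert not phasic_detect(raster).is_phasic

    def test_onset_estimate_near_truth(self, rng):
        def rate(t):
            return 8.0 + (40.0 if 0.05 <= t < 0.15 else 0.0)
        raster = poisson_raster(rate, 100, (-0.3, 0.6), rng)
        res = phasic_detect(raster)
        assert res.is_phasic
        assert res.onset == pytest.approx(0.05, abs=0.05)

    def test_insufficient_trials_flagged(self):
        from tests.conftest import rate_raster
        raster = rate_raster(np.full(3, 10.0), window=(-0.3, 0.6))
        assert phasic_detect(raster).insufficient_data


class TestClassify:
    def test_coherence_takes_precedence(self, rng):
        def rate(t):
            return 10.0 + (10.0 if t >= 0.0 else 0.0)
        raster = poisson_raster(rate, 60, (-0.3, 0.6), rng)
        lab = classify_modulation(raster, fake_coherence(True))
        assert lab.label == "Coh-Active"

    def test_coherent_without_evoked_response(self):
        # silent-at-cue neuron: no best window exists, coherence decides
        from tests.conftest import rate_raster
        raster = rate_raster(np.zeros(40), window=(-0.3, 0.6))
        lab = classify_modulation(raster, fake_coherence(True))
        assert lab.label == "Coherent-Non-evoked"
        assert lab.is_non_evoked

    def test_tonic_labels_by_sign(self, rng):
        up = poisson_raster(lambda t: 8.0 + (10.0 if t >= 0 else 0.0),
                            80, (-0.3, 0.6), rng)
        down = poisson_raster(lambda t: 15.0 - (11.0 if t >= 0 else 0.0),
                              80, (-0.3, 0.6), rng)
        assert classify_modulation(up, fake_coherence(False)).label == "Tonic-Active"
        assert classify_modulation(down, fake_coherence(False)).label == "Tonic-Inactive"

    def test_no_evidence_means_not_modulated(self):
        from tests.conftest import rate_raster
        raster = rate_raster(np.zeros(40), window=(-0.3, 0.6))
        lab = classify_modulation(raster, fake_coherence(False))
        assert lab.label == "Non-modulated"
        assert lab.best_window is None


def test_dry_lick_segments_end_at_cue(small_session):
    segs = dry_lick_segments(small_session, seg_len=0.512)
    assert segs.size > 0
    cues = {t.t_cue for t in small_session.cue_d_trials(correct_only=True)}
    for s in segs:
        assert any(abs(s + 0.512 - c) < 1e-9 for c in cues)
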