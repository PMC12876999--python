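import numpy as np
import pytest

from mindseye.aoi import aoi_profile
from mindseye.errors import ConfigError
from mindseye.events import detect_fixations
from mindseye.rqa import analyze
from mindseye.synthetic import (
    MODE_PRESETS,
    SyntheticCohortConfig,
    generate_cohort,
    generate_trial,
    render_raw_track,
    sample_anchors,
)


def _trial(seed=0, mode="free", **overrides):
    cfg = SyntheticCohortConfig(seed=seed, **overrides)
    return generate_trial(cfg, mode, rng=np.random.default_rng(seed))


class TestGenerateTrial:
    @pytest.mark.parametrize("mode", sorted(MODE_PRESETS))
    def test_exact_count_and_on_screen(self, mode):
        sp = _trial(seed=3, mode=mode, n_fixations=30)
        assert len(sp) == 30
        assert all(sp.geometry.contains(f.x_px, f.y_px) for f in sp.fixations)
        durations = sp.durations()
        assert ((durations >= 100) & (durations <= 5000)).all()

    def test_same_seed_is_bit_identical(self):
        a = _trial(seed=9, mode="imagery")
        b = _trial(seed=9, mode="imagery")
        assert a.fixations == b.fixations

    def test_double_tour_with_perfect_fidelity_is_pure_determinism(self):
        # anchors toured twice in the same order, no jitter, single dwells
        sp = _trial(seed=5, mode="free", n_anchors=5, n_fixations=10,
                    revisit_prob=0.0, order_fidelity=1.0, cluster_dwell=1.0,
                    jitter_sd=0.0)
        res = analyze(sp)
        assert res.determinism == 100.0

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigError):
            _trial(mode="dreaming")

    def test_impossible_anchor_packing_rejected(self):
        cfg = SyntheticCohortConfig(n_anchors=200, anchor_min_sep_px=400.0)
        with pytest.raises(ConfigError):
            sample_anchors(cfg, np.random.default_rng(0))


class TestCohortCoupling:
    def test_full_coupling_replays_aoi_profile_per_trial(self):
        cfg = SyntheticCohortConfig(n_participants=2, n_trials=3, seed=11,
                                    encoding_coupling=1.0, jitter_sd=0.0)
        scanpaths, _ = generate_cohort(cfg)
        by_key = {}
        for sp in scanpaths:
            by_key.setdefault((sp.participant_id, sp.trial_id), {})[sp.phase] = sp
        for phases in by_key.values():
            enc = aoi_profile(phases["encoding"])
            img = aoi_profile(phases["imagery"])
            assert img.proportions == pytest.approx(enc.proportions)

    def test_truth_table_carries_generating_parameters(self):
        cfg = SyntheticCohortConfig(n_participants=2, n_trials=3, seed=1)
        _, truth = generate_cohort(cfg)
        assert len(truth) == 6
        assert set(truth["condition"]) == {"FP", "GCW", "AS"}
        assert (truth["lambda"] == cfg.encoding_coupling).all()
        assert truth["accuracy"].isin([0, 1]).all()
        assert truth["vividness"].between(1, 7).all()

    def test_cohort_reproducible_and_extensible(self):
        small = SyntheticCohortConfig(n_participants=2, n_trials=2, seed=4)
        big = SyntheticCohortConfig(n_participants=3, n_trials=2, seed=4)
        sp_small, _ = generate_cohort(small)
        sp_big, _ = generate_cohort(big)
        # adding a participant never reshuffles existing trials
        for a, b in zip(sp_small, sp_big[: len(sp_small)]):
            assert a.fixations == b.fixations


class TestMonotoneLevers:
    """Each generative lever moves its RQA measure, in expectation."""

    N_TRIALS = 60

    def _mean_measure(self, attr, mode, **overrides):
        cfg = SyntheticCohortConfig(seed=17, **overrides)
        vals = []
        for t in range(self.N_TRIALS):
            sp = generate_trial(cfg, mode, rng=np.random.default_rng((17, t)))
            vals.append(getattr(analyze(sp), attr))
        return float(np.mean(vals))

    def test_recurrence_increases_with_revisit_prob(self):
        means = [self._mean_measure("recurrence_rate", "free", revisit_prob=p)
                 for p in (0.1, 0.4, 0.7)]
        assert means[0] < means[1] < means[2]

    def test_determinism_increases_with_order_fidelity(self):
        means = [self._mean_measure("determinism", "free", revisit_prob=0.5,
                                    order_fidelity=f) for f in (0.1, 0.5, 0.9)]
        assert means[0] < means[1] < means[2]

    def test_laminarity_increases_with_cluster_dwell(self):
        means = [self._mean_measure("laminarity", "free", revisit_prob=0.4,
                                    cluster_dwell=d) for d in (1.0, 2.0, 4.0)]
        assert means[0] < means[1] < means[2]


class TestRenderRawTrack:
    def test_single_fixation_sample_count(self, geometry):
        from conftest import make_scanpath

        sp = make_scanpath([(960, 540)], durations=[500.0], geometry=geometry)
        track = render_raw_track(sp, rate_hz=1000.0, noise_sd_deg=0.0)
        assert len(track) == 500

    def test_noise_free_roundtrip_recovers_count(self):
        cfg = SyntheticCohortConfig(seed=23, n_fixations=12, cluster_dwell=1.0)
        sp = generate_trial(cfg, "free", rng=np.random.default_rng(23))
        track = render_raw_track(sp, noise_sd_deg=0.0)
        detected = detect_fixations(track, sp.geometry)
        assert len(detected) == len(sp)

    def test_blink_gap_splits_fixation(self):
        from conftest import make_scanpath

        sp = make_scanpath([(960, 540)], durations=[600.0])
        track = render_raw_track(sp, noise_sd_deg=0.0, blink_gaps=[(250.0, 330.0)])
        detected = detect_fixations(track, sp.geometry)
        assert len(detected) == 2
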