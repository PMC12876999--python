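import numpy as np
import pytest

from mindseye.errors import InputError
from mindseye.rqa import (
    RQAConfig,
    analyze,
    determinism,
    fixation_spread,
    laminarity,
    recurrence_matrix,
    recurrence_rate,
)

from conftest import make_scanpath, random_scanpath
from oracles import (
    oracle_determinism,
    oracle_laminarity,
    oracle_recurrence_matrix,
    oracle_recurrence_rate,
)

EPS = 135.0


def _abc_tour():
    """Three clusters > eps apart, visited twice in the same order."""
    a, b, c = (200.0, 200.0), (960.0, 200.0), (1700.0, 900.0)
    return make_scanpath([a, b, c, a, b, c])


class TestRecurrenceMatrix:
    def test_identical_positions_recur(self):
        plot = recurrence_matrix(make_scanpath([(500, 500), (500, 500)]))
        assert plot.matrix.all()

    def test_dispersed_path_gives_identity(self):
        plot = recurrence_matrix(make_scanpath([(100, 100), (900, 100), (1700, 900)]))
        assert (plot.matrix == np.eye(3, dtype=bool)).all()

    def test_threshold_is_inclusive(self):
        plot = recurrence_matrix(make_scanpath([(100.0, 500.0), (100.0 + EPS, 500.0)]))
        assert plot.matrix.all()
        plot = recurrence_matrix(
            make_scanpath([(100.0, 500.0), (100.0 + EPS + 0.01, 500.0)]))
        assert not plot.matrix[0, 1]

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(12)
        sp = random_scanpath(rng, 12)
        plot = recurrence_matrix(sp)
        oracle = oracle_recurrence_matrix(sp.positions().tolist(), EPS)
        assert plot.matrix.tolist() == oracle

    def test_single_fixation_rejected(self):
        with pytest.raises(InputError):
            recurrence_matrix(make_scanpath([(100, 100)]))


class TestMeasures:
    def test_all_within_radius_gives_full_recurrence(self):
        rng = np.random.default_rng(1)
        pos = np.array([960.0, 540.0]) + rng.uniform(-40, 40, size=(8, 2))
        plot = recurrence_matrix(make_scanpath(pos))
        assert recurrence_rate(plot) == 100.0
        assert laminarity(plot) == 100.0

    def test_no_recurrence_gives_zero_by_convention(self):
        sp = make_scanpath([(100, 100), (900, 100), (1700, 900)])
        res = analyze(sp)
        assert res.recurrence_rate == 0.0
        assert res.determinism == 0.0 and res.laminarity == 0.0
        assert res.degenerate

    def test_ordered_cluster_tour_is_pure_determinism(self):
        # A,B,C,A,B,C: all recurrences form one length-3 diagonal, no dwells
        res = analyze(_abc_tour())
        assert res.determinism == 100.0
        assert res.laminarity == 0.0
        assert res.rec_count == 3

    def test_isolated_recurrences_give_zero_determinism(self):
        # single revisit separated by unrelated fixations -> isolated point
        a = (200.0, 200.0)
        sp = make_scanpath([a, (960, 200), a, (1700, 900)])
        plot = recurrence_matrix(sp)
        assert plot.rec_count == 1
        assert determinism(plot) == 0.0

    def test_all_identical_corner_convention(self):
        # every upper-triangle point except the single-cell corner diagonal
        # lies on a diagonal line, so DET = 100 (R-1)/R; dwell runs cover
        # everything, so LAM = 100
        n = 10
        res = analyze(make_scanpath([(960.0, 540.0)] * n))
        r = n * (n - 1) // 2
        assert res.recurrence_rate == 100.0
        assert res.determinism == pytest.approx(100.0 * (r - 1) / r)
        assert res.laminarity == 100.0

    @pytest.mark.parametrize("seed", range(12))
    def test_measures_match_bruteforce_enumerators(self, seed):
        rng = np.random.default_rng(100 + seed)
        sp = random_scanpath(rng, int(rng.integers(5, 30)))
        plot = recurrence_matrix(sp)
        m = oracle_recurrence_matrix(sp.positions().tolist(), EPS)
        assert recurrence_rate(plot) == pytest.approx(oracle_recurrence_rate(m))
        assert determinism(plot) == pytest.approx(oracle_determinism(m))
        assert laminarity(plot) == pytest.approx(oracle_laminarity(m))


class TestInvariances:
    def test_translation_and_rotation_leave_det_lam_unchanged(self):
        rng = np.random.default_rng(21)
        sp = random_scanpath(rng, 20)
        base = analyze(sp)
        pos = sp.positions() - sp.positions().mean(axis=0)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = pos @ rot.T + np.array([900.0, 500.0])
        # rotation about the centroid plus translation preserves distances
        res = analyze(make_scanpath(moved))
        assert res.determinism == pytest.approx(base.determinism)
        assert res.laminarity == pytest.approx(base.laminarity)
        assert res.recurrence_rate == pytest.approx(base.recurrence_rate)

    def test_recurrence_rate_monotone_in_radius(self):
        rng = np.random.default_rng(22)
        sp = random_scanpath(rng, 25)
        rates = [
            recurrence_rate(recurrence_matrix(sp, RQAConfig(radius_px=r)))
            for r in (50, 100, 135, 200, 400, 800)
        ]
        assert rates == sorted(rates)

    def test_shrinking_scanpath_saturates_measures(self):
        rng = np.random.default_rng(23)
        sp = random_scanpath(rng, 15)
        pos = sp.positions()
        centre = pos.mean(axis=0)
        shrunk = make_scanpath(centre + (pos - centre) * 0.01)
        res = analyze(shrunk)
        assert res.recurrence_rate == 100.0
        assert res.laminarity == 100.0
        assert res.determinism > 95.0


class TestFixationSpread:
    def test_point_mass_has_zero_spread(self):
        assert fixation_spread(make_scanpath([(500, 500)] * 4)) == 0.0

    def test_two_point_case(self):
        sp = make_scanpath([(500.0, 500.0), (700.0, 500.0)])  # 200 px apart
        assert fixation_spread(sp) == pytest.approx(100.0)

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(31)
        sp = random_scanpath(rng, 18)
        pos = sp.positions()
        expected = np.sqrt(np.mean(np.sum((pos - pos.mean(0)) ** 2, axis=1)))
        assert fixation_spread(sp) == pytest.approx(expected)
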