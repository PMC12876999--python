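import math

import numpy as np
import pytest

from mindseye.errors import InputError
from mindseye.similarity import (
    DIMENSIONS,
    SimilarityConfig,
    align_vectors,
    scanpath_to_vectors,
    similarity_profile,
    simplify_scanpath,
)

from conftest import make_scanpath, random_scanpath
from oracles import oracle_alignment_cost

NO_SIMPLIFY = SimilarityConfig(simplify=False)


class TestSimplify:
    def test_collinear_saccades_around_brief_fixation_merge(self):
        sp = make_scanpath([(100, 500), (400, 500), (700, 500)],
                           durations=[400, 100, 400])
        (vec,) = simplify_scanpath(sp)
        assert (vec.dx, vec.dy) == (600.0, 0.0)
        assert vec.duration_ms == 500.0  # pooled

    def test_long_orthogonal_saccades_unchanged(self):
        sp = make_scanpath([(100, 100), (1500, 100), (1500, 1000)],
                           durations=[400, 400, 400])
        assert len(simplify_scanpath(sp)) == 2

    def test_long_intervening_fixation_blocks_merge(self):
        sp = make_scanpath([(100, 500), (400, 500), (700, 500)],
                           durations=[400, 400, 400])
        assert len(simplify_scanpath(sp)) == 2

    def test_small_amplitude_merge(self):
        # two tiny non-collinear saccades around a brief fixation
        sp = make_scanpath([(500, 500), (540, 500), (540, 540)],
                           durations=[400, 100, 400])
        assert len(simplify_scanpath(sp)) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_reaches_fixed_point_and_never_grows(self, seed):
        rng = np.random.default_rng(200 + seed)
        sp = random_scanpath(rng, 15)
        vectors = simplify_scanpath(sp)
        assert len(vectors) <= len(sp) - 1
        # resultant displacement is preserved by merging
        raw = scanpath_to_vectors(sp)
        assert sum(v.dx for v in vectors) == pytest.approx(sum(v.dx for v in raw))
        assert sum(v.dy for v in vectors) == pytest.approx(sum(v.dy for v in raw))

    def test_requires_two_fixations(self):
        with pytest.raises(InputError):
            simplify_scanpath(make_scanpath([(100, 100)]))


class TestAlignment:
    def test_identical_sequences_align_on_diagonal(self):
        rng = np.random.default_rng(7)
        u = scanpath_to_vectors(random_scanpath(rng, 8))
        path = align_vectors(u, u)
        assert path == [(i, i) for i in range(len(u))]

    def test_singleton_absorbs_everything(self):
        rng = np.random.default_rng(8)
        u = scanpath_to_vectors(random_scanpath(rng, 6))
        path = align_vectors(u[:1], u)
        assert path == [(0, j) for j in range(len(u))]

    @pytest.mark.parametrize("seed", range(8))
    def test_cost_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(300 + seed)
        nu, nv = rng.integers(2, 7, size=2)
        u = scanpath_to_vectors(random_scanpath(rng, int(nu) + 1))
        v = scanpath_to_vectors(random_scanpath(rng, int(nv) + 1))
        diffs = [[math.hypot(a.dx - b.dx, a.dy - b.dy) for b in v] for a in u]
        path = align_vectors(u, v)
        cost = sum(diffs[i][j] for i, j in path)
        assert cost == pytest.approx(oracle_alignment_cost(diffs))

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            align_vectors([], [])


class TestSimilarityProfile:
    def test_identical_scanpaths_score_one_everywhere(self):
        rng = np.random.default_rng(9)
        sp = random_scanpath(rng, 10)
        profile = similarity_profile(sp, sp)
        assert all(v == pytest.approx(1.0) for v in profile.as_dict().values())

    def test_translation_only_degrades_position(self):
        pos = np.array([(300.0, 300.0), (900.0, 350.0), (600.0, 800.0), (1200.0, 700.0)])
        durations = [400, 350, 500, 300]
        a = make_scanpath(pos, durations)
        b = make_scanpath(pos + np.array([250.0, 120.0]), durations)
        p = similarity_profile(a, b)
        assert p.shape == pytest.approx(1.0)
        assert p.length == pytest.approx(1.0)
        assert p.direction == pytest.approx(1.0)
        assert p.duration == pytest.approx(1.0)
        assert p.position < 1.0

    def test_orthogonal_equal_saccades_halve_direction(self):
        a = make_scanpath([(400, 400), (1000, 400)], durations=[300, 300])
        b = make_scanpath([(400, 400), (400, 1000)], durations=[300, 300])
        p = similarity_profile(a, b)
        assert p.direction == pytest.approx(0.5)
        assert p.length == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(400 + seed)
        a, b = random_scanpath(rng, 9), random_scanpath(rng, 12)
        pab = similarity_profile(a, b)
        pba = similarity_profile(b, a)
        for dim in DIMENSIONS:
            va, vb = getattr(pab, dim), getattr(pba, dim)
            assert va == pytest.approx(vb)
            assert 0.0 <= va <= 1.0

    def test_position_similarity_degrades_with_noise_magnitude(self):
        rng = np.random.default_rng(13)
        pos = rng.uniform([300, 300], [1600, 800], size=(12, 2))
        durations = rng.uniform(150, 450, 12)
        a = make_scanpath(pos, durations)
        scores = []
        for sigma in (5.0, 40.0, 160.0):
            vals = []
            for rep in range(12):
                noisy = pos + np.random.default_rng(1000 + rep).normal(0, sigma, pos.shape)
                noisy = np.clip(noisy, [0, 0], [1919, 1079])
                vals.append(similarity_profile(a, make_scanpath(noisy, durations), NO_SIMPLIFY).position)
            scores.append(np.mean(vals))
        assert scores[0] > scores[1] > scores[2]

    def test_requires_two_fixations_each(self):
        a = make_scanpath([(100, 100)])
        b = make_scanpath([(100, 100), (500, 500)])
        with pytest.raises(InputError):
            similarity_profile(a, b)
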