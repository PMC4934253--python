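import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from localpls import (
    GRCParams,
    MahalanobisParams,
    absolute_grc,
    angle_scores,
    euclidean_scores,
    mahalanobis_scores,
    rank_calibration,
    relative_grc,
    sgrc_scores,
)


def literal_sgrc(query, cal, theta=0.2, xi=0.5):
    """Independent literal transcription of the S-GRC definition (loops)."""
    query = np.asarray(query, float)
    cal = np.asarray(cal, float)
    m_c, n = cal.shape

    def seq_sum(x):
        return sum(x[k] for k in range(n - 1)) + 0.5 * x[n - 1]

    out = np.zeros(m_c)
    for j in range(m_c):
        si = abs(seq_sum(query))
        sj = abs(seq_sum(cal[j]))
        sij = abs(seq_sum(query - cal[j]))
        eps = (1 + si + sj) / (1 + si + sj + sij)
        gks = []
        for k in range(n):
            devs = [abs(cal[l, k] - query[k]) for l in range(m_c)]
            dmin, dmax = min(devs), max(devs)
            num = dmin + xi * dmax
            den = abs(cal[j, k] - query[k]) + xi * dmax
            gks.append(1.0 if den == 0.0 else num / den)
        gamma = float(np.mean(gks))
        out[j] = theta * eps + (1 - theta) * gamma
    return out


class TestAbsoluteDegree:
    def test_identical_spectra_give_one(self, rng):
        x = rng.uniform(0, 2, size=12)
        assert absolute_grc(x, x) == 1.0

    def test_hand_example(self):
        # s_i = 1.5, s_j = 0  ->  eps = 2.5 / 4
        assert absolute_grc([1.0, 1.0], [0.0, 0.0]) == pytest.approx(0.625, abs=1e-15)

    def test_symmetry(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=(2, 9))
            assert absolute_grc(a, b) == pytest.approx(absolute_grc(b, a), abs=1e-15)

    def test_length_validation(self):
        with pytest.raises(ValueError):
            absolute_grc([1.0, 2.0], [1.0])
        with pytest.raises(ValueError):
            absolute_grc([1.0], [1.0])


class TestRelativeDegree:
    def test_self_row_scores_one(self, rng):
        cal = rng.uniform(0, 1, size=(5, 7))
        assert relative_grc(cal[2], 2, cal) == pytest.approx(1.0, abs=1e-15)

    def test_hand_example(self):
        cal = np.array([[1.0, 1.0], [0.0, 0.0]])
        # gamma(k) = (0 + 0.5) / (1 + 0.5) at both wavelengths
        assert relative_grc(np.array([1.0, 1.0]), 1, cal, 0.5) == pytest.approx(
            1 / 3, abs=1e-15
        )

    def test_degenerate_ensemble_gives_one(self):
        cal = np.tile([0.4, 0.6, 0.2], (3, 1))
        assert relative_grc(cal[0], 1, cal) == pytest.approx(1.0)

    def test_empty_calibration_rejected(self):
        with pytest.raises(ValueError):
            relative_grc(np.array([1.0, 2.0]), 0, np.empty((0, 2)))


class TestSGRC:
    def test_verbatim_query_attains_maximal_score_one(self, rng):
        cal = rng.uniform(0, 2, size=(6, 10))
        scores = sgrc_scores(cal[3], cal)
        assert scores[3] == pytest.approx(1.0, abs=1e-12)
        assert np.argmax(scores) == 3

    def test_convex_combination_endpoints(self, rng):
        cal = rng.uniform(0, 1, size=(4, 6))
        q = rng.uniform(0, 1, size=6)
        full_abs = sgrc_scores(q, cal, GRCParams(theta=1.0))
        full_rel = sgrc_scores(q, cal, GRCParams(theta=0.0))
        expect_abs = [absolute_grc(q, row) for row in cal]
        expect_rel = [relative_grc(q, j, cal) for j in range(4)]
        np.testing.assert_allclose(full_abs, expect_abs, atol=1e-14)
        np.testing.assert_allclose(full_rel, expect_rel, atol=1e-14)

    def test_hand_example(self):
        cal = np.array([[1.0, 1.0], [0.0, 0.0]])
        scores = sgrc_scores(np.array([1.0, 1.0]), cal)
        np.testing.assert_allclose(
            scores, [1.0, 0.2 * 0.625 + 0.8 / 3], atol=1e-12
        )

    def test_matches_literal_transcription_on_200_instances(self, rng):
        # optimized implementation vs independent loop transcription
        worst = 0.0
        for _ in range(200):
            n = int(rng.integers(2, 21))
            m_c = int(rng.integers(1, 11))
            cal = rng.uniform(0, 2, size=(m_c, n))
            q = rng.uniform(0, 2, size=n)
            got = sgrc_scores(q, cal)
            want = literal_sgrc(q, cal)
            worst = max(worst, float(np.abs(got - want).max()))
        assert worst <= 1e-10

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_scores_lie_in_unit_interval(self, seed):
        r = np.random.default_rng(seed)
        cal = r.uniform(0, 3, size=(int(r.integers(1, 8)), int(r.integers(2, 12))))
        q = r.uniform(0, 3, size=cal.shape[1])
        scores = sgrc_scores(q, cal)
        assert np.all(scores > 0) and np.all(scores <= 1 + 1e-12)

    def test_not_symmetric_in_general(self):
        # gamma depends on the calibration ensemble, so swapping the roles of
        # query and calibration row changes the score
        cal = np.array([[3.2, 1.3], [0.2, 0.1], [4.1, 4.6]])
        q = np.array([3.0, 3.6])
        forward = sgrc_scores(q, cal)[1]
        swapped_cal = cal.copy()
        swapped_cal[1] = q
        backward = sgrc_scores(cal[1], swapped_cal)[1]
        assert forward != pytest.approx(backward, abs=1e-6)


class TestComparators:
    def test_identical_spectra_zero_distance(self, rng):
        cal = rng.uniform(0.1, 1, size=(4, 6))
        assert euclidean_scores(cal[1], cal)[1] == 0.0
        assert angle_scores(cal[1], cal)[1] == pytest.approx(0.0, abs=1e-7)

    def test_three_four_five(self):
        assert euclidean_scores(np.array([3.0, 4.0]), np.array([[0.0, 0.0]]))[0] == 5.0

    def test_orthogonal_support_is_right_angle(self):
        cal = np.array([[0.0, 0.0, 1.0, 2.0]])
        q = np.array([1.0, 2.0, 0.0, 0.0])
        assert angle_scores(q, cal)[0] == pytest.approx(np.pi / 2)

    def test_zero_norm_angle_rejected(self):
        with pytest.raises(ValueError):
            angle_scores(np.zeros(3), np.ones((2, 3)))

    def test_mahalanobis_self_distance_zero(self, rng):
        cal = rng.normal(size=(10, 6))
        d = mahalanobis_scores(cal[4], cal, MahalanobisParams(2))
        assert d[4] == pytest.approx(0.0, abs=1e-8)

    def test_mahalanobis_quadratic_form_oracle(self):
        # diagonal COV = diag(4, 1), score offset (2, 1) -> MD^2 = 1 + 1
        diff = np.array([2.0, 1.0])
        cov = np.diag([4.0, 1.0])
        md2 = diff @ np.linalg.solve(cov, diff)
        assert md2 == pytest.approx(2.0)

    def test_mahalanobis_rotation_invariance(self, rng):
        cal = rng.normal(size=(8, 5))
        q = rng.normal(size=5)
        qmat, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        params = MahalanobisParams(n_scores=5)
        d1 = mahalanobis_scores(q, cal, params)
        d2 = mahalanobis_scores(q @ qmat, cal @ qmat, params)
        np.testing.assert_allclose(d1, d2, atol=1e-8)

    def test_mahalanobis_needs_enough_samples(self, rng):
        with pytest.raises(ValueError):
            mahalanobis_scores(rng.normal(size=4), rng.normal(size=(2, 4)), MahalanobisParams(2))


class TestRanking:
    def test_descending_with_index_tiebreak(self):
        r = rank_calibration(np.array([0.3, 0.9, 0.9]), "sgrc")
        np.testing.assert_array_equal(r.order, [1, 2, 0])

    def test_all_equal_scores_identity_order(self):
        r = rank_calibration(np.full(4, 0.5), "sgrc")
        np.testing.assert_array_equal(r.order, np.arange(4))

    def test_distance_ranking_matches_negation(self, rng):
        d = rng.uniform(0, 5, size=7)
        r = rank_calibration(d, "euclidean")
        np.testing.assert_array_equal(r.order, np.argsort(d, kind="stable"))
        assert np.all(np.diff(r.scores) <= 1e-12)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            rank_calibration(np.array([0.1, np.nan]), "sgrc")

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            rank_calibration(np.array([0.1]), "cosine")

    def test_export_table_shape(self):
        r = rank_calibration(np.array([0.2, 0.8, 0.5]), "sgrc", query_id="q1")
        frame = r.to_frame(calibration_ids=["a", "b", "c"])
        assert list(frame.columns) == ["query_id", "calibration_id", "method", "score", "rank"]
        assert list(frame["calibration_id"]) == ["b", "c", "a"]
        assert list(frame["rank"]) == [1, 2, 3]
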