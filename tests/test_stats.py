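"""Statistical battery vs exhaustive enumeration oracles on small samples."""

import itertools
import math

import numpy as np
import pytest

from phostim import stats_report as sr
from phostim.cohort_synthesis import load_fixtures


def manual_ranks(a):
    """Average ranks computed from scratch (independent of scipy)."""
    a = np.asarray(a, float)
    order = np.argsort(a, kind="stable")
    ranks = np.empty(len(a))
    i = 0
    while i < len(a):
        j = i
        while j + 1 < len(a) and a[order[j + 1]] == a[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


class TestSpearman:
    def test_perfect_and_reversed(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0])
        r1 = sr.spearman(x, x)
        assert r1.estimates["r_s"] == pytest.approx(1.0)
        r2 = sr.spearman(x, -x)
        assert r2.estimates["r_s"] == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            sr.spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_exact_p_matches_full_permutation_oracle_with_ties(self):
        """Median thresholds vs right-occipital densities: 7 tied pairs."""
        t2 = load_fixtures().table2
        x = t2["median_pt_uA"].to_numpy(float)  # ties: 125, 125 and 175, 175
        y = t2["right_oc"].to_numpy(float)
        res = sr.spearman(x, y, sided="greater")

        rx, ry = manual_ranks(x), manual_ranks(y)
        rs_obs = np.corrcoef(rx, ry)[0, 1]
        assert res.estimates["r_s"] == pytest.approx(rs_obs)
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if np.corrcoef(rx, perm)[0, 1] >= rs_obs - 1e-12:
                count += 1
        assert res.p == pytest.approx(count / total)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        a = sr.spearman(x, y)
        b = sr.spearman(np.exp(x), y**3)
        assert a.estimates["r_s"] == pytest.approx(b.estimates["r_s"])
        assert a.p == pytest.approx(b.p)


class TestPearson:
    def test_collinear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = sr.pearson_regression(x, 2 * x + 1)
        assert res.estimates["r2"] == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            res = sr.pearson_regression(x, y)
            # brute-force least squares via the normal equations
            A = np.stack([x, np.ones_like(x)], axis=1)
            slope, intercept = np.linalg.solve(A.T @ A, A.T @ y)
            assert res.estimates["slope"] == pytest.approx(slope)
            assert res.estimates["intercept"] == pytest.approx(intercept)
            r_direct = float(
                ((x - x.mean()) @ (y - y.mean()))
                / math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
            )
            assert res.estimates["r"] == pytest.approx(r_direct)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            sr.pearson_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestFriedman:
    def test_identical_columns_statistic_zero(self):
        X = np.tile(np.array([[3.0, 3.0, 3.0]]), (5, 1))
        res = sr.friedman(X)
        assert res.statistic == 0.0

    def test_hand_ranked_example(self):
        # ranks per row: [1,2,3], [1,2,3], [2,1,3] -> column sums 4, 5, 9
        X = np.array([[10, 20, 30], [1, 2, 3], [5, 4, 6]], dtype=float)
        n, k = X.shape
        col_sums = np.array([4.0, 5.0, 9.0])
        expected = (
            12.0 / (n * k * (k + 1)) * float((col_sums**2).sum()) - 3 * n * (k + 1)
        )
        res = sr.friedman(X)
        assert res.statistic == pytest.approx(expected)

    def test_exact_p_matches_within_row_permutation_oracle(self):
        X = np.array(
            [[75, 100, 150], [100, 125, 125], [50, 150, 100], [75, 75, 125]],
            dtype=float,
        )
        res = sr.friedman(X, exact=True)
        # independent oracle: enumerate all (3!)^4 orderings, manual ranks
        n, k = X.shape

        def stat(mat):
            ranks = np.vstack([manual_ranks(row) for row in mat])
            col = ranks.sum(axis=0)
            num = float(((col - n * (k + 1) / 2.0) ** 2).sum())
            tie = sum(
                float((c**3 - c).sum())
                for c in (
                    np.unique(row, return_counts=True)[1] for row in mat
                )
            )
            denom = n * k * (k + 1) / 12.0 - tie / (12.0 * (k - 1))
            return num / denom if denom > 0 else 0.0

        obs = stat(X)
        assert res.statistic == pytest.approx(obs)
        perms = list(itertools.permutations(range(k)))
        count = total = 0
        for combo in itertools.product(perms, repeat=n):
            mat = np.vstack([X[i, list(p)] for i, p in enumerate(combo)])
            total += 1
            if stat(mat) >= obs - 1e-12:
                count += 1
        assert res.p == pytest.approx(count / total)

    def test_missing_cells_rejected(self):
        X = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="missing"):
            sr.friedman(X)


class TestWilcoxon:
    def test_shifted_column_exact_p_matches_sign_enumeration(self):
        x = np.arange(1.0, 11.0)
        y = x + 25.0
        res = sr.wilcoxon_signed_rank(y, x, sided="greater")
        # oracle: all 2^10 sign assignments of the |d| ranks
        d = y - x
        ranks = manual_ranks(np.abs(d))
        w_obs = ranks[d > 0].sum()
        count = 0
        for signs in itertools.product([0, 1], repeat=10):
            w = sum(r for r, s in zip(ranks, signs) if s)
            if w >= w_obs - 1e-12:
                count += 1
        assert res.p == pytest.approx(count / 2**10)
        assert res.p == pytest.approx(1.0 / 1024.0)

    def test_exact_p_with_tied_magnitudes(self):
        rng = np.random.default_rng(11)
        d = rng.choice([-50.0, -25.0, 25.0, 50.0, 75.0], size=9)
        res = sr.wilcoxon_signed_rank(d, np.zeros(9), sided="two-sided")
        ranks = manual_ranks(np.abs(d))
        w_obs = ranks[d > 0].sum()
        ws = [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([0, 1], repeat=9)
        ]
        ws = np.array(ws)
        p_ge = float((ws >= w_obs - 1e-12).mean())
        p_le = float((ws <= w_obs + 1e-12).mean())
        assert res.p == pytest.approx(min(1.0, 2 * min(p_ge, p_le)))

    def test_identical_columns_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            sr.wilcoxon_signed_rank(np.ones(5), np.ones(5))

    def test_bonferroni_correction_by_definition(self):
        import pandas as pd

        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(12, 4)), columns=list("abcd"))
        results = sr.wilcoxon_pairwise(df)
        assert len(results) == 6
        for r in results:
            assert r.m_comparisons == 6
            assert r.p_corrected == pytest.approx(min(1.0, 6 * r.p))


class TestMannWhitney:
    def test_complete_separation(self):
        res = sr.mann_whitney([1.0, 2.0], [3.0, 4.0], sided="two-sided")
        assert res.statistic == 0.0

    def test_mirrored_samples_give_central_u(self):
        a = [1.0, 4.0, 6.0, 9.0]
        b = [2.0, 3.0, 7.0, 8.0]
        res = sr.mann_whitney(a, b)
        assert res.statistic == len(a) * len(b) / 2.0

    def test_exact_p_matches_labeling_enumeration(self):
        a = np.array([1.2, 3.4, 5.1, 2.2])
        b = np.array([4.0, 6.5, 7.1, 2.9])
        res = sr.mann_whitney(a, b, sided="two-sided")
        pooled = np.concatenate([a, b])
        n = len(a)

        def u_of(idx_a):
            xs = pooled[list(idx_a)]
            ys = np.delete(pooled, list(idx_a))
            return sum((x > y) + 0.5 * (x == y) for x in xs for y in ys)

        u_obs = u_of(range(n))
        us = np.array(
            [u_of(c) for c in itertools.combinations(range(8), n)]
        )
        mu = len(a) * len(b) / 2.0
        p_two = float((np.abs(us - mu) >= abs(u_obs - mu) - 1e-12).mean())
        assert res.p == pytest.approx(p_two)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            sr.mann_whitney([], [1.0])


class TestDistanceAnalysis:
    def _fake_montage(self, pa, pb):
        import types

        return types.SimpleNamespace(
            patches=[
                types.SimpleNamespace(centroid_mm=np.asarray(pa, float)),
                types.SimpleNamespace(centroid_mm=np.asarray(pb, float)),
            ]
        )

    def test_exclusion_and_positive_eye_correlation(self, small_head):
        eye = small_head.landmarks["right_eye_center"]
        montages, pts = {}, {}
        rng = np.random.default_rng(0)
        for i, name in enumerate(["Fp2-So", "F7-F8", "Fp2-Cz", "Fp2-O2", "So-rS"]):
            offset = 20.0 + 15.0 * i
            montages[name] = self._fake_montage(
                eye + [offset, 0, 0], eye + [0, offset, 0]
            )
            pts[name] = 75.0 + 30.0 * i + rng.normal(0, 1)
        oc_roi = np.array([0])  # any voxel: OC distance unused in the sign check
        out = sr.distance_analysis(small_head, montages, pts, oc_roi=oc_roi)
        assert out["eye_distance"].estimates["slope"] > 0
        prov = out["eye_distance"].provenance
        assert "So-rS" not in prov

    def test_equal_distances_degenerate(self, small_head):
        eye = small_head.landmarks["right_eye_center"]
        montages = {
            name: self._fake_montage(eye + [10, 0, 0], eye + [0, 10, 0])
            for name in ["a", "b", "c", "d"]
        }
        pts = {name: 100.0 + i for i, name in enumerate(montages)}
        with pytest.raises(ValueError, match="zero-variance"):
            sr.distance_analysis(
                small_head, montages, pts, oc_roi=np.array([0]), exclude=()
            )

    def test_too_few_montages_rejected(self, small_head):
        montages = {"a": None, "So-rS": None}
        with pytest.raises(ValueError, match="fewer than 3"):
            sr.distance_analysis(
                small_head, montages, {"a": 1.0, "So-rS": 2.0},
                oc_roi=np.array([0]),
            )
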