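"""Rank-test battery against brute-force oracles, summaries and PCA."""

import itertools
import math
import random

import numpy as np
import pytest
from scipy import stats as sps

from flavorisk.core import ContentRecord, Part, Status
from flavorisk.stats import (
    content_matrix,
    dunn_bonferroni,
    kruskal_wallis,
    mann_whitney,
    pca_scores,
    shapiro_wilk,
    summarize,
)

# ---------------------------------------------------------------- oracles


def _ranks(values):
    """Average ranks computed by explicit sorting (pure python)."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def _kw_oracle(groups):
    """H from the rank-sum definition with tie correction, by hand."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = _ranks(pooled)
    h = 0.0
    pos = 0
    for g in groups:
        rsum = sum(ranks[pos: pos + len(g)])
        h += rsum * rsum / len(g)
        pos += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    ties = {}
    for v in pooled:
        ties[v] = ties.get(v, 0) + 1
    correction = 1 - sum(t**3 - t for t in ties.values()) / (n**3 - n)
    return h / correction if correction > 0 else 0.0


def _mwu_exact_oracle(x, y):
    """Exact two-sided p by enumerating every assignment of pooled ranks."""
    n, m = len(x), len(y)
    pooled = sorted(x + y)
    u_obs = sum(1 for xi in x for yj in y if xi > yj) + 0.5 * sum(
        1 for xi in x for yj in y if xi == yj
    )
    stat_obs = min(u_obs, n * m - u_obs)
    count = total = 0
    for idx in itertools.combinations(range(n + m), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n + m) if i not in idx]
        u = sum(1 for xi in xs for yj in ys if xi > yj)
        total += 1
        if min(u, n * m - u) <= stat_obs + 1e-12:
            count += 1
    return u_obs, count / total


def _mean_rank_diff_oracle(groups, i, j):
    pooled = [v for g in groups for v in g]
    ranks = _ranks(pooled)
    bounds = [0]
    for g in groups:
        bounds.append(bounds[-1] + len(g))
    mr = [
        sum(ranks[bounds[k]: bounds[k + 1]]) / len(groups[k])
        for k in range(len(groups))
    ]
    return mr[i] - mr[j]


# ---------------------------------------------------------------- summaries


def _rec(cig, part, content, status=Status.QUANTIFIED, compound="Menthol"):
    return ContentRecord(
        cigarette_id=cig,
        has_capsule=False,
        part=Part(part),
        compound=compound,
        concentration_ng_per_g=content * 4000,
        content_ug_per_cigarette=content,
        status=status,
    )


class TestSummarize:
    def test_detected_only_statistics(self):
        rows = summarize(
            [
                _rec("A", Part.TOBACCO, 1.0),
                _rec("B", Part.TOBACCO, 2.0),
                _rec("C", Part.TOBACCO, 0.0, Status.NOT_DETECTED),
            ]
        )
        (row,) = rows
        assert row.n_detected == 2
        assert row.mean == pytest.approx(1.5)
        assert row.sd == pytest.approx(math.sqrt(0.5), abs=1e-9)
        assert row.min == 1.0 and row.max == 2.0

    def test_all_nd_renders_absent(self):
        rows = summarize([_rec("A", Part.TOBACCO, 0.0, Status.NOT_DETECTED)])
        assert rows[0].n_detected == 0
        assert rows[0].mean is None and rows[0].sd is None

    def test_singleton_sd_policy(self):
        recs = [_rec("A", Part.TOBACCO, 2.0)]
        assert summarize(recs)[0].sd == 0.0
        assert summarize(recs, sd_for_singleton=False)[0].sd is None


# ---------------------------------------------------------------- rank tests


class TestKruskalWallis:
    def test_hand_computed_h(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.statistic == pytest.approx(7.2)
        assert res.df == 2
        assert res.p_value == pytest.approx(
            float(sps.chi2.sf(7.2, 2)), abs=1e-12
        )

    def test_all_equal_gives_zero_h(self):
        res = kruskal_wallis([[5, 5], [5, 5, 5]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            kruskal_wallis([[1, 2], []])

    def test_matches_rank_formula_oracle_on_small_instances(self):
        rng = random.Random(11)
        for _ in range(200):
            k = rng.randint(2, 4)
            sizes = [rng.randint(1, 4) for _ in range(k)]
            if sum(sizes) < 3 or sum(sizes) > 10:
                continue
            groups = [
                [rng.choice([1, 2, 3, 4, 5, 2.5]) for _ in range(s)]
                for s in sizes
            ]
            pooled = [v for g in groups for v in g]
            if len(set(pooled)) == 1:
                continue
            assert kruskal_wallis(groups).statistic == pytest.approx(
                _kw_oracle(groups), abs=1e-8
            )

    def test_invariant_under_monotone_transform(self):
        rng = random.Random(5)
        groups = [[rng.random() for _ in range(6)] for _ in range(3)]
        transformed = [[math.exp(3 * v) for v in g] for g in groups]
        assert kruskal_wallis(groups).statistic == pytest.approx(
            kruskal_wallis(transformed).statistic, abs=1e-12
        )

    def test_two_group_h_equals_squared_mwu_z(self):
        """On tie-free data, H for two groups equals the squared normal
        z of the Mann–Whitney U (no continuity correction)."""
        rng = random.Random(3)
        x = [rng.random() for _ in range(9)]
        y = [rng.random() for _ in range(12)]
        h = kruskal_wallis([x, y]).statistic
        n, m = len(x), len(y)
        u = sum(1 for xi in x for yj in y if xi > yj)
        z = (u - n * m / 2) / math.sqrt(n * m * (n + m + 1) / 12)
        assert h == pytest.approx(z * z, abs=1e-10)


class TestDunnBonferroni:
    def test_mean_rank_difference_by_hand(self):
        pw = dunn_bonferroni([[1, 2, 3], [4, 5, 6], [7, 8, 9]],
                             ["g1", "g2", "g3"])
        first_vs_third = [p for p in pw if p.group_b == "g3" and p.group_a == "g1"]
        assert first_vs_third[0].mean_rank_difference == pytest.approx(-6.0)
        assert len(pw) == 3

    def test_bonferroni_never_below_raw_p(self):
        rng = random.Random(2)
        groups = [[rng.gauss(0, 1) for _ in range(8)] for _ in range(4)]
        for p in dunn_bonferroni(groups):
            assert p.adjusted_p >= p.p_value
            assert p.adjusted_p <= 1.0

    def test_mean_rank_differences_match_oracle_on_random_instances(self):
        rng = random.Random(13)
        for _ in range(50):
            k = rng.randint(3, 5)
            groups = [
                [rng.choice([1, 2, 3, 4, 5, 6, 2.0]) for _ in range(rng.randint(2, 6))]
                for _ in range(k)
            ]
            pw = dunn_bonferroni(groups)
            idx = 0
            for i in range(k):
                for j in range(i + 1, k):
                    assert pw[idx].mean_rank_difference == pytest.approx(
                        _mean_rank_diff_oracle(groups, i, j), abs=1e-8
                    )
                    idx += 1

    def test_z_consistent_with_two_group_kruskal(self):
        """With three tie-free groups of which two are compared, the Dunn z
        uses the pooled-rank variance; cross-check p against the normal CDF."""
        rng = random.Random(8)
        groups = [[rng.random() for _ in range(7)] for _ in range(3)]
        for p in dunn_bonferroni(groups):
            assert p.p_value == pytest.approx(
                2 * sps.norm.sf(abs(p.z)), abs=1e-12
            )

    def test_needs_three_groups(self):
        with pytest.raises(ValueError):
            dunn_bonferroni([[1, 2], [3, 4]])


class TestMannWhitney:
    def test_exact_small_sample(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1 / 3)

    def test_identical_samples_give_half_nm(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(4.5)

    def test_matches_exact_enumeration_on_small_instances(self):
        rng = random.Random(17)
        for _ in range(30):
            n = rng.randint(1, 5)
            m = rng.randint(1, min(9 - n, 5))
            x = [rng.random() for _ in range(n)]
            y = [rng.random() for _ in range(m)]
            u_oracle, p_oracle = _mwu_exact_oracle(x, y)
            res = mann_whitney(x, y)
            assert res.statistic == pytest.approx(u_oracle, abs=1e-12)
            assert res.p_value == pytest.approx(p_oracle, abs=1e-8)

    def test_invariant_under_monotone_transform(self):
        rng = random.Random(23)
        x = [rng.random() for _ in range(12)]
        y = [rng.random() for _ in range(15)]
        a = mann_whitney(x, y)
        b = mann_whitney([math.log(v) for v in x], [math.log(v) for v in y])
        assert a.statistic == b.statistic
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)


class TestShapiroGateway:
    def test_passthrough_matches_scipy(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=30)
        res = shapiro_wilk(v)
        stat, p = sps.shapiro(v)
        assert res.statistic == pytest.approx(float(stat))
        assert res.p_value == pytest.approx(float(p))

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])


# ---------------------------------------------------------------- PCA


class TestPca:
    def test_rank_one_data_explained_by_pc1(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.outer([1, 2, 3, 5], base)
        res = pca_scores(X, n_components=2)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 4))
        res = pca_scores(X, n_components=4)
        mu, sd = X.mean(0), X.std(0)
        Xs = (X - mu) / sd
        recon = res.scores @ res.loadings.T
        assert np.allclose(recon + Xs.mean(0), Xs, atol=1e-8)

    def test_capsule_classes_separate_on_scores(self):
        """Capsule and non-capsule cigarettes form separable fingerprints."""
        from sklearn.metrics import silhouette_score

        from flavorisk import (
            generate_study,
            load_compound_table,
            quantify,
            substitute_censored,
        )
        from flavorisk.synthetic import study_records

        compounds = load_compound_table()
        df = generate_study(seed=12, compounds=compounds)
        content = quantify(study_records(df, compounds), compounds)
        X, ids, names, flags = content_matrix(
            substitute_censored(content, compounds).records
        )
        res = pca_scores(X, n_components=2, row_ids=ids, columns=names)
        score = silhouette_score(res.scores[:, :1], flags)
        assert score > 0

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="ND"):
            pca_scores(np.array([[1.0, np.nan], [2.0, 3.0]]))
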