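import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from scfa_resilience import (
    bh_adjust,
    compare_lifestyles,
    comparison_table,
    dunn_posthoc,
    kruskal_wallis,
)

# ---------------------------------------------------------------------------
# Independent oracles (coded directly from the textbook formulas)
# ---------------------------------------------------------------------------


def oracle_h(groups):
    """Mid-rank H with tie correction, written independently."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(n)
    sorted_vals = pooled[order]
    i = 0
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # mid-rank of the tie run
        i = j
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        start += len(g)
        h += len(g) * (r.mean() - (n + 1) / 2.0) ** 2
    h *= 12.0 / (n * (n + 1))
    ties = sum(
        c**3 - c for c in np.unique(pooled, return_counts=True)[1]
    )
    denom = 1 - ties / (n**3 - n)
    return 0.0 if denom <= 0 else h / denom


def oracle_exact_p(groups):
    """Exact permutation p by enumerating every ordering of the pooled data."""
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    h_obs = oracle_h(groups)
    count = 0
    extreme = 0
    for perm in itertools.permutations(range(len(pooled))):
        parts = []
        start = 0
        for s in sizes:
            parts.append(pooled[list(perm[start : start + s])])
            start += s
        count += 1
        if oracle_h(parts) >= h_obs - 1e-12:
            extreme += 1
    return extreme / count


def oracle_dunn(groups):
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = scipy.stats.rankdata(pooled)
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        start += len(g)
    ties = sum(c**3 - c for c in np.unique(pooled, return_counts=True)[1])
    var = n * (n + 1) / 12.0 - ties / (12.0 * (n - 1))
    out = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = np.sqrt(var * (1 / len(groups[i]) + 1 / len(groups[j])))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        out.append((z, min(1.0, 2 * scipy.stats.norm.sf(abs(z)))))
    return out


def oracle_bh(pvals):
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, pvals[idx] * m / rank_from_top)
        adjusted[idx] = running_min
    return adjusted


# ---------------------------------------------------------------------------


class TestKruskalWallis:
    def test_identical_groups(self):
        h, p = kruskal_wallis([[1.0, 1.0, 1.0], [1.0, 1.0]])
        assert (h, p) == (0.0, 1.0)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])

    def test_separated_groups_exact_permutation(self):
        groups = [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]
        h, p = kruskal_wallis(groups, method="exact")
        assert h == pytest.approx(oracle_h(groups), rel=1e-12)
        # perfect separation: 2 of the C(6,3)=20 assignments are as extreme
        assert p == pytest.approx(2 / 20)
        assert p == pytest.approx(oracle_exact_p(groups), rel=1e-12)

    def test_exact_matches_enumeration_oracle_with_ties(self, rng):
        for sizes in [(2, 3), (3, 3), (2, 2, 2), (2, 2, 3)]:
            data = [rng.integers(0, 4, s).astype(float) for s in sizes]
            if np.all(np.concatenate(data) == data[0][0]):
                continue
            h, p = kruskal_wallis(data, method="exact")
            assert h == pytest.approx(oracle_h(data), rel=1e-12)
            assert p == pytest.approx(oracle_exact_p(data), rel=1e-12)

    def test_chi2_h_matches_direct_formula_with_ties(self, rng):
        for _ in range(25):
            data = [rng.integers(0, 6, rng.integers(4, 9)).astype(float)
                    for _ in range(3)]
            if np.all(np.concatenate(data) == np.concatenate(data)[0]):
                continue
            h, p = kruskal_wallis(data)
            assert h == pytest.approx(oracle_h(data), rel=1e-10)
            assert p == pytest.approx(
                scipy.stats.chi2.sf(h, 2), rel=1e-10
            )

    def test_invariant_under_monotone_transform(self, rng):
        data = [rng.normal(size=12), rng.normal(1, 1, 10), rng.normal(2, 1, 8)]
        h1, p1 = kruskal_wallis(data)
        h2, p2 = kruskal_wallis([np.exp(3 * d) for d in data])
        assert h1 == pytest.approx(h2, rel=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_two_groups_match_tie_corrected_rank_sum_chi2_form(self, rng):
        # with k = 2 the KW statistic is the square of the tie-corrected
        # normal rank-sum statistic, referred to chi-squared with 1 df
        a, b = rng.integers(0, 8, 10).astype(float), rng.integers(0, 8, 12).astype(float)
        h, p = kruskal_wallis([a, b])
        (z, _), = oracle_dunn([a, b])
        assert h == pytest.approx(z**2, rel=1e-10)
        assert p == pytest.approx(scipy.stats.chi2.sf(z**2, 1), rel=1e-10)


class TestDunnPosthoc:
    def test_identical_groups(self):
        res = dunn_posthoc([[2.0, 2.0], [2.0, 2.0, 2.0]])
        assert res.loc[0, "z"] == 0.0
        assert res.loc[0, "p_raw"] == 1.0

    def test_label_swap_negates_z_preserves_p(self, rng):
        a, b, c = (rng.normal(size=7) for _ in range(3))
        res1 = dunn_posthoc([a, b, c], labels=["A", "B", "C"])
        res2 = dunn_posthoc([b, a, c], labels=["B", "A", "C"])
        z_ab = res1.set_index(["group_a", "group_b"]).loc[("A", "B"), "z"]
        z_ba = res2.set_index(["group_a", "group_b"]).loc[("B", "A"), "z"]
        assert z_ab == pytest.approx(-z_ba, rel=1e-12)
        p_ab = res1.set_index(["group_a", "group_b"]).loc[("A", "B"), "p_raw"]
        p_ba = res2.set_index(["group_a", "group_b"]).loc[("B", "A"), "p_raw"]
        assert p_ab == pytest.approx(p_ba, rel=1e-12)

    def test_matches_direct_formula_oracle(self, rng):
        for _ in range(60):
            k = rng.integers(2, 5)
            data = [
                rng.integers(0, 6, rng.integers(3, 8)).astype(float)
                for _ in range(k)
            ]
            res = dunn_posthoc(data)
            expected = oracle_dunn(data)
            for row, (z, p) in zip(res.itertuples(), expected):
                assert row.z == pytest.approx(z, abs=1e-12)
                assert row.p_raw == pytest.approx(p, abs=1e-12)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_hand_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_matches_step_up_oracle(self, rng):
        for _ in range(100):
            p = rng.uniform(0, 1, rng.integers(1, 15))
            np.testing.assert_allclose(bh_adjust(p), oracle_bh(p), atol=1e-12)

    def test_output_dominates_input_and_preserves_order(self, rng):
        p = rng.uniform(0, 1, 20)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0).all()
        # adjusted values are ordered like the raw values
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCompareLifestyles:
    def _metrics(self, values_by_lifestyle, metric="hill_q1"):
        rows = []
        meta = []
        for lifestyle, values in values_by_lifestyle.items():
            for i, v in enumerate(values):
                sid = f"{lifestyle}_{i}"
                rows.append(
                    {
                        "sample_id": sid,
                        "group_name": "butyrate",
                        "level": "genus",
                        "metric": metric,
                        "value": v,
                    }
                )
                meta.append(
                    {"sample_id": sid, "lifestyle_group": lifestyle,
                     "dataset_label": ""}
                )
        return pd.DataFrame(rows), pd.DataFrame(meta)

    def test_identical_metric_gives_adjusted_p_of_one(self):
        metrics, meta = self._metrics(
            {"a": [1.0] * 5, "b": [1.0] * 5, "c": [1.0] * 5}
        )
        (res,) = compare_lifestyles(metrics, meta)
        assert res.p_omnibus == 1.0
        assert (res.pairwise["p_adj"] == 1.0).all()
        assert res.pairwise.shape[0] == 3  # all unordered pairs

    def test_missing_values_dropped_listwise_and_n_reported(self):
        metrics, meta = self._metrics(
            {"a": [1.0, 2.0, np.nan, 4.0], "b": [5.0, 6.0, 7.0]}
        )
        (res,) = compare_lifestyles(metrics, meta)
        assert res.per_group_n == {"a": 3, "b": 3}
        assert res.n_total == 6

    def test_global_fdr_scope_recorded_and_applied_across_families(self, rng):
        frames = []
        metas = []
        for metric in ("hill_q1", "hill_q2"):
            m, meta = self._metrics(
                {
                    "a": rng.normal(size=6).tolist(),
                    "b": rng.normal(2, 1, 6).tolist(),
                },
                metric=metric,
            )
            frames.append(m)
            metas.append(meta)
        metrics = pd.concat(frames, ignore_index=True)
        meta = metas[0]
        results = compare_lifestyles(metrics, meta, fdr_scope="global")
        all_raw = np.concatenate([r.pairwise["p_raw"] for r in results])
        all_adj = np.concatenate([r.pairwise["p_adj"] for r in results])
        np.testing.assert_allclose(all_adj, bh_adjust(all_raw), atol=1e-12)
        assert all(r.fdr_scope == "global" for r in results)

    def test_orphan_sample_rejected(self):
        metrics, meta = self._metrics({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        with pytest.raises(ValueError, match="metadata"):
            compare_lifestyles(metrics, meta.iloc[:1])

    def test_comparison_table_tidy_output(self):
        metrics, meta = self._metrics({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        results = compare_lifestyles(metrics, meta)
        tidy = comparison_table(results)
        assert {"metric", "gene_group", "level", "group_a", "group_b",
                "p_raw", "p_adj", "h_statistic", "p_omnibus",
                "fdr_scope"} <= set(tidy.columns)
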