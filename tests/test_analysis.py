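"""Expression catalogs, differential expression, co-expression, clustering,
and reference-gene stability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform

from boutiquenorm import (
    AnalysisConfig,
    DetectionCalls,
    SampleMeta,
    bh_qvalues,
    catalog_expression,
    cluster_expression,
    coexpression_screen,
    differential_expression,
    genorm_stability,
    venn_counts,
)
from boutiquenorm.errors import ValidationError

from conftest import make_expr, make_samples


def bh_oracle(p):
    """Brute-force BH step-up: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q_sorted = np.empty(m)
    running = np.inf
    for i in range(m - 1, -1, -1):
        running = min(running, p[order[i]] * m / (i + 1))
        q_sorted[i] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def tissue_samples(spec):
    """spec: dict tissue -> n replicates."""
    out = []
    for tissue, n in spec.items():
        for i in range(1, n + 1):
            out.append(SampleMeta(f"{tissue}_r{i}", tissue, tissue, tissue, i))
    return out


def calls_from_bool(expressed, samples, probesets):
    """Build DetectionCalls: True -> P with tiny p, False -> A with p=1."""
    arr = np.where(np.asarray(expressed), "P", "A")
    p = np.where(np.asarray(expressed), 0.001, 1.0)
    cols = [s.sample_id for s in samples]
    return DetectionCalls(
        calls=pd.DataFrame(arr, index=probesets, columns=cols),
        pvalues=pd.DataFrame(p, index=probesets, columns=cols),
    )


class TestCatalog:
    def test_two_of_three_rule(self):
        samples = tissue_samples({"leaf": 3})
        calls = calls_from_bool([[True, True, False]], samples, ["a"])
        cat = catalog_expression(calls, samples)
        assert bool(cat.flags.loc["a", "leaf"])

    def test_class_labels(self):
        samples = tissue_samples({"leaf": 3, "root": 3, "seed": 3})
        expressed = [
            [True] * 9,                                  # constitutive
            [True] * 3 + [False] * 6,                    # unique to leaf
            [True] * 3 + [True, True, False] + [False] * 3,  # leaf+root
            [False] * 9,                                 # not expressed
        ]
        calls = calls_from_bool(expressed, samples, ["c", "u", "m", "n"])
        cat = catalog_expression(calls, samples)
        assert cat.classes["c"] == "constitutive"
        assert cat.classes["u"] == "unique_to_one_tissue"
        assert cat.unique_tissue["u"] == "leaf"
        assert cat.classes["m"] == "multi_tissue"
        assert cat.classes["n"] == "not_expressed"

    def test_order_invariance_of_venn(self, rng):
        samples = tissue_samples({"t1": 3, "t2": 3, "t3": 3})
        ids = [f"p{i:02d}" for i in range(30)]
        expressed = rng.random((30, 9)) < 0.5
        calls = calls_from_bool(expressed, samples, ids)
        cat = catalog_expression(calls, samples)
        sets = {"A": ["t1"], "B": ["t2", "t3"]}
        counts = venn_counts(cat, sets)
        # permute probe sets
        perm = rng.permutation(30)
        calls2 = calls_from_bool(expressed[perm], samples,
                                 [ids[i] for i in perm])
        counts2 = venn_counts(catalog_expression(calls2, samples), sets)
        assert counts == counts2


class TestVenn:
    def _catalog(self, flags, tissues):
        samples = tissue_samples({t: 1 for t in tissues})
        cfg = AnalysisConfig(expressed_rule_min_present=1)
        calls = calls_from_bool(flags, samples, [f"g{i}" for i in range(len(flags))])
        return catalog_expression(calls, samples, cfg)

    def test_disjoint_sets(self):
        flags = [[True, False]] * 3 + [[False, True]] * 2
        cat = self._catalog(flags, ["t1", "t2"])
        counts = venn_counts(cat, {"A": ["t1"], "B": ["t2"]})
        assert counts == {("A",): 3, ("B",): 2, ("A", "B"): 0}
        assert sum(counts.values()) == 5

    def test_identical_sets(self):
        flags = [[True, True]] * 4
        cat = self._catalog(flags, ["t1", "t2"])
        counts = venn_counts(cat, {"A": ["t1"], "B": ["t2"]})
        assert counts == {("A",): 0, ("B",): 0, ("A", "B"): 4}

    def test_partition_property(self, rng):
        flags = rng.random((40, 3)) < 0.4
        cat = self._catalog(flags.tolist(), ["t1", "t2", "t3"])
        sets = {"A": ["t1"], "B": ["t2"], "C": ["t3"]}
        counts = venn_counts(cat, sets)
        union = int((cat.flags[["t1", "t2", "t3"]].any(axis=1)).sum())
        assert sum(counts.values()) == union

    def test_unknown_tissue_error(self):
        cat = self._catalog([[True]], ["t1"])
        with pytest.raises(ValidationError):
            venn_counts(cat, {"A": ["bogus"]})


class TestDifferentialExpression:
    def test_bh_hand_example(self):
        q = bh_qvalues(np.array([0.01, 0.02, 0.04, 0.5]))
        assert np.allclose(q, [0.04, 0.04, 0.04 * 4 / 3, 0.5])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000), st.integers(1, 200))
    def test_bh_matches_oracle(self, seed, m):
        p = np.random.default_rng(seed).uniform(0, 1, m)
        assert np.allclose(bh_qvalues(p), bh_oracle(p), atol=1e-12)

    def test_q_dominates_p(self, rng):
        p = rng.uniform(0, 1, 500)
        q = bh_qvalues(p)
        assert np.all(q >= p - 1e-15)

    def test_identical_groups_not_significant(self):
        samples = make_samples(3, group="a") + [
            SampleMeta(f"b_r{i}", "leaf", "b", "b", i) for i in (1, 2, 3)
        ]
        V = np.tile(np.array([[5.0], [7.0]]), (1, 6))
        expr = make_expr(V, ["x", "y"], samples)
        res = differential_expression(
            expr, {"a": expr.sample_ids[:3], "b": expr.sample_ids[3:]}
        )
        assert (res.table["pvalue"] == 1.0).all()
        assert not res.table["significant"].any()

    def test_null_calibration(self):
        rng = np.random.default_rng(99)
        n = 1000
        samples = make_samples(3, group="a") + [
            SampleMeta(f"b_r{i}", "leaf", "b", "b", i) for i in (1, 2, 3)
        ]
        V = rng.normal(8, 0.25, (n, 6))
        expr = make_expr(V, [f"p{i:04d}" for i in range(n)], samples)
        res = differential_expression(
            expr, {"a": expr.sample_ids[:3], "b": expr.sample_ids[3:]}
        )
        frac_raw = (res.table["pvalue"] < 0.05).mean()
        assert frac_raw == pytest.approx(0.05, abs=0.02)
        assert (res.table["qvalue"] < 0.05).mean() <= 0.005

    def test_anova_path(self, rng):
        samples = (
            make_samples(2, group="a")
            + [SampleMeta(f"b_r{i}", "x", "b", "b", i) for i in (1, 2)]
            + [SampleMeta(f"c_r{i}", "x", "c", "c", i) for i in (1, 2)]
        )
        V = rng.normal(8, 1, (20, 6))
        expr = make_expr(V, [f"p{i}" for i in range(20)], samples)
        design = {"a": expr.sample_ids[:2], "b": expr.sample_ids[2:4],
                  "c": expr.sample_ids[4:]}
        res = differential_expression(expr, design)
        assert set(res.group_means.columns) == {"a", "b", "c"}
        assert np.all((res.table["pvalue"] >= 0) & (res.table["pvalue"] <= 1))

    def test_small_group_rejected(self, rng):
        samples = make_samples(3)
        expr = make_expr(rng.normal(0, 1, (5, 3)), [f"p{i}" for i in range(5)],
                         samples)
        with pytest.raises(ValidationError):
            differential_expression(
                expr, {"a": expr.sample_ids[:1], "b": expr.sample_ids[1:]}
            )


class TestCoexpression:
    def test_sign_convention_and_oracle(self):
        samples = make_samples(4)
        seed = [1.0, 2.0, 3.0, 4.0]
        cand = [1.0, 2.0, 3.0, 5.0]
        anti = [-v for v in seed]
        expr = make_expr([seed, cand, anti], ["seed", "cand", "anti"], samples)
        out = coexpression_screen(expr, "seed")
        assert out.loc["seed", "r"] == pytest.approx(1.0)
        # direct Pearson formula oracle
        x, y = np.array(seed), np.array(cand)
        r_direct = (np.sum((x - x.mean()) * (y - y.mean()))
                    / np.sqrt(np.sum((x - x.mean()) ** 2)
                              * np.sum((y - y.mean()) ** 2)))
        assert out.loc["cand", "r"] == pytest.approx(r_direct, abs=1e-12)
        assert "anti" not in out.index  # r = -1 excluded by the r > 0 rule
        assert list(out["r"]) == sorted(out["r"], reverse=True)

    def test_zero_variance_seed_error(self):
        samples = make_samples(3)
        expr = make_expr([[1.0, 1.0, 1.0]], ["flat"], samples)
        with pytest.raises(ValidationError):
            coexpression_screen(expr, "flat")


def upgma_oracle(dist, ids):
    """Exhaustive UPGMA with lexicographic tie-breaking on member tuples."""
    clusters = {i: (ids[i],) for i in range(len(ids))}
    sizes = {i: 1 for i in range(len(ids))}
    d = {(i, j): dist[i, j] for i in range(len(ids)) for j in range(i + 1, len(ids))}
    merges = []
    nxt = len(ids)
    while len(clusters) > 1:
        items = sorted(clusters)
        best = None
        for ii, a in enumerate(items):
            for b in items[ii + 1:]:
                key = (min(a, b), max(a, b))
                cand = (d[key], tuple(sorted(clusters[a] + clusters[b])))
                if best is None or cand < best[0]:
                    best = (cand, a, b)
        (h, _), a, b = best
        ma, mb = clusters[a], clusters[b]
        merges.append((min(ma, mb), max(ma, mb), h))
        for c in clusters:
            if c in (a, b):
                continue
            key_a = (min(a, c), max(a, c))
            key_b = (min(b, c), max(b, c))
            d[(min(nxt, c), max(nxt, c))] = (
                sizes[a] * d[key_a] + sizes[b] * d[key_b]
            ) / (sizes[a] + sizes[b])
        clusters[nxt] = tuple(sorted(ma + mb))
        sizes[nxt] = sizes[a] + sizes[b]
        del clusters[a], clusters[b]
        nxt += 1
    return merges


class TestClustering:
    def test_identical_rows_merge_first_at_zero(self, rng):
        samples = make_samples(5)
        base = rng.normal(0, 1, 5)
        V = np.vstack([base, base * 2 + 1, rng.normal(0, 1, 5),
                       rng.normal(0, 1, 5)])
        # rows 0 and 1 are perfectly correlated -> d = 0
        expr = pd.DataFrame(V, index=["a", "b", "c", "d"],
                            columns=[s.sample_id for s in samples])
        res = cluster_expression(expr)
        assert res.merges[0][:2] == (("a",), ("b",))
        assert res.merges[0][2] == pytest.approx(0.0, abs=1e-12)

    def test_matches_exhaustive_oracle(self, rng):
        samples = make_samples(6)
        V = rng.normal(0, 1, (6, 6))
        ids = [f"r{i}" for i in range(6)]
        expr = pd.DataFrame(V, index=ids, columns=[s.sample_id for s in samples])
        res = cluster_expression(expr)
        xc = V - V.mean(axis=1, keepdims=True)
        corr = np.corrcoef(V)
        dist = 1 - corr
        np.fill_diagonal(dist, 0)
        expected = upgma_oracle(dist, ids)
        for (got, exp) in zip(res.merges, expected):
            assert got[0] == exp[0] and got[1] == exp[1]
            assert got[2] == pytest.approx(exp[2], abs=1e-9)

    def test_matches_scipy_heights(self, rng):
        """Merge heights agree with scipy's UPGMA on the same distances."""
        V = rng.normal(0, 1, (8, 5))
        ids = [f"r{i}" for i in range(8)]
        expr = pd.DataFrame(V, index=ids,
                            columns=[f"s{j}" for j in range(5)])
        res = cluster_expression(expr)
        dist = 1 - np.corrcoef(V)
        np.fill_diagonal(dist, 0)
        Z = scipy_linkage(squareform(dist, checks=False), method="average")
        assert np.allclose(sorted(res.linkage[:, 2]), sorted(Z[:, 2]), atol=1e-9)

    def test_tree_shape(self, rng):
        V = rng.normal(0, 1, (7, 4))
        ids = [f"r{i}" for i in range(7)]
        expr = pd.DataFrame(V, index=ids, columns=list("abcd"))
        res = cluster_expression(expr)
        assert len(res.merges) == 6
        assert sorted(res.leaf_order) == sorted(ids)


class TestGeNorm:
    def test_exact_scalar_multiples_all_zero(self):
        X = pd.DataFrame(
            [[1.0, 2.0, 4.0], [2.0, 4.0, 8.0], [0.5, 1.0, 2.0]],
            index=["g1", "g2", "g3"],
        )
        rank = genorm_stability(X)
        assert np.allclose(rank.table["M"], 0.0)

    def test_hand_computed_fixture(self):
        X = pd.DataFrame(
            [[100.0, 200.0, 150.0],
             [110.0, 190.0, 160.0],
             [300.0, 100.0, 200.0]],
            index=["g1", "g2", "g3"],
        )
        L = np.log2(X.to_numpy())
        M_expected = []
        for j in range(3):
            vs = []
            for k in range(3):
                if k == j:
                    continue
                vs.append(np.std(L[j] - L[k], ddof=1))
            M_expected.append(np.mean(vs))
        rank = genorm_stability(X)
        got = rank.table.sort_index()["M"].to_numpy()
        order = np.argsort(["g1", "g2", "g3"])
        assert np.allclose(got, np.array(M_expected)[order], atol=1e-12)
        # most stable pair (g1, g2) ranks above g3
        assert rank.ranking[-1] == "g3"

    def test_scale_factor_invariance(self, rng):
        X = pd.DataFrame(rng.uniform(50, 500, (4, 5)),
                         index=[f"g{i}" for i in range(4)])
        scaled = X.mul(pd.Series([2.0, 0.5, 7.0, 1.3], index=X.index), axis=0)
        a = genorm_stability(X).table.sort_index()["M"]
        b = genorm_stability(scaled).table.sort_index()["M"]
        assert np.allclose(a, b, atol=1e-12)

    def test_noisy_gene_ranks_last(self, rng):
        base = rng.uniform(100, 1000, 6)
        X = np.vstack([base * 2.0, base * 0.7, base * 1.5,
                       base * 2 ** rng.normal(0, 0.4, 6)])
        rank = genorm_stability(pd.DataFrame(X, index=["a", "b", "c", "noisy"]))
        assert rank.ranking[-1] == "noisy"

    def test_nonpositive_rejected(self):
        X = pd.DataFrame(np.ones((3, 3)))
        X.iloc[0, 0] = 0.0
        with pytest.raises(ValidationError):
            genorm_stability(X)


class TestHeatmap:
    def test_renders_file(self, tmp_path, rng):
        from boutiquenorm import plot_expression_heatmap

        V = rng.normal(0, 1, (12, 5))
        df = pd.DataFrame(V, index=[f"g{i}" for i in range(12)],
                          columns=[f"s{j}" for j in range(5)])
        out = tmp_path / "heat.png"
        plot_expression_heatmap(df, str(out), title="demo")
        assert out.exists() and out.stat().st_size > 0
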