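"""The two-step null-model framework: betaMNTD/betaNTI, RCbray, classification."""

import io as stdio
import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

import phyloturn as pt
from phyloturn.io import CommunityTable, ValidationError, validate_metadata
from phyloturn.assembly import (
    _null_community,
    _rc_from_null,
    bmntd,
    bmntd_all_pairs,
    bnti_all_pairs,
    classify,
    cophenetic,
    env_correlation,
    median_bnti,
    rcbray_all_pairs,
    rcbray_pair,
    summarize,
)

from conftest import random_table


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def naive_cophenetic(tree):
    """Path-sum oracle via lowest common ancestor, one pair at a time."""
    tips = list(tree.tips())
    depth = {}
    for node in tree.traverse(include_self=True):
        parent_depth = depth.get(id(node.parent), 0.0)
        depth[id(node)] = parent_depth + (node.length or 0.0)

    def ancestors(node):
        out = []
        while node is not None:
            out.append(node)
            node = node.parent
        return out

    n = len(tips)
    D = np.zeros((n, n))
    for i in range(n):
        anc_i = ancestors(tips[i])
        anc_i_ids = {id(a) for a in anc_i}
        for j in range(i + 1, n):
            node = tips[j]
            while id(node) not in anc_i_ids:
                node = node.parent
            lca = node
            D[i, j] = D[j, i] = depth[id(tips[i])] + depth[id(tips[j])] - 2 * depth[id(lca)]
    return [t.name for t in tips], D


def naive_bmntd(counts_a, counts_b, dist, weighted=True):
    """Nested-loop betaMNTD oracle, no vectorisation."""
    present_a = [i for i, v in enumerate(counts_a) if v > 0]
    present_b = [j for j, v in enumerate(counts_b) if v > 0]
    total_a = sum(counts_a[i] for i in present_a)
    total_b = sum(counts_b[j] for j in present_b)
    term_a = 0.0
    for i in present_a:
        nearest = min(dist[i][j] for j in present_b)
        w = counts_a[i] / total_a if weighted else 1.0 / len(present_a)
        term_a += w * nearest
    term_b = 0.0
    for j in present_b:
        nearest = min(dist[i][j] for i in present_a)
        w = counts_b[j] / total_b if weighted else 1.0 / len(present_b)
        term_b += w * nearest
    return 0.5 * (term_a + term_b)


# ---------------------------------------------------------------------------
# cophenetic
# ---------------------------------------------------------------------------


class TestCophenetic:
    def test_hand_values(self):
        tree = TreeNode.read(stdio.StringIO("((A:1,B:1):1,C:2);"))
        dm = cophenetic(tree)
        assert dm["A", "B"] == pytest.approx(2.0)
        assert dm["A", "C"] == pytest.approx(4.0)
        assert all(dm[t, t] == 0.0 for t in dm.ids)

    def test_matches_lca_oracle(self):
        tree = pt.simulate_tree(50, seed=9)
        dm = cophenetic(tree)
        names, D = naive_cophenetic(tree)
        assert np.allclose(dm.filter(names).data, D, atol=1e-9)


# ---------------------------------------------------------------------------
# betaMNTD
# ---------------------------------------------------------------------------


class TestBmntd:
    def test_identical_composition_is_zero(self, rng):
        D = np.abs(rng.random((5, 5)))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        v = rng.integers(1, 10, size=5).astype(float)
        assert bmntd(v, v, D) == 0.0

    def test_single_taxon_pair(self):
        D = np.array([[0.0, 0.7], [0.7, 0.0]])
        assert bmntd([3, 0], [0, 5], D) == pytest.approx(0.7)

    def test_hand_unrolled_fixture(self):
        """4 ASVs, 2 samples with unequal abundances, checked by hand.

        a = (2, 1, 0, 0), b = (0, 0, 3, 1); D below.
        a-side: taxon0 -> min(D02, D03) = 0.4 (w 2/3); taxon1 -> 0.2 (w 1/3)
        b-side: taxon2 -> 0.3 (w 3/4); taxon3 -> 0.2 (w 1/4)
        betaMNTD = 0.5*((2/3*0.4 + 1/3*0.2) + (3/4*0.3 + 1/4*0.2))
        """
        D = np.array(
            [
                [0.0, 0.5, 0.4, 0.9],
                [0.5, 0.0, 0.3, 0.2],
                [0.4, 0.3, 0.0, 0.6],
                [0.9, 0.2, 0.6, 0.0],
            ]
        )
        a = np.array([2, 1, 0, 0], float)
        b = np.array([0, 0, 3, 1], float)
        expected = 0.5 * ((2 / 3 * 0.4 + 1 / 3 * 0.2) + (3 / 4 * 0.3 + 1 / 4 * 0.2))
        assert bmntd(a, b, D) == pytest.approx(expected, abs=1e-12)
        assert bmntd(a, b, D) == pytest.approx(naive_bmntd(a, b, D), abs=1e-12)

    @pytest.mark.parametrize("weighted", [True, False])
    def test_matches_nested_loop_oracle(self, weighted):
        """Vectorised all-pairs betaMNTD equals the quadruple-loop oracle."""
        for k in range(50):
            rng = np.random.default_rng(k)
            n_taxa = int(rng.integers(3, 13))
            n_samples = int(rng.integers(2, 7))
            D = np.abs(rng.random((n_taxa, n_taxa)))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0)
            counts = rng.integers(0, 6, size=(n_samples, n_taxa))
            counts[np.arange(n_samples), rng.integers(n_taxa, size=n_samples)] += 1
            fast = bmntd_all_pairs(counts, D, weighted=weighted)
            for a in range(n_samples):
                for b in range(a + 1, n_samples):
                    slow = naive_bmntd(counts[a], counts[b], D, weighted=weighted)
                    assert fast[a, b] == pytest.approx(slow, abs=1e-10)

    def test_empty_sample_errors(self):
        D = np.zeros((2, 2))
        with pytest.raises(ValidationError):
            bmntd([0, 0], [1, 0], D)


# ---------------------------------------------------------------------------
# betaNTI
# ---------------------------------------------------------------------------


def _sparse_even_table(tree_seed, n_taxa=20, richness=8, n_samples=3, identical_first_two=True):
    tree = pt.simulate_tree(n_taxa, seed=tree_seed)
    names = [t.name for t in tree.tips()]
    rng = np.random.default_rng(tree_seed)
    rows = []
    for _ in range(n_samples):
        comp = np.zeros(n_taxa)
        comp[rng.choice(n_taxa, richness, replace=False)] = 1.0 / richness
        rows.append(np.round(comp * 1000).astype(int))
    counts = np.array(rows)
    if identical_first_two:
        counts[1] = counts[0]
    return tree, CommunityTable([f"s{i}" for i in range(n_samples)], names, counts)


class TestBnti:
    def test_clustered_vs_anticlustered_sign(self):
        """Communities on one clade score negative; communities split across
        distant clades score positive (shared-null scheme)."""
        tree = TreeNode.read(stdio.StringIO(
            "(((a:.1,b:.1):.1,(c:.1,d:.1):.1):2,((e:.1,f:.1):.1,(g:.1,h:.1):.1):2);"
        ))
        names = [t.name for t in tree.tips()]
        idx = {n: i for i, n in enumerate(names)}

        def comm(present):
            v = np.zeros(8, int)
            for n in present:
                v[idx[n]] = 10
            return v

        # clustered: both samples inside the left clade, partial overlap
        clustered = CommunityTable(
            ["x", "y"], names, np.vstack([comm("abc"), comm("bcd")])
        )
        p_neg = bnti_all_pairs(clustered, tree=tree, reps=199, seed=0).bnti.iloc[0]
        # anti-clustered: the two samples sit on opposite sides of the deep
        # divide, so every observed nearest-taxon path crosses it
        anti = CommunityTable(
            ["x", "y"], names, np.vstack([comm("ab"), comm("gh")])
        )
        p_pos = bnti_all_pairs(anti, tree=tree, reps=199, seed=0).bnti.iloc[0]
        assert p_neg < 0 < p_pos

    def test_identical_pair_independent_scheme_strongly_negative(self):
        tree, table = _sparse_even_table(0)
        out = bnti_all_pairs(table, tree=tree, reps=999, seed=7, null_scheme="independent")
        row = out[(out.sample_a == "s0") & (out.sample_b == "s1")].iloc[0]
        assert row.bnti <= -2

    def test_identical_pair_shared_scheme_degenerate(self):
        """Under a single shared relabeling, shared taxa always self-match, so
        an identical pair has an all-zero null and is flagged undefined."""
        tree, table = _sparse_even_table(0)
        out = bnti_all_pairs(table, tree=tree, reps=199, seed=7, null_scheme="shared")
        row = out[(out.sample_a == "s0") & (out.sample_b == "s1")].iloc[0]
        assert row.undefined and np.isnan(row.bnti)

    def test_star_tree_flagged_undefined(self):
        star = TreeNode.read(stdio.StringIO(
            "(" + ",".join(f"t{i}:1.0" for i in range(10)) + ");"
        ))
        rng = np.random.default_rng(1)
        counts = rng.multinomial(100, np.ones(10) / 10, size=3)
        table = CommunityTable(["a", "b", "c"], [f"t{i}" for i in range(10)], counts)
        out = bnti_all_pairs(table, tree=star, reps=199, seed=2)
        assert out.undefined.all()
        assert out.bnti.isna().all()

    def test_bitwise_reproducible(self, rng):
        table = random_table(rng, 5, 15, depth=300)
        tree = pt.simulate_tree(15, seed=4)
        table = CommunityTable(table.sample_ids, [t.name for t in tree.tips()], table.counts)
        a = bnti_all_pairs(table, tree=tree, reps=199, seed=123)
        b = bnti_all_pairs(table, tree=tree, reps=199, seed=123)
        pd.testing.assert_frame_equal(a, b)
        c = bnti_all_pairs(table, tree=tree, reps=199, seed=124)
        assert not np.array_equal(a.bnti.to_numpy(), c.bnti.to_numpy())

    def test_monte_carlo_stability(self):
        """betaNTI at 999 and 9999 reps agree within 0.2 across seeds."""
        tree, table = _sparse_even_table(3, identical_first_two=False)
        for seed in range(10):
            lo = bnti_all_pairs(table, tree=tree, reps=999, seed=seed).bnti.to_numpy()
            hi = bnti_all_pairs(table, tree=tree, reps=9999, seed=seed + 100).bnti.to_numpy()
            assert np.all(np.abs(lo - hi) < 0.2)


# ---------------------------------------------------------------------------
# RCbray
# ---------------------------------------------------------------------------


class TestRcbray:
    def test_bounds_on_random_pairs(self, rng):
        table = random_table(rng, 15, 40, depth=500)
        out = rcbray_all_pairs(table, reps=199, seed=5)
        assert out.rcbray.between(-1, 1).all()

    def test_rc_monotone_in_observed_dissimilarity(self, rng):
        """Given one fixed null sample, larger BC_obs never lowers RCbray."""
        bc_null = rng.random(999)
        values = [_rc_from_null(x, bc_null) for x in np.linspace(0, 1, 25)]
        assert np.all(np.diff(values) >= 0)

    def test_identical_pair_extreme(self, rng):
        rows = []
        for _ in range(20):
            sub = rng.choice(100, 30, replace=False)
            comp = np.zeros(100)
            comp[sub] = rng.dirichlet(np.ones(30))
            rows.append(rng.multinomial(2000, comp))
        ident = rows[0].copy()
        meta = CommunityTable(
            [f"s{i}" for i in range(20)] + ["a", "b"],
            [f"t{j}" for j in range(100)],
            np.vstack(rows + [ident, ident]),
        )
        rc = rcbray_pair(ident, ident, meta, reps=999, seed=11)
        assert rc <= -0.95

    def test_richness_exceeding_metacommunity_errors(self):
        meta = CommunityTable(["s1", "s2"], list("abcd"),
                              np.array([[5, 5, 0, 0], [3, 7, 0, 0]]))
        with pytest.raises(ValidationError, match="richness"):
            rcbray_pair(np.array([1, 1, 1, 1]), np.array([2, 2, 0, 0]), meta,
                        reps=99, seed=0)

    def test_bitwise_reproducible(self, rng):
        table = random_table(rng, 6, 25, depth=400)
        a = rcbray_all_pairs(table, reps=199, seed=9)
        b = rcbray_all_pairs(table, reps=199, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_null_community_respects_richness_and_depth(self, rng):
        occupancy = rng.integers(0, 10, size=50).astype(float)
        occupancy[:30] += 1
        rel = rng.dirichlet(np.ones(50))
        null = _null_community(rng, occupancy, rel, richness=12, depth=300)
        assert (null > 0).sum() == 12
        assert null.sum() == 300
        assert np.all(null[occupancy == 0] == 0)


# ---------------------------------------------------------------------------
# classification, summaries, environmental correlation
# ---------------------------------------------------------------------------


class TestClassify:
    @pytest.mark.parametrize(
        "bnti,rc,expected",
        [
            (-3.1, np.nan, "homogeneous_selection"),
            (3.1, np.nan, "heterogeneous_selection"),
            (1.0, 0.3, "drift"),
            (0.0, -0.99, "homogenising_dispersal"),
            (0.0, 0.99, "dispersal_limitation"),
            (-2.0, 0.0, "drift"),       # boundary: strict inequality
            (2.0, 0.97, "dispersal_limitation"),
            (1.0, 0.95, "drift"),       # RC boundary also strict
        ],
    )
    def test_threshold_rules(self, bnti, rc, expected):
        df = pd.DataFrame(
            {"sample_a": ["x"], "sample_b": ["y"], "bnti": [bnti],
             "rcbray": [rc], "undefined": [False]}
        )
        assert classify(df).process.iloc[0] == expected

    def test_missing_rc_where_required_errors(self):
        df = pd.DataFrame(
            {"sample_a": ["x"], "sample_b": ["y"], "bnti": [0.5],
             "rcbray": [np.nan], "undefined": [False]}
        )
        with pytest.raises(ValidationError, match="RCbray"):
            classify(df)

    def test_partition_is_total_and_exclusive(self, rng):
        n = 500
        df = pd.DataFrame(
            {
                "sample_a": [f"a{i}" for i in range(n)],
                "sample_b": [f"b{i}" for i in range(n)],
                "bnti": rng.normal(0, 3, n),
                "rcbray": rng.uniform(-1, 1, n),
                "undefined": np.zeros(n, bool),
            }
        )
        out = classify(df)
        assert out.process.notna().all()
        assert set(out.process) <= set(pt.PROCESSES)


class TestSummarize:
    def _meta(self, samples, substrate="leaf", time="t1"):
        return validate_metadata(
            pd.DataFrame(
                {
                    "sample_id": samples,
                    "site": [f"o{i}" for i in range(len(samples))],
                    "substrate": substrate,
                    "time": time,
                    "replicate": "1",
                }
            )
        )

    def test_all_drift(self):
        df = pd.DataFrame(
            {
                "sample_a": [f"s{i}" for i in range(10)],
                "sample_b": [f"s{i+10}" for i in range(10)],
                "process": ["drift"] * 10,
                "undefined": [False] * 10,
            }
        )
        out = summarize(df, meta=None)
        assert out["drift"].iloc[0] == pytest.approx(100.0)
        assert out["n_pairs"].iloc[0] == 10

    def test_sixty_forty(self):
        df = pd.DataFrame(
            {
                "sample_a": [f"s{i}" for i in range(10)],
                "sample_b": [f"s{i+10}" for i in range(10)],
                "process": ["homogeneous_selection"] * 6 + ["drift"] * 4,
                "undefined": [False] * 10,
            }
        )
        out = summarize(df, meta=None)
        assert out["homogeneous_selection"].iloc[0] == pytest.approx(60.0)
        assert out["drift"].iloc[0] == pytest.approx(40.0)

    def test_percentages_sum_to_100(self, rng):
        n = 200
        df = pd.DataFrame(
            {
                "sample_a": [f"a{i}" for i in range(n)],
                "sample_b": [f"b{i}" for i in range(n)],
                "process": rng.choice(pt.PROCESSES, n),
                "undefined": rng.random(n) < 0.1,
            }
        )
        df.loc[df.undefined, "process"] = None
        out = summarize(df, meta=None)
        assert out[list(pt.PROCESSES)].sum(axis=1).iloc[0] == pytest.approx(100.0, abs=1e-9)
        assert out["n_pairs"].iloc[0] + out["n_undefined"].iloc[0] == n

    def test_cross_group_pair_errors(self):
        meta = validate_metadata(
            pd.DataFrame(
                {
                    "sample_id": ["s1", "s2"],
                    "site": ["o1", "o2"],
                    "substrate": ["leaf", "soil"],
                    "time": "t1",
                    "replicate": "1",
                }
            )
        )
        df = pd.DataFrame(
            {"sample_a": ["s1"], "sample_b": ["s2"], "process": ["drift"],
             "undefined": [False]}
        )
        with pytest.raises(ValidationError, match="crosses"):
            summarize(df, meta, ("substrate", "time"))


class TestMedianBnti:
    def _meta(self, mapping):
        rows = [
            {"sample_id": s, "site": site, "substrate": "leaf", "time": "t1",
             "replicate": str(i)}
            for i, (s, site) in enumerate(mapping.items())
        ]
        return validate_metadata(pd.DataFrame(rows))

    def test_single_pair(self):
        meta = self._meta({"s1": "o1", "s2": "o1"})
        pairs = pd.DataFrame(
            {"sample_a": ["s1"], "sample_b": ["s2"], "bnti": [1.5]}
        )
        out = median_bnti(pairs, meta)
        assert out.median_bnti.iloc[0] == pytest.approx(1.5)

    def test_constant_values(self):
        meta = self._meta({"s1": "o1", "s2": "o2", "s3": "o3"})
        pairs = pd.DataFrame(
            {
                "sample_a": ["s1", "s1", "s2"],
                "sample_b": ["s2", "s3", "s3"],
                "bnti": [0.7, 0.7, 0.7],
            }
        )
        out = median_bnti(pairs, meta)
        assert np.allclose(out.median_bnti, 0.7)

    def test_three_site_hand_enumeration(self):
        meta = self._meta({"s1": "o1", "s2": "o2", "s3": "o3"})
        pairs = pd.DataFrame(
            {
                "sample_a": ["s1", "s1", "s2"],
                "sample_b": ["s2", "s3", "s3"],
                "bnti": [1.0, 3.0, -2.0],
            }
        )
        out = median_bnti(pairs, meta).set_index("site")
        # o1 pools pairs touching s1: {1.0, 3.0} -> 2.0
        assert out.loc["o1", "median_bnti"] == pytest.approx(2.0)
        # o2 pools {1.0, -2.0} -> -0.5 ; o3 pools {3.0, -2.0} -> 0.5
        assert out.loc["o2", "median_bnti"] == pytest.approx(-0.5)
        assert out.loc["o3", "median_bnti"] == pytest.approx(0.5)


class TestEnvCorrelation:
    def _median_df(self, sites, values):
        return pd.DataFrame({"site": sites, "median_bnti": values})

    def test_affine_relationship(self):
        sites = [f"o{i}" for i in range(6)]
        bnti = np.array([-2.0, -1.0, 0.0, 1.0, 2.0, 3.0])
        env = pd.DataFrame({"TN": 0.5 * bnti + 1.0}, index=sites)
        slope, r, p = env_correlation(self._median_df(sites, bnti), env, "TN")
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(1 / 0.5)

    def test_closed_form_five_points(self):
        sites = [f"o{i}" for i in range(5)]
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        env = pd.DataFrame({"TN": x}, index=sites)
        slope, r, _ = env_correlation(self._median_df(sites, y), env, "TN")
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        syy = ((y - y.mean()) ** 2).sum()
        assert slope == pytest.approx(sxy / sxx)
        assert r == pytest.approx(sxy / np.sqrt(sxx * syy))

    def test_null_calibration(self):
        """Independent vectors, n=12: rejection rate at alpha=0.05 stays ~5%."""
        rejections = 0
        for k in range(200):
            rng = np.random.default_rng(k)
            sites = [f"o{i}" for i in range(12)]
            env = pd.DataFrame({"TN": rng.normal(size=12)}, index=sites)
            _, _, p = env_correlation(
                self._median_df(sites, rng.normal(size=12)), env, "TN"
            )
            rejections += p < 0.05
        assert rejections <= 21  # Binomial(200, .05), ~3.5 sd above the mean

    def test_zero_variance_errors(self):
        sites = ["o1", "o2", "o3"]
        env = pd.DataFrame({"TN": [1.0, 1.0, 1.0]}, index=sites)
        with pytest.raises(ValidationError):
            env_correlation(self._median_df(sites, [0.1, 0.2, 0.3]), env, "TN")
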