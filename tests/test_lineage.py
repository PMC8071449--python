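"""Ortholog mapping, correlation mapping, Fisher exclusivity, clustering."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from nbstates.lineage import (
    binarize_expression,
    correlate_clones_to_cells,
    exclusivity_test,
    expression_vs_celltype_test,
    fisher_exact_2x2,
    hierarchical_cluster,
    map_orthologs,
    mean_correlation_by_type,
)


def fisher_bruteforce(table):
    """Two-sided p by full enumeration of tables with the observed margins."""
    (a, b), (c, d) = np.asarray(table)
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    weights = {x: comb(r1, x) * comb(n - r1, c1 - x) for x in range(lo, hi + 1)}
    total = sum(weights.values())
    observed = weights[a]
    return sum(w for w in weights.values() if w <= observed) / total


def annot_for(cells, types, orders=None):
    orders = orders or {t: i for i, t in enumerate(dict.fromkeys(types))}
    return pd.DataFrame(
        {"cell_type": types, "dev_order": [orders[t] for t in types]},
        index=cells,
    )


class TestOrthologs:
    def test_explicit_map_renames_and_reports(self):
        ref = pd.DataFrame(
            np.arange(6).reshape(3, 2), index=["Ret", "Axl", "Gene3"],
            columns=["c1", "c2"],
        )
        out, report = map_orthologs(ref, {"Ret": "RET", "Axl": "AXL"})
        assert list(out.index) == ["RET", "AXL"]
        assert report.unmapped == ["Gene3"]

    def test_identity_fallback_uppercases(self):
        ref = pd.DataFrame([[1, 2]], index=["Yap1"], columns=["c1", "c2"])
        out, _ = map_orthologs(ref)
        assert list(out.index) == ["YAP1"]

    def test_many_to_one_dropped(self):
        ref = pd.DataFrame(
            [[1], [2], [3]], index=["a1", "a2", "b"], columns=["c"]
        )
        out, report = map_orthologs(ref, {"a1": "A", "a2": "A", "b": "B"})
        assert list(out.index) == ["B"]
        assert report.dropped_many_to_one == ["a1", "a2"]

    def test_invertible_map_round_trip(self):
        ref = pd.DataFrame(
            np.eye(3, dtype=int), index=["x", "y", "z"], columns=list("abc")
        )
        fwd = {"x": "X", "y": "Y", "z": "Z"}
        inv = {v: k for k, v in fwd.items()}
        there, _ = map_orthologs(ref, fwd)
        back, _ = map_orthologs(there, inv)
        pd.testing.assert_frame_equal(back, ref)


class TestCorrelationMap:
    def test_identical_profile_gives_r_one(self, rng):
        profile = rng.gamma(2.0, size=150) * 10
        genes = [f"g{i}" for i in range(150)]
        clones = pd.DataFrame({"cl1": profile}, index=genes)
        cells = pd.DataFrame({"cell1": profile}, index=genes)
        cmap = correlate_clones_to_cells(
            clones, cells, annot_for(["cell1"], ["SCP"]), use_log=False,
            min_shared_genes=100,
        )
        assert cmap.r.loc["cell1", "cl1"] == pytest.approx(1.0)

    def test_anti_profile_gives_r_minus_one(self, rng):
        profile = rng.normal(size=120)
        genes = [f"g{i}" for i in range(120)]
        clones = pd.DataFrame({"cl1": profile}, index=genes)
        cells = pd.DataFrame({"cell1": -profile}, index=genes)
        cmap = correlate_clones_to_cells(
            clones, cells, annot_for(["cell1"], ["SCP"]), use_log=False,
            min_shared_genes=100,
        )
        assert cmap.r.loc["cell1", "cl1"] == pytest.approx(-1.0)

    def test_too_few_shared_genes_rejected(self, rng):
        clones = pd.DataFrame({"cl": rng.random(50)}, index=[f"g{i}" for i in range(50)])
        cells = pd.DataFrame({"ce": rng.random(50)}, index=[f"h{i}" for i in range(50)])
        with pytest.raises(ValueError, match="shared genes"):
            correlate_clones_to_cells(clones, cells, annot_for(["ce"], ["SCP"]))

    def test_replicates_averaged_into_clone_profile(self, rng):
        genes = [f"g{i}" for i in range(150)]
        base = rng.gamma(2.0, size=150)
        clones = pd.DataFrame(
            {"a_r1": base * 1.0, "a_r2": base * 1.0}, index=genes
        )
        cells = pd.DataFrame({"c": base}, index=genes)
        groups = pd.Series({"a_r1": "a", "a_r2": "a"})
        cmap = correlate_clones_to_cells(
            clones, cells, annot_for(["c"], ["SCP"]), clone_groups=groups,
            use_log=False, min_shared_genes=100,
        )
        assert list(cmap.r.columns) == ["a"]
        assert cmap.r.loc["c", "a"] == pytest.approx(1.0)

    def test_sign_flips_under_negative_affine_transform(self, rng):
        genes = [f"g{i}" for i in range(120)]
        x = rng.normal(size=120)
        y = x + rng.normal(scale=0.3, size=120)
        clones = pd.DataFrame({"cl": x}, index=genes)
        annot = annot_for(["ce"], ["SCP"])
        up = correlate_clones_to_cells(
            clones, pd.DataFrame({"ce": 2 * y + 3}, index=genes), annot,
            use_log=False, min_shared_genes=100,
        )
        down = correlate_clones_to_cells(
            clones, pd.DataFrame({"ce": -2 * y + 3}, index=genes), annot,
            use_log=False, min_shared_genes=100,
        )
        assert up.r.iloc[0, 0] == pytest.approx(-down.r.iloc[0, 0], abs=1e-12)
        assert up.r.iloc[0, 0] > 0


class TestMeanByType:
    def test_single_cell_per_type_equals_raw_values(self):
        from nbstates.lineage import CorrelationMap

        r = pd.DataFrame(
            [[0.5], [0.2]], index=["c1", "c2"], columns=["cl"]
        )
        cmap = CorrelationMap(
            r=r, annotations=annot_for(["c1", "c2"], ["SCP", "bridge"]),
            n_genes_used=100,
        )
        means = mean_correlation_by_type(cmap)
        assert means.loc["SCP", "cl"] == 0.5
        assert means.loc["bridge", "cl"] == 0.2

    def test_permutation_invariance_and_groupby_oracle(self, rng):
        from nbstates.lineage import CorrelationMap

        cells = [f"c{i}" for i in range(40)]
        types = [["SCP", "bridge", "chromaffin", "sympathoblast"][i % 4] for i in range(40)]
        r = pd.DataFrame(
            rng.uniform(-1, 1, size=(40, 3)), index=cells, columns=list("abc")
        )
        annot = annot_for(cells, types, {"SCP": 0, "bridge": 1, "chromaffin": 2, "sympathoblast": 3})
        means = mean_correlation_by_type(CorrelationMap(r, annot, 10))
        perm = rng.permutation(40)
        means_perm = mean_correlation_by_type(
            CorrelationMap(r.iloc[perm], annot, 10)
        )
        pd.testing.assert_frame_equal(means, means_perm)
        # brute-force group-by
        for t in set(types):
            keep = [c for c, ty in zip(cells, types) if ty == t]
            assert np.allclose(means.loc[t], r.loc[keep].mean(axis=0))


class TestBinarize:
    def test_examples(self):
        df = pd.DataFrame([[0, 3], [1, 0]], index=["g1", "g2"], columns=["c1", "c2"])
        out = binarize_expression(df)
        assert out.to_numpy().tolist() == [[False, True], [True, False]]
        assert not binarize_expression(df * 0).any().any()

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            binarize_expression(pd.DataFrame([[-1.0]]))

    def test_invariant_to_positive_rescaling(self, rng):
        df = pd.DataFrame(
            rng.poisson(0.5, size=(30, 10)),
            index=[f"g{i}" for i in range(30)],
        )
        norm = df / rng.uniform(0.5, 2.0, size=10)
        pd.testing.assert_frame_equal(
            binarize_expression(df), binarize_expression(norm)
        )


class TestFisher:
    def test_balanced_table_p_one(self):
        odds, p, flag = fisher_exact_2x2([[5, 5], [5, 5]])
        assert p == pytest.approx(1.0)
        assert odds == pytest.approx(1.0)
        assert not flag

    def test_diagonal_table_matches_enumeration(self):
        table = [[10, 0], [0, 10]]
        _, p, flag = fisher_exact_2x2(table)
        assert flag
        assert p == pytest.approx(fisher_bruteforce(table), rel=1e-10)

    def test_random_tables_match_enumeration(self, rng):
        for _ in range(500):
            t = rng.integers(0, 16, size=(2, 2))
            while min(t.sum(0).min(), t.sum(1).min()) == 0:
                t = rng.integers(0, 16, size=(2, 2))
            _, p, _ = fisher_exact_2x2(t)
            assert p == pytest.approx(fisher_bruteforce(t), rel=1e-10)

    def test_zero_margin_gives_p_one_or_undefined(self):
        odds, p, flag = fisher_exact_2x2([[0, 0], [3, 7]])
        assert p == 1.0 and np.isnan(odds) and flag

    def test_symmetry_under_transpose_and_relabel(self, rng):
        for _ in range(50):
            t = rng.integers(1, 12, size=(2, 2))
            _, p, _ = fisher_exact_2x2(t)
            _, p_t, _ = fisher_exact_2x2(t.T)
            _, p_swap, _ = fisher_exact_2x2(t[::-1, ::-1])
            assert p == pytest.approx(p_t, rel=1e-12)
            assert p == pytest.approx(p_swap, rel=1e-12)


class TestExclusivity:
    def test_perfectly_exclusive_pattern(self):
        genes = ["A", "B"]
        cells = [f"c{i}" for i in range(40)]
        data = np.zeros((2, 40), dtype=int)
        data[0, :20] = 5  # A on in first half
        data[1, 20:] = 5  # B on in second half
        binary = binarize_expression(pd.DataFrame(data, index=genes, columns=cells))
        res = exclusivity_test(binary, "A", "B")
        assert res.zero_cell
        assert res.direction == "exclusive"
        assert res.pvalue == pytest.approx(
            fisher_bruteforce([[0, 20], [20, 0]]), rel=1e-10
        )

    def test_absent_gene_named_in_error(self):
        binary = pd.DataFrame([[True]], index=["A"], columns=["c"])
        with pytest.raises(ValueError, match="'MISSING'"):
            exclusivity_test(binary, "A", "MISSING")

    def test_independent_genes_give_uniform_p(self, rng):
        # null calibration: Bernoulli(0.5) independent genes
        ps = []
        for _ in range(200):
            data = rng.integers(0, 2, size=(2, 1000))
            binary = pd.DataFrame(
                data, index=["A", "B"], columns=[f"c{i}" for i in range(1000)]
            ).astype(bool)
            ps.append(exclusivity_test(binary, "A", "B").pvalue)
        from scipy.stats import kstest

        assert kstest(ps, "uniform").pvalue > 0.01

    def test_gene_vs_celltype_contingency(self):
        cells = [f"c{i}" for i in range(30)]
        types = ["SCP"] * 10 + ["chromaffin"] * 20
        data = np.zeros((1, 30), dtype=int)
        data[0, :10] = 3  # expressed exactly in SCP cells
        binary = binarize_expression(pd.DataFrame(data, index=["AXL"], columns=cells))
        res = expression_vs_celltype_test(
            binary, "AXL", annot_for(cells, types), "SCP"
        )
        assert res.direction == "enriched"
        assert res.table[0, 0] == 10 and res.table[1, 1] == 20


class TestClustering:
    def test_two_identical_row_groups_split_first(self):
        rows = np.vstack([np.tile([0.9, 0.1], (4, 1)), np.tile([0.1, 0.9], (3, 1))])
        df = pd.DataFrame(rows, index=[f"r{i}" for i in range(7)], columns=["a", "b"])
        result = hierarchical_cluster(df, axis="rows")
        cut = result.cut(2)
        assert len(set(cut[:4])) == 1 and len(set(cut[4:])) == 1
        assert cut.iloc[0] != cut.iloc[-1]

    def test_merge_heights_non_decreasing(self, rng):
        df = pd.DataFrame(rng.normal(size=(25, 4)))
        result = hierarchical_cluster(df, axis="rows")
        heights = result.linkage[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_nan_rejected_with_location(self):
        df = pd.DataFrame([[0.1, np.nan], [0.2, 0.3]], index=["r1", "r2"])
        with pytest.raises(ValueError, match="non-finite"):
            hierarchical_cluster(df, axis="rows")

    def test_flat_clusters_invariant_to_row_order(self, rng):
        df = pd.DataFrame(
            np.vstack([rng.normal(0, 0.05, (10, 3)), rng.normal(3, 0.05, (10, 3))]),
            index=[f"r{i}" for i in range(20)],
        )
        cut1 = hierarchical_cluster(df, axis="rows").cut(2)
        perm = rng.permutation(20)
        cut2 = hierarchical_cluster(df.iloc[perm], axis="rows").cut(2)
        # same partition of labels, up to cluster-id relabeling
        part1 = {frozenset(cut1.index[cut1 == c]) for c in set(cut1)}
        part2 = {frozenset(cut2.index[cut2 == c]) for c in set(cut2)}
        assert part1 == part2

    def test_newick_is_well_formed(self, rng):
        import io as _io

        import skbio

        df = pd.DataFrame(rng.normal(size=(8, 3)), index=[f"leaf{i}" for i in range(8)])
        result = hierarchical_cluster(df, axis="rows")
        tree = skbio.TreeNode.read(_io.StringIO(result.newick))
        assert sorted(t.name for t in tree.tips()) == sorted(result.labels)
        assert sorted(result.leaf_order) == sorted(result.labels)

    def test_columns_axis_clusters_transpose(self, rng):
        df = pd.DataFrame(
            rng.normal(size=(6, 4)), columns=["w", "x", "y", "z"]
        )
        result = hierarchical_cluster(df, axis="columns")
        assert sorted(result.labels) == ["w", "x", "y", "z"]
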