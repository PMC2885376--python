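import logging

import numpy as np
import pytest

from miract import (
    ExpressionMatrix,
    GroupAssignment,
    TargetCountTable,
    ValidationError,
    between_group_condense,
    coinertia,
    impose_row_weights,
    nsc_transform,
    rv_coefficient,
    supervised_cia,
    total_inertia,
    unsupervised_cia,
    weighted_decomposition,
)

from conftest import random_positive_table


class TestImposeRowWeights:
    def test_own_weights_reduce_to_plain_nsc(self, rng):
        table = random_positive_table(rng, 6, 4)
        wt = nsc_transform(table)
        imposed = impose_row_weights(table, wt.row_weights)
        np.testing.assert_allclose(imposed.Z, wt.Z, atol=1e-12)

    def test_columns_centred_under_imposed_weights(self, rng):
        table = random_positive_table(rng, 6, 4)
        d = rng.random(6) + 0.1
        d /= d.sum()
        wt = impose_row_weights(table, d)
        np.testing.assert_allclose(d @ wt.Z, 0, atol=1e-10)

    def test_three_by_two_hand_oracle(self):
        X = np.array([[1.0, 3.0], [2.0, 2.0], [4.0, 0.5]])
        d = np.array([0.5, 0.25, 0.25])
        wt = impose_row_weights((X, ["a", "b", "c"], ["x", "y"]), d)
        q = X / X.sum(axis=1, keepdims=True)
        expected = 2 * (q - (d @ q)[None, :])
        np.testing.assert_allclose(wt.Z, expected, atol=1e-12)
        np.testing.assert_allclose(wt.row_weights, d)

    def test_mismatched_weights_rejected(self, rng):
        table = random_positive_table(rng, 5, 3)
        with pytest.raises(ValidationError):
            impose_row_weights(table, np.full(4, 0.25))
        with pytest.raises(ValidationError):
            impose_row_weights(table, np.array([0.5, 0.5, 0.5, -0.25, -0.25]))


class TestBetweenGroupCondense:
    def test_singleton_groups_reproduce_centred_table(self, rng):
        wt = nsc_transform(random_positive_table(rng, 6, 4))
        groups = GroupAssignment({c: c for c in wt.col_ids})
        condensed = between_group_condense(wt, groups)
        centroid = (wt.Z * wt.col_weights).sum(axis=1) / wt.col_weights.sum()
        np.testing.assert_allclose(condensed.Z, wt.Z - centroid[:, None], atol=1e-12)
        np.testing.assert_allclose(condensed.col_weights, wt.col_weights)

    def test_single_group_collapses_to_zero(self, rng):
        wt = nsc_transform(random_positive_table(rng, 6, 4))
        groups = GroupAssignment({c: "only" for c in wt.col_ids})
        condensed = between_group_condense(wt, groups)
        np.testing.assert_allclose(condensed.Z, 0, atol=1e-12)

    def test_two_equal_groups_give_group_means_minus_overall(self, rng):
        wt = nsc_transform(random_positive_table(rng, 5, 4))
        groups = GroupAssignment(
            {wt.col_ids[0]: "g1", wt.col_ids[1]: "g1",
             wt.col_ids[2]: "g2", wt.col_ids[3]: "g2"}
        )
        condensed = between_group_condense(wt, groups)
        overall = wt.Z.mean(axis=1)
        np.testing.assert_allclose(
            condensed.Z[:, 0], wt.Z[:, :2].mean(axis=1) - overall, atol=1e-12
        )
        np.testing.assert_allclose(
            condensed.Z[:, 1], wt.Z[:, 2:].mean(axis=1) - overall, atol=1e-12
        )
        np.testing.assert_allclose(condensed.col_weights, [0.5, 0.5])

    def test_between_inertia_bounded_by_total(self, rng):
        # condensing to centroids can only lose variance
        for _ in range(100):
            wt = nsc_transform(random_positive_table(rng, 6, 5))
            labels = rng.integers(0, 3, size=5)
            if len(set(labels.tolist())) < 2:
                continue
            groups = GroupAssignment(
                {c: f"grp{labels[j]}" for j, c in enumerate(wt.col_ids)}
            )
            condensed = between_group_condense(wt, groups)
            assert total_inertia(condensed) <= total_inertia(wt) + 1e-10

    def test_group_with_no_columns_rejected(self, rng):
        wt = nsc_transform(random_positive_table(rng, 4, 3))
        groups = GroupAssignment(
            {c: "a" for c in wt.col_ids}, labels=["a", "ghost"]
        )
        with pytest.raises(ValidationError, match="ghost"):
            between_group_condense(wt, groups)


class TestCoinertia:
    def test_self_coupling_reproduces_spectrum(self, rng):
        wt = nsc_transform(random_positive_table(rng, 8, 4))
        o = weighted_decomposition(wt, tol=1e-14)
        res = coinertia(wt, wt)
        np.testing.assert_allclose(
            res.singular_covariances, o.eigenvalues[: res.n_axes], atol=1e-10
        )
        assert res.rv == pytest.approx(1.0, abs=1e-10)

    def test_column_permutation_leaves_invariants(self, rng):
        wtX = nsc_transform(random_positive_table(rng, 8, 3))
        values, rows, cols = random_positive_table(rng, 8, 5)
        wtY = impose_row_weights((values, wtX.row_ids, cols), wtX.row_weights)
        res = coinertia(wtX, wtY)
        perm = rng.permutation(5)
        from miract import WeightedTable

        wtYp = WeightedTable(
            wtY.Z[:, perm], wtY.row_ids, [wtY.col_ids[j] for j in perm],
            wtY.row_weights, wtY.col_weights[perm],
        )
        resp = coinertia(wtX, wtYp)
        assert (resp.singular_covariances**2).sum() == pytest.approx(
            (res.singular_covariances**2).sum(), rel=1e-10
        )
        assert resp.rv == pytest.approx(res.rv, rel=1e-10)

    def test_covariances_match_brute_force_svd(self, rng):
        for _ in range(20):
            wtX = nsc_transform(random_positive_table(rng, 8, 3))
            values, _, cols = random_positive_table(rng, 8, 4)
            wtY = impose_row_weights((values, wtX.row_ids, cols), wtX.row_weights)
            res = coinertia(wtX, wtY)
            M = (
                np.diag(np.sqrt(wtX.col_weights))
                @ wtX.Z.T
                @ np.diag(wtX.row_weights)
                @ wtY.Z
                @ np.diag(np.sqrt(wtY.col_weights))
            )
            oracle = np.linalg.svd(M, compute_uv=False)
            np.testing.assert_allclose(
                res.singular_covariances, oracle[: res.n_axes], atol=1e-10
            )

    def test_axes_orthonormal_under_column_metrics(self, rng):
        wtX = nsc_transform(random_positive_table(rng, 8, 3))
        values, _, cols = random_positive_table(rng, 8, 4)
        wtY = impose_row_weights((values, wtX.row_ids, cols), wtX.row_weights)
        res = coinertia(wtX, wtY)
        gx = res.axes_X.T @ np.diag(wtX.col_weights) @ res.axes_X
        gy = res.axes_Y.T @ np.diag(wtY.col_weights) @ res.axes_Y
        np.testing.assert_allclose(gx, np.eye(res.n_axes), atol=1e-8)
        np.testing.assert_allclose(gy, np.eye(res.n_axes), atol=1e-8)

    def test_first_pair_beats_random_axes(self, rng):
        # sampling check of the maximal-covariance property
        wtX = nsc_transform(random_positive_table(rng, 8, 3))
        values, _, cols = random_positive_table(rng, 8, 4)
        wtY = impose_row_weights((values, wtX.row_ids, cols), wtX.row_weights)
        res = coinertia(wtX, wtY)
        best = res.singular_covariances[0] ** 2

        def rand_unit(dim, w):
            v = rng.normal(size=dim)
            return v / np.sqrt((w * v**2).sum())

        cross = wtX.Z.T @ (wtX.row_weights[:, None] * wtY.Z)
        for _ in range(1000):
            a = rand_unit(3, wtX.col_weights)
            b = rand_unit(4, wtY.col_weights)
            cov = (wtX.col_weights * a) @ cross @ (wtY.col_weights * b)
            assert cov**2 <= best + 1e-10

    def test_row_mismatch_reports_first_difference(self, rng):
        wtX = nsc_transform(random_positive_table(rng, 5, 3))
        values, _, cols = random_positive_table(rng, 5, 3)
        other_rows = list(wtX.row_ids)
        other_rows[2] = "ODD"
        wtY = nsc_transform((values, other_rows, cols))
        with pytest.raises(ValidationError, match="ODD"):
            coinertia(wtX, wtY)


class TestRvCoefficient:
    def test_self_is_one(self, rng):
        wt = nsc_transform(random_positive_table(rng, 6, 4))
        assert rv_coefficient(wt, wt) == pytest.approx(1.0, abs=1e-10)

    def test_invariant_under_positive_scaling(self, rng):
        from miract import WeightedTable

        wtX = nsc_transform(random_positive_table(rng, 6, 3))
        values, _, cols = random_positive_table(rng, 6, 4)
        wtY = impose_row_weights((values, wtX.row_ids, cols), wtX.row_weights)
        scaled = WeightedTable(
            3.7 * wtY.Z, wtY.row_ids, wtY.col_ids, wtY.row_weights, wtY.col_weights
        )
        assert rv_coefficient(wtX, scaled) == pytest.approx(
            rv_coefficient(wtX, wtY), rel=1e-10
        )

    def test_matches_direct_recomputation(self, rng):
        wtX = nsc_transform(random_positive_table(rng, 7, 3))
        values, _, cols = random_positive_table(rng, 7, 5)
        wtY = impose_row_weights((values, wtX.row_ids, cols), wtX.row_weights)

        def scaled_cross(a, b):
            return (
                np.diag(np.sqrt(a.col_weights))
                @ a.Z.T @ np.diag(a.row_weights) @ b.Z
                @ np.diag(np.sqrt(b.col_weights))
            )

        s2 = np.linalg.svd(scaled_cross(wtX, wtY), compute_uv=False) ** 2
        expected = s2.sum() / np.sqrt(
            (scaled_cross(wtX, wtX) ** 2).sum() * (scaled_cross(wtY, wtY) ** 2).sum()
        )
        assert rv_coefficient(wtX, wtY) == pytest.approx(expected, rel=1e-10)

    def test_zero_inertia_rejected(self, rng):
        from miract import WeightedTable

        wt = nsc_transform(random_positive_table(rng, 5, 3))
        zero = WeightedTable(
            np.zeros((5, 3)), wt.row_ids, wt.col_ids, wt.row_weights, wt.col_weights
        )
        with pytest.raises(ValidationError):
            rv_coefficient(wt, zero)


class TestUnsupervisedCia:
    def test_identical_structure_gives_rv_one(self):
        # target counts identical to (integer) expression values: the two
        # tables carry the same profiles, so coupling is perfect
        rng = np.random.default_rng(5)
        counts = rng.integers(1, 6, size=(12, 4))
        genes = [f"G{i}" for i in range(12)]
        cols = [f"s{j}" for j in range(4)]
        expr = ExpressionMatrix(counts.astype(float), genes, cols)
        targets = TargetCountTable(counts, genes, [f"miR-{j}" for j in range(4)], "p")
        res = unsupervised_cia(expr, targets)
        assert res.rv == pytest.approx(1.0, abs=1e-8)

    def test_gene_order_shuffle_in_targets_is_irrelevant(self, small_dataset, rng):
        res1 = unsupervised_cia(small_dataset.expression, small_dataset.targets)
        t = small_dataset.targets
        perm = rng.permutation(len(t.gene_ids))
        shuffled = TargetCountTable(
            t.counts[perm], [t.gene_ids[i] for i in perm], t.mirna_ids, t.source_label
        )
        res2 = unsupervised_cia(small_dataset.expression, shuffled)
        np.testing.assert_allclose(
            res2.singular_covariances, res1.singular_covariances, atol=1e-10
        )
        np.testing.assert_allclose(res2.display_Y, res1.display_Y, atol=1e-10)

    def test_active_mirnas_oppose_affected_group(self, planted_dataset):
        # planted activity in group A: the active miRNAs' axis-1 coordinates
        # must sit on the opposite half-axis from the group-A samples
        ds = planted_dataset
        res = unsupervised_cia(ds.expression, ds.targets)
        sample_side = np.sign(
            np.mean([res.display_X[res.col_ids_X.index(s), 0]
                     for s in ds.groups.members("A")])
        )
        for mid in ds.active_mirnas:
            coord = res.display_Y[res.col_ids_Y.index(mid), 0]
            assert np.sign(coord) == -sample_side


class TestSupervisedCia:
    def test_two_groups_yield_single_axis(self, small_dataset):
        ds = small_dataset
        res = supervised_cia(ds.expression, ds.targets, ds.groups, "A")
        assert res.coinertia.n_axes == 1
        assert res.group_coords[res.target_group] > 0

    def test_label_swap_leaves_mirna_coords(self, small_dataset):
        ds = small_dataset
        res_a = supervised_cia(ds.expression, ds.targets, ds.groups, "A")
        swapped = GroupAssignment(
            {s: ("B" if g == "A" else "A") for s, g in ds.groups.assignment.items()},
            ["A", "B"],
        )
        res_b = supervised_cia(ds.expression, ds.targets, swapped, "B")
        np.testing.assert_allclose(
            res_b.mirna_coords.values, res_a.mirna_coords.values, atol=1e-10
        )

    def test_missing_target_group_rejected(self, small_dataset):
        ds = small_dataset
        with pytest.raises(ValidationError, match="nope"):
            supervised_cia(ds.expression, ds.targets, ds.groups, "nope")

    def test_identical_centroids_degenerate_with_warning(self, caplog, rng):
        # mirror group A's samples into group B: centroids coincide exactly
        half = rng.random((10, 3)) + 0.5
        values = np.hstack([half, half])
        genes = [f"G{i}" for i in range(10)]
        samples = [f"A{j}" for j in range(3)] + [f"B{j}" for j in range(3)]
        expr = ExpressionMatrix(values, genes, samples)
        counts = rng.integers(1, 4, size=(10, 4))
        targets = TargetCountTable(counts, genes, [f"m{j}" for j in range(4)], "p")
        groups = GroupAssignment({s: s[0] for s in samples}, ["A", "B"])
        with caplog.at_level(logging.WARNING):
            res = supervised_cia(expr, targets, groups, "A")
        assert res.coinertia.n_axes == 0
        assert res.coinertia.singular_covariances[0] == 0
        assert any("degenerate" in r.message for r in caplog.records)

    def test_row_permutation_applied_to_both_is_invisible(self, small_dataset, rng):
        ds = small_dataset
        res1 = supervised_cia(ds.expression, ds.targets, ds.groups, "A")
        perm = rng.permutation(len(ds.expression.gene_ids))
        expr = ExpressionMatrix(
            ds.expression.values[perm],
            [ds.expression.gene_ids[i] for i in perm],
            ds.expression.sample_ids,
        )
        targets = TargetCountTable(
            ds.targets.counts[perm],
            [ds.targets.gene_ids[i] for i in perm],
            ds.targets.mirna_ids,
            ds.targets.source_label,
        )
        res2 = supervised_cia(expr, targets, ds.groups, "A")
        np.testing.assert_allclose(
            res2.mirna_coords.values, res1.mirna_coords.values, atol=1e-9
        )
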