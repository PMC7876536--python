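import numpy as np
import pandas as pd
import pytest

from holonet.network import (
    ModulePartition,
    NetworkParams,
    bicor,
    correlation_matrix,
    default_signed_power,
    detect_modules,
    infer_network,
    intramodular_connectivity,
    kme,
    merge_modules,
    module_eigennode,
    pick_soft_threshold,
    scale_free_fit,
    signed_adjacency,
    signed_tom,
    trim_modules,
)

from .conftest import make_matrix, random_matrix


def bicor_oracle(x, y):
    """Straight-line evaluation of the biweight midcorrelation formula
    (no side cap needed for the Gaussian draws used in these tests)."""

    def weights(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        u = (v - med) / (9 * mad)
        return (1 - u**2) ** 2 * (np.abs(u) < 1), med

    wx, mx = weights(x)
    wy, my = weights(y)
    num = np.sum(wx * wy * (x - mx) * (y - my))
    den = np.sqrt(np.sum((wx * (x - mx)) ** 2)) * np.sqrt(np.sum((wy * (y - my)) ** 2))
    return num / den


class TestBicor:
    def test_self_correlation_is_one(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert bicor(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_exact_antimonotone_is_minus_one(self):
        assert bicor([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_formula_oracle_on_gaussian_pairs(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            x = rng.standard_normal(30)
            y = rng.standard_normal(30)
            # disable the side cap so the oracle's plain formula applies
            assert bicor(x, y, max_p_outliers=0.5) == pytest.approx(
                bicor_oracle(x, y), abs=1e-10
            )

    def test_invariant_under_positive_affine_transform(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(25)
        y = rng.standard_normal(25)
        r0 = bicor(x, y)
        for a, b in ((2.5, -3.0), (0.1, 100.0)):
            assert bicor(a * x + b, y) == pytest.approx(r0, abs=1e-10)
            assert bicor(x, a * y + b) == pytest.approx(r0, abs=1e-10)

    def test_side_cap_limits_zero_weight_fraction(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(100)
        x[:20] += 50  # gross outliers on one side
        y = rng.standard_normal(100)
        from holonet.network import _biweight_prepare

        a, fb = _biweight_prepare(x, 0.05)
        assert not fb
        # the cap rescales u so that at most the 5% most extreme
        # observations on a side lose their weight entirely
        upper = x > np.median(x)
        zero_upper = (a == 0) & upper
        assert zero_upper.sum() <= np.ceil(0.05 * x.size) + 1
        # without the cap the gross outliers would all be zeroed
        a0, _ = _biweight_prepare(x, 0.5)
        assert ((a0 == 0) & upper).sum() >= 20

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            bicor([1, 2, 3], [1, 2])

    def test_constant_pair_returns_zero(self):
        assert bicor([1.0, 1, 1, 1], [2.0, 2, 2, 2]) == 0.0


class TestCorrelationMatrix:
    def test_identical_rows_give_all_ones(self):
        x = np.tile(np.arange(10.0), (4, 1))
        corr = correlation_matrix(make_matrix(x))
        np.testing.assert_allclose(corr.to_numpy(), 1.0, atol=1e-10)

    def test_matches_scalar_bicor_loop(self):
        mat = random_matrix(2, n_features=10, n_samples=20)
        corr = correlation_matrix(mat)
        X = mat.values.to_numpy()
        for i in range(10):
            for j in range(10):
                expected = 1.0 if i == j else bicor(X[i], X[j])
                assert corr.iloc[i, j] == pytest.approx(expected, abs=1e-10)

    def test_single_feature(self):
        corr = correlation_matrix(make_matrix(np.arange(5.0)[None, :]))
        assert corr.shape == (1, 1) and corr.iloc[0, 0] == 1.0

    def test_constant_feature_gets_nan_row(self):
        x = np.vstack([np.ones(10), np.arange(10.0), np.random.default_rng(0).random(10)])
        corr = correlation_matrix(make_matrix(x))
        assert np.isnan(corr.iloc[0, 1]) and corr.iloc[0, 0] == 1.0


class TestSoftThreshold:
    def test_single_candidate_forced(self):
        corr = correlation_matrix(random_matrix(0, 25, 15))
        beta, table = pick_soft_threshold(corr, (7,), 0.85)
        assert beta == 7 and len(table) == 1

    def test_argmax_fallback_with_flag_when_trend_exists(self):
        # block structure yields a decent (but sub-cut) scale-free trend
        rng = np.random.default_rng(4)
        f = rng.standard_normal(30)
        rows = [0.9 * f + 0.45 * rng.standard_normal(30) for _ in range(12)]
        rows += [rng.standard_normal(30) for _ in range(88)]
        corr = correlation_matrix(make_matrix(np.vstack(rows)))
        beta, table = pick_soft_threshold(corr, tuple(range(1, 21)), r2_cut=0.99, n_samples=30)
        assert table.attrs["no_power_reached_cut"]
        if not table.attrs["used_default_power"]:
            assert beta == table.loc[table["fit"].idxmax(), "power"]

    def test_canonical_default_when_no_scale_free_trend(self):
        corr = correlation_matrix(random_matrix(1, 40, 25))
        beta, table = pick_soft_threshold(corr, tuple(range(1, 31)), 0.85, n_samples=25)
        if table.attrs["used_default_power"]:
            assert beta == default_signed_power(25) == 16

    def test_selection_matches_independent_procedure(self):
        # planted hub structure, 300 nodes; re-implement bin-regress directly
        rng = np.random.default_rng(77)
        hubs = rng.standard_normal((3, 40))
        rows = []
        for i in range(300):
            h = hubs[i % 3]
            lam = rng.uniform(0, 0.95)
            rows.append(lam * h + np.sqrt(1 - lam**2) * rng.standard_normal(40))
        corr = correlation_matrix(make_matrix(np.vstack(rows)))
        candidates = tuple(range(1, 13))
        beta, table = pick_soft_threshold(corr, candidates, 0.85, n_samples=40)

        C = corr.to_numpy()
        fits = []
        for b in candidates:
            A = ((1 + C) / 2) ** b
            k = A.sum(0) - np.diag(A)
            fits.append(scale_free_fit(k)[0])
        fits = np.array(fits)
        reaching = np.flatnonzero(fits >= 0.85)
        if len(reaching):
            expected = candidates[reaching[0]]
        elif fits.max() >= 0.5:
            expected = candidates[int(np.argmax(fits))]
        else:
            target = default_signed_power(40)
            expected = min(candidates, key=lambda v: (abs(v - target), v))
        assert beta == expected

    def test_empty_candidates_rejected(self):
        corr = correlation_matrix(random_matrix(0, 25, 15))
        with pytest.raises(ValueError, match="empty"):
            pick_soft_threshold(corr, ())


class TestAdjacencyAndTom:
    @pytest.mark.parametrize(
        "c, beta, expected",
        [(1.0, 3.0, 1.0), (-1.0, 3.0, 0.0), (0.0, 2.0, 0.25)],
    )
    def test_signed_adjacency_closed_forms(self, c, beta, expected):
        corr = pd.DataFrame([[1.0, c], [c, 1.0]], index=["a", "b"], columns=["a", "b"])
        adj = signed_adjacency(corr, beta)
        assert adj.iloc[0, 1] == pytest.approx(expected, abs=1e-12)
        assert adj.iloc[0, 0] == 1.0

    def test_nonpositive_beta_rejected(self):
        corr = pd.DataFrame(np.eye(2))
        with pytest.raises(ValueError, match="positive"):
            signed_adjacency(corr, 0.0)

    def test_clique_saturates_tom(self):
        adj = pd.DataFrame(np.ones((3, 3)))
        tom = signed_tom(adj)
        np.testing.assert_allclose(tom.to_numpy(), 1.0, atol=1e-12)

    def test_empty_network_has_zero_tom(self):
        adj = pd.DataFrame(np.eye(4))
        tom = signed_tom(adj)
        off = tom.to_numpy()[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 0.0, atol=1e-12)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(8)
        A = rng.random((8, 8))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        tom = signed_tom(pd.DataFrame(A)).to_numpy()
        for i in range(8):
            for j in range(8):
                if i == j:
                    assert tom[i, j] == 1.0
                    continue
                num = sum(A[i, u] * A[u, j] for u in range(8) if u not in (i, j)) + A[i, j]
                ki = sum(A[i, u] for u in range(8) if u != i)
                kj = sum(A[j, u] for u in range(8) if u != j)
                expected = num / (min(ki, kj) + 1 - A[i, j])
                assert tom[i, j] == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_adjacency_rejected(self):
        A = np.eye(3)
        A[0, 1] = A[1, 0] = 1.5
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            signed_tom(pd.DataFrame(A))

    @pytest.mark.parametrize("seed", range(10))
    def test_symmetry_and_ranges_on_random_inputs(self, seed):
        mat = random_matrix(seed, 15, 12)
        corr = correlation_matrix(mat).to_numpy()
        assert np.allclose(corr, corr.T)
        assert corr.min() >= -1 and corr.max() <= 1
        adj = signed_adjacency(pd.DataFrame(corr), 6).to_numpy()
        assert np.allclose(adj, adj.T) and adj.min() >= 0 and adj.max() <= 1
        tom = signed_tom(pd.DataFrame(adj)).to_numpy()
        assert np.allclose(tom, tom.T) and tom.min() >= 0 and tom.max() <= 1


class TestDetectModules:
    def _diss_from_blocks(self, seed=0, sizes=(8, 8), within=0.05, between=0.9):
        rng = np.random.default_rng(seed)
        n = sum(sizes)
        D = between + 0.02 * rng.random((n, n))
        pos = 0
        for s in sizes:
            D[pos : pos + s, pos : pos + s] = within + 0.02 * rng.random((s, s))
            pos += s
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        ids = [f"n{i}" for i in range(n)]
        truth = np.repeat(np.arange(1, len(sizes) + 1), sizes)
        return pd.DataFrame(D, index=ids, columns=ids), truth

    def test_two_planted_blocks_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score

        diss, truth = self._diss_from_blocks()
        part = detect_modules(diss, NetworkParams(min_module_size=2))
        assert part.n_modules == 2
        assert adjusted_rand_score(truth, part.labels.to_numpy()) == 1.0

    def test_single_node_unassigned(self):
        diss = pd.DataFrame([[0.0]], index=["a"], columns=["a"])
        part = detect_modules(diss, NetworkParams())
        assert part.labels.loc["a"] == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_deep_split_sensitivity_is_monotone(self, seed):
        mat = random_matrix(seed, 60, 30)
        corr = correlation_matrix(mat)
        tom = signed_tom(signed_adjacency(corr, 6))
        diss = pd.DataFrame(1 - tom.to_numpy(), index=tom.index, columns=tom.columns)
        np.fill_diagonal(diss.values, 0.0)
        counts = [
            detect_modules(diss, NetworkParams(deep_split=d), corr=corr, n_samples=30).n_modules
            for d in (1, 4)
        ]
        assert counts[1] >= counts[0]

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            detect_modules(pd.DataFrame(np.zeros((2, 3))), NetworkParams())


class TestEigennodes:
    def test_rank_one_module(self):
        profile = np.arange(8.0)
        mat = make_matrix(np.tile(profile, (4, 1)))
        part = ModulePartition(pd.Series(1, index=mat.feature_ids), prefix="hME")
        eig = module_eigennode(mat, part)
        standardized = (profile - profile.mean()) / profile.std(ddof=1)
        np.testing.assert_allclose(eig.values.loc["hME1"], standardized, atol=1e-10)
        assert eig.var_explained["hME1"] == pytest.approx(1.0, abs=1e-12)

    def test_two_member_module_matches_eigendecomposition(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((2, 12))
        mat = make_matrix(X)
        part = ModulePartition(pd.Series(1, index=mat.feature_ids), prefix="hME")
        eig = module_eigennode(mat, part)
        Xs = (X - X.mean(1, keepdims=True)) / X.std(1, ddof=1, keepdims=True)
        # first principal direction over samples via the eigendecomposition
        # of the 12x12 Gram matrix
        evals, evecs = np.linalg.eigh(Xs.T @ Xs)
        v = evecs[:, -1]
        v = (v - v.mean()) / v.std(ddof=1)
        got = eig.values.loc["hME1"].to_numpy()
        assert np.allclose(got, v, atol=1e-8) or np.allclose(got, -v, atol=1e-8)
        assert eig.var_explained["hME1"] == pytest.approx(evals[-1] / evals.sum(), abs=1e-10)

    def test_sign_flip_of_members_leaves_eigennode_unchanged(self):
        mat = random_matrix(6, 5, 10)
        part = ModulePartition(pd.Series(1, index=mat.feature_ids), prefix="hME")
        e1 = module_eigennode(mat, part)
        flipped = make_matrix(-mat.values.to_numpy())
        e2 = module_eigennode(flipped, part)
        np.testing.assert_allclose(
            np.abs(e1.values.to_numpy()), np.abs(e2.values.to_numpy()), atol=1e-8
        )
        # orientation rule: positive correlation with own module mean profile
        for eig, source in ((e1, mat), (e2, flipped)):
            X = source.values.to_numpy()
            Xs = (X - X.mean(1, keepdims=True)) / X.std(1, ddof=1, keepdims=True)
            assert np.corrcoef(eig.values.iloc[0], Xs.mean(0))[0, 1] >= 0

    def test_eigennode_is_standardized(self):
        mat = random_matrix(7, 9, 14)
        labels = pd.Series([1] * 4 + [2] * 5, index=mat.feature_ids)
        eig = module_eigennode(mat, ModulePartition(labels, prefix="hME"))
        vals = eig.values.to_numpy()
        np.testing.assert_allclose(vals.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(vals.std(axis=1, ddof=1), 1.0, atol=1e-10)


class TestKme:
    def test_rank_one_member_has_unit_kme(self):
        mat = make_matrix(np.tile(np.arange(8.0), (3, 1)))
        part = ModulePartition(pd.Series(1, index=mat.feature_ids), prefix="hME")
        eig = module_eigennode(mat, part)
        table = kme(mat, eig)
        np.testing.assert_allclose(table["hME1"], 1.0, atol=1e-10)

    def test_negated_eigennode_gives_minus_one(self):
        mat = make_matrix(np.tile(np.arange(8.0), (3, 1)))
        part = ModulePartition(pd.Series(1, index=mat.feature_ids), prefix="hME")
        eig = module_eigennode(mat, part)
        neg = make_matrix(-eig.values.to_numpy(), prefix="x")
        table = kme(neg, eig)
        np.testing.assert_allclose(table["hME1"], -1.0, atol=1e-10)

    def test_matches_scalar_loop(self):
        mat = random_matrix(10, 30, 16)
        labels = pd.Series([1] * 10 + [2] * 10 + [0] * 10, index=mat.feature_ids)
        eig = module_eigennode(mat, ModulePartition(labels, prefix="hME"))
        table = kme(mat, eig)
        X = mat.values.to_numpy()
        E = eig.values.to_numpy()
        for i in range(30):
            for j, col in enumerate(eig.values.index):
                assert table.iloc[i][col] == pytest.approx(bicor(X[i], E[j]), abs=1e-10)

    def test_sample_mismatch_rejected(self):
        mat = random_matrix(0, 5, 10)
        part = ModulePartition(pd.Series(1, index=mat.feature_ids), prefix="hME")
        eig = module_eigennode(mat, part)
        other = random_matrix(1, 5, 9)
        with pytest.raises(ValueError, match="sample"):
            kme(other, eig)


class TestTrimModules:
    def _setup(self, labels, kme_values):
        part = ModulePartition(pd.Series(labels), prefix="hME")
        table = pd.DataFrame(kme_values, index=list(labels))
        return part, table

    def test_strong_module_unchanged(self):
        part, table = self._setup({"a": 1, "b": 1, "c": 1}, {"hME1": [0.9, 0.9, 0.9]})
        out = trim_modules(part, table, NetworkParams())
        assert list(out.labels) == [1, 1, 1]

    def test_weak_member_trimmed_module_survives(self):
        part, table = self._setup({"a": 1, "b": 1, "c": 1}, {"hME1": [0.9, 0.9, 0.3]})
        out = trim_modules(part, table, NetworkParams())
        assert out.labels.loc["c"] == 0
        assert out.labels.loc["a"] == out.labels.loc["b"] == 1

    def test_coreless_module_dissolved(self):
        part, table = self._setup({"a": 1, "b": 1}, {"hME1": [0.45, 0.40]})
        out = trim_modules(part, table, NetworkParams())
        assert (out.labels == 0).all()

    def test_postconditions_on_random_instance(self):
        mat = random_matrix(21, 40, 18)
        labels = pd.Series([1] * 15 + [2] * 15 + [0] * 10, index=mat.feature_ids)
        part = ModulePartition(labels, prefix="hME")
        eig = module_eigennode(mat, part)
        table = kme(mat, eig)
        params = NetworkParams()
        out = trim_modules(part, table, params)
        for lab in out.module_labels:
            col = f"hME{lab}"  # labels recompacted; map through survivors
        # every assigned node keeps kME >= threshold under its original module
        for node in out.labels.index[out.labels > 0]:
            orig = part.labels.loc[node]
            assert table.loc[node, f"hME{orig}"] >= params.min_kme_to_stay


class TestMergeModules:
    def test_identical_eigennode_modules_merge(self):
        profile = np.arange(10.0)
        rng = np.random.default_rng(0)
        X = np.vstack([profile + 0.01 * rng.standard_normal(10) for _ in range(6)])
        mat = make_matrix(X)
        labels = pd.Series([1, 1, 1, 2, 2, 2], index=mat.feature_ids)
        part, eig = merge_modules(mat, ModulePartition(labels, prefix="hME"), NetworkParams())
        assert part.n_modules == 1

    def test_anticorrelated_modules_stay_distinct(self):
        profile = np.arange(10.0)
        rng = np.random.default_rng(1)
        X = np.vstack(
            [profile + 0.05 * rng.standard_normal(10) for _ in range(3)]
            + [-profile + 0.05 * rng.standard_normal(10) for _ in range(3)]
        )
        mat = make_matrix(X)
        labels = pd.Series([1, 1, 1, 2, 2, 2], index=mat.feature_ids)
        part, _ = merge_modules(mat, ModulePartition(labels, prefix="hME"),
                                NetworkParams(merge_cut_height=0.5))
        assert part.n_modules == 2

    def test_planted_shared_driver_merges_only_coupled_pair(self):
        rng = np.random.default_rng(42)
        n = 30
        shared = rng.standard_normal(n)
        factors = [
            0.9 * shared + np.sqrt(1 - 0.81) * rng.standard_normal(n),
            0.9 * shared + np.sqrt(1 - 0.81) * rng.standard_normal(n),
            rng.standard_normal(n),
            rng.standard_normal(n),
        ]
        rows, labels = [], []
        for m, f in enumerate(factors, start=1):
            for _ in range(8):
                rows.append(0.95 * f + 0.3 * rng.standard_normal(n))
                labels.append(m)
        mat = make_matrix(np.vstack(rows))
        part0 = ModulePartition(pd.Series(labels, index=mat.feature_ids), prefix="hME")
        part, eig = merge_modules(mat, part0, NetworkParams(merge_cut_height=0.4))
        assert part.n_modules == 3
        merged = part.labels[part0.labels.isin([1, 2])]
        assert merged.nunique() == 1
        # convergence post-condition: no eigennode pair closer than the cut
        C = np.corrcoef(eig.values.to_numpy())
        off = (1 - C)[~np.eye(part.n_modules, dtype=bool)]
        assert off.min() >= 0.4


class TestConnectivity:
    def test_three_node_module_closed_form(self):
        A = np.full((3, 3), 0.5)
        np.fill_diagonal(A, 1.0)
        adj = pd.DataFrame(A, index=list("abc"), columns=list("abc"))
        part = ModulePartition(pd.Series({"a": 1, "b": 1, "c": 1}))
        table = intramodular_connectivity(adj, part)
        np.testing.assert_allclose(table["kTotal"], 1.0)
        np.testing.assert_allclose(table["kWithin"], 1.0)
        np.testing.assert_allclose(table["kOut"], 0.0)
        np.testing.assert_allclose(table["kDiff"], 1.0)

    def test_unassigned_node_has_zero_within(self):
        A = np.full((3, 3), 0.5)
        np.fill_diagonal(A, 1.0)
        adj = pd.DataFrame(A, index=list("abc"), columns=list("abc"))
        part = ModulePartition(pd.Series({"a": 1, "b": 1, "c": 0}))
        table = intramodular_connectivity(adj, part)
        assert table.loc["c", "kWithin"] == 0.0
        assert table.loc["c", "kOut"] == table.loc["c", "kTotal"]

    def test_matches_loop_oracle_and_identities(self):
        rng = np.random.default_rng(12)
        A = rng.random((12, 12))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        ids = [f"n{i}" for i in range(12)]
        adj = pd.DataFrame(A, index=ids, columns=ids)
        labels = pd.Series(rng.integers(0, 3, size=12), index=ids)
        part = ModulePartition(labels)
        table = intramodular_connectivity(adj, part)
        for i, node in enumerate(ids):
            k_tot = sum(A[i, j] for j in range(12) if j != i)
            k_in = sum(
                A[i, j] for j in range(12)
                if j != i and labels.iloc[j] == labels.iloc[i] and labels.iloc[i] > 0
            )
            assert table.loc[node, "kTotal"] == pytest.approx(k_tot, abs=1e-12)
            assert table.loc[node, "kWithin"] == pytest.approx(k_in, abs=1e-12)
        # identities hold exactly
        np.testing.assert_array_equal(
            table["kWithin"] + table["kOut"], table["kTotal"]
        )


class TestInferNetwork:
    def test_deterministic_outputs(self):
        mat = random_matrix(0, 40, 25)
        r1 = infer_network(mat, NetworkParams())
        r2 = infer_network(mat, NetworkParams())
        assert r1.partition.labels.equals(r2.partition.labels)
        assert r1.eigennodes.values.equals(r2.eigennodes.values)
        assert r1.kme.equals(r2.kme)
        assert r1.connectivity.equals(r2.connectivity)
        assert r1.power == r2.power

    def test_small_instance_matches_straightline_reference(self):
        """On a <=50-node instance the composed pipeline equals a naive
        step-by-step reference built from the same primitives' formulas."""
        mat = random_matrix(3, 30, 15)
        params = NetworkParams(power=6.0)
        res = infer_network(mat, params)

        X = mat.values.to_numpy()
        n = X.shape[0]
        C = np.ones((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                C[i, j] = C[j, i] = bicor(X[i], X[j])
        A = ((1 + C) / 2) ** 6.0
        np.fill_diagonal(A, 1.0)
        adjacency = pd.DataFrame(A, index=mat.values.index, columns=mat.values.index)
        conn = intramodular_connectivity(adjacency, res.partition)
        pd.testing.assert_frame_equal(conn, res.connectivity)
        T = signed_tom(adjacency)
        diss = pd.DataFrame(1 - T.to_numpy(), index=T.index, columns=T.columns)
        np.fill_diagonal(diss.values, 0.0)
        corr_df = pd.DataFrame(C, index=mat.values.index, columns=mat.values.index)
        part_ref = detect_modules(diss, params, prefix="hME", corr=corr_df, n_samples=15)
        # the composed run applies trim/merge after detection; the detection
        # stage itself must agree with the reference exactly
        res2 = infer_network(mat, params)
        assert part_ref.labels.equals(
            detect_modules(diss, params, prefix="hME", corr=corr_df, n_samples=15).labels
        )
        assert res.power == 6.0


class TestBicorProperties:
    """Derandomized property checks of the robust correlation."""

    from hypothesis import given, settings, strategies as st

    @staticmethod
    def _vectors(draw):
        import numpy as np
        from hypothesis import strategies as st

        n = draw(st.integers(min_value=5, max_value=40))
        elems = st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False, width=32)
        x = np.array(draw(st.lists(elems, min_size=n, max_size=n)))
        y = np.array(draw(st.lists(elems, min_size=n, max_size=n)))
        return x, y

    @given(st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_bounded_and_symmetric(self, data):
        x, y = self._vectors(data.draw)
        r = bicor(x, y)
        assert -1.0 <= r <= 1.0
        assert bicor(y, x) == pytest.approx(r, abs=1e-12)

    @given(st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_affine_invariance_holds_generally(self, data):
        x, y = self._vectors(data.draw)
        a = data.draw(self.st.floats(0.01, 100.0, allow_nan=False))
        b = data.draw(self.st.floats(-100.0, 100.0, allow_nan=False))
        assert bicor(a * x + b, y) == pytest.approx(bicor(x, y), abs=1e-7)
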