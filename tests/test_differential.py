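import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from ahquant.differential import (
    ConfigurationError,
    RunMatrix,
    cross_run_normalize,
    design_dia_windows,
    fold_change,
    oplsda,
    qvalue_filter,
    read_run_matrix,
    rollup,
    select_deps,
    validation_test,
    write_run_matrix,
)


def make_matrix(data, groups=None, qvalues=None):
    df = pd.DataFrame(data).T  # dict of run -> {protein: value}
    df = pd.DataFrame(data)
    if groups is None:
        groups = {c: ("before" if c.startswith("b") else "after") for c in df.columns}
    return RunMatrix(df, pd.Series(groups), None if qvalues is None else pd.Series(qvalues))


def frag_rows(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "protein_accession",
            "peptide_sequence",
            "fragment_id",
            "run_id",
            "group",
            "intensity",
        ],
    )


class TestRollup:
    def test_fragments_sum_to_protein_intensity(self):
        t = frag_rows(
            [
                ("P1", "PEPTIDEK", "y1", "b1", "before", 10.0),
                ("P1", "PEPTIDEK", "y2", "b1", "before", 20.0),
                ("P1", "PEPTIDEK", "y3", "b1", "before", 30.0),
            ]
        )
        m = rollup(t)
        assert m.data.loc["P1", "b1"] == pytest.approx(60.0)

    def test_row_order_invariance(self, small_study):
        _, _, fragments, _ = small_study
        shuffled = fragments.sample(frac=1.0, random_state=0)
        a = rollup(fragments)
        b = rollup(shuffled)
        pd.testing.assert_frame_equal(a.data.sort_index(), b.data.sort_index())

    def test_rollup_conserves_total_signal(self, small_study):
        _, peptides, fragments, _ = small_study
        m = rollup(fragments)
        assert m.data.sum().sum() == pytest.approx(fragments.intensity.sum(), rel=1e-9)
        assert m.data.sum().sum() == pytest.approx(peptides.intensity.sum(), rel=1e-9)

    def test_negative_area_rejected(self):
        t = frag_rows([("P1", "PEPTIDEK", "y1", "b1", "before", -1.0)])
        with pytest.raises(ValueError):
            rollup(t)


class TestQvalueFilter:
    def test_closed_boundary(self):
        m = make_matrix(
            {"b1": [1, 1, 1], "a1": [1, 1, 1]},
            groups={"b1": "before", "a1": "after"},
        )
        m.data.index = ["P1", "P2", "P3"]
        m.qvalues = pd.Series({"P1": 0.005, "P2": 0.02, "P3": 0.01})
        out = qvalue_filter(m, cutoff=0.01)
        assert list(out.data.index) == ["P1", "P3"]

    def test_all_zero_q_keeps_everything(self):
        m = make_matrix({"b1": [1.0, 2.0], "a1": [3.0, 4.0]})
        m.qvalues = pd.Series(0.0, index=m.data.index)
        assert qvalue_filter(m, cutoff=0.01).data.shape[0] == 2

    def test_cutoff_zero_keeps_only_zero_q(self):
        m = make_matrix({"b1": [1.0, 2.0], "a1": [3.0, 4.0]})
        m.qvalues = pd.Series([0.0, 0.001], index=m.data.index)
        assert qvalue_filter(m, cutoff=0.0).data.shape[0] == 1

    def test_missing_qvalues_pass_through_with_warning(self, caplog):
        m = make_matrix({"b1": [1.0], "a1": [2.0]})
        with caplog.at_level("WARNING"):
            out = qvalue_filter(m)
        assert out.data.shape[0] == 1
        assert "skipped" in caplog.text


class TestNormalization:
    def test_exact_recovery_of_pure_bias(self):
        rng = np.random.default_rng(0)
        base = rng.lognormal(10, 1, size=50)
        m = make_matrix({"b1": base, "a1": 2.0 * base})
        norm, factors = cross_run_normalize(m)
        assert factors["b1"] == pytest.approx(1.0)
        assert factors["a1"] == pytest.approx(2.0)
        assert np.allclose(norm.data["b1"], norm.data["a1"])

    def test_idempotence(self):
        rng = np.random.default_rng(1)
        m = make_matrix({"b1": rng.lognormal(8, 1, 40), "a1": rng.lognormal(8, 1, 40)})
        norm, _ = cross_run_normalize(m)
        _, factors2 = cross_run_normalize(norm)
        assert np.allclose(factors2.to_numpy(), 1.0, atol=1e-12)

    def test_bias_recovery_within_2pct_under_de_contamination(self):
        """Known multiplicative biases in [0.5, 2] recovered within 2% even
        with 10% of rows genuinely regulated."""
        rng = np.random.default_rng(2)
        n = 2000
        base = rng.lognormal(10, 1.0, size=n)
        true_bias = {"b1": 1.0, "b2": 0.5, "b3": 1.3, "a1": 2.0, "a2": 0.8, "a3": 1.6}
        data = {}
        # regulated rows split exactly evenly up/down, as in the generative model
        idx = rng.permutation(n)
        de_up = np.zeros(n, bool)
        de_down = np.zeros(n, bool)
        de_up[idx[: n // 20]] = True
        de_down[idx[n // 20 : n // 10]] = True
        for run, b in true_bias.items():
            v = base * b
            if run.startswith("a"):
                v = np.where(de_up, v * 4.0, np.where(de_down, v / 4.0, v))
            data[run] = v
        m = make_matrix(data)
        _, factors = cross_run_normalize(m)
        anchored = pd.Series(true_bias) / min(true_bias.values())
        for run in true_bias:
            assert factors[run] == pytest.approx(anchored[run], rel=0.02)

    def test_rt_local_mode_removes_rt_dependent_bias(self):
        rng = np.random.default_rng(3)
        n = 300
        rt = pd.Series(np.sort(rng.uniform(0, 100, n)))
        base = rng.lognormal(9, 1, n)
        # run a1 has a drift growing with retention time
        drift = np.exp(rt.to_numpy() / 100.0)
        m = make_matrix({"b1": base, "a1": base * drift})
        m.data.index = rt.index
        norm, _ = cross_run_normalize(m, mode="rt_local", rt=rt, n_bins=10)
        resid = np.log(norm.data["a1"] / norm.data["b1"])
        assert resid.abs().median() < 0.1

    def test_unknown_mode_rejected(self):
        m = make_matrix({"b1": [1.0], "a1": [1.0]})
        with pytest.raises(ConfigurationError):
            cross_run_normalize(m, mode="quantile")


class TestFoldChange:
    def test_geometric_mean_ratio(self):
        m = make_matrix(
            {"b1": [2.0], "b2": [2.0], "b3": [2.0], "a1": [8.0], "a2": [8.0], "a3": [8.0]}
        )
        fc = fold_change(m)
        assert fc.fc.iloc[0] == pytest.approx(4.0)

    def test_identical_groups_give_unit_fc(self):
        m = make_matrix({"b1": [5.0, 1.0], "a1": [5.0, 1.0]})
        assert np.allclose(fold_change(m).fc.to_numpy(), 1.0)

    def test_noise_free_truth_recovered_exactly(self, noise_free_study):
        records, peptides, truth = noise_free_study
        m = rollup(peptides)
        fc = fold_change(m).set_index("accession")
        want = truth.proteins.set_index("accession").true_fc
        got = fc.fc.loc[want.index]
        assert np.allclose(got.to_numpy(), want.to_numpy(), rtol=1e-9)

    def test_group_absence_flagged_not_dropped(self):
        m = make_matrix({"b1": [np.nan, 1.0], "a1": [2.0, 2.0]})
        fc = fold_change(m)
        assert fc.insufficient.tolist() == [True, False]
        assert np.isnan(fc.fc.iloc[0])

    def test_arithmetic_variant(self):
        m = make_matrix({"b1": [1.0], "b2": [3.0], "a1": [4.0], "a2": [4.0]})
        fc = fold_change(m, method="arithmetic")
        assert fc.fc.iloc[0] == pytest.approx(2.0)


class TestSelectDeps:
    def test_strict_inequality_partition(self):
        res = pd.DataFrame({"accession": list("abcd"), "fc": [2.0, 1.5, 0.5, 1.0]})
        out, counts = select_deps(res, threshold=1.5)
        by = out.set_index("accession").direction
        assert by["a"] == "up" and by["c"] == "down"
        assert by["b"] == "null" and by["d"] == "null"
        assert counts == {"up": 1, "down": 1, "null": 2}

    def test_reciprocal_boundary_is_null(self):
        res = pd.DataFrame({"accession": ["x"], "fc": [1.0 / 1.5]})
        out, _ = select_deps(res, threshold=1.5)
        assert out.direction.iloc[0] == "null"

    def test_partition_exhaustive_and_disjoint(self, small_study):
        _, peptides, _, _ = small_study
        fc = fold_change(rollup(peptides))
        out, counts = select_deps(fc)
        assert sum(counts.values()) == len(out)

    def test_threshold_must_exceed_one(self):
        with pytest.raises(ConfigurationError):
            select_deps(pd.DataFrame({"accession": [], "fc": []}), threshold=1.0)

    def test_spiked_counts_recovered_at_low_noise(self):
        from ahquant.synthetic import SimulationConfig, generate_protein_fasta, simulate_peptide_table

        cfg = SimulationConfig(
            n_proteins=70,
            seq_length_range=(60, 200),
            n_de_proteins=35,  # 18 up / 17 down by the even-split rule
            true_fc=4.0,
            peptide_cv=0.05,
            missing_rate=0.0,
            seed=13,
        )
        records = generate_protein_fasta(cfg)
        peptides, truth = simulate_peptide_table(records, cfg)
        m, _ = cross_run_normalize(rollup(peptides))
        out, counts = select_deps(fold_change(m))
        assert counts["up"] == (truth.proteins.de_flag == "up").sum()
        assert counts["down"] == (truth.proteins.de_flag == "down").sum()


class TestValidationTest:
    def test_identical_groups_p_one(self):
        m = make_matrix({"b1": [4.0], "b2": [4.0], "a1": [4.0], "a2": [4.0]})
        out = validation_test(m)
        assert out.p_value.iloc[0] == 1.0
        assert out.degenerate.iloc[0]

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(5)
        n = 1000
        data = {f"{g}{i}": rng.lognormal(8, 0.5, n) for g in "ba" for i in range(1, 4)}
        out = validation_test(make_matrix(data))
        rate = (out.p_value < 0.05).mean()
        assert 0.02 < rate < 0.08

    def test_large_shift_detected(self):
        rng = np.random.default_rng(6)
        before = {f"b{i}": np.exp(rng.normal(8, 0.01, 5)) for i in range(1, 4)}
        after = {f"a{i}": np.exp(rng.normal(8.7, 0.01, 5)) for i in range(1, 4)}  # 10 SDs on log2
        out = validation_test(make_matrix({**before, **after}))
        assert (out.p_value < 1e-3).all()


class TestOplsda:
    @staticmethod
    def _strong_matrix(n_rows=60, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.lognormal(9, 1, n_rows)
        de = np.zeros(n_rows, dtype=bool)
        de[: n_rows // 2] = True
        data = {}
        for i in range(1, 4):
            data[f"b{i}"] = base * rng.lognormal(0, 0.02, n_rows)
            data[f"a{i}"] = np.where(de, base * 16.0, base) * rng.lognormal(0, 0.02, n_rows)
        return make_matrix(data)

    def test_permutation_floor_under_strong_separation(self):
        m = self._strong_matrix()
        res = oplsda(m, n_permutations=999, seed=1)
        assert res.permutation_p == pytest.approx(1.0 / (res.n_permutations + 1))

    def test_scores_separate_groups(self):
        m = self._strong_matrix(seed=2)
        res = oplsda(m)
        after = res.predictive_scores[[r for r in res.predictive_scores.index if r.startswith("a")]]
        before = res.predictive_scores[[r for r in res.predictive_scores.index if r.startswith("b")]]
        assert min(after) > max(before) or max(after) < min(before)

    def test_duplicated_runs_give_same_scores_up_to_sign(self):
        m = self._strong_matrix(seed=3)
        dup = RunMatrix(
            pd.concat([m.data, m.data.add_suffix("_dup")], axis=1),
            pd.concat([m.groups, m.groups.rename(lambda r: r + "_dup")]),
        )
        r1 = oplsda(m, n_permutations=0)
        r2 = oplsda(dup, n_permutations=0)
        a = r1.predictive_scores.to_numpy()
        b = r2.predictive_scores[[f"{r}" for r in r1.predictive_scores.index]].to_numpy()
        assert np.allclose(a, b, rtol=1e-8) or np.allclose(a, -b, rtol=1e-8)

    def test_predictive_component_matches_pls_when_no_orthogonal(self):
        """With zero orthogonal components the predictive scores coincide
        (up to scale/sign) with the first PLS component of an independent
        implementation."""
        m = self._strong_matrix(seed=4)
        res = oplsda(m, n_orthogonal=0, n_permutations=0)
        X = np.log2(m.data.to_numpy().T)
        X = X - X.mean(axis=0)
        y = np.array([1.0 if m.groups[r] == "after" else -1.0 for r in m.data.columns])
        pls = PLSRegression(n_components=1, scale=False).fit(X, y - y.mean())
        t_sklearn = pls.x_scores_[:, 0]
        corr = np.corrcoef(res.predictive_scores.to_numpy(), t_sklearn)[0, 1]
        assert abs(corr) > 0.9999

    def test_null_labels_not_overcalled(self):
        rng = np.random.default_rng(7)
        n = 50
        data = {f"r{i}": rng.lognormal(9, 1, n) * rng.lognormal(0, 0.3, n) for i in range(8)}
        groups = {f"r{i}": ("before" if i < 4 else "after") for i in range(8)}
        m = RunMatrix(pd.DataFrame(data), pd.Series(groups))
        res = oplsda(m, n_permutations=199, seed=8)
        assert res.permutation_p > 0.05

    def test_too_few_runs_rejected(self):
        m = make_matrix({"b1": [1.0, 2.0], "a1": [2.0, 1.0]})
        with pytest.raises(ValueError):
            oplsda(m)


class TestDiaWindows:
    def test_single_window_covers_range(self):
        wins = design_dia_windows(np.linspace(410, 890, 100), n_windows=1)
        assert len(wins) == 1
        assert wins[0].lower_mz == 400.0 and wins[0].upper_mz == 900.0
        assert wins[0].precursor_count == 100

    def test_uniform_precursors_near_equal_widths(self):
        rng = np.random.default_rng(9)
        mz = rng.uniform(400, 900, 10000)
        wins = design_dia_windows(mz, n_windows=10)
        widths = np.array([w.upper_mz - w.lower_mz for w in wins])
        assert widths.std() / widths.mean() < 0.10

    def test_bimodal_counts_differ_by_at_most_one(self):
        rng = np.random.default_rng(10)
        mz = np.concatenate(
            [rng.normal(500, 20, 6000), rng.normal(750, 30, 4000)]
        )
        wins = design_dia_windows(mz, n_windows=38)
        counts = [w.precursor_count for w in wins]
        assert max(counts) - min(counts) <= 1
        assert len(wins) == 38
        # contiguous coverage of the configured range
        assert wins[0].lower_mz == 400.0 and wins[-1].upper_mz == 900.0
        for a, b in zip(wins[:-1], wins[1:]):
            assert a.upper_mz == b.lower_mz

    def test_too_few_precursors_rejected(self):
        with pytest.raises(ValueError):
            design_dia_windows([500.0, 600.0], n_windows=38)


class TestMatrixIO:
    def test_round_trip(self, tmp_path, small_study):
        _, peptides, _, _ = small_study
        m = rollup(peptides)
        path = tmp_path / "matrix.tsv"
        write_run_matrix(m, path)
        back = read_run_matrix(path)
        pd.testing.assert_frame_equal(
            back.data, m.data, check_exact=False, rtol=1e-12, check_names=False
        )
        assert (back.groups.loc[m.data.columns] == m.groups.loc[m.data.columns]).all()
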