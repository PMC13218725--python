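import numpy as np
import pandas as pd
import pytest
from scipy import stats

from abundmat import matrices, predict, simulate
from abundmat.io import POOL_COLUMNS


def _pool_two_proteins():
    rows = [
        ("PA", "A", 1, "A", "V", 0.9, 0.05),
        ("PA", "A", 2, "L", "D", 0.1, 0.05),
        ("PA", "A", 3, "K", "R", 0.8, 0.05),
        ("PB", "A", 1, "A", "V", 0.4, 0.05),
        ("PB", "A", 2, "L", "D", 0.2, 0.05),
        ("PB", "A", 3, "K", "R", 0.7, 0.05),
    ]
    pool = pd.DataFrame(rows, columns=POOL_COLUMNS)
    residues = pool[["protein", "chain", "position", "wt"]].drop_duplicates()
    features = residues.assign(rasa=0.05, wcn=5.0, ss3="loop", ss8="-",
                               phi=np.nan, psi=np.nan, crystal_resolved=True)
    return pool, features


class TestPredictLopo:
    def test_single_cell_mean_is_the_prediction(self):
        pool, features = _pool_two_proteins()
        pred = predict.predict_lopo(pool, features, scheme="exposure")
        pa = pred[pred["protein"] == "PA"]
        # the only buried A->V training record for PA is PB's, score 0.4
        assert pa.loc[pa["wt"] == "A", "prediction"].iloc[0] == pytest.approx(0.4)
        assert "buried[A->V]" in pa.loc[pa["wt"] == "A", "provenance"].iloc[0]

    def test_lopo_leakage(self, benchmark6):
        """Corrupting every score of one protein changes no prediction for
        that protein."""
        bm = benchmark6
        pred0 = predict.predict_lopo(bm.pool, bm.features, scheme="exposure")
        corrupted = bm.pool.copy()
        mask = corrupted["protein"] == "SYN2"
        corrupted.loc[mask, "score"] += 10.0
        pred1 = predict.predict_lopo(corrupted, bm.features, scheme="exposure")
        p0 = pred0[pred0["protein"] == "SYN2"]["prediction"].to_numpy()
        p1 = pred1[pred1["protein"] == "SYN2"]["prediction"].to_numpy()
        np.testing.assert_array_equal(p0, p1)

    def test_provenance_is_total(self, mini_benchmark):
        pred = predict.predict_lopo(mini_benchmark.pool, mini_benchmark.features)
        has_pred = pred["prediction"].notna()
        assert (pred.loc[has_pred, "provenance"] != "missing").all()
        assert (pred.loc[~has_pred, "provenance"] == "missing").all()

    def test_single_protein_pool_is_error(self):
        pool, features = _pool_two_proteins()
        pool = pool[pool["protein"] == "PA"]
        with pytest.raises(ValueError, match="two proteins"):
            predict.predict_lopo(pool, features)

    def test_per_protein_r_near_attenuation_ceiling(self):
        """With noise sd 0.1 on scores generated from known matrices, the
        per-protein r approaches sd(cell means)/sqrt(var(cell means)+0.01),
        the analytic attenuation ceiling."""
        cfg = simulate.GeneratorConfig(
            n_proteins=6, residues_per_protein=100, noise_sd=0.1,
            completeness=1.0, dimer_proteins=(), n_degron_sites=0,
            n_lefthanded_sites=0, seed=21,
        )
        bm = simulate.make_benchmark(cfg)
        pred = predict.predict_lopo(bm.pool, bm.features, scheme="exposure")
        ev = predict.evaluate(pred)
        merged = pred.dropna(subset=["prediction"])
        for _, row in ev.iterrows():
            g = merged[merged["protein"] == row["protein_id"]]
            s_true = np.std(g["prediction"])  # spread of cell means seen
            ceiling = s_true / np.sqrt(s_true**2 + 0.01)
            assert row["r"] == pytest.approx(ceiling, abs=0.05)


class TestMatrixRecovery:
    def test_lopo_matrices_unbiased_within_noise(self, benchmark6):
        """LOPO-recovered exposure matrices are unbiased estimates of the
        generating matrices: over all cells with count >= 20 the per-cell
        z = error/SEM behaves as a unit normal (>= 99% within 3 SEM, none
        beyond 5)."""
        bm = benchmark6
        ordinary = bm.truth[bm.truth["special"] == "none"][["protein", "position"]]
        pool = bm.pool.merge(ordinary, on=["protein", "position"])
        zs = []
        for prot in sorted(pool["protein"].unique()):
            ms = matrices.build_matrix_set(pool, bm.features, "exposure",
                                           exclude_proteins={prot})
            for env in ("buried", "exposed"):
                m = ms[env]
                mask = m.count >= 20
                sem = bm.config.noise_sd / np.sqrt(np.maximum(m.count, 1))
                z = np.abs(m.mean - bm.true_matrices[env]) / sem
                zs.extend(z[mask].tolist())
        zs = np.array(zs)
        assert len(zs) > 500
        assert np.mean(zs < 3.0) >= 0.99
        assert zs.max() < 5.0


class TestEvaluate:
    def _frame(self, score, pred):
        return pd.DataFrame({"protein": "P", "score": score, "prediction": pred})

    def test_perfect_prediction(self):
        x = [0.1, 0.5, 0.9, 0.3]
        ev = predict.evaluate(self._frame(x, x))
        assert ev["r"].iloc[0] == pytest.approx(1.0)
        assert ev["mae"].iloc[0] == pytest.approx(0.0)

    def test_anti_prediction(self):
        x = np.array([0.1, 0.5, 0.9, 0.3])
        ev = predict.evaluate(self._frame(x, 1 - x))
        assert ev["r"].iloc[0] == pytest.approx(-1.0)

    def test_textbook_formulas_on_hand_example(self):
        """r, r_s and MAE match direct textbook-formula computation on a
        five-pair example."""
        x = np.array([0.11, 0.52, 0.48, 0.97, 0.33])
        y = np.array([0.25, 0.40, 0.55, 0.80, 0.20])
        ev = predict.evaluate(self._frame(x, y))
        r_manual = (np.sum((x - x.mean()) * (y - y.mean()))
                    / np.sqrt(np.sum((x - x.mean())**2) * np.sum((y - y.mean())**2)))
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        rs_manual = (np.sum((rx - rx.mean()) * (ry - ry.mean()))
                     / np.sqrt(np.sum((rx - rx.mean())**2) * np.sum((ry - ry.mean())**2)))
        assert ev["r"].iloc[0] == pytest.approx(r_manual, abs=1e-12)
        assert ev["r_s"].iloc[0] == pytest.approx(rs_manual, abs=1e-12)
        assert ev["mae"].iloc[0] == pytest.approx(np.mean(np.abs(x - y)), abs=1e-12)

    def test_missing_predictions_counted(self):
        df = self._frame([0.1, 0.2, 0.3, 0.4], [0.1, np.nan, 0.3, 0.4])
        ev = predict.evaluate(df)
        assert ev["n_evaluated"].iloc[0] == 3
        assert ev["n_missing_predictions"].iloc[0] == 1

    def test_too_few_pairs_is_error(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            predict.evaluate(self._frame([0.1, 0.2], [0.1, 0.2]))


class TestGridSearch:
    def test_zero_wcn_rows_equal_pure_rasa_scan(self, mini_benchmark):
        """Classification with c_wcn = 0 reduces to the pure-rASA rule, so
        LOPO results at (c_rasa, 0) must be bit-identical to a scan that
        never considers WCN."""
        bm = mini_benchmark
        feats_nowcn = bm.features.copy()
        feats_nowcn["wcn"] = 0.0  # kill the WCN signal entirely
        grid = [0.0, 0.1, 0.2]
        a = predict.grid_search_cutoffs(bm.pool, bm.features,
                                        c_rasa_grid=grid, c_wcn_grid=[0.0])
        b = predict.grid_search_cutoffs(bm.pool, feats_nowcn,
                                        c_rasa_grid=grid, c_wcn_grid=[0.0])
        np.testing.assert_array_equal(a["mean_r"].to_numpy(), b["mean_r"].to_numpy())
        np.testing.assert_array_equal(a["mean_mae"].to_numpy(),
                                      b["mean_mae"].to_numpy())

    def test_recovers_planted_cutoff(self, benchmark6):
        """The generating burial threshold (rASA = 0.1) is recovered by the
        grid search within one grid step."""
        bm = benchmark6
        surface = predict.grid_search_cutoffs(
            bm.pool, bm.features,
            c_rasa_grid=np.round(np.arange(0, 0.51, 0.05), 2),
            c_wcn_grid=[0.0, 5.0, 10.0],
        )
        best = surface.attrs["best_r"]
        assert abs(best["c_rasa"] - 0.1) <= 0.05 + 1e-9

    def test_empty_grid_is_error(self, mini_benchmark):
        with pytest.raises(ValueError):
            predict.grid_search_cutoffs(mini_benchmark.pool,
                                        mini_benchmark.features, c_rasa_grid=[])


class TestCombinationAnalysis:
    def test_subset_counts_and_lopo_consistency(self, mini_benchmark):
        bm = mini_benchmark
        table = predict.dataset_combination_analysis(bm.pool, bm.features)
        n = bm.pool["protein"].nunique()
        per_target = table.groupby("target").size()
        assert (per_target == 2 ** (n - 1) - 1).all()
        # the all-others subset equals plain LOPO
        lopo = predict.evaluate(predict.predict_lopo(bm.pool, bm.features))
        full = table[table["n_datasets"] == n - 1]
        for _, row in full.iterrows():
            expected = lopo.loc[lopo["protein_id"] == row["target"], "r"].iloc[0]
            assert row["r"] == pytest.approx(expected, abs=1e-12)

    def test_mean_r_improves_with_more_datasets(self, benchmark6):
        table = predict.dataset_combination_analysis(
            benchmark6.pool, benchmark6.features)
        means = table.groupby("n_datasets")["r"].mean()
        assert means.iloc[-1] >= means.iloc[0] - 0.02


class TestBaselineMatrix:
    def test_symmetric_matrix_symmetric_predictions(self):
        rng = np.random.default_rng(3)
        sym = rng.normal(size=(20, 20))
        sym = (sym + sym.T) / 2
        pool, _ = _pool_two_proteins()
        fwd = predict.baseline_matrix_predict(pool, sym)
        swapped = pool.rename(columns={"wt": "var", "var": "wt"})
        rev = predict.baseline_matrix_predict(swapped, sym)
        np.testing.assert_allclose(fwd["prediction"], rev["prediction"])

    def test_hand_ranked_example(self):
        mat = np.zeros((20, 20))
        from abundmat._aa import AA_INDEX
        mat[AA_INDEX["A"], AA_INDEX["V"]] = 3.0
        mat[AA_INDEX["L"], AA_INDEX["D"]] = 1.0
        mat[AA_INDEX["K"], AA_INDEX["R"]] = 2.0
        pool, _ = _pool_two_proteins()
        pred = predict.baseline_matrix_predict(pool[pool["protein"] == "PA"], mat)
        ev = predict.evaluate(pred)
        # scores 0.9, 0.1, 0.8 vs predictions 3, 1, 2: same ranking
        assert ev["r_s"].iloc[0] == pytest.approx(1.0)

    def test_missing_entries_rejected(self):
        mat = np.full((20, 20), np.nan)
        pool, _ = _pool_two_proteins()
        with pytest.raises(ValueError, match="missing"):
            predict.baseline_matrix_predict(pool, mat)


class TestDdgPrepare:
    def _table(self, vals):
        return pd.DataFrame({"protein": "P", "position": range(1, len(vals) + 1),
                             "wt": "A", "var": "V", "ddg": vals})

    def test_reu_conversion(self):
        out = predict.ddg_prepare(self._table([5.8]), unit="REU")
        assert out["ddg_kcal"].iloc[0] == pytest.approx(2.0)

    def test_dimer_halving(self):
        out = predict.ddg_prepare(self._table([4.0]), unit="kcal", assembly="dimer")
        assert out["ddg_kcal"].iloc[0] == pytest.approx(2.0)

    def test_zero_invariant(self):
        for unit in ("kcal", "REU"):
            for assembly in ("monomer", "dimer"):
                out = predict.ddg_prepare(self._table([0.0]), unit=unit,
                                          assembly=assembly)
                assert out["ddg_kcal"].iloc[0] == 0.0

    def test_unknown_unit_is_error(self):
        with pytest.raises(ValueError, match="unit"):
            predict.ddg_prepare(self._table([1.0]), unit="kJ")


class TestDescriptorCorrelations:
    def test_monotone_scores_give_perfect_rank_correlation(self):
        n = 30
        pool = pd.DataFrame({
            "protein": "P", "chain": "A", "position": np.arange(1, n + 1),
            "wt": "A", "var": "V",
            "score": np.linspace(0, 1, n), "sd": 0.05,
        })
        features = pool[["protein", "chain", "position", "wt"]].assign(
            rasa=np.linspace(0, 0.8, n), wcn=np.linspace(20, 1, n),
            ss3="loop")
        out = predict.descriptor_correlations(pool, features)
        assert out["r_s_rasa"].iloc[0] == pytest.approx(1.0)
        assert out["r_s_wcn"].iloc[0] == pytest.approx(1.0)

    def test_shuffled_wcn_near_zero(self):
        rng = np.random.default_rng(9)
        n = 400
        pool = pd.DataFrame({
            "protein": "P", "chain": "A", "position": np.arange(1, n + 1),
            "wt": "A", "var": "V",
            "score": rng.uniform(0, 1, n), "sd": 0.05,
        })
        features = pool[["protein", "chain", "position", "wt"]].assign(
            rasa=rng.uniform(0, 1, n), wcn=rng.permutation(np.arange(n)).astype(float),
            ss3="loop")
        out = predict.descriptor_correlations(pool, features)
        assert abs(out["r_s_wcn"].iloc[0]) < 2 / np.sqrt(n)

    def test_constant_scores_flagged(self):
        pool = pd.DataFrame({
            "protein": "P", "chain": "A", "position": [1, 2, 3],
            "wt": "A", "var": "V", "score": 0.5, "sd": 0.05,
        })
        features = pool[["protein", "chain", "position", "wt"]].assign(
            rasa=[0.1, 0.2, 0.3], wcn=[1.0, 2.0, 3.0], ss3="loop")
        out = predict.descriptor_correlations(pool, features)
        assert bool(out["degenerate"].iloc[0])


class TestBootstrapCi:
    def test_interval_brackets_mean(self):
        vals = [0.3, 0.4, 0.5, 0.45, 0.55, 0.35]
        mean, lo, hi = predict.bootstrap_mean_ci(vals, n_draws=2000, seed=4)
        assert lo <= mean <= hi
        assert mean == pytest.approx(np.mean(vals))
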