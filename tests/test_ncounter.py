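import numpy as np
import pandas as pd
import pytest

from synores import (
    CalibrationMap,
    SimulationConfig,
    batch_adjust,
    evaluate,
    fit_calibration,
    hk_stability,
    normalize_ncounter,
    read_rcc,
    select_panel_genes,
    simulate_cohort,
    simulate_ncounter_run,
    to_pseudo_rnaseq,
    vst_transform,
    write_rcc,
)
from synores.ncounter import log_counts


@pytest.fixture(scope="module")
def cohort_run():
    cfg = SimulationConfig(n_samples=24, n_genes=150, seed=19)
    counts, clin, truth = simulate_cohort(cfg)
    vst = vst_transform(counts)
    run = simulate_ncounter_run(vst, truth, noise_sd=0.0, seed=4)
    return vst, truth, run


def _true_map(truth, genes, n):
    return CalibrationMap(
        pd.DataFrame(
            {
                "b0": truth.calibration_b0.loc[genes],
                "b1": truth.calibration_b1.loc[genes],
                "r": 1.0,
                "n": n,
            }
        )
    )


class TestRCC:
    def test_write_read_roundtrip_bit_identical(self, cohort_run, tmp_path):
        _, _, run = cohort_run
        paths = write_rcc(run, tmp_path)
        back = read_rcc(paths)
        assert back.counts[run.counts.columns].equals(run.counts)
        assert back.probe_info.equals(run.probe_info.loc[back.probe_info.index])

    def test_missing_code_summary_rejected(self, tmp_path):
        bad = tmp_path / "bad.RCC"
        bad.write_text("<Header>\nFileVersion,1.7\n</Header>\n")
        with pytest.raises(ValueError, match="Code_Summary"):
            read_rcc(bad)

    def test_non_integer_count_names_line(self, tmp_path):
        bad = tmp_path / "frac.RCC"
        bad.write_text(
            "<Code_Summary>\nCodeClass,Name,Accession,Count\n"
            "Endogenous,GENE1,ACC1,12.5\n"
            "Housekeeping,HK1,ACC2,7\nPositive,POS_A,ACC3,100\n</Code_Summary>\n"
        )
        with pytest.raises(ValueError, match="12.5"):
            read_rcc(bad)

    def test_duplicate_probe_rejected(self, tmp_path):
        bad = tmp_path / "dup.RCC"
        bad.write_text(
            "<Code_Summary>\nCodeClass,Name,Accession,Count\n"
            "Endogenous,GENE1,A,5\nEndogenous,GENE1,A,6\n</Code_Summary>\n"
        )
        with pytest.raises(ValueError, match="duplicate probe"):
            read_rcc(bad)

    def test_missing_negatives_warns(self, tmp_path):
        f = tmp_path / "noneg.RCC"
        f.write_text(
            "<Code_Summary>\nCodeClass,Name,Accession,Count\n"
            "Endogenous,GENE1,A,5\nHousekeeping,HK1,B,50\nPositive,POS_A,C,200\n"
            "</Code_Summary>\n"
        )
        with pytest.warns(UserWarning, match="Negative"):
            run = read_rcc(f)
        assert not run.has_negatives


class TestNormalisation:
    def test_doubled_lane_column_matches_its_twin(self, cohort_run):
        _, _, run = cohort_run
        import copy

        run2 = copy.deepcopy(run)
        # make lane 2 an exact doubled copy of lane 1
        run2.counts.iloc[:, 1] = run2.counts.iloc[:, 0] * 2
        norm = normalize_ncounter(run2)
        assert np.allclose(norm.iloc[:, 0], norm.iloc[:, 1], rtol=1e-9)

    def test_simulated_lane_factors_recovered(self, cohort_run):
        vst, truth, _ = cohort_run
        lane_factors = np.tile([0.5, 1.0, 2.0], 8)
        run = simulate_ncounter_run(vst, truth, noise_sd=0.0, lane_factors=lane_factors, seed=5)
        norm = normalize_ncounter(run)
        flat = simulate_ncounter_run(vst, truth, noise_sd=0.0, seed=5)
        norm_flat = normalize_ncounter(flat)
        keep = (norm_flat.mean(axis=1) > 50)  # rounding dominates tiny counts
        ratio = (norm.loc[keep] + 1) / (norm_flat.loc[keep] + 1)
        assert np.abs(ratio.median(axis=0) - 1.0).max() < 0.02

    def test_hk_exclusion_changes_only_geomean(self, cohort_run):
        _, _, run = cohort_run
        norm_all = normalize_ncounter(run, exclude_hk=())
        norm_excl = normalize_ncounter(run, exclude_hk=("HK1",))
        # per-lane ratio must be constant across genes (pure factor change)
        ratio = norm_excl / norm_all
        assert np.allclose(ratio.std(axis=0), 0.0, atol=1e-9)


class TestHkStability:
    def test_constant_probe_ranks_first_and_noisy_flagged(self, cohort_run):
        vst, truth, _ = cohort_run
        rng = np.random.default_rng(0)
        run = simulate_ncounter_run(vst, truth, noise_sd=0.0, seed=6)
        # housekeeping probes are lane-proportional (CV ~ 0) by design
        noisy = run.counts.loc["HK6"].to_numpy(dtype=float)
        run.counts.loc["HK6"] = np.round(
            noisy * np.exp(rng.normal(0, 0.5, size=noisy.size))
        ).astype(int)
        stab = hk_stability(run)
        assert stab["flagged"].loc["HK6"]
        assert stab.loc["HK6", "rank"] == stab["rank"].max()

    def test_ranking_invariant_to_lane_scaling(self, cohort_run):
        _, _, run = cohort_run
        import copy

        run2 = copy.deepcopy(run)
        run2.counts.iloc[:, 0] = run.counts.iloc[:, 0] * 4
        a = hk_stability(run)["rank"]
        b = hk_stability(run2)["rank"]
        assert a.equals(b)


class TestCalibration:
    def test_exact_linear_relation_recovered(self):
        rng = np.random.default_rng(8)
        logn = rng.uniform(1, 8, size=(30, 10))
        nc = pd.DataFrame(np.exp(logn) - 1.0, index=[f"g{i}" for i in range(30)])
        vst = pd.DataFrame(2.0 + 1.5 * logn, index=nc.index, columns=nc.columns)
        cmap = fit_calibration(vst, nc)
        assert np.allclose(cmap.table["b0"], 2.0, atol=1e-9)
        assert np.allclose(cmap.table["b1"], 1.5, atol=1e-9)
        assert np.allclose(cmap.table["r"], 1.0)

    def test_too_few_matched_samples_rejected(self):
        nc = pd.DataFrame(np.ones((3, 2)), index=list("abc"), columns=["s1", "s2"])
        vst = pd.DataFrame(np.ones((3, 2)), index=list("abc"), columns=["s1", "s2"])
        with pytest.raises(ValueError, match="matched samples"):
            fit_calibration(vst, nc)

    def test_noisy_simulation_gives_high_correlation(self, cohort_run):
        vst, truth, _ = cohort_run
        run = simulate_ncounter_run(vst, truth, noise_sd=0.1, seed=7)
        norm = normalize_ncounter(run)
        shared = [g for g in vst.values.index if g in norm.index]
        cmap = fit_calibration(vst, norm)
        variable = vst.values.loc[cmap.table.index].std(axis=1) > 1
        assert cmap.table.loc[variable, "r"].median() > 0.9


class TestPseudoRNASeq:
    def test_identity_map_passes_log_counts_through(self):
        nc = pd.DataFrame(
            np.array([[100.0, 200.0], [50.0, 25.0]]), index=["a", "b"]
        )
        cmap = CalibrationMap(
            pd.DataFrame({"b0": [0.0, 0.0], "b1": [1.0, 1.0], "r": 1.0, "n": 5}, index=["a", "b"])
        )
        pseudo = to_pseudo_rnaseq(nc, cmap)
        assert np.allclose(pseudo, log_counts(nc))

    def test_roundtrip_recovers_vst_within_rounding(self, cohort_run):
        vst, truth, run = cohort_run
        norm = normalize_ncounter(run)
        genes = [g for g in vst.values.index if g in norm.index]
        cmap = _true_map(truth, genes, vst.values.shape[1])
        pseudo = to_pseudo_rnaseq(norm, cmap, genes=genes)
        target = vst.values.loc[genes, pseudo.columns]
        # per-entry rounding bound: counts rounded by <= 0.5
        counts = norm.loc[genes].to_numpy()
        b1 = truth.calibration_b1.loc[genes].to_numpy()[:, None]
        tol = np.abs(b1) * (np.log(counts + 1.5) - np.log(np.maximum(counts - 0.5, 0.0) + 1.0))
        err = np.abs(pseudo.to_numpy() - target.to_numpy())
        assert (err <= tol + 1e-9).mean() > 0.99
        assert np.median(err) < 0.01

    def test_missing_gene_listed(self, cohort_run):
        vst, truth, run = cohort_run
        norm = normalize_ncounter(run)
        cmap = _true_map(truth, list(norm.index[:5]), 10)
        with pytest.raises(KeyError):
            to_pseudo_rnaseq(norm, cmap, genes=list(norm.index[:6]))

    def test_zero_slope_rejected_at_simulation(self, cohort_run):
        vst, truth, _ = cohort_run
        bad_truth = truth
        bad_truth.calibration_b1.iloc[0] = 0.0
        with pytest.raises(ValueError, match="zero calibration slope"):
            simulate_ncounter_run(vst, bad_truth, noise_sd=0.0, seed=1)
        bad_truth.calibration_b1.iloc[0] = 1.0  # restore shared fixture


class TestPanelSelection:
    def test_dynamic_range_rules(self):
        stats_df = pd.DataFrame(
            {
                "mean": [10_001, 500, 500, 9_999],
                "max": [20_000, 99, 5_000, 150],
            },
            index=["too_high", "too_low", "ok", "edge"],
        )
        kept = select_panel_genes(stats_df)
        assert kept == ["ok", "edge"]


class TestBatchAdjust:
    def test_constant_shift_removed_exactly(self, rng):
        ref = pd.DataFrame(rng.normal(6, 1, size=(40, 15)), index=[f"g{i}" for i in range(40)])
        tgt = ref + 3.0
        adj = batch_adjust(ref, tgt)
        assert np.allclose(adj.mean(axis=1), ref.mean(axis=1), atol=1e-9)

    def test_scale_matched(self, rng):
        ref = pd.DataFrame(rng.normal(6, 1, size=(40, 30)), index=[f"g{i}" for i in range(40)])
        tgt = pd.DataFrame(
            ref.to_numpy() * 2.0 - 6.0, index=ref.index, columns=[f"t{j}" for j in range(30)]
        )
        adj = batch_adjust(ref, tgt, eb=False)
        assert np.allclose(adj.std(axis=1, ddof=1), ref.std(axis=1, ddof=1), rtol=1e-9)

    def test_batch_classifier_degrades_after_adjustment(self, rng):
        n_genes, n = 100, 40
        base = rng.normal(7, 1, size=(n_genes, n))
        shift = rng.normal(0.8, 0.3, size=n_genes)
        ref = pd.DataFrame(base, index=[f"g{i}" for i in range(n_genes)],
                           columns=[f"r{j}" for j in range(n)])
        tgt = pd.DataFrame(
            rng.normal(7, 1, size=(n_genes, n)) + shift[:, None],
            index=ref.index,
            columns=[f"t{j}" for j in range(n)],
        )
        adj = batch_adjust(ref, tgt)

        def batch_auc(a, b):
            # held-out evaluation: train on even samples, test on odd
            X = np.hstack([a.to_numpy(), b.to_numpy()]).T
            y = np.array([0] * a.shape[1] + [1] * b.shape[1])
            from sklearn.linear_model import LogisticRegression

            tr, te = slice(0, None, 2), slice(1, None, 2)
            clf = LogisticRegression(max_iter=2000, C=0.1).fit(X[tr], y[tr])
            return evaluate(clf.predict_proba(X[te])[:, 1], y[te])["auc"]

        assert batch_auc(ref, tgt) >= 0.9
        assert batch_auc(ref, adj) <= 0.6
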