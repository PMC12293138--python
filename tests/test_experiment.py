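"""Study orchestration: per-subject search, aggregation, CLI."""

import json
from dataclasses import replace

import numpy as np
import pytest

import mi_esi as m
from mi_esi.experiment import (ExperimentConfig, _combination_features,
                               _feature_stats, aggregate, build_forward,
                               cli_main, run_subject)


@pytest.fixture(scope="module")
def small_config(atlas):
    pool = m.default_pool(atlas)[:5]  # C(5,4) = 5 combinations
    return ExperimentConfig(
        subjects=["aa"], channel_subsets=["19"], kernels=["linear"],
        roi_pool=pool, seed=7, split_scheme=40,
        generator=m.GeneratorConfig(n_trials_per_class=30, erd_attenuation=0.4,
                                    snr=5.0, seed=7),
        sources_per_patch=2)


@pytest.fixture(scope="module")
def small_forward(small_config):
    return build_forward(small_config)


class TestRunSubject:
    def test_small_search_reports_one_winner(self, small_config, small_forward):
        res = run_subject(small_config, "aa", small_forward, keep_accuracies=True)
        cell = res[("19", "linear")]
        assert cell.n_combinations == 5
        assert len(cell.accuracies) == 5
        assert set(cell.best_combination.regions) >= set(m.BASE_REGIONS)
        assert len(cell.best_combination.regions) == 6
        assert cell.selection_accuracy == max(cell.accuracies)

    def test_deterministic_under_fixed_seed(self, small_config, small_forward):
        a = run_subject(small_config, "aa", small_forward)
        b = run_subject(small_config, "aa", small_forward)
        assert a[("19", "linear")].metrics == b[("19", "linear")].metrics
        assert a[("19", "linear")].best_index == b[("19", "linear")].best_index

    def test_default_pool_enumerates_1820(self, atlas):
        combos = m.enumerate_combinations(atlas, None, 4)
        assert len(combos) == 1820

    def test_fast_features_match_plain_pipeline(self, small_config, small_forward, rng):
        """The sufficient-statistics feature path equals fit/apply/variance."""
        from mi_esi.csp import (apply_csp, fit_csp, variance_features)

        montage, atlas, lf = (small_forward.montage, small_forward.atlas,
                              small_forward.leadfield)
        roi_tc = rng.standard_normal((20, 24, 50))
        labels = np.array([m.RIGHT_HAND, m.RIGHT_FOOT] * 10)
        train = np.ones(20, bool)
        combo = m.enumerate_combinations(atlas, small_config.roi_pool, 4)[0]
        rows = np.array([atlas.names.index(r) for r in combo.regions])
        R, mm = _feature_stats(roi_tc)
        fast = _combination_features(R, mm, rows, 50, train, labels, 3)
        trials = [m.Trial(roi_tc[i][rows], labels[i], 100.0, list(combo.regions))
                  for i in range(20)]
        eps = m.EpochSet(trials, train)
        model = fit_csp(eps, 3)
        slow = np.stack([variance_features(apply_csp(model, t), 3)
                         for t in eps.trials])
        assert np.allclose(fast, slow, rtol=1e-9, atol=1e-12)

    def test_base_only_combination_is_competitive(self, small_config, small_forward):
        """Only M1HL/M1FL carry class signal, so the 2-region base alone
        classifies within noise of the best 6-region combination."""
        from mi_esi.roi import RoiCombination

        cfg = replace(small_config, split_scheme=30)
        res = run_subject(cfg, "aa", small_forward, keep_accuracies=True)
        best_acc = res[("19", "linear")].selection_accuracy

        # rerun the cell with a single base-only "combination"
        montage, atlas, lf = (small_forward.montage, small_forward.atlas,
                              small_forward.leadfield)
        from mi_esi.experiment import prepare_subject_epochs, roi_time_courses
        eps = prepare_subject_epochs(cfg, "aa", small_forward)
        idx = montage.index_of(montage.subset_names_for("19"))
        eps19 = m.subset_channels(eps, montage, "19")
        roi_tc = roi_time_courses(eps19, lf.restrict(idx), atlas, cfg.reg_lambda)
        rows = np.array([atlas.names.index(r) for r in m.BASE_REGIONS])
        labels = np.array(eps.labels)
        R, mm = _feature_stats(roi_tc)
        X = _combination_features(R, mm, rows, roi_tc.shape[2], eps.split,
                                  labels, cfg.n_pairs)
        clf = m.train_svm(X[eps.split], labels[eps.split], "linear")
        base_acc = float(np.mean(clf.predict(X[~eps.split]) == labels[~eps.split]))
        n_test = int((~eps.split).sum())
        sampling = 2.0 * np.sqrt(0.25 / n_test)
        assert base_acc >= best_acc - sampling - 0.05


class TestAggregate:
    @staticmethod
    def table_from(rows):
        t = m.ResultsTable()
        for subject, acc in rows:
            t.add(subject, 19, "linear",
                  {"Acc": acc, "Sen": 80.0, "Spec": 80.0, "Pre": 80.0, "F1": 80.0})
        return t.to_frame()

    def test_mean_of_benchmark_19ch_linear_accuracies(self):
        df = self.table_from([("aa", 66.96), ("al", 100.0), ("av", 74.49),
                              ("aw", 83.04), ("ay", 93.65)])
        assert df[df.subject == "mean"].Acc.iloc[0] == 83.63

    def test_single_subject_mean_is_identity(self):
        df = self.table_from([("aa", 77.77)])
        assert df[df.subject == "mean"].Acc.iloc[0] == 77.77

    def test_inconsistent_cells_rejected(self, small_config, small_forward):
        res = run_subject(small_config, "aa", small_forward)
        with pytest.raises(m.ConfigurationError):
            aggregate({"aa": res, "al": {("30", "linear"): res[("19", "linear")]}})


class TestCli:
    def test_verify_subcommand(self, capsys):
        assert cli_main(["verify"]) == 0
        out = capsys.readouterr().out
        assert "83.63" in out and "84.73" in out

    def test_run_and_report_roundtrip(self, tmp_path, atlas, capsys):
        pool = m.default_pool(atlas)[:4]  # single combination
        cfg = {
            "subjects": ["aa"], "channel_subsets": ["19"], "kernels": ["linear"],
            "roi_pool": pool, "split_scheme": 20, "sources_per_patch": 2,
            "generator": {"n_trials_per_class": 15, "erd_attenuation": 0.4,
                          "snr": 5.0, "n_background_sources": 20},
        }
        cfg_path = tmp_path / "cfg.json"
        cfg_path.write_text(json.dumps(cfg))
        out1, out2 = tmp_path / "run1", tmp_path / "run2"
        assert cli_main(["run", "--config", str(cfg_path), "--seed", "3",
                         "--out", str(out1)]) == 0
        assert cli_main(["run", "--config", str(cfg_path), "--seed", "3",
                         "--out", str(out2)]) == 0
        assert (out1 / "results.csv").read_text() == (out2 / "results.csv").read_text()
        prov = json.loads((out1 / "provenance.json").read_text())
        assert prov["seed"] == 3
        assert cli_main(["report", "--results", str(out1 / "results.json"),
                         "--out", str(tmp_path / "rep")]) == 0
        assert (tmp_path / "rep" / "report_means.csv").exists()

    def test_simulate_writes_readable_datasets(self, tmp_path):
        assert cli_main(["simulate", "--out", str(tmp_path), "--subjects", "ay",
                         "--seed", "5", "--config", str(_tiny_sim_config(tmp_path))]) == 0
        rec = m.read_competition_recording(tmp_path / "data_ay.mat")
        assert len(rec.cue_samples) == 280
        assert rec.fs == 100.0
        assert len(rec.channel_names) == 118

    def test_bad_config_nonzero_exit(self, tmp_path):
        bad = tmp_path / "bad.json"
        bad.write_text(json.dumps({"channel_subsets": ["64"]}))
        assert cli_main(["run", "--config", str(bad), "--out", str(tmp_path)]) == 2


def _tiny_sim_config(tmp_path):
    p = tmp_path / "sim.json"
    p.write_text(json.dumps({"sources_per_patch": 2,
                             "generator": {"n_background_sources": 10}}))
    return p
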