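"""Synthetic-data generators, table round-trips, config, CLI."""

import json

import numpy as np
import pytest
from click.testing import CliRunner
from scipy.stats import chisquare

import vaftree as vt
from vaftree.cli import main as cli_main
from conftest import tree_key


class TestRandomTree:
    def test_single_node(self):
        t = vt.random_tree(1, seed=0)
        assert t.n_nodes == 1 and t.root == "m1"

    def test_same_seed_identical(self):
        assert vt.random_tree(5, seed=42).parent == vt.random_tree(5, seed=42).parent

    def test_wildtype_mode_rooted_at_reference(self):
        t = vt.random_tree(3, seed=1, mode="wildtype")
        assert t.root == vt.WILDTYPE_ID and t.n_nodes == 4

    def test_uniform_over_fixed_root_topologies(self):
        """Chi-square against uniformity over the 16 labeled 4-node trees."""
        keys = [tree_key(t) for t in vt.enumerate_trees(
            4, fixed_root="m1", labels=("m1", "m2", "m3", "m4"))]
        index = {k: i for i, k in enumerate(keys)}
        counts = np.zeros(16)
        rng = np.random.default_rng(123)
        n_draws = 16000
        for _ in range(n_draws):
            counts[index[tree_key(vt.random_tree(4, rng=rng))]] += 1
        stat, p = chisquare(counts)
        assert p > 1e-4  # derandomized draw; uniform to sampling error
        assert (np.abs(counts / n_draws - 1 / 16)
                < 3 * np.sqrt((1 / 16) * (15 / 16) / n_draws)+ 1e-12).sum() >= 14


class TestRandomFrequencies:
    def test_single_clone(self):
        assert vt.random_frequencies(1, seed=0)[0] == pytest.approx(1.0)

    def test_simplex(self):
        f = vt.random_frequencies(5, seed=1)
        assert f.min() >= 0 and f.sum() == pytest.approx(1.0)

    def test_exchangeability_symmetry(self):
        rng = np.random.default_rng(2)
        draws = rng.dirichlet(np.ones(3), size=10000)
        assert np.mean(draws[:, 0] < draws[:, 2]) == pytest.approx(0.5, abs=0.02)

    def test_min_clone_freq_enforced(self):
        f = vt.random_frequencies(3, seed=3, min_clone_freq=0.1)
        assert f.min() >= 0.1

    def test_infeasible_floor_rejected(self):
        with pytest.raises(vt.ValidationError):
            vt.random_frequencies(4, seed=0, min_clone_freq=0.3)


class TestSimulatePatient:
    def test_noiseless_truth_among_exact_fits(self):
        p = vt.simulate_patient(n=4, seed=9, n_cells=300, vaf_noise_sd=0.0)
        report = vt.reconstruct(p.bulk_samples(), rank_all=False)
        assert any(f.tree.parent == p.truth.parent for f in report.exact_fits)

    def test_large_cell_count_recovers_drawn_frequencies(self):
        p = vt.simulate_patient(n=4, seed=10, n_cells=10**6,
                                timepoints=("diagnosis",))
        emp = p.sc_by_timepoint["diagnosis"].frequencies
        assert np.abs(emp - p.frequencies_by_timepoint["diagnosis"]).max() < 0.002

    def test_same_seed_byte_identical(self):
        a = vt.simulate_patient(n=3, seed=4).to_json()
        b = vt.simulate_patient(n=3, seed=4).to_json()
        assert a == b

    def test_noiseless_bulk_matches_single_cell_table(self):
        p = vt.simulate_patient(n=5, seed=6, n_cells=400)
        for tp in p.timepoints:
            recomputed = vt.bulk_vaf_from_sc(p.sc_by_timepoint[tp])
            assert np.allclose(recomputed.b, p.bulk_by_timepoint[tp].b)

    def test_genotype_matrix_invariants_hold(self):
        for seed in range(5):
            p = vt.simulate_patient(n=4, seed=seed)
            gm = vt.tree_to_genotype_matrix(p.truth)
            assert gm.integer_determinant() == 1
            for s in p.bulk_samples():
                assert vt.is_compatible(gm, s)


class TestTables:
    def test_vaf_roundtrip_full_precision(self, tmp_path):
        p = vt.simulate_patient(n=3, seed=1, n_cells=333)
        path = tmp_path / "vaf.tsv"
        vt.write_vaf_table(p.bulk_samples(), path)
        back = vt.read_vaf_table(path)
        for orig, rt in zip(p.bulk_samples(), back):
            assert rt.allele_ids == orig.allele_ids
            assert rt.timepoint == orig.timepoint
            assert np.array_equal(rt.b, orig.b)

    def test_vaf_out_of_range_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("mutation_id,timepoint,vaf_percent\n"
                        "m1,d,100\nm2,d,120\n")
        with pytest.raises(vt.ValidationError, match="line 3"):
            vt.read_vaf_table(path)

    def test_missing_column_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("mutation_id,vaf_percent\nm1,100\n")
        with pytest.raises(vt.ValidationError, match="timepoint"):
            vt.read_vaf_table(path)

    def test_ci_columns_become_weights(self, tmp_path):
        path = tmp_path / "ci.csv"
        path.write_text("mutation_id,timepoint,vaf_percent,ci_low,ci_high\n"
                        "m1,d,100,98,102\nm2,d,40,39,41\n")
        (s,) = vt.read_vaf_table(path)
        assert np.allclose(s.weights, [0.5, 1.0])

    def test_sc_roundtrip(self, tmp_path, chain3):
        ds = vt.SingleCellDataset.from_tree(chain3, counts=[5, 3, 2],
                                            timepoint="diagnosis")
        path = tmp_path / "sc.tsv"
        vt.write_sc_table([ds], path)
        (back,) = vt.read_sc_table(path)
        assert back.allele_ids == ds.allele_ids
        assert np.array_equal(back.genotypes, ds.genotypes)
        assert np.array_equal(back.counts, ds.counts)

    def test_report_json_schema(self, tmp_path):
        report = vt.reconstruct([vt.VAFSample(("m1", "m2"),
                                              np.array([100.0, 60.0]))])
        out = tmp_path / "report.json"
        nwk_dir = tmp_path / "trees"
        vt.write_report(report, out, newick_dir=nwk_dir)
        payload = json.loads(out.read_text())
        assert payload["schema_version"] == 1
        assert payload["n_trees_enumerated"] == 1
        assert payload["trees"][0]["exact"] is True
        assert list(nwk_dir.glob("*.nwk"))


class TestCli:
    def test_reconstruct_command(self, tmp_path):
        vaf = tmp_path / "vaf.csv"
        vaf.write_text("mutation_id,timepoint,vaf_percent\n"
                       "m1,d,100\nm2,d,60\nm3,d,30\n")
        out = tmp_path / "report.json"
        runner = CliRunner()
        result = runner.invoke(cli_main, [
            "reconstruct", "--vaf", str(vaf), "--out", str(out)])
        assert result.exit_code == 0, result.output
        payload = json.loads(out.read_text())
        assert payload["n_exact"] == 2

    def test_simulate_then_perturb_pipeline(self, tmp_path):
        runner = CliRunner()
        prefix = tmp_path / "pt"
        r1 = runner.invoke(cli_main, ["--seed", "5", "simulate", "--n", "3",
                                      "--out", str(prefix)])
        assert r1.exit_code == 0, r1.output
        r2 = runner.invoke(cli_main, [
            "--seed", "5", "perturb", "--sc", f"{prefix}.sc.tsv",
            "--truth", f"{prefix}.truth.nwk", "--reps", "5", "--sd", "0.5",
            "--out", str(tmp_path / "exp")])
        assert r2.exit_code == 0, r2.output
        assert (tmp_path / "exp" / "perturb_summary.json").exists()
        assert (tmp_path / "exp" / "perturb_replicates.tsv").exists()

    def test_uniqueness_command(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "uniq.json"
        result = runner.invoke(cli_main, [
            "--seed", "1", "uniqueness", "--n", "3", "--datasets", "200",
            "--timepoints", "1", "--out", str(out)])
        assert result.exit_code == 0, result.output
        payload = json.loads(out.read_text())
        assert sum(payload["pooled_histogram"].values()) == 3 * 200

    def test_config_file_provides_defaults(self, tmp_path):
        cfg = tmp_path / "cfg.json"
        cfg.write_text(json.dumps({"mode": "founder", "top": 1}))
        vaf = tmp_path / "vaf.csv"
        vaf.write_text("mutation_id,timepoint,vaf_percent\nm1,d,100\nm2,d,60\n")
        out = tmp_path / "r.json"
        runner = CliRunner()
        result = runner.invoke(cli_main, [
            "--config", str(cfg), "reconstruct", "--vaf", str(vaf),
            "--out", str(out)])
        assert result.exit_code == 0, result.output
        assert len(json.loads(out.read_text())["trees"]) == 1
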