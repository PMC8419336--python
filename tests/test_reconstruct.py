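"""End-to-end reconstruction pipeline: normalization, modes, ranking."""

import numpy as np
import pytest

import vaftree as vt


def sample(b, ids=None, tp="diagnosis"):
    ids = ids or tuple(f"m{i+1}" for i in range(len(b)))
    return vt.VAFSample(ids, np.asarray(b, dtype=float), timepoint=tp)


class TestNormalize:
    def test_scales_to_hundred(self):
        s = vt.normalize_vafs(sample([50, 20]))
        assert np.allclose(s.b, [100, 40])

    def test_idempotent(self):
        s = vt.normalize_vafs(sample([100, 40]))
        assert np.allclose(s.b, [100, 40])

    def test_ties_all_reach_hundred(self):
        s = vt.normalize_vafs(sample([25, 25]))
        assert np.allclose(s.b, [100, 100])

    def test_all_zero_rejected(self):
        with pytest.raises(vt.ValidationError):
            vt.normalize_vafs(sample([0, 0]))


class TestWildtypeRoot:
    def test_prepends_reference_allele(self):
        (out,) = vt.add_wildtype_root([sample([100, 40])])
        assert out.allele_ids[0] == vt.WILDTYPE_ID
        assert out.b[0] == 100.0 and np.allclose(out.b[1:], [100, 40])

    def test_id_collision_rejected(self):
        s = vt.VAFSample((vt.WILDTYPE_ID, "m1"), np.array([100.0, 50.0]))
        with pytest.raises(vt.ValidationError):
            vt.add_wildtype_root([s])

    def test_two_founder_solution_has_zero_wildtype(self):
        report = vt.reconstruct([sample([60, 40])], mode="wildtype")
        true_two_founder = vt.ClonalTree(
            {vt.WILDTYPE_ID: None, "m1": vt.WILDTYPE_ID, "m2": vt.WILDTYPE_ID})
        fit = next(f for f in report.exact_fits
                   if f.tree.parent == true_two_founder.parent)
        assert fit.x_as_dict("diagnosis")[vt.WILDTYPE_ID] == pytest.approx(0.0)


class TestRelax:
    def test_scales_mutated_alleles(self):
        (out,) = vt.relax([sample([100, 40])], 5.0)
        assert np.allclose(out.b, [95, 38])

    def test_zero_is_identity(self):
        (out,) = vt.relax([sample([100, 40])], 0.0)
        assert np.allclose(out.b, [100, 40])

    def test_wildtype_allele_untouched(self):
        (s,) = vt.add_wildtype_root([sample([100, 40])])
        (out,) = vt.relax([s], 10.0)
        assert out.b[0] == 100.0 and np.allclose(out.b[1:], [90, 36])

    def test_out_of_range_rejected(self):
        with pytest.raises(vt.ValidationError):
            vt.relax([sample([100, 40])], 100.0)

    def test_relaxation_recovers_healthy_fraction(self):
        """5% relaxation of exact data puts 5% of cells in the healthy clone."""
        patient = vt.simulate_patient(n=4, seed=11, n_cells=None)
        report = vt.reconstruct(patient.bulk_samples(), mode="wildtype",
                                relaxation_percent=5.0)
        truth_wt = patient.truth.with_wildtype_root()
        fit = next(f for f in report.fits
                   if f.tree.parent == truth_wt.parent)
        assert fit.exact
        for tp in patient.timepoints:
            assert fit.x_as_dict(tp)[vt.WILDTYPE_ID] == pytest.approx(5.0, abs=1e-9)


class TestReconstruct:
    def test_two_alleles_unique_chain(self):
        report = vt.reconstruct([sample([100, 70])])
        assert report.n_trees_enumerated == 1
        (fit,) = report.exact_fits
        assert fit.tree.parent == {"m1": None, "m2": "m1"}
        assert fit.x_as_dict("diagnosis") == pytest.approx({"m1": 30, "m2": 70})

    def test_three_alleles_two_exact_fits(self):
        """(100, 60, 30): the chain and the star fit, the other chain cannot."""
        report = vt.reconstruct([sample([100, 60, 30])])
        assert report.n_trees_enumerated == 3
        exact = {tuple(sorted((str(c), str(p)) for c, p in f.tree.parent.items()
                             if p is not None)): f for f in report.exact_fits}
        assert len(exact) == 2
        chain = exact[(("m2", "m1"), ("m3", "m2"))]
        star = exact[(("m2", "m1"), ("m3", "m1"))]
        assert chain.x_as_dict("diagnosis") == pytest.approx(
            {"m1": 40, "m2": 30, "m3": 30})
        assert star.x_as_dict("diagnosis") == pytest.approx(
            {"m1": 10, "m2": 60, "m3": 30})

    def test_unnormalized_input_is_normalized(self):
        report = vt.reconstruct([sample([50, 35])])
        (fit,) = report.exact_fits
        assert fit.x_as_dict("diagnosis") == pytest.approx({"m1": 30, "m2": 70})

    def test_missing_allele_read_as_zero_with_warning(self):
        s1 = sample([100, 40], tp="diagnosis")
        s2 = sample([100], ids=("m1",), tp="relapse")
        with pytest.warns(UserWarning, match="absent"):
            report = vt.reconstruct([s1, s2])
        assert report.samples[1].allele_ids == ("m1", "m2")
        assert report.samples[1].b[1] == 0.0

    def test_duplicate_timepoints_rejected(self):
        with pytest.raises(vt.ValidationError):
            vt.reconstruct([sample([100, 40]), sample([100, 30])])

    def test_founder_sum_conservation(self):
        """Exact founder-mode solutions always sum to 100."""
        for seed in range(20):
            patient = vt.simulate_patient(n=int(2 + seed % 5), seed=seed,
                                          n_cells=400)
            report = vt.reconstruct(patient.bulk_samples(), rank_all=False)
            for fit in report.exact_fits:
                for tp in patient.timepoints:
                    assert fit.x_by_timepoint[tp].sum() == pytest.approx(100.0)

    def test_generating_tree_among_exact_fits_two_timepoints(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(2, 6))
            tree = vt.random_tree(n, rng=rng)
            gm = vt.tree_to_genotype_matrix(tree)
            samples = []
            for tp in ("diagnosis", "relapse"):
                x = 100 * rng.dirichlet(np.ones(n))
                samples.append(vt.VAFSample(gm.allele_order, gm.A @ x, timepoint=tp))
            report = vt.reconstruct(samples, rank_all=False)
            assert any(f.tree.parent == tree.parent for f in report.exact_fits)

    def test_ranking_deterministic(self):
        patient = vt.simulate_patient(n=4, seed=5, n_cells=200,
                                      vaf_noise_sd=2.0)
        r1 = vt.reconstruct(patient.bulk_samples(), normalize=False)
        r2 = vt.reconstruct(patient.bulk_samples(), normalize=False)
        for f1, f2 in zip(r1.fits, r2.fits):
            assert f1.tree.parent == f2.tree.parent
            assert f1.combined_residual == f2.combined_residual
        assert [f.rank for f in r1.fits] == sorted(f.rank for f in r1.fits)

    def test_tied_roots_are_both_enumerated(self):
        report = vt.reconstruct([sample([50, 50])])
        roots = {f.tree.root for f in report.fits}
        assert roots == {"m1", "m2"}
        assert report.n_trees_enumerated == 2

    def test_enumeration_limit_error(self):
        b = np.linspace(100, 10, 9)
        s = vt.VAFSample(tuple(f"m{i}" for i in range(9)), b)
        with pytest.raises(vt.EnumerationLimitError):
            vt.reconstruct([s])


class TestRankSummary:
    def test_exact_data_rank_one(self):
        patient = vt.simulate_patient(n=4, seed=2, n_cells=None)
        report = vt.reconstruct(patient.bulk_samples())
        rs = vt.rank_summary(report, patient.truth)
        assert rs.rank == 1 and rs.is_optimal and rs.is_exact

    def test_three_allele_tie_not_unique(self):
        report = vt.reconstruct([sample([100, 60, 30])])
        chain = vt.ClonalTree({"m1": None, "m2": "m1", "m3": "m2"})
        rs = vt.rank_summary(report, chain)
        assert rs.rank == 1 and rs.is_optimal and rs.is_exact
        assert not rs.optimum_unique

    def test_allele_mismatch_rejected(self):
        report = vt.reconstruct([sample([100, 60])])
        with pytest.raises(vt.ValidationError):
            vt.rank_summary(report, vt.ClonalTree({"a": None, "b": "a"}))

    def test_truth_with_unenumerated_root_still_ranked(self):
        """Noise can displace the founder; truth is then fitted directly."""
        s = sample([90, 100])  # m2 now looks most abundant
        report = vt.reconstruct([s], normalize=False)
        truth = vt.ClonalTree({"m1": None, "m2": "m1"})
        rs = vt.rank_summary(report, truth)
        assert rs.rank >= 1 and rs.n_fits == 1
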