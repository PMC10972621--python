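"""Generator contracts: determinism, planted structure, moment convergence."""

import numpy as np
import pandas as pd
import pytest

import metaniche as mn
from metaniche.simulate import SimConfig, _expected_profiles


class TestScCohort:
    def test_determinism_bit_identical(self, small_cohort):
        counts, cells, genes, truth = small_cohort
        cfg = truth.config
        c2, ce2, g2, t2 = mn.generate_sc_cohort(cfg)
        assert (counts != c2).nnz == 0
        pd.testing.assert_frame_equal(cells, ce2)
        pd.testing.assert_frame_equal(truth.genes, t2.genes)

    def test_no_tumor_when_fractions_zero(self):
        cfg = SimConfig(
            n_samples_per_condition={"nonmetastatic": 2, "metastatic": 2},
            n_primary_samples=1, cells_per_sample=(40, 60), n_genes=200,
            n_chromosomes=2, cnv_segments=(),
            tumor_fraction_metastatic=0.0, tumor_fraction_primary=0.0, seed=1)
        _, cells, _, truth = mn.generate_sc_cohort(cfg)
        assert not (cells["cell_type"] == "tumor").any()
        assert not (truth.cells["true_type"] == "tumor").any()

    def test_degenerate_composition_rejected(self):
        cfg = SimConfig(base_composition={"T": 0.0, "myeloid": 8, "B": 4, "NK": 4})
        with pytest.raises(ValueError, match="zero expected cells"):
            cfg.validate()

    def test_cnv_bounds_validated(self):
        cfg = SimConfig(cnv_segments=(("chr3", 0, 10_000, 2.0),))
        with pytest.raises(ValueError, match="outside chr3"):
            cfg.validate()

    def test_total_umis_matches_matrix(self, small_cohort):
        counts, cells, _, _ = small_cohort
        np.testing.assert_array_equal(
            cells["total_umis"].to_numpy(),
            np.asarray(counts.sum(axis=0)).ravel())

    def test_doublet_scores_separate_doublets(self, small_cohort):
        _, cells, _, truth = small_cohort
        merged = cells.merge(truth.cells, on="cell_id")
        assert (merged.loc[merged["is_doublet"], "doublet_score"] > 0.4).all()
        assert (merged.loc[~merged["is_doublet"], "doublet_score"] <= 0.4).all()

    def test_mean_convergence_to_expected_profile(self):
        """Per-gene count shares converge to the configured expectation."""
        cfg = SimConfig(
            n_samples_per_condition={"nonmetastatic": 1, "metastatic": 0},
            n_primary_samples=0, cells_per_sample=(6000, 6000), n_genes=300,
            n_chromosomes=3, cnv_segments=(), doublet_rate=0.0,
            base_composition={"T": 300.0, "myeloid": 1.0, "B": 1.0, "NK": 1.0},
            seed=2)
        counts, cells, genes, truth = mn.generate_sc_cohort(cfg)
        rng = np.random.default_rng(cfg.seed)
        baseline = rng.lognormal(0.0, 1.0, cfg.n_genes)
        idx = {g: i for i, g in enumerate(genes["gene_id"])}
        planted = sorted({idx[g] for _, m, f in cfg.resolved_catalog() if f != 1
                          for g in m} | {idx[g] for g in cfg.resolved_signature()})
        baseline[planted] = rng.lognormal(1.0, 0.5, len(planted))
        profiles, _ = _expected_profiles(cfg, genes, baseline)
        t_cells = (cells["cell_type"] == "T").to_numpy()
        assert t_cells.sum() >= 5000
        emp = np.asarray(counts[:, t_cells].sum(axis=1)).ravel()
        emp_share = emp / emp.sum()
        w = profiles[("T", False)]
        exp_share = w / w.sum()
        big = exp_share > 1e-3  # genes with non-negligible expected share
        rel = np.abs(emp_share[big] - exp_share[big]) / exp_share[big]
        assert np.max(rel) < 0.05

    def test_composition_recovery(self):
        """Per-sample type proportions match the Dirichlet-shifted expectation."""
        cfg = SimConfig(
            n_samples_per_condition={"nonmetastatic": 0, "metastatic": 30},
            n_primary_samples=0, cells_per_sample=(400, 400), n_genes=200,
            n_chromosomes=2, cnv_segments=(), doublet_rate=0.0, seed=3)
        _, cells, _, _ = mn.generate_sc_cohort(cfg)
        props = pd.crosstab(cells["sample_id"], cells["cell_type"], normalize="index")
        conc = np.array([cfg.base_composition[t] * cfg.composition_shift[t]
                         for t in ("B", "NK", "T", "myeloid")])
        expect = (1 - cfg.tumor_fraction_metastatic) * conc / conc.sum()
        got = props[["B", "NK", "T", "myeloid"]].mean().to_numpy()
        assert np.all(np.abs(got - expect) < 0.05)
        assert abs(props["tumor"].mean() - cfg.tumor_fraction_metastatic) < 0.05

    def test_ground_truth_de_labels_match_applied_folds(self, small_cohort):
        _, _, _, truth = small_cohort
        cfg = truth.config
        assert truth.de_genes("met_tumor_vs_primary_tumor") == set(cfg.resolved_signature())
        markers = {g for _, m, f in cfg.resolved_catalog() if f != 1 for g in m}
        assert truth.de_genes("met_tumor_vs_normal") == markers | set(cfg.resolved_signature())

    def test_write_cohort_round_trips(self, tmp_path, small_cohort):
        counts, cells, genes, truth = small_cohort
        from metaniche.simulate import write_cohort
        paths = write_cohort(tmp_path, counts, cells, genes, truth)
        back, g, c = mn.read_mtx_bundle(paths["matrix"], paths["genes"], paths["cells"])
        assert (back != counts).nnz == 0


class TestBulkCohort:
    SIG = mn.GeneSet("sig", tuple(f"S{i}" for i in range(20)))

    def test_preconditions(self):
        with pytest.raises(ValueError, match="n_patients"):
            mn.generate_bulk_cohort(0, self.SIG, 2.0, seed=0)
        with pytest.raises(ValueError, match="hazard_ratio"):
            mn.generate_bulk_cohort(10, self.SIG, -1.0, seed=0)

    def test_determinism(self):
        b1, s1, t1 = mn.generate_bulk_cohort(50, self.SIG, 2.0, seed=4)
        b2, s2, t2 = mn.generate_bulk_cohort(50, self.SIG, 2.0, seed=4)
        pd.testing.assert_frame_equal(b1, b2)
        pd.testing.assert_frame_equal(s1, s2)

    def test_signature_score_tracks_burden(self):
        bulk, _, truth = mn.generate_bulk_cohort(300, self.SIG, 2.0, seed=5)
        score = bulk.loc[list(self.SIG.genes)].mean(axis=0)
        r = np.corrcoef(score, truth.patients["burden"])[0, 1]
        assert r > 0.9

    def test_null_hazard_calibration(self):
        """hazard_ratio=1: log-rank on true-burden quartiles rejects ~ alpha."""
        rej = trials = 0
        for seed in range(500):
            _, surv, truth = mn.generate_bulk_cohort(
                60, self.SIG, 1.0, seed=seed, n_background=0)
            strat = mn.stratify_by_score(
                truth.patients.set_index("patient_id")["burden"], 0.25)
            m = surv.merge(strat[["patient_id", "stratum"]], on="patient_id")
            m = m[m["stratum"].isin(["high", "low"])]
            try:
                _, p = mn.logrank_test(m, "high", "low")
            except ValueError:
                continue
            rej += p < 0.05
            trials += 1
        assert trials > 450
        # binomial 99% band around 0.05 plus slack for small-sample discreteness
        assert 0.02 <= rej / trials <= 0.08

    def test_power_under_planted_hazard(self):
        """hazard_ratio=3, n=200: high stratum dies faster, log-rank rejects."""
        hits = 0
        for seed in range(100):
            bulk, surv, _ = mn.generate_bulk_cohort(200, self.SIG, 3.0, seed=seed)
            score = bulk.loc[list(self.SIG.genes)].mean(axis=0)
            score.index.name = "patient_id"
            strat = mn.stratify_by_score(score, 0.25)
            m = surv.merge(strat[["patient_id", "stratum"]], on="patient_id")
            m = m[m["stratum"].isin(["high", "low"])]
            _, p = mn.logrank_test(m, "high", "low")
            hits += p < 0.05
        assert hits >= 80
        km_hi = mn.km_estimate(m, "high")
        km_lo = mn.km_estimate(m, "low")
        assert km_hi.survival_at(5.0) < km_lo.survival_at(5.0)


class TestLRDatabase:
    def test_single_pair(self):
        db = mn.generate_lr_database(1, [f"g{i}" for i in range(4)], seed=0)
        assert len(db) == 1 and db["ligand"].iloc[0] != db["receptor"].iloc[0]

    def test_determinism_and_uniqueness(self):
        universe = [f"g{i}" for i in range(100)]
        d1 = mn.generate_lr_database(40, universe, seed=1)
        d2 = mn.generate_lr_database(40, universe, seed=1)
        pd.testing.assert_frame_equal(d1, d2)
        used = pd.concat([d1["ligand"], d1["receptor"]])
        assert used.nunique() == 80

    def test_capacity_error(self):
        with pytest.raises(ValueError, match="cannot host"):
            mn.generate_lr_database(3, ["a", "b", "c", "d"], seed=0)
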