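"""Statistical and structural properties of the synthetic cohort generator."""

import numpy as np
import pandas as pd
import pytest

import polyhaz as ph
from polyhaz.simulate import true_linear_predictor


class TestGenotypes:
    def test_hardy_weinberg_moments(self, small_cohort):
        cfg, g, _ = small_cohort
        f = g.snp_meta["freq"].to_numpy()
        n = g.n_subjects
        # mean allele count within 4 binomial SEs of 2f
        se_mean = np.sqrt(2 * f * (1 - f) / n)
        assert np.all(np.abs(g.counts.mean(axis=0) - 2 * f) < 4 * se_mean)
        # homozygote frequency within 4 SEs of f^2
        hom = (g.counts == 2).mean(axis=0)
        se_hom = np.sqrt(f**2 * (1 - f**2) / n)
        assert np.all(np.abs(hom - f**2) < 4 * se_hom)

    def test_mean_count_binomial_oracle(self):
        cfg = ph.SimulationConfig(n_subjects=10_000, n_snps=1, n_causal=0,
                                  ld_dup_pairs=0,
                                  allele_freqs=np.array([0.5]), seed=2)
        g = ph.simulate_genotypes(cfg)
        se = np.sqrt(2 * 0.5 * 0.5 / 10_000)
        assert abs(g.counts.mean() - 1.0) < 3 * se

    def test_perfect_fidelity_duplicates_identical(self):
        cfg = ph.SimulationConfig(n_subjects=500, n_snps=10, n_causal=0,
                                  ld_dup_pairs=2, copy_fidelity=1.0, seed=5)
        g = ph.simulate_genotypes(cfg)
        for j in range(2):
            np.testing.assert_array_equal(g.counts[:, j], g.counts[:, 8 + j])

    def test_dup_pairs_exceed_r2_threshold(self):
        hits = total = 0
        for seed in range(10):
            cfg = ph.SimulationConfig(n_subjects=5000, n_snps=20, n_causal=0,
                                      ld_dup_pairs=4, seed=seed)
            g = ph.simulate_genotypes(cfg)
            for j in range(4):
                r = np.corrcoef(g.counts[:, j], g.counts[:, 16 + j])[0, 1]
                hits += r * r > 0.95
                total += 1
        assert hits >= 0.95 * total

    def test_determinism(self):
        cfg = ph.SimulationConfig(n_subjects=300, seed=99)
        a = ph.simulate_genotypes(cfg)
        b = ph.simulate_genotypes(cfg)
        np.testing.assert_array_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(a.snp_meta, b.snp_meta)

    def test_bad_frequency_rejected(self):
        with pytest.raises(ValueError, match="frequencies"):
            ph.SimulationConfig(n_snps=2, allele_freqs=np.array([0.5, 1.2]))
        with pytest.raises(ValueError, match="frequencies"):
            ph.SimulationConfig(n_snps=1, allele_freqs=np.array([np.nan]))


class TestOnset:
    def test_weibull_median_closed_form(self):
        # no genetic effects, censoring pushed beyond any onset
        cfg = ph.SimulationConfig(n_subjects=20_000, n_snps=10, n_causal=0,
                                  ld_dup_pairs=0, censor_age_lo=9e5,
                                  censor_age_hi=1e6, seed=7)
        g, phen = ph.simulate_cohort(cfg)
        assert (phen["status"] == "case").all()
        expected = cfg.baseline_scale * np.log(2.0) ** (1.0 / cfg.baseline_shape)
        med = float(np.median(phen["event_age"]))
        # Monte-Carlo tolerance: ~1.253*sd/sqrt(n) for a Weibull median
        assert abs(med - expected) < 1.0
        assert phen.attrs["population_prevalence"] == 1.0

    def test_death_implies_significant_case(self, small_cohort):
        _, _, phen = small_cohort
        dead = phen[phen["death_age"].notna()]
        assert len(dead) > 0
        assert (dead["status"] == "case").all()
        assert (dead["significant"] == 1).all()
        assert (dead["fatal"] == 1).all()
        assert (dead["death_age"] >= dead["event_age"]).all()

    def test_family_history_tracks_genetic_burden(self):
        cfg = ph.SimulationConfig(n_subjects=20_000, seed=13)
        g, phen = ph.simulate_cohort(cfg)
        lp = true_linear_predictor(g, cfg)
        known = (phen["family_history"] != "unknown").to_numpy()
        q = np.quantile(lp, [0.2, 0.8])
        fh = (phen["family_history"] == "yes").to_numpy()

        def odds(mask):
            r = fh[mask & known].mean()
            return r / (1 - r)

        assert odds(lp >= q[1]) / odds(lp < q[0]) > 1.0

    def test_proportional_hazards_recovery(self):
        # univariable Cox on one causal SNP recovers its log-hazard
        cfg = ph.SimulationConfig(n_subjects=20_000, n_snps=5, n_causal=1,
                                  ld_dup_pairs=0,
                                  causal_betas=np.array([0.3]), seed=17)
        g, phen = ph.simulate_cohort(cfg)
        event = (phen["status"] == "case").to_numpy()
        fit = ph.cox_newton(g.counts[:, :1], phen["event_age"].to_numpy(), event)
        assert abs(fit.beta[0] - 0.3) < 3 * fit.se[0]

    def test_dimension_mismatch(self):
        cfg = ph.SimulationConfig(n_subjects=100, n_snps=10, n_causal=5, seed=1)
        g = ph.simulate_genotypes(cfg)
        small = g.select_snps(g.snp_ids[:3])
        with pytest.raises(ValueError, match="fewer SNPs"):
            ph.simulate_onset(small, cfg)

    def test_phenotypes_deterministic(self):
        cfg = ph.SimulationConfig(n_subjects=500, seed=23)
        _, a = ph.simulate_cohort(cfg)
        _, b = ph.simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a, b)


@pytest.mark.parametrize(
    "rec,expected",
    [
        (dict(gleason=6, psa=4.0, t_stage="T2", node_positive=False,
              metastatic=False), False),
        (dict(gleason=7, psa=4.0, t_stage="T1", node_positive=False,
              metastatic=False), True),
        (dict(gleason=6, psa=10.0, t_stage="T1", node_positive=False,
              metastatic=False), True),  # PSA boundary is inclusive
        (dict(gleason=6, psa=2.0, t_stage="T3", node_positive=False,
              metastatic=False), True),
        (dict(gleason=2, psa=0.0, t_stage="T1", node_positive=True,
              metastatic=False), True),
        (dict(gleason=2, psa=0.0, t_stage="T1", node_positive=False,
              metastatic=True), True),
    ],
)
def test_classify_significance(rec, expected):
    assert ph.classify_significance(ph.ClinicalRecord(**rec)) is expected


def test_classify_significance_missing_field():
    rec = ph.ClinicalRecord(gleason=7, psa=None, t_stage="T1",
                            node_positive=False, metastatic=False)
    with pytest.raises(ph.simulate.MissingDataError, match="psa"):
        ph.classify_significance(rec)


class TestSampling:
    def _cohort(self, n_case, n_ctrl):
        n = n_case + n_ctrl
        phen = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(n)],
                "status": ["case"] * n_case + ["control"] * n_ctrl,
                "event_age": np.linspace(50, 80, n),
            }
        )
        return phen

    def test_ratio_arithmetic(self):
        phen = self._cohort(300, 6000)
        cfg = ph.SimulationConfig(n_subjects=10, seed=0,
                                  sampled_case_control_ratio=0.5)
        out = ph.apply_case_control_sampling(phen, cfg)
        vc = out["status"].value_counts()
        assert vc["case"] == 300 and vc["control"] == 600

    def test_matching_ratio_is_noop_up_to_shuffle(self):
        phen = self._cohort(200, 400)
        cfg = ph.SimulationConfig(n_subjects=10, seed=0,
                                  sampled_case_control_ratio=0.5)
        out = ph.apply_case_control_sampling(phen, cfg)
        assert sorted(out["subject_id"]) == sorted(phen["subject_id"])

    def test_deterministic(self):
        phen = self._cohort(500, 500)
        cfg = ph.SimulationConfig(n_subjects=10, seed=4,
                                  sampled_case_control_ratio=2.0)
        a = ph.apply_case_control_sampling(phen, cfg)
        b = ph.apply_case_control_sampling(phen, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_unattainable_ratio(self):
        phen = self._cohort(0, 100)
        cfg = ph.SimulationConfig(n_subjects=10, seed=0)
        with pytest.raises(ValueError, match="unattainable"):
            ph.apply_case_control_sampling(phen, cfg)


class TestScreening:
    def test_exact_ratio_among_screen_positives(self):
        cfg = ph.SimulationConfig(n_subjects=8000, seed=31,
                                  sampled_case_control_ratio=0.5,
                                  screen_controls_per_case=2.0)
        _, phen = ph.simulate_cohort(cfg)
        samp = ph.apply_case_control_sampling(phen, cfg)
        scr = ph.simulate_screening(samp, cfg)
        pos = scr[scr["psa_positive"] == 1]
        n_case = (pos["status"] == "case").sum()
        n_ctrl = (pos["status"] == "control").sum()
        assert n_ctrl == 2 * n_case

    def test_biopsy_semantics(self):
        cfg = ph.SimulationConfig(n_subjects=8000, seed=31,
                                  sampled_case_control_ratio=0.5)
        _, phen = ph.simulate_cohort(cfg)
        samp = ph.apply_case_control_sampling(phen, cfg)
        scr = ph.simulate_screening(samp, cfg)
        pos = scr[scr["psa_positive"] == 1]
        cases = pos[pos["status"] == "case"]
        ctrls = pos[pos["status"] == "control"]
        assert (cases["biopsy_significant"] == cases["significant"]).all()
        assert (ctrls["biopsy_significant"] == 0).all()
        neg = scr[scr["psa_positive"] == 0]
        assert neg["biopsy_significant"].isna().all()

    def test_insufficient_controls_rejected(self):
        cfg = ph.SimulationConfig(n_subjects=3000, seed=1,
                                  sampled_case_control_ratio=2.0)
        _, phen = ph.simulate_cohort(cfg)
        samp = ph.apply_case_control_sampling(phen, cfg)  # 2 cases : 1 control
        with pytest.raises(ValueError, match="screen-positive"):
            ph.simulate_screening(samp, cfg)


@pytest.mark.parametrize(
    "kwargs,msg",
    [
        (dict(n_snps=4, n_causal=5), "n_causal"),
        (dict(target_prevalence=0.0), "prevalence"),
        (dict(sampled_case_control_ratio=-1.0), "ratio"),
        (dict(copy_fidelity=0.90), "fidelity"),
        (dict(p_significant_given_case=1.5), "p_significant_given_case"),
        (dict(censor_age_lo=90.0, censor_age_hi=55.0), "censor"),
    ],
)
def test_config_validation(kwargs, msg):
    with pytest.raises(ValueError, match=msg):
        ph.SimulationConfig(**kwargs)
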