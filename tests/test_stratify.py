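"""Sample weights, band hazard ratios and the family-history comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import polyhaz as ph
from polyhaz.scoring import PercentileReference
from polyhaz.stratify import endpoint_survival, _format_p


def make_phen(n_case, n_ctrl, rng=None, fh=None):
    rng = rng or np.random.default_rng(0)
    n = n_case + n_ctrl
    phen = pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(n)],
            "status": ["case"] * n_case + ["control"] * n_ctrl,
            "event_age": rng.uniform(50, 80, size=n),
            "significant": np.r_[
                rng.integers(0, 2, n_case).astype(float), np.full(n_ctrl, np.nan)
            ],
            "fatal": np.zeros(n),
            "death_age": np.full(n, np.nan),
            "family_history": fh if fh is not None else ["no"] * n,
            "psa_positive": np.full(n, np.nan),
            "biopsy_significant": np.full(n, np.nan),
            "pc1": np.zeros(n), "pc2": np.zeros(n),
            "pc3": np.zeros(n), "pc4": np.zeros(n),
        }
    )
    return phen


def simple_ref(means=None):
    ref = PercentileReference()
    ref.thresholds_ = {20: -1.0, 30: -0.5, 70: 0.5, 80: 1.0, 95: 2.0}
    ref.band_means_ = means or {
        "bottom20": -1.5, "mid40_60": 0.0, "top20": 1.5, "top5": 2.5
    }
    ref.n_reference_ = 1000
    return ref


class TestSampleWeights:
    def test_balanced_half_prevalence_is_noop(self):
        phen = make_phen(100, 100)
        w = ph.sample_weights(phen, 0.5)
        np.testing.assert_allclose(w, 1.0)

    def test_hand_computed_weight(self):
        # N_case = 2 N_ctrl, pi = 0.2: w = (0.2/0.8) * (1/2) = 0.125
        phen = make_phen(200, 100)
        w = ph.sample_weights(phen, 0.2)
        case_w = w[(phen["status"] == "case").to_numpy()]
        np.testing.assert_allclose(case_w, 0.125)

    @pytest.mark.parametrize("n_case,n_ctrl,pi",
                             [(50, 500, 0.12), (300, 100, 0.4), (7, 13, 0.05)])
    def test_weighted_case_fraction_equals_pi(self, n_case, n_ctrl, pi):
        phen = make_phen(n_case, n_ctrl)
        w = ph.sample_weights(phen, pi)
        is_case = (phen["status"] == "case").to_numpy()
        assert w[is_case].sum() / w.sum() == pytest.approx(pi, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="cases and controls"):
            ph.sample_weights(make_phen(10, 0), 0.1)

    @given(
        n_case=st.integers(1, 400),
        n_ctrl=st.integers(1, 400),
        pi=st.floats(1e-4, 1 - 1e-4, allow_nan=False),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_weighted_fraction_identity_property(self, n_case, n_ctrl, pi):
        phen = make_phen(n_case, n_ctrl)
        w = ph.sample_weights(phen, pi)
        is_case = (phen["status"] == "case").to_numpy()
        assert w[is_case].sum() / w.sum() == pytest.approx(pi, rel=1e-9)


class TestEndpoints:
    def test_endpoint_conventions(self, small_cohort):
        _, _, phen = small_cohort
        ev_any, t_any = endpoint_survival(phen, "any")
        assert ev_any.sum() == (phen["status"] == "case").sum()
        ev_sig, _ = endpoint_survival(phen, "significant")
        assert ev_sig.sum() == (phen["significant"] == 1).sum()
        assert np.all(~ev_sig | ev_any)
        ev_fat, t_fat = endpoint_survival(phen, "fatal")
        assert ev_fat.sum() == (phen["fatal"] == 1).sum()
        # fatal events timed at death age, later than diagnosis
        assert np.all(
            t_fat[ev_fat] >= phen.loc[ev_fat, "event_age"].to_numpy()
        )

    def test_unknown_endpoint(self, small_cohort):
        _, _, phen = small_cohort
        with pytest.raises(ValueError, match="endpoint"):
            endpoint_survival(phen, "bogus")


class TestCoxBetaPHS:
    def test_null_scores(self):
        rng = np.random.default_rng(5)
        phen = make_phen(400, 1600, rng=rng)
        scores = rng.normal(size=2000)  # independent of outcome
        beta, se = ph.cox_beta_phs(scores, phen, "any")
        assert abs(beta) < 3 * se

    def test_effect_recovery(self):
        rng = np.random.default_rng(6)
        n = 10_000
        scores = rng.standard_normal(n)
        T = 116 * (-np.log(rng.uniform(size=n)) / np.exp(0.8 * scores)) ** (1 / 4.5)
        C = rng.uniform(55, 90, size=n)
        ev = T <= C
        phen = make_phen(int(ev.sum()), int((~ev).sum()))
        phen["status"] = np.where(ev, "case", "control")
        phen["event_age"] = np.where(ev, T, C)
        phen.loc[~ev, "significant"] = np.nan
        beta, se = ph.cox_beta_phs(scores, phen, "any")
        assert abs(beta - 0.8) < 3 * se

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(7)
        phen = make_phen(300, 700, rng=rng)
        scores = rng.normal(size=1000)
        w = ph.sample_weights(phen, 0.1)
        b1, _ = ph.cox_beta_phs(scores, phen, "any", weights=w)
        b2, _ = ph.cox_beta_phs(scores, phen, "any", weights=2 * w)
        assert b1 == pytest.approx(b2, abs=1e-9)


class TestBandHR:
    def test_log2_unit_contrast(self):
        ref = simple_ref({"bottom20": 0.0, "mid40_60": 1.0,
                          "top20": 2.0, "top5": 3.0})
        assert ph.band_hr(np.log(2.0), ref, "top20", "mid40_60") == pytest.approx(2.0)

    def test_same_band_is_unity(self):
        assert ph.band_hr(1.3, simple_ref(), "top20", "top20") == 1.0

    def test_multiplicative_identity(self):
        ref = simple_ref()
        beta = 0.77
        top_mid = ph.band_hr(beta, ref, "top20", "mid40_60")
        bot_mid = ph.band_hr(beta, ref, "bottom20", "mid40_60")
        top_bot = ph.band_hr(beta, ref, "top20", "bottom20")
        assert top_bot == pytest.approx(top_mid / bot_mid, rel=1e-12)

    def test_degenerate_reference_warns(self):
        ref = simple_ref({"bottom20": 0.0, "mid40_60": 0.0,
                          "top20": 0.0, "top5": 0.0})
        with pytest.warns(UserWarning, match="degenerate"):
            hr = ph.band_hr(1.0, ref, "top20", "mid40_60")
        assert hr == 1.0


class TestHRReport:
    @pytest.fixture(scope="class")
    def cohort(self):
        rng = np.random.default_rng(9)
        n = 1500
        scores = rng.standard_normal(n)
        T = 116 * (-np.log(rng.uniform(size=n)) / np.exp(0.6 * scores)) ** (1 / 4.5)
        C = rng.uniform(55, 90, size=n)
        ev = T <= C
        phen = make_phen(int(ev.sum()), int((~ev).sum()))
        phen["status"] = np.where(ev, "case", "control")
        phen["event_age"] = np.where(ev, T, C)
        phen["significant"] = np.where(ev, 1.0, np.nan)
        return scores, phen

    def test_single_replicate_degenerate_ci(self, cohort):
        scores, phen = cohort
        rep = ph.hr_report(scores, phen, simple_ref(), "any", 0.15,
                           n_boot=1, seed=0)
        for m, lo, hi in rep.hrs.values():
            assert m == lo == hi

    def test_same_seed_identical(self, cohort):
        scores, phen = cohort
        a = ph.hr_report(scores, phen, simple_ref(), "any", 0.15,
                         n_boot=20, seed=5)
        b = ph.hr_report(scores, phen, simple_ref(), "any", 0.15,
                         n_boot=20, seed=5)
        assert a.to_dict() == b.to_dict()

    def test_hr_identity_within_every_replicate(self, cohort):
        scores, phen = cohort
        rep = ph.hr_report(scores, phen, simple_ref(), "any", 0.15,
                           n_boot=25, seed=3)
        reps = rep.replicates
        np.testing.assert_allclose(
            reps["hr_80_20"], reps["hr_80_50"] / reps["hr_20_50"], rtol=1e-12
        )
        # beta > 0 and m95 > m80 force HR95/50 >= HR80/50
        assert (reps["hr_95_50"] >= reps["hr_80_50"]).all()

    def test_unit_weights_match_unweighted_fit(self, cohort):
        scores, phen = cohort
        pi = (phen["status"] == "case").mean()  # weights all 1
        w = ph.sample_weights(phen, pi)
        np.testing.assert_allclose(w, 1.0)
        beta_w, _ = ph.cox_beta_phs(scores, phen, "any", weights=w)
        beta_u, _ = ph.cox_beta_phs(scores, phen, "any")
        assert beta_w == pytest.approx(beta_u, abs=1e-10)


class TestFamilyHistory:
    def _fh_cohort(self, rng, n=2000, beta_scores=0.8, fh_unknown=0.2):
        scores = rng.standard_normal(n)
        T = 116 * (-np.log(rng.uniform(size=n)) / np.exp(beta_scores * scores)) ** (1 / 4.5)
        C = rng.uniform(55, 90, size=n)
        ev = T <= C
        fh = np.where(rng.random(n) < 0.12, "yes", "no").astype(object)
        fh[rng.random(n) < fh_unknown] = "unknown"
        phen = make_phen(int(ev.sum()), int((~ev).sum()))
        phen["status"] = np.where(ev, "case", "control")
        phen["event_age"] = np.where(ev, T, C)
        phen["significant"] = np.where(ev, 1.0, np.nan)
        phen["family_history"] = fh
        return scores, phen

    def test_unknown_fh_excluded(self):
        rng = np.random.default_rng(15)
        scores, phen = self._fh_cohort(rng)
        cmp = ph.family_history_comparison(scores, phen, "any", simple_ref())
        assert cmp.n_used == int((phen["family_history"] != "unknown").sum())

    def test_zero_phs_gives_null_lrt(self):
        rng = np.random.default_rng(16)
        scores, phen = self._fh_cohort(rng)
        cmp = ph.family_history_comparison(
            np.zeros(len(phen)), phen, "any", simple_ref()
        )
        assert cmp.lrt_stat == 0.0
        assert cmp.lrt_p == 1.0
        assert cmp.hr_phs == 1.0

    def test_strong_phs_truncated_p(self):
        rng = np.random.default_rng(17)
        scores, phen = self._fh_cohort(rng, n=6000, beta_scores=1.2)
        cmp = ph.family_history_comparison(scores, phen, "any", simple_ref())
        assert cmp.lrt_p_str == "<1e-16"
        assert cmp.p_phs_str == "<1e-16"
        assert cmp.hr_phs > 1.0
        assert cmp.hr_fh == pytest.approx(np.exp(cmp.beta_fh))

    def test_chi_square_p_matches_oracle(self):
        from scipy.stats import chi2

        rng = np.random.default_rng(18)
        scores, phen = self._fh_cohort(rng, beta_scores=0.15)
        cmp = ph.family_history_comparison(scores, phen, "any", simple_ref())
        assert cmp.lrt_p == pytest.approx(chi2.sf(cmp.lrt_stat, df=1))
        # alpha-boundary statistic: chi2 0.99 quantile gives p = alpha
        assert chi2.sf(chi2.isf(0.01, df=1), df=1) == pytest.approx(0.01)

    def test_nesting_never_decreases_loglik(self):
        rng = np.random.default_rng(19)
        scores, phen = self._fh_cohort(rng)
        known = phen["family_history"] != "unknown"
        sub = phen[known].reset_index(drop=True)
        fh = (sub["family_history"] == "yes").to_numpy(dtype=float)
        ev = (sub["status"] == "case").to_numpy()
        t = sub["event_age"].to_numpy()
        noise = rng.normal(size=len(sub))
        reduced = ph.cox_newton(fh[:, None], t, ev)
        full = ph.cox_newton(np.column_stack([fh, noise]), t, ev)
        assert full.loglik >= reduced.loglik - 1e-9


def test_p_value_formatting():
    assert _format_p(1e-30) == "<1e-16"
    assert _format_p(1e-16) != "<1e-16"
    assert _format_p(0.0123).startswith("0.0123")
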