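"""Cox validation stage: verdicts, frequencies, NNH, permutation FDR."""

import numpy as np
import pandas as pd
import pytest

from hteharm.cox import fit_cox
from hteharm.hypotheses import Condition, SubgroupHypothesis
from hteharm.validation import (
    adverse_event_cox,
    frequency_report,
    harm_verdict,
    interaction_model,
    number_needed_to_harm,
    permutation_fdr,
    validate_hypothesis,
    within_subgroup_model,
)

from conftest import cohort_from_counts, exponential_survival_frame


def make_result(hr, p, term="treatment:subgroup"):
    """Hand-assembled CoxResult stand-in for verdict logic tests."""
    from hteharm.cox import CoxResult

    idx = pd.Index([term])
    beta = np.log(hr)
    return CoxResult(
        terms=[term],
        beta=pd.Series([beta], index=idx),
        se=pd.Series([0.5], index=idx),
        hr=pd.Series([hr], index=idx),
        ci_low=pd.Series([hr * 0.5], index=idx),
        ci_high=pd.Series([hr * 2], index=idx),
        p=pd.Series([p], index=idx),
        loglik=0.0,
        n=100,
        n_events=20,
        n_strata=1,
        ties="breslow",
        converged=True,
    )


def make_fdr(value):
    from hteharm.validation import PermutationFdr

    return PermutationFdr(observed_beta=1.0, n_permutations=1000, n_greater=int(value * 1000), fdr=value, n_nonconverged=0, seed=0)


class TestHarmVerdict:
    def test_validated_when_both_criteria_hold(self):
        """Interaction HR 3.5 (p=.02, FDR=.007) + subgroup HR 10.6 (p=.03)."""
        v = harm_verdict(make_result(3.5, 0.02), make_result(10.6, 0.03, term="treatment"), make_fdr(0.007))
        assert v.criterion1 and v.criterion2 and v.validated

    def test_protective_interaction_never_validates(self):
        v = harm_verdict(make_result(0.8, 0.001), make_result(10.6, 0.01, term="treatment"), make_fdr(0.0))
        assert not v.validated
        assert any("<= 1" in r for r in v.reasons)

    def test_fdr_above_threshold_blocks_validation(self):
        v = harm_verdict(make_result(3.5, 0.01), make_result(10.6, 0.01, term="treatment"), make_fdr(0.06))
        assert not v.validated and not v.criterion1

    def test_nonconverged_fit_gives_indeterminate(self):
        bad = make_result(3.5, 0.02)
        bad.converged = False
        v = harm_verdict(bad, make_result(2.0, 0.01, term="treatment"), make_fdr(0.0))
        assert v.indeterminate and not v.validated


class TestFrequencyReport:
    def test_printed_count_percentages(self):
        """Counts like 12 events of 110 treated print as 10.9%."""
        df = cohort_from_counts(
            [(1, 110, 12, {"member": 1}), (0, 126, 6, {"member": 1}), (1, 500, 30, {"member": 0}), (0, 500, 40, {"member": 0})]
        )
        rep = frequency_report(df, df["member"].to_numpy(bool))
        assert rep.percent("subgroup", "treated") == 10.9
        assert rep.percent("subgroup", "control") == 4.8
        row = rep.table.set_index(["group", "arm"])
        assert row.loc[("subgroup", "treated"), "n"] == 110
        assert row.loc[("subgroup", "treated"), "events"] == 12

    def test_zero_events_is_zero_percent(self):
        df = cohort_from_counts([(1, 50, 0, {"member": 1}), (0, 50, 5, {"member": 1})])
        rep = frequency_report(df, df["member"].to_numpy(bool))
        assert rep.percent("subgroup", "treated") == 0.0

    def test_empty_subgroup_flagged(self):
        df = cohort_from_counts([(1, 20, 2), (0, 20, 2)])
        rep = frequency_report(df, np.zeros(40, bool))
        assert rep.empty_subgroup


class TestNNH:
    def test_closed_form_without_censoring(self):
        """Risks 0.10 vs 0.05 with no censoring give NNH = 20."""
        df = cohort_from_counts([(1, 100, 10, {"m": 1}), (0, 100, 5, {"m": 1})])
        out = number_needed_to_harm(df, df["m"].to_numpy(bool), horizon=2.0)
        assert out["nnh"] == pytest.approx(20.0, rel=1e-6)
        assert out["harmful"]

    def test_zero_risk_difference_flagged(self):
        df = cohort_from_counts([(1, 100, 5, {"m": 1}), (0, 100, 5, {"m": 1})])
        out = number_needed_to_harm(df, df["m"].to_numpy(bool), horizon=2.0)
        assert not out["harmful"]

    def test_protective_difference_signed(self):
        df = cohort_from_counts([(1, 100, 5, {"m": 1}), (0, 100, 10, {"m": 1})])
        out = number_needed_to_harm(df, df["m"].to_numpy(bool), horizon=2.0)
        assert out["nnh"] < 0 and not out["harmful"]

    def test_planted_absolute_risk_difference(self):
        """Exponential arms with a 2.5-point risk gap at the horizon: NNH ~ 40."""
        rng = np.random.default_rng(4)
        n = 20000
        h = 3.0
        lam_c = 0.02                      # control risk at 3y: 5.82%
        lam_t = -np.log(1 - 0.0832) / h   # treated risk: 8.32% -> ARD 2.5%
        arm = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        t = rng.exponential(1 / np.where(arm == 1, lam_t, lam_c))
        c = rng.uniform(3.5, 5.0, n)
        df = pd.DataFrame({"time": np.minimum(t, c), "event": (t <= c).astype(int), "arm": arm})
        out = number_needed_to_harm(df, np.ones(n, bool), horizon=h)
        assert out["nnh"] == pytest.approx(40.0, abs=8.0)


class TestPermutationFdr:
    def test_huge_observed_beta_gives_zero_fdr(self):
        df = exponential_survival_frame(800, 0.0, seed=1, subgroup_prevalence=0.3)
        obs = make_result(3.5, 0.02)
        obs.beta["treatment:subgroup"] = 50.0  # effectively +inf
        out = permutation_fdr(df.rename(columns={"sub": "ignore"}), df["sub"].to_numpy(), n_permutations=50, seed=0, observed=obs)
        assert out.fdr == 0.0

    def test_deterministic_given_seed(self):
        df = exponential_survival_frame(600, 0.0, seed=2, subgroup_prevalence=0.3)
        a = permutation_fdr(df, df["sub"].to_numpy(), n_permutations=100, seed=9)
        b = permutation_fdr(df, df["sub"].to_numpy(), n_permutations=100, seed=9)
        assert a.fdr == b.fdr and a.n_greater == b.n_greater

    def test_within_site_option_runs(self):
        df = exponential_survival_frame(600, 0.0, seed=3, subgroup_prevalence=0.3)
        out = permutation_fdr(df, df["sub"].to_numpy(), n_permutations=50, seed=1, within_site=True)
        assert 0.0 <= out.fdr <= 1.0

    def test_noise_subgroup_fdr_roughly_uniform(self):
        """Null subgroup labels: fdr behaves like a one-sided p-value, so
        P(fdr < 0.05) stays near 0.05 (loose 25-replicate check; the full
        100-replicate calibration lives in the acceptance suite)."""
        hits = 0
        for seed in range(25):
            df = exponential_survival_frame(1000, 0.0, seed=100 + seed, subgroup_prevalence=0.25, baseline=0.06)
            out = permutation_fdr(df, df["sub"].to_numpy(), n_permutations=100, seed=seed)
            hits += out.fdr < 0.05
        assert hits <= 5


class TestAdverseEvents:
    def test_planted_aki_multiplier_detected(self):
        from hteharm.simulate import generate_adverse_events, generate_cohort, sprint_like_config

        cfg = sprint_like_config(n_participants=8000, seed=21, treatment_log_hr=0.0)
        coh = generate_cohort(cfg)
        ae = generate_adverse_events(coh, cfg)
        member = coh["true_subgroup"].to_numpy(bool)
        out = adverse_event_cox(coh.drop(columns=["true_subgroup"]), ae, member)
        # remainder sees the global 1.6x treatment hazard; subgroup sees 1.6*3
        assert out["remainder"].hr["treatment"] == pytest.approx(1.6, rel=0.35)
        assert out["subgroup"].hr["treatment"] > out["remainder"].hr["treatment"]

    def test_aki_frequency_percents(self):
        df = cohort_from_counts([(1, 110, 0, {"m": 1}), (0, 126, 0, {"m": 1})])
        ae_ids = list(df[df.arm == 1].id[:11]) + list(df[df.arm == 0].id[:4])
        ae = pd.DataFrame({"id": ae_ids, "event_type": "AKI", "time": 0.5})
        out = adverse_event_cox(df, ae, df["m"].to_numpy(bool))
        assert out["frequency"].percent("subgroup", "treated") == 10.0
        assert out["frequency"].percent("subgroup", "control") == 3.2

    def test_no_events_raises_cleanly(self):
        df = cohort_from_counts([(1, 30, 0, {"m": 1}), (0, 30, 0, {"m": 1})])
        ae = pd.DataFrame({"id": [], "event_type": [], "time": []})
        with pytest.raises(ValueError, match="no events"):
            adverse_event_cox(df, ae, df["m"].to_numpy(bool))


class TestValidateHypothesis:
    def hypo(self, threshold=0.5):
        return SubgroupHypothesis(conditions=(Condition("sub", "==", 1, 1.0),), n_leaves=1, mean_tau=0.1)

    def test_strong_planted_interaction_validates(self):
        df = exponential_survival_frame(
            6000, 0.0, seed=8, subgroup_prevalence=0.15, subgroup_log_hr=1.5, baseline=0.06
        )
        res = validate_hypothesis(df, self.hypo(), n_permutations=200, seed=1)
        assert res.verdict.validated
        assert res.interaction.hr["treatment:subgroup"] > 1
        assert res.nnh["harmful"]

    def test_empty_subgroup_indeterminate(self):
        df = exponential_survival_frame(500, 0.0, seed=9)
        df["sub"] = 0
        res = validate_hypothesis(df, self.hypo(), n_permutations=20, seed=1)
        assert res.verdict.indeterminate
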