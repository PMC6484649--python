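"""Synthetic trial generator: null behaviour, rates, determinism, recovery."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hteharm.cox import fit_cox
from hteharm.simulate import (
    AdverseEventSpec,
    BPTrajectorySpec,
    ConfigError,
    Covariate,
    SimConfig,
    TRUTH_COLUMNS,
    generate_adverse_events,
    generate_bp_trajectories,
    generate_cohort,
    rule_mask,
    sprint_like_config,
    write_simulation,
)


def tiny_config(n=500, seed=0, **kw):
    covs = [Covariate("x", "continuous", mean=0, sd=1), Covariate("b", "binary", prevalence=0.3)]
    kw.setdefault("covariates", covs)
    kw.setdefault("n_sites", 5)
    return SimConfig(n_participants=n, seed=seed, **kw)


class TestCohort:
    def test_null_effect_event_counts_differ_only_by_noise(self):
        """Two-proportion z-test on treated vs control events: with no
        treatment effect, non-significant at alpha=.01 in >= 95% of 100 seeds."""
        nonsig = 0
        for seed in range(100):
            cfg = SimConfig(
                n_participants=10_000,
                n_sites=50,
                covariates=[Covariate("x", "continuous")],
                seed=seed,
            )
            coh = generate_cohort(cfg)
            p = coh.groupby("arm")["event"].agg(["sum", "size"])
            p1, n1 = p.loc[1, "sum"], p.loc[1, "size"]
            p0, n0 = p.loc[0, "sum"], p.loc[0, "size"]
            pool = (p1 + p0) / (n1 + n0)
            se = math.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n0))
            z = (p1 / n1 - p0 / n0) / se
            nonsig += abs(z) < stats.norm.ppf(0.995)
        assert nonsig >= 95

    def test_event_fraction_matches_exponential_cdf(self):
        """baseline_hazard = -ln(0.94)/3.3 gives ~6% cumulative events at 3.3y;
        the realized overall fraction sits within +-1.5 points of 6%."""
        cfg = sprint_like_config(n_participants=9361, seed=1, planted=False, treatment_log_hr=0.0)
        assert cfg.baseline_hazard == pytest.approx(-math.log(0.94) / 3.3)
        coh = generate_cohort(cfg)
        assert abs(coh["event"].mean() - 0.06) < 0.015

    def test_seeded_determinism_byte_identical(self, tmp_path):
        cfg = tiny_config(seed=9)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        pd.testing.assert_frame_equal(a, b)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        a.to_csv(pa, index=False)
        b.to_csv(pb, index=False)
        assert pa.read_bytes() == pb.read_bytes()

    def test_arms_exactly_balanced_and_covariates_randomized(self):
        """Mean standardized arm difference of each covariate stays < 0.05
        over 200 seeds at trial scale."""
        diffs = []
        for seed in range(200):
            cfg = tiny_config(n=9361, seed=seed)
            coh = generate_cohort(cfg)
            assert abs((coh["arm"] == 1).sum() - (coh["arm"] == 0).sum()) <= 1
            g = coh.groupby("arm")[["x", "b"]].mean()
            sd = coh[["x", "b"]].std()
            diffs.append(((g.loc[1] - g.loc[0]) / sd).to_numpy())
        mean_smd = np.abs(np.mean(diffs, axis=0))
        assert (mean_smd < 0.05).all()

    def test_planted_subgroup_membership_and_truth_column(self):
        cfg = sprint_like_config(n_participants=4000, seed=3)
        coh = generate_cohort(cfg)
        member = rule_mask(coh, cfg.harm_subgroup_rule)
        assert (coh["true_subgroup"].to_numpy() == member.astype(int)).all()
        assert 0.02 < member.mean() < 0.08  # smokers with top-tercile SBP

    def test_subgroup_log_hr_recovered_by_cox(self):
        """Planted treated-subgroup extra log-hazard is recovered within 2 SE
        (>= 5 of 6 replicates, since one replicate misses ~5% of the time)."""
        covered = 0
        for seed in range(6):
            cfg = sprint_like_config(n_participants=9361, seed=seed, treatment_log_hr=0.0)
            coh = generate_cohort(cfg)
            df = coh.rename(columns={"true_subgroup": "sub"})
            df["inter"] = df["arm"] * df["sub"]
            res = fit_cox(df, ["arm", "sub", "inter"], strata="site")
            covered += abs(res.beta["inter"] - 0.7) < 2 * res.se["inter"]
        assert covered >= 5

    def test_invalid_covariate_named_in_error(self):
        with pytest.raises(ConfigError, match="bad_cov"):
            generate_cohort(
                tiny_config(covariates=[Covariate("bad_cov", "continuous", sd=-1.0)])
            )

    def test_unknown_rule_covariate_rejected(self):
        with pytest.raises(ConfigError, match="nope"):
            generate_cohort(tiny_config(harm_subgroup_rule=[("nope", ">", 1)]))

    def test_smoker_sbp_correlation_option(self):
        covs = [Covariate("smoke", "binary", prevalence=0.2), Covariate("press", "continuous", mean=140, sd=15)]
        cfg = SimConfig(
            n_participants=20_000,
            covariates=covs,
            binary_continuous_correlation=("smoke", "press", -0.4),
            seed=4,
        )
        coh = generate_cohort(cfg)
        r = np.corrcoef(coh["smoke"], coh["press"])[0, 1]
        assert -0.45 < r < -0.2
        assert abs(coh["smoke"].mean() - 0.2) < 0.02


class TestBPTrajectories:
    def test_noise_free_complete_decay_hits_arm_target(self):
        cfg = tiny_config(
            covariates=[Covariate("sbp", "continuous", 140, 15), Covariate("dbp", "continuous", 78, 12)],
            bp=BPTrajectorySpec(noise_sd=0.0, decay_rate=50.0),
        )
        coh = generate_cohort(cfg)
        bp = generate_bp_trajectories(coh, cfg)
        last = bp.sort_values("visit_time").groupby("id").last().join(coh.set_index("id")["arm"])
        last = last[last["visit_time"] >= 0.5]  # early-event dropouts never decay fully
        target = np.where(last["arm"] == 1, 120.0, 135.0)
        assert np.allclose(last["sbp"], target, atol=1e-3)

    def test_zero_visits_gives_empty_table(self):
        cfg = tiny_config(
            covariates=[Covariate("sbp", "continuous", 140, 15), Covariate("dbp", "continuous", 78, 12)],
            bp=BPTrajectorySpec(visit_times=[]),
        )
        coh = generate_cohort(cfg)
        assert len(generate_bp_trajectories(coh, cfg)) == 0

    def test_subgroup_extra_drop_recovered_by_diff_in_diff(self):
        """Planted extra SBP drop of 5 mm Hg shows up as a ~-5 contrast."""
        from hteharm.mechanism import mechanism_contrast

        covs = [
            Covariate("current_smoker", "binary", prevalence=0.5),
            Covariate("sbp", "continuous", 140, 15),
            Covariate("dbp", "continuous", 78, 12),
        ]
        cfg = SimConfig(
            n_participants=2000,
            n_sites=10,
            covariates=covs,
            harm_subgroup_rule=[("current_smoker", "==", 1)],
            bp=BPTrajectorySpec(noise_sd=3.0, decay_rate=50.0, subgroup_extra_sbp_drop=5.0),
            seed=6,
        )
        coh = generate_cohort(cfg)
        bp = generate_bp_trajectories(coh, cfg)
        member = coh["true_subgroup"].to_numpy(bool)
        c = mechanism_contrast(bp, coh, member, quantity="sbp")
        assert c.estimate == pytest.approx(-5.0, abs=1.0)
        assert c.ci_low < -5.0 < c.ci_high

    def test_visits_never_exceed_follow_up_and_sbp_above_dbp(self):
        cfg = sprint_like_config(n_participants=500, seed=8)
        coh = generate_cohort(cfg)
        bp = generate_bp_trajectories(coh, cfg)
        fup = coh.set_index("id")["time"]
        assert (bp["visit_time"].to_numpy() <= fup.loc[bp["id"]].to_numpy() + 1e-12).all()
        assert (bp["sbp"] > bp["dbp"]).all()
        assert (bp["dbp"] > 0).all()


class TestAdverseEvents:
    def test_zero_hazard_gives_empty_table(self):
        cfg = tiny_config(adverse_events=AdverseEventSpec(baseline_hazard=0.0))
        coh = generate_cohort(cfg)
        assert len(generate_adverse_events(coh, cfg)) == 0

    def test_subgroup_treatment_multiplier_recovered(self):
        """e^1 treated-subgroup multiplier: Cox log-HR recovers 1.0 +- 0.3."""
        covs = [Covariate("flag", "binary", prevalence=0.5)]
        cfg = SimConfig(
            n_participants=10_000,
            n_sites=10,
            covariates=covs,
            harm_subgroup_rule=[("flag", "==", 1)],
            adverse_events=AdverseEventSpec(baseline_hazard=0.02, treatment_hr=1.0, subgroup_treatment_hr=math.e),
            seed=2,
        )
        coh = generate_cohort(cfg)
        ae = generate_adverse_events(coh, cfg)
        sub = coh[coh["true_subgroup"] == 1].copy()  # ~5000 members
        first = ae.groupby("id")["time"].min()
        ae_time = sub["id"].map(first)
        sub["ae_event"] = ae_time.notna().astype(int)
        sub["ae_time"] = ae_time.where(ae_time.notna(), sub["time"])
        res = fit_cox(sub, ["arm"], strata="site", time_col="ae_time", event_col="ae_event")
        assert res.beta["arm"] == pytest.approx(1.0, abs=0.3)

    def test_event_times_within_follow_up_and_determinism(self):
        cfg = sprint_like_config(n_participants=1000, seed=5)
        coh = generate_cohort(cfg)
        a = generate_adverse_events(coh, cfg)
        b = generate_adverse_events(coh, cfg)
        pd.testing.assert_frame_equal(a, b)
        fup = coh.set_index("id")["time"]
        assert (a["time"].to_numpy() <= fup.loc[a["id"]].to_numpy()).all()


class TestArtifacts:
    def test_truth_diverted_to_sidecar(self, tmp_path):
        cfg = sprint_like_config(n_participants=200, seed=1)
        coh = generate_cohort(cfg)
        bp = generate_bp_trajectories(coh, cfg)
        ae = generate_adverse_events(coh, cfg)
        paths = write_simulation(tmp_path, coh, bp, ae, cfg)
        main = pd.read_csv(paths["cohort"])
        assert not set(TRUTH_COLUMNS) & set(main.columns)
        truth = pd.read_csv(paths["truth"])
        assert set(truth.columns) == {"id", "true_subgroup"}
        rebuilt = SimConfig.from_yaml((tmp_path / "sim_config.yaml").read_text())
        assert rebuilt.to_yaml() == cfg.to_yaml()
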