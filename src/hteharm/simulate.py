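"""Synthetic two-arm blood-pressure trial generator.

Emulates a SPRINT-like randomized trial: ~9,000 participants at ~100 clinic
sites, 1:1 randomization to an intensive versus standard systolic-pressure
target, a Table-1-style panel of baseline covariates, exponential
proportional-hazards composite-event times with administrative censoring from
a uniform accrual window, quarterly blood-pressure visits decaying toward
arm-specific targets, and an acute-kidney-injury (AKI) adverse-event process.

A *planted harmful subgroup* — a conjunction of baseline-covariate conditions,
e.g. current smoker with top-tercile systolic pressure — can be given an extra
treated-arm log-hazard so that every downstream discovery/validation stage is
testable against known ground truth.  All effect sizes are simulation knobs:
the real trial provides no generative model, and nothing here is an estimate
of it.

True subgroup membership is carried in a ``true_subgroup`` column that the
writer diverts to a sidecar file so analysis stages cannot consume it.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ConfigError",
    "Covariate",
    "AdverseEventSpec",
    "BPTrajectorySpec",
    "SimConfig",
    "default_covariates",
    "sprint_like_config",
    "rule_mask",
    "generate_cohort",
    "generate_bp_trajectories",
    "generate_adverse_events",
    "write_simulation",
    "TRUTH_COLUMNS",
]

#: columns that carry simulation ground truth and must never reach analysis
TRUTH_COLUMNS = ("true_subgroup",)

#: reserved (non-covariate) columns of a trial table
RESERVED_COLUMNS = ("id", "site", "arm", "time", "event") + TRUTH_COLUMNS


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class Covariate:
    """One baseline covariate: Gaussian if continuous, Bernoulli if binary."""

    name: str
    kind: str  # "continuous" | "binary"
    mean: float = 0.0
    sd: float = 1.0
    prevalence: float = 0.5

    def validate(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ConfigError(f"covariate {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "continuous" and not (self.sd > 0 and math.isfinite(self.sd)):
            raise ConfigError(f"covariate {self.name!r}: sd must be positive")
        if self.kind == "binary" and not 0.0 <= self.prevalence <= 1.0:
            raise ConfigError(f"covariate {self.name!r}: prevalence outside [0, 1]")


@dataclass
class AdverseEventSpec:
    """Proportional-hazards process for a serious adverse event (AKI).

    ``treatment_hr`` multiplies the hazard in the intensive arm everywhere;
    ``subgroup_treatment_hr`` multiplies it *additionally* for treated members
    of the planted subgroup.
    """

    event_type: str = "AKI"
    baseline_hazard: float = 0.012  # events per person-year
    treatment_hr: float = 1.6
    subgroup_treatment_hr: float = 3.0

    def validate(self) -> None:
        if self.baseline_hazard < 0:
            raise ConfigError("adverse_events.baseline_hazard must be >= 0")
        if self.treatment_hr <= 0 or self.subgroup_treatment_hr <= 0:
            raise ConfigError("adverse-event hazard multipliers must be > 0")


@dataclass
class BPTrajectorySpec:
    """Per-arm blood-pressure decay model with quarterly visits.

    sbp(t) = target_arm + (sbp0 - target_arm) * exp(-decay_rate * t) + noise,
    likewise for DBP.  Treated members of the planted subgroup reach targets
    deeper by ``subgroup_extra_*_drop`` mm Hg (their harm mechanism).
    """

    sbp_target: tuple[float, float] = (135.0, 120.0)  # (standard, intensive)
    dbp_target: tuple[float, float] = (75.0, 68.0)
    decay_rate: float = 3.0  # per year
    visit_interval: float = 0.25  # years; the trial measured quarterly
    visit_times: list[float] | None = None  # overrides the interval schedule
    noise_sd: float = 7.0  # mm Hg, per visit
    subgroup_extra_sbp_drop: float = 0.0
    subgroup_extra_dbp_drop: float = 0.0

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ConfigError("bp.noise_sd must be >= 0")
        if self.decay_rate < 0:
            raise ConfigError("bp.decay_rate must be >= 0")
        if self.visit_times is not None:
            vt = list(self.visit_times)
            if any(b <= a for a, b in zip(vt, vt[1:])):
                raise ConfigError("bp.visit_times must be strictly increasing")
        elif self.visit_interval <= 0:
            raise ConfigError("bp.visit_interval must be > 0")


def default_covariates() -> list[Covariate]:
    """Baseline covariate panel with marginals mirroring the trial's Table 1."""
    c, b = "continuous", "binary"
    return [
        Covariate("framingham_risk", c, mean=20.1, sd=10.8),
        Covariate("current_smoker", b, prevalence=0.136),
        Covariate("sbp", c, mean=139.7, sd=15.6),
        Covariate("dbp", c, mean=78.2, sd=12.0),
        Covariate("aspirin", b, prevalence=0.511),
        Covariate("egfr", c, mean=71.7, sd=20.7),
        Covariate("creatinine", c, mean=1.10, sd=0.34),
        Covariate("black", b, prevalence=0.315),
        Covariate("age", c, mean=67.9, sd=9.4),
        Covariate("female", b, prevalence=0.356),
        Covariate("cholesterol", c, mean=190.0, sd=40.6),
        Covariate("glucose", c, mean=98.9, sd=13.6),
        Covariate("hdl", c, mean=52.8, sd=14.5),
        Covariate("triglycerides", c, mean=126.1, sd=84.0),
        Covariate("urine_acr", c, mean=42.5, sd=166.0),
        Covariate("bmi", c, mean=29.9, sd=5.8),
        Covariate("statin", b, prevalence=0.433),
    ]


@dataclass
class SimConfig:
    """Full description of one simulated trial.

    ``harm_subgroup_rule`` is a conjunction of ``(covariate, op, value)``
    conditions with ``op`` in {"==", ">", "<="}; an empty rule means no
    planted subgroup (global-effect null is then governed solely by
    ``treatment_log_hr``).
    """

    n_participants: int = 9361
    n_sites: int = 100
    covariates: list[Covariate] = field(default_factory=default_covariates)
    harm_subgroup_rule: list[tuple] = field(default_factory=list)
    baseline_hazard: float = 0.0188  # composite events per person-year
    treatment_log_hr: float = 0.0
    subgroup_extra_log_hr: float = 0.0
    accrual_years: float = 2.4
    study_years: float = 4.75  # fixed administrative study end
    site_frailty_sd: float = 0.0  # SD of log-normal per-site hazard multiplier
    binary_continuous_correlation: tuple[str, str, float] | None = None
    adverse_events: AdverseEventSpec = field(default_factory=AdverseEventSpec)
    bp: BPTrajectorySpec = field(default_factory=BPTrajectorySpec)
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ConfigError("n_participants must be > 0")
        if self.n_sites <= 0:
            raise ConfigError("n_sites must be > 0")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be > 0")
        if self.accrual_years < 0 or self.study_years <= self.accrual_years:
            raise ConfigError("need 0 <= accrual_years < study_years")
        if self.site_frailty_sd < 0:
            raise ConfigError("site_frailty_sd must be >= 0")
        names = [cv.name for cv in self.covariates]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate covariate names")
        for cv in self.covariates:
            cv.validate()
        for cond in self.harm_subgroup_rule:
            name, op, _ = cond
            if name not in names:
                raise ConfigError(f"harm_subgroup_rule references unknown covariate {name!r}")
            if op not in ("==", ">", "<="):
                raise ConfigError(f"harm_subgroup_rule: unknown operator {op!r}")
        if self.binary_continuous_correlation is not None:
            bname, cname, rho = self.binary_continuous_correlation
            if bname not in names or cname not in names:
                raise ConfigError("binary_continuous_correlation references unknown covariate")
            if not -1.0 < rho < 1.0:
                raise ConfigError("correlation must be in (-1, 1)")
        self.adverse_events.validate()
        self.bp.validate()

    def covariate_names(self) -> list[str]:
        return [cv.name for cv in self.covariates]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        d = self.to_dict()
        d["harm_subgroup_rule"] = [list(c) for c in self.harm_subgroup_rule]
        if d["binary_continuous_correlation"] is not None:
            d["binary_continuous_correlation"] = list(d["binary_continuous_correlation"])
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["covariates"] = [Covariate(**cv) for cv in d.get("covariates", [])]
        d["harm_subgroup_rule"] = [tuple(c) for c in d.get("harm_subgroup_rule", [])]
        if d.get("binary_continuous_correlation") is not None:
            d["binary_continuous_correlation"] = tuple(d["binary_continuous_correlation"])
        if "adverse_events" in d and isinstance(d["adverse_events"], dict):
            ae = dict(d["adverse_events"])
            ae["subgroup_treatment_hr"] = ae.get("subgroup_treatment_hr", 3.0)
            d["adverse_events"] = AdverseEventSpec(**ae)
        if "bp" in d and isinstance(d["bp"], dict):
            d["bp"] = BPTrajectorySpec(**{k: (tuple(v) if k.endswith("_target") else v) for k, v in d["bp"].items()})
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(text))


def sprint_like_config(
    n_participants: int = 9361,
    seed: int = 0,
    *,
    planted: bool = True,
    treatment_log_hr: float = math.log(0.75),
    subgroup_extra_log_hr: float = 0.7,
    n_sites: int = 100,
    covariates: list[Covariate] | None = None,
) -> SimConfig:
    """Trial-emulating configuration.

    Defaults follow the study being emulated: overall treatment benefit
    (HR 0.75), composite event probability near 6% by 3.3 years
    (``baseline_hazard = -ln(0.94)/3.3``), median follow-up ~3.3 years from
    2.4-year uniform accrual, and — when ``planted`` — a harmful subgroup of
    current smokers with top-tercile baseline SBP (>146.4 mm Hg under the
    Table-1 marginals, prevalence ~4.5%) whose treated members carry an extra
    log-hazard of 0.7 for the composite event, a 3-fold extra AKI hazard, and
    a deeper blood-pressure drop (5 mm Hg systolic, 10 mm Hg diastolic).
    """
    covs = covariates if covariates is not None else default_covariates()
    names = [cv.name for cv in covs]
    rule: list[tuple] = []
    extra = 0.0
    bp = BPTrajectorySpec()
    ae = AdverseEventSpec()
    if planted:
        if "current_smoker" not in names or "sbp" not in names:
            raise ConfigError("planted subgroup needs 'current_smoker' and 'sbp' covariates")
        sbp_cv = covs[names.index("sbp")]
        tercile = sbp_cv.mean + 0.430727 * sbp_cv.sd  # upper tercile of the Gaussian
        rule = [("current_smoker", "==", 1), ("sbp", ">", round(tercile, 1))]
        extra = subgroup_extra_log_hr
        bp = BPTrajectorySpec(subgroup_extra_sbp_drop=5.0, subgroup_extra_dbp_drop=10.0)
    return SimConfig(
        n_participants=n_participants,
        n_sites=n_sites,
        covariates=covs,
        harm_subgroup_rule=rule,
        baseline_hazard=-math.log(0.94) / 3.3,
        treatment_log_hr=treatment_log_hr,
        subgroup_extra_log_hr=extra,
        adverse_events=ae,
        bp=bp,
        seed=seed,
    )


def rule_mask(table: pd.DataFrame, rule: list[tuple]) -> np.ndarray:
    """Boolean membership vector for a conjunction of covariate conditions."""
    mask = np.ones(len(table), dtype=bool)
    for name, op, value in rule:
        col = table[name].to_numpy()
        if op == "==":
            mask &= col == value
        elif op == ">":
            mask &= col > value
        elif op == "<=":
            mask &= col <= value
        else:  # pragma: no cover - validated upstream
            raise ConfigError(f"unknown operator {op!r}")
    return mask


def _rng_for(config: SimConfig, stream: int) -> np.random.Generator:
    # streams: 0 cohort, 1 blood pressure, 2 adverse events
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """Draw the baseline table plus composite-outcome follow-up.

    Event times are exponential under a proportional-hazards model whose
    linear predictor is ``treatment_log_hr * arm + subgroup_extra_log_hr *
    arm * member``; follow-up is censored administratively at
    ``study_years - accrual_offset`` with accrual uniform on
    ``[0, accrual_years]``.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = _rng_for(config, 0)
    n = config.n_participants

    table: dict[str, np.ndarray] = {}
    table["id"] = np.arange(1, n + 1)
    table["site"] = rng.integers(0, config.n_sites, size=n)
    arm = np.zeros(n, dtype=int)
    arm[: n // 2] = 1
    rng.shuffle(arm)
    table["arm"] = arm

    corr = config.binary_continuous_correlation
    for cv in config.covariates:
        if corr is not None and cv.name in (corr[0], corr[1]):
            continue  # drawn jointly below
        if cv.kind == "continuous":
            table[cv.name] = cv.mean + cv.sd * rng.standard_normal(n)
        else:
            table[cv.name] = (rng.random(n) < cv.prevalence).astype(int)
    if corr is not None:
        bname, cname, rho = corr
        covs = {cv.name: cv for cv in config.covariates}
        z1 = rng.standard_normal(n)
        z2 = rho * z1 + math.sqrt(1 - rho**2) * rng.standard_normal(n)
        table[cname] = covs[cname].mean + covs[cname].sd * z1
        from scipy.stats import norm as _norm

        # larger latent z2 -> positive flag, so corr(flag, continuous) tracks rho
        table[bname] = (z2 > _norm.ppf(1.0 - covs[bname].prevalence)).astype(int)

    df = pd.DataFrame(table)
    member = rule_mask(df, config.harm_subgroup_rule) if config.harm_subgroup_rule else np.zeros(n, dtype=bool)

    frailty = np.ones(config.n_sites)
    if config.site_frailty_sd > 0:
        s = config.site_frailty_sd
        frailty = np.exp(rng.normal(-0.5 * s * s, s, size=config.n_sites))  # mean-one

    lp = config.treatment_log_hr * arm + config.subgroup_extra_log_hr * (arm * member)
    lam = config.baseline_hazard * frailty[df["site"].to_numpy()] * np.exp(lp)
    t_event = rng.exponential(1.0 / lam)
    horizon = config.study_years - rng.uniform(0.0, config.accrual_years, size=n)
    df["time"] = np.minimum(t_event, horizon)
    df["event"] = (t_event <= horizon).astype(int)
    df["true_subgroup"] = member.astype(int)
    return df


def _visit_schedule(config: SimConfig) -> np.ndarray:
    bp = config.bp
    if bp.visit_times is not None:
        return np.asarray(bp.visit_times, dtype=float)
    return np.arange(0.0, config.study_years + 1e-9, bp.visit_interval)


def generate_bp_trajectories(cohort: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Quarterly SBP/DBP visits while a participant remains under follow-up.

    Requires ``sbp`` and ``dbp`` baseline columns in the cohort.  Pressures
    decay exponentially from baseline toward the arm target (treated subgroup
    members: target lowered by the configured extra drops) with i.i.d.
    Gaussian visit noise; DBP is kept strictly below SBP.
    """
    config.validate()
    for col in ("sbp", "dbp"):
        if col not in cohort.columns:
            raise ConfigError(f"blood-pressure generation needs baseline column {col!r}")
    rng = _rng_for(config, 1)
    sched = _visit_schedule(config)
    if sched.size == 0:
        return pd.DataFrame({"id": [], "visit_time": [], "sbp": [], "dbp": []})

    if "true_subgroup" in cohort.columns:
        member = cohort["true_subgroup"].to_numpy(dtype=bool)
    elif config.harm_subgroup_rule:
        member = rule_mask(cohort, config.harm_subgroup_rule)
    else:
        member = np.zeros(len(cohort), dtype=bool)

    arm = cohort["arm"].to_numpy()
    fup = cohort["time"].to_numpy()
    sbp0 = cohort["sbp"].to_numpy(dtype=float)
    dbp0 = cohort["dbp"].to_numpy(dtype=float)
    ids = cohort["id"].to_numpy()
    bp = config.bp

    sbp_target = np.where(arm == 1, bp.sbp_target[1], bp.sbp_target[0]).astype(float)
    dbp_target = np.where(arm == 1, bp.dbp_target[1], bp.dbp_target[0]).astype(float)
    deep = (arm == 1) & member
    sbp_target -= bp.subgroup_extra_sbp_drop * deep
    dbp_target -= bp.subgroup_extra_dbp_drop * deep

    frames = []
    for t in sched:
        alive = t <= fup
        if not alive.any():
            continue
        decay = math.exp(-bp.decay_rate * t)
        sbp = sbp_target + (sbp0 - sbp_target) * decay
        dbp = dbp_target + (dbp0 - dbp_target) * decay
        if bp.noise_sd > 0:
            sbp = sbp + rng.normal(0.0, bp.noise_sd, size=len(cohort))
            dbp = dbp + rng.normal(0.0, bp.noise_sd, size=len(cohort))
        dbp = np.clip(dbp, 20.0, None)
        sbp = np.maximum(sbp, dbp + 1.0)
        frames.append(
            pd.DataFrame(
                {"id": ids[alive], "visit_time": t, "sbp": sbp[alive], "dbp": dbp[alive]}
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["id", "visit_time"], kind="stable").reset_index(drop=True)


def generate_adverse_events(cohort: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Time-to-first adverse event (AKI), censored at each follow-up time.

    Hazard: ``baseline * treatment_hr^arm * subgroup_treatment_hr^(arm*member)``.
    """
    config.validate()
    rng = _rng_for(config, 2)
    ae = config.adverse_events
    if ae.baseline_hazard == 0:
        return pd.DataFrame({"id": [], "event_type": [], "time": []})

    if "true_subgroup" in cohort.columns:
        member = cohort["true_subgroup"].to_numpy(dtype=bool)
    elif config.harm_subgroup_rule:
        member = rule_mask(cohort, config.harm_subgroup_rule)
    else:
        member = np.zeros(len(cohort), dtype=bool)
    arm = cohort["arm"].to_numpy()
    lam = ae.baseline_hazard * np.exp(
        math.log(ae.treatment_hr) * arm + math.log(ae.subgroup_treatment_hr) * (arm * member)
    )
    t_ae = rng.exponential(1.0 / lam)
    seen = t_ae <= cohort["time"].to_numpy()
    return pd.DataFrame(
        {
            "id": cohort["id"].to_numpy()[seen],
            "event_type": ae.event_type,
            "time": t_ae[seen],
        }
    )


def write_simulation(outdir, cohort: pd.DataFrame, bp: pd.DataFrame, adverse: pd.DataFrame, config: SimConfig) -> dict:
    """Write cohort/visits/adverse-event CSVs, the truth sidecar, and the config.

    Truth columns are stripped from ``cohort.csv`` and diverted to
    ``truth.csv`` so downstream stages cannot accidentally consume them.
    Returns the mapping of artifact names to paths.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_cols = [c for c in TRUTH_COLUMNS if c in cohort.columns]
    paths = {
        "cohort": outdir / "cohort.csv",
        "truth": outdir / "truth.csv",
        "bp_visits": outdir / "bp_visits.csv",
        "adverse_events": outdir / "adverse_events.csv",
        "config": outdir / "sim_config.yaml",
    }
    cohort.drop(columns=truth_cols).to_csv(paths["cohort"], index=False)
    cohort[["id", *truth_cols]].to_csv(paths["truth"], index=False)
    bp.to_csv(paths["bp_visits"], index=False)
    adverse.to_csv(paths["adverse_events"], index=False)
    paths["config"].write_text(config.to_yaml())
    return {k: str(v) for k, v in paths.items()}
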