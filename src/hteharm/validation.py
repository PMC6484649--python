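"""Split-sample validation of harm-subgroup hypotheses on held-out data.

Each distilled hypothesis is tested on the *testing* half of the cohort with
site-stratified Cox proportional-hazards models:

* an interaction model with terms ``treatment + subgroup + treatment:subgroup``,
* a treatment-only model restricted to subgroup members,

plus a permutation false-discovery rate for the interaction coefficient: the
subgroup indicator is randomly permuted across participants (arm, outcome and
site stay fixed), the interaction model refit, and the FDR estimated as the
proportion of permuted interaction coefficients strictly greater than the
observed one.  (Formally this exceedance proportion is a one-sided
permutation p-value; the term FDR is kept because it is how the estimate is
named in this validation design.)

A hypothesis is *validated* — judged genuinely harmful — only if
(1) the interaction HR is > 1 with two-tailed p < .05 and FDR < .05, and
(2) the within-subgroup treatment HR is > 1 with two-tailed p < .05.

Companion outputs: subgroup-by-arm event-frequency tables, number needed to
harm from Kaplan–Meier risks at a horizon, and adverse-event Cox fits inside
and outside the subgroup.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cox import CoxResult, StratifiedCoxEngine, fit_cox
from .hypotheses import SubgroupHypothesis

__all__ = [
    "PermutationFdr",
    "HarmVerdict",
    "FrequencyReport",
    "ValidationResult",
    "interaction_model",
    "within_subgroup_model",
    "permutation_fdr",
    "harm_verdict",
    "frequency_report",
    "number_needed_to_harm",
    "adverse_event_cox",
    "validate_hypothesis",
]

TERMS = ["treatment", "subgroup", "treatment:subgroup"]


def _design(data: pd.DataFrame, member: np.ndarray) -> pd.DataFrame:
    out = data[["time", "event", "site"]].copy()
    out["treatment"] = data["arm"].to_numpy()
    out["subgroup"] = member.astype(int)
    out["treatment:subgroup"] = out["treatment"] * out["subgroup"]
    return out


def interaction_model(test_data: pd.DataFrame, member: np.ndarray, *, ties: str = "breslow") -> CoxResult:
    """Site-stratified Cox fit with treatment, subgroup and their interaction."""
    return fit_cox(_design(test_data, member), TERMS, strata="site", ties=ties)


def within_subgroup_model(test_data: pd.DataFrame, member: np.ndarray, *, ties: str = "breslow") -> CoxResult:
    """Site-stratified treatment-only Cox fit restricted to subgroup members."""
    d = _design(test_data, member)
    return fit_cox(d[d["subgroup"] == 1], ["treatment"], strata="site", ties=ties)


@dataclass
class PermutationFdr:
    observed_beta: float
    n_permutations: int
    n_greater: int
    fdr: float
    n_nonconverged: int
    seed: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def permutation_fdr(
    test_data: pd.DataFrame,
    member: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
    *,
    observed: CoxResult | None = None,
    within_site: bool = False,
    ties: str = "breslow",
) -> PermutationFdr:
    """Permutation exceedance proportion for the interaction coefficient.

    The subgroup column is permuted globally across participants (or within
    clinic site with ``within_site=True``), the three-term stratified model
    refit each time, and ``fdr = #(permuted beta > observed beta) / B``.
    Permutation fits that fail to converge are recorded with a ``-inf``
    sentinel (they never exceed) and tallied in ``n_nonconverged``.  The
    observed fit must converge; pass it via ``observed`` to avoid refitting.
    """
    if observed is None:
        observed = interaction_model(test_data, member, ties=ties)
    if not observed.converged:
        raise ValueError("observed interaction fit did not converge; permutation FDR undefined")
    obs_beta = float(observed.beta["treatment:subgroup"])

    engine = StratifiedCoxEngine(
        test_data["time"].to_numpy(),
        test_data["event"].to_numpy(),
        test_data["site"].to_numpy(),
        ties=ties,
    )
    arm = test_data["arm"].to_numpy(dtype=float)
    sub = member.astype(float)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 43]))
    site_codes = pd.factorize(test_data["site"].to_numpy())[0]
    by_site = [np.flatnonzero(site_codes == s) for s in range(site_codes.max() + 1)] if within_site else None

    n_greater = 0
    n_bad = 0
    X = np.empty((len(arm), 3))
    X[:, 0] = arm
    for _ in range(n_permutations):
        if within_site:
            perm_sub = sub.copy()
            for idx in by_site:
                perm_sub[idx] = sub[idx][rng.permutation(idx.size)]
        else:
            perm_sub = sub[rng.permutation(sub.size)]
        X[:, 1] = perm_sub
        X[:, 2] = arm * perm_sub
        beta, conv = engine.fit_beta(X)
        if not conv:
            n_bad += 1
            continue  # -inf sentinel: never exceeds
        if beta[2] > obs_beta:
            n_greater += 1
    return PermutationFdr(
        observed_beta=obs_beta,
        n_permutations=n_permutations,
        n_greater=n_greater,
        fdr=n_greater / n_permutations,
        n_nonconverged=n_bad,
        seed=int(seed),
    )


@dataclass
class HarmVerdict:
    """The two-criterion decision, with structured failure reasons."""

    criterion1: bool  # interaction HR > 1, p < alpha, FDR < fdr_threshold
    criterion2: bool  # within-subgroup treatment HR > 1, p < alpha
    validated: bool
    indeterminate: bool = False
    reasons: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "criterion1": self.criterion1,
            "criterion2": self.criterion2,
            "validated": self.validated,
            "indeterminate": self.indeterminate,
            "reasons": list(self.reasons),
        }


def harm_verdict(
    interaction: CoxResult,
    within: CoxResult,
    fdr: PermutationFdr,
    *,
    alpha: float = 0.05,
    fdr_threshold: float = 0.05,
) -> HarmVerdict:
    """Apply both validation criteria literally."""
    if not (interaction.converged and within.converged):
        return HarmVerdict(False, False, False, indeterminate=True, reasons=("non-converged Cox fit",))
    reasons = []
    t = "treatment:subgroup"
    if not interaction.hr[t] > 1:
        reasons.append(f"interaction HR {interaction.hr[t]:.3g} <= 1")
    if not interaction.p[t] < alpha:
        reasons.append(f"interaction p {interaction.p[t]:.3g} >= {alpha}")
    if not fdr.fdr < fdr_threshold:
        reasons.append(f"FDR {fdr.fdr:.3g} >= {fdr_threshold}")
    c1 = interaction.hr[t] > 1 and interaction.p[t] < alpha and fdr.fdr < fdr_threshold
    if not within.hr["treatment"] > 1:
        reasons.append(f"within-subgroup HR {within.hr['treatment']:.3g} <= 1")
    if not within.p["treatment"] < alpha:
        reasons.append(f"within-subgroup p {within.p['treatment']:.3g} >= {alpha}")
    c2 = within.hr["treatment"] > 1 and within.p["treatment"] < alpha
    return HarmVerdict(bool(c1), bool(c2), bool(c1 and c2), reasons=tuple(reasons))


@dataclass
class FrequencyReport:
    """Participants and events per (membership x arm) cell, percents to 1 dp."""

    table: pd.DataFrame  # rows: subgroup/remainder x treated/control
    empty_subgroup: bool = False

    def percent(self, group: str, arm_label: str) -> float:
        row = self.table[(self.table["group"] == group) & (self.table["arm"] == arm_label)]
        return float(row["percent"].iloc[0])

    def to_dict(self) -> dict:
        return {"table": self.table.to_dict(orient="records"), "empty_subgroup": self.empty_subgroup}


def frequency_report(test_data: pd.DataFrame, member: np.ndarray, *, event_col: str = "event") -> FrequencyReport:
    """2x2 membership-by-arm counts of participants and events.

    Percents are ``100 * events / n`` rounded to one decimal, mirroring how
    trial outcome tables print "n (events)" cells.
    """
    rows = []
    member = np.asarray(member, dtype=bool)
    for gname, gmask in (("subgroup", member), ("remainder", ~member)):
        for aname, aval in (("treated", 1), ("control", 0)):
            m = gmask & (test_data["arm"].to_numpy() == aval)
            n = int(m.sum())
            ev = int(test_data.loc[m, event_col].sum())
            rows.append(
                {
                    "group": gname,
                    "arm": aname,
                    "n": n,
                    "events": ev,
                    "percent": round(100.0 * ev / n, 1) if n else float("nan"),
                }
            )
    return FrequencyReport(table=pd.DataFrame(rows), empty_subgroup=bool(~member.any()))


def number_needed_to_harm(
    test_data: pd.DataFrame,
    member: np.ndarray,
    horizon: float | None = None,
) -> dict:
    """NNH = 1 / (treated KM risk - control KM risk) at a horizon, in-subgroup.

    Risks are Kaplan–Meier event probabilities at ``horizon`` (default: the
    cohort's median follow-up).  A nonpositive risk difference yields a
    signed NNH with ``harmful=False`` ("no harm at this horizon").
    """
    from lifelines import KaplanMeierFitter

    member = np.asarray(member, dtype=bool)
    if horizon is None:
        horizon = float(test_data["time"].median())
    sub = test_data[member]
    risks = {}
    for aname, aval in (("treated", 1), ("control", 0)):
        d = sub[sub["arm"] == aval]
        if len(d) == 0 or d["event"].sum() == 0:
            km_risk = 0.0
        else:
            km = KaplanMeierFitter().fit(d["time"], d["event"])
            km_risk = float(1.0 - km.predict(horizon))
        risks[aname] = km_risk
    ard = risks["treated"] - risks["control"]
    nnh = float("inf") if ard == 0 else 1.0 / ard
    return {
        "horizon": horizon,
        "risk_treated": risks["treated"],
        "risk_control": risks["control"],
        "risk_difference": ard,
        "nnh": nnh,
        "harmful": ard > 0,
    }


def attach_adverse_event_outcome(
    test_data: pd.DataFrame, adverse: pd.DataFrame, event_type: str = "AKI"
) -> pd.DataFrame:
    """Derive time-to-first named adverse event, censored at follow-up."""
    ae = adverse[adverse["event_type"] == event_type]
    first = ae.groupby("id")["time"].min()
    out = test_data.copy()
    ae_time = out["id"].map(first)
    out["ae_event"] = (~ae_time.isna() & (ae_time <= out["time"])).astype(int)
    out["ae_time"] = np.where(out["ae_event"] == 1, ae_time.fillna(np.inf), out["time"])
    return out


def adverse_event_cox(
    test_data: pd.DataFrame,
    adverse: pd.DataFrame,
    member: np.ndarray,
    event_type: str = "AKI",
    *,
    ties: str = "breslow",
) -> dict:
    """Treatment-only AKI Cox fits inside and outside the subgroup.

    Both fits are site-stratified, using time-to-first event of the named
    type censored at each participant's follow-up; a companion frequency
    report counts adverse events per membership-by-arm cell.
    """
    member = np.asarray(member, dtype=bool)
    d = attach_adverse_event_outcome(test_data, adverse, event_type)
    d = d.rename(columns={"time": "_fup"}).rename(columns={"ae_time": "time"})
    d["treatment"] = d["arm"]
    if int(d["ae_event"].sum()) == 0:
        raise ValueError(f"no events of type {event_type!r}: adverse-event Cox model undefined")
    results = {}
    for name, mask in (("subgroup", member), ("remainder", ~member)):
        dd = d[mask]
        try:
            results[name] = fit_cox(dd, ["treatment"], strata="site", event_col="ae_event", ties=ties)
        except ValueError:
            results[name] = None  # empty group or no events on this side
    freq = frequency_report(d.rename(columns={"event": "_event"}).rename(columns={"ae_event": "event"}), member)
    return {"subgroup": results["subgroup"], "remainder": results["remainder"], "frequency": freq}


@dataclass
class ValidationResult:
    """Everything the validation stage reports for one hypothesis."""

    hypothesis: SubgroupHypothesis
    interaction: CoxResult
    within_subgroup: CoxResult | None
    fdr: PermutationFdr | None
    verdict: HarmVerdict
    frequency: FrequencyReport
    nnh: dict | None
    n_test_members: int

    def to_dict(self) -> dict:
        return {
            "hypothesis": self.hypothesis.to_dict(),
            "interaction": self.interaction.to_dict() if self.interaction else None,
            "within_subgroup": self.within_subgroup.to_dict() if self.within_subgroup else None,
            "fdr": self.fdr.to_dict() if self.fdr else None,
            "verdict": self.verdict.to_dict(),
            "frequency": self.frequency.to_dict(),
            "nnh": self.nnh,
            "n_test_members": self.n_test_members,
        }


def validate_hypothesis(
    test_data: pd.DataFrame,
    hypothesis: SubgroupHypothesis,
    *,
    n_permutations: int = 1000,
    seed: int = 0,
    horizon: float | None = None,
    alpha: float = 0.05,
    fdr_threshold: float = 0.05,
    within_site_permutation: bool = False,
    ties: str = "breslow",
) -> ValidationResult:
    """Full validation of one hypothesis on the test partition.

    Membership is evaluated with the hypothesis's frozen unit thresholds.
    Any Cox failure (no events, non-convergence) downgrades the verdict to
    indeterminate rather than raising, since sibling hypotheses may still be
    testable.
    """
    member = hypothesis.membership(test_data)
    freq = frequency_report(test_data, member)
    n_members = int(member.sum())

    def _indeterminate(reason):
        return ValidationResult(
            hypothesis=hypothesis,
            interaction=None,
            within_subgroup=None,
            fdr=None,
            verdict=HarmVerdict(False, False, False, indeterminate=True, reasons=(reason,)),
            frequency=freq,
            nnh=None,
            n_test_members=n_members,
        )

    if n_members == 0 or n_members == len(test_data):
        return _indeterminate("subgroup empty or all-inclusive in test data")
    try:
        inter = interaction_model(test_data, member, ties=ties)
        within = within_subgroup_model(test_data, member, ties=ties)
    except ValueError as exc:
        return _indeterminate(f"Cox fit failed: {exc}")
    if not inter.converged:
        res = _indeterminate("interaction fit non-converged")
        res.interaction = inter
        res.within_subgroup = within
        return res
    fdr = permutation_fdr(
        test_data,
        member,
        n_permutations=n_permutations,
        seed=seed,
        observed=inter,
        within_site=within_site_permutation,
        ties=ties,
    )
    verdict = harm_verdict(inter, within, fdr, alpha=alpha, fdr_threshold=fdr_threshold)
    nnh = number_needed_to_harm(test_data, member, horizon=horizon)
    return ValidationResult(
        hypothesis=hypothesis,
        interaction=inter,
        within_subgroup=within,
        fdr=fdr,
        verdict=verdict,
        frequency=freq,
        nnh=nnh,
        n_test_members=n_members,
    )
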