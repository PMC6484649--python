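"""Model/Results front end for the discovery-and-validation pipeline.

:class:`HarmDiscovery` is constructed from a participant-level trial table
(or straight from a simulation config) and holds the analysis settings;
:meth:`HarmDiscovery.fit` runs balanced splitting, discretization, the honest
forest, hypothesis distillation and Cox validation, returning a
:class:`HarmDiscoveryResults` that carries the estimates, their uncertainty,
diagnostics and a ``summary()`` table.

Example
-------
>>> from hteharm import simulate, HarmDiscovery
>>> cfg = simulate.sprint_like_config(n_participants=2000, seed=7)
>>> cohort = simulate.generate_cohort(cfg).drop(columns=["true_subgroup"])
>>> res = HarmDiscovery(cohort, n_trees=100, n_split_candidates=50,
...                     n_permutations=200, seed=7).fit()
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import prep
from .forest import Forest, ForestParams, build_forest
from .hypotheses import SubgroupHypothesis, covariate_frequency, distill_hypotheses, harvest_harm_leaves
from .io import validate_trial_table
from .mechanism import mechanism_contrast, summarize_pressures
from .validation import ValidationResult, validate_hypothesis

__all__ = ["HarmDiscovery", "HarmDiscoveryResults"]


class HarmDiscovery:
    """Treatment-harm subgroup discovery model for a two-arm trial table.

    Parameters
    ----------
    cohort : DataFrame
        One row per participant: ``id, site, arm, time, event`` plus numeric
        baseline covariates.
    covariates : list of str, optional
        Covariate columns to search over (default: all non-reserved columns).
    n_bins : quantile bins for continuous covariates (4 = quartiles).
    n_split_candidates : random 50/50 splits scored by entropy balance.
    n_trees, forest_params : forest size or a full :class:`ForestParams`.
    top_k, max_conditions, rank_by : hypothesis distillation settings.
    n_permutations, alpha, fdr_threshold, horizon : validation settings.
    seed : master seed; stage seeds are derived from it.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        covariates: list[str] | None = None,
        *,
        n_bins: int = 4,
        n_split_candidates: int = 1000,
        n_trees: int = 1000,
        forest_params: ForestParams | None = None,
        top_k: int = 5,
        max_conditions: int = 3,
        rank_by: str = "support",
        n_permutations: int = 1000,
        alpha: float = 0.05,
        fdr_threshold: float = 0.05,
        horizon: float | None = None,
        ties: str = "breslow",
        seed: int = 0,
    ):
        self.cohort = validate_trial_table(cohort.copy())
        self.covariates = covariates or prep.covariate_columns(self.cohort)
        self.n_bins = n_bins
        self.n_split_candidates = n_split_candidates
        self.forest_params = forest_params or ForestParams(n_trees=n_trees)
        self.top_k = top_k
        self.max_conditions = max_conditions
        self.rank_by = rank_by
        self.n_permutations = n_permutations
        self.alpha = alpha
        self.fdr_threshold = fdr_threshold
        self.horizon = horizon
        self.ties = ties
        self.seed = int(seed)

    @classmethod
    def from_simulation(cls, config, **kwargs) -> "HarmDiscovery":
        """Build the model from a :class:`~hteharm.simulate.SimConfig`."""
        from .simulate import TRUTH_COLUMNS, generate_cohort

        cohort = generate_cohort(config).drop(columns=list(TRUTH_COLUMNS))
        kwargs.setdefault("seed", config.seed)
        return cls(cohort, **kwargs)

    # stage seeds, derived deterministically from the master seed
    def _stage_seed(self, stage: str) -> int:
        stages = ["split", "forest", "permutation"]
        return int(np.random.SeedSequence([self.seed, stages.index(stage)]).generate_state(1)[0] % (2**31))

    def fit(self) -> "HarmDiscoveryResults":
        """Run the full discovery-and-validation pipeline."""
        table = self.cohort[["id", "site", "arm", "time", "event", *self.covariates]]

        candidates = prep.propose_and_score_splits(
            table, n_candidates=self.n_split_candidates, seed=self._stage_seed("split")
        )
        split = prep.select_split(candidates)
        train = table[split.train_mask]
        test = table[split.test_mask]

        train_binned, cutpoints = prep.discretize_covariates(train, n_bins=self.n_bins, columns=self.covariates)
        usable = [c for c in self.covariates if c not in cutpoints.excluded]

        fp = self.forest_params
        fp.seed = self._stage_seed("forest")
        forest = build_forest(train_binned, fp, covariates=usable)

        harm_leaves, harm_fraction = harvest_harm_leaves(forest)
        freq = covariate_frequency(harm_leaves)
        hypotheses = distill_hypotheses(
            harm_leaves,
            cutpoints,
            max_conditions=self.max_conditions,
            top_k=self.top_k,
            rank_by=self.rank_by,
            training_table=train,
        )

        validations = []
        perm_seed = self._stage_seed("permutation")
        for i, hyp in enumerate(hypotheses):
            validations.append(
                validate_hypothesis(
                    test,
                    hyp,
                    n_permutations=self.n_permutations,
                    seed=perm_seed + i,
                    horizon=self.horizon,
                    alpha=self.alpha,
                    fdr_threshold=self.fdr_threshold,
                    ties=self.ties,
                )
            )

        return HarmDiscoveryResults(
            model=self,
            split=split,
            n_candidates_scored=len(candidates),
            cutpoints=cutpoints,
            forest=forest,
            harm_fraction=harm_fraction,
            covariate_frequencies=freq,
            hypotheses=hypotheses,
            validations=validations,
            train=train,
            test=test,
        )


@dataclass
class HarmDiscoveryResults:
    """Fitted pipeline state: split, forest census, hypotheses, validations."""

    model: HarmDiscovery
    split: prep.SplitAssignment
    n_candidates_scored: int
    cutpoints: prep.CutpointMap
    forest: Forest
    harm_fraction: float
    covariate_frequencies: pd.DataFrame
    hypotheses: list[SubgroupHypothesis]
    validations: list[ValidationResult]
    train: pd.DataFrame = field(repr=False, default=None)
    test: pd.DataFrame = field(repr=False, default=None)

    @property
    def validated(self) -> list[ValidationResult]:
        return [v for v in self.validations if v.verdict.validated]

    def hypothesis_table(self) -> pd.DataFrame:
        rows = []
        for v in self.validations:
            h = v.hypothesis
            row = {
                "rank": h.rank,
                "subgroup": h.describe(),
                "n_leaves": h.n_leaves,
                "train_support": h.support,
                "test_members": v.n_test_members,
            }
            if v.interaction is not None:
                row.update(
                    interaction_hr=v.interaction.hr["treatment:subgroup"],
                    interaction_p=v.interaction.p["treatment:subgroup"],
                )
            if v.fdr is not None:
                row["fdr"] = v.fdr.fdr
            if v.within_subgroup is not None and v.within_subgroup.converged:
                row.update(
                    subgroup_hr=v.within_subgroup.hr["treatment"],
                    subgroup_p=v.within_subgroup.p["treatment"],
                )
            row["validated"] = v.verdict.validated
            rows.append(row)
        return pd.DataFrame(rows)

    def mechanism(self, trajectories: pd.DataFrame, hypothesis: SubgroupHypothesis | None = None, quantity: str = "map"):
        """Pressure contrast for a hypothesis (default: top-ranked) on test data."""
        hyp = hypothesis or self.hypotheses[0]
        member = hyp.membership(self.test)
        traj = trajectories[trajectories["id"].isin(self.test["id"])]
        return mechanism_contrast(traj, self.test, member, quantity=quantity)

    def pressure_summary(self, trajectories: pd.DataFrame, hypothesis: SubgroupHypothesis | None = None):
        hyp = hypothesis or self.hypotheses[0]
        member = hyp.membership(self.test)
        traj = trajectories[trajectories["id"].isin(self.test["id"])]
        return summarize_pressures(traj, self.test, member)

    def summary(self) -> str:
        """Human-readable report of the whole fitted pipeline."""
        m = self.model
        lines = []
        w = 78
        lines.append("=" * w)
        lines.append("Treatment-harm subgroup discovery and validation".center(w))
        lines.append("=" * w)
        lines.append(f"Participants: {len(m.cohort)}   train: {len(self.train)}   test: {len(self.test)}")
        lines.append(
            f"Split: best of {self.n_candidates_scored} candidates by entropy balance "
            f"(score {self.split.score:.5f}, max |SMD| {max(abs(v) for v in self.split.smd.values()):.4f})"
        )
        fp = self.forest.params
        lines.append(
            f"Forest: {fp.n_trees} honest trees, {self.forest.n_leaves} leaves "
            f"({self.forest.n_leaves / fp.n_trees:.2f}/tree), harm fraction {self.harm_fraction:.1%}"
        )
        top = ", ".join(
            f"{r.covariate} ({r.fraction:.0%})" for r in self.covariate_frequencies.head(5).itertuples()
        )
        lines.append(f"Most frequent covariates in harm leaves: {top or 'none'}")
        lines.append("-" * w)
        if not self.validations:
            lines.append("No harm-subgroup hypotheses were distilled.")
        for v in self.validations:
            h = v.hypothesis
            lines.append(f"[{h.rank}] {h.describe()}")
            lines.append(
                f"    leaves {h.n_leaves}, train support {h.support}, test members {v.n_test_members}"
            )
            if v.interaction is not None and v.interaction.converged:
                t = "treatment:subgroup"
                lines.append(
                    f"    interaction HR {v.interaction.hr[t]:.2f} "
                    f"(95% CI {v.interaction.ci_low[t]:.2f}-{v.interaction.ci_high[t]:.2f}, "
                    f"p={v.interaction.p[t]:.3f}, FDR={v.fdr.fdr:.3f})"
                )
            if v.within_subgroup is not None and v.within_subgroup.converged:
                lines.append(
                    f"    within-subgroup HR {v.within_subgroup.hr['treatment']:.2f} "
                    f"(95% CI {v.within_subgroup.ci_low['treatment']:.2f}-"
                    f"{v.within_subgroup.ci_high['treatment']:.2f}, p={v.within_subgroup.p['treatment']:.3f})"
                )
            if v.nnh is not None and v.nnh["harmful"]:
                lines.append(f"    NNH at {v.nnh['horizon']:.2f} y: {v.nnh['nnh']:.1f}")
            state = "VALIDATED" if v.verdict.validated else ("indeterminate" if v.verdict.indeterminate else "not validated")
            lines.append(f"    verdict: {state}" + (f" ({'; '.join(v.verdict.reasons)})" if v.verdict.reasons else ""))
        lines.append("=" * w)
        return "\n".join(lines)
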