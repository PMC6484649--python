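"""Distilling harm-indicating forest leaves into testable subgroup hypotheses.

A *harm leaf* is a terminal node whose honest estimated treatment–outcome
association is strictly positive: treated participants in that leaf had a
higher event rate than controls.  This module harvests those leaves from a
forest, tabulates which covariates define them, and canonicalizes their
root-to-leaf condition paths into a small ranked set of deduplicated
conjunctions ready for Cox validation on held-out data.

Bin-index conditions are translated into original measurement units using
the training :class:`~hteharm.prep.CutpointMap` (e.g. "sbp bin > 2" under
tercile cuts becomes "sbp > 144 mm Hg") and then *frozen*: test-set
membership is always evaluated against these unit thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forest import Forest, Leaf
from .prep import CutpointMap

__all__ = [
    "HarmLeaf",
    "Condition",
    "SubgroupHypothesis",
    "harvest_harm_leaves",
    "covariate_frequency",
    "distill_hypotheses",
]

log = logging.getLogger(__name__)


@dataclass
class HarmLeaf:
    """One harvested leaf with positive honest association."""

    tree: int
    leaf: int
    tau_hat: float
    n_estimation: int
    path: list[tuple[str, str, int]]


@dataclass(frozen=True)
class Condition:
    """One covariate condition of a subgroup definition.

    ``op`` is "<=", ">" (ordinal bins / continuous units) or "==" (binary).
    ``bin_threshold`` is in bin-index space; ``unit_threshold`` is the same
    boundary in original measurement units (equal to ``bin_threshold`` for
    binary covariates).
    """

    covariate: str
    op: str
    bin_threshold: int
    unit_threshold: float

    def describe(self) -> str:
        if self.op == "==":
            return f"{self.covariate} == {int(self.unit_threshold)}"
        return f"{self.covariate} {self.op} {self.unit_threshold:g}"


@dataclass
class SubgroupHypothesis:
    """A conjunction of covariate conditions defining a candidate harmed subgroup."""

    conditions: tuple[Condition, ...]
    n_leaves: int  # contributing harm leaves
    mean_tau: float
    support: int = 0  # matching participants in the training table
    rank: int = 0

    def describe(self) -> str:
        return " & ".join(c.describe() for c in self.conditions) or "<all participants>"

    def membership(self, table: pd.DataFrame) -> np.ndarray:
        """Frozen-unit-threshold membership in any table with raw covariates."""
        mask = np.ones(len(table), dtype=bool)
        for c in self.conditions:
            v = table[c.covariate].to_numpy(dtype=float)
            if c.op == "==":
                mask &= v == c.unit_threshold
            elif c.op == "<=":
                mask &= v <= c.unit_threshold
            else:
                mask &= v > c.unit_threshold
        return mask

    def to_dict(self) -> dict:
        return {
            "conditions": [
                {
                    "covariate": c.covariate,
                    "op": c.op,
                    "bin_threshold": c.bin_threshold,
                    "unit_threshold": c.unit_threshold,
                }
                for c in self.conditions
            ],
            "description": self.describe(),
            "n_leaves": self.n_leaves,
            "mean_tau": self.mean_tau,
            "support": self.support,
            "rank": self.rank,
        }


def harvest_harm_leaves(forest: Forest, *, side: str = "harm") -> tuple[list[HarmLeaf], float]:
    """All leaves with strictly positive honest association, plus their fraction.

    ``side="benefit"`` flips the sign convention (harvests ``tau_hat < 0``);
    ties at exactly zero are never harvested.  Returns ``(leaves, fraction)``
    where the fraction is relative to all leaves in the forest.
    """
    if side not in ("harm", "benefit"):
        raise ValueError("side must be 'harm' or 'benefit'")
    sign = 1.0 if side == "harm" else -1.0
    out = []
    total = 0
    for ti, tree in enumerate(forest.trees):
        for li, leaf in enumerate(tree.leaves()):
            total += 1
            if np.isfinite(leaf.tau_hat) and sign * leaf.tau_hat > 0:
                out.append(
                    HarmLeaf(tree=ti, leaf=li, tau_hat=leaf.tau_hat, n_estimation=leaf.n_estimation, path=list(leaf.path))
                )
    fraction = len(out) / total if total else 0.0
    return out, fraction


def covariate_frequency(harm_leaves: list[HarmLeaf]) -> pd.DataFrame:
    """How often each covariate appears in harm-leaf paths.

    A covariate is counted once per leaf regardless of how many conditions on
    it the path contains.  Returns columns ``covariate, count, fraction``
    sorted by descending count (ties alphabetically); fraction is relative to
    the number of harm leaves.
    """
    if not harm_leaves:
        return pd.DataFrame(columns=["covariate", "count", "fraction"])
    counts: dict[str, int] = {}
    for leaf in harm_leaves:
        for cov in {c for c, _, _ in leaf.path}:
            counts[cov] = counts.get(cov, 0) + 1
    df = pd.DataFrame(
        {"covariate": list(counts), "count": list(counts.values())}
    ).sort_values(["count", "covariate"], ascending=[False, True], kind="stable")
    df["fraction"] = df["count"] / len(harm_leaves)
    return df.reset_index(drop=True)


def _canonicalize(path: list[tuple[str, str, int]]) -> dict[str, list] | None:
    """Merge a path's conditions per covariate into the tightest interval.

    Returns ``{covariate: [lower, upper]}`` in bin space with lower exclusive
    (``bin > lower``) and upper inclusive (``bin <= upper``), ``None`` bounds
    meaning unbounded; or ``None`` for a contradictory (empty) conjunction.
    """
    iv: dict[str, list] = {}
    for cov, op, k in path:
        lo, hi = iv.get(cov, [None, None])
        if op == ">":
            lo = k if lo is None else max(lo, k)
        else:  # "<="
            hi = k if hi is None else min(hi, k)
        iv[cov] = [lo, hi]
    for lo, hi in iv.values():
        if lo is not None and hi is not None and lo >= hi:
            return None
    return iv


def _unit_threshold(cov: str, k: int, cutpoints: CutpointMap) -> float:
    if cov in cutpoints.binary:
        return float(k)
    cuts = cutpoints.cutpoints[cov]
    return float(cuts[k - 1])  # bin index k's upper boundary


def distill_hypotheses(
    harm_leaves: list[HarmLeaf],
    cutpoints: CutpointMap,
    *,
    max_conditions: int = 3,
    top_k: int = 5,
    rank_by: str = "support",
    training_table: pd.DataFrame | None = None,
) -> list[SubgroupHypothesis]:
    """Canonicalize, truncate, deduplicate and rank harm-leaf subgroups.

    Each leaf path is merged into its tightest per-covariate interval
    (contradictory paths are dropped with a log entry), truncated to
    conditions on the ``max_conditions`` covariates most frequent across all
    harm leaves, and deduplicated; identical canonical conjunctions pool
    their contributing leaves.  Ranking is by number of contributing leaves
    (``rank_by="support"``, the default) or by mean ``tau_hat``
    (``rank_by="tau"``), descending, and the ``top_k`` hypotheses are
    returned with ranks assigned from 1.  When ``training_table`` is given,
    each hypothesis's participant support is counted with its frozen unit
    thresholds and hypotheses with empty support are dropped.
    """
    if rank_by not in ("support", "tau"):
        raise ValueError("rank_by must be 'support' or 'tau'")
    freq = covariate_frequency(harm_leaves)
    keep_order = {cov: i for i, cov in enumerate(freq["covariate"])}

    pooled: dict[tuple, list[HarmLeaf]] = {}
    for leaf in harm_leaves:
        iv = _canonicalize(leaf.path)
        if iv is None:
            log.info("dropping contradictory leaf path: %s", leaf.path)
            continue
        kept = sorted(iv, key=lambda c: keep_order[c])[:max_conditions]
        key = []
        for cov in sorted(kept):
            lo, hi = iv[cov]
            key.append((cov, lo, hi))
        if not key:
            continue
        pooled.setdefault(tuple(key), []).append(leaf)

    hyps = []
    for key, leaves in pooled.items():
        conditions = []
        for cov, lo, hi in key:
            if cov in cutpoints.binary:
                # bins are raw 0/1; "> k" pins value above k, "<= k" below
                if lo is not None:
                    conditions.append(Condition(cov, "==", lo + 1, float(lo + 1)))
                if hi is not None:
                    conditions.append(Condition(cov, "==", hi, float(hi)))
            else:
                if lo is not None:
                    conditions.append(Condition(cov, ">", lo, _unit_threshold(cov, lo, cutpoints)))
                if hi is not None:
                    conditions.append(Condition(cov, "<=", hi, _unit_threshold(cov, hi, cutpoints)))
        hyp = SubgroupHypothesis(
            conditions=tuple(conditions),
            n_leaves=len(leaves),
            mean_tau=float(np.mean([l.tau_hat for l in leaves])),
        )
        if training_table is not None:
            hyp.support = int(hyp.membership(training_table).sum())
            if hyp.support == 0:
                continue
        hyps.append(hyp)

    if rank_by == "support":
        hyps.sort(key=lambda h: (-h.n_leaves, -h.mean_tau, h.describe()))
    else:
        hyps.sort(key=lambda h: (-h.mean_tau, -h.n_leaves, h.describe()))
    hyps = hyps[:top_k]
    for i, h in enumerate(hyps, start=1):
        h.rank = i
    return hyps
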