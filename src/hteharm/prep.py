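"""Covariate discretization and entropy-balanced train/test split selection.

Two jobs happen before subgroup discovery:

1. Continuous baseline covariates are cut into ordinal quantile bins
   (quartiles by default), because the discovery forest splits on interval
   conditions like "SBP above its top tercile boundary".  Bins are half-open
   ``(a, b]`` — a value equal to a cutpoint falls in the lower bin — and a
   train-derived :class:`CutpointMap` can be re-applied to held-out data.

2. The cohort is divided 50/50 into a training half (hypothesis generation)
   and a testing half (inference).  Rather than accept one arbitrary random
   split, many candidate splits are drawn and each is scored by *entropy
   balancing*: the minimal Kullback–Leibler divergence from uniform of
   weights on the training half whose weighted covariate/outcome/arm means
   reproduce the full-sample means.  A score of zero means the train half
   already mirrors the whole cohort; the candidate with the smallest score is
   kept.  Candidates for which balancing is infeasible (some full-sample mean
   outside the train half's convex hull) receive an infinite score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import RESERVED_COLUMNS

__all__ = [
    "CutpointMap",
    "SplitAssignment",
    "discretize_covariates",
    "entropy_balance_weights",
    "entropy_balance_score",
    "propose_and_score_splits",
    "select_split",
    "covariate_columns",
]

#: score assigned to candidates whose balancing program is infeasible
INFEASIBLE = float("inf")


def covariate_columns(table: pd.DataFrame) -> list[str]:
    """All baseline-covariate columns (everything except id/site/arm/time/event/truth)."""
    return [c for c in table.columns if c not in RESERVED_COLUMNS]


@dataclass
class CutpointMap:
    """Per-covariate binning recipe.

    ``cutpoints[name]`` holds the ordered interior quantile boundaries for a
    continuous covariate; binary covariates are passed through unchanged;
    constant covariates are recorded in ``excluded`` (single bin, unusable
    for splitting).
    """

    cutpoints: dict[str, list[float]] = field(default_factory=dict)
    binary: list[str] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)

    def n_bins(self, name: str) -> int:
        if name in self.binary:
            return 2
        return len(self.cutpoints[name]) + 1

    def assign(self, name: str, values: np.ndarray) -> np.ndarray:
        """Bin index 1..K under the (a, b] convention (boundary -> lower bin)."""
        cuts = np.asarray(self.cutpoints[name], dtype=float)
        return 1 + np.sum(values[:, None] > cuts[None, :], axis=1)

    def to_dict(self) -> dict:
        return {
            "cutpoints": {k: [float(x) for x in v] for k, v in self.cutpoints.items()},
            "binary": list(self.binary),
            "excluded": list(self.excluded),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CutpointMap":
        return cls(
            cutpoints={k: list(v) for k, v in d.get("cutpoints", {}).items()},
            binary=list(d.get("binary", [])),
            excluded=list(d.get("excluded", [])),
        )


def _is_binary(values: np.ndarray) -> bool:
    u = np.unique(values)
    return u.size <= 2 and np.all(np.isin(u, (0, 1)))


def discretize_covariates(
    table: pd.DataFrame,
    n_bins: int = 4,
    cutpoints: CutpointMap | None = None,
    columns: list[str] | None = None,
) -> tuple[pd.DataFrame, CutpointMap]:
    """Replace continuous covariates by ordinal quantile-bin indices 1..n_bins.

    With ``cutpoints`` supplied (e.g. derived from the training half), the
    stored boundaries are applied instead of re-estimating quantiles — the
    route by which train-derived subgroup definitions transfer to test data.
    Binary covariates pass through; constant covariates collapse to a single
    bin, are flagged with a warning and recorded as excluded.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    cols = columns if columns is not None else covariate_columns(table)
    out = table.copy()

    if cutpoints is not None:
        known = set(cutpoints.cutpoints) | set(cutpoints.binary) | set(cutpoints.excluded)
        unknown = [c for c in cols if c not in known]
        if unknown:
            raise KeyError(f"covariates missing from supplied CutpointMap: {unknown}")
        for name in cols:
            if name in cutpoints.cutpoints:
                out[name] = cutpoints.assign(name, table[name].to_numpy(dtype=float))
            elif name in cutpoints.excluded:
                out[name] = 1
        return out, cutpoints

    cmap = CutpointMap()
    for name in cols:
        values = table[name].to_numpy(dtype=float)
        if _is_binary(values):
            cmap.binary.append(name)
            continue
        qs = np.quantile(values, np.arange(1, n_bins) / n_bins)  # linear interpolation
        cuts = sorted(set(float(q) for q in qs))
        if not cuts or np.unique(values).size == 1:
            warnings.warn(f"covariate {name!r} is constant: single bin, excluded from splitting")
            cmap.excluded.append(name)
            out[name] = 1
            continue
        cmap.cutpoints[name] = cuts
        out[name] = cmap.assign(name, values)
    return out, cmap


# ---------------------------------------------------------------------------
# entropy balancing
# ---------------------------------------------------------------------------


def _balance_matrix(table: pd.DataFrame, second_moments: bool = False) -> np.ndarray:
    """Standardized moment matrix: baseline covariates + event indicator + arm.

    Matching first moments of this matrix makes the weighted train half
    reproduce the full sample's covariate means, outcome rate, and arm mix.
    """
    cols = covariate_columns(table) + ["event", "arm"]
    Z = table[cols].to_numpy(dtype=float)
    if second_moments:
        Z = np.hstack([Z, Z**2])
    mu = Z.mean(axis=0)
    sd = Z.std(axis=0)
    keep = sd > 0
    return (Z[:, keep] - mu[keep]) / sd[keep]


def entropy_balance_weights(
    Z_train: np.ndarray,
    target_mean: np.ndarray,
    *,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> np.ndarray | None:
    """Solve the entropy-balancing dual program.

    Finds weights ``w`` on the rows of ``Z_train`` minimizing
    ``KL(w || uniform)`` subject to ``sum_i w_i Z_i = target_mean`` via the
    unconstrained convex dual ``min_l log mean_i exp(-l . (Z_i - m))``
    (Newton with step halving).  Returns the normalized weights, or ``None``
    when the program is infeasible (target outside the convex hull).
    """
    D = Z_train - target_mean
    n, p = D.shape
    lam = np.zeros(p)

    def dual(lam):
        a = -D @ lam
        amax = a.max()
        e = np.exp(a - amax)
        s = e.sum()
        f = amax + np.log(s / n)
        w = e / s
        g = -D.T @ w  # gradient wrt lam
        Dw = D * w[:, None]
        H = D.T @ Dw - np.outer(g, g)
        return f, g, H, w

    f, g, H, w = dual(lam)
    for _ in range(max_iter):
        if np.max(np.abs(g)) < tol:
            return w
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(p), -g)
        except np.linalg.LinAlgError:
            return None
        scale = 1.0
        for _ in range(40):
            cand = lam + scale * step
            f2, g2, H2, w2 = dual(cand)
            if np.isfinite(f2) and f2 <= f + 1e-12:
                break
            scale *= 0.5
        lam, f, g, H, w = cand, f2, g2, H2, w2
        if np.linalg.norm(lam) > 1e6:
            return None
    return w if np.max(np.abs(g)) < 1e-6 else None


@dataclass
class SplitAssignment:
    """One scored 50/50 train/test partition."""

    labels: pd.Series  # "train"/"test", aligned to the table index
    candidate: int
    score: float
    smd: dict[str, float]  # per-covariate (train mean - full mean) / full sd
    seed: int | None = None

    @property
    def train_mask(self) -> np.ndarray:
        return (self.labels == "train").to_numpy()

    @property
    def test_mask(self) -> np.ndarray:
        return (self.labels == "test").to_numpy()


def entropy_balance_score(split: SplitAssignment, table: pd.DataFrame, *, second_moments: bool = False) -> float:
    """KL divergence from uniform of the balancing weights on the train half.

    Zero iff uniform weights on the train half already match the full-sample
    means; ``inf`` when balancing is infeasible.
    """
    if len(split.labels) != len(table):
        raise ValueError("split does not cover the table")
    Z = _balance_matrix(table, second_moments=second_moments)
    train = split.train_mask
    w = entropy_balance_weights(Z[train], Z.mean(axis=0))
    if w is None:
        return INFEASIBLE
    n = w.size
    kl = float(np.sum(w * np.log(np.clip(w * n, 1e-300, None))))
    return max(kl, 0.0)


def _smd(table: pd.DataFrame, train: np.ndarray) -> dict[str, float]:
    out = {}
    for c in covariate_columns(table):
        v = table[c].to_numpy(dtype=float)
        sd = v.std()
        out[c] = float((v[train].mean() - v.mean()) / sd) if sd > 0 else 0.0
    return out


def propose_and_score_splits(
    table: pd.DataFrame,
    n_candidates: int = 1000,
    seed: int = 0,
    *,
    second_moments: bool = False,
) -> list[SplitAssignment]:
    """Draw and score ``n_candidates`` random 50/50 partitions.

    Each candidate's training half gets an entropy-balance score against the
    full sample; deterministic given ``seed``.
    """
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    n = len(table)
    if n < 20:
        raise ValueError(f"cohort of {n} is too small to split meaningfully")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17]))
    Z = _balance_matrix(table, second_moments=second_moments)
    target = Z.mean(axis=0)
    n_train = n // 2

    out = []
    for k in range(n_candidates):
        perm = rng.permutation(n)
        train = np.zeros(n, dtype=bool)
        train[perm[:n_train]] = True
        w = entropy_balance_weights(Z[train], target)
        if w is None:
            score = INFEASIBLE
        else:
            score = max(float(np.sum(w * np.log(np.clip(w * w.size, 1e-300, None)))), 0.0)
        labels = pd.Series(np.where(train, "train", "test"), index=table.index)
        out.append(SplitAssignment(labels=labels, candidate=k, score=score, smd=_smd(table, train), seed=int(seed)))
    return out


def select_split(candidates: list[SplitAssignment]) -> SplitAssignment:
    """Argmin balance score; ties broken by lowest candidate index."""
    feasible = [c for c in candidates if np.isfinite(c.score)]
    if not feasible:
        raise ValueError(
            "entropy balancing infeasible for every candidate split; "
            "use a larger cohort or match fewer moments"
        )
    return min(feasible, key=lambda c: (c.score, c.candidate))
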