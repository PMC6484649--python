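"""Honest causal forest for treatment-effect heterogeneity discovery.

Each of (by default) 1000 trees is grown on a 50% subsample of the training
half, drawn without replacement and itself halved into a *structure* sample
(chooses the splits) and an *estimation* sample (estimates each leaf's
treatment–outcome association).  Because the two samples are disjoint, the
leaf estimates are "honest": selecting a split cannot inflate the effect
subsequently estimated in it.

The outcome is the binary event indicator; censoring is deliberately ignored
at this stage (the Cox validation stage handles it).  Covariates must be
discretized to ordinal bins beforehand (see :mod:`hteharm.prep`); splits take
the interval form ``bin <= k`` vs ``bin > k``, which preserves interpretable
subgroup conditions such as "SBP above its top-tercile boundary".

Split criterion.  At a node with structure-half data, a candidate split into
children L, R is scored by ``sum_child [n * tau^2 - penalty * n * Var(tau)]``
where ``tau`` is the child's treated-minus-control event-rate difference,
``n`` its structure count, and ``Var(tau)`` the usual two-sample variance
estimate of ``tau``.  The first term concentrates effect heterogeneity across
leaves (it is the algebraic complement of minimizing within-leaf squared
error of a leaf-constant effect prediction); the variance term — the honest
causal-tree correction, default weight 2 for the two equal-sized samples that
will touch the leaf — charges a split for the estimator noise it creates, so
that pure-noise splits have negative expected gain.  Setting
``variance_penalty=0`` recovers the raw maximization of
:func:`split_criterion`.  A split is accepted only if it strictly improves on
the parent's no-split score and both children retain the per-arm minimum
counts in BOTH halves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ForestParams",
    "SplitRule",
    "Leaf",
    "Internal",
    "CausalTree",
    "Forest",
    "split_criterion",
    "node_score",
    "grow_tree",
    "build_forest",
]


@dataclass
class ForestParams:
    """Forest hyperparameters (defaults follow the discovery design)."""

    n_trees: int = 1000
    subsample_fraction: float = 0.5  # of the training data, without replacement
    structure_fraction: float = 0.5  # of the subsample (resplit scheme only)
    min_leaf_treated: int = 10  # enforced in both halves
    min_leaf_control: int = 10
    max_depth: int = 4
    honest: bool = True
    #: False (default): the subsample IS the structure sample and its
    #: complement within the training data the estimation sample.  True: the
    #: subsample is itself re-split by ``structure_fraction`` and the
    #: complement is unused.
    resplit_subsample: bool = False
    #: weight on the estimator-variance term of the split score; 0 disables
    #: the honest correction.
    variance_penalty: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must be in (0, 1]")
        if not 0 < self.structure_fraction < 1:
            raise ValueError("structure_fraction must be in (0, 1)")
        if self.min_leaf_treated < 1 or self.min_leaf_control < 1:
            raise ValueError("per-arm leaf minima must be >= 1")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.max_depth < 0:
            raise ValueError("max_depth must be >= 0")
        if self.variance_penalty < 0:
            raise ValueError("variance_penalty must be >= 0")


@dataclass(frozen=True)
class SplitRule:
    """`bin(covariate) <= threshold` goes left; `> threshold` goes right."""

    covariate: str
    threshold: int


@dataclass
class Leaf:
    tau_hat: float
    n_structure: int
    n_estimation: int
    n_treated: int  # estimation half
    n_control: int
    path: list[tuple[str, str, int]] = field(default_factory=list)  # (cov, "<="|">", k)

    is_leaf = True


@dataclass
class Internal:
    rule: SplitRule
    left: "Leaf | Internal"
    right: "Leaf | Internal"

    is_leaf = False


@dataclass
class CausalTree:
    root: Leaf | Internal
    structure_ids: np.ndarray  # participant ids, for honesty audits
    estimation_ids: np.ndarray
    warning: str | None = None

    def leaves(self) -> list[Leaf]:
        out: list[Leaf] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend([node.right, node.left])
        return out


@dataclass
class Forest:
    trees: list[CausalTree]
    params: ForestParams
    covariates: list[str]
    n_leaves: int = 0

    def __post_init__(self):
        self.n_leaves = sum(len(t.leaves()) for t in self.trees)

    def leaf_census(self) -> pd.DataFrame:
        rows = []
        for ti, tree in enumerate(self.trees):
            for li, leaf in enumerate(tree.leaves()):
                rows.append(
                    {
                        "tree": ti,
                        "leaf": li,
                        "tau_hat": leaf.tau_hat,
                        "n_structure": leaf.n_structure,
                        "n_estimation": leaf.n_estimation,
                        "n_treated": leaf.n_treated,
                        "n_control": leaf.n_control,
                        "depth": len(leaf.path),
                        "path": " & ".join(f"{c}{op}{k}" for c, op, k in leaf.path),
                    }
                )
        return pd.DataFrame(rows)

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        def node_dict(node):
            if node.is_leaf:
                return {
                    "tau_hat": node.tau_hat,
                    "n_structure": node.n_structure,
                    "n_estimation": node.n_estimation,
                    "n_treated": node.n_treated,
                    "n_control": node.n_control,
                    "path": [list(c) for c in node.path],
                }
            return {
                "rule": [node.rule.covariate, node.rule.threshold],
                "left": node_dict(node.left),
                "right": node_dict(node.right),
            }

        return json.dumps(
            {
                "params": self.params.__dict__,
                "covariates": self.covariates,
                "n_leaves": self.n_leaves,
                "trees": [
                    {
                        "root": node_dict(t.root),
                        "structure_ids": t.structure_ids.tolist(),
                        "estimation_ids": t.estimation_ids.tolist(),
                        "warning": t.warning,
                    }
                    for t in self.trees
                ],
            },
            indent=None,
            separators=(",", ":"),
        )

    @classmethod
    def from_json(cls, text: str) -> "Forest":
        def parse(d, path):
            if "rule" in d:
                cov, k = d["rule"]
                rule = SplitRule(cov, int(k))
                return Internal(
                    rule=rule,
                    left=parse(d["left"], path + [(cov, "<=", int(k))]),
                    right=parse(d["right"], path + [(cov, ">", int(k))]),
                )
            return Leaf(
                tau_hat=d["tau_hat"],
                n_structure=d["n_structure"],
                n_estimation=d["n_estimation"],
                n_treated=d["n_treated"],
                n_control=d["n_control"],
                path=[tuple(c) for c in d["path"]],
            )

        obj = json.loads(text)
        params = ForestParams(**obj["params"])
        trees = [
            CausalTree(
                root=parse(t["root"], []),
                structure_ids=np.asarray(t["structure_ids"]),
                estimation_ids=np.asarray(t["estimation_ids"]),
                warning=t.get("warning"),
            )
            for t in obj["trees"]
        ]
        return cls(trees=trees, params=params, covariates=obj["covariates"])


def _tau(y_t_events: float, n_t: int, y_c_events: float, n_c: int) -> float:
    if n_t == 0 or n_c == 0:
        return np.nan
    return y_t_events / n_t - y_c_events / n_c


def split_criterion(
    n_left: int, tau_left: float, n_right: int, tau_right: float
) -> float:
    """Raw maximization score ``n_L tau_L^2 + n_R tau_R^2`` for a candidate split.

    This is the heterogeneity term of the split score, without the honest
    variance correction (see :func:`node_score`); it is what a forest with
    ``variance_penalty=0`` maximizes.
    """
    return n_left * tau_left**2 + n_right * tau_right**2


def node_score(n_t: int, n_c: int, events_t: float, events_c: float, penalty: float) -> float:
    """Penalized score ``n tau^2 - penalty * n * Var(tau)`` of a single node.

    ``Var(tau)`` is the two-sample variance estimate ``s_t^2/n_t + s_c^2/n_c``
    with per-arm Bernoulli sample variances.  A candidate split's score is the
    sum of its children's node scores; empty-arm nodes are inadmissible and
    return ``-inf``.
    """
    if n_t == 0 or n_c == 0:
        return -np.inf
    p_t = events_t / n_t
    p_c = events_c / n_c
    tau = p_t - p_c
    s2_t = p_t * (1.0 - p_t) * n_t / max(n_t - 1, 1)
    s2_c = p_c * (1.0 - p_c) * n_c / max(n_c - 1, 1)
    n = n_t + n_c
    return n * tau * tau - penalty * n * (s2_t / n_t + s2_c / n_c)


class _TreeGrower:
    """Grows one tree on pre-extracted numpy arrays (bins, arm, event)."""

    def __init__(self, X: np.ndarray, arm: np.ndarray, y: np.ndarray, covariates: list[str], bin_max: np.ndarray, bin_min: np.ndarray, params: ForestParams):
        self.X = X
        self.arm = arm
        self.y = y
        self.covariates = covariates
        self.bin_max = bin_max
        self.bin_min = bin_min
        self.params = params

    def _cell_counts(self, idx: np.ndarray, j: int):
        """Per-bin (n, events) by arm for covariate j restricted to idx."""
        bins = self.X[idx, j]
        arm = self.arm[idx]
        y = self.y[idx]
        K = self.bin_max[j]
        nt = np.bincount(bins[arm == 1], minlength=K + 1)
        nc = np.bincount(bins[arm == 0], minlength=K + 1)
        et = np.bincount(bins[arm == 1], weights=y[arm == 1], minlength=K + 1)
        ec = np.bincount(bins[arm == 0], weights=y[arm == 0], minlength=K + 1)
        return nt, nc, et, ec

    def _best_split(self, s_idx: np.ndarray, e_idx: np.ndarray):
        """Exhaustive search over (covariate, threshold); returns best or None.

        Admissibility: both children keep >= min treated and control counts in
        both the structure and the estimation halves.  The best admissible
        split must strictly beat the parent's no-split score.
        """
        p = self.params
        pen = p.variance_penalty
        best = None  # (score, j, k)
        nt_all = int((self.arm[s_idx] == 1).sum())
        nc_all = s_idx.size - nt_all
        et_all = float(self.y[s_idx][self.arm[s_idx] == 1].sum())
        ec_all = float(self.y[s_idx][self.arm[s_idx] == 0].sum())
        parent_score = node_score(nt_all, nc_all, et_all, ec_all, pen)
        if not np.isfinite(parent_score):
            return None

        for j in range(self.X.shape[1]):
            K = self.bin_max[j]
            if self.bin_min[j] >= K:
                continue  # single observed level: nothing to split
            nt, nc, et, ec = self._cell_counts(s_idx, j)
            ent, enc, _, _ = self._cell_counts(e_idx, j)
            cnt, cnc = np.cumsum(nt), np.cumsum(nc)
            cet, cec = np.cumsum(et), np.cumsum(ec)
            cent, cenc = np.cumsum(ent), np.cumsum(enc)
            for k in range(self.bin_min[j], K):
                nt_l, nc_l = int(cnt[k]), int(cnc[k])
                nt_r, nc_r = nt_all - nt_l, nc_all - nc_l
                if min(nt_l, nt_r) < p.min_leaf_treated or min(nc_l, nc_r) < p.min_leaf_control:
                    continue
                ent_l, enc_l = int(cent[k]), int(cenc[k])
                ent_r = int(cent[K]) - ent_l
                enc_r = int(cenc[K]) - enc_l
                if min(ent_l, ent_r) < p.min_leaf_treated or min(enc_l, enc_r) < p.min_leaf_control:
                    continue
                score = node_score(nt_l, nc_l, float(cet[k]), float(cec[k]), pen) + node_score(
                    nt_r, nc_r, et_all - float(cet[k]), ec_all - float(cec[k]), pen
                )
                if score > parent_score + 1e-12 and (best is None or score > best[0] + 1e-12):
                    best = (score, j, k)
        return best

    def _leaf(self, s_idx: np.ndarray, e_idx: np.ndarray, path) -> Leaf:
        arm_e = self.arm[e_idx]
        y_e = self.y[e_idx]
        n_t = int((arm_e == 1).sum())
        n_c = e_idx.size - n_t
        tau = _tau(float(y_e[arm_e == 1].sum()), n_t, float(y_e[arm_e == 0].sum()), n_c)
        return Leaf(
            tau_hat=float(tau) if not np.isnan(tau) else float("nan"),
            n_structure=int(s_idx.size),
            n_estimation=int(e_idx.size),
            n_treated=n_t,
            n_control=n_c,
            path=list(path),
        )

    def grow(self, s_idx: np.ndarray, e_idx: np.ndarray, depth: int, path) -> Leaf | Internal:
        if depth >= self.params.max_depth:
            return self._leaf(s_idx, e_idx, path)
        best = self._best_split(s_idx, e_idx)
        if best is None:
            return self._leaf(s_idx, e_idx, path)
        _, j, k = best
        cov = self.covariates[j]
        s_left = s_idx[self.X[s_idx, j] <= k]
        s_right = s_idx[self.X[s_idx, j] > k]
        e_left = e_idx[self.X[e_idx, j] <= k]
        e_right = e_idx[self.X[e_idx, j] > k]
        return Internal(
            rule=SplitRule(cov, k),
            left=self.grow(s_left, e_left, depth + 1, path + [(cov, "<=", k)]),
            right=self.grow(s_right, e_right, depth + 1, path + [(cov, ">", k)]),
        )


def _extract_arrays(training: pd.DataFrame, covariates: list[str]):
    X = training[covariates].to_numpy(dtype=np.int64)
    arm = training["arm"].to_numpy(dtype=np.int64)
    y = training["event"].to_numpy(dtype=float)
    ids = training["id"].to_numpy() if "id" in training.columns else np.arange(len(training))
    return X, arm, y, ids, X.max(axis=0), X.min(axis=0)


def grow_tree(
    training: pd.DataFrame,
    params: ForestParams,
    tree_seed,
    covariates: list[str] | None = None,
) -> CausalTree:
    """Grow one honest tree from a fresh subsample of the training data.

    A random subsample (``subsample_fraction`` of the rows, without
    replacement) chooses the tree's structure; the *remaining* training rows
    estimate the leaf associations, so the two roles never share a
    participant.  With ``resplit_subsample=True`` the subsample is instead
    itself divided into structure and estimation parts by
    ``structure_fraction`` and the complement is unused.  ``honest=False``
    uses the subsample for both roles (diagnostics only).
    """
    params.validate()
    if covariates is None:
        from .prep import covariate_columns

        covariates = covariate_columns(training)
    X, arm, y, ids, bin_max, bin_min = _extract_arrays(training, covariates)
    rng = np.random.default_rng(tree_seed)
    n = len(training)
    m = max(2, min(int(round(params.subsample_fraction * n)), n - 2 if params.honest and not params.resplit_subsample else n))
    perm = rng.permutation(n)
    sub = perm[:m]
    if not params.honest:
        s_idx = e_idx = sub
    elif params.resplit_subsample:
        n_struct = int(round(params.structure_fraction * m))
        s_idx, e_idx = sub[:n_struct], sub[n_struct:]
    else:
        s_idx, e_idx = sub, perm[m:]

    grower = _TreeGrower(X, arm, y, covariates, bin_max, bin_min, params)
    warning = None
    p = params
    ok_root = (
        (arm[s_idx] == 1).sum() >= p.min_leaf_treated
        and (arm[s_idx] == 0).sum() >= p.min_leaf_control
        and (arm[e_idx] == 1).sum() >= p.min_leaf_treated
        and (arm[e_idx] == 0).sum() >= p.min_leaf_control
    )
    if not ok_root:
        warning = "root violates per-arm minima; single-leaf tree"
        root = grower._leaf(s_idx, e_idx, [])
    else:
        root = grower.grow(s_idx, e_idx, 0, [])
    return CausalTree(
        root=root,
        structure_ids=np.sort(ids[s_idx]),
        estimation_ids=np.sort(ids[e_idx]) if params.honest else np.array([], dtype=ids.dtype),
        warning=warning,
    )


def build_forest(
    training: pd.DataFrame,
    params: ForestParams,
    covariates: list[str] | None = None,
) -> Forest:
    """Grow ``params.n_trees`` independent honest trees.

    Per-tree seeds are spawned from ``params.seed`` via
    :class:`numpy.random.SeedSequence`, so trees are independent and the
    result does not depend on execution order.
    """
    params.validate()
    if covariates is None:
        from .prep import covariate_columns

        covariates = covariate_columns(training)
    seeds = np.random.SeedSequence([int(params.seed), 29]).spawn(params.n_trees)
    trees = [grow_tree(training, params, s, covariates) for s in seeds]
    return Forest(trees=trees, params=params, covariates=list(covariates))
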