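"""Stratified Cox proportional-hazards regression.

Maximizes the stratified partial likelihood by Newton–Raphson with Breslow
(default) or Efron handling of tied event times, and reports Wald inference
(hazard ratios, standard errors, 95% CIs, two-tailed p-values).  Each stratum
(here: clinic site) keeps its own unspecified baseline hazard; strata without
events contribute nothing to the likelihood.

The engine is deliberately lean — a handful of covariates, many refits — so
that permutation schemes which refit the same model thousands of times (with
only the covariate matrix changing) stay cheap: all time/event/stratum
bookkeeping is precomputed once in :class:`StratifiedCoxEngine` and reused
across fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CoxResult", "StratifiedCoxEngine", "fit_cox"]

#: Newton iterations are declared divergent past this coefficient magnitude
#: (monotone likelihood / perfect separation): a log-hazard ratio of 15 is
#: far beyond anything estimable, and past it the score flattens numerically.
MAX_ABS_BETA = 15.0


@dataclass
class CoxResult:
    """Wald-style summary of one stratified Cox fit.

    All per-coefficient fields are :class:`pandas.Series` indexed by term
    name, so ``result.hr["treatment:subgroup"]`` reads naturally.
    """

    terms: list[str]
    beta: pd.Series
    se: pd.Series
    hr: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    p: pd.Series
    loglik: float
    n: int
    n_events: int
    n_strata: int
    ties: str
    converged: bool
    flag: str | None = None
    n_iter: int = 0

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.beta,
                "HR": self.hr,
                "se(coef)": self.se,
                "HR 95% low": self.ci_low,
                "HR 95% high": self.ci_high,
                "p": self.p,
            }
        )

    def to_dict(self) -> dict:
        d = {
            "terms": list(self.terms),
            "beta": self.beta.to_dict(),
            "se": self.se.to_dict(),
            "hr": self.hr.to_dict(),
            "ci_low": self.ci_low.to_dict(),
            "ci_high": self.ci_high.to_dict(),
            "p": self.p.to_dict(),
            "loglik": self.loglik,
            "n": self.n,
            "n_events": self.n_events,
            "n_strata": self.n_strata,
            "ties": self.ties,
            "converged": self.converged,
            "flag": self.flag,
        }
        return d


def _segment_cumsum(values: np.ndarray, seg_id: np.ndarray, seg_start: np.ndarray) -> np.ndarray:
    """Cumulative sum restarting at each segment start; works on 1-D or 2-D."""
    c = np.cumsum(values, axis=0)
    offsets = np.zeros_like(c[seg_start])
    offsets[1:] = c[seg_start[1:] - 1]
    return c - offsets[seg_id]


class StratifiedCoxEngine:
    """Partial-likelihood machinery for fixed (time, event, strata).

    Parameters
    ----------
    time, event : array-like
        Follow-up time (> 0) and 0/1 event indicator.
    strata : array-like or None
        Stratum labels; ``None`` means a single stratum.
    ties : {"breslow", "efron"}
    """

    def __init__(self, time, event, strata=None, ties: str = "breslow"):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        n = time.shape[0]
        if n == 0:
            raise ValueError("empty dataset")
        if np.any(time <= 0):
            raise ValueError("all follow-up times must be > 0")
        if event.sum() == 0:
            raise ValueError("no events in the data: Cox model undefined")
        if ties not in ("breslow", "efron"):
            raise ValueError(f"unknown ties method {ties!r}")
        if strata is None:
            codes = np.zeros(n, dtype=int)
        else:
            codes = pd.factorize(np.asarray(strata))[0]

        # Rows sorted by stratum, then time descending, so each stratum's
        # risk set at time t is a prefix of that stratum's rows.
        order = np.lexsort((-time, codes))
        self.order = order
        self.time = time[order]
        self.event = event[order]
        codes = codes[order]
        self.n = n
        self.ties = ties

        new_seg = np.r_[True, codes[1:] != codes[:-1]]
        self.seg_start = np.flatnonzero(new_seg)
        self.seg_id = np.cumsum(new_seg) - 1
        self.n_strata = len(self.seg_start)

        # Tie groups: identical (stratum, time).  Every event in a tie group
        # shares the same risk set, which ends at the group's last row.
        new_grp = np.r_[True, (codes[1:] != codes[:-1]) | (self.time[1:] != self.time[:-1])]
        grp_id = np.cumsum(new_grp) - 1
        grp_sizes = np.bincount(grp_id)
        grp_last = np.cumsum(grp_sizes) - 1
        self.riskset_end = grp_last[grp_id]
        self.grp_id = grp_id

        self.event_rows = np.flatnonzero(self.event == 1)
        self.n_events = int(self.event.sum())

        if ties == "efron":
            egrp = grp_id[self.event_rows]
            firsts = np.r_[0, np.flatnonzero(np.diff(egrp)) + 1]
            counts = np.diff(np.r_[firsts, len(egrp)])
            self._efron_rank = np.arange(len(egrp)) - np.repeat(firsts, counts)
            self._efron_d = np.repeat(counts, counts)
            self._efron_egrp = egrp
            self._efron_ngrp = grp_id[-1] + 1

    # -- likelihood ----------------------------------------------------------

    def _loglik_grad_info(self, Xs: np.ndarray, beta: np.ndarray):
        """Log partial likelihood, gradient, and observed information at beta.

        ``Xs`` must already be in engine row order.
        """
        p = Xs.shape[1]
        eta = Xs @ beta
        # per-stratum recentring for exp() stability
        seg_max = np.maximum.reduceat(eta, self.seg_start)
        eta_c = eta - seg_max[self.seg_id]
        w = np.exp(eta_c)

        S0 = _segment_cumsum(w, self.seg_id, self.seg_start)
        S1 = _segment_cumsum(Xs * w[:, None], self.seg_id, self.seg_start)
        iu, ju = np.triu_indices(p)
        xx = Xs[:, iu] * Xs[:, ju]
        S2 = _segment_cumsum(xx * w[:, None], self.seg_id, self.seg_start)

        ev = self.event_rows
        re = self.riskset_end[ev]
        s0 = S0[re]
        s1 = S1[re]
        s2 = S2[re]

        if self.ties == "efron":
            frac = self._efron_rank / self._efron_d
            t0 = np.bincount(self._efron_egrp, weights=w[ev], minlength=self._efron_ngrp)
            s0 = s0 - frac * t0[self._efron_egrp]
            t1 = np.vstack(
                [
                    np.bincount(self._efron_egrp, weights=(Xs[ev, k] * w[ev]), minlength=self._efron_ngrp)
                    for k in range(p)
                ]
            ).T
            s1 = s1 - frac[:, None] * t1[self._efron_egrp]
            t2 = np.vstack(
                [
                    np.bincount(self._efron_egrp, weights=(xx[ev, k] * w[ev]), minlength=self._efron_ngrp)
                    for k in range(len(iu))
                ]
            ).T
            s2 = s2 - frac[:, None] * t2[self._efron_egrp]

        with np.errstate(divide="ignore", invalid="ignore"):
            loglik = float(np.sum(eta_c[ev] - np.log(s0)))
            u = s1 / s0[:, None]
        grad = Xs[ev].sum(axis=0) - u.sum(axis=0)

        info = np.zeros((p, p))
        m2 = (s2 / s0[:, None]).sum(axis=0)
        info[iu, ju] = m2
        info[ju, iu] = m2
        info -= u.T @ u
        return loglik, grad, info

    def fit(self, X, terms: list[str] | None = None, tol: float = 1e-8, max_iter: int = 60) -> CoxResult:
        """Newton–Raphson fit; `X` is in the caller's original row order."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != self.n:
            X = X.T
        p = X.shape[1]
        if terms is None:
            terms = [f"x{k}" for k in range(p)]
        Xs = X[self.order]

        beta = np.zeros(p)
        loglik, grad, info = self._loglik_grad_info(Xs, beta)
        converged = False
        flag = None
        it = 0
        for it in range(1, max_iter + 1):
            if np.max(np.abs(grad)) < tol:
                converged = True
                break
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.solve(info + 1e-8 * np.eye(p), grad)
            # step halving keeps the likelihood non-decreasing
            scale = 1.0
            for _ in range(35):
                cand = beta + scale * step
                ll_new, g_new, i_new = self._loglik_grad_info(Xs, cand)
                if np.isfinite(ll_new) and ll_new >= loglik - 1e-10 * (abs(loglik) + 1.0):
                    break
                scale *= 0.5
            beta, loglik, grad, info = cand, ll_new, g_new, i_new
            if np.max(np.abs(beta)) > MAX_ABS_BETA:
                flag = "monotone_likelihood"
                break
        else:
            flag = "max_iter"
        if flag is None and not converged and np.max(np.abs(grad)) < tol:
            converged = True

        try:
            cov = np.linalg.inv(info)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
            converged = False
            flag = flag or "singular_information"

        z = np.divide(beta, se, out=np.full(p, np.nan), where=se > 0)
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
        idx = pd.Index(terms)
        with np.errstate(over="ignore"):  # diverged fits have huge se; CI -> inf is fine
            hr = np.exp(beta)
            ci_lo = np.exp(beta - 1.959963984540054 * se)
            ci_hi = np.exp(beta + 1.959963984540054 * se)
        return CoxResult(
            terms=list(terms),
            beta=pd.Series(beta, index=idx),
            se=pd.Series(se, index=idx),
            hr=pd.Series(hr, index=idx),
            ci_low=pd.Series(ci_lo, index=idx),
            ci_high=pd.Series(ci_hi, index=idx),
            p=pd.Series(pvals, index=idx),
            loglik=loglik,
            n=self.n,
            n_events=self.n_events,
            n_strata=self.n_strata,
            ties=self.ties,
            converged=converged,
            flag=flag,
            n_iter=it,
        )

    def fit_beta(self, X, tol: float = 1e-8, max_iter: int = 60):
        """Coefficients only, no Wald bookkeeping — the permutation fast path.

        Returns ``(beta, converged)``; a non-converged fit signals monotone
        likelihood or iteration exhaustion.
        """
        X = np.asarray(X, dtype=float)
        Xs = X[self.order]
        p = Xs.shape[1]
        beta = np.zeros(p)
        loglik, grad, info = self._loglik_grad_info(Xs, beta)
        for _ in range(max_iter):
            if np.max(np.abs(grad)) < tol:
                return beta, True
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError:
                return beta, False
            scale = 1.0
            for _ in range(35):
                cand = beta + scale * step
                ll_new, g_new, i_new = self._loglik_grad_info(Xs, cand)
                if np.isfinite(ll_new) and ll_new >= loglik - 1e-10 * (abs(loglik) + 1.0):
                    break
                scale *= 0.5
            beta, loglik, grad, info = cand, ll_new, g_new, i_new
            if np.max(np.abs(beta)) > MAX_ABS_BETA:
                return beta, False
        return beta, bool(np.max(np.abs(grad)) < tol)


def fit_cox(
    data: pd.DataFrame,
    terms: list[str],
    strata: str | None = None,
    *,
    time_col: str = "time",
    event_col: str = "event",
    ties: str = "breslow",
) -> CoxResult:
    """Fit a site-stratified Cox model with the named covariate columns.

    Parameters
    ----------
    data : DataFrame with `time_col` (> 0), `event_col` (0/1), the `terms`
        columns and, if requested, the `strata` column.
    terms : covariate column names entering the linear predictor.
    strata : optional stratum column (e.g. clinic site).

    Raises
    ------
    ValueError
        If a required column is missing or the data contain no events.
    """
    for col in [time_col, event_col, *terms] + ([strata] if strata else []):
        if col not in data.columns:
            raise ValueError(f"column {col!r} not found in data")
    engine = StratifiedCoxEngine(
        data[time_col].to_numpy(),
        data[event_col].to_numpy(),
        data[strata].to_numpy() if strata else None,
        ties=ties,
    )
    X = data[terms].to_numpy(dtype=float)
    return engine.fit(X, terms=terms)
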