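"""Survival statistics: Kaplan–Meier, log-rank, Cox proportional hazards.

The Cox model is fitted by Newton–Raphson on the partial likelihood with
Efron's correction for tied event times (Breslow available by flag); the
two are identical when no event times tie.  Step-halving guarantees the
partial likelihood never decreases across iterations.  A monotone
likelihood (perfect separation) is detected by a diverging coefficient,
which is capped and flagged as non-converged.

These primitives back both the univariate screen of candidate gene pairs
and the multivariate independence analysis of the fitted risk score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import PairIndicatorMatrix, ValidationError, pair_token

#: |coefficient| beyond which a monotone likelihood is declared.
_SEPARATION_CAP = 20.0


@dataclass
class KMCurve:
    """Kaplan–Meier product-limit estimate of the survival function."""

    event_times: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    n_samples: int

    def survival_at(self, t: float | np.ndarray) -> np.ndarray:
        """S(t) as a right-continuous step function, S(0) = 1."""
        idx = np.searchsorted(self.event_times, np.atleast_1d(t), side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]


def km_estimate(time: np.ndarray, event: np.ndarray) -> KMCurve:
    """Product-limit estimator over the distinct event times.

    ``S(t) = prod_{t_i <= t} (1 - d_i / n_i)`` with d_i events and n_i at
    risk at each distinct event time t_i.  Censored samples leave the risk
    set just after their censoring time.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValidationError("cannot estimate a survival curve from no samples")
    if (time <= 0).any():
        raise ValidationError("all times must be > 0")
    t_sorted = np.sort(time)
    uniq = np.unique(time[event == 1])
    if uniq.size == 0:
        return KMCurve(np.array([]), np.array([]), np.array([]),
                       np.array([]), time.size)
    # at risk at u: samples with time >= u
    at_risk = time.size - np.searchsorted(t_sorted, uniq, side="left")
    d = np.array([(time[event == 1] == u).sum() for u in uniq])
    surv = np.cumprod(1.0 - d / at_risk)
    return KMCurve(uniq, at_risk.astype(int), d.astype(int), surv, time.size)


def logrank_test(time_a, event_a, time_b, event_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, 1-df p-value).

    With zero events in both groups combined the statistic is undefined;
    a warning is issued and p = 1 returned.
    """
    ta, da = np.asarray(time_a, float), np.asarray(event_a, int)
    tb, db = np.asarray(time_b, float), np.asarray(event_b, int)
    if ta.size == 0 or tb.size == 0:
        raise ValidationError("both groups must be non-empty")
    if da.sum() + db.sum() == 0:
        warnings.warn("no events in either group; log-rank p set to 1")
        return 0.0, 1.0
    t_all = np.concatenate([ta, tb])
    d_all = np.concatenate([da, db])
    uniq = np.unique(t_all[d_all == 1])
    sa, sb = np.sort(ta), np.sort(tb)
    n1 = ta.size - np.searchsorted(sa, uniq, side="left")
    n2 = tb.size - np.searchsorted(sb, uniq, side="left")
    d1 = np.array([((ta == u) & (da == 1)).sum() for u in uniq])
    d2 = np.array([((tb == u) & (db == 1)).sum() for u in uniq])
    n = n1 + n2
    d = d1 + d2
    expected = n1 * d / n
    with np.errstate(invalid="ignore", divide="ignore"):
        var = np.where(n > 1,
                       d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1), 0.0)
    v = var.sum()
    if v <= 0:
        warnings.warn("log-rank variance is zero; p set to 1")
        return 0.0, 1.0
    chi2 = float((d1.sum() - expected.sum()) ** 2 / v)
    return chi2, float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

class CoxData:
    """Time/event data pre-sorted and grouped for partial-likelihood sums.

    Building this once and reusing it across fits (e.g. screening many
    single covariates against the same follow-up) avoids re-sorting.
    """

    def __init__(self, time, event):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        if time.size == 0:
            raise ValidationError("empty survival data")
        self.order = np.argsort(time, kind="stable")
        self.t = time[self.order]
        self.d = event[self.order].astype(float)
        _, inverse, counts = np.unique(self.t, return_inverse=True,
                                       return_counts=True)
        self.start = np.concatenate([[0], np.cumsum(counts)[:-1]]).astype(int)
        self.n = time.size
        self.d_per_group = np.add.reduceat(self.d, self.start)
        self.has_ties = bool((self.d_per_group > 1).any())
        self.n_events = int(self.d.sum())


def _suffix_sum(a: np.ndarray) -> np.ndarray:
    return np.cumsum(a[::-1], axis=0)[::-1]


def _cox_loglik(cd: CoxData, Xs: np.ndarray, beta: np.ndarray,
                ties: str) -> float:
    """Partial log-likelihood (centered for numerical stability)."""
    eta = Xs @ beta
    eta = eta - eta.max()
    w = np.exp(eta)
    s0 = _suffix_sum(w)[cd.start]
    eta_d = np.add.reduceat(eta * cd.d, cd.start)
    w_d = np.add.reduceat(w * cd.d, cd.start)
    ll = 0.0
    for g in np.flatnonzero(cd.d_per_group > 0):
        dg = int(cd.d_per_group[g])
        ll += eta_d[g]
        if ties == "efron" and dg > 1:
            frac = np.arange(dg) / dg
            ll -= np.log(s0[g] - frac * w_d[g]).sum()
        else:
            ll -= dg * np.log(s0[g])
    return float(ll)


def _cox_derivatives(cd: CoxData, Xs: np.ndarray, beta: np.ndarray,
                     ties: str) -> tuple[float, np.ndarray, np.ndarray]:
    """(loglik, gradient, observed information) at beta."""
    n, p = Xs.shape
    eta = Xs @ beta
    eta = eta - eta.max()
    w = np.exp(eta)
    wx = w[:, None] * Xs
    wxx = wx[:, :, None] * Xs[:, None, :]
    s0 = _suffix_sum(w)[cd.start]
    s1 = _suffix_sum(wx)[cd.start]
    s2 = _suffix_sum(wxx)[cd.start]
    dmask = cd.d[:, None]
    eta_d = np.add.reduceat(eta * cd.d, cd.start)
    w_d = np.add.reduceat(w * cd.d, cd.start)
    x_d = np.add.reduceat(Xs * dmask, cd.start, axis=0)
    s1_d = np.add.reduceat(wx * dmask, cd.start, axis=0)
    s2_d = np.add.reduceat(wxx * dmask[:, :, None], cd.start, axis=0)

    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    ev_groups = np.flatnonzero(cd.d_per_group > 0)
    singles = ev_groups[(cd.d_per_group[ev_groups] == 1)
                        | (np.full(ev_groups.shape, ties == "breslow"))]
    multis = np.setdiff1d(ev_groups, singles)
    if singles.size:
        dg = cd.d_per_group[singles]
        s0g = s0[singles]
        u = s1[singles] / s0g[:, None]
        ll += eta_d[singles].sum() - (dg * np.log(s0g)).sum()
        grad += x_d[singles].sum(axis=0) - (dg[:, None] * u).sum(axis=0)
        info += np.einsum("g,gij->ij", dg, s2[singles] / s0g[:, None, None])
        info -= np.einsum("g,gi,gj->ij", dg, u, u)
    for g in multis:  # Efron correction for tied event times
        dg = int(cd.d_per_group[g])
        frac = np.arange(dg) / dg
        phi = s0[g] - frac * w_d[g]                       # (dg,)
        s1_l = s1[g][None, :] - frac[:, None] * s1_d[g]   # (dg, p)
        s2_l = s2[g][None, :, :] - frac[:, None, None] * s2_d[g]
        u = s1_l / phi[:, None]
        ll += eta_d[g] - np.log(phi).sum()
        grad += x_d[g] - u.sum(axis=0)
        info += (s2_l / phi[:, None, None]).sum(axis=0)
        info -= np.einsum("li,lj->ij", u, u)
    return float(ll), grad, info


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model.

    Hazard ratios are ``exp(coef)`` with 95% CI ``exp(coef +- 1.96 se)``;
    p-values are two-sided Wald.
    """

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    n: int
    n_events: int
    ties: str

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci_lower(self) -> np.ndarray:
        return np.exp(self.coef - 1.959963984540054 * self.se)

    @property
    def ci_upper(self) -> np.ndarray:
        return np.exp(self.coef + 1.959963984540054 * self.se)

    @property
    def z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(self.se > 0, self.coef / self.se, 0.0)
        return z

    @property
    def p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coef, "se": self.se, "HR": self.hr,
             "CI95_lower": self.ci_lower, "CI95_upper": self.ci_upper,
             "z": self.z, "p": self.p}, index=self.names)


def cox_fit(X, time=None, event=None, *, ties: str = "efron",
            tol: float = 1e-9, max_iter: int = 50,
            cox_data: CoxData | None = None) -> CoxFit:
    """Maximize the Cox partial likelihood by Newton–Raphson.

    Parameters
    ----------
    X : array-like or DataFrame, shape (n, p)
        Covariates.  A constant column cannot be estimated: it is flagged
        with coefficient 0 and infinite standard error.
    ties : {"efron", "breslow"}
        Tie correction; the two agree exactly when no event times tie.
    cox_data : CoxData, optional
        Pre-sorted time/event data; pass this when fitting many models
        against the same follow-up.

    Step-halving keeps the partial likelihood non-decreasing; convergence
    is declared when the largest Newton step falls below ``tol``.  A
    monotone likelihood (perfect separation) leaves a coefficient at the
    cap with ``converged=False`` and a warning.
    """
    if ties not in ("efron", "breslow"):
        raise ValidationError(f"unknown tie method {ties!r}")
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        if Xa.ndim == 1:
            Xa = Xa[:, None]
        names = [f"x{i}" for i in range(Xa.shape[1])]
    cd = cox_data if cox_data is not None else CoxData(time, event)
    if Xa.shape[0] != cd.n:
        raise ValidationError("X and survival data have different lengths")
    Xs = Xa[cd.order]

    const = Xs.std(axis=0) == 0
    if const.any():
        warnings.warn(
            "constant covariate(s) "
            f"{[names[i] for i in np.flatnonzero(const)]}: coefficient set "
            "to 0 with infinite standard error")
    free = np.flatnonzero(~const)
    Xf = Xs[:, free]
    beta = np.zeros(free.size)
    ll, grad, info = _cox_derivatives(cd, Xf, beta, ties)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.pinv(info) @ grad
        # step-halving: the partial likelihood must not decrease
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            ll_new = _cox_loglik(cd, Xf, cand, ties)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = np.clip(cand, -_SEPARATION_CAP, _SEPARATION_CAP)
        moved = np.abs(scale * step).max() if step.size else 0.0
        ll, grad, info = _cox_derivatives(cd, Xf, beta, ties)
        if moved < tol:
            converged = True
            break
    separated = (np.abs(beta) >= _SEPARATION_CAP).any()
    if separated:
        converged = False
        warnings.warn("monotone partial likelihood (perfect separation): "
                      "coefficient capped; estimates unreliable")

    coef = np.zeros(Xa.shape[1])
    se = np.full(Xa.shape[1], np.inf)
    coef[free] = beta
    if free.size:
        try:
            cov = np.linalg.inv(info)
            se[free] = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            pass
    return CoxFit(names=names, coef=coef, se=se, loglik=ll,
                  converged=converged, n_iter=n_iter, n=cd.n,
                  n_events=cd.n_events, ties=ties)


def univariate_screen(pm: PairIndicatorMatrix, time, event,
                      alpha: float = 0.01) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """One single-covariate Cox fit per pair; keep Wald p < alpha (strict).

    Returns the retained pairs and the full per-pair table (coef, se, HR,
    CI bounds, p) indexed by pair token, in input order.
    """
    if pm.n_pairs == 0:
        raise ValidationError("empty pair matrix")
    cd = CoxData(time, event)
    rows = []
    for k in range(pm.n_pairs):
        x = pm.values[k].astype(float)
        if x.std() == 0:
            rows.append((0.0, np.inf, 1.0, 0.0, np.inf, 1.0))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = cox_fit(x[:, None], cox_data=cd)
        rows.append((fit.coef[0], fit.se[0], fit.hr[0],
                     fit.ci_lower[0], fit.ci_upper[0], fit.p[0]))
    table = pd.DataFrame(rows, columns=["coef", "se", "HR", "CI95_lower",
                                        "CI95_upper", "p"],
                         index=[pair_token(p) for p in pm.pairs])
    selected = [pm.pairs[k] for k in range(pm.n_pairs)
                if table["p"].iloc[k] < alpha]
    return selected, table
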