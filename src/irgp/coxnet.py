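"""L1-penalized Cox regression: coordinate-descent path and k-fold CV.

The penalized objective is ``-(1/n) log PL(beta) + lambda * ||b||_1``
where PL is the Breslow partial likelihood and ``b`` are the coefficients
on the internally standardized covariate scale (coefficients are reported
back on the original scale).  Each outer iteration forms the usual
quadratic approximation with per-sample working weights and responses
derived from the gradient and diagonal Hessian of the partial likelihood;
the inner problem is solved by cyclic coordinate descent with
soft-thresholding over an active set, with full Karush–Kuhn–Tucker checks
before a lambda is accepted.

The lambda grid descends geometrically from ``lambda_max`` (the smallest
penalty with an all-zero solution, computed from the null-model score)
with warm starts along the path.  Cross-validation scores each lambda by
the Verweij–van Houwelingen held-out partial-likelihood deviance
``-2 [logPL_all(beta_(-k)) - logPL_(-k)(beta_(-k))]`` and selects the
minimizer (the "lambda_min" rule; a one-standard-error rule is optional).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd

from .datatypes import ValidationError
from .survival import CoxData, _suffix_sum


@numba.njit(cache=False)
def _cd_sweeps(gram, diag, ca, ba, lam, inner_tol, max_sweeps):
    """Cyclic soft-threshold sweeps over the active-set quadratic problem."""
    a = ba.shape[0]
    for _ in range(max_sweeps):
        delta_max = 0.0
        for j in range(a):
            if diag[j] <= 0.0:
                continue
            num = ca[j] - np.dot(gram[j], ba) + diag[j] * ba[j]
            mag = abs(num) - lam
            if mag > 0.0:
                new = (mag / diag[j]) if num > 0 else (-mag / diag[j])
            else:
                new = 0.0
            diff = new - ba[j]
            if diff != 0.0:
                ba[j] = new
                if abs(diff) > delta_max:
                    delta_max = abs(diff)
        if delta_max < inner_tol:
            break
    return ba


def _breslow_working(cd: CoxData, eta: np.ndarray):
    """(loglik, per-sample gradient d ll/d eta, diagonal Hessian weight).

    All quantities on the sorted scale of ``cd``.  Samples that precede
    the first event have zero weight.
    """
    c = eta.max()
    w = np.exp(eta - c)
    s0 = _suffix_sum(w)[cd.start]
    d_g = cd.d_per_group
    ev = d_g > 0
    # cumulative hazard increments at each unique time, prefix-summed
    inc_p = np.zeros_like(s0)
    inc_q = np.zeros_like(s0)
    inc_p[ev] = d_g[ev] / s0[ev]
    inc_q[ev] = d_g[ev] / s0[ev] ** 2
    cum_p = np.cumsum(inc_p)
    cum_q = np.cumsum(inc_q)
    # group index of each sorted sample
    gid = np.searchsorted(cd.start, np.arange(cd.n), side="right") - 1
    p_i = cum_p[gid]
    q_i = cum_q[gid]
    grad = cd.d - w * p_i
    hess = np.clip(w * p_i - w * w * q_i, 0.0, None)
    eta_d = (eta - c) * cd.d
    ll = float(eta_d.sum() - (d_g[ev] * np.log(s0[ev])).sum())
    return ll, grad, hess


def breslow_loglik(time, event, eta: np.ndarray) -> float:
    """Breslow partial log-likelihood of a fixed linear predictor."""
    cd = CoxData(time, event)
    ll, _, _ = _breslow_working(cd, np.asarray(eta, float)[cd.order])
    return ll


@dataclass
class LassoPath:
    """A fitted L1 path: one coefficient vector per lambda (original scale)."""

    lambdas: np.ndarray
    coefs: np.ndarray            # (n_lambda, p)
    n_nonzero: np.ndarray
    converged: np.ndarray
    lambda_max: float
    names: list[str]
    cv_mean: np.ndarray | None = None
    cv_se: np.ndarray | None = None
    selected_lambda: float | None = None

    def coef_at(self, lam: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.lambdas - lam)))
        return self.coefs[idx]


def _cd_solve(Xs, cd: CoxData, lam: float, beta: np.ndarray,
              outer_tol: float, inner_tol: float,
              max_outer: int = 50, max_sweeps: int = 1000) -> tuple[np.ndarray, bool]:
    """Solve one lambda by IRLS + active-set coordinate descent.

    ``Xs`` is (n, p) on the sorted sample order of ``cd``; ``beta`` is the
    warm start (modified in place semantics avoided: a copy is returned).
    """
    n, p = Xs.shape
    beta = beta.copy()
    eta = Xs @ beta
    ll, grad, h = _breslow_working(cd, eta)
    obj = -ll / n + lam * np.abs(beta).sum()
    ok = False
    for _ in range(max_outer):
        # quadratic approximation at the current eta; the weighted inner
        # problem is solved over the active set with its Gram matrix, so
        # each coordinate update costs O(|active|) rather than O(n)
        hz = h * eta + grad                          # h * working response z
        active = np.flatnonzero(beta != 0.0).tolist()
        while True:
            if active:
                aidx = np.asarray(active)
                Xa = Xs[:, aidx]
                gram = (Xa * h[:, None]).T @ Xa / n  # (a, a)
                ca = (Xa.T @ hz) / n
                diag = np.ascontiguousarray(np.diag(gram))
                ba = _cd_sweeps(np.ascontiguousarray(gram), diag,
                                np.ascontiguousarray(ca),
                                beta[aidx].copy(), lam, inner_tol,
                                max_sweeps)
                beta[aidx] = ba
            # KKT check over all coordinates
            wres = hz - h * (Xs @ beta)
            g_all = np.abs(Xs.T @ wres) / n
            viol = np.flatnonzero((g_all > lam * (1 + 1e-9)) & (beta == 0.0))
            in_active = set(active)
            viol = [j for j in viol if j not in in_active]
            if not viol:
                break
            active.extend(viol)
        eta = Xs @ beta
        ll, grad, h = _breslow_working(cd, eta)
        new_obj = -ll / n + lam * np.abs(beta).sum()
        if abs(obj - new_obj) <= outer_tol * (abs(new_obj) + 1e-10):
            ok = True
            obj = new_obj
            break
        obj = new_obj
    beta[np.abs(beta) < 1e-12] = 0.0
    return beta, ok


def lasso_cox_path(X, time, event, *, n_lambda: int = 100,
                   lambda_min_ratio: float = 0.01,
                   lambdas: np.ndarray | None = None,
                   standardize: bool = True,
                   outer_tol: float = 1e-7, inner_tol: float = 1e-9) -> LassoPath:
    """Fit the full L1-penalized Cox coefficient path.

    ``standardize=True`` (the default, glmnet-compatible) scales columns
    to zero mean and unit variance for the penalty and reports
    coefficients back on the original scale; pass ``False`` to penalize
    raw coefficients (useful when comparing objectives directly).
    Non-convergence at a lambda is flagged but the path is still
    returned.
    """
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"x{i}" for i in range(Xa.shape[1])]
    n, p = Xa.shape
    cd = CoxData(time, event)
    if n != cd.n:
        raise ValidationError("X and survival data have different lengths")

    mean = Xa.mean(axis=0)
    sd = Xa.std(axis=0)  # 1/n variance, glmnet convention
    usable = sd > 0
    if standardize:
        scale = np.where(usable, sd, 1.0)
    else:
        scale = np.ones(p)
    Xs_full = (Xa - mean) / scale  # centering leaves the Cox PL invariant
    Xs_full[:, ~usable] = 0.0
    Xs = Xs_full[cd.order]

    _, grad0, _ = _breslow_working(cd, np.zeros(n))
    score0 = np.abs(Xs.T @ grad0) / n
    lam_max = float(score0.max())
    if lam_max <= 0:
        raise ValidationError("degenerate design: null score is zero")
    if lambdas is None:
        lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)
    else:
        lambdas = np.sort(np.asarray(lambdas, dtype=float))[::-1]

    coefs = np.zeros((len(lambdas), p))
    conv = np.zeros(len(lambdas), dtype=bool)
    beta = np.zeros(p)
    for i, lam in enumerate(lambdas):
        beta, ok = _cd_solve(Xs, cd, lam, beta, outer_tol, inner_tol)
        conv[i] = ok
        coefs[i] = beta / scale
        coefs[i, ~usable] = 0.0
    if not conv.all():
        warnings.warn(f"{(~conv).sum()} lambda value(s) did not fully converge")
    return LassoPath(lambdas=np.asarray(lambdas), coefs=coefs,
                     n_nonzero=(coefs != 0).sum(axis=1),
                     converged=conv, lambda_max=lam_max, names=names)


@dataclass
class CVSelection:
    """Result of cross-validated lambda selection."""

    lambda_: float
    coef: pd.Series
    selected: list[str]
    path: LassoPath
    cv_table: pd.DataFrame
    fold_ids: np.ndarray = field(repr=False, default=None)

    @property
    def n_nonzero(self) -> int:
        return int((self.coef != 0).sum())


def _fold_assignment(n: int, folds: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    ids = np.repeat(np.arange(folds), int(np.ceil(n / folds)))[:n]
    return ids[rng.permutation(n)]


def cv_select(X, time, event, *, folds: int = 10, seed: int = 0,
              rule: str = "min", n_lambda: int = 100,
              lambda_min_ratio: float = 0.01, standardize: bool = True,
              outer_tol: float = 1e-7, inner_tol: float = 1e-9) -> CVSelection:
    """Select lambda by k-fold cross-validated held-out deviance.

    Folds come from a seeded permutation into near-equal blocks.  The
    full-data path fixes the lambda grid; each training fold is refit on
    that grid and scored by the Verweij–van Houwelingen deviance.  The
    final model is the full-data fit at the selected lambda; its nonzero
    coefficients define the signature.  ``rule="1se"`` picks the sparsest
    lambda within one standard error of the minimum.
    """
    if folds < 2:
        raise ValidationError("folds must be at least 2")
    if rule not in ("min", "1se"):
        raise ValidationError(f"unknown selection rule {rule!r}")
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"x{i}" for i in range(Xa.shape[1])]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = Xa.shape[0]

    full_path = lasso_cox_path(Xa, time, event, n_lambda=n_lambda,
                               lambda_min_ratio=lambda_min_ratio,
                               standardize=standardize,
                               outer_tol=outer_tol, inner_tol=inner_tol)
    lambdas = full_path.lambdas

    fold_ids = _fold_assignment(n, folds, seed)
    dev = np.full((folds, len(lambdas)), np.nan)
    for k in range(folds):
        train = fold_ids != k
        ev_train = int(event[train].sum())
        if ev_train == 0:
            warnings.warn(f"fold {k} has no training events; skipped")
            continue
        if int(event[~train].sum()) < 3:
            warnings.warn(f"fold {k} holds out fewer than 3 events")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sub = lasso_cox_path(Xa[train], time[train], event[train],
                                 lambdas=lambdas, standardize=standardize,
                                 outer_tol=outer_tol, inner_tol=inner_tol)
        for i in range(len(lambdas)):
            eta_all = Xa @ sub.coefs[i]
            ll_all = breslow_loglik(time, event, eta_all)
            ll_train = breslow_loglik(time[train], event[train],
                                      eta_all[train])
            dev[k, i] = -2.0 * (ll_all - ll_train)
    valid = ~np.isnan(dev).all(axis=1)
    cv_mean = np.nanmean(dev[valid], axis=0)
    cv_se = np.nanstd(dev[valid], axis=0, ddof=1) / np.sqrt(valid.sum())

    i_min = int(np.argmin(cv_mean))
    if rule == "1se":
        bound = cv_mean[i_min] + cv_se[i_min]
        i_sel = int(np.flatnonzero(cv_mean <= bound)[0])  # largest lambda
    else:
        i_sel = i_min
    lam = float(lambdas[i_sel])
    coef = pd.Series(full_path.coefs[i_sel], index=names)
    full_path.cv_mean = cv_mean
    full_path.cv_se = cv_se
    full_path.selected_lambda = lam
    cv_table = pd.DataFrame({"lambda": lambdas, "cv_mean": cv_mean,
                             "cv_se": cv_se,
                             "n_nonzero": full_path.n_nonzero})
    return CVSelection(lambda_=lam, coef=coef,
                       selected=[nm for nm, c in coef.items() if c != 0],
                       path=full_path, cv_table=cv_table, fold_ids=fold_ids)
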