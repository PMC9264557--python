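"""Simulation experiments that validate the pipeline's statistics.

Each function draws synthetic cohorts from the generator, runs the
corresponding piece of the pipeline, and reports a calibration or
recovery measure: type-I error of the log-rank test and of the
univariate Cox screen under the null, the one-year AUC under null and
strong-signal conditions, sparsity of the penalized selection on pure
noise, and recovery of planted pairs by the cross-validated penalized
fit.  They exist so that the same experiment, at the same problem sizes,
backs both the test suite and the reproduction script.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .coxnet import cv_select
from .datatypes import ClinicalTable, PairIndicatorMatrix, SimulationConfig
from .risk import one_year_roc
from .simulate import (default_planted_pairs, simulate_expression,
                       simulate_survival)
from .survival import CoxData, cox_fit, logrank_test


def _null_survival(n: int, rng: np.random.Generator,
                   baseline: float = 1e-3, censor: float = 1e-3,
                   admin: float = 1825.0) -> tuple[np.ndarray, np.ndarray]:
    t_event = rng.exponential(1.0 / baseline, size=n)
    t_cens = np.minimum(rng.exponential(1.0 / censor, size=n), admin)
    time = np.maximum(np.minimum(t_event, t_cens), 1e-9)
    event = (t_event <= t_cens).astype(int)
    return time, event


def logrank_type1(n_reps: int = 1000, n_per_group: int = 50,
                  alpha: float = 0.05, seed: int = 0) -> float:
    """Rejection rate of the log-rank test on two identical-law groups."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        ta, ea = _null_survival(n_per_group, rng)
        tb, eb = _null_survival(n_per_group, rng)
        _, p = logrank_test(ta, ea, tb, eb)
        rejections += p < alpha
    return rejections / n_reps


def screen_type1(n_pairs: int = 1000, n: int = 200, alpha: float = 0.05,
                 seed: int = 0) -> float:
    """Fraction of pure-noise binary covariates with Wald p < alpha.

    Covariates are fair-coin indicators independent of an exponential
    null survival law, each tested by a single-covariate Cox fit.
    """
    rng = np.random.default_rng(seed)
    time, event = _null_survival(n, rng)
    cd = CoxData(time, event)
    hits = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_pairs):
            x = rng.integers(0, 2, size=n).astype(float)
            if x.std() == 0:
                continue
            fit = cox_fit(x[:, None], cox_data=cd)
            hits += fit.p[0] < alpha
    return hits / n_pairs


def cox_null_z(n_reps: int = 200, n: int = 500, seed: int = 0) -> np.ndarray:
    """Wald z of a covariate independent of survival, across replicates."""
    rng = np.random.default_rng(seed)
    zs = np.empty(n_reps)
    for r in range(n_reps):
        time, event = _null_survival(n, rng)
        x = rng.integers(0, 2, size=n).astype(float)
        fit = cox_fit(x[:, None], time, event)
        zs[r] = fit.z[0]
    return zs


def _signal_cohort(cfg_seed: int, n: int = 500, n_planted: int = 5,
                   beta: float = 1.0) -> tuple[SimulationConfig,
                                               "PairIndicatorMatrix",
                                               ClinicalTable]:
    base = SimulationConfig(n_tumor=n, n_normal=2, n_genes=2 * n_planted + 2,
                            immune_fraction=1.0, n_de_genes=0, mu_low=6.0,
                            mu_high=6.0, seed=cfg_seed)
    cfg = SimulationConfig(n_tumor=n, n_normal=2, n_genes=2 * n_planted + 2,
                           immune_fraction=1.0, n_de_genes=0, mu_low=6.0,
                           mu_high=6.0, seed=cfg_seed,
                           planted_pairs=default_planted_pairs(
                               base, n_planted, beta=beta))
    _, truth = simulate_expression(cfg)
    clinical = simulate_survival(cfg, truth)
    return cfg, truth.indicators, clinical


def null_auc(n: int = 1000, seed: int = 0) -> float:
    """One-year AUC of a score independent of outcome."""
    rng = np.random.default_rng(seed)
    time, event = _null_survival(n, rng)
    clinical = ClinicalTable(pd.DataFrame(
        {"time": time, "event": event},
        index=pd.Index([f"S{i}" for i in range(n)], name="sample_id")))
    scores = pd.Series(rng.normal(size=n), index=clinical.sample_ids)
    return one_year_roc(scores, clinical).auc


def strong_signal_auc(n_runs: int = 20, n: int = 500, beta: float = 1.0,
                      seed: int = 0) -> np.ndarray:
    """One-year AUC of the true-coefficient score on planted cohorts.

    The score is the generating linear predictor itself (five planted
    pairs, |beta| as given), so this measures how discriminative the
    planted signal is, independent of estimation error.
    """
    aucs = np.empty(n_runs)
    for r in range(n_runs):
        cfg, ind, clinical = _signal_cohort(seed + 7919 * r, n=n, beta=beta)
        betas = np.array([b for _, _, b in cfg.planted_pairs])
        scores = pd.Series(betas @ ind.values.astype(float),
                           index=ind.sample_ids)
        aucs[r] = one_year_roc(scores, clinical).auc
    return aucs


def planted_recovery(n_runs: int = 20, n: int = 500, n_candidates: int = 100,
                     n_planted: int = 5, beta: float = 1.0, folds: int = 10,
                     seed: int = 0, n_lambda: int = 100) -> pd.DataFrame:
    """Recovery of planted pairs by cross-validated penalized selection.

    Each run simulates ``n`` tumor samples whose hazard depends on
    ``n_planted`` disjoint planted pairs (log hazard ratios ``+-beta``),
    embeds their indicators among ``n_candidates`` candidate-pair
    indicators built from disjoint decoy genes, and runs ``cv_select``.
    A planted pair counts as recovered when its coefficient is nonzero
    with the generating sign.  Returns one row per run with columns
    ``n_recovered`` (correct-sign recoveries), ``n_selected`` (total
    nonzeros) and ``sign_errors``.
    """
    n_genes = 2 * n_candidates + 2
    rows = []
    for r in range(n_runs):
        run_seed = seed + 104729 * r
        base = SimulationConfig(n_tumor=n, n_normal=2, n_genes=n_genes,
                                immune_fraction=1.0, n_de_genes=0,
                                mu_low=6.0, mu_high=6.0, seed=run_seed)
        planted = default_planted_pairs(base, n_planted, beta=beta)
        cfg = SimulationConfig(n_tumor=n, n_normal=2, n_genes=n_genes,
                               immune_fraction=1.0, n_de_genes=0,
                               mu_low=6.0, mu_high=6.0, seed=run_seed,
                               planted_pairs=planted)
        em, truth = simulate_expression(cfg)
        clinical = simulate_survival(cfg, truth)
        genes = list(em.values.index)
        decoys = [(genes[2 * k], genes[2 * k + 1])
                  for k in range(n_planted, n_candidates)]
        all_pairs = [(gi, gj) for gi, gj, _ in planted] + decoys
        from .pairs import build_indicator_matrix
        pm = build_indicator_matrix(em, all_pairs,
                                    em.samples_in_group("tumor"))
        X = pd.DataFrame(pm.values.T.astype(float),
                         index=pm.sample_ids,
                         columns=[f"{a}|{b}" for a, b in pm.pairs])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv = cv_select(X, clinical.time.to_numpy(),
                           clinical.event.to_numpy(), folds=folds,
                           seed=run_seed, n_lambda=n_lambda)
        recovered = 0
        sign_errors = 0
        for (gi, gj, b) in planted:
            c = cv.coef[f"{gi}|{gj}"]
            if c != 0 and np.sign(c) == np.sign(b):
                recovered += 1
            elif c != 0:
                sign_errors += 1
        rows.append((recovered, int((cv.coef != 0).sum()), sign_errors))
    return pd.DataFrame(rows, columns=["n_recovered", "n_selected",
                                       "sign_errors"])


def null_sparsity(n_runs: int = 20, n: int = 300, n_candidates: int = 50,
                  folds: int = 10, seed: int = 0) -> np.ndarray:
    """Nonzero count selected by CV on a pure-noise design, per run."""
    out = np.empty(n_runs, dtype=int)
    for r in range(n_runs):
        rng = np.random.default_rng(seed + 15485863 * r)
        time, event = _null_survival(n, rng)
        X = rng.integers(0, 2, size=(n, n_candidates)).astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv = cv_select(X, time, event, folds=folds, seed=seed + r)
        out[r] = cv.n_nonzero
    return out
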