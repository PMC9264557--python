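"""Risk scores, ROC-based cutoff selection, stratification and independence.

A sample's risk score is the linear combination of its pair indicators
with the signature coefficients.  The cutoff separating high from low
risk maximizes Youden's J on the one-year ROC, where a positive is a
death by the horizon, a negative is any sample still under observation
past the horizon, and samples censored before the horizon are excluded
(simple exclusion rather than censoring-weighted estimates; documented
limitation).  Stratification is strict: high risk means score > cutoff.
The independence analysis fits one univariate Cox model per clinical
variable and a joint multivariate model including the risk score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import (ClinicalTable, ExpressionMatrix, PairIndicatorMatrix,
                        SignatureModel, ValidationError, pair_token)
from .pairs import build_indicator_matrix
from .survival import CoxFit, KMCurve, cox_fit, km_estimate, logrank_test


def split_cohort(clinical: ClinicalTable, ratio: float = 0.5,
                 seed: int = 0) -> tuple[list[str], list[str]]:
    """Seeded random train/test partition of samples with survival data.

    At ratio 0.5 the two sides differ in size by at most one (e.g. 387
    samples split 194/193).  Samples lacking follow-up time or event
    status are excluded beforehand; fewer than 10 usable samples is an
    error.
    """
    if not (0.0 < ratio < 1.0):
        raise ValidationError("split ratio must lie in (0, 1)")
    usable = clinical.data.index[clinical.data["time"].notna()
                                 & clinical.data["event"].notna()]
    n = len(usable)
    if n < 10:
        raise ValidationError(f"too few samples with survival data ({n} < 10)")
    n_train = int(np.floor(n * ratio + 0.5))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = sorted(usable[perm[:n_train]])
    test = sorted(usable[perm[n_train:]])
    return list(train), list(test)


def risk_score(sig: SignatureModel,
               pm: PairIndicatorMatrix | None = None,
               expression: ExpressionMatrix | None = None) -> pd.Series:
    """Per-sample score ``sum_k coef_k * indicator_k``.

    Signature pairs are looked up in ``pm``; any missing pair is computed
    from ``expression`` when given, otherwise it is an error naming the
    pair.
    """
    if pm is None and expression is None:
        raise ValidationError("need a pair matrix or an expression matrix")
    have = {p: i for i, p in enumerate(pm.pairs)} if pm is not None else {}
    missing = [p for p in sig.pairs if p not in have]
    if missing and expression is None:
        raise ValidationError(
            f"pair {pair_token(missing[0])} absent from the indicator matrix "
            "and no expression matrix was given to compute it")
    if pm is not None:
        samples = pm.sample_ids
        rows = []
        extra = (build_indicator_matrix(expression, missing, samples)
                 if missing else None)
        extra_idx = {p: i for i, p in enumerate(missing)}
        for p in sig.pairs:
            if p in have:
                rows.append(pm.values[have[p]])
            else:
                rows.append(extra.values[extra_idx[p]])
        ind = np.vstack(rows)
    else:
        full = build_indicator_matrix(expression, sig.pairs)
        ind = full.values
        samples = full.sample_ids
    scores = sig.coefficients @ ind
    return pd.Series(scores, index=samples, name="risk_score")


@dataclass
class ROCCurve:
    """Empirical ROC of a score against death-by-horizon status.

    ``thresholds`` are midpoints between adjacent distinct scores (plus
    sentinels below the minimum and above the maximum), so a perfectly
    separating score yields a cutoff strictly between the two groups.
    AUC is the Mann–Whitney concordance (tied pairs count one half),
    identical to the trapezoid area under the full empirical curve.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    horizon: float
    n_positive: int
    n_negative: int
    n_excluded: int

    def youden(self) -> np.ndarray:
        return self.sensitivity + self.specificity - 1.0


def one_year_roc(scores: pd.Series, clinical: ClinicalTable,
                 horizon: float = 365.0) -> ROCCurve:
    """Time-dependent ROC at a fixed horizon (one year by default).

    Positives: event observed at or before the horizon.  Negatives:
    follow-up extends past the horizon regardless of later status.
    Samples censored before the horizon are excluded (their one-year
    status is unknown).
    """
    common = [s for s in scores.index if s in set(clinical.sample_ids)]
    s = scores.loc[common].to_numpy(dtype=float)
    t = clinical.data.loc[common, "time"].to_numpy(dtype=float)
    e = clinical.data.loc[common, "event"].to_numpy(dtype=int)
    pos = (e == 1) & (t <= horizon)
    neg = t > horizon
    excluded = ~(pos | neg)
    if pos.sum() == 0 or neg.sum() == 0:
        raise ValidationError(
            f"horizon {horizon}: need at least one death by the horizon "
            f"({pos.sum()}) and one sample followed past it ({neg.sum()})")
    sp, sn = s[pos], s[neg]

    uniq = np.unique(np.concatenate([sp, sn]))
    gaps = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.array([])
    lo = uniq[0] - 1.0
    hi = uniq[-1] + 1.0
    thresholds = np.concatenate([[lo], gaps, [hi]])
    # high scores indicate death: call positive when score > threshold
    sens = np.array([(sp > c).mean() for c in thresholds])
    spec = np.array([(sn <= c).mean() for c in thresholds])

    ranks = rankdata(np.concatenate([sp, sn]))
    auc = float((ranks[:sp.size].sum() - sp.size * (sp.size + 1) / 2.0)
                / (sp.size * sn.size))
    return ROCCurve(thresholds=thresholds, sensitivity=sens,
                    specificity=spec, auc=auc, horizon=horizon,
                    n_positive=int(pos.sum()), n_negative=int(neg.sum()),
                    n_excluded=int(excluded.sum()))


def select_cutoff(roc: ROCCurve) -> float:
    """Threshold maximizing Youden's J; ties go to the smaller threshold.

    A degenerate curve (a single distinct score) returns that score with
    a warning.
    """
    if roc.thresholds.size == 2 and roc.thresholds[1] - roc.thresholds[0] == 2.0:
        # single distinct score: sentinels only
        warnings.warn("degenerate ROC curve (all scores equal); "
                      "returning the common score as cutoff")
        return float(roc.thresholds[0] + 1.0)
    j = roc.youden()
    best = int(np.argmax(j))  # argmax returns the first (smallest) maximizer
    return float(roc.thresholds[best])


@dataclass
class RiskAssignment:
    """Per-sample risk score and group under a given cutoff."""

    table: pd.DataFrame  # columns: score, group
    cutoff: float

    @property
    def high(self) -> list[str]:
        return list(self.table.index[self.table["group"] == "high"])

    @property
    def low(self) -> list[str]:
        return list(self.table.index[self.table["group"] == "low"])


def assign_risk(scores: pd.Series, cutoff: float) -> RiskAssignment:
    """High risk iff score is strictly greater than the cutoff."""
    group = np.where(scores.to_numpy(dtype=float) > cutoff, "high", "low")
    table = pd.DataFrame({"score": scores, "group": group}, index=scores.index)
    return RiskAssignment(table=table, cutoff=float(cutoff))


@dataclass
class StratifiedComparison:
    """Survival comparison between high- and low-risk groups."""

    assignment: RiskAssignment
    km_high: KMCurve
    km_low: KMCurve
    chi_square: float
    p_value: float
    death_fraction: dict[str, float]
    n: dict[str, int]


def stratify_and_compare(scores: pd.Series, cutoff: float,
                         clinical: ClinicalTable) -> StratifiedComparison:
    """Stratify at the cutoff, then KM curves, log-rank and death rates."""
    assignment = assign_risk(scores, cutoff)
    for name, ids in (("high", assignment.high), ("low", assignment.low)):
        if not ids:
            raise ValidationError(
                f"cutoff {cutoff} leaves the {name}-risk group empty; "
                "choose a different cutoff")
    out = {}
    for name, ids in (("high", assignment.high), ("low", assignment.low)):
        sub = clinical.subset(ids)
        out[name] = (sub.time.to_numpy(), sub.event.to_numpy())
    chi2, p = logrank_test(*out["high"], *out["low"])
    death = {k: float(v[1].mean()) for k, v in out.items()}
    n = {k: int(v[1].size) for k, v in out.items()}
    return StratifiedComparison(
        assignment=assignment,
        km_high=km_estimate(*out["high"]),
        km_low=km_estimate(*out["low"]),
        chi_square=chi2, p_value=p, death_fraction=death, n=n)


#: Ordinal/binary encodings for clinical covariates.  Grade I-IV maps to
#: 1-4; stage and T/N status collapse to their numeric rank; gender is
#: male=1, female=0.  Unknown or missing entries become NaN.
_GENDER = {"male": 1.0, "m": 1.0, "female": 0.0, "f": 0.0}
_ROMAN = {"i": 1.0, "ii": 2.0, "iii": 3.0, "iv": 4.0}


def _encode(value, kind: str) -> float:
    if pd.isna(value):
        return np.nan
    text = str(value).strip().lower()
    if not text or text in ("nan", "na", "unknown", "x"):
        return np.nan
    if kind == "gender":
        return _GENDER.get(text, np.nan)
    if text in _ROMAN:
        return _ROMAN[text]
    digits = "".join(ch for ch in text if ch.isdigit() or ch == ".")
    try:
        return float(digits)
    except ValueError:
        return np.nan


def encode_clinical(clinical: ClinicalTable) -> pd.DataFrame:
    """Numeric covariate matrix: age continuous, others ordinal/binary."""
    df = clinical.data
    out = pd.DataFrame(index=df.index)
    for col, kind in (("age", "numeric"), ("gender", "gender"),
                      ("grade", "ordinal"), ("stage", "ordinal"),
                      ("t_stage", "ordinal"), ("n_stage", "ordinal")):
        if col in df.columns:
            if col == "age":
                out[col] = pd.to_numeric(df[col], errors="coerce")
            else:
                out[col] = [_encode(v, kind) for v in df[col]]
    return out


@dataclass
class IndependenceResult:
    """Univariate and joint multivariate Cox analyses of the risk score."""

    univariate: pd.DataFrame
    multivariate: pd.DataFrame
    multivariate_fit: CoxFit
    n_dropped: dict[str, int]


def multivariate_independence(scores: pd.Series, clinical: ClinicalTable,
                              score_form: str = "continuous",
                              cutoff: float | None = None) -> IndependenceResult:
    """Test whether the risk score is prognostic beyond clinical covariates.

    ``score_form="continuous"`` enters the raw score; ``"group"`` enters
    the binary high/low indicator (requires ``cutoff``).  Samples with a
    missing value are dropped per-model, and the number dropped is
    reported.  Constant or collinear covariates are removed from the
    joint model (the later column goes) with a warning.
    """
    if score_form not in ("continuous", "group"):
        raise ValidationError(f"unknown score_form {score_form!r}")
    common = [s for s in scores.index if s in set(clinical.sample_ids)]
    cov = encode_clinical(clinical.subset(common))
    if score_form == "group":
        if cutoff is None:
            raise ValidationError("score_form='group' requires a cutoff")
        cov["riskScore"] = (scores.loc[common] > cutoff).astype(float)
    else:
        cov["riskScore"] = scores.loc[common].astype(float)
    time = clinical.data.loc[common, "time"].to_numpy(dtype=float)
    event = clinical.data.loc[common, "event"].to_numpy(dtype=int)

    uni_rows = []
    n_dropped: dict[str, int] = {}
    for col in cov.columns:
        x = cov[col]
        keep = x.notna().to_numpy()
        n_dropped[col] = int((~keep).sum())
        if keep.sum() < 3 or x[keep].nunique() < 2:
            warnings.warn(f"covariate {col!r} is constant or nearly empty; "
                          "skipped in univariate analysis")
            uni_rows.append((col, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        fit = cox_fit(x[keep].to_numpy()[:, None], time[keep], event[keep])
        uni_rows.append((col, fit.coef[0], fit.se[0], fit.hr[0],
                         fit.ci_lower[0], fit.ci_upper[0], fit.p[0]))
    univariate = pd.DataFrame(
        uni_rows, columns=["variable", "coef", "se", "HR", "CI95_lower",
                           "CI95_upper", "p"]).set_index("variable")

    # joint model: complete cases over the usable covariates
    joint_cols = []
    for col in cov.columns:
        x = cov[col]
        if x.notna().sum() >= 3 and x.dropna().nunique() >= 2:
            joint_cols.append(col)
        else:
            warnings.warn(f"covariate {col!r} dropped from the joint model "
                          "(constant or missing)")
    sub = cov[joint_cols].dropna()
    n_dropped["_joint"] = len(cov) - len(sub)
    # drop collinear columns, later ones first
    kept: list[str] = []
    for col in joint_cols:
        trial = sub[kept + [col]].to_numpy(dtype=float)
        if np.linalg.matrix_rank(trial - trial.mean(axis=0)) == len(kept) + 1:
            kept.append(col)
        else:
            warnings.warn(f"covariate {col!r} is collinear with earlier "
                          "covariates; dropped from the joint model")
    pos = {s: i for i, s in enumerate(common)}
    rows = [pos[s] for s in sub.index]
    fit = cox_fit(sub[kept], time[rows], event[rows])
    multivariate = fit.summary_frame()
    return IndependenceResult(univariate=univariate, multivariate=multivariate,
                              multivariate_fit=fit, n_dropped=n_dropped)
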