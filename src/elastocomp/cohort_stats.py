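"""Cohort-level statistical battery.

Group comparison (Mann-Whitney U), partial correlation with tumor type as
covariate, stepwise multiple regression (forward selection with backward
elimination), ROC analysis with the rank-based AUC estimator and
Hanley-McNeil standard errors, dichotomization rules, and the AUC-based
sample-size calculation used for study planning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "StepwiseModel",
    "RocResult",
    "mann_whitney",
    "partial_correlation",
    "stepwise_regression",
    "roc_auc",
    "dichotomize",
    "auc_sample_size",
    "hanley_mcneil_variance",
]


@dataclass
class StepwiseModel:
    """Result of stepwise multiple regression."""

    response: str
    included_predictors: list[str]
    coefficients: dict[str, float]
    partial_r: dict[str, float]
    p_values: dict[str, float]
    r_squared: float
    excluded: list[str]
    intercept: float = 0.0


@dataclass
class RocResult:
    """AUC with Hanley-McNeil SE and two-sided significance versus 0.5."""

    auc: float
    se: float
    p_vs_half: float
    threshold_definition: dict = field(default_factory=dict)
    negated: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC must be in [0, 1]")


# --------------------------------------------------------------------------
# group comparison
# --------------------------------------------------------------------------

def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact p for combined n <= 20 without ties; normal approximation with tie
    correction (and continuity correction) otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < combined.size
    method = "exact" if (combined.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# partial correlation
# --------------------------------------------------------------------------

def _residualize(v: np.ndarray, z: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones_like(z, dtype=float), z])
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ coef


def partial_correlation(x, y, covariate) -> tuple[float, float]:
    """Pearson correlation of x and y after removing the linear effect of a
    (possibly binary) covariate from both; p from t with n - 3 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(covariate, dtype=float)
    n = x.size
    if not (y.size == n == z.size) or n < 4:
        raise ValueError("need equal-length inputs with n >= 4")
    rx = _residualize(x, z)
    ry = _residualize(y, z)
    sx = float(rx @ rx)
    sy = float(ry @ ry)
    tol_x = 1e-12 * (float(x @ x) + 1.0)
    tol_y = 1e-12 * (float(y @ y) + 1.0)
    if sx <= tol_x or sy <= tol_y:
        raise ValueError("zero residual variance")
    r = float(rx @ ry) / math.sqrt(sx * sy)
    r = max(-1.0, min(1.0, r))
    df = n - 3
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * math.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)


# --------------------------------------------------------------------------
# stepwise multiple regression
# --------------------------------------------------------------------------

def _fit(response: np.ndarray, X: dict[str, np.ndarray], names: list[str]):
    design = sm.add_constant(
        np.column_stack([X[n] for n in names]) if names
        else np.empty((response.size, 0)))
    return sm.OLS(response, design).fit()


def stepwise_regression(response, candidates: dict,
                        p_enter: float = 0.05,
                        p_remove: float = 0.10,
                        response_name: str = "response") -> StepwiseModel:
    """Forward selection with backward elimination.

    A candidate enters when its partial F-test p-value (equivalently the
    t-test of its coefficient in the augmented model) is the smallest below
    ``p_enter``; included predictors are removed when their p-value exceeds
    ``p_remove``; iterate to a fixed point.  A candidate that is (near-)
    collinear with the included set is skipped with a warning.
    """
    y = np.asarray(response, dtype=float)
    X = {k: np.asarray(v, dtype=float) for k, v in candidates.items()}
    n = y.size
    if n <= len(X) + 2:
        raise ValueError("need n > number of candidates + 2")
    for k, v in X.items():
        if v.size != n:
            raise ValueError(f"candidate {k!r} has wrong length")

    included: list[str] = []
    skipped: set[str] = set()
    for _ in range(4 * len(X) + 4):
        changed = False
        # forward step
        best_name, best_p = None, p_enter
        for name in X:
            if name in included or name in skipped:
                continue
            if included:
                aux = _fit(X[name], X, included)
                if aux.rsquared > 1.0 - 1e-10:
                    warnings.warn(
                        f"candidate {name!r} is collinear with the included "
                        "set; skipped", RuntimeWarning, stacklevel=2)
                    skipped.add(name)
                    continue
            elif np.ptp(X[name]) == 0:
                skipped.add(name)
                continue
            res = _fit(y, X, included + [name])
            p = float(res.pvalues[-1])
            if p < best_p:
                best_name, best_p = name, p
        if best_name is not None:
            included.append(best_name)
            changed = True
        # backward step
        while included:
            res = _fit(y, X, included)
            ps = res.pvalues[1:]
            worst = int(np.argmax(ps))
            if float(ps[worst]) > p_remove:
                included.pop(worst)
                changed = True
            else:
                break
        if not changed:
            break

    res = _fit(y, X, included)
    df_resid = res.df_resid
    coefs, pvals, partial = {}, {}, {}
    for i, name in enumerate(included, start=1):
        t = float(res.tvalues[i])
        coefs[name] = float(res.params[i])
        pvals[name] = float(res.pvalues[i])
        partial[name] = t / math.sqrt(t * t + df_resid)
    return StepwiseModel(
        response=response_name,
        included_predictors=list(included),
        coefficients=coefs,
        partial_r=partial,
        p_values=pvals,
        r_squared=float(res.rsquared) if included else 0.0,
        excluded=[k for k in X if k not in included],
        intercept=float(res.params[0]),
    )


# --------------------------------------------------------------------------
# ROC analysis
# --------------------------------------------------------------------------

def hanley_mcneil_variance(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil variance of the empirical AUC."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    return (auc * (1.0 - auc)
            + (n_pos - 1) * (q1 - auc * auc)
            + (n_neg - 1) * (q2 - auc * auc)) / (n_pos * n_neg)


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> float:
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    v10 = np.array([np.mean((p > neg) + 0.5 * (p == neg)) for p in pos])
    v01 = np.array([np.mean((pos > n) + 0.5 * (pos == n)) for n in neg])
    return float(np.var(v10, ddof=1) / pos.size + np.var(v01, ddof=1) / neg.size)


def roc_auc(scores, labels, negate: bool = False,
            se_method: str = "hanley-mcneil",
            threshold_definition: dict | None = None) -> RocResult:
    """Rank-based AUC with tie correction, SE and two-sided p versus 0.5.

    ``negate=True`` reverses the score orientation (used for markers that
    decrease with the condition, such as the stiffening rate versus solid
    stress); the flag is recorded in the result.
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels, dtype=int)
    if set(np.unique(lab)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    n_pos = int(lab.sum())
    n_neg = int(lab.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both label classes must be present")
    if negate:
        s = -s
    ranks = stats.rankdata(s)
    auc = (float(ranks[lab == 1].sum()) - n_pos * (n_pos + 1) / 2.0) \
        / (n_pos * n_neg)
    if se_method == "hanley-mcneil":
        var = hanley_mcneil_variance(auc, n_pos, n_neg)
    elif se_method == "delong":
        var = _delong_variance(s, lab)
    else:
        raise ValueError(f"unknown se_method {se_method!r}")
    se = math.sqrt(max(var, 0.0))
    if se > 0:
        p = 2.0 * stats.norm.sf(abs(auc - 0.5) / se)
    else:
        p = 0.0 if auc != 0.5 else 1.0
    return RocResult(auc=auc, se=se, p_vs_half=float(p),
                     threshold_definition=threshold_definition or {},
                     negated=negate)


def dichotomize(values, cutoff: float, direction: str = "ge") -> np.ndarray:
    """Binary labels: positive when value >= cutoff (``ge``, default; the
    boundary value itself is positive) or <= cutoff (``le``)."""
    v = np.asarray(values, dtype=float)
    if not math.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    if direction == "ge":
        return (v >= cutoff).astype(int)
    if direction == "le":
        return (v <= cutoff).astype(int)
    raise ValueError(f"unknown direction {direction!r}")


# --------------------------------------------------------------------------
# AUC-based sample size
# --------------------------------------------------------------------------

def auc_sample_size(expected_auc: float,
                    null_auc: float = 0.5,
                    alpha: float = 0.05,
                    power: float = 0.80,
                    neg_pos_ratio: float = 1.0,
                    max_n_pos: int = 100000) -> int:
    """Smallest total n for a two-sided z-test of AUC against the null.

    The positive-group size is increased until the test of the expected AUC
    against ``null_auc``, with Hanley-McNeil variances under the null and the
    alternative and ``n_neg = ceil(ratio * n_pos)``, reaches the requested
    power; returns ``n_pos + n_neg``.
    """
    if not 0.5 <= null_auc < expected_auc < 1.0:
        raise ValueError(
            "need 0.5 <= null_auc < expected_auc < 1 (otherwise the "
            "required sample size is unbounded)")
    if not (0.0 < alpha < 1.0 and 0.0 < power < 1.0):
        raise ValueError("alpha and power must be in (0, 1)")
    if neg_pos_ratio <= 0:
        raise ValueError("neg_pos_ratio must be positive")
    z_alpha = stats.norm.ppf(1.0 - alpha / 2.0)
    delta = expected_auc - null_auc
    for n_pos in range(2, max_n_pos + 1):
        n_neg = int(math.ceil(neg_pos_ratio * n_pos))
        se0 = math.sqrt(hanley_mcneil_variance(null_auc, n_pos, n_neg))
        se1 = math.sqrt(hanley_mcneil_variance(expected_auc, n_pos, n_neg))
        achieved = stats.norm.cdf((delta - z_alpha * se0) / se1)
        if achieved >= power:
            return n_pos + n_neg
    raise RuntimeError("sample-size search did not converge")
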