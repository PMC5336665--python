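"""Agreement, predictive-value and ROC statistics for diagnostic systems.

Implements the evaluation machinery used to compare two binary diagnostic
systems (algorithm vs expert, or two nosologies used by the same expert):
2x2 cross-tabs, Cohen's kappa with a case-resampling bootstrap CI, overlap
percentages, per-criterion PPV/NPV, a criteria-based logistic ROC (all binary
criteria entered as equally weighted predictors; AUC by the rank /
Mann-Whitney estimator with tie correction), and per-domain group contrasts
with unequal-variance tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "CrossTab2x2",
    "AgreementStats",
    "RocResult",
    "PredictiveValues",
    "DegenerateTableError",
    "crosstab",
    "cohen_kappa",
    "kappa_bootstrap_ci",
    "criteria_logit_roc",
    "criterion_ppv_npv",
    "overlap_stats",
    "group_profile_contrast",
    "rank_auc",
]


class DegenerateTableError(ValueError):
    """Kappa is undefined because expected agreement equals 1."""


@dataclass(frozen=True)
class CrossTab2x2:
    """Counts by (reference system, comparison system): rows=ref, cols=cmp."""

    n_nn: int
    n_ny: int
    n_yn: int
    n_yy: int

    def __post_init__(self) -> None:
        if min(self.n_nn, self.n_ny, self.n_yn, self.n_yy) < 0:
            raise ValueError("counts must be nonnegative")
        if self.total == 0:
            raise ValueError("empty table")

    @property
    def total(self) -> int:
        return self.n_nn + self.n_ny + self.n_yn + self.n_yy

    @property
    def ref_positive(self) -> int:
        return self.n_yn + self.n_yy

    @property
    def cmp_positive(self) -> int:
        return self.n_ny + self.n_yy


def crosstab(labels_ref: Sequence[int], labels_cmp: Sequence[int]) -> CrossTab2x2:
    """Cross-tabulate two equal-length binary label sequences."""
    a = np.asarray(labels_ref, dtype=int)
    b = np.asarray(labels_cmp, dtype=int)
    if a.shape != b.shape:
        raise ValueError("label sequences differ in length")
    return CrossTab2x2(
        n_nn=int(np.sum((a == 0) & (b == 0))),
        n_ny=int(np.sum((a == 0) & (b == 1))),
        n_yn=int(np.sum((a == 1) & (b == 0))),
        n_yy=int(np.sum((a == 1) & (b == 1))),
    )


def cohen_kappa(ct: CrossTab2x2) -> float:
    """Chance-corrected agreement: kappa = (p_o - p_e) / (1 - p_e).

    Expected agreement p_e is the marginal product under independence.
    Raises :class:`DegenerateTableError` when p_e = 1 (both marginals
    concentrated in the same single cell), where kappa is undefined.
    """
    n = ct.total
    p_o = (ct.n_nn + ct.n_yy) / n
    row_yes = ct.ref_positive / n
    col_yes = ct.cmp_positive / n
    p_e = row_yes * col_yes + (1 - row_yes) * (1 - col_yes)
    if p_e == 1.0:
        raise DegenerateTableError("degenerate marginals: expected agreement is 1")
    return (p_o - p_e) / (1 - p_e)


@dataclass
class AgreementStats:
    kappa: float
    se: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    n_degenerate_skipped: int = 0


def kappa_bootstrap_ci(
    labels_ref: Sequence[int],
    labels_cmp: Sequence[int],
    n_boot: int = 1000,
    seed: int = 0,
) -> AgreementStats:
    """Kappa point estimate with a percentile 95% CI over case resamples.

    Resamples participants with replacement; a resample on which kappa is
    undefined (one marginal completely concentrated) is skipped and counted.
    Deterministic given (seed, n_boot); the bootstrap SD is reported as se.
    """
    a = np.asarray(labels_ref, dtype=int)
    b = np.asarray(labels_cmp, dtype=int)
    n = a.size
    if n < 2 or a.shape != b.shape:
        raise ValueError("need two equal-length sequences with n >= 2")
    point = cohen_kappa(crosstab(a, b))
    rng = np.random.default_rng(seed)
    boots: list[float] = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            boots.append(cohen_kappa(crosstab(a[idx], b[idx])))
        except DegenerateTableError:
            skipped += 1
    if boots:
        arr = np.asarray(boots)
        lo, hi = np.percentile(arr, [2.5, 97.5])
        se = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        lo = min(float(lo), point)
        hi = max(float(hi), point)
    else:
        lo = hi = point
        se = 0.0
    return AgreementStats(
        kappa=point,
        se=se,
        ci_low=lo,
        ci_high=hi,
        n_boot=n_boot,
        seed=seed,
        n_degenerate_skipped=skipped,
    )


def rank_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC by the rank (Mann-Whitney) estimator with average-rank ties."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("need both classes present to compute AUC")
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    coefficients: dict[str, float]
    penalized: bool = False
    dropped_columns: list[str] = field(default_factory=list)
    predicted: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)


def criteria_logit_roc(
    criteria_matrix: pd.DataFrame,
    expert_labels: Sequence[int],
    n_boot: int = 2000,
    seed: int = 0,
) -> RocResult:
    """Fit expert label on binary criteria; AUC of predicted probabilities.

    All criteria enter additively and unweighted a priori (coefficients are
    estimated by maximum likelihood); constant columns are dropped first. On
    perfect separation or non-convergence the fit falls back to an L2-
    penalized logistic regression and the result is flagged. The AUC CI is a
    percentile bootstrap over case resamples, deterministic given seed.
    """
    y = np.asarray(expert_labels, dtype=int)
    X = criteria_matrix.astype(float).copy()
    if len(X) != y.size:
        raise ValueError("criteria matrix and labels differ in length")
    dropped = [c for c in X.columns if X[c].nunique() <= 1]
    X = X.drop(columns=dropped)
    if X.shape[1] == 0:
        raise ValueError("no informative criterion columns remain")

    penalized = False
    coefs: dict[str, float]
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, sm.add_constant(X, has_constant="add")).fit(disp=0)
        if not np.all(np.isfinite(fit.params)) or not fit.mle_retvals.get(
            "converged", True
        ):
            raise np.linalg.LinAlgError("logit did not converge")
        probs = np.asarray(fit.predict())
        coefs = {c: float(fit.params[c]) for c in X.columns}
    except Exception:
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(C=1.0, max_iter=1000)
        lr.fit(X.values, y)
        probs = lr.predict_proba(X.values)[:, 1]
        coefs = {c: float(b) for c, b in zip(X.columns, lr.coef_[0])}
        penalized = True

    auc = rank_auc(probs, y)
    rng = np.random.default_rng(seed)
    boots = []
    n = y.size
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if yb.min() == yb.max():
            continue
        boots.append(rank_auc(probs[idx], yb))
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
        lo, hi = min(float(lo), auc), max(float(hi), auc)
    else:
        lo = hi = auc
    return RocResult(
        auc=auc,
        ci_low=lo,
        ci_high=hi,
        coefficients=coefs,
        penalized=penalized,
        dropped_columns=dropped,
        predicted=probs,
    )


@dataclass
class PredictiveValues:
    ppv: Optional[float]
    npv: Optional[float]
    tp: int
    fp: int
    fn: int
    tn: int


def criterion_ppv_npv(
    criterion_flags: Sequence[int], diagnosis_labels: Sequence[int]
) -> PredictiveValues:
    """PPV = TP/(TP+FP), NPV = TN/(TN+FN); empty denominators yield None."""
    c = np.asarray(criterion_flags, dtype=int)
    d = np.asarray(diagnosis_labels, dtype=int)
    if c.shape != d.shape:
        raise ValueError("sequences differ in length")
    tp = int(np.sum((c == 1) & (d == 1)))
    fp = int(np.sum((c == 1) & (d == 0)))
    fn = int(np.sum((c == 0) & (d == 1)))
    tn = int(np.sum((c == 0) & (d == 0)))
    ppv = tp / (tp + fp) if tp + fp > 0 else None
    npv = tn / (tn + fn) if tn + fn > 0 else None
    return PredictiveValues(ppv=ppv, npv=npv, tp=tp, fp=fp, fn=fn, tn=tn)


def overlap_stats(ct: CrossTab2x2) -> dict[str, float]:
    """Overlap of the comparison system with the reference system.

    pct_of_ref_captured: % of reference-positive cases also positive under
    the comparison system. pct_increase: % change in the positive count of
    the comparison system relative to the reference. n_additional: cases
    positive only under the comparison system.
    """
    if ct.ref_positive == 0:
        raise ValueError("no reference-positive cases")
    return {
        "pct_of_ref_captured": 100.0 * ct.n_yy / ct.ref_positive,
        "pct_increase": 100.0 * (ct.cmp_positive - ct.ref_positive) / ct.ref_positive,
        "n_additional": float(ct.n_ny),
    }


def group_profile_contrast(
    domain_scores: pd.DataFrame, group_labels: Sequence
) -> pd.DataFrame:
    """Per-domain mean difference between two groups with Welch's t test.

    ``domain_scores`` is participants x domains; ``group_labels`` must take
    exactly two values, each with at least two members. Returns one row per
    domain with group means, difference (group b - group a), t and p.
    """
    labels = pd.Series(list(group_labels), index=domain_scores.index)
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    ga, gb = groups
    rows = []
    for domain in domain_scores.columns:
        xa = domain_scores.loc[labels == ga, domain].dropna()
        xb = domain_scores.loc[labels == gb, domain].dropna()
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError(f"singleton group for domain {domain!r}")
        if xa.var(ddof=1) == 0 and xb.var(ddof=1) == 0:
            t, p = (np.inf if xa.mean() != xb.mean() else 0.0), (
                0.0 if xa.mean() != xb.mean() else 1.0
            )
        else:
            t, p = stats.ttest_ind(xb, xa, equal_var=False)
        rows.append(
            {
                "domain": domain,
                f"mean_{ga}": xa.mean(),
                f"mean_{gb}": xb.mean(),
                "difference": xb.mean() - xa.mean(),
                "t": float(t),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows).set_index("domain")
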