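"""Clinical statistics on qPCR Ct tables.

The cohort table carries one row per stool sample: a diagnosis class
(normal, CRC, AA, polyp, enteritis), per-marker cycle-threshold (Ct)
values with a sentinel for nondetected reactions, and an ACTB reference
Ct that gauges whether enough amplifiable human DNA was recovered.

The stage implements: the ACTB sufficiency QC rule, 2^-dCt relative
methylation levels, normality-gated group tests, ROC/AUC with a
Hanley-McNeil confidence interval and the Youden-index cutoff,
sensitivity/specificity with Clopper-Pearson intervals,
forward:conditional stepwise logistic panel models, OR-combination of
binary marker calls, Spearman marker correlation, and Ward hierarchical
clustering of samples.

ROC orientation is fixed to lower-Ct-is-positive: methylated template is
more abundant in cases, so its amplification crosses threshold earlier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.metrics import roc_curve
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.proportion import proportion_confint
import statsmodels.api as sm

__all__ = [
    "RocResult",
    "DiagnosticModel",
    "qc_filter",
    "relative_level",
    "group_difference_test",
    "roc_auc",
    "youden_cutoff",
    "sens_spec",
    "logistic_forward_conditional",
    "combine_or_rule",
    "marker_correlation",
    "cluster_samples",
]


# ---------------------------------------------------------------- QC ---


def qc_filter(cohort: pd.DataFrame, cutoff: float = 24.5) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop samples with insufficient human DNA (ACTB Ct > cutoff).

    The boundary is retained: exclusion is strictly greater than the
    cutoff.  Rows with a missing ACTB value are excluded with reason
    ``missing_reference``.  Returns (retained table, excluded table with
    a ``reason`` column).
    """
    if "ACTB_Ct" not in cohort.columns:
        raise ValueError("cohort has no ACTB_Ct column")
    actb = pd.to_numeric(cohort["ACTB_Ct"], errors="coerce")
    missing = actb.isna()
    high = actb > cutoff
    excluded = cohort[missing | high].copy()
    excluded["reason"] = np.where(missing[missing | high], "missing_reference", "insufficient_dna")
    return cohort[~(missing | high)].copy(), excluded


def relative_level(marker_ct: float, actb_ct: float) -> float:
    """Relative methylation level 2^-(Ct_marker - Ct_ACTB).

    Equal Cts give 1.0; each extra marker cycle halves the level.  A
    sentinel marker Ct yields the corresponding floor value rather than
    a missing result.
    """
    return float(2.0 ** (-(marker_ct - actb_ct)))


# --------------------------------------------------------- group test ---


def group_difference_test(
    values_by_group: Mapping[str, Sequence[float]],
    alpha_normality: float = 0.05,
) -> dict:
    """Two-group comparison gated on a normality pre-test.

    Both groups are screened with the Lilliefors variant of the
    Kolmogorov-Smirnov test (mean and sd estimated from the data).  If
    both pass at ``alpha_normality`` the two-tailed t-test runs;
    otherwise the two-sided Mann-Whitney U with tie correction.
    Constant groups cannot be normal-tested and fall through to
    Mann-Whitney.
    """
    if len(values_by_group) != 2:
        raise ValueError("exactly two groups required")
    (ga, xa), (gb, xb) = [(k, np.asarray(v, dtype=float)) for k, v in values_by_group.items()]
    if xa.size < 3 or xb.size < 3:
        raise ValueError("each group needs at least 3 observations")

    def _normal(x: np.ndarray) -> bool:
        if np.ptp(x) == 0:
            return False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = lilliefors(x, dist="norm")
        return p >= alpha_normality

    if _normal(xa) and _normal(xb):
        stat, p = stats.ttest_ind(xa, xb, equal_var=True)
        test = "t-test"
    else:
        stat, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        test = "mann-whitney"
    return {"test": test, "p_value": float(p), "statistic": float(stat), "groups": (ga, gb)}


# ---------------------------------------------------------------- ROC ---


@dataclass
class RocResult:
    """ROC on a Ct-valued marker; lower Ct scores as more positive."""

    auc: float
    ci: tuple
    points: pd.DataFrame  # ct_cutoff, sensitivity, specificity
    orientation: str = "lower_ct_positive"
    n_positive: int = 0
    n_negative: int = 0

    @property
    def youden_j(self) -> float:
        j = self.points["sensitivity"] + self.points["specificity"] - 1.0
        return float(j.max())


def _hanley_mcneil_ci(auc: float, n1: int, n2: int, level: float = 0.95) -> tuple:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n2 - 1) * (q2 - auc**2)) / (n1 * n2)
    se = np.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (float(max(0.0, auc - z * se)), float(min(1.0, auc + z * se)))


def roc_auc(
    cohort: pd.DataFrame,
    marker: str,
    positive_class: str = "CRC",
    negative_class: str = "normal",
) -> RocResult:
    """ROC of one marker's Ct for positive vs negative class.

    Scores are -Ct (so earlier amplification ranks higher); the AUC is
    the trapezoid area over all unique thresholds with the 95%
    Hanley-McNeil normal-approximation interval.
    """
    sub = cohort[cohort["class"].isin([positive_class, negative_class])]
    y = (sub["class"] == positive_class).to_numpy(int)
    n1, n2 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError(f"empty class among ({positive_class}, {negative_class})")
    score = -sub[marker].to_numpy(dtype=float)
    fpr, tpr, thr = roc_curve(y, score, drop_intermediate=False)
    points = pd.DataFrame(
        {"ct_cutoff": -thr, "sensitivity": tpr, "specificity": 1.0 - fpr}
    )
    # trapezoid over the full curve
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(
        auc=auc,
        ci=_hanley_mcneil_ci(auc, n1, n2),
        points=points,
        n_positive=n1,
        n_negative=n2,
    )


def youden_cutoff(roc: RocResult) -> dict:
    """Exhaustive-scan maximizer of J = sensitivity + specificity - 1.

    Ties break toward higher sensitivity (a screening assay prefers to
    miss fewer cases at equal J).
    """
    if roc.points.empty:
        raise ValueError("ROC has no operating points")
    pts = roc.points
    j = (pts["sensitivity"] + pts["specificity"] - 1.0).to_numpy()
    best = np.flatnonzero(j == j.max())
    sens = pts["sensitivity"].to_numpy()[best]
    pick = best[np.argmax(sens)]
    return {
        "cutoff": float(pts["ct_cutoff"].iloc[pick]),
        "youden_j": float(j[pick]),
        "sensitivity": float(pts["sensitivity"].iloc[pick]),
        "specificity": float(pts["specificity"].iloc[pick]),
    }


def sens_spec(
    predictions: Sequence,
    labels: Sequence,
    positive_class,
    level: float = 0.95,
) -> dict:
    """Sensitivity and specificity with Clopper-Pearson exact intervals.

    ``predictions`` and ``labels`` are aligned per-sample class calls.
    A side with a zero denominator is reported as ``None`` (undefined),
    never as 0.
    """
    pred = np.asarray(predictions)
    lab = np.asarray(labels)
    if pred.shape != lab.shape:
        raise ValueError("predictions and labels differ in length")
    pos = lab == positive_class
    tp = int(np.sum(pred[pos] == positive_class))
    fn = int(np.sum(pred[pos] != positive_class))
    tn = int(np.sum(pred[~pos] != positive_class))
    fp = int(np.sum(pred[~pos] == positive_class))
    alpha = 1.0 - level
    out: dict = {"tp": tp, "fn": fn, "tn": tn, "fp": fp, "ci_method": "clopper-pearson"}
    if tp + fn:
        lo, hi = proportion_confint(tp, tp + fn, alpha=alpha, method="beta")
        out["sensitivity"] = tp / (tp + fn)
        out["sensitivity_ci"] = (float(lo), float(hi))
    else:
        out["sensitivity"] = None
        out["sensitivity_ci"] = None
    if tn + fp:
        lo, hi = proportion_confint(tn, tn + fp, alpha=alpha, method="beta")
        out["specificity"] = tn / (tn + fp)
        out["specificity_ci"] = (float(lo), float(hi))
    else:
        out["specificity"] = None
        out["specificity_ci"] = None
    return out


# --------------------------------------------- forward: conditional ----


@dataclass
class DiagnosticModel:
    """Stepwise logistic panel: markers in entry order plus the fit."""

    markers: list
    coefficients: pd.Series  # includes "const"
    entry_pvalues: dict
    p_enter: float
    p_remove: float
    separation_flag: bool = False
    history: list = field(default_factory=list)

    def linear_score(self, X: pd.DataFrame) -> np.ndarray:
        Z = np.column_stack([np.ones(len(X)), X[self.markers].to_numpy(dtype=float)])
        return Z @ self.coefficients.loc[["const"] + self.markers].to_numpy()

    def predict(self, X: pd.DataFrame, score_cutoff: float = 0.0) -> np.ndarray:
        return (self.linear_score(X) > score_cutoff).astype(int)


def _design(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    if X.size == 0:
        return np.ones((len(y), 1))
    return np.column_stack([np.ones(len(y)), X])


def _fit_logit(y: np.ndarray, X: np.ndarray):
    """ML logistic fit; falls back to a small ridge under separation."""
    Z = _design(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Z).fit(disp=0, maxiter=200)
            if res.mle_retvals.get("converged", False) and np.all(np.abs(res.params) < 1e3):
                return np.asarray(res.params), float(res.llf), False
        except Exception:
            pass
    # ridge-stabilized fit (intercept unpenalized)
    from scipy.optimize import minimize

    lam = 1e-3

    def negll(beta):
        eta = Z @ beta
        ll = y @ eta - np.logaddexp(0.0, eta).sum()
        return -ll + 0.5 * lam * np.sum(beta[1:] ** 2)

    x0 = np.zeros(Z.shape[1])
    res = minimize(negll, x0, method="BFGS")
    beta = res.x
    eta = Z @ beta
    llf = float(y @ eta - np.logaddexp(0.0, eta).sum())
    return beta, llf, True


def _score_test(y: np.ndarray, Xcur: np.ndarray, xnew: np.ndarray) -> float:
    """Rao score test p-value for adding one column to a fitted logit."""
    beta, _, _ = _fit_logit(y, Xcur)
    Z = _design(y, Xcur)
    eta = Z @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    u = float(xnew @ (y - p))
    zw = Z * w[:, None]
    a = float(xnew @ (w * xnew))
    b = xnew @ zw
    try:
        c = np.linalg.solve(Z.T @ zw, b)
    except np.linalg.LinAlgError:
        return 1.0
    v = a - float(b @ c)
    if v <= 0:
        return 1.0
    return float(stats.chi2.sf(u * u / v, df=1))


def logistic_forward_conditional(
    cohort: pd.DataFrame,
    candidates: Sequence[str],
    positive_class: str = "CRC",
    negative_class: str = "normal",
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> DiagnosticModel:
    """Stepwise logistic regression, score-test entry / LR removal.

    At each step the candidate with the smallest score-test p-value
    enters if p < ``p_enter``; every included marker is then re-checked
    with a likelihood-ratio test against the model without it and
    removed if p > ``p_remove`` (the marker that just entered is exempt
    from immediate removal to guarantee termination).  With no
    informative candidate the model is intercept-only.  Perfect
    separation is handled with a small ridge stabilizer and flagged.
    """
    candidates = list(candidates)
    sub = cohort[cohort["class"].isin([positive_class, negative_class])]
    y = (sub["class"] == positive_class).to_numpy(int)
    X = sub[candidates].to_numpy(dtype=float)
    included: list = []
    history: list = []
    entry_p: dict = {}
    sep_flag = False
    while True:
        remaining = [c for c in candidates if c not in included]
        if not remaining:
            break
        Xcur = X[:, [candidates.index(c) for c in included]]
        pvals = {c: _score_test(y, Xcur, X[:, candidates.index(c)]) for c in remaining}
        best = min(pvals, key=pvals.get)
        if pvals[best] >= p_enter:
            break
        included.append(best)
        entry_p[best] = pvals[best]
        history.append({"step": len(history) + 1, "entered": best, "p": pvals[best]})
        # removal sweep (exempting the marker that just entered)
        changed = True
        while changed and len(included) > 1:
            changed = False
            Xin = X[:, [candidates.index(c) for c in included]]
            _, ll_full, f1 = _fit_logit(y, Xin)
            worst, worst_p = None, -1.0
            for c in included:
                if c == best:
                    continue
                rest = [d for d in included if d != c]
                Xr = X[:, [candidates.index(d) for d in rest]]
                _, ll_r, f2 = _fit_logit(y, Xr)
                sep_flag = sep_flag or f1 or f2
                lr = max(0.0, 2.0 * (ll_full - ll_r))
                p = float(stats.chi2.sf(lr, df=1))
                if p > worst_p:
                    worst, worst_p = c, p
            if worst is not None and worst_p > p_remove:
                included.remove(worst)
                history.append({"step": len(history) + 1, "removed": worst, "p": worst_p})
                changed = True
    Xin = X[:, [candidates.index(c) for c in included]]
    beta, _, flagged = _fit_logit(y, Xin)
    sep_flag = sep_flag or flagged
    names = ["const"] + included
    coef = pd.Series(beta, index=names)
    return DiagnosticModel(
        markers=included,
        coefficients=coef,
        entry_pvalues=entry_p,
        p_enter=p_enter,
        p_remove=p_remove,
        separation_flag=sep_flag,
        history=history,
    )


# ------------------------------------------------- combination rules ---


def combine_or_rule(calls_by_marker: Mapping[str, Sequence[bool]], markers: Sequence[str]) -> np.ndarray:
    """Per-sample OR over the listed markers' binary calls.

    The union call is at least as sensitive as any member and at most
    as specific as any member.
    """
    arrs = [np.asarray(calls_by_marker[m], dtype=bool) for m in markers]
    if not arrs:
        raise ValueError("no markers to combine")
    n = arrs[0].shape[0]
    if any(a.shape[0] != n for a in arrs):
        raise ValueError("marker call vectors are not aligned")
    return np.logical_or.reduce(arrs)


def marker_correlation(cohort: pd.DataFrame, markers: Sequence[str]) -> pd.DataFrame:
    """Spearman rank correlation on Ct values.

    Sentinel Cts enter as tied maxima, which rank correlation absorbs
    gracefully.  A constant marker has no rank ordering: its
    correlations are reported as 0 and flagged via the ``constant``
    attribute on the returned frame.
    """
    markers = list(markers)
    if len(cohort) < 3:
        raise ValueError("need at least 3 samples")
    X = cohort[markers].to_numpy(dtype=float)
    constant = [m for m, col in zip(markers, X.T) if np.ptp(col) == 0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(X).statistic if len(markers) > 2 else None
    out = pd.DataFrame(np.eye(len(markers)), index=markers, columns=markers)
    for i in range(len(markers)):
        for j in range(i + 1, len(markers)):
            if markers[i] in constant or markers[j] in constant:
                r = 0.0
            elif rho is not None:
                r = float(rho[i, j])
            else:
                r = float(stats.spearmanr(X[:, i], X[:, j]).statistic)
            out.iloc[i, j] = out.iloc[j, i] = r
    out.attrs["constant_markers"] = constant
    return out


def cluster_samples(data: pd.DataFrame, markers: Sequence[str]) -> dict:
    """Ward-linkage hierarchical clustering on z-scored marker values.

    Returns the merge tree (scipy linkage matrix), the deterministic
    leaf order, and a two-group cut of the top split.
    """
    markers = list(markers)
    X = data[markers].to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    linkage = hierarchy.linkage(pdist(Z, metric="euclidean"), method="ward")
    leaves = hierarchy.leaves_list(linkage)
    two = hierarchy.fcluster(linkage, t=2, criterion="maxclust")
    return {"linkage": linkage, "leaf_order": leaves, "two_group": two}
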