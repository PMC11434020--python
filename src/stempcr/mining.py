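"""CpG biomarker mining: prefilter, importance ranking, SVM wrapper.

The discovery procedure works on a two-class beta-value matrix:

1. two-sided two-sample t-test per site; keep p < alpha;
2. F-score importance (Chen-Lin feature-selection statistic) per
   surviving site,

       F = [(m+ - m)^2 + (m- - m)^2] / (s+^2 + s-^2)

   with m the grand mean, m+/m- the class means and s+^2/s-^2 the
   sample (n-1) variances; combined with genomic coordinates: each site's score is boosted
   multiplicatively by the number of other surviving sites within a
   window on the same chromosome (co-methylation tends to concentrate
   within ~1 kb, so clustered discriminative sites are preferred);
3. incremental wrapper selection: walk the ranked list, adding each
   site to a linear SVM panel; keep it only if repeated stratified
   cross-validated accuracy improves by more than ``epsilon``; sites
   that leave accuracy unchanged are labeled redundant, sites that
   lower it are noise;
4. held-out evaluation of the final panel on an independent matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .simulate import MethylationMatrix

__all__ = [
    "CrossValSpec",
    "SelectionResult",
    "ttest_filter",
    "f_score",
    "f_scores",
    "rank_sites",
    "incremental_svm_select",
    "evaluate_panel",
    "mine_sites",
]


@dataclass(frozen=True)
class CrossValSpec:
    """Repeated, subsampled, stratified k-fold CV (10 x 80% x 5-fold)."""

    n_repeats: int = 10
    n_folds: int = 5
    subsample_fraction: float = 0.80
    seed: int = 0

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must lie in (0, 1]")


@dataclass
class SelectionResult:
    """Outcome of the incremental wrapper selection."""

    candidates: pd.DataFrame  # site, p_value, f_score, adjusted_score (ranked order)
    panel: list = field(default_factory=list)  # in addition order
    trace: list = field(default_factory=list)  # per-candidate dicts
    rejected: dict = field(default_factory=dict)  # site -> "noise" | "redundant"
    cv_accuracy: float = float("nan")  # of the final panel
    warning: str | None = None

    def accuracy_trace(self) -> list:
        return [t["cv_accuracy"] for t in self.trace if t["action"] == "accepted"]

    def to_dict(self) -> dict:
        return {
            "panel": list(self.panel),
            "cv_accuracy": self.cv_accuracy,
            "candidates": self.candidates.to_dict(orient="records"),
            "trace": self.trace,
            "rejected": self.rejected,
            "warning": self.warning,
        }


def _two_class_arrays(matrix: MethylationMatrix):
    classes = matrix.classes
    if len(classes) != 2:
        raise ValueError(f"mining needs exactly two classes, got {classes}")
    pos, neg = classes[0], classes[1]
    mask = (matrix.labels == pos).to_numpy()
    return mask, pos, neg


def ttest_filter(matrix: MethylationMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Sites with two-sided two-sample t-test p < alpha.

    A site with zero variance in both classes carries no mean-difference
    evidence and is reported with p = 1 rather than raising.
    Returns a DataFrame indexed by site id with a ``p_value`` column,
    ordered by ascending p.
    """
    mask, _, _ = _two_class_arrays(matrix)
    X = matrix.betas.to_numpy()
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("each class needs at least 2 samples")
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(X[mask], X[~mask], axis=0, equal_var=True)
    pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    out = pd.DataFrame({"p_value": pvals}, index=matrix.betas.columns)
    out = out[out["p_value"] < alpha]
    return out.sort_values("p_value")


def _f_score_arrays(xpos: np.ndarray, xneg: np.ndarray) -> float:
    m = np.mean(np.concatenate([xpos, xneg]))
    mp, mn = xpos.mean(), xneg.mean()
    num = (mp - m) ** 2 + (mn - m) ** 2
    den = xpos.var(ddof=1) + xneg.var(ddof=1)
    if den == 0.0:
        return float("inf") if num > 0 else 0.0
    return float(num / den)


def f_score(matrix: MethylationMatrix, site_id: str) -> float:
    """Chen-Lin F-score of one site (class separation over within-class spread)."""
    mask, _, _ = _two_class_arrays(matrix)
    x = matrix.betas[site_id].to_numpy()
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("each class needs at least 2 samples")
    return _f_score_arrays(x[mask], x[~mask])


def f_scores(matrix: MethylationMatrix, sites: Sequence[str] | None = None) -> pd.Series:
    sites = list(matrix.betas.columns) if sites is None else list(sites)
    return pd.Series({s: f_score(matrix, s) for s in sites}, name="f_score")


def rank_sites(
    scores: pd.Series,
    coords: pd.DataFrame,
    window: int = 1000,
    cluster_bonus: float = 0.1,
) -> pd.DataFrame:
    """Order sites by F-score boosted for local clustering.

    adjusted = F * (1 + cluster_bonus * k), with k the number of other
    scored sites within ``window`` bp on the same chromosome.  Ties
    break by descending adjusted score, then chromosome string, then
    ascending position, so the ordering is fully deterministic.
    ``cluster_bonus = 0`` recovers the pure F-score ranking.
    """
    missing = set(scores.index) - set(coords.index)
    if missing:
        raise ValueError(f"sites without coordinates: {sorted(missing)[:5]}")
    sub = coords.loc[scores.index]
    k = np.zeros(len(scores), dtype=int)
    chroms = sub["chrom"].to_numpy()
    pos = sub["pos"].to_numpy()
    for i in range(len(scores)):
        k[i] = np.sum((chroms == chroms[i]) & (np.abs(pos - pos[i]) <= window)) - 1
    out = pd.DataFrame(
        {
            "f_score": scores.to_numpy(dtype=float),
            "neighbors": k,
            "adjusted_score": scores.to_numpy(dtype=float) * (1.0 + cluster_bonus * k),
            "chrom": chroms,
            "pos": pos,
        },
        index=scores.index,
    )
    out = out.sort_values(
        ["adjusted_score", "chrom", "pos"], ascending=[False, True, True], kind="mergesort"
    )
    out.index.name = "site"
    return out


def _make_svm():
    return make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))


def _cv_splits(y: np.ndarray, cv: CrossValSpec):
    """Seeded subsample-then-stratified-kfold index pairs."""
    rng = np.random.default_rng(cv.seed)
    classes = np.unique(y)
    for _ in range(cv.n_repeats):
        keep = []
        for c in classes:
            idx = np.flatnonzero(y == c)
            n_keep = max(cv.n_folds, int(round(cv.subsample_fraction * idx.size)))
            n_keep = min(n_keep, idx.size)
            keep.append(rng.choice(idx, size=n_keep, replace=False))
        keep = np.concatenate(keep)
        # stratified folds: deal each class round-robin after a shuffle
        folds = [[] for _ in range(cv.n_folds)]
        for c in classes:
            cidx = rng.permutation(keep[y[keep] == c])
            for j, s in enumerate(cidx):
                folds[j % cv.n_folds].append(s)
        for j in range(cv.n_folds):
            test = np.array(folds[j])
            train = np.concatenate([folds[m] for m in range(cv.n_folds) if m != j])
            yield train, test


def _cv_accuracy(X: np.ndarray | None, y: np.ndarray, cv: CrossValSpec) -> float:
    """Mean held-out accuracy; an empty panel predicts the train majority."""
    accs = []
    for train, test in _cv_splits(y, cv):
        if X is None or X.shape[1] == 0:
            vals, counts = np.unique(y[train], return_counts=True)
            pred = np.full(test.size, vals[np.argmax(counts)])
        else:
            clf = _make_svm()
            clf.fit(X[train], y[train])
            pred = clf.predict(X[test])
        accs.append(np.mean(pred == y[test]))
    return float(np.mean(accs))


def incremental_svm_select(
    matrix: MethylationMatrix,
    ranked: Sequence[str],
    cv: CrossValSpec = CrossValSpec(),
    epsilon: float = 0.005,
) -> SelectionResult:
    """Forward wrapper selection over a ranked candidate list.

    Each candidate joins the panel only if the repeated-CV accuracy of
    panel + candidate exceeds the current panel's by more than
    ``epsilon``; a change within ``epsilon`` labels it redundant and a
    larger drop labels it noise.  The accepted-step accuracy trace is
    non-decreasing by construction.  If nothing is accepted and even the
    best single site performs at chance, the best single site is
    returned with a warning flag.
    """
    if len(ranked) == 0:
        raise ValueError("ranked candidate list is empty")
    y = matrix.labels.to_numpy()
    panel: list = []
    trace: list = []
    rejected: dict = {}
    current = _cv_accuracy(None, y, cv)
    singles: dict = {}
    for site in ranked:
        X = matrix.betas[panel + [site]].to_numpy()
        acc = _cv_accuracy(X, y, cv)
        if not panel:
            singles[site] = acc
        delta = acc - current
        if delta > epsilon:
            panel.append(site)
            current = acc
            action = "accepted"
        elif abs(delta) <= epsilon:
            rejected[site] = "redundant"
            action = "redundant"
        else:
            rejected[site] = "noise"
            action = "noise"
        trace.append({"site": site, "action": action, "cv_accuracy": acc, "delta": delta})
    warning = None
    if not panel:
        best = max(singles, key=singles.get)
        panel = [best]
        current = singles[best]
        if current <= 0.5 + epsilon:
            warning = "no_informative_site"
        else:
            warning = "fallback_single_site"
    candidates = pd.DataFrame({"site": list(ranked)}).set_index("site")
    return SelectionResult(
        candidates=candidates, panel=panel, trace=trace, rejected=rejected,
        cv_accuracy=current, warning=warning,
    )


def evaluate_panel(
    train: MethylationMatrix,
    test: MethylationMatrix,
    panel: Sequence[str],
) -> dict:
    """Fit the panel SVM on the full training set, score it held-out.

    Returns accuracy at the decision boundary and the AUC of the signed
    decision score, on both the training (resubstitution) and test sets.
    """
    panel = list(panel)
    for name, m in (("train", train), ("test", test)):
        missing = [s for s in panel if s not in m.betas.columns]
        if missing:
            raise ValueError(f"panel site {missing[0]!r} missing from {name} matrix")
    ytr = train.labels.to_numpy()
    yte = test.labels.to_numpy()
    clf = _make_svm()
    clf.fit(train.betas[panel].to_numpy(), ytr)
    pos_label = clf.classes_[1]
    out = {}
    for name, X, y in (
        ("train", train.betas[panel].to_numpy(), ytr),
        ("test", test.betas[panel].to_numpy(), yte),
    ):
        pred = clf.predict(X)
        score = clf.decision_function(X)
        out[f"{name}_accuracy"] = float(np.mean(pred == y))
        out[f"{name}_auc"] = float(roc_auc_score((y == pos_label).astype(int), score))
    out["accuracy"] = out["test_accuracy"]
    out["auc"] = out["test_auc"]
    return out


def mine_sites(
    matrix: MethylationMatrix,
    alpha: float = 0.05,
    window: int = 1000,
    cluster_bonus: float = 0.1,
    cv: CrossValSpec = CrossValSpec(),
    epsilon: float = 0.005,
) -> SelectionResult:
    """Full discovery pipeline: t-test filter -> F-score + coordinate
    ranking -> incremental SVM selection.  The final panel is always a
    subset of the t-test survivors."""
    survivors = ttest_filter(matrix, alpha)
    if survivors.empty:
        raise ValueError("no site passes the t-test prefilter")
    scores = f_scores(matrix, survivors.index)
    ranked = rank_sites(scores, matrix.coords, window=window, cluster_bonus=cluster_bonus)
    result = incremental_svm_select(matrix, list(ranked.index), cv=cv, epsilon=epsilon)
    cand = ranked.join(survivors)
    result.candidates = cand
    return result
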