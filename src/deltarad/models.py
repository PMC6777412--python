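"""Recurrence prediction on small serial-imaging cohorts.

Three analyses over a patients x features table with 0/1 recurrence
labels (1 = recurrence):

* a univariate screen — per feature, the nonparametric (Mann-Whitney) AUC
  and a Wilcoxon rank-sum p-value, exact by enumeration for small cohorts;
* greedy forward multivariate logistic regression, adding at each step the
  feature with the smallest likelihood-ratio-test p-value and stopping at
  a significance threshold, with a small ridge penalty so perfectly
  separating features keep finite coefficients;
* a naive Bayes classifier whose class-conditional feature densities are
  Gaussian kernel density estimates rather than single Gaussians, scored
  by leave-one-out cross-validation (LOOCV) and wrapped in a greedy
  feature-set search.

Missing cells are handled by pairwise deletion: each statistic uses the
patients observed for the features it involves.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.special import logsumexp
from sklearn.linear_model import LogisticRegression

#: Ridge strength (sklearn C, inverse regularization) for logistic fits.
#: Large enough to leave ordinary fits untouched, small enough to keep
#: coefficients finite under complete separation.
LOGISTIC_C = 1000.0

EXACT_WILCOXON_MAX_N = 25


# ---------------------------------------------------------------------------
# Nonparametric univariate statistics


def auc_mann_whitney(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC = P(pos > neg) + 0.5 P(pos = neg) over all pairs."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    pos = pos[~np.isnan(pos)]
    neg = neg[~np.isnan(neg)]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be non-empty")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (pos.size * neg.size))


def _rank_sum_exact_p(scores: np.ndarray, m: int, observed: float) -> float:
    """Exact two-sided p for the rank sum of m of len(scores) mid-ranks.

    Mid-ranks are multiples of 1/2, so doubling them gives integers; the
    exact null distribution of the doubled rank sum over all C(n, m) group
    assignments comes from a subset-sum dynamic program (number of
    m-subsets attaining each sum).
    """
    scores2 = np.rint(2 * scores).astype(np.int64)
    total = int(scores2.sum())
    # dp[k, s] = number of k-subsets with doubled-rank sum s
    dp = np.zeros((m + 1, total + 1), dtype=float)
    dp[0, 0] = 1.0
    for sc in scores2:
        dp[1:, sc:] += dp[:-1, : total + 1 - sc]
    n_subsets = dp[m].sum()
    w2 = int(np.rint(2 * observed))
    p_le = dp[m, : w2 + 1].sum() / n_subsets
    p_ge = dp[m, w2:].sum() / n_subsets
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_rank_sum(pos: np.ndarray, neg: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact permutation distribution (mid-ranks for ties) when the combined
    sample has at most 25 observations, normal approximation with tie and
    continuity correction otherwise.  All-equal data gives p = 1.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    pos = pos[~np.isnan(pos)]
    neg = neg[~np.isnan(neg)]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([pos, neg])
    if np.all(combined == combined[0]):
        return 1.0
    ranks = stats.rankdata(combined)  # mid-ranks
    w = float(ranks[: pos.size].sum())
    if combined.size <= EXACT_WILCOXON_MAX_N:
        return _rank_sum_exact_p(ranks, pos.size, w)
    res = stats.mannwhitneyu(pos, neg, alternative="two-sided",
                             method="asymptotic")
    return float(res.pvalue)


@dataclass
class UnivariateResult:
    feature: str
    association: str  # '+': larger value -> more likely recurrent
    auc: float
    p_value: float
    n_pos: int
    n_neg: int
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value <= self.alpha


def univariate_screen(table: pd.DataFrame, labels: pd.Series,
                      alpha: float = 0.05) -> list[UnivariateResult]:
    """Per-feature AUC + rank-sum p, sorted by (p, then larger AUC).

    Pairwise deletion of missing cells; zero-variance features are skipped
    with a warning.  ``significant`` marks p <= alpha.
    """
    labels = labels.loc[table.index]
    if labels.nunique() != 2 or (labels == 1).sum() < 2 or (labels == 0).sum() < 2:
        raise ValueError("univariate screen needs >= 2 patients per class")
    results = []
    for col in table.columns:
        x = table[col]
        ok = x.notna()
        pos = x[ok & (labels == 1)].to_numpy(float)
        neg = x[ok & (labels == 0)].to_numpy(float)
        if pos.size == 0 or neg.size == 0:
            warnings.warn(f"{col}: one class fully missing, skipped", stacklevel=2)
            continue
        both = np.concatenate([pos, neg])
        if np.all(both == both[0]):
            warnings.warn(f"{col}: zero variance, skipped", stacklevel=2)
            continue
        auc = auc_mann_whitney(pos, neg)
        p = wilcoxon_rank_sum(pos, neg)
        sign = "+" if pos.mean() > neg.mean() else "-"
        results.append(UnivariateResult(str(col), sign, auc, p,
                                        pos.size, neg.size, alpha))
    results.sort(key=lambda r: (r.p_value, -r.auc, r.feature))
    return results


def screen_to_frame(results: list[UnivariateResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "feature": r.feature, "association": r.association, "auc": r.auc,
        "p_value": r.p_value, "n_pos": r.n_pos, "n_neg": r.n_neg,
    } for r in results])


# ---------------------------------------------------------------------------
# Penalized multivariate logistic regression + forward selection


@dataclass
class LogisticFit:
    features: list[str]
    coef: np.ndarray           # on standardized features
    intercept: float
    probabilities: pd.Series   # in-sample P(recurrence)
    log_likelihood: float
    auc: float
    dropped: list[str] = field(default_factory=list)


def _drop_collinear(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    if X.shape[1] <= 1:
        return X, names, []
    _, r, piv = linalg.qr(X - X.mean(axis=0), mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps * 1e3 if diag.size else 0
    keep_idx = sorted(piv[i] for i in range(len(diag)) if diag[i] > tol)
    dropped = [names[i] for i in range(len(names)) if i not in keep_idx]
    if dropped:
        warnings.warn(f"dropping collinear columns: {dropped}", stacklevel=3)
    return X[:, keep_idx], [names[i] for i in keep_idx], dropped


def fit_logistic(X: pd.DataFrame, y: pd.Series) -> LogisticFit:
    """Ridge-stabilized maximum-likelihood logistic regression.

    Features are standardized internally; the small penalty keeps
    coefficients finite under complete separation.  Rows with missing
    cells are dropped; collinear columns are dropped with a warning.
    """
    X = pd.DataFrame(X)
    ok = X.notna().all(axis=1)
    X = X.loc[ok]
    y_arr = pd.Series(y).loc[X.index].to_numpy(int)
    names = [str(c) for c in X.columns]
    mat = X.to_numpy(float)
    dropped: list[str] = []
    if mat.shape[1] > 0:
        mat, names, dropped = _drop_collinear(mat, names)
    if mat.shape[1] == 0:
        p0 = y_arr.mean() if len(y_arr) else 0.5
        probs = np.full(len(y_arr), p0 if 0 < p0 < 1 else 0.5)
        ll = float(np.sum(y_arr * np.log(probs) + (1 - y_arr) * np.log1p(-probs)))
        return LogisticFit([], np.zeros(0), float(np.log(probs[0] / (1 - probs[0]))),
                           pd.Series(probs, index=X.index), ll, 0.5, dropped)
    mu = mat.mean(axis=0)
    sd = mat.std(axis=0)
    sd[sd == 0] = 1.0
    z = (mat - mu) / sd
    clf = LogisticRegression(C=LOGISTIC_C, max_iter=5000, tol=1e-8,
                             solver="newton-cg")
    clf.fit(z, y_arr)
    probs = clf.predict_proba(z)[:, 1]
    eps = 1e-300
    ll = float(np.sum(y_arr * np.log(probs + eps)
                      + (1 - y_arr) * np.log(1 - probs + eps)))
    auc = auc_mann_whitney(probs[y_arr == 1], probs[y_arr == 0])
    return LogisticFit(names, clf.coef_[0].copy(), float(clf.intercept_[0]),
                       pd.Series(probs, index=X.index), ll, auc, dropped)


def point_biserial_corr(feature: pd.Series | np.ndarray,
                        labels: pd.Series | np.ndarray) -> float:
    """Pearson correlation between a feature and the 0/1 label."""
    x = np.asarray(feature, dtype=float)
    y = np.asarray(labels, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class SelectionResult:
    features: list[str]                 # in order of selection
    correlations: dict[str, float]      # point-biserial r per feature
    auc: float                          # in-sample AUC of the final model
    p_values: list[float]               # LRT p at each accepted step
    model: LogisticFit | None


def forward_select(table: pd.DataFrame, labels: pd.Series,
                   alpha: float = 0.05,
                   candidates: list[str] | None = None) -> SelectionResult:
    """Greedy forward logistic selection with likelihood-ratio stopping.

    At each step the candidate whose addition gives the smallest LRT
    p-value (chi-square, 1 df) against the current model joins the set;
    selection stops when the best p exceeds ``alpha``.  Each comparison is
    computed on the rows complete for the features involved.
    """
    labels = pd.Series(labels).loc[table.index]
    cand = [str(c) for c in (candidates if candidates is not None
                             else table.columns)]
    selected: list[str] = []
    p_trace: list[float] = []
    while cand:
        best: tuple[float, str, LogisticFit] | None = None
        for c in cand:
            cols = selected + [c]
            sub = table[cols].dropna()
            if sub.empty or labels.loc[sub.index].nunique() < 2:
                continue
            fit_new = fit_logistic(sub, labels)
            if c not in fit_new.features:
                continue  # collinear with the current set
            fit_cur = fit_logistic(sub[selected], labels.loc[sub.index])
            lrt = max(0.0, 2.0 * (fit_new.log_likelihood - fit_cur.log_likelihood))
            p = float(stats.chi2.sf(lrt, df=1))
            if best is None or p < best[0] - 1e-12 or (
                    abs(p - best[0]) <= 1e-12 and c < best[1]):
                best = (p, c, fit_new)
        if best is None or best[0] > alpha:
            break
        p_trace.append(best[0])
        selected.append(best[1])
        cand.remove(best[1])
    if not selected:
        return SelectionResult([], {}, 0.5, [], None)
    final = fit_logistic(table[selected].dropna(), labels)
    corrs = {c: point_biserial_corr(table[c], labels) for c in selected}
    return SelectionResult(selected, corrs, final.auc, p_trace, final)


# ---------------------------------------------------------------------------
# Kernel-density naive Bayes with LOOCV


@dataclass
class Kde1D:
    """Gaussian-kernel density on one feature of one class.

    Bandwidth by Silverman's rule h = 0.9 min(sd, IQR/1.34) n^(-1/5),
    floored at 1e-3 of the data range so a degenerate sample still yields
    a proper (narrow) density.
    """

    points: np.ndarray
    bandwidth: float

    def logpdf(self, x: float | np.ndarray) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        z = (x[:, None] - self.points[None, :]) / self.bandwidth
        log_k = -0.5 * z**2 - 0.5 * np.log(2 * np.pi) - np.log(self.bandwidth)
        return logsumexp(log_k, axis=1) - np.log(self.points.size)

    def pdf(self, x: float | np.ndarray) -> np.ndarray:
        return np.exp(self.logpdf(x))


def kde_fit(values: np.ndarray) -> Kde1D:
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("kde_fit needs at least one value")
    if v.size == 1:
        warnings.warn("single training value: degenerate narrow kernel",
                      stacklevel=2)
    sd = v.std(ddof=1) if v.size > 1 else 0.0
    iqr = np.subtract(*np.percentile(v, [75, 25]))
    spread = min(x for x in (sd, iqr / 1.34) if x > 0) if (sd > 0 or iqr > 0) \
        else 0.0
    data_range = float(v.max() - v.min())
    floor = 1e-3 * (data_range + 1e-9)
    h = max(0.9 * spread * v.size ** (-1 / 5), floor) if spread > 0 else max(floor, 1e-9)
    return Kde1D(v, float(h))


@dataclass
class KdeNaiveBayesModel:
    """Per-class priors and per-feature 1D KDEs (independent features)."""

    features: list[str]
    priors: dict[int, float]
    densities: dict[int, dict[str, Kde1D]]

    @classmethod
    def fit(cls, X: pd.DataFrame, y: pd.Series) -> "KdeNaiveBayesModel":
        X = pd.DataFrame(X).dropna()
        y = pd.Series(y).loc[X.index].astype(int)
        classes = sorted(y.unique())
        if len(classes) != 2:
            raise ValueError("need both classes in the training data")
        priors = {c: float((y == c).mean()) for c in classes}
        densities = {
            c: {str(f): kde_fit(X.loc[y == c, f].to_numpy(float))
                for f in X.columns}
            for c in classes
        }
        return cls([str(f) for f in X.columns], priors, densities)

    def posterior(self, x: pd.Series | dict | np.ndarray) -> float:
        """p(C = 1 | X = x), computed in log space.

        If the data likelihood underflows to zero in both classes the
        posterior falls back to the priors, with a warning.
        """
        if isinstance(x, (pd.Series, dict)):
            vec = np.array([float(x[f]) for f in self.features])
        else:
            vec = np.asarray(x, dtype=float)
            if vec.shape != (len(self.features),):
                raise ValueError("feature vector length mismatch")
        logs = {}
        for c, prior in self.priors.items():
            lp = np.log(prior) if prior > 0 else -np.inf
            for f, xi in zip(self.features, vec):
                lp += float(self.densities[c][f].logpdf(xi)[0])
            logs[c] = lp
        vals = np.array([logs[c] for c in sorted(logs)])
        if not np.any(np.isfinite(vals)):
            warnings.warn("zero density under both classes: falling back to "
                          "priors", stacklevel=2)
            return self.priors[1]
        norm = logsumexp(vals)
        return float(np.exp(logs[1] - norm))


def nb_posterior(x, model: KdeNaiveBayesModel) -> float:
    return model.posterior(x)


def loocv_evaluate(table: pd.DataFrame, labels: pd.Series,
                   feature_set: list[str]) -> float:
    """Pooled leave-one-out AUC of the KDE naive Bayes on a feature set.

    Each patient is scored by a model trained on all others; held-out
    posteriors are pooled into a single ROC.  Folds whose training set
    loses an entire class are skipped with a warning.
    """
    if not feature_set:
        raise ValueError("feature_set must not be empty")
    sub = table[list(feature_set)].dropna()
    y = pd.Series(labels).loc[sub.index].astype(int)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("LOOCV needs >= 2 patients per class")
    scores, truth = [], []
    for pid in sub.index:
        train = sub.drop(index=pid)
        y_train = y.drop(index=pid)
        if y_train.nunique() < 2:
            warnings.warn(f"fold {pid}: training set lost a class, skipped",
                          stacklevel=2)
            continue
        model = KdeNaiveBayesModel.fit(train, y_train)
        scores.append(model.posterior(sub.loc[pid]))
        truth.append(int(y.loc[pid]))
    scores_arr = np.asarray(scores)
    truth_arr = np.asarray(truth)
    return auc_mann_whitney(scores_arr[truth_arr == 1], scores_arr[truth_arr == 0])


@dataclass
class NbSearchResult:
    features: list[str]
    auc: float
    trace: list[tuple[tuple[str, ...], float]]


def nb_feature_search(table: pd.DataFrame, labels: pd.Series,
                      max_set_size: int = 3,
                      candidates: list[str] | None = None) -> NbSearchResult:
    """Greedy forward search maximizing the LOOCV AUC.

    Ties prefer the smaller set, then the lexicographically smaller
    feature name; the search stops when adding a feature no longer
    improves the AUC or the set reaches ``max_set_size``.
    """
    cand = sorted(str(c) for c in (candidates if candidates is not None
                                   else table.columns))
    selected: list[str] = []
    best_auc = -np.inf
    trace: list[tuple[tuple[str, ...], float]] = []
    while len(selected) < max_set_size and cand:
        step_best: tuple[float, str] | None = None
        for c in cand:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("once")  # tame repeated fold warnings
                    auc = loocv_evaluate(table, labels, selected + [c])
            except ValueError:
                continue
            if step_best is None or auc > step_best[0] + 1e-12:
                step_best = (auc, c)
        if step_best is None:
            break
        auc, c = step_best
        trace.append((tuple(selected + [c]), auc))
        if auc <= best_auc + 1e-12:
            break  # no improvement: keep the smaller set
        best_auc = auc
        selected.append(c)
        cand.remove(c)
    if not selected:
        raise ValueError("no scoreable feature set found")
    return NbSearchResult(selected, float(best_auc), trace)
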