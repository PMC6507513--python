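"""Model development: LOO-repeated stepwise logistic feature selection,
frequency ranking, classifier training and leave-one-out evaluation.

The development procedure is:

1. run bidirectional stepwise logistic regression n times, once per
   leave-one-subject-out subset, and count how often each feature is
   retained (its *selection frequency*);
2. keep the features selected in at least ``min_iterations`` of the n runs;
3. evaluate that fixed feature set with leave-one-out cross-validation of a
   linear classifier (logistic regression, linear SVM, or LDA), reporting
   accuracy / sensitivity / specificity with Responder as the positive
   class;
4. compare the achieved accuracy against chance with an exact one-sided
   binomial test.

Steps 2-3 reuse all subjects in the frequency ranking; an optional fully
nested mode redoes the selection inside every cross-validation training fold
for a leakage-free error estimate.

Stepwise selection itself uses likelihood-ratio tests on hand-rolled
Newton-IRLS logistic fits (batched over candidate features for speed):
repeatedly add the candidate with the smallest LR p-value below ``p_enter``,
then drop any retained feature whose removal p-value exceeds ``p_remove``,
until a fixpoint or the model-size cap. Ties break toward the lower column
index. Steps that separate perfectly fall back to a ridge-penalized fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import NONRESPONDER, RESPONDER
from .features import FeatureMatrix

logger = logging.getLogger(__name__)

_SEPARATION_COEF = 30.0  # |beta| beyond this on standardized X means separation
_RIDGE_FALLBACK = 1e-2


# ---------------------------------------------------------------------------
# fast logistic fits


def _fit_logistic_batch(
    X: np.ndarray, y: np.ndarray, beta0: np.ndarray, ridge: float = 0.0,
    max_iter: int = 40, tol: float = 1e-7,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Newton-IRLS fits of logistic models, batched over a leading axis.

    ``X`` is (m, n, k) — m candidate design matrices (intercept included),
    ``beta0`` is (m, k). Returns (beta, loglik, converged); loglik is the
    ridge-penalized log-likelihood when ridge > 0 (intercept unpenalized).
    """
    m, n, k = X.shape
    beta = beta0.copy()
    pen = np.zeros(k)
    if ridge > 0:
        pen[1:] = ridge
    converged = np.zeros(m, dtype=bool)
    eye = np.eye(k)
    Xt = np.ascontiguousarray(X.transpose(0, 2, 1))  # (m, k, n)
    for _ in range(max_iter):
        eta = (X @ beta[..., None])[..., 0]
        eta = np.clip(eta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu) + 1e-12
        grad = (Xt @ (y[None, :] - mu)[..., None])[..., 0] - pen * beta
        hess = (Xt * w[:, None, :]) @ X + np.diag(pen)
        rhs = grad[..., None]
        try:
            step = np.linalg.solve(hess + 1e-10 * eye, rhs)[..., 0]
        except np.linalg.LinAlgError:
            step = np.linalg.solve(hess + 1e-6 * eye, rhs)[..., 0]
        beta = beta + step
        gnorm = np.abs(grad).max(axis=1)
        converged = gnorm < tol
        if converged.all():
            break
    eta = np.clip((X @ beta[..., None])[..., 0], -35, 35)
    ll = np.sum(y[None, :] * eta - np.log1p(np.exp(eta)), axis=1)
    ll = ll - 0.5 * np.sum(pen * beta**2, axis=1)
    big = np.abs(beta).max(axis=1) > _SEPARATION_COEF
    converged = converged & ~big
    return beta, ll, converged


def _fit_logistic(X, y, ridge=0.0):
    """Single logistic fit; X is (n, k) with intercept column included."""
    X3 = X[None, :, :]
    beta0 = np.zeros((1, X.shape[1]))
    beta, ll, conv = _fit_logistic_batch(X3, y, beta0, ridge=ridge)
    return beta[0], float(ll[0]), bool(conv[0])


def _lr_pvalues(ll_alt: np.ndarray, ll_null: float) -> np.ndarray:
    stat = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    return sps.chi2.sf(stat, df=1)


# ---------------------------------------------------------------------------
# stepwise selection


def _as_xy(features, labels):
    if isinstance(features, FeatureMatrix):
        X = features.to_array()
        sids = features.subject_ids
        y = np.array([1 if labels[s] == RESPONDER else 0 for s in sids], float)
    else:
        X = np.asarray(features, dtype=float)
        y = np.asarray(labels, dtype=float)
    return X, y


def stepwise_logistic_select(
    features,
    labels,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_features: int | None = None,
) -> list[int]:
    """Bidirectional stepwise logistic selection; returns sorted column indices.

    ``features`` may be a FeatureMatrix with ``labels`` a subject -> class
    mapping, or a plain (n, p) array with 0/1 labels. Deterministic: equal
    p-values resolve to the lower column index.
    """
    X, y = _as_xy(features, labels)
    n, p = X.shape
    # both classes must be present; leave-one-out folds of minimal cohorts
    # may legitimately carry a single member of one class
    if min((y == 1).sum(), (y == 0).sum()) < 1:
        raise ValueError("need both classes present")
    if max_features is None:
        max_features = int(np.ceil(n / 10))

    col_sd = X.std(axis=0)
    usable = col_sd > 0
    if not usable.all():
        warnings.warn(f"dropping {int((~usable).sum())} constant feature columns",
                      stacklevel=2)
    # standardize internally: improves Newton conditioning; LR tests are
    # invariant to affine rescaling of the predictors
    mu, sd = X.mean(axis=0), np.where(usable, col_sd, 1.0)
    Z = (X - mu) / sd
    ones = np.ones((n, 1))

    selected: list[int] = []
    seen_sets: set[frozenset] = set()
    beta_cur, ll_cur, _ = _fit_logistic(ones, y)
    ridge_cur = 0.0

    while len(selected) < max_features:
        cands = [j for j in range(p) if usable[j] and j not in selected]
        if not cands:
            break
        base = np.concatenate([ones, Z[:, selected]], axis=1)
        k = base.shape[1]
        Xc = np.broadcast_to(base[None], (len(cands), n, k))
        Xc = np.concatenate([Xc, Z[:, cands].T[:, :, None]], axis=2)
        # warm start from the current model, zero weight on the newcomer
        beta0 = np.zeros((len(cands), k + 1))
        beta0[:, :k] = beta_cur[None, :]
        _, ll_alt, conv = _fit_logistic_batch(Xc, y, beta0, ridge=ridge_cur)
        if not conv.all():
            # separation in at least one candidate model: redo the whole scan
            # with a ridge-penalized likelihood so p-values stay comparable
            logger.info("stepwise: separation detected, ridge fallback engaged")
            ridge_cur = _RIDGE_FALLBACK
            _, ll_cur, _ = _fit_logistic(base, y, ridge=ridge_cur)
            _, ll_alt, _ = _fit_logistic_batch(Xc, y, beta0, ridge=ridge_cur)
        pvals = _lr_pvalues(ll_alt, ll_cur)
        best = int(np.argmin(pvals))  # ties -> first, i.e. lower column index
        if pvals[best] >= p_enter:
            break
        selected.append(cands[best])

        # backward sweep
        while True:
            design = np.concatenate([ones, Z[:, selected]], axis=1)
            beta_full, ll_full, conv_full = _fit_logistic(design, y,
                                                          ridge=ridge_cur)
            if not conv_full and ridge_cur == 0.0:
                logger.info("stepwise: separation in full model, ridge fallback")
                ridge_cur = _RIDGE_FALLBACK
                beta_full, ll_full, _ = _fit_logistic(design, y, ridge=ridge_cur)
            ll_cur, beta_cur = ll_full, beta_full
            if len(selected) <= 1:
                break
            drop_p = np.empty(len(selected))
            for i in range(len(selected)):
                keep = [s for t, s in enumerate(selected) if t != i]
                red = np.concatenate([ones, Z[:, keep]], axis=1)
                _, ll_red, _ = _fit_logistic(red, y, ridge=ridge_cur)
                drop_p[i] = _lr_pvalues(np.array([ll_full]), ll_red)[0]
            worst = int(np.argmax(drop_p))
            if drop_p[worst] <= p_remove:
                break
            removed = selected.pop(worst)
            logger.debug("stepwise: removed feature %d (p=%.3f)",
                         removed, drop_p[worst])

        key = frozenset(selected)
        if key in seen_sets:
            break
        seen_sets.add(key)

    return sorted(selected)


def loo_selection_frequency(features, labels, **stepwise_kwargs) -> pd.Series:
    """Per-feature count of retention over the n leave-one-out stepwise runs.

    Returns an integer Series indexed by column position, with the number of
    iterations stored in ``.attrs["n_iterations"]``.
    """
    X, y = _as_xy(features, labels)
    n, p = X.shape
    if n < 3:
        raise ValueError("leave-one-out selection needs at least 3 subjects")
    counts = np.zeros(p, dtype=int)
    mask = np.ones(n, dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n):
            mask[:] = True
            mask[i] = False
            sel = stepwise_logistic_select(X[mask], y[mask], **stepwise_kwargs)
            counts[sel] += 1
    out = pd.Series(counts, name="selection_count")
    out.attrs["n_iterations"] = n
    return out


def top_features(freq: pd.Series, min_iterations: int) -> list[int]:
    """Features retained in at least ``min_iterations`` LOO runs."""
    n = freq.attrs.get("n_iterations")
    if min_iterations < 1 or (n is not None and min_iterations > n):
        raise ValueError(f"min_iterations must lie in [1, {n}]")
    idx = [int(i) for i, c in freq.items() if c >= min_iterations]
    if not idx:
        warnings.warn(f"no features reach {min_iterations} selections",
                      stacklevel=2)
    return idx


# ---------------------------------------------------------------------------
# classifiers and evaluation


@dataclass(frozen=True)
class ClassifierSpec:
    """A linear classifier family and its (few) hyperparameters.

    ``standardize=None`` means the per-family default: train-fold z-scoring
    for LR and the linear SVM, raw features for LDA (whose pooled-covariance
    decision rule is scale-equivariant already).
    """

    kind: str = "LR"
    C: float = 1.0
    lr_C: float = 1e4  # weak L2 for logistic regression
    standardize: bool | None = None
    seed: int = 0

    def build(self):
        if self.kind == "LR":
            clf = LogisticRegression(C=self.lr_C, solver="lbfgs", max_iter=5000)
            scale = True
        elif self.kind == "SVM_linear":
            clf = SVC(kernel="linear", C=self.C, random_state=self.seed)
            scale = True
        elif self.kind == "LDA":
            clf = LinearDiscriminantAnalysis()
            scale = False
        else:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        scale = self.standardize if self.standardize is not None else scale
        if scale:
            return Pipeline([("scale", StandardScaler()), ("clf", clf)])
        return clf


def binomial_vs_chance(correct: int, n: int, chance: float) -> float:
    """Exact one-sided binomial tail P(X >= correct | n, chance)."""
    if not 0 <= correct <= n:
        raise ValueError("correct must lie in [0, n]")
    if not 0 < chance < 1:
        raise ValueError("chance must lie in (0, 1)")
    return float(sps.binomtest(correct, n, chance, alternative="greater").pvalue)


@dataclass
class PerformanceReport:
    """Confusion counts and derived metrics, Responder = positive class."""

    tp: int
    fp: int
    tn: int
    fn: int
    chance: float = 0.5

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return 100.0 * self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return 100.0 * self.tn / neg if neg else float("nan")

    @property
    def binomial_p(self) -> float:
        return binomial_vs_chance(self.tp + self.tn, self.n, self.chance)

    @classmethod
    def from_predictions(cls, y_true, y_pred, chance: float | None = None):
        """Build from 0/1 (or label-string) vectors; ``chance=None`` uses the
        majority-class proportion."""
        yt = np.asarray([1 if v == RESPONDER else 0 if v == NONRESPONDER else v
                         for v in y_true], dtype=int)
        yp = np.asarray([1 if v == RESPONDER else 0 if v == NONRESPONDER else v
                         for v in y_pred], dtype=int)
        tp = int(((yt == 1) & (yp == 1)).sum())
        fn = int(((yt == 1) & (yp == 0)).sum())
        tn = int(((yt == 0) & (yp == 0)).sum())
        fp = int(((yt == 0) & (yp == 1)).sum())
        if chance is None:
            chance = max(yt.mean(), 1 - yt.mean())
        return cls(tp=tp, fp=fp, tn=tn, fn=fn, chance=float(chance))

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "n": self.n, "accuracy": self.accuracy,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "chance": self.chance, "binomial_p": self.binomial_p,
        }


def loo_classify(
    features,
    labels,
    spec: ClassifierSpec = ClassifierSpec(),
    selected: list[int] | None = None,
    chance: float | None = None,
) -> PerformanceReport:
    """Leave-one-out cross-validated classification on a fixed feature set.

    Each subject is predicted once by a model trained on the other n-1;
    confusion counts are pooled over all n held-out predictions.
    """
    X, y = _as_xy(features, labels)
    if selected is not None:
        if len(selected) == 0:
            raise ValueError("selected feature set is empty")
        X = X[:, sorted(selected)]
    n = X.shape[0]
    preds = np.empty(n, dtype=int)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[:] = True
        mask[i] = False
        ytr = y[mask]
        if ytr.min() == ytr.max():
            raise ValueError("a training fold lost one class entirely")
        model = spec.build()
        model.fit(X[mask], ytr)
        preds[i] = int(model.predict(X[i:i + 1])[0])
    return PerformanceReport.from_predictions(y, preds, chance=chance)


def threshold_sweep(
    features,
    labels,
    spec: ClassifierSpec = ClassifierSpec(),
    freq: pd.Series | None = None,
    nested: bool = False,
    chance: float | None = None,
    **stepwise_kwargs,
) -> pd.DataFrame:
    """LOO accuracy as a function of the selection-frequency threshold.

    For each candidate ``min_iterations`` value the corresponding top-feature
    set is evaluated with ``loo_classify``. In nested mode the frequency
    ranking is recomputed inside every training fold (no sight of the
    held-out subject); default mode follows the development procedure, which
    ranks on all n runs first.
    """
    X, y = _as_xy(features, labels)
    if freq is None:
        freq = loo_selection_frequency(X, y, **stepwise_kwargs)
    thresholds = sorted({int(c) for c in freq if c > 0})
    rows = []
    for t in thresholds:
        sel = [int(i) for i, c in freq.items() if c >= t]
        if not sel:
            continue
        if nested:
            rep = _nested_loo(X, y, t, spec, chance, **stepwise_kwargs)
        else:
            rep = loo_classify(X, y, spec=spec, selected=sel, chance=chance)
        rows.append((t, len(sel), rep.accuracy, rep.sensitivity,
                     rep.specificity, rep.binomial_p))
    return pd.DataFrame(rows, columns=[
        "min_iterations", "n_features", "accuracy", "sensitivity",
        "specificity", "binomial_p",
    ])


def _nested_loo(X, y, min_iterations, spec, chance, return_preds=False,
                **stepwise_kwargs):
    n = X.shape[0]
    preds = np.empty(n, dtype=int)
    mask = np.ones(n, dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n):
            mask[:] = True
            mask[i] = False
            freq = loo_selection_frequency(X[mask], y[mask], **stepwise_kwargs)
            t = min(min_iterations, freq.attrs["n_iterations"])
            sel = [int(j) for j, c in freq.items() if c >= t]
            if not sel:
                sel = [int(freq.idxmax())]
            model = spec.build()
            model.fit(X[mask][:, sel], y[mask])
            preds[i] = int(model.predict(X[i:i + 1, sel])[0])
    report = PerformanceReport.from_predictions(y, preds, chance=chance)
    if return_preds:
        return report, preds
    return report


def choose_working_point(sweep: pd.DataFrame) -> int:
    """Accuracy-maximizing threshold; ties resolve to the fewest features."""
    if sweep.empty:
        raise ValueError("empty sweep")
    best = sweep.sort_values(
        ["accuracy", "n_features", "min_iterations"],
        ascending=[False, True, False],
    ).iloc[0]
    return int(best["min_iterations"])
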