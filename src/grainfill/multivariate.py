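"""PCA, PLS-DA with VIP scores, double cross-validation and marker selection.

The marker-selection strategy follows common chemometric practice for
designed metabolomics studies: a PLS-DA (or PLS regression) model is
optimised and validated by *double* (nested) cross-validation — an inner
loop picks the number of latent variables, an outer loop gives unbiased
error estimates — and variables are selected by combining variable
importance for projection (VIP > threshold) with regression-coefficient sign
stability across the outer folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "PCAResults",
    "fit_pca",
    "PLSDA",
    "PLSDAResults",
    "vip_scores",
    "CvReport",
    "double_cross_validate",
    "MarkerReport",
    "select_markers",
]


# --------------------------------------------------------------------- PCA
@dataclass
class PCAResults:
    scores: np.ndarray
    loadings: np.ndarray
    explained_pct: np.ndarray


def fit_pca(X, n_components: int = 2) -> PCAResults:
    """SVD-based PCA of a (column-centred) matrix.

    Deterministic up to sign; signs are fixed so that each component's
    largest-magnitude loading is positive. ``n_components`` beyond the matrix
    rank is truncated.
    """
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > (s[0] * 1e-12 if s.size and s[0] > 0 else 0)))
    n_components = min(n_components, max(rank, 1))
    V = Vt[:n_components].T
    flip = np.where(V[np.abs(V).argmax(axis=0), np.arange(V.shape[1])] < 0, -1.0, 1.0)
    V = V * flip
    scores = Xc @ V
    total = float(np.sum(s**2))
    explained = 100.0 * s[:n_components] ** 2 / total if total > 0 else np.zeros(n_components)
    return PCAResults(scores=scores, loadings=V, explained_pct=explained)


# ------------------------------------------------------------------ PLS-DA
def _one_hot(labels, classes) -> np.ndarray:
    Y = np.zeros((len(labels), len(classes)))
    for j, c in enumerate(classes):
        Y[np.asarray(labels) == c, j] = 1.0
    return Y


def vip_scores(pls: PLSRegression) -> np.ndarray:
    """Variable importance for projection of a fitted PLS model.

    ``VIP_j = sqrt( K · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a )`` where
    ``SSY_a = ‖t_a‖²‖q_a‖²`` is the response variance captured by component
    ``a``. The mean of squared VIPs over variables is exactly 1.
    """
    W = pls.x_weights_
    T = pls.x_scores_
    Q = pls.y_loadings_
    K, A = W.shape
    ssy = np.einsum("na,na->a", T, T) * np.einsum("ca,ca->a", Q, Q)
    Wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    denom = ssy.sum()
    if denom == 0:
        return np.ones(K)
    return np.sqrt(K * (Wn**2 @ ssy) / denom)


class PLSDA:
    """PLS discriminant analysis with a one-hot response.

    A single PLS2 model is fitted against the indicator matrix of all
    classes; prediction is arg-max of the predicted responses. For binary
    problems this coincides with the usual one-vs-rest formulation.
    """

    def __init__(self, X, labels, n_components: int = 2):
        X = np.asarray(X, dtype=float)
        labels = np.asarray(labels)
        self.classes_ = np.array(sorted(pd.unique(labels)))
        if len(self.classes_) < 2:
            raise ValueError("PLS-DA needs at least two classes")
        counts = pd.Series(labels).value_counts()
        if (counts < 2).any():
            raise ValueError("every class needs at least two samples")
        self.X = X
        self.labels = labels
        self.n_components = min(n_components, X.shape[1], len(X) - 1)

    def fit(self) -> "PLSDAResults":
        Y = _one_hot(self.labels, self.classes_)
        pls = PLSRegression(n_components=self.n_components, scale=False)
        pls.fit(self.X, Y)
        return PLSDAResults(model=self, pls=pls, classes_=self.classes_)


@dataclass
class PLSDAResults:
    model: PLSDA
    pls: PLSRegression
    classes_: np.ndarray

    @property
    def coef_(self) -> np.ndarray:
        """Regression coefficients, variables × classes."""
        return self.pls.coef_.T

    @property
    def x_scores_(self) -> np.ndarray:
        return self.pls.x_scores_

    def vip(self) -> np.ndarray:
        return vip_scores(self.pls)

    def decision_values(self, X) -> np.ndarray:
        return self.pls.predict(np.asarray(X, dtype=float))

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_values(X), axis=1)]

    def misclassification(self, X, labels) -> float:
        return float(np.mean(self.predict(X) != np.asarray(labels)))


# ----------------------------------------------------------- double CV
@dataclass
class CvReport:
    """Outer-loop predictions and error estimates of a double CV."""

    task: str
    classes_: np.ndarray | None
    y_true: np.ndarray
    y_pred: np.ndarray
    y_score: np.ndarray | None
    chosen_n_components: list
    fold_coefs: list  # per outer fold: variables × classes (or × 1)
    misclassification: float | None
    auc: dict | None
    r2: float | None
    rmsep: float | None
    seed: int | None

    def summary(self) -> pd.DataFrame:
        if self.task == "classification":
            rows = [
                {"metric": "misclassification", "value": self.misclassification},
                *(
                    {"metric": f"AUC[{c}]", "value": self.auc[c]}
                    for c in self.classes_
                ),
            ]
        else:
            rows = [
                {"metric": "r2", "value": self.r2},
                {"metric": "RMSEP", "value": self.rmsep},
            ]
        rows.append(
            {"metric": "median n_components", "value": float(np.median(self.chosen_n_components))}
        )
        return pd.DataFrame(rows)


def _fit_pls(X, Y, n_components):
    n_components = min(n_components, X.shape[1], len(X) - 1)
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, Y)
    return pls


def double_cross_validate(
    X,
    y,
    task: str = "classification",
    n_comp_grid=range(1, 11),
    outer_k: int = 8,
    inner_k: int = 7,
    seed: int | None = None,
) -> CvReport:
    """Nested cross-validation of a PLS(-DA) model.

    The inner loop (on each outer training set) picks the number of latent
    variables minimising inner-CV misclassification (classification) or
    RMSECV (regression); the outer loop pools test-set predictions for
    unbiased error estimates. Classification folds are stratified by class;
    regression folds are stratified by the discrete response levels (DAF
    days). No sample is ever predicted by a model that saw it in training.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if task == "classification":
        strata = y
        classes = np.array(sorted(pd.unique(y)))
        Y_full = _one_hot(y, classes)
        target = lambda idx: Y_full[idx]
    elif task == "regression":
        strata = y  # discrete sampling days act as strata
        classes = None
        yf = y.astype(float)
        target = lambda idx: yf[idx, None]
    else:
        raise ValueError("task must be 'classification' or 'regression'")
    min_stratum = pd.Series(strata).value_counts().min()
    if outer_k > min_stratum:
        raise ValueError(
            f"outer_k={outer_k} exceeds the smallest stratum size {min_stratum}"
        )
    rng = np.random.default_rng(seed)
    outer = StratifiedKFold(
        n_splits=outer_k, shuffle=True, random_state=int(rng.integers(2**31 - 1))
    )
    grid = [a for a in n_comp_grid if a >= 1]

    y_pred = np.empty(n, dtype=object if task == "classification" else float)
    y_score = np.zeros((n, len(classes))) if task == "classification" else None
    chosen, fold_coefs = [], []
    for train, test in outer.split(X, strata):
        inner_splits = min(inner_k, pd.Series(strata[train]).value_counts().min())
        if inner_splits < 2:
            raise ValueError("inner fold count exceeds stratum size in training set")
        inner = StratifiedKFold(
            n_splits=inner_splits, shuffle=True,
            random_state=int(rng.integers(2**31 - 1)),
        )
        inner_err = []
        for a in grid:
            errs = []
            for itr, iva in inner.split(X[train], strata[train]):
                pls = _fit_pls(X[train][itr], target(train[itr]), a)
                pred = pls.predict(X[train][iva])
                if task == "classification":
                    lab = classes[np.argmax(pred, axis=1)]
                    errs.append(np.mean(lab != y[train][iva]))
                else:
                    errs.append(np.mean((pred[:, 0] - y[train][iva].astype(float)) ** 2))
            inner_err.append(np.mean(errs))
        a_opt = grid[int(np.argmin(inner_err))]
        chosen.append(a_opt)
        pls = _fit_pls(X[train], target(train), a_opt)
        fold_coefs.append(pls.coef_.T.copy())
        pred = pls.predict(X[test])
        if task == "classification":
            y_score[test] = pred
            y_pred[test] = classes[np.argmax(pred, axis=1)]
        else:
            y_pred[test] = pred[:, 0]

    if task == "classification":
        mis = float(np.mean(y_pred != y))
        auc = {}
        for j, c in enumerate(classes):
            binary = (y == c).astype(int)
            auc[c] = float(roc_auc_score(binary, y_score[:, j]))
        return CvReport(
            task=task, classes_=classes, y_true=y, y_pred=np.asarray(y_pred),
            y_score=y_score, chosen_n_components=chosen, fold_coefs=fold_coefs,
            misclassification=mis, auc=auc, r2=None, rmsep=None, seed=seed,
        )
    resid = y_pred.astype(float) - y.astype(float)
    rmsep = float(np.sqrt(np.mean(resid**2)))
    r = np.corrcoef(y_pred.astype(float), y.astype(float))[0, 1]
    return CvReport(
        task=task, classes_=None, y_true=y, y_pred=y_pred.astype(float),
        y_score=None, chosen_n_components=chosen, fold_coefs=fold_coefs,
        misclassification=None, auc=None, r2=float(r**2), rmsep=rmsep, seed=seed,
    )


# ------------------------------------------------------- marker selection
@dataclass
class MarkerReport:
    """Per-class marker metabolites with the selection-rule provenance."""

    table: pd.DataFrame  # variable, class, vip, coefficient, direction, stability
    params: dict
    variables: list

    def markers_for(self, cls) -> list:
        return self.table.loc[self.table["class"] == cls, "variable"].tolist()

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def attach_univariate(self, p_values: pd.Series, alpha: float = 0.05) -> dict:
        """Join per-variable ANOVA p-values; report multivariate/univariate
        agreement (the count of selected markers that are also univariately
        significant)."""
        self.table = self.table.assign(
            anova_p=np.asarray(p_values.reindex(self.table["variable"]))
        )
        n_agree = int((self.table["anova_p"] < alpha).sum())
        self.params["univariate_alpha"] = alpha
        self.params["n_univariate_agreement"] = n_agree
        return {"n_agreement": n_agree, "n_markers": self.n_markers}

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def select_markers(
    X,
    labels,
    cv_report: CvReport,
    vip_threshold: float = 1.0,
    coef_stability: float = 0.8,
    n_components: int | None = None,
    variable_names=None,
    require_validated: bool = True,
    validation_alpha: float = 0.05,
) -> MarkerReport:
    """VIP- and coefficient-based marker selection against a validated model.

    A variable is selected when its VIP (from the full-data model refitted at
    the median cross-validated complexity) exceeds ``vip_threshold`` AND its
    regression-coefficient sign for the assigned class agrees across at
    least ``coef_stability`` of the outer CV folds. Each selected variable is
    assigned to the class in which it is most strongly elevated (largest
    coefficient), so per-class marker sets are disjoint. Raising the VIP
    threshold can only shrink the selection.

    Markers are only meaningful when the model itself validates: with
    ``require_validated`` (default), selection is empty unless the outer-CV
    accuracy beats chance at ``validation_alpha`` (one-sided binomial test).
    Coefficient signs from overlapping CV folds are strongly correlated, so
    without this gate the VIP/stability rule alone admits a large fraction
    of uninformative variables on null data.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if variable_names is None:
        variable_names = [f"v{j}" for j in range(X.shape[1])]
    variable_names = list(variable_names)
    if n_components is None:
        n_components = int(round(float(np.median(cv_report.chosen_n_components))))

    if require_validated and cv_report.task == "classification":
        from scipy import stats as _stats

        n = len(cv_report.y_true)
        n_correct = int(np.sum(cv_report.y_pred == cv_report.y_true))
        chance = 1.0 / len(cv_report.classes_)
        p_chance = float(_stats.binom.sf(n_correct - 1, n, chance))
        if p_chance >= validation_alpha:
            return MarkerReport(
                table=pd.DataFrame(
                    columns=["variable", "class", "vip", "coefficient",
                             "direction", "sign_stability"]
                ),
                params={
                    "vip_threshold": vip_threshold,
                    "coef_stability": coef_stability,
                    "n_components": n_components,
                    "model_validated": False,
                    "p_vs_chance": p_chance,
                },
                variables=variable_names,
            )
    fit = PLSDA(X, labels, n_components=n_components).fit()
    vips = fit.vip()
    coef = fit.coef_  # K × C
    classes = fit.classes_

    sign_stab = np.zeros_like(coef)
    full_sign = np.sign(coef)
    for fold_coef in cv_report.fold_coefs:
        sign_stab += np.sign(fold_coef) == full_sign
    sign_stab /= max(len(cv_report.fold_coefs), 1)

    rows = []
    assigned = np.argmax(coef, axis=1)
    for j, name in enumerate(variable_names):
        c = assigned[j]
        if vips[j] > vip_threshold and sign_stab[j, c] >= coef_stability:
            rows.append(
                {
                    "variable": name,
                    "class": classes[c],
                    "vip": float(vips[j]),
                    "coefficient": float(coef[j, c]),
                    "direction": "up" if coef[j, c] > 0 else "down",
                    "sign_stability": float(sign_stab[j, c]),
                }
            )
    table = pd.DataFrame(
        rows, columns=["variable", "class", "vip", "coefficient", "direction", "sign_stability"]
    )
    return MarkerReport(
        table=table,
        params={
            "vip_threshold": vip_threshold,
            "coef_stability": coef_stability,
            "n_components": n_components,
            "model_validated": True,
        },
        variables=variable_names,
    )
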