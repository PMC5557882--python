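"""ANOVA-simultaneous component analysis (ASCA) of designed omics tables.

ASCA partitions a column-centred samples × variables matrix into additive
effect matrices defined by a balanced factorial design::

    X = X_GT + X_TEMP + X_DAF + X_GT×TEMP + X_DAF×TEMP + X_GT×DAF + E

where a main-effect row is the level mean minus the grand mean, an
interaction row is the cell mean minus both level means plus the grand mean,
and ``E`` absorbs replicate variation (and any higher-order structure). On a
balanced complete design all terms are mutually orthogonal, so their sums of
squares add exactly to the total — each term's SSQ% is its unambiguous share
of the variance. Term significance is assessed by permutation of the term's
labels; each effect matrix can then be explored with PCA, free of the
confounding that masks small effects in a PCA of the raw table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import check_balanced
from .preprocess import MetaboliteTable

__all__ = ["ASCA", "ASCAResults", "EffectPCA", "DEFAULT_TERMS", "term_name"]

DEFAULT_TERMS = (
    ("genotype",),
    ("daf",),
    ("temperature",),
    ("genotype", "temperature"),
    ("daf", "temperature"),
    ("genotype", "daf"),
)

_FACTOR_ALIAS = {"genotype": "GT", "temperature": "TEMP", "daf": "DAF"}


def term_name(term: tuple) -> str:
    return "×".join(_FACTOR_ALIAS.get(f, f.upper()) for f in term)


def _level_codes(values) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(values), sort=True)
    return codes, len(uniques)


def _group_mean_rows(X: np.ndarray, codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Per-row level means of X (broadcast back to full row order)."""
    sums = np.zeros((n_levels, X.shape[1]))
    np.add.at(sums, codes, X)
    counts = np.bincount(codes, minlength=n_levels).astype(float)
    means = sums / counts[:, None]
    return means[codes]


def _effect_matrix(X: np.ndarray, design: pd.DataFrame, term: tuple) -> np.ndarray:
    """Effect matrix of one term for centred X (grand mean assumed 0)."""
    if len(term) == 1:
        codes, L = _level_codes(design[term[0]])
        return _group_mean_rows(X, codes, L)
    if len(term) == 2:
        ca, La = _level_codes(design[term[0]])
        cb, Lb = _level_codes(design[term[1]])
        cell = ca * Lb + cb
        return (
            _group_mean_rows(X, cell, La * Lb)
            - _group_mean_rows(X, ca, La)
            - _group_mean_rows(X, cb, Lb)
        )
    raise ValueError("only main effects and two-factor interactions are supported")


class ASCA:
    """Model object: ASCA decomposition of a designed metabolite table.

    Parameters
    ----------
    table
        A scaled :class:`~grainfill.preprocess.MetaboliteTable`, or a
        samples × variables DataFrame/array together with ``design``.
    design
        Design table (required when ``table`` is a plain matrix).
    terms
        Tuples of design-factor column names; defaults to the three main
        effects and all two-factor interactions of genotype, DAF and
        temperature.
    """

    def __init__(self, table, design: pd.DataFrame | None = None, terms=DEFAULT_TERMS):
        if isinstance(table, MetaboliteTable):
            X = table.X
            design = table.design
        else:
            X = table
            if design is None:
                raise ValueError("design is required when table is a plain matrix")
        self.columns = (
            list(X.columns) if isinstance(X, pd.DataFrame)
            else [f"v{j}" for j in range(np.asarray(X).shape[1])]
        )
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2 or len(self.X) != len(design):
            raise ValueError("matrix and design are inconsistent")
        self.design = design.reset_index(drop=True)
        self.terms = [tuple(t) if not isinstance(t, str) else (t,) for t in terms]
        factors = sorted({f for t in self.terms for f in t})
        check_balanced(self.design, factors=factors)
        self.factors = factors

    def fit(self, n_permutations: int = 0, seed: int | None = None) -> "ASCAResults":
        """Decompose, and optionally permutation-test every term."""
        grand = self.X.mean(axis=0)
        Xc = self.X - grand  # defensive centring; no-op on properly scaled input
        effects = {}
        for term in self.terms:
            effects[term] = _effect_matrix(Xc, self.design, term)
        residual = Xc - sum(effects.values())
        ssq = {term: float(np.sum(m**2)) for term, m in effects.items()}
        ssq_res = float(np.sum(residual**2))
        total = float(np.sum(Xc**2))
        if total == 0:
            raise ValueError("matrix has no variance")
        p_values = {}
        if n_permutations > 0:
            rng = np.random.default_rng(seed)
            for term in self.terms:
                p_values[term] = self._permutation_p(
                    Xc, effects, term, n_permutations, rng
                )
        return ASCAResults(
            model=self,
            grand_mean=grand,
            effects=effects,
            residual=residual,
            ssq=ssq,
            ssq_residual=ssq_res,
            ssq_total=total,
            p_values=p_values,
            n_permutations=n_permutations,
            seed=seed,
        )

    # ------------------------------------------------------------ permutation
    def permutation_test(
        self, term, n_permutations: int, seed: int | None = None
    ) -> float:
        """Permutation p-value for one term (add-one convention)."""
        term = tuple(term) if not isinstance(term, str) else (term,)
        if term not in self.terms:
            raise ValueError(f"term {term} is not part of this decomposition")
        grand = self.X.mean(axis=0)
        Xc = self.X - grand
        effects = {t: _effect_matrix(Xc, self.design, t) for t in self.terms}
        rng = np.random.default_rng(seed)
        return self._permutation_p(Xc, effects, term, n_permutations, rng)

    def _permutation_p(self, Xc, effects, term, n_perm, rng) -> float:
        """Null by permuting the term's labels over rows.

        Main effects permute the factor's labels directly; interactions first
        remove both observed main effects, then permute the cell labels of
        the residualized data — the standard ASCA permutation scheme.
        """
        if n_perm < 1:
            raise ValueError("n_permutations must be >= 1")
        if len(term) == 1:
            data = Xc
            codes, L = _level_codes(self.design[term[0]])
            observed = float(np.sum(effects[term] ** 2))
            stat = _MainEffectSSQ(codes, L)
        else:
            a, b = term
            data = Xc - effects[(a,)] - effects[(b,)]
            ca, La = _level_codes(self.design[a])
            cb, Lb = _level_codes(self.design[b])
            observed = float(np.sum(effects[term] ** 2))
            stat = _InteractionSSQ(ca, La, cb, Lb)
        n = len(data)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            if stat(data[perm]) >= observed:
                count += 1
        return (1 + count) / (1 + n_perm)


class _MainEffectSSQ:
    """SSQ of a main-effect matrix for fixed labels, fast on permuted data."""

    def __init__(self, codes, n_levels):
        order = np.argsort(codes, kind="stable")
        self.order = order
        sorted_codes = codes[order]
        self.offsets = np.searchsorted(sorted_codes, np.arange(n_levels))
        self.counts = np.bincount(codes, minlength=n_levels).astype(float)

    def __call__(self, X) -> float:
        sums = np.add.reduceat(X[self.order], self.offsets, axis=0)
        # grand mean is zero for centred data and invariant under permutation
        return float(np.sum(sums**2 / self.counts[:, None]))


class _InteractionSSQ:
    """SSQ of an interaction matrix (cell − a − b + grand) for fixed labels."""

    def __init__(self, ca, La, cb, Lb):
        self.a = _MainEffectSSQ(ca, La)
        self.b = _MainEffectSSQ(cb, Lb)
        cell = ca * Lb + cb
        self.cell = _MainEffectSSQ(cell, La * Lb)

    def __call__(self, X) -> float:
        # orthogonality on balanced designs: ||cell||² = ||a||² + ||b||² + ||int||²
        return self.cell(X) - self.a(X) - self.b(X)


@dataclass
class EffectPCA:
    term: tuple
    scores: np.ndarray
    loadings: np.ndarray
    explained_pct: np.ndarray
    augmented: bool

    def scores_frame(self, design: pd.DataFrame) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        out = design.copy()
        out[cols] = self.scores
        return out

    def plot_scores(self, design, color_by="genotype", ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        groups = pd.Series(np.asarray(design[color_by])).astype(str)
        for g in groups.unique():
            m = (groups == g).to_numpy()
            ax.scatter(self.scores[m, 0], self.scores[m, 1], label=g, s=18)
        ax.set_xlabel(f"PC1 ({self.explained_pct[0]:.1f}%)")
        if self.scores.shape[1] > 1:
            ax.set_ylabel(f"PC2 ({self.explained_pct[1]:.1f}%)")
        ax.legend(title=color_by)
        ax.set_title(f"PCA of effect {term_name(self.term)}")
        return ax


@dataclass
class ASCAResults:
    """Fitted ASCA decomposition with SSQ shares and permutation p-values."""

    model: ASCA
    grand_mean: np.ndarray
    effects: dict
    residual: np.ndarray
    ssq: dict
    ssq_residual: float
    ssq_total: float
    p_values: dict
    n_permutations: int
    seed: int | None

    def ssq_percent(self, term=None):
        if term is None:
            out = {t: 100.0 * s / self.ssq_total for t, s in self.ssq.items()}
            out["residual"] = 100.0 * self.ssq_residual / self.ssq_total
            return out
        term = tuple(term) if not isinstance(term, str) else (term,)
        return 100.0 * self.ssq[term] / self.ssq_total

    def reconstruction(self) -> np.ndarray:
        return sum(self.effects.values()) + self.residual

    def summary(self) -> pd.DataFrame:
        """Per-term variance-partition table (effect, SSQ, SSQ%, p-value)."""
        rows = []
        pct = self.ssq_percent()
        for term in self.model.terms:
            rows.append(
                {
                    "effect": term_name(term),
                    "ssq": self.ssq[term],
                    "ssq_percent": pct[term],
                    "p_value": self.p_values.get(term, np.nan),
                }
            )
        rows.append(
            {
                "effect": "residual",
                "ssq": self.ssq_residual,
                "ssq_percent": pct["residual"],
                "p_value": np.nan,
            }
        )
        return pd.DataFrame(rows)

    def effect_frame(self, term) -> pd.DataFrame:
        term = tuple(term) if not isinstance(term, str) else (term,)
        return pd.DataFrame(
            self.effects[term],
            index=pd.Index(self.model.design["sample_id"], name="sample_id"),
            columns=self.model.columns,
        )

    def pca_of_effect(
        self, term, n_components: int = 2, augment_with_residual: bool = False
    ) -> EffectPCA:
        """SVD-based PCA of one effect matrix.

        With ``augment_with_residual`` the per-sample scores are the
        projections of effect + residual onto the effect's loadings, showing
        replicate dispersion around the level means; loadings and explained
        variance always describe the pure effect matrix.
        """
        term = tuple(term) if not isinstance(term, str) else (term,)
        if term not in self.effects:
            raise ValueError(f"term {term} not in decomposition")
        M = self.effects[term]
        U, s, Vt = np.linalg.svd(M, full_matrices=False)
        rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
        if n_components > rank:
            warnings.warn(
                f"requested {n_components} components but effect rank is {rank}; truncating"
            )
            n_components = max(rank, 1)
        # sign convention: largest-|loading| entry positive per component
        V = Vt[:n_components].T
        flip = np.where(V[np.abs(V).argmax(axis=0), np.arange(V.shape[1])] < 0, -1, 1)
        V = V * flip
        if augment_with_residual:
            scores = (M + self.residual) @ V
        else:
            scores = M @ V
        total = float(np.sum(s**2))
        explained = 100.0 * (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
        return EffectPCA(
            term=term,
            scores=scores,
            loadings=V,
            explained_pct=explained,
            augmented=augment_with_residual,
        )
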