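"""Developmental trend classification and univariate per-metabolite ANOVA.

Working on the closure-corrected (raw-scale) table, each metabolite's
replicate-averaged profile over the sampling days is labelled as
accumulation, depletion, accumulation-then-depletion, or none, by rank
correlation with DAF plus an interior-maximum rule for the transient class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import MetaboliteTable

__all__ = ["classify_trends", "anova_univariate", "daf_profile_matrix"]


def daf_profile_matrix(X: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Metabolites × DAF matrix of replicate-averaged values (all samples)."""
    daf = np.asarray(design["daf"])
    levels = np.unique(daf)
    prof = np.stack([X.to_numpy()[daf == d].mean(axis=0) for d in levels], axis=1)
    return pd.DataFrame(prof, index=X.columns, columns=levels)


def classify_trends(
    table,
    design: pd.DataFrame | None = None,
    rho_min: float = 0.6,
    bump_margin: float = 0.2,
) -> pd.DataFrame:
    """Label each metabolite's grain-filling trend.

    A profile is ``accumulation`` when its Spearman correlation with DAF is
    ≥ ``rho_min``, ``depletion`` when ≤ −``rho_min``; otherwise it is
    ``acc_then_depl`` when an interior maximum exceeds both endpoints by at
    least ``bump_margin`` of the profile range AND the profile ranks rise up
    to that maximum and fall after it (segment Spearman ≥ ``rho_min`` on the
    way up and ≤ −``rho_min`` on the way down — without this, replicate noise
    on flat profiles routinely fakes an interior maximum); else ``none``.
    Requires at least four DAF levels.
    """
    if isinstance(table, MetaboliteTable):
        X, design = table.X, table.design
    else:
        X = table
        if design is None:
            raise ValueError("design required with a plain matrix")
    prof = daf_profile_matrix(X, design)
    levels = prof.columns.to_numpy(dtype=float)
    if len(levels) < 4:
        raise ValueError("trend classification needs at least four DAF levels")
    P = prof.to_numpy()
    # Spearman against DAF: Pearson correlation of within-row ranks (ties get
    # average ranks; sampling days are distinct so the DAF ranks are exact)
    rp = stats.rankdata(P, axis=1)
    rd = stats.rankdata(levels)
    rp_c = rp - rp.mean(axis=1, keepdims=True)
    rd_c = rd - rd.mean()
    denom = np.sqrt((rp_c**2).sum(axis=1) * (rd_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, (rp_c @ rd_c) / denom, 0.0)

    rng_span = P.max(axis=1) - P.min(axis=1)
    interior_max = P[:, 1:-1].max(axis=1)
    endpoint_max = np.maximum(P[:, 0], P[:, -1])
    margin_ok = (rng_span > 0) & (
        interior_max - endpoint_max >= bump_margin * np.where(rng_span > 0, rng_span, 1.0)
    )

    def _segment_rho(x: np.ndarray) -> float:
        if len(x) < 3:
            return 0.0
        return float(stats.spearmanr(np.arange(len(x)), x).statistic)

    is_bump = np.zeros(len(P), dtype=bool)
    for i in np.flatnonzero(margin_ok):
        m = 1 + int(np.argmax(P[i, 1:-1]))
        rho_up = _segment_rho(P[i, : m + 1])
        rho_down = _segment_rho(P[i, m:])
        is_bump[i] = rho_up >= rho_min and rho_down <= -rho_min

    labels = np.full(len(P), "none", dtype=object)
    labels[rho >= rho_min] = "accumulation"
    labels[rho <= -rho_min] = "depletion"
    transient = (np.abs(rho) < rho_min) & is_bump
    labels[transient] = "acc_then_depl"
    argmax_daf = levels[np.argmax(P, axis=1)]
    return pd.DataFrame(
        {
            "trend": labels,
            "spearman_rho": rho,
            "peak_daf": argmax_daf,
            "profile_range": rng_span,
        },
        index=prof.index,
    )


def _oneway_f(X: np.ndarray, labels) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised one-way ANOVA over all columns of X at once."""
    codes, uniques = pd.factorize(np.asarray(labels), sort=True)
    L = len(uniques)
    n = len(X)
    grand = X.mean(axis=0)
    ss_tot = ((X - grand) ** 2).sum(axis=0)
    ss_between = np.zeros(X.shape[1])
    for l in range(L):
        rows = codes == l
        n_l = rows.sum()
        ss_between += n_l * (X[rows].mean(axis=0) - grand) ** 2
    ss_within = ss_tot - ss_between
    df1, df2 = L - 1, n - L
    with np.errstate(invalid="ignore", divide="ignore"):
        F = (ss_between / df1) / (ss_within / df2)
    p = stats.f.sf(F, df1, df2)
    p = np.where(np.isnan(F), 1.0, p)
    return F, p


def anova_univariate(
    table,
    design: pd.DataFrame | None = None,
    factors=("genotype", "temperature", "daf"),
    fdr: bool = False,
) -> pd.DataFrame:
    """One-way ANOVA per metabolite, per design factor.

    Raw p-values are reported at face value (significance is conventionally
    read at α = 0.05); Benjamini–Hochberg adjusted columns are appended when
    ``fdr`` is set.
    """
    if isinstance(table, MetaboliteTable):
        X, design = table.X, table.design
    else:
        X = table
        if design is None:
            raise ValueError("design required with a plain matrix")
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    index = X.columns if isinstance(X, pd.DataFrame) else pd.RangeIndex(Xv.shape[1])
    out = {}
    for f in factors:
        _, p = _oneway_f(Xv, design[f])
        out[f"p_{f}"] = p
    frame = pd.DataFrame(out, index=index)
    if fdr:
        from statsmodels.stats.multitest import multipletests

        for f in factors:
            frame[f"q_{f}"] = multipletests(frame[f"p_{f}"], method="fdr_bh")[1]
    return frame
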