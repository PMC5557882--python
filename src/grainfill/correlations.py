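"""Pearson correlation fingerprints of metabolites over grain filling.

Within one genotype × temperature group, every metabolite's replicate-
averaged profile over the DAF sampling days is correlated against every
other metabolite's profile (within-group) or against the profiles of a
second group (between-group). The resulting K × K coefficient matrices are
developmental fingerprints: counting their significantly positive and
negative entries, and comparing coefficient distributions between groups,
summarises how concerted metabolite development is under each condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import MetaboliteTable

__all__ = [
    "daf_profiles",
    "fingerprint",
    "critical_r",
    "CorrelationFingerprint",
]


def daf_profiles(
    table,
    genotype: str,
    temperature: str,
    design: pd.DataFrame | None = None,
    average_replicates: bool = True,
) -> pd.DataFrame:
    """Metabolites × DAF profile matrix of one genotype × temperature group.

    Values are replicate means per DAF level, ordered by DAF. With
    ``average_replicates`` off, replicate-resolved columns are returned
    (ordered by DAF, then replicate).
    """
    if isinstance(table, MetaboliteTable):
        X, design = table.X, table.design
    else:
        X = table
        if design is None:
            raise ValueError("design required with a plain matrix")
    mask = (np.asarray(design["genotype"]) == genotype) & (
        np.asarray(design["temperature"]) == temperature
    )
    if not mask.any():
        raise ValueError(f"group {genotype}/{temperature} not present in design")
    sub = X.loc[np.asarray(mask)] if isinstance(X, pd.DataFrame) else X[mask]
    daf = np.asarray(design["daf"])[mask]
    levels = np.unique(daf)
    expected = np.unique(np.asarray(design["daf"]))
    missing = set(expected) - set(levels)
    if missing:
        raise ValueError(f"group {genotype}/{temperature} lacks DAF levels {sorted(missing)}")
    subv = sub.to_numpy(dtype=float)
    if average_replicates:
        prof = np.stack([subv[daf == d].mean(axis=0) for d in levels], axis=1)
        cols = levels
    else:
        order = np.lexsort((np.arange(mask.sum()), daf))
        prof = subv[order].T
        cols = [f"{d}_{i}" for d in levels for i in range(int((daf == d).sum()))]
    names = X.columns if isinstance(X, pd.DataFrame) else pd.RangeIndex(prof.shape[0])
    return pd.DataFrame(prof, index=names, columns=cols)


def critical_r(n_points: int, alpha: float = 0.05) -> float:
    """Two-sided significance threshold on r via the t-distribution.

    ``t = r √(n−2) / √(1−r²)`` inverted at the α/2 tail; for n = 8 and
    α = 0.05 this is ≈ 0.7067.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_points < 3:
        raise ValueError("need at least 3 points for a correlation test")
    t_crit = stats.t.ppf(1 - alpha / 2, df=n_points - 2)
    return float(t_crit / np.sqrt(n_points - 2 + t_crit**2))


@dataclass
class CorrelationFingerprint:
    """K × K Pearson matrix between the DAF profiles of two groups.

    ``r[i, j]`` correlates metabolite ``i`` in group A with metabolite ``j``
    in group B; A = B gives the symmetric within-group fingerprint with unit
    diagonal. Zero-variance profiles produce NaN entries, which are excluded
    from every count and histogram.
    """

    r: pd.DataFrame
    group_a: tuple
    group_b: tuple
    n_points: int

    @property
    def within_group(self) -> bool:
        return self.group_a == self.group_b

    def count_significant(self, alpha: float = 0.05) -> tuple[int, int]:
        """(n_positive, n_negative) beyond the two-sided t threshold.

        Within-group counts scan unique off-diagonal pairs (upper triangle);
        between-group matrices are not symmetric, so all K² entries count.
        """
        r_crit = critical_r(self.n_points, alpha)
        R = self.r.to_numpy()
        if self.within_group:
            iu = np.triu_indices_from(R, k=1)
            vals = R[iu]
        else:
            vals = R.ravel()
        vals = vals[~np.isnan(vals)]
        return int(np.sum(vals > r_crit)), int(np.sum(vals < -r_crit))

    def coefficient_distribution(self, n_bins: int = 40) -> pd.DataFrame:
        """Histogram of coefficients over [−1, 1]; totals conserve the number
        of valid (non-NaN) counted entries."""
        R = self.r.to_numpy()
        if self.within_group:
            iu = np.triu_indices_from(R, k=1)
            vals = R[iu]
        else:
            vals = R.ravel()
        vals = vals[~np.isnan(vals)]
        counts, edges = np.histogram(vals, bins=n_bins, range=(-1.0, 1.0))
        return pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
        )

    def n_valid(self) -> int:
        R = self.r.to_numpy()
        if self.within_group:
            iu = np.triu_indices_from(R, k=1)
            return int(np.sum(~np.isnan(R[iu])))
        return int(np.sum(~np.isnan(R)))

    def plot_distribution(self, ax=None, n_bins: int = 40):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        hist = self.coefficient_distribution(n_bins)
        ax.bar(hist["bin_left"], hist["count"], width=hist["bin_right"] - hist["bin_left"],
               align="edge")
        ax.set_xlabel("Pearson r")
        ax.set_ylabel("count")
        a, b = "/".join(self.group_a), "/".join(self.group_b)
        ax.set_title(f"{a} vs {b}" if not self.within_group else f"within {a}")
        return ax


def fingerprint(profiles_a: pd.DataFrame, profiles_b: pd.DataFrame | None = None,
                group_a: tuple = ("A",), group_b: tuple | None = None) -> CorrelationFingerprint:
    """Pearson fingerprint between two profile matrices (rows = metabolites).

    With one argument the within-group fingerprint is computed. Profiles of
    zero variance yield NaN rows/columns (flagged, excluded from counts).
    """
    same = profiles_b is None
    if same:
        profiles_b, group_b = profiles_a, group_a
    if profiles_a.shape[1] != profiles_b.shape[1]:
        raise ValueError("profile lengths differ between groups")
    A = profiles_a.to_numpy(dtype=float)
    B = profiles_b.to_numpy(dtype=float)
    n = A.shape[1]
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    sa = np.sqrt((Ac**2).sum(axis=1))
    sb = np.sqrt((Bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (Ac @ Bc.T) / np.outer(sa, sb)
    R[np.outer(sa == 0, np.ones(len(sb), bool))] = np.nan
    R[np.outer(np.ones(len(sa), bool), sb == 0)] = np.nan
    R = np.clip(R, -1.0, 1.0)
    if same:
        np.fill_diagonal(R, np.where(sa > 0, 1.0, np.nan))
    frame = pd.DataFrame(R, index=profiles_a.index, columns=profiles_b.index)
    return CorrelationFingerprint(
        r=frame,
        group_a=tuple(group_a),
        group_b=tuple(group_b),
        n_points=n,
    )
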