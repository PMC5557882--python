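"""Scoring deconvolution output against a synthetic study's ground truth.

Only meaningful for simulated cubes, which carry the planted peak registry;
real studies have no such truth and these helpers do not apply.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cube import RawGCMSCube
from .deconvolution import PeakTable

__all__ = ["match_peaks_to_truth", "recovery_correlations"]


def match_peaks_to_truth(table: PeakTable, cube: RawGCMSCube) -> pd.DataFrame:
    """Match each planted metabolite to the nearest estimated peak.

    A truth peak matches the estimated component in the same interval whose
    apex is closest; each estimated peak is used at most once (greedy by
    apex distance).
    """
    registry = cube.attrs["peak_registry"]
    comp = table.components
    rows = []
    used: set[str] = set()
    for _, t in registry.iterrows():
        if t["peak"] == "internal_standard":
            continue
        cands = comp[(comp["interval"] == t["interval"]) & ~comp["peak"].isin(used)]
        if cands.empty:
            rows.append({"metabolite": t["peak"], "matched_peak": None,
                         "apex_truth": int(t["apex"]), "apex_est": -1})
            continue
        dist = (cands["apex"] - t["apex"]).abs()
        best = dist.idxmin()
        used.add(str(comp.loc[best, "peak"]))
        rows.append({
            "metabolite": t["peak"],
            "matched_peak": str(comp.loc[best, "peak"]),
            "apex_truth": int(t["apex"]),
            "apex_est": int(comp.loc[best, "apex"]),
        })
    return pd.DataFrame(rows)


def recovery_correlations(
    table: PeakTable, cube: RawGCMSCube, true_areas: pd.DataFrame
) -> pd.Series:
    """Pearson r between estimated and planted concentration per metabolite.

    Unmatched metabolites get NaN.
    """
    matches = match_peaks_to_truth(table, cube)
    out = {}
    for _, row in matches.iterrows():
        met = row["metabolite"]
        if row["matched_peak"] is None:
            out[met] = np.nan
            continue
        est = table.concentrations[row["matched_peak"]].to_numpy()
        tru = true_areas[met].to_numpy()
        if est.std() == 0 or tru.std() == 0:
            out[met] = np.nan
        else:
            out[met] = float(np.corrcoef(est, tru)[0, 1])
    return pd.Series(out, name="pearson_r")
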