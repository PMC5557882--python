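"""Balanced full-factorial study designs for developing-seed metabolomics.

The reference design crosses three barley genotypes (the mother line Bomi and
its near-isogenic high-lysine ``lys3.a`` and high-β-glucan ``lys5.f`` mutants)
with two growth temperatures (15 °C / 25 °C) and eight grain-filling sampling
days (days after flowering, DAF), with two biological replicates per cell:
3 × 2 × 8 × 2 = 96 samples.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "GENOTYPES",
    "TEMPERATURES",
    "DAF_DAYS",
    "StudyDesignSpec",
    "build_design",
]

GENOTYPES: tuple[str, ...] = ("Bomi", "lys3.a", "lys5.f")
TEMPERATURES: tuple[str, ...] = ("LT", "HT")
#: sampling days after flowering during grain filling
DAF_DAYS: tuple[int, ...] = (9, 13, 16, 20, 23, 30, 39, 47)

FACTOR_COLUMNS = ("genotype", "temperature", "daf")


@dataclass(frozen=True)
class StudyDesignSpec:
    """Factor levels and replication of a balanced factorial study.

    Parameters
    ----------
    genotype_levels, temperature_levels
        Non-empty, duplicate-free label lists.
    daf_levels
        Sampling days after flowering, non-empty and duplicate-free.
    n_replicates
        Biological replicates per factor-level cell (≥ 1).
    seed
        RNG seed forwarded to downstream simulation stages.
    """

    genotype_levels: tuple[str, ...] = GENOTYPES
    temperature_levels: tuple[str, ...] = TEMPERATURES
    daf_levels: tuple[int, ...] = DAF_DAYS
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("genotype_levels", "temperature_levels", "daf_levels"):
            levels = getattr(self, name)
            if len(levels) == 0:
                raise ValueError(f"{name} must be non-empty")
            if len(set(levels)) != len(levels):
                raise ValueError(f"{name} contains duplicate levels: {levels!r}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def n_samples(self) -> int:
        return (
            len(self.genotype_levels)
            * len(self.temperature_levels)
            * len(self.daf_levels)
            * self.n_replicates
        )


def build_design(spec: StudyDesignSpec) -> pd.DataFrame:
    """Expand a :class:`StudyDesignSpec` into a balanced complete design table.

    Returns a DataFrame with columns ``sample_id, genotype, temperature, daf,
    replicate`` and exactly one row per factor-level combination × replicate.
    Deterministic given ``spec``.
    """
    rows = []
    for gt, temp, daf, rep in itertools.product(
        spec.genotype_levels,
        spec.temperature_levels,
        spec.daf_levels,
        range(1, spec.n_replicates + 1),
    ):
        sample_id = f"{gt}_{temp}_d{int(daf):02d}_r{rep}"
        rows.append((sample_id, gt, temp, int(daf), rep))
    table = pd.DataFrame(
        rows, columns=["sample_id", "genotype", "temperature", "daf", "replicate"]
    )
    assert len(table) == spec.n_samples
    return table


def check_balanced(design: pd.DataFrame, factors=FACTOR_COLUMNS) -> None:
    """Raise ``ValueError`` unless every factor-level cell has equal counts."""
    counts = design.groupby(list(factors), observed=True).size()
    expected = len(design) / counts.size
    if counts.nunique() != 1 or counts.iloc[0] != expected:
        raise ValueError(
            "design is not a balanced complete factorial over "
            f"{factors}; cell counts: {sorted(counts.unique())}"
        )
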