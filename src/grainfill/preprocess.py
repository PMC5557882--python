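"""Normalization chain for the metabolite table: X → Xi → Xs → scaled.

``Xi(i,k) = X(i,k) / IS(i)`` removes injection and extraction variability via
the spiked internal standard; ``Xs(i,k) = Xi(i,k) × Seed(i)`` multiplies back
the seed dry-matter weight, undoing the closure (dilution) effect that starch
accumulation imposes on every other metabolite measured per unit flour mass.
Multivariate analysis then runs on column-centred (optionally unit-variance
or Pareto scaled) data. The stage order is enforced: the transforms do not
commute and the downstream statistics are defined on ``Xs``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import check_balanced

__all__ = ["MetaboliteTable", "STAGES", "SCALING_METHODS"]

STAGES = ("raw", "is_normalized", "closure_corrected", "scaled")
SCALING_METHODS = ("autoscale", "pareto", "center")


@dataclass
class MetaboliteTable:
    """Samples × metabolites matrix bound to its design and normalizers.

    Parameters
    ----------
    X
        Concentration (peak-area) matrix, rows aligned with ``design``.
    design
        Sample metadata (``sample_id, genotype, temperature, daf, replicate``).
    is_area
        Internal-standard area per sample (required to reach ``Xi``).
    seed_weight
        Seed dry matter (mg) per sample (required to reach ``Xs``).
    stage
        One of ``raw, is_normalized, closure_corrected, scaled``.
    """

    X: pd.DataFrame
    design: pd.DataFrame
    is_area: pd.Series | None = None
    seed_weight: pd.Series | None = None
    stage: str = "raw"
    center_: pd.Series | None = None
    scale_: pd.Series | None = None
    scaling_method: str | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if len(self.X) != len(self.design):
            raise ValueError("X rows and design rows differ")
        if not np.array_equal(
            np.asarray(self.X.index), np.asarray(self.design["sample_id"])
        ):
            raise ValueError("X index must equal design sample_id order")
        for name, vec in (("is_area", self.is_area), ("seed_weight", self.seed_weight)):
            if vec is not None:
                if len(vec) != len(self.X):
                    raise ValueError(f"{name} length mismatch")
                if (np.asarray(vec, dtype=float) <= 0).any():
                    raise ValueError(f"{name} must be strictly positive")

    # ------------------------------------------------------------- stages
    def normalize_is(self, is_column: str | None = None) -> "MetaboliteTable":
        """Divide each row by its internal-standard area (stage raw → Xi).

        If ``is_column`` names a column of ``X`` it is used as the per-sample
        IS area and dropped from the table (its normalized value is 1 by
        construction and carries no information).
        """
        if self.stage != "raw":
            raise ValueError(f"normalize_is requires stage 'raw', got {self.stage!r}")
        X = self.X
        is_area = self.is_area
        if is_column is not None:
            if is_column not in X.columns:
                raise ValueError(f"IS column {is_column!r} not in table")
            is_area = X[is_column].rename("is_area")
            X = X.drop(columns=[is_column])
        if is_area is None:
            raise ValueError("internal-standard areas are required")
        if (np.asarray(is_area, dtype=float) <= 0).any():
            raise ValueError("internal-standard areas must be strictly positive")
        Xi = X.div(np.asarray(is_area, dtype=float), axis=0)
        return MetaboliteTable(
            X=Xi,
            design=self.design,
            is_area=is_area,
            seed_weight=self.seed_weight,
            stage="is_normalized",
        )

    def correct_closure(self) -> "MetaboliteTable":
        """Multiply each row by seed dry matter (stage Xi → Xs)."""
        if self.stage != "is_normalized":
            raise ValueError(
                f"correct_closure requires stage 'is_normalized', got {self.stage!r}"
            )
        if self.seed_weight is None:
            raise ValueError("seed weights are required for closure correction")
        Xs = self.X.mul(np.asarray(self.seed_weight, dtype=float), axis=0)
        return MetaboliteTable(
            X=Xs,
            design=self.design,
            is_area=self.is_area,
            seed_weight=self.seed_weight,
            stage="closure_corrected",
        )

    def scale(self, method: str = "autoscale") -> "MetaboliteTable":
        """Column-centre (and scale) for multivariate analysis (Xs → scaled).

        ``autoscale`` divides by the sample standard deviation (ddof=1),
        ``pareto`` by its square root, ``center`` only centres. Zero-variance
        columns are flagged, centred and left unscaled.
        """
        if self.stage != "closure_corrected":
            raise ValueError(
                f"scale requires stage 'closure_corrected', got {self.stage!r}"
            )
        if method not in SCALING_METHODS:
            raise ValueError(f"unknown scaling method {method!r}")
        center = self.X.mean(axis=0)
        sd = self.X.std(axis=0, ddof=1)
        zero_var = sd == 0
        if method == "autoscale":
            scale = sd.where(~zero_var, 1.0)
        elif method == "pareto":
            scale = np.sqrt(sd).where(~zero_var, 1.0)
        else:
            scale = pd.Series(1.0, index=self.X.columns)
        scaled = (self.X - center) / scale
        out = MetaboliteTable(
            X=scaled,
            design=self.design,
            is_area=self.is_area,
            seed_weight=self.seed_weight,
            stage="scaled",
            center_=center,
            scale_=scale,
            scaling_method=method,
        )
        out.zero_variance_columns = list(self.X.columns[zero_var])
        return out

    def inverse_scale(self) -> "MetaboliteTable":
        """Recover the closure-corrected table from a scaled one."""
        if self.stage != "scaled":
            raise ValueError("inverse_scale requires a scaled table")
        Xs = self.X * self.scale_ + self.center_
        return MetaboliteTable(
            X=Xs,
            design=self.design,
            is_area=self.is_area,
            seed_weight=self.seed_weight,
            stage="closure_corrected",
        )

    # ------------------------------------------------------------- helpers
    @property
    def values(self) -> np.ndarray:
        return self.X.to_numpy()

    def check_balanced(self) -> None:
        check_balanced(self.design)

    def reorder(self, order) -> "MetaboliteTable":
        order = np.asarray(order)
        return MetaboliteTable(
            X=self.X.iloc[order],
            design=self.design.iloc[order].reset_index(drop=True),
            is_area=None if self.is_area is None else self.is_area.iloc[order],
            seed_weight=None if self.seed_weight is None else self.seed_weight.iloc[order],
            stage=self.stage,
            center_=self.center_,
            scale_=self.scale_,
            scaling_method=self.scaling_method,
        )

    # ----------------------------------------------------------------- I/O
    def to_csv(self, path, sidecar: str | None = None) -> None:
        out = self.design.copy()
        if self.is_area is not None:
            out["is_area"] = np.asarray(self.is_area)
        if self.seed_weight is not None:
            out["seed_weight_mg"] = np.asarray(self.seed_weight)
        out = pd.concat([out, self.X.reset_index(drop=True)], axis=1)
        out.to_csv(path, index=False)
        if sidecar is not None:
            with open(sidecar, "w") as fh:
                json.dump({"stage": self.stage, "scaling_method": self.scaling_method}, fh)

    @classmethod
    def from_csv(cls, path, stage: str = "raw") -> "MetaboliteTable":
        frame = pd.read_csv(path)
        meta_cols = ["sample_id", "genotype", "temperature", "daf", "replicate"]
        extra = [c for c in ("is_area", "seed_weight_mg") if c in frame.columns]
        design = frame[meta_cols].copy()
        X = frame.drop(columns=meta_cols + extra)
        X.index = pd.Index(design["sample_id"], name="sample_id")
        return cls(
            X=X,
            design=design,
            is_area=frame["is_area"] if "is_area" in extra else None,
            seed_weight=frame["seed_weight_mg"] if "seed_weight_mg" in extra else None,
            stage=stage,
        )
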