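"""Three-way raw GC-MS data container (sample × elution time × m/z).

The cube is stored on disk as a NetCDF (classic format, written through
xarray's scipy backend) with dimensions ``(sample, time, mz)``, variables
``intensity``, ``time_axis``, ``mz_axis`` and the per-sample design table as
coordinate variables. Synthetic cubes additionally carry the internal
standard's interval/apex position as attributes — the analogue of knowing the
spiked standard's retention time on a real instrument.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

__all__ = ["RawGCMSCube"]

_DESIGN_COLS = ("sample_id", "genotype", "temperature", "daf", "replicate")


@dataclass
class RawGCMSCube:
    """Raw three-way GC-MS intensities with per-sample metadata.

    Attributes
    ----------
    intensity
        Array of shape ``(n_samples, n_timepoints, n_mz)``; finite.
    time_axis
        Strictly increasing scan indices or seconds, length ``n_timepoints``.
    mz_axis
        Strictly increasing m/z channel centres, length ``n_mz``.
    design
        Sample metadata aligned with the first axis.
    attrs
        Free-form metadata; synthetic cubes record ``is_interval`` and
        ``is_apex`` (internal-standard location) here.
    """

    intensity: np.ndarray
    time_axis: np.ndarray
    mz_axis: np.ndarray
    design: pd.DataFrame
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        self.mz_axis = np.asarray(self.mz_axis, dtype=float)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be (sample, time, mz)")
        n_s, n_t, n_m = self.intensity.shape
        if len(self.time_axis) != n_t or len(self.mz_axis) != n_m:
            raise ValueError("axis lengths inconsistent with intensity shape")
        if len(self.design) != n_s:
            raise ValueError("design row count inconsistent with intensity")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")
        for ax in (self.time_axis, self.mz_axis):
            if np.any(np.diff(ax) <= 0):
                raise ValueError("axes must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.intensity.shape[1]

    @property
    def n_mz(self) -> int:
        return self.intensity.shape[2]

    def slab(self, i: int) -> np.ndarray:
        """Time × m/z matrix of one sample."""
        return self.intensity[i]

    def reorder_samples(self, order: np.ndarray) -> "RawGCMSCube":
        order = np.asarray(order)
        return RawGCMSCube(
            self.intensity[order],
            self.time_axis,
            self.mz_axis,
            self.design.iloc[order].reset_index(drop=True),
            dict(self.attrs),
        )

    # ------------------------------------------------------------------ I/O
    def to_dataset(self) -> xr.Dataset:
        coords = {
            "time": ("time", self.time_axis),
            "mz": ("mz", self.mz_axis),
        }
        for col in self.design.columns:
            coords[f"sample_{col}"] = ("sample", self.design[col].to_numpy())
        ds = xr.Dataset(
            {
                "intensity": (("sample", "time", "mz"), self.intensity),
                "time_axis": ("time", self.time_axis),
                "mz_axis": ("mz", self.mz_axis),
            },
            coords=coords,
            attrs={k: v for k, v in self.attrs.items() if np.isscalar(v)},
        )
        return ds

    def to_netcdf(self, path) -> None:
        # NetCDF3 classic: portable, no HDF5 dependency
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "RawGCMSCube":
        design_cols = {}
        for name in ds.coords:
            sname = str(name)
            if sname.startswith("sample_"):
                design_cols[sname[len("sample_"):]] = np.asarray(ds[name].values)
        design = pd.DataFrame(design_cols)
        if "sample_id" in design.columns:
            design["sample_id"] = design["sample_id"].astype(str)
        for col in ("genotype", "temperature"):
            if col in design.columns:
                design[col] = design[col].astype(str)
        return cls(
            np.asarray(ds["intensity"].values),
            np.asarray(ds["time_axis"].values),
            np.asarray(ds["mz_axis"].values),
            design,
            dict(ds.attrs),
        )

    @classmethod
    def from_netcdf(cls, path) -> "RawGCMSCube":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load())
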