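"""Synthetic developing-seed GC-MS studies with known ground truth.

The generator plays the role of the wet lab: it plants developmental trends
(accumulation, depletion, accumulation-then-depletion), genotype- and
temperature-specific markers and genotype-specific developmental effects into
per-seed metabolite concentrations, then emulates the measurement chain —
starch-driven dilution (the closure effect), internal-standard injection
variability, retention-time shifts, co-elution and detector noise — to render
raw three-way chromatographic cubes. Every downstream stage of the pipeline
can therefore be scored against a known truth.

Measurement model
-----------------
Per-seed concentration of metabolite ``k`` in sample ``i``::

    conc(i,k) = baseline · trend_k(DAF_i) · (1 + δ terms) · exp(ε),  ε~N(0, σ²)

The detector sees a fixed flour mass, so the injected peak area is diluted by
seed dry matter and scaled by injection efficiency ``inj(i)``::

    area(i,k) = conc(i,k) · (w_ref / seed_weight_i) · inj(i)
    IS_area(i) = IS_baseline · inj(i)

Dividing by the internal standard (``Xi = X/IS``) removes ``inj``; multiplying
by seed weight (``Xs = Xi × Seed``) removes the dilution (closure) and recovers
``conc`` up to a constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .cube import RawGCMSCube
from .design import StudyDesignSpec, build_design, check_balanced
from .intervals import split_time_axis

__all__ = [
    "EffectSpec",
    "GroundTruth",
    "ChromatogramSpec",
    "simulate_concentrations",
    "render_raw_cube",
    "simulate_study",
    "logistic_seed_weight",
]

TREND_LABELS = ("accumulation", "depletion", "acc_then_depl", "flat")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def logistic_seed_weight(
    daf, w_min: float = 5.0, w_max: float = 45.0, d_mid: float = 22.0, rate: float = 6.0
):
    """Monotone logistic dry-matter accumulation (mg per seed) over DAF."""
    d = np.asarray(daf, dtype=float)
    return w_min + (w_max - w_min) * _sigmoid((d - d_mid) / rate)


def _trend_factor(label: str, amplitude: float, daf: np.ndarray) -> np.ndarray:
    """Multiplicative developmental profile, 1 at the low end of its range.

    Accumulation and depletion are logistic in DAF (smooth, strictly
    monotone); the transient trend is a Gaussian bump peaking near DAF 23.
    """
    d = np.asarray(daf, dtype=float)
    if label == "accumulation":
        return 1.0 + amplitude * _sigmoid((d - 20.0) / 5.0)
    if label == "depletion":
        return 1.0 + amplitude * _sigmoid(-(d - 20.0) / 5.0)
    if label == "acc_then_depl":
        return 1.0 + amplitude * np.exp(-0.5 * ((d - 23.0) / 6.0) ** 2)
    if label == "flat":
        return np.ones_like(d)
    raise ValueError(f"unknown trend label {label!r}")


@dataclass
class EffectSpec:
    """Planted effect structure of a synthetic study.

    The default factory :meth:`default_study` emulates the reference study's
    observed composition: 247 variables of which 136 accumulate, 28 deplete,
    10 accumulate then deplete (the rest are flat), 72 genotype markers
    (27 Bomi / 21 lys3.a / 24 lys5.f) and 14 temperature markers (9 LT / 5 HT).
    Effect magnitudes are free generator parameters, not estimates of the
    study.
    """

    n_metabolites: int
    baseline: float
    trend_labels: np.ndarray  # (K,) of TREND_LABELS
    trend_amplitude: float
    gt_markers: dict  # genotype -> np.ndarray of metabolite indices
    delta_gt: float
    temp_markers: dict  # temperature -> indices
    delta_temp: float
    gtxdaf_markers: dict  # genotype -> indices
    delta_gtxdaf: float
    noise_sd: float
    is_cv: float
    is_baseline: float = 5000.0
    seed_weight_curve: Callable = logistic_seed_weight
    seed_weight_cv: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        self.trend_labels = np.asarray(self.trend_labels, dtype=object)
        if len(self.trend_labels) != self.n_metabolites:
            raise ValueError("trend_labels length must equal n_metabolites")
        bad = set(self.trend_labels) - set(TREND_LABELS)
        if bad:
            raise ValueError(f"unknown trend labels: {bad}")
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if self.noise_sd < 0 or self.is_cv < 0:
            raise ValueError("noise_sd and is_cv must be non-negative")
        for d in (self.delta_gt, self.delta_temp, self.delta_gtxdaf):
            if not np.isfinite(d):
                raise ValueError("effect sizes must be finite")
        for marker_map in (self.gt_markers, self.temp_markers, self.gtxdaf_markers):
            for key, idx in marker_map.items():
                idx = np.asarray(idx, dtype=int)
                if idx.size and (idx.min() < 0 or idx.max() >= self.n_metabolites):
                    raise ValueError(f"marker indices for {key!r} out of range")
                marker_map[key] = idx

    @classmethod
    def default_study(
        cls,
        n_metabolites: int = 247,
        baseline: float = 1000.0,
        trend_amplitude: float = 1.5,
        delta_gt: float = 0.55,
        delta_temp: float = 0.15,
        delta_gtxdaf: float = 0.8,
        noise_sd: float = 0.35,
        is_cv: float = 0.10,
        n_gtxdaf: int = 18,
        seed: int = 0,
        genotypes=("Bomi", "lys3.a", "lys5.f"),
        temperatures=("LT", "HT"),
    ) -> "EffectSpec":
        """Effect structure proportioned after the reference barley study."""
        rng = np.random.default_rng(seed)
        frac = n_metabolites / 247.0
        n_acc = int(round(136 * frac))
        n_dep = int(round(28 * frac))
        n_bump = max(int(round(10 * frac)), 1)
        n_flat = n_metabolites - n_acc - n_dep - n_bump
        if n_flat < 1:  # tiny studies: give up accumulation slots first
            n_acc = max(n_acc + n_flat - 1, 0)
            n_flat = n_metabolites - n_acc - n_dep - n_bump
        if n_flat < 1:
            raise ValueError("n_metabolites too small for the default allocation")
        labels = np.array(
            ["accumulation"] * n_acc
            + ["depletion"] * n_dep
            + ["acc_then_depl"] * n_bump
            + ["flat"] * n_flat,
            dtype=object,
        )
        rng.shuffle(labels)

        def _draw(n):
            return rng.choice(n_metabolites, size=n, replace=False)

        gt_counts = dict(zip(genotypes, (27, 21, 24)))
        temp_counts = dict(zip(temperatures, (9, 5)))
        all_gt = _draw(int(round(sum(gt_counts.values()) * frac)))
        gt_markers, pos = {}, 0
        for g in genotypes:
            n_g = int(round(gt_counts[g] * frac))
            gt_markers[g] = all_gt[pos : pos + n_g]
            pos += n_g
        all_temp = _draw(max(int(round(sum(temp_counts.values()) * frac)), 2))
        temp_markers, pos = {}, 0
        for t in temperatures:
            n_t = max(int(round(temp_counts[t] * frac)), 1)
            temp_markers[t] = all_temp[pos : pos + n_t]
            pos += n_t
        n_int = max(int(round(n_gtxdaf * frac)), 1)
        all_int = _draw(n_int * len(genotypes))
        gtxdaf_markers = {
            g: all_int[j * n_int : (j + 1) * n_int] for j, g in enumerate(genotypes)
        }
        return cls(
            n_metabolites=n_metabolites,
            baseline=baseline,
            trend_labels=labels,
            trend_amplitude=trend_amplitude,
            gt_markers=gt_markers,
            delta_gt=delta_gt,
            temp_markers=temp_markers,
            delta_temp=delta_temp,
            gtxdaf_markers=gtxdaf_markers,
            delta_gtxdaf=delta_gtxdaf,
            noise_sd=noise_sd,
            is_cv=is_cv,
            seed=seed,
        )

    @classmethod
    def null(cls, n_metabolites: int, baseline: float = 1000.0, noise_sd: float = 0.0,
             is_cv: float = 0.0, seed: int = 0) -> "EffectSpec":
        """No planted effects at all: flat trends, zero deltas."""
        return cls(
            n_metabolites=n_metabolites,
            baseline=baseline,
            trend_labels=np.array(["flat"] * n_metabolites, dtype=object),
            trend_amplitude=0.0,
            gt_markers={},
            delta_gt=0.0,
            temp_markers={},
            delta_temp=0.0,
            gtxdaf_markers={},
            delta_gtxdaf=0.0,
            noise_sd=noise_sd,
            is_cv=is_cv,
            seed=seed,
        )

    def metabolite_names(self) -> list[str]:
        return [f"met_{k + 1:04d}" for k in range(self.n_metabolites)]


@dataclass
class GroundTruth:
    """Everything the generator knows about one simulated study."""

    design: pd.DataFrame
    concentrations: pd.DataFrame  # samples × metabolites, closure-free
    areas: pd.DataFrame  # samples × metabolites, as seen by the detector
    trend_labels: pd.Series  # per metabolite
    gt_markers: dict
    temp_markers: dict
    gtxdaf_markers: dict
    seed_weight: pd.Series  # mg per seed, per sample
    is_area: pd.Series  # internal-standard area per sample
    effect_spec: EffectSpec

    def __post_init__(self) -> None:
        n = len(self.design)
        for frame in (self.concentrations, self.areas):
            if frame.shape != (n, self.effect_spec.n_metabolites):
                raise ValueError("matrix dimensions inconsistent with design/spec")
        if len(self.seed_weight) != n or len(self.is_area) != n:
            raise ValueError("per-sample vectors inconsistent with design")

    def to_csv(self, path) -> None:
        """Design + per-sample IS/seed-weight + observed areas, one wide CSV."""
        out = self.design.copy()
        out["is_area"] = self.is_area.to_numpy()
        out["seed_weight_mg"] = self.seed_weight.to_numpy()
        out = pd.concat([out, self.areas.reset_index(drop=True)], axis=1)
        out.to_csv(path, index=False)


def simulate_concentrations(design: pd.DataFrame, eff: EffectSpec) -> GroundTruth:
    """Plant the specified effects into a samples × metabolites matrix.

    ``conc(i,k) = baseline · trend_k(DAF_i) · (1 + δ·membership) · exp(ε)``
    with log-normal replicate noise; the measurement-side ``areas`` add the
    dilution (closure) and injection factors described in the module
    docstring. Fully determined by ``eff.seed``.
    """
    check_balanced(design)
    rng = np.random.default_rng(eff.seed)
    n = len(design)
    K = eff.n_metabolites
    daf = design["daf"].to_numpy(dtype=float)
    gt = design["genotype"].to_numpy()
    temp = design["temperature"].to_numpy()

    conc = np.full((n, K), eff.baseline, dtype=float)
    for k in range(K):
        conc[:, k] *= _trend_factor(eff.trend_labels[k], eff.trend_amplitude, daf)

    for g, idx in eff.gt_markers.items():
        rows = gt == g
        if rows.any() and idx.size:
            conc[np.ix_(rows, idx)] *= 1.0 + eff.delta_gt
    for t, idx in eff.temp_markers.items():
        rows = temp == t
        if rows.any() and idx.size:
            conc[np.ix_(rows, idx)] *= 1.0 + eff.delta_temp
    # genotype-specific developmental modulation, mean-free over DAF so it
    # loads on the GT×DAF interaction rather than the GT main effect
    if eff.gtxdaf_markers:
        span = daf.max() - daf.min()
        u = (daf - daf.mean()) / span if span > 0 else np.zeros_like(daf)
        for g, idx in eff.gtxdaf_markers.items():
            rows = gt == g
            if rows.any() and idx.size:
                conc[np.ix_(rows, idx)] *= (1.0 + eff.delta_gtxdaf * u[rows])[:, None]

    if eff.noise_sd > 0:
        conc *= np.exp(rng.normal(0.0, eff.noise_sd, size=(n, K)))
    assert np.all(conc > 0)

    weights = eff.seed_weight_curve(daf)
    if eff.seed_weight_cv > 0:
        weights = weights * np.exp(rng.normal(0.0, eff.seed_weight_cv, size=n))
    inj = np.exp(rng.normal(0.0, eff.is_cv, size=n)) if eff.is_cv > 0 else np.ones(n)
    w_ref = float(np.mean(eff.seed_weight_curve(np.unique(daf))))
    areas = conc * (w_ref / weights)[:, None] * inj[:, None]

    names = eff.metabolite_names()
    index = pd.Index(design["sample_id"], name="sample_id")
    return GroundTruth(
        design=design.reset_index(drop=True),
        concentrations=pd.DataFrame(conc, index=index, columns=names),
        areas=pd.DataFrame(areas, index=index, columns=names),
        trend_labels=pd.Series(list(eff.trend_labels), index=names, name="trend"),
        gt_markers=eff.gt_markers,
        temp_markers=eff.temp_markers,
        gtxdaf_markers=eff.gtxdaf_markers,
        seed_weight=pd.Series(weights, index=index, name="seed_weight_mg"),
        is_area=pd.Series(eff.is_baseline * inj, index=index, name="is_area"),
        effect_spec=eff,
    )


@dataclass
class ChromatogramSpec:
    """Rendering parameters for raw three-way cubes.

    Defaults emulate the reference acquisition: 4800 elution time points ×
    450 m/z channels, modelled in 121 elution-time intervals. ``peak_width``
    is the Gaussian σ in scan points; per-sample retention-time shifts are
    drawn from N(0, rt_shift_sd²) truncated at ±3σ so every peak stays inside
    its interval.
    """

    n_timepoints: int = 4800
    n_mz_channels: int = 450
    n_intervals: int = 121
    peak_width: float = 3.0
    rt_shift_sd: float = 1.0
    peaks_per_interval: int = 3
    baseline: float = 5.0
    noise_sd: float = 2.0
    spectrum_sparsity: float = 0.04
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.peak_width <= 0:
            raise ValueError("peak_width must be positive")
        if self.rt_shift_sd < 0 or self.noise_sd < 0 or self.baseline < 0:
            raise ValueError("rt_shift_sd, noise_sd and baseline must be >= 0")
        if self.peaks_per_interval < 1:
            raise ValueError("peaks_per_interval must be >= 1")
        if not 0 < self.spectrum_sparsity <= 1:
            raise ValueError("spectrum_sparsity must be in (0, 1]")
        interval_len = self.n_timepoints // self.n_intervals
        margin = self._edge_margin()
        if interval_len < 2 * margin + 1:
            raise ValueError(
                "intervals too short for the configured peak width and shifts"
            )

    def _edge_margin(self) -> int:
        # keep the apex plus its ±3σ shift envelope away from interval edges
        return int(np.ceil(2.0 * self.peak_width + 3.0 * self.rt_shift_sd))


def _random_spectrum(rng: np.random.Generator, n_mz: int, sparsity: float) -> np.ndarray:
    """Sparse non-negative unit-norm fragment spectrum."""
    n_frag = max(int(round(sparsity * n_mz)), 3)
    channels = rng.choice(n_mz, size=n_frag, replace=False)
    s = np.zeros(n_mz)
    s[channels] = rng.exponential(1.0, size=n_frag)
    s[channels[rng.integers(n_frag)]] += 1.0  # guarantee a dominant fragment
    return s / np.linalg.norm(s)


def render_raw_cube(truth: GroundTruth, cspec: ChromatogramSpec) -> RawGCMSCube:
    """Render observed areas into a raw (sample × time × m/z) cube.

    Each metabolite gets one elution-time interval (the internal standard an
    interval of its own), a Gaussian elution profile normalised to unit time
    integral — so the time-and-m/z sum of a noiseless peak equals
    ``area(i,k) · Σ_m s_k(m)`` — shifted per sample, and a fixed sparse
    non-negative spectrum shared across samples. Detector noise is truncated
    so intensities stay non-negative whenever ``baseline ≥ 0``.
    """
    eff = truth.effect_spec
    seed = cspec.seed if cspec.seed is not None else eff.seed + 1
    rng = np.random.default_rng(seed)
    bounds = split_time_axis(cspec.n_timepoints, cspec.n_intervals)
    K = eff.n_metabolites
    capacity = (cspec.n_intervals - 1) * cspec.peaks_per_interval
    if K > capacity:
        raise ValueError(
            f"{K} metabolites exceed capacity {capacity} "
            f"({cspec.n_intervals - 1} intervals × {cspec.peaks_per_interval} peaks; "
            "one interval is reserved for the internal standard)"
        )

    # assign metabolites to intervals round-robin; IS gets the last interval
    assignment: list[list[int]] = [[] for _ in range(cspec.n_intervals - 1)]
    for k in range(K):
        assignment[k % (cspec.n_intervals - 1)].append(k)

    margin = cspec._edge_margin()
    apex = np.empty(K + 1, dtype=int)  # last entry: internal standard
    interval_of = np.empty(K + 1, dtype=int)
    for iv, members in enumerate(assignment):
        if not members:
            continue
        start, stop = bounds[iv]
        usable = np.linspace(start + margin, stop - 1 - margin, num=len(members) + 2)
        for j, k in enumerate(members):
            apex[k] = int(round(usable[j + 1]))
            interval_of[k] = iv
    is_iv = cspec.n_intervals - 1
    s0, s1 = bounds[is_iv]
    apex[K] = (s0 + s1) // 2
    interval_of[K] = is_iv
    if np.any(apex < 0) or np.any(apex >= cspec.n_timepoints):
        raise ValueError("peak placed outside the time axis")

    spectra = np.stack(
        [_random_spectrum(rng, cspec.n_mz_channels, cspec.spectrum_sparsity)
         for _ in range(K + 1)]
    )

    n = len(truth.design)
    amounts = np.column_stack([truth.areas.to_numpy(), truth.is_area.to_numpy()])
    # retention drift is locally rigid: one shift per sample and interval,
    # shared by all compounds eluting there (this is also what keeps the
    # cross-product of co-eluting profiles constant across samples)
    interval_shifts = (
        np.clip(
            rng.normal(0.0, cspec.rt_shift_sd, size=(n, cspec.n_intervals)),
            -3.0 * cspec.rt_shift_sd,
            3.0 * cspec.rt_shift_sd,
        )
        if cspec.rt_shift_sd > 0
        else np.zeros((n, cspec.n_intervals))
    )
    shifts = interval_shifts[:, interval_of]

    t = np.arange(cspec.n_timepoints, dtype=float)
    cube = np.full((n, cspec.n_timepoints, cspec.n_mz_channels), cspec.baseline)
    for k in range(K + 1):
        centres = apex[k] + shifts[:, k]  # (n,)
        g = np.exp(-0.5 * ((t[None, :] - centres[:, None]) / cspec.peak_width) ** 2)
        g /= g.sum(axis=1, keepdims=True)  # unit time integral per sample
        # rank-1 outer product per sample, restricted to nonzero channels
        nz = np.flatnonzero(spectra[k])
        cube[:, :, nz] += (
            amounts[:, k, None, None] * g[:, :, None] * spectra[k][nz][None, None, :]
        )
    if cspec.noise_sd > 0:
        cube += rng.normal(0.0, cspec.noise_sd, size=cube.shape)
        np.clip(cube, 0.0, None, out=cube)

    registry = pd.DataFrame(
        {
            "peak": truth.areas.columns.tolist() + ["internal_standard"],
            "interval": interval_of,
            "apex": apex,
        }
    )
    attrs = {
        "is_interval": int(is_iv),
        "is_apex": int(apex[K]),
        "n_intervals": int(cspec.n_intervals),
        "peak_registry": registry,
        "spectra": spectra,
    }
    return RawGCMSCube(
        intensity=cube,
        time_axis=t,
        mz_axis=np.arange(50, 50 + cspec.n_mz_channels, dtype=float),
        design=truth.design.copy(),
        attrs=attrs,
    )


def simulate_study(
    design_spec: StudyDesignSpec,
    eff: EffectSpec | None = None,
    cspec: ChromatogramSpec | None = None,
    render: bool = True,
):
    """Convenience wrapper: design → ground truth → (optionally) raw cube."""
    design = build_design(design_spec)
    if eff is None:
        eff = EffectSpec.default_study(seed=design_spec.seed)
    truth = simulate_concentrations(design, eff)
    if not render:
        return design, truth, None
    if cspec is None:
        cspec = ChromatogramSpec()
    return design, truth, render_raw_cube(truth, cspec)
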