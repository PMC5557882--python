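"""End-to-end pipeline: simulate → deconvolve → preprocess → ASCA → markers →
trends → correlations → report, with a reproducibility manifest.

Every stage reads only the previous stage's files, all randomness is pinned
by explicit seeds in the configuration, and a manifest records the config
hash and SHA-256 digests of every output so that re-runs can be verified
bit-for-bit on the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .asca import ASCA, term_name
from .correlations import critical_r, daf_profiles, fingerprint
from .cube import RawGCMSCube
from .deconvolution import (
    ValidationRules,
    deconvolve_cube,
    locate_internal_standard,
    write_model_summaries,
)
from .design import StudyDesignSpec, build_design
from .multivariate import double_cross_validate, select_markers
from .preprocess import MetaboliteTable
from .simulate import ChromatogramSpec, EffectSpec, render_raw_cube, simulate_concentrations
from .trends import anova_univariate, classify_trends

__all__ = ["PipelineConfig", "RunManifest", "PipelineStageError", "run_pipeline", "render_report"]

STAGE_ORDER = ("simulate", "deconvolve", "preprocess", "asca", "markers", "trends", "correlate", "report")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def _strict(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")


@dataclass
class PipelineConfig:
    """Typed, strictly validated pipeline configuration.

    All seeds must be explicit; unknown keys anywhere are rejected.
    """

    schema_version: int = 1
    design: dict = field(default_factory=dict)
    effects: dict = field(default_factory=dict)
    chromatogram: dict = field(default_factory=dict)
    deconvolution: dict = field(default_factory=dict)
    scaling: str = "autoscale"
    asca: dict = field(default_factory=dict)
    markers: dict = field(default_factory=dict)
    trends: dict = field(default_factory=dict)
    correlations: dict = field(default_factory=dict)

    _DESIGN_KEYS = {"genotype_levels", "temperature_levels", "daf_levels", "n_replicates", "seed"}
    _EFFECT_KEYS = {
        "n_metabolites", "baseline", "trend_amplitude", "delta_gt", "delta_temp",
        "delta_gtxdaf", "noise_sd", "is_cv", "n_gtxdaf", "seed",
    }
    _CHROM_KEYS = {
        "n_timepoints", "n_mz_channels", "n_intervals", "peak_width", "rt_shift_sd",
        "peaks_per_interval", "baseline", "noise_sd", "spectrum_sparsity", "seed",
    }
    _DECONV_KEYS = {"r_max", "tol", "max_iter", "fit_gain_threshold", "min_median_snr"}
    _ASCA_KEYS = {"n_permutations", "seed"}
    _MARKER_KEYS = {
        "vip_threshold", "coef_stability", "outer_k", "inner_k", "n_comp_max", "seed",
    }
    _TREND_KEYS = {"rho_min", "bump_margin"}
    _CORR_KEYS = {"alpha", "average_replicates"}

    def __post_init__(self) -> None:
        if self.schema_version != 1:
            raise ValueError(f"unsupported schema_version {self.schema_version}")
        _strict(self.design, self._DESIGN_KEYS, "design")
        _strict(self.effects, self._EFFECT_KEYS, "effects")
        _strict(self.chromatogram, self._CHROM_KEYS, "chromatogram")
        _strict(self.deconvolution, self._DECONV_KEYS, "deconvolution")
        _strict(self.asca, self._ASCA_KEYS, "asca")
        _strict(self.markers, self._MARKER_KEYS, "markers")
        _strict(self.trends, self._TREND_KEYS, "trends")
        _strict(self.correlations, self._CORR_KEYS, "correlations")
        for block, name in ((self.design, "design"), (self.asca, "asca"), (self.markers, "markers")):
            if "seed" not in block:
                raise ValueError(f"config block {name!r} must declare an explicit seed")
        if self.scaling not in ("autoscale", "pareto", "center"):
            raise ValueError(f"unknown scaling {self.scaling!r}")

    # ------------------------------------------------------------- factories
    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        _strict(raw, {f.name for f in dataclasses.fields(cls)}, "top level")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def small(cls, seed: int = 0) -> "PipelineConfig":
        """24-sample, 40-metabolite, 20-interval smoke-scale study."""
        return cls(
            design={
                "genotype_levels": ["Bomi", "lys3.a", "lys5.f"],
                "temperature_levels": ["LT", "HT"],
                "daf_levels": [9, 16, 23, 39],
                "n_replicates": 1,
                "seed": seed,
            },
            effects={"n_metabolites": 40, "noise_sd": 0.12, "seed": seed + 1},
            chromatogram={
                "n_timepoints": 800,
                "n_mz_channels": 60,
                "n_intervals": 20,
                "peak_width": 2.5,
                "rt_shift_sd": 1.0,
                "peaks_per_interval": 3,
                "baseline": 5.0,
                "noise_sd": 1.5,
                "seed": seed + 2,
            },
            deconvolution={"r_max": 4},
            asca={"n_permutations": 200, "seed": seed + 3},
            markers={"outer_k": 4, "inner_k": 3, "n_comp_max": 5, "seed": seed + 4},
        )

    # -------------------------------------------------------------- builders
    def design_spec(self) -> StudyDesignSpec:
        d = dict(self.design)
        for key in ("genotype_levels", "temperature_levels", "daf_levels"):
            if key in d:
                d[key] = tuple(d[key])
        return StudyDesignSpec(**d)

    def effect_spec(self) -> EffectSpec:
        return EffectSpec.default_study(**self.effects)

    def chromatogram_spec(self) -> ChromatogramSpec:
        return ChromatogramSpec(**self.chromatogram)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    version: str
    started: str
    finished: str | None
    seeds: dict
    stages: dict  # stage -> {"status", "outputs": {path: digest}}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir, verbose: bool = False) -> RunManifest:
    """Execute all stages in fixed order, writing files and a manifest.

    A stage failure halts the run with a stage-named error; files already
    written are retained for inspection.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.config_hash(),
        version=__version__,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
        finished=None,
        seeds={
            "design": config.design.get("seed"),
            "effects": config.effects.get("seed"),
            "chromatogram": config.chromatogram.get("seed"),
            "asca": config.asca.get("seed"),
            "markers": config.markers.get("seed"),
        },
        stages={},
    )

    def record(stage: str, outputs: list[Path]) -> None:
        manifest.stages[stage] = {
            "status": "ok",
            "outputs": {p.name: _digest(p) for p in outputs},
        }
        if verbose:
            import sys

            print(f"[{stage}] ok: {', '.join(p.name for p in outputs)}", file=sys.stderr)

    state: dict = {}
    for stage in STAGE_ORDER[:-1]:
        try:
            outputs = _STAGES[stage](config, out, state)
            record(stage, outputs)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            manifest.stages[stage] = {"status": "failed", "error": str(exc)}
            manifest.to_json(out / "manifest.json")
            raise PipelineStageError(stage, exc) from exc

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.to_json(out / "manifest.json")
    report_path = render_report(out)
    manifest.stages["report"] = {"status": "ok", "outputs": {report_path.name: _digest(report_path)}}
    manifest.to_json(out / "manifest.json")
    return manifest


# ------------------------------------------------------------------ stages
def _stage_simulate(config, out, state):
    design = build_design(config.design_spec())
    eff = config.effect_spec()
    truth = simulate_concentrations(design, eff)
    cube = render_raw_cube(truth, config.chromatogram_spec())
    design.to_csv(out / "design.csv", index=False)
    truth.to_csv(out / "ground_truth_areas.csv")
    truth.concentrations.to_csv(out / "ground_truth_concentrations.csv")
    cube.to_netcdf(out / "cube.nc")
    state.update(design=design, truth=truth, cube=cube)
    return [out / "design.csv", out / "ground_truth_areas.csv",
            out / "ground_truth_concentrations.csv", out / "cube.nc"]


def _stage_deconvolve(config, out, state):
    cube = state["cube"]
    d = config.deconvolution
    rules = ValidationRules(
        fit_gain_threshold=d.get("fit_gain_threshold", 1.0),
        min_median_snr=d.get("min_median_snr", 5.0),
    )
    table, models = deconvolve_cube(
        cube,
        n_intervals=int(cube.attrs.get("n_intervals", config.chromatogram.get("n_intervals", 121))),
        R_max=d.get("r_max", 5),
        rules=rules,
        tol=d.get("tol", 1e-8),
        max_iter=d.get("max_iter", 2000),
    )
    table.to_csv(out / "peak_table.csv")
    table.components_to_csv(out / "peak_components.csv")
    write_model_summaries(models, out / "interval_models.json")
    state["peak_table"] = table
    return [out / "peak_table.csv", out / "peak_components.csv", out / "interval_models.json"]


def _stage_preprocess(config, out, state):
    table = state["peak_table"]
    cube = state["cube"]
    truth = state["truth"]
    is_peak = locate_internal_standard(
        table, int(cube.attrs["is_interval"]), int(cube.attrs["is_apex"])
    )
    raw = MetaboliteTable(
        X=table.concentrations,
        design=cube.design,
        seed_weight=truth.seed_weight.reset_index(drop=True),
        stage="raw",
    )
    xi = raw.normalize_is(is_column=is_peak)
    xs = xi.correct_closure()
    scaled = xs.scale(method=config.scaling)
    xi.to_csv(out / "table_xi.csv", sidecar=out / "table_xi.stage.json")
    xs.to_csv(out / "table_xs.csv", sidecar=out / "table_xs.stage.json")
    scaled.to_csv(out / "table_scaled.csv", sidecar=out / "table_scaled.stage.json")
    state.update(xs=xs, scaled=scaled)
    return [out / "table_xi.csv", out / "table_xs.csv", out / "table_scaled.csv"]


def _stage_asca(config, out, state):
    scaled = state["scaled"]
    res = ASCA(scaled).fit(
        n_permutations=config.asca.get("n_permutations", 1000),
        seed=config.asca["seed"],
    )
    res.summary().to_csv(out / "asca_summary.csv", index=False)
    for term in res.model.terms:
        res.effect_frame(term).to_csv(out / f"effect_{term_name(term).replace('×', 'x')}.csv")
    pca = res.pca_of_effect(("genotype",), n_components=2)
    pca.scores_frame(res.model.design).to_csv(out / "asca_scores_GT.csv", index=False)
    state["asca"] = res
    return sorted(out.glob("effect_*.csv")) + [out / "asca_summary.csv", out / "asca_scores_GT.csv"]


def _stage_markers(config, out, state):
    scaled = state["scaled"]
    m = config.markers
    labels = scaled.design["genotype"].to_numpy()
    report_cv = double_cross_validate(
        scaled.values,
        labels,
        task="classification",
        n_comp_grid=range(1, m.get("n_comp_max", 10) + 1),
        outer_k=m.get("outer_k", 8),
        inner_k=m.get("inner_k", 7),
        seed=m["seed"],
    )
    markers = select_markers(
        scaled.values,
        labels,
        report_cv,
        vip_threshold=m.get("vip_threshold", 1.0),
        coef_stability=m.get("coef_stability", 0.8),
        variable_names=scaled.X.columns,
    )
    anova = anova_univariate(state["xs"])
    markers.attach_univariate(anova["p_genotype"])
    markers.to_csv(out / "markers.csv")
    report_cv.summary().to_csv(out / "cv_summary.csv", index=False)
    anova.to_csv(out / "anova.csv")
    state["markers"] = markers
    state["cv"] = report_cv
    return [out / "markers.csv", out / "cv_summary.csv", out / "anova.csv"]


def _stage_trends(config, out, state):
    t = config.trends
    labels = classify_trends(
        state["xs"], rho_min=t.get("rho_min", 0.6), bump_margin=t.get("bump_margin", 0.2)
    )
    labels.to_csv(out / "trends.csv")
    state["trends"] = labels
    return [out / "trends.csv"]


def _stage_correlate(config, out, state):
    xs = state["xs"]
    c = config.correlations
    alpha = c.get("alpha", 0.05)
    avg = c.get("average_replicates", True)
    rows = []
    hists = []
    groups = (
        xs.design[["genotype", "temperature"]].drop_duplicates().itertuples(index=False)
    )
    for gt, temp in groups:
        prof = daf_profiles(xs, gt, temp, average_replicates=avg)
        fp = fingerprint(prof, group_a=(gt, temp))
        n_pos, n_neg = fp.count_significant(alpha)
        rows.append(
            {
                "genotype": gt,
                "temperature": temp,
                "n_positive": n_pos,
                "n_negative": n_neg,
                "n_valid_pairs": fp.n_valid(),
                "r_critical": critical_r(fp.n_points, alpha),
            }
        )
        h = fp.coefficient_distribution()
        h.insert(0, "temperature", temp)
        h.insert(0, "genotype", gt)
        hists.append(h)
    pd.DataFrame(rows).to_csv(out / "correlation_counts.csv", index=False)
    pd.concat(hists).to_csv(out / "correlation_histograms.csv", index=False)
    return [out / "correlation_counts.csv", out / "correlation_histograms.csv"]


_STAGES = {
    "simulate": _stage_simulate,
    "deconvolve": _stage_deconvolve,
    "preprocess": _stage_preprocess,
    "asca": _stage_asca,
    "markers": _stage_markers,
    "trends": _stage_trends,
    "correlate": _stage_correlate,
}


def render_report(out_dir) -> Path:
    """Consolidate stage outputs into a single markdown report.

    Raises with the list of missing stage outputs when the run is incomplete.
    """
    out = Path(out_dir)
    required = {
        "asca": out / "asca_summary.csv",
        "markers": out / "markers.csv",
        "trends": out / "trends.csv",
        "correlate": out / "correlation_counts.csv",
        "cv": out / "cv_summary.csv",
    }
    missing = [name for name, p in required.items() if not p.exists()]
    if missing:
        raise FileNotFoundError(f"cannot render report; missing stage outputs: {missing}")
    asca = pd.read_csv(required["asca"])
    markers = pd.read_csv(required["markers"])
    trends = pd.read_csv(required["trends"], index_col=0)
    corr = pd.read_csv(required["correlate"])
    cv = pd.read_csv(required["cv"])

    trend_counts = trends["trend"].value_counts().reindex(
        ["accumulation", "depletion", "acc_then_depl", "none"], fill_value=0
    )
    lines = [
        "# Pipeline report",
        "",
        "## Variance partition (ASCA)",
        asca.to_string(index=False),
        "",
        "## Genotype classification (double cross-validation)",
        cv.to_string(index=False),
        "",
        f"## Markers ({len(markers)} selected)",
        markers.to_string(index=False) if len(markers) else "(none selected)",
        "",
        "## Developmental trends",
        trend_counts.to_string(),
        f"total variables: {int(trend_counts.sum())}",
        "",
        "## Significant developmental correlations per group",
        corr.to_string(index=False),
        "",
    ]
    path = out / "report.md"
    path.write_text("\n".join(lines))
    return path
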