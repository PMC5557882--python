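import numpy as np
import pandas as pd
import pytest
from scipy import stats

from grainfill.design import StudyDesignSpec, build_design
from grainfill.simulate import (
    ChromatogramSpec,
    EffectSpec,
    render_raw_cube,
    simulate_concentrations,
)
from grainfill.cube import RawGCMSCube


@pytest.fixture(scope="module")
def small_design():
    return build_design(StudyDesignSpec())


def _null_spec(K=4, **kw):
    return EffectSpec.null(n_metabolites=K, **kw)


class TestConcentrations:
    def test_null_model_all_entries_equal_baseline(self, small_design):
        eff = _null_spec(baseline=1000.0)
        eff.seed_weight_cv = 0.0
        truth = simulate_concentrations(small_design, eff)
        assert np.all(truth.concentrations.to_numpy() == 1000.0)

    def test_accumulation_trend_monotone_without_noise(self, small_design):
        eff = EffectSpec(
            n_metabolites=1, baseline=100.0,
            trend_labels=np.array(["accumulation"], dtype=object),
            trend_amplitude=2.0, gt_markers={}, delta_gt=0.0,
            temp_markers={}, delta_temp=0.0, gtxdaf_markers={}, delta_gtxdaf=0.0,
            noise_sd=0.0, is_cv=0.0,
        )
        truth = simulate_concentrations(small_design, eff)
        sub = truth.design.assign(v=truth.concentrations.iloc[:, 0].to_numpy())
        one = sub[(sub.genotype == "Bomi") & (sub.temperature == "LT") & (sub.replicate == 1)]
        vals = one.sort_values("daf")["v"].to_numpy()
        assert np.all(np.diff(vals) > 0)

    def test_genotype_marker_log_ratio_matches_delta(self, small_design):
        """Monte-Carlo oracle: the planted δ_GT appears as a log(1+δ) group
        mean shift, within 3 SEM over 200 seeded simulations."""
        ratios = []
        for seed in range(200):
            eff = EffectSpec(
                n_metabolites=3, baseline=500.0,
                trend_labels=np.array(["flat"] * 3, dtype=object),
                trend_amplitude=0.0,
                gt_markers={"Bomi": np.array([1])}, delta_gt=0.5,
                temp_markers={}, delta_temp=0.0, gtxdaf_markers={},
                delta_gtxdaf=0.0, noise_sd=0.2, is_cv=0.0, seed=seed,
            )
            truth = simulate_concentrations(small_design, eff)
            logc = np.log(truth.concentrations.iloc[:, 1].to_numpy())
            carrier = truth.design.genotype == "Bomi"
            ratios.append(logc[carrier].mean() - logc[~carrier].mean())
        ratios = np.array(ratios)
        sem = ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert abs(ratios.mean() - np.log(1.5)) < 3 * sem

    def test_seed_determinism_is_bitwise(self, small_design):
        eff_a = EffectSpec.default_study(n_metabolites=20, seed=42)
        eff_b = EffectSpec.default_study(n_metabolites=20, seed=42)
        ta = simulate_concentrations(small_design, eff_a)
        tb = simulate_concentrations(small_design, eff_b)
        assert np.array_equal(ta.concentrations.to_numpy(), tb.concentrations.to_numpy())
        assert np.array_equal(ta.areas.to_numpy(), tb.areas.to_numpy())
        assert np.array_equal(ta.is_area.to_numpy(), tb.is_area.to_numpy())

    def test_closure_dilution_planted_and_removed(self, small_design):
        """Flat metabolites acquire a negative DAF trend through seed-weight
        dilution in Xi-space and lose it after the closure correction."""
        hits = 0
        n_runs = 10
        for seed in range(n_runs):
            eff = _null_spec(K=6, noise_sd=0.1, is_cv=0.1)
            eff.seed = seed
            truth = simulate_concentrations(small_design, eff)
            xi = truth.areas.div(truth.is_area, axis=0)
            xs = xi.mul(truth.seed_weight, axis=0)
            daf = truth.design.daf.to_numpy()
            rho_xi = np.mean([stats.spearmanr(xi.iloc[:, k], daf).statistic for k in range(6)])
            rho_xs = np.mean([abs(stats.spearmanr(xs.iloc[:, k], daf).statistic) for k in range(6)])
            if rho_xi < -0.5 and rho_xs < 0.3:
                hits += 1
        assert hits >= int(0.9 * n_runs)

    def test_default_allocation_matches_study_proportions(self):
        eff = EffectSpec.default_study(n_metabolites=247, seed=0)
        counts = pd.Series(list(eff.trend_labels)).value_counts()
        assert counts["accumulation"] == 136
        assert counts["depletion"] == 28
        assert counts["acc_then_depl"] == 10
        assert sum(len(v) for v in eff.gt_markers.values()) == 72
        assert sum(len(v) for v in eff.temp_markers.values()) == 14


class TestRenderedCube:
    def _tiny_chrom(self, **kw):
        base = dict(
            n_timepoints=200, n_mz_channels=40, n_intervals=4,
            peak_width=2.5, rt_shift_sd=0.0, baseline=0.0, noise_sd=0.0, seed=3,
        )
        base.update(kw)
        return ChromatogramSpec(**base)

    def test_no_shift_no_noise_profiles_identical_across_samples(self, small_design):
        truth = simulate_concentrations(small_design, _null_spec(K=2))
        cube = render_raw_cube(truth, self._tiny_chrom(baseline=0.0))
        registry = cube.attrs["peak_registry"]
        apex = int(registry.loc[registry.peak == "met_0001", "apex"].iloc[0])
        window = cube.intensity[:, apex - 8 : apex + 9, :].sum(axis=2)
        norm = window / window.sum(axis=1, keepdims=True)
        assert np.allclose(norm, norm[0], atol=1e-12)

    def test_noiseless_integral_equals_area_times_spectrum_sum(self, small_design):
        """Numeric integration oracle: total signal = Σ_k area·Σ_m s_k(m)."""
        eff = _null_spec(K=1, noise_sd=0.0, is_cv=0.0)
        truth = simulate_concentrations(small_design, eff)
        cube = render_raw_cube(truth, self._tiny_chrom())
        spectra = cube.attrs["spectra"]
        expected = (
            truth.areas.iloc[:, 0].to_numpy() * spectra[0].sum()
            + truth.is_area.to_numpy() * spectra[1].sum()
        )
        observed = cube.intensity.sum(axis=(1, 2))
        assert np.allclose(observed, expected, rtol=1e-6)

    def test_doubling_concentration_doubles_signal(self, small_design):
        t1 = simulate_concentrations(small_design, _null_spec(K=1, baseline=100.0))
        t2 = simulate_concentrations(small_design, _null_spec(K=1, baseline=200.0))
        c1 = render_raw_cube(t1, self._tiny_chrom())
        c2 = render_raw_cube(t2, self._tiny_chrom())
        # the internal-standard peak is identical in both renders and cancels
        assert np.allclose(
            (c2.intensity - c1.intensity).sum(axis=(1, 2)),
            (t2.areas.iloc[:, 0] - t1.areas.iloc[:, 0]).to_numpy()
            * cube_spec_sum(c1),
            rtol=1e-6,
        )

    def test_cube_nonnegative_with_noise(self, small_design):
        truth = simulate_concentrations(small_design, _null_spec(K=2, noise_sd=0.1))
        cube = render_raw_cube(
            truth, self._tiny_chrom(baseline=2.0, noise_sd=3.0, rt_shift_sd=0.8)
        )
        assert cube.intensity.min() >= 0

    def test_render_determinism(self, small_design):
        truth = simulate_concentrations(small_design, _null_spec(K=2, noise_sd=0.1))
        a = render_raw_cube(truth, self._tiny_chrom(noise_sd=1.0))
        b = render_raw_cube(truth, self._tiny_chrom(noise_sd=1.0))
        assert np.array_equal(a.intensity, b.intensity)

    def test_capacity_overflow_rejected(self, small_design):
        truth = simulate_concentrations(small_design, _null_spec(K=12))
        with pytest.raises(ValueError, match="capacity"):
            render_raw_cube(truth, self._tiny_chrom(peaks_per_interval=1))

    def test_interval_too_short_for_peaks_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            ChromatogramSpec(n_timepoints=100, n_intervals=20, peak_width=4.0,
                             rt_shift_sd=2.0)

    def test_netcdf_round_trip(self, small_design, tmp_path):
        truth = simulate_concentrations(small_design, _null_spec(K=2, noise_sd=0.1))
        cube = render_raw_cube(truth, self._tiny_chrom(noise_sd=1.0))
        path = tmp_path / "cube.nc"
        cube.to_netcdf(path)
        back = RawGCMSCube.from_netcdf(path)
        assert np.allclose(back.intensity, cube.intensity)
        assert back.attrs["is_interval"] == cube.attrs["is_interval"]
        assert list(back.design["sample_id"]) == list(cube.design["sample_id"])


def cube_spec_sum(cube) -> float:
    return float(cube.attrs["spectra"][0].sum())
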