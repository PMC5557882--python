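import numpy as np
import pandas as pd
import pytest
from scipy import stats

from grainfill.correlations import critical_r, daf_profiles, fingerprint
from grainfill.design import StudyDesignSpec, build_design
from grainfill.simulate import EffectSpec, simulate_concentrations


@pytest.fixture(scope="module")
def design96():
    return build_design(StudyDesignSpec())


@pytest.fixture(scope="module")
def k12_profiles():
    """A 12-metabolite profile fixture over 8 DAF points."""
    rng = np.random.default_rng(42)
    prof = rng.normal(size=(12, 8)).cumsum(axis=1)
    return pd.DataFrame(prof, index=[f"m{k}" for k in range(12)],
                        columns=range(8))


class TestProfiles:
    def test_replicate_mean(self, design96):
        X = pd.DataFrame(
            np.zeros((96, 1)),
            index=pd.Index(design96["sample_id"], name="sample_id"),
            columns=["m0"],
        )
        grp = (design96["genotype"] == "Bomi") & (design96["temperature"] == "LT")
        first_daf = design96["daf"].min()
        rows = grp & (design96["daf"] == first_daf)
        X.loc[rows.to_numpy(), "m0"] = [3.0, 5.0]
        prof = daf_profiles(X, "Bomi", "LT", design=design96)
        assert prof.loc["m0", first_daf] == pytest.approx(4.0)
        assert prof.shape[1] == 8

    def test_replicate_order_invariance(self, design96):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(96, 4)),
                         index=pd.Index(design96["sample_id"], name="sample_id"))
        prof1 = daf_profiles(X, "Bomi", "LT", design=design96)
        order = rng.permutation(96)
        prof2 = daf_profiles(X.iloc[order], "Bomi", "LT",
                             design=design96.iloc[order].reset_index(drop=True))
        assert np.allclose(prof1.to_numpy(), prof2.to_numpy())

    def test_missing_group_and_daf_level_rejected(self, design96):
        X = pd.DataFrame(np.zeros((96, 1)),
                         index=pd.Index(design96["sample_id"], name="sample_id"))
        with pytest.raises(ValueError, match="not present"):
            daf_profiles(X, "Morex", "LT", design=design96)
        keep = ~((design96["genotype"] == "Bomi") & (design96["daf"] == 9))
        with pytest.raises(ValueError, match="lacks DAF"):
            daf_profiles(X[keep.to_numpy()], "Bomi", "LT",
                         design=design96[keep].reset_index(drop=True))


class TestFingerprint:
    def test_matches_brute_force_pearson_oracle(self, k12_profiles):
        fp = fingerprint(k12_profiles, group_a=("A", "LT"))
        R = fp.r.to_numpy()
        P = k12_profiles.to_numpy()
        for i in range(12):
            for j in range(12):
                expected = stats.pearsonr(P[i], P[j]).statistic
                assert R[i, j] == pytest.approx(expected, abs=1e-12)

    def test_self_correlation_is_unity(self, k12_profiles):
        fp = fingerprint(k12_profiles, group_a=("A", "LT"))
        assert np.allclose(np.diag(fp.r.to_numpy()), 1.0)

    def test_between_group_transpose_symmetry(self, k12_profiles):
        other = k12_profiles * 2.0 + np.random.default_rng(1).normal(
            size=k12_profiles.shape
        )
        ab = fingerprint(k12_profiles, other, group_a=("A",), group_b=("B",))
        ba = fingerprint(other, k12_profiles, group_a=("B",), group_b=("A",))
        assert np.allclose(ab.r.to_numpy(), ba.r.to_numpy().T, atol=1e-12)

    def test_between_group_with_itself_equals_within(self, k12_profiles):
        within = fingerprint(k12_profiles, group_a=("A",))
        between = fingerprint(k12_profiles, k12_profiles.copy(),
                              group_a=("A",), group_b=("A2",))
        off = ~np.eye(12, dtype=bool)
        assert np.allclose(within.r.to_numpy()[off], between.r.to_numpy()[off],
                           atol=1e-12)

    def test_inverted_trend_pair_strongly_negative(self, design96):
        eff = EffectSpec.default_study(n_metabolites=20, seed=6, noise_sd=0.05)
        truth = simulate_concentrations(design96, eff)
        labels = truth.trend_labels
        acc = labels[labels == "accumulation"].index[0]
        dep = labels[labels == "depletion"].index[0]
        prof = daf_profiles(truth.concentrations, "Bomi", "LT", design=design96)
        fp = fingerprint(prof, group_a=("Bomi", "LT"))
        assert fp.r.loc[acc, dep] < -0.9

    def test_zero_variance_profile_excluded(self, k12_profiles):
        prof = k12_profiles.copy()
        prof.iloc[0] = 5.0
        fp = fingerprint(prof, group_a=("A",))
        assert np.isnan(fp.r.to_numpy()[0, 1])
        assert fp.n_valid() == (12 * 11) // 2 - 11
        n_pos, n_neg = fp.count_significant(0.05)
        assert n_pos + n_neg <= fp.n_valid()


class TestSignificanceCounting:
    def test_critical_r_matches_t_inversion(self):
        """|r|_crit at n = 8, α = 0.05 from the t distribution ≈ 0.7067."""
        assert critical_r(8, 0.05) == pytest.approx(0.7067, abs=5e-4)
        # independent check: t statistic of r_crit reproduces the quantile
        r = critical_r(8, 0.05)
        t = r * np.sqrt(6) / np.sqrt(1 - r**2)
        assert t == pytest.approx(stats.t.ppf(0.975, 6), rel=1e-12)

    def test_all_positive_matrix_counts(self):
        prof = pd.DataFrame(np.tile(np.arange(8.0), (3, 1)),
                            index=["a", "b", "c"])
        fp = fingerprint(prof, group_a=("G",))
        n_pos, n_neg = fp.count_significant(0.05)
        assert (n_pos, n_neg) == (3, 0)  # three off-diagonal pairs

    def test_counts_match_brute_force_scan(self, k12_profiles):
        fp = fingerprint(k12_profiles, group_a=("A",))
        r_crit = critical_r(8, 0.05)
        R = fp.r.to_numpy()
        iu = np.triu_indices(12, k=1)
        expected = (int(np.sum(R[iu] > r_crit)), int(np.sum(R[iu] < -r_crit)))
        assert fp.count_significant(0.05) == expected

    def test_invalid_alpha_rejected(self, k12_profiles):
        fp = fingerprint(k12_profiles, group_a=("A",))
        with pytest.raises(ValueError, match="alpha"):
            fp.count_significant(alpha=1.5)


class TestDistribution:
    def test_single_bin_for_constant_matrix(self):
        prof = pd.DataFrame(np.tile(np.arange(8.0), (4, 1)))
        fp = fingerprint(prof, group_a=("G",))
        hist = fp.coefficient_distribution(n_bins=10)
        assert hist["count"].sum() == 6
        assert (hist["count"] > 0).sum() == 1
        assert hist.loc[hist["count"] > 0, "bin_right"].iloc[0] == pytest.approx(1.0)

    def test_histogram_conserves_counts(self, k12_profiles):
        fp = fingerprint(k12_profiles, group_a=("A",))
        hist = fp.coefficient_distribution()
        assert hist["count"].sum() == fp.n_valid()

    def test_accumulation_dominated_group_right_skewed(self, design96):
        # strong accumulation dominance relative to replicate noise
        eff = EffectSpec.default_study(n_metabolites=60, seed=8, noise_sd=0.15)
        truth = simulate_concentrations(design96, eff)
        prof = daf_profiles(truth.concentrations, "Bomi", "LT", design=design96)
        fp = fingerprint(prof, group_a=("Bomi", "LT"))
        hist = fp.coefficient_distribution(n_bins=40)
        mode_bin = hist.loc[hist["count"].idxmax()]
        assert mode_bin["bin_left"] > 0.5
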