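import numpy as np
import pandas as pd
import pytest

from grainfill.design import StudyDesignSpec, build_design
from grainfill.preprocess import MetaboliteTable
from grainfill.simulate import EffectSpec, simulate_concentrations


@pytest.fixture(scope="session")
def reference_design():
    """The reference balanced factorial: 3 GT × 2 TEMP × 8 DAF × 2 reps."""
    return build_design(StudyDesignSpec())


@pytest.fixture(scope="session")
def default_truth(reference_design):
    """A default-condition synthetic study at the reference 247 variables."""
    eff = EffectSpec.default_study(n_metabolites=247, seed=7)
    return simulate_concentrations(reference_design, eff)


@pytest.fixture(scope="session")
def preprocessed(default_truth):
    raw = MetaboliteTable(
        X=default_truth.areas,
        design=default_truth.design,
        is_area=default_truth.is_area,
        seed_weight=default_truth.seed_weight,
        stage="raw",
    )
    xi = raw.normalize_is()
    xs = xi.correct_closure()
    return {"raw": raw, "xi": xi, "xs": xs, "scaled": xs.scale()}


def make_peak_slabs(
    rng,
    n_samples=12,
    n_time=40,
    n_mz=60,
    peaks=((18, 3.0),),
    conc_low=0.5,
    conc_high=3.0,
    shift_sd=1.5,
    noise_sd=0.0,
):
    """Directly constructed shifted-Gaussian rank-R slabs with known truth.

    The retention shift is drawn once per sample and applied to every peak
    (rigid local drift), matching the generator's chromatographic model.
    """
    t = np.arange(n_time)
    spectra, concs = [], []
    X = np.zeros((n_samples, n_time, n_mz))
    sample_shifts = np.clip(
        rng.normal(0, shift_sd, n_samples), -3 * shift_sd, 3 * shift_sd
    )
    for apex, width in peaks:
        s = np.zeros(n_mz)
        chan = rng.choice(n_mz, 10, replace=False)
        s[chan] = rng.exponential(1.0, 10)
        s /= np.linalg.norm(s)
        c = rng.uniform(conc_low, conc_high, n_samples)
        shifts = sample_shifts
        for k in range(n_samples):
            g = np.exp(-0.5 * ((t - (apex + shifts[k])) / width) ** 2)
            g /= g.sum()
            X[k] += c[k] * np.outer(g, s)
        spectra.append(s)
        concs.append(c)
    if noise_sd > 0:
        X = X + rng.normal(0, noise_sd, X.shape)
    return X, np.array(spectra), np.array(concs)
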