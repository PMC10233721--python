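import numpy as np
import pandas as pd
import pytest

from blastoquant.presets import DEFAULT_PRESETS
from blastoquant.simulate import gen_intensity_table


@pytest.fixture(scope="session")
def d7_cohort():
    """5 embryos x 200 ICM cells at D7, with ground-truth lineage labels."""
    preset = DEFAULT_PRESETS["D7"].with_size(n_cells_icm=200, n_embryos=5)
    table, truth = gen_intensity_table(preset, seed=11)
    return table, truth


@pytest.fixture(scope="session")
def known_mixture_sample():
    """1000 draws from a two-Gaussian mixture with known parameters."""
    params = dict(w1=0.4, mu1=30.0, sigma1=15.0, w2=0.6, mu2=180.0, sigma2=20.0)
    rng = np.random.default_rng(42)
    n1 = rng.binomial(1000, params["w1"])
    x = np.concatenate([
        rng.normal(params["mu1"], params["sigma1"], n1),
        rng.normal(params["mu2"], params["sigma2"], 1000 - n1),
    ])
    return np.clip(x, 0, None), params


def true_intersection_grid(w1, mu1, sigma1, w2, mu2, sigma2, n_grid=2_000_001):
    """Independent oracle: dense-grid root of w1*N1(x) = w2*N2(x) between the means."""
    x = np.linspace(mu1, mu2, n_grid)
    pdf1 = w1 / (sigma1 * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((x - mu1) / sigma1) ** 2)
    pdf2 = w2 / (sigma2 * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((x - mu2) / sigma2) ** 2)
    diff = pdf1 - pdf2
    sign_change = np.nonzero(np.diff(np.sign(diff)))[0]
    assert len(sign_change) >= 1
    i = sign_change[0]
    return 0.5 * (x[i] + x[i + 1])
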