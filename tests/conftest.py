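"""Shared fixtures: small covariance instances and simulated datasets."""

import numpy as np
import pytest

from regsi.index_solvers import CovariancePair
from regsi.evaluation import PlotData
from regsi.synthetic_data import make_covariance_structures, simulate


@pytest.fixture
def two_band_cov() -> CovariancePair:
    """The 2-band worked example: P = [[1, .5], [.5, 1]], G = [.3, .2]."""
    return CovariancePair(
        P=np.array([[1.0, 0.5], [0.5, 1.0]]),
        G=np.array([0.3, 0.2]),
        sigma2_gy=0.5,
    )


def random_cov(rng: np.random.Generator, p: int,
               n: int | None = None) -> CovariancePair:
    """Random well-conditioned covariance instance for property tests."""
    n = n or max(4 * p, 40)
    A = rng.standard_normal((n, p))
    P = A.T @ A / n + 0.1 * np.eye(p)
    G = 0.3 * rng.standard_normal(p)
    return CovariancePair(P=P, G=G, sigma2_gy=1.0)


@pytest.fixture(scope="session")
def nuisance_free_truth():
    """p=30 truth with 3 genetic factors and no design nuisance effects."""
    return make_covariance_structures(
        p=30, n_factors=3, decay=60.0,
        nuisance_variances=dict(trial=0.0, rep=0.0, subblock=0.0),
    )


@pytest.fixture(scope="session")
def nuisance_free_data(nuisance_free_truth) -> PlotData:
    """Simulated plot data (already on the adjusted scale) for evaluation."""
    sim = simulate(nuisance_free_truth, n_trials=12, genotypes_per_trial=20,
                   replicates=2, subblocks=4, seed=42)
    t = sim.target.data
    return PlotData(
        genotype=t["genotype"].to_numpy(),
        trial=t["trial"].to_numpy(),
        y=sim.target.values,
        X=sim.X,
        band_labels=sim.band_labels,
        wavelengths=sim.wavelengths,
    )
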