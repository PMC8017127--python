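"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import lognorm, multivariate_normal, norm

from timeirt import (
    Dataset,
    ItemAccuracyParams,
    ItemTimeParams,
    LatentSpec,
    ModelSpec,
)


# ---------------------------------------------------------------------------
# brute-force oracles (dense-grid integration, independent of the package's
# quadrature path)
# ---------------------------------------------------------------------------

def _oracle_person_like(x_row, t_row, spec: ModelSpec, TH, TA):
    """Likelihood of one person's observed entries on a latent grid,
    written directly from the model equations with scipy distributions
    (independent of the package's vectorized likelihood path)."""
    like = np.ones_like(TH)
    for i, item in enumerate(spec.item_acc):
        if not np.isfinite(x_row[i]):
            continue
        k = int(x_row[i])
        a, b = item.discrimination, np.asarray(item.thresholds)
        upper = 1.0 / (1.0 + np.exp(-a * (TH - b[k - 1]))) if k >= 1 else np.ones_like(TH)
        lower = 1.0 / (1.0 + np.exp(-a * (TH - b[k]))) if k < len(b) else np.zeros_like(TH)
        like = like * (upper - lower)
    if spec.model_id != "M1":
        for i, item in enumerate(spec.item_time):
            if not np.isfinite(t_row[i]):
                continue
            mu = item.intensity - item.speed_loading * TA + item.cross_loading * TH
            like = like * lognorm.pdf(t_row[i], np.sqrt(item.residual_var), scale=np.exp(mu))
    return like


def grid_marginal_loglik(data: Dataset, spec: ModelSpec, n_grid: int = 401,
                         half_width: float = 6.0) -> float:
    """Dense trapezoid-grid integration of the marginal likelihood over
    [-hw, hw] standardized latent units (2-D for M2/M3, 1-D for M1)."""
    lat = spec.latent
    g = np.linspace(-half_width, half_width, n_grid)
    theta = lat.mean_theta + np.sqrt(lat.var_theta) * g
    total = 0.0
    if spec.model_id == "M1":
        dens = norm.pdf(theta, lat.mean_theta, np.sqrt(lat.var_theta))
        for p in range(data.n_persons):
            vals = _oracle_person_like(data.responses[p], data.times[p], spec,
                                       theta, np.zeros_like(theta))
            total += np.log(np.trapezoid(vals * dens, theta))
        return total
    tau = lat.mean_tau + np.sqrt(lat.var_tau) * g
    TH, TA = np.meshgrid(theta, tau, indexing="ij")
    c = lat.corr * np.sqrt(lat.var_theta * lat.var_tau)
    cov = [[lat.var_theta, c], [c, lat.var_tau]]
    dens = multivariate_normal([lat.mean_theta, lat.mean_tau], cov).pdf(np.dstack([TH, TA]))
    for p in range(data.n_persons):
        pl = _oracle_person_like(data.responses[p], data.times[p], spec, TH, TA)
        val = np.trapezoid(np.trapezoid(pl * dens, tau, axis=1), theta)
        total += np.log(val)
    return total


def grid_posterior_theta(x_row, t_row, spec: ModelSpec, n_grid: int = 801,
                         half_width: float = 7.0):
    """Dense-grid posterior mean and SD of theta for one person."""
    lat = spec.latent
    g = np.linspace(-half_width, half_width, n_grid)
    theta = lat.mean_theta + np.sqrt(lat.var_theta) * g
    if spec.model_id == "M1":
        dens = norm.pdf(theta, lat.mean_theta, np.sqrt(lat.var_theta))
        w = _oracle_person_like(x_row, t_row, spec, theta, np.zeros_like(theta)) * dens
        w /= np.trapezoid(w, theta)
        m = np.trapezoid(w * theta, theta)
        v = np.trapezoid(w * theta ** 2, theta) - m ** 2
        return m, np.sqrt(v)
    tau = lat.mean_tau + np.sqrt(lat.var_tau) * g
    TH, TA = np.meshgrid(theta, tau, indexing="ij")
    c = lat.corr * np.sqrt(lat.var_theta * lat.var_tau)
    dens = multivariate_normal(
        [lat.mean_theta, lat.mean_tau],
        [[lat.var_theta, c], [c, lat.var_tau]]).pdf(np.dstack([TH, TA]))
    w = _oracle_person_like(x_row, t_row, spec, TH, TA) * dens
    marg = np.trapezoid(w, tau, axis=1)
    marg /= np.trapezoid(marg, theta)
    m = np.trapezoid(marg * theta, theta)
    v = np.trapezoid(marg * theta ** 2, theta) - m ** 2
    return m, np.sqrt(v)


# ---------------------------------------------------------------------------
# small reusable model pieces
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def toy_items():
    return (
        ItemAccuracyParams(1.2, (0.0,)),
        ItemAccuracyParams(0.9, (-0.5, 0.7)),
        ItemAccuracyParams(1.5, (0.4,)),
    )


@pytest.fixture(scope="session")
def toy_time_items():
    return (
        ItemTimeParams(0.5, 0.3, 0.25),
        ItemTimeParams(0.2, 0.4, 0.16),
        ItemTimeParams(0.7, 0.35, 0.30),
    )


@pytest.fixture(scope="session")
def toy_m2(toy_items, toy_time_items):
    return ModelSpec("M2", toy_items, toy_time_items,
                     LatentSpec(0.1, 1.2, -0.1, 0.9, 0.3))


@pytest.fixture(scope="session")
def toy_m3(toy_items, toy_time_items):
    tim = tuple(
        ItemTimeParams(t.intensity, t.speed_loading, t.residual_var, phi)
        for t, phi in zip(toy_time_items, (0.2, -0.15, 0.1)))
    return ModelSpec("M3", toy_items, tim, LatentSpec(0.1, 1.2, 0.0, 1.0, 0.0))


@pytest.fixture(scope="session")
def toy_data(toy_m2):
    """Five persons, three items, with scattered missing entries."""
    x = np.array([
        [1, 2, 0],
        [0, 0, 1],
        [1, np.nan, 1],
        [np.nan, 1, np.nan],
        [np.nan, np.nan, np.nan],
    ], dtype=float)
    t = np.array([
        [1.5, 0.8, 2.1],
        [0.9, 1.7, 1.2],
        [2.4, 1.1, np.nan],
        [np.nan, np.nan, 0.7],
        [np.nan, np.nan, np.nan],
    ])
    return Dataset(x, t, np.array(["A", "A", "B", "B", "B"]))
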