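"""Measurement models for joint item-response / response-time data.

Three models on a bivariate latent space (proficiency theta, speed tau):

* M1 -- graded response model (GRM) for scored responses only.
* M2 -- simple-structure hierarchical model: GRM for accuracy plus a
  lognormal factor model for response times, latents linked by a
  bivariate-normal correlation rho.
* M3 -- extended hierarchical model in which log response times load on
  both a speed factor tau* and directly on proficiency (cross-loadings);
  theta and tau* are kept uncorrelated for identification.

Times are modelled in minutes; time intensities are therefore on the
log-minute scale.  All likelihood evaluations accumulate in log space and
treat missing entries (NaN) as ignorable given the observed data (MAR).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import expit, log_expit, logsumexp, roots_hermitenorm

__all__ = [
    "ItemAccuracyParams",
    "ItemTimeParams",
    "LatentSpec",
    "Dataset",
    "ModelSpec",
    "QuadratureSpec",
    "grm_cumulative_prob",
    "grm_category_probs",
    "logtime_density",
    "person_loglik",
    "marginal_loglik",
    "implied_logtime_moments",
]

MISSING_TOKEN = "NA"
MODEL_IDS = ("M1", "M2", "M3")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ItemAccuracyParams:
    """GRM parameters for one item: discrimination a > 0 and strictly
    increasing thresholds b_1 < ... < b_m (m + 1 score categories)."""

    discrimination: float
    thresholds: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "thresholds", tuple(float(b) for b in np.atleast_1d(self.thresholds)))
        if not self.discrimination > 0:
            raise ValueError(f"discrimination must be positive, got {self.discrimination}")
        if len(self.thresholds) < 1:
            raise ValueError("at least one threshold is required")
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError(f"thresholds must be strictly increasing, got {self.thresholds}")

    @property
    def n_categories(self) -> int:
        return len(self.thresholds) + 1


@dataclass(frozen=True)
class ItemTimeParams:
    """Lognormal time-model parameters for one item.

    The log-scale mean is ``intensity - speed_loading * tau`` under M2 and
    ``intensity - speed_loading * tau* + cross_loading * theta`` under M3.
    """

    intensity: float
    speed_loading: float
    residual_var: float
    cross_loading: float = 0.0

    def __post_init__(self):
        if not self.residual_var > 0:
            raise ValueError(f"residual_var must be positive, got {self.residual_var}")


@dataclass(frozen=True)
class LatentSpec:
    """Bivariate-normal distribution of (theta, tau) with correlation."""

    mean_theta: float = 0.0
    var_theta: float = 1.0
    mean_tau: float = 0.0
    var_tau: float = 1.0
    corr: float = 0.0

    def __post_init__(self):
        if not (self.var_theta > 0 and self.var_tau > 0):
            raise ValueError("latent variances must be positive")
        if not abs(self.corr) <= 1:
            raise ValueError(f"|corr| must be <= 1, got {self.corr}")


@dataclass(frozen=True)
class QuadratureSpec:
    """Gauss-Hermite quadrature settings (nodes per latent dimension)."""

    nodes_per_dim: int = 21
    adaptive: bool = True

    def __post_init__(self):
        if self.nodes_per_dim < 2:
            raise ValueError("nodes_per_dim must be >= 2")


@dataclass
class Dataset:
    """Persons x items matrices of scored responses and times (minutes).

    Missing entries are ``NaN`` in both matrices; a response may be missing
    while its time is observed and vice versa.
    """

    responses: np.ndarray
    times: np.ndarray
    group: np.ndarray
    person_id: np.ndarray | None = None
    item_id: np.ndarray | None = None

    def __post_init__(self):
        self.responses = np.asarray(self.responses, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.group = np.asarray(self.group)
        if self.responses.shape != self.times.shape:
            raise ValueError("responses and times must share shape")
        if self.group.shape[0] != self.responses.shape[0]:
            raise ValueError("group labels must align with persons")
        if self.person_id is None:
            self.person_id = np.arange(self.responses.shape[0])
        else:
            self.person_id = np.asarray(self.person_id)
        if self.item_id is None:
            self.item_id = np.array([f"item{i + 1}" for i in range(self.responses.shape[1])])
        else:
            self.item_id = np.asarray(self.item_id)
        obs_t = self.times[np.isfinite(self.times)]
        if obs_t.size and np.any(obs_t <= 0):
            raise ValueError("observed times must be positive")
        obs_x = self.responses[np.isfinite(self.responses)]
        if obs_x.size and (np.any(obs_x < 0) or np.any(obs_x != np.round(obs_x))):
            raise ValueError("observed responses must be nonnegative integers")

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    def groups(self) -> list:
        seen: list = []
        for g in self.group:
            if g not in seen:
                seen.append(g)
        return seen

    def subset(self, group) -> "Dataset":
        mask = self.group == group
        return Dataset(
            self.responses[mask],
            self.times[mask],
            self.group[mask],
            person_id=self.person_id[mask],
            item_id=self.item_id,
        )

    def validate_against(self, spec: "ModelSpec") -> None:
        if len(spec.item_acc) != self.n_items:
            raise ValueError("item count mismatch between data and model spec")
        for i, item in enumerate(spec.item_acc):
            col = self.responses[:, i]
            obs = col[np.isfinite(col)]
            if obs.size and obs.max() > item.n_categories - 1:
                raise ValueError(f"item {i}: response above category range")


@dataclass(frozen=True)
class ModelSpec:
    """Complete parameterization of one of the three measurement models."""

    model_id: str
    item_acc: tuple[ItemAccuracyParams, ...]
    item_time: tuple[ItemTimeParams, ...] | None = None
    latent: LatentSpec = field(default_factory=LatentSpec)

    def __post_init__(self):
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"model_id must be one of {MODEL_IDS}")
        object.__setattr__(self, "item_acc", tuple(self.item_acc))
        if self.item_time is not None:
            object.__setattr__(self, "item_time", tuple(self.item_time))
        if self.model_id == "M1":
            if self.item_time is not None:
                raise ValueError("M1 carries no time parameters")
        else:
            if self.item_time is None:
                raise ValueError(f"{self.model_id} requires time parameters")
            if len(self.item_time) != len(self.item_acc):
                raise ValueError("accuracy and time parameter lists must align")
        # identification: corr is fixed to 0 whenever cross-loadings are
        # freely estimated (unrotated M3); with anchored cross-loadings the
        # country-level M3 fits legitimately carry a free corr, so nonzero
        # values are allowed by this type

        if self.model_id in ("M1", "M2") and self.item_time is not None:
            if any(it.cross_loading != 0.0 for it in self.item_time):
                raise ValueError("cross-loadings are fixed at 0 under M1/M2")

    @property
    def n_items(self) -> int:
        return len(self.item_acc)

    def with_latent(self, latent: LatentSpec) -> "ModelSpec":
        return replace(self, latent=latent)


# ---------------------------------------------------------------------------
# GRM probabilities
# ---------------------------------------------------------------------------

def grm_cumulative_prob(theta, item: ItemAccuracyParams, k: int):
    """Pr(X >= k | theta) for category index 1 <= k <= m (logistic curve)."""
    m = len(item.thresholds)
    if not 1 <= k <= m:
        raise IndexError(f"category index k={k} out of range 1..{m}")
    return expit(item.discrimination * (np.asarray(theta, dtype=float) - item.thresholds[k - 1]))


def grm_category_probs(theta, item: ItemAccuracyParams) -> np.ndarray:
    """Category probabilities (Pr(X=0), ..., Pr(X=m)) at ``theta``.

    Adjacent differences of the cumulative logistic curves, with the
    boundary conventions Pr(X >= 0) = 1 and Pr(X >= m+1) = 0.
    """
    theta = np.asarray(theta, dtype=float)
    b = np.asarray(item.thresholds)
    cum = expit(item.discrimination * (theta[..., None] - b))  # P(X>=k), k=1..m
    ones = np.ones_like(theta[..., None])
    zeros = np.zeros_like(theta[..., None])
    full = np.concatenate([ones, cum, zeros], axis=-1)
    return -np.diff(full, axis=-1)


def _grm_log_tables(items: Sequence[ItemAccuracyParams], theta_nodes: np.ndarray) -> list[np.ndarray]:
    """Per item: (n_nodes, n_cat) log category probabilities.

    Computed via differences of log-survival terms for numerical safety:
    log P_k uses log(expit) pieces, clipped away from -inf only through the
    floor applied to the probability difference.
    """
    tables = []
    for item in items:
        p = grm_category_probs(theta_nodes, item)
        tables.append(np.log(np.clip(p, 1e-300, None)))
    return tables


def _acc_loglik_nodes(responses: np.ndarray, items: Sequence[ItemAccuracyParams],
                      theta_nodes: np.ndarray) -> np.ndarray:
    """(persons, n_nodes) accuracy log-likelihood; missing entries add 0."""
    P = responses.shape[0]
    out = np.zeros((P, theta_nodes.shape[0]))
    tables = _grm_log_tables(items, theta_nodes)
    for i, tab in enumerate(tables):
        col = responses[:, i]
        mask = np.isfinite(col)
        if not mask.any():
            continue
        x = np.where(mask, col, 0).astype(int)
        out += np.where(mask[:, None], tab[:, x].T, 0.0)
    return out


# ---------------------------------------------------------------------------
# lognormal time model
# ---------------------------------------------------------------------------

def _time_log_mean(item: ItemTimeParams, theta, tau, model_id: str):
    if model_id == "M2":
        return item.intensity - item.speed_loading * np.asarray(tau, dtype=float)
    if model_id == "M3":
        return (item.intensity - item.speed_loading * np.asarray(tau, dtype=float)
                + item.cross_loading * np.asarray(theta, dtype=float))
    raise ValueError(f"time model undefined for model_id={model_id}")


def logtime_density(t, theta, tau, item: ItemTimeParams, model_id: str = "M2"):
    """Lognormal density of a response time ``t`` (minutes) given latents."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("response times must be positive")
    mu = _time_log_mean(item, theta, tau, model_id)
    s2 = item.residual_var
    z = np.log(t)
    return np.exp(-0.5 * (z - mu) ** 2 / s2) / (t * math.sqrt(2 * math.pi * s2))


def _time_loglik_nodes(z: np.ndarray, tmask: np.ndarray, xi: np.ndarray, lam: np.ndarray,
                       sig2: np.ndarray, phi: np.ndarray, theta_grid: np.ndarray,
                       tau_grid: np.ndarray) -> np.ndarray:
    """(persons, Q) time log-likelihood on the latent grid.

    ``z`` is log-time with zeros at missing entries, ``tmask`` the observed
    indicator.  Decomposes the Gaussian quadratic so the grid dependence is
    two matrix products.
    """
    mu = xi[:, None] - lam[:, None] * tau_grid[None, :] + phi[:, None] * theta_grid[None, :]
    const = tmask @ (-0.5 * np.log(2 * math.pi * sig2)) - (tmask * z ** 2) @ (0.5 / sig2) - (tmask * z).sum(axis=1)
    cross = (tmask * z / sig2) @ mu
    quad = (tmask / (2 * sig2)) @ (mu ** 2)
    return const[:, None] + cross - quad


# ---------------------------------------------------------------------------
# quadrature grid and marginal likelihood
# ---------------------------------------------------------------------------

def _std_normal_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Hermite nodes/weights for integration against N(0, 1)."""
    x, w = roots_hermitenorm(n)
    return x, w / math.sqrt(2 * math.pi)


@dataclass(frozen=True)
class _Grid:
    """Flattened quadrature grid in latent space (theta outer, tau inner)."""

    theta: np.ndarray          # (Q,) proficiency values
    tau: np.ndarray | None     # (Q,) speed values, None for M1
    logw: np.ndarray           # (Q,) log weights of the latent prior
    u: np.ndarray              # (n_theta,) standardized theta nodes
    v: np.ndarray | None       # (n_tau,) standardized second nodes
    n_theta: int
    n_tau: int


def _grid_for_spec(spec: ModelSpec, quad: QuadratureSpec) -> _Grid:
    lat = spec.latent
    n = quad.nodes_per_dim
    u, wu = _std_normal_nodes(n)
    theta1 = lat.mean_theta + math.sqrt(lat.var_theta) * u
    if spec.model_id == "M1":
        return _Grid(theta1, None, np.log(wu), u, None, n, 1)
    v, wv = _std_normal_nodes(n)
    rho = lat.corr
    s = math.sqrt(max(1.0 - rho ** 2, 1e-12))
    sd_tau = math.sqrt(lat.var_tau)
    theta = np.repeat(theta1, n)
    uu = np.repeat(u, n)
    vv = np.tile(v, n)
    tau = lat.mean_tau + sd_tau * (rho * uu + s * vv)
    logw = np.log(np.repeat(wu, n)) + np.log(np.tile(wv, n))
    return _Grid(theta, tau, logw, u, v, n, n)


def _loglik_matrix(data: Dataset, spec: ModelSpec, quad: QuadratureSpec):
    """Per-person log-likelihood on the grid: (L (P, Q), grid)."""
    data.validate_against(spec)
    grid = _grid_for_spec(spec, quad)
    theta1 = spec.latent.mean_theta + math.sqrt(spec.latent.var_theta) * grid.u
    A = _acc_loglik_nodes(data.responses, spec.item_acc, theta1)  # (P, n_theta)
    if spec.model_id == "M1":
        return A, grid
    tmask = np.isfinite(data.times)
    z = np.where(tmask, np.log(np.where(tmask, data.times, 1.0)), 0.0)
    tmaskf = tmask.astype(float)
    xi = np.array([it.intensity for it in spec.item_time])
    lam = np.array([it.speed_loading for it in spec.item_time])
    sig2 = np.array([it.residual_var for it in spec.item_time])
    phi = np.array([it.cross_loading for it in spec.item_time])
    T = _time_loglik_nodes(z, tmaskf, xi, lam, sig2, phi, grid.theta, grid.tau)
    L = np.repeat(A, grid.n_tau, axis=1) + T
    return L, grid


def marginal_loglik(data: Dataset, spec: ModelSpec, quad: QuadratureSpec | None = None) -> float:
    """Marginal log-likelihood, integrating the latents out by adapted
    Gauss-Hermite quadrature (univariate for M1, product grid otherwise)."""
    quad = quad or QuadratureSpec()
    L, grid = _loglik_matrix(data, spec, quad)
    return float(logsumexp(L + grid.logw[None, :], axis=1).sum())


def person_loglik(x_row, t_row, theta: float, tau: float, spec: ModelSpec) -> float:
    """Joint log-likelihood of one person's observed entries at fixed
    (theta, tau); missing entries contribute nothing (MAR/FIML)."""
    x_row = np.asarray(x_row, dtype=float)
    t_row = np.asarray(t_row, dtype=float)
    if x_row.shape[0] != spec.n_items or t_row.shape[0] != spec.n_items:
        raise ValueError("row lengths must match the model's item count")
    total = 0.0
    for i, item in enumerate(spec.item_acc):
        if np.isfinite(x_row[i]):
            k = int(x_row[i])
            if not 0 <= k <= item.n_categories - 1:
                raise ValueError(f"item {i}: response {k} outside category range")
            total += float(np.log(grm_category_probs(np.array(theta), item)[k]))
    if spec.model_id != "M1":
        for i, item in enumerate(spec.item_time):
            if np.isfinite(t_row[i]):
                total += float(np.log(logtime_density(t_row[i], theta, tau, item, spec.model_id)))
    return total


# ---------------------------------------------------------------------------
# implied moments of log-times
# ---------------------------------------------------------------------------

def implied_logtime_moments(spec: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied mean vector and covariance matrix of log response times.

    mean_i = xi_i - lambda_i mu_tau + phi_i mu_theta;
    cov    = lambda lambda' var_tau + phi phi' var_theta
             - (lambda phi' + phi lambda') cov(theta, tau) + diag(sigma_i^2).
    """
    if spec.model_id == "M1":
        raise ValueError("log-time moments are undefined for M1")
    lat = spec.latent
    xi = np.array([it.intensity for it in spec.item_time])
    lam = np.array([it.speed_loading for it in spec.item_time])
    phi = np.array([it.cross_loading for it in spec.item_time])
    sig2 = np.array([it.residual_var for it in spec.item_time])
    mean = xi - lam * lat.mean_tau + phi * lat.mean_theta
    cov_tt = lat.corr * math.sqrt(lat.var_theta * lat.var_tau)
    cov = (np.outer(lam, lam) * lat.var_tau + np.outer(phi, phi) * lat.var_theta
           - (np.outer(lam, phi) + np.outer(phi, lam)) * cov_tt)
    cov += np.diag(sig2)
    return mean, cov


# ---------------------------------------------------------------------------
# generalized two-factor evaluator (used to verify rotation invariance)
# ---------------------------------------------------------------------------

def bifactor_marginal_loglik(data: Dataset, items_acc: Sequence[ItemAccuracyParams],
                             theta_mean: float, theta_coef: np.ndarray,
                             time_intercept: np.ndarray, time_load: np.ndarray,
                             residual_var: np.ndarray, quad: QuadratureSpec | None = None) -> float:
    """Marginal log-likelihood of a general two-factor representation.

    Latents (eta1, eta2) are iid N(0,1); proficiency is
    ``theta_mean + theta_coef . eta`` and log-times are
    ``N(time_intercept_i + time_load_i . eta, residual_var_i)``.  Both the
    M2 and the (rotated or unrotated) M3 models are instances of this form,
    so an orthogonal rotation of (theta_coef, time_load) must leave the
    value unchanged.
    """
    quad = quad or QuadratureSpec()
    n = quad.nodes_per_dim
    x1, w1 = _std_normal_nodes(n)
    eta1 = np.repeat(x1, n)
    eta2 = np.tile(x1, n)
    logw = np.log(np.repeat(w1, n)) + np.log(np.tile(w1, n))
    theta = theta_mean + theta_coef[0] * eta1 + theta_coef[1] * eta2
    A = _acc_loglik_nodes(data.responses, items_acc, theta)  # full grid
    tmask = np.isfinite(data.times)
    z = np.where(tmask, np.log(np.where(tmask, data.times, 1.0)), 0.0)
    tmaskf = tmask.astype(float)
    mu = (time_intercept[:, None] + time_load[:, 0][:, None] * eta1[None, :]
          + time_load[:, 1][:, None] * eta2[None, :])
    sig2 = residual_var
    const = tmaskf @ (-0.5 * np.log(2 * math.pi * sig2)) - (tmaskf * z ** 2) @ (0.5 / sig2) - (tmaskf * z).sum(axis=1)
    T = const[:, None] + (tmaskf * z / sig2) @ mu - (tmaskf / (2 * sig2)) @ (mu ** 2)
    return float(logsumexp(A + T + logw[None, :], axis=1).sum())


def spec_to_bifactor(spec: ModelSpec) -> dict:
    """Express an M2/M3 spec in the general two-factor form.

    The basis is (eta1, eta2) with theta = mean_theta + sd_theta * eta1 and
    tau = mean_tau + sd_tau * (rho * eta1 + sqrt(1-rho^2) * eta2).
    """
    if spec.model_id == "M1":
        raise ValueError("M1 has no two-factor time representation")
    lat = spec.latent
    sd_t = math.sqrt(lat.var_theta)
    sd_s = math.sqrt(lat.var_tau)
    rho = lat.corr
    s = math.sqrt(max(1.0 - rho ** 2, 0.0))
    xi = np.array([it.intensity for it in spec.item_time])
    lam = np.array([it.speed_loading for it in spec.item_time])
    phi = np.array([it.cross_loading for it in spec.item_time])
    sig2 = np.array([it.residual_var for it in spec.item_time])
    intercept = xi - lam * lat.mean_tau + phi * lat.mean_theta
    load = np.column_stack([
        phi * sd_t - lam * sd_s * rho,
        -lam * sd_s * s,
    ])
    return {
        "items_acc": spec.item_acc,
        "theta_mean": lat.mean_theta,
        "theta_coef": np.array([sd_t, 0.0]),
        "time_intercept": intercept,
        "time_load": load,
        "residual_var": sig2,
    }
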