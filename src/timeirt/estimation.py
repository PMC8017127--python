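"""Marginal maximum likelihood estimation of the joint models.

The study design is a two-step scheme:

1. *International* calibration on the pooled sample: M1 estimates the GRM
   item parameters (latent proficiency standardized); M2 and M3 fix the
   accuracy parameters to the M1 estimates and estimate the time-model
   parameters (latent speed standardized).
2. *Country* analyses per group across a measurement-invariance ladder
   (Full -> Strong -> Weak -> Struct), progressively freeing item time
   parameters while anchoring the rest on the international estimates.

Free parameters are optimized on transformed scales (log for variances and
discriminations, atanh for the latent correlation) with L-BFGS-B.  For the
parameters that are free in M2/M3 fits (time-model and latent parameters)
the gradient of the marginal log-likelihood is computed analytically from
posterior moments of the latent variables; fits that free accuracy
parameters (M1, univariate latent) use finite differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logit, logsumexp

from .model_core import (
    Dataset,
    ItemAccuracyParams,
    ItemTimeParams,
    LatentSpec,
    ModelSpec,
    QuadratureSpec,
    _acc_loglik_nodes,
    _grid_for_spec,
    _loglik_matrix,
    grm_category_probs,
)

__all__ = [
    "ParamEntry",
    "ParameterSpace",
    "FitResult",
    "FitOptions",
    "MissingAnchorError",
    "build_parameter_space",
    "fit",
    "two_step_analysis",
    "fits_to_table",
    "COUNTRY_LEVELS",
]

COUNTRY_LEVELS = ("Full", "Strong", "Weak", "Struct")

_LOG_SYMBOLS = {"a", "sig2", "var_theta", "var_tau"}
_ATANH_SYMBOLS = {"rho"}
# symbols with analytic marginal-likelihood gradients (all free params of
# any M2/M3 fit in the study design)
_ANALYTIC_SYMBOLS = {"xi", "lam", "sig2", "phi",
                     "mu_theta", "var_theta", "mu_tau", "var_tau", "rho"}


class MissingAnchorError(KeyError):
    """A required previously-fitted anchor is absent."""


@dataclass(frozen=True)
class ParamEntry:
    """One model parameter: identity, free/fixed status and value."""

    symbol: str
    item: int | None = None
    cat: int | None = None  # 0-based threshold index for symbol 'b'
    free: bool = True
    value: float | None = None

    def __post_init__(self):
        if not self.free and (self.value is None or not np.isfinite(self.value)):
            raise ValueError(f"fixed entry {self.key} must carry a finite value")

    @property
    def key(self) -> tuple:
        return (self.symbol, self.item, self.cat)

    @property
    def transform(self) -> str:
        if self.symbol in _LOG_SYMBOLS:
            return "log"
        if self.symbol in _ATANH_SYMBOLS:
            return "atanh"
        return "none"


@dataclass(frozen=True)
class ParameterSpace:
    """Free/fixed pattern realizing one row of the estimation framework."""

    model_id: str
    entries: tuple[ParamEntry, ...]
    n_cats: tuple[int, ...]
    level: str = "international"

    def __post_init__(self):
        keys = [e.key for e in self.entries]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate parameter entries")

    @property
    def n_items(self) -> int:
        return len(self.n_cats)

    @property
    def free_entries(self) -> tuple[ParamEntry, ...]:
        return tuple(e for e in self.entries if e.free)

    @property
    def n_free(self) -> int:
        return len(self.free_entries)

    def to_spec(self, free_values: Sequence[float] | None = None) -> ModelSpec:
        """Assemble a ModelSpec from fixed values plus ``free_values``
        (natural scale, in free-entry order)."""
        values = {}
        it = iter(free_values if free_values is not None else [])
        for e in self.entries:
            values[e.key] = next(it) if e.free else e.value
        I = self.n_items
        acc = []
        for i in range(I):
            m = self.n_cats[i] - 1
            acc.append(ItemAccuracyParams(
                values[("a", i, None)],
                tuple(values[("b", i, k)] for k in range(m)),
            ))
        latent = LatentSpec(
            mean_theta=values[("mu_theta", None, None)],
            var_theta=values[("var_theta", None, None)],
            mean_tau=values[("mu_tau", None, None)],
            var_tau=values[("var_tau", None, None)],
            corr=values[("rho", None, None)],
        )
        if self.model_id == "M1":
            return ModelSpec("M1", acc, None, latent)
        tim = [ItemTimeParams(values[("xi", i, None)], values[("lam", i, None)],
                              values[("sig2", i, None)], values[("phi", i, None)])
               for i in range(I)]
        return ModelSpec(self.model_id, acc, tim, latent)

    def analytic_gradient_ok(self) -> bool:
        return (self.model_id in ("M2", "M3")
                and all(e.symbol in _ANALYTIC_SYMBOLS for e in self.free_entries))


@dataclass
class FitOptions:
    maxiter: int = 500
    gtol: float = 1e-5
    ftol: float = 1e-11
    compute_se: bool = True
    se_step: float = 1e-4


@dataclass
class FitResult:
    """Completed estimates with uncertainty and convergence diagnostics."""

    estimates: ModelSpec
    standard_errors: dict
    loglik: float
    n_persons: int
    n_free: int
    converged: bool
    gradient_norm: float
    space: ParameterSpace
    n_iter: int = 0
    se_available: bool = True


# ---------------------------------------------------------------------------
# building parameter spaces from the estimation framework tables
# ---------------------------------------------------------------------------

def _spec_of(anchor) -> ModelSpec:
    return anchor.estimates if isinstance(anchor, FitResult) else anchor


def _require(anchors: Mapping | None, name: str) -> ModelSpec:
    if not anchors or name not in anchors:
        raise MissingAnchorError(
            f"parameter space requires the '{name}' fit as an anchor")
    return _spec_of(anchors[name])


def _acc_entries_free(n_cats) -> list[ParamEntry]:
    out = []
    for i, nc in enumerate(n_cats):
        out.append(ParamEntry("a", i))
        out.extend(ParamEntry("b", i, k) for k in range(nc - 1))
    return out


def _acc_entries_fixed(spec: ModelSpec) -> list[ParamEntry]:
    out = []
    for i, item in enumerate(spec.item_acc):
        out.append(ParamEntry("a", i, free=False, value=item.discrimination))
        out.extend(ParamEntry("b", i, k, free=False, value=item.thresholds[k])
                   for k in range(len(item.thresholds)))
    return out


def _time_entries(I: int, *, model_id: str, xi, lam, sig2, phi) -> list[ParamEntry]:
    """Time-parameter entries; each of xi/lam/sig2/phi is either the string
    'free' or a per-item sequence of fixed values ('phi' ignored for M2)."""
    out = []
    for sym, src in (("xi", xi), ("lam", lam), ("sig2", sig2)):
        for i in range(I):
            if isinstance(src, str):
                out.append(ParamEntry(sym, i))
            else:
                out.append(ParamEntry(sym, i, free=False, value=src[i]))
    for i in range(I):
        if model_id == "M3" and isinstance(phi, str):
            out.append(ParamEntry("phi", i))
        elif model_id == "M3":
            out.append(ParamEntry("phi", i, free=False, value=phi[i]))
        else:
            out.append(ParamEntry("phi", i, free=False, value=0.0))
    return out


def _latent_entries(*, mu_theta, var_theta, mu_tau, var_tau, rho) -> list[ParamEntry]:
    out = []
    for sym, src in (("mu_theta", mu_theta), ("var_theta", var_theta),
                     ("mu_tau", mu_tau), ("var_tau", var_tau), ("rho", rho)):
        if isinstance(src, str):
            out.append(ParamEntry(sym))
        else:
            out.append(ParamEntry(sym, free=False, value=float(src)))
    return out


def build_parameter_space(model_id: str, level: str,
                          anchors: Mapping | None = None, *,
                          n_cats: Sequence[int] | None = None) -> ParameterSpace:
    """Free/fixed pattern for a row of the international or country-level
    estimation framework.

    ``level`` is ``"international"`` or one of ``Full``, ``Strong``,
    ``Weak``, ``Struct``.  ``anchors`` maps names of prerequisite fits
    (``"M1_international"``, ``"M2_international"``, ``"M3_international"``,
    ``"M1_Full"``) to their FitResult (or ModelSpec).
    """
    if model_id not in ("M1", "M2", "M3"):
        raise ValueError(f"unknown model_id {model_id}")
    if level != "international" and level not in COUNTRY_LEVELS:
        raise ValueError(f"unknown level {level}")

    if level == "international":
        if model_id == "M1":
            if n_cats is None:
                raise ValueError("n_cats is required for the M1 international fit")
            entries = (_acc_entries_free(n_cats)
                       + _latent_entries(mu_theta=0, var_theta=1, mu_tau=0, var_tau=1, rho=0))
            return ParameterSpace("M1", tuple(entries), tuple(n_cats), level)
        m1 = _require(anchors, "M1_international")
        nc = tuple(it.n_categories for it in m1.item_acc)
        I = len(nc)
        entries = (_acc_entries_fixed(m1)
                   + _time_entries(I, model_id=model_id, xi="free", lam="free",
                                   sig2="free", phi="free")
                   + _latent_entries(mu_theta="free", var_theta="free", mu_tau=0,
                                     var_tau=1, rho=0 if model_id == "M3" else "free"))
        return ParameterSpace(model_id, tuple(entries), nc, level)

    # --- country level ---
    m1 = _require(anchors, "M1_international")
    nc = tuple(it.n_categories for it in m1.item_acc)
    I = len(nc)
    acc = _acc_entries_fixed(m1)
    if model_id == "M1":
        if level != "Full":
            raise ValueError("the accuracy-only model has a single country level (Full)")
        entries = acc + _latent_entries(mu_theta="free", var_theta="free",
                                        mu_tau=0, var_tau=1, rho=0)
        return ParameterSpace("M1", tuple(entries), nc, level)

    intl = _require(anchors, f"{model_id}_international")
    xi_a = [it.intensity for it in intl.item_time]
    lam_a = [it.speed_loading for it in intl.item_time]
    sig2_a = [it.residual_var for it in intl.item_time]
    phi_a = [it.cross_loading for it in intl.item_time]

    if level == "Full":
        tim = _time_entries(I, model_id=model_id, xi=xi_a, lam=lam_a, sig2=sig2_a, phi=phi_a)
        lat = _latent_entries(mu_theta="free", var_theta="free", mu_tau="free",
                              var_tau="free", rho="free")
    elif level == "Strong":
        tim = _time_entries(I, model_id=model_id, xi=xi_a, lam=lam_a, sig2="free", phi=phi_a)
        lat = _latent_entries(mu_theta="free", var_theta="free", mu_tau="free",
                              var_tau="free", rho="free")
    elif level == "Weak":
        tim = _time_entries(I, model_id=model_id, xi="free", lam=lam_a, sig2="free", phi=phi_a)
        lat = _latent_entries(mu_theta="free", var_theta="free", mu_tau=0,
                              var_tau="free", rho="free")
    elif level == "Struct":
        tim = _time_entries(I, model_id=model_id, xi="free", lam="free", sig2="free", phi="free")
        if model_id == "M3":
            # the proficiency variance is anchored on the accuracy-only
            # country fit so that theta keeps its M1 interpretation
            m1_full = _require(anchors, "M1_Full")
            lat = _latent_entries(mu_theta="free", var_theta=m1_full.latent.var_theta,
                                  mu_tau=0, var_tau=1, rho=0)
        else:
            lat = _latent_entries(mu_theta="free", var_theta="free", mu_tau=0,
                                  var_tau=1, rho="free")
    entries = acc + tim + lat
    return ParameterSpace(model_id, tuple(entries), nc, level)


# ---------------------------------------------------------------------------
# starting values
# ---------------------------------------------------------------------------

def starting_values(data: Dataset, space: ParameterSpace) -> np.ndarray:
    """Deterministic starts: discrimination 1, thresholds from inverse
    logits of observed cumulative proportions, time intensities/variances
    from observed log-time moments, loadings 0.3, latents standard."""
    x0 = []
    logt = np.where(np.isfinite(data.times), np.log(np.where(np.isfinite(data.times), data.times, 1.0)), np.nan)
    for e in space.free_entries:
        if e.symbol == "a":
            x0.append(1.0)
        elif e.symbol == "b":
            col = data.responses[:, e.item]
            obs = col[np.isfinite(col)]
            if obs.size == 0:
                x0.append(float(e.cat))
                continue
            p = np.clip(np.mean(obs >= e.cat + 1), 0.02, 0.98)
            b = float(-logit(p))
            # keep thresholds strictly increasing at the start
            prev = x0[-1] if e.cat and space.free_entries[len(x0) - 1].symbol == "b" else None
            if prev is not None and b <= prev:
                b = prev + 0.1
            x0.append(b)
        elif e.symbol == "xi":
            col = logt[:, e.item]
            obs = col[np.isfinite(col)]
            x0.append(float(obs.mean()) if obs.size else 0.0)
        elif e.symbol == "lam":
            x0.append(0.3)
        elif e.symbol == "sig2":
            col = logt[:, e.item]
            obs = col[np.isfinite(col)]
            x0.append(float(max(obs.var(), 0.05)) if obs.size > 1 else 0.5)
        elif e.symbol == "phi":
            x0.append(0.0)
        elif e.symbol in ("mu_theta", "mu_tau"):
            x0.append(0.0)
        elif e.symbol in ("var_theta", "var_tau"):
            x0.append(1.0)
        elif e.symbol == "rho":
            x0.append(0.0)
        else:  # pragma: no cover
            raise ValueError(f"no start rule for {e.symbol}")
    return np.array(x0)


def _to_transformed(x: np.ndarray, entries) -> np.ndarray:
    y = np.array(x, dtype=float)
    for j, e in enumerate(entries):
        if e.transform == "log":
            y[j] = math.log(max(x[j], 1e-10))
        elif e.transform == "atanh":
            y[j] = math.atanh(np.clip(x[j], -0.999, 0.999))
    return y


def _to_natural(y: np.ndarray, entries) -> np.ndarray:
    x = np.array(y, dtype=float)
    for j, e in enumerate(entries):
        if e.transform == "log":
            x[j] = math.exp(np.clip(y[j], -30, 30))
        elif e.transform == "atanh":
            x[j] = math.tanh(y[j])
    return x


def _chain(y: np.ndarray, entries) -> np.ndarray:
    """dx/dy per entry at transformed point y."""
    d = np.ones_like(y)
    for j, e in enumerate(entries):
        if e.transform == "log":
            d[j] = math.exp(np.clip(y[j], -30, 30))
        elif e.transform == "atanh":
            d[j] = 1.0 - math.tanh(y[j]) ** 2
    return d


# ---------------------------------------------------------------------------
# analytic gradient of the marginal log-likelihood (M2/M3)
# ---------------------------------------------------------------------------

def _grm_dlog_tables(items, theta_nodes):
    """Per item: (n_nodes, n_cat) d log P(X=k|theta) / d theta."""
    out = []
    for item in items:
        a = item.discrimination
        b = np.asarray(item.thresholds)
        F = 1.0 / (1.0 + np.exp(-a * (theta_nodes[:, None] - b)))
        Fp = F * (1.0 - F)
        Fp_ext = np.concatenate([np.zeros((len(theta_nodes), 1)), Fp,
                                 np.zeros((len(theta_nodes), 1))], axis=1)
        dP = a * (Fp_ext[:, :-1] - Fp_ext[:, 1:])
        P = np.clip(grm_category_probs(theta_nodes, item), 1e-300, None)
        out.append(dP / P)
    return out


def _acc_score_nodes(responses, items, theta_nodes):
    """(persons, n_nodes) d/dtheta of the accuracy log-likelihood."""
    P = responses.shape[0]
    out = np.zeros((P, theta_nodes.shape[0]))
    for i, tab in enumerate(_grm_dlog_tables(items, theta_nodes)):
        col = responses[:, i]
        mask = np.isfinite(col)
        if not mask.any():
            continue
        x = np.where(mask, col, 0).astype(int)
        out += np.where(mask[:, None], tab[:, x].T, 0.0)
    return out


def _loglik_and_grad(data: Dataset, space: ParameterSpace, quad: QuadratureSpec,
                     x_nat: np.ndarray):
    """Marginal log-likelihood and its gradient w.r.t. the free natural
    parameters, via posterior latent moments (M2/M3 only)."""
    spec = space.to_spec(x_nat)
    L, grid = _loglik_matrix(data, spec, quad)
    lw = L + grid.logw[None, :]
    lse = logsumexp(lw, axis=1)
    loglik = float(lse.sum())
    post = np.exp(lw - lse[:, None])

    lat = spec.latent
    th = grid.theta
    ta = grid.tau
    Eth = post @ th
    Eta = post @ ta
    Eth2 = post @ (th * th)
    Eta2 = post @ (ta * ta)
    Etht = post @ (th * ta)

    tmask = np.isfinite(data.times).astype(float)
    z = np.where(tmask > 0, np.log(np.where(tmask > 0, data.times, 1.0)), 0.0)
    xi = np.array([it.intensity for it in spec.item_time])
    lam = np.array([it.speed_loading for it in spec.item_time])
    sig2 = np.array([it.residual_var for it in spec.item_time])
    phi = np.array([it.cross_loading for it in spec.item_time])

    zc = z - xi[None, :]
    lamB, phiB = lam[None, :], phi[None, :]
    R0 = (zc + Eta[:, None] * lamB - Eth[:, None] * phiB) / sig2[None, :]
    R1 = (zc * Eta[:, None] + lamB * Eta2[:, None] - phiB * Etht[:, None]) / sig2[None, :]
    R2 = (zc * Eth[:, None] + lamB * Etht[:, None] - phiB * Eth2[:, None]) / sig2[None, :]
    S = (zc ** 2 + 2 * zc * (lamB * Eta[:, None] - phiB * Eth[:, None])
         + lamB ** 2 * Eta2[:, None] + phiB ** 2 * Eth2[:, None]
         - 2 * lamB * phiB * Etht[:, None])

    free = space.free_entries
    syms = {e.symbol for e in free}
    grad = {}
    if "xi" in syms:
        g = (tmask * R0).sum(axis=0)
        for i in range(space.n_items):
            grad[("xi", i, None)] = g[i]
    if "lam" in syms:
        g = -(tmask * R1).sum(axis=0)
        for i in range(space.n_items):
            grad[("lam", i, None)] = g[i]
    if "phi" in syms:
        g = (tmask * R2).sum(axis=0)
        for i in range(space.n_items):
            grad[("phi", i, None)] = g[i]
    if "sig2" in syms:
        g = (tmask * (S / (2 * sig2[None, :] ** 2) - 1.0 / (2 * sig2[None, :]))).sum(axis=0)
        for i in range(space.n_items):
            grad[("sig2", i, None)] = g[i]

    need_theta = "mu_theta" in syms or "var_theta" in syms
    need_u = ("var_theta" in syms) or ("rho" in syms)
    sd_th = math.sqrt(lat.var_theta)
    sd_ta = math.sqrt(lat.var_tau)
    rho = lat.corr
    s2c = max(1.0 - rho ** 2, 1e-12)

    if need_u or need_theta:
        Eu = (Eth - lat.mean_theta) / sd_th
        Etau_u = (Etht - lat.mean_theta * Eta) / sd_th
        Eth_u = (Eth2 - lat.mean_theta * Eth) / sd_th
        R0u = (zc * Eu[:, None] + lamB * Etau_u[:, None] - phiB * Eth_u[:, None]) / sig2[None, :]

    if need_theta:
        theta1 = lat.mean_theta + sd_th * grid.u
        dA = _acc_score_nodes(data.responses, spec.item_acc, theta1)
        postU = post.reshape(post.shape[0], grid.n_theta, grid.n_tau).sum(axis=2)
        acc0 = (postU * dA).sum(axis=1)
        Ttheta0 = (tmask * R0 * phiB).sum(axis=1)
        if "mu_theta" in syms:
            grad[("mu_theta", None, None)] = float((acc0 + Ttheta0).sum())
        if "var_theta" in syms:
            accu = (postU * dA * grid.u[None, :]).sum(axis=1)
            Tthetau = (tmask * R0u * phiB).sum(axis=1)
            grad[("var_theta", None, None)] = float(((accu + Tthetau) / (2 * sd_th)).sum())

    if "mu_tau" in syms or "var_tau" in syms or "rho" in syms:
        Ttau0 = (tmask * R0 * lamB).sum(axis=1)
        Ttaut = (tmask * (R1 - lat.mean_tau * R0) * lamB).sum(axis=1)
        if "mu_tau" in syms:
            grad[("mu_tau", None, None)] = float(-Ttau0.sum())
        if "var_tau" in syms:
            grad[("var_tau", None, None)] = float(-(Ttaut / (2 * lat.var_tau)).sum())
        if "rho" in syms:
            Ttauu = (tmask * R0u * lamB).sum(axis=1)
            grad[("rho", None, None)] = float(-((sd_ta * Ttauu - rho * Ttaut) / s2c).sum())

    return loglik, np.array([grad[e.key] for e in free])


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_BIG = 1e12


def _safe_loglik(data, space, quad, x_nat):
    try:
        spec = space.to_spec(x_nat)
    except ValueError:
        return -_BIG
    from .model_core import marginal_loglik
    val = marginal_loglik(data, spec, quad)
    return val if np.isfinite(val) else -_BIG


def fit(data: Dataset, space: ParameterSpace, quad: QuadratureSpec | None = None,
        options: FitOptions | None = None) -> FitResult:
    """Maximize the marginal log-likelihood over the free parameters.

    Deterministic: identical inputs and options give identical results.
    Non-convergence is flagged on the result, never silent; a
    non-positive-definite observed information flags SEs unavailable.
    """
    quad = quad or QuadratureSpec()
    options = options or FitOptions()

    if space.n_free == 0:
        from .model_core import marginal_loglik
        spec = space.to_spec()
        ll = marginal_loglik(data, spec, quad)
        return FitResult(spec, {}, ll, data.n_persons, 0, True, 0.0, space)

    free = space.free_entries
    x0 = starting_values(data, space)
    y0 = _to_transformed(x0, free)
    analytic = space.analytic_gradient_ok()

    if analytic:
        def objective(y):
            x = _to_natural(y, free)
            ll, g = _loglik_and_grad(data, space, quad, x)
            if not np.isfinite(ll):
                return _BIG, np.zeros_like(y)
            return -ll, -g * _chain(y, free)
        res = minimize(objective, y0, jac=True, method="L-BFGS-B",
                       options={"maxiter": options.maxiter, "gtol": options.gtol,
                                "ftol": options.ftol})
    else:
        def objective(y):
            return -_safe_loglik(data, space, quad, _to_natural(y, free))
        res = minimize(objective, y0, method="L-BFGS-B",
                       options={"maxiter": options.maxiter, "gtol": options.gtol,
                                "ftol": options.ftol})

    x_hat = _to_natural(res.x, free)
    spec = space.to_spec(x_hat)
    loglik = float(-res.fun)
    gnorm = float(np.max(np.abs(res.jac))) if res.jac is not None else math.inf
    converged = bool(res.success or gnorm < 10 * options.gtol)

    ses: dict = {}
    se_ok = False
    if options.compute_se:
        H = _observed_information(data, space, quad, x_hat, analytic, options.se_step)
        try:
            cov = np.linalg.inv(H)
            d = np.diag(cov)
            if np.all(d > 0):
                se_vals = np.sqrt(d)
                ses = {e.key: float(se_vals[j]) for j, e in enumerate(free)}
                se_ok = True
        except np.linalg.LinAlgError:
            pass

    return FitResult(spec, ses, loglik, data.n_persons, space.n_free, converged,
                     gnorm, space, n_iter=int(res.nit), se_available=se_ok)


def _observed_information(data, space, quad, x_hat, analytic, h0):
    """Observed information of the free natural parameters: central finite
    differences of the score."""
    free = space.free_entries
    p = len(free)

    if analytic:
        def score(x):
            return _loglik_and_grad(data, space, quad, x)[1]
    else:
        def score(x):
            g = np.zeros(p)
            for j in range(p):
                h = h0 * (1 + abs(x[j]))
                xp, xm = x.copy(), x.copy()
                xp[j] += h
                xm[j] -= h
                g[j] = (_safe_loglik(data, space, quad, xp)
                        - _safe_loglik(data, space, quad, xm)) / (2 * h)
            return g

    H = np.zeros((p, p))
    for j in range(p):
        h = h0 * (1 + abs(x_hat[j]))
        xp, xm = x_hat.copy(), x_hat.copy()
        xp[j] += h
        xm[j] -= h
        H[:, j] = -(score(xp) - score(xm)) / (2 * h)
    return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# two-step study driver
# ---------------------------------------------------------------------------

@dataclass
class TwoStepResults:
    """Every fit of the two-step analysis, keyed by (model, level, group);
    international fits carry group=None."""

    fits: dict = field(default_factory=dict)

    def international(self, model_id: str) -> FitResult:
        return self.fits[(model_id, "international", None)]

    def table(self) -> pd.DataFrame:
        return fits_to_table(self.fits)


def two_step_analysis(data: Dataset, quad: QuadratureSpec | None = None,
                      options: FitOptions | None = None,
                      models: Sequence[str] = ("M1", "M2", "M3"),
                      levels: Sequence[str] = COUNTRY_LEVELS) -> TwoStepResults:
    """International calibration on the pooled sample, then the
    measurement-invariance ladder per group."""
    groups = data.groups()
    if len(groups) < 2:
        raise ValueError("the country step requires at least two groups")
    quad = quad or QuadratureSpec()
    results = TwoStepResults()
    n_cats = _infer_n_cats(data)

    anchors: dict = {}

    def run(model_id, level, group, dset, extra_anchors=None):
        anc = dict(anchors)
        if extra_anchors:
            anc.update(extra_anchors)
        try:
            space = build_parameter_space(model_id, level, anc, n_cats=n_cats)
            return fit(dset, space, quad, options)
        except Exception as exc:
            raise RuntimeError(
                f"fit failed for model={model_id} level={level} group={group}") from exc

    # step 1: international
    for model_id in models:
        fr = run(model_id, "international", None, data)
        anchors[f"{model_id}_international"] = fr
        results.fits[(model_id, "international", None)] = fr

    # step 2: per country
    for g in groups:
        dg = data.subset(g)
        m1_full = run("M1", "Full", g, dg) if "M1" in models else None
        if m1_full is not None:
            results.fits[("M1", "Full", g)] = m1_full
        for model_id in models:
            if model_id == "M1":
                continue
            for level in levels:
                extra = {"M1_Full": m1_full} if (model_id == "M3" and level == "Struct") else None
                results.fits[(model_id, level, g)] = run(model_id, level, g, dg, extra)
    return results


def _infer_n_cats(data: Dataset) -> tuple[int, ...]:
    out = []
    for i in range(data.n_items):
        col = data.responses[:, i]
        obs = col[np.isfinite(col)]
        out.append(int(obs.max()) + 1 if obs.size else 2)
    return tuple(out)


def fits_to_table(fits: Mapping) -> pd.DataFrame:
    """Tidy table of estimates and SEs keyed by model/level/group/symbol."""
    rows = []
    for (model_id, level, group), fr in fits.items():
        for e in fr.space.entries:
            val = _entry_value(fr.estimates, e)
            rows.append({
                "model": model_id, "level": level,
                "group": "" if group is None else group,
                "symbol": e.symbol,
                "item": -1 if e.item is None else e.item,
                "cat": -1 if e.cat is None else e.cat,
                "estimate": val, "free": e.free,
                "se": fr.standard_errors.get(e.key, np.nan),
            })
    return pd.DataFrame(rows)


def _entry_value(spec: ModelSpec, e: ParamEntry) -> float:
    if e.symbol == "a":
        return spec.item_acc[e.item].discrimination
    if e.symbol == "b":
        return spec.item_acc[e.item].thresholds[e.cat]
    if e.symbol in ("xi", "lam", "sig2", "phi"):
        it = spec.item_time[e.item]
        return {"xi": it.intensity, "lam": it.speed_loading,
                "sig2": it.residual_var, "phi": it.cross_loading}[e.symbol]
    lat = spec.latent
    return {"mu_theta": lat.mean_theta, "var_theta": lat.var_theta,
            "mu_tau": lat.mean_tau, "var_tau": lat.var_tau, "rho": lat.corr}[e.symbol]
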