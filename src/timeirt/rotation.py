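"""Rotation of the cross-loading model's latent space.

Under M3 the speed factor tau* is identified as uncorrelated with
proficiency, so it explains only the response-time covariance that
proficiency cannot.  To compare with the simple-structure model, the
latent space is rotated so that the speed factor is the unit-variance
linear combination of (theta, tau*) explaining the most common
response-time variance; its correlation with proficiency is then the
analogue of the simple-structure rho.

The rotation only re-expresses the latent basis: the model-implied
distribution of the data (log-time moments, marginal likelihood) is
unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_core import ModelSpec

__all__ = ["RotationResult", "rotate_m3"]


@dataclass(frozen=True)
class RotationResult:
    """Rotated loadings and the implied speed-proficiency correlation.

    ``rotation_coefficients`` = (c_theta, c_tau) define the rotated speed
    factor f = c_theta * theta + c_tau * tau* (unit variance).
    """

    rotated_speed_loadings: np.ndarray
    rotated_cross_loadings: np.ndarray
    implied_corr: float
    rotation_coefficients: tuple[float, float]
    variance_explained: float
    variance_explained_unrotated: float


def rotate_m3(spec: ModelSpec) -> RotationResult:
    """Rotate an (unrotated) M3 spec so the speed factor explains the most
    common response-time variance.

    In the standardized basis eta = (tau*/sd_tau, theta/sd_theta) the item
    log-times load with B = [-lambda sd_tau, phi sd_theta]; the rotated
    speed direction is the top eigenvector of B'B (2x2 closed form).  Sign
    convention: speed loadings predominantly positive, so higher speed
    means shorter times.
    """
    if spec.model_id != "M3":
        raise ValueError("rotation applies to M3 specs")
    if spec.latent.corr != 0.0:
        raise ValueError("rotation expects the unrotated identification (corr = 0)")
    lam = np.array([it.speed_loading for it in spec.item_time])
    phi = np.array([it.cross_loading for it in spec.item_time])
    sd_tau = math.sqrt(spec.latent.var_tau)
    sd_theta = math.sqrt(spec.latent.var_theta)
    B = np.column_stack([-lam * sd_tau, phi * sd_theta])
    M = B.T @ B
    if not M.any():
        raise ValueError("rotation undefined: all speed and cross loadings are zero")
    evals, evecs = np.linalg.eigh(M)
    r = evecs[:, -1]  # direction maximizing sum of squared loadings
    if np.allclose(M[0, 1], 0.0) and M[0, 0] >= M[1, 1]:
        # degenerate tie-break: keep the identity orientation
        r = np.array([1.0, 0.0])
    speed_load = -(B @ r)
    if speed_load.sum() < 0:
        r = -r
        speed_load = -speed_load
    r_perp = np.array([-r[1], r[0]])
    cross_load = B @ r_perp
    # correlation of the rotated factor with theta = sd_theta * eta2
    implied_corr = float(r[1])
    coeffs = (float(r[1] / sd_theta), float(r[0] / sd_tau))
    return RotationResult(
        rotated_speed_loadings=speed_load,
        rotated_cross_loadings=cross_load,
        implied_corr=implied_corr,
        rotation_coefficients=coeffs,
        variance_explained=float(evals[-1]),
        variance_explained_unrotated=float(M[0, 0]),
    )
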