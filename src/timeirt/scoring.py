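"""EAP person scoring, reliability and cross-model score comparisons.

Person estimates are posterior means (EAP) of the latent variables under a
fitted model, with posterior standard deviations quantifying residual
uncertainty.  Measurement precision is summarized by EAP reliability,
var(EAP) / (var(EAP) + mean(PSD^2)), and by the average posterior SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .model_core import Dataset, ModelSpec, QuadratureSpec, _loglik_matrix

__all__ = [
    "ScoreSet",
    "ScoreCorrelations",
    "eap_scores",
    "eap_reliability",
    "average_se",
    "score_correlations",
]


@dataclass
class ScoreSet:
    """Per-person EAP estimates and posterior SDs under one model."""

    person_id: np.ndarray
    group: np.ndarray
    eap_theta: np.ndarray
    psd_theta: np.ndarray
    eap_tau: np.ndarray | None
    psd_tau: np.ndarray | None
    model_id: str
    level: str = ""

    def __post_init__(self):
        if np.any(self.psd_theta <= 0):
            raise ValueError("posterior SDs must be positive")

    @property
    def n_persons(self) -> int:
        return len(self.eap_theta)

    def to_frame(self) -> pd.DataFrame:
        d = {"person_id": self.person_id, "group": self.group,
             "model": self.model_id, "level": self.level,
             "eap_theta": self.eap_theta, "psd_theta": self.psd_theta}
        if self.eap_tau is not None:
            d["eap_tau"] = self.eap_tau
            d["psd_tau"] = self.psd_tau
        return pd.DataFrame(d)


def eap_scores(data: Dataset, spec: ModelSpec, quad: QuadratureSpec | None = None,
               level: str = "") -> ScoreSet:
    """Posterior mean and SD of proficiency (and speed, for M2/M3) per
    person by quadrature over the latent posterior.

    Persons with no observed entries get the prior mean and SD (their
    posterior equals the prior).
    """
    quad = quad or QuadratureSpec()
    L, grid = _loglik_matrix(data, spec, quad)
    lw = L + grid.logw[None, :]
    post = np.exp(lw - logsumexp(lw, axis=1)[:, None])
    eap_t = post @ grid.theta
    var_t = post @ (grid.theta ** 2) - eap_t ** 2
    psd_t = np.sqrt(np.clip(var_t, 1e-12, None))
    eap_s = psd_s = None
    if spec.model_id != "M1":
        eap_s = post @ grid.tau
        var_s = post @ (grid.tau ** 2) - eap_s ** 2
        psd_s = np.sqrt(np.clip(var_s, 1e-12, None))
    return ScoreSet(data.person_id.copy(), data.group.copy(), eap_t, psd_t,
                    eap_s, psd_s, spec.model_id, level)


def eap_reliability(scores: ScoreSet) -> float:
    """EAP reliability of the proficiency scores:
    var(EAP) / (var(EAP) + mean(PSD^2)), in [0, 1]."""
    if scores.n_persons < 2:
        raise ValueError("EAP reliability requires at least two persons")
    v = float(np.var(scores.eap_theta, ddof=1))
    e = float(np.mean(scores.psd_theta ** 2))
    return v / (v + e)


def average_se(scores: ScoreSet) -> float:
    """Arithmetic mean of the proficiency posterior SDs."""
    if scores.n_persons < 1:
        raise ValueError("no persons to average over")
    return float(np.mean(scores.psd_theta))


@dataclass
class ScoreCorrelations:
    """Pearson correlations of EAP proficiency across models."""

    pooled: pd.DataFrame
    per_group: dict


def score_correlations(score_sets: list[ScoreSet]) -> ScoreCorrelations:
    """Correlation matrix of EAP proficiency vectors across models,
    pooled over all persons and within each group."""
    if not score_sets:
        raise ValueError("need at least one ScoreSet")
    base = score_sets[0]
    for s in score_sets[1:]:
        if s.n_persons != base.n_persons or not np.array_equal(s.person_id, base.person_id):
            raise ValueError("ScoreSets must cover identical persons in the same order")
    names = []
    for s in score_sets:
        name = s.model_id if not s.level else f"{s.model_id}_{s.level}"
        names.append(name)
    mat = np.column_stack([s.eap_theta for s in score_sets])
    pooled = pd.DataFrame(np.corrcoef(mat, rowvar=False), index=names, columns=names)
    per_group = {}
    for g in dict.fromkeys(base.group):
        m = base.group == g
        sub = mat[m]
        if sub.shape[0] >= 2:
            per_group[g] = pd.DataFrame(np.corrcoef(sub, rowvar=False),
                                        index=names, columns=names)
    return ScoreCorrelations(pooled, per_group)
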