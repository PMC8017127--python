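"""Model selection (BIC, invariance ladder) and GRM approximate fit.

The invariance ladder compares, per group and model family, the four
country-level parameterizations Full / Strong / Weak / Struct by BIC; the
overall preference sums BIC across groups per level.  GRM fit is assessed
with limited-information statistics computed from univariate and bivariate
response margins (SRMR on inter-item score correlations, RMSEA from a
bivariate-margin chi-square).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import COUNTRY_LEVELS, FitResult
from .model_core import Dataset, ModelSpec, QuadratureSpec, _std_normal_nodes, grm_category_probs

__all__ = [
    "LadderTable",
    "bic",
    "build_ladder",
    "select_invariance",
    "grm_fit_statistics",
]

logger = logging.getLogger(__name__)

# acceptability guidelines for the approximate fit statistics
SRMR_CUTOFF = 0.08
RMSEA_CUTOFF = 0.06


def bic(fit: FitResult) -> float:
    """Bayesian information criterion: -2 loglik + n_free * ln(n_persons)."""
    if not fit.converged:
        raise ValueError("refusing to compute BIC for an unconverged fit")
    return -2.0 * fit.loglik + fit.n_free * math.log(fit.n_persons)


@dataclass
class LadderTable:
    """Per group: BIC of each invariance level for one model family."""

    model_family: str
    values: pd.DataFrame  # index: group, columns: levels

    def range_bic(self) -> pd.DataFrame:
        return pd.DataFrame({
            "min": self.values.min(axis=1),
            "max": self.values.max(axis=1),
        })

    def preferred(self) -> pd.Series:
        """Per-group level attaining the minimum BIC; ties resolve toward
        the more constrained level (the column order Full..Struct)."""
        return self.values.idxmin(axis=1)

    def total(self) -> pd.Series:
        return self.values.sum(axis=0)


def build_ladder(fits: dict, model_family: str,
                 levels: tuple[str, ...] = COUNTRY_LEVELS) -> LadderTable:
    """Assemble the BIC ladder for one model family from two-step fits
    keyed by (model, level, group)."""
    groups = sorted({k[2] for k in fits if k[0] == model_family and k[2] is not None},
                    key=str)
    if not groups:
        raise ValueError(f"no country-level fits found for {model_family}")
    tab = pd.DataFrame(index=groups, columns=list(levels), dtype=float)
    for g in groups:
        for lev in levels:
            tab.loc[g, lev] = bic(fits[(model_family, lev, g)])
    return LadderTable(model_family, tab)


@dataclass
class InvarianceSelection:
    per_group: pd.Series
    overall: str
    total_bic: pd.Series
    ties: dict


def select_invariance(ladder: LadderTable) -> InvarianceSelection:
    """Preferred level per group (argmin BIC) and overall (argmin of the
    BIC total across groups).  Ties are reported and resolved toward the
    more constrained level."""
    vals = ladder.values
    per_group = vals.idxmin(axis=1)
    ties = {}
    for g in vals.index:
        row = vals.loc[g]
        tied = list(row.index[np.isclose(row, row.min())])
        if len(tied) > 1:
            ties[g] = tied
    total = ladder.total()
    overall = str(total.idxmin())
    return InvarianceSelection(per_group, overall, total, ties)


# ---------------------------------------------------------------------------
# limited-information GRM fit statistics
# ---------------------------------------------------------------------------

def _implied_margins(spec: ModelSpec, quad: QuadratureSpec):
    """Model-implied univariate category probabilities and per-item score
    moments, plus conditional category probabilities on the theta nodes."""
    nodes, w = _std_normal_nodes(quad.nodes_per_dim)
    theta = spec.latent.mean_theta + math.sqrt(spec.latent.var_theta) * nodes
    cond = [grm_category_probs(theta, item) for item in spec.item_acc]  # (n, K_i)
    pi = [w @ c for c in cond]
    return cond, pi, w


def grm_fit_statistics(data: Dataset, m1: ModelSpec,
                       quad: QuadratureSpec | None = None) -> dict:
    """Approximate GRM fit from univariate and bivariate response margins.

    SRMR: root mean squared difference between observed and model-implied
    inter-item Pearson correlations of the scores (pairwise complete).
    RMSEA: from the bivariate-margin chi-square
    ``X2 = sum_pairs n_pair * sum_cells (p_obs - p_exp)^2 / p_exp`` with
    ``df = sum_pairs (K_i K_j - 1) - n_item_params``, as
    ``sqrt(max(X2 - df, 0) / (df * n))``.  Item categories never observed
    are excluded from the affected margins and logged.
    """
    if m1.model_id != "M1":
        raise ValueError("fit statistics are defined for the accuracy-only model")
    quad = quad or QuadratureSpec()
    data.validate_against(m1)
    cond, pi, w = _implied_margins(m1, quad)
    I = data.n_items
    X = data.responses

    # model-implied score moments per item
    scores = [np.arange(len(p)) for p in pi]
    mean_imp = np.array([s @ p for s, p in zip(scores, pi)])
    var_imp = np.array([(s ** 2) @ p for s, p in zip(scores, pi)]) - mean_imp ** 2

    chi2 = 0.0
    df = 0.0
    sq_diffs = []
    n_pairs_used = 0
    for i in range(I):
        for j in range(i + 1, I):
            mask = np.isfinite(X[:, i]) & np.isfinite(X[:, j])
            n_pair = int(mask.sum())
            if n_pair < 2:
                continue
            xi, xj = X[mask, i].astype(int), X[mask, j].astype(int)
            Ki, Kj = len(pi[i]), len(pi[j])
            # observed bivariate table
            obs = np.zeros((Ki, Kj))
            np.add.at(obs, (xi, xj), 1.0)
            p_obs = obs / n_pair
            # implied bivariate table by quadrature (local independence)
            p_exp = np.einsum("q,qk,ql->kl", w, cond[i], cond[j])
            keep = p_exp > 1e-10
            if not keep.all():
                logger.info("pair (%d, %d): %d near-empty cells excluded",
                            i, j, int((~keep).sum()))
            chi2 += n_pair * float(((p_obs[keep] - p_exp[keep]) ** 2 / p_exp[keep]).sum())
            df += keep.sum() - 1
            n_pairs_used += 1
            # observed vs implied score correlation
            r_obs = np.corrcoef(xi, xj)[0, 1] if xi.std() > 0 and xj.std() > 0 else np.nan
            cov_imp = float(np.einsum("q,q,q->", w, cond[i] @ scores[i], cond[j] @ scores[j])) \
                - mean_imp[i] * mean_imp[j]
            r_imp = cov_imp / math.sqrt(var_imp[i] * var_imp[j])
            if np.isfinite(r_obs):
                sq_diffs.append((r_obs - r_imp) ** 2)

    n_item_params = sum(1 + it.n_categories - 1 for it in m1.item_acc)
    df = max(df - n_item_params, 1.0)
    n = data.n_persons
    rmsea = math.sqrt(max(chi2 - df, 0.0) / (df * n))
    srmr = math.sqrt(float(np.mean(sq_diffs))) if sq_diffs else float("nan")
    return {"rmsea": rmsea, "srmr": srmr, "chi2": chi2, "df": df,
            "n_pairs": n_pairs_used}
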