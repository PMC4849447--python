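"""Between-site effect heterogeneity: Cochran's Q, DerSimonian-Laird random effects.

Each link carries one effect estimate per site (the adjusted patient -
control Fisher-z difference) with its sampling variance.  Cochran's Q
tests whether the sites share a common true effect; links with Q-test
p < 0.05 are re-estimated under a random-effects model whose
between-site variance tau^2 is the DerSimonian-Laird moment estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class HeterogeneityResult:
    q_statistic: np.ndarray
    df: int
    q_p_value: np.ndarray
    heterogeneous: np.ndarray
    tau_squared: np.ndarray
    re_effect: np.ndarray
    re_z: np.ndarray
    re_p: np.ndarray


def _check(effects, variances):
    e = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    if e.ndim == 1:
        e = e[:, None]
    if v.ndim == 1:
        v = v[:, None]
    if e.shape != v.shape:
        raise ValueError("effects and variances must share shape")
    if e.shape[0] < 2:
        raise ValueError("need k >= 2 sites")
    if np.any(v <= 0):
        raise ValueError("variances must be positive")
    return e, v


def cochran_q(effects: np.ndarray, variances: np.ndarray):
    """Cochran's Q with its chi-square p-value (df = k - 1).

    ``effects``/``variances`` are (k,) or (k, n_links).  Fixed-effect
    weights are 1/v; Q = sum_i u_i (e_i - e_pooled)^2.
    """
    e, v = _check(effects, variances)
    u = 1.0 / v
    pooled = (u * e).sum(axis=0) / u.sum(axis=0)
    q = (u * (e - pooled) ** 2).sum(axis=0)
    df = e.shape[0] - 1
    p = stats.chi2.sf(q, df)
    if np.ndim(effects) == 1:
        return float(q[0]), float(p[0])
    return q, p


def random_effects(effects: np.ndarray, variances: np.ndarray):
    """DerSimonian-Laird random-effects pooling.

    tau^2 = max(0, (Q - (k-1)) / (sum u - sum u^2 / sum u)) with fixed-
    effect weights u = 1/v; the pooled effect then uses weights
    1/(v + tau^2).  Returns (tau2, re_effect, re_z, re_p), scalars for
    1-D input.
    """
    e, v = _check(effects, variances)
    k = e.shape[0]
    u = 1.0 / v
    su = u.sum(axis=0)
    pooled = (u * e).sum(axis=0) / su
    q = (u * (e - pooled) ** 2).sum(axis=0)
    denom = su - (u**2).sum(axis=0) / su
    tau2 = np.maximum(0.0, (q - (k - 1)) / denom)
    w = 1.0 / (v + tau2)
    re_effect = (w * e).sum(axis=0) / w.sum(axis=0)
    re_se = np.sqrt(1.0 / w.sum(axis=0))
    re_z = re_effect / re_se
    re_p = np.clip(2.0 * stats.norm.sf(np.abs(re_z)), 1e-300, 1.0)
    if np.ndim(effects) == 1:
        return float(tau2[0]), float(re_effect[0]), float(re_z[0]), float(re_p[0])
    return tau2, re_effect, re_z, re_p


def screen_links(effects: np.ndarray, variances: np.ndarray, alpha: float = 0.05) -> HeterogeneityResult:
    """Q-screen every link and re-estimate all of them under random effects."""
    e, v = _check(effects, variances)
    q, q_p = cochran_q(e, v)
    tau2, re_effect, re_z, re_p = random_effects(e, v)
    return HeterogeneityResult(
        q_statistic=q,
        df=e.shape[0] - 1,
        q_p_value=q_p,
        heterogeneous=q_p < alpha,
        tau_squared=tau2,
        re_effect=re_effect,
        re_z=re_z,
        re_p=re_p,
    )


def consistency_summary(
    site_effects: np.ndarray,
    combined_direction: np.ndarray,
    significant: np.ndarray,
) -> tuple[pd.DataFrame, float]:
    """Sign agreement of per-site effects with the combined direction.

    For each significant link, counts sites whose effect sign matches the
    combined direction; a link with exactly one dissenting site is
    flagged ``single_center_variation``.  Returns the per-link table and
    the fraction of significant links fully consistent across sites.
    """
    e = np.atleast_2d(np.asarray(site_effects, dtype=float))
    direction = np.asarray(combined_direction)
    sig = np.asarray(significant, dtype=bool)
    k = e.shape[0]
    idx = np.flatnonzero(sig)
    agree = (np.sign(e[:, idx]) == direction[idx]).sum(axis=0)
    table = pd.DataFrame(
        {
            "link": idx,
            "n_sites": k,
            "n_agree": agree,
            "consistent": agree == k,
            "single_center_variation": agree == k - 1,
        }
    )
    frac = float(table["consistent"].mean()) if len(table) else float("nan")
    return table, frac


def forest_export(
    effects: np.ndarray,
    variances: np.ndarray,
    site_ids,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Forest-plot data for one link: per-site effect +/- CI plus the pooled rows."""
    e = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    zq = stats.norm.ppf(0.5 + ci_level / 2.0)
    half = zq * np.sqrt(v)
    u = 1.0 / v
    fe = (u * e).sum() / u.sum()
    fe_se = np.sqrt(1.0 / u.sum())
    tau2, re_eff, re_z, _ = random_effects(e, v)
    re_se = re_eff / re_z if re_z != 0 else np.sqrt(1.0 / (1.0 / (v + tau2)).sum())
    rows = [
        {"site": s, "effect": ei, "ci_low": ei - h, "ci_high": ei + h, "weight": ui}
        for s, ei, h, ui in zip(site_ids, e, half, u)
    ]
    rows.append(
        {
            "site": "pooled (fixed)",
            "effect": fe,
            "ci_low": fe - zq * fe_se,
            "ci_high": fe + zq * fe_se,
            "weight": u.sum(),
        }
    )
    rows.append(
        {
            "site": "pooled (random)",
            "effect": re_eff,
            "ci_low": re_eff - zq * abs(re_se),
            "ci_high": re_eff + zq * abs(re_se),
            "weight": (1.0 / (v + tau2)).sum(),
        }
    )
    return pd.DataFrame(rows)
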