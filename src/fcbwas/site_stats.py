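"""Per-site, per-link covariate-adjusted two-sample comparison.

Within each imaging site, every connectivity link is tested for a
patient-control difference with a linear model

    z_link ~ intercept + group + covariates

whose group coefficient carries the adjusted mean Fisher-z difference.
The two-tailed p of that coefficient is converted to a *signed* normal
quantile z = sign(t) * Phi^-1(1 - p/2), which preserves effect direction
for the downstream Liptak-Stouffer combination (|z| is identical to the
unsigned textbook conversion Phi^-1(1 - p)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

P_FLOOR = 1e-300


@dataclass
class SiteLinkResult:
    """Vectorized link-wise test results for one site."""

    site_id: str
    t_statistic: np.ndarray
    df: int
    p_two_tailed: np.ndarray
    signed_z: np.ndarray
    mean_diff: np.ndarray  # adjusted patient - control Fisher-z difference
    var_diff: np.ndarray  # squared SE of that difference
    n_patients: int
    n_controls: int

    @property
    def n_links(self) -> int:
        return len(self.t_statistic)


def p_to_signed_z(p_two_tailed, sign=1, unsigned: bool = False):
    """Convert a two-tailed p-value to a normal-quantile z-score.

    Default carries direction: z = sign * Phi^-1(1 - p/2).  With
    ``unsigned=True`` the direction is dropped and z = Phi^-1(1 - p),
    the literal one-sided conversion.  p is clipped to [1e-300, 1].
    """
    p = np.clip(np.asarray(p_two_tailed, dtype=float), P_FLOOR, 1.0)
    if unsigned:
        z = stats.norm.isf(p)
    else:
        z = np.asarray(sign, dtype=float) * stats.norm.isf(p / 2.0)
    return float(z) if np.ndim(z) == 0 else z


def site_link_test(
    z_values: np.ndarray,
    groups: np.ndarray,
    covariates: np.ndarray | None = None,
    site_id: str = "",
    mode: str = "model",
) -> SiteLinkResult:
    """Test every link for a group difference within one site.

    Parameters
    ----------
    z_values : (n_subjects, n_links) Fisher-z link strengths.
    groups : binary labels, 1 = patient, 0 = control.
    covariates : optional (n_subjects, c) matrix regressed alongside the
        group indicator (``mode="model"``, default) or removed from the
        links first with a plain two-sample t on the residuals
        (``mode="residualize"``).
    """
    z = np.atleast_2d(np.asarray(z_values, dtype=float))
    g = np.asarray(groups, dtype=float).ravel()
    n = z.shape[0]
    if g.shape[0] != n:
        raise ValueError("groups length must match subject rows")
    n_pat = int((g == 1).sum())
    n_con = int((g == 0).sum())
    if n_pat < 3 or n_con < 3:
        raise ValueError(
            f"site {site_id!r}: need >= 3 subjects per group "
            f"(got {n_pat} patients, {n_con} controls)"
        )
    if covariates is None or np.size(covariates) == 0:
        cov = np.empty((n, 0))
    else:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            raise ValueError("covariate rows must match subjects")

    if mode == "residualize" and cov.shape[1]:
        nuis = np.column_stack([np.ones(n), cov])
        beta, *_ = np.linalg.lstsq(nuis, z, rcond=None)
        z = z - nuis @ beta
        cov = np.empty((n, 0))
    elif mode not in ("model", "residualize"):
        raise ValueError("mode must be 'model' or 'residualize'")

    design = np.column_stack([np.ones(n), g, cov])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            f"site {site_id!r}: rank-deficient design "
            "(a covariate is collinear with the intercept or group)"
        )
    df = n - design.shape[1]
    if mode == "residualize":
        # residualization consumed covariate df invisibly to this design
        df = n - 2 - (np.size(covariates) // n if covariates is not None else 0)
    if df < 1:
        raise ValueError("non-positive residual degrees of freedom")

    xtx_inv = np.linalg.inv(design.T @ design)
    beta = xtx_inv @ design.T @ z
    resid = z - design @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    var_b = sigma2 * xtx_inv[1, 1]
    mean_diff = beta[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean_diff / np.sqrt(var_b)
    t = np.where(var_b == 0, 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, P_FLOOR, 1.0)
    signed_z = p_to_signed_z(p, np.where(t >= 0, 1.0, -1.0))
    return SiteLinkResult(
        site_id=site_id,
        t_statistic=t,
        df=df,
        p_two_tailed=p,
        signed_z=np.asarray(signed_z),
        mean_diff=mean_diff,
        var_diff=var_b,
        n_patients=n_pat,
        n_controls=n_con,
    )
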