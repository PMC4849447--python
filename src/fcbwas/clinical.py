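"""Clinical correlates: site-adjusted partial correlation with FDR control.

Within the patient sample, each altered link's Fisher-z strength is
partially correlated with symptom scores (PANSS subscales) and illness
duration after removing site effects: both variables are residualized on
site indicator dummies (plus intercept) and the residuals' Pearson
correlation is tested against a t reference with df = n - n_sites - 1.
Benjamini-Hochberg step-up controls the false discovery rate within each
clinical variable's family of links.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ClinicalCorrelation:
    link: int
    variable: str
    partial_r: float
    p: float
    fdr_significant: bool


def _site_dummies(site_labels) -> np.ndarray:
    sites, inverse = np.unique(np.asarray(site_labels), return_inverse=True)
    dummies = np.zeros((len(inverse), len(sites)))
    dummies[np.arange(len(inverse)), inverse] = 1.0
    return dummies[:, 1:]  # drop one level; intercept added by the caller


def partial_correlation_site_adjusted(
    link_strength: np.ndarray,
    clinical: np.ndarray,
    site_labels,
) -> tuple[float, float]:
    """Correlation of two subject-level variables after removing site means.

    Both vectors are regressed on site dummies + intercept; the Pearson r
    of the residuals is returned with its two-tailed p from
    t = r * sqrt(df / (1 - r^2)), df = n - n_sites - 1.  Sites with fewer
    than two subjects are dropped with a warning.  With a single site
    this reduces to the plain Pearson correlation.
    """
    x = np.asarray(link_strength, dtype=float).ravel()
    y = np.asarray(clinical, dtype=float).ravel()
    site = np.asarray(site_labels)
    if not (len(x) == len(y) == len(site)):
        raise ValueError("inputs must share length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y, site = x[keep], y[keep], site[keep]
    sites, counts = np.unique(site, return_counts=True)
    small = sites[counts < 2]
    if small.size:
        warnings.warn(f"dropping sites with < 2 patients: {small.tolist()}")
        keep = ~np.isin(site, small)
        x, y, site = x[keep], y[keep], site[keep]
        sites = np.unique(site)
    n = len(x)
    n_sites = len(sites)
    df = n - n_sites - 1
    if df < 3:
        raise ValueError("need at least 3 residual degrees of freedom")
    design = np.column_stack([np.ones(n), _site_dummies(site)])
    hat = design @ np.linalg.lstsq(design, np.column_stack([x, y]), rcond=None)[0]
    rx = x - hat[:, 0]
    ry = y - hat[:, 1]
    denom = np.linalg.norm(rx) * np.linalg.norm(ry)
    if denom == 0:
        return 0.0, 1.0
    r = float(np.clip(rx @ ry / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags.

    Rejects all hypotheses with p <= p_(k*) where k* is the largest k
    such that p_(k) <= k q / m.  Deterministic under ties.  An empty
    input yields an empty flag vector.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    below = np.flatnonzero(ranked <= (np.arange(1, m + 1) * q / m))
    flags = np.zeros(m, dtype=bool)
    if below.size:
        flags[order[: below[-1] + 1]] = True
    return flags


def clinical_scan(
    link_matrix: np.ndarray,
    clinical_table: pd.DataFrame,
    site_labels,
    variables=None,
    q: float = 0.05,
    family: str = "per_variable",
) -> pd.DataFrame:
    """Partial-correlation scan of every altered link against each clinical variable.

    ``link_matrix`` is (n_patients, n_altered_links); ``clinical_table``
    holds one column per variable (NaN = missing, dropped per variable).
    FDR families are per variable by default (each variable's links form
    one family) or ``family="global"`` for a single family.  Constant
    variables are skipped with a warning.
    """
    links = np.atleast_2d(np.asarray(link_matrix, dtype=float))
    n_links = links.shape[1]
    if variables is None:
        variables = list(clinical_table.columns)
    rows: list[dict] = []
    for var in variables:
        y = clinical_table[var].to_numpy(dtype=float)
        mask = np.isfinite(y)
        if mask.sum() < 8 or np.nanstd(y) == 0:
            warnings.warn(f"clinical variable {var!r} constant or too sparse; skipped")
            continue
        site = np.asarray(site_labels)[mask]
        for link in range(n_links):
            r, p = partial_correlation_site_adjusted(links[mask, link], y[mask], site)
            rows.append({"link": link, "variable": var, "partial_r": r, "p": p})
    table = pd.DataFrame(rows, columns=["link", "variable", "partial_r", "p"])
    if len(table) == 0:
        table["fdr_significant"] = pd.Series(dtype=bool)
        return table
    flags = np.zeros(len(table), dtype=bool)
    if family == "global":
        flags = bh_fdr(table["p"].to_numpy(), q)
    elif family == "per_variable":
        for var in table["variable"].unique():
            sel = (table["variable"] == var).to_numpy()
            flags[sel] = bh_fdr(table.loc[sel, "p"].to_numpy(), q)
    else:
        raise ValueError("family must be 'per_variable' or 'global'")
    table["fdr_significant"] = flags
    return table
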