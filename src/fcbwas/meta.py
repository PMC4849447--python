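"""Liptak-Stouffer combination across sites, the MA statistic, and cluster maps.

Per-site signed z-scores for each link are combined as

    Z = sum_i w_i z_i / sqrt(sum_i w_i^2)

which is standard normal under the null for any positive weights.  The
default weight is sqrt(n_i) (sample-size weighting in the Liptak sense);
``weights="n"`` uses the raw site sample size instead.  Combined Z is
converted to a two-tailed p and Bonferroni-corrected over the link
family.  The per-node MA (measure of association) counts the node's
links whose combined p falls below the corrected threshold; painted onto
the analysis grid, its connected components form the cluster map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .connectivity import AtlasSpec


@dataclass
class MetaLinkResult:
    """Combined meta-analytic results for every link."""

    combined_z: np.ndarray
    combined_p: np.ndarray
    significant: np.ndarray
    direction: np.ndarray  # +1 increase in patients, -1 decrease
    alpha_bonf: float
    site_zs: np.ndarray  # (k_sites, n_links)
    weights: np.ndarray  # (k_sites,)
    site_ids: list = field(default_factory=list)

    @property
    def n_links(self) -> int:
        return len(self.combined_z)


@dataclass
class MAMap:
    """Per-node count of significantly altered links."""

    counts: np.ndarray
    alpha: float

    @property
    def n_nodes(self) -> int:
        return len(self.counts)


@dataclass
class Cluster:
    members: np.ndarray  # (m, 3) voxel indices
    size: int
    peak_voxel: tuple
    peak_mm: tuple
    peak_ma: int
    total_links: int


def stouffer_combine(site_zs: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted Stouffer combination; scale-invariant in the weights.

    ``site_zs`` is (k,) or (k, n_links); a single site returns its z
    unchanged for any weight.  Links with any non-finite site z yield
    NaN (flagged missing).
    """
    z = np.asarray(site_zs, dtype=float)
    one_dim = z.ndim == 1
    if one_dim:
        z = z[:, None]
    w = np.asarray(weights, dtype=float).ravel()
    if w.shape[0] != z.shape[0]:
        raise ValueError("one weight per site required")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    combined = (w[:, None] * z).sum(axis=0) / np.sqrt((w**2).sum())
    combined = np.where(np.isfinite(z).all(axis=0), combined, np.nan)
    return float(combined[0]) if one_dim else combined


def bonferroni_threshold(n_links: int, family_alpha: float = 0.05) -> float:
    """Per-link alpha controlling the family-wise error over all links."""
    if n_links < 1:
        raise ValueError("n_links must be >= 1")
    return family_alpha / n_links


def site_weights(site_results, scheme: str = "sqrt_n") -> np.ndarray:
    """Stouffer weights from per-site sample sizes (sqrt(n) or n)."""
    n = np.array([r.n_patients + r.n_controls for r in site_results], dtype=float)
    if scheme == "sqrt_n":
        return np.sqrt(n)
    if scheme == "n":
        return n
    raise ValueError("weights scheme must be 'sqrt_n' or 'n'")


def combine_sites(
    site_results,
    weights: str | np.ndarray = "sqrt_n",
    family_alpha: float = 0.05,
) -> MetaLinkResult:
    """Combine per-site link tests into Bonferroni-flagged meta results."""
    if not site_results:
        raise ValueError("no site results to combine")
    n_links_ = site_results[0].n_links
    if any(r.n_links != n_links_ for r in site_results):
        raise ValueError("site results cover different link sets")
    z = np.vstack([r.signed_z for r in site_results])
    w = site_weights(site_results, weights) if isinstance(weights, str) else np.asarray(weights, float)
    combined_z = stouffer_combine(z, w)
    combined_p = np.clip(2.0 * stats.norm.sf(np.abs(combined_z)), 1e-300, 1.0)
    alpha_bonf = bonferroni_threshold(n_links_, family_alpha)
    significant = combined_p < alpha_bonf
    return MetaLinkResult(
        combined_z=np.asarray(combined_z),
        combined_p=combined_p,
        significant=significant,
        direction=np.where(combined_z >= 0, 1, -1),
        alpha_bonf=alpha_bonf,
        site_zs=z,
        weights=w,
        site_ids=[r.site_id for r in site_results],
    )


def compute_ma(p_values: np.ndarray, alpha: float, n_nodes: int) -> MAMap:
    """Per-node MA = number of the node's links with p < alpha.

    ``p_values`` is the canonical upper-triangle link vector.  The counts
    satisfy sum(MA) = 2 * number of significant links exactly.
    """
    p = np.asarray(p_values, dtype=float)
    i, j = np.triu_indices(n_nodes, k=1)
    if p.shape[0] != i.shape[0]:
        raise ValueError("p vector length does not match n_nodes")
    hits = p < alpha
    counts = np.bincount(i[hits], minlength=n_nodes) + np.bincount(
        j[hits], minlength=n_nodes
    )
    return MAMap(counts=counts, alpha=alpha)


_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def extract_clusters(
    ma_volume: np.ndarray,
    affine: np.ndarray,
    min_size: int = 20,
    connectivity: int = 26,
    ma_threshold: int = 1,
    link_volume: np.ndarray | None = None,
) -> list[Cluster]:
    """Connected components of {MA >= threshold}, size-filtered.

    Returns clusters sorted by descending peak MA; peaks are reported in
    mm via the affine.  ``link_volume`` (same grid, per-voxel link
    counts) fills ``total_links``; defaults to summing MA over members.
    """
    ma = np.asarray(ma_volume)
    if ma.ndim != 3:
        raise ValueError("MA volume must be 3D")
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be 6, 18 or 26")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n_comp = ndimage.label(ma >= ma_threshold, structure=structure)
    clusters: list[Cluster] = []
    for comp in range(1, n_comp + 1):
        members = np.argwhere(labels == comp)
        if len(members) < min_size:
            continue
        vals = ma[tuple(members.T)]
        peak = tuple(int(v) for v in members[np.argmax(vals)])
        peak_mm = tuple(np.round((affine @ np.array([*peak, 1.0]))[:3], 6))
        if link_volume is not None:
            total = int(np.asarray(link_volume)[tuple(members.T)].sum())
        else:
            total = int(vals.sum())
        clusters.append(
            Cluster(
                members=members,
                size=len(members),
                peak_voxel=peak,
                peak_mm=peak_mm,
                peak_ma=int(vals.max()),
                total_links=total,
            )
        )
    clusters.sort(key=lambda c: c.peak_ma, reverse=True)
    return clusters


def ma_to_volume(ma: MAMap, atlas: AtlasSpec) -> np.ndarray:
    """Paint region-level MA counts onto the atlas grid (background 0)."""
    vol = np.zeros(atlas.label_volume.shape, dtype=np.int32)
    for count, rid in zip(ma.counts, atlas.region_ids):
        vol[atlas.label_volume == rid] = int(count)
    return vol


def cluster_table(clusters: list[Cluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "peak_x_mm": c.peak_mm[0],
                "peak_y_mm": c.peak_mm[1],
                "peak_z_mm": c.peak_mm[2],
                "size": c.size,
                "peak_ma": c.peak_ma,
                "n_links": c.total_links,
            }
            for c in clusters
        ]
    )


def manhattan_export(
    p_values: np.ndarray,
    node_regions: np.ndarray,
    n_nodes: int,
    p_cutoff: float = 1e-5,
) -> pd.DataFrame:
    """Manhattan-plot table: one row per link with p below the cutoff.

    ``node_regions`` maps each node to its atlas region id (0 =
    unlabelled -> excluded).  Homologous left/right atlas labels are
    numbered adjacently in the AAL convention, so sorting by region id
    reproduces the plotting order.
    """
    p = np.asarray(p_values, dtype=float)
    regions = np.asarray(node_regions)
    i, j = np.triu_indices(n_nodes, k=1)
    keep = (p < p_cutoff) & (regions[i] > 0) & (regions[j] > 0)
    table = pd.DataFrame(
        {
            "region_a": regions[i[keep]],
            "region_b": regions[j[keep]],
            "neg_log10_p": -np.log10(np.clip(p[keep], 1e-300, 1.0)),
        }
    )
    return table.sort_values(["region_a", "region_b"], kind="stable").reset_index(
        drop=True
    )
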