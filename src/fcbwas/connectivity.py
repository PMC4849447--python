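"""Per-subject functional connectivity: region extraction, Fisher-z matrices, link indexing.

Functional connectivity between two nodes (voxels or atlas regions) is the
Pearson correlation of their BOLD time series, variance-stabilized with the
Fisher transform z = atanh(r). Whole-brain analyses store only the upper
triangle of the symmetric node x node matrix; ``link_index`` defines the
canonical 0-based, row-major flattening used everywhere in this package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# r is clipped to +/-(1 - R_CLIP_EPS) before atanh so degenerate node pairs
# (duplicated series) yield a large finite z instead of infinity.
R_CLIP_EPS = 1e-7

ANATOMICAL_CLASSES = (
    "Frontal",
    "Sensorimotor",
    "Parietal",
    "Occipital",
    "Temporal",
    "Subcortical",
)


@dataclass
class AtlasSpec:
    """A labelled parcellation volume plus its lookup table.

    ``label_volume`` holds integer region ids (0 = background) on the
    analysis grid; ``affine`` maps voxel indices to mm coordinates.
    ``lookup`` has columns id, name, abbreviation, anatomical_class.
    """

    label_volume: np.ndarray
    affine: np.ndarray
    lookup: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        self.label_volume = np.asarray(self.label_volume)
        if self.label_volume.ndim != 3:
            raise ValueError("atlas label volume must be 3D")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.lookup is None:
            ids = self.region_ids
            self.lookup = pd.DataFrame(
                {
                    "id": ids,
                    "name": [f"region_{i}" for i in ids],
                    "abbreviation": [f"R{i}" for i in ids],
                    "anatomical_class": ["Subcortical"] * len(ids),
                }
            )
        bad = set(self.lookup["anatomical_class"]) - set(ANATOMICAL_CLASSES)
        if bad:
            raise ValueError(f"unknown anatomical classes: {sorted(bad)}")

    @property
    def region_ids(self) -> np.ndarray:
        ids = np.unique(self.label_volume)
        return ids[ids > 0]


@dataclass
class ConnectivityMatrix:
    """Symmetric Fisher-z connectivity matrix for one subject.

    The diagonal is stored as 0 and excluded from analysis.  Nodes whose
    series had zero variance are listed in ``bad_nodes``; their links are
    NaN.
    """

    node_ids: np.ndarray
    z_values: np.ndarray
    n_timepoints_used: int
    bad_nodes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def upper_triangle(self) -> np.ndarray:
        """Flatten to the canonical link vector (see :func:`link_index`)."""
        i, j = np.triu_indices(self.n_nodes, k=1)
        return self.z_values[i, j]


def n_links(n_nodes: int) -> int:
    """Number of unique undirected links among ``n_nodes`` nodes."""
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    return n_nodes * (n_nodes - 1) // 2


def link_index(node_i, node_j, n_nodes: int):
    """Map an ordered node pair (i < j) to its flat upper-triangle index.

    Row-major over the strict upper triangle: for n=4 the pairs
    (0,1),(0,2),(0,3),(1,2),(1,3),(2,3) map to 0..5.  Accepts scalars or
    arrays.  Exact for arbitrarily large n (integer arithmetic only).
    """
    i = np.asarray(node_i)
    j = np.asarray(node_j)
    if np.any(i < 0) or np.any(j >= n_nodes) or np.any(i >= j):
        raise ValueError("require 0 <= i < j < n_nodes")
    idx = i * (2 * n_nodes - i - 1) // 2 + (j - i - 1)
    if np.isscalar(node_i) or (i.ndim == 0 and j.ndim == 0):
        return int(idx)
    return idx


def link_pair(index: int, n_nodes: int) -> tuple[int, int]:
    """Inverse of :func:`link_index`; exact via integer square root."""
    total = n_links(n_nodes)
    if not 0 <= index < total:
        raise ValueError(f"link index {index} out of range for n={n_nodes}")
    # count pairs from the end of the triangle; t = largest triangular root
    rev = total - 1 - index
    t = (math.isqrt(8 * rev + 1) - 1) // 2
    i = n_nodes - 2 - t
    j = n_nodes - 1 - (rev - t * (t + 1) // 2)
    return int(i), int(j)


def extract_region_series(image: np.ndarray, atlas: AtlasSpec) -> np.ndarray:
    """Average a 4D image over each atlas region.

    Returns a (n_regions, n_timepoints) matrix ordered by ascending region
    id.  Regions present in the lookup but absent from the grid raise.
    """
    image = np.asarray(image)
    if image.ndim != 4:
        raise ValueError("expected a 4D (x, y, z, t) image")
    if image.shape[:3] != atlas.label_volume.shape:
        raise ValueError(
            f"grid mismatch: image {image.shape[:3]} vs atlas "
            f"{atlas.label_volume.shape}"
        )
    ids = atlas.region_ids
    flat_img = image.reshape(-1, image.shape[3])
    flat_lab = atlas.label_volume.ravel()
    out = np.empty((len(ids), image.shape[3]))
    for k, rid in enumerate(ids):
        members = flat_lab == rid
        if not members.any():
            raise ValueError(f"region {rid} has no voxels on the grid")
        out[k] = flat_img[members].mean(axis=0)
    return out


def fisher_z(r: np.ndarray) -> np.ndarray:
    """atanh with clipping at +/-(1 - 1e-7) so r = +/-1 stays finite."""
    return np.arctanh(np.clip(r, -1 + R_CLIP_EPS, 1 - R_CLIP_EPS))


def correlation_matrix(series: np.ndarray, node_ids=None) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of node series, Fisher z-transformed.

    ``series`` is (n_nodes, n_timepoints).  Zero-variance nodes get NaN
    links and are reported in ``bad_nodes``.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("series must be 2D (nodes x time)")
    n_nodes, n_t = series.shape
    if n_t < 3:
        raise ValueError("need at least 3 timepoints")
    if node_ids is None:
        node_ids = np.arange(n_nodes)
    sd = series.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(series)
    r = (r + r.T) / 2.0  # corrcoef is symmetric only up to rounding
    z = fisher_z(r)
    z[bad, :] = np.nan
    z[:, bad] = np.nan
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(
        node_ids=np.asarray(node_ids),
        z_values=z,
        n_timepoints_used=n_t,
        bad_nodes=bad,
    )


def voxel_link_z(series: np.ndarray, block_size: int = 512) -> np.ndarray:
    """Upper-triangle Fisher-z link vector computed in row blocks.

    At voxel scale the full node x node matrix cannot be materialized;
    this streams row strips of the standardized series against the whole
    matrix and emits links in canonical :func:`link_index` order.
    """
    series = np.asarray(series, dtype=float)
    n, t = series.shape
    s = series - series.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(s, axis=1, keepdims=True)
    norm[norm == 0] = np.nan
    s /= norm
    out = np.empty(n_links(n), dtype=np.float32)
    pos = 0
    for start in range(0, n - 1, block_size):
        stop = min(start + block_size, n - 1)
        r_block = s[start:stop] @ s[start + 1 :].T  # rows i, cols j-start-1
        for local, i in enumerate(range(start, stop)):
            row = r_block[local, i - start :]
            out[pos : pos + row.size] = fisher_z(row)
            pos += row.size
    return out
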