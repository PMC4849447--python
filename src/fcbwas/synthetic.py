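"""Synthetic multi-site resting-state cohorts with planted hub dysconnectivity.

Emulates the data structure a multi-site patient/control connectome
study assumes: several imaging sites, each contributing patients and
controls whose region-level BOLD series are drawn from a multivariate
normal with a controlled correlation structure.  A subject's target
Fisher-z connectivity for link (a, b) is

    z_ab = baseline + site_offset_ab + covariate terms + group * delta_ab

where delta_ab is nonzero only on the planted effect links (typically a
designated hub region with mixed-sign link shifts).  Series are obtained
by Cholesky mixing of latent white innovations — giving exact analytic
control of the expected correlation — optionally passed through an AR(1)
recursion with variance-preserving scaling so the lag-0 correlation is
untouched.  Voxel series are their region's series plus independent
noise.

The planted truth is emitted alongside the data and is never consumed by
any inference stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import AtlasSpec, correlation_matrix, fisher_z

_AR_BURN_IN = 50


def default_effect_map(
    hub_region: int, n_regions: int, n_links: int = 10, magnitude: float = 0.3
) -> list[tuple[int, int, float]]:
    """Mixed-sign link shifts between a hub and its first ``n_links`` partners.

    Signs alternate (+, -, +, ...) so the hub carries both increased and
    decreased connectivity, the pattern a dysconnectivity hub shows.
    """
    partners = [r for r in range(1, n_regions + 1) if r != hub_region][:n_links]
    if len(partners) < n_links:
        raise ValueError("not enough regions for the requested number of hub links")
    return [
        (min(hub_region, p), max(hub_region, p), magnitude * (1 if k % 2 == 0 else -1))
        for k, p in enumerate(partners)
    ]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults are a desk-scale stand-in for a multi-site study: 3 sites
    of 40 patients + 40 controls, a 12x12x12 voxel grid tiled into 27
    regions, 150 timepoints at TR = 2 s, and ten mixed-sign links of
    |delta z| = 0.3 planted on a hub region.
    """

    n_sites: int = 3
    n_patients: int = 40
    n_controls: int = 40
    grid_shape: tuple = (12, 12, 12)
    n_regions: int = 27
    n_timepoints: int = 150
    tr_seconds: float = 2.0
    hub_region: int = 14
    effect_map: list = None
    site_shift_sd: float = 0.1
    covariate_effects: dict = field(
        default_factory=lambda: {
            "age": -0.001,  # per year from age 30
            "sex": 0.02,
            "dose": -0.005,  # per 100 mg CPZ-equivalent
            "motion": -0.05,  # per mm mean FD
        }
    )
    ar1_coefficient: float = 0.3
    baseline_z: float = 0.1
    voxel_noise_sd: float = 1.0
    clinical_coupling: list = field(default_factory=list)  # (a, b, variable, r)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_map is None:
            self.effect_map = default_effect_map(self.hub_region, self.n_regions)
        for name in ("n_sites", "n_patients", "n_controls", "n_regions", "n_timepoints"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.ar1_coefficient < 1:
            raise ValueError("ar1_coefficient must lie in [0, 1)")
        for a, b, dz in self.effect_map:
            if not (1 <= a <= self.n_regions and 1 <= b <= self.n_regions) or a == b:
                raise ValueError(f"effect link ({a}, {b}) outside the atlas tiling")
            if abs(dz) >= 2:
                raise ValueError("|delta_z| must be < 2")
        _tile_factors(self.grid_shape, self.n_regions)  # validates divisibility

    @property
    def n_subjects(self) -> int:
        return self.n_sites * (self.n_patients + self.n_controls)


@dataclass
class SyntheticCohort:
    """Generated data plus its planted ground truth."""

    level: str  # "region" or "voxel"
    region_series: np.ndarray  # (n_subjects, n_regions, n_timepoints)
    images: list | None  # per-subject 4D arrays (voxel level only)
    atlas: AtlasSpec
    phenotypes: pd.DataFrame
    truth: pd.DataFrame  # columns region_a, region_b, delta_z
    config: SimulationConfig

    @property
    def n_subjects(self) -> int:
        return len(self.phenotypes)


def _tile_factors(grid_shape, n_regions) -> tuple[int, int, int]:
    """Factor n_regions into per-axis block counts dividing the grid."""
    best = None
    for kx in range(1, n_regions + 1):
        if n_regions % kx:
            continue
        rest = n_regions // kx
        for ky in range(1, rest + 1):
            if rest % ky:
                continue
            kz = rest // ky
            if grid_shape[0] % kx or grid_shape[1] % ky or grid_shape[2] % kz:
                continue
            spread = max(kx, ky, kz) - min(kx, ky, kz)
            if best is None or spread < best[0]:
                best = (spread, (kx, ky, kz))
    if best is None:
        raise ValueError(
            f"cannot tile grid {grid_shape} into {n_regions} equal blocks"
        )
    return best[1]


def make_atlas(grid_shape, n_regions, voxel_size_mm: float = 3.0) -> AtlasSpec:
    """Tile the grid into near-cubic blocks labelled 1..n_regions."""
    kx, ky, kz = _tile_factors(grid_shape, n_regions)
    bx, by, bz = grid_shape[0] // kx, grid_shape[1] // ky, grid_shape[2] // kz
    ix, iy, iz = np.indices(grid_shape)
    labels = ((ix // bx) * ky * kz + (iy // by) * kz + (iz // bz) + 1).astype(np.int16)
    affine = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
    affine[:3, 3] = -voxel_size_mm * (np.asarray(grid_shape) - 1) / 2.0
    return AtlasSpec(label_volume=labels, affine=affine)


def _target_z_matrix(config, site_offsets, covariates, is_patient) -> np.ndarray:
    r = config.n_regions
    z = np.full((r, r), config.baseline_z)
    z += site_offsets
    refs = {"age": 30.0, "sex": 0.5, "dose": 0.0, "motion": 0.0}
    for name, coef in config.covariate_effects.items():
        z += coef * (covariates[name] - refs.get(name, 0.0))
    if is_patient:
        for a, b, dz in config.effect_map:
            z[a - 1, b - 1] += dz
            z[b - 1, a - 1] += dz
    np.fill_diagonal(z, 0.0)
    return z


def _correlation_from_z(z: np.ndarray) -> np.ndarray:
    c = np.tanh(z)
    np.fill_diagonal(c, 1.0)
    w, v = np.linalg.eigh(c)
    if w.min() < 1e-8:  # rare with default magnitudes; clip and renormalize
        w = np.clip(w, 1e-8, None)
        c = (v * w) @ v.T
        d = np.sqrt(np.diag(c))
        c = c / np.outer(d, d)
    return c


def _subject_series(config, c: np.ndarray, rng) -> np.ndarray:
    t_total = config.n_timepoints + (_AR_BURN_IN if config.ar1_coefficient > 0 else 0)
    chol = np.linalg.cholesky(c)
    innovations = chol @ rng.standard_normal((config.n_regions, t_total))
    phi = config.ar1_coefficient
    if phi == 0:
        return innovations[:, -config.n_timepoints :]
    x = np.empty_like(innovations)
    scale = np.sqrt(1 - phi**2)
    x[:, 0] = innovations[:, 0]
    for t in range(1, t_total):
        x[:, t] = phi * x[:, t - 1] + scale * innovations[:, t]
    return x[:, -config.n_timepoints :]


_SITE_AGE_RANGES = [(20, 40), (18, 38), (25, 48), (22, 45), (20, 50)]


def _draw_phenotype(rng, site_name: str, site_idx: int, group: str) -> dict:
    lo, hi = _SITE_AGE_RANGES[site_idx % len(_SITE_AGE_RANGES)]
    patient = group == "patient"
    row = {
        "site": site_name,
        "group": group,
        "age": rng.uniform(lo, hi),
        "sex": int(rng.random() < 0.5),
        "dose": rng.gamma(2.0, 1.5) if patient else 0.0,
        "motion": abs(rng.normal(0.0, 0.15)),
    }
    if patient:
        row["panss_pos"] = float(np.clip(rng.normal(16, 5), 7, 49))
        row["panss_neg"] = float(np.clip(rng.normal(17, 6), 7, 49))
        row["panss_gen"] = float(np.clip(rng.normal(35, 9), 16, 112))
        row["duration"] = abs(rng.normal(6.0, 5.0))
    else:
        row.update(panss_pos=np.nan, panss_neg=np.nan, panss_gen=np.nan, duration=np.nan)
    return row


def simulate_cohort(config: SimulationConfig, level: str = "region") -> SyntheticCohort:
    """Generate a cohort; deterministic given ``config.seed``.

    Per-subject random streams are keyed by (seed, site, subject slot),
    so changing subject counts never reshuffles earlier subjects.
    ``level="voxel"`` additionally materializes 4D images in which every
    voxel is its region's series plus independent unit-SD noise.
    """
    if level not in ("region", "voxel"):
        raise ValueError("level must be 'region' or 'voxel'")
    atlas = make_atlas(config.grid_shape, config.n_regions)
    n_per_site = config.n_patients + config.n_controls
    region_series = np.empty(
        (config.n_subjects, config.n_regions, config.n_timepoints), dtype=np.float64
    )
    images = [] if level == "voxel" else None
    rows = []
    flat_labels = atlas.label_volume.ravel()
    for s in range(config.n_sites):
        site_name = f"site{s + 1:02d}"
        site_rng = np.random.default_rng([config.seed, 10_000 + s])
        offsets = site_rng.normal(0.0, config.site_shift_sd, (config.n_regions,) * 2)
        offsets = (offsets + offsets.T) / 2.0
        np.fill_diagonal(offsets, 0.0)
        for k in range(n_per_site):
            rng = np.random.default_rng([config.seed, s, k])
            group = "patient" if k < config.n_patients else "control"
            row = _draw_phenotype(rng, site_name, s, group)
            z = _target_z_matrix(config, offsets, row, group == "patient")
            c = _correlation_from_z(z)
            series = _subject_series(config, c, rng)
            idx = s * n_per_site + k
            region_series[idx] = series
            row["subject_id"] = f"sub-{idx:04d}"
            rows.append(row)
            if level == "voxel":
                vox = series[flat_labels - 1].astype(np.float32)
                vox += config.voxel_noise_sd * rng.standard_normal(vox.shape).astype(
                    np.float32
                )
                images.append(vox.reshape(*config.grid_shape, config.n_timepoints))
    phenotypes = pd.DataFrame(rows)[
        [
            "subject_id",
            "site",
            "group",
            "age",
            "sex",
            "dose",
            "motion",
            "panss_pos",
            "panss_neg",
            "panss_gen",
            "duration",
        ]
    ]
    truth = pd.DataFrame(
        config.effect_map, columns=["region_a", "region_b", "delta_z"]
    )
    cohort = SyntheticCohort(
        level=level,
        region_series=region_series,
        images=images,
        atlas=atlas,
        phenotypes=phenotypes,
        truth=truth,
        config=config,
    )
    if config.clinical_coupling:
        _apply_clinical_coupling(cohort)
    return cohort


def _apply_clinical_coupling(cohort: SyntheticCohort) -> None:
    """Rewrite coupled symptom scores so that, within each site, patients'
    scores correlate ~r with the realized Fisher-z of the coupled link."""
    config = cohort.config
    pheno = cohort.phenotypes
    score_scales = {"panss_pos": (16, 5), "panss_neg": (17, 6), "panss_gen": (35, 9), "duration": (6, 4)}
    for a, b, variable, r in config.clinical_coupling:
        if not -1 < r < 1:
            raise ValueError("coupling r must lie in (-1, 1)")
        zlink = np.array(
            [
                fisher_z(np.corrcoef(cohort.region_series[i, a - 1], cohort.region_series[i, b - 1])[0, 1])
                for i in range(cohort.n_subjects)
            ]
        )
        mu, sd = score_scales.get(variable, (0.0, 1.0))
        rng = np.random.default_rng([config.seed, 77_000, a, b])
        for s_idx, site in enumerate(pheno["site"].unique()):
            sel = ((pheno["site"] == site) & (pheno["group"] == "patient")).to_numpy()
            zs = zlink[sel]
            zstd = (zs - zs.mean()) / (zs.std() if zs.std() > 0 else 1.0)
            noise = rng.standard_normal(sel.sum())
            site_shift = rng.normal(0.0, sd / 2.0)
            pheno.loc[sel, variable] = (
                mu + site_shift + sd * (r * zstd + np.sqrt(1 - r**2) * noise)
            )


def region_link_matrix(cohort: SyntheticCohort) -> np.ndarray:
    """(n_subjects, n_links) Fisher-z upper-triangle link strengths."""
    out = np.empty(
        (cohort.n_subjects, cohort.config.n_regions * (cohort.config.n_regions - 1) // 2)
    )
    for i in range(cohort.n_subjects):
        out[i] = correlation_matrix(cohort.region_series[i]).upper_triangle()
    return out


def write_cohort(cohort: SyntheticCohort, directory) -> Path:
    """Write the cohort to disk; returns the JSON manifest path.

    Layout: per-subject NIfTI images (voxel level) or region-series TSVs,
    the atlas NIfTI, phenotypes.tsv, truth.tsv and manifest.json.  The
    directory must already exist.
    """
    import nibabel as nib

    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"output directory does not exist: {directory}")
    subjects = []
    for i, sid in enumerate(cohort.phenotypes["subject_id"]):
        if cohort.level == "voxel":
            fname = f"{sid}.nii.gz"
            img = nib.Nifti1Image(
                np.asarray(cohort.images[i], dtype=np.float32), cohort.atlas.affine
            )
            nib.save(img, directory / fname)
        else:
            fname = f"{sid}_regions.tsv"
            pd.DataFrame(cohort.region_series[i]).to_csv(
                directory / fname, sep="\t", header=False, index=False,
                float_format="%.8g",
            )
        subjects.append({"subject_id": sid, "file": fname})
    nib.save(
        nib.Nifti1Image(cohort.atlas.label_volume.astype(np.int16), cohort.atlas.affine),
        directory / "atlas.nii.gz",
    )
    cohort.phenotypes.to_csv(directory / "phenotypes.tsv", sep="\t", index=False)
    cohort.truth.to_csv(directory / "truth.tsv", sep="\t", index=False)
    manifest = {
        "level": cohort.level,
        "n_subjects": cohort.n_subjects,
        "subjects": subjects,
        "atlas": "atlas.nii.gz",
        "phenotypes": "phenotypes.tsv",
        "truth": "truth.tsv",
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cohort.config).items()
        },
    }
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_cohort(directory) -> SyntheticCohort:
    """Reload a cohort written by :func:`write_cohort`."""
    import nibabel as nib

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    cfg_dict = dict(manifest["config"])
    cfg_dict["grid_shape"] = tuple(cfg_dict["grid_shape"])
    cfg_dict["effect_map"] = [tuple(e) for e in cfg_dict["effect_map"]]
    cfg_dict["clinical_coupling"] = [tuple(e) for e in cfg_dict["clinical_coupling"]]
    config = SimulationConfig(**cfg_dict)
    atlas_img = nib.load(directory / manifest["atlas"])
    atlas = AtlasSpec(
        label_volume=np.asarray(atlas_img.dataobj).astype(np.int16),
        affine=atlas_img.affine,
    )
    phenotypes = pd.read_csv(directory / manifest["phenotypes"], sep="\t")
    truth = pd.read_csv(directory / manifest["truth"], sep="\t")
    images = None
    region_series = np.empty(
        (manifest["n_subjects"], config.n_regions, config.n_timepoints)
    )
    flat_labels = atlas.label_volume.ravel()
    if manifest["level"] == "voxel":
        images = []
        for i, entry in enumerate(manifest["subjects"]):
            img = np.asarray(
                nib.load(directory / entry["file"]).dataobj, dtype=np.float32
            )
            images.append(img)
            flat = img.reshape(-1, img.shape[3])
            for rid in range(1, config.n_regions + 1):
                region_series[i, rid - 1] = flat[flat_labels == rid].mean(axis=0)
    else:
        for i, entry in enumerate(manifest["subjects"]):
            region_series[i] = pd.read_csv(
                directory / entry["file"], sep="\t", header=None
            ).to_numpy()
    return SyntheticCohort(
        level=manifest["level"],
        region_series=region_series,
        images=images,
        atlas=atlas,
        phenotypes=phenotypes,
        truth=truth,
        config=config,
    )
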