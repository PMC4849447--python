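"""End-to-end pipeline over a synthetic cohort: simulate -> site tests -> meta
-> heterogeneity -> clinical -> classification.

``run_pipeline`` executes the stages in dependency order and writes
human-facing tables (TSV), link-level vectors (HDF5), the MA/cluster
volumes (NIfTI) and a JSON provenance record to the results directory.
The same stage functions are importable individually, which is how the
``analysis/`` drivers, the tests and the acceptance script use them.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, clinical, heterogeneity, io, meta, site_stats
from .synthetic import SimulationConfig, SyntheticCohort, region_link_matrix, simulate_cohort

COVARIATE_COLUMNS = ["age", "sex", "dose", "motion"]


@dataclass
class PipelineConfig:
    """Parameters for every stage; unknown keys are rejected on load."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    weights: str = "sqrt_n"  # Stouffer weighting: sqrt_n | n
    family_alpha: float = 0.05
    min_cluster_size: int = 20
    cluster_connectivity: int = 26
    fdr_q: float = 0.05
    svm_c: float = 1.0
    n_permutations: int = 199
    test_mode: str = "model"  # covariate handling in site tests

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sim = data.pop("simulation", {})
        if isinstance(sim, dict):
            allowed = set(SimulationConfig.__dataclass_fields__)
            unknown = set(sim) - allowed
            if unknown:
                raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
            if "grid_shape" in sim:
                sim["grid_shape"] = tuple(sim["grid_shape"])
            if "effect_map" in sim and sim["effect_map"] is not None:
                sim["effect_map"] = [tuple(e) for e in sim["effect_map"]]
            sim = SimulationConfig(**sim)
        unknown = set(data) - (set(cls.__dataclass_fields__) - {"simulation"})
        if unknown:
            raise ValueError(f"unknown pipeline keys: {sorted(unknown)}")
        return cls(simulation=sim, **data)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def site_tests(
    cohort: SyntheticCohort,
    link_matrix: np.ndarray | None = None,
    mode: str = "model",
) -> list[site_stats.SiteLinkResult]:
    """Covariate-adjusted link tests within each site of a cohort."""
    if link_matrix is None:
        link_matrix = region_link_matrix(cohort)
    pheno = cohort.phenotypes
    results = []
    for site in pheno["site"].unique():
        sel = (pheno["site"] == site).to_numpy()
        groups = (pheno.loc[sel, "group"] == "patient").to_numpy().astype(int)
        covs = pheno.loc[sel, COVARIATE_COLUMNS].to_numpy(dtype=float)
        results.append(
            site_stats.site_link_test(
                link_matrix[sel], groups, covs, site_id=str(site), mode=mode
            )
        )
    return results


def truth_link_indices(cohort: SyntheticCohort):
    """Flat link indices and planted deltas of the cohort's truth table."""
    from .connectivity import link_index

    n = cohort.config.n_regions
    idx = [
        link_index(int(a) - 1, int(b) - 1, n)
        for a, b in zip(cohort.truth["region_a"], cohort.truth["region_b"])
    ]
    return np.asarray(idx), cohort.truth["delta_z"].to_numpy(dtype=float)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage on a fresh synthetic cohort; returns a summary dict.

    Outputs written under ``out_dir``: meta_links.tsv, ma_regions.tsv,
    ma_map.nii.gz, cluster_table.tsv, heterogeneity.tsv, consistency.tsv,
    clinical_correlations.tsv, classification.json, links.h5 and
    provenance.json.  Rerunning with the same config is deterministic.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    cohort = simulate_cohort(config.simulation)
    links = region_link_matrix(cohort)
    n_regions = cohort.config.n_regions

    sites = site_tests(cohort, links, mode=config.test_mode)
    combined = meta.combine_sites(sites, config.weights, config.family_alpha)
    ma = meta.compute_ma(combined.combined_p, combined.alpha_bonf, n_regions)
    ma_volume = meta.ma_to_volume(ma, cohort.atlas)
    clusters = meta.extract_clusters(
        ma_volume,
        cohort.atlas.affine,
        min_size=config.min_cluster_size,
        connectivity=config.cluster_connectivity,
    )
    effects = np.vstack([s.mean_diff for s in sites])
    variances = np.vstack([s.var_diff for s in sites])
    het = heterogeneity.screen_links(effects, variances)
    consistency, consistent_frac = heterogeneity.consistency_summary(
        effects, combined.direction, combined.significant
    )

    pheno = cohort.phenotypes
    patients = (pheno["group"] == "patient").to_numpy()
    altered = np.flatnonzero(combined.significant)
    clin = clinical.clinical_scan(
        links[np.ix_(patients, altered)],
        pheno.loc[patients, ["panss_pos", "panss_neg", "panss_gen", "duration"]],
        pheno.loc[patients, "site"],
        q=config.fdr_q,
    )
    clin = clin.assign(link=altered[clin["link"].to_numpy(dtype=int)]) if len(clin) else clin

    labels = patients.astype(int)
    if altered.size:
        report = classify.loocv_classify(
            links[:, altered], labels, scope="pooled", c=config.svm_c,
            site_labels=pheno["site"],
        )
        report.permutation_p = float("nan")  # optional, heavy; drivers opt in
    else:
        report = None

    i, j = np.triu_indices(n_regions, k=1)
    meta_table = pd.DataFrame(
        {
            "region_a": i + 1,
            "region_b": j + 1,
            "combined_z": combined.combined_z,
            "combined_p": combined.combined_p,
            "significant": combined.significant,
            "direction": combined.direction,
            "q_statistic": het.q_statistic,
            "q_p": het.q_p_value,
            "heterogeneous": het.heterogeneous,
            "tau2": het.tau_squared,
            "re_z": het.re_z,
            "re_p": het.re_p,
        }
    )
    meta_table.to_csv(out / "meta_links.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"region": np.arange(1, n_regions + 1), "ma": ma.counts}
    ).to_csv(out / "ma_regions.tsv", sep="\t", index=False)
    io.write_nifti(out / "ma_map.nii.gz", ma_volume, cohort.atlas.affine, np.int32)
    meta.cluster_table(clusters).to_csv(out / "cluster_table.tsv", sep="\t", index=False)
    consistency.to_csv(out / "consistency.tsv", sep="\t", index=False)
    clin.to_csv(out / "clinical_correlations.tsv", sep="\t", index=False)
    io.save_link_vectors(
        out / "links.h5",
        combined_z=combined.combined_z,
        combined_p=combined.combined_p,
        significant=combined.significant.astype(np.int8),
        site_zs=combined.site_zs,
        effects=effects,
        variances=variances,
    )
    summary = {
        "n_subjects": cohort.n_subjects,
        "n_links": int(links.shape[1]),
        "alpha_bonf": combined.alpha_bonf,
        "n_significant": int(combined.significant.sum()),
        "consistent_fraction": consistent_frac,
        "n_clusters": len(clusters),
        "top_ma_region": int(np.argmax(ma.counts) + 1),
    }
    if report is not None:
        summary["classification"] = {
            "accuracy": report.accuracy,
            "sensitivity": report.sensitivity,
            "specificity": report.specificity,
            "auc": report.auc,
            "best_cutoff": report.best_cutoff,
        }
        (out / "classification.json").write_text(
            json.dumps(summary["classification"], indent=2)
        )
    provenance = {
        "config": _jsonable(asdict(config)),
        "seed": config.simulation.seed,
        "elapsed_seconds": round(time.time() - t0, 2),
        "package_version": "0.1.0",
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
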