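#!/usr/bin/env python
"""Combine sites (Liptak-Stouffer), Bonferroni-flag links, map MA and clusters.

Per-site signed z-scores are combined with sqrt(n) weights; links with
combined p below 0.05/n_links are flagged.  The per-region MA (count of
significant links) is painted onto the atlas grid, clusters are
extracted (26-connectivity, size > 20 voxels) and a Manhattan-plot table
of sub-1e-5 links is exported.  Outputs under results/meta/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fcbwas import meta
from fcbwas.io import load_link_vectors, save_link_vectors, write_nifti
from fcbwas.pipeline import site_tests, truth_link_indices
from fcbwas.synthetic import read_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_cohort(RESULTS / "cohort")
    links = load_link_vectors(RESULTS / "derived" / "links.h5", ["z"])["z"]
    sites = site_tests(cohort, links.astype(np.float64))
    combined = meta.combine_sites(sites)
    n_regions = cohort.config.n_regions

    ma = meta.compute_ma(combined.combined_p, combined.alpha_bonf, n_regions)
    ma_volume = meta.ma_to_volume(ma, cohort.atlas)
    clusters = meta.extract_clusters(ma_volume, cohort.atlas.affine, min_size=20)
    node_regions = np.arange(1, n_regions + 1)
    manhattan = meta.manhattan_export(combined.combined_p, node_regions, n_regions)

    out = RESULTS / "meta"
    out.mkdir(exist_ok=True)
    i, j = np.triu_indices(n_regions, k=1)
    pd.DataFrame(
        {
            "region_a": i + 1,
            "region_b": j + 1,
            "combined_z": combined.combined_z,
            "combined_p": combined.combined_p,
            "significant": combined.significant,
            "direction": combined.direction,
        }
    ).to_csv(out / "meta_links.tsv", sep="\t", index=False)
    save_link_vectors(out / "combined.h5", Z=combined.combined_z,
                      p=combined.combined_p,
                      significant=combined.significant.astype(np.int8))
    write_nifti(out / "ma_map.nii.gz", ma_volume, cohort.atlas.affine, np.int32)
    meta.cluster_table(clusters).to_csv(out / "cluster_table.tsv", sep="\t", index=False)
    manhattan.to_csv(out / "manhattan.tsv", sep="\t", index=False)

    n_sig = int(combined.significant.sum())
    print(f"alpha_bonf = {combined.alpha_bonf:.3e}; "
          f"{n_sig} / {combined.n_links} links significant")
    print(f"top MA region: {int(np.argmax(ma.counts)) + 1} "
          f"(MA = {int(ma.counts.max())}); {len(clusters)} clusters")
    idx, deltas = truth_link_indices(cohort)
    rec = combined.significant[idx]
    print(f"planted-link recovery: {rec.sum()} / {len(idx)}; "
          f"directions correct: "
          f"{(combined.direction[idx] == np.sign(deltas)).sum()} / {len(idx)}")


if __name__ == "__main__":
    main()
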