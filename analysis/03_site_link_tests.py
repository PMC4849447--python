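#!/usr/bin/env python
"""Per-site, link-wise patient-control tests with covariate adjustment.

Within each site every link gets a linear model z ~ group + age + sex +
dose + motion; the group coefficient's two-tailed p is converted to a
signed normal z.  Stores per-site t, p, signed z, adjusted effect and
its variance in results/derived/site_stats.h5.
"""

from pathlib import Path

import numpy as np

from fcbwas.io import load_link_vectors, save_link_vectors
from fcbwas.pipeline import site_tests
from fcbwas.synthetic import read_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_cohort(RESULTS / "cohort")
    links = load_link_vectors(RESULTS / "derived" / "links.h5", ["z"])["z"]
    results = site_tests(cohort, links.astype(np.float64))
    save_link_vectors(
        RESULTS / "derived" / "site_stats.h5",
        t=np.vstack([r.t_statistic for r in results]),
        p=np.vstack([r.p_two_tailed for r in results]),
        signed_z=np.vstack([r.signed_z for r in results]),
        effect=np.vstack([r.mean_diff for r in results]),
        variance=np.vstack([r.var_diff for r in results]),
        n_subjects=np.array([r.n_patients + r.n_controls for r in results]),
    )
    for r in results:
        n_small = int((r.p_two_tailed < 0.001).sum())
        print(f"{r.site_id}: {r.n_patients}+{r.n_controls} subjects, "
              f"df={r.df}, {n_small} links with p < 1e-3")


if __name__ == "__main__":
    main()
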