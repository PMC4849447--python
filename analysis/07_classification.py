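#!/usr/bin/env python
"""Discriminate patients from controls with the altered links (LOOCV SVM).

Features are the Bonferroni-significant links' Fisher-z strengths,
site-mean-centered; a linear SVM (C = 1) is evaluated with leave-one-out
cross-validation pooled across sites and within each site, with a
99-permutation test of the pooled accuracy and ROC export.
Outputs under results/classification/.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from fcbwas import meta
from fcbwas.classify import loocv_classify, permutation_test
from fcbwas.io import load_link_vectors
from fcbwas.pipeline import site_tests
from fcbwas.synthetic import read_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--permutations", type=int, default=99)
    args = parser.parse_args()

    cohort = read_cohort(RESULTS / "cohort")
    links = load_link_vectors(RESULTS / "derived" / "links.h5", ["z"])["z"]
    combined = meta.combine_sites(site_tests(cohort, links.astype(np.float64)))
    altered = np.flatnonzero(combined.significant)
    features = links[:, altered].astype(np.float64)
    pheno = cohort.phenotypes
    labels = (pheno["group"] == "patient").to_numpy().astype(int)

    pooled = loocv_classify(features, labels, scope="pooled",
                            site_labels=pheno["site"])
    pooled.permutation_p = permutation_test(
        features, labels, n_permutations=args.permutations, seed=args.seed,
        observed_accuracy=pooled.accuracy,
    )
    reports = {"pooled": pooled}
    for site in pheno["site"].unique():
        sel = (pheno["site"] == site).to_numpy()
        reports[site] = loocv_classify(features[sel], labels[sel], scope="per-site")

    out = RESULTS / "classification"
    out.mkdir(exist_ok=True)
    summary = {
        name: {
            "accuracy": r.accuracy,
            "sensitivity": r.sensitivity,
            "specificity": r.specificity,
            "auc": r.auc,
            "best_cutoff": r.best_cutoff,
            "permutation_p": r.permutation_p,
        }
        for name, r in reports.items()
    }
    (out / "report.json").write_text(json.dumps(summary, indent=2))
    pd.DataFrame(pooled.roc_points, columns=["fpr", "tpr"]).to_csv(
        out / "roc_pooled.tsv", sep="\t", index=False
    )
    for name, r in reports.items():
        perm = ("" if np.isnan(r.permutation_p)
                else f", permutation p = {r.permutation_p:.3g}")
        print(f"{name}: accuracy {r.accuracy * 100:.1f}%, "
              f"sensitivity {r.sensitivity * 100:.1f}%, "
              f"specificity {r.specificity * 100:.1f}%, AUC {r.auc:.3f}{perm}")


if __name__ == "__main__":
    main()
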