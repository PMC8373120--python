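#!/usr/bin/env python
"""Differential + survival screen and the six-criterion exclusion cascade."""

from pathlib import Path

import pandas as pd

from spliceprio.events import enumerate_events, parse_annotation
from spliceprio.prioritize import (
    apply_prioritization,
    differential_psi,
    read_survival_tsv,
    survival_association,
)

ROOT = Path(__file__).resolve().parent.parent
BUNDLE = ROOT / "results" / "bundle"
RESULTS = ROOT / "results"


def main():
    events = [
        e for e in enumerate_events(parse_annotation(BUNDLE / "annotation.gtf"))
        if e.inclusion_junctions and e.exclusion_junctions
    ]
    psi = pd.read_csv(RESULTS / "psi_matrix.tsv", sep="\t", index_col="event_id",
                      na_values="NA")
    groups = pd.read_csv(BUNDLE / "groups.tsv", sep="\t", dtype=str) \
        .set_index("sample_id")["group"]

    diff = differential_psi(psi, groups)
    n_sig = int((diff["wilcoxon_p"] < 0.05).sum())
    print(f"differential screen: {n_sig} of {len(diff)} events at p < 0.05")

    surv = survival_association(psi, read_survival_tsv(BUNDLE / "survival.tsv"))
    n_surv = int((surv["logrank_p"] < 0.05).sum())
    print(f"survival screen: {n_surv} events associated with DFS at p < 0.05")

    cand = apply_prioritization(events, diff, surv, psi, groups)
    cand.to_csv(RESULTS / "candidates.tsv", sep="\t")
    retained = cand[cand["retained"]]
    print(f"cascade: {len(retained)} of {len(cand)} events retained")
    if len(retained):
        cols = ["gene_id", "alt_length", "delta_psi", "wilcoxon_p", "logrank_p"]
        print(retained[cols].to_string())


if __name__ == "__main__":
    main()
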