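#!/usr/bin/env python
"""Rank trans-regulators against the top candidate's PSI, scan alternative
exons for the GGAA motif, and filter/rank promoter TF sites."""

from pathlib import Path

import pandas as pd

from spliceprio.events import enumerate_events, event_sequences, parse_annotation
from spliceprio.regulators import (
    correlate_regulators,
    filter_tf_sites,
    rank_tf_candidates,
    read_regulator_list,
    scan_motif,
)

ROOT = Path(__file__).resolve().parent.parent
BUNDLE = ROOT / "results" / "bundle"
RESULTS = ROOT / "results"


def main():
    cand = pd.read_csv(RESULTS / "candidates.tsv", sep="\t", index_col="event_id")
    retained = cand[cand["retained"]]
    target = retained.sort_values(["wilcoxon_p", "logrank_p"]).index[0]
    print(f"target event: {target}")

    psi = pd.read_csv(RESULTS / "psi_matrix.tsv", sep="\t", index_col="event_id",
                      na_values="NA")
    expr = pd.read_csv(BUNDLE / "regulator_expression.tsv", sep="\t",
                       index_col="regulator_id")
    ranking = correlate_regulators(
        psi.loc[target], expr, read_regulator_list(BUNDLE / "regulator_list.txt")
    )
    ranking.to_csv(RESULTS / "regulator_ranking.tsv", sep="\t")
    top = ranking.iloc[0]
    print(f"top regulator: {ranking.index[0]} (r={top.r:.3f}, R^2={top.r_squared:.3f}, "
          f"p={top.p:.2e}, n={int(top.n_used)})")

    events = enumerate_events(parse_annotation(BUNDLE / "annotation.gtf"))
    seqs = event_sequences(events, BUNDLE / "genome.fa")
    hits, frac = scan_motif(seqs)
    pd.DataFrame(
        [{"event_id": h.seq_id, "present": int(h.present),
          "positions": ";".join(map(str, h.positions))} for h in hits]
    ).to_csv(RESULTS / "motif_hits.tsv", sep="\t", index=False)
    print(f"GGAA motif present in {sum(h.present for h in hits)} of {len(hits)} "
          f"alternative segments ({frac}%)")

    sites = pd.read_csv(BUNDLE / "tf_sites.tsv", sep="\t")
    tss = pd.read_csv(BUNDLE / "tss_table.tsv", sep="\t")
    kept = filter_tf_sites(sites, tss)
    print(f"TF sites in the -2500..+500 window with score > 50: "
          f"{len(kept)} of {len(sites)}")
    cohorts = [
        pd.read_csv(BUNDLE / f"tf_expression_cohort{c}.tsv", sep="\t", index_col="gene_id")
        for c in ("A", "B")
    ]
    tf_ranking = rank_tf_candidates(kept, cohorts, str(tss["gene"].iloc[0]))
    tf_ranking.to_csv(RESULTS / "tf_ranking.tsv", sep="\t")
    n_sig = int(tf_ranking["significant_all_cohorts"].sum())
    print(f"TFs significant in both cohorts: {n_sig}; strongest: {tf_ranking.index[0]}")


if __name__ == "__main__":
    main()
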