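# spliceprio

Alternative-splicing event discovery and candidate prioritization for bulk
tumor transcriptomes, built around the analysis logic of splicing-driven
oncogene studies: a cassette exon whose inclusion rises in tumors, predicts
poor disease-free survival, sits in the coding region, and is driven by an
RNA-binding protein (RBP) recognizing an exonic enhancer motif.

The package is aimed at computational biologists who have spliced alignments
(or junction-count tables), a clinical survival table and gene-level
expression for a tumor/control cohort, and want to go from annotation to a
ranked shortlist of splicing events and candidate trans-regulators.

## What it computes

**PSI (percent spliced-in).** For a cassette exon with inclusion junction
reads *I* (summed over the two flanking junctions) and exclusion (skipping)
reads *S*,

    PSI = (I / 2) / (I / 2 + S)

the division by 2 removing the two-junction counting bias of the inclusion
form. PSI is NA when *I* + *S* < 10 reads (configurable). Junctions are
extracted from the `N` operations of SAM CIGAR strings with a minimum
aligned overhang of 6 bases.

**Candidate cascade.** Events are screened with a two-sided Wilcoxon
rank-sum test (tumor vs control PSI; exact null for tie-free groups of
size ≤ 8) and a survival screen (median-PSI dichotomization, Kaplan–Meier +
log-rank). Six exclusion criteria then fire per event: (1) PSI NA in ≥ 2/3
of samples, (2) in-frame micro-segment (< 5 codons), (3) log-rank p ≥ α,
(4) rank-sum p ≥ α, (5) PSI NA in > 4 control samples, (6) |ΔPSI| ≤ 0.1 —
plus shortlist filters: alternative-segment length in 30–300 bp, located in
the coding region, tumor-high PSI.

**Regulators.** Candidate RBPs are ranked by Pearson correlation (r, R²,
two-sided p) between their expression and the target event's PSI;
alternative-exon sequences are scanned for the literal GGAA enhancer motif
(the RBFOX binding core); TF ChIP sites are filtered to a strand-aware
−2500..+500 bp promoter window with ChIP score > 50 and ranked by
expression correlation with the target gene across one or more cohorts.

**Expression.** TPM normalization with exonic-union gene lengths and the
mean-TPM < 2 removal filter; immunohistochemistry H-scores
(intensity × percent stained).

A synthetic-cohort generator (`spliceprio.simulate`) emits GTF, FASTA,
SAM/junction tables, expression, survival, regulator and TF layers with a
ground-truth record, so every stage is testable without external data.

## Worked example

```bash
spliceprio simulate --out-dir results/bundle --seed 0
spliceprio run-all --bundle-dir results/bundle --out-dir results/run
```

or equivalently the step-by-step drivers:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_catalog_events.py
python analysis/03_quantify_psi.py
python analysis/04_prioritize_candidates.py
python analysis/05_regulators_and_motifs.py
```

On the default cohort (85 tumor / 10 control, 200 cassette events, ~100
junction reads per event) this prints:

```
PSI: 200 events x 95 samples (4.8% NA)
PSI RMSE vs truth: 0.0491 over 18080 cells
differential screen: 26 of 200 events at p < 0.05
survival screen: 7 events associated with DFS at p < 0.05
cascade: 1 of 200 events retained
                            gene_id  alt_length  delta_psi  wilcoxon_p     logrank_p
G0001:CASSETTE:chr1:560-644   G0001          84   0.210723    0.000573  8.866095e-07
top regulator: RBP001 (r=0.761, R^2=0.580, p=3.42e-19, n=95)
GGAA motif present in 70 of 200 alternative segments (35.0%)
TFs significant in both cohorts: 1; strongest: TF001
```

The single retained event is the planted 84-bp flagship exon — tumor-high
(ΔPSI 0.21), survival-linked (log-rank p ≈ 9e-7), in-frame-coding and
inside the length window — and the planted regulator and TF top their
rankings: the cascade recovers exactly the evidence profile it was designed
to find while discarding the other 199 events.

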