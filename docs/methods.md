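# Methods

## Event model and catalog

Transcript structures are parsed from GTF (via gffutils) into 0-based
half-open exon intervals; segment length is always `end − start`, so the
84-bp flagship cassette exon has `alt_length = 84` by construction. Events
are enumerated by pairwise comparison of transcripts within a gene and
classified into the five standard categories:

* **Cassette**: internal exon of one transcript absent from another whose
  flanks are joined directly; two inclusion junctions, one exclusion
  junction.
* **MXE**: two non-overlapping internal exons spliced between the same
  flanking donor/acceptor sites, mutually absent and never co-present in
  any annotated transcript of the gene. The single `alt_segment` slot stores
  the 5'-most exon; its splice path is the inclusion form (the convention
  rMATS uses).
* **A5SS / A3SS**: exon pairs sharing one boundary whose junction partner
  site is shared; classified by which splice site (donor or acceptor) moves,
  which depends on strand.
* **RI**: a junction of one transcript covered by a single exon of another
  with matching outer boundaries. Retention leaves no junction, so RI events
  carry an empty inclusion-junction set and are catalogued but not PSI-
  quantified from junction evidence; their PSI is NA.

Events are deduplicated on (type, chrom, strand, segment, exclusion
junctions), merging discoveries from multiple transcript pairs; output
order is sorted and therefore independent of input order. The catalog is
annotation-driven; unannotated junctions are not discovered from reads.

## PSI estimation

Only junction reads count. Each CIGAR `N` operation contributes one
junction per read; junctions with aligned (`M`) overhang < 6 bases on
either side are discarded (both defaults configurable). Because a cassette
inclusion form spans two junctions while exclusion spans one, raw counts
are normalized per junction before forming the ratio,
`PSI = (I/n_inc) / (I/n_inc + S/n_exc)`, which removes the 2:1 counting
bias; under the generator's sampling model this estimator is unbiased.
PSI is NA below `min_total_reads = 10` total supporting reads — the NA
state feeds two of the exclusion criteria, so it is explicit rather than
imputed.

TPM uses exonic-union gene lengths; the low-expression filter removes
genes with mean TPM strictly below 2 and deliberately does not renormalize
the survivors (renormalization is a separate, explicit call).

## Screens and the cascade

The differential screen is a two-sided Mann–Whitney rank-sum test on
non-NA PSI per event, with the exact null distribution when both groups
have ≤ 8 observations and no ties, and the tie-corrected normal
approximation otherwise; two all-identical groups are assigned p = 1. The
survival screen dichotomizes samples at the median PSI of each event (ties
to the low group, deterministically), then compares groups with the
one-degree log-rank test on Kaplan–Meier curves (both via lifelines).
A continuous-PSI survival model is intentionally out of scope; the grouped
analysis is what the candidate table and KM displays are built on.

The cascade evaluates six exclusion criteria and three shortlist filters
independently per event (order-free; the retained set is the intersection
of the survivor sets), with α = 0.05 on nominal p-values by default and an
optional Benjamini–Hochberg mode (`use_fdr=True`). Boundary conventions
follow the criteria wording exactly: ΔPSI of exactly 0.1 is excluded
("no more than 0.1"), mean TPM of exactly 2 is retained ("< 2" removed),
ChIP score of exactly 50 is dropped ("over 50"), promoter-window offsets
−2500 and +500 are retained (inclusive window). The in-frame micro-segment
criterion is read as: length divisible by 3 AND shorter than 5 codons
(< 15 nt) — the strictest reading that only discards trivially small
in-frame segments. "High tumor PSI" is operationalized as
mean(tumor) > mean(control), a direction filter, since no cutoff is
standard. Whether the ΔPSI criterion is signed is ambiguous; the absolute
value is used.

## Regulator, motif and TF layers

Regulator ranking uses Pearson correlation over pairwise-complete samples
(≥ 3 required), sorted by p then |r|; R² is reported alongside r because
both conventions circulate. Motif scanning is exact substring matching on
the mRNA-sense strand, all overlapping occurrences reported; the summary
fraction is gene-level (≥ 1 occurrence anywhere in the gene's alternative
segment) and reported to one decimal. TF promoter filtering computes
strand-aware TSS offsets (upstream of a minus-strand gene lies at larger
coordinates); multi-cohort TF significance is the intersection rule
(p < α in every cohort supplied).

## Synthetic cohort generator

The generator emulates the cohort structure this kind of study analyses:
85 tumor and 10 control samples; 200 cassette-exon genes (3-exon skeleton,
full-exon CDS, every 7th gene on the minus strand) plus 50 filler genes;
~100 expected junction reads per event per sample. Specifically:

* **PSI**: event baseline π₀ ~ Beta(2, 2); 20 planted differential events
  (always including the flagship) get +0.25 in tumors, planted on mid-PSI
  events (π₀ ∈ [0.15, 0.6]) where a screen operates; per-sample logit-normal
  jitter (σ = 0.25) adds biological noise. The survival-linked flagship
  event gets wider tumor jitter (σ = 1.0): patient-to-patient spread in a
  regulator-driven exon is what gives a median split a detectable hazard
  contrast.
* **Reads**: junction depth d ~ Poisson(100) per cell; inclusion reads
  I ~ Binomial(d, 2π/(1+π)) — the junction-level inclusion probability
  accounting for the two-junction inclusion form — split evenly between the
  two inclusion junctions; 5% of events are sequenced at depth/20 to
  exercise the NA criteria. SAM output (optional) writes one `50M{gap}N50M`
  single-end 100-nt read per junction count, the simplest structure that
  exercises CIGAR parsing; junction extraction round-trips these counts
  exactly.
* **Survival**: tumor-only table, time ~ Exponential(h₀·exp(β·(π−0.5)))
  with h₀ = 0.02/month, β = 3 per unit PSI (≈ e¹ hazard ratio across the
  flagship's median split given its PSI spread), centering at π = 0.5 so β
  reads as a log hazard ratio over the PSI range; independent Uniform(0, m)
  censoring with m solved numerically so the expected censoring fraction at
  baseline hazard is 0.3.
* **Motif**: GGAA is planted into exactly round(fraction·n) randomly chosen
  alternative segments (positions random) and scrubbed from the rest by
  single-base substitution; exact-count planting makes gene-level fractions
  reproducible at printed precision, which Bernoulli planting would not.
  Default fraction 0.352.
* **Regulators / TFs**: the planted regulator's expression is
  r·z(PSI) + √(1−r²)·noise with r = 0.8 plus 30 independent decoys; the TF
  layer plants one high-score in-window site and an expression correlation
  of r = 0.7 with the target gene in two cohorts (95 and 40 samples) among
  20 decoy TFs with a mix of in-window/out-of-window/low-score sites.

Generation is fully deterministic given the config (seed included;
byte-identical bundles). What the generator does **not** emulate:
sequencing error, quality strings, paired-end inserts, GC/positional bias,
multi-mapping, isoform families beyond one event per gene, correlated
events, or non-exponential hazards. Passing tests therefore demonstrate
correctness of the estimators and screens under an idealized read model,
not robustness to alignment artifacts or biological confounding in real
cohorts.

## Numerical and calibration notes

* The PSI estimator's sampling variance is π(1−π)(1+π)²/(2d) under the
  read model, at most twice the plain binomial variance π(1−π)/d; averaged
  over the Beta(2, 2) baseline, fewer than 1% of cells fall outside the
  3·√(π(1−π)/d) band, which the recovery suite asserts (≥ 99% inside).
* Null calibration (50 panels of 200 events with no planted effects) keeps
  the 5%-level false-positive fraction of both screens inside [0.03, 0.07];
  the joint six-criterion cascade retains < 1 event per 200-event panel on
  average — its stringency comes from requiring two independent screens at
  α = 0.05 plus an effect-size and a direction filter simultaneously.
* The log-rank implementation is validated at the statistic level against a
  definitional oracle (hypergeometric O−E and variance sums) and its
  permutation distribution (10⁵ vectorized shuffles); an asymptotic
  chi-square p cannot coincide with an exact permutation p at n ≤ 12, where
  the permutation law has granularity 1/C(n, n₁), so p-values are compared
  qualitatively and statistics exactly.
* Degenerate inputs resolve deterministically: all-tied rank-sum groups
  give p = 1; constant-PSI events give a degenerate split and NA survival
  p; events with junctions on one side only (RI) give NA PSI; an event with
  no junctions at all is an error.
* Problem sizes in the test and acceptance runs (200-event panels, 50 or
  20 null seeds, 100 recovery replicates) were chosen so each experiment's
  Monte-Carlo error is well inside the asserted margins.

## Known limitations

Annotation-driven catalog only (no novel junctions); junction-only PSI
cannot quantify retained introns; no multiple-testing correction by
default (nominal-p convention of the candidate-table style it follows,
with BH available); no continuous-PSI survival model or Cox covariates;
single-chromosome synthetic genomes; TPM filtering assumes gene lengths
are trustworthy.
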