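"""Synthetic cohort generator with ground truth.

Emulates the data shape of a bulk-transcriptome splicing study of a tumor
cohort: a multi-transcript annotation harbouring cassette-exon events, a
genome with a splicing-enhancer motif planted into a controlled fraction of
alternative exons, junction reads drawn binomially around per-sample true
PSI, gene-level expression counts, disease-free survival whose hazard
depends on the PSI of a planted event, regulator expression correlated with
that PSI, and scored TF ChIP sites around a target-gene TSS.

Defaults mirror the cohort structure the pipeline is aimed at: 85 tumor and
10 control samples, ~100 junction reads per event per sample, a planted
84-bp cassette exon that is tumor-high, survival-linked, motif-positive and
regulator-driven — the full evidence profile the prioritization cascade is
designed to retain.

Sampling model per event e and sample s (cassette events):

* group-level PSI: pi0_e ~ Beta(alpha, beta); planted differential events get
  pi0_e + delta in tumor samples; per-sample biological jitter on the logit
  scale gives the true PSI pi_es recorded in the truth matrix;
* junction depth d ~ Poisson(depth_mean); the inclusion form spans two
  junctions, so inclusion reads I ~ Binomial(d, 2*pi/(1+pi)) (the junction-
  level inclusion probability), split evenly (binomially) between the two
  inclusion junctions; exclusion reads S = d - I. The junction-normalized
  estimator (I/2)/((I/2)+S) is unbiased for pi under this model;
* survival (tumor samples): time ~ Exponential(h0 * exp(beta_h * (pi - 0.5)))
  with independent Uniform(0, c_max) censoring, c_max solved so the expected
  censoring fraction at baseline hazard equals ``censoring_rate``.

Every dataset is emitted with a :class:`SyntheticTruth` record for recovery
tests; generation is fully deterministic given the config (seed included).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .events import SpliceEvent

READ_LENGTH = 100
FLANK_EXON_LEN = 150
INTRON_LEN = 300
GENE_SPACING = 500


@dataclass
class SimulationConfig:
    n_genes: int = 250            # event genes + single-transcript filler genes
    n_events: int = 200           # cassette-event genes (one event each)
    n_tumor: int = 85
    n_control: int = 10
    depth_mean: float = 100.0     # expected junction reads per event per sample
    psi_base_alpha: float = 2.0   # Beta prior of baseline PSI
    psi_base_beta: float = 2.0
    psi_sample_sd: float = 0.25   # per-sample biological jitter, logit scale
    psi_survival_sd: float = 1.0  # tumor-cell jitter of the survival-linked event
    delta_psi_effect: float = 0.25
    n_planted_differential: int = 20
    low_coverage_fraction: float = 0.05  # events sequenced at depth_mean/20
    hazard_baseline: float = 0.02        # events per month at PSI 0.5
    hazard_log_ratio: float = 3.0        # log hazard ratio per unit PSI
    censoring_rate: float = 0.3
    regulator_r_target: float = 0.8
    n_decoy_regulators: int = 30
    motif_fraction: float = 0.352
    motif: str = "GGAA"
    tf_r_target: float = 0.7
    tf_window_density: int = 20   # decoy TF sites drawn around the target TSS
    n_cohort_b: int = 40          # sample size of the second TF cohort
    seed: int = 0

    def __post_init__(self):
        if self.n_events > self.n_genes:
            raise ValueError("n_events cannot exceed n_genes")
        if self.n_planted_differential > self.n_events:
            raise ValueError("planted differential events exceed n_events")
        if not 0 <= self.motif_fraction <= 1:
            raise ValueError("motif_fraction must be in [0, 1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")


@dataclass
class SyntheticTruth:
    psi_true: pd.DataFrame                  # events x samples true PSI
    planted_differential: list[str]
    planted_survival: list[str]
    planted_regulator: str
    regulator_r: float
    motif_positive: list[str]
    planted_tf: str
    tf_r: float
    sample_groups: dict[str, str]
    config: SimulationConfig

    def to_json(self, path) -> None:
        payload = {
            "psi_true": {
                "index": list(self.psi_true.index),
                "columns": list(self.psi_true.columns),
                "data": [[round(float(v), 6) for v in row] for row in self.psi_true.to_numpy()],
            },
            "planted_differential": self.planted_differential,
            "planted_survival": self.planted_survival,
            "planted_regulator": self.planted_regulator,
            "regulator_r": self.regulator_r,
            "motif_positive": self.motif_positive,
            "planted_tf": self.planted_tf,
            "tf_r": self.tf_r,
            "sample_groups": self.sample_groups,
            "config": asdict(self.config),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        psi = pd.DataFrame(
            payload["psi_true"]["data"],
            index=payload["psi_true"]["index"],
            columns=payload["psi_true"]["columns"],
        )
        return cls(
            psi_true=psi,
            planted_differential=payload["planted_differential"],
            planted_survival=payload["planted_survival"],
            planted_regulator=payload["planted_regulator"],
            regulator_r=payload["regulator_r"],
            motif_positive=payload["motif_positive"],
            planted_tf=payload["planted_tf"],
            tf_r=payload["tf_r"],
            sample_groups=payload["sample_groups"],
            config=SimulationConfig(**payload["config"]),
        )


# ---------------------------------------------------------------------------
# Gene/event layout


def _logit(p):
    return np.log(p / (1 - p))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _event_gene_layout(cfg: SimulationConfig, rng: np.random.Generator):
    """Lay event genes and filler genes along one chromosome.

    Event gene i: E1(150) - intron(300) - ALT(L_i) - intron(300) - E3(150),
    two transcripts (inclusion E1-ALT-E3 and skipping E1-E3), full-exon CDS.
    The first event is the 84-bp flagship exon. Every 7th event gene lies on
    the minus strand to exercise strand handling downstream.
    """
    genes = []
    cursor = READ_LENGTH + 10  # keep junction reads on the contig
    alt_lengths = rng.integers(30, 301, size=cfg.n_events)
    alt_lengths[0] = 84
    for i in range(cfg.n_events):
        gid = f"G{i + 1:04d}"
        strand = "-" if (i % 7 == 6) else "+"
        L = int(alt_lengths[i])
        e1 = (cursor, cursor + FLANK_EXON_LEN)
        alt = (e1[1] + INTRON_LEN, e1[1] + INTRON_LEN + L)
        e3 = (alt[1] + INTRON_LEN, alt[1] + INTRON_LEN + FLANK_EXON_LEN)
        genes.append(
            {"gene_id": gid, "strand": strand, "exons": (e1, alt, e3), "alt": alt,
             "has_event": True}
        )
        cursor = e3[1] + GENE_SPACING
    for i in range(cfg.n_genes - cfg.n_events):
        gid = f"X{i + 1:04d}"
        e1 = (cursor, cursor + FLANK_EXON_LEN)
        e2 = (e1[1] + INTRON_LEN, e1[1] + INTRON_LEN + FLANK_EXON_LEN)
        genes.append(
            {"gene_id": gid, "strand": "+", "exons": (e1, e2), "alt": None,
             "has_event": False}
        )
        cursor = e2[1] + GENE_SPACING
    return genes, cursor + READ_LENGTH


def _event_id(gene: Mapping) -> str:
    # mirrors the id convention of events.enumerate_events
    a = gene["alt"]
    return f"{gene['gene_id']}:CASSETTE:chr1:{a[0]}-{a[1]}"


def _write_gtf(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            gid, strand = g["gene_id"], g["strand"]
            if g["has_event"]:
                forms = {f"{gid}.T1": g["exons"], f"{gid}.T2": (g["exons"][0], g["exons"][2])}
            else:
                forms = {f"{gid}.T1": g["exons"]}
            for tid, exons in forms.items():
                for s, e in exons:
                    attrs = f'gene_id "{gid}"; transcript_id "{tid}";'
                    fh.write(f"chr1\tsim\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs}\n")
                    fh.write(f"chr1\tsim\tCDS\t{s + 1}\t{e}\t.\t{strand}\t0\t{attrs}\n")


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _strip_motif(seq: str, motif: str) -> str:
    """Remove every motif occurrence by a single-base substitution."""
    while motif in seq:
        idx = seq.index(motif)
        swap = "C" if seq[idx + 2] != "C" else "T"
        seq = seq[: idx + 2] + swap + seq[idx + 3 :]
    return seq


def _write_genome(genes, genome_len, cfg, rng, path) -> list[str]:
    """Random genome with the motif planted into an exact fraction of alt segments.

    Returns the event ids of motif-positive segments. Planting is exact
    (round(fraction * n_events) segments chosen at random) so gene-level
    motif fractions are reproducible at printed precision; positions within
    each segment are random. Motif-negative segments are scrubbed of chance
    occurrences on the sense strand.
    """
    base = rng.integers(0, 4, size=genome_len)
    seq = np.array(list("ACGT"))[base]
    event_genes = [g for g in genes if g["has_event"]]
    n_pos = int(round(cfg.motif_fraction * len(event_genes)))
    pos_idx = set(rng.choice(len(event_genes), size=n_pos, replace=False).tolist())
    motif_positive = []
    for i, g in enumerate(event_genes):
        a0, a1 = g["alt"]
        sense = "".join(seq[a0:a1])
        if g["strand"] == "-":
            sense = _revcomp(sense)
        sense = _strip_motif(sense, cfg.motif)
        if i in pos_idx:
            off = int(rng.integers(0, len(sense) - len(cfg.motif) + 1))
            sense = sense[:off] + cfg.motif + sense[off + len(cfg.motif):]
            motif_positive.append(_event_id(g))
        genomic = _revcomp(sense) if g["strand"] == "-" else sense
        seq[a0:a1] = list(genomic)
    with open(path, "w") as fh:
        fh.write(">chr1\n")
        s = "".join(seq)
        for i in range(0, len(s), 80):
            fh.write(s[i : i + 80] + "\n")
    return motif_positive


# ---------------------------------------------------------------------------
# PSI truth and junction counts


def simulate_true_psi(cfg: SimulationConfig, rng: np.random.Generator):
    """True per-cell PSI matrix plus planted-event bookkeeping.

    Returns (psi_true DataFrame, planted_differential indices, sample ids,
    group labels dict, low_coverage event indices).
    """
    samples = [f"T{i + 1:03d}" for i in range(cfg.n_tumor)] + [
        f"N{i + 1:02d}" for i in range(cfg.n_control)
    ]
    groups = {s: ("tumor" if s.startswith("T") else "control") for s in samples}
    pi0 = rng.beta(cfg.psi_base_alpha, cfg.psi_base_beta, size=cfg.n_events)

    # plant the differential shift on mid-PSI events (where a screen operates);
    # the flagship event 0 is always planted
    eligible = np.where((pi0 >= 0.15) & (pi0 <= 0.6))[0]
    eligible = eligible[eligible != 0]
    n_extra = max(0, cfg.n_planted_differential - 1)
    if cfg.n_planted_differential == 0:
        planted = np.array([], dtype=int)
    elif len(eligible) >= n_extra:
        planted = np.concatenate(
            [[0], rng.choice(eligible, size=n_extra, replace=False)]
        ).astype(int)
    else:
        planted = np.concatenate([[0], eligible]).astype(int)
    if cfg.n_planted_differential > 0:
        pi0[0] = float(np.clip(pi0[0], 0.2, 0.5))  # flagship stays mid-range

    group_pi = np.tile(pi0[:, None], (1, len(samples)))
    tumor_mask = np.array([groups[s] == "tumor" for s in samples])
    if len(planted):
        shifted = np.clip(pi0[planted] + cfg.delta_psi_effect, 0.02, 0.98)
        group_pi[np.ix_(planted, tumor_mask)] = shifted[:, None]

    jitter = rng.normal(0.0, cfg.psi_sample_sd, size=group_pi.shape)
    # the survival-linked flagship event varies widely across tumors (patient
    # heterogeneity drives the hazard spread the survival screen detects)
    jitter[0, tumor_mask] = rng.normal(0.0, cfg.psi_survival_sd, size=int(tumor_mask.sum()))
    psi = _sigmoid(_logit(np.clip(group_pi, 1e-4, 1 - 1e-4)) + jitter)

    n_low = int(round(cfg.low_coverage_fraction * cfg.n_events))
    candidates = np.setdiff1d(np.arange(cfg.n_events), planted)
    low_cov = rng.choice(candidates, size=min(n_low, len(candidates)), replace=False)

    index = [f"__event_{i}" for i in range(cfg.n_events)]  # relabelled by caller
    df = pd.DataFrame(psi, index=index, columns=samples)
    return df, planted, samples, groups, np.sort(low_cov)


def simulate_junction_counts(
    psi_true: np.ndarray, depth: np.ndarray, rng: np.random.Generator
):
    """Draw (I1, I2, S) junction counts for a PSI matrix.

    ``depth`` is the expected total junction depth per cell (broadcastable);
    the inclusion form spans two junctions, so the junction-level inclusion
    probability is 2*pi/(1+pi).
    """
    d = rng.poisson(np.broadcast_to(depth, psi_true.shape))
    p_inc = 2 * psi_true / (1 + psi_true)
    inc = rng.binomial(d, p_inc)
    i1 = rng.binomial(inc, 0.5)
    return i1, inc - i1, d - inc


# ---------------------------------------------------------------------------
# Downstream layers


def _censoring_horizon(h0: float, rate: float) -> float:
    """Uniform(0, m) censoring horizon giving expected censoring ``rate`` at h0."""
    if rate <= 0:
        return 1e12
    f = lambda m: (1 - math.exp(-h0 * m)) / (h0 * m) - rate
    return brentq(f, 1e-9, 1e9)


def simulate_survival(
    psi_event: pd.Series, tumor_samples, cfg: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Exponential survival with hazard h0*exp(beta*(PSI-0.5)) and uniform censoring."""
    h = cfg.hazard_baseline * np.exp(
        cfg.hazard_log_ratio * (psi_event[tumor_samples].to_numpy(float) - 0.5)
    )
    t = rng.exponential(1.0 / h)
    m = _censoring_horizon(cfg.hazard_baseline, cfg.censoring_rate)
    c = rng.uniform(0, m, size=len(t))
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    time = np.maximum(time, 1e-3)
    return pd.DataFrame(
        {"sample_id": tumor_samples, "time_months": np.round(time, 4), "event_01": event}
    )


def simulate_regulators(
    psi_event: pd.Series, cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, str]:
    """Regulator expression: one planted r_target regulator plus decoys."""
    samples = psi_event.index
    z = psi_event.to_numpy(float)
    z = (z - z.mean()) / z.std()
    r = cfg.regulator_r_target
    planted = r * z + math.sqrt(1 - r * r) * rng.normal(size=len(z))
    rows = {"RBP001": 50 + 10 * planted}
    for i in range(cfg.n_decoy_regulators):
        rows[f"RBPD{i + 1:03d}"] = 50 + 10 * rng.normal(size=len(z))
    df = pd.DataFrame(rows, index=samples).T.round(4)
    return df, "RBP001"


def simulate_tf_layer(cfg: SimulationConfig, rng: np.random.Generator):
    """TSS table, scored TF sites around the target TSS, and two expression cohorts."""
    target = "TGT001"
    tss = 1_000_000
    tss_table = pd.DataFrame(
        [{"gene": target, "chrom": "chr9", "strand": "+", "tss": tss}]
    )
    rows = [
        {"chrom": "chr9", "position": tss - 500, "tf_name": "TF001",
         "chip_score": 85.0, "target_gene": target}
    ]
    for i in range(cfg.tf_window_density):
        name = f"TFD{i + 1:03d}"
        if i % 2 == 0:  # in-window, high score: passes the filter but is a decoy
            pos = tss + int(rng.integers(-2500, 501))
            score = float(rng.uniform(51, 100))
        elif i % 4 == 1:  # out of window
            pos = tss + int(rng.choice([-1, 1]) * rng.integers(3000, 10000))
            score = float(rng.uniform(51, 100))
        else:  # in window, low score
            pos = tss + int(rng.integers(-2500, 501))
            score = float(rng.uniform(5, 50))
        rows.append({"chrom": "chr9", "position": pos, "tf_name": name,
                     "chip_score": round(score, 2), "target_gene": target})
    sites = pd.DataFrame(rows)

    def cohort(n):
        tgt = rng.normal(size=n)
        r = cfg.tf_r_target
        data = {target: 100 + 20 * tgt,
                "TF001": 100 + 20 * (r * tgt + math.sqrt(1 - r * r) * rng.normal(size=n))}
        for i in range(cfg.tf_window_density):
            data[f"TFD{i + 1:03d}"] = 100 + 20 * rng.normal(size=n)
        cols = [f"S{j + 1:03d}" for j in range(n)]
        return pd.DataFrame(data, index=cols).T.round(4)

    cohort_a = cohort(cfg.n_tumor + cfg.n_control)
    cohort_b = cohort(cfg.n_cohort_b)
    return tss_table, sites, cohort_a, cohort_b, target, "TF001"


def simulate_expression(
    genes, cfg: SimulationConfig, samples, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.Series]:
    """Log-normal gene counts and exonic-union gene lengths."""
    gids = [g["gene_id"] for g in genes]
    log_mu = rng.normal(4.0, 2.0, size=len(gids))
    noise = rng.normal(0.0, 0.4, size=(len(gids), len(samples)))
    counts = np.rint(np.exp(log_mu[:, None] + noise)).astype(int)
    lengths = pd.Series(
        {g["gene_id"]: sum(e - s for s, e in g["exons"]) for g in genes}, name="length"
    )
    return pd.DataFrame(counts, index=gids, columns=samples), lengths


# ---------------------------------------------------------------------------
# Bundle emission


def _write_sam(path, chrom, junction_counts: Mapping[tuple[int, int], int],
               contig_len: int, sample_id: str) -> None:
    """Minimal single-end spliced SAM: one 50M{gap}N50M read per junction count."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{chrom}\tLN:{contig_len}\n")
        n = 0
        for (donor, acceptor), count in sorted(junction_counts.items()):
            gap = acceptor - donor
            pos = donor - 50  # 0-based
            cigar = f"50M{gap}N50M"
            for _ in range(count):
                n += 1
                fh.write(
                    f"{sample_id}.r{n}\t0\t{chrom}\t{pos + 1}\t255\t{cigar}\t*\t0\t0\t"
                    f"{'A' * READ_LENGTH}\t*\n"
                )


def generate_dataset(
    cfg: SimulationConfig, out_dir, junction_format: str = "tsv"
) -> tuple[dict[str, str], SyntheticTruth]:
    """Emit the full synthetic bundle and its ground truth.

    ``junction_format``: ``"tsv"`` writes one aggregated junction-count table
    (compact; the default), ``"sam"`` additionally writes one spliced SAM per
    sample (read-level; intended for small configs). Returns (paths, truth).
    """
    if junction_format not in ("tsv", "sam"):
        raise ValueError("junction_format must be 'tsv' or 'sam'")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    genes, genome_len = _event_gene_layout(cfg, rng)
    event_genes = [g for g in genes if g["has_event"]]
    event_ids = [_event_id(g) for g in event_genes]

    paths = {"annotation": str(out / "annotation.gtf"), "genome": str(out / "genome.fa")}
    _write_gtf(genes, paths["annotation"])
    motif_positive = _write_genome(genes, genome_len, cfg, rng, paths["genome"])

    psi_true, planted, samples, groups, low_cov = simulate_true_psi(cfg, rng)
    psi_true.index = event_ids

    depth = np.full((cfg.n_events, 1), cfg.depth_mean)
    depth[low_cov] = cfg.depth_mean / 20.0
    i1, i2, s_counts = simulate_junction_counts(psi_true.to_numpy(), depth, rng)

    junc_rows = []
    per_sample_juncs: dict[str, dict[tuple[int, int], int]] = {s: {} for s in samples}
    for ei, g in enumerate(event_genes):
        e1, alt, e3 = g["exons"]
        inc1 = (e1[1], alt[0])
        inc2 = (alt[1], e3[0])
        exc = (e1[1], e3[0])
        strand = g["strand"]
        for si, s in enumerate(samples):
            for junc, cnt in ((inc1, int(i1[ei, si])), (inc2, int(i2[ei, si])),
                              (exc, int(s_counts[ei, si]))):
                if cnt > 0:
                    junc_rows.append(("chr1", junc[0], junc[1], strand, cnt, s))
                    per_sample_juncs[s][junc] = per_sample_juncs[s].get(junc, 0) + cnt
    paths["junctions"] = str(out / "junctions.tsv")
    pd.DataFrame(
        junc_rows, columns=["chrom", "donor", "acceptor", "strand", "count", "sample"]
    ).to_csv(paths["junctions"], sep="\t", index=False)

    if junction_format == "sam":
        sam_dir = out / "reads"
        sam_dir.mkdir(exist_ok=True)
        paths["sam_dir"] = str(sam_dir)
        for s in samples:
            _write_sam(sam_dir / f"{s}.sam", "chr1", per_sample_juncs[s], genome_len, s)

    counts, lengths = simulate_expression(genes, cfg, samples, rng)
    paths["gene_counts"] = str(out / "gene_counts.tsv")
    counts.rename_axis("gene_id").to_csv(paths["gene_counts"], sep="\t")
    paths["gene_lengths"] = str(out / "gene_lengths.tsv")
    lengths.rename_axis("gene_id").to_frame().to_csv(paths["gene_lengths"], sep="\t")

    flagship = event_ids[0]
    surv = simulate_survival(psi_true.loc[flagship], samples[: cfg.n_tumor], cfg, rng)
    paths["survival"] = str(out / "survival.tsv")
    surv.to_csv(paths["survival"], sep="\t", index=False)

    paths["groups"] = str(out / "groups.tsv")
    pd.DataFrame(
        {"sample_id": samples, "group": [groups[s] for s in samples]}
    ).to_csv(paths["groups"], sep="\t", index=False)

    reg_expr, planted_reg = simulate_regulators(psi_true.loc[flagship], cfg, rng)
    paths["regulator_expression"] = str(out / "regulator_expression.tsv")
    reg_expr.rename_axis("regulator_id").to_csv(paths["regulator_expression"], sep="\t")
    paths["regulator_list"] = str(out / "regulator_list.txt")
    with open(paths["regulator_list"], "w") as fh:
        fh.write("\n".join(reg_expr.index) + "\n")

    tss_table, sites, cohort_a, cohort_b, target, planted_tf = simulate_tf_layer(cfg, rng)
    paths["tss_table"] = str(out / "tss_table.tsv")
    tss_table.to_csv(paths["tss_table"], sep="\t", index=False)
    paths["tf_sites"] = str(out / "tf_sites.tsv")
    sites.to_csv(paths["tf_sites"], sep="\t", index=False)
    paths["tf_expression_a"] = str(out / "tf_expression_cohortA.tsv")
    cohort_a.rename_axis("gene_id").to_csv(paths["tf_expression_a"], sep="\t")
    paths["tf_expression_b"] = str(out / "tf_expression_cohortB.tsv")
    cohort_b.rename_axis("gene_id").to_csv(paths["tf_expression_b"], sep="\t")

    truth = SyntheticTruth(
        psi_true=psi_true,
        planted_differential=[event_ids[i] for i in planted],
        planted_survival=[flagship] if cfg.hazard_log_ratio != 0 else [],
        planted_regulator=planted_reg,
        regulator_r=cfg.regulator_r_target,
        motif_positive=motif_positive,
        planted_tf=planted_tf,
        tf_r=cfg.tf_r_target,
        sample_groups=groups,
        config=cfg,
    )
    paths["truth"] = str(out / "truth.json")
    truth.to_json(paths["truth"])
    return paths, truth


# ---------------------------------------------------------------------------
# In-memory panel (no file I/O) for repeated-seed experiments


@dataclass
class SimulatedPanel:
    events: list
    psi_true: pd.DataFrame
    junction_tables: dict
    survival: list
    groups: dict
    planted_differential: list[str]


def simulate_panel(cfg: SimulationConfig) -> SimulatedPanel:
    """Simulate events, junction counts, survival and groups in memory.

    Produces the same cohort structure as :func:`generate_dataset` (event
    objects instead of a GTF, junction tables instead of a TSV) without
    touching the filesystem; used for repeated-seed calibration and power
    studies.
    """
    from .prioritize import SurvivalRecord
    from .quantify import JunctionCountTable

    rng = np.random.default_rng(cfg.seed)
    genes, _ = _event_gene_layout(cfg, rng)
    event_genes = [g for g in genes if g["has_event"]]

    events = []
    for g in event_genes:
        e1, alt, e3 = g["exons"]
        events.append(
            SpliceEvent(
                event_id=_event_id(g),
                event_type="CASSETTE",
                gene_id=g["gene_id"],
                chrom="chr1",
                strand=g["strand"],
                alt_segment=alt,
                flank_upstream=e1,
                flank_downstream=e3,
                inclusion_junctions=frozenset({(e1[1], alt[0]), (alt[1], e3[0])}),
                exclusion_junctions=frozenset({(e1[1], e3[0])}),
                in_cds=True,
            )
        )

    psi_true, planted, samples, groups, low_cov = simulate_true_psi(cfg, rng)
    psi_true.index = [ev.event_id for ev in events]
    depth = np.full((cfg.n_events, 1), cfg.depth_mean)
    depth[low_cov] = cfg.depth_mean / 20.0
    i1, i2, s_counts = simulate_junction_counts(psi_true.to_numpy(), depth, rng)

    tables = {}
    for si, s in enumerate(samples):
        counts = {}
        for ei, g in enumerate(event_genes):
            e1, alt, e3 = g["exons"]
            strand = g["strand"]
            for junc, cnt in (((e1[1], alt[0]), int(i1[ei, si])),
                              ((alt[1], e3[0]), int(i2[ei, si])),
                              ((e1[1], e3[0]), int(s_counts[ei, si]))):
                if cnt > 0:
                    counts[("chr1", junc[0], junc[1], strand)] = cnt
        tables[s] = JunctionCountTable(sample_id=s, counts=counts)

    surv_df = simulate_survival(psi_true.iloc[0], samples[: cfg.n_tumor], cfg, rng)
    survival = [
        SurvivalRecord(str(r.sample_id), float(r.time_months), int(r.event_01))
        for r in surv_df.itertuples()
    ]
    return SimulatedPanel(
        events=events,
        psi_true=psi_true,
        junction_tables=tables,
        survival=survival,
        groups=groups,
        planted_differential=[events[i].event_id for i in planted],
    )


# ---------------------------------------------------------------------------
# Recovery metrics


def truth_report(
    truth: SyntheticTruth,
    psi_est: pd.DataFrame,
    differential: pd.DataFrame | None = None,
    regulator_ranking: pd.DataFrame | None = None,
    tf_ranking: pd.DataFrame | None = None,
    motif_hits=None,
    alpha: float = 0.05,
) -> dict:
    """Compare pipeline outputs against the planted truth.

    Raises on an id mismatch between the truth record and the outputs.
    """
    missing = set(truth.psi_true.index) - set(psi_est.index)
    if missing:
        raise ValueError(f"events missing from PSI estimate: {sorted(missing)[:3]}")
    est = psi_est.loc[truth.psi_true.index, truth.psi_true.columns]
    diff = (est - truth.psi_true).to_numpy()
    finite = np.isfinite(diff)
    report: dict = {
        "psi_rmse": float(np.sqrt(np.nanmean(diff[finite] ** 2))),
        "psi_cells_evaluated": int(finite.sum()),
    }
    if differential is not None:
        planted = set(truth.planted_differential)
        if planted - set(differential.index):
            raise ValueError("planted differential events missing from results")
        sig = (differential["wilcoxon_p"] < alpha) & (differential["delta_psi"].abs() > 0.1)
        is_planted = differential.index.isin(planted)
        if planted:
            report["differential_sensitivity"] = float(sig[is_planted].mean())
        report["differential_false_positive_rate"] = (
            float(sig[~is_planted].mean()) if (~is_planted).any() else math.nan
        )
    if regulator_ranking is not None:
        if truth.planted_regulator not in regulator_ranking.index:
            raise ValueError("planted regulator missing from ranking")
        report["planted_regulator_rank"] = (
            int(regulator_ranking.index.get_loc(truth.planted_regulator)) + 1
        )
    if tf_ranking is not None:
        if truth.planted_tf not in tf_ranking.index:
            raise ValueError("planted TF missing from ranking")
        report["planted_tf_rank"] = int(tf_ranking.index.get_loc(truth.planted_tf)) + 1
    if motif_hits is not None:
        present = {h.seq_id for h in motif_hits if h.present}
        truth_pos = set(truth.motif_positive)
        if truth_pos - {h.seq_id for h in motif_hits}:
            raise ValueError("motif-positive ids missing from scan")
        n = len(motif_hits)
        report["motif_fraction_recovered"] = round(100.0 * len(present) / n, 1) if n else math.nan
        report["motif_exact_match"] = present == truth_pos
    return report


def read_config_file(path) -> SimulationConfig:
    """Parse a ``key = value`` text file into a SimulationConfig."""
    kwargs = {}
    fields = {f: t for f, t in SimulationConfig.__annotations__.items()}
    with open(path) as fh:
        for line in fh:
            line = line.split("#")[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in fields:
                raise KeyError(f"unknown simulation parameter {key!r}")
            target = SimulationConfig.__dataclass_fields__[key].type
            if target in ("int",):
                kwargs[key] = int(val)
            elif target in ("float",):
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
    return SimulationConfig(**kwargs)
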