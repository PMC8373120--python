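"""End-to-end orchestration: simulate -> catalog -> quantify -> prioritize -> regulators.

Each stage is a pure function of its declared inputs plus the run
configuration; the run manifest records input checksums, per-stage row
counts and the config echo so reruns are verifiable byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .events import enumerate_events, event_sequences, parse_annotation, write_catalog
from .prioritize import (
    DEFAULT_ALPHA,
    DEFAULT_DELTA_PSI_CUTOFF,
    DEFAULT_LENGTH_WINDOW,
    apply_prioritization,
    differential_psi,
    read_survival_tsv,
    survival_association,
)
from .quantify import (
    DEFAULT_MIN_OVERHANG,
    DEFAULT_MIN_TOTAL_READS,
    compute_tpm,
    extract_junctions,
    filter_low_expression,
    psi_matrix,
    read_junction_tsv,
)
from .regulators import (
    DEFAULT_MOTIF,
    DEFAULT_TF_MIN_SCORE,
    DEFAULT_TF_WINDOW,
    correlate_regulators,
    filter_tf_sites,
    rank_tf_candidates,
    read_regulator_list,
    scan_motif,
)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    annotation: str
    out_dir: str
    junctions_tsv: str | None = None
    sam_dir: str | None = None
    genome: str | None = None
    gene_counts: str | None = None
    gene_lengths: str | None = None
    survival: str | None = None
    groups: str | None = None
    regulator_list: str | None = None
    regulator_expression: str | None = None
    tf_sites: str | None = None
    tss_table: str | None = None
    tf_expression: tuple[str, ...] = ()
    target_event: str | None = None  # default: best retained candidate
    min_total_reads: int = DEFAULT_MIN_TOTAL_READS
    min_overhang: int = DEFAULT_MIN_OVERHANG
    alpha: float = DEFAULT_ALPHA
    delta_psi_cutoff: float = DEFAULT_DELTA_PSI_CUTOFF
    length_window: tuple[int, int] = DEFAULT_LENGTH_WINDOW
    tpm_threshold: float = 2.0
    tf_window: tuple[int, int] = DEFAULT_TF_WINDOW
    tf_min_score: float = DEFAULT_TF_MIN_SCORE
    motif: str = DEFAULT_MOTIF
    seed: int = 0

    def input_paths(self) -> dict[str, str]:
        named = {
            "annotation": self.annotation,
            "junctions_tsv": self.junctions_tsv,
            "genome": self.genome,
            "gene_counts": self.gene_counts,
            "gene_lengths": self.gene_lengths,
            "survival": self.survival,
            "groups": self.groups,
            "regulator_list": self.regulator_list,
            "regulator_expression": self.regulator_expression,
            "tf_sites": self.tf_sites,
            "tss_table": self.tss_table,
        }
        out = {k: v for k, v in named.items() if v}
        for i, p in enumerate(self.tf_expression):
            out[f"tf_expression_{i}"] = p
        return out


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_full(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, path in config.input_paths().items():
        if not Path(path).exists():
            raise FileNotFoundError(f"input {name!r} not found: {path}")

    manifest: dict = {
        "tool": "spliceprio",
        "version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "inputs": {k: _sha256(v) for k, v in sorted(config.input_paths().items())},
        "stages": [],
    }

    def record(stage: str, t0: float, **counts):
        manifest["stages"].append(
            {"stage": stage, "elapsed_s": round(time.perf_counter() - t0, 3), **counts}
        )

    # --- catalog ----------------------------------------------------------
    t0 = time.perf_counter()
    try:
        transcripts = parse_annotation(config.annotation)
        events = enumerate_events(transcripts)
        write_catalog(events, out / "event_catalog.tsv")
    except Exception as exc:  # noqa: BLE001 - stage-tagged abort
        raise StageError("catalog", exc) from exc
    record("catalog", t0, transcripts=len(transcripts), events=len(events))

    # --- quantify ---------------------------------------------------------
    t0 = time.perf_counter()
    try:
        if config.junctions_tsv:
            tables = read_junction_tsv(config.junctions_tsv)
        elif config.sam_dir:
            tables = {}
            for sam in sorted(Path(config.sam_dir).glob("*.sam")):
                t = extract_junctions(sam, min_overhang=config.min_overhang)
                tables[t.sample_id] = t
        else:
            raise ValueError("either junctions_tsv or sam_dir is required")
        quantifiable = [ev for ev in events if ev.inclusion_junctions and ev.exclusion_junctions]
        psi = psi_matrix(quantifiable, tables, min_total_reads=config.min_total_reads)
        psi.rename_axis("event_id").to_csv(out / "psi_matrix.tsv", sep="\t", na_rep="NA")
        tpm = None
        if config.gene_counts and config.gene_lengths:
            counts = pd.read_csv(config.gene_counts, sep="\t", index_col="gene_id")
            lengths = pd.read_csv(config.gene_lengths, sep="\t", index_col="gene_id")["length"]
            tpm = filter_low_expression(compute_tpm(counts, lengths), config.tpm_threshold)
            tpm.rename_axis("gene_id").to_csv(out / "tpm_filtered.tsv", sep="\t")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("quantify", exc) from exc
    record("quantify", t0, samples=len(tables), events_quantified=psi.shape[0],
           genes_after_tpm_filter=0 if tpm is None else tpm.shape[0])

    # --- prioritize -------------------------------------------------------
    t0 = time.perf_counter()
    try:
        groups = pd.read_csv(config.groups, sep="\t", dtype=str).set_index("sample_id")["group"]
        diff = differential_psi(psi, groups)
        surv_records = read_survival_tsv(config.survival)
        surv = survival_association(psi, surv_records)
        candidates = apply_prioritization(
            quantifiable, diff, surv, psi, groups,
            alpha=config.alpha,
            delta_psi_cutoff=config.delta_psi_cutoff,
            length_window=config.length_window,
        )
        candidates.to_csv(out / "candidates.tsv", sep="\t")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("prioritize", exc) from exc
    retained = candidates[candidates["retained"]]
    record("prioritize", t0, events_tested=len(candidates), retained=int(len(retained)))

    # --- regulators -------------------------------------------------------
    t0 = time.perf_counter()
    try:
        target_event = config.target_event
        if target_event is None and len(retained):
            target_event = (
                retained.sort_values(["wilcoxon_p", "logrank_p"]).index[0]
            )
        reg_ranking = None
        if target_event is not None and config.regulator_expression and config.regulator_list:
            reg_expr = pd.read_csv(
                config.regulator_expression, sep="\t", index_col="regulator_id"
            )
            reg_ids = read_regulator_list(config.regulator_list)
            reg_ranking = correlate_regulators(psi.loc[target_event], reg_expr, reg_ids)
            reg_ranking.to_csv(out / "regulator_ranking.tsv", sep="\t")
        motif_summary = float("nan")
        motif_hits = []
        if config.genome:
            seqs = event_sequences(quantifiable, config.genome)
            motif_hits, motif_summary = scan_motif(seqs, config.motif)
            pd.DataFrame(
                [
                    {"event_id": h.seq_id, "present": int(h.present),
                     "positions": ";".join(map(str, h.positions))}
                    for h in motif_hits
                ]
            ).to_csv(out / "motif_hits.tsv", sep="\t", index=False)
        tf_ranking = None
        if config.tf_sites and config.tss_table and config.tf_expression:
            sites = pd.read_csv(config.tf_sites, sep="\t")
            tss = pd.read_csv(config.tss_table, sep="\t")
            retained_sites = filter_tf_sites(
                sites, tss, window=config.tf_window, min_score=config.tf_min_score
            )
            retained_sites.to_csv(out / "tf_sites_retained.tsv", sep="\t", index=False)
            cohorts = [
                pd.read_csv(p, sep="\t", index_col="gene_id") for p in config.tf_expression
            ]
            target_gene = str(tss["gene"].iloc[0])
            tf_ranking = rank_tf_candidates(retained_sites, cohorts, target_gene,
                                            alpha=config.alpha)
            tf_ranking.to_csv(out / "tf_ranking.tsv", sep="\t")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("regulators", exc) from exc
    record(
        "regulators", t0,
        target_event=target_event or "",
        regulators_ranked=0 if reg_ranking is None else len(reg_ranking),
        motif_fraction_pct=None if motif_summary != motif_summary else motif_summary,
        tf_candidates=0 if tf_ranking is None else len(tf_ranking),
    )

    # --- report -----------------------------------------------------------
    t0 = time.perf_counter()
    outputs = sorted(p.name for p in out.glob("*.tsv"))
    record("report", t0, output_files=len(outputs))
    manifest["outputs"] = {name: _sha256(str(out / name)) for name in outputs}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
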