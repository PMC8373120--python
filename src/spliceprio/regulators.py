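"""Trans-regulator ranking, exonic motif scanning, and promoter TF-site filtering.

Candidate RNA-binding proteins are ranked by the Pearson correlation between
their expression and the PSI of a target splicing event across samples
(two-sided t-distribution p, R^2 = r^2). Alternative-exon sequences are
scanned for a literal splicing-enhancer motif (default GGAA, the RBFOX
binding element core); the summary is the percentage of sequences (genes)
carrying at least one occurrence. Transcription-factor ChIP sites are
filtered to a strand-aware promoter window around the target gene TSS
(default -2500..+500, inclusive) with a strict ChIP-score cutoff (> 50).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_MOTIF = "GGAA"
DEFAULT_TF_WINDOW = (-2500, 500)
DEFAULT_TF_MIN_SCORE = 50.0


@dataclass
class RegulatorCorrelation:
    regulator_id: str
    r: float
    r_squared: float
    p: float
    n_used: int


@dataclass
class MotifHit:
    seq_id: str
    motif: str
    positions: list[int]

    @property
    def present(self) -> bool:
        return len(self.positions) > 0


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def correlate_regulators(
    target_psi: pd.Series,
    expression: pd.DataFrame,
    regulator_ids: Sequence[str],
) -> pd.DataFrame:
    """Pearson correlation of each regulator's expression with the target PSI.

    Pairwise-complete samples are used per regulator; regulators absent from
    the expression matrix are skipped with a warning, and fewer than 3 usable
    pairs yields an NA row. Result is sorted by p ascending, ties broken by
    |r| descending, and indexed by regulator id.
    """
    rows = []
    for reg in regulator_ids:
        if reg not in expression.index:
            warnings.warn(f"regulator {reg!r} absent from expression matrix; skipped",
                          stacklevel=2)
            continue
        joined = pd.concat([target_psi, expression.loc[reg]], axis=1, join="inner").dropna()
        n = len(joined)
        if n < 3:
            rows.append((reg, math.nan, math.nan, math.nan, n))
            continue
        r, p = _pearson(joined.iloc[:, 0].to_numpy(float), joined.iloc[:, 1].to_numpy(float))
        rows.append((reg, r, r * r if not math.isnan(r) else math.nan, p, n))
    df = pd.DataFrame(rows, columns=["regulator_id", "r", "r_squared", "p", "n_used"])
    df["_absr"] = df["r"].abs()
    df = df.sort_values(["p", "_absr"], ascending=[True, False], na_position="last")
    return df.drop(columns="_absr").set_index("regulator_id")


# ---------------------------------------------------------------------------
# Motif scanning


def scan_motif(
    sequences: Mapping[str, str], motif: str = DEFAULT_MOTIF
) -> tuple[list[MotifHit], float]:
    """Locate all (possibly overlapping) exact motif occurrences per sequence.

    Returns the per-sequence hits and the summary fraction: the percentage of
    ids with at least one occurrence, rounded to one decimal (NaN for an
    empty input). Matching is exact on the given (mRNA-sense) strand.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    motif = motif.upper()
    hits = []
    for seq_id, seq in sequences.items():
        s = seq.upper()
        positions = []
        start = 0
        while True:
            idx = s.find(motif, start)
            if idx == -1:
                break
            positions.append(idx)
            start = idx + 1
        hits.append(MotifHit(seq_id=seq_id, motif=motif, positions=positions))
    if not hits:
        return hits, math.nan
    frac = 100.0 * sum(h.present for h in hits) / len(hits)
    return hits, round(frac, 1)


# ---------------------------------------------------------------------------
# TF-site promoter filtering


def tss_offset(position: int, tss: int, strand: str) -> int:
    """Strand-aware offset of a genomic position from a TSS.

    Negative = upstream of the TSS in the gene's reading direction; on the
    minus strand upstream lies at numerically greater coordinates.
    """
    return position - tss if strand == "+" else tss - position


def filter_tf_sites(
    sites: pd.DataFrame,
    tss_table: pd.DataFrame,
    window: tuple[int, int] = DEFAULT_TF_WINDOW,
    min_score: float = DEFAULT_TF_MIN_SCORE,
) -> pd.DataFrame:
    """Retain ChIP sites inside the promoter window with score above cutoff.

    ``sites`` columns: chrom, position, tf_name, chip_score, target_gene.
    ``tss_table`` columns: gene, chrom, strand, tss. Window boundaries are
    inclusive; the score cutoff is strict (chip_score > min_score). Sites
    whose target gene has no TSS entry are dropped with a warning. The result
    adds an ``offset_from_tss`` column; filtering is idempotent.
    """
    tss = tss_table.set_index("gene")
    keep_rows = []
    for row in sites.itertuples():
        if row.target_gene not in tss.index:
            warnings.warn(f"gene {row.target_gene!r} has no TSS entry; site dropped",
                          stacklevel=2)
            continue
        entry = tss.loc[row.target_gene]
        off = tss_offset(int(row.position), int(entry.tss), str(entry.strand))
        if window[0] <= off <= window[1] and float(row.chip_score) > min_score:
            keep_rows.append((row.Index, off))
    if not keep_rows:
        out = sites.iloc[0:0].copy()
        out["offset_from_tss"] = pd.Series(dtype=int)
        return out
    idx, offsets = zip(*keep_rows)
    out = sites.loc[list(idx)].copy()
    out["offset_from_tss"] = offsets
    return out


def rank_tf_candidates(
    retained_sites: pd.DataFrame,
    expression: pd.DataFrame | Sequence[pd.DataFrame],
    target_gene: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank TFs with promoter-window sites by expression correlation with the target.

    One or more cohort expression matrices (genes x samples) may be supplied;
    per cohort the Pearson r/p of TF vs target-gene expression is computed,
    and ``significant_all_cohorts`` requires p < alpha in every cohort
    (intersection rule). Ranking: significant-everywhere first, then worst
    per-cohort p ascending, then |r| descending.
    """
    cohorts = [expression] if isinstance(expression, pd.DataFrame) else list(expression)
    if not len(retained_sites):
        raise ValueError("no retained TF sites to rank")
    tf_names = sorted(set(retained_sites["tf_name"]))
    rows = []
    for tf in tf_names:
        per_r, per_p = [], []
        for ex in cohorts:
            if target_gene not in ex.index or tf not in ex.index:
                per_r.append(math.nan)
                per_p.append(math.nan)
                continue
            joined = pd.concat([ex.loc[target_gene], ex.loc[tf]], axis=1).dropna()
            r, p = _pearson(joined.iloc[:, 0].to_numpy(float), joined.iloc[:, 1].to_numpy(float))
            per_r.append(r)
            per_p.append(p)
        sig_all = all(not math.isnan(p) and p < alpha for p in per_p)
        worst_p = max(per_p) if not any(math.isnan(p) for p in per_p) else math.nan
        rows.append((tf, per_r[0], per_p[0], worst_p, sig_all))
    df = pd.DataFrame(rows, columns=["tf_name", "r", "p", "worst_p", "significant_all_cohorts"])
    df["_absr"] = df["r"].abs()
    df = df.sort_values(
        ["significant_all_cohorts", "worst_p", "_absr"],
        ascending=[False, True, False],
        na_position="last",
    )
    return df.drop(columns="_absr").set_index("tf_name")


def read_regulator_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]
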