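"""Junction counting, PSI and expression quantification.

PSI (percent spliced-in) for an event is estimated from junction-read support
only: reads whose alignments gap (CIGAR ``N``) across an inclusion or
exclusion junction of the event. Because a cassette inclusion form spans two
junctions while the exclusion form spans one, raw counts are normalized by
the number of junctions per form before forming the ratio:

    PSI = (I / n_inc) / (I / n_inc + S / n_exc)

where I and S are summed inclusion / exclusion junction counts. PSI is NA
when I + S falls below ``min_total_reads`` (insufficient evidence), and for
events whose retained form has no junction (retained introns).
"""

from __future__ import annotations

import math
import os
import tempfile
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .events import SpliceEvent

DEFAULT_MIN_TOTAL_READS = 10
DEFAULT_MIN_OVERHANG = 6


class EventJunctionsError(ValueError):
    """Raised for an event with no junctions on either form (malformed)."""


@dataclass
class JunctionCountTable:
    """Junction read counts for one sample.

    ``counts`` maps (chrom, donor, acceptor, strand) to a non-negative read
    count; donor/acceptor are 0-based half-open reference positions (donor =
    first skipped base, acceptor = first aligned base after the gap).
    """

    sample_id: str
    counts: dict[tuple[str, int, int, str], int]
    skipped_records: int = 0

    def get(self, chrom: str, donor: int, acceptor: int) -> int:
        """Count for a junction summed over strand annotations."""
        index = self.__dict__.get("_index")
        if index is None or self.__dict__.get("_index_size") != len(self.counts):
            index = {}
            for (ch, d, a, _s), c in self.counts.items():
                key = (ch, d, a)
                index[key] = index.get(key, 0) + c
            self.__dict__["_index"] = index
            self.__dict__["_index_size"] = len(self.counts)
        return index.get((chrom, donor, acceptor), 0)


@dataclass
class PsiValue:
    event_id: str
    sample_id: str
    psi: float  # NaN encodes NA
    inclusion_reads: int
    exclusion_reads: int


@dataclass
class IhcScore:
    """Immunohistochemistry H-score: staining intensity x percent stained cells."""

    sample_id: str
    intensity: int
    percent_stained: float

    def __post_init__(self):
        if self.intensity not in (0, 1, 2, 3):
            raise ValueError(f"intensity must be in 0..3, got {self.intensity}")
        if not 0 <= self.percent_stained <= 100:
            raise ValueError(f"percent_stained must be in [0, 100], got {self.percent_stained}")

    @property
    def score(self) -> float:
        return self.intensity * self.percent_stained


def ihc_score(intensity: int, percent_stained: float, sample_id: str = "") -> IhcScore:
    return IhcScore(sample_id=sample_id, intensity=intensity, percent_stained=percent_stained)


# ---------------------------------------------------------------------------
# Junction extraction from SAM


def _ensure_header(path: str) -> str:
    """Return a readable SAM path, synthesizing an @SQ header if absent.

    Headerless SAM is tolerated: reference names are collected from column 3
    and given a generous length so pysam can resolve them.
    """
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("@"):
        return path
    refs: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            f = line.split("\t")
            if len(f) >= 4 and f[2] != "*":
                try:
                    pos = int(f[3])
                except ValueError:
                    continue
                refs[f[2]] = max(refs.get(f[2], 0), pos + 10_000_000)
    tmp = tempfile.NamedTemporaryFile(
        "w", suffix=".sam", delete=False, dir=os.path.dirname(os.path.abspath(path))
    )
    with tmp as out, open(path) as fh:
        for name, ln in refs.items():
            out.write(f"@SQ\tSN:{name}\tLN:{ln}\n")
        out.write(fh.read())
    return tmp.name


def extract_junctions(
    sam_path,
    sample_id: str | None = None,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> JunctionCountTable:
    """Count splice junctions (CIGAR N gaps) from spliced SAM alignments.

    Each N operation contributes one junction count per read, keyed by the
    half-open gap (donor, acceptor). A junction is discarded when the aligned
    (M) overhang between it and the nearest read end or neighbouring gap is
    below ``min_overhang`` on either side. Unmapped records and records
    without a usable CIGAR are tallied in ``skipped_records``.
    """
    sam_path = str(sam_path)
    if sample_id is None:
        sample_id = os.path.splitext(os.path.basename(sam_path))[0]
    readable = _ensure_header(sam_path)
    counts: dict[tuple[str, int, int, str], int] = {}
    skipped = 0
    try:
        with pysam.AlignmentFile(readable, "r", check_sq=False) as sam:
            for rec in sam:
                if rec.is_unmapped or rec.cigartuples is None:
                    skipped += 1
                    continue
                strand = "."
                if rec.has_tag("XS"):
                    strand = rec.get_tag("XS")
                ref = rec.reference_name
                pos = rec.reference_start
                # segment aligned lengths between N gaps: M/D consume reference
                # and M counts as overhang; I/S consume only the query.
                segs: list[int] = [0]
                gaps: list[tuple[int, int]] = []
                for op, ln in rec.cigartuples:
                    if op == 0:  # M
                        segs[-1] += ln
                        pos += ln
                    elif op == 2:  # D
                        pos += ln
                    elif op == 3:  # N
                        gaps.append((pos, pos + ln))
                        pos += ln
                        segs.append(0)
                    # I (1) and S (4) consume no reference and add no overhang
                for i, (donor, acceptor) in enumerate(gaps):
                    if segs[i] >= min_overhang and segs[i + 1] >= min_overhang:
                        key = (ref, donor, acceptor, strand)
                        counts[key] = counts.get(key, 0) + 1
    finally:
        if readable != sam_path:
            os.unlink(readable)
    return JunctionCountTable(sample_id=sample_id, counts=counts, skipped_records=skipped)


def read_junction_tsv(path) -> dict[str, JunctionCountTable]:
    """Read a junction-count TSV (chrom, donor, acceptor, strand, count, sample)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str, "sample": str})
    tables: dict[str, JunctionCountTable] = {}
    for sample, sub in df.groupby("sample", sort=True):
        counts = {
            (r.chrom, int(r.donor), int(r.acceptor), r.strand): int(r.count)
            for r in sub.itertuples()
        }
        tables[str(sample)] = JunctionCountTable(sample_id=str(sample), counts=counts)
    return tables


def write_junction_tsv(tables: Mapping[str, JunctionCountTable], path) -> None:
    rows = []
    for sample in sorted(tables):
        for (chrom, d, a, s), c in sorted(tables[sample].counts.items()):
            rows.append((chrom, d, a, s, c, sample))
    pd.DataFrame(
        rows, columns=["chrom", "donor", "acceptor", "strand", "count", "sample"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PSI


def compute_psi(
    event: SpliceEvent,
    junctions: JunctionCountTable,
    min_total_reads: int = DEFAULT_MIN_TOTAL_READS,
) -> PsiValue:
    """Junction-normalized PSI for one event in one sample.

    Raises :class:`EventJunctionsError` when the event defines no junctions at
    all. Events with junctions on only one form (retained introns) cannot be
    quantified from junction evidence and yield NA.
    """
    n_inc = len(event.inclusion_junctions)
    n_exc = len(event.exclusion_junctions)
    if n_inc == 0 and n_exc == 0:
        raise EventJunctionsError(f"event {event.event_id} defines no junctions")
    inc = sum(junctions.get(event.chrom, d, a) for d, a in event.inclusion_junctions)
    exc = sum(junctions.get(event.chrom, d, a) for d, a in event.exclusion_junctions)
    if n_inc == 0 or n_exc == 0 or inc + exc < min_total_reads:
        psi = math.nan
    else:
        inc_bar = inc / n_inc
        exc_bar = exc / n_exc
        psi = inc_bar / (inc_bar + exc_bar) if inc_bar + exc_bar > 0 else math.nan
    return PsiValue(
        event_id=event.event_id,
        sample_id=junctions.sample_id,
        psi=psi,
        inclusion_reads=inc,
        exclusion_reads=exc,
    )


def psi_matrix(
    events: Sequence[SpliceEvent],
    samples: Mapping[str, JunctionCountTable] | Iterable[JunctionCountTable],
    min_total_reads: int = DEFAULT_MIN_TOTAL_READS,
) -> pd.DataFrame:
    """Events x samples PSI matrix (NaN encodes NA).

    The per-event NA fraction is attached as ``df.attrs['na_fraction']``.
    """
    if isinstance(samples, Mapping):
        tables = [samples[k] for k in samples]
    else:
        tables = list(samples)
    data = {
        t.sample_id: [compute_psi(ev, t, min_total_reads).psi for ev in events]
        for t in tables
    }
    df = pd.DataFrame(data, index=[ev.event_id for ev in events])
    df.attrs["na_fraction"] = df.isna().mean(axis=1)
    return df


# ---------------------------------------------------------------------------
# Expression


def compute_tpm(counts: pd.DataFrame, gene_lengths: Mapping[str, float]) -> pd.DataFrame:
    """Transcripts-per-million from a genes x samples raw count matrix.

    tpm[g, s] = (count[g, s] / length_kb[g]) / sum_g'(count[g', s] / length_kb[g']) * 1e6.
    Gene length is the effective (exonic-union) length in bp; every column of
    the result sums to 1e6. Raises for a sample with zero total rate.
    """
    missing = [g for g in counts.index if g not in gene_lengths]
    if missing:
        raise KeyError(f"no length for genes: {missing[:5]}")
    lengths = pd.Series({g: float(gene_lengths[g]) for g in counts.index})
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.div(lengths / 1000.0, axis=0)
    totals = rate.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total expression rate")
    return rate.div(totals, axis=1) * 1e6


def filter_low_expression(tpm: pd.DataFrame, threshold: float = 2.0) -> pd.DataFrame:
    """Drop genes whose mean TPM across all samples is below ``threshold``.

    The inequality is strict (mean < threshold removed), so a gene at exactly
    the threshold is retained. Columns are not renormalized; re-running
    :func:`compute_tpm` on the retained set is an explicit, separate step.
    """
    if tpm.empty:
        return tpm
    return tpm.loc[tpm.mean(axis=1) >= threshold]
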