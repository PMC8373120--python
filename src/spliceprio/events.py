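"""Alternative-splicing event catalog.

Parses transcript annotation (GTF) into :class:`TranscriptModel` objects and
enumerates alternative-splicing events between the transcripts of each gene,
classifying them into the five standard categories:

* ``CASSETTE`` — an internal exon included in one transcript and skipped
  (flanks joined directly) in another;
* ``MXE`` — two non-overlapping internal exons that are never co-present,
  exactly one of which is spliced between shared flanks;
* ``A5SS`` / ``A3SS`` — an alternative donor / acceptor shifting one exon
  boundary while the partner boundary of the junction is shared;
* ``RI`` — an intron spliced out in one transcript and retained (covered by a
  single exon with the same outer boundaries) in another.

All internal coordinates are 0-based half-open; GTF input (1-based inclusive)
is converted on parse, so segment length is always ``end - start``.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio.Seq import Seq
from pyfaidx import Fasta

Interval = tuple[int, int]
Junction = tuple[int, int]

EVENT_TYPES = ("CASSETTE", "MXE", "A5SS", "A3SS", "RI")


class AnnotationParseError(ValueError):
    """Raised for a malformed annotation line; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"annotation parse error at line {line_number}: {message}")


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: an ordered run of exons on a chromosome strand.

    ``exons`` are 0-based half-open genomic intervals sorted by start and
    non-overlapping. ``cds_intervals``, when present, are each contained in
    some exon.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]
    cds_intervals: tuple[Interval, ...] | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        prev_end = None
        for start, end in self.exons:
            if start >= end:
                raise ValueError(f"empty/inverted exon ({start}, {end}) in {self.transcript_id}")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"overlapping/unsorted exons in {self.transcript_id}")
            prev_end = end
        if self.cds_intervals:
            for cs, ce in self.cds_intervals:
                if not any(es <= cs and ce <= ee for es, ee in self.exons):
                    raise ValueError(
                        f"CDS interval ({cs}, {ce}) not contained in any exon of {self.transcript_id}"
                    )

    @property
    def junctions(self) -> tuple[Junction, ...]:
        """Intron junctions as (donor_end_of_upstream_exon, acceptor_start_of_downstream_exon)."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )

    @property
    def exon_set(self) -> frozenset[Interval]:
        return frozenset(self.exons)


@dataclass(frozen=True)
class SpliceEvent:
    """One alternative-splicing event.

    ``alt_segment`` is the alternatively included sequence (cassette exon,
    5'-most MXE exon, donor/acceptor extension, or retained intron);
    ``inclusion_junctions`` / ``exclusion_junctions`` are the junction sets
    whose read support evidences each form. Retained introns have an empty
    inclusion set: intron retention leaves no junction.
    """

    event_id: str
    event_type: str
    gene_id: str
    chrom: str
    strand: str
    alt_segment: Interval
    flank_upstream: Interval
    flank_downstream: Interval
    inclusion_junctions: frozenset[Junction]
    exclusion_junctions: frozenset[Junction]
    in_cds: bool = False

    def __post_init__(self):
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if self.inclusion_junctions & self.exclusion_junctions:
            raise ValueError("inclusion and exclusion junction sets must be disjoint")
        if self.alt_length < 1:
            raise ValueError("alt_segment must be non-empty")
        if self.event_type == "CASSETTE":
            if len(self.inclusion_junctions) != 2 or len(self.exclusion_junctions) != 1:
                raise ValueError("cassette events have 2 inclusion and 1 exclusion junction")

    @property
    def alt_length(self) -> int:
        return self.alt_segment[1] - self.alt_segment[0]


# ---------------------------------------------------------------------------
# GTF parsing


def _read_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    text = str(source)
    if "\t" in text or "\n" in text:
        return text
    with open(text) as fh:
        return fh.read()


def parse_annotation(source) -> list[TranscriptModel]:
    """Parse GTF text (path, file object or string) into transcript models.

    Exon features are grouped by their ``transcript_id`` attribute; CDS
    features are attached to the same transcript. 1-based inclusive GTF
    coordinates become 0-based half-open. Transcripts with zero exons (e.g. a
    bare ``transcript`` feature) are skipped with a warning.
    """
    text = _read_text(source)
    for i, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        if len(line.split("\t")) != 9:
            raise AnnotationParseError(i, "expected 9 tab-separated fields")

    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    exons: dict[str, list[Interval]] = {}
    cds: dict[str, list[Interval]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    declared: list[str] = []

    for feat in db.all_features():
        try:
            tid = feat.attributes["transcript_id"][0]
            gid = feat.attributes["gene_id"][0]
        except KeyError:
            if feat.featuretype in ("exon", "CDS", "transcript"):
                raise AnnotationParseError(
                    getattr(feat, "line_number", 0) or 0,
                    f"{feat.featuretype} feature lacks gene_id/transcript_id",
                )
            continue
        meta.setdefault(tid, (gid, feat.seqid, feat.strand))
        if feat.featuretype == "exon":
            exons.setdefault(tid, []).append((feat.start - 1, feat.end))
        elif feat.featuretype == "CDS":
            cds.setdefault(tid, []).append((feat.start - 1, feat.end))
        elif feat.featuretype == "transcript":
            declared.append(tid)

    for tid in declared:
        if tid not in exons:
            warnings.warn(f"transcript {tid} has zero exons; skipped", stacklevel=2)

    models = []
    for tid, ex in exons.items():
        gid, chrom, strand = meta[tid]
        models.append(
            TranscriptModel(
                gene_id=gid,
                transcript_id=tid,
                chrom=chrom,
                strand=strand,
                exons=tuple(sorted(ex)),
                cds_intervals=tuple(sorted(cds[tid])) if tid in cds else None,
            )
        )
    return models


# ---------------------------------------------------------------------------
# Event enumeration


def _overlaps(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _cds_overlap(transcripts: Sequence[TranscriptModel], segment: Interval) -> bool:
    for t in transcripts:
        for c in t.cds_intervals or ():
            if _overlaps(c, segment):
                return True
    return False


def _pair_events(t1: TranscriptModel, t2: TranscriptModel, gene: Sequence[TranscriptModel]):
    """Yield raw event tuples from the ordered comparison of two transcripts.

    Each yielded tuple is (event_type, alt_segment, flank_up, flank_down,
    inclusion_junctions, exclusion_junctions, inclusion_transcripts).
    """
    j1, j2 = set(t1.junctions), set(t2.junctions)
    e1s, e2s = t1.exon_set, t2.exon_set

    # CASSETTE: internal exon of t1 absent from t2, flanks joined in t2.
    for i in range(1, len(t1.exons) - 1):
        exon = t1.exons[i]
        prev, nxt = t1.exons[i - 1], t1.exons[i + 1]
        skip_junc = (prev[1], nxt[0])
        if exon not in e2s and skip_junc in j2:
            inc = frozenset({(prev[1], exon[0]), (exon[1], nxt[0])})
            yield ("CASSETTE", exon, prev, nxt, inc, frozenset({skip_junc}), (t1,))

    # MXE: internal exons with shared flank junction ends, mutually absent and
    # never co-present in any transcript of the gene.
    for i in range(1, len(t1.exons) - 1):
        a = t1.exons[i]
        p1, n1 = t1.exons[i - 1], t1.exons[i + 1]
        for k in range(1, len(t2.exons) - 1):
            b = t2.exons[k]
            p2, n2 = t2.exons[k - 1], t2.exons[k + 1]
            if p1[1] != p2[1] or n1[0] != n2[0]:
                continue
            if _overlaps(a, b) or a in e2s or b in e1s:
                continue
            if any(a in t.exon_set and b in t.exon_set for t in gene):
                continue
            first, second = (a, b) if a[0] < b[0] else (b, a)
            d, acc = p1[1], n1[0]
            inc = frozenset({(d, first[0]), (first[1], acc)})
            exc = frozenset({(d, second[0]), (second[1], acc)})
            inc_t = (t1,) if first == a else (t2,)
            yield ("MXE", first, p1, n1, inc, exc, inc_t)

    # A5SS / A3SS: exon pair sharing one boundary, junction partner shared.
    for i, a in enumerate(t1.exons):
        for k, b in enumerate(t2.exons):
            if a == b:
                continue
            if a[0] == b[0] and i < len(t1.exons) - 1 and k < len(t2.exons) - 1:
                # variable right boundary; downstream acceptor must be shared
                c1, c2 = t1.exons[i + 1][0], t2.exons[k + 1][0]
                if c1 != c2:
                    continue
                short, long_ = (a, b) if a[1] < b[1] else (b, a)
                seg = (short[1], long_[1])
                etype = "A5SS" if t1.strand == "+" else "A3SS"
                inc = frozenset({(long_[1], c1)})
                exc = frozenset({(short[1], c1)})
                inc_t = (t1,) if long_ == a else (t2,)
                yield (etype, seg, long_, (c1, c1 + 1), inc, exc, inc_t)
            elif a[1] == b[1] and i > 0 and k > 0:
                # variable left boundary; upstream donor must be shared
                d1, d2 = t1.exons[i - 1][1], t2.exons[k - 1][1]
                if d1 != d2:
                    continue
                short, long_ = (a, b) if a[0] > b[0] else (b, a)
                seg = (long_[0], short[0])
                etype = "A3SS" if t1.strand == "+" else "A5SS"
                inc = frozenset({(d1, long_[0])})
                exc = frozenset({(d1, short[0])})
                inc_t = (t1,) if long_ == a else (t2,)
                yield (etype, seg, (d1 - 1, d1), long_, inc, exc, inc_t)

    # RI: junction of t1 covered by a single t2 exon with matching boundaries.
    for i in range(len(t1.exons) - 1):
        up, down = t1.exons[i], t1.exons[i + 1]
        merged = (up[0], down[1])
        for b in t2.exons:
            if b[0] <= up[0] and down[1] <= b[1] and _overlaps(b, (up[1], down[0])):
                seg = (up[1], down[0])
                yield ("RI", seg, up, down, frozenset(), frozenset({(up[1], down[0])}), (t2,))
                break


def enumerate_events(transcripts: Iterable[TranscriptModel]) -> list[SpliceEvent]:
    """Enumerate deduplicated splice events from all transcript pairs per gene.

    The deduplication key is (event_type, chrom, strand, alt_segment,
    exclusion_junctions); identical events found in several transcript pairs
    are merged (``in_cds`` is OR-ed over the inclusion-form transcripts).
    Output order is deterministic and independent of input order.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)

    found: dict[tuple, dict] = {}
    for gid in sorted(by_gene):
        gene = sorted(by_gene[gid], key=lambda t: t.transcript_id)
        for t1 in gene:
            for t2 in gene:
                if t1 is t2:
                    continue
                for etype, seg, fu, fd, inc, exc, inc_ts in _pair_events(t1, t2, gene):
                    key = (etype, t1.chrom, t1.strand, seg, exc)
                    rec = found.setdefault(
                        key,
                        {
                            "gene_id": gid,
                            "flank_upstream": fu,
                            "flank_downstream": fd,
                            "inclusion_junctions": inc,
                            "in_cds": False,
                        },
                    )
                    rec["in_cds"] = rec["in_cds"] or _cds_overlap(inc_ts, seg)

    events = []
    for n, (key, rec) in enumerate(
        sorted(found.items(), key=lambda kv: (kv[0][1], kv[0][3], kv[0][0], sorted(kv[0][4]))),
        start=1,
    ):
        etype, chrom, strand, seg, exc = key
        events.append(
            SpliceEvent(
                event_id=f"{rec['gene_id']}:{etype}:{chrom}:{seg[0]}-{seg[1]}",
                event_type=etype,
                gene_id=rec["gene_id"],
                chrom=chrom,
                strand=strand,
                alt_segment=seg,
                flank_upstream=rec["flank_upstream"],
                flank_downstream=rec["flank_downstream"],
                inclusion_junctions=rec["inclusion_junctions"],
                exclusion_junctions=exc,
                in_cds=rec["in_cds"],
            )
        )
    return events


# ---------------------------------------------------------------------------
# Sequences and I/O


def event_sequences(events: Iterable[SpliceEvent], genome_fasta) -> dict[str, str]:
    """Return the alternative-segment sequence per event (mRNA sense strand).

    Minus-strand segments are reverse-complemented. Raises ``KeyError`` for a
    missing chromosome and ``ValueError`` for a segment beyond the contig end.
    """
    fa = genome_fasta if isinstance(genome_fasta, Fasta) else Fasta(str(genome_fasta))
    out = {}
    for ev in events:
        if ev.chrom not in fa:
            raise KeyError(f"chromosome {ev.chrom!r} absent from FASTA")
        contig_len = len(fa[ev.chrom])
        start, end = ev.alt_segment
        if end > contig_len:
            raise ValueError(
                f"segment ({start}, {end}) of event {ev.event_id} beyond end of "
                f"{ev.chrom} (length {contig_len})"
            )
        seq = str(fa[ev.chrom][start:end]).upper()
        if ev.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        out[ev.event_id] = seq
    return out


def _fmt_junctions(juncs: frozenset[Junction]) -> str:
    return ";".join(f"{d}-{a}" for d, a in sorted(juncs))


def _parse_junctions(text: str) -> frozenset[Junction]:
    if not text or text == ".":
        return frozenset()
    return frozenset(tuple(int(x) for x in item.split("-")) for item in text.split(";"))


def write_catalog(events: Sequence[SpliceEvent], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "event_id\ttype\tgene_id\tchrom\tstrand\talt_start\talt_end\t"
            "alt_length\tin_cds\tinclusion_junctions\texclusion_junctions\n"
        )
        for ev in events:
            fh.write(
                f"{ev.event_id}\t{ev.event_type}\t{ev.gene_id}\t{ev.chrom}\t{ev.strand}\t"
                f"{ev.alt_segment[0]}\t{ev.alt_segment[1]}\t{ev.alt_length}\t"
                f"{int(ev.in_cds)}\t{_fmt_junctions(ev.inclusion_junctions) or '.'}\t"
                f"{_fmt_junctions(ev.exclusion_junctions) or '.'}\n"
            )


def read_catalog(path) -> list[SpliceEvent]:
    events = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            f = line.rstrip("\n").split("\t")
            seg = (int(f[5]), int(f[6]))
            events.append(
                SpliceEvent(
                    event_id=f[0],
                    event_type=f[1],
                    gene_id=f[2],
                    chrom=f[3],
                    strand=f[4],
                    alt_segment=seg,
                    flank_upstream=(max(0, seg[0] - 1), seg[0]),
                    flank_downstream=(seg[1], seg[1] + 1),
                    inclusion_junctions=_parse_junctions(f[9]),
                    exclusion_junctions=_parse_junctions(f[10]),
                    in_cds=bool(int(f[8])),
                )
            )
    return events


def summarize_event_categories(events_or_counts) -> "pd.Series":
    """Tally events per category (plus a ``total`` row).

    Accepts an iterable of :class:`SpliceEvent` or a precomputed mapping
    ``category -> count`` (e.g. a published table read from TSV).
    """
    import pandas as pd

    if isinstance(events_or_counts, Mapping):
        counts = {k: int(v) for k, v in events_or_counts.items()}
    else:
        counts = {t: 0 for t in EVENT_TYPES}
        for ev in events_or_counts:
            counts[ev.event_type] = counts.get(ev.event_type, 0) + 1
    ser = pd.Series(counts, dtype=int)
    ser.loc["total"] = int(ser.sum())
    return ser
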