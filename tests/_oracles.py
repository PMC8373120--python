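"""Independent brute-force oracles used to cross-check the library.

Everything here is written definitionally and shares no code with the
implementation paths it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


# ---------------------------------------------------------------------------
# Splice-event enumeration oracle: test every exon/junction pattern directly.


def brute_force_events(transcripts):
    """Definitional event set from a collection of TranscriptModel.

    Returns a set of (event_type, alt_segment, inclusion_junctions,
    exclusion_junctions) tuples with frozenset junction sets.
    """
    by_gene = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    found = set()
    for gene in by_gene.values():
        for t1 in gene:
            for t2 in gene:
                if t1 is t2:
                    continue
                j1 = set(zip([e[1] for e in t1.exons[:-1]], [e[0] for e in t1.exons[1:]]))
                j2 = set(zip([e[1] for e in t2.exons[:-1]], [e[0] for e in t2.exons[1:]]))
                e1s, e2s = set(t1.exons), set(t2.exons)

                # cassette: triple (a, e, b) spliced a-e-b in t1, a-b in t2
                for a in e1s:
                    for e in e1s:
                        for b in e1s:
                            if (
                                (a[1], e[0]) in j1
                                and (e[1], b[0]) in j1
                                and (a[1], b[0]) in j2
                                and e not in e2s
                            ):
                                found.add((
                                    "CASSETTE", e,
                                    frozenset({(a[1], e[0]), (e[1], b[0])}),
                                    frozenset({(a[1], b[0])}),
                                ))

                # MXE: x spliced d-x-c in t1 and y spliced d-y-c in t2 between
                # the same flanking splice sites, exons exclusive everywhere
                for d in {j[0] for j in j1} & {j[0] for j in j2}:
                    for c in {j[1] for j in j1} & {j[1] for j in j2}:
                        for x in e1s - e2s:
                            for y in e2s - e1s:
                                if not (
                                    (d, x[0]) in j1 and (x[1], c) in j1
                                    and (d, y[0]) in j2 and (y[1], c) in j2
                                ):
                                    continue
                                if x[0] < y[1] and y[0] < x[1]:  # overlap
                                    continue
                                if any(x in set(t.exons) and y in set(t.exons) for t in gene):
                                    continue
                                first, second = (x, y) if x[0] < y[0] else (y, x)
                                found.add((
                                    "MXE", first,
                                    frozenset({(d, first[0]), (first[1], c)}),
                                    frozenset({(d, second[0]), (second[1], c)}),
                                ))

                # alternative donor/acceptor: shared one boundary + shared partner
                for x in e1s:
                    for y in e2s:
                        if x == y:
                            continue
                        if x[0] == y[0]:
                            for c in {j[1] for j in j1 if j[0] == x[1]}:
                                if (y[1], c) in j2:
                                    lo, hi = sorted((x[1], y[1]))
                                    etype = "A5SS" if t1.strand == "+" else "A3SS"
                                    found.add((
                                        etype, (lo, hi),
                                        frozenset({(hi, c)}), frozenset({(lo, c)}),
                                    ))
                        if x[1] == y[1]:
                            for d in {j[0] for j in j1 if j[1] == x[0]}:
                                if (d, y[0]) in j2:
                                    lo, hi = sorted((x[0], y[0]))
                                    etype = "A3SS" if t1.strand == "+" else "A5SS"
                                    found.add((
                                        etype, (lo, hi),
                                        frozenset({(d, lo)}), frozenset({(d, hi)}),
                                    ))

                # retained intron: junction of t1 inside a covering exon of t2
                for (d, a) in j1:
                    flank_up = [e for e in e1s if e[1] == d]
                    flank_dn = [e for e in e1s if e[0] == a]
                    for fu in flank_up:
                        for fd in flank_dn:
                            if any(y[0] <= fu[0] and fd[1] <= y[1] for y in e2s):
                                found.add(("RI", (d, a), frozenset(), frozenset({(d, a)})))
    return found


def random_gene(rng: np.random.Generator, gene_id: str = "g"):
    """Random gene structures (<=6 exon slots, <=4 transcripts) for property tests.

    Builds a pool of exons including boundary variants of some slots, then
    draws transcripts as sorted non-overlapping subsets.
    """
    from spliceprio.events import TranscriptModel

    n_slots = int(rng.integers(3, 7))
    starts = np.cumsum(rng.integers(50, 200, size=n_slots)) + 100
    slots = [(int(s), int(s + rng.integers(30, 120))) for s in starts]
    pool = list(slots)
    for s, e in slots:
        if rng.random() < 0.3:
            pool.append((s, e + int(rng.integers(5, 30))))  # alt right boundary
        if rng.random() < 0.3:
            pool.append((max(0, s - int(rng.integers(5, 30))), e))  # alt left boundary
    strand = "+" if rng.random() < 0.5 else "-"
    transcripts = []
    n_tx = int(rng.integers(1, 5))
    for k in range(n_tx):
        chosen: list[tuple[int, int]] = []
        for ex in sorted(pool, key=lambda iv: (iv[0], iv[1])):
            if rng.random() < 0.6 and all(
                ex[1] <= c[0] or c[1] <= ex[0] for c in chosen
            ):
                chosen.append(ex)
        if len(chosen) >= 2:
            transcripts.append(
                TranscriptModel(
                    gene_id=gene_id,
                    transcript_id=f"{gene_id}.t{k}",
                    chrom="chrR",
                    strand=strand,
                    exons=tuple(sorted(chosen)),
                )
            )
    return transcripts


# ---------------------------------------------------------------------------
# Exact Mann-Whitney by full enumeration


def exact_rank_sum_p(x, y) -> float:
    """Two-sided rank-sum p by enumerating every group assignment (no ties)."""
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1, n2 = len(x), len(y)
    mu = n1 * n2 / 2.0

    def u_stat(group):
        r = sum(ranks[v] for v in group)
        return r - n1 * (n1 + 1) / 2.0

    observed = abs(u_stat(x) - mu)
    total = 0
    extreme = 0
    for combo in combinations(pooled, n1):
        total += 1
        if abs(u_stat(list(combo)) - mu) >= observed - 1e-12:
            extreme += 1
    return extreme / total


# ---------------------------------------------------------------------------
# Definitional log-rank statistic and permutation machinery


def logrank_stat_oracle(times, events, in_a) -> float:
    """Chi-square log-rank statistic from first principles.

    At each distinct event time: observed deaths in group A vs the
    hypergeometric expectation given the risk sets; variance summed the same
    way; statistic = (sum(O-E))^2 / sum(V).
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    in_a = np.asarray(in_a, bool)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        dead = (times == t) & (events == 1)
        n = at_risk.sum()
        n1 = (at_risk & in_a).sum()
        d = dead.sum()
        d1 = (dead & in_a).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return float(o_minus_e**2 / var)


def permutation_logrank_stats(times, events, n_a, n_perm, rng) -> np.ndarray:
    """Log-rank statistics over ``n_perm`` random group relabelings (vectorized)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    n = len(times)
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    labels = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(labels, order[:, :n_a], True, axis=1)
    o_minus_e = np.zeros(n_perm)
    var = np.zeros(n_perm)
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        dead = (times == t) & (events == 1)
        n_t = at_risk.sum()
        d_t = dead.sum()
        n1 = labels[:, at_risk].sum(axis=1)
        d1 = labels[:, dead].sum(axis=1)
        o_minus_e += d1 - d_t * n1 / n_t
        if n_t > 1:
            var += d_t * (n1 / n_t) * (1 - n1 / n_t) * (n_t - d_t) / (n_t - 1)
    stats = np.zeros(n_perm)
    ok = var > 0
    stats[ok] = o_minus_e[ok] ** 2 / var[ok]
    return stats


# ---------------------------------------------------------------------------
# Quadratic substring scan


def quadratic_motif_positions(seq: str, motif: str) -> list[int]:
    return [
        i
        for i in range(len(seq) - len(motif) + 1)
        if seq[i : i + len(motif)] == motif
    ]
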