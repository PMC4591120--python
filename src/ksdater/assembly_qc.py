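"""Assembly summary statistics and the Ortholog Hit Ratio completeness metric.

N50 is the length L such that contigs of length >= L hold at least half the
assembled bases.  The Ortholog Hit Ratio (OHR) of a transcript is the number
of query bases covered by its best protein hit divided by three times the
length of the matched protein; OHR >= 1 marks a full-length transcript.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seq_io import HitRecord, SeqRecord


@dataclasses.dataclass
class LengthStats:
    n_seqs: int
    total_bases: int
    mean_len: float
    n50: int
    at_content: float
    #: ordered (bin_low, bin_high, count); the last bin is open-ended
    #: (bin_high is None).
    histogram: list[tuple[int, int | None, int]]


@dataclasses.dataclass
class OhrRecord:
    qid: str
    sid: str
    hit_bases: int
    protein_len: int
    ohr: float


def n50(lengths: Sequence[int]) -> int:
    """Sort descending, return the first length whose running sum reaches
    half of the total."""
    if not lengths:
        raise ValueError("N50 of an empty length set is undefined")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    half = arr.sum() / 2.0
    idx = int(np.searchsorted(np.cumsum(arr), half))
    return int(arr[idx])


def length_stats(
    records: Sequence[SeqRecord],
    bin_width: int = 100,
    bin_start: int = 200,
    bin_open_end: int = 3000,
) -> LengthStats:
    """Summary length statistics of a nucleotide assembly.

    The length histogram runs from ``bin_start`` in steps of ``bin_width``
    with an open-ended final bin at ``bin_open_end`` (sequences shorter than
    ``bin_start`` land in an initial [0, bin_start) bin so counts always sum
    to the number of sequences).
    """
    if not records:
        raise ValueError("length_stats requires at least one sequence")
    lengths = [len(r) for r in records]
    total = int(sum(lengths))

    a = t = c = g = 0
    for r in records:
        a += r.seq.count("A")
        t += r.seq.count("T")
        c += r.seq.count("C")
        g += r.seq.count("G")
    acgt = a + c + g + t
    at = (a + t) / acgt if acgt else float("nan")

    edges = list(range(bin_start, bin_open_end + 1, bin_width))
    hist: list[tuple[int, int | None, int]] = []
    larr = np.asarray(lengths)
    if bin_start > 0:
        hist.append((0, bin_start, int((larr < bin_start).sum())))
    for lo in edges[:-1]:
        hi = lo + bin_width
        hist.append((lo, hi, int(((larr >= lo) & (larr < hi)).sum())))
    hist.append((edges[-1], None, int((larr >= edges[-1]).sum())))

    return LengthStats(
        n_seqs=len(records),
        total_bases=total,
        mean_len=total / len(records),
        n50=n50(lengths),
        at_content=at,
        histogram=hist,
    )


def coverage_depth(cleaned_read_bases: int, unigene_bases: int) -> float:
    """Sequencing depth: nucleotides in the cleaned reads divided by
    nucleotides in the assembled unigenes."""
    if unigene_bases <= 0:
        raise ValueError("unigene_bases must be positive")
    if cleaned_read_bases <= 0:
        raise ValueError("cleaned_read_bases must be positive")
    return cleaned_read_bases / unigene_bases


def best_hits(hits: Iterable[HitRecord], rule: str = "bitscore") -> dict[str, HitRecord]:
    """Best hit per query: maximum bitscore (default) or minimum E-value;
    ties broken by smaller E-value (resp. larger bitscore), then by
    lexicographically smallest subject id."""
    if rule not in ("bitscore", "evalue"):
        raise ValueError(f"unknown best-hit rule {rule!r}")

    def key(h: HitRecord):
        if rule == "bitscore":
            return (-h.bitscore, h.evalue, h.sid)
        return (h.evalue, -h.bitscore, h.sid)

    best: dict[str, HitRecord] = {}
    for h in hits:
        cur = best.get(h.qid)
        if cur is None or key(h) < key(cur):
            best[h.qid] = h
    return best


@dataclasses.dataclass
class OhrSummary:
    n_queries: int
    n_full_length: int          # ohr >= 1
    n_over_75: int              # ohr > 0.75 (cumulative)
    n_over_50: int              # ohr > 0.5 (cumulative)
    #: disjoint bins of width 0.1: [(low, high, count)], last bin open (>= 1.0)
    bins: list[tuple[float, float | None, int]]


def ortholog_hit_ratio(
    best: Mapping[str, HitRecord],
    protein_lengths: Mapping[str, int],
) -> tuple[list[OhrRecord], OhrSummary]:
    """OHR per query from its best protein hit, plus coverage-class summary.

    The numerator is the query-side nucleotide span of the hit
    (|qend - qstart| + 1); the denominator is 3x the matched protein length.
    """
    records: list[OhrRecord] = []
    for qid in sorted(best):
        hit = best[qid]
        if hit.sid not in protein_lengths:
            raise KeyError(f"no protein length for subject id {hit.sid!r}")
        plen = protein_lengths[hit.sid]
        if plen <= 0:
            raise ValueError(f"non-positive protein length for {hit.sid!r}")
        hb = hit.query_hit_bases
        records.append(
            OhrRecord(qid=qid, sid=hit.sid, hit_bases=hb, protein_len=plen,
                      ohr=hb / (3 * plen))
        )

    ohrs = np.array([r.ohr for r in records]) if records else np.empty(0)
    bins: list[tuple[float, float | None, int]] = []
    for i in range(10):
        lo, hi = i / 10, (i + 1) / 10
        bins.append((lo, hi, int(((ohrs >= lo) & (ohrs < hi)).sum())))
    bins.append((1.0, None, int((ohrs >= 1.0).sum())))

    summary = OhrSummary(
        n_queries=len(records),
        n_full_length=int((ohrs >= 1.0).sum()),
        n_over_75=int((ohrs > 0.75).sum()),
        n_over_50=int((ohrs > 0.5).sum()),
        bins=bins,
    )
    return records, summary


def clean_reads(reads, min_q: int = 20, max_low_q_frac: float = 0.10):
    """Minimal read filter: drop reads containing any N, or with more than
    ``max_low_q_frac`` of bases below quality ``min_q``.

    ``reads`` yields (sequence, phred_scores) pairs; returns the surviving
    pairs.  Utility only — raw-read cleaning is upstream of this package's
    main path.
    """
    kept = []
    for seq, quals in reads:
        if "N" in seq.upper():
            continue
        if len(quals) and sum(1 for q in quals if q < min_q) / len(quals) > max_low_q_frac:
            continue
        kept.append((seq, quals))
    return kept
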