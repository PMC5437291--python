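"""Collapse aligned, UMI-tagged reads into unique DSB events.

A DSB end is identified by (genomic location, strand, UMI). Sequencing and
amplification scatter the reads from one break over nearby positions and
near-identical UMIs, so collapsing happens in two stages:

1. *Neighbourhood clustering* — per (sample, chrom, strand), reads whose
   5'-end positions are at most ``window`` nt apart (single-linkage chaining)
   form one neighbourhood, whose consensus location is the position of the
   most frequent read (ties: leftmost).
2. *UMI error correction* — within a neighbourhood, UMIs within Hamming
   distance ``umi_max_mismatch`` are merged greedily into the most frequent
   UMI already kept (ties: lexicographically smallest).

The number of distinct corrected UMIs at a location is the number of
independent break events observed there; reads sharing a location and UMI are
PCR duplicates and count once.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

__all__ = [
    "TaggedRead",
    "DsbEvent",
    "LoadStats",
    "load_alignments",
    "cluster_and_dedup",
    "dedup_umis",
    "write_events",
    "read_events",
]


@dataclass(frozen=True)
class TaggedRead:
    """One aligned read: 5'-most base of the alignment (the DSB-proximal
    base), strand, and the UMI carried over from prefix scanning."""

    chrom: str
    pos5: int  # 0-based
    strand: str
    umi: str
    mapq: int = 60
    sample_id: str = "S1"

    def __post_init__(self) -> None:
        if self.pos5 < 0:
            raise ValueError("pos5 must be >= 0")
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass
class DsbEvent:
    """A unique DSB end location with its set of corrected UMIs."""

    chrom: str
    pos: int  # 0-based consensus position of the neighbourhood
    strand: str
    umis: frozenset[str]
    read_support: int
    sample_id: str = "S1"

    @property
    def n_umis(self) -> int:
        return len(self.umis)


@dataclass
class LoadStats:
    retained: int = 0
    dropped_mapq: int = 0
    dropped_blacklist: int = 0
    dropped_no_umi: int = 0


def _parse_umi_from_name(name: str) -> Optional[tuple[str, str]]:
    # read names carry "...UMI:<seq>:BC:<id>" appended by the scanner
    idx = name.find("UMI:")
    if idx < 0:
        return None
    parts = name[idx:].split(":")
    if len(parts) >= 4 and parts[0] == "UMI" and parts[2] == "BC":
        return parts[1], parts[3].split()[0]
    if len(parts) >= 2 and parts[0] == "UMI":
        return parts[1], "S1"
    return None


def _load_blacklist(path):
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 3:
            raise ValueError(f"malformed blacklist line: {line!r}")
        start, end = int(f[1]), int(f[2])
        if end > start:
            trees[f[0]].addi(start, end)
    return trees


def load_alignments(
    path,
    min_mapq: int = 5,
    blacklist=None,
    stats: Optional[LoadStats] = None,
) -> Iterator[TaggedRead]:
    """Stream TaggedReads from a BAM/SAM or 6-column BED file.

    Reads below ``min_mapq``, overlapping a blacklist interval, or lacking a
    UMI tag are dropped (and counted in ``stats`` if given). For BAM/SAM the
    UMI comes from a ``UB``/``RX`` tag or the read-name suffix; pos5 is the
    leftmost aligned base for + alignments and the rightmost for −. For BED,
    the name field holds ``UMI[:BC:<sample>]`` (or the scanner's read-name
    form) and pos5 is start for + / end−1 for −.
    """
    if stats is None:
        stats = LoadStats()
    trees = _load_blacklist(blacklist) if blacklist is not None else None

    def blacklisted(chrom: str, pos: int) -> bool:
        return trees is not None and chrom in trees and bool(trees[chrom].overlap(pos, pos + 1))

    path = Path(path)
    if path.suffix.lower() in (".bam", ".sam", ".cram"):
        import pysam

        mode = "rb" if path.suffix.lower() == ".bam" else "r"
        with pysam.AlignmentFile(str(path), mode, check_sq=False) as bam:
            for aln in bam:
                if aln.is_unmapped:
                    continue
                if aln.mapping_quality < min_mapq:
                    stats.dropped_mapq += 1
                    continue
                umi = None
                sample = "S1"
                for tag in ("UB", "RX"):
                    if aln.has_tag(tag):
                        umi = aln.get_tag(tag)
                        break
                if umi is None:
                    parsed = _parse_umi_from_name(aln.query_name or "")
                    if parsed is not None:
                        umi, sample = parsed
                if umi is None:
                    stats.dropped_no_umi += 1
                    continue
                strand = "-" if aln.is_reverse else "+"
                pos5 = aln.reference_end - 1 if aln.is_reverse else aln.reference_start
                if blacklisted(aln.reference_name, pos5):
                    stats.dropped_blacklist += 1
                    continue
                stats.retained += 1
                yield TaggedRead(aln.reference_name, pos5, strand, umi, aln.mapping_quality, sample)
    else:
        for line in path.read_text().splitlines():
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"BED line needs 6 columns: {line!r}")
            chrom, start, end, name, score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            parsed = _parse_umi_from_name(name)
            if parsed is not None:
                umi, sample = parsed
            elif name and set(name) <= set("ACGTN"):
                umi, sample = name, "S1"
            else:
                stats.dropped_no_umi += 1
                continue
            mapq = int(score) if score not in (".", "") else 60
            if mapq < min_mapq:
                stats.dropped_mapq += 1
                continue
            pos5 = start if strand == "+" else end - 1
            if blacklisted(chrom, pos5):
                stats.dropped_blacklist += 1
                continue
            stats.retained += 1
            yield TaggedRead(chrom, pos5, strand, umi, mapq, sample)


def dedup_umis(umi_counts: Counter, max_mismatch: int = 2) -> dict[str, str]:
    """Greedy frequency-descending UMI merge; returns raw UMI -> representative.

    UMIs are visited in order of descending count (ties lexicographic); each
    merges into the most frequent already-kept UMI within Hamming distance
    ``max_mismatch`` (same length only), else is kept itself. The Hamming
    comparisons against the kept set are vectorised so high-multiplicity
    locations (thousands of UMIs at a recurrent cut site) stay tractable.
    """
    import numpy as np

    order = sorted(umi_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    assign: dict[str, str] = {}
    # kept representatives bucketed by UMI length, in kept (frequency) order
    kept_strs: dict[int, list[str]] = {}
    kept_mats: dict[int, np.ndarray] = {}
    kept_n: dict[int, int] = {}
    for umi, _ in order:
        L = len(umi)
        arr = np.frombuffer(umi.encode(), dtype=np.uint8)
        n = kept_n.get(L, 0)
        rep = None
        if n:
            dists = (kept_mats[L][:n] != arr).sum(axis=1)
            hit = np.nonzero(dists <= max_mismatch)[0]
            if hit.size:
                rep = kept_strs[L][int(hit[0])]
        if rep is None:
            if L not in kept_mats:
                kept_mats[L] = np.empty((16, L), dtype=np.uint8)
                kept_strs[L] = []
                kept_n[L] = 0
            if kept_n[L] == kept_mats[L].shape[0]:
                kept_mats[L] = np.vstack([kept_mats[L], np.empty_like(kept_mats[L])])
            kept_mats[L][kept_n[L]] = arr
            kept_strs[L].append(umi)
            kept_n[L] += 1
            rep = umi
        assign[umi] = rep
    return assign


def cluster_and_dedup(
    reads: Iterable[TaggedRead],
    window: int = 8,
    umi_max_mismatch: int = 2,
) -> list[DsbEvent]:
    """Collapse reads into unique DSB events; see module docstring.

    Output is sorted by (sample, chrom, pos, strand) and independent of the
    input read order.
    """
    groups: dict[tuple[str, str, str], list[TaggedRead]] = defaultdict(list)
    for r in reads:
        groups[(r.sample_id, r.chrom, r.strand)].append(r)

    events: list[DsbEvent] = []
    for (sample, chrom, strand), grp in groups.items():
        grp.sort(key=lambda r: r.pos5)
        # single-linkage chaining: a gap > window between consecutive sorted
        # positions splits neighbourhoods
        start = 0
        for i in range(1, len(grp) + 1):
            if i == len(grp) or grp[i].pos5 - grp[i - 1].pos5 > window:
                hood = grp[start:i]
                start = i
                pos_counts = Counter(r.pos5 for r in hood)
                consensus = min(
                    pos_counts, key=lambda p: (-pos_counts[p], p)
                )  # most frequent, tie -> leftmost
                umi_counts = Counter(r.umi for r in hood)
                assign = dedup_umis(umi_counts, umi_max_mismatch)
                events.append(
                    DsbEvent(
                        chrom=chrom,
                        pos=consensus,
                        strand=strand,
                        umis=frozenset(assign.values()),
                        read_support=len(hood),
                        sample_id=sample,
                    )
                )
    events.sort(key=lambda e: (e.sample_id, e.chrom, e.pos, e.strand))
    return events


def write_events(events: list[DsbEvent], path) -> int:
    """Write events as BED6: name = sample_id, score = number of UMIs,
    half-open [pos, pos+1). Events are written in sorted order."""
    ordered = sorted(events, key=lambda e: (e.chrom, e.pos, e.strand, e.sample_id))
    with open(path, "w") as out:
        for e in ordered:
            out.write(f"{e.chrom}\t{e.pos}\t{e.pos + 1}\t{e.sample_id}\t{e.n_umis}\t{e.strand}\n")
    return len(ordered)


def read_events(path) -> list[DsbEvent]:
    """Read a BED file written by :func:`write_events`.

    The per-location UMI *count* survives a round trip; the UMI strings
    themselves are not stored in BED and are re-materialised as placeholders.
    """
    events = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        chrom, start, _end, name, score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
        n = int(score)
        umis = frozenset(f"umi{i}" for i in range(n))
        events.append(DsbEvent(chrom, start, strand, umis, read_support=n, sample_id=name))
    return events


def write_summary(stats: LoadStats, events: list[DsbEvent], path) -> None:
    total_umis = sum(e.n_umis for e in events)
    lines = [
        "metric\tvalue",
        f"reads_retained\t{stats.retained}",
        f"dropped_mapq\t{stats.dropped_mapq}",
        f"dropped_blacklist\t{stats.dropped_blacklist}",
        f"dropped_no_umi\t{stats.dropped_no_umi}",
        f"events\t{len(events)}",
        f"unique_umis\t{total_umis}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")
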