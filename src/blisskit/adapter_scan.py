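"""Prefix scanning of raw reads: UMI extraction, barcode demultiplexing, quality filtering.

Each raw read is expected to start with an adapter-derived prefix::

    [ UMI (8-12 nt random) ][ sample barcode ][ optional anchor, e.g. HindIII AAGCTT ]

followed by the genomic sequence. The scanner validates the prefix under a
mismatch-only error model (no indels), extracts the UMI verbatim, and trims
the prefix off. UMI mismatch tolerance is *not* applied here: any base call in
the UMI slot is a legal UMI, and error-tolerant UMI collapsing happens later,
at deduplication, where UMIs are compared against each other.

A fixed-UMI audit mode supports libraries built with a known constant UMI in
front of a restriction-site anchor, used to measure the empirical UMI error
rate as a mismatch histogram.
"""

from __future__ import annotations

import gzip
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

__all__ = [
    "AdapterSpec",
    "PrefixMatch",
    "Rejection",
    "ScanStats",
    "UmiMismatchHistogram",
    "FastqRead",
    "read_fastq",
    "write_fastq",
    "scan_read",
    "demultiplex",
    "audit_fixed_umi",
]

_VALID = set("ACGT")

REJECT_REASONS = ("too_short", "low_quality", "barcode_mismatch", "anchor_mismatch")


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"hamming requires equal lengths, got {len(a)} and {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class AdapterSpec:
    """Declared adapter prefix structure for one sample.

    Parameters
    ----------
    barcode : str
        Sample barcode sequence, immediately 3' of the UMI.
    sample_id : str
        Label attached to accepted reads.
    umi_length : int
        Length of the random UMI stretch (default 8).
    barcode_max_mismatch : int
        Mismatches tolerated in the barcode (default 1; indels never allowed).
    umi_max_mismatch : int
        UMI tolerance recorded here but applied only at dedup (default 2).
    anchor : str, optional
        Fixed sequence after the barcode (e.g. a HindIII site AAGCTT for
        sticky-end libraries); checked when present.
    anchor_max_mismatch : int
        Mismatches tolerated in the anchor (default 1).
    min_phred : int
        Minimum per-base Phred score (default 30).
    quality_scope : {"prefix", "read"}
        Whether the Phred rule applies to the prefix region only (default) or
        to every base of the read (strict mode).
    """

    barcode: str
    sample_id: str = "S1"
    umi_length: int = 8
    barcode_max_mismatch: int = 1
    umi_max_mismatch: int = 2
    anchor: Optional[str] = None
    anchor_max_mismatch: int = 1
    min_phred: int = 30
    quality_scope: str = "prefix"

    def __post_init__(self) -> None:
        if self.umi_length < 1:
            raise ValueError("umi_length must be >= 1")
        for name in ("barcode_max_mismatch", "umi_max_mismatch", "anchor_max_mismatch"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.barcode or set(self.barcode) - _VALID:
            raise ValueError(f"barcode must be non-empty ACGT, got {self.barcode!r}")
        if self.anchor is not None and (not self.anchor or set(self.anchor) - _VALID):
            raise ValueError(f"anchor must be non-empty ACGT, got {self.anchor!r}")
        if self.quality_scope not in ("prefix", "read"):
            raise ValueError("quality_scope must be 'prefix' or 'read'")

    @property
    def prefix_length(self) -> int:
        return self.umi_length + len(self.barcode) + (len(self.anchor) if self.anchor else 0)


@dataclass(frozen=True)
class PrefixMatch:
    """Successful prefix scan: extracted fields plus the trimmed read."""

    umi: str
    barcode_id: str
    trimmed_sequence: str
    trimmed_qualities: tuple[int, ...]


@dataclass(frozen=True)
class Rejection:
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in REJECT_REASONS:
            raise ValueError(f"unknown reject reason {self.reason!r}")


@dataclass
class ScanStats:
    """Accepted/rejected-by-reason accounting for one sample or stream."""

    accepted: int = 0
    rejected: Counter = field(default_factory=Counter)

    @property
    def total(self) -> int:
        return self.accepted + sum(self.rejected.values())

    def to_dict(self) -> dict:
        return {"accepted": self.accepted, "rejected": dict(self.rejected), "total": self.total}


@dataclass
class UmiMismatchHistogram:
    """Distribution of mismatch counts against a fixed UMI."""

    counts: dict[int, int]
    total_screened: int

    def fraction(self, k: int) -> float:
        if self.total_screened == 0:
            raise ValueError("empty histogram")
        return self.counts.get(k, 0) / self.total_screened


@dataclass(frozen=True)
class FastqRead:
    name: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence/quality length mismatch")


def read_fastq(path) -> Iterator[FastqRead]:
    """Stream a FASTQ file (gzip-transparent) as FastqRead records."""
    import pysam

    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            quals = tuple(rec.get_quality_array()) if rec.quality is not None else ()
            yield FastqRead(rec.name, rec.sequence, quals)


def write_fastq(reads: Iterable[FastqRead], path) -> int:
    """Write FASTQ (gzip if the path ends with .gz). Returns records written."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    n = 0
    with opener(path, "wt") as out:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            out.write(f"@{r.name}\n{r.sequence}\n+\n{qual}\n")
            n += 1
    return n


def scan_read(read: FastqRead, spec: AdapterSpec):
    """Scan one read for the adapter prefix.

    Returns a :class:`PrefixMatch` on acceptance or a :class:`Rejection`
    naming the first rule violated (checked in order: length, quality,
    barcode, anchor). The UMI is the first ``umi_length`` bases, taken
    verbatim.
    """
    plen = spec.prefix_length
    if len(read.sequence) < plen + 1:
        return Rejection("too_short")

    qscope = read.qualities if spec.quality_scope == "read" else read.qualities[:plen]
    if any(q < spec.min_phred for q in qscope):
        return Rejection("low_quality")

    umi = read.sequence[: spec.umi_length]
    bc_start = spec.umi_length
    bc_end = bc_start + len(spec.barcode)
    if hamming(read.sequence[bc_start:bc_end], spec.barcode) > spec.barcode_max_mismatch:
        return Rejection("barcode_mismatch")

    if spec.anchor is not None:
        a_end = bc_end + len(spec.anchor)
        if hamming(read.sequence[bc_end:a_end], spec.anchor) > spec.anchor_max_mismatch:
            return Rejection("anchor_mismatch")

    return PrefixMatch(
        umi=umi,
        barcode_id=spec.sample_id,
        trimmed_sequence=read.sequence[plen:],
        trimmed_qualities=read.qualities[plen:],
    )


def _check_barcode_separability(specs: list[AdapterSpec]) -> None:
    for i, a in enumerate(specs):
        for b in specs[i + 1 :]:
            if len(a.barcode) != len(b.barcode):
                continue  # different lengths are trivially distinguishable
            d = hamming(a.barcode, b.barcode)
            need = 2 * max(a.barcode_max_mismatch, b.barcode_max_mismatch)
            if d <= need:
                raise ValueError(
                    f"barcodes {a.barcode!r} ({a.sample_id}) and {b.barcode!r} "
                    f"({b.sample_id}) are ambiguous: Hamming distance {d} <= {need}"
                )


def demultiplex(
    reads: Iterable[FastqRead], specs: list[AdapterSpec]
) -> tuple[dict[str, list[FastqRead]], dict[str, ScanStats]]:
    """Assign each read to at most one sample by barcode match.

    Barcodes must be pairwise separated by more than twice the mismatch
    allowance (checked up front); a read is then rejected or accepted by
    exactly one sample. Trimmed reads carry ``UMI:<seq>:BC:<id>`` appended to
    the read name. Returns (per-sample trimmed reads, per-sample stats); the
    pseudo-sample ``"unassigned"`` collects global rejections.
    """
    if not specs:
        raise ValueError("no adapter specs given")
    ids = [s.sample_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in specs")
    _check_barcode_separability(specs)

    out: dict[str, list[FastqRead]] = {s.sample_id: [] for s in specs}
    stats: dict[str, ScanStats] = {s.sample_id: ScanStats() for s in specs}
    stats["unassigned"] = ScanStats()

    for read in reads:
        results = [(spec, scan_read(read, spec)) for spec in specs]
        hits = [(spec, r) for spec, r in results if isinstance(r, PrefixMatch)]
        if hits:
            spec, match = hits[0]  # separability guarantees uniqueness
            name = read.name.split()[0] + f" UMI:{match.umi}:BC:{match.barcode_id}"
            out[spec.sample_id].append(
                FastqRead(name, match.trimmed_sequence, match.trimmed_qualities)
            )
            stats[spec.sample_id].accepted += 1
        else:
            # prefer the most specific reason: a barcode match that failed later
            reasons = [r.reason for _, r in results]
            for pref in ("anchor_mismatch", "low_quality", "too_short", "barcode_mismatch"):
                if pref in reasons:
                    stats["unassigned"].rejected[pref] += 1
                    break
    return out, stats


def audit_fixed_umi(
    reads: Iterable[FastqRead],
    fixed_umi: str,
    anchor: str,
    anchor_max_mismatch: int = 1,
) -> UmiMismatchHistogram:
    """Mismatch histogram of a known constant UMI placed before an anchor.

    Screens each read for the first occurrence of ``anchor`` (within
    ``anchor_max_mismatch`` mismatches) at an offset of at least
    ``len(fixed_umi)``; the stretch immediately before the anchor is compared
    to the fixed UMI and its mismatch count tallied. Reads with no qualifying
    anchor are not screened.
    """
    if not anchor:
        raise ValueError("anchor must be non-empty")
    k = len(fixed_umi)
    counts: Counter = Counter()
    total = 0
    for read in reads:
        seq = read.sequence
        for i in range(k, len(seq) - len(anchor) + 1):
            if hamming(seq[i : i + len(anchor)], anchor) <= anchor_max_mismatch:
                counts[hamming(seq[i - k : i], fixed_umi)] += 1
                total += 1
                break
    return UmiMismatchHistogram(counts=dict(counts), total_screened=total)


def write_stats(stats: dict[str, ScanStats], tsv_path, json_path=None) -> None:
    """Emit per-sample scan statistics as TSV (and optional JSON log)."""
    lines = ["sample_id\taccepted\t" + "\t".join(REJECT_REASONS)]
    for sid, st in stats.items():
        cells = [sid, str(st.accepted)] + [str(st.rejected.get(r, 0)) for r in REJECT_REASONS]
        lines.append("\t".join(cells))
    Path(tsv_path).write_text("\n".join(lines) + "\n")
    if json_path is not None:
        Path(json_path).write_text(
            json.dumps({sid: st.to_dict() for sid, st in stats.items()}, indent=2) + "\n"
        )
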