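"""Nuclease on/off-target calling from DSB events.

Candidate cleavage loci are DSB clusters (paired plus/minus ends) ranked by
unique-UMI support. Around each cluster center the best local match to the
guide is sought at every PAM occurrence on either strand, scored by a guide
homology score: global alignment of the 20-nt spacer against the genomic
protospacer with match +3, mismatch −1 and gap −5 (maximum 60; a legacy mode
additionally credits matched PAM bases, maximum 69 for a 3-nt PAM). Clusters
whose best score reaches the cutoff (default 41, i.e. up to 4 mismatches or
2 gaps) are called as nuclease targets and ranked by normalised DSB signal.

Also provides cut-overhang profiling (the signed offset between minus- and
plus-strand DSB ends at a cut), exhaustive enumeration of perfect-PAM
mismatch sites in a genome (a desk-scale stand-in for genome-wide off-target
site prediction), and ROC analysis of the score cutoff.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from blisskit.umi_dedup import DsbEvent

__all__ = [
    "ScoringScheme",
    "GuideTarget",
    "DsbCluster",
    "GuideMatch",
    "OfftargetHit",
    "rank_clusters",
    "score_alignment",
    "find_best_guide_match",
    "call_offtargets",
    "overhang_histogram",
    "enumerate_mismatch_sites",
    "roc_cutoff",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMP = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def iupac_match(base: str, code: str) -> bool:
    return base in IUPAC.get(code, "")


@dataclass(frozen=True)
class ScoringScheme:
    """Guide homology weights: +3 match, −1 mismatch, −5 gap."""

    match: int = 3
    mismatch: int = -1
    gap: int = -5
    include_pam_in_score: bool = False

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch > self.gap):
            raise ValueError("weights must satisfy match > 0 > mismatch > gap")


@dataclass(frozen=True)
class GuideTarget:
    """A nuclease guide: 20-nt spacer, PAM patterns and PAM side.

    SpCas9: 3' PAM, patterns {NGG, NAG}. Cpf1 (AsCpf1/LbCpf1): 5' PAM,
    canonically TTTN; for maximum calling sensitivity the all-PAMs mode
    (pattern NNNN) admits a candidate protospacer at every offset.
    """

    name: str
    spacer: str
    pam_patterns: frozenset[str] = frozenset({"NGG", "NAG"})
    pam_side: str = "3prime"

    def __post_init__(self) -> None:
        if len(self.spacer) != 20:
            raise ValueError(f"spacer must be 20 nt, got {len(self.spacer)}")
        if set(self.spacer) - set("ACGT"):
            raise ValueError("spacer must be ACGT only")
        if self.pam_side not in ("3prime", "5prime"):
            raise ValueError("pam_side must be '3prime' or '5prime'")
        if not self.pam_patterns:
            raise ValueError("need at least one PAM pattern")
        lens = {len(p) for p in self.pam_patterns}
        if len(lens) != 1:
            raise ValueError("all PAM patterns must share one length")

    @property
    def pam_length(self) -> int:
        return len(next(iter(self.pam_patterns)))


@dataclass
class DsbCluster:
    """Paired plus/minus DSB events forming one candidate cleavage locus."""

    chrom: str
    center: int
    total_umis: int
    events: list[DsbEvent] = field(default_factory=list)

    @property
    def start(self) -> int:
        return min(e.pos for e in self.events)

    @property
    def end(self) -> int:
        return max(e.pos for e in self.events) + 1


@dataclass
class GuideMatch:
    """Best local guide alignment at a candidate locus."""

    score: int
    chrom: str
    protospacer_start: int  # genomic, 0-based, leftmost base of matched segment
    protospacer_end: int
    strand: str
    aligned_spacer: str
    aligned_genomic: str
    pam: str
    pam_pattern: str
    mismatches: int
    gaps: int


@dataclass
class OfftargetHit:
    cluster: DsbCluster
    match: GuideMatch
    signal: float  # unique DSB ends per 1e5 unique library ends

    def to_row(self) -> dict:
        m = self.match
        return {
            "chrom": self.cluster.chrom,
            "cluster_center": self.cluster.center,
            "cluster_umis": self.cluster.total_umis,
            "signal_per_1e5": self.signal,
            "score": m.score,
            "strand": m.strand,
            "protospacer_start": m.protospacer_start,
            "protospacer_end": m.protospacer_end,
            "aligned_spacer": m.aligned_spacer,
            "aligned_genomic": m.aligned_genomic,
            "pam": m.pam,
            "mismatches": m.mismatches,
            "gaps": m.gaps,
        }


def rank_clusters(
    events: Sequence[DsbEvent], top_n: int = 5000, pairing_window: int = 8
) -> list[DsbCluster]:
    """Pair plus/minus events within ``pairing_window`` nt (single-linkage,
    per chromosome, across strands) into clusters, ranked by total unique
    UMIs descending (ties: genomic order). Returns at most ``top_n``."""
    by_chrom: dict[str, list[DsbEvent]] = defaultdict(list)
    for e in events:
        by_chrom[e.chrom].append(e)

    clusters: list[DsbCluster] = []
    for chrom in sorted(by_chrom):
        evs = sorted(by_chrom[chrom], key=lambda e: (e.pos, e.strand))
        start = 0
        for i in range(1, len(evs) + 1):
            if i == len(evs) or evs[i].pos - evs[i - 1].pos > pairing_window:
                members = evs[start:i]
                start = i
                total = sum(e.n_umis for e in members)
                center = int(sum(e.pos * e.n_umis for e in members) // total)
                clusters.append(DsbCluster(chrom, center, total, members))
    clusters.sort(key=lambda c: (-c.total_umis, c.chrom, c.center))
    return clusters[:top_n]


def _aligner(scheme: ScoringScheme):
    from Bio import Align

    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = scheme.match
    a.mismatch_score = scheme.mismatch
    a.open_gap_score = scheme.gap
    a.extend_gap_score = scheme.gap
    # unaligned genomic flanks are free: the spacer must be fully aligned but
    # may sit anywhere inside the candidate genomic segment
    try:
        a.end_insertion_score = 0
    except AttributeError:  # older attribute name
        a.target_end_gap_score = 0
    return a


def _align_full(spacer: str, genomic_window: str, scheme: ScoringScheme):
    """Returns (score, aligned_spacer, aligned_genomic, genomic_offset):
    rows trimmed of free genomic flanks; genomic_offset = genomic bases
    preceding the first aligned column."""
    aligner = _aligner(scheme)
    alns = aligner.align(spacer, genomic_window)
    aln = alns[0]
    score = int(round(alns.score))
    sp_row, gn_row = str(aln[0]), str(aln[1])
    # columns where the spacer row is an end gap are free genomic flank
    left = 0
    while left < len(sp_row) and sp_row[left] == "-":
        left += 1
    right = len(sp_row)
    while right > left and sp_row[right - 1] == "-":
        right -= 1
    g_off = sum(1 for ch in gn_row[:left] if ch != "-")
    return score, sp_row[left:right], gn_row[left:right], g_off


def score_alignment(
    spacer: str, genomic_window: str, scheme: ScoringScheme = ScoringScheme()
) -> tuple[int, tuple[str, str]]:
    """Guide homology score of a spacer against a genomic segment.

    Global alignment of the full spacer; unaligned genomic flanking bases are
    free, internal gaps on either side cost the gap weight. Returns
    (score, (aligned_spacer, aligned_genomic)) with gaps shown as ``-`` and
    unaligned genomic flanks trimmed.
    """
    if not spacer:
        raise ValueError("empty spacer")
    if not genomic_window:
        raise ValueError("empty genomic window")
    score, al_sp, al_gn, _ = _align_full(spacer, genomic_window, scheme)
    return score, (al_sp, al_gn)


def _alignment_stats(aligned_spacer: str, aligned_genomic: str) -> tuple[int, int]:
    mism = sum(
        1 for a, b in zip(aligned_spacer, aligned_genomic) if a != "-" and b != "-" and a != b
    )
    gaps = sum(1 for a, b in zip(aligned_spacer, aligned_genomic) if a == "-" or b == "-")
    return mism, gaps


def _pam_occurrences(seq: str, patterns: Iterable[str]) -> list[tuple[int, str]]:
    out = []
    for pat in patterns:
        L = len(pat)
        for i in range(len(seq) - L + 1):
            if all(iupac_match(seq[i + j], pat[j]) for j in range(L)):
                out.append((i, pat))
    return out


def find_best_guide_match(
    center: int,
    chrom: str,
    genome: dict[str, str],
    guide: GuideTarget,
    flank: int = 50,
    scheme: ScoringScheme = ScoringScheme(),
    gap_slack: int = 3,
) -> Optional[GuideMatch]:
    """Best-scoring guide match within ``center +- flank`` on either strand.

    Every PAM occurrence (per pattern and strand) proposes a candidate
    protospacer segment of 20 nt anchored at the PAM, extended ``gap_slack``
    nt away from the PAM so gapped alignments can be found. Ties go to the
    candidate closest to the center, then genomic order, then + strand.
    Returns None when no PAM occurs in the window (distinct from a low
    score).
    """
    seq = genome[chrom].upper()
    win_start = max(0, center - flank)
    win_end = min(len(seq), center + flank + 1)
    window = seq[win_start:win_end]
    if not window:
        return None
    L = len(guide.spacer)
    pam_len = guide.pam_length

    candidates: list[tuple[tuple, GuideMatch]] = []
    for strand in "+-":
        s = window if strand == "+" else revcomp(window)
        for pam_i, pat in _pam_occurrences(s, guide.pam_patterns):
            if guide.pam_side == "3prime":
                seg_end = pam_i
                seg_start = max(0, seg_end - L - gap_slack)
            else:
                seg_start = pam_i + pam_len
                seg_end = min(len(s), seg_start + L + gap_slack)
            if seg_end - seg_start < L - 2 * abs(scheme.gap):  # hopeless stubs
                continue
            segment = s[seg_start:seg_end]
            if not segment:
                continue
            score, al_sp, al_gn, g_off = _align_full(guide.spacer, segment, scheme)
            pam_seq = s[pam_i : pam_i + pam_len]
            if scheme.include_pam_in_score:
                score += scheme.match * sum(
                    iupac_match(b, c) for b, c in zip(pam_seq, pat)
                )
            # genomic coordinates of the matched segment
            used = len(al_gn.replace("-", ""))
            local_start = seg_start + g_off
            local_end = local_start + used
            if strand == "+":
                g_start = win_start + local_start
                g_end = win_start + local_end
            else:
                g_start = win_start + (len(window) - local_end)
                g_end = win_start + (len(window) - local_start)
            mism, gaps = _alignment_stats(al_sp, al_gn)
            mid = (g_start + g_end) // 2
            match = GuideMatch(
                score=score,
                chrom=chrom,
                protospacer_start=g_start,
                protospacer_end=g_end,
                strand=strand,
                aligned_spacer=al_sp,
                aligned_genomic=al_gn,
                pam=pam_seq,
                pam_pattern=pat,
                mismatches=mism,
                gaps=gaps,
            )
            candidates.append(((-score, abs(mid - center), g_start, strand), match))
    if not candidates:
        return None
    candidates.sort(key=lambda c: c[0])
    return candidates[0][1]


def call_offtargets(
    clusters: Sequence[DsbCluster],
    genome: dict[str, str],
    guide: GuideTarget,
    cutoff: int = 41,
    flank: int = 50,
    scheme: ScoringScheme = ScoringScheme(),
    total_library_ends: Optional[int] = None,
) -> list[OfftargetHit]:
    """Score each cluster's best guide match; keep those at or above the
    cutoff, annotate with signal per 1e5 unique library ends, sort by signal
    descending (ties: genomic order)."""
    if total_library_ends is None:
        total_library_ends = sum(c.total_umis for c in clusters)
    hits = []
    for cluster in clusters:
        match = find_best_guide_match(
            cluster.center, cluster.chrom, genome, guide, flank=flank, scheme=scheme
        )
        if match is None or match.score < cutoff:
            continue
        signal = 1e5 * cluster.total_umis / total_library_ends if total_library_ends else 0.0
        hits.append(OfftargetHit(cluster, match, signal))
    hits.sort(key=lambda h: (-h.signal, h.cluster.chrom, h.cluster.center))
    return hits


def overhang_histogram(
    events: Sequence[DsbEvent],
    center: int,
    pairing_window: int = 25,
    mode: str = "pairs",
) -> Counter:
    """Distribution of (minus-strand end − plus-strand end) offsets at a cut.

    ``mode="pairs"``: every plus/minus position pair within the window
    contributes, weighted by the product of UMI counts. ``mode="modal"``:
    a single difference between the modal minus and modal plus positions.
    An empty Counter (with a warning) results when either strand is absent.
    """
    import warnings

    plus = Counter()
    minus = Counter()
    for e in events:
        if abs(e.pos - center) <= pairing_window:
            (plus if e.strand == "+" else minus)[e.pos] += e.n_umis
    if not plus or not minus:
        warnings.warn("overhang histogram: one strand absent near the cut site")
        return Counter()
    hist: Counter = Counter()
    if mode == "modal":
        p = min(plus, key=lambda x: (-plus[x], x))
        m = min(minus, key=lambda x: (-minus[x], x))
        hist[m - p] = 1
    elif mode == "pairs":
        for p, wp in plus.items():
            for m, wm in minus.items():
                hist[m - p] += wp * wm
    else:
        raise ValueError("mode must be 'pairs' or 'modal'")
    return hist


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.uint8)
    for base, code in _BASE_CODE.items():
        out[arr == ord(base)] = code
    return out


def _pam_mask(enc: np.ndarray, pattern: str, offset: int, n: int) -> np.ndarray:
    """Boolean mask over protospacer start indices 0..n-1 for a perfect PAM
    match at ``offset`` relative to the protospacer start."""
    mask = np.ones(n, dtype=bool)
    for j, code in enumerate(pattern):
        allowed = np.array([_BASE_CODE[b] for b in IUPAC[code]], dtype=np.uint8)
        col = enc[offset + j : offset + j + n]
        mask &= np.isin(col, allowed)
    return mask


def enumerate_mismatch_sites(
    genome: dict[str, str],
    guide: GuideTarget,
    max_mismatches: int = 1,
) -> pd.DataFrame:
    """Exhaustively enumerate genomic sites with a perfect PAM and at most
    ``max_mismatches`` (0 or 1) mismatches to the spacer, on both strands.

    Returns a DataFrame with columns (chrom, start, end, strand, mismatches,
    mismatch_position); ``mismatch_position`` is 1..20 counted from the
    PAM-proximal spacer base (0 for perfect sites). Coordinates are the
    protospacer interval on the forward strand, 0-based half-open.
    """
    if max_mismatches not in (0, 1):
        raise ValueError("max_mismatches must be 0 or 1")
    spacer_enc = _encode(guide.spacer)
    L = len(guide.spacer)
    pam_len = guide.pam_length
    rows = []
    for chrom, seq in genome.items():
        for strand in "+-":
            s = seq.upper() if strand == "+" else revcomp(seq.upper())
            enc = _encode(s)
            total = len(enc) - L - pam_len + 1
            if total <= 0:
                continue
            if guide.pam_side == "3prime":
                proto_off, pam_off = 0, L
            else:
                proto_off, pam_off = pam_len, 0
            # window start index i: site occupies [i, i + L + pam_len)
            mm = np.zeros(total, dtype=np.int16)
            for j in range(L):
                col = enc[proto_off + j : proto_off + j + total]
                mm += (col != spacer_enc[j]) | (col == 4)
            pam_ok = np.zeros(total, dtype=bool)
            for pat in guide.pam_patterns:
                pam_ok |= _pam_mask(enc, pat, pam_off, total)
            hit_idx = np.nonzero(pam_ok & (mm <= max_mismatches))[0]
            for i in hit_idx:
                nmm = int(mm[i])
                if nmm == 0:
                    mpos = 0
                else:
                    for j in range(L):
                        if enc[proto_off + i + j] != spacer_enc[j]:
                            # PAM-proximal = 1: 3' PAM counts from spacer 3'
                            mpos = (L - j) if guide.pam_side == "3prime" else (j + 1)
                            break
                p_start = int(i) + proto_off
                if strand == "+":
                    start, end = p_start, p_start + L
                else:
                    start = len(seq) - (p_start + L)
                    end = len(seq) - p_start
                rows.append(
                    {
                        "chrom": chrom,
                        "start": start,
                        "end": end,
                        "strand": strand,
                        "mismatches": nmm,
                        "mismatch_position": mpos,
                    }
                )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "mismatches", "mismatch_position"]
    )


def roc_cutoff(scores: Sequence[float], labels: Sequence[int]) -> dict:
    """ROC analysis of the homology-score cutoff.

    ``labels``: 1 = validated target, 0 = not. Returns fpr/tpr/threshold
    arrays, AUC, and the Youden-optimal cutoff (max tpr − fpr; ties go to
    the higher threshold, i.e. the more specific cutoff).
    """
    from sklearn.metrics import auc, roc_curve

    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(set(labels.tolist())) < 2:
        raise ValueError("need both validated and non-validated examples")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    j = tpr - fpr
    best = int(np.argmax(j))  # roc_curve thresholds descend: first max = highest cutoff
    return {
        "fpr": fpr,
        "tpr": tpr,
        "thresholds": thresholds,
        "auc": float(auc(fpr, tpr)),
        "optimal_cutoff": float(thresholds[best]),
        "youden_j": float(j[best]),
    }
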