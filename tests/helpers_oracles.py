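"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results with naive algorithms (pairwise
adjacency + BFS components, all-offsets scanning, per-read re-checking)
rather than calling the library's optimised paths.
"""

from __future__ import annotations

from collections import Counter, defaultdict


def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


def scan_oracle(seq: str, quals, spec) -> str:
    """Re-check one read against the adapter rules; returns 'accepted' or a
    reject reason. Independent of blisskit.adapter_scan.scan_read."""
    plen = spec.umi_length + len(spec.barcode) + (len(spec.anchor) if spec.anchor else 0)
    if len(seq) < plen + 1:
        return "too_short"
    scope = quals if spec.quality_scope == "read" else quals[:plen]
    for q in scope:
        if q < spec.min_phred:
            return "low_quality"
    bc = seq[spec.umi_length : spec.umi_length + len(spec.barcode)]
    if hamming(bc, spec.barcode) > spec.barcode_max_mismatch:
        return "barcode_mismatch"
    if spec.anchor:
        a0 = spec.umi_length + len(spec.barcode)
        if hamming(seq[a0 : a0 + len(spec.anchor)], spec.anchor) > spec.anchor_max_mismatch:
            return "anchor_mismatch"
    return "accepted"


def dedup_oracle(reads, window: int = 8, umi_mm: int = 2):
    """O(n^2) clustering + UMI merge; returns a set of event tuples
    (sample, chrom, pos, strand, frozenset(umis), read_support)."""
    groups = defaultdict(list)
    for r in reads:
        groups[(r.sample_id, r.chrom, r.strand)].append(r)

    events = set()
    for (sample, chrom, strand), grp in groups.items():
        n = len(grp)
        adj = [[] for _ in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                if abs(grp[i].pos5 - grp[j].pos5) <= window:
                    adj[i].append(j)
                    adj[j].append(i)
        seen = [False] * n
        for s in range(n):
            if seen[s]:
                continue
            comp, stack = [], [s]
            seen[s] = True
            while stack:
                u = stack.pop()
                comp.append(u)
                for v in adj[u]:
                    if not seen[v]:
                        seen[v] = True
                        stack.append(v)
            members = [grp[i] for i in comp]
            pos_counts = Counter(r.pos5 for r in members)
            best_count = max(pos_counts.values())
            pos = min(p for p, c in pos_counts.items() if c == best_count)
            umi_counts = Counter(r.umi for r in members)
            order = sorted(umi_counts, key=lambda u: (-umi_counts[u], u))
            kept = []
            for u in order:
                target = None
                for k in kept:
                    if len(k) == len(u) and hamming(k, u) <= umi_mm:
                        target = k
                        break
                if target is None:
                    kept.append(u)
            events.add((sample, chrom, pos, strand, frozenset(kept), len(members)))
    return events


def events_as_set(events):
    return {
        (e.sample_id, e.chrom, e.pos, e.strand, e.umis, e.read_support) for e in events
    }


def best_match_oracle(spacer: str, window: str, pam_patterns, pam_side: str):
    """Exhaustive gapless scan: best Hamming score (3*match - mismatch) over
    every offset and strand whose PAM matches. Returns (score, strand, local
    protospacer start in window coordinates) or None."""
    from blisskit.crispr_offtarget import iupac_match, revcomp

    L = len(spacer)
    best = None
    for strand in "+-":
        s = window if strand == "+" else revcomp(window)
        for pat in pam_patterns:
            P = len(pat)
            for i in range(len(s) - P + 1):
                if not all(iupac_match(s[i + k], pat[k]) for k in range(P)):
                    continue
                if pam_side == "3prime":
                    a, b = i - L, i
                else:
                    a, b = i + P, i + P + L
                if a < 0 or b > len(s):
                    continue
                proto = s[a:b]
                m = sum(x == y for x, y in zip(spacer, proto))
                score = 3 * m - (L - m)
                if best is None or score > best[0]:
                    best = (score, strand, a)
    return best
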