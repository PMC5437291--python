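"""Downstream quantitative analyses of unique DSB events.

Covers: rarefaction/saturation estimation of DSBs per cell, UMI-threshold
sweeps comparing treated vs control samples (recurrent-break quantification),
TSS-proximal and gene-body enrichment stratified by expression, telomeric
C-rich strand read screening, and binned accessibility-vs-DSB comparison.

Unique DSB ends are (location, strand, UMI) triples: a location with ``n``
distinct UMIs contributes ``n`` ends. Saturation of unique ends with
sequencing depth ``r`` follows the hyperbolic model

    DSB(r) = DSB_max * r / (k + r)

where ``DSB_max`` is the asymptotic number of breaks per cell and ``k`` the
half-saturation read count; one DSB is assumed to produce two unique reads
(one per end).
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from blisskit.umi_dedup import DsbEvent, TaggedRead

__all__ = [
    "SaturationFit",
    "UmiThresholdSweep",
    "TelomereProfile",
    "TELOMERE_PATTERNS",
    "hyperbolic",
    "subsample_reads",
    "estimate_dsb_per_cell",
    "umi_threshold_sweep",
    "tss_fraction",
    "expression_stratified_profiles",
    "telomere_screen",
    "accessibility_vs_dsb",
]


def hyperbolic(r, dsb_max, k):
    """Saturation model DSB(r) = DSB_max * r / (k + r); passes through 0."""
    r = np.asarray(r, dtype=float)
    return dsb_max * r / (k + r)


@dataclass
class SaturationFit:
    """Fitted hyperbolic saturation model for DSBs per cell vs depth."""

    dsb_max: float
    k: float
    ci95: tuple[float, float]
    se_dsb_max: float
    depths: np.ndarray
    dsb_per_cell: np.ndarray
    n_cells: int

    def predict(self, r):
        return hyperbolic(r, self.dsb_max, self.k)

    def summary(self) -> str:
        lo, hi = self.ci95
        lines = [
            "Saturation fit: DSB(r) = DSB_max * r / (k + r)",
            f"  DSB_max : {self.dsb_max:.2f} breaks/cell (95% CI {lo:.2f}-{hi:.2f})",
            f"  k       : {self.k:.3g} reads",
            f"  n depths: {len(self.depths)}, n cells: {self.n_cells}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "dsb_max": self.dsb_max,
            "k": self.k,
            "ci95": list(self.ci95),
            "se_dsb_max": self.se_dsb_max,
            "n_cells": self.n_cells,
            "depths": self.depths.tolist(),
            "dsb_per_cell": self.dsb_per_cell.tolist(),
        }


def subsample_reads(reads: Sequence, depth: int, seed: int) -> list:
    """Uniform subsample of ``depth`` reads without replacement (seeded)."""
    if depth > len(reads):
        raise ValueError(f"depth {depth} exceeds total reads {len(reads)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(reads), size=depth, replace=False)
    idx.sort()
    return [reads[i] for i in idx]


def estimate_dsb_per_cell(
    depth_series: Sequence[tuple[float, float]],
    n_cells: int,
    bootstrap: int = 0,
    seed: int = 0,
) -> SaturationFit:
    """Fit the hyperbolic saturation model to (total reads, unique-UMI reads).

    Each depth point contributes DSBs/cell = unique_umi_read_count /
    (2 * n_cells), on the assumption that one break yields two unique reads.
    The 95% CI on DSB_max comes from the linearised covariance of the
    nonlinear least-squares fit; with ``bootstrap > 0`` a nonparametric
    percentile CI over depth-point resamples is used instead.
    """
    if len(depth_series) < 3:
        raise ValueError("need at least 3 depth points")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    r = np.array([d[0] for d in depth_series], dtype=float)
    y = np.array([d[1] for d in depth_series], dtype=float) / (2.0 * n_cells)

    p0 = (max(y.max(), 1e-9) * 1.5, max(np.median(r), 1.0))
    try:
        popt, pcov = optimize.curve_fit(hyperbolic, r, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"saturation fit failed to converge: {exc}") from exc
    dsb_max, k = float(popt[0]), float(popt[1])

    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(bootstrap):
            idx = rng.integers(0, len(r), size=len(r))
            if len(np.unique(r[idx])) < 3:
                continue
            try:
                b, _ = optimize.curve_fit(hyperbolic, r[idx], y[idx], p0=popt, maxfev=20000)
                boots.append(b[0])
            except RuntimeError:
                continue
        if len(boots) < 10:
            raise RuntimeError("bootstrap failed: too few converged resamples")
        lo, hi = np.percentile(boots, [2.5, 97.5])
        se = float(np.std(boots, ddof=1))
    else:
        se = float(np.sqrt(pcov[0, 0]))
        lo, hi = dsb_max - 1.96 * se, dsb_max + 1.96 * se
    return SaturationFit(
        dsb_max=dsb_max,
        k=k,
        ci95=(float(lo), float(hi)),
        se_dsb_max=se,
        depths=r,
        dsb_per_cell=y,
        n_cells=n_cells,
    )


@dataclass
class UmiThresholdSweep:
    """Recurrent-break quantification: locations with >= t UMIs, vs control.

    ``counts`` has one row per (chrom, t): location counts with
    t <= n_umis <= t_cap for each sample; ``fold_change`` holds the
    depth-normalised treated/control ratio averaged over chromosomes
    (equal weight per chromosome), for all locations and for locations
    exclusive to each sample.
    """

    counts: pd.DataFrame
    fold_change: pd.DataFrame
    total_ends_a: int
    total_ends_b: int
    skipped_chroms: list[str] = field(default_factory=list)


def _event_key(e: DsbEvent) -> tuple:
    return (e.chrom, e.pos, e.strand)


def umi_threshold_sweep(
    events_a: Sequence[DsbEvent],
    events_b: Sequence[DsbEvent],
    t_range: Sequence[int] = range(1, 11),
    t_cap: int = 500,
) -> UmiThresholdSweep:
    """Count DSB locations passing each UMI threshold, normalise by sequencing
    depth (total unique ends per sample) and report treated/control fold
    changes averaged over chromosomes.

    Chromosomes present in only one sample are excluded from the fold-change
    average (listed in ``skipped_chroms``). Exclusive-location fold changes
    use only locations absent from the other sample.
    """
    total_a = sum(e.n_umis for e in events_a)
    total_b = sum(e.n_umis for e in events_b)
    if total_a == 0 or total_b == 0:
        raise ValueError("both samples need at least one DSB end")

    keys_a = {_event_key(e) for e in events_a}
    keys_b = {_event_key(e) for e in events_b}

    def per_chrom_counts(events, exclude_keys=None):
        out: dict[str, Counter] = defaultdict(Counter)
        for e in events:
            if exclude_keys is not None and _event_key(e) in exclude_keys:
                continue
            if e.n_umis > t_cap:
                continue
            out[e.chrom][e.n_umis] += 1
        # cumulative: n(t) = count of locations with n_umis >= t
        table = {}
        for chrom, c in out.items():
            arr = {t: sum(v for u, v in c.items() if u >= t) for t in t_range}
            table[chrom] = arr
        return table

    tab_a = per_chrom_counts(events_a)
    tab_b = per_chrom_counts(events_b)
    tab_a_excl = per_chrom_counts(events_a, exclude_keys=keys_b)
    tab_b_excl = per_chrom_counts(events_b, exclude_keys=keys_a)

    chroms = sorted(set(tab_a) | set(tab_b))
    shared = [c for c in chroms if c in tab_a and c in tab_b]
    skipped = [c for c in chroms if c not in shared]

    rows = []
    for chrom in chroms:
        for t in t_range:
            rows.append(
                {
                    "chrom": chrom,
                    "t": t,
                    "n_a": tab_a.get(chrom, {}).get(t, 0),
                    "n_b": tab_b.get(chrom, {}).get(t, 0),
                    "n_a_exclusive": tab_a_excl.get(chrom, {}).get(t, 0),
                    "n_b_exclusive": tab_b_excl.get(chrom, {}).get(t, 0),
                }
            )
    counts = pd.DataFrame(rows)

    fc_rows = []
    for t in t_range:
        ratios, ratios_excl = [], []
        for chrom in shared:
            na = tab_a[chrom].get(t, 0) / total_a
            nb = tab_b[chrom].get(t, 0) / total_b
            if nb > 0:
                ratios.append(na / nb)
            nae = tab_a_excl.get(chrom, {}).get(t, 0) / total_a
            nbe = tab_b_excl.get(chrom, {}).get(t, 0) / total_b
            if nbe > 0:
                ratios_excl.append(nae / nbe)
        fc_rows.append(
            {
                "t": t,
                "fold_change": float(np.mean(ratios)) if ratios else math.nan,
                "fold_change_exclusive": float(np.mean(ratios_excl)) if ratios_excl else math.nan,
                "n_chroms": len(ratios),
            }
        )
    return UmiThresholdSweep(
        counts=counts,
        fold_change=pd.DataFrame(fc_rows),
        total_ends_a=total_a,
        total_ends_b=total_b,
        skipped_chroms=skipped,
    )


def _merge_windows(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def tss_fraction(
    events: Sequence[DsbEvent],
    tss_list: Sequence[tuple[str, int]],
    halfwidth: int = 5000,
    t_range: Sequence[int] = (1,),
) -> dict[int, Optional[float]]:
    """Fraction of unique DSB locations within +-halfwidth of any TSS.

    TSS windows are merged per chromosome before overlap testing, so
    duplicated or overlapping TSS entries are not double counted. Computed
    per UMI threshold t (locations with n_umis >= t); an empty event set at
    some t yields None rather than 0.
    """
    from bisect import bisect_right

    windows: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for chrom, pos in tss_list:
        windows[chrom].append((max(0, pos - halfwidth), pos + halfwidth + 1))
    merged = {chrom: _merge_windows(iv) for chrom, iv in windows.items()}
    starts = {chrom: [s for s, _ in iv] for chrom, iv in merged.items()}

    def in_window(chrom: str, pos: int) -> bool:
        if chrom not in merged:
            return False
        i = bisect_right(starts[chrom], pos) - 1
        return i >= 0 and pos < merged[chrom][i][1]

    out: dict[int, Optional[float]] = {}
    for t in t_range:
        passing = [e for e in events if e.n_umis >= t]
        if not passing:
            out[t] = None
            continue
        hits = sum(in_window(e.chrom, e.pos) for e in passing)
        out[t] = hits / len(passing)
    return out


@dataclass
class GeneAnnotation:
    """One gene: TSS plus gene-body interval (0-based half-open)."""

    gene_id: str
    chrom: str
    tss: int
    body_start: int
    body_end: int

    @property
    def length_kb(self) -> float:
        return (self.body_end - self.body_start) / 1000.0


def expression_stratified_profiles(
    events: Sequence[DsbEvent],
    genes: Sequence[GeneAnnotation],
    expression: dict[str, float],
    tss_halfwidth: int = 1000,
    profile_halfwidth: int = 5000,
    profile_bin: int = 250,
    n_strata: int = 10,
) -> dict:
    """Stratify DSB-end enrichment by gene expression decile.

    Deciles are computed over genes with nonzero expression (stable gene-id
    order breaks ties). Returns a dict with:

    - ``tss_percent``: per-decile percentage of all sequenced unique DSB ends
      within +-1 kb of the decile's TSSs (UMI-weighted; windows merged).
    - ``body_density``: per-gene ends/kb in the gene body for the top and
      bottom deciles.
    - ``tss_profile``: UMI-weighted positional end counts around the TSS
      (binned), for top and bottom deciles.
    - ``excluded_genes``: annotated genes without an expression value.
    """
    expressed = [g for g in genes if expression.get(g.gene_id, 0.0) > 0.0]
    excluded = [g.gene_id for g in genes if g.gene_id not in expression]
    if not expressed:
        raise ValueError("no annotated gene has nonzero expression")
    expressed.sort(key=lambda g: (expression[g.gene_id], g.gene_id))
    n = len(expressed)
    decile_of = {
        g.gene_id: min(n_strata - 1, i * n_strata // n) for i, g in enumerate(expressed)
    }

    total_ends = sum(e.n_umis for e in events)
    by_chrom: dict[str, list[DsbEvent]] = defaultdict(list)
    for e in events:
        by_chrom[e.chrom].append(e)
    for lst in by_chrom.values():
        lst.sort(key=lambda e: e.pos)
    pos_arrays = {c: np.array([e.pos for e in lst]) for c, lst in by_chrom.items()}
    umi_arrays = {c: np.array([e.n_umis for e in lst]) for c, lst in by_chrom.items()}

    def ends_in(chrom: str, start: int, end: int) -> int:
        if chrom not in pos_arrays:
            return 0
        pos = pos_arrays[chrom]
        i, j = np.searchsorted(pos, [start, end])
        return int(umi_arrays[chrom][i:j].sum())

    # per-decile TSS-proximal percentages over merged +-1 kb windows
    tss_pct = {}
    for d in range(n_strata):
        wins: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for g in expressed:
            if decile_of[g.gene_id] == d:
                wins[g.chrom].append((max(0, g.tss - tss_halfwidth), g.tss + tss_halfwidth + 1))
        ends = 0
        for chrom, iv in wins.items():
            for s, e in _merge_windows(iv):
                ends += ends_in(chrom, s, e)
        tss_pct[d] = 100.0 * ends / total_ends if total_ends else math.nan

    top = [g for g in expressed if decile_of[g.gene_id] == n_strata - 1]
    bottom = [g for g in expressed if decile_of[g.gene_id] == 0]

    def body_densities(group):
        rows = []
        for g in group:
            if g.length_kb <= 0:
                continue
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "ends": ends_in(g.chrom, g.body_start, g.body_end),
                    "density_per_kb": ends_in(g.chrom, g.body_start, g.body_end) / g.length_kb,
                }
            )
        return pd.DataFrame(rows)

    nbins = 2 * profile_halfwidth // profile_bin

    def tss_profile(group):
        prof = np.zeros(nbins)
        for g in group:
            if g.chrom not in pos_arrays:
                continue
            pos = pos_arrays[g.chrom]
            lo, hi = g.tss - profile_halfwidth, g.tss + profile_halfwidth
            i, j = np.searchsorted(pos, [lo, hi])
            rel = pos[i:j] - lo
            np.add.at(prof, np.minimum(rel // profile_bin, nbins - 1), umi_arrays[g.chrom][i:j])
        centers = np.arange(nbins) * profile_bin + profile_bin // 2 - profile_halfwidth
        return pd.DataFrame({"offset": centers, "ends": prof})

    return {
        "tss_percent": pd.Series(tss_pct, name="percent_of_ends"),
        "body_density": {"top": body_densities(top), "bottom": body_densities(bottom)},
        "tss_profile": {"top": tss_profile(top), "bottom": tss_profile(bottom)},
        "excluded_genes": excluded,
    }


# Phase patterns of the telomeric C-rich strand: a partial repeat followed by
# a full CCCTAA unit, longest partial first so each read matches at most once.
TELOMERE_PATTERNS: tuple[str, ...] = (
    "CCCTAA" + "CCCTAA",
    "CCTAA" + "CCCTAA",
    "CTAA" + "CCCTAA",
    "TAA" + "CCCTAA",
    "AA" + "CCCTAA",
    "A" + "CCCTAA",
)


@dataclass
class TelomereProfile:
    """Counts of prefix-trimmed reads per telomeric phase pattern."""

    counts: dict[str, int]
    total_reads: int

    @property
    def assigned(self) -> int:
        return sum(self.counts.values())


def telomere_screen(sequences: Iterable[str]) -> TelomereProfile:
    """Assign each trimmed read to at most one of the six telomeric phase
    patterns, anchored at the read start, longest pattern first."""
    counts = {p: 0 for p in TELOMERE_PATTERNS}
    total = 0
    for seq in sequences:
        total += 1
        for pat in TELOMERE_PATTERNS:  # tuple order = longest first
            if seq.startswith(pat):
                counts[pat] += 1
                break
    return TelomereProfile(counts=counts, total_reads=total)


def accessibility_vs_dsb(
    events_dsb: Sequence[DsbEvent],
    events_access: Sequence[DsbEvent],
    bin_size: int = 100_000,
    chrom_sizes: Optional[dict[str, int]] = None,
) -> tuple[pd.DataFrame, float, float]:
    """Binned comparison of chromatin accessibility (e.g. HindIII cut ends)
    against DSB density.

    Returns (per-bin table, Spearman rho, p-value); rho is NaN when either
    binned density has zero variance.
    """
    if chrom_sizes is None:
        chrom_sizes = defaultdict(int)
        for e in list(events_dsb) + list(events_access):
            chrom_sizes[e.chrom] = max(chrom_sizes[e.chrom], e.pos + 1)

    rows = []
    for chrom in sorted(chrom_sizes):
        nbins = max(1, -(-chrom_sizes[chrom] // bin_size))
        dsb = np.zeros(nbins)
        acc = np.zeros(nbins)
        for e in events_dsb:
            if e.chrom == chrom:
                dsb[min(e.pos // bin_size, nbins - 1)] += e.n_umis
        for e in events_access:
            if e.chrom == chrom:
                acc[min(e.pos // bin_size, nbins - 1)] += e.n_umis
        for i in range(nbins):
            rows.append(
                {"chrom": chrom, "bin_start": i * bin_size, "dsb": dsb[i], "accessibility": acc[i]}
            )
    table = pd.DataFrame(rows)
    if table["dsb"].nunique() < 2 or table["accessibility"].nunique() < 2:
        return table, math.nan, math.nan
    rho, p = stats.spearmanr(table["accessibility"], table["dsb"])
    return table, float(rho), float(p)
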