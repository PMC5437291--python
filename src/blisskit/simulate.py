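"""Synthetic fixture generation with known ground truth.

Generates every input the pipeline consumes — a genome FASTA with planted
cleavage sites, adapter-prefixed FASTQ reads with PCR duplication and
sequencing errors, a matching "perfect alignment" BED (positions are known
by construction, so tests never need an external aligner), expression and
annotation tables, and single-mismatch cutting-frequency tables for the
tolerance model — together with truth tables sufficient to score every
pipeline stage.

The generative model mirrors the assay: a break at a cut site exposes two
ends; each end is ligated independently (its own UMI) and read away from the
break (plus-strand read 5' end at the cut position, minus-strand read 5' end
offset by the cut's 5'-overhang length). PCR replicates each (end, UMI)
molecule; sequencing adds independent per-base substitution errors over the
whole read, prefix included.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from blisskit.adapter_scan import FastqRead
from blisskit.crispr_offtarget import GuideTarget, revcomp
from blisskit.umi_dedup import TaggedRead

__all__ = [
    "PlantedSite",
    "SimConfig",
    "make_genome",
    "simulate_library",
    "simulate_mismatch_table",
    "LibrarySim",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedSite:
    """One planted DSB site.

    ``sequence`` (protospacer+PAM, given 5'->3' on ``strand``) is embedded in
    the genome at ``pos`` so homology searches can rediscover it; plain
    (non-CRISPR) sites leave it None. ``cut_pos`` is the genomic coordinate
    of the plus-strand DSB end; the minus-strand end sits at
    ``cut_pos + overhang`` (0 = blunt, positive = 5' overhang).
    """

    site_id: str
    chrom: str
    pos: int
    strand: str = "+"
    sequence: Optional[str] = None
    cut_pos: Optional[int] = None
    overhang: int = 0
    break_frequency: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 <= self.break_frequency <= 1.0):
            raise ValueError("break_frequency must be in [0, 1]")

    @property
    def span(self) -> tuple[int, int]:
        n = len(self.sequence) if self.sequence else 1
        return self.pos, self.pos + n

    @property
    def effective_cut(self) -> int:
        return self.cut_pos if self.cut_pos is not None else self.pos


@dataclass
class SimConfig:
    """Study conditions for one simulated library."""

    seed: int = 0
    genome_length: int = 100_000
    chrom: str = "chr1"
    gc: float = 0.41  # human-like base composition
    sites: tuple[PlantedSite, ...] = ()
    n_cells: int = 100
    background_events: int = 0  # sporadic breaks at uniform random positions
    umi_length: int = 8
    barcode: str = "CATCACGC"
    anchor: Optional[str] = None
    read_length: int = 60
    per_base_error_rate: float = 0.0
    pcr_duplication_mean: float = 1.0  # mean copies per molecule (>= 1)
    distinct_site_umis: bool = False  # force per-end UMIs pairwise Hamming > 2

    def __post_init__(self) -> None:
        if self.pcr_duplication_mean < 1.0:
            raise ValueError("pcr_duplication_mean must be >= 1")
        if not (0.0 <= self.per_base_error_rate < 1.0):
            raise ValueError("per_base_error_rate must be in [0, 1)")


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    cum = np.cumsum([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return np.searchsorted(cum, rng.random(n), side="right").astype(np.uint8)


def make_genome(config: SimConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Build the genome with planted site sequences embedded.

    Returns (genome dict, planted-site table in BED-like columns). Raises if
    two planted sequences overlap.
    """
    if config.genome_length < 1000:
        raise ValueError("genome must be at least 1 kb")
    rng = np.random.default_rng(config.seed)
    enc = _random_seq(rng, config.genome_length, config.gc)
    spans = sorted((s.span, s.site_id) for s in config.sites if s.sequence)
    for (a, b) in zip(spans, spans[1:]):
        if b[0][0] < a[0][1]:
            raise ValueError(f"planted sites {a[1]} and {b[1]} overlap")
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    for s in config.sites:
        if s.sequence is None:
            continue
        seq = s.sequence if s.strand == "+" else revcomp(s.sequence)
        if s.pos + len(seq) > config.genome_length:
            raise ValueError(f"site {s.site_id} runs off the genome")
        enc[s.pos : s.pos + len(seq)] = [code[b] for b in seq]
    ascii_lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = {config.chrom: ascii_lut[enc].tobytes().decode()}
    table = pd.DataFrame(
        [
            {
                "site_id": s.site_id,
                "chrom": s.chrom,
                "start": s.span[0],
                "end": s.span[1],
                "strand": s.strand,
                "cut_pos": s.effective_cut,
                "overhang": s.overhang,
                "break_frequency": s.break_frequency,
            }
            for s in config.sites
        ]
    )
    return genome, table


@dataclass
class LibrarySim:
    """Simulated library: reads, their true alignments, and the truth table."""

    fastq: list[FastqRead]
    aligned: list[TaggedRead]
    bed_lines: list[str]
    truth: pd.DataFrame  # one row per sequenced read copy
    config: SimConfig

    @property
    def n_true_ends(self) -> int:
        """Planted unique (location, strand, UMI) triples."""
        return self.truth.drop_duplicates(["chrom", "pos5", "strand", "true_umi"]).shape[0]


def _draw_umis(
    rng: np.random.Generator, n: int, length: int, min_dist: int = 0
) -> list[str]:
    out: list[str] = []
    arrs: list[np.ndarray] = []
    guard = 0
    while len(out) < n:
        cand = rng.integers(0, 4, size=length)
        if min_dist > 0 and any(int((cand != a).sum()) <= min_dist for a in arrs):
            guard += 1
            if guard > 10000:
                raise RuntimeError("UMI space exhausted under min-distance constraint")
            continue
        arrs.append(cand)
        out.append("".join(_BASES[cand]))
    return out


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    if not hit.any():
        return seq
    idx = np.nonzero(hit)[0]
    for i in idx:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def simulate_library(genome: dict[str, str], config: SimConfig) -> LibrarySim:
    """Draw break events, molecules and read copies; see module docstring.

    Per site, the number of breaks is Binomial(n_cells, break_frequency);
    each break yields one plus-end and one minus-end molecule with
    independent UMIs. PCR copies per molecule are 1 + Poisson(mean − 1).
    """
    rng = np.random.default_rng(config.seed + 1)
    chrom = config.chrom
    seq = genome[chrom]
    glen = len(seq)

    prefix_extra = config.barcode + (config.anchor or "")
    genomic_len = config.read_length - config.umi_length - len(prefix_extra)
    if genomic_len < 20:
        raise ValueError("read_length too short for prefix plus genomic sequence")

    events: list[tuple[str, int, int, str]] = []  # (site_id, cut_pos, overhang, origin)
    for s in config.sites:
        n_events = rng.binomial(config.n_cells, s.break_frequency)
        events += [(s.site_id, s.effective_cut, s.overhang, "planted")] * int(n_events)
    for i in range(config.background_events):
        pos = int(rng.integers(50, glen - 50))
        events.append((f"bg{i}", pos, 0, "background"))

    fastq: list[FastqRead] = []
    aligned: list[TaggedRead] = []
    bed_lines: list[str] = []
    truth_rows: list[dict] = []
    umis_at: dict[tuple[int, str], list[str]] = {}

    read_no = 0
    for event_id, (site_id, cut, overhang, origin) in enumerate(events):
        for strand in "+-":
            pos5 = cut if strand == "+" else cut + overhang
            if not (0 <= pos5 < glen):
                continue
            key = (pos5, strand)
            if config.distinct_site_umis:
                have = umis_at.setdefault(key, [])
                guard = 0
                while True:
                    umi = _draw_umis(rng, 1, config.umi_length)[0]
                    from blisskit.adapter_scan import hamming

                    if all(hamming(umi, u) > 2 for u in have):
                        break
                    guard += 1
                    if guard > 10000:
                        raise RuntimeError("cannot place a distinct UMI")
                have.append(umi)
            else:
                umi = _draw_umis(rng, 1, config.umi_length)[0]

            if strand == "+":
                genomic = seq[pos5 : pos5 + genomic_len]
            else:
                genomic = revcomp(seq[max(0, pos5 - genomic_len + 1) : pos5 + 1])
            if len(genomic) < genomic_len:  # near a genome edge
                genomic = genomic + "A" * (genomic_len - len(genomic))

            n_copies = 1 + (
                rng.poisson(config.pcr_duplication_mean - 1.0)
                if config.pcr_duplication_mean > 1.0
                else 0
            )
            for _copy in range(int(n_copies)):
                read_no += 1
                name = f"read{read_no}"
                raw = umi + prefix_extra + genomic
                obs = _apply_errors(rng, raw, config.per_base_error_rate)
                fastq.append(FastqRead(name, obs, tuple([38] * len(obs))))
                obs_umi = obs[: config.umi_length]
                aligned.append(TaggedRead(chrom, pos5, strand, obs_umi, 60, "S1"))
                if strand == "+":
                    b_start, b_end = pos5, min(glen, pos5 + genomic_len)
                else:
                    b_start, b_end = max(0, pos5 - genomic_len + 1), pos5 + 1
                bed_lines.append(
                    f"{chrom}\t{b_start}\t{b_end}\tUMI:{obs_umi}:BC:S1\t60\t{strand}"
                )
                truth_rows.append(
                    {
                        "read": name,
                        "event_id": event_id,
                        "site_id": site_id,
                        "origin": origin,
                        "chrom": chrom,
                        "cut_pos": cut,
                        "overhang": overhang,
                        "strand": strand,
                        "pos5": pos5,
                        "true_umi": umi,
                        "observed_umi": obs_umi,
                    }
                )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "read", "event_id", "site_id", "origin", "chrom", "cut_pos",
            "overhang", "strand", "pos5", "true_umi", "observed_umi",
        ],
    )
    return LibrarySim(fastq=fastq, aligned=aligned, bed_lines=bed_lines, truth=truth, config=config)


def simulate_mismatch_table(
    t_curve: Callable[[float], float],
    guides: dict[str, float],
    noise: float = 0.05,
    seed: int = 0,
    positions: Sequence[int] = range(1, 21),
    base_rate: float = 0.6,
    n_identities: int = 3,
    guide_ratio_effects: Optional[dict[str, float]] = None,
) -> pd.DataFrame:
    """Single-mismatch cutting-frequency table from the tolerance model.

    Emulates a saturated single-mismatch guide panel: ``n_identities``
    independent measurements per position (default 3, one per alternative
    base). ``guides`` maps guide id -> overall activity scale s(g), which
    multiplies both the matched and the mismatched rate and therefore
    cancels from the normalised ratio. ``guide_ratio_effects`` optionally
    adds a log-scale per-guide offset a(g) to the mismatched rates only (the
    quantity the tolerance fit estimates); ``noise`` is the s.d. of the
    additive log-scale error eps.
    """
    rng = np.random.default_rng(seed)
    rows = []
    a_of = guide_ratio_effects or {}
    identities = ["A", "C", "G"][: max(1, n_identities)]
    for g, scale in guides.items():
        f_match = base_rate * scale
        for x in positions:
            for ident in identities:
                eps = rng.normal(0.0, noise) if noise > 0 else 0.0
                f_mm = f_match * float(t_curve(float(x))) * float(
                    np.exp(a_of.get(g, 0.0) + eps)
                )
                rows.append(
                    {
                        "guide_id": g,
                        "nuclease": "AsCpf1",
                        "mismatch_position": x,
                        "mismatch_identity": ident,
                        "modification_rate": f_mm,
                        "matched_rate": f_match,
                        "true_tolerance": float(t_curve(float(x))),
                    }
                )
    return pd.DataFrame(rows)
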