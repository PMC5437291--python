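import numpy as np
import pytest

from blisskit.adapter_scan import FastqRead
from blisskit.umi_dedup import TaggedRead


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


BASES = "ACGT"


def random_seq(rng, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def mutate(rng, seq: str, k: int) -> str:
    """Introduce exactly k substitutions at distinct random positions."""
    pos = rng.choice(len(seq), size=k, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = rng.choice([b for b in BASES if b != out[p]])
    return "".join(out)


def make_read(name: str, seq: str, q: int = 40) -> FastqRead:
    return FastqRead(name, seq, tuple([q] * len(seq)))


def random_tagged_reads(rng, n: int, span: int = 300, umi_len: int = 8,
                        n_chroms: int = 2) -> list[TaggedRead]:
    reads = []
    for i in range(n):
        reads.append(
            TaggedRead(
                chrom=f"chr{int(rng.integers(1, n_chroms + 1))}",
                pos5=int(rng.integers(0, span)),
                strand="+" if rng.random() < 0.5 else "-",
                umi=random_seq(rng, umi_len),
                mapq=60,
            )
        )
    return reads
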