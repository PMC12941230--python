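import pandas as pd
import pytest

from tcskit import CodingSequence, DepthTable, polr1c_transcript
from tcskit.genome_model import build_transcript


@pytest.fixture(scope="session")
def polr1c():
    return polr1c_transcript()


@pytest.fixture
def toy_cds():
    # ATG AAA GTT GAC TAA -> MKVD*
    return CodingSequence("toy", "ATGAAAGTTGACTAA")


def make_depth_table(chrom, start_pos, depth_by_sample):
    """Build a DepthTable from per-sample depth lists starting at start_pos."""
    n = len(next(iter(depth_by_sample.values())))
    frame = pd.DataFrame(
        {
            "chrom": [chrom] * n,
            "pos": list(range(start_pos, start_pos + n)),
            **{s: d for s, d in depth_by_sample.items()},
        }
    )
    return DepthTable(frame)


def random_transcript(rng, strand="+", max_exons=8):
    """Random valid transcript; transcript order runs along the strand."""
    n = int(rng.integers(1, max_exons + 1))
    lengths = [int(x) for x in rng.integers(3, 60, n)]
    gaps = [int(x) for x in rng.integers(5, 100, n)]
    pos = int(rng.integers(1000, 5000))
    intervals = []
    for length, gap in zip(lengths, gaps):
        intervals.append((pos, pos + length))
        pos += length + gap
    if strand == "-":
        intervals = intervals[::-1]  # exon 1 = highest genomic coordinates
    records = [
        {"index": i + 1, "chrom": "chrT", "start": s, "end": e, "strand": strand}
        for i, (s, e) in enumerate(intervals)
    ]
    return build_transcript(records, gene="TOY", transcript_id="TOY.1", strand=strand)


def enumerate_cdna_to_genomic(t):
    """Brute-force oracle: list of genomic positions indexed by c - 1."""
    out = []
    for ex in t.exons:
        span = range(ex.genomic.start, ex.genomic.end)
        out.extend(span if t.strand == "+" else reversed(span))
    return out


# Independent standard-genetic-code oracle (classic TCAG-order encoding).
_BASES = "TCAG"
_AMINO = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


def oracle_translate(seq):
    """Codon-by-codon translation to the first stop; independent of Biopython."""
    prot = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aa = CODON_TABLE[seq[i : i + 3]]
        if aa == "*":
            return "".join(prot), True
        prot.append(aa)
    return "".join(prot), False
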