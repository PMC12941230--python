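"""Transcript models linking genomic and coding (c.) coordinate systems.

A transcript is an ordered list of exons, each carrying a genomic interval
and the matching stretch of coding (CDS-relative, 1-based) coordinates.
Genomic intervals are 0-based half-open internally; printed exon tables in
the start-end style are read as half-open pairs (length = end - start),
which is the self-consistent reading of the nine-exon POLR1C model shipped
here (every exon's genomic and cDNA lengths then agree). cDNA coordinates
are coding coordinates only; UTRs are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ParseError, ValidationError

__all__ = [
    "GenomicInterval",
    "ExonModel",
    "TranscriptModel",
    "build_transcript",
    "map_cdna_to_genomic",
    "write_bed",
    "read_bed",
    "write_exon_table",
    "read_exon_table",
    "polr1c_transcript",
    "POLR1C_EXON_TABLE",
]


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not self.chrom:
            raise ValidationError("chromosome name must be non-empty")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValidationError(
                f"interval start must be < end (half-open), got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class ExonModel:
    """One exon: a genomic interval paired with its coding interval.

    ``cdna_start``/``cdna_end`` are 1-based inclusive c. coordinates; their
    span must equal the genomic length.
    """

    index: int
    genomic: GenomicInterval
    cdna_start: int
    cdna_end: int

    def __post_init__(self):
        if self.index < 1:
            raise ValidationError(f"exon index must be >= 1, got {self.index}")
        if self.cdna_start < 1 or self.cdna_end < self.cdna_start:
            raise ValidationError(
                f"exon {self.index}: invalid cDNA interval c.{self.cdna_start}-{self.cdna_end}"
            )
        if self.cdna_end - self.cdna_start + 1 != len(self.genomic):
            raise ValidationError(
                f"exon {self.index}: cDNA length {self.cdna_end - self.cdna_start + 1} "
                f"does not match genomic length {len(self.genomic)}"
            )

    @property
    def cdna_length(self) -> int:
        return self.cdna_end - self.cdna_start + 1


@dataclass(frozen=True)
class TranscriptModel:
    """Validated multi-exon transcript with contiguous coding coordinates."""

    gene: str
    transcript_id: str
    exons: tuple[ExonModel, ...]
    strand: str = "+"

    def __post_init__(self):
        if not self.exons:
            raise ValidationError("transcript must have at least one exon")
        prev_c_end = 0
        for ex in self.exons:
            if ex.genomic.strand != self.strand:
                raise ValidationError(
                    f"exon {ex.index}: strand {ex.genomic.strand} differs from transcript "
                    f"strand {self.strand}"
                )
            if ex.cdna_start != prev_c_end + 1:
                raise ValidationError(
                    f"exon {ex.index}: cDNA interval starts at c.{ex.cdna_start}, "
                    f"expected c.{prev_c_end + 1} (contiguity)"
                )
            prev_c_end = ex.cdna_end
        indices = [ex.index for ex in self.exons]
        if indices != sorted(set(indices)):
            raise ValidationError("exon indices must be strictly increasing")
        # transcript order runs along the strand; genomic order follows it
        ordered = sorted(self.exons, key=lambda e: e.genomic.start, reverse=self.strand == "-")
        if tuple(ordered) != self.exons:
            raise ValidationError(
                "exons are not ordered by genomic coordinate along the transcript strand"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if a.genomic.overlaps(b.genomic):
                raise ValidationError(f"exons {a.index} and {b.index} overlap genomically")

    @property
    def chrom(self) -> str:
        return self.exons[0].genomic.chrom

    @property
    def coding_length(self) -> int:
        return self.exons[-1].cdna_end

    def exon(self, index: int) -> ExonModel:
        for ex in self.exons:
            if ex.index == index:
                return ex
        raise KeyError(f"no exon with index {index}")

    def exon_for_cdna(self, c_pos: int) -> ExonModel:
        for ex in self.exons:
            if ex.cdna_start <= c_pos <= ex.cdna_end:
                return ex
        raise ValidationError(
            f"c.{c_pos} outside coding range 1-{self.coding_length} of {self.transcript_id}"
        )


def build_transcript(
    records,
    gene: str = "GENE",
    transcript_id: str = "TX",
    strand: str = "+",
) -> TranscriptModel:
    """Build a validated :class:`TranscriptModel` from exon records.

    ``records`` are dicts with keys ``index, chrom, start, end`` and
    optionally ``strand, c_start, c_end``. When cDNA coordinates are
    omitted they are derived contiguously (first exon starts at c.1) from
    the genomic lengths, walking exons in index order.
    """

    records = sorted(records, key=lambda r: r["index"])
    exons = []
    next_c = 1
    for rec in records:
        g = GenomicInterval(
            rec["chrom"], int(rec["start"]), int(rec["end"]), rec.get("strand", strand)
        )
        if "c_start" in rec and rec["c_start"] is not None:
            c_start, c_end = int(rec["c_start"]), int(rec["c_end"])
        else:
            c_start, c_end = next_c, next_c + len(g) - 1
        exons.append(ExonModel(int(rec["index"]), g, c_start, c_end))
        next_c = c_end + 1
    return TranscriptModel(gene, transcript_id, tuple(exons), strand)


def map_cdna_to_genomic(t: TranscriptModel, c_pos: int, offset: int = 0) -> int:
    """Map a coding coordinate (with optional intronic offset) to a genomic one.

    Returns a 0-based genomic position. ``offset > 0`` (donor side) is valid
    only when ``c_pos`` is the last coding base of a non-terminal exon;
    ``offset < 0`` (acceptor side) only when ``c_pos`` is the first coding
    base of a non-initial exon.
    """

    ex = t.exon_for_cdna(c_pos)
    if t.strand == "+":
        g = ex.genomic.start + (c_pos - ex.cdna_start)
    else:
        g = ex.genomic.end - 1 - (c_pos - ex.cdna_start)
    if offset == 0:
        return g
    if offset > 0:
        if c_pos != ex.cdna_end or ex is t.exons[-1]:
            raise ValidationError(
                f"intronic offset +{offset} requires c.{c_pos} to be the 3' boundary of an "
                f"internal exon"
            )
    else:
        if c_pos != ex.cdna_start or ex is t.exons[0]:
            raise ValidationError(
                f"intronic offset {offset} requires c.{c_pos} to be the 5' boundary of a "
                f"non-initial exon"
            )
    return g + offset if t.strand == "+" else g - offset


# ---------------------------------------------------------------------------
# I/O: BED (0-based half-open) and a paired genomic/cDNA exon table TSV
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ("exon_index", "chrom", "start", "end", "strand", "c_start", "c_end")


def write_bed(t: TranscriptModel, path) -> None:
    """Write the exon model as 0-based half-open BED6 (name = gene_exonN)."""
    with open(path, "w") as fh:
        for ex in t.exons:
            fh.write(
                f"{ex.genomic.chrom}\t{ex.genomic.start}\t{ex.genomic.end}\t"
                f"{t.gene}_exon{ex.index}\t0\t{ex.genomic.strand}\n"
            )


def read_bed(path) -> list[dict]:
    """Read BED exon records back (exon index recovered from the name field)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("BED line has fewer than 3 fields", lineno, str(path))
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError("non-integer BED coordinates", lineno, str(path)) from None
            if end <= start:
                raise ParseError(f"end ({end}) <= start ({start})", lineno, str(path))
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else "+"
            if "_exon" in name:
                try:
                    index = int(name.rsplit("_exon", 1)[1])
                except ValueError:
                    index = len(records) + 1
            else:
                index = len(records) + 1
            records.append(
                {"index": index, "chrom": fields[0], "start": start, "end": end, "strand": strand}
            )
    return records


def write_exon_table(t: TranscriptModel, path) -> None:
    """Write the paired genomic/cDNA exon table TSV (half-open genomic pairs)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for ex in t.exons:
            fh.write(
                f"{ex.index}\t{ex.genomic.chrom}\t{ex.genomic.start}\t{ex.genomic.end}\t"
                f"{ex.genomic.strand}\t{ex.cdna_start}\t{ex.cdna_end}\n"
            )


def read_exon_table(path) -> list[dict]:
    records = []
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = set(_TABLE_COLUMNS) - set(header)
                if missing:
                    raise ParseError(
                        f"exon table missing columns: {sorted(missing)}", lineno, str(path)
                    )
                continue
            row = dict(zip(header, fields))
            try:
                records.append(
                    {
                        "index": int(row["exon_index"]),
                        "chrom": row["chrom"],
                        "start": int(row["start"]),
                        "end": int(row["end"]),
                        "strand": row["strand"],
                        "c_start": int(row["c_start"]),
                        "c_end": int(row["c_end"]),
                    }
                )
            except (KeyError, ValueError):
                raise ParseError("malformed exon table row", lineno, str(path)) from None
    return records


# ---------------------------------------------------------------------------
# Built-in POLR1C model (MANE Select ENST00000642195.1, GRCh38, chr6, + strand)
# ---------------------------------------------------------------------------

#: Nine-exon POLR1C model: (index, chrom, start, end, strand, c_start, c_end).
#: Genomic pairs are half-open; coding length totals 1275 nt.
POLR1C_EXON_TABLE: tuple[tuple, ...] = (
    (1, "chr6", 43517088, 43517178, "+", 1, 90),
    (2, "chr6", 43517305, 43517377, "+", 91, 162),
    (3, "chr6", 43519332, 43519440, "+", 163, 270),
    (4, "chr6", 43519705, 43519838, "+", 271, 403),
    (5, "chr6", 43520065, 43520185, "+", 404, 523),
    (6, "chr6", 43520274, 43520427, "+", 524, 676),
    (7, "chr6", 43520624, 43520774, "+", 677, 826),
    (8, "chr6", 43520931, 43521048, "+", 827, 943),
    (9, "chr6", 43521181, 43521513, "+", 944, 1275),
)


def polr1c_transcript() -> TranscriptModel:
    """The built-in nine-exon POLR1C transcript model (GRCh38, + strand)."""
    records = [
        dict(zip(("index", "chrom", "start", "end", "strand", "c_start", "c_end"), row))
        for row in POLR1C_EXON_TABLE
    ]
    return build_transcript(records, gene="POLR1C", transcript_id="ENST00000642195.1", strand="+")
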