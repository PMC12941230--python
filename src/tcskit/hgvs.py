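"""Coding-level HGVS parsing and protein-consequence arithmetic.

Supports the descriptor classes a single-gene Mendelian workup actually
produces: exonic substitutions, small insertions/deletions/delins, and
intronic substitutions at splice sites (``c.4345+1G>A``). Consequences are
derived by editing the coding sequence, translating both alleles with the
standard genetic code, and comparing codon-by-codon. Frameshift
nomenclature follows the fs*N convention: N counts the new-frame stop with
the first changed residue as position 1, so the stop lands at protein
position ``first_affected + N - 1`` (e.g. p.Arg77Ilefs*97 terminates at
residue 173, a truncated product of 172 residues before the stop).

A 2-nt deletion shifts the frame by -2 ≡ +1 (mod 3); frame offset is
reported as ``(length change) mod 3``, matching the field's habit of
calling such deletions "+1 frameshifts".
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, asdict
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqUtils import seq1, seq3

from .errors import (
    NotApplicableError,
    ParseError,
    ReferenceMismatchError,
    ValidationError,
)
from .genome_model import TranscriptModel

__all__ = [
    "CodingSequence",
    "CodingVariant",
    "ProteinConsequence",
    "SpliceClass",
    "parse_c",
    "parse_p",
    "apply_variant",
    "translate",
    "consequence",
    "fs_stop_position",
    "FrameshiftStop",
    "classify_splice",
    "read_cds_fasta",
    "read_variant_sheet",
    "write_consequence_report",
]

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class CodingSequence:
    """A coding sequence (CDS) over {A,C,G,T}, optionally flagged complete.

    A complete CDS starts with ATG, ends with a stop codon and contains no
    internal in-frame stop; consequence arithmetic requires completeness.
    """

    id: str
    seq: str
    complete: bool = True

    def __post_init__(self):
        seq = self.seq.upper()
        object.__setattr__(self, "seq", seq)
        if set(seq) - set("ACGT"):
            raise ValidationError(
                f"{self.id}: CDS contains non-ACGT characters: "
                f"{sorted(set(seq) - set('ACGT'))}"
            )
        if self.complete:
            if len(seq) < 6:
                raise ValidationError(f"{self.id}: complete CDS must be >= 6 nt")
            if len(seq) % 3:
                raise ValidationError(f"{self.id}: complete CDS length not a multiple of 3")
            if not seq.startswith("ATG"):
                raise ValidationError(f"{self.id}: complete CDS must start with ATG")
            codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
            if codons[-1] not in _STOPS:
                raise ValidationError(f"{self.id}: complete CDS must end with a stop codon")
            if any(c in _STOPS for c in codons[:-1]):
                raise ValidationError(f"{self.id}: internal in-frame stop codon")

    def protein(self) -> str:
        return translate(self.seq)[0]


@dataclass(frozen=True)
class CodingVariant:
    """A structured c.-level variant."""

    kind: str  # substitution | insertion | deletion | delins | intronic_substitution
    pos1: int
    pos2: Optional[int] = None
    offset: int = 0
    ref: str = ""
    alt: str = ""
    transcript_id: Optional[str] = None

    def __post_init__(self):
        if self.kind == "insertion" and self.pos2 != self.pos1 + 1:
            raise ValidationError("insertion must sit between adjacent flanks (pos2 = pos1+1)")
        if self.kind in ("deletion", "delins") and self.pos2 is not None and self.pos2 < self.pos1:
            raise ValidationError("deletion/delins needs pos1 <= pos2")
        if self.offset != 0 and self.kind != "intronic_substitution":
            raise ValidationError("nonzero intronic offset only valid for intronic_substitution")

    @property
    def length_change(self) -> int:
        if self.kind == "substitution":
            return 0
        if self.kind == "insertion":
            return len(self.alt)
        span = (self.pos2 or self.pos1) - self.pos1 + 1
        if self.kind == "deletion":
            return -span
        if self.kind == "delins":
            return len(self.alt) - span
        return 0


@dataclass(frozen=True)
class ProteinConsequence:
    """Protein-level outcome of applying a coding variant."""

    kind: str  # synonymous | missense | nonsense | frameshift | inframe_indel | no_stop_found
    hgvs_p: str
    first_affected_residue: Optional[int] = None
    ref_residue: Optional[str] = None  # 1-letter
    new_residue: Optional[str] = None  # 1-letter ('*' for stop)
    ter_offset: Optional[int] = None  # the N of fs*N
    stop_position: Optional[int] = None  # protein coordinate of the new stop

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


@dataclass(frozen=True)
class SpliceClass:
    """Donor/acceptor assignment of an intronic boundary substitution."""

    site: str  # donor | acceptor
    offset: int

    @property
    def canonical(self) -> bool:
        return abs(self.offset) <= 2


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_SUB_RE = re.compile(r"(\d+)([+-]\d+)?([ACGT])>([ACGT])$")
_INS_RE = re.compile(r"(\d+)_(\d+)ins([ACGT]+)$")
_DELINS_RE = re.compile(r"(\d+)(?:_(\d+))?delins([ACGT]+)$")
_DEL_RE = re.compile(r"(\d+)(?:_(\d+))?del([ACGT]*)$")


def parse_c(hgvs: str) -> CodingVariant:
    """Parse a (possibly transcript-prefixed) HGVS c. descriptor.

    Whitespace-tolerant: ``"c.4345 + 1 G > A"`` parses the same as
    ``"c.4345+1G>A"``.
    """

    raw = hgvs
    compact = re.sub(r"\s+", "", hgvs)
    transcript_id = None
    if ":" in compact:
        transcript_id, compact = compact.split(":", 1)
    if not compact.startswith("c."):
        raise ParseError(f"not a c. descriptor (position 0): {raw!r}")
    body = compact[2:]

    m = _SUB_RE.fullmatch(body)
    if m:
        pos, off, ref, alt = m.groups()
        offset = int(off) if off else 0
        kind = "intronic_substitution" if offset else "substitution"
        return CodingVariant(kind, int(pos), None, offset, ref, alt, transcript_id)
    m = _INS_RE.fullmatch(body)
    if m:
        p1, p2, alt = int(m.group(1)), int(m.group(2)), m.group(3)
        if p2 != p1 + 1:
            raise ParseError(
                f"insertion flanks must be adjacent, got c.{p1}_{p2} in {raw!r}"
            )
        return CodingVariant("insertion", p1, p2, 0, "", alt, transcript_id)
    m = _DELINS_RE.fullmatch(body)
    if m:
        p1 = int(m.group(1))
        p2 = int(m.group(2)) if m.group(2) else p1
        return CodingVariant("delins", p1, p2, 0, "", m.group(3), transcript_id)
    m = _DEL_RE.fullmatch(body)
    if m:
        p1 = int(m.group(1))
        p2 = int(m.group(2)) if m.group(2) else p1
        ref = m.group(3)
        if ref and len(ref) != p2 - p1 + 1:
            raise ParseError(
                f"deleted bases {ref!r} do not span c.{p1}_{p2} in {raw!r}"
            )
        return CodingVariant("deletion", p1, p2, 0, ref, "", transcript_id)
    # locate how far a plausible position prefix reaches, for the error message
    pref = re.match(r"\d*", body)
    raise ParseError(
        f"cannot parse c. descriptor {raw!r} (syntax error at position "
        f"{2 + (pref.end() if pref else 0)})"
    )


_AA3 = r"(?:[A-Z][a-z]{2}|\*)"
_P_FS_RE = re.compile(rf"p\.\(?({_AA3}|[A-Z])(\d+)({_AA3}|[A-Z])?fs(?:\*(\d+|\?))?\)?$")
_P_SUB_RE = re.compile(rf"p\.\(?({_AA3}|[A-Z])(\d+)({_AA3}|[A-Z*])\)?$")


def _to1(aa: str) -> str:
    if aa in ("*", "Ter"):
        return "*"
    return aa if len(aa) == 1 else seq1(aa)


def parse_p(hgvs_p: str) -> ProteinConsequence:
    """Re-parse a p. string emitted by :func:`consequence` (round-trip aid)."""
    s = re.sub(r"\s+", "", hgvs_p)
    if ":" in s:
        s = s.split(":", 1)[1]
    if s in ("p.(=)", "p.="):
        return ProteinConsequence("synonymous", "p.(=)")
    m = _P_FS_RE.fullmatch(s)
    if m:
        ref, pos, new, n = m.group(1), int(m.group(2)), m.group(3), m.group(4)
        ter = int(n) if n and n != "?" else None
        kind = "frameshift" if ter is not None else "no_stop_found"
        return ProteinConsequence(
            kind,
            hgvs_p=s,
            first_affected_residue=pos,
            ref_residue=_to1(ref),
            new_residue=_to1(new) if new else None,
            ter_offset=ter,
            stop_position=pos + ter - 1 if ter is not None else None,
        )
    m = _P_SUB_RE.fullmatch(s)
    if m:
        ref, pos, new = m.group(1), int(m.group(2)), _to1(m.group(3))
        if new == "*":
            return ProteinConsequence(
                "nonsense", s, pos, _to1(ref), "*", stop_position=pos
            )
        return ProteinConsequence("missense", s, pos, _to1(ref), new)
    raise ParseError(f"cannot parse p. descriptor {hgvs_p!r}")


# ---------------------------------------------------------------------------
# Sequence arithmetic
# ---------------------------------------------------------------------------

def apply_variant(cds: CodingSequence, v: CodingVariant) -> str:
    """Apply an exonic variant to the CDS, returning the edited string."""
    if v.kind == "intronic_substitution":
        raise NotApplicableError(
            "intronic variants do not edit the CDS; use classify_splice"
        )
    seq = cds.seq
    n = len(seq)
    p1, p2 = v.pos1, v.pos2 or v.pos1
    if v.kind == "substitution":
        if not 1 <= p1 <= n:
            raise ValidationError(f"c.{p1} outside CDS of length {n}")
        if v.ref and seq[p1 - 1] != v.ref:
            raise ReferenceMismatchError(p1, v.ref, seq[p1 - 1])
        return seq[: p1 - 1] + v.alt + seq[p1:]
    if v.kind == "insertion":
        if not 1 <= p1 < n:
            raise ValidationError(f"insertion flank c.{p1} outside CDS of length {n}")
        return seq[:p1] + v.alt + seq[p1:]
    if v.kind in ("deletion", "delins"):
        if not (1 <= p1 <= p2 <= n):
            raise ValidationError(f"c.{p1}_{p2} outside CDS of length {n}")
        if v.ref and seq[p1 - 1 : p2] != v.ref:
            raise ReferenceMismatchError(p1, v.ref, seq[p1 - 1 : p2])
        return seq[: p1 - 1] + v.alt + seq[p2:]
    raise ValidationError(f"unknown variant kind {v.kind!r}")


def translate(seq: str) -> tuple[str, bool]:
    """Translate from position 1 to the first stop.

    Returns ``(protein, stop_reached)``; trailing bases beyond the last
    full codon are ignored.
    """

    if len(seq) < 3:
        raise ValidationError("sequence shorter than one codon")
    chunk = seq[: len(seq) // 3 * 3]
    prot = str(Seq(chunk).translate())
    if "*" in prot:
        return prot[: prot.index("*")], True
    return prot, False


def _p_sub(ref: str, pos: int, new: str) -> str:
    new3 = "Ter" if new == "*" else seq3(new)
    return f"p.{seq3(ref)}{pos}{new3}"


def consequence(cds: CodingSequence, v: CodingVariant) -> ProteinConsequence:
    """Protein-level consequence of an exonic variant on a complete CDS.

    Wild-type and mutant translations are compared residue-by-residue; the
    first differing residue anchors the description. A variant is a
    frameshift iff its length change is not a multiple of 3. If the mutant
    frame runs off the end of the supplied sequence without a stop, the
    kind is ``no_stop_found`` (no 3'UTR readthrough is attempted).
    """

    if v.kind == "intronic_substitution":
        raise NotApplicableError("intronic variant: classify with classify_splice")
    if not cds.complete:
        raise ValidationError("consequence arithmetic requires a complete CDS")
    wt, _ = translate(cds.seq)
    mut_seq = apply_variant(cds, v)
    mut, stop_found = translate(mut_seq)
    frame = v.length_change % 3

    if mut == wt and stop_found and frame == 0:
        return ProteinConsequence("synonymous", "p.(=)")

    # first differing residue
    i = None
    for k in range(min(len(wt), len(mut))):
        if wt[k] != mut[k]:
            i = k
            break

    if i is None:
        if len(mut) < len(wt) and stop_found:
            # truncation with intact prefix: new stop at residue len(mut)+1
            pos = len(mut) + 1
            return ProteinConsequence(
                "nonsense",
                _p_sub(wt[pos - 1], pos, "*"),
                first_affected_residue=pos,
                ref_residue=wt[pos - 1],
                new_residue="*",
                stop_position=pos,
            )
        if not stop_found:
            pos = len(wt) + 1
            return ProteinConsequence(
                "no_stop_found",
                f"p.Ter{pos}ext*?",
                first_affected_residue=pos,
            )
        # same translated protein but length change upstream of stop is
        # impossible without a differing residue; treat as synonymous
        return ProteinConsequence("synonymous", "p.(=)")

    pos = i + 1
    ref_res, new_res = wt[i], mut[i]
    ref3, new3 = seq3(ref_res), seq3(new_res)

    if frame != 0:
        if not stop_found:
            return ProteinConsequence(
                "no_stop_found",
                f"p.{ref3}{pos}{new3}fs*?",
                first_affected_residue=pos,
                ref_residue=ref_res,
                new_residue=new_res,
            )
        stop_position = len(mut) + 1
        ter = stop_position - pos + 1
        return ProteinConsequence(
            "frameshift",
            f"p.{ref3}{pos}{new3}fs*{ter}",
            first_affected_residue=pos,
            ref_residue=ref_res,
            new_residue=new_res,
            ter_offset=ter,
            stop_position=stop_position,
        )

    if v.kind == "substitution":
        if not stop_found:
            return ProteinConsequence(
                "no_stop_found",
                f"p.{ref3}{pos}{new3}",
                first_affected_residue=pos,
                ref_residue=ref_res,
                new_residue=new_res,
            )
        return ProteinConsequence(
            "missense",
            _p_sub(ref_res, pos, new_res),
            first_affected_residue=pos,
            ref_residue=ref_res,
            new_residue=new_res,
        )
    # in-frame indel (length change multiple of 3)
    return ProteinConsequence(
        "inframe_indel",
        f"p.({ref3}{pos}{new3})",
        first_affected_residue=pos,
        ref_residue=ref_res,
        new_residue=new_res,
    )


@dataclass(frozen=True)
class FrameshiftStop:
    """fs*N arithmetic: the stop's protein coordinate and the residues before it.

    The truncated-product residue count (``residues_before_stop``) is the
    stop position minus one; published reports often quote the stop
    position itself as the truncated-protein length, so both are carried.
    ``None`` fields mean the stop is not defined (fs*?).
    """

    stop_position: Optional[int]
    residues_before_stop: Optional[int]


def fs_stop_position(p_hgvs: str) -> FrameshiftStop:
    """Stop coordinate implied by a ``p.<Ref><Pos><New>fs*<N>`` description.

    Returns ``Pos + N - 1`` (the fs*N convention counts the first changed
    residue as 1). ``fs*?`` yields an undefined result.
    """

    m = _P_FS_RE.fullmatch(re.sub(r"\s+", "", p_hgvs))
    if not m:
        raise ParseError(f"not a frameshift p. descriptor: {p_hgvs!r}")
    pos = int(m.group(2))
    n = m.group(4)
    if n is None or n == "?":
        return FrameshiftStop(None, None)
    stop = pos + int(n) - 1
    return FrameshiftStop(stop, stop - 1)


def classify_splice(v: CodingVariant, t: TranscriptModel) -> SpliceClass:
    """Classify an intronic boundary substitution as donor or acceptor.

    Donor: the position is an exon's 3' coding end and the offset is
    positive. Acceptor: an exon's 5' coding start with negative offset.
    Canonical iff |offset| <= 2 (the invariant GT/AG dinucleotides).
    """

    if v.kind != "intronic_substitution" or v.offset == 0:
        raise ValidationError("classify_splice needs an intronic substitution with offset")
    for ex in t.exons:
        if v.offset > 0 and v.pos1 == ex.cdna_end and ex is not t.exons[-1]:
            return SpliceClass("donor", v.offset)
        if v.offset < 0 and v.pos1 == ex.cdna_start and ex is not t.exons[0]:
            return SpliceClass("acceptor", v.offset)
    raise ValidationError(
        f"c.{v.pos1}{v.offset:+d} is not at an exon boundary of {t.transcript_id}"
    )


# ---------------------------------------------------------------------------
# I/O: FASTA CDSs, TSV variant sheets, JSON-lines consequence reports
# ---------------------------------------------------------------------------

def read_cds_fasta(path, complete: bool = True) -> dict[str, CodingSequence]:
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = CodingSequence(rec.id, str(rec.seq), complete=complete)
    if not out:
        raise ParseError("no FASTA records found", source=str(path))
    return out


def read_variant_sheet(path) -> list[tuple[str, str]]:
    """Read a TSV of (transcript_id, hgvs_c) pairs; header required."""
    rows = []
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if "transcript_id" not in header or "hgvs_c" not in header:
                    raise ParseError(
                        "variant sheet needs 'transcript_id' and 'hgvs_c' columns",
                        lineno,
                        str(path),
                    )
                continue
            row = dict(zip(header, fields))
            rows.append((row["transcript_id"], row["hgvs_c"]))
    return rows


def write_consequence_report(
    results: Iterable[tuple[str, str, ProteinConsequence]], path
) -> None:
    """JSON-lines report: one object per (transcript, variant, consequence)."""
    with open(path, "w") as fh:
        for transcript_id, hgvs_c, cons in results:
            obj = {"transcript_id": transcript_id, "hgvs_c": hgvs_c}
            obj.update(json.loads(cons.to_json()))
            fh.write(json.dumps(obj, sort_keys=True) + "\n")
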