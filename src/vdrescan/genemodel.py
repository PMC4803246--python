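"""Gene models and coding-coordinate variant notation.

Anchors the clinical-genetics coordinate dialect used for promoter and
intronic variants of a gene ("c.1-N" = N bp upstream of the translation
start ATG; "c.42-N" = N bp upstream of the first base of exon 2, i.e.
inside intron 1 when exon 1 carries c.1-c.41) to 0-based offsets on a
reference contig, and applies SNVs, duplications, deletions and
insertions to produce mutant alleles.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

from .errors import (
    CoordinateRangeError,
    ReferenceMismatchError,
    VariantParseError,
)


@dataclass(frozen=True)
class GeneModel:
    """Exon structure of one gene on a forward-oriented contig.

    ``exons`` are 0-based half-open intervals in ascending contig order;
    ``translation_start`` is the contig offset of the A of the ATG and
    must lie inside exon 1. Reverse-strand gene models are accepted but
    experimental: coordinate anchoring assumes the contig is oriented
    with the gene (as reference sequences for single genes usually are).
    """

    contig_id: str
    exons: tuple[tuple[int, int], ...]
    translation_start: int
    gene_strand: int = 1

    def __post_init__(self):
        exons = tuple((int(a), int(b)) for a, b in self.exons)
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise ValueError("gene model needs at least one exon")
        for a, b in exons:
            if a >= b:
                raise ValueError(f"empty or inverted exon [{a}, {b})")
        for (_, b1), (a2, _) in zip(exons, exons[1:]):
            if a2 < b1:
                raise ValueError("exons must be non-overlapping and ascending")
        a1, b1 = exons[0]
        if not a1 <= self.translation_start < b1:
            raise ValueError("translation_start must lie inside exon 1")
        if self.gene_strand not in (1, -1):
            raise ValueError("gene_strand must be +1 or -1")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon(self, i: int) -> tuple[int, int]:
        """1-based exon lookup."""
        if not 1 <= i <= self.n_exons:
            raise CoordinateRangeError(
                f"exon {i} out of range (model has {self.n_exons} exons)"
            )
        return self.exons[i - 1]

    def intron(self, i: int) -> tuple[int, int]:
        """1-based intron lookup: intron i lies between exons i and i+1."""
        if not 1 <= i <= self.n_exons - 1:
            raise CoordinateRangeError(
                f"intron {i} out of range (model has {self.n_exons - 1} introns)"
            )
        return (self.exons[i - 1][1], self.exons[i][0])

    def c_of_exon_start(self, i: int) -> int:
        """Coding coordinate of the first base of exon ``i`` (1-based exon).

        Exon 1 contributes bases from the ATG to its 3' end, so the first
        base of exon 2 is c.(exon1_end - translation_start + 1).
        """
        start, end = self.exon(1)
        if i == 1:
            return 1
        c = end - self.translation_start
        for j in range(2, i):
            a, b = self.exon(j)
            c += b - a
        return c + 1


class VariantKind(str, Enum):
    SNV = "SNV"
    DUP = "dup"
    DEL = "del"
    INS = "ins"


@dataclass(frozen=True)
class CVariant:
    """A parsed variant in the coding-coordinate dialect.

    ``anchor_c`` is the coding position the upstream offsets hang off
    (1 = the ATG; the c-index of an exon's first base for intronic
    variants). ``start_offset``/``end_offset`` are the signed offsets as
    written (e.g. -1060 .. -1057), start <= end.
    """

    raw_text: str
    kind: VariantKind
    anchor_c: int
    start_offset: int
    end_offset: int
    ref_bases: str = ""
    alt_bases: str = ""

    def __post_init__(self):
        if self.start_offset > self.end_offset:
            raise VariantParseError(
                f"{self.raw_text!r}: reversed offset range "
                f"{self.start_offset}..{self.end_offset}"
            )
        if self.start_offset >= 0 or self.end_offset >= 0:
            raise VariantParseError(
                f"{self.raw_text!r}: offsets must be negative (upstream); "
                "offset 0 does not exist in this coordinate system"
            )

    @property
    def span(self) -> int:
        """Reference length of the addressed interval (bases)."""
        if self.kind is VariantKind.INS:
            return 1
        return self.end_offset - self.start_offset + 1


_VARIANT_RE = re.compile(
    r"""^c\.
        (?:(?P<anchor>\d+)-|-)          # 'c.42-' style anchor, or bare 'c.-'
        (?P<n1>\d+)
        (?:_-(?P<n2>\d+))?              # optional range end '_-1057'
        \s*
        (?:
            (?P<ref>[ACGTacgt])\s*>\s*(?P<alt>[ACGTacgt])   # SNV
          | (?P<op>dup|del|ins)(?P<opbases>[ACGTacgt]*)
        )
        $""",
    re.VERBOSE,
)


def parse_cvariant(text: str) -> CVariant:
    """Parse a variant string such as ``c.42-1060_-1057dupTTGA``,
    ``c.1-171 C>G`` or standard-dialect ``c.-171C>G``.

    Raises :class:`VariantParseError` for zero offsets, reversed ranges or
    unknown operation suffixes.
    """
    raw = text.strip()
    m = _VARIANT_RE.match(raw)
    if m is None:
        raise VariantParseError(f"cannot parse variant {raw!r}")
    anchor_c = int(m.group("anchor")) if m.group("anchor") else 1
    n1 = int(m.group("n1"))
    n2 = int(m.group("n2")) if m.group("n2") else n1
    if n1 == 0 or n2 == 0:
        raise VariantParseError(f"{raw!r}: offset 0 is illegal (position of '-0')")

    if m.group("ref"):
        kind = VariantKind.SNV
        ref, alt = m.group("ref").upper(), m.group("alt").upper()
        if n1 != n2:
            raise VariantParseError(f"{raw!r}: SNV cannot address a range")
    else:
        op = m.group("op")
        kind = VariantKind(op)
        bases = m.group("opbases").upper()
        if kind is VariantKind.INS and not bases:
            raise VariantParseError(f"{raw!r}: insertion requires inserted bases")
        ref = bases if kind in (VariantKind.DUP, VariantKind.DEL) else ""
        alt = bases if kind is VariantKind.INS else ""
    return CVariant(
        raw_text=raw,
        kind=kind,
        anchor_c=anchor_c,
        start_offset=-n1,
        end_offset=-n2,
        ref_bases=ref,
        alt_bases=alt,
    )


def _anchor_contig_offset(model: GeneModel, anchor_c: int) -> int:
    """Contig offset of the base the negative offsets count back from."""
    if anchor_c == 1:
        return model.translation_start
    for i in range(2, model.n_exons + 1):
        if model.c_of_exon_start(i) == anchor_c:
            return model.exon(i)[0]
    raise CoordinateRangeError(
        f"anchor c.{anchor_c} is not the first base of any exon in this model"
    )


def c_to_contig(model: GeneModel, variant: CVariant) -> tuple[int, int]:
    """Map a variant's addressed interval to 0-based half-open contig
    coordinates. ``c.<anchor>-N`` maps to ``anchor_offset - N``.
    """
    base = _anchor_contig_offset(model, variant.anchor_c)
    start = base + variant.start_offset
    end = base + variant.end_offset + 1
    if start < 0:
        raise CoordinateRangeError(
            f"{variant.raw_text!r} maps upstream of the contig (offset {start})"
        )
    return (start, end)


def c_position_to_contig(model: GeneModel, anchor_c: int, offset_n: int) -> int:
    """Single-position convenience: ``c.<anchor>-<offset_n>`` -> contig offset."""
    if offset_n <= 0:
        raise VariantParseError("upstream offset must be a positive count")
    pos = _anchor_contig_offset(model, anchor_c) - offset_n
    if pos < 0:
        raise CoordinateRangeError(f"position maps upstream of the contig ({pos})")
    return pos


def apply_variant(reference: str, model: GeneModel, v: CVariant) -> str:
    """Return the mutant allele of ``reference`` under variant ``v``.

    SNVs substitute one base; duplications insert a second copy of the
    addressed interval immediately 3' of it; deletions remove the
    interval; insertions place ``alt_bases`` after the anchor base.
    Stated reference bases are checked against the mapped interval.
    """
    start, end = c_to_contig(model, v)
    if end > len(reference):
        raise CoordinateRangeError(
            f"{v.raw_text!r} maps beyond the reference (interval [{start}, {end}))"
        )
    segment = reference[start:end]
    if v.kind is VariantKind.SNV:
        if segment.upper() != v.ref_bases:
            raise ReferenceMismatchError(
                f"{v.raw_text!r}: expected {v.ref_bases!r} at contig offset "
                f"{start}, found {segment!r}"
            )
        return reference[:start] + v.alt_bases + reference[end:]
    if v.kind is VariantKind.DUP:
        if v.ref_bases and segment.upper() != v.ref_bases:
            raise ReferenceMismatchError(
                f"{v.raw_text!r}: expected duplicated bases {v.ref_bases!r} at "
                f"[{start}, {end}), found {segment!r}"
            )
        return reference[:end] + segment + reference[end:]
    if v.kind is VariantKind.DEL:
        if v.ref_bases and segment.upper() != v.ref_bases:
            raise ReferenceMismatchError(
                f"{v.raw_text!r}: expected deleted bases {v.ref_bases!r} at "
                f"[{start}, {end}), found {segment!r}"
            )
        return reference[:start] + reference[end:]
    # insertion: alt placed after the single anchored base
    return reference[: start + 1] + v.alt_bases + reference[start + 1 :]


def variant_length_change(v: CVariant) -> int:
    """Length difference (mutant - reference) produced by the variant."""
    if v.kind is VariantKind.SNV:
        return 0
    if v.kind is VariantKind.DUP:
        return v.span
    if v.kind is VariantKind.DEL:
        return -v.span
    return len(v.alt_bases)


def extract_region(
    model: GeneModel, reference: str, region: tuple
) -> tuple[str, tuple[int, int]]:
    """Extract a named region of the gene.

    ``region`` is ``("promoter", length)``, ``("intron", i)`` or
    ``("exon", i)`` with 1-based indices. Returns the subsequence and its
    0-based half-open contig interval.
    """
    kind = region[0]
    if kind == "promoter":
        length = int(region[1])
        if length > model.translation_start:
            raise CoordinateRangeError(
                f"promoter length {length} exceeds upstream sequence "
                f"({model.translation_start} bp available)"
            )
        interval = (model.translation_start - length, model.translation_start)
    elif kind == "intron":
        interval = model.intron(int(region[1]))
    elif kind == "exon":
        interval = model.exon(int(region[1]))
    else:
        raise ValueError(f"unknown region kind {kind!r}")
    a, b = interval
    if b > len(reference):
        raise CoordinateRangeError(
            f"region {region!r} interval [{a}, {b}) exceeds the reference"
        )
    return reference[a:b], interval


def read_gene_model_tsv(path_or_handle) -> GeneModel:
    """Read a gene model from a BED-like TSV.

    Columns: contig, start, end, feature; features are ``exon`` rows
    (0-based half-open) plus one ``CDS-start`` row whose start column is
    the contig offset of the ATG.
    """
    own = not hasattr(path_or_handle, "read")
    fh = open(path_or_handle) if own else path_or_handle
    try:
        exons: list[tuple[int, int]] = []
        contig = None
        tstart = None
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            parts = ln.split("\t")
            if len(parts) < 4:
                raise VariantParseError(f"gene model row needs 4 columns: {ln!r}")
            contig = parts[0]
            if parts[3] == "exon":
                exons.append((int(parts[1]), int(parts[2])))
            elif parts[3] == "CDS-start":
                tstart = int(parts[1])
    finally:
        if own:
            fh.close()
    if contig is None or tstart is None or not exons:
        raise VariantParseError("gene model TSV needs exon rows and a CDS-start row")
    exons.sort()
    return GeneModel(contig_id=contig, exons=tuple(exons), translation_start=tstart)


def write_gene_model_tsv(model: GeneModel, path_or_handle) -> None:
    own = not hasattr(path_or_handle, "write")
    fh = open(path_or_handle, "w") if own else path_or_handle
    try:
        fh.write("#contig\tstart\tend\tfeature\n")
        fh.write(
            f"{model.contig_id}\t{model.translation_start}\t"
            f"{model.translation_start + 3}\tCDS-start\n"
        )
        for a, b in model.exons:
            fh.write(f"{model.contig_id}\t{a}\t{b}\texon\n")
    finally:
        if own:
            fh.close()
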