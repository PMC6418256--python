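"""Reference sequences, transcript models and coordinate arithmetic.

Internal convention: all genomic coordinates are 0-based half-open on the
plus strand of the assembly.  GFF3 (1-based inclusive) and VCF (1-based)
are converted at the I/O boundary.  Exons of a transcript are stored in
transcription (5'→3') order, so "first exon" and "the donor of exon k" are
strand-agnostic concepts: for a minus-strand transcript the first exon is
the genomically last one.

The coding region is addressed in transcript coordinates: ``cds_start`` /
``cds_end`` are 0-based half-open offsets into the spliced cDNA.  HGVS-style
``c.`` positions (1-based within the CDS, with ``+k``/``-k`` intronic
offsets counted from the donor and acceptor respectively) are parsed by
:func:`parse_cdot` and mapped to genomic bases by
:func:`map_coding_position`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio.Seq import Seq

from .errors import CoordinateError, ModelError, ParseError, SequenceError

_COMPLEMENT = str.maketrans("ACGTNRYKMSWacgtnrykmsw", "TGCANYRMKSWtgcanyrmksw")

VALID_STRANDS = ("+", "-")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Reference access
# ---------------------------------------------------------------------------

def fetch_sequence(ref, contig: str, start: int, end: int) -> str:
    """Fetch [start, end) from ``ref`` (a dict of strings or a pyfaidx.Fasta).

    Raises :class:`CoordinateError` when the interval falls outside the
    contig or the contig is absent.
    """
    try:
        record = ref[contig]
    except KeyError as exc:
        raise CoordinateError(f"contig {contig!r} not in reference") from exc
    length = len(record)
    if start < 0 or end > length or start > end:
        raise CoordinateError(
            f"interval {contig}:{start}-{end} outside contig of length {length}"
        )
    chunk = record[start:end]
    seq = chunk.seq if hasattr(chunk, "seq") else chunk
    return str(seq).upper()


def contig_length(ref, contig: str) -> int:
    try:
        return len(ref[contig])
    except KeyError as exc:
        raise CoordinateError(f"contig {contig!r} not in reference") from exc


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open stranded genomic interval."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in VALID_STRANDS:
            raise CoordinateError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class CodingPosition:
    """HGVS-like coding position: CDS base (1-based) plus intronic offset.

    ``intron_offset`` 0 means exonic; +k is the k-th base of the intron
    downstream of the addressed exonic base (donor side); -k is the k-th
    base upstream of the acceptor.
    """

    coding_pos: int
    intron_offset: int = 0
    ref_allele: str = ""
    alt_allele: str = ""

    def __post_init__(self) -> None:
        if self.coding_pos < 1:
            raise ParseError(f"coding position must be >= 1, got {self.coding_pos}")

    def __str__(self) -> str:
        off = ""
        if self.intron_offset > 0:
            off = f"+{self.intron_offset}"
        elif self.intron_offset < 0:
            off = str(self.intron_offset)
        change = f"{self.ref_allele}>{self.alt_allele}" if self.ref_allele else ""
        return f"c.{self.coding_pos}{off}{change}"


@dataclass(frozen=True)
class TranscriptModel:
    """Ordered exons with a coding region, on one strand.

    ``exons`` are in transcription order.  ``cds_start``/``cds_end`` are
    0-based half-open offsets into the spliced cDNA.  A coding length that
    is not a multiple of 3 is flagged (``frame_incomplete``), not fatal.
    """

    transcript_id: str
    gene_id: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    cds_start: int
    cds_end: int
    label: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise ModelError(f"invalid strand {self.strand!r}")
        if not self.exons:
            raise ModelError(f"{self.transcript_id}: transcript needs >= 1 exon")
        object.__setattr__(self, "exons", tuple(self.exons))
        contigs = {e.contig for e in self.exons}
        if len(contigs) != 1:
            raise ModelError(f"{self.transcript_id}: exons span multiple contigs")
        starts = [e.start for e in self.exons]
        ordered = starts == sorted(starts) if self.strand == "+" else starts == sorted(starts, reverse=True)
        if not ordered:
            raise ModelError(f"{self.transcript_id}: exons not in transcription order")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise ModelError(f"{self.transcript_id}: overlapping exons")
        if not (0 <= self.cds_start < self.cds_end <= self.spliced_length):
            raise ModelError(
                f"{self.transcript_id}: CDS [{self.cds_start}, {self.cds_end}) "
                f"outside spliced length {self.spliced_length}"
            )

    # -- geometry -----------------------------------------------------------

    @property
    def contig(self) -> str:
        return self.exons[0].contig

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start

    @property
    def frame_incomplete(self) -> bool:
        return self.cds_length % 3 != 0

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        """Introns in transcription order (intron k follows exon k)."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append(GenomicInterval(self.contig, a.end, b.start, "+"))
            else:
                out.append(GenomicInterval(self.contig, b.end, a.start, "-"))
        return tuple(out)

    @property
    def span(self) -> GenomicInterval:
        start = min(e.start for e in self.exons)
        end = max(e.end for e in self.exons)
        return GenomicInterval(self.contig, start, end, self.strand)

    # -- coordinate maps ----------------------------------------------------

    def transcript_to_genomic(self, toff: int) -> int:
        """Genomic (plus-strand) position of spliced offset ``toff``."""
        if not 0 <= toff < self.spliced_length:
            raise CoordinateError(
                f"{self.transcript_id}: offset {toff} outside spliced length"
            )
        for exon in self.exons:
            if toff < len(exon):
                if self.strand == "+":
                    return exon.start + toff
                return exon.end - 1 - toff
            toff -= len(exon)
        raise AssertionError("unreachable")

    def genomic_to_transcript(self, gpos: int) -> int | None:
        """Spliced offset of genomic position ``gpos``, or None if intronic."""
        acc = 0
        for exon in self.exons:
            if exon.contains(gpos):
                if self.strand == "+":
                    return acc + (gpos - exon.start)
                return acc + (exon.end - 1 - gpos)
            acc += len(exon)
        return None

    def exon_index_of_offset(self, toff: int) -> int:
        acc = 0
        for i, exon in enumerate(self.exons):
            acc += len(exon)
            if toff < acc:
                return i
        raise CoordinateError(f"offset {toff} outside transcript")

    def exon_offset_range(self, index: int) -> tuple[int, int]:
        """Half-open spliced-offset range occupied by exon ``index``."""
        start = sum(len(e) for e in self.exons[:index])
        return start, start + len(self.exons[index])

    def cds_genomic_intervals(self) -> tuple[GenomicInterval, ...]:
        """Genomic intervals covered by the CDS, transcription order."""
        out = []
        for i, exon in enumerate(self.exons):
            lo, hi = self.exon_offset_range(i)
            s = max(lo, self.cds_start)
            e = min(hi, self.cds_end)
            if s >= e:
                continue
            if self.strand == "+":
                g0 = exon.start + (s - lo)
                out.append(GenomicInterval(self.contig, g0, g0 + (e - s), "+"))
            else:
                g1 = exon.end - (s - lo)
                out.append(GenomicInterval(self.contig, g1 - (e - s), g1, "-"))
        return tuple(out)

    # -- sequence -----------------------------------------------------------

    def cdna(self, ref) -> str:
        return extract_cdna(self, ref)

    def cds_sequence(self, ref) -> str:
        return self.cdna(ref)[self.cds_start : self.cds_end]


# ---------------------------------------------------------------------------
# c.-notation
# ---------------------------------------------------------------------------

_CDOT_RE = re.compile(
    r"^c\.(?P<pos>\d+)(?:(?P<sign>[+-])(?P<off>\d+))?"
    r"(?P<ref>[ACGTN])>(?P<alt>[ACGTN])$"
)


def parse_cdot(notation: str) -> CodingPosition:
    """Parse ``c.<pos>[±<offset>]<ref>><alt>`` (whitespace/case tolerant).

    The published form ``C.901 + 1 G > A`` normalises to ``c.901+1G>A``.
    """
    compact = re.sub(r"\s+", "", notation)
    if not compact.lower().startswith("c."):
        raise ParseError(f"expected 'c.' prefix in {notation!r}")
    body = "c." + compact[2:].upper()
    m = _CDOT_RE.match(body)
    if m is None:
        # locate the offending token for a usable message
        rest = body[2:]
        if not re.match(r"^\d+", rest):
            raise ParseError(f"expected coding position after 'c.' in {notation!r}")
        tail = re.sub(r"^\d+([+-]\d+)?", "", rest)
        raise ParseError(f"malformed allele change {tail!r} in {notation!r}")
    sign = -1 if m.group("sign") == "-" else 1
    off = int(m.group("off")) * sign if m.group("off") else 0
    return CodingPosition(int(m.group("pos")), off, m.group("ref"), m.group("alt"))


def format_cdot(c: CodingPosition) -> str:
    return str(c)


def map_coding_position(t: TranscriptModel, c: CodingPosition) -> GenomicInterval:
    """Genomic base addressed by ``c`` on transcript ``t`` (length-1 interval)."""
    if c.coding_pos > t.cds_length:
        raise CoordinateError(
            f"c.{c.coding_pos} beyond CDS length {t.cds_length} of {t.transcript_id}"
        )
    toff = t.cds_start + c.coding_pos - 1
    if c.intron_offset == 0:
        g = t.transcript_to_genomic(toff)
        return GenomicInterval(t.contig, g, g + 1, t.strand)

    idx = t.exon_index_of_offset(toff)
    lo, hi = t.exon_offset_range(idx)
    if c.intron_offset > 0:
        if toff != hi - 1:
            raise CoordinateError(
                f"{c}: coding position is not the last base of exon {idx + 1}"
            )
        if idx >= len(t.exons) - 1:
            raise CoordinateError(f"{c}: exon {idx + 1} has no downstream intron")
        intron = t.introns[idx]
        if c.intron_offset > len(intron):
            raise CoordinateError(f"{c}: offset beyond intron length {len(intron)}")
        if t.strand == "+":
            g = intron.start + c.intron_offset - 1
        else:
            g = intron.end - c.intron_offset
    else:
        if toff != lo:
            raise CoordinateError(
                f"{c}: coding position is not the first base of exon {idx + 1}"
            )
        if idx == 0:
            raise CoordinateError(f"{c}: exon 1 has no upstream intron")
        intron = t.introns[idx - 1]
        if -c.intron_offset > len(intron):
            raise CoordinateError(f"{c}: offset beyond intron length {len(intron)}")
        if t.strand == "+":
            g = intron.end + c.intron_offset  # offset negative
        else:
            g = intron.start - c.intron_offset - 1
    return GenomicInterval(t.contig, g, g + 1, t.strand)


def coding_position_of(t: TranscriptModel, gpos: int) -> CodingPosition:
    """Inverse of :func:`map_coding_position` for CDS and intronic bases.

    Intronic bases are assigned to the nearer junction (donor side as +k,
    acceptor side as -k; ties go to the donor side, the HGVS convention).
    """
    toff = t.genomic_to_transcript(gpos)
    if toff is not None:
        cpos = toff - t.cds_start + 1
        if not 1 <= cpos <= t.cds_length:
            raise CoordinateError(f"position {gpos} is exonic but outside the CDS")
        return CodingPosition(cpos, 0)
    for k, intron in enumerate(t.introns):
        if not intron.contains(gpos):
            continue
        if t.strand == "+":
            d_donor = gpos - intron.start + 1
            d_acc = intron.end - gpos
        else:
            d_donor = intron.end - gpos
            d_acc = gpos - intron.start + 1
        _, hi = t.exon_offset_range(k)
        lo_next, _ = t.exon_offset_range(k + 1)
        if d_donor <= d_acc:
            return CodingPosition(hi - t.cds_start, d_donor)
        return CodingPosition(lo_next - t.cds_start + 1, -d_acc)
    raise CoordinateError(f"position {gpos} not within {t.transcript_id}")


# ---------------------------------------------------------------------------
# Sequence extraction / translation
# ---------------------------------------------------------------------------

def extract_cdna(t: TranscriptModel, ref) -> str:
    """Spliced cDNA of ``t``: exon sequences in transcription order,
    reverse-complemented for minus-strand transcripts."""
    parts = []
    for exon in t.exons:
        seq = fetch_sequence(ref, exon.contig, exon.start, exon.end)
        parts.append(reverse_complement(seq) if t.strand == "-" else seq)
    return "".join(parts)


@dataclass(frozen=True)
class TranslationReport:
    peptide: str
    stop_found: bool
    stop_codon_aa_position: int | None
    incomplete_codon: bool


_IUPAC = set("ACGTNRYKMSWBDHV")


def translate_cds(cdna: str, cds_start: int = 0) -> TranslationReport:
    """Translate from ``cds_start`` to the first stop (standard code).

    The peptide excludes the stop residue; ``stop_codon_aa_position`` is the
    1-based codon index of the stop codon itself.  A trailing incomplete
    codon is flagged when no stop is reached.
    """
    if not 0 <= cds_start <= len(cdna):
        raise CoordinateError(f"cds_start {cds_start} outside sequence")
    coding = cdna[cds_start:].upper()
    bad = set(coding) - _IUPAC
    if bad:
        raise SequenceError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    n_full = len(coding) // 3
    aa = str(Seq(coding[: n_full * 3]).translate())
    stop = aa.find("*")
    if stop >= 0:
        return TranslationReport(aa[:stop], True, stop + 1, False)
    return TranslationReport(aa, False, None, len(coding) % 3 != 0)


# ---------------------------------------------------------------------------
# GFF3 I/O
# ---------------------------------------------------------------------------

def write_gff3(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    """Write gene/mRNA/exon/CDS features (1-based inclusive at the boundary)."""
    lines = ["##gff-version 3"]
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    for gene_id, ts in by_gene.items():
        contig = ts[0].contig
        strand = ts[0].strand
        g_start = min(t.span.start for t in ts)
        g_end = max(t.span.end for t in ts)
        lines.append(
            f"{contig}\tsplicemap\tgene\t{g_start + 1}\t{g_end}\t.\t{strand}\t.\t"
            f"ID={gene_id};gene_id={gene_id}"
        )
        for t in ts:
            attrs = f"ID={t.transcript_id};Parent={gene_id};gene_id={gene_id};transcript_id={t.transcript_id}"
            if t.label:
                attrs += f";isoform_label={t.label}"
            lines.append(
                f"{contig}\tsplicemap\tmRNA\t{t.span.start + 1}\t{t.span.end}\t.\t"
                f"{t.strand}\t.\t{attrs}"
            )
            for i, exon in enumerate(t.exons, 1):
                lines.append(
                    f"{contig}\tsplicemap\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                    f"{t.strand}\t.\tID={t.transcript_id}.exon{i};Parent={t.transcript_id}"
                )
            phase = 0
            for j, cds in enumerate(t.cds_genomic_intervals(), 1):
                lines.append(
                    f"{contig}\tsplicemap\tCDS\t{cds.start + 1}\t{cds.end}\t.\t"
                    f"{t.strand}\t{phase}\tID={t.transcript_id}.cds{j};Parent={t.transcript_id}"
                )
                phase = (3 - ((len(cds) - phase) % 3)) % 3
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models (mRNA + exon + CDS) from a GFF3 file."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    out: list[TranscriptModel] = []
    for mrna in db.features_of_type("mRNA"):
        strand = mrna.strand
        exons = sorted(
            db.children(mrna, featuretype="exon"),
            key=lambda f: f.start,
            reverse=(strand == "-"),
        )
        intervals = tuple(
            GenomicInterval(e.seqid, e.start - 1, e.end, strand) for e in exons
        )
        cds_feats = list(db.children(mrna, featuretype="CDS"))
        if not cds_feats:
            raise ModelError(f"{mrna.id}: no CDS features")
        t_probe = TranscriptModel(
            transcript_id=mrna.id,
            gene_id=mrna.attributes.get("gene_id", [mrna.id])[0],
            strand=strand,
            exons=intervals,
            cds_start=0,
            cds_end=sum(len(i) for i in intervals),
        )
        offsets = []
        for cf in cds_feats:
            for g in (cf.start - 1, cf.end - 1):
                toff = t_probe.genomic_to_transcript(g)
                if toff is None:
                    raise ModelError(f"{mrna.id}: CDS outside exons")
                offsets.append(toff)
        label = mrna.attributes.get("isoform_label", [None])[0]
        out.append(
            replace(
                t_probe,
                cds_start=min(offsets),
                cds_end=max(offsets) + 1,
                label=label,
            )
        )
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    """Deterministic plain-text FASTA writer (insertion order preserved)."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
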