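"""Variant consequence classification and HIGH-impact shortlisting.

Each (variant, transcript) pair receives exactly one most-severe term from
a fixed severity ranking, with the usual annotator impact tiers:

HIGH      splice_donor_variant, splice_acceptor_variant, stop_gained,
          frameshift_variant, stop_lost, start_lost
MODERATE  missense_variant, inframe_indel
LOW       synonymous_variant, splice_region_variant
MODIFIER  intron_variant, utr_variant, upstream_variant,
          downstream_variant, intergenic_variant

Conventions (documented because the literature varies): the donor site is
intronic positions +1/+2, the acceptor -1/-2; splice_region_variant covers
intronic positions 3-8 from either junction and the first/last 3 exonic
bases of an exon; upstream/downstream extend 5 kb from the transcript span
in transcription orientation.  Intronic offsets are always counted in
transcription orientation, so minus-strand genes behave like mirrored
plus-strand genes.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from Bio.Seq import Seq

from .errors import DataError
from .genome_model import (
    GenomicInterval,
    TranscriptModel,
    fetch_sequence,
    reverse_complement,
)
from .synthetic_cohort import Variant

logger = logging.getLogger(__name__)

UPSTREAM_WINDOW = 5000
SPLICE_REGION_INTRON = range(3, 9)  # intronic distance from junction
SPLICE_REGION_EXON = 3  # exonic bases adjacent to a junction


class Term(str, enum.Enum):
    splice_donor_variant = "splice_donor_variant"
    splice_acceptor_variant = "splice_acceptor_variant"
    stop_gained = "stop_gained"
    frameshift_variant = "frameshift_variant"
    stop_lost = "stop_lost"
    start_lost = "start_lost"
    missense_variant = "missense_variant"
    inframe_indel = "inframe_indel"
    synonymous_variant = "synonymous_variant"
    splice_region_variant = "splice_region_variant"
    intron_variant = "intron_variant"
    utr_variant = "utr_variant"
    upstream_variant = "upstream_variant"
    downstream_variant = "downstream_variant"
    intergenic_variant = "intergenic_variant"


_SEVERITY = {term: rank for rank, term in enumerate(Term)}

IMPACT = {
    Term.splice_donor_variant: "HIGH",
    Term.splice_acceptor_variant: "HIGH",
    Term.stop_gained: "HIGH",
    Term.frameshift_variant: "HIGH",
    Term.stop_lost: "HIGH",
    Term.start_lost: "HIGH",
    Term.missense_variant: "MODERATE",
    Term.inframe_indel: "MODERATE",
    Term.synonymous_variant: "LOW",
    Term.splice_region_variant: "LOW",
    Term.intron_variant: "MODIFIER",
    Term.utr_variant: "MODIFIER",
    Term.upstream_variant: "MODIFIER",
    Term.downstream_variant: "MODIFIER",
    Term.intergenic_variant: "MODIFIER",
}


@dataclass(frozen=True)
class ConsequenceCall:
    variant: Variant
    transcript_id: str | None
    term: Term

    @property
    def impact(self) -> str:
        return IMPACT[self.term]

    def severity_rank(self) -> int:
        return _SEVERITY[self.term]


def severity_key(call: "ConsequenceCall") -> int:
    return call.severity_rank()


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _changed_range(v: Variant) -> tuple[int, int, int]:
    """(start0, end0, length_delta) of the genomic bases actually changed.

    VCF indel records carry an anchor base; the shared prefix is stripped.
    For a pure insertion the affected range is the zero-length point after
    the anchor, widened to one base for overlap tests.
    """
    ref, alt = v.ref, v.alt
    k = 0
    while k < len(ref) and k < len(alt) and ref[k] == alt[k]:
        k += 1
    start = v.pos - 1 + k
    end = v.pos - 1 + max(len(ref), k + 1)
    return start, end, len(alt) - len(ref)


def _intron_distance(t: TranscriptModel, intron: GenomicInterval, gpos: int) -> tuple[int, int]:
    """(distance from donor, distance from acceptor), both 1-based, in
    transcription orientation."""
    if t.strand == "+":
        return gpos - intron.start + 1, intron.end - gpos
    return intron.end - gpos, gpos - intron.start + 1


def _exonic_near_junction(t: TranscriptModel, exon_idx: int, gpos: int) -> bool:
    exon = t.exons[exon_idx]
    if t.strand == "+":
        d5, d3 = gpos - exon.start + 1, exon.end - gpos
    else:
        d5, d3 = exon.end - gpos, gpos - exon.start + 1
    near5 = exon_idx > 0 and d5 <= SPLICE_REGION_EXON
    near3 = exon_idx < len(t.exons) - 1 and d3 <= SPLICE_REGION_EXON
    return near5 or near3


def _snv_cds_term(t: TranscriptModel, toff: int, alt_plus: str, ref) -> Term:
    """Codon-comparison call for an exonic CDS SNV."""
    cds = t.cds_sequence(ref)
    ci = toff - t.cds_start  # offset within CDS, transcription orientation
    alt_tx = alt_plus if t.strand == "+" else reverse_complement(alt_plus)
    codon_i = ci // 3
    codon_lo = codon_i * 3
    wt_codon = cds[codon_lo : codon_lo + 3]
    if len(wt_codon) < 3:
        return Term.synonymous_variant  # trailing incomplete codon: no aa change
    mut_codon = wt_codon[: ci % 3] + alt_tx + wt_codon[ci % 3 + 1 :]
    wt_aa = str(Seq(wt_codon).translate())
    mut_aa = str(Seq(mut_codon).translate())
    if codon_i == 0 and wt_codon == "ATG" and mut_codon != "ATG":
        return Term.start_lost
    if wt_aa == mut_aa:
        return Term.synonymous_variant
    if mut_aa == "*":
        return Term.stop_gained
    if wt_aa == "*":
        return Term.stop_lost
    return Term.missense_variant


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_variant(v: Variant, t: TranscriptModel, ref) -> ConsequenceCall:
    """Most-severe consequence of ``v`` on transcript ``t``.

    Raises :class:`DataError` when the VCF REF allele disagrees with the
    reference sequence.
    """
    if v.contig != t.contig:
        return ConsequenceCall(v, t.transcript_id, Term.intergenic_variant)
    obs = fetch_sequence(ref, v.contig, v.pos - 1, v.pos - 1 + len(v.ref))
    if obs != v.ref.upper():
        raise DataError(
            f"{v}: REF allele disagrees with reference sequence ({obs!r})"
        )
    start, end, delta = _changed_range(v)
    is_snv = len(v.ref) == 1 and len(v.alt) == 1
    positions = range(start, end)

    terms: list[Term] = []
    span = t.span
    donor_hit = acceptor_hit = False
    for k, intron in enumerate(t.introns):
        for gpos in positions:
            if not intron.contains(gpos):
                continue
            d_donor, d_acc = _intron_distance(t, intron, gpos)
            if d_donor <= 2:
                donor_hit = True
            elif d_acc <= 2:
                acceptor_hit = True
            elif d_donor in SPLICE_REGION_INTRON or d_acc in SPLICE_REGION_INTRON:
                terms.append(Term.splice_region_variant)
            else:
                terms.append(Term.intron_variant)
    if donor_hit:
        terms.append(Term.splice_donor_variant)
    if acceptor_hit:
        terms.append(Term.splice_acceptor_variant)

    exonic_offsets = []
    for gpos in positions:
        toff = t.genomic_to_transcript(gpos)
        if toff is None:
            continue
        exonic_offsets.append(toff)
        exon_idx = t.exon_index_of_offset(toff)
        in_cds = t.cds_start <= toff < t.cds_end
        if is_snv and in_cds:
            terms.append(_snv_cds_term(t, toff, v.alt, ref))
        elif not is_snv and in_cds:
            terms.append(
                Term.frameshift_variant if delta % 3 else Term.inframe_indel
            )
        else:
            terms.append(Term.utr_variant)
        if _exonic_near_junction(t, exon_idx, gpos):
            terms.append(Term.splice_region_variant)

    if not terms:
        # outside the transcript entirely
        if t.strand == "+":
            before, after = start < span.start, start >= span.end
        else:
            before, after = start >= span.end, start < span.start
        dist = min(
            abs(start - span.start),
            abs(start - (span.end - 1)),
            abs(end - 1 - span.start),
            abs(end - 1 - (span.end - 1)),
        )
        if dist <= UPSTREAM_WINDOW and before:
            terms.append(Term.upstream_variant)
        elif dist <= UPSTREAM_WINDOW and after:
            terms.append(Term.downstream_variant)
        else:
            terms.append(Term.intergenic_variant)

    best = min(terms, key=lambda term: _SEVERITY[term])
    return ConsequenceCall(v, t.transcript_id, best)


def best_call(
    v: Variant, transcripts: Sequence[TranscriptModel], ref
) -> ConsequenceCall:
    """Most severe call of ``v`` over all transcripts (skipping data errors)."""
    calls = []
    for t in transcripts:
        try:
            calls.append(classify_variant(v, t, ref))
        except DataError as exc:
            logger.warning("skipping call: %s", exc)
    if not calls:
        return ConsequenceCall(v, None, Term.intergenic_variant)
    return min(calls, key=severity_key)


def shortlist_high_impact(
    candidates: Sequence[Variant],
    transcripts: Sequence[TranscriptModel],
    ref,
) -> tuple[list[ConsequenceCall], Counter]:
    """Retain candidates whose best call over any transcript is HIGH.

    Returns (HIGH calls, per-term counts over ALL candidates' best calls).
    """
    shortlist: list[ConsequenceCall] = []
    counts: Counter = Counter()
    for v in candidates:
        call = best_call(v, transcripts, ref)
        counts[call.term.value] += 1
        if call.impact == "HIGH":
            shortlist.append(call)
    return shortlist, counts


def write_annotated_vcf(
    calls: Sequence[ConsequenceCall], path: str | Path
) -> None:
    """Minimal annotated VCF: CSQ INFO key with term|impact|transcript."""
    lines = [
        "##fileformat=VCFv4.2",
        "##source=splicemap",
        '##INFO=<ID=CSQ,Number=.,Type=String,Description="term|impact|transcript_id">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for call in sorted(calls, key=lambda c: c.variant.key):
        v = call.variant
        info = f"CSQ={call.term.value}|{call.impact}|{call.transcript_id or '.'}"
        lines.append(f"{v.contig}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}")
    Path(path).write_text("\n".join(lines) + "\n")
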