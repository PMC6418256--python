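"""Aberrant-splicing outcomes of donor-site mutations, with ORF analysis.

A mutated splice donor (intronic +1/+2, canonically the GT dinucleotide)
abolishes constitutive splicing of its junction.  Two textbook outcomes
are enumerated rather than predicted:

* **exon skipping** — the exon whose donor was hit is omitted from the
  mature transcript (observed for the MLPH-type mutation);
* **intron retention** — the intron downstream of the mutated donor stays
  in the mature transcript (observed for the MITF-M-type mutation); the
  retained sequence carries the ALT base, and translation reads from the
  exon straight into the intron (and onward into the next exon if no stop
  occurs within the intron).

For a first-exon donor only intron retention is modelled (skipping the
first exon has no meaning for a cap-proximal exon).  Each outcome carries
an ORF report: frameshift arithmetic, premature-stop position in both
counting conventions (the stop codon's own 1-based codon index, and the
peptide length excluding the stop), the count of retained-intron
nucleotides preceding an intronic stop, the fraction of the wild-type
protein retained, and an NMD flag based on the 50-nt junction rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import AnnotationError, UsageError
from .genome_model import (
    GenomicInterval,
    TranscriptModel,
    fetch_sequence,
    reverse_complement,
    translate_cds,
)
from .synthetic_cohort import Variant

EXON_SKIP = "exon_skip"
INTRON_RETENTION = "intron_retention"

NMD_JUNCTION_RULE_NT = 50


@dataclass(frozen=True)
class DomainAnnotation:
    """A named domain on the wild-type protein, 1-based inclusive."""

    name: str
    aa_start: int
    aa_end: int

    def __post_init__(self) -> None:
        if not 1 <= self.aa_start <= self.aa_end:
            raise AnnotationError(
                f"domain {self.name}: invalid interval {self.aa_start}-{self.aa_end}"
            )


@dataclass(frozen=True)
class MutantTranscript:
    """A spliced mutant structure: genomic blocks in transcription order
    plus the realised cDNA (ALT base applied inside a retained intron)."""

    transcript_id: str
    mode: str
    blocks: tuple[GenomicInterval, ...]
    cdna: str
    cds_start: int | None  # None: the WT start codon exon was removed
    coding_delta: int  # removed (negative) or inserted (positive) coding nt
    retained_intron_range: tuple[int, int] | None  # spliced offsets
    junction_offsets: tuple[int, ...]  # spliced offsets of exon-exon junctions


@dataclass(frozen=True)
class OrfReport:
    frameshift: bool
    peptide: str
    peptide_length: int
    stop_found: bool
    stop_codon_aa_position: int | None
    stop_in_retained_intron_nt: int | None
    wt_identical_residues: int
    fraction_wt_retained: float
    wt_length: int
    no_start: bool = False
    incomplete_codon: bool = False


@dataclass(frozen=True)
class SpliceOutcome:
    mode: str
    transcript: MutantTranscript
    orf: OrfReport
    nmd_flag: bool


# ---------------------------------------------------------------------------
# mutant construction
# ---------------------------------------------------------------------------

def _donor_intron_index(t: TranscriptModel, v: Variant) -> int:
    """Intron whose donor (+1/+2) the variant hits, else UsageError."""
    gpos = v.pos - 1
    for k, intron in enumerate(t.introns):
        if not intron.contains(gpos):
            continue
        if t.strand == "+":
            d = gpos - intron.start + 1
        else:
            d = intron.end - gpos
        if d in (1, 2):
            return k
        raise UsageError(
            f"{v} is intronic position +{d} of {t.transcript_id}, not a donor base"
        )
    raise UsageError(f"{v} is not within an intron of {t.transcript_id}")


def _extract_blocks(blocks: Sequence[GenomicInterval], strand: str, ref) -> str:
    parts = []
    for b in blocks:
        seq = fetch_sequence(ref, b.contig, b.start, b.end)
        parts.append(reverse_complement(seq) if strand == "-" else seq)
    return "".join(parts)


def _junctions(blocks: Sequence[GenomicInterval]) -> tuple[int, ...]:
    out, acc = [], 0
    for b in blocks[:-1]:
        acc += len(b)
        out.append(acc)
    return tuple(out)


def _build_skip(t: TranscriptModel, k: int, ref) -> MutantTranscript:
    lo, hi = t.exon_offset_range(k)
    blocks = t.exons[:k] + t.exons[k + 1 :]
    cdna = _extract_blocks(blocks, t.strand, ref)
    if lo <= t.cds_start < hi:
        cds_start = None
    elif t.cds_start >= hi:
        cds_start = t.cds_start - (hi - lo)
    else:
        cds_start = t.cds_start
    removed_coding = max(0, min(hi, t.cds_end) - max(lo, t.cds_start))
    return MutantTranscript(
        transcript_id=t.transcript_id,
        mode=EXON_SKIP,
        blocks=blocks,
        cdna=cdna,
        cds_start=cds_start,
        coding_delta=-removed_coding,
        retained_intron_range=None,
        junction_offsets=_junctions(blocks),
    )


def _build_retention(t: TranscriptModel, k: int, v: Variant, ref) -> MutantTranscript:
    exon_a, exon_b = t.exons[k], t.exons[k + 1]
    intron = t.introns[k]
    if t.strand == "+":
        merged = GenomicInterval(t.contig, exon_a.start, exon_b.end, "+")
    else:
        merged = GenomicInterval(t.contig, exon_b.start, exon_a.end, "-")
    blocks = t.exons[:k] + (merged,) + t.exons[k + 2 :]
    cdna = list(_extract_blocks(blocks, t.strand, ref))

    # apply the ALT base inside the retained intron (transcription orientation)
    before = sum(len(b) for b in t.exons[:k])
    if t.strand == "+":
        var_off = before + (v.pos - 1 - exon_a.start)
        alt_tx = v.alt
    else:
        var_off = before + (exon_a.end - 1 - (v.pos - 1))
        alt_tx = reverse_complement(v.alt)
    cdna[var_off] = alt_tx

    junction_toff = before + len(exon_a)
    ilen = len(intron)
    cds_start = t.cds_start if t.cds_start < junction_toff else t.cds_start + ilen
    inserted_coding = ilen if t.cds_start <= junction_toff < t.cds_end else 0
    return MutantTranscript(
        transcript_id=t.transcript_id,
        mode=INTRON_RETENTION,
        blocks=blocks,
        cdna="".join(cdna),
        cds_start=cds_start,
        coding_delta=inserted_coding,
        retained_intron_range=(junction_toff, junction_toff + ilen),
        junction_offsets=_junctions(blocks),
    )


# ---------------------------------------------------------------------------
# ORF analysis
# ---------------------------------------------------------------------------

def analyze_orf(mt: MutantTranscript, wt_peptide: str) -> OrfReport:
    """Translate the mutant structure from the wild-type start codon.

    ``stop_codon_aa_position`` is the 1-based codon index of the stop
    itself; ``peptide_length`` excludes the stop — both conventions are
    reported because truncation sizes are quoted either way in the
    literature.
    """
    wt_len = len(wt_peptide)
    if mt.cds_start is None:
        return OrfReport(
            frameshift=mt.coding_delta % 3 != 0,
            peptide="",
            peptide_length=0,
            stop_found=False,
            stop_codon_aa_position=None,
            stop_in_retained_intron_nt=None,
            wt_identical_residues=0,
            fraction_wt_retained=0.0,
            wt_length=wt_len,
            no_start=True,
        )
    tr = translate_cds(mt.cdna, mt.cds_start)
    stop_intron_nt = None
    if (
        mt.mode == INTRON_RETENTION
        and tr.stop_found
        and mt.retained_intron_range is not None
    ):
        stop_start = mt.cds_start + 3 * (tr.stop_codon_aa_position - 1)
        lo, hi = mt.retained_intron_range
        if lo <= stop_start < hi:
            stop_intron_nt = stop_start - lo
    ident = 0
    for a, b in zip(tr.peptide, wt_peptide):
        if a != b:
            break
        ident += 1
    return OrfReport(
        frameshift=mt.coding_delta % 3 != 0,
        peptide=tr.peptide,
        peptide_length=len(tr.peptide),
        stop_found=tr.stop_found,
        stop_codon_aa_position=tr.stop_codon_aa_position,
        stop_in_retained_intron_nt=stop_intron_nt,
        wt_identical_residues=ident,
        fraction_wt_retained=ident / wt_len if wt_len else 0.0,
        wt_length=wt_len,
        incomplete_codon=tr.incomplete_codon,
    )


def _nmd_flag(mt: MutantTranscript, orf: OrfReport, wt_peptide: str) -> bool:
    """50-nt rule: premature stop more than 50 nt upstream of the last
    exon-exon junction of the MUTANT transcript."""
    if not orf.stop_found or mt.cds_start is None:
        return False
    premature = orf.peptide != wt_peptide
    if not premature or not mt.junction_offsets:
        return False
    stop_end = mt.cds_start + 3 * orf.stop_codon_aa_position
    return mt.junction_offsets[-1] - stop_end > NMD_JUNCTION_RULE_NT


def model_donor_loss(
    t: TranscriptModel, v: Variant, ref
) -> list[SpliceOutcome]:
    """Enumerate splicing outcomes of a donor-site variant on ``t``.

    Internal-exon donor: exon skipping AND intron retention (the model
    enumerates, it does not predict which occurs).  First-exon donor:
    intron retention only.
    """
    k = _donor_intron_index(t, v)
    wt = translate_cds(t.cdna(ref), t.cds_start)
    mutants = []
    if k > 0:
        mutants.append(_build_skip(t, k, ref))
    mutants.append(_build_retention(t, k, v, ref))
    outcomes = []
    for mt in mutants:
        orf = analyze_orf(mt, wt.peptide)
        outcomes.append(
            SpliceOutcome(
                mode=mt.mode,
                transcript=mt,
                orf=orf,
                nmd_flag=_nmd_flag(mt, orf, wt.peptide),
            )
        )
    return outcomes


# ---------------------------------------------------------------------------
# Domain loss
# ---------------------------------------------------------------------------

def domain_loss(
    orf: OrfReport, domains: Sequence[DomainAnnotation]
) -> dict[str, str]:
    """Classify each WT domain as lost / truncated / intact.

    The boundary is the last wild-type-identical residue of the mutant
    peptide; frameshifted residues downstream of it never count as
    domain-bearing.
    """
    boundary = orf.wt_identical_residues
    out = {}
    for d in domains:
        if d.aa_end > orf.wt_length:
            raise AnnotationError(
                f"domain {d.name}: interval {d.aa_start}-{d.aa_end} beyond "
                f"WT length {orf.wt_length}"
            )
        if d.aa_start > boundary:
            out[d.name] = "lost"
        elif d.aa_end > boundary:
            out[d.name] = "truncated"
        else:
            out[d.name] = "intact"
    return out


def read_domain_annotations(path: str | Path) -> list[DomainAnnotation]:
    """TSV columns: protein_id, name, aa_start, aa_end."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        DomainAnnotation(rec.name, int(rec.aa_start), int(rec.aa_end))
        for rec in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def outcome_record(v: Variant, outcome: SpliceOutcome, domains=None) -> dict:
    rec = {
        "variant": str(v),
        "transcript_id": outcome.transcript.transcript_id,
        "mode": outcome.mode,
        "frameshift": outcome.orf.frameshift,
        "peptide_length": outcome.orf.peptide_length,
        "stop_codon_aa_position": outcome.orf.stop_codon_aa_position,
        "stop_in_retained_intron_nt": outcome.orf.stop_in_retained_intron_nt,
        "wt_identical_residues": outcome.orf.wt_identical_residues,
        "fraction_wt_retained": round(outcome.orf.fraction_wt_retained, 6),
        "wt_length": outcome.orf.wt_length,
        "no_start": outcome.orf.no_start,
        "nmd_flag": outcome.nmd_flag,
    }
    if domains:
        rec["domains"] = domain_loss(outcome.orf, domains)
    return rec


def write_outcome_report(records: Sequence[dict], json_path: str | Path, tsv_path: str | Path | None = None) -> None:
    Path(json_path).write_text(json.dumps(list(records), indent=2, sort_keys=True) + "\n")
    if tsv_path is not None:
        flat = [{k: v for k, v in r.items() if k != "domains"} for r in records]
        pd.DataFrame(flat).to_csv(tsv_path, sep="\t", index=False)
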