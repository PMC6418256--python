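"""Alternative-first-exon isoform grafting and re-annotation.

Genes like MITF express many isoforms that differ only in their first exon
(each driven by its own promoter) and then splice into a shared block of
downstream exons; some isoforms additionally include a short linker exon
(the 1B1b-like exon) between their first exon and the shared block, while
the melanocyte-specific M-type isoform splices directly.  Variant calls
made against the single annotated transcript miss consequences that exist
only on unannotated first exons — re-annotating against the augmented
transcript set is what turns such a "MODIFIER" intergenic/upstream call
into a HIGH splice-donor call.

First-exon coordinates are supplied as input (a TSV spec file); homology
discovery of the exons themselves is out of scope.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .consequence_annotator import ConsequenceCall, best_call, severity_key
from .errors import ModelError
from .genome_model import GenomicInterval, TranscriptModel
from .synthetic_cohort import Variant

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FirstExonSpec:
    """One alternative first exon: its interval, whether the linker exon is
    spliced in, and the CDS start offset within the first exon."""

    label: str
    interval: GenomicInterval
    includes_linker_exon: bool
    cds_start_offset: int

    def __post_init__(self) -> None:
        if self.cds_start_offset < 0 or self.cds_start_offset >= len(self.interval):
            raise ModelError(
                f"isoform {self.label}: cds_start_offset outside first exon"
            )


def _is_upstream(interval: GenomicInterval, block: Sequence[GenomicInterval], strand: str) -> bool:
    if strand == "+":
        return interval.end <= min(e.start for e in block)
    return interval.start >= max(e.end for e in block)


def add_first_exon_isoform(
    base: TranscriptModel,
    spec: FirstExonSpec,
    shared_exons: Sequence[GenomicInterval] | None = None,
    linker_exon: GenomicInterval | None = None,
) -> TranscriptModel:
    """Graft one alternative first exon onto the shared exon block.

    ``shared_exons`` defaults to every exon of ``base`` except its first.
    The grafted transcript inherits the genomic CDS end of ``base`` (the
    shared stop codon); its CDS starts at ``spec.cds_start_offset`` within
    the new first exon.  A non-ATG start is a warning, not an error.
    """
    if shared_exons is None:
        shared_exons = base.exons[1:]
    shared_exons = tuple(shared_exons)
    if not shared_exons:
        raise ModelError("shared exon block is empty")
    for exon in shared_exons + ((linker_exon,) if linker_exon else ()):
        if spec.interval.overlaps(exon):
            raise ModelError(
                f"isoform {spec.label}: first exon overlaps shared/linker exon {exon}"
            )
    if not _is_upstream(spec.interval, shared_exons, base.strand):
        raise ModelError(
            f"isoform {spec.label}: first exon is not upstream of the shared block"
        )
    exons = [GenomicInterval(spec.interval.contig, spec.interval.start, spec.interval.end, base.strand)]
    if spec.includes_linker_exon:
        if linker_exon is None:
            raise ModelError(f"isoform {spec.label}: linker exon requested but none given")
        exons.append(GenomicInterval(linker_exon.contig, linker_exon.start, linker_exon.end, base.strand))
    exons.extend(shared_exons)

    # genomic position of the last CDS base of the base transcript, mapped
    # into the grafted transcript to recompute cds_end
    cds_end_g = base.transcript_to_genomic(base.cds_end - 1)
    probe = TranscriptModel(
        transcript_id=f"{base.gene_id}-{spec.label}",
        gene_id=base.gene_id,
        strand=base.strand,
        exons=tuple(exons),
        cds_start=0,
        cds_end=sum(len(e) for e in exons),
        label=spec.label,
    )
    toff_end = probe.genomic_to_transcript(cds_end_g)
    if toff_end is None:
        raise ModelError(
            f"isoform {spec.label}: base CDS end is not inside the shared exons"
        )
    t = TranscriptModel(
        transcript_id=probe.transcript_id,
        gene_id=base.gene_id,
        strand=base.strand,
        exons=tuple(exons),
        cds_start=spec.cds_start_offset,
        cds_end=toff_end + 1,
        label=spec.label,
    )
    return t


def augment_gene(
    base: TranscriptModel,
    specs: Sequence[FirstExonSpec],
    shared_exons: Sequence[GenomicInterval] | None = None,
    linker_exon: GenomicInterval | None = None,
    ref=None,
) -> list[TranscriptModel]:
    """Base transcript plus one grafted transcript per first-exon spec."""
    out = [base]
    for spec in specs:
        t = add_first_exon_isoform(base, spec, shared_exons, linker_exon)
        if ref is not None:
            start = t.cdna(ref)[t.cds_start : t.cds_start + 3]
            if start != "ATG":
                logger.warning(
                    "isoform %s: CDS starts with %s, not ATG", spec.label, start
                )
        out.append(t)
    return out


def reannotate(
    candidates: Sequence[Variant],
    augmented: Sequence[TranscriptModel],
    ref,
    base: Sequence[TranscriptModel] | None = None,
) -> tuple[list[ConsequenceCall], Counter, list[dict]]:
    """HIGH shortlist over the augmented transcript set.

    When ``base`` is given, also reports candidates whose impact tier
    changed relative to the base annotation.
    """
    shortlist: list[ConsequenceCall] = []
    counts: Counter = Counter()
    changed: list[dict] = []
    for v in candidates:
        call = best_call(v, augmented, ref)
        counts[call.term.value] += 1
        if call.impact == "HIGH":
            shortlist.append(call)
        if base is not None:
            old = best_call(v, base, ref)
            if old.impact != call.impact:
                changed.append(
                    {
                        "variant": str(v),
                        "before": f"{old.term.value}|{old.impact}",
                        "after": f"{call.term.value}|{call.impact}",
                    }
                )
    return shortlist, counts, changed


# ---------------------------------------------------------------------------
# spec file I/O
# ---------------------------------------------------------------------------

_SPEC_COLUMNS = [
    "label",
    "contig",
    "start",
    "end",
    "strand",
    "includes_linker_exon",
    "cds_start_offset",
]


def read_first_exon_specs(path: str | Path) -> list[FirstExonSpec]:
    """TSV columns: label, contig, start, end (1-based inclusive), strand,
    includes_linker_exon, cds_start_offset."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"label": str})
    missing = set(_SPEC_COLUMNS) - set(df.columns)
    if missing:
        raise ModelError(f"first-exon spec file missing columns: {sorted(missing)}")
    specs = []
    for rec in df.itertuples(index=False):
        specs.append(
            FirstExonSpec(
                label=rec.label,
                interval=GenomicInterval(
                    rec.contig, int(rec.start) - 1, int(rec.end), rec.strand
                ),
                includes_linker_exon=bool(rec.includes_linker_exon),
                cds_start_offset=int(rec.cds_start_offset),
            )
        )
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise ModelError("duplicate isoform labels in spec file")
    return specs
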