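"""Self-contained synthetic study fixtures.

Emulates the mapping design of the source study: a small diploid cohort of
affected ("case") animals homozygous for a planted recessive splice-donor
SNV, plus unaffected controls, on a synthetic multi-gene reference.  The
generator is fully deterministic: one :class:`numpy.random.SeedSequence`
per run, spawned into independent child streams with a fixed draw order
(reference, causal genotypes, background variants, missingness) so that
changing the background-variant rate never perturbs the causal-site draw.

Default cohort sizes follow the study design the toolkit emulates: three
sequenced affected genomes filtered against unaffected genomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError
from .genome_model import (
    GenomicInterval,
    TranscriptModel,
    coding_position_of,
    reverse_complement,
    write_fasta,
    write_gff3,
)

# genotype codes used throughout the toolkit
HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

_GT_STRING = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@dataclass(frozen=True)
class Variant:
    """A biallelic variant; ``pos`` is 1-based as in VCF."""

    contig: str
    pos: int
    ref: str
    alt: str

    @property
    def key(self) -> tuple:
        return (self.contig, self.pos, self.ref, self.alt)

    def __str__(self) -> str:
        return f"{self.contig}:{self.pos}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class SampleRow:
    sample_id: str
    phenotype_group: str
    population: str


@dataclass
class CohortGenotypes:
    """Variant x sample genotype matrix joined to phenotype groups."""

    variants: list[Variant]
    matrix: np.ndarray  # int8, codes HOM_REF/HET/HOM_ALT/MISSING
    samples: list[str]
    sample_sheet: list[SampleRow]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.shape != (len(self.variants), len(self.samples)):
            raise ConfigError("genotype matrix shape mismatch")
        ids = [r.sample_id for r in self.sample_sheet]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate sample_ids in sample sheet")

    def group_of(self, sample: str) -> str:
        for row in self.sample_sheet:
            if row.sample_id == sample:
                return row.phenotype_group
        raise KeyError(sample)

    def sample_indices(self, groups: Sequence[str]) -> list[int]:
        wanted = set(groups)
        return [
            i
            for i, s in enumerate(self.samples)
            if self.group_of(s) in wanted
        ]


@dataclass(frozen=True)
class CausalSite:
    gene_index: int = 0
    exon_index: int = 1
    donor_offset: int = 1  # +1 or +2 into the downstream intron


@dataclass(frozen=True)
class CohortConfig:
    seed: int = 0
    n_contigs: int = 2
    contig_length: int = 30_000
    n_genes: int = 4
    exons_per_gene: tuple[int, int] = (4, 9)       # half-open draw range
    exon_length_range: tuple[int, int] = (60, 300)
    intron_length_range: tuple[int, int] = (100, 600)
    n_cases: int = 3
    n_controls: int = 3
    background_snv_rate: float = 1e-3
    causal_site: CausalSite = field(default_factory=CausalSite)
    control_het_fraction: float = 0.5
    missing_rate: float = 0.0
    avoid_splice_sites: bool = True
    phenotype_labels: Mapping[str, str] = field(
        default_factory=lambda: {"case": "silverblue", "control": "dark_brown"}
    )

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ConfigError("n_cases must be >= 1")
        if self.background_snv_rate < 0:
            raise ConfigError("background_snv_rate must be >= 0")
        if self.causal_site.donor_offset not in (1, 2):
            raise ConfigError("donor_offset must be +1 or +2")
        if self.causal_site.exon_index < 0:
            raise ConfigError("causal exon index must be >= 0")


# ---------------------------------------------------------------------------
# Reference + gene models
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _build_gene_region(
    rng: np.random.Generator,
    exon_lens: list[int],
    intron_lens: list[int],
) -> tuple[str, list[tuple[int, int]], int, int]:
    """Gene region in transcription orientation.

    Returns (region sequence, exon offsets within region, cds_start,
    cds_end in spliced coordinates).  Introns start GT and end AG; the CDS
    is stop-free with an ATG start and a terminal stop codon.
    """
    spliced = sum(exon_lens)
    utr5, utr3 = 12, 12
    coding = spliced - utr5 - utr3
    coding -= coding % 3
    cds_start = utr5
    cds_end = utr5 + coding
    n_codon = coding // 3
    codons = [_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_codon)]
    codons[0] = "ATG"
    codons[-1] = "TAA"
    cdna = _random_seq(rng, utr5) + "".join(codons) + _random_seq(
        rng, spliced - cds_end
    )
    parts = []
    exon_offsets = []
    pos = 0
    consumed = 0
    for i, elen in enumerate(exon_lens):
        exon_offsets.append((pos, pos + elen))
        parts.append(cdna[consumed : consumed + elen])
        consumed += elen
        pos += elen
        if i < len(intron_lens):
            ilen = intron_lens[i]
            intron = "GT" + _random_seq(rng, ilen - 4) + "AG"
            parts.append(intron)
            pos += ilen
    return "".join(parts), exon_offsets, cds_start, cds_end


def generate_reference(
    cfg: CohortConfig,
) -> tuple[dict[str, str], list[TranscriptModel]]:
    """Synthesize contigs and multi-exon gene models on both strands.

    Genes alternate strands (so both are represented whenever
    ``n_genes >= 2``) and are distributed round-robin over contigs.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(4)[0])
    contig_names = [f"ctg{i + 1}" for i in range(cfg.n_contigs)]
    contigs = {name: list(_random_seq(rng, cfg.contig_length)) for name in contig_names}
    cursors = {name: 500 for name in contig_names}
    transcripts: list[TranscriptModel] = []
    for g in range(cfg.n_genes):
        contig = contig_names[g % cfg.n_contigs]
        strand = "+" if g % 2 == 0 else "-"
        n_ex = int(rng.integers(*cfg.exons_per_gene))
        exon_lens = [int(x) for x in rng.integers(*cfg.exon_length_range, n_ex)]
        intron_lens = [int(x) for x in rng.integers(*cfg.intron_length_range, n_ex - 1)]
        region, exon_offsets, cds_start, cds_end = _build_gene_region(
            rng, exon_lens, intron_lens
        )
        g_start = cursors[contig]
        g_end = g_start + len(region)
        if g_end + 500 > cfg.contig_length:
            raise ConfigError(
                f"gene {g} does not fit on {contig}: needs {g_end + 500} bp, "
                f"contig_length is {cfg.contig_length}"
            )
        placed = region if strand == "+" else reverse_complement(region)
        contigs[contig][g_start:g_end] = list(placed)
        cursors[contig] = g_end + 1000
        exons = []
        for lo, hi in exon_offsets:
            if strand == "+":
                exons.append(GenomicInterval(contig, g_start + lo, g_start + hi, "+"))
            else:
                exons.append(
                    GenomicInterval(contig, g_end - hi, g_end - lo, "-")
                )
        transcripts.append(
            TranscriptModel(
                transcript_id=f"tx{g + 1}",
                gene_id=f"gene{g + 1}",
                strand=strand,
                exons=tuple(exons),
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    return {name: "".join(seq) for name, seq in contigs.items()}, transcripts


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _splice_site_positions(transcripts: Sequence[TranscriptModel]) -> set[tuple[str, int]]:
    """Genomic donor/acceptor dinucleotide positions of every intron."""
    out: set[tuple[str, int]] = set()
    for t in transcripts:
        for intron in t.introns:
            out.update((t.contig, p) for p in (intron.start, intron.start + 1))
            out.update((t.contig, p) for p in (intron.end - 2, intron.end - 1))
    return out


def simulate_cohort(
    cfg: CohortConfig,
    ref: Mapping[str, str],
    transcripts: Sequence[TranscriptModel],
) -> tuple[CohortGenotypes, list[SampleRow], Variant]:
    """Plant a recessive donor-site SNV and draw background variation.

    The planted variant is homozygous-alt in every case; each control is
    heterozygous with probability ``control_het_fraction`` and otherwise
    homozygous-reference.  Background SNVs are placed per-base at
    ``background_snv_rate`` with Hardy-Weinberg genotypes at a uniform
    allele frequency in [0.05, 0.95), avoiding splice dinucleotides when
    ``avoid_splice_sites`` is set.
    """
    seqs = np.random.SeedSequence(cfg.seed).spawn(4)
    rng_causal = np.random.default_rng(seqs[1])
    rng_bg = np.random.default_rng(seqs[2])
    rng_missing = np.random.default_rng(seqs[3])

    site = cfg.causal_site
    if site.gene_index >= len(transcripts):
        raise ConfigError(f"causal gene index {site.gene_index} out of range")
    t = transcripts[site.gene_index]
    if site.exon_index >= len(t.exons) - 1:
        raise ConfigError(
            f"causal exon {site.exon_index} of {t.transcript_id} has no "
            "downstream intron (cannot disrupt a donor of the last exon)"
        )
    intron = t.introns[site.exon_index]
    if t.strand == "+":
        gpos = intron.start + site.donor_offset - 1
    else:
        gpos = intron.end - site.donor_offset
    ref_base = ref[t.contig][gpos]
    # G>A in transcription orientation; express on the plus strand for VCF
    alt_base = "A" if t.strand == "+" else "T"
    planted = Variant(t.contig, gpos + 1, ref_base, alt_base)

    samples: list[str] = []
    sheet: list[SampleRow] = []
    case_label = cfg.phenotype_labels["case"]
    control_label = cfg.phenotype_labels["control"]
    for i in range(cfg.n_cases):
        sid = f"case_{i + 1}"
        samples.append(sid)
        pop = "novosibirsk" if i % 2 == 0 else "tver"
        sheet.append(SampleRow(sid, case_label, pop))
    for i in range(cfg.n_controls):
        sid = f"control_{i + 1}"
        samples.append(sid)
        sheet.append(SampleRow(sid, control_label, "novosibirsk"))

    causal_gts = [HOM_ALT] * cfg.n_cases + [
        HET if rng_causal.random() < cfg.control_het_fraction else HOM_REF
        for _ in range(cfg.n_controls)
    ]

    forbidden = {(t.contig, planted.pos - 1)}
    if cfg.avoid_splice_sites:
        forbidden |= _splice_site_positions(transcripts)

    variants: list[Variant] = []
    rows: list[list[int]] = []
    bases = "ACGT"
    for contig in sorted(ref):
        seq = ref[contig]
        hits = np.nonzero(rng_bg.random(len(seq)) < cfg.background_snv_rate)[0]
        for p in hits:
            p = int(p)
            if (contig, p) in forbidden:
                continue
            rb = seq[p]
            if rb not in bases:
                continue
            alt = bases.replace(rb, "")[int(rng_bg.integers(0, 3))]
            af = 0.05 + 0.9 * rng_bg.random()
            gts = [int(g) for g in rng_bg.binomial(2, af, len(samples))]
            variants.append(Variant(contig, p + 1, rb, alt))
            rows.append(gts)

    if cfg.missing_rate > 0 and rows:
        mask = rng_missing.random((len(rows), len(samples))) < cfg.missing_rate
        for i in range(len(rows)):
            for j in range(len(samples)):
                if mask[i, j]:
                    rows[i][j] = MISSING

    variants.append(planted)
    rows.append(causal_gts)
    order = sorted(range(len(variants)), key=lambda i: (variants[i].contig, variants[i].pos))
    variants = [variants[i] for i in order]
    matrix = np.array([rows[i] for i in order], dtype=np.int8)
    cohort = CohortGenotypes(variants, matrix, samples, sheet)
    return cohort, sheet, planted


# ---------------------------------------------------------------------------
# Emission
# ---------------------------------------------------------------------------

def write_vcf(cohort: CohortGenotypes, path: str | Path) -> None:
    """Plain VCF v4.2 with GT-only genotypes, sorted by contig then pos."""
    contigs = []
    for v in cohort.variants:
        if v.contig not in contigs:
            contigs.append(v.contig)
    lines = ["##fileformat=VCFv4.2", "##source=splicemap"]
    lines += [f"##contig=<ID={c}>" for c in sorted(contigs)]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(cohort.samples)
    )
    order = sorted(range(len(cohort.variants)), key=lambda i: (cohort.variants[i].contig, cohort.variants[i].pos))
    for i in order:
        v = cohort.variants[i]
        gts = "\t".join(_GT_STRING[int(g)] for g in cohort.matrix[i])
        lines.append(f"{v.contig}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_sample_sheet(sheet: Sequence[SampleRow], path: str | Path) -> None:
    lines = ["sample_id\tphenotype_group\tpopulation"]
    lines += [f"{r.sample_id}\t{r.phenotype_group}\t{r.population}" for r in sheet]
    Path(path).write_text("\n".join(lines) + "\n")


def read_sample_sheet(path: str | Path) -> list[SampleRow]:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if not line.strip():
                continue
            rec = dict(zip(header, line.rstrip("\n").split("\t")))
            rows.append(
                SampleRow(rec["sample_id"], rec["phenotype_group"], rec["population"])
            )
    return rows


def emit_cohort(
    cfg: CohortConfig,
    ref: Mapping[str, str],
    transcripts: Sequence[TranscriptModel],
    cohort: CohortGenotypes,
    planted: Variant,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write FASTA + GFF3 + multi-sample VCF + sample sheet + ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "reference.fa",
        "gff3": out / "genes.gff3",
        "vcf": out / "cohort.vcf",
        "samples": out / "samples.tsv",
        "truth": out / "ground_truth.json",
    }
    write_fasta(ref, paths["fasta"])
    write_gff3(transcripts, paths["gff3"])
    write_vcf(cohort, paths["vcf"])
    write_sample_sheet(cohort.sample_sheet, paths["samples"])
    t = transcripts[cfg.causal_site.gene_index]
    cdot = coding_position_of(t, planted.pos - 1)
    truth = {
        "variant": {"contig": planted.contig, "pos": planted.pos, "ref": planted.ref, "alt": planted.alt},
        "gene_id": t.gene_id,
        "transcript_id": t.transcript_id,
        "exon_index": cfg.causal_site.exon_index,
        "donor_offset": cfg.causal_site.donor_offset,
        "cdot": str(cdot),
        "seed": cfg.seed,
    }
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return paths


def generate_cohort_files(cfg: CohortConfig, out_dir: str | Path) -> dict[str, Path]:
    """One-shot: reference + cohort + emission (the `simulate` stage)."""
    ref, transcripts = generate_reference(cfg)
    cohort, _, planted = simulate_cohort(cfg, ref, transcripts)
    return emit_cohort(cfg, ref, transcripts, cohort, planted, out_dir)
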