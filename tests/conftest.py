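"""Shared fixtures: toy transcripts and synthetic reconstructions of the
two studied splice-donor loci (gene structures engineered so that the
published truncation arithmetic is reproduced exactly; the sequences
themselves are synthetic)."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from splicemap import (
    CohortConfig,
    GenomicInterval,
    TranscriptModel,
    Variant,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def random_sense_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n))


def no_t_seq(rng: np.random.Generator, n: int) -> str:
    """A sequence over {A, C, G}: stop-free in every reading frame."""
    return "".join("ACG"[i] for i in rng.integers(0, 3, n))


# ---------------------------------------------------------------------------
# toy two-exon transcript (plus the mirrored minus-strand version)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def toy_plus():
    """CDS exon A = [100, 130), intron [130, 200), exon B = [200, 260)."""
    rng = np.random.default_rng(11)
    seq = list("".join("ACGT"[i] for i in rng.integers(0, 4, 400)))
    seq[130:132] = "GT"
    seq[198:200] = "AG"
    contig = "".join(seq)
    t = TranscriptModel(
        transcript_id="toy+",
        gene_id="toy",
        strand="+",
        exons=(
            GenomicInterval("c1", 100, 130, "+"),
            GenomicInterval("c1", 200, 260, "+"),
        ),
        cds_start=0,
        cds_end=90,
    )
    return {"ref": {"c1": contig}, "t": t}


@pytest.fixture(scope="session")
def toy_minus(toy_plus):
    """Genomic mirror of ``toy_plus``: same spliced sequence, minus strand."""
    from splicemap.genome_model import reverse_complement

    L = len(toy_plus["ref"]["c1"])
    contig = reverse_complement(toy_plus["ref"]["c1"])
    t = TranscriptModel(
        transcript_id="toy-",
        gene_id="toy",
        strand="-",
        exons=(
            GenomicInterval("c1", L - 130, L - 100, "-"),
            GenomicInterval("c1", L - 260, L - 200, "-"),
        ),
        cds_start=0,
        cds_end=90,
    )
    return {"ref": {"c1": contig}, "t": t}


# ---------------------------------------------------------------------------
# MLPH-like reconstruction: exon-7 donor c.901+1G>A, skip stop at codon 308
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def mlph_like():
    """Synthetic nine-exon gene whose exon-7 skip reproduces the published
    frameshift arithmetic: exon 7 spans coding 796-901 (106 nt), the
    frameshifted read-through after the skip first hits a stop at codon
    308, and the 540-residue WT protein carries RBD/MBD/EFBD/ABD-style
    domain annotations."""
    rng = np.random.default_rng(77)
    exon_coding = [135, 132, 132, 132, 132, 132, 106, 400, 322]
    assert sum(exon_coding) == 1623

    prefix = "ATG" + random_sense_codons(rng, 264)          # coding 1..795
    filler = "GGG" + no_t_seq(rng, 103)                      # exon 7: 796..901
    tail = list("CCC" + no_t_seq(rng, 719))                  # coding 902..1623
    tail[126:129] = "TAA"   # skip-frame codon 308
    tail[719:722] = "TAA"   # WT stop (codon 541)
    cds = prefix + filler + "".join(tail)
    assert len(cds) == 1623

    intron_len = 200
    parts, exons, pos = [], [], 100
    consumed = 0
    contig = "chrMLPH"
    for i, elen in enumerate(exon_coding):
        exons.append(GenomicInterval(contig, pos, pos + elen, "+"))
        parts.append(cds[consumed : consumed + elen])
        consumed += elen
        pos += elen
        if i < len(exon_coding) - 1:
            parts.append("GT" + no_t_seq(rng, intron_len - 4) + "AG")
            pos += intron_len
    region = "".join(parts)
    genome = no_t_seq(rng, 100) + region + no_t_seq(rng, 100)
    t = TranscriptModel(
        transcript_id="MLPH_like_t1",
        gene_id="MLPH_like",
        strand="+",
        exons=tuple(exons),
        cds_start=0,
        cds_end=1623,
    )
    donor_pos0 = exons[6].end  # +1 base of intron 7
    variant = Variant(contig, donor_pos0 + 1, "G", "A")
    domains = {"RBD": (1, 146), "MBD": (147, 400), "EFBD": (320, 400), "ABD": (401, 540)}
    return {"ref": {contig: genome}, "t": t, "variant": variant, "domains": domains}


# ---------------------------------------------------------------------------
# MITF-like reconstruction: alternative first exons, 1M donor c.33+1G>A
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def mitf_like():
    """Synthetic multi-promoter gene: eight alternative first exons (A, J,
    C, E, H, D, B, M; all but M splice through a linker exon) over a
    shared block of eight downstream exons.  The M-type first exon has 33
    coding nt; its first intron carries an in-frame stop at intron
    positions 52-54, so retention yields a 28+stop product (stop codon at
    residue 29) keeping the first 11 WT residues."""
    rng = np.random.default_rng(99)
    contig = "chrMITF"

    shared_starts = [3400 + i * 400 for i in range(8)]  # exons 2..9, 150 nt
    shared = [GenomicInterval(contig, s, s + 150, "+") for s in shared_starts]
    linker = GenomicInterval(contig, 3000, 3030, "+")
    first_exon_starts = {
        "1A": 200, "1J": 500, "1C": 800, "1E": 1100,
        "1H": 1400, "1D": 1700, "1B": 2000, "1M": 2600,
    }

    genome = list(no_t_seq(rng, 12000))

    # shared coding content, frame-aligned for every isoform; the CDS ends
    # 12 nt before the end of exon 9 (block offset 1188)
    shared_block = random_sense_codons(rng, 395) + "TAA" + no_t_seq(rng, 12)
    assert len(shared_block) == 1200
    for exon, off in zip(shared, range(0, 1200, 150)):
        genome[exon.start : exon.end] = shared_block[off : off + 150]

    genome[linker.start : linker.end] = no_t_seq(rng, 30)

    # exon 1M: 20 nt UTR + ATG + 10 sense codons = 53 nt, then intron with
    # GT donor and an in-frame TAA at intron nt 52-54
    exon1m = no_t_seq(rng, 20) + "ATG" + random_sense_codons(rng, 10)
    m_start = first_exon_starts["1M"]
    m_iv = GenomicInterval(contig, m_start, m_start + 53, "+")
    genome[m_iv.start : m_iv.end] = exon1m
    intron = list(genome[m_iv.end : 3400])
    intron[0:2] = "GT"
    intron[2:51] = no_t_seq(rng, 49)
    intron[51:54] = "TAA"
    intron[-2:] = "AG"
    genome[m_iv.end : 3400] = intron

    # other first exons: 60 nt, 30 nt UTR + ATG + 9 codons; give each a
    # GT donor immediately downstream
    first_ivs = {}
    for label, start in first_exon_starts.items():
        if label == "1M":
            first_ivs[label] = m_iv
            continue
        iv = GenomicInterval(contig, start, start + 60, "+")
        genome[iv.start : iv.end] = no_t_seq(rng, 30) + "ATG" + random_sense_codons(rng, 9)
        genome[iv.end : iv.end + 2] = "GT"
        first_ivs[label] = iv
    # acceptor upstream of the linker and of shared exon 2
    genome[linker.start - 2 : linker.start] = "AG"
    genome[shared[0].start - 2 : shared[0].start] = "AG"
    genome[linker.end : linker.end + 2] = "GT"

    # the single annotated ("base") transcript: its own first exon + shared
    base_first = GenomicInterval(contig, 2300, 2360, "+")
    genome[base_first.start : base_first.end] = (
        no_t_seq(rng, 30) + "ATG" + random_sense_codons(rng, 9)
    )
    genome[base_first.end : base_first.end + 2] = "GT"
    base = TranscriptModel(
        transcript_id="MITF_base",
        gene_id="MITF_like",
        strand="+",
        exons=(base_first,) + tuple(shared),
        cds_start=30,
        cds_end=60 + 1188,
    )
    ref = {contig: "".join(genome)}
    donor_pos0 = m_iv.end  # +1 base of the M-isoform first intron
    variant = Variant(contig, donor_pos0 + 1, "G", "A")
    return {
        "ref": ref,
        "base": base,
        "shared": tuple(shared),
        "linker": linker,
        "first_exons": first_ivs,
        "variant": variant,
        "m_interval": m_iv,
    }


@pytest.fixture(scope="session")
def default_cohort(tmp_path_factory):
    """Default synthetic cohort emitted to disk once per session."""
    from splicemap import generate_cohort_files

    out = tmp_path_factory.mktemp("cohort")
    paths = generate_cohort_files(CohortConfig(seed=1), out)
    return paths
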