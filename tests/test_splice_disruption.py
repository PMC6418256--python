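"""Exon-skip / intron-retention modelling and ORF truncation analysis."""

import numpy as np
import pytest

from splicemap import (
    CohortConfig,
    DomainAnnotation,
    FirstExonSpec,
    Variant,
    add_first_exon_isoform,
    analyze_orf,
    domain_loss,
    generate_reference,
    model_donor_loss,
    translate_cds,
)
from splicemap.errors import AnnotationError, UsageError
from splicemap.splice_disruption import EXON_SKIP, INTRON_RETENTION

from tests._oracles import splice_surgery


def _modes(outcomes):
    return sorted(o.mode for o in outcomes)


class TestModeEnumeration:
    def test_internal_exon_donor_gives_skip_and_retention(self, mlph_like):
        outcomes = model_donor_loss(mlph_like["t"], mlph_like["variant"], mlph_like["ref"])
        assert _modes(outcomes) == [EXON_SKIP, INTRON_RETENTION]

    def test_first_exon_donor_gives_retention_only(self, mitf_like):
        spec = FirstExonSpec("1M", mitf_like["m_interval"], False, 20)
        t = add_first_exon_isoform(mitf_like["base"], spec, mitf_like["shared"])
        outcomes = model_donor_loss(t, mitf_like["variant"], mitf_like["ref"])
        assert _modes(outcomes) == [INTRON_RETENTION]

    def test_deep_intronic_variant_is_usage_error(self, mlph_like):
        t, ref = mlph_like["t"], mlph_like["ref"]
        pos0 = t.exons[6].end + 9
        v = Variant(t.contig, pos0 + 1, ref[t.contig][pos0], "T")
        with pytest.raises(UsageError):
            model_donor_loss(t, v, ref)


class TestPublishedArithmetic:
    """Synthetic reconstructions engineered to the published gene geometry."""

    def test_exon7_skip_frameshift_stops_at_codon_308(self, mlph_like):
        outcomes = model_donor_loss(mlph_like["t"], mlph_like["variant"], mlph_like["ref"])
        skip = next(o for o in outcomes if o.mode == EXON_SKIP)
        assert skip.orf.frameshift is True  # 106 nt removed, not a multiple of 3
        assert skip.orf.stop_codon_aa_position == 308
        assert skip.orf.peptide_length == 307
        assert skip.nmd_flag is True

    def test_exon7_skip_loses_cterminal_domains(self, mlph_like):
        outcomes = model_donor_loss(mlph_like["t"], mlph_like["variant"], mlph_like["ref"])
        skip = next(o for o in outcomes if o.mode == EXON_SKIP)
        domains = [
            DomainAnnotation(name, lo, hi)
            for name, (lo, hi) in mlph_like["domains"].items()
        ]
        status = domain_loss(skip.orf, domains)
        assert status == {
            "RBD": "intact", "MBD": "truncated", "EFBD": "lost", "ABD": "lost"
        }

    def test_first_intron_retention_truncates_after_11_wt_residues(self, mitf_like):
        spec = FirstExonSpec("1M", mitf_like["m_interval"], False, 20)
        t = add_first_exon_isoform(mitf_like["base"], spec, mitf_like["shared"])
        [ret] = model_donor_loss(t, mitf_like["variant"], mitf_like["ref"])
        assert ret.mode == INTRON_RETENTION
        assert ret.orf.wt_identical_residues == 11
        assert ret.orf.stop_in_retained_intron_nt == 51
        assert ret.orf.stop_codon_aa_position == 29  # counting the stop codon
        assert ret.orf.peptide_length == 28          # excluding the stop
        assert ret.nmd_flag is True                  # consistent with absent mRNA

    def test_retained_intron_carries_the_alt_base(self, mitf_like):
        spec = FirstExonSpec("1M", mitf_like["m_interval"], False, 20)
        t = add_first_exon_isoform(mitf_like["base"], spec, mitf_like["shared"])
        [ret] = model_donor_loss(t, mitf_like["variant"], mitf_like["ref"])
        lo, hi = ret.transcript.retained_intron_range
        assert ret.transcript.cdna[lo] == "A"  # GT -> AT donor
        assert ret.transcript.cdna[lo + 1] == "T"


class TestOrfReports:
    def test_toy_retention_counts_intronic_nucleotides(self):
        """33-nt coding first exon; retained intron reads GTAGGCTGA...: the
        in-frame TGA begins after 6 intronic nt."""
        from splicemap import GenomicInterval, TranscriptModel

        exon1 = "AAAAA" + "ATG" + "GCTGCTGCTGCTGCTGCTGCTGCTGCTGCT"  # 5 UTR + 33 CDS
        intron = "GTAGGCTGA" + "C" * 51  # stop TGA at intron nt 7-9
        exon2 = "GGGCCCGGGCCCTAAGGG"
        ref = {"c": exon1 + intron + exon2}
        i2 = len(exon1) + len(intron)
        t = TranscriptModel(
            "t", "g", "+",
            (
                GenomicInterval("c", 0, len(exon1), "+"),
                GenomicInterval("c", i2, i2 + len(exon2), "+"),
            ),
            5,
            5 + 33 + 12,
        )
        v = Variant("c", len(exon1) + 1, "G", "A")
        [ret] = model_donor_loss(t, v, ref)
        assert ret.orf.stop_in_retained_intron_nt == 6
        assert ret.orf.peptide_length == 11 + 2  # 11 exonic + 2 intronic residues
        assert ret.orf.stop_codon_aa_position == 14

    def test_inframe_exon_skip_is_clean_deletion(self):
        """An internal exon whose length is a multiple of 3 deletes exactly
        its codons without a frameshift."""
        found = 0
        ts_all = []
        for seed in range(41, 49):
            ref, ts = generate_reference(CohortConfig(seed=seed))
            ts_all.extend((t, ref) for t in ts)
        for t, ref in ts_all:
            wt = translate_cds(t.cds_sequence(ref))
            for k in range(1, len(t.exons) - 1):
                if len(t.exons[k]) % 3 != 0:
                    continue
                lo, hi = t.exon_offset_range(k)
                if not (t.cds_start <= lo and hi <= t.cds_end):
                    continue
                if (lo - t.cds_start) % 3 != 0:
                    continue  # codon-aligned skips only, for exact arithmetic
                intron = t.introns[k]
                if t.strand == "+":
                    pos0 = intron.start
                else:
                    pos0 = intron.end - 1
                v = Variant(t.contig, pos0 + 1, ref[t.contig][pos0],
                            "A" if ref[t.contig][pos0] != "A" else "C")
                outcomes = model_donor_loss(t, v, ref)
                skip = next(o for o in outcomes if o.mode == EXON_SKIP)
                assert skip.orf.frameshift is False
                # codon-aligned in-frame skip removes exactly the exon codons
                assert skip.orf.peptide_length == len(wt.peptide) - len(t.exons[k]) // 3
                found += 1
        assert found >= 1

    def test_fraction_wt_retained_decreases_as_donor_moves_5prime(self, mlph_like):
        t, ref = mlph_like["t"], mlph_like["ref"]
        fractions = []
        for k in range(1, len(t.exons) - 1):
            intron = t.introns[k]
            v = Variant(t.contig, intron.start + 1, ref[t.contig][intron.start], "A")
            outcomes = model_donor_loss(t, v, ref)
            ret = next(o for o in outcomes if o.mode == INTRON_RETENTION)
            fractions.append(ret.orf.fraction_wt_retained)
        assert fractions == sorted(fractions)


class TestSurgeryOracle:
    def test_matches_string_surgery_oracle_on_random_transcripts(self):
        """Both outcome modes vs an independent string-surgery + literal
        codon-table translation oracle, across many generated genes."""
        checked = 0
        for seed in range(30):
            cfg = CohortConfig(seed=100 + seed)
            ref, ts = generate_reference(cfg)
            for t in ts:
                coords = [(e.start, e.end) for e in t.exons]
                for k in range(1, len(t.exons) - 1):
                    intron = t.introns[k]
                    pos0 = intron.start if t.strand == "+" else intron.end - 1
                    rb = ref[t.contig][pos0]
                    v = Variant(t.contig, pos0 + 1, rb, "A" if rb != "A" else "C")
                    outcomes = model_donor_loss(t, v, ref)
                    for o in outcomes:
                        mode = "skip" if o.mode == EXON_SKIP else "retain"
                        exp = splice_surgery(
                            ref[t.contig], coords, t.strand, t.cds_start,
                            mode, k, var_pos0=pos0, alt=v.alt,
                        )
                        got = (o.orf.peptide, o.orf.stop_found, o.orf.stop_codon_aa_position)
                        assert got == exp, (seed, t.transcript_id, k, mode)
                        checked += 1
                    if checked >= 500:
                        return
        assert checked >= 100


class TestDomainLoss:
    @pytest.mark.parametrize(
        "interval, status",
        [((310, 400), "lost"), ((250, 350), "truncated"), ((10, 50), "intact")],
    )
    def test_boundary_classification(self, interval, status):
        from splicemap.splice_disruption import OrfReport

        orf = OrfReport(
            frameshift=True, peptide="M" * 330, peptide_length=330,
            stop_found=True, stop_codon_aa_position=331,
            stop_in_retained_intron_nt=None, wt_identical_residues=300,
            fraction_wt_retained=0.6, wt_length=500,
        )
        [result] = domain_loss(orf, [DomainAnnotation("D", *interval)]).values()
        assert result == status

    def test_domain_beyond_wt_length_is_annotation_error(self):
        from splicemap.splice_disruption import OrfReport

        orf = OrfReport(
            frameshift=False, peptide="M", peptide_length=1, stop_found=True,
            stop_codon_aa_position=2, stop_in_retained_intron_nt=None,
            wt_identical_residues=1, fraction_wt_retained=1.0, wt_length=10,
        )
        with pytest.raises(AnnotationError):
            domain_loss(orf, [DomainAnnotation("D", 5, 11)])
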