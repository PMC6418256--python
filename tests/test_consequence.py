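"""Consequence classification vs definitional oracles; strand symmetry."""

import numpy as np
import pytest

from splicemap import Term, Variant, classify_variant, shortlist_high_impact
from splicemap.consequence_annotator import IMPACT, UPSTREAM_WINDOW
from splicemap.errors import DataError

from tests._oracles import naive_translate_full, rc

SEVERITY = list(Term)


def oracle_classify_snv(t, ref, pos0, alt):
    """Independent classifier: region sets built directly from exon
    coordinates; coding calls via full-peptide comparison after mutating
    the contig string."""
    contig = ref[t.contig]
    applicable = set()

    for intron in t.introns:
        if intron.contains(pos0):
            if t.strand == "+":
                d_donor, d_acc = pos0 - intron.start + 1, intron.end - pos0
            else:
                d_donor, d_acc = intron.end - pos0, pos0 - intron.start + 1
            if d_donor <= 2:
                applicable.add(Term.splice_donor_variant)
            elif d_acc <= 2:
                applicable.add(Term.splice_acceptor_variant)
            elif 3 <= d_donor <= 8 or 3 <= d_acc <= 8:
                applicable.add(Term.splice_region_variant)
            else:
                applicable.add(Term.intron_variant)

    toff = t.genomic_to_transcript(pos0)
    if toff is not None:
        idx = t.exon_index_of_offset(toff)
        exon = t.exons[idx]
        if t.strand == "+":
            d5, d3 = pos0 - exon.start + 1, exon.end - pos0
        else:
            d5, d3 = exon.end - pos0, pos0 - exon.start + 1
        if (idx > 0 and d5 <= 3) or (idx < len(t.exons) - 1 and d3 <= 3):
            applicable.add(Term.splice_region_variant)
        if t.cds_start <= toff < t.cds_end:
            mut_contig = contig[:pos0] + alt + contig[pos0 + 1 :]

            def cds_of(seq):
                parts = []
                for e in t.exons:
                    chunk = seq[e.start : e.end]
                    parts.append(rc(chunk) if t.strand == "-" else chunk)
                return "".join(parts)[t.cds_start : t.cds_end]

            wt_pep = naive_translate_full(cds_of(contig))
            mut_pep = naive_translate_full(cds_of(mut_contig))
            ci = toff - t.cds_start
            if ci // 3 == 0 and cds_of(contig)[:3] == "ATG" and cds_of(mut_contig)[:3] != "ATG":
                applicable.add(Term.start_lost)
            elif wt_pep == mut_pep:
                applicable.add(Term.synonymous_variant)
            else:
                i = next(j for j in range(len(wt_pep)) if wt_pep[j] != mut_pep[j])
                if mut_pep[i] == "*":
                    applicable.add(Term.stop_gained)
                elif wt_pep[i] == "*":
                    applicable.add(Term.stop_lost)
                else:
                    applicable.add(Term.missense_variant)
        else:
            applicable.add(Term.utr_variant)

    if not applicable:
        span = t.span
        upstream = pos0 < span.start if t.strand == "+" else pos0 >= span.end
        dist = min(abs(pos0 - span.start), abs(pos0 - (span.end - 1)))
        if dist <= UPSTREAM_WINDOW:
            applicable.add(
                Term.upstream_variant if upstream else Term.downstream_variant
            )
        else:
            applicable.add(Term.intergenic_variant)

    return min(applicable, key=SEVERITY.index)


class TestClassifyExamples:
    def test_donor_plus_one_is_high(self, mlph_like):
        call = classify_variant(mlph_like["variant"], mlph_like["t"], mlph_like["ref"])
        assert call.term == Term.splice_donor_variant and call.impact == "HIGH"

    def test_intronic_plus_ten_is_modifier(self, mlph_like):
        t, ref = mlph_like["t"], mlph_like["ref"]
        pos0 = t.exons[6].end + 9
        v = Variant(t.contig, pos0 + 1, ref[t.contig][pos0], "T")
        call = classify_variant(v, t, ref)
        assert call.term == Term.intron_variant and call.impact == "MODIFIER"

    def test_synonymous_third_position_is_low(self):
        # single-exon gene: ATG AAA TAA; AAA->AAG is Lys->Lys
        from splicemap import GenomicInterval, TranscriptModel

        ref = {"c": "ATGAAATAA"}
        t = TranscriptModel("t", "g", "+", (GenomicInterval("c", 0, 9, "+"),), 0, 9)
        call = classify_variant(Variant("c", 6, "A", "G"), t, ref)
        assert call.term == Term.synonymous_variant and call.impact == "LOW"

    def test_ref_mismatch_is_data_error(self, mlph_like):
        t, ref = mlph_like["t"], mlph_like["ref"]
        v = Variant(t.contig, 1, "T" if ref[t.contig][0] != "T" else "A", "C")
        with pytest.raises(DataError):
            classify_variant(v, t, ref)

    def test_frameshift_vs_inframe_indel(self, mlph_like):
        t, ref = mlph_like["t"], mlph_like["ref"]
        exon3 = t.exons[2]
        pos0 = exon3.start + 10
        anchor = ref[t.contig][pos0]
        tail2 = ref[t.contig][pos0 + 1 : pos0 + 3]
        tail3 = ref[t.contig][pos0 + 1 : pos0 + 4]
        fs = classify_variant(Variant(t.contig, pos0 + 1, anchor + tail2, anchor), t, ref)
        inf = classify_variant(Variant(t.contig, pos0 + 1, anchor + tail3, anchor), t, ref)
        assert fs.term == Term.frameshift_variant and fs.impact == "HIGH"
        assert inf.term == Term.inframe_indel and inf.impact == "MODERATE"

    def test_deletion_spanning_donor_is_splice_call(self, mlph_like):
        t, ref = mlph_like["t"], mlph_like["ref"]
        exon7 = t.exons[6]
        pos0 = exon7.end - 2  # anchor inside exon, deletion eats the GT donor
        seq = ref[t.contig][pos0 : pos0 + 4]
        call = classify_variant(Variant(t.contig, pos0 + 1, seq, seq[0]), t, ref)
        assert call.term == Term.splice_donor_variant


class TestOracleEquivalence:
    @pytest.mark.parametrize("fixture", ["mitf_like", "mlph_like"])
    def test_matches_definitional_oracle_on_random_positions(self, fixture, request):
        data = request.getfixturevalue(fixture)
        t = data.get("base") or data["t"]
        ref = data["ref"]
        contig = ref[t.contig]
        rng = np.random.default_rng(31)
        span = t.span
        lo = max(0, span.start - 6000)
        hi = min(len(contig) - 1, span.end + 6000)
        n_checked = 0
        for pos0 in rng.integers(lo, hi, 300):
            pos0 = int(pos0)
            base = contig[pos0]
            alt = "ACGT"[("ACGT".index(base) + 1) % 4]
            v = Variant(t.contig, pos0 + 1, base, alt)
            call = classify_variant(v, t, ref)
            assert call.term == oracle_classify_snv(t, ref, pos0, alt), (
                f"pos0={pos0}"
            )
            n_checked += 1
        assert n_checked >= 100

    def test_strand_symmetry_on_mirrored_gene(self, toy_plus, toy_minus):
        rng = np.random.default_rng(37)
        L = len(toy_plus["ref"]["c1"])
        for pos0 in rng.integers(80, 280, 120):
            pos0 = int(pos0)
            base = toy_plus["ref"]["c1"][pos0]
            alt = "ACGT"[("ACGT".index(base) + 2) % 4]
            v = Variant("c1", pos0 + 1, base, alt)
            mpos0 = L - 1 - pos0
            mv = Variant("c1", mpos0 + 1, rc(base), rc(alt))
            a = classify_variant(v, toy_plus["t"], toy_plus["ref"])
            b = classify_variant(mv, toy_minus["t"], toy_minus["ref"])
            assert a.term == b.term


class TestShortlist:
    def test_impact_table_is_total_over_terms(self):
        assert set(IMPACT) == set(Term)
        assert set(IMPACT.values()) == {"HIGH", "MODERATE", "LOW", "MODIFIER"}

    def test_empty_candidates_give_empty_shortlist(self, mlph_like):
        short, counts = shortlist_high_impact([], [mlph_like["t"]], mlph_like["ref"])
        assert short == [] and sum(counts.values()) == 0

    def test_second_high_candidate_grows_shortlist_to_two(self, mlph_like):
        """A stop-gained candidate alongside the donor variant gives a
        two-entry HIGH shortlist."""
        t, ref = mlph_like["t"], mlph_like["ref"]
        cds = t.cds_sequence(ref)
        # find a codon-aligned TGC/TGT: third base -> A creates TGA
        ci = next(
            i for i in range(0, len(cds) - 3, 3) if cds[i : i + 2] == "TG" and cds[i + 2] in "CT"
        )
        pos0 = t.transcript_to_genomic(t.cds_start + ci + 2)
        stop_v = Variant(t.contig, pos0 + 1, ref[t.contig][pos0], "A")
        short, _ = shortlist_high_impact([mlph_like["variant"], stop_v], [t], ref)
        assert len(short) == 2
        assert {c.term for c in short} == {Term.splice_donor_variant, Term.stop_gained}

    def test_shortlist_keeps_only_high(self, mlph_like):
        t, ref = mlph_like["t"], mlph_like["ref"]
        intronic = Variant(
            t.contig, t.exons[0].end + 10, ref[t.contig][t.exons[0].end + 9], "T"
        )
        short, counts = shortlist_high_impact(
            [mlph_like["variant"], intronic], [t], ref
        )
        assert [c.variant for c in short] == [mlph_like["variant"]]
        assert counts["splice_donor_variant"] == 1 and counts["intron_variant"] == 1
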