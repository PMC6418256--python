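"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive and shares no code path with the
package: a literal codon table, plain-python scans, string surgery and
Fraction arithmetic.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

# literal standard genetic code (independent of Bio.Seq)
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def naive_translate_full(seq: str) -> str:
    """Translate every complete codon, stops rendered as '*'."""
    return "".join(
        CODON_TABLE.get(seq[i : i + 3], "X") for i in range(0, len(seq) - 2, 3)
    )


def naive_translate_to_stop(seq: str) -> tuple[str, bool, int | None]:
    """(peptide, stop_found, 1-based stop codon index)."""
    pep = []
    for i in range(0, len(seq) - 2, 3):
        aa = CODON_TABLE.get(seq[i : i + 3], "X")
        if aa == "*":
            return "".join(pep), True, i // 3 + 1
        pep.append(aa)
    return "".join(pep), False, None


def brute_recessive(
    codes_by_variant,
    case_idx,
    control_idx,
    missing_case_policy="disqualify",
    missing_control_policy="not_hom_alt",
):
    """Indices of kept variants by a per-variant literal scan.

    Codes: 0 hom_ref, 1 het, 2 hom_alt, -1 missing.
    """
    kept = []
    for i, row in enumerate(codes_by_variant):
        case = [row[j] for j in case_idx]
        if missing_case_policy == "disqualify":
            ok = all(c == 2 for c in case)
        else:
            seen = [c for c in case if c != -1]
            ok = bool(seen) and all(c == 2 for c in seen)
        if not ok:
            continue
        ctrl = [row[j] for j in control_idx]
        if any(c == 2 for c in ctrl):
            continue
        if missing_control_policy == "disqualify" and any(c == -1 for c in ctrl):
            continue
        kept.append(i)
    return kept


def naive_amplicons(template, forward, reverse, max_product):
    """Exact-match amplicon scan over all position pairs."""
    t = template.upper()
    f = forward.upper()
    r = rc(reverse.upper())
    out = []
    for i in range(len(t) - len(f) + 1):
        if t[i : i + len(f)] != f:
            continue
        for j in range(i + len(f), len(t) - len(r) + 1):
            if t[j : j + len(r)] != r:
                continue
            size = j + len(r) - i
            if size <= max_product:
                out.append((i, j + len(r), size))
    return sorted(out, key=lambda x: (x[2], x[0]))


def fisher_enumeration(a, b, c, d) -> Fraction:
    """Two-sided exact p as an exact Fraction, by table enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    obs = Fraction(comb(r1, a) * comb(r2, c1 - a), comb(n, c1))
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = Fraction(comb(r1, x) * comb(r2, c1 - x), comb(n, c1))
        if p <= obs:
            total += p
    return total


def splice_surgery(contig_seq, exon_coords, strand, cds_start, mode, k, var_pos0=None, alt=None):
    """Rebuild a mutant cDNA by string surgery and translate it naively.

    ``exon_coords``: genomic (start, end) pairs in transcription order.
    ``mode``: 'skip' removes exon k; 'retain' keeps intron k (with the alt
    base substituted at genomic position ``var_pos0``).
    Returns (peptide, stop_found, stop_idx) from translating the mutant
    cDNA at the WT ``cds_start`` offset (None when the start exon is gone).
    """
    seq = contig_seq
    if mode == "skip":
        coords = exon_coords[:k] + exon_coords[k + 1 :]
        lo = sum(e - s for s, e in exon_coords[:k])
        hi = lo + (exon_coords[k][1] - exon_coords[k][0])
        if lo <= cds_start < hi:
            return None
        new_start = cds_start if cds_start < lo else cds_start - (hi - lo)
    else:
        if strand == "+":
            merged = (exon_coords[k][0], exon_coords[k + 1][1])
        else:
            merged = (exon_coords[k + 1][0], exon_coords[k][1])
        coords = exon_coords[:k] + [merged] + exon_coords[k + 2 :]
        if var_pos0 is not None:
            seq = seq[:var_pos0] + alt + seq[var_pos0 + 1 :]
        junction = sum(e - s for s, e in exon_coords[: k + 1])
        if strand == "+":
            ilen = exon_coords[k + 1][0] - exon_coords[k][1]
        else:
            ilen = exon_coords[k][0] - exon_coords[k + 1][1]
        new_start = cds_start if cds_start < junction else cds_start + ilen
    parts = []
    for s, e in coords:
        chunk = seq[s:e]
        parts.append(rc(chunk) if strand == "-" else chunk)
    cdna = "".join(parts)
    return naive_translate_to_stop(cdna[new_start:])
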