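"""In-silico PCR: amplicon prediction on genomic or cDNA templates.

The forward primer is matched on the sense strand, the reverse primer as
its reverse complement downstream; the product size counts both primer
footprints (size = end - start with a half-open product interval).  The
default is exact matching (validation primers are exact designs); a small
mismatch tolerance exists for robustness experiments.  IUPAC degenerate
bases in primers match their expansion sets; an N in the template matches
nothing (conservative).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ConfigError
from .genome_model import reverse_complement

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward: str
    reverse: str
    max_product: int = 5000
    max_mismatches: int = 0
    expected_size: int | None = None
    annealing_t: float | None = None

    def __post_init__(self) -> None:
        for primer in (self.forward, self.reverse):
            if len(primer) < 10:
                raise ConfigError(f"{self.name}: primer shorter than 10 nt")
            bad = set(primer.upper()) - set(IUPAC_SETS)
            if bad:
                raise ConfigError(f"{self.name}: invalid primer bases {sorted(bad)}")
        if self.max_product <= len(self.forward) + len(self.reverse):
            raise ConfigError(f"{self.name}: max_product too small")


@dataclass(frozen=True)
class Amplicon:
    start: int  # 0-based, 5' end of the forward footprint
    end: int    # exclusive, 3' end of the reverse footprint
    size: int


def _match_positions(template: str, primer: str, max_mm: int) -> list[int]:
    """Start positions where ``primer`` matches ``template`` with at most
    ``max_mm`` mismatches.  Template N never matches a primer base."""
    template = template.upper()
    primer = primer.upper()
    n, m = len(template), len(primer)
    sets = [IUPAC_SETS[b] for b in primer]
    out = []
    for i in range(n - m + 1):
        mm = 0
        for j in range(m):
            if template[i + j] not in sets[j]:
                mm += 1
                if mm > max_mm:
                    break
        else:
            out.append(i)
    return out


def find_amplicons(
    template: str, p: PrimerPair, *, search_swapped: bool = False
) -> list[Amplicon]:
    """All products of ``p`` on ``template`` up to ``p.max_product`` bp,
    sorted by size then start.  Empty list when either primer is absent.
    """
    if not template:
        return []

    def _scan(fwd: str, rev: str) -> list[Amplicon]:
        f_hits = _match_positions(template, fwd, p.max_mismatches)
        r_hits = _match_positions(template, reverse_complement(rev), p.max_mismatches)
        found = []
        for f in f_hits:
            for r in r_hits:
                end = r + len(rev)
                if r >= f + len(fwd) and end - f <= p.max_product:
                    found.append(Amplicon(f, end, end - f))
        return found

    amps = _scan(p.forward, p.reverse)
    if search_swapped:
        amps += _scan(p.reverse, p.forward)
    return sorted(set(amps), key=lambda a: (a.size, a.start))


def rtpcr_presence(
    transcript_variants: Sequence[tuple[str, str]], p: PrimerPair
) -> list[dict]:
    """One row per (label, cDNA) template: the predicted product sizes.

    An empty product list models a blank gel lane (no amplification).
    """
    rows = []
    for label, cdna in transcript_variants:
        amps = find_amplicons(cdna, p)
        rows.append({"label": label, "product_sizes": [a.size for a in amps]})
    return rows


def read_primer_table(path: str | Path) -> list[PrimerPair]:
    """TSV columns: name, forward, reverse, expected_size, annealing_t
    (last two optional, for report comparison only)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    pairs = []
    for rec in df.itertuples(index=False):
        pairs.append(
            PrimerPair(
                name=str(rec.name),
                forward=str(rec.forward),
                reverse=str(rec.reverse),
                expected_size=(
                    int(rec.expected_size)
                    if "expected_size" in df.columns and pd.notna(rec.expected_size)
                    else None
                ),
                annealing_t=(
                    float(rec.annealing_t)
                    if "annealing_t" in df.columns and pd.notna(rec.annealing_t)
                    else None
                ),
            )
        )
    return pairs
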