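"""Genotype-phenotype cosegregation from genotype-count tables.

Input rows are phenotype groups (optionally by population) with genotype
class counts (hom-ref / het / hom-alt) and a carrier flag saying whether
the phenotype implies homozygosity for the trait allele.  Perfect
cosegregation of a recessive causal variant means every carrier-phenotype
animal is hom-alt and no non-carrier animal is: both concordance ratios
equal 1.0.  The carrier flag is explicit input (a config mapping), not
parsed from phenotype strings, because published tables mix coat-colour
names with genotype shorthand.

``fisher_exact`` gives the standard two-sided exact test by the method of
small p-values (sum of hypergeometric probabilities of all tables with
fixed margins no more probable than the observed one), computed in exact
integer arithmetic so ties are handled without floating-point ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import UndefinedResultError


@dataclass(frozen=True)
class GenotypeRow:
    phenotype: str
    population: str
    carrier: bool  # phenotype implies homozygosity for the trait allele
    n_hom_ref: int
    n_het: int
    n_hom_alt: int

    def __post_init__(self) -> None:
        if min(self.n_hom_ref, self.n_het, self.n_hom_alt) < 0:
            raise UndefinedResultError(f"{self.phenotype}: negative counts")

    @property
    def total(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt


def read_genotype_table(path: str | Path) -> list[GenotypeRow]:
    """TSV columns: phenotype, population, carrier, n_hom_ref, n_het,
    n_hom_alt.  Lines starting with '#' are comments."""
    df = pd.read_csv(path, sep="\t", comment="#")
    rows = []
    for rec in df.itertuples(index=False):
        carrier = str(rec.carrier).strip().lower() in ("1", "true", "yes")
        rows.append(
            GenotypeRow(
                str(rec.phenotype),
                str(rec.population),
                carrier,
                int(rec.n_hom_ref),
                int(rec.n_het),
                int(rec.n_hom_alt),
            )
        )
    return rows


def concordance(rows: Sequence[GenotypeRow]) -> dict[str, float]:
    """Carrier / non-carrier / overall genotype-phenotype concordance.

    carrier_concordance: fraction of carrier-phenotype animals that are
    hom-alt.  noncarrier_concordance: fraction of non-carrier animals that
    are NOT hom-alt.  overall: weighted mean over all animals.
    """
    carriers = [r for r in rows if r.carrier]
    noncarriers = [r for r in rows if not r.carrier]
    n_car = sum(r.total for r in carriers)
    n_non = sum(r.total for r in noncarriers)
    if n_car == 0 or n_non == 0:
        raise UndefinedResultError(
            "concordance needs >= 1 carrier and >= 1 non-carrier animal"
        )
    car_ok = sum(r.n_hom_alt for r in carriers)
    non_ok = sum(r.total - r.n_hom_alt for r in noncarriers)
    return {
        "carrier_concordance": car_ok / n_car,
        "noncarrier_concordance": non_ok / n_non,
        "overall": (car_ok + non_ok) / (n_car + n_non),
    }


def fisher_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Exact integer hypergeometric enumeration; p = sum of P(table) over all
    tables with the observed margins whose probability is <= that of the
    observed table (ties included exactly).
    """
    if min(a, b, c, d) < 0:
        raise UndefinedResultError("counts must be non-negative")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        raise UndefinedResultError("all-zero margin: test undefined")
    # weights proportional to hypergeometric probabilities (common
    # denominator comb(n, c1) cancels in the comparison)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    w_obs = comb(r1, a) * comb(r2, c1 - a)
    num = sum(
        w
        for x in range(lo, hi + 1)
        if (w := comb(r1, x) * comb(r2, c1 - x)) <= w_obs
    )
    return num / comb(n, c1)


def cosegregation_report(rows: Sequence[GenotypeRow]) -> dict:
    """Concordance ratios plus an exact carrier-vs-genotype association test.

    The 2x2 table is carrier/non-carrier phenotype x hom-alt/other
    genotype, pooled over populations.
    """
    conc = concordance(rows)
    a = sum(r.n_hom_alt for r in rows if r.carrier)
    b = sum(r.total - r.n_hom_alt for r in rows if r.carrier)
    c = sum(r.n_hom_alt for r in rows if not r.carrier)
    d = sum(r.total - r.n_hom_alt for r in rows if not r.carrier)
    return {
        **conc,
        "table": {"carrier_hom_alt": a, "carrier_other": b,
                  "noncarrier_hom_alt": c, "noncarrier_other": d},
        "fisher_p_two_sided": fisher_exact(a, b, c, d),
    }
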