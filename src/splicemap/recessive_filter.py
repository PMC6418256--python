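"""Case/control homozygosity filtering for recessive traits.

The selection rule: keep a variant iff it is homozygous for the alternate
allele in EVERY case sample and NOT homozygous-alt in ANY control sample.
Phenotype groups whose mutation is epistatic over the mapped trait (e.g. an
amelanotic group that cannot express a pigment-dilution phenotype) can be
excluded from the control set via configuration rather than silently used.

Missing-genotype policies are explicit because low-coverage genotype
matrices always contain no-calls:

* ``missing_case_policy`` default ``disqualify`` — a variant unobserved in
  a case cannot be called "common homozygous".
* ``missing_control_policy`` default ``not_hom_alt`` — the control
  criterion is literally "not in homozygous state", which a missing call
  satisfies; a warning is logged.  ``disqualify`` drops such variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .errors import ConfigError
from .synthetic_cohort import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    CohortGenotypes,
    SampleRow,
    Variant,
)

logger = logging.getLogger(__name__)

MISSING_CASE_POLICIES = ("disqualify", "tolerate")
MISSING_CONTROL_POLICIES = ("not_hom_alt", "disqualify")


@dataclass(frozen=True)
class FilterConfig:
    case_group: str
    control_groups: tuple[str, ...]
    excluded_groups: tuple[str, ...] = ()
    missing_case_policy: str = "disqualify"
    missing_control_policy: str = "not_hom_alt"

    def __post_init__(self) -> None:
        object.__setattr__(self, "control_groups", tuple(self.control_groups))
        object.__setattr__(self, "excluded_groups", tuple(self.excluded_groups))
        if self.case_group in self.control_groups:
            raise ConfigError("case_group cannot also be a control group")
        if set(self.excluded_groups) & set(self.control_groups):
            raise ConfigError("excluded_groups must be disjoint from control_groups")
        if self.missing_case_policy not in MISSING_CASE_POLICIES:
            raise ConfigError(f"unknown missing_case_policy {self.missing_case_policy!r}")
        if self.missing_control_policy not in MISSING_CONTROL_POLICIES:
            raise ConfigError(
                f"unknown missing_control_policy {self.missing_control_policy!r}"
            )


@dataclass
class FilterReport:
    """Stage counts of the selection funnel."""

    n_input: int = 0
    n_after_case: int = 0
    n_output: int = 0
    n_missing_control_passed: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# VCF loading
# ---------------------------------------------------------------------------

def _gt_code_for_alt(gt: tuple, alt_index: int) -> int:
    """Genotype code of a (possibly multi-allelic) GT w.r.t. one alt.

    Half-calls (one missing allele) are treated as missing.  Alleles other
    than the addressed alt count as reference for the decomposed row, so a
    het-alt genotype like 1/2 is het for each split row and hom-alt for
    neither.
    """
    if gt is None or len(gt) != 2 or any(a is None for a in gt):
        return MISSING
    n = sum(1 for a in gt if a == alt_index)
    return {0: HOM_REF, 1: HET, 2: HOM_ALT}[n]


def load_cohort_vcf(
    vcf_paths: Sequence[str | Path] | str | Path,
    sample_sheet: Sequence[SampleRow],
) -> CohortGenotypes:
    """Load one multi-sample VCF or merge several per-sample VCFs.

    Multi-allelic records are decomposed into biallelic rows (one per alt,
    input order preserved).  Per-sample files are merged on exact
    contig/pos/ref/alt; sites absent from a file are missing for its
    samples.  A sample-sheet sample found in no VCF is an error.
    """
    if isinstance(vcf_paths, (str, Path)):
        vcf_paths = [vcf_paths]
    wanted = [row.sample_id for row in sample_sheet]
    found: set[str] = set()
    sites: dict[tuple, dict[str, int]] = {}
    order: list[tuple] = []
    for path in vcf_paths:
        with pysam.VariantFile(str(path)) as vf:
            file_samples = [s for s in vf.header.samples if s in wanted]
            found.update(file_samples)
            for rec in vf.fetch() if vf.index is not None else vf:
                alts = rec.alts or ()
                for ai, alt in enumerate(alts, start=1):
                    key = (rec.contig, rec.pos, rec.ref, alt)
                    if key not in sites:
                        sites[key] = {}
                        order.append(key)
                    row = sites[key]
                    for s in file_samples:
                        gt = rec.samples[s].get("GT")
                        row[s] = _gt_code_for_alt(gt, ai)
    absent = [s for s in wanted if s not in found]
    if absent:
        raise ConfigError(
            "sample-sheet samples absent from all VCFs: " + ", ".join(absent)
        )
    variants = [Variant(*key) for key in order]
    matrix = np.full((len(order), len(wanted)), MISSING, dtype=np.int8)
    for i, key in enumerate(order):
        row = sites[key]
        for j, s in enumerate(wanted):
            if s in row:
                matrix[i, j] = row[s]
    return CohortGenotypes(variants, matrix, wanted, list(sample_sheet))


# ---------------------------------------------------------------------------
# Candidate selection
# ---------------------------------------------------------------------------

def recessive_candidates(
    g: CohortGenotypes, cfg: FilterConfig
) -> tuple[list[Variant], FilterReport]:
    """Apply the recessive-homozygosity rule; return sorted candidates.

    Output is sorted by (contig, pos, ref, alt) and is invariant under
    permutations of the sample columns.
    """
    groups = {row.phenotype_group for row in g.sample_sheet}
    case_idx = g.sample_indices([cfg.case_group])
    if cfg.control_groups:
        control_groups = [c for c in cfg.control_groups if c in groups]
    else:
        control_groups = sorted(
            groups - {cfg.case_group} - set(cfg.excluded_groups)
        )
    control_idx = g.sample_indices(control_groups)
    control_idx = [
        i for i in control_idx if g.group_of(g.samples[i]) not in cfg.excluded_groups
    ]
    if not case_idx:
        raise ConfigError(f"no case samples in group {cfg.case_group!r}")
    if not control_idx:
        raise ConfigError("no control samples remain after exclusions")

    report = FilterReport(n_input=len(g.variants))
    kept: list[Variant] = []
    cases = g.matrix[:, case_idx]
    controls = g.matrix[:, control_idx]
    for i, v in enumerate(g.variants):
        crow = cases[i]
        if cfg.missing_case_policy == "disqualify":
            case_ok = bool(np.all(crow == HOM_ALT))
        else:  # tolerate: missing case genotypes do not veto
            obs = crow[crow != MISSING]
            case_ok = obs.size > 0 and bool(np.all(obs == HOM_ALT))
        if not case_ok:
            continue
        report.n_after_case += 1
        krow = controls[i]
        if np.any(krow == HOM_ALT):
            continue
        n_missing = int(np.sum(krow == MISSING))
        if n_missing:
            if cfg.missing_control_policy == "disqualify":
                continue
            report.n_missing_control_passed += 1
            logger.warning(
                "variant %s: %d missing control genotype(s) treated as "
                "not-homozygous",
                v,
                n_missing,
            )
        kept.append(v)
    kept.sort(key=lambda v: v.key)
    report.n_output = len(kept)
    return kept, report


def write_filtered_vcf(
    g: CohortGenotypes, candidates: Sequence[Variant], path: str | Path
) -> None:
    """Emit the candidate subset as a plain VCF (same sample columns)."""
    from .synthetic_cohort import write_vcf

    wanted = {v.key for v in candidates}
    idx = [i for i, v in enumerate(g.variants) if v.key in wanted]
    sub = CohortGenotypes(
        [g.variants[i] for i in idx], g.matrix[idx], g.samples, g.sample_sheet
    )
    write_vcf(sub, path)


def write_filter_report(report: FilterReport, path: str | Path) -> None:
    lines = ["stage\tcount"]
    lines.append(f"input_variants\t{report.n_input}")
    lines.append(f"hom_alt_in_all_cases\t{report.n_after_case}")
    lines.append(f"not_hom_alt_in_controls\t{report.n_output}")
    lines.append(f"missing_control_passed\t{report.n_missing_control_passed}")
    Path(path).write_text("\n".join(lines) + "\n")
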