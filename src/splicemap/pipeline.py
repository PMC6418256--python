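"""End-to-end orchestration: simulate → filter → annotate → augment →
splice-report → pcr → cosegregate, as one reproducible run.

A single YAML config drives the run; every stage writes its outputs under
the run directory and is recorded (with record counts and output file
checksums) in ``manifest.json``.  Identical config + seed gives
byte-identical stage outputs; manifests differ only in timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import pyfaidx
import yaml

from . import __version__
from .consequence_annotator import Term, shortlist_high_impact, write_annotated_vcf
from .cosegregation import GenotypeRow, cosegregation_report
from .errors import ConfigError, SpliceMapError
from .genome_model import GenomicInterval, TranscriptModel, read_gff3, reverse_complement
from .insilico_pcr import PrimerPair, read_primer_table, rtpcr_presence
from .isoform_builder import augment_gene, read_first_exon_specs, reannotate
from .recessive_filter import (
    FilterConfig,
    load_cohort_vcf,
    recessive_candidates,
    write_filter_report,
    write_filtered_vcf,
)
from .splice_disruption import (
    model_donor_loss,
    outcome_record,
    read_domain_annotations,
    write_outcome_report,
)
from .synthetic_cohort import (
    HET,
    HOM_ALT,
    HOM_REF,
    CausalSite,
    CohortConfig,
    generate_cohort_files,
)

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "filter",
    "annotate",
    "augment",
    "splice_report",
    "pcr",
    "cosegregate",
)

_GT_LABEL = {HOM_REF: "n_hom_ref", HET: "n_het", HOM_ALT: "n_hom_alt"}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    return cfg


def _build_cohort_config(section: Mapping[str, Any], seed: int) -> CohortConfig:
    known = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(section) - known
    if unknown:
        raise ConfigError(f"unknown cohort config keys: {sorted(unknown)}")
    kwargs = dict(section)
    if "causal_site" in kwargs and isinstance(kwargs["causal_site"], Mapping):
        kwargs["causal_site"] = CausalSite(**kwargs["causal_site"])
    for tup_key in ("exons_per_gene", "exon_length_range", "intron_length_range"):
        if tup_key in kwargs:
            kwargs[tup_key] = tuple(kwargs[tup_key])
    kwargs.setdefault("seed", seed)
    return CohortConfig(**kwargs)


def validate_config(cfg: Mapping[str, Any]) -> None:
    """Schema check; raises ConfigError before any stage runs."""
    if "cohort" not in cfg and "inputs" not in cfg:
        raise ConfigError("config needs a 'cohort' (simulate) or 'inputs' section")
    if "filter" not in cfg or "case_group" not in cfg["filter"]:
        raise ConfigError("config needs filter.case_group")
    if "inputs" in cfg:
        inputs = cfg["inputs"]
        for key in ("vcf", "gff3", "fasta", "samples"):
            if key not in inputs:
                raise ConfigError(f"inputs section missing {key!r}")
            if not Path(inputs[key]).exists():
                raise ConfigError(f"inputs.{key}: no such file {inputs[key]!r}")
    for section in ("augment", "splice", "pcr", "cosegregate"):
        sec = cfg.get(section) or {}
        for key in ("first_exons", "domains", "primers", "table"):
            if key in sec and not Path(sec[key]).exists():
                raise ConfigError(f"{section}.{key}: no such file {sec[key]!r}")


def design_flanking_primers(
    t: TranscriptModel, exon_index: int, ref, size: int = 20
) -> PrimerPair:
    """Exact primers bracketing the affected exon on the WT cDNA.

    Forward: first ``size`` nt of the exon upstream of the affected exon
    (the affected exon itself for a first-exon site); reverse: complement
    of the last ``size`` nt of the exon downstream.
    """
    cdna = t.cdna(ref)
    f_exon = max(0, exon_index - 1)
    r_exon = exon_index + 1
    flo, _ = t.exon_offset_range(f_exon)
    _, rhi = t.exon_offset_range(r_exon)
    forward = cdna[flo : flo + size]
    reverse = reverse_complement(cdna[rhi - size : rhi])
    return PrimerPair(
        name=f"{t.transcript_id}_ex{f_exon + 1}-{r_exon + 1}",
        forward=forward,
        reverse=reverse,
        max_product=len(cdna) + 10_000,
    )


def run_pipeline(config: str | Path | Mapping[str, Any], out_dir: str | Path | None = None) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    cfg = load_config(config) if isinstance(config, (str, Path)) else dict(config)
    validate_config(cfg)
    seed = int(cfg.get("seed", 0))
    out = Path(out_dir or cfg.get("out_dir", "splicemap_run"))
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict[str, Any] = {
        "tool": "splicemap",
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "started": datetime.now(timezone.utc).isoformat(),
        "stages": [],
    }

    def record(stage: str, counts: dict, outputs: dict[str, Path]) -> None:
        manifest["stages"].append(
            {
                "name": stage,
                "counts": counts,
                "outputs": {
                    k: {"path": str(p), "sha256": _sha256(Path(p))}
                    for k, p in outputs.items()
                },
            }
        )
        logger.info("[%s] %s", stage, counts)

    # -- simulate -----------------------------------------------------------
    truth = None
    if "cohort" in cfg:
        ccfg = _build_cohort_config(cfg["cohort"] or {}, seed)
        paths = generate_cohort_files(ccfg, out / "sim")
        truth = json.loads(Path(paths["truth"]).read_text())
        files = {k: Path(v) for k, v in paths.items()}
        record("simulate", {"samples": ccfg.n_cases + ccfg.n_controls}, files)
    else:
        inputs = cfg["inputs"]
        files = {
            "vcf": Path(inputs["vcf"]),
            "gff3": Path(inputs["gff3"]),
            "fasta": Path(inputs["fasta"]),
            "samples": Path(inputs["samples"]),
        }
        record("simulate", {"provided_inputs": len(files)}, files)

    # -- filter -------------------------------------------------------------
    from .synthetic_cohort import read_sample_sheet

    sheet = read_sample_sheet(files["samples"])
    fsec = cfg["filter"]
    fcfg = FilterConfig(
        case_group=fsec["case_group"],
        control_groups=tuple(fsec.get("control_groups", ())),
        excluded_groups=tuple(fsec.get("excluded_groups", ())),
        missing_case_policy=fsec.get("missing_case_policy", "disqualify"),
        missing_control_policy=fsec.get("missing_control_policy", "not_hom_alt"),
    )
    cohort = load_cohort_vcf(files["vcf"], sheet)
    candidates, report = recessive_candidates(cohort, fcfg)
    cand_vcf = out / "candidates.vcf"
    report_tsv = out / "filter_report.tsv"
    write_filtered_vcf(cohort, candidates, cand_vcf)
    write_filter_report(report, report_tsv)
    record(
        "filter",
        {"variants_in": report.n_input, "candidates": report.n_output},
        {"candidates_vcf": cand_vcf, "report": report_tsv},
    )

    # -- annotate -----------------------------------------------------------
    ref = pyfaidx.Fasta(str(files["fasta"]))
    base_models = read_gff3(files["gff3"])
    shortlist, term_counts = shortlist_high_impact(candidates, base_models, ref)
    ann_vcf = out / "high_impact.vcf"
    write_annotated_vcf(shortlist, ann_vcf)
    record(
        "annotate",
        {"candidates": len(candidates), "high_shortlist": len(shortlist),
         "terms": dict(term_counts)},
        {"annotated_vcf": ann_vcf},
    )

    # -- augment ------------------------------------------------------------
    asec = cfg.get("augment") or {}
    models = list(base_models)
    changed: list = []
    if "first_exons" in asec:
        specs = read_first_exon_specs(asec["first_exons"])
        base_id = asec.get("base_transcript")
        base_t = next((t for t in models if t.transcript_id == base_id), None)
        if base_t is None:
            raise ConfigError(f"augment.base_transcript {base_id!r} not found in GFF3")
        linker = None
        if "linker" in asec:
            lk = asec["linker"]
            linker = GenomicInterval(
                lk["contig"], int(lk["start"]) - 1, int(lk["end"]), base_t.strand
            )
        grafted = augment_gene(
            base_t, specs, asec.get("shared_exons"), linker, ref=ref
        )[1:]
        models.extend(grafted)
        shortlist, term_counts, changed = reannotate(
            candidates, models, ref, base=base_models
        )
        write_annotated_vcf(shortlist, ann_vcf)
    aug_gff = out / "augmented.gff3"
    from .genome_model import write_gff3

    write_gff3(models, aug_gff)
    record(
        "augment",
        {"transcripts": len(models), "high_shortlist": len(shortlist),
         "tier_changes": len(changed)},
        {"augmented_gff3": aug_gff},
    )

    # -- splice report ------------------------------------------------------
    ssec = cfg.get("splice") or {}
    domains = (
        read_domain_annotations(ssec["domains"]) if "domains" in ssec else None
    )
    by_id = {t.transcript_id: t for t in models}
    outcome_rows = []
    donor_calls = [
        c for c in shortlist if c.term == Term.splice_donor_variant
    ]
    outcomes_by_call = []
    for call in donor_calls:
        t = by_id[call.transcript_id]
        outcomes = model_donor_loss(t, call.variant, ref)
        outcomes_by_call.append((call, t, outcomes))
        for oc in outcomes:
            try:
                outcome_rows.append(outcome_record(call.variant, oc, domains))
            except SpliceMapError:
                outcome_rows.append(outcome_record(call.variant, oc))
    splice_json = out / "splice_outcomes.json"
    splice_tsv = out / "splice_outcomes.tsv"
    write_outcome_report(outcome_rows, splice_json, splice_tsv)
    record(
        "splice_report",
        {"donor_variants": len(donor_calls), "outcomes": len(outcome_rows)},
        {"json": splice_json, "tsv": splice_tsv},
    )

    # -- pcr ----------------------------------------------------------------
    psec = cfg.get("pcr") or {}
    pcr_rows = []
    for call, t, outcomes in outcomes_by_call:
        exon_index = None
        for k, intron in enumerate(t.introns):
            if intron.contains(call.variant.pos - 1):
                exon_index = k
        if "primers" in psec:
            pairs = read_primer_table(psec["primers"])
        else:
            pairs = [design_flanking_primers(t, exon_index, ref)]
        templates = [("wild_type", t.cdna(ref))] + [
            (oc.mode, oc.transcript.cdna) for oc in outcomes
        ]
        for pair in pairs:
            for row in rtpcr_presence(templates, pair):
                pcr_rows.append(
                    {"variant": str(call.variant), "transcript": t.transcript_id,
                     "primer_pair": pair.name, **row}
                )
    pcr_json = out / "pcr_products.json"
    pcr_json.write_text(json.dumps(pcr_rows, indent=2, sort_keys=True) + "\n")
    record("pcr", {"lanes": len(pcr_rows)}, {"json": pcr_json})

    # -- cosegregate --------------------------------------------------------
    csec = cfg.get("cosegregate") or {}
    if "table" in csec:
        from .cosegregation import read_genotype_table

        rows = read_genotype_table(csec["table"])
    else:
        # derive a genotype table from the cohort at the top candidate site
        target = None
        if truth is not None:
            tv = truth["variant"]
            target = (tv["contig"], tv["pos"], tv["ref"], tv["alt"])
        elif shortlist:
            target = shortlist[0].variant.key
        if target is None:
            raise ConfigError("no cosegregation table and no candidate to genotype")
        idx = next(
            i for i, v in enumerate(cohort.variants) if v.key == target
        )
        counts: dict[tuple[str, str], dict[str, int]] = {}
        for j, sample in enumerate(cohort.samples):
            row_meta = next(r for r in cohort.sample_sheet if r.sample_id == sample)
            key = (row_meta.phenotype_group, row_meta.population)
            bucket = counts.setdefault(
                key, {"n_hom_ref": 0, "n_het": 0, "n_hom_alt": 0}
            )
            code = int(cohort.matrix[idx, j])
            if code in _GT_LABEL:
                bucket[_GT_LABEL[code]] += 1
        rows = [
            GenotypeRow(
                phenotype=grp,
                population=pop,
                carrier=(grp == fcfg.case_group),
                **cnt,
            )
            for (grp, pop), cnt in sorted(counts.items())
        ]
    coseg = cosegregation_report(rows)
    coseg_json = out / "cosegregation.json"
    coseg_json.write_text(json.dumps(coseg, indent=2, sort_keys=True) + "\n")
    record("cosegregate", {"rows": len(rows)}, {"json": coseg_json})

    manifest["finished"] = datetime.now(timezone.utc).isoformat()
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
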