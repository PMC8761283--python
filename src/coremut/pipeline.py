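"""End-to-end orchestration: configured, logged, reproducible runs.

``run_pipeline`` ties the stages together — promoter loading, paired VCF
ingest, origin classification, polymorphism/novelty/recurrence cascade,
motif annotation and enrichment, expression cross-referencing, luciferase
testing, driver-panel intersection — and writes the full report bundle.
Every filtering stage logs input/removed/surviving counts so the cascade is
auditable end to end.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import expression as expr
from . import motifs as mot
from . import variants as var
from .regions import CorePromoter, read_promoter_set, reverse_complement

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    promoter_bed: str
    reference_fasta: str
    vcf_dir: str
    panel_paths: list[str] = field(default_factory=list)
    catalog_dir: str | None = None
    motif_catalog: str | None = None        # None -> built-in default catalog
    expression_matrix: str | None = None
    expression_groups: str | None = None
    luciferase_table: str | None = None
    driver_panel: str | None = None
    out_dir: str = "results"
    maf_max: float = 0.01
    min_carriers: int = 2
    p_max: float = 0.05
    fold_min: float = 1.5
    enrichment_factor_min: float = 1.5
    equal_var: bool = False
    log_transform: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except OSError as e:
            raise ConfigError(f"cannot read config file: {e}") from e
        if not isinstance(raw, dict):
            raise ConfigError("config file must hold a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**raw)

    def content_hash(self) -> str:
        """Hash of the analytic configuration (the output location is not
        part of the analysis identity)."""
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def discover_cases(vcf_dir: str | Path) -> dict[str, dict[str, Path]]:
    """Map case_id -> {tumor: path, blood: path} from ``<case>_<comp>.vcf``."""
    cases: dict[str, dict[str, Path]] = {}
    for p in sorted(Path(vcf_dir).glob("*.vcf")):
        stem = p.stem
        for comp in ("tumor", "blood"):
            if stem.endswith(f"_{comp}"):
                cases.setdefault(stem[: -len(comp) - 1], {})[comp] = p
    return cases


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of violations (empty means the config is runnable)."""
    v: list[str] = []
    for name in ("maf_max", "p_max"):
        if not 0 < getattr(config, name) <= 1:
            v.append(f"{name}: must be in (0, 1]")
    for name in ("min_carriers",):
        if getattr(config, name) < 1:
            v.append(f"{name}: must be >= 1")
    for name in ("fold_min", "enrichment_factor_min"):
        if getattr(config, name) <= 0:
            v.append(f"{name}: must be positive")
    for name in ("promoter_bed", "reference_fasta", "vcf_dir"):
        if not Path(getattr(config, name)).exists():
            v.append(f"{name}: path {getattr(config, name)!r} does not exist")
    for name in ("catalog_dir", "motif_catalog", "expression_matrix",
                 "expression_groups", "luciferase_table", "driver_panel"):
        value = getattr(config, name)
        if value is not None and not Path(value).exists():
            v.append(f"{name}: path {value!r} does not exist")
    for p in config.panel_paths:
        if not Path(p).exists():
            v.append(f"panel_paths: path {p!r} does not exist")
    if Path(config.vcf_dir).exists():
        for case_id, comps in discover_cases(config.vcf_dir).items():
            missing = {"tumor", "blood"} - set(comps)
            if missing:
                v.append(f"vcf manifest: case {case_id} missing {sorted(missing)}")
    return v


def transcribed_alleles(promoter: CorePromoter, pos: int, ref: str,
                        alt: str) -> tuple[int, str, str]:
    """Genomic allele pair expressed in the promoter's transcribed-strand
    relative frame: (relative start, ref, alt)."""
    if promoter.strand == "+":
        return promoter.genomic_to_relative(pos), ref, alt
    rel = promoter.genomic_to_relative(pos + len(ref) - 1)
    return rel, reverse_complement(ref), reverse_complement(alt)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the report bundle to ``config.out_dir``.

    Returns a dictionary with the in-memory results (mutations, summary,
    impacts, enrichment, expression cross-reference, luciferase results,
    driver intersection, run log).
    """
    violations = validate_config(config)
    if violations:
        raise ConfigError("invalid configuration:\n" + "\n".join(violations))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    promoters = read_promoter_set(config.promoter_bed, config.reference_fasta)
    by_gene = {p.gene_id: p for p in promoters}
    cases = discover_cases(config.vcf_dir)
    calls: list[var.VariantCall] = []
    for case_id, comps in sorted(cases.items()):
        for comp, path in sorted(comps.items()):
            calls.extend(var.ingest_vcf(path, case_id, comp, promoters))
    paired = [cid for cid, comps in cases.items()
              if {"tumor", "blood"} <= set(comps)]
    case_origins = var.classify_origin_from_paired(calls, paired)
    mutations = var.build_mutations(case_origins, promoters)
    log.info("classified %d distinct promoter mutations from %d cases",
             len(mutations), len(case_origins))

    panels = [var.read_population_panel(p) for p in config.panel_paths]
    mutations = var.filter_polymorphisms(mutations, panels, config.maf_max)
    catalogs = {}
    if config.catalog_dir:
        for p in sorted(Path(config.catalog_dir).glob("*.tsv")):
            catalogs[p.stem] = var.read_catalog(p)
    mutations = var.annotate_novelty(mutations, catalogs)
    mutations = var.apply_recurrence(mutations, config.min_carriers)

    n_cases = len(case_origins)
    summary = var.summarize(mutations, n_cases)
    mut_frame = var.mutations_to_frame(mutations)
    mut_frame.to_csv(out / "distinct_mutations.tsv", sep="\t", index=False)
    _write_summary(summary, out)

    # internal consistency: the summary must be recomputable from the table
    _check_summary_consistency(out / "distinct_mutations.tsv", summary, n_cases)

    catalog = (mot.read_catalog_file(config.motif_catalog)
               if config.motif_catalog else list(mot.DEFAULT_CATALOG))
    impact_rows, location_rows, footprints = [], [], []
    for m in mutations:
        promoter = by_gene[m.gene_id]
        rel, ref_t, alt_t = transcribed_alleles(promoter, m.pos, m.ref, m.alt)
        impact = mot.motif_impact(promoter, rel, ref_t, alt_t, catalog)
        end = mot._advance(rel, max(len(ref_t), 1) - 1)
        footprints.append((rel, end))
        impact_rows.append({
            "gene_id": m.gene_id, "relative_pos": m.relative_pos,
            "ref": m.ref, "alt": m.alt, "origin": m.origin,
            "gained": ",".join(sorted({h.motif for h in impact.gained})),
            "lost": ",".join(sorted({h.motif for h in impact.lost})),
            "located_in": ",".join(impact.located_in)})
        for name in impact.located_in:
            location_rows.append({"motif": name, "origin": m.origin})
    pd.DataFrame(impact_rows, columns=["gene_id", "relative_pos", "ref", "alt",
                                       "origin", "gained", "lost", "located_in"]
                 ).to_csv(out / "motif_impacts.tsv", sep="\t", index=False)
    loc_counts = (pd.DataFrame(location_rows, columns=["motif", "origin"])
                  .value_counts().rename("count").reset_index()
                  .sort_values(["motif", "origin"]))
    loc_counts.to_csv(out / "motif_locations.tsv", sep="\t", index=False)

    if footprints:
        wu, wd = promoters[0].window_up, promoters[0].window_down
        enr = mot.motif_enrichment(footprints, catalog, wu, wd,
                                   config.p_max, config.enrichment_factor_min)
        pd.DataFrame([e.__dict__ for e in enr]).to_csv(
            out / "motif_enrichment.tsv", sep="\t", index=False)
    else:
        enr = []

    mutated_genes = {
        origin: {m.gene_id for m in mutations if m.origin == origin}
        for origin in ("somatic", "germline")}

    crossref = None
    de_results = []
    if config.expression_matrix and config.expression_groups:
        matrix, groups = expr.read_expression_matrix(
            config.expression_matrix, config.expression_groups)
        genes = sorted(mutated_genes["somatic"] | mutated_genes["germline"])
        de_results = expr.differential_expression(
            matrix, groups, genes, p_max=config.p_max,
            fold_min=config.fold_min, log_transform=config.log_transform,
            equal_var=config.equal_var)
        expr.de_results_to_frame(de_results).to_csv(
            out / "de_results.tsv", sep="\t", index=False)
        crossref = expr.cross_reference(mutated_genes, de_results)
        pd.DataFrame(crossref).T.rename_axis("origin").to_csv(
            out / "expression_crossref.tsv", sep="\t")

    luciferase_results = []
    if config.luciferase_table:
        arms = expr.read_luciferase_table(config.luciferase_table)
        for construct in sorted(arms):
            pair = arms[construct]
            if {"wild_type", "mutant"} <= set(pair):
                luciferase_results.append(expr.test_luciferase(
                    pair["wild_type"], pair["mutant"], config.p_max,
                    config.fold_min, config.equal_var))
        pd.DataFrame(luciferase_results).to_csv(
            out / "luciferase_results.tsv", sep="\t", index=False)

    driver_hits: dict[str, list[str]] = {}
    if config.driver_panel:
        panel = [l.strip() for l in
                 Path(config.driver_panel).read_text().splitlines() if l.strip()]
        for origin, genes in mutated_genes.items():
            driver_hits[origin] = sorted(
                expr.intersect_driver_panel(genes, panel))
        (out / "driver_intersection.txt").write_text(
            "".join(f"{o}\t{g}\n" for o in sorted(driver_hits)
                    for g in driver_hits[o]))

    run_log = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "n_cases": n_cases,
        "n_promoters": len(promoters),
        "n_calls_ingested": len(calls),
        "n_distinct_mutations": len(mutations),
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2) + "\n")

    return {
        "mutations": mutations, "summary": summary,
        "motif_impacts": impact_rows, "enrichment": enr,
        "crossref": crossref, "de_results": de_results,
        "luciferase": luciferase_results, "driver_hits": driver_hits,
        "run_log": run_log, "out_dir": out,
    }


def _write_summary(summary: dict, out: Path) -> None:
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    rows = []
    for origin, s in summary.items():
        flat = {k: v for k, v in s.items() if k != "types"}
        for t, tv in s["types"].items():
            flat[t] = tv["count"]
            flat[f"{t}_pct"] = tv["pct"]
        rows.append({"origin": origin, **flat})
    pd.DataFrame(rows).to_csv(out / "summary.tsv", sep="\t", index=False)


def _check_summary_consistency(table_path: Path, summary: dict,
                               n_cases: int) -> None:
    df = pd.read_csv(table_path, sep="\t")
    for origin, s in summary.items():
        sub = df[df["origin"] == origin]
        if len(sub) != s["distinct"] or int(sub["n_carriers"].sum()) != \
                s["total_occurrences"]:
            raise RuntimeError(
                f"summary inconsistent with mutation table for {origin}")
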