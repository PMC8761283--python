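"""Synthetic cohort generator with planted ground truth.

Emulates the study design the pipeline targets: 77 cancer cases with
patient-matched blood, core promoter windows containing plantable
cis-motif instances and simple tandem repeats, recurrent somatic and
germline mutations at configurable carrier counts, decoy singletons, a
population polymorphism panel with allele frequencies straddling the 0.01
threshold, known-variant catalogs, an expression matrix with planted fold
changes (including large effects such as 7.5-fold up and 25.7-fold down)
and triplicate dual-luciferase measurements with planted effects (such as
a 4.8-fold decrease).  Every planted feature is recorded in truth tables
so the full cascade can be validated offline; generation is fully
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .regions import CorePromoter, build_core_promoter, reverse_complement, write_promoter_set

BASES = "ACGT"


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedMotif:
    gene: str
    rel_start: int          # TSS-relative start of the instance
    sequence: str


@dataclass(frozen=True)
class PlantedRepeat:
    gene: str
    rel_start: int
    unit: str
    copies: int


@dataclass(frozen=True)
class PlantedVariant:
    """A mutation planted in the transcribed-strand relative frame.

    ``kind`` is sub / ins / del; ``detail`` is the alternate base for a
    substitution, the inserted string for an insertion, or the deleted
    length for a deletion.  ``expected_gains`` names motifs the mutation is
    engineered to create (verified downstream by re-scanning).
    """
    gene: str
    rel_pos: int
    origin: str             # "somatic" | "germline"
    n_carriers: int
    kind: str               # "sub" | "ins" | "del"
    detail: str | int
    in_catalogs: tuple[str, ...] = ()
    expected_gains: tuple[str, ...] = ()


@dataclass(frozen=True)
class PlantedPolymorphism:
    gene: str
    rel_pos: int
    alt: str                # substituted base
    maf: float | None       # None -> presence-only panel entry


@dataclass
class CohortSpec:
    """Everything the generator needs; defaults are the study conditions."""
    seed: int
    n_cases: int = 77
    n_promoters: int = 30
    window_up: int = 120
    window_down: int = 120
    flank: int = 50
    n_decoy_singletons: int = 6
    n_per_group: int = 19           # expression samples per group
    expression_sigma: float = 0.15  # natural-log scale noise
    luciferase_cv: float = 0.08
    planted_motifs: list[PlantedMotif] = field(default_factory=list)
    planted_repeats: list[PlantedRepeat] = field(default_factory=list)
    planted_variants: list[PlantedVariant] = field(default_factory=list)
    planted_polymorphisms: list[PlantedPolymorphism] = field(default_factory=list)
    expression_effects: dict[str, float] = field(default_factory=dict)
    luciferase_effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in self.planted_variants:
            if v.n_carriers > self.n_cases:
                raise SyntheticError(f"{v.gene}: carriers exceed n_cases")
            if not (-self.window_up <= v.rel_pos <= self.window_down) or v.rel_pos == 0:
                raise SyntheticError(f"{v.gene}: position {v.rel_pos} outside window")
        for factor in list(self.expression_effects.values()) + \
                list(self.luciferase_effects.values()):
            if factor <= 0:
                raise SyntheticError("effect factors must be positive")

    @property
    def genes(self) -> list[str]:
        return [f"GENE{i:03d}" for i in range(1, self.n_promoters + 1)]


def default_cohort_spec(seed: int) -> CohortSpec:
    """The default study-like conditions: 77 cases, 30 promoters, planted
    recurrent somatic/germline mutations (including an Ets-creating
    substitution and a CT-track insertion into a CT repeat), polymorphisms
    straddling MAF 0.01, large planted expression effects and a panel of
    ten luciferase constructs of which five carry real effects."""
    spec = CohortSpec(seed=seed)
    g = spec.genes
    spec.planted_motifs = [
        PlantedMotif(g[0], -30, "TATAAAAG"),       # canonical TATA
        PlantedMotif(g[1], -63, "CCCACC"),          # GAB2-style target
        PlantedMotif(g[2], 40, "GGCA"),             # one substitution from GGAA (Ets)
        PlantedMotif(g[3], -2, "TCATTCC"),          # Inr-like
    ]
    spec.planted_repeats = [
        PlantedRepeat(g[4], 60, "CT", 6),           # CT track
        PlantedRepeat(g[5], -80, "T", 8),           # homopolymer
        PlantedRepeat(g[6], 25, "CAG", 4),
    ]
    spec.planted_variants = [
        # somatic recurrent
        PlantedVariant(g[2], 42, "somatic", 3, "sub", "A",
                       expected_gains=("Ets",)),     # GGCA -> GGAA
        PlantedVariant(g[0], -66, "somatic", 4, "sub", "T"),
        PlantedVariant(g[4], 61, "somatic", 2, "ins", "CT"),  # into the CT track
        PlantedVariant(g[7], 93, "somatic", 2, "del", 2),
        PlantedVariant(g[8], -15, "somatic", 5, "sub", "C", in_catalogs=("cosmic",)),
        PlantedVariant(g[9], 10, "somatic", 2, "sub", "G", in_catalogs=("dbsnp",)),
        PlantedVariant(g[10], -100, "somatic", 3, "sub", "T"),
        PlantedVariant(g[11], 55, "somatic", 2, "del", 1),
        # germline recurrent
        PlantedVariant(g[1], -60, "germline", 6, "sub", "C"),  # CCCACC -> CCCCCC
        PlantedVariant(g[5], -79, "germline", 3, "sub", "G"),  # in the T homopolymer
        PlantedVariant(g[12], 90, "germline", 2, "sub", "A",
                       in_catalogs=("dbsnp", "clinvar")),
        PlantedVariant(g[13], -45, "germline", 4, "ins", "TGA"),
        PlantedVariant(g[14], 101, "germline", 2, "del", 3),
    ]
    spec.planted_polymorphisms = [
        PlantedPolymorphism(g[15], 30, "A", 0.05),    # common -> filtered
        PlantedPolymorphism(g[16], -20, "G", 0.02),   # common -> filtered
        PlantedPolymorphism(g[17], 70, "T", 0.008),   # rare -> survives MAF rule
        PlantedPolymorphism(g[18], -50, "C", None),   # presence-only entry
    ]
    spec.expression_effects = {
        g[2]: 7.5,          # TERT-like strong up-regulation
        g[19]: 1.0 / 25.7,  # CFD-like strong down-regulation
        g[0]: 2.5,
        g[1]: 1.0 / 2.0,
        g[4]: 1.0 / 3.0,
    }
    spec.luciferase_effects = {
        "TERT_like": 1.0 / 4.8,
        "CDA_like": 1.0 / 2.2,
        "LCE4A_like": 1.0 / 1.9,
        "SLC9A1_like": 2.4,
        "CLCNKB_like": 1.8,
        "NULL_1": 1.0, "NULL_2": 1.0, "NULL_3": 1.0, "NULL_4": 1.0,
        "NULL_5": 1.0,
    }
    return spec


# ---------------------------------------------------------------------------
# sequence-level helpers

def _rel_to_index(rel: int, window_up: int) -> int:
    return rel + window_up if rel < 0 else rel + window_up - 1


def _brute_force_repetitive(seq: str, lo_idx: int, hi_idx: int) -> bool:
    """Independent (substring-enumeration) simple-repeat check used for
    truth tables: does any perfect tandem run (unit 1-6, >=3 copies,
    length >=6) overlap [lo_idx-1, hi_idx+1]?"""
    n = len(seq)
    for u in range(1, 7):
        for start in range(n - 3 * u + 1):
            copies = 1
            while (start + (copies + 1) * u <= n and
                   seq[start + copies * u:start + (copies + 1) * u]
                   == seq[start:start + u]):
                copies += 1
            length = copies * u
            if copies >= 3 and length >= 6:
                if start <= hi_idx + 1 and start + length - 1 >= lo_idx - 1:
                    return True
    return False


# ---------------------------------------------------------------------------
# promoters

def generate_promoters(spec: CohortSpec, rng: np.random.Generator
                       ) -> tuple[list[CorePromoter], dict[str, str]]:
    """Random promoter sequences with planted motifs/repeats, one contig per
    promoter, alternating strands.  Returns promoters and the reference."""
    width = spec.window_up + spec.window_down
    reference: dict[str, str] = {}
    promoters: list[CorePromoter] = []
    for i, gene in enumerate(spec.genes):
        seq = "".join(rng.choice(list(BASES), size=width))
        for pm in spec.planted_motifs:
            if pm.gene == gene:
                idx = _rel_to_index(pm.rel_start, spec.window_up)
                if idx < 0 or idx + len(pm.sequence) > width:
                    raise SyntheticError(
                        f"{gene}: motif at {pm.rel_start} does not fit the window")
                seq = seq[:idx] + pm.sequence.upper() + seq[idx + len(pm.sequence):]
        for pr in spec.planted_repeats:
            if pr.gene == gene:
                run = pr.unit.upper() * pr.copies
                idx = _rel_to_index(pr.rel_start, spec.window_up)
                if idx < 0 or idx + len(run) > width:
                    raise SyntheticError(
                        f"{gene}: repeat at {pr.rel_start} does not fit the window")
                seq = seq[:idx] + run + seq[idx + len(run):]
        strand = "+" if i % 2 == 0 else "-"
        chrom = f"chr{i + 1}"
        flanks = ["".join(rng.choice(list(BASES), size=spec.flank))
                  for _ in range(2)]
        genomic = seq if strand == "+" else reverse_complement(seq)
        reference[chrom] = flanks[0] + genomic + flanks[1]
        tss = (spec.flank + spec.window_up + 1 if strand == "+"
               else spec.flank + spec.window_down)
        promoters.append(build_core_promoter(
            gene, chrom, tss, strand, spec.window_up, spec.window_down,
            reference))
    return promoters, reference


# ---------------------------------------------------------------------------
# variants

def _resolve_alleles(promoter: CorePromoter, v_kind: str, rel_pos: int,
                     detail: str | int, rng: np.random.Generator
                     ) -> tuple[str, str]:
    """Transcribed-strand (ref, alt) for a planted variant."""
    idx = _rel_to_index(rel_pos, promoter.window_up)
    seq = promoter.sequence
    if v_kind == "sub":
        ref = seq[idx]
        alt = str(detail).upper()
        if alt == ref:
            alt = BASES[(BASES.index(ref) + 1) % 4]
        return ref, alt
    if v_kind == "ins":
        ref = seq[idx]
        return ref, ref + str(detail).upper()
    if v_kind == "del":
        span = int(detail)
        ref = seq[idx:idx + span + 1]
        if len(ref) != span + 1:
            raise SyntheticError(f"deletion at {rel_pos} runs off the window")
        return ref, ref[0]
    raise SyntheticError(f"unknown variant kind {v_kind!r}")


def _to_genomic(promoter: CorePromoter, rel_pos: int, ref_t: str, alt_t: str
                ) -> tuple[str, int, str, str]:
    """Map a transcribed-strand allele pair to genomic coordinates."""
    idx = _rel_to_index(rel_pos, promoter.window_up)
    if promoter.strand == "+":
        pos = promoter.genomic_start + idx
        return promoter.chrom, pos, ref_t, alt_t
    pos = promoter.genomic_end - (idx + len(ref_t) - 1)
    return promoter.chrom, pos, reverse_complement(ref_t), reverse_complement(alt_t)


def _vcf_text(contig_lengths: dict[str, int],
              records: Sequence[tuple[str, int, str, str]]) -> str:
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c},length={l}>" for c, l in contig_lengths.items()]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    order = {c: i for i, c in enumerate(contig_lengths)}
    for chrom, pos, ref, alt in sorted(records, key=lambda r: (order[r[0]], r[1], r[3])):
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.")
    return "\n".join(lines) + "\n"


def generate_cohort_vcfs(spec: CohortSpec, promoters: Sequence[CorePromoter],
                         reference: dict[str, str], outdir: Path,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Write one VCF per (case, compartment) plus panel and catalogs; return
    the mutation truth table.

    Planted somatic variants appear only in their carriers' tumor files,
    germline variants in both compartments of their carriers, polymorphisms
    in both compartments of binomially sampled carriers (presence
    probability 2*MAF per case).  Decoy singleton somatic variants exercise
    the recurrence filter.
    """
    by_gene = {p.gene_id: p for p in promoters}
    cases = [f"case{i:02d}" for i in range(1, spec.n_cases + 1)]
    tumor: dict[str, list] = {c: [] for c in cases}
    blood: dict[str, list] = {c: [] for c in cases}
    truth_rows = []
    catalog_entries: dict[str, list[tuple[str, int, str, str]]] = {
        t: [] for t in ("dbsnp", "1000genome", "esp6500", "exac", "gnomad",
                        "cosmic", "clinvar")}
    panel_rows = []
    used_positions: set[tuple[str, int]] = set()

    def plant(gene: str, rel_pos: int, kind: str, detail, origin: str,
              carriers: list[str], maf: float | None, in_catalogs: tuple[str, ...],
              expected_final: str, expected_gains: tuple[str, ...] = ()) -> None:
        promoter = by_gene[gene]
        ref_t, alt_t = _resolve_alleles(promoter, kind, rel_pos, detail, rng)
        chrom, pos, ref_g, alt_g = _to_genomic(promoter, rel_pos, ref_t, alt_t)
        if (chrom, pos) in used_positions:
            raise SyntheticError(f"position collision at {chrom}:{pos}")
        used_positions.add((chrom, pos))
        rec = (chrom, pos, ref_g, alt_g)
        for case in carriers:
            tumor[case].append(rec)
            if origin == "germline":
                blood[case].append(rec)
        for tag in in_catalogs:
            catalog_entries[tag].append(rec)
        if maf is not None or expected_final == "filtered_polymorphism":
            panel_rows.append({"chrom": chrom, "pos": pos, "ref": ref_g,
                               "alt": alt_g, "maf": maf})
        idx = _rel_to_index(rel_pos, promoter.window_up)
        truth_rows.append({
            "gene_id": gene, "chrom": chrom, "pos": pos, "ref": ref_g,
            "alt": alt_g, "relative_pos": rel_pos, "origin": origin,
            "mut_type": {"sub": "substitution", "ins": "insertion",
                         "del": "deletion"}[kind],
            "n_carriers": len(carriers),
            "carriers": ",".join(sorted(carriers)),
            "novel": not in_catalogs and maf is None
                     and expected_final != "filtered_polymorphism",
            "in_cosmic": "cosmic" in in_catalogs,
            "repetitive": _brute_force_repetitive(
                promoter.sequence, idx, idx + len(ref_t) - 1),
            "expected_final": expected_final,
            "expected_gains": ",".join(expected_gains),
        })

    for v in spec.planted_variants:
        carriers = sorted(rng.choice(cases, size=v.n_carriers, replace=False))
        plant(v.gene, v.rel_pos, v.kind, v.detail, v.origin, carriers,
              None, v.in_catalogs, "kept", v.expected_gains)

    # decoy singletons: somatic, one carrier each, dropped by recurrence
    decoy_genes = rng.choice(spec.genes, size=spec.n_decoy_singletons, replace=False)
    for gene in decoy_genes:
        for _attempt in range(50):
            rel = int(rng.integers(-spec.window_up, spec.window_down))
            if rel == 0:
                continue
            promoter = by_gene[gene]
            ref_t, _ = _resolve_alleles(promoter, "sub", rel, "A", rng)
            chrom, pos, _, _ = _to_genomic(promoter, rel, ref_t, ref_t)
            if (chrom, pos) not in used_positions:
                break
        carrier = [str(rng.choice(cases))]
        plant(gene, rel, "sub", BASES[int(rng.integers(4))], "somatic",
              carrier, None, (), "filtered_nonrecurrent")

    # polymorphisms: panel entries scattered through the cohort
    for pp in spec.planted_polymorphisms:
        presence = min(1.0, 2.0 * pp.maf) if pp.maf is not None else 0.08
        carriers = sorted(c for c in cases if rng.random() < presence)
        removed = pp.maf is None or pp.maf > 0.01
        expected = ("filtered_polymorphism" if removed else
                    ("kept" if len(carriers) >= 2 else "filtered_nonrecurrent"))
        plant(pp.gene, pp.rel_pos, "sub", pp.alt, "germline", carriers,
              pp.maf, ("1000genome",), expected)

    # catalog decoys at flank positions (outside every promoter window)
    for tag, entries in catalog_entries.items():
        for _ in range(3):
            chrom = f"chr{int(rng.integers(1, spec.n_promoters + 1))}"
            pos = int(rng.integers(1, spec.flank // 2))
            ref = reference[chrom][pos - 1]
            entries.append((chrom, pos, ref, BASES[(BASES.index(ref) + 1) % 4]))

    contig_lengths = {c: len(s) for c, s in reference.items()}
    vcf_dir = outdir / "vcf"
    vcf_dir.mkdir(parents=True, exist_ok=True)
    for case in cases:
        (vcf_dir / f"{case}_tumor.vcf").write_text(
            _vcf_text(contig_lengths, tumor[case]))
        (vcf_dir / f"{case}_blood.vcf").write_text(
            _vcf_text(contig_lengths, blood[case]))

    pd.DataFrame(panel_rows, columns=["chrom", "pos", "ref", "alt", "maf"]
                 ).to_csv(outdir / "panel.tsv", sep="\t", index=False)
    cat_dir = outdir / "catalogs"
    cat_dir.mkdir(exist_ok=True)
    for tag, entries in catalog_entries.items():
        pd.DataFrame(sorted(entries), columns=["chrom", "pos", "ref", "alt"]
                     ).to_csv(cat_dir / f"{tag}.tsv", sep="\t", index=False)

    truth = pd.DataFrame(truth_rows)
    truth.to_csv(outdir / "truth_mutations.tsv", sep="\t", index=False)
    return truth


# ---------------------------------------------------------------------------
# expression

def generate_expression(spec: CohortSpec, outdir: Path,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Log-normal expression matrix with planted multiplicative effects.

    Null genes draw both groups from the same log-normal; effect genes
    multiply the cancer-group scale by the planted factor.  Genes with a
    planted effect are modelled as well-expressed (high baseline) so the
    planted ratio is identifiable above the pseudo-count.
    """
    genes = spec.genes
    n = spec.n_per_group
    cancer_cols = [f"cancer{i:02d}" for i in range(1, n + 1)]
    normal_cols = [f"normal{i:02d}" for i in range(1, n + 1)]
    rows = {}
    truth_rows = []
    for gene in genes:
        factor = spec.expression_effects.get(gene, 1.0)
        mu = 8.0 if factor != 1.0 else float(rng.uniform(4.0, 7.0))
        normal = rng.lognormal(mu, spec.expression_sigma, size=n)
        cancer = rng.lognormal(mu + np.log(factor), spec.expression_sigma, size=n)
        rows[gene] = np.concatenate([cancer, normal])
        truth_rows.append({"gene_id": gene, "factor": factor,
                           "direction": ("up" if factor > 1 else
                                         "down" if factor < 1 else "null")})
    matrix = pd.DataFrame.from_dict(rows, orient="index",
                                    columns=cancer_cols + normal_cols).round(3)
    matrix.index.name = "gene_id"
    matrix.to_csv(outdir / "expression.tsv", sep="\t")
    groups = pd.DataFrame({
        "sample": cancer_cols + normal_cols,
        "group": ["cancer"] * n + ["normal"] * n})
    groups.to_csv(outdir / "groups.tsv", sep="\t", index=False)
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(outdir / "truth_expression.tsv", sep="\t", index=False)
    return truth


# ---------------------------------------------------------------------------
# luciferase

def generate_luciferase(spec: CohortSpec, outdir: Path,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Triplicate (firefly, Renilla) pairs per construct arm.

    The wild-type arm's normalized activity centres on a per-construct
    baseline; the mutant arm's centre is scaled by the planted factor.
    Noise is multiplicative (log-normal) on both readouts; Renilla is
    strictly positive by construction.
    """
    rows = []
    truth_rows = []
    for construct in sorted(spec.luciferase_effects):
        factor = spec.luciferase_effects[construct]
        baseline = float(rng.uniform(1.5, 3.0))
        for arm, scale in (("wild_type", 1.0), ("mutant", factor)):
            for _rep in range(3):
                renilla = float(rng.lognormal(0.0, 0.10))
                el = baseline * scale * float(rng.lognormal(0.0, spec.luciferase_cv))
                rows.append({"construct": construct, "arm": arm,
                             "E_f": round(el * renilla, 6),
                             "E_r": round(renilla, 6)})
        truth_rows.append({"construct": construct, "factor": factor})
    pd.DataFrame(rows).to_csv(outdir / "luciferase.tsv", sep="\t", index=False)
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(outdir / "truth_luciferase.tsv", sep="\t", index=False)
    return truth


# ---------------------------------------------------------------------------
# full fixture

def generate_fixture(spec: CohortSpec, outdir: str | Path) -> dict[str, Path]:
    """Generate the complete input bundle (promoters, VCFs, panel, catalogs,
    expression, luciferase, driver panel) with truth tables, deterministic
    under ``spec.seed``.  Returns a path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    promoters, reference = generate_promoters(spec, rng)
    write_promoter_set(promoters, outdir / "promoters.bed",
                       outdir / "reference.fa", reference)
    generate_cohort_vcfs(spec, promoters, reference, outdir, rng)
    generate_expression(spec, outdir, rng)
    generate_luciferase(spec, outdir, rng)
    # driver panel: a few mutated genes plus unrelated symbols
    panel_genes = [spec.genes[2], spec.genes[0], spec.genes[1],
                   "TP53", "KRAS", "PIK3CA"]
    (outdir / "driver_panel.txt").write_text("\n".join(panel_genes) + "\n")
    return {
        "bed": outdir / "promoters.bed",
        "fasta": outdir / "reference.fa",
        "vcf_dir": outdir / "vcf",
        "panel": outdir / "panel.tsv",
        "catalog_dir": outdir / "catalogs",
        "expression": outdir / "expression.tsv",
        "groups": outdir / "groups.tsv",
        "luciferase": outdir / "luciferase.tsv",
        "driver_panel": outdir / "driver_panel.txt",
        "truth_mutations": outdir / "truth_mutations.tsv",
        "truth_expression": outdir / "truth_expression.tsv",
        "truth_luciferase": outdir / "truth_luciferase.tsv",
    }
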