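"""The filtering/classification cascade for paired tumor/blood variant calls.

Calls are restricted to core promoter windows, compared between tumor and
matched blood to assign somatic vs germline origin, cleansed of population
polymorphisms (presence match or MAF above threshold), annotated for novelty
against known-variant catalogs, reduced to recurrent mutations (carried by
at least two cases), typed (substitution / insertion / deletion) and flagged
for simple-tandem-repeat context.  The distinct mutation — identified by
(gene, TSS-relative position, ref, alt) after normalization — is the unit
the summary table counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from .regions import CorePromoter, PromoterError

log = logging.getLogger(__name__)

KNOWN_CATALOG_TAGS = frozenset(
    {"dbsnp", "1000genome", "esp6500", "exac", "gnomad", "cosmic", "clinvar"})

VarKey = tuple[str, int, str, str]  # (chrom, pos, ref, alt), normalized


class VariantError(ValueError):
    pass


@dataclass(frozen=True)
class VariantCall:
    """One normalized allele call from one sample compartment."""
    chrom: str
    pos: int            # 1-based
    ref: str
    alt: str
    case_id: str
    compartment: str    # "tumor" | "blood"

    @property
    def key(self) -> VarKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class PopulationPanelEntry:
    chrom: str
    pos: int
    ref: str
    alt: str
    maf: float | None = None   # None → presence-only entry

    @property
    def key(self) -> VarKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class ClassifiedMutation:
    """A distinct mutation with its carriers and all cascade annotations."""
    gene_id: str
    chrom: str
    pos: int
    relative_pos: int
    ref: str
    alt: str
    origin: str                      # "somatic" | "germline"
    mut_type: str                    # "substitution" | "insertion" | "deletion"
    carriers: frozenset[str] = field(default_factory=frozenset)
    recurrent: bool = False
    novel: bool = False
    in_cosmic_analog: bool = False
    repetitive_context: bool = False

    @property
    def key(self) -> VarKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def occurrences(self) -> int:
        return len(self.carriers)


# ---------------------------------------------------------------------------
# allele normalization

def normalize_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Minimal representation: trim shared suffix, then shared prefix.

    Keeps at least one base on each allele; the position moves right with
    the trimmed prefix.  Raises if ref == alt after trimming input that was
    identical to begin with.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise VariantError(f"ref and alt alleles identical ({ref}) at {pos}")
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def classify_type(ref: str, alt: str) -> str:
    """Substitution / insertion / deletion from normalized allele lengths."""
    if ref == alt:
        raise VariantError("identical alleles have no mutation type")
    if len(ref) == len(alt):
        return "substitution"
    return "insertion" if len(alt) > len(ref) else "deletion"


# ---------------------------------------------------------------------------
# ingest

def _overlapping_promoter(promoters: Sequence[CorePromoter], chrom: str,
                          pos: int, ref: str) -> CorePromoter | None:
    end = pos + len(ref) - 1
    for p in promoters:
        if p.chrom == chrom and pos <= p.genomic_end and end >= p.genomic_start:
            return p
    return None


def ingest_vcf(vcf_path: str | Path, case_id: str, compartment: str,
               promoter_set: Sequence[CorePromoter]) -> list[VariantCall]:
    """Read one VCF, split multiallelic records, normalize alleles and keep
    only calls whose reference footprint overlaps a core promoter window."""
    if not promoter_set:
        raise VariantError("promoter_set must be non-empty")
    if compartment not in ("tumor", "blood"):
        raise VariantError(f"compartment must be tumor|blood, got {compartment!r}")
    calls: list[VariantCall] = []
    skipped_contigs = 0
    known_contigs = {p.chrom for p in promoter_set}
    with pysam.VariantFile(str(vcf_path)) as vf:
        for rec in vf:
            if rec.chrom not in known_contigs:
                skipped_contigs += 1
                continue
            if rec.ref is None or not rec.alts:
                raise VariantError(
                    f"{vcf_path}: malformed record at line for {rec.chrom}:{rec.pos}")
            for alt in rec.alts:
                if alt is None or set(alt.upper()) - set("ACGTN"):
                    continue  # symbolic / breakend alleles are not promoter SNVs
                pos, ref, alt_n = normalize_alleles(rec.pos, rec.ref, alt)
                if _overlapping_promoter(promoter_set, rec.chrom, pos, ref):
                    calls.append(VariantCall(rec.chrom, pos, ref, alt_n,
                                             case_id, compartment))
    if skipped_contigs:
        log.info("%s: skipped %d records on contigs outside the promoter set",
                 vcf_path, skipped_contigs)
    return calls


# ---------------------------------------------------------------------------
# somatic / germline classification

def classify_origin(tumor_calls: Iterable[VariantCall],
                    blood_calls: Iterable[VariantCall],
                    paired_cases: Iterable[str] | None = None
                    ) -> dict[str, dict[VarKey, str]]:
    """Per-case origin of every distinct variant from paired compartments.

    A variant present in a case's tumor but absent from its blood is somatic
    for that case; presence in blood (with or without tumor) makes it
    germline.  ``paired_cases`` names the cases for which both compartments
    were sequenced (a case with an empty VCF still counts as sequenced);
    when omitted, pairing is inferred from the calls themselves and cases
    with calls in only one compartment are excluded with a warning.
    """
    tumor_by_case: dict[str, set[VarKey]] = {}
    blood_by_case: dict[str, set[VarKey]] = {}
    for c in tumor_calls:
        tumor_by_case.setdefault(c.case_id, set()).add(c.key)
    for c in blood_calls:
        blood_by_case.setdefault(c.case_id, set()).add(c.key)
    out: dict[str, dict[VarKey, str]] = {}
    if paired_cases is not None:
        case_ids = sorted(paired_cases)
    else:
        case_ids = []
        for case_id in sorted(set(tumor_by_case) | set(blood_by_case)):
            if case_id not in tumor_by_case or case_id not in blood_by_case:
                log.warning("case %s missing a compartment; excluded", case_id)
                continue
            case_ids.append(case_id)
    for case_id in case_ids:
        tumor = tumor_by_case.get(case_id, set())
        blood = blood_by_case.get(case_id, set())
        origins = {k: "somatic" for k in tumor - blood}
        origins.update({k: "germline" for k in blood})
        out[case_id] = origins
    return out


def classify_origin_from_paired(calls: Iterable[VariantCall],
                                paired_cases: Iterable[str] | None = None
                                ) -> dict[str, dict[VarKey, str]]:
    """Convenience wrapper splitting a mixed call list by compartment."""
    calls = list(calls)
    return classify_origin([c for c in calls if c.compartment == "tumor"],
                           [c for c in calls if c.compartment == "blood"],
                           paired_cases)


def build_mutations(case_origins: Mapping[str, Mapping[VarKey, str]],
                    promoter_set: Sequence[CorePromoter]) -> list[ClassifiedMutation]:
    """Aggregate per-case origin calls into distinct classified mutations.

    Origin conflicts across cases (somatic in some carriers, germline in
    others) resolve by carrier majority; ties fall to germline, the
    conservative call.  Repeat context and mutation type are assigned here.
    """
    carriers: dict[VarKey, set[str]] = {}
    votes: dict[VarKey, list[str]] = {}
    for case_id, origins in case_origins.items():
        for key, origin in origins.items():
            carriers.setdefault(key, set()).add(case_id)
            votes.setdefault(key, []).append(origin)
    mutations: list[ClassifiedMutation] = []
    for key in sorted(carriers):
        chrom, pos, ref, alt = key
        promoter = _overlapping_promoter(promoter_set, chrom, pos, ref)
        if promoter is None:
            continue
        n_som = votes[key].count("somatic")
        n_ger = votes[key].count("germline")
        origin = "somatic" if n_som > n_ger else "germline"
        rel = footprint_relative_start(promoter, pos, ref)
        mutations.append(ClassifiedMutation(
            gene_id=promoter.gene_id, chrom=chrom, pos=pos, relative_pos=rel,
            ref=ref, alt=alt, origin=origin,
            mut_type=classify_type(ref, alt),
            carriers=frozenset(carriers[key]),
            recurrent=len(carriers[key]) >= 2,
            repetitive_context=classify_repeat_context(
                promoter, rel, max(len(ref), 1)),
        ))
    return mutations


def footprint_relative_start(promoter: CorePromoter, pos: int, ref: str) -> int:
    """TSS-relative position of the transcribed-strand 5'-most footprint base.

    For "+" promoters this is the relative coordinate of ``pos``; for "-"
    promoters the footprint's genomic *end* is its transcribed-strand start.
    Footprint bases hanging outside the window are clamped to the window edge.
    """
    end = pos + len(ref) - 1
    anchor = pos if promoter.strand == "+" else end
    anchor = min(max(anchor, promoter.genomic_start), promoter.genomic_end)
    return promoter.genomic_to_relative(anchor)


# ---------------------------------------------------------------------------
# polymorphism filter

def filter_polymorphisms(mutations: Sequence[ClassifiedMutation],
                         panels: Sequence[Sequence[PopulationPanelEntry]],
                         maf_max: float = 0.01) -> list[ClassifiedMutation]:
    """Remove common population polymorphisms.

    A panel entry carrying a MAF removes the matching mutation iff
    MAF > ``maf_max`` (strict); an entry without a MAF removes it on
    presence alone.
    """
    removing: set[VarKey] = set()
    for panel in panels:
        for entry in panel:
            if entry.maf is None or entry.maf > maf_max:
                removing.add(entry.key)
    survivors = [m for m in mutations if m.key not in removing]
    log.info("polymorphism filter: %d in, %d removed, %d surviving",
             len(mutations), len(mutations) - len(survivors), len(survivors))
    return survivors


# ---------------------------------------------------------------------------
# novelty

def annotate_novelty(mutations: Sequence[ClassifiedMutation],
                     catalogs: Mapping[str, set[VarKey]]) -> list[ClassifiedMutation]:
    """Flag mutations absent from every known-variant catalog as novel.

    ``catalogs`` maps a source tag (dbsnp, cosmic, ...) to its site+allele
    set.  ``in_cosmic_analog`` reflects the catalog tagged "cosmic".
    """
    for tag in catalogs:
        if tag not in KNOWN_CATALOG_TAGS:
            raise VariantError(
                f"unknown catalog tag {tag!r}; known: {sorted(KNOWN_CATALOG_TAGS)}")
    cosmic = catalogs.get("cosmic", set())
    out = []
    for m in mutations:
        m.novel = not any(m.key in cat for cat in catalogs.values())
        m.in_cosmic_analog = m.key in cosmic
        out.append(m)
    return out


# ---------------------------------------------------------------------------
# recurrence

def apply_recurrence(mutations: Sequence[ClassifiedMutation],
                     min_carriers: int = 2) -> list[ClassifiedMutation]:
    """Keep mutations carried by at least ``min_carriers`` cases."""
    survivors = [m for m in mutations if m.occurrences >= min_carriers]
    log.info("recurrence filter: %d in, %d removed, %d surviving",
             len(mutations), len(mutations) - len(survivors), len(survivors))
    return survivors


# ---------------------------------------------------------------------------
# repeat context

def find_tandem_repeats(seq: str, max_unit: int = 6, min_copies: int = 3,
                        min_length: int = 6) -> list[tuple[int, int, int]]:
    """Perfect tandem repeat runs in ``seq``.

    Returns maximal runs as (start, end, unit) with ``end`` exclusive, for
    unit sizes 1..max_unit, at least ``min_copies`` full copies and total
    run length >= ``min_length``.  Overlapping runs of different unit sizes
    are all reported.
    """
    n = len(seq)
    runs: list[tuple[int, int, int]] = []
    for u in range(1, max_unit + 1):
        i = 0
        while i + u <= n:
            j = i + u
            while j < n and seq[j] == seq[j - u]:
                j += 1
            run_len = j - i
            if run_len >= min_copies * u and run_len >= min_length:
                # reject runs whose true period divides u (already found)
                unit = seq[i:i + u]
                if not any(u % p == 0 and unit == unit[:p] * (u // p)
                           for p in range(1, u)):
                    runs.append((i, j, u))
                i = j - u + 1
            else:
                i += 1
    return sorted(set(runs))


def classify_repeat_context(promoter: CorePromoter, relative_pos: int,
                            span: int) -> bool:
    """True iff the mutation footprint (±1 bp) overlaps a simple tandem
    repeat run detected in the promoter window."""
    start_idx = promoter.relative_to_index(relative_pos)
    lo, hi = start_idx - 1, start_idx + span  # inclusive bounds, ±1 slack
    for r_start, r_end, _unit in find_tandem_repeats(promoter.sequence):
        if lo <= r_end - 1 and hi >= r_start:
            return True
    return False


# ---------------------------------------------------------------------------
# summary (the Table-1-style report)

def round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(1).scaleb(-ndigits) if ndigits > 0 else Decimal(1)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def summarize(mutations: Sequence[ClassifiedMutation], n_cases: int) -> dict:
    """Per-origin cohort summary: occurrences, per-case average, distinct
    counts, affected promoters/genes, novelty, repeat and type breakdown.

    Percentages are 100·part/distinct, rounded half-up to one decimal; the
    per-case average is occurrences/cases rounded half-up to an integer.
    """
    out: dict[str, dict] = {}
    for origin in ("somatic", "germline"):
        subset = [m for m in mutations if m.origin == origin]
        distinct = len(subset)
        occurrences = sum(m.occurrences for m in subset)
        by_type = {t: sum(1 for m in subset if m.mut_type == t)
                   for t in ("substitution", "insertion", "deletion")}
        pct = (lambda k: round_half_up(100.0 * k / distinct, 1) if distinct else 0.0)
        n_rep = sum(1 for m in subset if m.repetitive_context)
        out[origin] = {
            "total_occurrences": occurrences,
            "avg_per_case": int(round_half_up(occurrences / n_cases, 0)) if n_cases else 0,
            "distinct": distinct,
            "promoters": len({(m.chrom, m.gene_id) for m in subset}),
            "genes": len({m.gene_id for m in subset}),
            "absent_in_cosmic": sum(1 for m in subset if not m.in_cosmic_analog),
            "novel": sum(1 for m in subset if m.novel),
            "repetitive": n_rep,
            "non_repetitive": distinct - n_rep,
            "types": {t: {"count": c, "pct": pct(c)} for t, c in by_type.items()},
        }
    return out


# ---------------------------------------------------------------------------
# I/O helpers

def read_population_panel(path: str | Path) -> list[PopulationPanelEntry]:
    """Population panel from VCF (AF INFO field) or TSV (chrom pos ref alt maf)."""
    path = Path(path)
    entries: list[PopulationPanelEntry] = []
    if path.suffix in (".vcf", ".gz", ".bcf"):
        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                afs = rec.info.get("AF")
                if afs is not None and not isinstance(afs, (tuple, list)):
                    afs = (afs,)
                for i, alt in enumerate(rec.alts or ()):
                    maf = float(afs[i]) if afs is not None else None
                    if maf is not None and maf > 0.5:
                        maf = 1.0 - maf
                    pos, ref, alt_n = normalize_alleles(rec.pos, rec.ref, alt)
                    entries.append(PopulationPanelEntry(rec.chrom, pos, ref, alt_n, maf))
    else:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        for row in df.itertuples(index=False):
            maf = getattr(row, "maf", None)
            maf = None if maf is None or pd.isna(maf) else float(maf)
            pos, ref, alt = normalize_alleles(int(row.pos), row.ref, row.alt)
            entries.append(PopulationPanelEntry(str(row.chrom), pos, ref, alt, maf))
    return entries


def read_catalog(path: str | Path) -> set[VarKey]:
    """Known-variant catalog: TSV with chrom, pos, ref, alt columns."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    keys = set()
    for row in df.itertuples(index=False):
        pos, ref, alt = normalize_alleles(int(row.pos), row.ref, row.alt)
        keys.add((str(row.chrom), pos, ref, alt))
    return keys


def mutations_to_frame(mutations: Sequence[ClassifiedMutation]) -> pd.DataFrame:
    rows = [{
        "gene_id": m.gene_id, "chrom": m.chrom, "pos": m.pos,
        "relative_pos": m.relative_pos, "ref": m.ref, "alt": m.alt,
        "origin": m.origin, "mut_type": m.mut_type,
        "n_carriers": m.occurrences,
        "carriers": ",".join(sorted(m.carriers)),
        "recurrent": m.recurrent, "novel": m.novel,
        "in_cosmic_analog": m.in_cosmic_analog,
        "repetitive_context": m.repetitive_context,
    } for m in mutations]
    cols = ["gene_id", "chrom", "pos", "relative_pos", "ref", "alt", "origin",
            "mut_type", "n_carriers", "carriers", "recurrent", "novel",
            "in_cosmic_analog", "repetitive_context"]
    return pd.DataFrame(rows, columns=cols)
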