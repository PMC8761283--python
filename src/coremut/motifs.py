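"""Core promoter cis-element scanning and mutation-induced motif gain/loss.

Motifs are IUPAC consensus strings with an optional TSS-relative start
window (core promoter elements are position- and orientation-dependent;
transcription-factor sites like Ets are position-free and double-stranded).
A mutation's regulatory impact is called by re-scanning the wild-type and
mutant sequences and diffing the hit sets; enrichment of mutations in motif
windows uses the upper cumulative hypergeometric tail against uniform
placement over the promoter frame.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from scipy.stats import hypergeom

from .regions import CorePromoter, reverse_complement

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class MotifError(ValueError):
    pass


@dataclass(frozen=True)
class MotifDefinition:
    """A cis-element consensus with its permissible start window.

    ``window`` is a TSS-relative (start, end) inclusive interval constraining
    where a match may *start*, or ``None`` for position-free motifs.
    ``strand_policy`` is ``"sense_only"`` or ``"both"``.
    """
    name: str
    consensus: str
    window: tuple[int, int] | None = None
    strand_policy: str = "sense_only"

    def __post_init__(self) -> None:
        bad = set(self.consensus.upper()) - set(IUPAC)
        if bad:
            raise MotifError(
                f"motif {self.name}: non-IUPAC code(s) {sorted(bad)}")
        if self.strand_policy not in ("sense_only", "both"):
            raise MotifError(f"motif {self.name}: bad strand_policy")
        if self.window is not None and (0 in self.window
                                        or self.window[0] > self.window[1]):
            raise MotifError(f"motif {self.name}: invalid window {self.window}")

    @property
    def regex(self) -> re.Pattern:
        return re.compile("".join(f"[{IUPAC[c]}]"
                                  for c in self.consensus.upper()))


@dataclass(frozen=True)
class MotifHit:
    motif: str
    start: int          # TSS-relative position of the 5'-most sense base
    strand: str         # "+" sense, "-" a both-strand motif on the antisense
    matched: str        # sense-strand substring at the hit

    @property
    def identity(self) -> tuple[str, int, str]:
        return (self.motif, self.start, self.strand)


@dataclass
class MotifImpact:
    """Motif-level consequences of one mutation."""
    gained: list[MotifHit]
    lost: list[MotifHit]
    located_in: list[str]


@dataclass
class EnrichmentResult:
    motif: str
    overlap: int
    expected: float
    enrichment_factor: float
    p_value: float
    enriched: bool


# Literature consensi for the canonical elements; DTIE and the MTE box
# split are provisional placeholders and should be overridden by users with
# better definitions.  Windows constrain the match start, TSS-relative.
DEFAULT_CATALOG: tuple[MotifDefinition, ...] = (
    MotifDefinition("BREu", "SSRCGCC", (-38, -32)),
    MotifDefinition("TATA", "TATAWAAR", (-31, -24)),
    MotifDefinition("Inr", "YYANWYY", (-2, 3)),
    MotifDefinition("TCT", "YYCTTTYY", (-2, 2)),
    MotifDefinition("MTE_box1", "CSARC", (18, 22)),
    MotifDefinition("MTE_box2", "SSAACGS", (23, 27)),
    MotifDefinition("DPE", "RGWYVT", (28, 32)),
    MotifDefinition("DCE_box1", "CTTC", (6, 11)),
    MotifDefinition("DCE_box2", "CTGT", (16, 21)),
    MotifDefinition("DCE_box3", "AGC", (30, 34)),
    MotifDefinition("DTIE", "RGGGA", (20, 40)),
    MotifDefinition("Ets", "GGAW", None, "both"),
)


def validate_catalog(catalog: Sequence[MotifDefinition]) -> None:
    seen = set()
    for m in catalog:
        if m.name in seen:
            raise MotifError(f"duplicate motif name {m.name}")
        seen.add(m.name)


# ---------------------------------------------------------------------------
# scanning

def _frame_relative(idx: int, window_up: int) -> int:
    rel = idx - window_up
    return rel if rel < 0 else rel + 1


def scan_motifs(promoter: CorePromoter,
                catalog: Sequence[MotifDefinition] = DEFAULT_CATALOG) -> list[MotifHit]:
    """All consensus matches on the transcribed-strand sequence.

    A hit is reported when the match *start* (5'-most sense base) lies in
    the motif's window; position-free motifs match anywhere.  Motifs with
    ``strand_policy="both"`` are additionally matched as their reverse
    complement, reported with strand "-" and the sense-strand coordinates
    of the covered bases.  Order is deterministic: position, name, strand.
    """
    validate_catalog(catalog)
    seq = promoter.sequence.upper()
    hits: list[MotifHit] = []
    for motif in catalog:
        patterns = [(motif.regex, "+")]
        if motif.strand_policy == "both":
            rc = "".join(f"[{IUPAC[c]}]" for c in
                         reverse_complement(motif.consensus.upper()))
            patterns.append((re.compile(rc), "-"))
        for pattern, strand in patterns:
            for i in range(len(seq) - len(motif.consensus) + 1):
                if not pattern.match(seq, i):
                    continue
                rel = _frame_relative(i, promoter.window_up)
                if motif.window is not None and not (
                        motif.window[0] <= rel <= motif.window[1]):
                    continue
                hits.append(MotifHit(motif.name, rel, strand,
                                     seq[i:i + len(motif.consensus)]))
    hits.sort(key=lambda h: (h.start, h.motif, h.strand))
    return hits


# ---------------------------------------------------------------------------
# mutating the frame

def apply_variant(promoter: CorePromoter, relative_pos: int, ref: str,
                  alt: str) -> CorePromoter:
    """Apply a mutation in the TSS-relative frame of the transcribed strand.

    ``ref`` must match the sequence starting at ``relative_pos``; the
    returned frame is re-anchored so the TSS base stays at +1 (an indel
    upstream of the TSS changes ``window_up`` by the length difference).
    """
    ref, alt = ref.upper(), alt.upper()
    idx = promoter.relative_to_index(relative_pos)
    observed = promoter.sequence[idx:idx + len(ref)]
    if observed != ref:
        raise MotifError(
            f"reference mismatch at {relative_pos:+d}: expected {ref!r}, "
            f"sequence has {observed!r}")
    mutated = promoter.sequence[:idx] + alt + promoter.sequence[idx + len(ref):]
    delta = len(alt) - len(ref)
    if idx + len(ref) <= promoter.window_up:       # footprint fully upstream
        new_up = promoter.window_up + delta
    else:
        new_up = promoter.window_up
    return promoter.with_sequence(mutated, window_up=new_up)


def diff_motifs(wt_hits: Sequence[MotifHit], mut_hits: Sequence[MotifHit],
                footprint: tuple[int, int],
                catalog: Sequence[MotifDefinition] = DEFAULT_CATALOG) -> MotifImpact:
    """Gain/loss of motif hits plus the motif classes the mutation sits in.

    Hits are compared by (name, start, strand).  ``located_in`` lists
    positional motifs whose window overlaps the footprint (TSS-relative
    inclusive interval) and position-free motifs with an actual hit
    overlapping it.
    """
    wt_ids = {h.identity for h in wt_hits}
    mut_ids = {h.identity for h in mut_hits}
    gained = sorted((h for h in mut_hits if h.identity not in wt_ids),
                    key=lambda h: h.identity)
    lost = sorted((h for h in wt_hits if h.identity not in mut_ids),
                  key=lambda h: h.identity)
    lo, hi = footprint
    located: list[str] = []
    for motif in catalog:
        if motif.window is not None:
            if _intervals_overlap(motif.window, (lo, hi)):
                located.append(motif.name)
        else:
            span = len(motif.consensus)
            for h in list(wt_hits) + list(mut_hits):
                if h.motif != motif.name:
                    continue
                h_end = _advance(h.start, span - 1)
                if _intervals_overlap((h.start, h_end), (lo, hi)):
                    located.append(motif.name)
                    break
    return MotifImpact(gained=gained, lost=lost, located_in=located)


def _advance(rel: int, steps: int) -> int:
    """Move a no-zero relative coordinate right by ``steps`` bases."""
    out = rel + steps
    if rel < 0 and out >= 0:
        out += 1
    return out


def _intervals_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def motif_impact(promoter: CorePromoter, relative_pos: int, ref: str,
                 alt: str,
                 catalog: Sequence[MotifDefinition] = DEFAULT_CATALOG) -> MotifImpact:
    """Convenience: scan wild type and mutant and diff the hit sets."""
    wt = scan_motifs(promoter, catalog)
    mut = scan_motifs(apply_variant(promoter, relative_pos, ref, alt), catalog)
    end = _advance(relative_pos, max(len(ref), 1) - 1)
    return diff_motifs(wt, mut, (relative_pos, end), catalog)


# ---------------------------------------------------------------------------
# enrichment

def _window_width(window: tuple[int, int]) -> int:
    lo, hi = window
    width = hi - lo + 1
    if lo < 0 < hi:  # interval straddles the absent position 0
        width -= 1
    return width


def motif_enrichment(footprints: Sequence[tuple[int, int]],
                     catalog: Sequence[MotifDefinition],
                     window_up: int, window_down: int,
                     p_max: float = 0.05,
                     enrichment_factor_min: float = 1.5) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of mutation positions in motif windows.

    ``footprints`` are TSS-relative inclusive intervals of the mutations'
    reference footprints.  The null places the mutations uniformly without
    replacement over the frame's ``window_up + window_down`` positions; for
    each positional motif, overlap counts mutations whose footprint
    intersects the window, and the p-value is the upper cumulative
    hypergeometric tail.  A motif is enriched iff p < ``p_max`` AND
    overlap >= 1 AND enrichment factor > ``enrichment_factor_min``.
    Position-free motifs have no window and are skipped.
    """
    if not footprints:
        raise MotifError("enrichment requires at least one mutation")
    frame = window_up + window_down
    n = len(footprints)
    results = []
    for motif in catalog:
        if motif.window is None:
            continue
        if motif.window[0] < -window_up or motif.window[1] > window_down:
            raise MotifError(
                f"motif {motif.name} window {motif.window} outside frame "
                f"[-{window_up}, +{window_down}]")
        width = _window_width(motif.window)
        overlap = sum(_intervals_overlap(motif.window, f) for f in footprints)
        expected = n * width / frame
        ef = overlap / expected if expected > 0 else 0.0
        p = float(hypergeom.sf(overlap - 1, frame, width, n))
        results.append(EnrichmentResult(
            motif=motif.name, overlap=overlap, expected=expected,
            enrichment_factor=ef, p_value=p,
            enriched=(p < p_max and overlap >= 1
                      and ef > enrichment_factor_min)))
    return results


# ---------------------------------------------------------------------------
# catalog I/O

def read_catalog_file(path: str | Path) -> list[MotifDefinition]:
    """Motif catalog from YAML: list of {name, consensus, window_start,
    window_end, strand_policy}; window "any"/null means position-free."""
    raw = yaml.safe_load(Path(path).read_text())
    catalog = []
    for entry in raw:
        ws, we = entry.get("window_start", "any"), entry.get("window_end", "any")
        window = None if ws in ("any", None) else (int(ws), int(we))
        catalog.append(MotifDefinition(
            name=str(entry["name"]), consensus=str(entry["consensus"]),
            window=window,
            strand_policy=entry.get("strand_policy", "sense_only")))
    validate_catalog(catalog)
    return catalog


def write_catalog_file(catalog: Sequence[MotifDefinition], path: str | Path) -> None:
    rows = []
    for m in catalog:
        rows.append({
            "name": m.name, "consensus": m.consensus,
            "window_start": m.window[0] if m.window else "any",
            "window_end": m.window[1] if m.window else "any",
            "strand_policy": m.strand_policy})
    Path(path).write_text(yaml.safe_dump(rows, sort_keys=False))
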