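"""Core promoter windows around transcription start sites.

A core promoter is modelled as a fixed window around a gene's TSS, held in
the *transcribed-strand* orientation so that downstream motif and repeat
analysis never has to think about strand again.  Relative coordinates follow
the promoter-literature convention: there is no position 0, the TSS base is
+1 and the base immediately upstream is -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from pyfaidx import Fasta

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


class PromoterError(ValueError):
    """Raised for invalid promoter construction or coordinate lookups."""


@dataclass(frozen=True)
class CorePromoter:
    """A TSS-centred core promoter window.

    Parameters
    ----------
    gene_id : str
        Gene symbol or identifier; unique within a promoter set.
    chrom : str
        Contig name.
    tss : int
        1-based genomic position of the first transcribed base.
    strand : str
        ``"+"`` or ``"-"``.
    window_up, window_down : int
        Bases upstream / downstream of the TSS covered by the window.
        The TSS base itself counts as the first downstream base (+1).
    sequence : str
        Transcribed-strand bases covering the window; length is always
        ``window_up + window_down``.
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str
    window_up: int
    window_down: int
    sequence: str = field(repr=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise PromoterError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.window_up < 1 or self.window_down < 1:
            raise PromoterError("window_up and window_down must be >= 1")
        if len(self.sequence) != self.window_up + self.window_down:
            raise PromoterError(
                f"{self.gene_id}: sequence length {len(self.sequence)} != "
                f"window_up + window_down = {self.window_up + self.window_down}")

    # -- genomic interval ------------------------------------------------

    @property
    def genomic_start(self) -> int:
        """1-based first genomic position covered by the window."""
        if self.strand == "+":
            return self.tss - self.window_up
        return self.tss - self.window_down + 1

    @property
    def genomic_end(self) -> int:
        """1-based last genomic position covered by the window."""
        if self.strand == "+":
            return self.tss + self.window_down - 1
        return self.tss + self.window_up

    def contains(self, pos: int) -> bool:
        return self.genomic_start <= pos <= self.genomic_end

    # -- coordinate transforms -------------------------------------------

    def genomic_to_relative(self, pos: int) -> int:
        """Signed TSS-relative coordinate of a genomic position.

        Upstream of the TSS is negative, the TSS base is +1; there is no 0.
        """
        if not self.contains(pos):
            raise PromoterError(
                f"{self.gene_id}: position {pos} outside window "
                f"[{self.genomic_start}, {self.genomic_end}]")
        if self.strand == "+":
            offset = pos - self.tss
        else:
            offset = self.tss - pos
        return offset + 1 if offset >= 0 else offset

    def relative_to_genomic(self, rel: int) -> int:
        """Inverse of :meth:`genomic_to_relative`."""
        if rel == 0:
            raise PromoterError("relative position 0 does not exist")
        if not (-self.window_up <= rel <= self.window_down):
            raise PromoterError(
                f"{self.gene_id}: relative position {rel} outside window "
                f"[-{self.window_up}, +{self.window_down}]")
        offset = rel - 1 if rel > 0 else rel
        return self.tss + offset if self.strand == "+" else self.tss - offset

    def relative_to_index(self, rel: int) -> int:
        """0-based index into :attr:`sequence` of a relative position."""
        if rel == 0 or not (-self.window_up <= rel <= self.window_down):
            raise PromoterError(f"relative position {rel} outside window")
        return rel + self.window_up if rel < 0 else rel + self.window_up - 1

    def index_to_relative(self, idx: int) -> int:
        """Relative position of a 0-based :attr:`sequence` index."""
        if not 0 <= idx < len(self.sequence):
            raise PromoterError(f"sequence index {idx} out of range")
        rel = idx - self.window_up
        return rel if rel < 0 else rel + 1

    def base_at(self, rel: int) -> str:
        return self.sequence[self.relative_to_index(rel)]

    def with_sequence(self, sequence: str, window_up: int | None = None) -> "CorePromoter":
        """Copy with a replaced sequence (used for mutant frames)."""
        wu = self.window_up if window_up is None else window_up
        return replace(self, sequence=sequence, window_up=wu,
                       window_down=len(sequence) - wu)


def build_core_promoter(gene_id: str, chrom: str, tss: int, strand: str,
                        window_up: int, window_down: int,
                        reference: Mapping[str, object] | Fasta) -> CorePromoter:
    """Extract a strand-oriented core promoter window from a reference.

    ``reference`` maps contig name to an indexable sequence (a
    :class:`pyfaidx.Fasta` or a plain ``dict`` of strings).  The window must
    lie fully within the contig; a window running past either end raises
    :class:`PromoterError` rather than silently clipping.
    """
    if strand == "+":
        start = tss - window_up          # 1-based inclusive
        end = tss + window_down - 1
    elif strand == "-":
        start = tss - window_down + 1
        end = tss + window_up
    else:
        raise PromoterError(f"strand must be '+' or '-', got {strand!r}")
    try:
        contig = reference[chrom]
    except KeyError:
        raise PromoterError(f"{gene_id}: contig {chrom!r} not in reference")
    contig_len = len(contig)
    if start < 1 or end > contig_len:
        raise PromoterError(
            f"{gene_id}: window [{start}, {end}] extends past contig "
            f"{chrom} (length {contig_len}); refusing to truncate")
    raw = str(contig[start - 1:end]).upper()
    seq = raw if strand == "+" else reverse_complement(raw)
    return CorePromoter(gene_id=gene_id, chrom=chrom, tss=tss, strand=strand,
                        window_up=window_up, window_down=window_down,
                        sequence=seq)


def read_promoter_set(bed_path: str | Path, fasta_path: str | Path) -> list[CorePromoter]:
    """Load promoters from a BED6 file plus an indexed reference FASTA.

    BED columns: chrom, start, end, gene_id, score (ignored), strand; the
    interval is 0-based half-open.  Optional columns 7 and 8 carry the
    1-based TSS and ``window_up`` (promoter BEDs written by this package
    include them).  Without them the TSS is placed at the strand-aware
    midpoint, i.e. an equal up/down split of the interval.
    """
    bed_path, fasta_path = Path(bed_path), Path(fasta_path)
    ref = Fasta(str(fasta_path), as_raw=False, sequence_always_upper=True)
    promoters: list[CorePromoter] = []
    seen: set[str] = set()
    for lineno, line in enumerate(bed_path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 6:
            raise PromoterError(f"{bed_path}:{lineno}: need >= 6 BED columns")
        chrom, start, end, gene_id, _score, strand = parts[:6]
        start_i, end_i = int(start), int(end)
        if gene_id in seen:
            raise PromoterError(f"{bed_path}:{lineno}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        if len(parts) >= 8:
            tss = int(parts[6])
            window_up = int(parts[7])
            window_down = (end_i - start_i) - window_up
        else:
            # Without an explicit TSS column the TSS is the strand-aware
            # midpoint boundary: equal up/down halves.
            half = (end_i - start_i) // 2
            window_up = window_down = half
            tss = start_i + half + 1 if strand == "+" else end_i - half
        if chrom not in ref:
            raise PromoterError(
                f"{bed_path}:{lineno}: contig {chrom!r} for {gene_id} "
                f"missing from {fasta_path}")
        promoters.append(build_core_promoter(
            gene_id, chrom, tss, strand, window_up, window_down, ref))
    return promoters


def write_promoter_set(promoters: Iterable[CorePromoter], bed_path: str | Path,
                       fasta_path: str | Path,
                       reference: Mapping[str, str]) -> None:
    """Write a promoter set as a BED (+TSS columns) and reference FASTA."""
    bed_lines = []
    for p in promoters:
        bed_lines.append("\t".join(map(str, [
            p.chrom, p.genomic_start - 1, p.genomic_end, p.gene_id, 0,
            p.strand, p.tss, p.window_up])))
    Path(bed_path).write_text("\n".join(bed_lines) + "\n")
    with open(fasta_path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
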