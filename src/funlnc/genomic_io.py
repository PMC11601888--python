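"""Readers/writers for the interval-level input formats and promoter derivation.

All coordinates are BED semantics: 0-based, half-open ``[start, end)``.
GTF-style 1-based inputs are converted on load. Chromosome names are matched
as exact strings; no liftover or name normalization is attempted.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "LncRNAGene",
    "AnchorPair",
    "PairRow",
    "read_bed",
    "write_bed",
    "read_bedpe",
    "write_bedpe",
    "read_genes_bed",
    "read_pair_table",
    "write_pair_table",
    "read_fasta",
    "write_fasta",
    "derive_promoters",
    "overlaps",
]

VALID_STRANDS = {"+", "-", "."}
PARTNER_KINDS = {"mRNA", "miRNA", "protein"}


class FormatError(ValueError):
    """Raised for malformed records in any supported input format."""


@dataclasses.dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with an optional signal value."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."
    signal: float = 1.0

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {sorted(VALID_STRANDS)}")
        if self.signal < 0:
            raise ValueError(f"signal must be >= 0, got {self.signal}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Half-open intersection test; element strand is ignored."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


@dataclasses.dataclass(frozen=True)
class LncRNAGene:
    """A lncRNA gene reduced to the fields the pipeline consumes."""

    id: str
    tss: GenomicInterval
    strand: str
    promoter: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if self.tss.width != 1:
            raise ValueError(f"TSS of {self.id} must have width 1")
        if self.promoter is not None and not overlaps(self.promoter, self.tss):
            raise ValueError(f"promoter of {self.id} does not contain its TSS")


@dataclasses.dataclass(frozen=True)
class AnchorPair:
    """A pair of 3D-contact anchors with a positive contact frequency."""

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    frequency: float = 1.0
    name: str = "."

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError(f"frequency must be > 0, got {self.frequency}")


@dataclasses.dataclass(frozen=True)
class PairRow:
    lncrna_id: str
    partner_id: str
    partner_kind: str

    def __post_init__(self) -> None:
        if self.partner_kind not in PARTNER_KINDS:
            raise ValueError(
                f"partner_kind must be one of {sorted(PARTNER_KINDS)}, "
                f"got {self.partner_kind!r}"
            )


def _split_line(line: str) -> list[str]:
    return line.rstrip("\n").split("\t")


def read_bed(path: str | Path, kind: str | None = None) -> list[GenomicInterval]:
    """Read a BED3/5/6 file into validated intervals sorted by (chrom, start).

    Column 4 is the name (auto-generated when absent), column 5 the signal
    (defaults to 1.0) and column 6 the strand. ``kind`` is only used to label
    auto-generated names.
    """
    path = Path(path)
    prefix = kind or path.stem
    records: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _split_line(line)
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 columns")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else (
                    f"{prefix}_{lineno}"
                )
                signal = (
                    float(fields[4]) if len(fields) > 4 and fields[4] not in ("", ".")
                    else 1.0
                )
                strand = fields[5] if len(fields) > 5 and fields[5] else "."
                records.append(
                    GenomicInterval(chrom, start, end, strand, name, signal)
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    records.sort(key=lambda r: (r.chrom, r.start, r.end))
    return records


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.signal!r}\t{iv.strand}\n"
            )


def read_bedpe(path: str | Path) -> list[AnchorPair]:
    """Read a BEDPE file of anchor pairs; column 8 is the contact frequency."""
    path = Path(path)
    pairs: list[AnchorPair] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = _split_line(line)
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected >=6 columns")
            try:
                a = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                b = GenomicInterval(fields[3], int(fields[4]), int(fields[5]))
                name = fields[6] if len(fields) > 6 and fields[6] else "."
                freq = (
                    float(fields[7]) if len(fields) > 7 and fields[7] not in ("", ".")
                    else 1.0
                )
                pairs.append(AnchorPair(a, b, freq, name))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return pairs


def write_bedpe(pairs: Iterable[AnchorPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(
                f"{p.anchor_a.chrom}\t{p.anchor_a.start}\t{p.anchor_a.end}\t"
                f"{p.anchor_b.chrom}\t{p.anchor_b.start}\t{p.anchor_b.end}\t"
                f"{p.name}\t{p.frequency!r}\n"
            )


def read_genes_bed(path: str | Path) -> list[LncRNAGene]:
    """Read lncRNA genes from BED6/BED12; only chrom, TSS, strand, id used.

    The TSS is the 5' end of the interval: ``start`` on + or ``.`` strand,
    ``end - 1`` on -.
    """
    genes: list[LncRNAGene] = []
    seen: set[str] = set()
    for iv in read_bed(path, kind="lncrna"):
        if iv.name in seen:
            raise FormatError(f"duplicate gene id {iv.name!r} in {path}")
        seen.add(iv.name)
        pos = iv.start if iv.strand in ("+", ".") else iv.end - 1
        tss = GenomicInterval(iv.chrom, pos, pos + 1, iv.strand, f"{iv.name}_tss")
        genes.append(LncRNAGene(id=iv.name, tss=tss, strand=iv.strand))
    return genes


def derive_promoters(
    genes: Sequence[LncRNAGene], window: int = 2000
) -> list[LncRNAGene]:
    """Attach a promoter of ``[tss - window, tss + window)`` clipped at 0.

    The window is symmetric around the TSS regardless of strand.
    """
    if window <= 0:
        raise ValueError(f"window must be > 0, got {window}")
    out: list[LncRNAGene] = []
    for g in genes:
        if g.tss is None:  # pragma: no cover - dataclass forbids this
            raise ValueError(f"gene {g.id} has no TSS")
        start = max(0, g.tss.start - window)
        promoter = GenomicInterval(
            g.tss.chrom, start, g.tss.start + window, g.strand, f"{g.id}_promoter"
        )
        out.append(dataclasses.replace(g, promoter=promoter))
    return out


def read_pair_table(path: str | Path) -> list[PairRow]:
    """Read a TSV of (lncrna_id, partner_id, partner_kind) rows, deduplicated."""
    path = Path(path)
    rows: list[PairRow] = []
    seen: set[tuple[str, str, str]] = set()
    with open(path) as fh:
        header = fh.readline()
        cols = _split_line(header)
        if cols[:3] != ["lncrna_id", "partner_id", "partner_kind"]:
            raise FormatError(
                f"{path}: expected header 'lncrna_id\\tpartner_id\\tpartner_kind'"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = _split_line(line)
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            try:
                row = PairRow(fields[0], fields[1], fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            key = (row.lncrna_id, row.partner_id, row.partner_kind)
            if key not in seen:
                seen.add(key)
                rows.append(row)
    return rows


def write_pair_table(rows: Iterable[PairRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("lncrna_id\tpartner_id\tpartner_kind\n")
        for r in rows:
            fh.write(f"{r.lncrna_id}\t{r.partner_id}\t{r.partner_kind}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Minimal FASTA reader returning ``{id: sequence}`` (first token of header)."""
    seqs: dict[str, str] = {}
    current: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if current is not None:
                    seqs[current] = "".join(chunks)
                current = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if current is not None:
        seqs[current] = "".join(chunks)
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
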