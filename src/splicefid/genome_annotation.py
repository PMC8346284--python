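"""Genomic intervals, gene models, sequences and annotation I/O.

All coordinates are 0-based half-open (BED convention). GTF input, which is
1-based inclusive, is converted on read. Strand is one of ``+``, ``-`` or
``.``; minus-strand sequence fetches return the reverse complement, so every
downstream sequence operation (nucleotide composition, motif scans, splice
site windows) sees the transcribed strand.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils

__all__ = [
    "GenomeInterval",
    "GeneModel",
    "GenomeSequence",
    "AnnotationError",
    "interval_overlap",
    "merge_intervals",
    "read_annotation",
    "collapse_to_longest",
    "gene_length",
    "read_bed",
    "write_bed",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A half-open genomic interval ``[start, end)`` on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return interval_overlap(self, other) > 0


def interval_overlap(a: GenomeInterval, b: GenomeInterval) -> int:
    """Overlap length in bp between two intervals (0 if different chroms)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def merge_intervals(intervals: Iterable[GenomeInterval]) -> list[GenomeInterval]:
    """Merge overlapping or book-ended intervals into a sorted disjoint set.

    Book-ended intervals (``[0,5)`` + ``[5,8)``) merge into one: when counting
    "non-overlapping sites" an abutting pair is one locus, not two. Strand is
    ignored for merging; merged intervals carry strand ``.`` unless all inputs
    in a run share one strand.
    """
    by_chrom: dict[str, list[GenomeInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomeInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        strands = {ivs[0].strand}
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or book-ended
                cur_end = max(cur_end, iv.end)
                strands.add(iv.strand)
            else:
                out.append(
                    GenomeInterval(chrom, cur_start, cur_end,
                                   strands.pop() if len(strands) == 1 else ".")
                )
                cur_start, cur_end, strands = iv.start, iv.end, {iv.strand}
        out.append(
            GenomeInterval(chrom, cur_start, cur_end,
                           strands.pop() if len(strands) == 1 else ".")
        )
    return out


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware exon/intron structure of one transcript.

    Exons are stored sorted by genomic start and must be non-overlapping and
    share one chromosome and strand. Introns are the gaps between consecutive
    exons; exon and intron union is the contiguous gene span.
    """

    gene_id: str
    transcript_id: str
    exons: tuple[GenomeInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: transcript has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise AnnotationError(
                f"{self.transcript_id}: exons span multiple chromosomes or strands"
            )
        ordered = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", ordered)
        for a, b in itertools.pairwise(ordered):
            if b.start < a.end:
                raise AnnotationError(
                    f"{self.transcript_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def introns(self) -> tuple[GenomeInterval, ...]:
        out = []
        for a, b in itertools.pairwise(self.exons):
            if b.start > a.end:
                out.append(GenomeInterval(self.chrom, a.end, b.start, self.strand))
        return tuple(out)

    @property
    def span(self) -> GenomeInterval:
        return GenomeInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)

    def exons_transcript_order(self) -> tuple[GenomeInterval, ...]:
        """Exons in 5'→3' transcriptional order."""
        return self.exons if self.strand != "-" else tuple(reversed(self.exons))


class GenomeSequence:
    """Per-chromosome nucleotide strings with strand-aware slicing."""

    def __init__(self, chromosomes: Mapping[str, str]):
        self._chroms = {name: seq.upper() for name, seq in chromosomes.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path))
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def chrom_length(self, chrom: str) -> int:
        return len(self._chroms[chrom])

    def chromosomes(self) -> list[str]:
        return sorted(self._chroms)

    def fetch(self, interval: GenomeInterval) -> str:
        """Sequence of an interval; minus strand returns reverse complement."""
        seq = self._chroms[interval.chrom][interval.start:interval.end]
        if len(seq) != interval.length:
            raise AnnotationError(
                f"interval [{interval.start},{interval.end}) off the end of "
                f"{interval.chrom} (length {self.chrom_length(interval.chrom)})"
            )
        return reverse_complement(seq) if interval.strand == "-" else seq

    def to_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name in sorted(self._chroms):
                fh.write(f">{name}\n")
                seq = self._chroms[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")


def _validate_gtf_lines(path: str | Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{path}: malformed GTF line {lineno}: expected 9 tab-separated "
                    f"fields, got {len(fields)}"
                )
            try:
                int(fields[3]), int(fields[4])
            except ValueError:
                raise AnnotationError(
                    f"{path}: malformed GTF line {lineno}: non-integer coordinates"
                ) from None


def read_annotation(gtf_path: str | Path) -> list[GeneModel]:
    """Read a GTF and return one :class:`GeneModel` per transcript.

    Only ``exon`` features are used; introns are derived from the gaps.
    Output is deterministically ordered by (chrom, span start, gene_id,
    transcript_id). Malformed lines and overlapping exons raise
    :class:`AnnotationError`.
    """
    _validate_gtf_lines(gtf_path)
    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_transcript: dict[tuple[str, str], list[GenomeInterval]] = {}
    for feat in db.features_of_type("exon"):
        key = (feat["gene_id"][0], feat["transcript_id"][0])
        by_transcript.setdefault(key, []).append(
            GenomeInterval(feat.seqid, feat.start - 1, feat.end, feat.strand or ".")
        )
    models = [
        GeneModel(gene_id=g, transcript_id=t, exons=tuple(exons))
        for (g, t), exons in by_transcript.items()
    ]
    models.sort(key=lambda m: (m.chrom, m.span.start, m.gene_id, m.transcript_id))
    return models


def collapse_to_longest(models: Sequence[GeneModel]) -> list[GeneModel]:
    """One model per gene: the transcript with the largest exonic length.

    Ties break deterministically on transcript_id.
    """
    best: dict[str, GeneModel] = {}
    for m in models:
        cur = best.get(m.gene_id)
        if cur is None or (m.exonic_length, m.transcript_id) > (
            cur.exonic_length, cur.transcript_id
        ):
            best[m.gene_id] = m
    return sorted(
        best.values(), key=lambda m: (m.chrom, m.span.start, m.gene_id)
    )


def gene_length(model: GeneModel, mode: str = "exonic") -> int:
    """Gene length statistic: ``exonic`` (sum of exon lengths, the default,
    i.e. mature transcript length) or ``span`` (genomic footprint)."""
    if mode == "exonic":
        return model.exonic_length
    if mode == "span":
        return model.span.length
    raise ValueError(f"unknown gene length mode {mode!r}")


def read_bed(path: str | Path) -> list[tuple[GenomeInterval, str, float]]:
    """Read BED(6) as (interval, name, score) tuples; missing columns default."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise AnnotationError(f"{path}: malformed BED line {lineno}")
            name = f[3] if len(f) > 3 else "."
            score = float(f[4]) if len(f) > 4 and f[4] != "." else 0.0
            strand = f[5] if len(f) > 5 else "."
            out.append((GenomeInterval(f[0], int(f[1]), int(f[2]), strand), name, score))
    return out


def write_bed(
    path: str | Path,
    records: Iterable[tuple[GenomeInterval, str, float]],
) -> None:
    """Write BED6, deterministically sorted by (chrom, start, end, name)."""
    rows = sorted(records, key=lambda r: (r[0].chrom, r[0].start, r[0].end, r[1]))
    with open(path, "w") as fh:
        for iv, name, score in rows:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
            )
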