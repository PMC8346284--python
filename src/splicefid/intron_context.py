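"""Intron-context statistics around mis-splicing events.

For a cassette (skipped-exon) event the introns immediately upstream (-1)
and downstream (+1) of the cassette are its flanking proximal introns; for a
backsplice event the same labels apply to the introns just outside the
circularised span, with introns inside the span labelled "internal".
Upstream/downstream are transcriptional: on the minus strand the labels
mirror genomic order.

Provided statistics: unique-intron length contrasts (Wilcoxon rank-sum),
non-overlapping binding-site density per kb, repeat-track overlap fractions,
and position-weight-matrix splice-site strength of event vs original
flanking splice sites.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_annotation import (
    GeneModel,
    GenomeInterval,
    GenomeSequence,
    interval_overlap,
    merge_intervals,
)
from .peak_analysis import Peak

__all__ = [
    "IntronContext",
    "SpliceSitePwm",
    "label_introns",
    "intron_length_contrast",
    "binding_density",
    "repeat_overlap",
    "build_pwm",
    "donor_window",
    "acceptor_window",
    "site_strength_contrast",
]

DONOR_EXONIC, DONOR_INTRONIC = 3, 6       # 9-mer: 3 exonic + 6 intronic nt
ACCEPTOR_INTRONIC, ACCEPTOR_EXONIC = 20, 3  # 23-mer: 20 intronic + 3 exonic nt


@dataclass(frozen=True)
class IntronContext:
    intron: GenomeInterval
    label: str  # upstream | downstream | internal | other


def _exon_index(gene: GeneModel, exon: GenomeInterval) -> int:
    for i, e in enumerate(gene.exons):
        if e.start == exon.start and e.end == exon.end:
            return i
    raise ValueError(f"exon [{exon.start},{exon.end}) not found in {gene.transcript_id}")


def label_introns(
    gene: GeneModel,
    span_first_exon: int,
    span_last_exon: int,
    event_kind: str = "SE",
) -> list[IntronContext]:
    """Label a transcript's introns relative to an event exon span.

    `span_first_exon`/`span_last_exon` are 0-based genomic exon indices
    (inclusive); for an SE event both equal the cassette index. Labels are
    strand-aware: "upstream" (-1) is the intron on the transcriptional 5'
    side. For SE events introns between the span bounds do not arise; for
    circ events they are "internal". Missing flanks (terminal-exon events)
    simply yield no upstream/downstream entry.
    """
    if event_kind not in ("SE", "circ"):
        raise ValueError(f"unknown event kind {event_kind!r}")
    n_exons = len(gene.exons)
    if not (0 <= span_first_exon <= span_last_exon < n_exons):
        raise ValueError("event exon span outside transcript")
    out = []
    minus = gene.strand == "-"
    for idx, intron in enumerate(gene.introns):
        # intron idx sits between genomic exons idx and idx+1
        if idx == span_first_exon - 1:
            label = "downstream" if minus else "upstream"
        elif idx == span_last_exon:
            label = "upstream" if minus else "downstream"
        elif span_first_exon <= idx < span_last_exon:
            label = "internal"
        else:
            label = "other"
        out.append(IntronContext(intron=intron, label=label))
    return out


def unique_introns(introns: Iterable[GenomeInterval]) -> list[GenomeInterval]:
    """Deduplicate introns by (chrom, start, end, strand)."""
    return sorted(set(introns))


def intron_length_contrast(
    groups: Mapping[str, Sequence[GenomeInterval]],
) -> dict:
    """Median unique-intron length per group + pairwise two-sided rank-sum p.

    Introns are deduplicated by coordinates within each group before the
    length statistics. Degenerate singleton-vs-singleton comparisons return
    p = 1.0.
    """
    if len(groups) < 2:
        raise ValueError("need at least two intron groups")
    lengths = {}
    for name, introns in groups.items():
        uniq = unique_introns(introns)
        if not uniq:
            raise ValueError(f"intron group {name!r} is empty")
        lengths[name] = np.array([iv.length for iv in uniq], dtype=float)
    medians = {name: float(np.median(v)) for name, v in lengths.items()}
    pairwise = {}
    for a, b in itertools.combinations(sorted(lengths), 2):
        if len(lengths[a]) == 1 and len(lengths[b]) == 1:
            p = 1.0
        else:
            p = float(stats.ranksums(lengths[a], lengths[b]).pvalue)
        pairwise[(a, b)] = p
    return {"medians": medians, "n": {k: len(v) for k, v in lengths.items()},
            "pairwise_p": pairwise}


def binding_density(
    intron: GenomeInterval, peaks: Sequence[Peak] | Sequence[GenomeInterval]
) -> float:
    """Non-overlapping binding sites per kb of intron.

    Peaks are merged (book-ended included) first; a merged site counts if it
    overlaps the intron by >= 1 bp.
    """
    if intron.length <= 0:
        raise ValueError("intron length must be positive")
    intervals = [
        p.interval if isinstance(p, Peak) else p for p in peaks
    ]
    merged = merge_intervals(intervals) if intervals else []
    n_sites = sum(1 for iv in merged if interval_overlap(iv, intron) > 0)
    return n_sites / (intron.length / 1000.0)


def repeat_overlap(
    peaks: Sequence[Peak],
    repeats: Sequence[tuple[GenomeInterval, str]],
) -> dict:
    """Fraction of peaks overlapping >= 1 repeat element, with a per-class
    breakdown. A peak counts once toward the overall fraction even if it hits
    several classes; per-class counts may therefore sum to more than the
    overall hit count.
    """
    by_chrom: dict[str, list[tuple[GenomeInterval, str]]] = {}
    for iv, cls in repeats:
        by_chrom.setdefault(iv.chrom, []).append((iv, cls))
    n_hit = 0
    per_class: dict[str, int] = {}
    for p in peaks:
        classes = {
            cls for iv, cls in by_chrom.get(p.interval.chrom, ())
            if interval_overlap(p.interval, iv) > 0
        }
        if classes:
            n_hit += 1
            for cls in classes:
                per_class[cls] = per_class.get(cls, 0) + 1
    n = len(peaks)
    return {
        "n_peaks": n,
        "n_overlapping": n_hit,
        "fraction": (n_hit / n) if n else 0.0,
        "per_class": dict(sorted(per_class.items())),
    }


@dataclass(frozen=True)
class SpliceSitePwm:
    """Log2-odds position weight matrix for donor or acceptor windows.

    matrix is positions x 4 (A, C, G, T) against a uniform 0.25 background,
    with a 0.5 pseudocount per cell.
    """

    kind: str  # "donor" (9-mer) or "acceptor" (23-mer)
    matrix: np.ndarray

    _BASES = "ACGT"

    def score(self, seq: str) -> float:
        if len(seq) != self.matrix.shape[0]:
            raise ValueError(
                f"{self.kind} window must be {self.matrix.shape[0]} nt, got {len(seq)}"
            )
        total = 0.0
        for i, base in enumerate(seq.upper()):
            j = self._BASES.find(base)
            if j < 0:  # N scores the background average of the column
                total += float(self.matrix[i].mean())
            else:
                total += float(self.matrix[i, j])
        return total


def expected_pwm_length(kind: str) -> int:
    if kind == "donor":
        return DONOR_EXONIC + DONOR_INTRONIC
    if kind == "acceptor":
        return ACCEPTOR_INTRONIC + ACCEPTOR_EXONIC
    raise ValueError(f"unknown splice site kind {kind!r}")


def build_pwm(site_seqs: Sequence[str], kind: str) -> SpliceSitePwm:
    """Build a log2-odds PWM from aligned splice-site windows.

    Each cell is log2(((count + 0.5) / (N + 2)) / 0.25). Requires >= 10
    training sequences of the window length for the site kind.
    """
    width = expected_pwm_length(kind)
    if len(site_seqs) == 0:
        raise ValueError("no training sequences")
    if len(site_seqs) < 10:
        raise ValueError(f"need >= 10 training sequences, got {len(site_seqs)}")
    counts = np.zeros((width, 4))
    for s in site_seqs:
        if len(s) != width:
            raise ValueError(f"{kind} window must be {width} nt, got {len(s)}")
        for i, base in enumerate(s.upper()):
            j = "ACGT".find(base)
            if j >= 0:
                counts[i, j] += 1
    n = len(site_seqs)
    matrix = np.log2(((counts + 0.5) / (n + 2)) / 0.25)
    return SpliceSitePwm(kind=kind, matrix=matrix)


def donor_window(genome: GenomeSequence, exon: GenomeInterval) -> str:
    """9-nt donor window (3 exonic + 6 intronic) at an exon's 3' end."""
    if exon.strand == "-":
        iv = GenomeInterval(exon.chrom, exon.start - DONOR_INTRONIC,
                            exon.start + DONOR_EXONIC, "-")
    else:
        iv = GenomeInterval(exon.chrom, exon.end - DONOR_EXONIC,
                            exon.end + DONOR_INTRONIC, exon.strand)
    return genome.fetch(iv)


def acceptor_window(genome: GenomeSequence, exon: GenomeInterval) -> str:
    """23-nt acceptor window (20 intronic + 3 exonic) at an exon's 5' end."""
    if exon.strand == "-":
        iv = GenomeInterval(exon.chrom, exon.end - ACCEPTOR_EXONIC,
                            exon.end + ACCEPTOR_INTRONIC, "-")
    else:
        iv = GenomeInterval(exon.chrom, exon.start - ACCEPTOR_INTRONIC,
                            exon.start + ACCEPTOR_EXONIC, exon.strand)
    return genome.fetch(iv)


def site_strength_contrast(
    events: Sequence[tuple[GenomeInterval, GenomeInterval, GenomeInterval]],
    genome: GenomeSequence,
    pwm_donor: SpliceSitePwm,
    pwm_acceptor: SpliceSitePwm,
) -> pd.DataFrame:
    """Event splice-site PWM scores vs the original flanking sites.

    Each event is (upstream exon, event exon/span, downstream exon) in
    transcriptional order. Compared pairs: the event acceptor (5' end of the
    event span) vs the downstream exon's acceptor it competes with, and the
    event donor (3' end) vs the upstream exon's donor. Returns per-event
    scores and paired differences (event - original); events whose windows
    run off the contig are skipped. A Wilcoxon signed-rank p on the paired
    differences is attached in ``DataFrame.attrs``.
    """
    if not events:
        raise ValueError("empty event list")
    rows = []
    for i, (up, mid, down) in enumerate(events):
        try:
            ev_donor = pwm_donor.score(donor_window(genome, mid))
            ev_acc = pwm_acceptor.score(acceptor_window(genome, mid))
            orig_donor = pwm_donor.score(donor_window(genome, up))
            orig_acc = pwm_acceptor.score(acceptor_window(genome, down))
        except Exception:
            continue  # window off contig: skip event
        rows.append({
            "event_index": i,
            "event_donor": ev_donor, "original_donor": orig_donor,
            "donor_diff": ev_donor - orig_donor,
            "event_acceptor": ev_acc, "original_acceptor": orig_acc,
            "acceptor_diff": ev_acc - orig_acc,
        })
    df = pd.DataFrame(rows)
    for col in ("donor_diff", "acceptor_diff"):
        diffs = df[col].to_numpy() if not df.empty else np.array([])
        if diffs.size == 0 or np.allclose(diffs, 0.0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(diffs).pvalue)
        df.attrs[f"{col}_p"] = p
    return df
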