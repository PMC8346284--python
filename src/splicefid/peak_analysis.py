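"""Binding-peak analytics: confidence filtering, replicate reproducibility,
genomic-feature classification, nucleotide composition, k-mer motif
enrichment against a dinucleotide-shuffled background, and bound-gene length
comparison.

Peaks are intervals with a log2 fold enrichment over a matched input and a
p-value. A "bound gene" is a gene whose span overlaps at least one
high-confidence peak.
"""

from __future__ import annotations

import itertools
import random as _random
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .genome_annotation import (
    GeneModel,
    GenomeInterval,
    GenomeSequence,
    interval_overlap,
    merge_intervals,
)

__all__ = [
    "Peak",
    "FeatureDistribution",
    "filter_high_confidence",
    "reproducible_peaks",
    "classify_peaks",
    "nucleotide_frequencies",
    "dinucleotide_shuffle",
    "kmer_enrichment",
    "gene_length_comparison",
    "bound_gene_ids",
    "read_peaks_bed",
    "write_peaks_bed",
]


@dataclass(frozen=True)
class Peak:
    interval: GenomeInterval
    fold_enrichment: float = 1.0
    p_value: float = 1.0
    name: str = "."

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class FeatureDistribution:
    """Counts and fractions of peaks per genomic feature category."""

    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[str, float]:
        t = self.total
        return {k: v / t for k, v in self.counts.items()} if t else {}


def filter_high_confidence(
    peaks: Iterable[Peak], p_max: float = 0.05, min_fold: float = 1.5
) -> list[Peak]:
    """Keep peaks with p-value <= p_max and fold enrichment >= min_fold.

    The defaults follow the running-text thresholds (p <= 0.05, fold >= 1.5);
    a stricter fold > 2 variant is available by passing min_fold explicitly.
    """
    return [p for p in peaks if p.p_value <= p_max and p.fold_enrichment >= min_fold]


def reproducible_peaks(rep1: Sequence[Peak], rep2: Sequence[Peak]) -> list[Peak]:
    """Peaks of rep1 with >= 1 bp overlap with any rep2 peak."""
    merged2 = merge_intervals([p.interval for p in rep2]) if rep2 else []
    by_chrom: dict[str, list[GenomeInterval]] = {}
    for iv in merged2:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out = []
    for p in rep1:
        for iv in by_chrom.get(p.interval.chrom, ()):
            if interval_overlap(p.interval, iv) > 0:
                out.append(p)
                break
    return out


def _merged_feature_intervals(
    genes: Sequence[GeneModel],
) -> tuple[list[GenomeInterval], list[GenomeInterval]]:
    exons = merge_intervals([e for g in genes for e in g.exons])
    introns = [i for g in genes for i in g.introns]
    introns = merge_intervals(introns) if introns else []
    return exons, introns


def classify_peaks(
    peaks: Sequence[Peak], genes: Sequence[GeneModel]
) -> FeatureDistribution:
    """Assign each peak one category in {exonic, intronic, intergenic}.

    Majority-overlap rule: the category with the most overlapping bp wins;
    exact ties break exonic > intronic > intergenic. Exonic/intronic bp are
    measured against the merged exons/introns of all supplied genes.
    """
    exons, introns = _merged_feature_intervals(genes)
    counts = {"exonic": 0, "intronic": 0, "intergenic": 0}
    for p in peaks:
        exon_bp = sum(interval_overlap(p.interval, e) for e in exons)
        intron_bp = sum(interval_overlap(p.interval, i) for i in introns)
        intergenic_bp = p.interval.length - exon_bp - intron_bp
        best = max(
            [("exonic", exon_bp), ("intronic", intron_bp),
             ("intergenic", intergenic_bp)],
            key=lambda kv: kv[1],
        )
        # max() keeps the first of tied categories, giving the stated tie order
        counts[best[0]] += 1
    return FeatureDistribution(counts=counts)


def nucleotide_frequencies(
    peaks: Sequence[Peak], genome: GenomeSequence
) -> dict[str, float]:
    """Pooled per-base frequencies over {A, C, G, U} in peak sequences.

    Sequences are fetched strand-aware and reported in the RNA alphabet
    (T as U). N bases are excluded from the denominator; all-N peaks are
    skipped with a warning.
    """
    counts = {"A": 0, "C": 0, "G": 0, "U": 0}
    for p in peaks:
        seq = genome.fetch(p.interval)
        informative = 0
        for base in seq:
            if base == "T":
                counts["U"] += 1
                informative += 1
            elif base in counts:
                counts[base] += 1
                informative += 1
        if informative == 0:
            warnings.warn(f"peak {p.name} at {p.interval} is all-N; excluded")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no informative bases in any peak")
    return {b: c / total for b, c in counts.items()}


def dinucleotide_shuffle(seq: str, rng: _random.Random) -> str:
    """Shuffle a sequence preserving its exact dinucleotide counts.

    Altschul–Erickson style: build the transition multigraph, pick a random
    last edge per vertex forming an arborescence into the terminal base, then
    randomise the remaining edge order and walk the Eulerian path.
    """
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in itertools.pairwise(seq):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = [v for v in edges if v != last]
    # sample last-edge choices until they form an arborescence toward `last`
    while True:
        last_edge = {v: rng.choice(edges[v]) for v in vertices}
        ok = True
        for v in vertices:
            seen, cur = {v}, last_edge[v]
            while cur != last:
                if cur in seen or cur not in last_edge:
                    ok = False
                    break
                seen.add(cur)
                cur = last_edge[cur]
            if not ok:
                break
        if ok:
            break
    shuffled_edges = {}
    for v, targets in edges.items():
        rest = list(targets)
        if v in last_edge:
            rest.remove(last_edge[v])
        rng.shuffle(rest)
        shuffled_edges[v] = rest + ([last_edge[v]] if v in last_edge else [])
    out = [seq[0]]
    counters = {v: 0 for v in edges}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled_edges[cur][counters[cur]]
        counters[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def _count_kmers(seqs: Iterable[str], k: int) -> tuple[dict[str, int], int]:
    counts: dict[str, int] = {}
    total = 0
    for s in seqs:
        for i in range(len(s) - k + 1):
            kmer = s[i:i + k]
            if "N" in kmer:
                continue
            counts[kmer] = counts.get(kmer, 0) + 1
            total += 1
    return counts, total


def kmer_enrichment(
    peaks: Sequence[Peak],
    genome: GenomeSequence,
    k: int = 6,
    flank: int = 30,
    n_shuffles: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank k-mers enriched in peak +/- flank sequences over shuffled background.

    Each peak sequence is extended by `flank` bp on both sides (clipped at
    contig ends) and fetched strand-aware. The background expectation per
    k-mer comes from `n_shuffles` dinucleotide-preserving shuffles of the same
    sequences, so enrichment reflects base arrangement rather than overall
    G/U content. One-sided binomial p-values are BH-adjusted; the table is
    sorted by (q, -observed, kmer).
    """
    if n_shuffles <= 0:
        raise ValueError("n_shuffles must be positive")
    if not 4 <= k <= 8:
        raise ValueError("k must be in [4, 8]")
    rng = _random.Random(seed)
    seqs = []
    for p in peaks:
        iv = p.interval
        start = max(0, iv.start - flank)
        end = min(genome.chrom_length(iv.chrom), iv.end + flank)
        seq = genome.fetch(GenomeInterval(iv.chrom, start, end, iv.strand))
        if len(seq) >= k:
            seqs.append(seq)
    observed, n_obs = _count_kmers(seqs, k)
    bg_counts: dict[str, float] = {}
    n_bg = 0
    for _ in range(n_shuffles):
        shuffled = [dinucleotide_shuffle(s, rng) for s in seqs]
        c, t = _count_kmers(shuffled, k)
        for kmer, v in c.items():
            bg_counts[kmer] = bg_counts.get(kmer, 0.0) + v
        n_bg += t
    rows = []
    for kmer in sorted(set(observed) | set(bg_counts)):
        obs = observed.get(kmer, 0)
        expected = bg_counts.get(kmer, 0.0) / n_shuffles
        # background probability with a half-count floor to keep p finite
        p0 = max(bg_counts.get(kmer, 0.0), 0.5) / max(n_bg, 1)
        pval = float(stats.binom.sf(obs - 1, n_obs, p0)) if obs > 0 else 1.0
        rows.append((kmer, obs, expected, pval))
    df = pd.DataFrame(rows, columns=["kmer", "observed", "expected", "p_value"])
    df["q_value"] = bh_adjust(df["p_value"].to_numpy())
    df = df.sort_values(
        ["q_value", "observed", "kmer"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return df


def bound_gene_ids(
    genes: Sequence[GeneModel], peaks: Sequence[Peak]
) -> set[str]:
    """Gene ids whose span overlaps >= 1 peak."""
    merged = merge_intervals([p.interval for p in peaks]) if peaks else []
    by_chrom: dict[str, list[GenomeInterval]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out = set()
    for g in genes:
        span = g.span
        if any(interval_overlap(span, iv) > 0 for iv in by_chrom.get(g.chrom, ())):
            out.add(g.gene_id)
    return out


def gene_length_comparison(
    genes: Sequence[GeneModel],
    bound_gene_ids: set[str],
    expressed_gene_ids: set[str],
    length_mode: str = "exonic",
) -> dict:
    """Median gene length for bound-and-expressed vs expressed vs
    expressed-not-bound genes, with a two-sided Wilcoxon rank-sum p between
    bound and non-bound groups."""
    from .genome_annotation import gene_length

    lengths = {g.gene_id: gene_length(g, length_mode) for g in genes}
    expressed = [lengths[g] for g in lengths if g in expressed_gene_ids]
    bound = [
        lengths[g] for g in lengths
        if g in expressed_gene_ids and g in bound_gene_ids
    ]
    unbound = [
        lengths[g] for g in lengths
        if g in expressed_gene_ids and g not in bound_gene_ids
    ]
    if not expressed or not bound or not unbound:
        raise ValueError("all three gene groups must be non-empty")
    p = float(stats.ranksums(bound, unbound).pvalue)
    return {
        "median_bound": float(np.median(bound)),
        "median_expressed": float(np.median(expressed)),
        "median_unbound": float(np.median(unbound)),
        "ranksum_p_bound_vs_unbound": p,
        "n_bound": len(bound),
        "n_expressed": len(expressed),
        "n_unbound": len(unbound),
    }


def read_peaks_bed(path: str | Path) -> list[Peak]:
    """Read peaks from BED6+2 (name, score, strand, log2 fold, p-value)."""
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8:
                raise ValueError(f"{path}: line {lineno}: expected 8 BED6+2 fields")
            peaks.append(
                Peak(
                    interval=GenomeInterval(f[0], int(f[1]), int(f[2]), f[5]),
                    name=f[3],
                    fold_enrichment=float(f[6]),
                    p_value=float(f[7]),
                )
            )
    return peaks


def write_peaks_bed(path: str | Path, peaks: Iterable[Peak]) -> None:
    rows = sorted(
        peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end)
    )
    with open(path, "w") as fh:
        for p in rows:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t0\t{iv.strand}"
                f"\t{p.fold_enrichment:g}\t{p.p_value:g}\n"
            )
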