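"""G-quadruplex candidate detection (QGRS-style) and per-kb intron density.

A candidate G-quadruplex-forming sequence is four G-tracts of equal length
``x`` separated by three loops: ``G{x} N{y1} G{x} N{y2} G{x} N{y3} G{x}``.
Candidates are scored with an explicit G-score that rewards more tetrads,
shorter loops and more even loops; the score is this package's own
codification of that qualitative behaviour and is used only for relative
ranking when picking one candidate per locus.

Density per kb is computed from a greedy non-overlapping selection so that a
single G-rich locus, which typically spawns many overlapping candidate
arrangements, is counted once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .genome_annotation import GenomeInterval, GenomeSequence

__all__ = ["QgrsParams", "QgrsHit", "find_qgrs", "select_nonoverlapping",
           "gq_density", "gq_density_interval"]


@dataclass(frozen=True)
class QgrsParams:
    """Motif-search parameters.

    min_tetrad: minimum G-tract length x (>= 2).
    max_length: maximum total candidate length 4x + y1 + y2 + y3.
    max_loop: maximum individual loop length (loops may be empty).
    """

    min_tetrad: int = 2
    max_length: int = 30
    max_loop: int = 12
    min_loop: int = 0

    def __post_init__(self) -> None:
        if self.min_tetrad < 2:
            raise ValueError("min_tetrad must be >= 2")
        if 4 * self.min_tetrad > self.max_length:
            raise ValueError("max_length too small for four minimum G-tracts")
        if not (0 <= self.min_loop <= self.max_loop):
            raise ValueError("need 0 <= min_loop <= max_loop")


@dataclass(frozen=True)
class QgrsHit:
    start: int
    length: int
    tetrads: int
    loops: tuple[int, int, int]
    g_score: int

    @property
    def end(self) -> int:
        return self.start + self.length


def g_score(x: int, loops: tuple[int, int, int], max_loop: int = 12) -> int:
    """Integer score: higher for more tetrads, evener loops, shorter loops."""
    y = sorted(loops)
    return (
        20 * (x - 2)
        + (max_loop - (y[2] - y[0]))
        + (max_loop - math.ceil(sum(y) / 3))
    )


def find_qgrs(sequence: str, params: QgrsParams | None = None) -> list[QgrsHit]:
    """Exhaustively enumerate all candidate G-quadruplexes in a sequence.

    U is treated as T (both are simply non-G here); N never matches a G-tract.
    Returns hits sorted by (start, length).
    """
    params = params or QgrsParams()
    seq = sequence.upper()
    n = len(seq)
    # run[i] = length of the G-run starting at i (0 if seq[i] != 'G')
    run = [0] * (n + 1)
    for i in range(n - 1, -1, -1):
        run[i] = run[i + 1] + 1 if seq[i] == "G" else 0

    hits: list[QgrsHit] = []
    x_max = params.max_length // 4
    for i in range(n):
        r0 = run[i]
        if r0 < params.min_tetrad:
            continue
        for x in range(params.min_tetrad, min(r0, x_max) + 1):
            budget = params.max_length - 4 * x  # max total loop length
            y_cap = min(params.max_loop, budget)
            p1 = i + x
            for y1 in range(params.min_loop, y_cap + 1):
                p2 = p1 + y1
                if p2 + 3 * x > n or run[p2] < x:
                    continue
                rem1 = budget - y1
                for y2 in range(params.min_loop, min(params.max_loop, rem1) + 1):
                    p3 = p2 + x + y2
                    if p3 + 2 * x > n or run[p3] < x:
                        continue
                    rem2 = rem1 - y2
                    for y3 in range(params.min_loop, min(params.max_loop, rem2) + 1):
                        p4 = p3 + x + y3
                        if p4 + x > n or run[p4] < x:
                            continue
                        loops = (y1, y2, y3)
                        hits.append(
                            QgrsHit(
                                start=i,
                                length=4 * x + y1 + y2 + y3,
                                tetrads=x,
                                loops=loops,
                                g_score=g_score(x, loops, params.max_loop),
                            )
                        )
    hits.sort(key=lambda h: (h.start, h.length, h.tetrads))
    return hits


def select_nonoverlapping(hits: list[QgrsHit]) -> list[QgrsHit]:
    """Greedy best-score-first selection of mutually non-overlapping hits.

    Order: g_score descending, then start ascending, then length descending.
    Greedy selection is not guaranteed to maximise total score over all
    independent sets; it deterministically picks one representative per
    G-rich locus, which is what per-kb counting needs.
    """
    chosen: list[QgrsHit] = []
    for h in sorted(hits, key=lambda h: (-h.g_score, h.start, -h.length)):
        if all(h.end <= c.start or h.start >= c.end for c in chosen):
            chosen.append(h)
    chosen.sort(key=lambda h: h.start)
    return chosen


def gq_density(sequence: str, params: QgrsParams | None = None) -> float:
    """Non-overlapping candidate G-quadruplexes per kb of sequence."""
    if len(sequence) == 0:
        raise ValueError("empty sequence has no defined density")
    n_sites = len(select_nonoverlapping(find_qgrs(sequence, params)))
    return n_sites / (len(sequence) / 1000.0)


def gq_density_interval(
    genome: GenomeSequence,
    interval: GenomeInterval,
    params: QgrsParams | None = None,
) -> float:
    """Density on the transcribed strand of a genomic interval."""
    return gq_density(genome.fetch(interval), params)
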