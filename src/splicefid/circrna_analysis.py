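"""Backsplicing (circRNA) analytics: differential backsplice-count testing
across two knockdowns, single- vs multi-exon classification, bound-gene
fractions, and a rolling-circle open-reading-frame scan for coding potential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._stats import bh_adjust, two_sample_t_p
from .splicing_analysis import STOP_CODONS, bound_fraction

__all__ = [
    "CircEvent",
    "test_circ",
    "classify_exon_count",
    "circ_bound_fraction",
    "circ_orf_scan",
    "read_backsplice_counts",
]


@dataclass(frozen=True)
class CircEvent:
    """A backsplice event: a contiguous run of circularised exons.

    exon_first/exon_last are 0-based exon indices in transcriptional order
    (inclusive); counts maps sample -> backsplice junction count.
    """

    circ_id: str
    gene_id: str
    exon_first: int
    exon_last: int
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.exon_first < 0 or self.exon_last < self.exon_first:
            raise ValueError(f"{self.circ_id}: invalid circularised exon span")

    @property
    def n_exons(self) -> int:
        return self.exon_last - self.exon_first + 1


def classify_exon_count(circ: CircEvent) -> str:
    """'multi_exonic' iff the circle spans >= 2 exons, else 'single_exon'."""
    return "multi_exonic" if circ.n_exons >= 2 else "single_exon"


def test_circ(
    circs: Sequence[CircEvent],
    control_samples: Sequence[str],
    kd1_samples: Sequence[str],
    kd2_samples: Sequence[str],
    fold_min: float = 2.0,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Differential backsplicing table over two knockdowns vs control.

    Two-sample t on log2(count + 1) per knockdown, BH-adjusted; a circRNA passes
    iff |fold| >= fold_min and q < q_max in both knockdowns with concordant
    direction. CircRNAs with zero counts in every sample are dropped.
    """
    if len(control_samples) < 2 or len(kd1_samples) < 2 or len(kd2_samples) < 2:
        raise ValueError("need >= 2 replicates per condition")
    kept = [
        c for c in circs
        if any(c.counts.get(s, 0) > 0
               for s in (*control_samples, *kd1_samples, *kd2_samples))
    ]
    rows = []
    for c in kept:
        ctrl = np.log2([c.counts.get(s, 0) + 1.0 for s in control_samples])
        row: dict = {
            "circ_id": c.circ_id,
            "gene_id": c.gene_id,
            "n_exons": c.n_exons,
            "structure": classify_exon_count(c),
        }
        for label, samples in (("kd1", kd1_samples), ("kd2", kd2_samples)):
            kd = np.log2([c.counts.get(s, 0) + 1.0 for s in samples])
            row[f"log2fc_{label}"] = float(kd.mean() - ctrl.mean())
            row[f"p_{label}"] = two_sample_t_p(ctrl, kd)
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    for label in ("kd1", "kd2"):
        df[f"q_{label}"] = bh_adjust(df[f"p_{label}"].to_numpy())
    lf_min = math.log2(fold_min)
    df["significant"] = (
        (df["log2fc_kd1"].abs() >= lf_min) & (df["q_kd1"] < q_max)
        & (df["log2fc_kd2"].abs() >= lf_min) & (df["q_kd2"] < q_max)
        & (np.sign(df["log2fc_kd1"]) == np.sign(df["log2fc_kd2"]))
    )
    mean_fold = (df["log2fc_kd1"] + df["log2fc_kd2"]) / 2.0
    df["direction"] = np.where(mean_fold > 0, "up", "down")
    return df.reset_index(drop=True)


def circ_bound_fraction(
    circ_gene_ids: Iterable[str], bound_gene_ids: set[str], decimals: int = 0
) -> tuple[int, int, float]:
    """(n_bound, n_total, percentage) of circRNAs in bound genes.

    Same computation as the skipped-exon bound fraction; the default rounding
    is to whole percent, matching how circRNA fractions are usually printed.
    """
    return bound_fraction(circ_gene_ids, bound_gene_ids, decimals)


def circ_orf_scan(
    circ_seq: str, min_aa: int = 20, max_passes: int = 3
) -> tuple[int, bool]:
    """Longest junction-spanning ORF (in aa) in a circular sequence.

    The circle is linearised by concatenating up to `max_passes` copies and
    scanned in all three frames for ATG...stop ORFs; an ORF counts only if it
    crosses the backsplice junction (i.e. spans a copy boundary). ORFs with
    no stop within the pass guard are truncated there. Returns
    (longest_orf_aa, coding), with coding = longest_orf_aa >= min_aa.
    """
    if len(circ_seq) < 3:
        raise ValueError("circular sequence shorter than one codon")
    seq = circ_seq.upper()
    L = len(seq)
    doubled = seq * max_passes
    best = 0
    for offset in range(len(doubled) - 2):
        if doubled[offset:offset + 3] != "ATG":
            continue
        if offset >= L:  # same ORF as an earlier rotation
            continue
        end = None
        for i in range(offset, len(doubled) - 2, 3):
            if doubled[i:i + 3] in STOP_CODONS:
                end = i
                break
        stop_end = end if end is not None else (len(doubled) - (len(doubled) - offset) % 3)
        # junction-spanning: the ORF must extend past the first copy boundary
        if stop_end <= L:
            continue
        aa = (stop_end - offset) // 3
        best = max(best, aa)
    return best, best >= min_aa


def read_backsplice_counts(path) -> pd.DataFrame:
    """Read a backsplice TSV (circ_id, gene_id, exon_first, exon_last,
    sample, count)."""
    df = pd.read_csv(path, sep="\t")
    required = {"circ_id", "gene_id", "exon_first", "exon_last", "sample", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"backsplice table missing columns: {sorted(missing)}")
    return df


def circ_events_from_table(df: pd.DataFrame) -> list[CircEvent]:
    """Build CircEvent objects from a long-format backsplice count table."""
    events = []
    for (circ_id, gene_id, e0, e1), grp in df.groupby(
        ["circ_id", "gene_id", "exon_first", "exon_last"], sort=True
    ):
        counts = dict(zip(grp["sample"], grp["count"].astype(int)))
        events.append(
            CircEvent(
                circ_id=str(circ_id), gene_id=str(gene_id),
                exon_first=int(e0), exon_last=int(e1), counts=counts,
            )
        )
    return events
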