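"""Cassette-exon (skipped exon) splicing analytics.

PSI (percent spliced in) is estimated from junction counts with effective
length normalisation: psi = (I/lI) / (I/lI + S/lS), where I is the inclusion
junction count, S the skipping junction count, and lI/lS the effective
junction numbers of each isoform (by default 2 inclusion junctions vs 1
skipping junction). Differential inclusion between knockdown and control is
tested per event with a two-sided two-sample t on replicate-level PSIs and
BH-adjusted across events; the "core" set intersects two independent
knockdowns with same-sign significant changes, mirroring a two-hairpin
design.

Transcript-consequence calls (NMD / frame-preserving insertion / frameshift /
noncoding) follow the 50-nt premature-termination-codon heuristic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._stats import bh_adjust, fraction_pct, two_sample_t_p
from .genome_annotation import GenomeInterval

__all__ = [
    "SkippedExonEvent",
    "PsiEstimate",
    "CodingTranscript",
    "ConsequenceCall",
    "compute_psi",
    "test_event",
    "test_events_table",
    "core_event_set",
    "bound_fraction",
    "expressed_genes",
    "differential_expression",
    "predict_consequence",
    "read_junction_counts",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class SkippedExonEvent:
    """A cassette exon between two flanking exons, with junction counts.

    counts maps sample -> (inclusion I, skipping S).
    """

    event_id: str
    gene_id: str
    upstream: GenomeInterval
    cassette: GenomeInterval
    downstream: GenomeInterval
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    eff_len_inclusion: float = 2.0
    eff_len_skipping: float = 1.0

    def __post_init__(self) -> None:
        if not (self.upstream.end <= self.cassette.start
                and self.cassette.end <= self.downstream.start):
            raise ValueError(
                f"{self.event_id}: cassette must lie strictly between flanks"
            )


@dataclass(frozen=True)
class PsiEstimate:
    psi: float | None
    n_informative: int


def compute_psi(
    inclusion: int, skipping: int,
    eff_len_inclusion: float = 2.0, eff_len_skipping: float = 1.0,
) -> PsiEstimate:
    """Length-normalised PSI from one sample's junction counts.

    Undefined (psi=None) when no informative reads were observed.
    """
    if inclusion < 0 or skipping < 0:
        raise ValueError("junction counts must be non-negative")
    if eff_len_inclusion <= 0 or eff_len_skipping <= 0:
        raise ValueError("effective lengths must be positive")
    n = inclusion + skipping
    if n == 0:
        return PsiEstimate(psi=None, n_informative=0)
    inc = inclusion / eff_len_inclusion
    skp = skipping / eff_len_skipping
    return PsiEstimate(psi=inc / (inc + skp), n_informative=n)


def test_event(
    control_psis: Sequence[float], kd_psis: Sequence[float]
) -> tuple[float, float]:
    """(delta_psi, p_value) for one event: mean(kd) - mean(control), t-test."""
    delta = float(np.mean(kd_psis) - np.mean(control_psis))
    return delta, two_sample_t_p(control_psis, kd_psis)


def _replicate_psis(event: SkippedExonEvent, samples: Sequence[str]) -> list[float] | None:
    psis = []
    for s in samples:
        i, k = event.counts[s]
        est = compute_psi(i, k, event.eff_len_inclusion, event.eff_len_skipping)
        if est.psi is None:
            return None
        psis.append(est.psi)
    return psis


def test_events_table(
    events: Sequence[SkippedExonEvent],
    control_samples: Sequence[str],
    kd_samples: Sequence[str],
) -> pd.DataFrame:
    """Per-event differential inclusion table for one knockdown vs control.

    Events with an undefined PSI in any replicate are reported with
    status="dropped" and excluded from BH adjustment.
    """
    if len(control_samples) < 2 or len(kd_samples) < 2:
        raise ValueError("need >= 2 replicates per condition")
    rows = []
    for ev in events:
        ctrl = _replicate_psis(ev, control_samples)
        kd = _replicate_psis(ev, kd_samples)
        if ctrl is None or kd is None:
            rows.append((ev.event_id, ev.gene_id, np.nan, np.nan, "dropped"))
            continue
        delta, p = test_event(ctrl, kd)
        rows.append((ev.event_id, ev.gene_id, delta, p, "tested"))
    df = pd.DataFrame(
        rows, columns=["event_id", "gene_id", "delta_psi", "p_value", "status"]
    )
    tested = df["status"] == "tested"
    q = np.full(len(df), np.nan)
    q[tested.to_numpy()] = bh_adjust(df.loc[tested, "p_value"].to_numpy())
    df["q_value"] = q
    return df


def core_event_set(
    results_kd1: pd.DataFrame,
    results_kd2: pd.DataFrame,
    dpsi_min: float = 0.2,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Events significant in BOTH knockdowns with same-sign delta PSI.

    Significance per condition: q <= q_max and |delta_psi| > dpsi_min.
    Opposite-sign changes are excluded: they are not the same perturbation
    observed twice.
    """
    def _sig(df: pd.DataFrame) -> pd.DataFrame:
        keep = (df["status"] == "tested") & (df["q_value"] <= q_max) \
            & (df["delta_psi"].abs() > dpsi_min)
        return df.loc[keep, ["event_id", "gene_id", "delta_psi"]]

    a, b = _sig(results_kd1), _sig(results_kd2)
    m = a.merge(b, on=["event_id", "gene_id"], suffixes=("_kd1", "_kd2"))
    m = m[np.sign(m["delta_psi_kd1"]) == np.sign(m["delta_psi_kd2"])]
    return m.reset_index(drop=True)


def bound_fraction(
    event_gene_ids: Iterable[str], bound_gene_ids: set[str], decimals: int = 1
) -> tuple[int, int, float]:
    """(n_bound, n_total, percentage) of events whose gene is bound."""
    ids = list(event_gene_ids)
    if not ids:
        raise ValueError("empty event set")
    n_bound = sum(1 for g in ids if g in bound_gene_ids)
    return n_bound, len(ids), fraction_pct(n_bound, len(ids), decimals)


def expressed_genes(
    fpkm: pd.DataFrame, control_samples: Sequence[str], min_fpkm: float = 1.0
) -> set[str]:
    """Genes with FPKM > min_fpkm in every control replicate.

    `fpkm` is a gene x sample table indexed by gene id.
    """
    sub = fpkm[list(control_samples)]
    return set(sub.index[(sub > min_fpkm).all(axis=1)])


def differential_expression(
    fpkm: pd.DataFrame,
    control_samples: Sequence[str],
    kd1_samples: Sequence[str],
    kd2_samples: Sequence[str],
    fold_min: float = 2.0,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Per-gene differential expression vs control for two knockdowns.

    log2 fold change is the difference of group means of log2(FPKM + 1);
    Two-sample t on the same transformed values, BH-adjusted per knockdown. A gene
    passes iff |fold| >= fold_min and q < q_max in BOTH knockdowns.
    """
    log = np.log2(fpkm.astype(float) + 1.0)
    out = pd.DataFrame(index=fpkm.index)
    for label, samples in (("kd1", kd1_samples), ("kd2", kd2_samples)):
        ctrl = log[list(control_samples)].to_numpy()
        kd = log[list(samples)].to_numpy()
        lfc = kd.mean(axis=1) - ctrl.mean(axis=1)
        pvals = np.array(
            [two_sample_t_p(ctrl[i], kd[i]) for i in range(len(fpkm))]
        )
        out[f"log2fc_{label}"] = lfc
        out[f"p_{label}"] = pvals
        out[f"q_{label}"] = bh_adjust(pvals)
    lf_min = math.log2(fold_min)
    out["pass"] = (
        (out["log2fc_kd1"].abs() >= lf_min) & (out["q_kd1"] < q_max)
        & (out["log2fc_kd2"].abs() >= lf_min) & (out["q_kd2"] < q_max)
        & (np.sign(out["log2fc_kd1"]) == np.sign(out["log2fc_kd2"]))
    )
    return out


@dataclass(frozen=True)
class CodingTranscript:
    """Spliced transcript model for consequence prediction.

    exon_seqs: exon sequences in transcriptional order, WITHOUT the cassette.
    cds_start/cds_end: half-open CDS bounds in exclusion-isoform transcript
    coordinates (None for a noncoding transcript).
    """

    exon_seqs: tuple[str, ...]
    cds_start: int | None
    cds_end: int | None


@dataclass(frozen=True)
class ConsequenceCall:
    consequence: str  # NMD | frame_preserving_insertion | frameshift | noncoding
    ptc_position: int | None = None  # transcript coord of new stop, if NMD


def _first_stop(seq: str, start: int) -> int | None:
    """Transcript position of the first in-frame stop codon at/after start."""
    for i in range(start, len(seq) - 2, 3):
        if seq[i:i + 3] in STOP_CODONS:
            return i
    return None


def predict_consequence(
    transcript: CodingTranscript,
    cassette_seq: str,
    cassette_after_exon: int,
    nmd_rule_nt: int = 50,
) -> ConsequenceCall:
    """Predict the consequence of including a cassette exon in a transcript.

    The cassette is inserted after exon index `cassette_after_exon` (0-based,
    transcriptional order; it becomes a new internal exon). If translation of
    the inclusion isoform hits a stop codon earlier than the original stop
    and more than `nmd_rule_nt` nt upstream of the last exon-exon junction,
    the call is NMD. Otherwise a length-divisible-by-3 cassette is a
    frame-preserving insertion and anything else a frameshift. Events outside
    an annotated CDS (or in a noncoding transcript) are noncoding.
    """
    if transcript.cds_start is None or transcript.cds_end is None:
        return ConsequenceCall("noncoding")
    if not (0 <= cassette_after_exon < len(transcript.exon_seqs) - 1):
        raise ValueError("cassette must be internal (not before/after terminal exons)")
    insert_pos = sum(len(s) for s in transcript.exon_seqs[: cassette_after_exon + 1])
    if not (transcript.cds_start <= insert_pos < transcript.cds_end):
        return ConsequenceCall("noncoding")

    new_exons = (
        transcript.exon_seqs[: cassette_after_exon + 1]
        + (cassette_seq,)
        + transcript.exon_seqs[cassette_after_exon + 1:]
    )
    new_seq = "".join(new_exons)
    last_junction = len(new_seq) - len(new_exons[-1])
    old_seq = "".join(transcript.exon_seqs)
    old_stop = _first_stop(old_seq, transcript.cds_start)
    new_stop = _first_stop(new_seq, transcript.cds_start)
    # original stop position in inclusion-isoform coordinates
    old_stop_shifted = None if old_stop is None else (
        old_stop + len(cassette_seq) if old_stop >= insert_pos else old_stop
    )
    premature = new_stop is not None and (
        old_stop_shifted is None or new_stop < old_stop_shifted
    )
    if premature and (last_junction - (new_stop + 3)) > nmd_rule_nt:
        return ConsequenceCall("NMD", ptc_position=new_stop)
    if len(cassette_seq) % 3 == 0:
        return ConsequenceCall("frame_preserving_insertion")
    return ConsequenceCall("frameshift")


def read_junction_counts(path) -> pd.DataFrame:
    """Read a junction-count TSV (event_id, sample, inclusion, skipping)."""
    df = pd.read_csv(path, sep="\t")
    required = {"event_id", "sample", "inclusion", "skipping"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"junction count table missing columns: {sorted(missing)}")
    return df
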