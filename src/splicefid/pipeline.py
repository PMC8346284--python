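"""End-to-end orchestration: simulate -> peaks -> splicing -> circRNA ->
intron context -> G-quadruplex -> patient cohort, producing one JSON report.

The report is deterministic for a fixed configuration and seed: it carries
every threshold used, the seed, and per-stage summary numbers, but no
timestamps. All stage tables are also written as TSVs next to the report.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import circrna_analysis as circ_mod
from . import gquad as gq_mod
from . import intron_context as ctx_mod
from . import patient_survival as surv_mod
from . import peak_analysis as peaks_mod
from . import splicing_analysis as spl_mod
from .genome_annotation import GeneModel, GenomeInterval
from .synthetic_data import (
    CONTROL_SAMPLES,
    KD1_SAMPLES,
    KD2_SAMPLES,
    SimConfig,
    SimWorld,
    generate_cohort,
    generate_counts,
    generate_world,
    write_cohort,
    write_counts,
    write_world,
)

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """All pipeline thresholds plus the simulation configuration.

    Unknown keys in a config mapping are rejected so that typos cannot
    silently fall back to defaults.
    """

    seed: int = 0
    simulate: bool = True
    # input paths, used when simulate is false
    annotation: str | None = None
    genome: str | None = None
    peaks: str | None = None
    repeats: str | None = None
    junctions: str | None = None
    backsplice: str | None = None
    fpkm: str | None = None
    truth: str | None = None
    # peak thresholds
    peak_p_max: float = 0.05
    peak_min_fold: float = 1.5
    kmer_k: int = 6
    kmer_flank: int = 30
    kmer_shuffles: int = 10
    # splicing thresholds
    dpsi_min: float = 0.2
    q_max: float = 0.05
    min_fpkm: float = 1.0
    fold_min: float = 2.0
    junction_depth: int = 200
    # survival thresholds
    delta_inclusion: float = 0.1
    low_pct: float = 25.0
    high_pct: float = 75.0
    # G-quadruplex scan cap (genes scanned for the density contrast)
    gq_max_genes: int = 40
    sim: SimConfig = field(default_factory=SimConfig)

    @classmethod
    def from_mapping(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sim_data = data.pop("sim", {})
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        sim_known = {f.name for f in fields(SimConfig)}
        sim_unknown = set(sim_data) - sim_known
        if sim_unknown:
            raise ValueError(f"unknown sim configuration keys: {sorted(sim_unknown)}")
        cfg = cls(**data, sim=SimConfig(**sim_data)) if sim_data else cls(**data)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)

    def thresholds(self) -> dict:
        d = asdict(self)
        d["sim"] = asdict(self.sim)
        return d


def _se_events_from_tables(
    genes: dict[str, GeneModel],
    junctions: pd.DataFrame,
    cassette_index: dict[str, int],
    eff_len_inclusion: float,
    eff_len_skipping: float,
) -> list[spl_mod.SkippedExonEvent]:
    events = []
    for (event_id, gene_id), grp in junctions.groupby(
        ["event_id", "gene_id"], sort=True
    ):
        gene = genes[gene_id]
        ci = cassette_index[event_id]
        counts = {
            row["sample"]: (int(row["inclusion"]), int(row["skipping"]))
            for _, row in grp.iterrows()
        }
        events.append(spl_mod.SkippedExonEvent(
            event_id=event_id, gene_id=gene_id,
            upstream=gene.exons[ci - 1], cassette=gene.exons[ci],
            downstream=gene.exons[ci + 1], counts=counts,
            eff_len_inclusion=eff_len_inclusion,
            eff_len_skipping=eff_len_skipping,
        ))
    return events


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage and write the report bundle into `outdir`.

    Returns the report dict (also written as report.json).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "thresholds": config.thresholds(),
                    "stages": {}}

    # ---- simulate ---------------------------------------------------------
    if config.simulate:
        sim = SimConfig(**{**asdict(config.sim), "seed": config.seed})
        world = _stage("simulate")(generate_world)(sim)
        junctions, backsplice, fpkm = _stage("simulate")(generate_counts)(
            world, depth=config.junction_depth
        )
        write_world(world, out / "sim")
        write_counts(junctions, backsplice, fpkm, out / "sim")
        genes = world.genes
        genome = world.genome
        all_peaks = world.peaks
        repeats = world.repeats
        truth = world.truth
        cassette_index = {
            eid: rec["cassette_index"] for eid, rec in truth.events.items()
        }
    else:
        from .genome_annotation import GenomeSequence, read_annotation, read_bed

        for key in ("annotation", "genome", "peaks", "junctions",
                    "backsplice", "fpkm", "truth"):
            path = getattr(config, key)
            if path is None or not Path(path).exists():
                raise PipelineError(
                    f"stage 'load-inputs' failed: missing input '{key}'"
                )
        genes = _stage("load-inputs")(read_annotation)(config.annotation)
        genome = _stage("load-inputs")(GenomeSequence.from_fasta)(config.genome)
        all_peaks = _stage("load-inputs")(peaks_mod.read_peaks_bed)(config.peaks)
        repeats = [
            (iv, name) for iv, name, _ in
            (_stage("load-inputs")(read_bed)(config.repeats)
             if config.repeats else [])
        ]
        junctions = spl_mod.read_junction_counts(config.junctions)
        backsplice = circ_mod.read_backsplice_counts(config.backsplice)
        fpkm = pd.read_csv(config.fpkm, sep="\t", index_col=0)
        with open(config.truth) as fh:
            truth_data = json.load(fh)
        cassette_index = {
            eid: rec["cassette_index"]
            for eid, rec in truth_data["events"].items()
        }
    genes_by_id = {g.gene_id: g for g in genes}

    # ---- peaks ------------------------------------------------------------
    hc = _stage("peaks")(peaks_mod.filter_high_confidence)(
        all_peaks, config.peak_p_max, config.peak_min_fold
    )
    feature_dist = _stage("peaks")(peaks_mod.classify_peaks)(hc, genes)
    base_freqs = _stage("peaks")(peaks_mod.nucleotide_frequencies)(hc, genome)
    bound = _stage("peaks")(peaks_mod.bound_gene_ids)(genes, hc)
    expressed = spl_mod.expressed_genes(fpkm.drop(index="REG", errors="ignore"),
                                        list(CONTROL_SAMPLES), config.min_fpkm)
    kmers = _stage("peaks")(peaks_mod.kmer_enrichment)(
        hc, genome, k=config.kmer_k, flank=config.kmer_flank,
        n_shuffles=config.kmer_shuffles, seed=config.seed,
    )
    kmers.to_csv(out / "kmer_enrichment.tsv", sep="\t", index=False)
    try:
        # span mode: the planted bound-gene signal is long introns, which
        # only the genomic footprint reflects
        lengths = peaks_mod.gene_length_comparison(genes, bound, expressed,
                                                   length_mode="span")
    except ValueError:
        lengths = None
    report["stages"]["peaks"] = {
        "n_peaks_total": len(all_peaks),
        "n_high_confidence": len(hc),
        "feature_counts": feature_dist.counts,
        "feature_fractions": {k: round(v, 4)
                              for k, v in feature_dist.fractions.items()},
        "base_frequencies": {k: round(v, 4) for k, v in base_freqs.items()},
        "top_kmer": (kmers.iloc[0]["kmer"] if len(kmers) else None),
        "top_kmer_q": (float(kmers.iloc[0]["q_value"]) if len(kmers) else None),
        "n_bound_genes": len(bound),
        "n_expressed_genes": len(expressed),
        "gene_length_comparison": lengths,
    }

    # ---- splicing ---------------------------------------------------------
    events = _stage("splicing")(_se_events_from_tables)(
        genes_by_id, junctions, cassette_index,
        config.sim.eff_len_inclusion, config.sim.eff_len_skipping,
    )
    res_kd1 = _stage("splicing")(spl_mod.test_events_table)(
        events, list(CONTROL_SAMPLES), list(KD1_SAMPLES))
    res_kd2 = _stage("splicing")(spl_mod.test_events_table)(
        events, list(CONTROL_SAMPLES), list(KD2_SAMPLES))
    core = _stage("splicing")(spl_mod.core_event_set)(
        res_kd1, res_kd2, config.dpsi_min, config.q_max)
    res_kd1.to_csv(out / "splicing_kd1.tsv", sep="\t", index=False)
    res_kd2.to_csv(out / "splicing_kd2.tsv", sep="\t", index=False)
    core.to_csv(out / "core_events.tsv", sep="\t", index=False)
    splicing_report = {
        "n_events": len(events),
        "n_core": len(core),
        "n_core_increased_inclusion": int((core["delta_psi_kd1"] > 0).sum())
        if len(core) else 0,
    }
    if len(core):
        nb, nt, pct = spl_mod.bound_fraction(core["gene_id"], bound)
        splicing_report["core_bound"] = {"n_bound": nb, "n_total": nt, "pct": pct}
    de = _stage("splicing")(spl_mod.differential_expression)(
        fpkm, list(CONTROL_SAMPLES), list(KD1_SAMPLES), list(KD2_SAMPLES),
        config.fold_min, config.q_max,
    )
    de.to_csv(out / "differential_expression.tsv", sep="\t")
    bound_de = de.loc[[g for g in de.index if g in bound]]
    splicing_report["n_de_genes"] = int(de["pass"].sum())
    if len(bound_de):
        splicing_report["bound_de_pct"] = float(
            round(100.0 * bound_de["pass"].sum() / len(bound_de), 2)
        )
    report["stages"]["splicing"] = splicing_report

    # ---- circRNA ----------------------------------------------------------
    circs = _stage("circ")(circ_mod.circ_events_from_table)(backsplice)
    circ_res = _stage("circ")(circ_mod.test_circ)(
        circs, list(CONTROL_SAMPLES), list(KD1_SAMPLES), list(KD2_SAMPLES),
        config.fold_min, config.q_max,
    )
    circ_res.to_csv(out / "circ_results.tsv", sep="\t", index=False)
    sig = circ_res[circ_res["significant"]] if len(circ_res) else circ_res
    circ_report = {
        "n_circ": len(circ_res),
        "n_significant": len(sig),
        "n_up": int((sig["direction"] == "up").sum()) if len(sig) else 0,
        "n_down": int((sig["direction"] == "down").sum()) if len(sig) else 0,
        "n_multi_exonic": int((sig["structure"] == "multi_exonic").sum())
        if len(sig) else 0,
    }
    if len(sig):
        nb, nt, pct = circ_mod.circ_bound_fraction(sig["gene_id"], bound)
        circ_report["sig_bound"] = {"n_bound": nb, "n_total": nt, "pct": pct}
        n_coding = 0
        for _, row in sig.head(50).iterrows():
            gene = genes_by_id[row["gene_id"]]
            circ = next(c for c in circs if c.circ_id == row["circ_id"])
            circ_exons = gene.exons[circ.exon_first:circ.exon_last + 1]
            if gene.strand == "-":
                circ_exons = tuple(reversed(circ_exons))
            seq = "".join(genome.fetch(e) for e in circ_exons)
            _, coding = circ_mod.circ_orf_scan(seq)
            n_coding += int(coding)
        circ_report["n_coding_of_first_50_sig"] = n_coding
    report["stages"]["circ"] = circ_report

    # ---- intron context ---------------------------------------------------
    core_ids = set(core["event_id"]) if len(core) else set()
    flank_introns, other_introns = [], []
    density_rows = []
    for ev in events:
        if ev.event_id not in core_ids:
            continue
        gene = genes_by_id[ev.gene_id]
        ci = cassette_index[ev.event_id]
        labels = ctx_mod.label_introns(gene, ci, ci, "SE")
        for item in labels:
            dens = ctx_mod.binding_density(item.intron, hc)
            density_rows.append((ev.event_id, item.label, item.intron.length, dens))
            if item.label in ("upstream", "downstream"):
                flank_introns.append(item.intron)
            else:
                other_introns.append(item.intron)
    ctx_report: dict = {"n_core_events_contextualised": len(core_ids)}
    if flank_introns and other_introns:
        contrast = ctx_mod.intron_length_contrast(
            {"flanking": flank_introns, "other": other_introns}
        )
        dens_df = pd.DataFrame(
            density_rows, columns=["event_id", "label", "intron_length", "density"]
        )
        dens_df.to_csv(out / "binding_density.tsv", sep="\t", index=False)
        flank_kb = sum(iv.length for iv in flank_introns) / 1000.0
        other_kb = sum(iv.length for iv in other_introns) / 1000.0
        n_flank = sum(
            1 for iv in ctx_mod.merge_intervals([p.interval for p in hc])
            for fi in flank_introns if ctx_mod.interval_overlap(iv, fi) > 0
        )
        n_other = sum(
            1 for iv in ctx_mod.merge_intervals([p.interval for p in hc])
            for oi in other_introns if ctx_mod.interval_overlap(iv, oi) > 0
        )
        pooled_flank = n_flank / flank_kb if flank_kb else 0.0
        pooled_other = n_other / other_kb if other_kb else 0.0
        ctx_report.update({
            "intron_length_medians": contrast["medians"],
            "intron_length_p": {f"{a}|{b}": p
                                for (a, b), p in contrast["pairwise_p"].items()},
            "pooled_density_flanking_per_kb": round(pooled_flank, 3),
            "pooled_density_other_per_kb": round(pooled_other, 3),
            "density_ratio": round(pooled_flank / pooled_other, 3)
            if pooled_other else None,
        })
    rep = _stage("context")(ctx_mod.repeat_overlap)(hc, repeats)
    ctx_report["repeat_overlap_fraction"] = round(rep["fraction"], 4)
    ctx_report["repeat_per_class"] = rep["per_class"]
    # splice-site strength: train PWMs on all annotated sites, score core events
    donors, acceptors = [], []
    for g in genes:
        order = g.exons_transcript_order()
        for e in order[:-1]:
            try:
                donors.append(ctx_mod.donor_window(genome, e))
            except Exception:
                pass
        for e in order[1:]:
            try:
                acceptors.append(ctx_mod.acceptor_window(genome, e))
            except Exception:
                pass
    if len(donors) >= 10 and len(acceptors) >= 10 and core_ids:
        pwm_d = ctx_mod.build_pwm(donors, "donor")
        pwm_a = ctx_mod.build_pwm(acceptors, "acceptor")
        triples = []
        for ev in events:
            if ev.event_id in core_ids:
                gene = genes_by_id[ev.gene_id]
                order = gene.exons_transcript_order()
                ci = cassette_index[ev.event_id]
                gi = ci if gene.strand != "-" else len(order) - 1 - ci
                triples.append((order[gi - 1], order[gi], order[gi + 1]))
        strength = ctx_mod.site_strength_contrast(triples, genome, pwm_d, pwm_a)
        if len(strength):
            ctx_report["site_strength"] = {
                "mean_donor_diff": round(float(strength["donor_diff"].mean()), 3),
                "mean_acceptor_diff": round(
                    float(strength["acceptor_diff"].mean()), 3),
                "donor_p": round(strength.attrs["donor_diff_p"], 6),
                "acceptor_p": round(strength.attrs["acceptor_diff_p"], 6),
            }
    report["stages"]["context"] = ctx_report

    # ---- G-quadruplex density --------------------------------------------
    gq_flank, gq_other = [], []
    scanned = 0
    for ev in events:
        if ev.event_id not in core_ids or scanned >= config.gq_max_genes:
            continue
        scanned += 1
        gene = genes_by_id[ev.gene_id]
        ci = cassette_index[ev.event_id]
        for item in ctx_mod.label_introns(gene, ci, ci, "SE"):
            dens = gq_mod.gq_density_interval(genome, item.intron)
            (gq_flank if item.label in ("upstream", "downstream")
             else gq_other).append(dens)
    report["stages"]["gquad"] = {
        "n_genes_scanned": scanned,
        "mean_flanking_gq_per_kb": round(float(np.mean(gq_flank)), 3)
        if gq_flank else None,
        "mean_other_gq_per_kb": round(float(np.mean(gq_other)), 3)
        if gq_other else None,
    }

    # ---- patient cohort ---------------------------------------------------
    target_events = sorted(eid for eid in cassette_index if eid in core_ids) or None
    cohort_cfg = SimConfig(**{**asdict(config.sim), "seed": config.seed})
    survival, psi, circ_counts, cohort_truth = _stage("cohort")(generate_cohort)(
        cohort_cfg, target_event_ids=target_events,
    )
    write_cohort(survival, psi, circ_counts, out / "cohort")
    high = surv_mod.classify_inclusion(psi, config.delta_inclusion)
    scores = surv_mod.patient_event_score(high)
    strata = surv_mod.stratify_quartiles(scores, config.low_pct, config.high_pct)
    two = strata.groups.isin(["low", "high"])
    km = surv_mod.km_logrank(strata.groups[two], survival["time_days"][two],
                             survival["event"][two])
    cox_strata = surv_mod.cox_hr(strata.groups[two],
                                 survival["time_days"][two],
                                 survival["event"][two])
    latent = pd.Series(cohort_truth.patients)[survival.index]
    cox_latent = surv_mod.cox_hr(latent.astype(float), survival["time_days"],
                                 survival["event"])
    burden = surv_mod.circ_burden(circ_counts, survival["regulator_fpkm"],
                                  config.high_pct)
    r, p_corr = surv_mod.zscore_correlation(circ_counts,
                                            survival["regulator_fpkm"])
    cohort_report = {
        "n_patients": len(survival),
        "n_cohort_events": len(psi),
        "strata_sizes": {g: int((strata.groups == g).sum())
                         for g in ("low", "mid", "high")},
        "logrank_p_low_vs_high": round(km["logrank_p"], 6),
        "cox_strata": cox_strata,
        "cox_latent_hr": (round(cox_latent["terms"]["score"]["hr"], 3)
                          if cox_latent.get("converged") else None),
        "true_hr": cohort_truth.true_hr,
        "circ_burden_regulator_contrast": burden.get("regulator_contrast"),
        "zscore_correlation_r": round(r, 4),
        "zscore_correlation_p": float(f"{p_corr:.3e}"),
    }
    report["stages"]["cohort"] = cohort_report

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    return report
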