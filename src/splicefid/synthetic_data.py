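"""Self-consistent synthetic world with known ground truth.

The generator emulates the data the downstream analyses consume, without any
read-level simulation:

* a toy genome (one pseudo-chromosome by default) with multi-exon genes laid
  out end to end; a configurable fraction are "target" genes whose cassette
  exon is flanked by introns drawn from a long-intron distribution;
* GU-rich binding peaks (fixed width) planted in introns at a per-kb density
  that is higher in the flanking introns of target genes than elsewhere,
  mirroring a repressor enriched in long proximal introns;
* canonical G-quadruplex motifs planted at a higher per-kb rate in the same
  flanking introns;
* junction counts drawn binomially around true PSIs, with knockdown
  conditions shifting target-event PSI upward (loss of a splicing repressor
  increases inclusion);
* backsplice counts drawn negative-binomially with means anti-correlated
  with the regulator's expression;
* a patient cohort with Beta-distributed PSIs, negative-binomial circRNA
  counts anti-correlated with regulator expression, and exponential survival
  whose hazard depends on a latent inclusion score.

Everything is a deterministic function of the seed: the same configuration
yields byte-identical output files.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_annotation import GeneModel, GenomeInterval, GenomeSequence
from .peak_analysis import Peak

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimWorld",
    "generate_world",
    "generate_counts",
    "generate_cohort",
    "write_world",
    "write_counts",
    "write_cohort",
    "CONTROL_SAMPLES",
    "KD1_SAMPLES",
    "KD2_SAMPLES",
]

CONTROL_SAMPLES = ("SCR_1", "SCR_2", "SCR_3")
KD1_SAMPLES = ("KD1_1", "KD1_2", "KD1_3")
KD2_SAMPLES = ("KD2_1", "KD2_2", "KD2_3")

_G4_MOTIF = "GGGTGGGTGGGTGGG"


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; the defaults define the simulated study.

    Lengths are in bp, densities in sites per kb, times in days.
    """

    seed: int = 0
    n_genes: int = 120
    n_chromosomes: int = 1
    target_fraction: float = 0.5
    unbound_fraction: float = 0.3
    # gene structure
    min_exons: int = 4
    max_exons: int = 8
    exon_len_log_mean: float = float(np.log(150.0))
    exon_len_log_sd: float = 0.25
    intron_len_log_mean: float = float(np.log(1000.0))
    intron_len_log_sd: float = 0.5
    long_intron_log_mean: float = float(np.log(3000.0))
    long_intron_log_sd: float = 0.35
    min_intron_len: int = 200
    min_long_intron_len: int = 2000
    intergenic_gap: int = 500
    # binding peaks
    peak_width: int = 50
    flanking_peak_density: float = 5.0
    other_peak_density: float = 1.0
    gu_motif: str = "GGTGGT"
    # G-quadruplex planting
    flanking_gq_density: float = 0.5
    other_gq_density: float = 0.1
    # repeats
    repeat_density: float = 1.5
    repeat_length: int = 300
    # splicing truth
    base_psi: float = 0.5
    kd_psi_shift: float = 0.2
    eff_len_inclusion: float = 2.0
    eff_len_skipping: float = 1.0
    # expression / backsplicing
    regulator_control_fpkm: float = 50.0
    regulator_kd_fpkm: float = 10.0
    circ_base_mean: float = 30.0
    circ_nb_dispersion: float = 8.0
    circ_regulator_coef: float = 1.0
    de_fraction: float = 0.05
    de_fold: float = 4.0
    # patient cohort
    n_patients: int = 200
    psi_concentration: float = 20.0
    cohort_psi_low: float = 0.4
    cohort_psi_high: float = 0.6
    baseline_hazard: float = 1.0 / 1000.0
    log_hazard_beta: float = float(np.log(2.0))
    censoring_rate: float = 0.3
    cohort_circ_mean: float = 20.0
    cohort_circ_anticorr: float = 0.7

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_fraction <= 1.0:
            raise ValueError("target_fraction must be in [0, 1]")
        if not 0.0 <= self.base_psi <= 1.0:
            raise ValueError("base_psi must be in [0, 1]")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ValueError("censoring_rate must be in [0, 1]")
        for name in ("flanking_peak_density", "other_peak_density",
                     "flanking_gq_density", "other_gq_density", "repeat_density",
                     "baseline_hazard"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SimTruth:
    """Ground truth emitted alongside the world (the acceptance oracle)."""

    events: dict = field(default_factory=dict)     # event_id -> truth record
    introns: list = field(default_factory=list)    # per-intron planting records
    circs: dict = field(default_factory=dict)      # circ_id -> truth record
    patients: dict = field(default_factory=dict)   # patient_id -> latent score
    true_hr: float | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "events": self.events,
            "introns": self.introns,
            "circs": self.circs,
            "patients": self.patients,
            "true_hr": self.true_hr,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


@dataclass
class SimWorld:
    config: SimConfig
    genes: list[GeneModel]
    genome: GenomeSequence
    peaks: list[Peak]
    repeats: list[tuple[GenomeInterval, str]]
    truth: SimTruth

    @property
    def target_gene_ids(self) -> list[str]:
        return sorted(
            rec["gene_id"] for rec in self.truth.events.values() if rec["target"]
        )


def _lognormal_len(rng, log_mean: float, log_sd: float, minimum: int) -> int:
    return max(minimum, int(rng.lognormal(log_mean, log_sd)))


def _plant_peaks(
    rng, intron: GenomeInterval, density: float, width: int
) -> list[GenomeInterval]:
    """Plant non-overlapping fixed-width peaks at a per-kb density.

    The count is density * length_kb with the fractional part resolved by a
    Bernoulli draw (stochastic rounding), so planted density is unbiased even
    for introns much shorter than 1 kb. The intron is split into `count`
    equal bins with one peak placed uniformly inside each, which guarantees
    non-overlap whenever a bin is at least one peak wide.
    """
    if density <= 0:
        return []
    if intron.length < width:
        warnings.warn(
            f"intron of {intron.length} bp cannot hold a {width} bp site; "
            "no peaks planted"
        )
        return []
    expected = density * intron.length / 1000.0
    n = int(expected) + int(rng.random() < (expected - int(expected)))
    if n == 0:
        return []
    bin_w = intron.length // n if n else 0
    if n and bin_w < width:
        warnings.warn("peak density too high for peak width; truncating")
        n = max(1, intron.length // width)
        bin_w = intron.length // n
    out = []
    for i in range(n):
        lo = intron.start + i * bin_w
        offset = int(rng.integers(0, bin_w - width + 1))
        out.append(GenomeInterval(intron.chrom, lo + offset, lo + offset + width,
                                  intron.strand))
    return out


def _gu_rich(rng, length: int, motif: str) -> str:
    """GU-rich DNA (G/T with minor A/C) with the motif planted at the centre."""
    bases = rng.choice(list("GTAC"), size=length, p=[0.42, 0.42, 0.08, 0.08])
    seq = list(bases)
    mid = (length - len(motif)) // 2
    if 0 <= mid and mid + len(motif) <= length:
        seq[mid:mid + len(motif)] = list(motif)
    return "".join(seq)


def generate_world(config: SimConfig) -> SimWorld:
    """Build the genome, annotation, peaks, repeats and ground truth."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    genes: list[GeneModel] = []
    truth = SimTruth()
    peak_plan: list[tuple[GenomeInterval, bool]] = []  # (interval, in_flank)
    gq_plan: list[int] = []  # genome positions for planted G4 motifs
    chrom_seqs: dict[str, list[str]] = {}

    genes_per_chrom = int(np.ceil(config.n_genes / config.n_chromosomes))
    gene_idx = 0
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        cursor = config.intergenic_gap
        n_here = min(genes_per_chrom, config.n_genes - gene_idx)
        for _ in range(n_here):
            gid = f"G{gene_idx + 1:04d}"
            target = rng.random() < config.target_fraction
            # a slice of non-target genes carries no peaks at all, so the
            # world has a genuine bound vs non-bound gene contrast
            peak_free = (not target) and rng.random() < config.unbound_fraction
            n_exons = int(rng.integers(config.min_exons, config.max_exons + 1))
            cassette = n_exons // 2
            strand = "+" if rng.random() < 0.5 else "-"
            exon_lens = [
                _lognormal_len(rng, config.exon_len_log_mean,
                               config.exon_len_log_sd, 30)
                for _ in range(n_exons)
            ]
            intron_lens = []
            for k in range(n_exons - 1):
                flank = k in (cassette - 1, cassette)
                if target and flank:
                    intron_lens.append(_lognormal_len(
                        rng, config.long_intron_log_mean,
                        config.long_intron_log_sd, config.min_long_intron_len))
                else:
                    intron_lens.append(_lognormal_len(
                        rng, config.intron_len_log_mean,
                        config.intron_len_log_sd, config.min_intron_len))
            exons = []
            pos = cursor
            intron_records = []
            for k in range(n_exons):
                exons.append(GenomeInterval(chrom, pos, pos + exon_lens[k], strand))
                pos += exon_lens[k]
                if k < n_exons - 1:
                    intron = GenomeInterval(chrom, pos, pos + intron_lens[k], strand)
                    flank = k in (cassette - 1, cassette)
                    if peak_free:
                        density = 0.0
                    elif target and flank:
                        density = config.flanking_peak_density
                    else:
                        density = config.other_peak_density
                    planted = _plant_peaks(rng, intron, density, config.peak_width)
                    peak_plan.extend((iv, target and flank) for iv in planted)
                    gq_density = (config.flanking_gq_density if target and flank
                                  else config.other_gq_density)
                    n_gq = int(round(gq_density * intron.length / 1000.0))
                    gq_positions = []
                    for g in range(n_gq):
                        bin_w = intron.length // n_gq
                        lo = intron.start + g * bin_w
                        if bin_w > len(_G4_MOTIF):
                            off = int(rng.integers(0, bin_w - len(_G4_MOTIF)))
                            gq_positions.append(lo + off)
                    gq_plan.extend(gq_positions)
                    intron_records.append({
                        "gene_id": gid, "chrom": chrom, "intron_index": k,
                        "start": intron.start, "end": intron.end,
                        "strand": strand, "target": bool(target),
                        "peak_free": bool(peak_free),
                        "flanking": bool(target and flank),
                        "planted_peaks": len(planted),
                        "planted_gq": len(gq_positions),
                    })
                    pos += intron_lens[k]
            model = GeneModel(gene_id=gid, transcript_id=f"{gid}.t1",
                              exons=tuple(exons))
            genes.append(model)
            truth.introns.extend(intron_records)
            psi0 = config.base_psi
            psi_kd = min(1.0, psi0 + config.kd_psi_shift) if target else psi0
            truth.events[f"SE_{gid}"] = {
                "gene_id": gid, "cassette_index": cassette,
                "target": bool(target),
                "psi": {"control": psi0, "kd1": psi_kd, "kd2": psi_kd},
            }
            truth.circs[f"circ_{gid}"] = {
                "gene_id": gid,
                "exon_first": cassette - 1, "exon_last": cassette,
                "target": bool(target),
                "regulator_coef": config.circ_regulator_coef if target else 0.0,
            }
            cursor = pos + config.intergenic_gap
            gene_idx += 1
        chrom_seqs[chrom] = list(
            rng.choice(list("ACGT"), size=cursor + config.intergenic_gap)
        )

    # overwrite peak windows with GU-rich sequence on the TRANSCRIBED strand
    # (reverse-complemented into the forward strand for minus-strand genes),
    # then plant G4 motifs the same way
    from .genome_annotation import reverse_complement

    for iv, _ in peak_plan:
        gu = _gu_rich(rng, iv.length, config.gu_motif)
        if iv.strand == "-":
            gu = reverse_complement(gu)
        chrom_seqs[iv.chrom][iv.start:iv.end] = list(gu)
    # G4 positions were recorded in the same order as the intron records,
    # so a single cursor walks both in lockstep
    gq_cursor = 0
    for rec in truth.introns:
        n_gq = rec["planted_gq"]
        motif = (_G4_MOTIF if rec["strand"] != "-"
                 else reverse_complement(_G4_MOTIF))
        for _ in range(n_gq):
            pos = gq_plan[gq_cursor]
            gq_cursor += 1
            chrom_seqs[rec["chrom"]][pos:pos + len(motif)] = list(motif)

    genome = GenomeSequence({c: "".join(s) for c, s in chrom_seqs.items()})

    # repeats: fixed-length intervals at a per-kb density across each chromosome
    repeats: list[tuple[GenomeInterval, str]] = []
    classes = ("LINE", "SINE", "LTR", "DNA")
    for chrom in sorted(chrom_seqs):
        clen = genome.chrom_length(chrom)
        n_rep = int(round(config.repeat_density * clen / 1000.0))
        if n_rep:
            starts = np.sort(rng.integers(0, clen - config.repeat_length, size=n_rep))
            for s in starts:
                cls = classes[int(rng.integers(0, len(classes)))]
                repeats.append(
                    (GenomeInterval(chrom, int(s), int(s) + config.repeat_length, "."),
                     cls)
                )

    peaks = []
    for i, (iv, in_flank) in enumerate(
        sorted(peak_plan, key=lambda t: (t[0].chrom, t[0].start))
    ):
        # fold/p drawn so that all planted peaks pass the default
        # high-confidence gate, with a spread for threshold tests
        fold = float(1.5 + rng.random() * 4.0)
        p = float(rng.random() * 0.05)
        peaks.append(Peak(interval=iv, fold_enrichment=fold, p_value=p,
                          name=f"peak_{i + 1:05d}"))

    truth.true_hr = float(np.exp(config.log_hazard_beta))
    return SimWorld(config=config, genes=genes, genome=genome, peaks=peaks,
                    repeats=repeats, truth=truth)


def inclusion_read_probability(psi: float, l_inc: float, l_skip: float) -> float:
    """Probability that an informative junction read supports inclusion."""
    num = psi * l_inc
    den = psi * l_inc + (1.0 - psi) * l_skip
    return num / den if den > 0 else 0.0


def _nb_draw(rng, mean: float, dispersion: float) -> int:
    """NB draw parameterised by mean and size (dispersion)."""
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def generate_counts(
    world: SimWorld, depth: int = 200, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw junction, backsplice and expression tables for the world.

    Returns (junctions, backsplice, fpkm). Junction inclusion counts are
    Binomial(depth, p) with p the length-adjusted inclusion probability of
    the sample's true PSI. Backsplice counts are negative binomial with the
    target circRNAs' means scaled by (control regulator / sample regulator)
    raised to the configured coefficient - i.e. anti-correlated with the
    regulator. FPKM rows include the regulator gene "REG".
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    cfg = world.config
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed if seed is None else seed, 2])
    )
    sample_condition = {
        **{s: "control" for s in CONTROL_SAMPLES},
        **{s: "kd1" for s in KD1_SAMPLES},
        **{s: "kd2" for s in KD2_SAMPLES},
    }
    jrows = []
    for event_id in sorted(world.truth.events):
        rec = world.truth.events[event_id]
        for sample, cond in sample_condition.items():
            psi = rec["psi"][cond]
            p = inclusion_read_probability(psi, cfg.eff_len_inclusion,
                                           cfg.eff_len_skipping)
            inc = int(rng.binomial(depth, p))
            jrows.append((event_id, rec["gene_id"], sample, inc, depth - inc))
    junctions = pd.DataFrame(
        jrows, columns=["event_id", "gene_id", "sample", "inclusion", "skipping"]
    )

    regulator = {
        **{s: cfg.regulator_control_fpkm for s in CONTROL_SAMPLES},
        **{s: cfg.regulator_kd_fpkm for s in KD1_SAMPLES},
        **{s: cfg.regulator_kd_fpkm for s in KD2_SAMPLES},
    }
    brows = []
    for circ_id in sorted(world.truth.circs):
        rec = world.truth.circs[circ_id]
        for sample in sample_condition:
            scale = (cfg.regulator_control_fpkm / regulator[sample]) \
                ** rec["regulator_coef"]
            mean = cfg.circ_base_mean * scale
            brows.append((
                circ_id, rec["gene_id"], rec["exon_first"], rec["exon_last"],
                sample, _nb_draw(rng, mean, cfg.circ_nb_dispersion),
            ))
    backsplice = pd.DataFrame(
        brows,
        columns=["circ_id", "gene_id", "exon_first", "exon_last", "sample", "count"],
    )

    samples = list(sample_condition)
    gene_ids = sorted(g.gene_id for g in world.genes)
    base = rng.lognormal(np.log(10.0), 0.8, size=len(gene_ids))
    de_mask = rng.random(len(gene_ids)) < cfg.de_fraction
    mat = {}
    for sample in samples:
        noise = rng.lognormal(0.0, 0.1, size=len(gene_ids))
        vals = base * noise
        if sample_condition[sample] != "control":
            vals = np.where(de_mask, vals * cfg.de_fold, vals)
        mat[sample] = vals
    fpkm = pd.DataFrame(mat, index=gene_ids)
    fpkm.loc["REG"] = [regulator[s] * float(rng.lognormal(0.0, 0.05))
                       for s in samples]
    fpkm.index.name = "gene_id"
    return junctions, backsplice, fpkm


def generate_cohort(
    config: SimConfig, target_event_ids: list[str] | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate a patient cohort tied to the configured splicing truth.

    Returns (survival, psi, circ_counts, truth):
    survival has per-patient time_days, event flag and regulator expression;
    psi is event x patient Beta-distributed around latent-group means;
    circ_counts is circRNA x patient with means anti-correlated with the
    regulator. The latent per-patient inclusion indicator drives an
    exponential hazard h0 * exp(beta * latent); truth records the latent
    values and the true hazard ratio exp(beta).
    """
    if config.n_patients < 20:
        raise ValueError("need at least 20 patients")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, 3])
    )
    n = config.n_patients
    patients = [f"P{i + 1:04d}" for i in range(n)]
    latent = rng.integers(0, 2, size=n)

    n_events = len(target_event_ids) if target_event_ids else 30
    event_ids = target_event_ids or [f"SE_{i + 1:03d}" for i in range(n_events)]
    k = config.psi_concentration
    psi_rows = {}
    for eid in event_ids:
        means = np.where(latent == 1, config.cohort_psi_high, config.cohort_psi_low)
        psi_rows[eid] = rng.beta(means * k, (1.0 - means) * k)
    psi = pd.DataFrame(psi_rows, index=patients).T

    rate = config.baseline_hazard * np.exp(config.log_hazard_beta * latent)
    times = rng.exponential(1.0 / rate)
    censored = rng.random(n) < config.censoring_rate
    obs_event = np.where(censored, 0, 1)
    obs_time = np.where(censored, times * rng.random(n), times)
    obs_time = np.maximum(obs_time, 1.0)

    log_reg = rng.normal(np.log(10.0), 0.5, size=n)
    regulator = np.exp(log_reg)
    zreg = (log_reg - log_reg.mean()) / log_reg.std()
    n_circ = 25
    circ_rows = {}
    for i in range(n_circ):
        mean = config.cohort_circ_mean * np.exp(-config.cohort_circ_anticorr * zreg)
        circ_rows[f"circ_{i + 1:03d}"] = np.array(
            [_nb_draw(rng, m, 8.0) for m in mean]
        )
    circ_counts = pd.DataFrame(circ_rows, index=patients).T

    survival = pd.DataFrame({
        "patient_id": patients,
        "time_days": np.round(obs_time, 1),
        "event": obs_event,
        "regulator_fpkm": np.round(regulator, 3),
    }).set_index("patient_id")

    truth = SimTruth(
        patients={p: int(z) for p, z in zip(patients, latent)},
        true_hr=float(np.exp(config.log_hazard_beta)),
    )
    return survival, psi, circ_counts, truth


def _write_gtf(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            for e in g.exons:
                attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.transcript_id}";'
                fh.write(
                    f"{e.chrom}\tsplicefid_sim\texon\t{e.start + 1}\t{e.end}"
                    f"\t.\t{e.strand}\t.\t{attrs}\n"
                )


def write_world(world: SimWorld, outdir: str | Path) -> dict[str, Path]:
    """Write annotation.gtf, genome.fa, peaks.bed, repeats.bed, truth.json."""
    from .peak_analysis import write_peaks_bed

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": out / "annotation.gtf",
        "genome": out / "genome.fa",
        "peaks": out / "peaks.bed",
        "repeats": out / "repeats.bed",
        "truth": out / "truth.json",
    }
    _write_gtf(world.genes, paths["annotation"])
    world.genome.to_fasta(paths["genome"])
    write_peaks_bed(paths["peaks"], world.peaks)
    with open(paths["repeats"], "w") as fh:
        for iv, cls in sorted(world.repeats, key=lambda t: (t[0].chrom, t[0].start)):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{cls}\t0\t{iv.strand}\n")
    world.truth.to_json(paths["truth"])
    return paths


def write_counts(
    junctions: pd.DataFrame, backsplice: pd.DataFrame, fpkm: pd.DataFrame,
    outdir: str | Path,
) -> dict[str, Path]:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "junctions": out / "junction_counts.tsv",
        "backsplice": out / "backsplice_counts.tsv",
        "fpkm": out / "expression_fpkm.tsv",
    }
    junctions.to_csv(paths["junctions"], sep="\t", index=False)
    backsplice.to_csv(paths["backsplice"], sep="\t", index=False)
    fpkm.to_csv(paths["fpkm"], sep="\t")
    return paths


def write_cohort(
    survival: pd.DataFrame, psi: pd.DataFrame, circ_counts: pd.DataFrame,
    outdir: str | Path,
) -> dict[str, Path]:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "survival": out / "cohort_survival.tsv",
        "psi": out / "cohort_psi.tsv",
        "circ": out / "cohort_circ_counts.tsv",
    }
    survival.to_csv(paths["survival"], sep="\t")
    psi.to_csv(paths["psi"], sep="\t")
    circ_counts.to_csv(paths["circ"], sep="\t")
    return paths
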