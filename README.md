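# splicefid

Splicing-fidelity analytics around a repressive RNA-binding protein.

Loss of certain heterogeneous nuclear ribonucleoproteins (hnRNPs) in cancer
cells causes two coupled mis-splicing phenotypes: increased inclusion of
cassette exons in linear transcripts, and increased backsplicing that
produces circular RNAs (circRNAs). Both event classes tend to occur in genes
with long introns flanking the affected exons, where the regulator binds
GU-rich elements at high density. `splicefid` implements the downstream
statistics of such a study as a reusable, fully tested pipeline for

* **molecular biologists / computational biologists** quantifying exon
  inclusion and backsplicing from junction-count tables,
* **bioinformaticians** characterising binding-peak context (genomic
  features, nucleotide composition, k-mer motif enrichment, intron lengths,
  per-kb binding-site and G-quadruplex density, repeat overlap, splice-site
  strength), and
* **translational researchers** scoring patients by inclusion-event or
  circRNA burden and stratifying survival.

A seeded synthetic-data generator produces a self-consistent toy genome,
annotation, peaks, count tables and patient cohort with known ground truth,
so the entire pipeline runs and is testable without any downloads.

## The statistics at the core

**Percent spliced in (PSI).** For a cassette exon with inclusion-junction
count $I$, skipping-junction count $S$ and effective junction numbers
$l_I = 2$, $l_S = 1$:

$$\hat\Psi = \frac{I/l_I}{I/l_I + S/l_S}$$

Differential inclusion between knockdown and control is tested per event on
replicate-level PSIs (two-sided two-sample t, pooled variance,
Benjamini–Hochberg across events). An event enters the **core set** when it
is significant with the same sign in *both* independent knockdowns
(defaults: $q \le 0.05$, $|\Delta\Psi| > 0.2$).

**Backsplicing.** CircRNA counts are tested on $\log_2(\text{count}+1)$ per
knockdown; a circRNA is called when $|fold| \ge 2$ and $q < 0.05$ in both
knockdowns with concordant direction.

**Intron context.** Binding-site density is the number of *merged,
non-overlapping* sites overlapping an intron divided by intron length in kb;
G-quadruplex density counts greedily selected non-overlapping
$G_xN_{y_1}G_xN_{y_2}G_xN_{y_3}G_x$ candidates per kb, scored with
$20(x-2) + (12 - (y_{max}-y_{min})) + (12 - \lceil\bar y\rceil)$.

**Patient scoring.** An event is "high inclusion" in a patient when its PSI
is at least the event's population median + 0.1; a circRNA is "highly
expressed" when its count reaches the cohort 75th percentile (and is
nonzero). Per-patient burdens are stratified at score quartiles
(low $\le$ P25 < mid $\le$ P75 < high) and compared with Kaplan–Meier
curves, log-rank tests and Cox proportional-hazards ratios (reference =
high group).

## Worked example

```bash
splicefid run --seed 4 --out results/demo
```

simulates a 120-gene world (half the genes are regulator targets whose
cassette exon gains +0.2 PSI under knockdown and whose flanking introns are
long, GU-peak-rich and G4-rich), then runs every stage. From
`results/demo/report.json`:

* peaks: 2058 high-confidence sites, 100% intronic; base composition
  G = 0.45, U = 0.41 (GU-rich); top enriched 6-mer `GGTGGT` (q ≈ 0) — the
  planted binding motif is recovered against a dinucleotide-shuffled
  background.
* splicing: 21 core events significant in both knockdowns, all with
  increased inclusion, 21/21 (100.0%) in bound genes.
* circRNAs: 32 of 120 significantly changed, all up-regulated under
  knockdown, all multi-exonic and bound.
* context: flanking-intron median 3126 bp vs 1002 bp for other introns;
  merged binding-site density ratio flanking/other = 5.01 (5× planted);
  40.8% of peaks overlap a repeat element.
* G-quadruplexes: 8.8 candidate sites/kb in flanking introns vs 3.9
  elsewhere.
* cohort (n = 200): high- vs low-inclusion-burden strata separate
  disease-free survival (log-rank p = 0.00097); Cox HR on the latent
  inclusion score 2.52 against a true simulated HR of 2.0; circRNA burden
  anti-correlates with regulator expression (pooled z-score r = −0.62).

Every number above is read back from the report the command writes.

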