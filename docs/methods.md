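# Methods

This note documents the models, rules and numerical choices behind
`splicefid`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the analysis logic was genuinely open.

## Coordinates and annotation

All intervals are 0-based half-open (BED convention); GTF input (1-based
inclusive) is converted on read. Strand-aware sequence fetches return the
reverse complement on the minus strand, so every sequence statistic
(nucleotide composition, k-mer enrichment, splice-site windows, G-quadruplex
scans) operates on the transcribed strand. Overlapping or book-ended
intervals merge into one: a "non-overlapping binding site" count must not
double-count abutting peaks. One transcript is kept per gene for gene-level
statistics (the longest by exonic length, ties broken on transcript id).
"Gene length" defaults to the sum of exon lengths (mature transcript
length); the genomic span is available via `gene_length(model, "span")` and
is what the pipeline reports, because the bound-gene signal the generator
plants is long introns, which exonic length cannot see.

## PSI estimation and differential inclusion

PSI is estimated per sample as `(I/lI) / (I/lI + S/lS)` with effective
lengths `lI = 2` (two inclusion junctions) and `lS = 1` (one skipping
junction), both configurable. A sample with `I + S = 0` has undefined PSI
and drops its event from testing, with the reason recorded in the results
table.

Differential inclusion is a two-sided **two-sample t-test with pooled
variance** on replicate-level PSIs, BH-adjusted across events. Pooled
variance rather than the Welch correction is a deliberate choice: replicate
groups are sequenced at matched depth, so their PSI variances are equal by
design, and at n = 3 per group the pooled test holds the nominal 5% level
(empirical size ≈ 0.049 under the binomial null at depth 200) while the
Welch correction is markedly conservative there (≈ 0.035). The same test
backs the expression (on log2(FPKM+1)) and backsplice-count (on
log2(count+1)) comparisons.

The core event set intersects two independent knockdowns and requires the
same sign of ΔPSI in both: opposite-sign changes are not one perturbation
observed twice. Gates default to q ≤ 0.05 and |ΔPSI| > 0.2; the more lenient
0.1 gate that appears in some analysis conventions is available via
`dpsi_min` and is deliberately not silently resolved.

## Transcript consequences

Cassette inclusion is classified with the standard 50-nt
premature-termination-codon heuristic: translate the inclusion isoform from
the annotated CDS start; if the first stop codon is earlier than the
original stop and ends more than 50 nt upstream of the last exon–exon
junction, the call is NMD. Otherwise a cassette whose length is divisible
by 3 is a frame-preserving insertion and anything else a frameshift; events
outside an annotated CDS are noncoding. This is a transparent rule set, not
a reimplementation of any isoform-function predictor.

## Peak analytics

High-confidence peaks require p ≤ 0.05 and fold enrichment ≥ 1.5 by default
(a stricter fold > 2 convention exists in the field; both are exposed).
Feature classification assigns each peak the category with the largest
overlap in bp (ties: exonic > intronic > intergenic), measured against the
merged exons and introns of all supplied genes. A gene is "bound" when its
span overlaps ≥ 1 high-confidence peak.

K-mer enrichment compares observed k-mer counts in peak ± 30 bp sequences
with the expectation from dinucleotide-preserving (Altschul–Erickson)
shuffles of the same sequences; preserving dinucleotide counts keeps the
GU content of the background identical, so enrichment reflects motif
arrangement rather than base bias. One-sided binomial p-values (background
probability floored at half a count to stay finite) are BH-adjusted.
Default 50 shuffles (10 in the pipeline for speed).

## Intron context

Flanking proximal introns are the introns immediately upstream (−1) and
downstream (+1) of the cassette exon or circularised exon span, in
transcriptional orientation; introns inside a circularised span are
"internal". Intron-length contrasts deduplicate introns by coordinates
("unique intron lengths") and use two-sided Wilcoxon rank-sum tests;
degenerate singleton-vs-singleton contrasts report p = 1.

Binding density = merged non-overlapping sites overlapping the intron by
≥ 1 bp, divided by intron length in kb. Both per-event densities and pooled
(total sites / total kb) summaries are emitted, since either convention is
defensible.

Splice-site strength uses log2-odds position weight matrices against a
uniform background with 0.5 pseudocounts: donor windows are 9-mers (3 exonic
+ 6 intronic nt), acceptor windows 23-mers (20 intronic + 3 exonic nt) —
field-standard windows; no maximum-entropy model is attempted. Event sites
are compared pairwise with the original flanking sites they compete with
(Wilcoxon signed-rank on paired differences; all-zero differences give
p = 1).

## G-quadruplex scan

Candidates match `G{x} N{y1} G{x} N{y2} G{x} N{y3} G{x}` with x ≥ 2,
per-loop length ≤ 12 (zero allowed), total length ≤ 30. The integer G-score

    20·(x − 2) + (12 − (y_max − y_min)) + (12 − ceil(mean(y)))

rises with tetrad count and falls with loop length and unevenness. It is
this package's explicit codification of that qualitative behaviour;
replicating any external tool's exact scores is not claimed, and only
relative per-kb densities are used downstream. Density counts a greedy
best-score-first non-overlapping selection (deterministic tie-breaks:
score desc, start asc, length desc), so one G-rich locus counts once; greedy
selection does not guarantee a maximum-weight independent set, which is
irrelevant for counting loci. The scanner is verified against brute-force
pattern enumeration on random sequences.

## Patient survival

"High inclusion": PSI ≥ event population median + 0.1; medians may be
supplied externally to score new patients against an existing cohort.
Missing PSIs are excluded from the median and count as low — conservative
toward the high stratum. "Highly expressed" circRNA: count at or above the
cohort 75th percentile *and nonzero* (a circRNA that is undetected in a
patient is never "highly expressed", which also keeps an all-zero matrix at
zero burden). Quantiles use linear interpolation (numpy default, type 7);
ties at a threshold go to the lower stratum (low ≤ P25 < mid ≤ P75 < high),
so heavily tied scores can leave the high group empty — reported with a
warning, not an error.

Both log-rank and Cox p-values are reported for group comparisons because
both conventions appear in practice; categorical covariates are coded
against the *high* group as reference, so reported HRs describe low/mid
risk relative to high. Non-convergence of the Cox fit is surfaced in the
result, never silently dropped. The pooled z-score correlation standardises
each circRNA row and the regulator vector across samples and computes one
Pearson r over all (circRNA, sample) pairs; zero-variance rows are dropped
with a warning.

## Synthetic-data generator

The generator is the package's study-conditions definition, not a tuning
dial. Defaults: 120 genes on one pseudo-chromosome, 4–8 exons per gene
(exon lengths log-normal, median ≈ 150 bp), intron lengths log-normal with
median ≈ 1 kb (minimum 200 bp); half the genes are regulator targets whose
two cassette-flanking introns come from a long-intron distribution (median
≈ 3 kb, minimum 2 kb). Binding peaks are 50-bp windows planted at 5/kb in
target flanking introns and 1/kb elsewhere (stochastic rounding keeps
planted density unbiased in short introns; 30% of non-target genes carry no
peaks at all so that bound vs non-bound contrasts exist). Peak windows are
GU-rich (G/T ≈ 0.42/0.42) with the `GGTGGT` motif at the centre, written on
the transcribed strand. Canonical G4 motifs (`GGGTGGGTGGGTGGG`) are planted
at 0.5/kb in flanking vs 0.1/kb in other introns, also strand-aware.
Repeats (LINE/SINE/LTR/DNA) are 300-bp intervals at 1.5/kb, giving ~45%
genomic coverage so that roughly 40–50% of peaks overlap a repeat.

Counts: junction reads are Binomial(depth, p) with p the length-adjusted
inclusion probability of the sample's true PSI (control PSI 0.5; knockdown
+0.2 on target events — knockdown of a repressor increases inclusion);
backsplice counts are negative binomial (mean 30, size 8) with target-circ
means scaled by (control regulator / sample regulator)^1, i.e.
anti-correlated with the regulator (control FPKM 50, knockdown 10). Five
percent of genes carry a planted 4-fold expression change.

Cohort: 200 patients; a latent binary inclusion indicator drives
(1) Beta-distributed PSIs (means 0.6 vs 0.4, concentration 20) and
(2) exponential survival with hazard h0·exp(β·latent), h0 = 1/1000 days,
β = ln 2 (true HR 2.0); censoring is Bernoulli (rate 0.3) with the censored
time drawn uniformly below the event time. Patient circRNA counts are
negative binomial with means scaled by exp(−0.7·z) of the patient's
log-regulator expression.

Everything is a deterministic function of the seed (numpy `SeedSequence`
spawning per stage); identical configurations yield byte-identical files
and reports.

**What the generator does not emulate:** read-level sequencing error,
mappability, isoform complexity beyond one transcript per gene, real
splice-site sequence composition (PWMs trained on the toy genome are nearly
uniform), inter-chromosomal structure, covariate-driven censoring, and any
real-genome sequence. Passing tests therefore demonstrate the correctness
and calibration of the statistics under the stated generative model, not
performance on real sequencing data.

## Problem sizes and runtime choices

The default test and acceptance workloads use 100–120-gene worlds,
500-event simulations, 200-patient cohorts and 20-seed Cox replications —
sizes chosen so the full suite runs in seconds while every estimator's
recovery band is still tight. The pipeline caps the G-quadruplex contrast
at 40 genes (`gq_max_genes`) because GU-rich peak regions spawn many
overlapping motif candidates and the contrast stabilises well before that
cap. File-based (non-simulated) pipeline runs require the generator's
`truth.json` sidecar for event-to-cassette-exon definitions, since junction
count tables carry no coordinates.

## Known limitations

* The per-event t-test ignores junction-count uncertainty within a
  replicate (no hierarchical/binomial layer); at very low depth its power
  is limited, which the type-I/recovery suites quantify.
* The ORF scan requires AUG starts and standard stops, caps rolling-circle
  ORFs at three passes, and ignores internal ribosome entry or m6A-driven
  initiation.
* PWM splice-site scores are position-independent log-odds; no dependency
  structure between positions is modelled.
* Cox models are univariate; no clinical covariates or competing risks.
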