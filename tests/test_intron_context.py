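import numpy as np
import pytest

from splicefid.genome_annotation import (
    GeneModel,
    GenomeInterval,
    GenomeSequence,
    merge_intervals,
)
from splicefid.intron_context import (
    acceptor_window,
    binding_density,
    build_pwm,
    donor_window,
    intron_length_contrast,
    label_introns,
    repeat_overlap,
    site_strength_contrast,
)
from splicefid.peak_analysis import Peak


def _gene(n_exons, strand="+", exon_len=100, intron_len=200, chrom="chr1"):
    exons = []
    pos = 100
    for _ in range(n_exons):
        exons.append(GenomeInterval(chrom, pos, pos + exon_len, strand))
        pos += exon_len + intron_len
    return GeneModel("g1", "t1", tuple(exons))


def _peak(start, end, chrom="chr1"):
    return Peak(GenomeInterval(chrom, start, end), 2.0, 0.01)


class TestLabelIntrons:
    def test_plus_strand_cassette_flanks(self):
        gene = _gene(4, "+")
        labels = [c.label for c in label_introns(gene, 1, 1, "SE")]
        assert labels == ["upstream", "downstream", "other"]

    def test_minus_strand_mirrors_labels(self):
        gene = _gene(4, "-")
        labels = [c.label for c in label_introns(gene, 2, 2, "SE")]
        assert labels == ["other", "downstream", "upstream"]

    def test_circ_span_has_internal_introns(self):
        gene = _gene(5, "+")
        labels = [c.label for c in label_introns(gene, 1, 2, "circ")]
        assert labels == ["upstream", "internal", "downstream", "other"]

    def test_terminal_exon_event_lacks_a_flank(self):
        gene = _gene(3, "+")
        labels = [c.label for c in label_introns(gene, 0, 0, "SE")]
        assert "upstream" not in labels

    def test_labels_partition_all_introns(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(3, 8))
            strand = "+" if rng.random() < 0.5 else "-"
            gene = _gene(n, strand)
            first = int(rng.integers(1, n - 1))
            out = label_introns(gene, first, first, "SE")
            assert len(out) == n - 1
            assert all(c.label in {"upstream", "downstream", "internal", "other"}
                       for c in out)


class TestIntronLengthContrast:
    def _intervals(self, lengths):
        out = []
        pos = 0
        for L in lengths:
            out.append(GenomeInterval("chr1", pos, pos + L))
            pos += L + 10
        return out

    def test_identical_length_multisets_indistinguishable(self):
        a = self._intervals([100, 200, 300])
        b = [GenomeInterval("chr2", iv.start, iv.end) for iv in a]
        res = intron_length_contrast({"a": a, "b": b})
        assert res["pairwise_p"][("a", "b")] >= 0.99

    def test_planted_fivefold_difference_detected(self):
        rng = np.random.default_rng(1)
        flank = self._intervals((rng.lognormal(np.log(5000), 0.2, 100)).astype(int))
        other = [GenomeInterval("chr2", iv.start, iv.end) for iv in
                 self._intervals((rng.lognormal(np.log(1000), 0.2, 100)).astype(int))]
        res = intron_length_contrast({"flank": flank, "other": other})
        ratio = res["medians"]["flank"] / res["medians"]["other"]
        assert 4.0 <= ratio <= 6.0
        assert res["pairwise_p"][("flank", "other")] < 1e-4

    def test_singleton_groups_return_unit_p(self):
        res = intron_length_contrast({
            "a": [GenomeInterval("chr1", 0, 100)],
            "b": [GenomeInterval("chr1", 0, 500)],
        })
        assert res["pairwise_p"][("a", "b")] == 1.0

    def test_duplicate_introns_collapse(self):
        iv = GenomeInterval("chr1", 0, 100)
        res = intron_length_contrast({"a": [iv, iv, iv], "b": [iv, iv]})
        assert res["n"] == {"a": 1, "b": 1}

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            intron_length_contrast({"a": [GenomeInterval("chr1", 0, 10)], "b": []})


class TestBindingDensity:
    def test_no_peaks_is_zero(self):
        assert binding_density(GenomeInterval("chr1", 0, 1500), []) == 0.0

    def test_three_disjoint_sites_per_1500bp(self):
        intron = GenomeInterval("chr1", 0, 1500)
        peaks = [_peak(0, 50), _peak(500, 550), _peak(1000, 1050)]
        assert binding_density(intron, peaks) == pytest.approx(2.0)

    def test_overlapping_sites_merge_before_counting(self):
        intron = GenomeInterval("chr1", 0, 2000)
        peaks = [_peak(100, 160), _peak(140, 200), _peak(1000, 1050)]
        assert binding_density(intron, peaks) == pytest.approx(1.0)

    def test_matches_merge_free_sweep_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            intron = GenomeInterval("chr1", 200, 200 + int(rng.integers(500, 3000)))
            peaks = [_peak(int(s), int(s) + int(rng.integers(10, 80)))
                     for s in rng.integers(0, 3500, size=int(rng.integers(1, 100)))]
            # sweep-line oracle: count maximal covered runs touching the intron
            events = sorted((p.interval.start, p.interval.end) for p in peaks)
            runs = []
            cur_s, cur_e = events[0]
            for s, e in events[1:]:
                if s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    runs.append((cur_s, cur_e))
                    cur_s, cur_e = s, e
            runs.append((cur_s, cur_e))
            n = sum(1 for s, e in runs
                    if min(e, intron.end) > max(s, intron.start))
            expected = n / (intron.length / 1000)
            assert binding_density(intron, peaks) == pytest.approx(expected)


class TestRepeatOverlap:
    def test_no_repeats_gives_zero_fraction(self):
        res = repeat_overlap([_peak(0, 50)], [])
        assert res["fraction"] == 0.0

    def test_all_peaks_in_one_class(self):
        peaks = [_peak(i * 100, i * 100 + 50) for i in range(5)]
        repeats = [(GenomeInterval("chr1", 0, 1000), "LINE")]
        res = repeat_overlap(peaks, repeats)
        assert res["fraction"] == 1.0
        assert res["per_class"] == {"LINE": 5}

    def test_counts_each_peak_once_overall(self):
        peaks = [_peak(i * 100, i * 100 + 50) for i in range(10)]
        repeats = [
            (GenomeInterval("chr1", 0, 380), "LINE"),
            (GenomeInterval("chr1", 0, 120), "SINE"),
        ]
        res = repeat_overlap(peaks, repeats)
        assert res["n_overlapping"] == 4
        assert res["fraction"] == pytest.approx(0.4)
        assert res["per_class"]["LINE"] == 4 and res["per_class"]["SINE"] == 2


class TestSpliceSitePwm:
    def test_training_consensus_scores_maximal(self):
        rng = np.random.default_rng(3)
        consensus = "CAGGTAAGT"
        pwm = build_pwm([consensus] * 20, "donor")
        others = ["".join(rng.choice(list("ACGT"), size=9)) for _ in range(50)]
        assert all(pwm.score(consensus) >= pwm.score(s) for s in others)

    def test_uniform_training_scores_near_zero(self):
        rng = np.random.default_rng(4)
        seqs = ["".join(rng.choice(list("ACGT"), size=9)) for _ in range(5000)]
        pwm = build_pwm(seqs, "donor")
        assert np.abs(pwm.matrix).max() < 0.1

    def test_empty_or_short_training_rejected(self):
        with pytest.raises(ValueError):
            build_pwm([], "donor")
        with pytest.raises(ValueError):
            build_pwm(["CAGGTAAGT"] * 5, "donor")

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_pwm(["CAGGT"] * 10, "donor")


class TestSiteStrengthContrast:
    def _world(self):
        # 4 exons of 100 bp separated by 200 bp introns on a 2 kb contig
        gene = _gene(4, "+")
        rng = np.random.default_rng(5)
        seq = rng.choice(list("ACGT"), size=2000)
        genome_str = "".join(seq)
        return gene, GenomeSequence({"chr1": genome_str})

    def test_identical_sites_give_zero_differences(self):
        gene, genome = self._world()
        donors = [donor_window(genome, e) for e in gene.exons[:-1]]
        acceptors = [acceptor_window(genome, e) for e in gene.exons[1:]]
        pwm_d = build_pwm(donors * 4, "donor")
        pwm_a = build_pwm(acceptors * 4, "acceptor")
        # event exon identical to the upstream/downstream originals
        events = [(gene.exons[1], gene.exons[1], gene.exons[1])]
        df = site_strength_contrast(events, genome, pwm_d, pwm_a)
        assert df["donor_diff"].iloc[0] == 0.0
        assert df["acceptor_diff"].iloc[0] == 0.0
        assert df.attrs["donor_diff_p"] == 1.0

    def test_weaker_event_sites_score_below_originals(self):
        consensus_d = "CAGGTAAGT"
        # genome: exon0 donor at consensus, exon1 donor one mismatch off
        gene = _gene(3, "+")
        base = list("A" * 1200)
        for exon, site in ((gene.exons[0], consensus_d),
                           (gene.exons[1], "CAGCTAAGT")):  # G->C mismatch
            start = exon.end - 3
            base[start:start + 9] = list(site)
        genome = GenomeSequence({"chr1": "".join(base)})
        pwm_d = build_pwm([consensus_d] * 20, "donor")
        pwm_a = build_pwm([acceptor_window(genome, gene.exons[2])] * 20,
                          "acceptor")
        df = site_strength_contrast(
            [(gene.exons[0], gene.exons[1], gene.exons[2])],
            genome, pwm_d, pwm_a,
        )
        assert df["donor_diff"].iloc[0] < 0

    def test_empty_event_list_rejected(self):
        gene, genome = self._world()
        pwm_d = build_pwm(["CAGGTAAGT"] * 10, "donor")
        pwm_a = build_pwm(["T" * 23] * 10, "acceptor")
        with pytest.raises(ValueError):
            site_strength_contrast([], genome, pwm_d, pwm_a)
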