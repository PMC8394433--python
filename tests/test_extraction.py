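"""Flank anchoring, trimming and histogram construction."""

from __future__ import annotations

import random

import numpy as np
import pytest

from msicall.extraction import (
    FastqFormatError,
    LengthHistogram,
    build_histogram,
    extract_histograms,
    extract_length,
    find_flanks,
    histograms_from_fastq,
    histograms_from_tsv,
    histograms_to_tsv,
    iter_fastq,
    reverse_complement,
)
from msicall.loci import AlignmentScoring, HomopolymerRule, MicrosatelliteLocus
from msicall.simulate import SimulatedLocusSpec, simulate_sample


def sw_score_oracle(seq: str, flank: str, match=1, mismatch=1, gap_open=2, gap_extend=1):
    """Exhaustive O(nm) Smith-Waterman fill (affine gaps), independent of
    the production aligner; returns the best local score."""
    n, m = len(seq), len(flank)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in flank
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in seq
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = match if seq[i - 1] == flank[j - 1] != "N" else -mismatch
            E[i][j] = max(H[i - 1][j] - gap_open, E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - gap_open, F[i][j - 1] - gap_extend)
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


@pytest.fixture()
def simple_locus():
    return MicrosatelliteLocus(
        name="L1",
        repeat_base="A",
        flank5="ACGTGCATCGATCGATCGTC",
        flank3="GGCTAGCTAGCATCGGATCG",
    )


class TestFindFlanks:
    def test_exact_flanks_give_exact_span(self, simple_locus):
        read = simple_locus.flank5 + "A" * 26 + simple_locus.flank3
        hit = find_flanks(read, simple_locus)
        assert hit is not None
        assert hit.end - hit.start == 26
        assert read[hit.start : hit.end] == "A" * 26

    def test_single_flank_is_rejected(self, simple_locus):
        read = simple_locus.flank5 + "A" * 26
        assert find_flanks(read, simple_locus) is None
        read = "A" * 26 + simple_locus.flank3
        assert find_flanks(read, simple_locus) is None

    def test_reverse_complement_strand(self, simple_locus):
        insert = simple_locus.flank5 + "A" * 20 + simple_locus.flank3
        hit = find_flanks(reverse_complement(insert), simple_locus)
        assert hit is not None
        assert hit.strand == "-"
        assert hit.end - hit.start == 20

    def test_strand_symmetric_span_lengths(self, simple_locus):
        rng = random.Random(7)
        for _ in range(20):
            ctx5 = "".join(rng.choice("ACGT") for _ in range(15))
            ctx3 = "".join(rng.choice("ACGT") for _ in range(15))
            read = ctx5 + simple_locus.flank5 + "A" * 22 + simple_locus.flank3 + ctx3
            fwd = find_flanks(read, simple_locus)
            rev = find_flanks(reverse_complement(read), simple_locus)
            assert fwd is not None and rev is not None
            assert fwd.end - fwd.start == rev.end - rev.start

    def test_substituted_flank_rescued_by_alignment(self, simple_locus):
        mutated5 = simple_locus.flank5[:9] + "T" + simple_locus.flank5[10:]
        assert mutated5 != simple_locus.flank5
        read = "GG" + mutated5 + "A" * 26 + simple_locus.flank3 + "CC"
        hit = find_flanks(read, simple_locus)
        assert hit is not None
        assert hit.end - hit.start == 26
        # independent dynamic-programming oracle confirms the acceptance
        score = sw_score_oracle(read, simple_locus.flank5)
        assert score >= 0.8 * len(simple_locus.flank5)

    def test_badly_corrupted_flank_rejected(self, simple_locus):
        corrupt = "TGCATGCATGCATGCATGCA"  # unrelated 20-mer
        read = corrupt + "A" * 26 + simple_locus.flank3
        assert find_flanks(read, simple_locus) is None
        assert sw_score_oracle(read[:25], simple_locus.flank5) < 16

    def test_n_bases_score_as_mismatch(self, simple_locus):
        two_n = "NN" + simple_locus.flank5[2:]
        read = two_n + "A" * 26 + simple_locus.flank3
        hit = find_flanks(read, simple_locus)  # 18/20 = 0.9 >= 0.8
        assert hit is not None
        five_n = "NNNNN" + simple_locus.flank5[5:]
        read = five_n + "A" * 26 + simple_locus.flank3
        assert find_flanks(read, simple_locus) is None

    def test_empty_read_raises(self, simple_locus):
        with pytest.raises(ValueError):
            find_flanks("", simple_locus)


class TestExtractLength:
    def test_pure_run(self, simple_locus):
        read = "TT" + simple_locus.flank5 + "A" * 26 + simple_locus.flank3 + "GG"
        assert extract_length(read, simple_locus) == 26

    def test_non_homopolymer_excluded(self, simple_locus):
        read = simple_locus.flank5 + "ACGTACGTACGT" + simple_locus.flank3
        assert extract_length(read, simple_locus) is None

    def test_adjacent_flanks_excluded(self, simple_locus):
        read = simple_locus.flank5 + simple_locus.flank3
        assert extract_length(read, simple_locus) is None

    def test_internal_error_does_not_shorten_length(self, simple_locus):
        # a substitution inside the run: full inter-flank span is reported
        run = "A" * 12 + "G" + "A" * 13
        read = simple_locus.flank5 + run + simple_locus.flank3
        assert extract_length(read, simple_locus) == 26

    def test_homopolymer_rule_thresholds(self):
        rule = HomopolymerRule(min_run=8, min_content=0.8)
        assert rule.passes("A" * 8, "A")
        assert not rule.passes("A" * 7, "A")
        assert rule.passes("A" * 12 + "G" + "A" * 9, "A")
        assert not rule.passes("AG" * 10, "A")  # 50% content
        assert not rule.passes("", "A")


class TestBuildHistogram:
    def test_identical_reads(self, simple_locus):
        reads = [simple_locus.flank5 + "A" * 26 + simple_locus.flank3] * 100
        h = build_histogram(reads, simple_locus)
        assert dict(h.counts) == {26: 100}
        assert h.n_reads == 100

    def test_order_invariance(self, simple_locus):
        rng = random.Random(3)
        reads = [
            simple_locus.flank5 + "A" * rng.choice([24, 25, 26]) + simple_locus.flank3
            for _ in range(200)
        ]
        h1 = build_histogram(reads, simple_locus)
        shuffled = reads[:]
        rng.shuffle(shuffled)
        h2 = build_histogram(shuffled, simple_locus)
        assert dict(h1.counts) == dict(h2.counts)

    def test_unanchored_reads_do_not_contribute(self, simple_locus):
        good = simple_locus.flank5 + "A" * 26 + simple_locus.flank3
        junk = "CGTACGTACGTACGTACGTACGTACGTACGTACGTACGTA"
        h = build_histogram([good, junk, junk], simple_locus)
        assert h.n_reads == 1

    def test_noiseless_simulator_round_trip(self, panel):
        loci, stable = panel
        l = loci[0]
        spec = SimulatedLocusSpec.with_unstable(
            l, stable[l.name], 0.0, depth=500, stutter_sd=0.0, seed=4
        )
        mates, _ = simulate_sample([spec])
        h = build_histogram(mates, l)
        # both mates of each pair carry the repeat
        assert dict(h.counts) == {stable[l.name]: 1000}

    def test_mixture_fraction_recovered(self, panel):
        loci, _stable = panel
        l = loci[0]
        spec = SimulatedLocusSpec(
            locus=l, stable_length=26, alleles=((26, 0.7), (21, 0.3)),
            depth=10_000, stutter_sd=0.0, seed=11,
        )
        mates, _ = simulate_sample([spec])
        h = build_histogram(mates, l)
        frac21 = h.counts[21] / h.n_reads
        se = (0.3 * 0.7 / 10_000) ** 0.5
        assert abs(frac21 - 0.3) <= 3 * se

    def test_immutable_counts(self, simple_locus):
        h = build_histogram([simple_locus.flank5 + "A" * 26 + simple_locus.flank3], simple_locus)
        with pytest.raises(TypeError):
            h.counts[26] = 5  # type: ignore[index]

    def test_histogram_validation(self):
        with pytest.raises(ValueError):
            LengthHistogram.from_counts("X", {-1: 5})


class TestFastqIO:
    def test_round_trip_plain_and_gzip(self, tmp_path, panel):
        loci, stable = panel
        l = loci[1]
        spec = SimulatedLocusSpec.with_unstable(l, stable[l.name], 0.0, depth=50, seed=6)
        from msicall.simulate import simulate_fastq

        for suffix in (".fastq", ".fastq.gz"):
            r1 = tmp_path / f"r1{suffix}"
            r2 = tmp_path / f"r2{suffix}"
            simulate_fastq(spec, r1, r2)
            hists = histograms_from_fastq([r1, r2], [l])
            assert hists[l.name].n_reads == 100

    def test_malformed_record_names_index(self, tmp_path, simple_locus):
        path = tmp_path / "bad.fastq"
        path.write_text("@ok\nACGT\n+\nIIII\n@broken\nACGT\nMISSING_PLUS\nIIII\n")
        with pytest.raises(FastqFormatError, match="record 1"):
            list(iter_fastq(path))

    def test_histogram_tsv_round_trip(self, tmp_path, simple_locus):
        reads = [simple_locus.flank5 + "A" * n + simple_locus.flank3 for n in (26, 26, 24)]
        hists = extract_histograms(reads, [simple_locus])
        out = tmp_path / "h.tsv"
        histograms_to_tsv(hists, out)
        back = histograms_from_tsv(out)
        assert dict(back["L1"].counts) == dict(hists["L1"].counts)
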