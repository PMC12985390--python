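import numpy as np
import pandas as pd
import pytest

from cfends import end_motifs, io_core
from cfends.io_core import AlignedFragment, ReferenceGenome


def naive_quartet(genome: ReferenceGenome, chrom, start, end, strand, k):
    """Independent string-scan oracle for the four end motifs."""

    def rc(s):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
        return "".join(comp[c] for c in reversed(s))

    seq = genome.contigs[chrom]
    locus = seq[start:end] if strand == "+" else rc(seq[start:end])
    up = seq[start - k : start] if start >= k else None
    down = seq[end : end + k] if end + k <= len(seq) else None
    if strand == "-":
        up, down = (rc(down) if down else None), (rc(up) if up else None)
    ok = lambda m: m if (m and len(m) == k and "N" not in m) else None
    em5 = ok(locus[:k]) if end - start >= k else None
    em3 = ok(locus[-k:]) if end - start >= k else None
    return {"PREM": ok(up) if up else None, "EM5": em5, "EM3": em3, "POEM": ok(down) if down else None}


class TestExtractEndMotifs:
    @pytest.mark.parametrize(
        "strand,expected",
        [
            ("+", dict(prem="GGTT", em5="ACGT", em3="AACC", poem="GGTT")),
            ("-", dict(prem="AACC", em5="GGTT", em3="ACGT", poem="AACC")),
        ],
    )
    def test_worked_example(self, toy_genome, strand, expected):
        q = end_motifs.extract_end_motifs(AlignedFragment("chr1", 8, 16, strand), toy_genome, 4)
        assert q == end_motifs.EndMotifQuartet(**expected)

    def test_contig_boundary_unavailable(self, toy_genome):
        q = end_motifs.extract_end_motifs(AlignedFragment("chr1", 0, 8, "+"), toy_genome, 4)
        assert q.prem is None and q.em5 == "AACC"

    def test_short_fragment_terminal_motifs_unavailable(self, toy_genome):
        q = end_motifs.extract_end_motifs(AlignedFragment("chr1", 8, 10, "+"), toy_genome, 4)
        assert q.em5 is None and q.em3 is None
        assert q.prem is not None and q.poem is not None

    def test_n_in_motif_unavailable(self):
        g = ReferenceGenome({"c": "ACGTNACGTACGTACGT"})
        q = end_motifs.extract_end_motifs(AlignedFragment("c", 4, 12, "+"), g, 4)
        assert q.em5 is None  # covers the N
        assert q.prem == "ACGT"

    def test_matches_oracle_on_random_fragments(self, sim_genome, random_fragments):
        sub = random_fragments.head(300)
        for row in sub.itertuples():
            q = end_motifs.extract_end_motifs(
                AlignedFragment(row.chrom, row.start, row.end, row.strand), sim_genome, 4
            )
            expected = naive_quartet(sim_genome, row.chrom, row.start, row.end, row.strand, 4)
            for cls in end_motifs.MOTIF_CLASSES:
                assert q.get(cls) == expected[cls]


class TestMotifSpectrum:
    def test_single_motif_fixture(self, toy_genome):
        df = pd.DataFrame(
            {"chrom": "chr1", "start": [8, 8], "end": [16, 16], "strand": "+"}
        )
        spec = end_motifs.motif_spectrum(df, toy_genome, "EM5", 4)
        freq = spec.frequency_series()
        assert freq["ACGT"] == 1.0 and freq.sum() == 1.0

    def test_domain_is_4_to_the_k(self, toy_genome):
        df = pd.DataFrame({"chrom": ["chr1"], "start": [8], "end": [16], "strand": ["+"]})
        assert len(end_motifs.motif_spectrum(df, toy_genome, "EM5", 4).counts) == 256
        assert len(end_motifs.motif_spectrum(df, toy_genome, "EM5", 2).counts) == 16

    def test_counts_match_naive_scan_all_classes(self, sim_genome, random_fragments):
        for motif_class in end_motifs.MOTIF_CLASSES:
            spec = end_motifs.motif_spectrum(random_fragments, sim_genome, motif_class, 4)
            counts = {}
            for row in random_fragments.itertuples():
                m = naive_quartet(sim_genome, row.chrom, row.start, row.end, row.strand, 4)[
                    motif_class
                ]
                if m is not None:
                    counts[m] = counts.get(m, 0) + 1
            observed = dict(zip(spec.motifs, spec.counts))
            assert {k: v for k, v in observed.items() if v} == counts

    def test_frequencies_sum_to_one(self, sim_genome, random_fragments):
        spec = end_motifs.motif_spectrum(random_fragments, sim_genome, "EM3", 4)
        assert spec.n_ends > 0
        assert abs(spec.frequencies.sum() - 1.0) < 1e-9

    def test_zero_usable_ends_flagged(self, toy_genome):
        df = pd.DataFrame({"chrom": ["chr1"], "start": [8], "end": [16], "strand": ["+"]})
        spec = end_motifs.motif_spectrum(df, toy_genome, "EM5", 4, size_range=(100, 200))
        assert spec.n_ends == 0
        assert np.isnan(spec.frequencies).all()

    def test_per_stratum_counts_sum_to_total(self, sim_genome, random_fragments):
        strata = end_motifs.DEFAULT_STRATA
        size = random_fragments["end"] - random_fragments["start"]
        covered = random_fragments[(size >= 42) & (size < 601)]
        total = end_motifs.motif_spectrum(covered, sim_genome, "EM5", 4)
        summed = sum(
            end_motifs.motif_spectrum(random_fragments, sim_genome, "EM5", 4, rng).counts
            for rng in strata
        )
        assert np.array_equal(summed, total.counts)

    def test_strand_symmetry(self, sim_genome, random_fragments):
        """Reverse-complementing the genome and flipping strands preserves spectra."""
        L = sim_genome.lengths["sim1"]
        flipped_genome = ReferenceGenome({"sim1": io_core.revcomp(sim_genome.contigs["sim1"])})
        flipped = pd.DataFrame(
            {
                "chrom": "sim1",
                "start": L - random_fragments["end"],
                "end": L - random_fragments["start"],
                "strand": np.where(random_fragments["strand"] == "+", "-", "+"),
            }
        )
        for cls in end_motifs.MOTIF_CLASSES:
            a = end_motifs.motif_spectrum(random_fragments, sim_genome, cls, 4)
            b = end_motifs.motif_spectrum(flipped, flipped_genome, cls, 4)
            assert np.array_equal(a.counts, b.counts)


class TestExpectedGenomeFrequency:
    def test_homopolymer_both_strands(self):
        g = ReferenceGenome({"c": "AAAA"})
        e = end_motifs.expected_genome_frequency(g, 4)
        assert e[end_motifs.kmer_to_index("AAAA")] == 0.5
        assert e[end_motifs.kmer_to_index("TTTT")] == 0.5

    def test_matches_window_enumeration(self):
        g = ReferenceGenome({"c": "ACGTACGT"})
        e = end_motifs.expected_genome_frequency(g, 4)
        seq = "ACGTACGT"
        windows = [seq[i : i + 4] for i in range(5)]
        windows += [io_core.revcomp(seq)[i : i + 4] for i in range(5)]
        for motif in set(windows):
            assert e[end_motifs.kmer_to_index(motif)] == pytest.approx(
                windows.count(motif) / len(windows)
            )

    def test_uniform_genome_approaches_uniform(self, sim_genome):
        e = end_motifs.expected_genome_frequency(sim_genome, 4)
        # i.i.d. genome at GC 0.42: frequencies vary with composition but every
        # motif is represented and the vector normalizes
        assert e.sum() == pytest.approx(1.0)
        assert (e > 0).all()

    def test_too_short_genome(self):
        g = ReferenceGenome({"c": "ACG"})
        with pytest.raises(ValueError):
            end_motifs.expected_genome_frequency(g, 4)


class TestCorrectFrequencies:
    @staticmethod
    def _spectrum(freqs, n_ends=1000, k=1):
        counts = np.asarray(freqs) * n_ends
        return end_motifs.MotifSpectrum("EM5", k, "all", counts, n_ends)

    def test_pointwise_arithmetic(self):
        # observed 0.08 / sonicated 0.04 * expected 0.02 = 0.04 (pre-normalization)
        plasma = self._spectrum([0.08, 0.92])
        son = self._spectrum([0.04, 0.96])
        expected = np.array([0.02, 0.98])
        out = end_motifs.correct_frequencies(plasma, son, expected, pseudocount=0.0)
        pre_norm = 0.08 / 0.04 * 0.02
        other = 0.92 / 0.96 * 0.98
        assert out.frequencies[0] == pytest.approx(pre_norm / (pre_norm + other))

    def test_identity_when_sonicated_equals_expected(self):
        plasma = self._spectrum([0.3, 0.7])
        son = self._spectrum([0.4, 0.6])
        out = end_motifs.correct_frequencies(plasma, son, np.array([0.4, 0.6]), pseudocount=0.0)
        assert np.allclose(out.frequencies, plasma.frequencies)

    def test_identity_when_plasma_equals_sonicated(self):
        plasma = self._spectrum([0.4, 0.6])
        son = self._spectrum([0.4, 0.6])
        expected = np.array([0.25, 0.75])
        out = end_motifs.correct_frequencies(plasma, son, expected, pseudocount=0.0)
        assert np.allclose(out.frequencies, expected)

    def test_domain_and_normalization_errors(self):
        plasma = self._spectrum([0.5, 0.5])
        son = self._spectrum([0.25, 0.25, 0.25, 0.25], k=1)
        with pytest.raises(ValueError):
            end_motifs.correct_frequencies(plasma, son, np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            end_motifs.correct_frequencies(plasma, self._spectrum([0.5, 0.5]), np.array([0.5, 0.7]))


class TestSizeProfileAndStrata:
    def test_histogram_counts(self):
        df = pd.DataFrame({"chrom": "c", "start": 0, "end": [50, 50, 166], "strand": "+"})
        profile = end_motifs.size_profile(df)
        assert profile.histogram.to_dict() == {50: 2, 166: 1}

    def test_empty_profile(self):
        df = pd.DataFrame({"chrom": [], "start": [], "end": [], "strand": []})
        assert end_motifs.size_profile(df).histogram.empty

    def test_stratify_half_open_boundaries(self, sim_genome):
        df = pd.DataFrame(
            {"chrom": "c", "start": 0, "end": [70, 166, 30, 600], "strand": "+"}
        )
        out = end_motifs.stratify(df)
        assert out[(70, 166)]["end"].tolist() == [70]
        assert out[(166, 601)]["end"].tolist() == [166, 600]
        assert len(out[(42, 70)]) == 0  # size 30 dropped

    def test_overlapping_strata_rejected(self):
        with pytest.raises(ValueError):
            end_motifs.SizeStratification(((42, 80), (70, 166)))


class TestPartitionIdentity:
    def test_prem_equals_shifted_em3_and_poem_equals_shifted_em5(self, sim_genome):
        """Abutting fragments share cut sites: each fragment's PREM is its left
        neighbour's EM3 and its POEM is its right neighbour's EM5, so pooled
        counts agree up to the two contig-boundary fragments."""
        rng = np.random.default_rng(3)
        L = sim_genome.lengths["sim1"]
        # cut spacing > k so every fragment's own terminal motifs exist
        cuts = np.sort(rng.choice(np.arange(100, L - 100, 16), 400, replace=False))
        bounds = np.concatenate([[50], cuts, [L - 50]])
        df = pd.DataFrame(
            {
                "chrom": "sim1",
                "start": bounds[:-1],
                "end": bounds[1:],
                "strand": "+",
            }
        )
        prem = end_motifs.motif_spectrum(df, sim_genome, "PREM", 4).counts
        em3 = end_motifs.motif_spectrum(df.iloc[:-1], sim_genome, "EM3", 4).counts
        prem_inner = end_motifs.motif_spectrum(df.iloc[1:], sim_genome, "PREM", 4).counts
        assert np.array_equal(prem_inner, em3)
        poem_inner = end_motifs.motif_spectrum(df.iloc[:-1], sim_genome, "POEM", 4).counts
        em5 = end_motifs.motif_spectrum(df.iloc[1:], sim_genome, "EM5", 4).counts
        assert np.array_equal(poem_inner, em5)
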