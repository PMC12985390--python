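import itertools

import numpy as np
import pandas as pd
import pytest

from cfends import end_motifs, four_end
from cfends.four_end import (
    BLUNT,
    FIVE_PRIME,
    THREE_PRIME,
    DsMolecule,
    FourEndMotifSpec,
)
from cfends.io_core import ReferenceGenome, revcomp


@pytest.fixture(scope="module")
def pool():
    return four_end.build_adapter_pool()


@pytest.fixture(scope="module")
def genome():
    rng = np.random.default_rng(17)
    seq = "".join(rng.choice(list("ACGT"), 5000))
    return ReferenceGenome({"c": seq})


class TestAdapterPool:
    def test_pool_size_and_modalities(self, pool):
        assert len(pool) == 41
        modalities = {(a.kind, a.overhang_len) for a in pool}
        expected = {(BLUNT, 0)}
        expected |= {(FIVE_PRIME, n) for n in range(1, 21)}
        expected |= {(THREE_PRIME, n) for n in range(1, 21)}
        assert modalities == expected

    def test_pairwise_hamming_distance(self, pool):
        dists = [
            sum(x != y for x, y in zip(a.barcode, b.barcode))
            for a, b in itertools.combinations(pool, 2)
        ]
        assert min(dists) >= 2  # contract: at least 2
        assert min(dists) >= 3  # actual code distance: unique 1-mismatch rescue

    def test_barcode_identifies_modality(self, pool):
        assert len({a.barcode for a in pool}) == 41


class TestCodec:
    def test_round_trip_all_41_modalities(self, genome, pool):
        base = 1000
        for adapter_l in pool:
            for adapter_r in (pool[0], pool[7], pool[25]):
                mol = _molecule_with(adapter_l, adapter_r, base)
                rec = four_end.encode_molecule(mol, genome, pool)
                assert rec is not None
                assert four_end.decode_read(rec, pool) == mol

    def test_round_trip_random_molecules(self, genome, pool):
        rng = np.random.default_rng(23)
        for _ in range(2000):
            mol = _random_molecule(rng)
            rec = four_end.encode_molecule(mol, genome, pool)
            assert four_end.decode_read(rec, pool) == mol

    def test_one_mismatch_rescue(self, genome, pool):
        mol = DsMolecule("c", 1000, 1100, 1000, 1100)
        rec = four_end.encode_molecule(mol, genome, pool)
        corrupted = rec.left_barcode
        alt = "A" if corrupted[0] != "A" else "C"
        rec2 = four_end.ReadRecord(
            rec.chrom, rec.insert_start, rec.insert_end,
            alt + corrupted[1:], rec.right_barcode,
        )
        assert four_end.decode_read(rec2, pool) == mol

    def test_unrescuable_barcode_rejected(self, genome, pool):
        mol = DsMolecule("c", 1000, 1100, 1000, 1100)
        rec = four_end.encode_molecule(mol, genome, pool)
        bc = list(rec.left_barcode)
        # corrupt two positions away from every codeword (distance-3 code:
        # a doubly-corrupted word is >= 1 from the origin and >= 1 from others)
        for i in (0, 1):
            bc[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[bc[i]]
        bad = "".join(bc)
        if any(sum(x != y for x, y in zip(a.barcode, bad)) <= 1 for a in pool):
            pytest.skip("corruption accidentally near a codeword")
        rec2 = four_end.ReadRecord(
            rec.chrom, rec.insert_start, rec.insert_end, bad, rec.right_barcode
        )
        with pytest.raises(four_end.BarcodeError):
            four_end.decode_read(rec2, pool)

    def test_overhang_beyond_pool_unligatable(self, genome, pool):
        mol = DsMolecule("c", 1000, 1100, 1021, 1100)  # left overhang 21
        assert four_end.encode_molecule(mol, genome, pool) is None


def _molecule_with(adapter_l, adapter_r, base, size=120):
    w_start, w_end = base, base + size
    if adapter_l.kind == BLUNT:
        c_start = w_start
    elif adapter_l.kind == FIVE_PRIME:
        c_start = w_start + adapter_l.overhang_len
    else:
        c_start = w_start - adapter_l.overhang_len
    if adapter_r.kind == BLUNT:
        c_end = w_end
    elif adapter_r.kind == THREE_PRIME:
        c_end = w_end - adapter_r.overhang_len
    else:
        c_end = w_end + adapter_r.overhang_len
    return DsMolecule("c", w_start, w_end, c_start, c_end)


def _random_molecule(rng, chrom="c", lo=100, hi=4000):
    w_start = int(rng.integers(lo, hi))
    size = int(rng.integers(40, 400))
    w_end = w_start + size
    c_start = w_start + int(rng.integers(-20, 21))
    c_end = w_end + int(rng.integers(-20, 21))
    if c_start >= c_end:
        c_start, c_end = w_start, w_end
    return DsMolecule(chrom, w_start, w_end, c_start, c_end)


class TestJaggedType:
    def test_blunt_both_sides(self):
        t = four_end.jagged_type(DsMolecule("c", 100, 200, 100, 200))
        assert t == {"left": ("blunt", 0), "right": ("blunt", 0)}

    def test_left_watson_five_prime_protrusion(self):
        t = four_end.jagged_type(DsMolecule("c", 100, 200, 103, 200))
        assert t["left"] == ("five_prime_jagged", 3)

    def test_right_watson_three_prime_protrusion(self):
        t = four_end.jagged_type(DsMolecule("c", 100, 205, 100, 200))
        assert t["right"] == ("three_prime_jagged", 5)

    def test_agrees_with_end_modality(self, genome):
        rng = np.random.default_rng(5)
        mapping = {BLUNT: "blunt", FIVE_PRIME: "five_prime_jagged", THREE_PRIME: "three_prime_jagged"}
        for _ in range(200):
            mol = _random_molecule(rng)
            t = four_end.jagged_type(mol)
            for side in ("left", "right"):
                m = mol.modality(side, genome)
                assert t[side] == (mapping[m.kind], m.overhang_len)
                assert len(m.overhang_seq) == m.overhang_len

    def test_non_overlapping_strands_rejected(self):
        with pytest.raises(ValueError):
            DsMolecule("c", 100, 150, 160, 210)


class TestFourEndMotif:
    def test_blunt_acgt_one_mers(self):
        g = ReferenceGenome({"c": "NNACGTNN"})
        mol = DsMolecule("c", 2, 6, 2, 6)
        assert four_end.four_end_motif(mol, g, FourEndMotifSpec(1, 1, 1, 1)) == "A→TT←A"

    def test_watson_only_two_mers(self):
        g = ReferenceGenome({"c": "NNACGTNN"})
        mol = DsMolecule("c", 2, 6, 2, 6)
        assert four_end.four_end_motif(mol, g, FourEndMotifSpec(2, 2, 0, 0)) == "AC→GT←"

    def test_notation_strings(self):
        assert FourEndMotifSpec(1, 1, 1, 1).notation == "1→11←1"
        assert FourEndMotifSpec(2, 2, 0, 0).notation == "2→20←0"
        assert FourEndMotifSpec(0, 0, 2, 2).notation == "0→02←2"

    def test_motif_space_size(self):
        spec = FourEndMotifSpec(1, 1, 1, 1)
        assert spec.space_size == 256
        assert len(four_end.motif_space(spec)) == 256

    def test_n_excluded(self):
        g = ReferenceGenome({"c": "NNANGTNN"})
        mol = DsMolecule("c", 2, 6, 2, 6)
        assert four_end.four_end_motif(mol, g, FourEndMotifSpec(2, 2, 0, 0)) is None


class TestFourEndSpectrum:
    def test_identical_blunt_duplexes(self):
        g = ReferenceGenome({"c": "NNACGTNN"})
        mols = [DsMolecule("c", 2, 6, 2, 6)] * 10
        freq = four_end.four_end_spectrum(mols, g, FourEndMotifSpec(1, 1, 1, 1))
        assert freq["A→TT←A"] == 1.0 and freq.sum() == 1.0

    def test_matches_brute_force_on_random_fixture(self, genome):
        rng = np.random.default_rng(31)
        mols = [_random_molecule(rng) for _ in range(500)]
        spec = FourEndMotifSpec(1, 1, 1, 1)
        freq = four_end.four_end_spectrum(mols, genome, spec)
        # brute force: read the four terminal bases directly
        counts = {}
        seq = genome.contigs["c"]
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for m in mols:
            w5, w3 = seq[m.w_start], seq[m.w_end - 1]
            c5 = comp[seq[m.c_end - 1]]
            c3 = comp[seq[m.c_start]]
            key = f"{w5}→{w3}{c3}←{c5}"
            counts[key] = counts.get(key, 0) + 1
        for key, n in counts.items():
            assert freq[key] == pytest.approx(n / len(mols))

    def test_marginalizes_to_em5_spectrum(self, genome):
        """1→00←0 spectrum equals the 1-mer EM5 spectrum of the Watson strands."""
        rng = np.random.default_rng(37)
        mols = [_random_molecule(rng) for _ in range(400)]
        freq = four_end.four_end_spectrum(mols, genome, FourEndMotifSpec(1, 0, 0, 0))
        frags = pd.DataFrame(
            {
                "chrom": "c",
                "start": [m.w_start for m in mols],
                "end": [m.w_end for m in mols],
                "strand": "+",
            }
        )
        em5 = end_motifs.motif_spectrum(frags, genome, "EM5", 1)
        for base, f in em5.frequency_series().items():
            assert freq[f"{base}→←"] == pytest.approx(f)

    def test_blunt_duplexes_self_consistent_support(self, genome):
        rng = np.random.default_rng(41)
        mols = []
        for _ in range(300):
            s = int(rng.integers(100, 4000))
            mols.append(DsMolecule("c", s, s + 100, s, s + 100))
        freq = four_end.four_end_spectrum(mols, genome, FourEndMotifSpec(1, 1, 1, 1))
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for motif, f in freq[freq > 0].items():
            w5, w3, c3, c5 = motif[0], motif[2], motif[3], motif[5]
            assert c3 == comp[w5] and c5 == comp[w3]


class TestNucleaseAttribution:
    @staticmethod
    def _molecule_for(genome_seq, w_start=10, size=60, left_off=3):
        g = ReferenceGenome({"c": genome_seq})
        return g, DsMolecule("c", w_start, w_start + size, w_start + left_off, w_start + size)

    def _engineered(self, five, three_rc, left_off=4):
        # Watson 5' 2-mer = five at w_start; Crick 3' 2-mer = three at c_start
        seq = ["A"] * 200
        w_start = 50
        seq[w_start : w_start + 2] = list(five)
        crick3 = revcomp(three_rc)
        seq[w_start + left_off : w_start + left_off + 2] = list(crick3)
        g = ReferenceGenome({"c": "".join(seq)})
        mol = DsMolecule("c", w_start, w_start + 60, w_start + left_off, w_start + 60)
        return g, mol

    @pytest.mark.parametrize(
        "five,three,label",
        [
            ("GG", "CT", "DNASE1L3-DNASE1L3"),
            ("CT", "CG", "DNASE1-DNASE1"),
            ("GG", "GT", "DFFB-DNASE1L3"),  # GT is a DFFB 3' signature
            ("CC", "CT", "unassigned"),
        ],
    )
    def test_pair_labels(self, five, three, label):
        g, mol = self._engineered(five, three)
        assert four_end.assign_nuclease_pair(mol, g, side="left") == label

    def test_label_set_has_six_categories(self):
        assert len(four_end.PAIR_LABELS) == 6

    def test_uniform_molecules_self_normalize(self, genome):
        rng = np.random.default_rng(43)
        mols = []
        for _ in range(12_000):
            s = int(rng.integers(100, 4500))
            size = int(rng.integers(60, 300))
            if s + size > 4900:
                continue
            off = int(rng.integers(-5, 6))
            mols.append(DsMolecule("c", s, s + size, s + off, s + size))
        table = four_end.signature_size_abundance(
            mols, genome, size_bins=((20, 400),), seed=11, expected_factor=5
        )
        vals = table.iloc[0].dropna()
        assert (np.abs(vals - 1.0) < 0.5).all()  # Monte-Carlo tolerance

    def test_gg_ct_only_cutting_enriches_l3(self, genome):
        from cfends import synthetic_data

        model = synthetic_data.NucleaseModel(
            activities={"DNASE1L3": [(float("inf"), 5.0)]}, background=0.02
        )
        cfg = synthetic_data.DuplexSimConfig(seed=3, n_molecules=1500, size_max=400)
        big = synthetic_data.simulate_reference(
            synthetic_data.SimulationConfig(seed=19, genome_length=50_000)
        )
        res = synthetic_data.simulate_ds_molecules(big, cfg, model)
        table = four_end.signature_size_abundance(
            res.molecules, big, size_bins=((20, 400),), seed=13, expected_factor=5
        )
        row = table.iloc[0]
        assert row["DNASE1L3-DNASE1L3"] > 5
        others = row.drop(["DNASE1L3-DNASE1L3", "DFFB-DNASE1L3"]).dropna()
        assert (row["DNASE1L3-DNASE1L3"] > 3 * others).all()
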