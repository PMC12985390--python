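"""Duplex (4-end) cfDNA molecules: stem-loop adapter pool and barcode codec,
jagged-end typing, 4-end motif notation and spectra, and nuclease-signature
attribution.

A duplex molecule is described by the genomic intervals of its Watson strand
[w_start, w_end) and Crick strand [c_start, c_end). The left side is where
the Watson 5' end sits (lower coordinates); the right side the Watson 3'.
Jagged geometry follows from the interval offsets: at the left side,
w_start < c_start means the Watson 5' end protrudes (a 5' overhang), and at
the right side w_end > c_end means the Watson 3' end protrudes.

The 4-end motif notation a→b d←c places the Watson strand's 5'->3' motifs in
the numerator and the Crick strand's in the denominator, with the Crick
strand displayed antiparallel (3' end first). A blunt "ACGT" duplex thus
renders its four 1-mer termini as "A→TT←A".
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import ReferenceGenome, revcomp

logger = logging.getLogger(__name__)

BLUNT = "blunt"
FIVE_PRIME = "five_prime_overhang"
THREE_PRIME = "three_prime_overhang"
MAX_OVERHANG = 20  # longest single-stranded overhang ligatable by the pool

_BASES = "ACGT"

# dinucleotide cutting signatures attributed to plasma nucleases from
# knockout-vs-wild-type comparisons (5' and 3' end 2-mers)
NUCLEASE_SIGNATURES: dict[str, dict[str, frozenset[str]]] = {
    "DNASE1L3": {"5p": frozenset({"GG"}), "3p": frozenset({"CT"})},
    "DNASE1": {"5p": frozenset({"CT"}), "3p": frozenset({"CG"})},
    "DFFB": {
        "5p": frozenset({"AC", "AT", "AA", "AG", "GA"}),
        "3p": frozenset({"GC", "GT", "AG", "GG", "TC"}),
    },
}

_NUCLEASE_ORDER = ("DFFB", "DNASE1", "DNASE1L3")

#: the 6 unordered nuclease pair labels plus the unassigned sentinel
PAIR_LABELS = (
    "DNASE1L3-DNASE1L3",
    "DNASE1-DNASE1",
    "DFFB-DFFB",
    "DNASE1-DNASE1L3",
    "DFFB-DNASE1L3",
    "DFFB-DNASE1",
)
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class EndModality:
    """Geometry of one duplex terminus."""

    side: str  # left | right
    kind: str  # blunt | five_prime_overhang | three_prime_overhang
    overhang_len: int
    overhang_seq: str = ""

    def __post_init__(self):
        if self.kind == BLUNT and self.overhang_len != 0:
            raise ValueError("blunt end with nonzero overhang")
        if self.kind != BLUNT and not (1 <= self.overhang_len):
            raise ValueError("overhang length must be >= 1")


@dataclass(frozen=True)
class StemLoopAdapter:
    """A stem-loop adapter: 6-bp barcode encoding (end kind, overhang length)."""

    barcode: str
    kind: str
    overhang_len: int


def _distance_code(n_words: int, length: int = 6, min_dist: int = 3) -> list[str]:
    """Deterministic greedy lexicographic code over {A,C,G,T}^length with
    pairwise Hamming distance >= min_dist."""
    chosen: list[str] = []
    for word in itertools.product(_BASES, repeat=length):
        w = "".join(word)
        if all(sum(a != b for a, b in zip(w, c)) >= min_dist for c in chosen):
            chosen.append(w)
            if len(chosen) == n_words:
                return chosen
    raise RuntimeError("could not build barcode pool")  # pragma: no cover


def build_adapter_pool() -> list[StemLoopAdapter]:
    """The 41-adapter stem-loop pool: 1 blunt + 20 five-prime-overhang
    (lengths 1..20) + 20 three-prime-overhang (lengths 1..20) adapters.

    Barcodes are a deterministic 6-mer code with pairwise Hamming distance
    >= 3, so a single substitution is unambiguously rescuable. These are
    synthetic functional equivalents of the published adapters, whose actual
    oligo sequences are not reproduced here.
    """
    modalities = [(BLUNT, 0)]
    modalities += [(FIVE_PRIME, n) for n in range(1, MAX_OVERHANG + 1)]
    modalities += [(THREE_PRIME, n) for n in range(1, MAX_OVERHANG + 1)]
    barcodes = _distance_code(len(modalities))
    return [
        StemLoopAdapter(barcode=bc, kind=kind, overhang_len=n)
        for bc, (kind, n) in zip(barcodes, modalities)
    ]


@dataclass(frozen=True)
class DsMolecule:
    """A double-stranded cfDNA molecule with possibly jagged ends."""

    chrom: str
    w_start: int
    w_end: int
    c_start: int
    c_end: int

    def __post_init__(self):
        if self.w_start >= self.w_end or self.c_start >= self.c_end:
            raise ValueError("empty strand interval")
        if self.w_end <= self.c_start or self.c_end <= self.w_start:
            raise ValueError("Watson and Crick strands do not overlap")

    @property
    def size(self) -> int:
        """Duplex size = Watson strand length (single-strand convention)."""
        return self.w_end - self.w_start

    @property
    def outer_span(self) -> tuple[int, int]:
        return min(self.w_start, self.c_start), max(self.w_end, self.c_end)

    def modality(self, side: str, genome: ReferenceGenome | None = None) -> EndModality:
        """End geometry of one side, with overhang sequence if genome given."""
        if side == "left":
            delta = self.c_start - self.w_start
            if delta == 0:
                return EndModality("left", BLUNT, 0)
            if delta > 0:  # Watson 5' protrudes
                seq = genome.fetch(self.chrom, self.w_start, self.c_start) if genome else ""
                return EndModality("left", FIVE_PRIME, delta, seq)
            seq = (
                revcomp(genome.fetch(self.chrom, self.c_start, self.w_start))
                if genome
                else ""
            )
            return EndModality("left", THREE_PRIME, -delta, seq)
        if side == "right":
            delta = self.w_end - self.c_end
            if delta == 0:
                return EndModality("right", BLUNT, 0)
            if delta > 0:  # Watson 3' protrudes
                seq = genome.fetch(self.chrom, self.c_end, self.w_end) if genome else ""
                return EndModality("right", THREE_PRIME, delta, seq)
            seq = (
                revcomp(genome.fetch(self.chrom, self.w_end, self.c_end))
                if genome
                else ""
            )
            return EndModality("right", FIVE_PRIME, -delta, seq)
        raise ValueError(f"side must be left or right, got {side!r}")


def jagged_type(molecule: DsMolecule) -> dict[str, tuple[str, int]]:
    """Per-side jagged classification: {blunt, five_prime_jagged,
    three_prime_jagged} with overhang length."""
    mapping = {BLUNT: "blunt", FIVE_PRIME: "five_prime_jagged", THREE_PRIME: "three_prime_jagged"}
    out = {}
    for side in ("left", "right"):
        m = molecule.modality(side)
        out[side] = (mapping[m.kind], m.overhang_len)
    return out


@dataclass(frozen=True)
class ReadRecord:
    """A circularized-read record: insert span plus the two end barcodes."""

    chrom: str
    insert_start: int  # outer span of the duplex, 0-based half-open
    insert_end: int
    left_barcode: str
    right_barcode: str
    insert_seq: str | None = None


def encode_molecule(
    molecule: DsMolecule,
    genome: ReferenceGenome,
    pool: list[StemLoopAdapter] | None = None,
) -> ReadRecord | None:
    """Encode a duplex molecule as a read record with end-typing barcodes.

    Molecules with an overhang longer than the pool supports (20 nt) cannot
    circularize and are dropped (returns None), emulating exonuclease loss
    of incompletely ligated products.
    """
    pool = pool if pool is not None else build_adapter_pool()
    lookup = {(a.kind, a.overhang_len): a.barcode for a in pool}
    barcodes = []
    for side in ("left", "right"):
        m = molecule.modality(side)
        if m.overhang_len > MAX_OVERHANG:
            logger.debug("overhang %d > %d: unligatable", m.overhang_len, MAX_OVERHANG)
            return None
        barcodes.append(lookup[(m.kind, m.overhang_len)])
    lo, hi = molecule.outer_span
    return ReadRecord(
        chrom=molecule.chrom,
        insert_start=lo,
        insert_end=hi,
        left_barcode=barcodes[0],
        right_barcode=barcodes[1],
        insert_seq=genome.fetch(molecule.chrom, lo, hi),
    )


class BarcodeError(ValueError):
    """Raised when a record's barcode cannot be (unambiguously) decoded."""


def _decode_barcode(barcode: str, pool: list[StemLoopAdapter], max_rescue: int = 1):
    exact = [a for a in pool if a.barcode == barcode]
    if exact:
        return exact[0]
    if max_rescue >= 1:
        near = [
            a
            for a in pool
            if sum(x != y for x, y in zip(a.barcode, barcode)) <= max_rescue
        ]
        if len(near) == 1:
            return near[0]
        if len(near) > 1:  # pragma: no cover - impossible with a distance-3 pool
            raise BarcodeError(f"barcode {barcode!r} ambiguous")
    raise BarcodeError(f"barcode {barcode!r} not decodable")


def decode_read(
    record: ReadRecord,
    pool: list[StemLoopAdapter] | None = None,
    max_rescue: int = 1,
) -> DsMolecule:
    """Reconstruct the duplex molecule from a read record.

    ``decode_read(encode_molecule(m))`` is the identity. Barcodes with one
    substitution are rescued to the nearest adapter (unique thanks to the
    distance-3 pool); unrescuable barcodes raise BarcodeError.
    """
    pool = pool if pool is not None else build_adapter_pool()
    left = _decode_barcode(record.left_barcode, pool, max_rescue)
    right = _decode_barcode(record.right_barcode, pool, max_rescue)
    lo, hi = record.insert_start, record.insert_end

    if left.kind == BLUNT:
        w_start = c_start = lo
    elif left.kind == FIVE_PRIME:  # Watson 5' protrudes at the outer edge
        w_start = lo
        c_start = lo + left.overhang_len
    else:  # Crick 3' protrudes
        c_start = lo
        w_start = lo + left.overhang_len
    if right.kind == BLUNT:
        w_end = c_end = hi
    elif right.kind == THREE_PRIME:  # Watson 3' protrudes
        w_end = hi
        c_end = hi - right.overhang_len
    else:  # Crick 5' protrudes
        c_end = hi
        w_end = hi - right.overhang_len
    return DsMolecule(record.chrom, w_start, w_end, c_start, c_end)


@dataclass(frozen=True)
class FourEndMotifSpec:
    """Motif lengths (w5, w3, c5, c3) for the four termini of a duplex."""

    w5: int
    w3: int
    c5: int
    c3: int

    def __post_init__(self):
        if min(self.w5, self.w3, self.c5, self.c3) < 0:
            raise ValueError("motif lengths must be >= 0")
        if self.w5 + self.w3 + self.c5 + self.c3 == 0:
            raise ValueError("at least one motif length must be > 0")

    @property
    def notation(self) -> str:
        """Length notation, e.g. 1→11←1 or 2→20←0."""
        return f"{self.w5}→{self.w3}{self.c3}←{self.c5}"

    @property
    def space_size(self) -> int:
        return 4 ** (self.w5 + self.w3 + self.c5 + self.c3)


def render_four_end_motif(w5: str, w3: str, c5: str, c3: str) -> str:
    """Flattened sequence form: numerator Watson 5'->3', denominator Crick
    displayed antiparallel (3'-end first)."""
    return f"{w5}→{w3}{c3[::-1]}←{c5[::-1]}"


def four_end_motif(
    molecule: DsMolecule, genome: ReferenceGenome, spec: FourEndMotifSpec
) -> str | None:
    """The molecule's 4-end motif string under ``spec``; None when any
    requested motif contains N or exceeds a strand's length."""
    chrom = molecule.chrom
    if spec.w5 + spec.w3 > molecule.w_end - molecule.w_start:
        return None
    if spec.c5 + spec.c3 > molecule.c_end - molecule.c_start:
        return None
    w5 = genome.fetch(chrom, molecule.w_start, molecule.w_start + spec.w5)
    w3 = genome.fetch(chrom, molecule.w_end - spec.w3, molecule.w_end)
    # Crick strand runs right-to-left: its 5' end is at c_end, 3' end at c_start
    c5 = revcomp(genome.fetch(chrom, molecule.c_end - spec.c5, molecule.c_end))
    c3 = revcomp(genome.fetch(chrom, molecule.c_start, molecule.c_start + spec.c3))
    if "N" in w5 + w3 + c5 + c3:
        return None
    return render_four_end_motif(w5, w3, c5, c3)


def motif_space(spec: FourEndMotifSpec) -> list[str]:
    """All rendered motif strings of a spec (4**total, deterministic order)."""
    out = []
    for w5 in itertools.product(_BASES, repeat=spec.w5):
        for w3 in itertools.product(_BASES, repeat=spec.w3):
            for c5 in itertools.product(_BASES, repeat=spec.c5):
                for c3 in itertools.product(_BASES, repeat=spec.c3):
                    out.append(
                        render_four_end_motif(
                            "".join(w5), "".join(w3), "".join(c5), "".join(c3)
                        )
                    )
    return out


def four_end_spectrum(
    molecules: list[DsMolecule], genome: ReferenceGenome, spec: FourEndMotifSpec
) -> pd.Series:
    """Frequency vector over the spec's motif space (sums to 1)."""
    counts = pd.Series(0, index=motif_space(spec), dtype=float)
    usable = 0
    for mol in molecules:
        motif = four_end_motif(mol, genome, spec)
        if motif is not None:
            counts[motif] += 1
            usable += 1
    if usable == 0:
        raise ValueError("zero usable molecules")
    return counts / usable


def _side_dimers(
    molecule: DsMolecule, genome: ReferenceGenome, side: str
) -> tuple[str, str] | None:
    """(5' 2-mer, 3' 2-mer) of the two strands at one side, or None if N /
    too short."""
    chrom = molecule.chrom
    if side == "left":
        five = genome.fetch(chrom, molecule.w_start, molecule.w_start + 2)
        three = revcomp(genome.fetch(chrom, molecule.c_start, molecule.c_start + 2))
    elif side == "right":
        five = revcomp(genome.fetch(chrom, molecule.c_end - 2, molecule.c_end))
        three = genome.fetch(chrom, molecule.w_end - 2, molecule.w_end)
    else:
        raise ValueError(f"side must be left or right, got {side!r}")
    if "N" in five + three:
        return None
    return five, three


def assign_nuclease_pair(
    molecule: DsMolecule,
    genome: ReferenceGenome,
    signatures: dict[str, dict[str, frozenset[str]]] = NUCLEASE_SIGNATURES,
    side: str = "left",
) -> str:
    """Attribute one side of a duplex to an (unordered) nuclease pair.

    The 5' 2-mer of one strand and the 3' 2-mer of the complementary strand
    at the same side are looked up in the signature sets; a motif matching
    no or more than one nuclease leaves the side unassigned.
    """
    dimers = _side_dimers(molecule, genome, side)
    if dimers is None:
        return UNASSIGNED
    five, three = dimers
    five_hits = [n for n, sig in signatures.items() if five in sig["5p"]]
    three_hits = [n for n, sig in signatures.items() if three in sig["3p"]]
    if len(five_hits) != 1 or len(three_hits) != 1:
        return UNASSIGNED
    pair = sorted((five_hits[0], three_hits[0]), key=_NUCLEASE_ORDER.index)
    return f"{pair[0]}-{pair[1]}"


#: size landmarks for nuclease-engagement profiling (bp)
DEFAULT_SIZE_BINS = ((20, 130), (130, 200), (200, 400), (400, 600), (600, 1000))


def signature_size_abundance(
    molecules: list[DsMolecule],
    genome: ReferenceGenome,
    signatures: dict[str, dict[str, frozenset[str]]] = NUCLEASE_SIGNATURES,
    size_bins: tuple[tuple[int, int], ...] = DEFAULT_SIZE_BINS,
    seed: int = 0,
    expected_factor: int = 10,
) -> pd.DataFrame:
    """Observed/expected abundance of the 6 nuclease-pair labels per size bin.

    Expected frequencies come from molecules redrawn uniformly at random
    from the genome with the observed (size, jagged-offset) multiset,
    ``expected_factor`` times the observed count (seed-fixed Monte Carlo).
    Empty bins are reported as missing (NaN), not zero.
    """
    for (lo1, hi1), (lo2, hi2) in zip(size_bins, size_bins[1:]):
        if lo2 < hi1:
            raise ValueError("size bins overlap or are not ordered")
    rng = np.random.default_rng(seed)

    def _label_counts(mols):
        table = {b: {lab: 0 for lab in PAIR_LABELS + (UNASSIGNED,)} for b in size_bins}
        totals = {b: 0 for b in size_bins}
        for mol in mols:
            bin_ = next(
                (b for b in size_bins if b[0] <= mol.size < b[1]), None
            )
            if bin_ is None:
                continue
            for side in ("left", "right"):
                lab = assign_nuclease_pair(mol, genome, signatures, side)
                table[bin_][lab] += 1
                totals[bin_] += 1
        freq = {}
        for b in size_bins:
            freq[b] = {
                lab: (table[b][lab] / totals[b] if totals[b] else np.nan)
                for lab in PAIR_LABELS
            }
        return freq, totals

    obs_freq, obs_totals = _label_counts(molecules)

    # uniform redraw preserving the observed geometry multiset
    chroms = list(genome.contigs)
    lengths = np.array([genome.lengths[c] for c in chroms])
    expected_mols = []
    for mol in molecules:
        for _ in range(expected_factor):
            size = mol.size
            left_off = mol.c_start - mol.w_start
            right_off = mol.w_end - mol.c_end
            ci = rng.integers(len(chroms))
            margin = MAX_OVERHANG + 2
            hi = lengths[ci] - size - margin
            if hi <= margin:
                continue
            s = int(rng.integers(margin, hi))
            expected_mols.append(
                DsMolecule(chroms[ci], s, s + size, s + left_off, s + size - right_off)
            )
    exp_freq, _ = _label_counts(expected_mols)

    rows = []
    for b in size_bins:
        if obs_totals[b] == 0:
            rows.append({lab: np.nan for lab in PAIR_LABELS})
            continue
        row = {}
        for lab in PAIR_LABELS:
            e = exp_freq[b][lab]
            o = obs_freq[b][lab]
            row[lab] = o / e if (e and not np.isnan(e) and e > 0) else np.nan
        rows.append(row)
    return pd.DataFrame(rows, index=[f"[{lo},{hi})" for lo, hi in size_bins])
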