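"""End-motif extraction and k-mer spectra for cfDNA fragments.

Four motif classes are defined per fragment, all written 5'->3' in the
molecule's own orientation:

* EM5  — first k bases of the sequenced fragment,
* EM3  — last k bases of the sequenced fragment,
* PREM — the k reference bases immediately upstream of the 5' end,
* POEM — the k reference bases immediately downstream of the 3' end.

For "-" fragments the definitions are applied to the reverse complement of
the reference locus, so the upstream flank of a minus-strand molecule lies
at higher genomic coordinates. Motifs overlapping a contig boundary or
containing N are "unavailable" and excluded from both the numerator and the
denominator of spectrum frequencies.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .io_core import AlignedFragment, ReferenceGenome, revcomp

logger = logging.getLogger(__name__)

MOTIF_CLASSES = ("PREM", "EM5", "EM3", "POEM")

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


def all_kmers(k: int) -> list[str]:
    """All 4**k k-mers in alphabetical order."""
    return ["".join(p) for p in itertools.product(_BASES, repeat=k)]


def kmer_to_index(kmer: str) -> int:
    idx = 0
    for c in kmer:
        idx = idx * 4 + _BASE_INDEX[c]
    return idx


@dataclass(frozen=True)
class EndMotifQuartet:
    """PREM/EM5/EM3/POEM motifs of one fragment; None marks 'unavailable'."""

    prem: str | None
    em5: str | None
    em3: str | None
    poem: str | None

    def get(self, motif_class: str) -> str | None:
        return getattr(self, motif_class.lower())


def _clean(motif: str) -> str | None:
    return motif if motif and "N" not in motif else None


def extract_end_motifs(
    fragment: AlignedFragment, genome: ReferenceGenome, k: int = 4
) -> EndMotifQuartet:
    """Extract the four end motifs of a single fragment (string-based).

    This is the definitional, per-fragment implementation; ``motif_spectrum``
    uses an equivalent vectorized path and is tested against this one.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    chrom, s, e = fragment.chrom, fragment.start, fragment.end
    length = genome.lengths[chrom]
    if s < 0 or e > length:
        raise ValueError("fragment out of genome bounds")

    if fragment.size < k:
        logger.debug("fragment shorter than k=%d; EM5/EM3 unavailable", k)
        em5_fwd = em3_fwd = None
    else:
        em5_fwd = _clean(genome.fetch(chrom, s, s + k))
        em3_fwd = _clean(genome.fetch(chrom, e - k, e))
    up = _clean(genome.fetch(chrom, s - k, s)) if s - k >= 0 else None
    down = _clean(genome.fetch(chrom, e, e + k)) if e + k <= length else None

    if fragment.strand == "+":
        return EndMotifQuartet(prem=up, em5=em5_fwd, em3=em3_fwd, poem=down)
    # minus strand: motifs live on the reverse complement of the locus
    rc = lambda m: revcomp(m) if m is not None else None
    return EndMotifQuartet(prem=rc(down), em5=rc(em3_fwd), em3=rc(em5_fwd), poem=rc(up))


@dataclass(frozen=True)
class SizeStratification:
    """Ordered, non-overlapping half-open size intervals in nt."""

    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self):
        prev_hi = None
        for lo, hi in self.intervals:
            if lo >= hi:
                raise ValueError(f"empty stratum [{lo},{hi})")
            if prev_hi is not None and lo < prev_hi:
                raise ValueError("strata overlap or are not ascending")
            prev_hi = hi

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self):
        return len(self.intervals)

    def assign(self, size: int) -> tuple[int, int] | None:
        for lo, hi in self.intervals:
            if lo <= size < hi:
                return (lo, hi)
        return None


#: short / mononucleosomal / long strata; 601 encodes the 20-600 bp retention
DEFAULT_STRATA = SizeStratification(((42, 70), (70, 166), (166, 601)))


def stratify(
    fragments: pd.DataFrame, strata: SizeStratification = DEFAULT_STRATA
) -> dict[tuple[int, int], pd.DataFrame]:
    """Assign each fragment to at most one stratum by size; the rest are
    dropped (count logged)."""
    size = fragments["end"] - fragments["start"]
    out: dict[tuple[int, int], pd.DataFrame] = {}
    assigned = pd.Series(False, index=fragments.index)
    for lo, hi in strata:
        mask = (size >= lo) & (size < hi)
        out[(lo, hi)] = fragments[mask]
        assigned |= mask
    n_dropped = int((~assigned).sum())
    if n_dropped:
        logger.info("%d fragments outside all strata dropped", n_dropped)
    return out


@dataclass
class MotifSpectrum:
    """Per-sample k-mer frequency vector for one motif class / size range."""

    motif_class: str
    k: int
    size_range: tuple[int, int] | str  # half-open (lo, hi) or "all"
    counts: np.ndarray  # length 4**k, alphabetical motif order
    n_ends: int
    sample_id: str | None = None

    @property
    def motifs(self) -> list[str]:
        return all_kmers(self.k)

    @property
    def frequencies(self) -> np.ndarray:
        if self.n_ends == 0:
            logger.warning("spectrum has zero usable ends; frequencies undefined")
            return np.full(len(self.counts), np.nan)
        return self.counts / self.n_ends

    def frequency_series(self) -> pd.Series:
        return pd.Series(self.frequencies, index=self.motifs, name=self.sample_id)

    def to_frame(self) -> pd.DataFrame:
        lo, hi = (self.size_range if self.size_range != "all" else ("all", "all"))
        return pd.DataFrame(
            {
                "motif": self.motifs,
                "count": self.counts,
                "frequency": self.frequencies,
                "motif_class": self.motif_class,
                "k": self.k,
                "size_lo": lo,
                "size_hi": hi,
                "sample_id": self.sample_id,
            }
        )


# ---------------------------------------------------------------------------
# vectorized rolling k-mer machinery

def _kmer_id_arrays(genome: ReferenceGenome, chrom: str, k: int):
    """(fwd, rc) int arrays: fwd[i] = id of genome[i:i+k], rc[i] = id of its
    reverse complement; -1 where the window contains N. Cached on the genome."""
    key = (chrom, k)
    if key in genome._kmer_cache:
        return genome._kmer_cache[key]
    seq = genome.contigs[chrom]
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    base = np.full(len(codes), -1, dtype=np.int64)
    for c, v in _BASE_INDEX.items():
        base[codes == ord(c)] = v
    n = len(base) - k + 1
    if n <= 0:
        fwd = rc = np.empty(0, dtype=np.int64)
    else:
        fwd = np.zeros(n, dtype=np.int64)
        rc = np.zeros(n, dtype=np.int64)
        valid = np.ones(n, dtype=bool)
        for j in range(k):
            b = base[j : j + n]
            valid &= b >= 0
            fwd = fwd * 4 + np.where(b >= 0, b, 0)
            rc = rc + np.where(b >= 0, 3 - b, 0) * (4 ** j)
        fwd[~valid] = -1
        rc[~valid] = -1
    genome._kmer_cache[key] = (fwd, rc)
    return fwd, rc


def _end_motif_ids(
    fragments: pd.DataFrame, genome: ReferenceGenome, motif_class: str, k: int
) -> np.ndarray:
    """Vectorized motif ids (-1 = unavailable) for one class over a table."""
    fragments = fragments.reset_index(drop=True)
    ids = np.full(len(fragments), -1, dtype=np.int64)
    for chrom, sub in fragments.groupby("chrom", sort=False):
        fwd, rc = _kmer_id_arrays(genome, chrom, k)
        n_pos = len(fwd)
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        plus = (sub["strand"] == "+").to_numpy()
        size_ok = (e - s) >= k
        # window start position on the forward strand per (class, strand)
        if motif_class == "EM5":
            pos = np.where(plus, s, e - k)
        elif motif_class == "EM3":
            pos = np.where(plus, e - k, s)
        elif motif_class == "PREM":
            pos = np.where(plus, s - k, e)
        elif motif_class == "POEM":
            pos = np.where(plus, e, s - k)
        else:
            raise ValueError(f"unknown motif class {motif_class!r}")
        ok = (pos >= 0) & (pos < n_pos)
        if motif_class in ("EM5", "EM3"):
            ok &= size_ok
        val = np.full(len(sub), -1, dtype=np.int64)
        safe = np.where(ok, pos, 0)
        val[ok & plus] = fwd[safe[ok & plus]]
        val[ok & ~plus] = rc[safe[ok & ~plus]]
        ids[sub.index.to_numpy()] = val
    return ids


def motif_spectrum(
    fragments: pd.DataFrame,
    genome: ReferenceGenome,
    motif_class: str,
    k: int = 4,
    size_range: tuple[int, int] | str = "all",
    sample_id: str | None = None,
) -> MotifSpectrum:
    """k-mer spectrum of one motif class over a fragment table.

    Only ends whose motif is available (in-bounds, N-free, fragment >= k for
    EM5/EM3) and whose fragment size falls in ``size_range`` contribute;
    frequencies are counts / n_ends over all 4**k motifs.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sub = fragments
    if size_range != "all":
        lo, hi = size_range
        size = fragments["end"] - fragments["start"]
        sub = fragments[(size >= lo) & (size < hi)]
    ids = _end_motif_ids(sub, genome, motif_class, k)
    ids = ids[ids >= 0]
    counts = np.bincount(ids, minlength=4 ** k).astype(np.int64)
    return MotifSpectrum(
        motif_class=motif_class,
        k=k,
        size_range=size_range,
        counts=counts,
        n_ends=int(counts.sum()),
        sample_id=sample_id,
    )


def motif_spectra(
    fragments: pd.DataFrame,
    genome: ReferenceGenome,
    k: int = 4,
    strata: SizeStratification | None = None,
    classes: tuple[str, ...] = MOTIF_CLASSES,
    sample_id: str | None = None,
) -> dict[tuple[str, tuple[int, int] | str], MotifSpectrum]:
    """Spectra for several classes (and optionally size strata) at once."""
    ranges = list(strata) if strata is not None else ["all"]
    return {
        (cls, rng): motif_spectrum(fragments, genome, cls, k, rng, sample_id)
        for cls in classes
        for rng in ranges
    }


def expected_genome_frequency(genome: ReferenceGenome, k: int = 4) -> np.ndarray:
    """Expected k-mer frequencies from a step-1 sliding window over both
    strands of every contig (windows containing N are skipped)."""
    counts = np.zeros(4 ** k, dtype=np.int64)
    any_window = False
    for chrom in genome.contigs:
        fwd, rc = _kmer_id_arrays(genome, chrom, k)
        if len(fwd) == 0:
            continue
        any_window = True
        counts += np.bincount(fwd[fwd >= 0], minlength=4 ** k)
        counts += np.bincount(rc[rc >= 0], minlength=4 ** k)
    if not any_window or counts.sum() == 0:
        raise ValueError("genome shorter than k (no usable windows)")
    return counts / counts.sum()


def correct_frequencies(
    observed_plasma: MotifSpectrum,
    observed_sonicated: MotifSpectrum,
    expected: np.ndarray,
    pseudocount: float = 0.5,
) -> MotifSpectrum:
    """Sonicated-DNA correction of pre-analytical end-motif bias.

    corrected_i = observed_i(plasma) / observed_i(sonicated) * expected_i,
    computed motif-wise with ``pseudocount`` added to the sonicated counts
    (to avoid division by zero), then renormalized to sum to 1. The returned
    spectrum carries the corrected frequencies scaled back to plasma n_ends
    as (non-integer) counts.
    """
    if observed_plasma.k != observed_sonicated.k or len(observed_plasma.counts) != len(
        observed_sonicated.counts
    ):
        raise ValueError("plasma and sonicated spectra have different domains")
    if len(expected) != len(observed_plasma.counts):
        raise ValueError("expected vector has wrong domain size")
    if not np.isclose(expected.sum(), 1.0, atol=1e-6):
        raise ValueError("expected vector not normalized")
    son = (observed_sonicated.counts + pseudocount) / (
        observed_sonicated.n_ends + pseudocount * len(observed_sonicated.counts)
    )
    corrected = observed_plasma.frequencies / son * expected
    corrected = corrected / corrected.sum()
    return MotifSpectrum(
        motif_class=observed_plasma.motif_class,
        k=observed_plasma.k,
        size_range=observed_plasma.size_range,
        counts=corrected * observed_plasma.n_ends,
        n_ends=observed_plasma.n_ends,
        sample_id=observed_plasma.sample_id,
    )


@dataclass
class SizeProfile:
    """Integer-resolution fragment size histogram with detected modes."""

    histogram: pd.Series  # index size (nt), value count
    modes: list[int] = field(default_factory=list)


def size_profile(fragments: pd.DataFrame, prominence: float = 0.05) -> SizeProfile:
    """Histogram of fragment sizes plus local maxima whose prominence exceeds
    ``prominence`` x max count."""
    sizes = (fragments["end"] - fragments["start"]).to_numpy()
    if len(sizes) == 0:
        logger.warning("no fragments; empty size profile")
        return SizeProfile(histogram=pd.Series(dtype=int))
    counts = np.bincount(sizes)
    hist = pd.Series(counts, index=np.arange(len(counts)))
    hist = hist[hist > 0]
    # smooth lightly so the 10-nt comb does not split the principal peaks
    dense = np.asarray(counts, dtype=float)
    kernel = np.ones(7) / 7.0
    smooth = np.convolve(dense, kernel, mode="same")
    peaks, _ = find_peaks(smooth, prominence=prominence * smooth.max())
    return SizeProfile(histogram=hist, modes=[int(p) for p in peaks])
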