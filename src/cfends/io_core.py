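"""Reference genomes, aligned fragments, cohorts, and alignment-level filters.

Coordinates are 0-based half-open (BED convention) throughout. The strand of a
fragment denotes the orientation of the sequenced single-stranded molecule:
"-" fragments are handled in their own 5'->3' frame (i.e. the reverse
complement of the reference locus) by all motif logic downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from . import __version__

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN")

#: canonical fragment-table columns; mismatches / mapq / sample_id are optional
FRAGMENT_COLUMNS = ("chrom", "start", "end", "strand")
OPTIONAL_COLUMNS = ("mismatches", "mapq", "sample_id")


def revcomp(seq: str) -> str:
    """Reverse complement of a sequence over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


class ReferenceGenome:
    """In-memory reference: contig name -> uppercase sequence over {A,C,G,T,N}.

    Non-ACGTN characters are mapped to N on construction. ``fetch`` returns
    exactly ``end - start`` characters for any in-bounds half-open interval.
    """

    def __init__(self, contigs: dict[str, str]):
        if not contigs:
            raise ValueError("reference genome has no contigs")
        cleaned: dict[str, str] = {}
        for name, seq in contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
            seq = seq.upper()
            if not set(seq) <= _VALID:
                seq = "".join(c if c in _VALID else "N" for c in seq)
            cleaned[name] = seq
        self.contigs = cleaned
        self.lengths = {name: len(seq) for name, seq in cleaned.items()}
        self._kmer_cache: dict = {}  # used by end_motifs for rolling k-mer ids

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self.contigs:
            raise KeyError(f"unknown contig {chrom!r}")
        if start < 0 or end > self.lengths[chrom] or start > end:
            raise ValueError(
                f"interval {chrom}:{start}-{end} out of bounds "
                f"(contig length {self.lengths[chrom]})"
            )
        return self.contigs[chrom][start:end]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceGenome":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        contigs: dict[str, str] = {}
        for record in SeqIO.parse(str(path), "fasta"):
            if record.id in contigs:
                raise ValueError(f"duplicate contig name {record.id!r}")
            contigs[record.id] = str(record.seq)
        if not contigs:
            raise ValueError(f"no FASTA records in {path}")
        return cls(contigs)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")


def load_reference(path: str | Path) -> ReferenceGenome:
    """Load a FASTA reference (uppercased, non-ACGTN mapped to N)."""
    return ReferenceGenome.from_fasta(path)


@dataclass(frozen=True)
class AlignedFragment:
    """One sequenced single-stranded cfDNA molecule mapped to the genome."""

    chrom: str
    start: int
    end: int
    strand: str
    sample_id: str | None = None
    mismatches: int | None = None
    mapq: int | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"start >= end ({self.start} >= {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r}")

    @property
    def size(self) -> int:
        return self.end - self.start


def load_fragments(
    path: str | Path,
    sample_id: str | None = None,
    genome: ReferenceGenome | None = None,
    one_based: bool = False,
) -> pd.DataFrame:
    """Read a fragment TSV/BED into a DataFrame (file order preserved).

    Required columns: chrom, start, end, strand. Lines starting with '#' are
    treated as headers/comments. ``one_based=True`` converts 1-based inclusive
    start coordinates to the internal 0-based half-open convention.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    columns = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#"):
                columns = line.lstrip("#").rstrip("\n").split("\t")
            break
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None, dtype={0: str})
    if columns is not None and len(columns) == df.shape[1]:
        df.columns = columns
    else:
        names = list(FRAGMENT_COLUMNS) + list(OPTIONAL_COLUMNS)
        df.columns = names[: df.shape[1]]
    for col in ("start", "end"):
        df[col] = df[col].astype(int)
    if one_based:
        df["start"] -= 1
    _validate_fragments(df, genome)
    if sample_id is not None:
        df["sample_id"] = sample_id
    return df


def _validate_fragments(df: pd.DataFrame, genome: ReferenceGenome | None = None) -> None:
    for col in FRAGMENT_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"fragment table missing column {col!r}")
    bad = df["start"] >= df["end"]
    if bad.any():
        row = df[bad].iloc[0]
        raise ValueError(f"inverted interval {row.chrom}:{row.start}-{row.end}")
    if not df["strand"].isin(["+", "-"]).all():
        bad_strand = df.loc[~df["strand"].isin(["+", "-"]), "strand"].iloc[0]
        raise ValueError(f"unknown strand symbol {bad_strand!r}")
    if genome is not None:
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in genome:
                raise ValueError(f"unknown contig {chrom!r}")
            if (sub["start"] < 0).any() or (sub["end"] > genome.lengths[chrom]).any():
                raise ValueError(f"fragment out of bounds on contig {chrom!r}")


def write_fragments(df: pd.DataFrame, path: str | Path) -> None:
    """Write a fragment table as canonical TSV (round-trips byte-identically)."""
    with open(path, "w") as fh:
        fh.write(f"## cfends {__version__}\n")
        fh.write("#" + "\t".join(df.columns) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


@dataclass
class FilterReport:
    """Per-rule counts of fragments removed by ``apply_alignment_filters``."""

    n_in: int
    n_out: int
    removed: dict[str, int] = field(default_factory=dict)

    def total_removed(self) -> int:
        return sum(self.removed.values())


def apply_alignment_filters(
    fragments: pd.DataFrame,
    min_size: int = 20,
    max_size: int = 600,
    max_mismatches: int | None = 2,
    min_mapq: int | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Retain fragments with min_size <= size <= max_size (inclusive bounds)
    and, when the columns are present, mismatches <= max_mismatches and
    mapq >= min_mapq. Filters on absent columns are skipped (logged once).

    Defaults match short-read practice (20-600 bp insert, <=2 mismatches);
    pass ``min_mapq=30`` for the duplex/long-read mode.
    """
    if min_size < 0 or max_size < 0:
        raise ValueError("size thresholds must be nonnegative")
    report = FilterReport(n_in=len(fragments), n_out=0)
    keep = pd.Series(True, index=fragments.index)
    size = fragments["end"] - fragments["start"]

    fail = keep & (size < min_size)
    report.removed["min_size"] = int(fail.sum())
    keep &= ~fail
    fail = keep & (size > max_size)
    report.removed["max_size"] = int(fail.sum())
    keep &= ~fail

    if max_mismatches is not None:
        if "mismatches" in fragments.columns:
            fail = keep & (fragments["mismatches"] > max_mismatches)
            report.removed["max_mismatches"] = int(fail.sum())
            keep &= ~fail
        else:
            logger.info("mismatches column absent; mismatch filter skipped")
    if min_mapq is not None:
        if "mapq" in fragments.columns:
            fail = keep & (fragments["mapq"] < min_mapq)
            report.removed["min_mapq"] = int(fail.sum())
            keep &= ~fail
        else:
            logger.info("mapq column absent; mapQ filter skipped")

    out = fragments[keep].copy()
    report.n_out = len(out)
    if report.n_out == 0:
        logger.warning("all %d fragments removed by filters", report.n_in)
    return out, report


@dataclass
class Cohort:
    """A two-group collection of per-sample fragment tables."""

    samples: list[tuple[str, str, pd.DataFrame]]  # (sample_id, label, fragments)

    def __post_init__(self):
        ids = [s for s, _, _ in self.samples]
        if len(ids) != len(set(ids)):
            raise ValueError("sample_ids not unique")
        for sid, label, df in self.samples:
            if label not in ("case", "control"):
                raise ValueError(f"label {label!r} for {sid!r} not in {{case, control}}")
            if len(df) == 0:
                raise ValueError(f"sample {sid!r} has no fragments")

    @property
    def sample_ids(self) -> list[str]:
        return [s for s, _, _ in self.samples]

    @property
    def labels(self) -> list[str]:
        return [l for _, l, _ in self.samples]

    def fragments(self, sample_id: str) -> pd.DataFrame:
        for sid, _, df in self.samples:
            if sid == sample_id:
                return df
        raise KeyError(sample_id)

    def subset_fragments(self, fn) -> "Cohort":
        """New cohort with ``fn`` applied to each sample's fragment table."""
        return Cohort([(s, l, fn(df)) for s, l, df in self.samples])
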