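"""Cleavage-proportion profiling around CpG sites (FRAGMA).

The cleavage proportion at a genomic site i is the number of fragment ends
(5' or 3', in each molecule's own orientation) terminating exactly at i,
divided by the sequencing depth at i, times 100. A cleavage profile collects
the mean per-position proportion across a set of CpG sites within a window
of +-5 nt around the CpG; position 0 anchors on the Watson-strand C.

Because CpG methylation is usually symmetric, Watson- and Crick-strand
fragments are merged in the 5'->3' direction: a minus-strand fragment
contributes at the mirrored relative position of the symmetric CpG frame
(anchor = the G at pos+1, orientation flipped).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import ReferenceGenome

logger = logging.getLogger(__name__)

CPG_CATEGORIES = (
    "tissue_hyper",
    "tissue_hypo",
    "hcc_specific_hyper",
    "hcc_specific_hypo",
)

END_TYPES = ("5p", "3p")


@dataclass(frozen=True)
class TissueConfig:
    """Which methylation-table columns play which role.

    ``tissues`` are all columns used for the tissue-wide hyper/hypo rules
    (normal and tumoral); ``tumor`` and ``buffy`` name the columns used for
    the tumor-specific rules.
    """

    tissues: tuple[str, ...]
    tumor: str = "hcc_tumor"
    buffy: str = "buffy_coat"


def classify_cpgs(cpg_table: pd.DataFrame, config: TissueConfig) -> pd.Series:
    """Label CpG sites from per-tissue methylation densities (% in [0,100]).

    tissue_hyper: density > 70 in all configured tissues; tissue_hypo: < 30
    in all. hcc_specific_hyper: tumor > 70 and buffy coat < 30;
    hcc_specific_hypo: tumor < 30 and buffy coat > 70. Tumor-specific labels
    take precedence when both apply; everything else is "unclassified".
    """
    for col in set(config.tissues) | {config.tumor, config.buffy}:
        if col not in cpg_table.columns:
            raise ValueError(f"missing tissue column {col!r}")
    dens = cpg_table[list(config.tissues)]
    tumor = cpg_table[config.tumor]
    buffy = cpg_table[config.buffy]

    labels = pd.Series("unclassified", index=cpg_table.index, dtype=object)
    labels[(dens > 70).all(axis=1)] = "tissue_hyper"
    labels[(dens < 30).all(axis=1)] = "tissue_hypo"
    labels[(tumor > 70) & (buffy < 30)] = "hcc_specific_hyper"
    labels[(tumor < 30) & (buffy > 70)] = "hcc_specific_hypo"
    return labels


def validate_cpg_sites(cpg_table: pd.DataFrame, genome: ReferenceGenome) -> None:
    """Check that every (chrom, pos) is the C of a Watson-strand CpG."""
    for chrom, sub in cpg_table.groupby("chrom", sort=False):
        seq = genome.contigs[chrom]
        for pos in sub["pos"]:
            if seq[pos : pos + 2] != "CG":
                raise ValueError(f"{chrom}:{pos} is not a CpG (found {seq[pos:pos+2]!r})")


class _EndIndex:
    """Sorted per-(chrom, strand) arrays for fast depth / end-at-site queries."""

    def __init__(self, fragments: pd.DataFrame):
        self._by_key: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        for (chrom, strand), sub in fragments.groupby(["chrom", "strand"], sort=False):
            starts = np.sort(sub["start"].to_numpy())
            ends = np.sort(sub["end"].to_numpy())
            self._by_key[(chrom, strand)] = (starts, ends)

    def depth(self, chrom: str, strand: str, site: int) -> int:
        if (chrom, strand) not in self._by_key:
            return 0
        starts, ends = self._by_key[(chrom, strand)]
        return int(
            np.searchsorted(starts, site, "right") - np.searchsorted(ends, site, "right")
        )

    def ends_at(self, chrom: str, strand: str, site: int, end_type: str) -> int:
        """Fragment ends of the given type terminating at genomic site."""
        if (chrom, strand) not in self._by_key:
            return 0
        starts, ends = self._by_key[(chrom, strand)]
        # 5' terminal base: start (+) / end-1 (-); 3' terminal: end-1 (+) / start (-)
        if (end_type == "5p") == (strand == "+"):
            arr, val = starts, site
        else:
            arr, val = ends, site + 1
        return int(np.searchsorted(arr, val, "right") - np.searchsorted(arr, val, "left"))


def cleavage_proportion(
    fragments: pd.DataFrame, chrom: str, site: int, end_type: str
) -> float | None:
    """Cleavage proportion (%) at one genomic site, both strands pooled.

    Returns None (site excluded) when depth is 0.
    """
    if end_type not in END_TYPES:
        raise ValueError(f"end_type must be one of {END_TYPES}")
    index = _EndIndex(fragments)
    depth = index.depth(chrom, "+", site) + index.depth(chrom, "-", site)
    if depth == 0:
        logger.debug("no coverage at %s:%d; site excluded", chrom, site)
        return None
    ends = index.ends_at(chrom, "+", site, end_type) + index.ends_at(
        chrom, "-", site, end_type
    )
    return 100.0 * ends / depth


@dataclass
class CleavageProfile:
    """Mean cleavage proportions at relative positions around a CpG set."""

    end_type: str
    positions: np.ndarray  # -window .. +window, 0 = the Watson C
    mean_proportion: np.ndarray  # % in [0, 100]
    n_sites: np.ndarray  # CpGs contributing per position

    def as_series(self) -> pd.Series:
        return pd.Series(self.mean_proportion, index=self.positions)


def cleavage_profile(
    fragments: pd.DataFrame,
    cpg_sites: pd.DataFrame,
    end_type: str,
    window: int = 5,
    min_depth: int = 1,
    pooled: bool = False,
) -> CleavageProfile:
    """Windowed cleavage profile around a CpG set, strands merged 5'->3'.

    For a CpG with Watson C at p, a plus-strand fragment end at genomic site
    i contributes at relative position i - p; a minus-strand end at i
    contributes at (p + 1) - i (the symmetric frame anchored on the G). By
    default per-site proportions are averaged unweighted across CpGs (robust
    to coverage heterogeneity); ``pooled=True`` pools counts instead.
    """
    if end_type not in END_TYPES:
        raise ValueError(f"end_type must be one of {END_TYPES}")
    if len(cpg_sites) == 0:
        raise ValueError("empty CpG set")
    index = _EndIndex(fragments)
    positions = np.arange(-window, window + 1)
    sum_prop = np.zeros(len(positions))
    n_sites = np.zeros(len(positions), dtype=int)
    pooled_ends = np.zeros(len(positions))
    pooled_depth = np.zeros(len(positions))
    any_cov = False

    for chrom, p in zip(cpg_sites["chrom"], cpg_sites["pos"]):
        for j, d in enumerate(positions):
            site_plus = p + d
            site_minus = (p + 1) - d
            depth = index.depth(chrom, "+", site_plus) + index.depth(
                chrom, "-", site_minus
            )
            if depth < min_depth or depth == 0:
                continue
            ends = index.ends_at(chrom, "+", site_plus, end_type) + index.ends_at(
                chrom, "-", site_minus, end_type
            )
            any_cov = True
            sum_prop[j] += 100.0 * ends / depth
            n_sites[j] += 1
            pooled_ends[j] += ends
            pooled_depth[j] += depth

    if not any_cov:
        raise ValueError("no coverage at any CpG site")
    if pooled:
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(pooled_depth > 0, 100.0 * pooled_ends / pooled_depth, np.nan)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(n_sites > 0, sum_prop / np.maximum(n_sites, 1), np.nan)
    return CleavageProfile(
        end_type=end_type, positions=positions, mean_proportion=mean, n_sites=n_sites
    )


def fragma_features(
    fragments: pd.DataFrame,
    cpg_table: pd.DataFrame,
    labels: pd.Series,
    end_type: str,
    window: int = 5,
    min_depth: int = 1,
) -> pd.Series:
    """FRAGMA feature vector: the 4 CpG-category profiles concatenated.

    Deterministic ordering: category (tissue_hyper, tissue_hypo,
    hcc_specific_hyper, hcc_specific_hypo), then position ascending;
    4 x (2*window+1) features (44 for the default window of 5).
    """
    values: list[float] = []
    names: list[str] = []
    for category in CPG_CATEGORIES:
        sites = cpg_table[labels == category]
        if len(sites) == 0:
            raise ValueError(f"CpG category {category!r} is empty")
        profile = cleavage_profile(
            fragments, sites, end_type, window=window, min_depth=min_depth
        )
        filled = np.nan_to_num(profile.mean_proportion, nan=0.0)
        values.extend(filled)
        names.extend(f"fragma_{end_type}_{category}_{d:+d}" for d in profile.positions)
    return pd.Series(values, index=names)
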