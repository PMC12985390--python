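"""Synthetic cfDNA data with the statistical structure the analyses assume.

The generator emulates, at desk scale, the salient features of plasma cfDNA
sequenced with single-stranded library preparation:

* a bimodal fragment-size mixture with peaks near 52 and 166 nt and a mild
  10-nt comb on the short component;
* motif-biased cleavage: cut positions are accepted in proportion to
  configurable 4-mer context weights at both fragment ends (the 5'-side
  weight reads the upstream/PREM frame, the 3'-side weight the
  downstream/POEM frame, each in the molecule's own orientation);
* a two-group cohort contrast: the case group re-weights the size mixture
  per stratum (fewer short fragments, slightly more mononucleosomal, fewer
  long) and multiplies selected end-motif context weights;
* methylation-dependent cleavage: a fraction of fragments is re-anchored at
  hypermethylated CpGs with the 5' terminal base exactly at the C and the
  3' terminal base 1 nt before the CpG, with tumor-specific sites further
  enriched in cases;
* duplex molecules with jagged ends (blunt / 5' / 3' overhangs, lengths
  1..20) whose terminal dinucleotides follow nuclease cutting signatures
  with size-dependent activities;
* a sonicated control with uniform, motif-blind cut positions.

All randomness flows from a single seed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .end_motifs import DEFAULT_STRATA, _kmer_id_arrays
from .four_end import (
    MAX_OVERHANG,
    NUCLEASE_SIGNATURES,
    DsMolecule,
    ReadRecord,
    build_adapter_pool,
    encode_molecule,
)
from .fragma import TissueConfig
from .io_core import Cohort, ReferenceGenome, revcomp

logger = logging.getLogger(__name__)

_EDGE = 8  # bp kept clear of contig boundaries so flanking motifs exist


@dataclass(frozen=True)
class JaggedMixture:
    """Per-side end-geometry mixture for duplex molecules."""

    p_blunt: float = 0.25
    p_five: float = 0.35
    p_three: float = 0.40
    geom_p: float = 0.35  # truncated geometric length distribution on 1..20

    def __post_init__(self):
        total = self.p_blunt + self.p_five + self.p_three
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("jagged mixture probabilities must sum to 1")

    def length_pmf(self) -> np.ndarray:
        k = np.arange(1, MAX_OVERHANG + 1)
        pmf = self.geom_p * (1 - self.geom_p) ** (k - 1)
        return pmf / pmf.sum()


#: default case-vs-control multiplicative shifts on 5'-side (PREM-frame)
#: context weights, echoing the directions reported for liver cancer plasma
DEFAULT_GROUP_EFFECT5 = {
    "TATA": 1.8,
    "CATA": 1.6,
    "TAAA": 1.6,
    "CTAA": 1.5,
    "TATC": 1.5,
    "CGCG": 0.5,
    "CCGT": 0.6,
    "CCCG": 0.6,
    "CCGC": 0.6,
    "CGGT": 0.6,
}


@dataclass
class SimulationConfig:
    """Parameters of the single-strand cohort simulator.

    Sizes are nt; weights are dimensionless multipliers (1 = neutral).
    """

    seed: int = 0
    genome_length: int = 200_000
    gc_fraction: float = 0.42
    # bimodal size mixture (short, mononucleosomal)
    size_weights: tuple[float, float] = (0.30, 0.70)
    size_means: tuple[float, float] = (52.0, 166.0)
    size_sds: tuple[float, float] = (9.0, 22.0)
    comb_amplitude: float = 0.2  # 10-nt periodic modulation of the short mode
    comb_period: float = 10.0
    size_min: int = 20
    size_max: int = 600
    # biological motif-biased cleavage (both groups)
    cut_bias5: dict = field(default_factory=dict)  # 4-mer -> weight, PREM frame
    cut_bias3: dict = field(default_factory=dict)  # 4-mer -> weight, POEM frame
    # pre-analytical (library/protocol) end bias, shared by plasma AND the
    # sonicated control; the correction stage is designed to cancel it
    protocol_bias5: dict = field(default_factory=dict)
    protocol_bias3: dict = field(default_factory=dict)
    # case-only multiplicative shifts
    group_effect5: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_EFFECT5))
    group_effect3: dict = field(default_factory=dict)
    case_size_multipliers: tuple[float, float, float] = (0.75, 1.05, 0.90)
    # methylation-dependent cleavage offsets: 5' at 0, 3' at -1
    methyl_anchor_prob: float = 0.12
    case_hcc_methyl_boost: float = 2.0
    # cohort shape
    n_fragments: int = 50_000
    n_case: int = 20
    n_control: int = 20

    def __post_init__(self):
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must be in (0, 1)")
        if any(w <= 0 for w in self.size_weights):
            raise ValueError("size mixture weights must be positive")
        if min(self.case_size_multipliers) <= 0:
            raise ValueError("case size multipliers must be positive")

    def manifest(self) -> dict:
        return asdict(self)


def write_manifest(config, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(config.manifest(), fh, indent=2, default=str)


def simulate_reference(config: SimulationConfig) -> ReferenceGenome:
    """I.i.d. reference sequence at the requested GC content (one contig)."""
    if config.genome_length < 10_000:
        raise ValueError("genome_length must be >= 10 kb for cohort simulations")
    rng = np.random.default_rng(config.seed)
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=config.genome_length, p=probs)
    return ReferenceGenome({"sim1": bases.tobytes().decode()})


def simulate_methylome(
    genome: ReferenceGenome,
    seed: int = 0,
    tissue_config: TissueConfig | None = None,
    proportions: dict[str, float] | None = None,
    max_sites: int | None = 2000,
) -> tuple[pd.DataFrame, TissueConfig]:
    """Per-tissue methylation densities (%) at the genome's CpG sites.

    Categories are populated by construction: tissue-wide hyper sites draw
    >70% in every column, tissue-wide hypo <30% in every column;
    tumor-specific hyper/hypo sites mix a >70/<30 tumor-vs-buffy contrast
    with intermediate densities elsewhere; the remainder is intermediate
    everywhere. ``classify_cpgs`` on the output reproduces the generating
    labels exactly.
    """
    tissue_config = tissue_config or TissueConfig(
        tissues=("buffy_coat", "liver", "colon", "hcc_tumor"),
        tumor="hcc_tumor",
        buffy="buffy_coat",
    )
    proportions = proportions or {
        "tissue_hyper": 0.20,
        "tissue_hypo": 0.20,
        "hcc_specific_hyper": 0.15,
        "hcc_specific_hypo": 0.15,
        "unclassified": 0.30,
    }
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, seq in genome.contigs.items():
        pos = 0
        while True:
            pos = seq.find("CG", pos)
            if pos == -1:
                break
            if _EDGE <= pos < len(seq) - _EDGE:
                rows.append((chrom, pos))
            pos += 2
    if len(rows) < 100:
        raise ValueError("too few CpGs in genome")
    if max_sites is not None and len(rows) > max_sites:
        idx = np.sort(rng.choice(len(rows), max_sites, replace=False))
        rows = [rows[i] for i in idx]

    categories = list(proportions)
    draw = rng.choice(len(categories), size=len(rows), p=list(proportions.values()))
    hi = lambda n: rng.uniform(75, 95, n)
    lo = lambda n: rng.uniform(5, 25, n)
    mid = lambda n: rng.uniform(35, 65, n)

    columns = list(dict.fromkeys(tissue_config.tissues + (tissue_config.tumor, tissue_config.buffy)))
    table = pd.DataFrame(rows, columns=["chrom", "pos"])
    n = len(table)
    dens = {c: mid(n) for c in columns}
    for i, cat in enumerate(categories):
        mask = draw == i
        m = int(mask.sum())
        if cat == "tissue_hyper":
            for c in columns:
                dens[c][mask] = hi(m)
        elif cat == "tissue_hypo":
            for c in columns:
                dens[c][mask] = lo(m)
        elif cat == "hcc_specific_hyper":
            dens[tissue_config.tumor][mask] = hi(m)
            dens[tissue_config.buffy][mask] = lo(m)
        elif cat == "hcc_specific_hypo":
            dens[tissue_config.tumor][mask] = lo(m)
            dens[tissue_config.buffy][mask] = hi(m)
    for c in columns:
        table[c] = dens[c]
    return table, tissue_config


# ---------------------------------------------------------------------------
# single-strand fragment cohorts

def _weight_lut(k: int, *bias_maps: dict[str, float] | None) -> np.ndarray:
    from .end_motifs import kmer_to_index

    lut = np.ones(4 ** k)
    for bias in bias_maps:
        if bias:
            for motif, w in bias.items():
                lut[kmer_to_index(motif)] *= w
    return lut


class _CutModel:
    """Per-position end-context weights for one genome/group combination.

    ``biology=False`` keeps only the protocol (pre-analytical) bias, which is
    what the sonicated control experiences.
    """

    def __init__(
        self,
        genome: ReferenceGenome,
        config: SimulationConfig,
        is_case: bool,
        biology: bool = True,
    ):
        self.genome = genome
        chrom = next(iter(genome.contigs))
        self.chrom = chrom
        fwd, rc = _kmer_id_arrays(genome, chrom, 4)
        lut5 = _weight_lut(
            4,
            config.protocol_bias5,
            config.cut_bias5 if biology else None,
            config.group_effect5 if (biology and is_case) else None,
        )
        lut3 = _weight_lut(
            4,
            config.protocol_bias3,
            config.cut_bias3 if biology else None,
            config.group_effect3 if (biology and is_case) else None,
        )
        L = genome.lengths[chrom]
        n = len(fwd)

        def lookup(lut, ids):
            w = np.zeros(len(ids))
            ok = ids >= 0
            w[ok] = lut[ids[ok]]
            return w

        # plus strand: 5' context = upstream 4-mer at s-4; 3' context = downstream at e
        self.w5_plus = np.zeros(L + 1)
        self.w5_plus[4 : 4 + n] = lookup(lut5, fwd)
        self.w3_plus = np.zeros(L + 1)
        self.w3_plus[:n] = lookup(lut3, fwd)
        # minus strand: 5' context = revcomp of downstream 4-mer at e; 3' = revcomp upstream
        self.w5_minus = np.zeros(L + 1)
        self.w5_minus[:n] = lookup(lut5, rc)
        self.w3_minus = np.zeros(L + 1)
        self.w3_minus[4 : 4 + n] = lookup(lut3, rc)
        self.wmax = max(
            self.w5_plus.max() * self.w3_plus.max(),
            self.w5_minus.max() * self.w3_minus.max(),
        )
        if self.wmax <= 0:
            raise ValueError("cut bias weights are all zero")

    def accept_prob(self, starts, ends, plus_mask):
        w = np.where(
            plus_mask,
            self.w5_plus[starts] * self.w3_plus[ends],
            self.w5_minus[ends] * self.w3_minus[starts],
        )
        return w / self.wmax


def _stratum_multiplier(sizes: np.ndarray, multipliers: tuple[float, float, float]) -> np.ndarray:
    out = np.ones(len(sizes))
    for (lo, hi), m in zip(DEFAULT_STRATA, multipliers):
        out[(sizes >= lo) & (sizes < hi)] = m
    return out


def _draw_sizes(rng, config: SimulationConfig, n: int, is_case: bool) -> np.ndarray:
    """Mixture sizes with the 10-nt comb and (for cases) stratum re-weighting."""
    out = np.empty(0, dtype=np.int64)
    w = np.asarray(config.size_weights, dtype=float)
    w = w / w.sum()
    mmax = max(config.case_size_multipliers) if is_case else 1.0
    while len(out) < n:
        batch = 2 * (n - len(out)) + 256
        comp = rng.choice(len(w), size=batch, p=w)
        sizes = np.rint(
            rng.normal(np.take(config.size_means, comp), np.take(config.size_sds, comp))
        ).astype(np.int64)
        keep = (sizes >= config.size_min) & (sizes <= config.size_max)
        # cosine comb on the short component only
        short = comp == 0
        if config.comb_amplitude > 0:
            phase = 2 * np.pi * (sizes - config.size_means[0]) / config.comb_period
            comb_p = (1 + config.comb_amplitude * np.cos(phase)) / (1 + config.comb_amplitude)
            keep &= ~short | (rng.random(batch) < comb_p)
        if is_case:
            mult = _stratum_multiplier(sizes, config.case_size_multipliers)
            keep &= rng.random(batch) < mult / mmax
        out = np.concatenate([out, sizes[keep]])
    return out[:n]


def _anchor_fragments(
    rng,
    starts: np.ndarray,
    ends: np.ndarray,
    strands: np.ndarray,
    config: SimulationConfig,
    methylome: pd.DataFrame | None,
    labels: pd.Series | None,
    is_case: bool,
    genome_length: int,
) -> None:
    """Re-anchor a random subset of fragments at hypermethylated CpGs
    (in place): 5' terminal base at the C (offset 0) or 3' terminal base
    1 nt before the CpG (offset -1), in the molecule's orientation."""
    if methylome is None or config.methyl_anchor_prob <= 0:
        return
    hyper = methylome[labels.isin(["tissue_hyper", "hcc_specific_hyper"])]
    if len(hyper) == 0:
        return
    site_pos = hyper["pos"].to_numpy()
    weights = np.ones(len(hyper))
    if is_case and config.case_hcc_methyl_boost != 1.0:
        weights[(labels[labels.isin(["tissue_hyper", "hcc_specific_hyper"])] == "hcc_specific_hyper").to_numpy()] = config.case_hcc_methyl_boost
    weights = weights / weights.sum()

    n = len(starts)
    chosen = np.where(rng.random(n) < config.methyl_anchor_prob)[0]
    for i in chosen:
        p = int(site_pos[rng.choice(len(site_pos), p=weights)])
        size = ends[i] - starts[i]
        plus = strands[i] == "+"
        five_end = rng.random() < 0.5
        if plus and five_end:
            s, e = p, p + size
        elif plus:
            e = p  # 3' terminal base at p-1
            s = e - size
        elif five_end:
            e = p + 2  # 5' terminal base at p+1 (symmetric frame offset 0)
            s = e - size
        else:
            s = p + 2  # 3' terminal base at p+2 (symmetric frame offset -1)
            e = s + size
        if s >= _EDGE and e <= genome_length - _EDGE:
            starts[i], ends[i] = s, e


def _simulate_sample(
    rng,
    genome: ReferenceGenome,
    config: SimulationConfig,
    cut_model: _CutModel,
    methylome: pd.DataFrame | None,
    labels: pd.Series | None,
    is_case: bool,
) -> pd.DataFrame:
    chrom = cut_model.chrom
    L = genome.lengths[chrom]
    n = config.n_fragments
    starts_list, ends_list, strand_list = [], [], []
    got = 0
    while got < n:
        batch = 2 * (n - got) + 512
        sizes = _draw_sizes(rng, config, batch, is_case)
        starts = rng.integers(_EDGE, L - sizes - _EDGE)
        ends = starts + sizes
        plus = rng.random(batch) < 0.5
        accept = rng.random(batch) < cut_model.accept_prob(starts, ends, plus)
        starts_list.append(starts[accept])
        ends_list.append(ends[accept])
        strand_list.append(plus[accept])
        got += int(accept.sum())
    starts = np.concatenate(starts_list)[:n]
    ends = np.concatenate(ends_list)[:n]
    strands = np.where(np.concatenate(strand_list)[:n], "+", "-")
    _anchor_fragments(rng, starts, ends, strands, config, methylome, labels, is_case, L)
    return pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": ends, "strand": strands}
    )


def simulate_cohort(
    genome: ReferenceGenome,
    methylome: pd.DataFrame | None,
    config: SimulationConfig,
    cpg_labels: pd.Series | None = None,
) -> Cohort:
    """Two-group cohort of per-sample fragment tables (deterministic in seed)."""
    if methylome is not None and cpg_labels is None:
        from .fragma import classify_cpgs

        cpg_labels = classify_cpgs(
            methylome,
            TissueConfig(
                tissues=tuple(c for c in methylome.columns if c not in ("chrom", "pos")),
            ),
        )
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_case + config.n_control)
    cut_case = _CutModel(genome, config, is_case=True)
    cut_ctrl = _CutModel(genome, config, is_case=False)
    samples = []
    for i in range(config.n_case):
        rng = np.random.default_rng(seeds[i])
        df = _simulate_sample(rng, genome, config, cut_case, methylome, cpg_labels, True)
        samples.append((f"case_{i+1:02d}", "case", df))
    for i in range(config.n_control):
        rng = np.random.default_rng(seeds[config.n_case + i])
        df = _simulate_sample(rng, genome, config, cut_ctrl, methylome, cpg_labels, False)
        samples.append((f"control_{i+1:02d}", "control", df))
    return Cohort(samples)


def simulate_sonicated(
    genome: ReferenceGenome,
    n: int,
    seed: int = 0,
    config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Sonicated control: uniform random cut positions with no biological
    motif bias. Without a configured protocol bias its spectrum converges to
    the genome's expected k-mer frequencies; with one, it carries exactly
    the shared pre-analytical bias that the correction stage cancels."""
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    chrom = next(iter(genome.contigs))
    L = genome.lengths[chrom]
    if not config.protocol_bias5 and not config.protocol_bias3:
        sizes = _draw_sizes(rng, config, n, is_case=False)
        starts = rng.integers(_EDGE, L - sizes - _EDGE)
        strands = np.where(rng.random(n) < 0.5, "+", "-")
        return pd.DataFrame(
            {"chrom": chrom, "start": starts, "end": starts + sizes, "strand": strands}
        )
    cut_model = _CutModel(genome, config, is_case=False, biology=False)
    protocol_cfg = SimulationConfig(**{**config.manifest(), "n_fragments": n})
    return _simulate_sample(rng, genome, protocol_cfg, cut_model, None, None, False)


# ---------------------------------------------------------------------------
# duplex (4-end) molecules

@dataclass
class NucleaseModel:
    """Size-dependent nuclease activities over the shipped 2-mer signatures.

    ``activities`` maps nuclease -> [(size_upper_bound, weight), ...]; the
    weight for a molecule is the first entry whose bound exceeds its size.
    ``background`` is the weight of an unconstrained (signature-free) cut.
    """

    activities: dict[str, list[tuple[float, float]]] = field(
        default_factory=lambda: {
            "DNASE1": [(130, 2.0), (math.inf, 0.4)],
            "DNASE1L3": [(130, 1.5), (600, 2.5), (math.inf, 1.5)],
            "DFFB": [(130, 0.3), (600, 0.8), (math.inf, 2.5)],
        }
    )
    background: float = 0.5
    signatures: dict = field(default_factory=lambda: dict(NUCLEASE_SIGNATURES))

    def __post_init__(self):
        if not self.activities:
            raise ValueError("at least one nuclease must be active")

    def side_weights(self, size: int) -> tuple[list[str], np.ndarray]:
        names = list(self.activities)
        w = []
        for n in names:
            for bound, weight in self.activities[n]:
                if size < bound:
                    w.append(weight)
                    break
        names.append(None)  # background
        w.append(self.background)
        w = np.asarray(w, dtype=float)
        return names, w / w.sum()


@dataclass
class DuplexSimConfig:
    """Parameters of the duplex-molecule simulator (sizes in bp)."""

    seed: int = 0
    n_molecules: int = 5000
    size_weights: tuple[float, float] = (0.85, 0.15)
    size_means: tuple[float, float] = (167.0, 450.0)
    size_sds: tuple[float, float] = (25.0, 170.0)
    size_min: int = 20
    size_max: int = 1000
    jagged: JaggedMixture = field(default_factory=JaggedMixture)
    comb_amplitude: float = 0.0
    comb_period: float = 10.0
    case_size_multipliers: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def manifest(self) -> dict:
        return asdict(self)


@dataclass
class DuplexSimResult:
    molecules: list[DsMolecule]
    records: list[ReadRecord]
    n_unligatable: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (m.chrom, m.w_start, m.w_end, m.c_start, m.c_end)
                for m in self.molecules
            ],
            columns=["chrom", "w_start", "w_end", "c_start", "c_end"],
        )


def _dimer_match_positions(genome: ReferenceGenome, chrom: str, dimers: frozenset[str], frame: str):
    """Sorted positions i where the 2-mer context matches.

    frame "fwd": genome[i:i+2] in dimers; frame "rc": revcomp(genome[i:i+2])
    in dimers.
    """
    seq = genome.contigs[chrom]
    if frame == "rc":
        dimers = frozenset(revcomp(d) for d in dimers)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    mask = np.zeros(len(seq) - 1, dtype=bool)
    for d in dimers:
        mask |= (arr[:-1] == ord(d[0])) & (arr[1:] == ord(d[1]))
    return np.where(mask)[0], mask


def simulate_ds_molecules(
    genome: ReferenceGenome,
    config: DuplexSimConfig,
    nuclease_model: NucleaseModel | None = None,
) -> DuplexSimResult:
    """Duplex molecules with jagged ends and nuclease-signature termini.

    For each side a nuclease (or background) is drawn from the
    size-dependent activities. A nuclease-constrained left side places the
    Watson 5' end at a position whose leading 2-mer matches the nuclease's
    5' signature and picks a Crick offset whose 3' 2-mer matches its 3'
    signature (offsets weighted by the jagged mixture); right sides are
    symmetric with the roles of the strands swapped. Records are encoded
    with the 41-adapter pool; molecules with overhangs beyond the pool's
    support are counted as unligatable.
    """
    model = nuclease_model or NucleaseModel()
    rng = np.random.default_rng(config.seed)
    chrom = next(iter(genome.contigs))
    L = genome.lengths[chrom]
    pool = build_adapter_pool()

    # per-nuclease context masks
    pos5_w: dict[str, np.ndarray] = {}
    mask3_c: dict[str, np.ndarray] = {}
    mask3_w: dict[str, np.ndarray] = {}
    mask5_c: dict[str, np.ndarray] = {}
    for name, sig in model.signatures.items():
        pos5_w[name], _ = _dimer_match_positions(genome, chrom, sig["5p"], "fwd")
        _, mask3_c[name] = _dimer_match_positions(genome, chrom, sig["3p"], "rc")
        _, mask3_w[name] = _dimer_match_positions(genome, chrom, sig["3p"], "fwd")
        _, mask5_c[name] = _dimer_match_positions(genome, chrom, sig["5p"], "rc")

    jag = config.jagged
    len_pmf = jag.length_pmf()
    offsets = np.arange(-MAX_OVERHANG, MAX_OVERHANG + 1)
    # prior weight of each Crick offset under the jagged mixture; on both
    # sides a positive offset is a 5' overhang (Watson 5' at the left side,
    # Crick 5' at the right side) and a negative one a 3' overhang
    prior = np.zeros(len(offsets))
    for j, d in enumerate(offsets):
        if d == 0:
            prior[j] = jag.p_blunt
        elif d > 0:
            prior[j] = jag.p_five * len_pmf[d - 1]
        else:
            prior[j] = jag.p_three * len_pmf[-d - 1]
    left_prior = right_prior = prior

    size_cfg = SimulationConfig(
        seed=config.seed,
        size_weights=config.size_weights,
        size_means=config.size_means,
        size_sds=config.size_sds,
        size_min=config.size_min,
        size_max=config.size_max,
        comb_amplitude=config.comb_amplitude,
        comb_period=config.comb_period,
        case_size_multipliers=config.case_size_multipliers,
    )
    sizes = _draw_sizes(rng, size_cfg, config.n_molecules, is_case=False)

    margin = MAX_OVERHANG + _EDGE
    molecules: list[DsMolecule] = []
    records: list[ReadRecord] = []
    n_unligatable = 0
    for size in sizes:
        size = int(size)
        names, w = model.side_weights(size)
        left_nuc = names[rng.choice(len(names), p=w)]
        right_nuc = names[rng.choice(len(names), p=w)]

        # Watson placement, optionally constrained by the left 5' signature
        lo, hi = margin, L - size - margin
        if left_nuc is not None:
            pos = pos5_w[left_nuc]
            a, b = np.searchsorted(pos, lo), np.searchsorted(pos, hi)
            w_start = int(pos[rng.integers(a, b)]) if b > a else int(rng.integers(lo, hi))
        else:
            w_start = int(rng.integers(lo, hi))
        w_end = w_start + size
        if right_nuc is not None:
            # shift the Watson 3' end to the nearest matching 3' context
            window = np.arange(max(w_start + 10, w_end - 12), min(L - margin, w_end + 12))
            cand = window[mask3_w[right_nuc][window - 2]]
            if len(cand):
                w_end = int(cand[np.argmin(np.abs(cand - w_end))])

        # Crick offsets
        def pick_offset(prior, match_mask, anchor, left_side: bool):
            pri = prior.copy()
            if match_mask is not None:
                for j, d in enumerate(offsets):
                    i = anchor + d
                    ctx = i if left_side else i - 2
                    if not (0 <= ctx < len(match_mask)) or not match_mask[ctx]:
                        pri[j] = 0.0
            if pri.sum() == 0:
                pri = prior
            pri = pri / pri.sum()
            return int(offsets[rng.choice(len(offsets), p=pri)])

        d_left = pick_offset(
            left_prior, mask3_c[left_nuc] if left_nuc else None, w_start, True
        )
        d_right = pick_offset(
            right_prior, mask5_c[right_nuc] if right_nuc else None, w_end, False
        )
        c_start = w_start + d_left
        c_end = w_end + d_right
        if c_start >= c_end or c_end <= w_start or w_end <= c_start:
            c_start, c_end = w_start, w_end  # degenerate geometry -> blunt
        mol = DsMolecule(chrom, w_start, w_end, c_start, c_end)
        molecules.append(mol)
        rec = encode_molecule(mol, genome, pool)
        if rec is None:
            n_unligatable += 1
        else:
            records.append(rec)
    return DuplexSimResult(molecules=molecules, records=records, n_unligatable=n_unligatable)
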