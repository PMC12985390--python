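"""Differential end motifs, the end-motif ratio (EMR), Z-score normalization
and inter-class spectrum correlations.

Group comparison is motif-wise: a two-sided Wilcoxon rank-sum test on
per-sample motif frequencies (exact p for group sizes <= 10 without ties,
normal approximation with continuity correction otherwise; ties mid-ranked),
with Benjamini-Hochberg adjustment across all 4**k motifs of one class.
Fold change is the ratio of group medians; motifs with adjusted q < alpha are
called increased (fold change > 1) or decreased (fold change < 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .end_motifs import MotifSpectrum

logger = logging.getLogger(__name__)


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact when both groups have n <= 10 and there are no cross-group ties;
    otherwise a normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= 10 and len(y) <= 10 and not has_ties) else "asymptotic"
    if len(x) == len(y) and np.array_equal(np.sort(x), np.sort(y)):
        return 1.0  # identical groups: no evidence against the null
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (q-values)."""
    return multipletests(pvalues, method="fdr_bh")[1]


def _frequency_matrix(spectra: list[MotifSpectrum]) -> pd.DataFrame:
    """motifs x samples frequency matrix from same-class/k/stratum spectra."""
    first = spectra[0]
    for s in spectra[1:]:
        if (s.motif_class, s.k, s.size_range) != (
            first.motif_class,
            first.k,
            first.size_range,
        ):
            raise ValueError("spectra differ in motif class, k, or size range")
    cols = {
        s.sample_id if s.sample_id is not None else i: s.frequencies
        for i, s in enumerate(spectra)
    }
    return pd.DataFrame(cols, index=first.motifs)


def differential_motifs(
    case_spectra: list[MotifSpectrum],
    control_spectra: list[MotifSpectrum],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-motif differential table between case and control spectra.

    Columns: motif_class, motif, median_case, median_control, fold_change,
    rel_pct_change, p, q, direction. When a group median is 0 the fold change
    uses a pseudo-frequency of 1/(2 * median n_ends) of that group.
    """
    if len(case_spectra) < 2 or len(control_spectra) < 2:
        raise ValueError("need >= 2 samples per group")
    case = _frequency_matrix(case_spectra)
    control = _frequency_matrix(control_spectra)
    if not case.index.equals(control.index):
        raise ValueError("mismatched motif domains")

    med_case = case.median(axis=1).to_numpy()
    med_ctrl = control.median(axis=1).to_numpy()
    pseudo_case = 1.0 / (2.0 * np.median([s.n_ends for s in case_spectra]))
    pseudo_ctrl = 1.0 / (2.0 * np.median([s.n_ends for s in control_spectra]))
    num = np.where(med_case > 0, med_case, pseudo_case)
    den = np.where(med_ctrl > 0, med_ctrl, pseudo_ctrl)
    fold = num / den

    pvals = np.array(
        [
            wilcoxon_rank_sum(case.iloc[i].to_numpy(), control.iloc[i].to_numpy())
            for i in range(len(case))
        ]
    )
    qvals = benjamini_hochberg(pvals)
    direction = np.where(
        qvals < alpha,
        np.where(fold > 1, "increased", np.where(fold < 1, "decreased", "ns")),
        "ns",
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_pct = np.where(med_ctrl > 0, (med_case - med_ctrl) / med_ctrl * 100.0, np.nan)
    first = case_spectra[0]
    return pd.DataFrame(
        {
            "motif_class": first.motif_class,
            "motif": case.index,
            "median_case": med_case,
            "median_control": med_ctrl,
            "fold_change": fold,
            "rel_pct_change": rel_pct,
            "p": pvals,
            "q": qvals,
            "direction": direction,
        }
    ).set_index("motif")


def rank_top(table: pd.DataFrame, n: int = 5) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-n increased and decreased motifs ranked by |relative % change|.

    Motifs with a zero control median are excluded from ranking (logged).
    """
    excluded = table["rel_pct_change"].isna() & (table["direction"] != "ns")
    if excluded.any():
        logger.info(
            "%d motifs with zero control median excluded from ranking",
            int(excluded.sum()),
        )
    usable = table[~table["rel_pct_change"].isna()]
    inc = usable[usable["direction"] == "increased"]
    dec = usable[usable["direction"] == "decreased"]
    inc = inc.reindex(inc["rel_pct_change"].abs().sort_values(ascending=False).index)
    dec = dec.reindex(dec["rel_pct_change"].abs().sort_values(ascending=False).index)
    return inc.head(n), dec.head(n)


@dataclass
class EndMotifRatio:
    """Per-sample ratio of cumulative increased- to decreased-motif frequency."""

    value: float | None
    increased_set: tuple[str, ...]
    decreased_set: tuple[str, ...]
    undefined: bool = False


def emr(
    sample_spectrum: MotifSpectrum,
    increased_set: list[str],
    decreased_set: list[str],
) -> EndMotifRatio:
    """End-motif ratio: sum F(increased) / sum F(decreased) for one sample."""
    inc = tuple(increased_set)
    dec = tuple(decreased_set)
    if not inc or not dec:
        raise ValueError("increased/decreased sets must be nonempty")
    if set(inc) & set(dec):
        raise ValueError("increased and decreased sets are not disjoint")
    freq = sample_spectrum.frequency_series()
    num = float(freq.loc[list(inc)].sum())
    den = float(freq.loc[list(dec)].sum())
    if den == 0:
        logger.warning("EMR undefined: cumulative decreased frequency is 0")
        return EndMotifRatio(value=None, increased_set=inc, decreased_set=dec, undefined=True)
    return EndMotifRatio(value=num / den, increased_set=inc, decreased_set=dec)


def row_zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise Z scores, z = (f - m)/s with sample SD (ddof=1).

    Zero-variance rows are returned as all zeros (logged).
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples for Z scores")
    m = matrix.mean(axis=1)
    s = matrix.std(axis=1, ddof=1)
    zero = s == 0
    if zero.any():
        logger.info("%d zero-variance rows set to z=0", int(zero.sum()))
    z = matrix.sub(m, axis=0).div(s.replace(0, np.nan), axis=0)
    return z.fillna(0.0)


def correlate_spectra(
    spectrum_a: MotifSpectrum, spectrum_b: MotifSpectrum
) -> tuple[float, float]:
    """Pearson r (and p) between two spectra over their shared motif domain."""
    if spectrum_a.k != spectrum_b.k:
        raise ValueError("spectra have different motif domains")
    a = spectrum_a.frequencies
    b = spectrum_b.frequencies
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance spectrum")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
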