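"""Feature assembly and the SVM/LOOCV classification harness.

Features are per-sample end-motif frequencies (optionally size-stratified,
4 classes x 4**k motifs x n strata; 3,072 columns for the default k=4 with
three strata), optionally concatenated with FRAGMA cleavage-profile vectors
and/or 4-end motif spectra. Classification uses a linear-kernel SVM under
leave-one-out cross-validation; standardization (and Platt calibration of
probabilities) is fitted within each training fold only, so no test sample
ever influences its own preprocessing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score, roc_curve
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .end_motifs import (
    DEFAULT_STRATA,
    MOTIF_CLASSES,
    SizeStratification,
    all_kmers,
    motif_spectrum,
)
from .io_core import Cohort, ReferenceGenome

logger = logging.getLogger(__name__)

DEFAULT_SPECIFICITIES = (0.80, 0.85, 0.90, 0.95)

#: downsampling grid (fragments per sample)
DEFAULT_DOWNSAMPLE_GRID = (500, 1000, 2000, 3000, 4000, 5000, 10000, 20000, 30000, 40000)


@dataclass
class FeatureMatrix:
    """Samples x named features with a {case, control} label vector."""

    X: pd.DataFrame
    y: np.ndarray  # 1 = case, 0 = control
    provenance: dict[str, tuple] = field(default_factory=dict)

    def __post_init__(self):
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing values")


def assemble_features(
    cohort: Cohort,
    genome: ReferenceGenome,
    classes: tuple[str, ...] = MOTIF_CLASSES,
    k: int = 4,
    strata: SizeStratification | None = DEFAULT_STRATA,
    extra_features=None,
) -> FeatureMatrix:
    """Concatenate per-class, per-stratum motif spectra into a feature matrix.

    Deterministic column order: class, then stratum, then motif
    (alphabetical). ``extra_features`` may be a callable mapping
    (sample_id, fragments) -> pd.Series (e.g. FRAGMA vectors or 4-end
    spectra) appended after the motif blocks. A sample with no usable ends
    in a requested stratum is an error naming the sample and stratum.
    """
    ranges = list(strata) if strata is not None else ["all"]
    motifs = all_kmers(k)
    provenance: dict[str, tuple] = {}
    rows = []
    for sample_id, label, frags in cohort.samples:
        values: list[float] = []
        names: list[str] = []
        for cls in classes:
            for rng in ranges:
                spec = motif_spectrum(frags, genome, cls, k, rng, sample_id)
                if spec.n_ends == 0:
                    raise ValueError(
                        f"sample {sample_id!r} has no usable ends in "
                        f"{cls} stratum {rng}"
                    )
                tag = "all" if rng == "all" else f"{rng[0]}-{rng[1]}"
                cols = [f"{cls}_{tag}_{m}" for m in motifs]
                values.extend(spec.frequencies)
                names.extend(cols)
                for c, m in zip(cols, motifs):
                    provenance[c] = ("end_motifs", cls, rng, m)
        series = pd.Series(values, index=names, name=sample_id)
        if extra_features is not None:
            extra = extra_features(sample_id, frags)
            for c in extra.index:
                provenance[c] = ("extra", c)
            series = pd.concat([series, extra.rename(sample_id)])
        rows.append(series)
    X = pd.DataFrame(rows)
    y = np.array([1 if l == "case" else 0 for l in cohort.labels])
    return FeatureMatrix(X=X, y=y, provenance=provenance)


@dataclass
class RocMetrics:
    auc: float
    aupr: float
    sensitivity_at_specificity: dict[float, float]


def roc_metrics(
    scores: np.ndarray,
    labels: np.ndarray,
    specificities: tuple[float, ...] = DEFAULT_SPECIFICITIES,
) -> RocMetrics:
    """AUC (Mann-Whitney form, ties 0.5), AUPR, and sensitivity at given
    specificity thresholds (highest sensitivity among operating points with
    specificity >= threshold)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(labels, scores))
    aupr = float(average_precision_score(labels, scores))
    fpr, tpr, _ = roc_curve(labels, scores)
    sens = {}
    for spec in specificities:
        ok = (1 - fpr) >= spec
        sens[spec] = float(tpr[ok].max()) if ok.any() else 0.0
    return RocMetrics(auc=auc, aupr=aupr, sensitivity_at_specificity=sens)


@dataclass
class ClassifierResult:
    """Out-of-fold scores/probabilities and summary metrics of a LOOCV run."""

    sample_ids: list[str]
    scores: np.ndarray  # decision-function values, one per sample
    probabilities: np.ndarray  # Platt-calibrated P(case)
    labels: np.ndarray
    auc: float
    aupr: float
    sensitivity_at_specificity: dict[float, float]
    seed: int


def loocv_svm(
    matrix: FeatureMatrix, seed: int = 0, C: float = 1.0
) -> ClassifierResult:
    """Leave-one-out cross-validated linear SVM.

    Each sample is scored exactly once by a model never trained on it.
    Within each fold: standardize on the training split, fit
    SVC(kernel="linear", C=C), then Platt-scale the training decision
    scores with a logistic fit to obtain P(case) for the held-out sample.
    """
    X = matrix.X.to_numpy(dtype=float)
    y = matrix.y
    n = len(y)
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("need >= 2 samples per class")
    scores = np.zeros(n)
    probs = np.zeros(n)
    for i in range(n):
        train = np.arange(n) != i
        scaler = StandardScaler().fit(X[train])
        Xtr = scaler.transform(X[train])
        Xte = scaler.transform(X[[i]])
        clf = SVC(kernel="linear", C=C, random_state=seed)
        clf.fit(Xtr, y[train])
        train_scores = clf.decision_function(Xtr).reshape(-1, 1)
        platt = LogisticRegression(max_iter=1000).fit(train_scores, y[train])
        score = float(clf.decision_function(Xte)[0])
        scores[i] = score
        probs[i] = float(platt.predict_proba([[score]])[0, 1])
    metrics = roc_metrics(scores, y)
    return ClassifierResult(
        sample_ids=list(matrix.X.index),
        scores=scores,
        probabilities=probs,
        labels=y,
        auc=metrics.auc,
        aupr=metrics.aupr,
        sensitivity_at_specificity=metrics.sensitivity_at_specificity,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# DeLong's test for paired AUC comparison (fast midrank algorithm)

def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x)
    ranks = np.zeros(len(x))
    i = 0
    sorted_x = x[order]
    while i < len(x):
        j = i
        while j < len(x) and sorted_x[j] == sorted_x[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + j - 1) + 1
        i = j
    return ranks


def _delong_covariance(scores: np.ndarray, labels: np.ndarray):
    """AUCs and covariance matrix of k paired ROC curves (rows of scores)."""
    pos = scores[:, labels == 1]
    neg = scores[:, labels == 0]
    m, n = pos.shape[1], neg.shape[1]
    k = scores.shape[0]
    v01 = np.zeros((k, m))
    v10 = np.zeros((k, n))
    aucs = np.zeros(k)
    for r in range(k):
        combined = np.concatenate([pos[r], neg[r]])
        tx = _midrank(pos[r])
        ty = _midrank(neg[r])
        tz = _midrank(combined)
        aucs[r] = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        v01[r] = (tz[:m] - tx) / n
        v10[r] = 1.0 - (tz[m:] - ty) / m
    s01 = np.cov(v01)
    s10 = np.cov(v10)
    cov = s01 / m + s10 / n
    return aucs, np.atleast_2d(cov)


def compare_auc_delong(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> float:
    """Two-sided DeLong p-value for the difference of two paired AUCs."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if scores_a.shape != scores_b.shape or len(scores_a) != len(labels):
        raise ValueError("scores must be paired on identical samples")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    aucs, cov = _delong_covariance(np.vstack([scores_a, scores_b]), labels)
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 0:
        return 1.0
    z = (aucs[0] - aucs[1]) / np.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


@dataclass
class BootstrapResult:
    auc: float
    auc_ci: tuple[float, float]
    aupr: float
    aupr_ci: tuple[float, float]
    n_boot: int
    seed: int


def bootstrap_metrics(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> BootstrapResult:
    """Stratified-bootstrap percentile 95% CIs for AUC and AUPR."""
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    pos = np.where(labels == 1)[0]
    neg = np.where(labels == 0)[0]
    aucs = np.zeros(n_boot)
    auprs = np.zeros(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos, len(pos), replace=True), rng.choice(neg, len(neg), replace=True)]
        )
        aucs[b] = roc_auc_score(labels[idx], scores[idx])
        auprs[b] = average_precision_score(labels[idx], scores[idx])
    point = roc_metrics(scores, labels)
    return BootstrapResult(
        auc=point.auc,
        auc_ci=(float(np.percentile(aucs, 2.5)), float(np.percentile(aucs, 97.5))),
        aupr=point.aupr,
        aupr_ci=(float(np.percentile(auprs, 2.5)), float(np.percentile(auprs, 97.5))),
        n_boot=n_boot,
        seed=seed,
    )


def bootstrap_compare(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> float:
    """Paired-bootstrap two-sided p for AUC(a) != AUC(b) on shared samples."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    pos = np.where(labels == 1)[0]
    neg = np.where(labels == 0)[0]
    deltas = np.zeros(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos, len(pos), replace=True), rng.choice(neg, len(neg), replace=True)]
        )
        deltas[b] = roc_auc_score(labels[idx], scores_a[idx]) - roc_auc_score(
            labels[idx], scores_b[idx]
        )
    observed = roc_auc_score(labels, scores_a) - roc_auc_score(labels, scores_b)
    # symmetric tail probability of the bootstrap delta crossing zero
    p = 2 * min((deltas <= 0).mean(), (deltas >= 0).mean())
    return float(min(1.0, max(p, 1.0 / n_boot))) if observed != 0 else 1.0


def downsample_curve(
    cohort: Cohort,
    genome: ReferenceGenome,
    grid: tuple[int, ...] = DEFAULT_DOWNSAMPLE_GRID,
    seed: int = 0,
    **assemble_kwargs,
) -> dict[int, float]:
    """LOOCV AUC as a function of fragments subsampled per sample.

    At each grid level, fragments are drawn without replacement per sample
    (seed-fixed), features are re-assembled, and LOOCV is re-run. Levels
    exceeding the smallest sample are skipped with a warning.
    """
    if not grid:
        raise ValueError("empty downsampling grid")
    rng = np.random.default_rng(seed)
    min_n = min(len(df) for _, _, df in cohort.samples)
    out: dict[int, float] = {}
    for level in grid:
        if level > min_n:
            logger.warning("level %d exceeds smallest sample (%d); skipped", level, min_n)
            continue
        sub = Cohort(
            [
                (sid, lab, df.iloc[np.sort(rng.choice(len(df), level, replace=False))])
                for sid, lab, df in cohort.samples
            ]
        )
        fm = assemble_features(sub, genome, **assemble_kwargs)
        out[level] = loocv_svm(fm, seed=seed).auc
    return out
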