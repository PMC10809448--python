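"""Per-batch reliability metrics for Quartet profiles.

Covers the coefficient of variation of technical replicates, the two-way
absolute-agreement intraclass correlation ICC(A,1), replicate and
cross-sample Pearson correlations, metabolite filtering, deterministic PCA,
and the multi-sample signal-to-noise ratio (SNR).

The SNR compares, on the first two principal components, the weighted mean
squared distance between samples of *different* Quartet groups ("signal")
with that between technical replicates of the *same* group ("noise"):

    SNR = 10 * log10(signal_mean_sq / noise_mean_sq)

with each squared coordinate difference weighted by the fraction of
variance W_p explained by component p.  For m groups of n replicates the
signal averages over all C(m,2)*n*n between-group sample pairs and the
noise over all m*C(n,2) within-group replicate pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    InsufficientFeaturesError,
    InsufficientReplicatesError,
    MissingDataError,
    ValidationError,
)
from .profiles_io import (
    GROUPS,
    SAMPLE_COLUMNS,
    BatchProfile,
    MetaboliteKey,
    complete_case_metabolites,
    group_of,
)

logger = logging.getLogger(__name__)

FILTER_MODES = ("none", "no_missing", "cv_only", "icc_only", "cv_and_icc")


@dataclass(frozen=True)
class FilterCriteria:
    """Reliable-metabolite filter settings.

    ``cv_max`` is a fraction (0.30 means "CV < 30%"); ``icc_min`` the
    ICC(A,1) threshold; ``cv_agg`` how the four per-group CVs collapse to
    one value ("max" is the strict reading, "mean" available).
    """

    cv_max: float = 0.30
    icc_min: float = 0.4
    mode: str = "cv_and_icc"
    cv_agg: str = "max"

    def __post_init__(self):
        if self.mode not in FILTER_MODES:
            raise ValidationError(f"unknown filter mode {self.mode!r}")
        if not self.cv_max > 0:
            raise ValidationError("cv_max must be positive")
        if not -1.0 <= self.icc_min <= 1.0:
            raise ValidationError("icc_min must lie in [-1, 1]")
        if self.cv_agg not in ("max", "mean"):
            raise ValidationError("cv_agg must be 'max' or 'mean'")


@dataclass
class PcaScores:
    """Sample coordinates on the leading principal components."""

    scores: pd.DataFrame          # samples x PC1..PCk
    explained: np.ndarray         # variance fraction per component

    def __post_init__(self):
        e = np.asarray(self.explained, dtype=float)
        if np.any(np.diff(e) > 1e-12) or np.any(e < -1e-12) or e.sum() > 1 + 1e-9:
            raise ValidationError("explained fractions must be nonincreasing "
                                  "values in [0,1] summing to at most 1")
        self.explained = e


@dataclass
class SnrResult:
    snr_db: float
    n_metabolites_used: int
    signal_mean_sq: float
    noise_mean_sq: float


def cv(values: Iterable[float]) -> float:
    """Coefficient of variation of replicate abundances (raw scale).

    Sample standard deviation (ddof=1) divided by the mean.
    """
    arr = np.asarray([v for v in np.asarray(list(values), dtype=float)
                      if np.isfinite(v)])
    if arr.size < 2:
        raise InsufficientReplicatesError(
            f"CV needs at least 2 replicates, got {arr.size}")
    if np.any(arr <= 0):
        raise ValidationError("CV is defined for positive abundances only")
    return float(np.std(arr, ddof=1) / np.mean(arr))


def _icc_a1_stack(matrices: np.ndarray) -> np.ndarray:
    """ICC(A,1) for a stack of complete subjects-x-raters matrices.

    Two-way ANOVA decomposition: with n subjects and k raters,
    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)).
    Shape in: (batch, n, k); out: (batch,).
    """
    x = np.asarray(matrices, dtype=float)
    _, n, k = x.shape
    grand = x.mean(axis=(1, 2), keepdims=True)
    row = x.mean(axis=2, keepdims=True)
    col = x.mean(axis=1, keepdims=True)
    ss_subj = k * ((row - grand) ** 2).sum(axis=(1, 2))
    ss_rater = n * ((col - grand) ** 2).sum(axis=(1, 2))
    ss_total = ((x - grand) ** 2).sum(axis=(1, 2))
    ss_err = ss_total - ss_subj - ss_rater
    msr = ss_subj / (n - 1)
    msc = ss_rater / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (msr - mse) / denom


def icc_agreement(matrix) -> float:
    """Single-measure two-way absolute-agreement ICC, i.e. ICC(A,1).

    Rows are subjects (here: the four Quartet groups), columns raters
    (technical replicates).  The matrix must be complete.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValidationError("ICC needs at least 2 subjects and 2 raters")
    if not np.isfinite(x).all():
        raise MissingDataError("ICC requires a complete matrix")
    if np.allclose(x, x.flat[0]):
        raise DegenerateInputError("ICC undefined: zero total variance")
    val = float(_icc_a1_stack(x[None, ...])[0])
    if math.isnan(val):
        raise DegenerateInputError("ICC undefined on this matrix")
    return val


@dataclass
class PccPairs:
    """Pearson correlations for replicate (within-group) and cross-group
    sample pairs, computed on log2 abundances over a metabolite scope."""

    within: pd.DataFrame   # columns: sample_a, sample_b, group, pcc
    between: pd.DataFrame  # columns: sample_a, sample_b, group_a, group_b, pcc


def replicate_and_cross_pcc(profile: BatchProfile,
                            scope: Optional[set[MetaboliteKey]] = None,
                            log_scale: bool = True) -> PccPairs:
    """Pearson correlations of all sample pairs of one batch.

    Reproducibility: the 12 within-group replicate pairs (C(3,2) per group,
    4 groups).  Similarity: the 54 between-group pairs (3x3 replicate
    combinations for each of the C(4,2) group pairs).  Computed over the
    metabolite ``scope`` (default: the batch's complete cases).
    """
    if scope is None:
        scope = complete_case_metabolites(profile)
    rows = [k for k in profile.data.index if k in scope]
    if len(rows) < 3:
        raise InsufficientFeaturesError(
            f"PCC needs at least 3 metabolites in scope, got {len(rows)}")
    mat = profile.data.loc[rows]
    if log_scale:
        mat = np.log2(mat)
    cols = list(mat.columns)
    corr = np.corrcoef(mat.to_numpy(dtype=float).T)
    within, between = [], []
    for i, j in combinations(range(len(cols)), 2):
        a, b = cols[i], cols[j]
        ga, gb = group_of(a), group_of(b)
        r = float(corr[i, j])
        if ga == gb:
            within.append((a, b, ga, r))
        else:
            between.append((a, b, ga, gb, r))
    return PccPairs(
        within=pd.DataFrame(within,
                            columns=["sample_a", "sample_b", "group", "pcc"]),
        between=pd.DataFrame(between, columns=["sample_a", "sample_b",
                                               "group_a", "group_b", "pcc"]),
    )


def _group_matrix(profile: BatchProfile) -> np.ndarray:
    """Values as (metabolite, group, replicate) with NaN for missing."""
    df = profile.data.reindex(columns=list(SAMPLE_COLUMNS))
    arr = df.to_numpy(dtype=float)
    # SAMPLE_COLUMNS is run order (replicate-major); reshape then transpose
    return arr.reshape(arr.shape[0], 3, 4).transpose(0, 2, 1)


def per_group_cv(profile: BatchProfile) -> pd.DataFrame:
    """Per-metabolite, per-group CV table (NaN where <2 replicates)."""
    arr = _group_matrix(profile)
    finite = np.isfinite(arr)
    n = finite.sum(axis=2)
    filled = np.where(finite, arr, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = filled.sum(axis=2) / n
        ss = (np.where(finite, (arr - mean[..., None]) ** 2, 0.0)).sum(axis=2)
        sd = np.sqrt(ss / (n - 1))
        out = sd / mean
    out[n < 2] = np.nan
    return pd.DataFrame(out, index=profile.data.index, columns=list(GROUPS))


def icc_per_metabolite(profile: BatchProfile) -> pd.Series:
    """ICC(A,1) per metabolite on log2 abundances, groups as subjects and
    replicates as raters; NaN where the 4x3 matrix is incomplete."""
    arr = _group_matrix(profile)
    complete = np.isfinite(arr).all(axis=(1, 2))
    vals = np.full(arr.shape[0], np.nan)
    if complete.any():
        vals[complete] = _icc_a1_stack(np.log2(arr[complete]))
    return pd.Series(vals, index=profile.data.index)


def filter_metabolites(profile: BatchProfile,
                       criteria: FilterCriteria) -> set[MetaboliteKey]:
    """Select reliably detected metabolites under the given criteria.

    ``none``: detected in any sample.  ``no_missing``: complete cases.
    CV modes require the per-group CV aggregate below ``cv_max`` (every
    group needs >=2 replicates); ICC modes require ICC(A,1) above
    ``icc_min`` (complete 4x3 matrix).  Metabolites where a criterion is
    not computable are excluded with a logged reason.
    """
    if criteria.mode == "none":
        return profile.detected_any()
    if criteria.mode == "no_missing":
        return complete_case_metabolites(profile)
    index = profile.data.index
    passed = pd.Series(True, index=index)
    if criteria.mode in ("cv_only", "cv_and_icc"):
        cvs = per_group_cv(profile)
        computable = cvs.notna().all(axis=1)
        agg = cvs.max(axis=1) if criteria.cv_agg == "max" else cvs.mean(axis=1)
        ok = computable & (agg < criteria.cv_max)
        n_skip = int((~computable).sum())
        if n_skip:
            logger.info("batch %s: %d metabolites lack replicates for CV",
                        profile.batch_id, n_skip)
        passed &= ok
    if criteria.mode in ("icc_only", "cv_and_icc"):
        icc = icc_per_metabolite(profile)
        n_skip = int(icc.isna().sum())
        if n_skip:
            logger.info("batch %s: %d metabolites incomplete for ICC",
                        profile.batch_id, n_skip)
        passed &= icc.notna() & (icc > criteria.icc_min)
    return set(index[passed.to_numpy()])


# ---------------------------------------------------------------------------
# PCA and SNR
# ---------------------------------------------------------------------------

PREPROCESSING = ("log2_center", "log2_autoscale", "center", "autoscale")


def pca(matrix: pd.DataFrame, preprocessing: str = "log2_autoscale",
        n_components: int = 2) -> PcaScores:
    """Deterministic PCA of a samples-x-metabolites matrix.

    ``log2_*`` modes log2-transform abundances first; plain ``center`` /
    ``autoscale`` operate on values that are already on a log/ratio scale.
    Each metabolite is centred, and autoscaling additionally divides by its
    sample SD — putting heterogeneous-intensity metabolites on comparable
    footing (the default for abundances).  Components come from an SVD
    with a fixed sign convention: the largest-magnitude loading of each
    component is positive.
    """
    if preprocessing not in PREPROCESSING:
        raise ValidationError(f"unknown preprocessing {preprocessing!r}")
    X = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) \
        else np.asarray(matrix, dtype=float)
    if not np.isfinite(X).all():
        raise MissingDataError("PCA requires a complete matrix")
    if X.shape[0] < 3:
        raise ValidationError("PCA needs at least 3 samples")
    if preprocessing.startswith("log2_"):
        X = np.log2(X)
    X = X - X.mean(axis=0, keepdims=True)
    if preprocessing.endswith("autoscale"):
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        if (~keep).any():
            logger.info("dropping %d constant metabolites before autoscaling",
                        int((~keep).sum()))
        X = X[:, keep] / sd[keep]
    if X.shape[1] < 2:
        raise InsufficientFeaturesError(
            "PCA needs at least 2 usable metabolites")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, s.size)
    scores = U[:, :k] * s[:k]
    for p in range(k):  # sign convention: dominant loading positive
        j = int(np.argmax(np.abs(Vt[p])))
        if Vt[p, j] < 0:
            scores[:, p] *= -1.0
    total = float((s ** 2).sum())
    explained = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    idx = matrix.index if isinstance(matrix, pd.DataFrame) \
        else pd.RangeIndex(X.shape[0])
    frame = pd.DataFrame(scores, index=idx,
                         columns=[f"PC{p + 1}" for p in range(k)])
    return PcaScores(frame, explained)


def snr_from_scores(scores: np.ndarray, weights: Sequence[float],
                    groups: Sequence[str]) -> SnrResult:
    """SNR from already-computed component scores.

    ``scores`` is (samples x components); ``weights`` the per-component
    variance fractions W_p; ``groups`` the per-sample group labels.
    """
    pts = np.asarray(scores, dtype=float)
    w = np.asarray(weights, dtype=float)
    groups = list(groups)
    if pts.shape[0] != len(groups) or pts.shape[1] != w.size:
        raise ValidationError("scores, weights and groups shapes disagree")
    sig, noi = [], []
    for i, j in combinations(range(len(groups)), 2):
        d2 = float(np.sum(w * (pts[i] - pts[j]) ** 2))
        (noi if groups[i] == groups[j] else sig).append(d2)
    if not sig or not noi:
        raise ValidationError("need both between- and within-group pairs")
    signal = float(np.mean(sig))
    noise = float(np.mean(noi))
    if noise <= 0:
        raise DegenerateInputError(
            "all replicates coincide: SNR undefined (zero noise)")
    return SnrResult(snr_db=10.0 * math.log10(signal / noise),
                     n_metabolites_used=0, signal_mean_sq=signal,
                     noise_mean_sq=noise)


def snr(profile: BatchProfile,
        criteria: Optional[FilterCriteria] = None,
        preprocessing: str = "log2_autoscale") -> SnrResult:
    """Multi-sample signal-to-noise ratio of one batch.

    Uses metabolites detected in all 12 samples (further narrowed by
    ``criteria`` when given), 2-component PCA scores weighted by explained
    variance, and averages squared distances over the 54 between-group and
    12 within-group sample pairs.
    """
    if criteria is None:
        criteria = FilterCriteria(mode="no_missing")
    if set(SAMPLE_COLUMNS) - set(profile.data.columns) or \
            profile.data[list(SAMPLE_COLUMNS)].isna().all(axis=0).any():
        raise MissingDataError(
            f"batch {profile.batch_id!r}: SNR needs all 12 Quartet samples")
    scope = filter_metabolites(profile, criteria) & \
        complete_case_metabolites(profile)
    rows = [k for k in profile.data.index if k in scope]
    if len(rows) < 2:
        raise InsufficientFeaturesError(
            f"SNR needs >=2 usable metabolites, got {len(rows)}")
    mat = profile.data.loc[rows, list(SAMPLE_COLUMNS)].T  # samples x mets
    comp = pca(mat, preprocessing=preprocessing, n_components=2)
    res = snr_from_scores(comp.scores.to_numpy(), comp.explained,
                          [group_of(c) for c in comp.scores.index])
    res.n_metabolites_used = len(rows)
    return res
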