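import math

import numpy as np
import pandas as pd
import pytest

from quartetqc import (
    BatchProfile,
    DegenerateInputError,
    FilterCriteria,
    InsufficientFeaturesError,
    InsufficientReplicatesError,
    MissingDataError,
    cv,
    filter_metabolites,
    icc_agreement,
    pca,
    replicate_and_cross_pcc,
    snr,
    snr_from_scores,
)
from quartetqc.profiles_io import GROUPS, SAMPLE_COLUMNS

from conftest import profile_from_log2, structured_log2

GROUP_LABELS = [c.split("-")[0] for c in SAMPLE_COLUMNS]


# ---------------------------------------------------------------------- CV

@pytest.mark.parametrize("values,expected", [
    ((10, 10, 10), 0.0),
    ((1, 2, 3), 0.5),       # sample SD 1, mean 2
])
def test_cv_known_values(values, expected):
    assert cv(values) == pytest.approx(expected, abs=1e-12)


def test_cv_matches_two_pass_oracle(rng):
    for _ in range(50):
        vals = rng.lognormal(10, 0.5, size=3)
        mean = vals.sum() / 3
        sd = math.sqrt(((vals - mean) ** 2).sum() / 2)
        assert cv(vals) == pytest.approx(sd / mean, rel=1e-12)


def test_cv_requires_two_replicates():
    with pytest.raises(InsufficientReplicatesError):
        cv([5.0])
    with pytest.raises(InsufficientReplicatesError):
        cv([5.0, np.nan])


# --------------------------------------------------------------------- ICC

def test_icc_perfect_agreement_is_one():
    m = np.array([[1.0, 1, 1], [2, 2, 2], [3, 3, 3], [4, 4, 4]])
    assert icc_agreement(m) == pytest.approx(1.0, abs=1e-12)


def test_icc_null_mean_near_zero():
    """Pure-noise 4x3 matrices: the agreement ICC averages near 0."""
    rng = np.random.default_rng(42)
    vals = [icc_agreement(rng.normal(size=(4, 3))) for _ in range(1000)]
    assert abs(float(np.mean(vals))) < 0.05


def _icc_anova_parts(x):
    n, k = x.shape
    grand = x.mean()
    ss_total = ((x - grand) ** 2).sum()
    ss_r = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_c = n * ((x.mean(axis=0) - grand) ** 2).sum()
    msr = ss_r / (n - 1)
    msc = ss_c / (k - 1)
    mse = (ss_total - ss_r - ss_c) / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def test_rater_offset_lowers_agreement_but_not_consistency(rng):
    x = rng.normal(size=(4, 3)) + np.arange(4)[:, None]
    shifted = x.copy()
    shifted[:, 0] += 5.0
    assert icc_agreement(shifted) < icc_agreement(x)

    def consistency(m):
        msr, msc, mse, n, k = _icc_anova_parts(m)
        return (msr - mse) / (msr + (k - 1) * mse)

    assert consistency(shifted) == pytest.approx(consistency(x), rel=1e-9)


def test_icc_matches_pingouin_two_way_agreement(rng):
    pingouin = pytest.importorskip("pingouin")
    for _ in range(5):
        x = rng.normal(size=(4, 3)) + rng.normal(size=(4, 1))
        long = pd.DataFrame(
            [(s, r, x[s, r]) for s in range(4) for r in range(3)],
            columns=["subject", "rater", "value"])
        res = pingouin.intraclass_corr(long, targets="subject",
                                       raters="rater", ratings="value")
        expected = float(res.loc[res["Type"].isin(["ICC2", "ICC(A,1)"]),
                                 "ICC"].iloc[0])
        assert icc_agreement(x) == pytest.approx(expected, abs=1e-9)


def test_icc_error_cases():
    with pytest.raises(MissingDataError):
        icc_agreement([[1, np.nan, 2], [1, 2, 3]])
    with pytest.raises(DegenerateInputError):
        icc_agreement(np.full((4, 3), 7.0))


# --------------------------------------------------------------------- PCC

def test_pcc_pair_counts_and_identical_replicates(rng):
    log2 = structured_log2(10, rng)
    log2[:, SAMPLE_COLUMNS.index("D5-2")] = log2[:, SAMPLE_COLUMNS.index("D5-1")]
    prof = profile_from_log2(log2)
    pairs = replicate_and_cross_pcc(prof)
    assert len(pairs.within) == 12 and len(pairs.between) == 54
    row = pairs.within[(pairs.within.sample_a == "D5-1") &
                       (pairs.within.sample_b == "D5-2")]
    assert float(row.pcc.iloc[0]) == pytest.approx(1.0, abs=1e-12)


def test_pcc_anticorrelated_vectors(rng):
    log2 = structured_log2(10, rng)
    i, j = SAMPLE_COLUMNS.index("D5-1"), SAMPLE_COLUMNS.index("D5-2")
    log2[:, j] = 40.0 - log2[:, i]   # exactly anti-correlated after centering
    prof = profile_from_log2(log2)
    pairs = replicate_and_cross_pcc(prof)
    row = pairs.within[(pairs.within.sample_a == "D5-1") &
                       (pairs.within.sample_b == "D5-2")]
    assert float(row.pcc.iloc[0]) == pytest.approx(-1.0, abs=1e-9)


def test_pcc_requires_three_metabolites(rng):
    prof = profile_from_log2(structured_log2(2, rng))
    with pytest.raises(InsufficientFeaturesError):
        replicate_and_cross_pcc(prof)


# ------------------------------------------------------------------ filter

def test_filter_sets_match_per_metabolite_oracle(rng):
    log2 = structured_log2(60, rng, group_sd=0.8, noise_sd=0.25)
    vals = np.exp2(log2)
    vals[rng.random(vals.shape) < 0.05] = np.nan
    prof = BatchProfile("f", pd.DataFrame(
        vals, index=profile_from_log2(log2).data.index,
        columns=list(SAMPLE_COLUMNS)))
    crit = FilterCriteria(cv_max=0.30, icc_min=0.4)

    def oracle_cv_ok(row):
        worst = 0.0
        for g in GROUPS:
            reps = [row[f"{g}-{r}"] for r in (1, 2, 3)]
            reps = [v for v in reps if np.isfinite(v)]
            if len(reps) < 2:
                return False
            worst = max(worst, float(np.std(reps, ddof=1) / np.mean(reps)))
        return worst < crit.cv_max

    def oracle_icc_ok(row):
        mat = np.array([[row[f"{g}-{r}"] for r in (1, 2, 3)] for g in GROUPS])
        if not np.isfinite(mat).all():
            return False
        return icc_agreement(np.log2(mat)) > crit.icc_min

    cv_expect = {k for k, row in prof.data.iterrows() if oracle_cv_ok(row)}
    icc_expect = {k for k, row in prof.data.iterrows() if oracle_icc_ok(row)}
    cv_got = filter_metabolites(prof, FilterCriteria(mode="cv_only"))
    icc_got = filter_metabolites(prof, FilterCriteria(mode="icc_only"))
    both_got = filter_metabolites(prof, crit)
    assert cv_got == cv_expect
    assert icc_got == icc_expect
    assert both_got == cv_got & icc_got


def test_filter_cv_threshold_boundary(rng):
    log2 = structured_log2(5, rng, noise_sd=0.001)
    prof0 = profile_from_log2(log2)
    vals = prof0.data.to_numpy().copy()
    # give metabolite 0 a D5-group CV of about 0.4
    m = vals[0, [0, 4, 8]].mean()
    vals[0, [0, 4, 8]] = [m * (1 - 0.4), m, m * (1 + 0.4)]
    prof = BatchProfile("b", pd.DataFrame(
        vals, index=prof0.data.index, columns=prof0.data.columns))
    got = filter_metabolites(prof, FilterCriteria(mode="cv_only", cv_max=0.30))
    assert prof.data.index[0] not in got
    assert set(prof.data.index[1:]) <= got


def test_noiseless_profile_passes_combined_filter(rng):
    log2 = structured_log2(10, rng, group_sd=1.5, noise_sd=0.01)
    prof = profile_from_log2(log2)
    got = filter_metabolites(prof, FilterCriteria())
    assert got == set(prof.data.index)


# --------------------------------------------------------------------- PCA

def test_pca_rank_one_matrix(rng):
    base = rng.lognormal(12, 1, size=6)
    mat = pd.DataFrame(np.outer(np.array([1, 2, 4, 8, 16, 32.0]), base))
    comp = pca(mat, preprocessing="log2_center")
    assert comp.explained[0] == pytest.approx(1.0, abs=1e-9)
    assert comp.explained[1] == pytest.approx(0.0, abs=1e-9)


def test_pca_duplicate_samples_share_scores(rng):
    mat = np.exp2(rng.normal(15, 1, size=(5, 6)))
    mat = np.vstack([mat, mat[2]])
    comp = pca(pd.DataFrame(mat))
    np.testing.assert_allclose(comp.scores.iloc[2], comp.scores.iloc[-1],
                               atol=1e-9)


def test_pca_matches_covariance_eigendecomposition(rng):
    mat = np.exp2(rng.normal(15, 1, size=(6, 4)))
    comp = pca(pd.DataFrame(mat), preprocessing="log2_autoscale",
               n_components=2)
    X = np.log2(mat)
    X = X - X.mean(axis=0)
    X = X / X.std(axis=0, ddof=1)
    cov = X.T @ X
    evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    np.testing.assert_allclose(comp.explained,
                               evals[:2] / evals.sum(), rtol=1e-9)
    # squared score norms equal the eigenvalues
    np.testing.assert_allclose(
        (comp.scores.to_numpy() ** 2).sum(axis=0), evals[:2], rtol=1e-9)


def test_pca_rejects_missing(rng):
    mat = np.exp2(rng.normal(15, 1, size=(5, 4)))
    mat[1, 1] = np.nan
    with pytest.raises(MissingDataError):
        pca(pd.DataFrame(mat))


# --------------------------------------------------------------------- SNR

def _brute_force_snr(pts, w, groups):
    sig, noi = [], []
    idx = range(len(groups))
    for i in idx:
        for j in idx:
            if j <= i:
                continue
            d2 = sum(w[p] * (pts[i][p] - pts[j][p]) ** 2
                     for p in range(len(w)))
            (noi if groups[i] == groups[j] else sig).append(d2)
    return 10 * math.log10((sum(sig) / len(sig)) / (sum(noi) / len(noi)))


def test_snr_matches_bruteforce_enumeration(rng):
    groups = GROUP_LABELS
    for _ in range(25):
        pts = rng.normal(size=(12, 2))
        w = rng.uniform(0.2, 0.8, size=2)
        got = snr_from_scores(pts, w, groups)
        assert got.snr_db == pytest.approx(
            _brute_force_snr(pts, w, groups), rel=1e-9)


def test_snr_zero_db_when_signal_equals_noise():
    """Shared mean-zero replicate offsets around centroids whose mean squared
    separation equals the mean squared offset give exactly 0 dB."""
    centroids = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]], dtype=float)
    offsets = np.array([[2, 0], [0, 2], [-2, -2]], dtype=float)
    pts = np.vstack([c + offsets for c in centroids])
    groups = [g for g in GROUPS for _ in range(3)]
    res = snr_from_scores(pts, [0.5, 0.5], groups)
    assert res.signal_mean_sq == res.noise_mean_sq
    assert res.snr_db == 0.0


def test_snr_zero_noise_is_degenerate_error():
    centroids = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
    pts = np.repeat(centroids, 3, axis=0)
    groups = [g for g in GROUPS for _ in range(3)]
    with pytest.raises(DegenerateInputError):
        snr_from_scores(pts, [0.5, 0.5], groups)


def test_snr_invariant_under_rotation_translation_with_uniform_weights(rng):
    pts = rng.normal(size=(12, 2))
    groups = GROUP_LABELS
    theta = 0.7
    R = np.array([[math.cos(theta), -math.sin(theta)],
                  [math.sin(theta), math.cos(theta)]])
    moved = pts @ R.T + np.array([3.0, -2.0])
    w = [0.5, 0.5]
    assert snr_from_scores(moved, w, groups).snr_db == pytest.approx(
        snr_from_scores(pts, w, groups).snr_db, abs=1e-9)
    # replicate relabeling within a group never changes SNR
    perm = pts.copy()
    perm[[0, 4]] = perm[[4, 0]]   # swap two D5 replicates
    w2 = [0.7, 0.3]
    assert snr_from_scores(perm, w2, GROUP_LABELS).snr_db == pytest.approx(
        snr_from_scores(pts, w2, GROUP_LABELS).snr_db, abs=1e-12)


def test_snr_doubling_centroids_adds_six_db(rng):
    """With group-centred scatter much smaller than the centroid spread,
    doubling the centroids raises SNR by 20*log10(2)."""
    groups = [g for g in GROUPS for _ in range(3)]
    for seed in range(10):
        r = np.random.default_rng(seed)
        centroids = r.normal(size=(4, 2))
        offs = r.normal(scale=1e-4, size=(4, 3, 2))
        offs -= offs.mean(axis=1, keepdims=True)
        p1 = np.vstack([centroids[g] + offs[g] for g in range(4)])
        p2 = np.vstack([2 * centroids[g] + offs[g] for g in range(4)])
        w = [0.6, 0.4]
        delta = snr_from_scores(p2, w, groups).snr_db - \
            snr_from_scores(p1, w, groups).snr_db
        assert delta == pytest.approx(20 * math.log10(2), abs=1e-6)


def test_snr_profile_requires_all_samples(structured_profile):
    df = structured_profile.data.drop(columns=["M8-3"])
    with pytest.raises(MissingDataError):
        snr(BatchProfile("x", df))


def test_snr_uses_complete_cases(structured_profile, rng):
    res = snr(structured_profile)
    assert res.n_metabolites_used == len(structured_profile.data)
    assert res.snr_db == pytest.approx(
        10 * math.log10(res.signal_mean_sq / res.noise_mean_sq))
    df = structured_profile.data.copy()
    df.iloc[0, 0] = np.nan
    res2 = snr(BatchProfile("x", df))
    assert res2.n_metabolites_used == len(df) - 1
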