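import numpy as np
import pytest
from scipy.stats import spearmanr, ttest_ind

import fetalmorph as fm
from fetalmorph.stats import (
    age_effect_model,
    divergence_field,
    hotelling_t2_field,
    max_stat_permutation,
    mode_visualization_meshes,
    pca_momenta,
    regression_lrt_field,
)
from fetalmorph.kernel import momentum_field


# ---------------------------------------------------------------------------
# PCA


def test_pca_rank_one_matrix():
    rng = np.random.default_rng(0)
    direction = rng.normal(size=30)
    M = np.outer(rng.normal(size=20), direction)
    pca = pca_momenta(M, 3)
    assert pca.explained_fractions[0] == pytest.approx(1.0, abs=1e-9)


def test_pca_reconstruction_with_all_modes():
    rng = np.random.default_rng(1)
    M = rng.normal(size=(15, 24))
    pca = pca_momenta(M)
    centered = M - pca.mean
    recon = pca.scores @ pca.modes
    np.testing.assert_allclose(recon, centered, atol=1e-9)


def test_pca_invariant_to_subject_order():
    rng = np.random.default_rng(2)
    M = rng.normal(size=(25, 12))
    s1 = pca_momenta(M).singular_values
    s2 = pca_momenta(M[rng.permutation(25)]).singular_values
    np.testing.assert_allclose(s1, s2, rtol=1e-9)


def test_pca_explained_invariant_to_common_rotation():
    """Rotating every 3-vector block by one rotation preserves the spectrum."""
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(3)
    M = rng.normal(size=(20, 18))
    R = Rotation.random(random_state=5).as_matrix()
    blocks = M.reshape(20, 6, 3) @ R.T
    M_rot = blocks.reshape(20, 18)
    np.testing.assert_allclose(
        pca_momenta(M_rot).explained_fractions,
        pca_momenta(M).explained_fractions,
        atol=1e-12,
    )


def test_pca_recovers_generating_variance_split():
    """Two orthogonal latent modes with SD 3 and 1 explain ~9:1 variance."""
    spec = fm.SyntheticPopulationSpec(
        n_subjects=500, seed=9, age_effect_scale=0.0, vertex_noise_sd=0.0,
        template_resolution=(16, 18),
    )
    sample = fm.sample_population(spec)
    pca = pca_momenta(sample.truth.momenta, 2)
    assert pca.explained_fractions[0] + pca.explained_fractions[1] > 0.999
    ratio = pca.explained_fractions[0] / pca.explained_fractions[1]
    assert 9.0 * 0.8 < ratio < 9.0 * 1.25  # sampling error at n=500


def test_mode_visualization_properties(score_atlas):
    _, atlas = score_atlas
    pca = pca_momenta(atlas.momenta_matrix(), 2)
    (tpl_only,) = mode_visualization_meshes(atlas, pca, 0, sd_multiples=[0.0])
    np.testing.assert_allclose(tpl_only.vertices, atlas.template.vertices, atol=1e-12)
    minus, plus = mode_visualization_meshes(atlas, pca, 0, sd_multiples=[-2, 2])
    d_plus = plus.vertices - atlas.template.vertices
    d_minus = minus.vertices - atlas.template.vertices
    np.testing.assert_allclose(d_plus, -d_minus, atol=1e-9)
    (one_sd,) = mode_visualization_meshes(atlas, pca, 0, sd_multiples=[1.0])
    ratio = np.linalg.norm(d_plus) / np.linalg.norm(one_sd.vertices - atlas.template.vertices)
    assert ratio == pytest.approx(2.0, rel=1e-6)
    with pytest.raises(IndexError):
        mode_visualization_meshes(atlas, pca, 99)


# ---------------------------------------------------------------------------
# Hotelling t2


def test_t2_zero_for_identical_groups():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(10, 12))
    M = np.vstack([X, X])
    labels = np.array([0] * 10 + [1] * 10)
    field = hotelling_t2_field(M, labels)
    np.testing.assert_allclose(field.values, 0, atol=1e-9)


def test_t2_reduces_to_squared_t_statistic_in_1d():
    rng = np.random.default_rng(5)
    M = np.zeros((30, 15))
    M[:, ::3] = rng.normal(size=(30, 5))
    M[:10, ::3] += 1.0
    labels = np.array([0] * 10 + [1] * 20)
    field = hotelling_t2_field(M, labels)
    for p in range(5):
        t, _ = ttest_ind(M[:10, 3 * p], M[10:, 3 * p])
        # singular 3x3 covariance triggers the tiny ridge, hence rel 1e-6
        assert field.values[p] == pytest.approx(t**2, rel=1e-6)


def test_t2_affine_invariance_per_point():
    rng = np.random.default_rng(6)
    M = rng.normal(size=(24, 9))
    labels = np.array([0] * 12 + [1] * 12)
    base = hotelling_t2_field(M, labels).values
    for _ in range(3):
        A = rng.normal(size=(3, 3)) + 2 * np.eye(3)
        M2 = M.copy()
        M2[:, 3:6] = M[:, 3:6] @ A.T  # invertible map at point 1 only
        vals = hotelling_t2_field(M2, labels).values
        assert vals[1] == pytest.approx(base[1], rel=1e-8)


def test_t2_localizes_injected_group_offset():
    """An FGR-like momenta offset is detected at the control points carrying it."""
    spec = fm.SyntheticPopulationSpec(
        n_subjects=100, seed=17, group_fraction=0.5, group_offset_scale=0.0,
        template_resolution=(16, 18), vertex_noise_sd=0.0,
    )
    sample = fm.sample_population(spec)
    truth = sample.truth
    rng = np.random.default_rng(99)
    # full-rank per-point variability: latent modes plus iid momenta jitter
    jitter_sd = 0.1
    M = truth.momenta + rng.normal(0, jitter_sd, truth.momenta.shape)
    labels = (sample.metadata["group"] == "FGR").to_numpy()
    # localized offset at the control points nearest the nose, SNR 2
    nose = truth.template_landmarks.nose
    support = np.linalg.norm(truth.cps.points - nose, axis=1) <= spec.lambda_V
    assert support.any()
    per_coord_sd = M.std(axis=0).mean()
    offset = np.zeros((len(truth.cps.points), 3))
    offset[support, 2] = 2.0 * per_coord_sd
    M[labels] += offset.ravel()
    stat = hotelling_t2_field(M, labels)
    peak = truth.cps.points[int(np.argmax(stat.values))]
    dists = np.linalg.norm(truth.cps.points[support] - peak, axis=1)
    assert dists.min() <= 2 * spec.lambda_V


def test_t2_requires_two_sufficient_groups():
    M = np.random.default_rng(0).normal(size=(6, 6))
    with pytest.raises(ValueError):
        hotelling_t2_field(M, np.array([0, 0, 0, 0, 0, 1]))


# ---------------------------------------------------------------------------
# Regression LRT


def test_lrt_null_covariate_statistic_small():
    rng = np.random.default_rng(7)
    n, p = 60, 8
    M = rng.normal(size=(n, 3 * p))
    z = rng.normal(size=n)  # independent of M
    X = np.column_stack([np.ones(n), z])
    stat = regression_lrt_field(M, X, [1]).values
    from scipy.stats import chi2

    # under H0 the statistic is asymptotically chi2_3: most points below median
    assert np.mean(stat < chi2.ppf(0.5, 3)) > 0.2
    assert stat.max() < chi2.ppf(0.9999, 3) * 3


def test_lrt_equivalent_to_t2_for_binary_covariate():
    rng = np.random.default_rng(8)
    M = rng.normal(size=(40, 30))
    labels = rng.integers(0, 2, 40)
    while len(np.unique(labels)) < 2:
        labels = rng.integers(0, 2, 40)
    X = np.column_stack([np.ones(40), labels])
    lrt = regression_lrt_field(M, X, [1]).values
    t2 = hotelling_t2_field(M, labels).values
    rho = spearmanr(lrt, t2).statistic
    assert rho == pytest.approx(1.0, abs=1e-12)


def test_lrt_duplicated_tested_column_errors():
    rng = np.random.default_rng(9)
    M = rng.normal(size=(30, 9))
    z = rng.normal(size=30)
    X = np.column_stack([np.ones(30), z, z])
    with pytest.raises(ValueError, match="rank-deficient"):
        regression_lrt_field(M, X, [2])


# ---------------------------------------------------------------------------
# Permutation testing


def test_permutation_degenerate_momenta_p_is_one():
    M = np.tile(np.arange(9.0), (30, 1)) * 0  # all-zero momenta
    labels = np.array([0] * 15 + [1] * 15)
    _, res = max_stat_permutation(M, labels, "t2", n_perm=100, seed=0)
    assert res.p_value == 1.0


def test_permutation_seed_determinism():
    rng = np.random.default_rng(10)
    M = rng.normal(size=(30, 18))
    labels = np.array([0] * 15 + [1] * 15)
    _, r1 = max_stat_permutation(M, labels, "t2", n_perm=200, seed=11)
    _, r2 = max_stat_permutation(M, labels, "t2", n_perm=200, seed=11)
    assert r1.p_value == r2.p_value
    np.testing.assert_array_equal(r1.max_stat_sample, r2.max_stat_sample)


def test_permutation_detects_group_effect_with_power():
    """Injected SNR-2 effect found at p <= 0.05 in >= 90% of replicates."""
    rng = np.random.default_rng(12)
    detections = 0
    reps = 25
    for r in range(reps):
        p = 60
        M = rng.normal(size=(100, 3 * p))
        labels = np.array([0] * 50 + [1] * 50)
        M[labels == 1, :9] += 2.0  # SNR 2 at three control points
        _, res = max_stat_permutation(M, labels, "t2", n_perm=500, seed=r)
        detections += res.p_value <= 0.05
    assert detections >= 0.9 * reps


def test_permutation_lrt_age_effect_runs():
    rng = np.random.default_rng(13)
    n = 50
    ga = rng.uniform(24, 34, n)
    M = rng.normal(size=(n, 24))
    M[:, 0] += 0.8 * (ga - 29)  # strong age trend on one coordinate
    field, res = max_stat_permutation(M, ga, "lrt", n_perm=150, seed=3)
    assert res.p_value <= 0.05
    assert int(np.argmax(field.values)) == 0
    assert field.point_p_values is not None


def test_permutation_constant_labels_rejected():
    M = np.random.default_rng(0).normal(size=(20, 9))
    with pytest.raises(ValueError, match="constant"):
        max_stat_permutation(M, np.zeros(20), "t2", n_perm=100, seed=0)


# ---------------------------------------------------------------------------
# Age effect and divergence


def test_age_effect_exact_linear_case():
    rng = np.random.default_rng(14)
    u = rng.normal(size=12)
    ga = np.linspace(24, 34, 20)
    M = np.outer(ga, u)
    b1, predict = age_effect_model(M, ga)
    np.testing.assert_allclose(b1.ravel(), u, atol=1e-9)
    np.testing.assert_allclose(predict(30.0).ravel(), 30 * u, atol=1e-8)


def test_age_effect_null_is_small():
    rng = np.random.default_rng(15)
    n, D = 120, 30
    ga = rng.uniform(24, 34, n)
    M = rng.normal(size=(n, D))
    b1, _ = age_effect_model(M, ga)
    # null simulation of the slope norm
    norms = []
    for _ in range(200):
        bb, _ = age_effect_model(rng.normal(size=(n, D)), ga)
        norms.append(np.linalg.norm(bb))
    assert np.linalg.norm(b1) < np.percentile(norms, 95)


def test_age_effect_direction_recovered_from_generator():
    spec = fm.SyntheticPopulationSpec(n_subjects=200, seed=5, template_resolution=(16, 18))
    sample = fm.sample_population(spec)
    b1, _ = age_effect_model(sample.truth.momenta, sample.metadata["ga_weeks"].to_numpy())
    truth_dir = sample.truth.age_field.ravel()
    cos = abs(b1.ravel() @ truth_dir) / np.linalg.norm(b1)
    assert cos > 0.9


def test_age_effect_constant_ga_rejected():
    with pytest.raises(ValueError):
        age_effect_model(np.zeros((10, 6)), np.full(10, 29.0))


def test_divergence_zero_momenta_and_symmetry():
    cps = np.array([[0.0, 0, 0], [3.0, 0, 0]])
    q = np.array([[1.0, 1, 1]])
    assert divergence_field(cps, np.zeros((2, 3)), 5.0, q)[0] == 0
    # at the control point itself the kernel gradient vanishes
    single = np.array([[2.0, -1, 0.5]])
    assert divergence_field(single, np.array([[1.0, 2, 3]]), 5.0, single)[0] == pytest.approx(
        0.0, abs=1e-12
    )


def test_divergence_matches_finite_differences():
    rng = np.random.default_rng(16)
    cps = rng.normal(size=(10, 3)) * 5
    a = rng.normal(size=(10, 3))
    lam = 6.0
    queries = rng.normal(size=(8, 3)) * 5
    analytic = divergence_field(cps, a, lam, queries)
    h = 1e-4 * lam
    fd = np.zeros(len(queries))
    for d in range(3):
        e = np.zeros(3)
        e[d] = h
        fp = momentum_field(queries + e, cps, a, lam)[:, d]
        fmn = momentum_field(queries - e, cps, a, lam)[:, d]
        fd += (fp - fmn) / (2 * h)
    np.testing.assert_allclose(analytic, fd, atol=1e-5)
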