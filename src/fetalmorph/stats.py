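"""Statistics on atlas momenta: PCA, pointwise multivariate tests with
max-statistic permutation p-values, age-effect regression and divergence maps.

A subject is a row of the momenta matrix ``M`` (n_subjects x D with
D = 3 x n_control_points).  Pointwise tests treat each control point's 3-D
momentum block as the response: Hotelling's t-squared for a two-group
contrast, a multivariate-Gaussian log-likelihood-ratio statistic for general
regressors.  Family-wise error over control points is handled by permuting
labels and comparing the observed maximum statistic with its permutation
distribution (p-values carry the +1/(N+1) correction, which keeps them valid
for any number of permutations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernel import ControlPointSet, KernelConfig, Momenta, gaussian_kernel, warp_mesh
from .mesh import SurfaceMesh

__all__ = [
    "PcaDecomposition",
    "PointwiseStatField",
    "PermutationTestResult",
    "pca_momenta",
    "mode_visualization_meshes",
    "hotelling_t2_field",
    "regression_lrt_field",
    "max_stat_permutation",
    "age_effect_model",
    "divergence_field",
]

RIDGE_COND_LIMIT = 1e8
RIDGE_GAMMA = 1e-8


@dataclass
class PcaDecomposition:
    """Mean-centred SVD of the momenta matrix."""

    mean: np.ndarray  # (D,)
    modes: np.ndarray  # (n_modes, D), orthonormal rows
    singular_values: np.ndarray  # (n_modes,)
    explained_fractions: np.ndarray  # (n_modes,), of total variance
    scores: np.ndarray  # (n_subjects, n_modes)

    def mode_sd(self, idx: int) -> float:
        """Standard deviation of the scores along one mode."""
        n = len(self.scores)
        return float(self.singular_values[idx] / np.sqrt(n - 1))


@dataclass
class PointwiseStatField:
    """One scalar statistic per control point plus its observed maximum."""

    values: np.ndarray
    statistic: str
    observed_max: float
    point_p_values: np.ndarray | None = None


@dataclass
class PermutationTestResult:
    p_value: float
    n_permutations: int
    seed: int
    max_stat_sample: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("permutation p-value must lie in (0, 1]")


def pca_momenta(M: np.ndarray, n_modes: int | None = None) -> PcaDecomposition:
    """Principal modes of momenta variation via SVD of the centred matrix."""
    M = np.asarray(M, dtype=float)
    n = len(M)
    if n < 2:
        raise ValueError("PCA needs at least 2 subjects")
    mean = M.mean(axis=0)
    centered = M - mean
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    total_var = float(np.sum(s**2))
    if n_modes is None:
        n_modes = len(s)
    n_modes = min(n_modes, len(s))
    fractions = s[:n_modes] ** 2 / total_var if total_var > 0 else np.zeros(n_modes)
    return PcaDecomposition(
        mean=mean,
        modes=Vt[:n_modes],
        singular_values=s[:n_modes],
        explained_fractions=fractions,
        scores=centered @ Vt[:n_modes].T,
    )


def mode_visualization_meshes(
    atlas, pca: PcaDecomposition, mode_idx: int, sd_multiples=(-2.0, 2.0)
) -> list[SurfaceMesh]:
    """Template warped along one PCA mode at the requested SD multiples."""
    if not 0 <= mode_idx < len(pca.modes):
        raise IndexError(f"mode {mode_idx} out of range")
    sd = pca.mode_sd(mode_idx)
    out = []
    for mult in np.atleast_1d(sd_multiples):
        a = (mult * sd * pca.modes[mode_idx]).reshape(-1, 3)
        out.append(warp_mesh(atlas.template, atlas.cps, a, atlas.config))
    return out


def _blocks(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.shape[1] % 3:
        raise ValueError("momenta matrix width must be a multiple of 3")
    return M.reshape(len(M), -1, 3)


def _regularize(S: np.ndarray) -> np.ndarray:
    """Ridge 3x3 covariances whose condition number exceeds the shared limit."""
    eigvals = np.linalg.eigvalsh(S)
    lo = eigvals[..., 0]
    hi = eigvals[..., -1]
    bad = (lo <= 0) | (hi > RIDGE_COND_LIMIT * np.maximum(lo, 1e-300))
    if np.any(bad):
        tr = np.einsum("...ii->...", S)
        ridge = np.maximum(RIDGE_GAMMA * tr / 3.0, 1e-300)
        S = S.copy()
        S[bad] += ridge[bad, None, None] * np.eye(3)
    return S


def hotelling_t2_field(M: np.ndarray, labels) -> PointwiseStatField:
    """Two-sample Hotelling t-squared at each control point's 3-D block.

    ``t2 = (n1*n2/(n1+n2)) * d^T S^-1 d`` with the pooled covariance ``S``
    (divisor n1+n2-2); near-singular covariances receive the shared ridge.
    """
    X = _blocks(M)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("hotelling_t2_field needs exactly two groups")
    m1 = labels == groups[0]
    n1, n2 = int(m1.sum()), int((~m1).sum())
    if min(n1, n2) < 2:
        raise ValueError("each group needs at least 2 subjects")
    mu1 = X[m1].mean(axis=0)
    mu2 = X[~m1].mean(axis=0)
    c1 = X[m1] - mu1
    c2 = X[~m1] - mu2
    S = (np.einsum("npi,npj->pij", c1, c1) + np.einsum("npi,npj->pij", c2, c2)) / (
        n1 + n2 - 2
    )
    S = _regularize(S)
    d = mu1 - mu2
    sol = np.linalg.solve(S, d[..., None])[..., 0]
    t2 = (n1 * n2 / (n1 + n2)) * np.einsum("pi,pi->p", d, sol)
    t2 = np.maximum(t2, 0.0)
    return PointwiseStatField(t2, "t2", float(t2.max()))


def _batched_max_t2(X: np.ndarray, group1_masks: np.ndarray) -> np.ndarray:
    """Maximum per-point t-squared for many labelings at once.

    ``X`` is (n, p, 3); ``group1_masks`` is (B, n) boolean.  Uses the identity
    pooled-scatter = total-scatter - n1 mu1 mu1^T - n2 mu2 mu2^T so the heavy
    second-moment sum is computed once.
    """
    n = X.shape[0]
    T = np.einsum("npi,npj->pij", X, X)  # total second moment
    total = X.sum(axis=0)  # (p, 3)
    G = group1_masks.astype(float)  # (B, n)
    n1 = G.sum(axis=1)  # (B,)
    n2 = n - n1
    s1 = np.einsum("bn,npi->bpi", G, X)
    mu1 = s1 / n1[:, None, None]
    mu2 = (total[None] - s1) / n2[:, None, None]
    S = (
        T[None]
        - n1[:, None, None, None] * np.einsum("bpi,bpj->bpij", mu1, mu1)
        - n2[:, None, None, None] * np.einsum("bpi,bpj->bpij", mu2, mu2)
    ) / (n - 2)
    S = _regularize(S)
    d = mu1 - mu2
    sol = np.linalg.solve(S, d[..., None])[..., 0]
    coef = n1 * n2 / n
    t2 = coef[:, None] * np.einsum("bpi,bpi->bp", d, sol)
    return np.maximum(t2, 0.0)


def regression_lrt_field(
    M: np.ndarray, design_matrix: np.ndarray, tested_columns
) -> PointwiseStatField:
    """Log-likelihood-ratio statistic for multivariate linear regression.

    At each control point the 3-variate Gaussian linear model with the full
    design is compared against the design with ``tested_columns`` removed:
    ``LRT = n * ln(det(S0) / det(S1))`` with ML residual covariances.  With a
    single binary tested column this is a monotone function of Hotelling's
    t-squared.
    """
    X = np.asarray(design_matrix, dtype=float)
    tested = np.atleast_1d(np.asarray(tested_columns, dtype=int))
    n, q = X.shape
    if np.linalg.matrix_rank(X) < q:
        # name offending columns: those whose removal does not reduce rank
        redundant = [
            j for j in range(q)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == np.linalg.matrix_rank(X)
        ]
        raise ValueError(f"rank-deficient design matrix; redundant columns: {redundant}")
    if n <= q + 3:
        raise ValueError("too few subjects for the design")
    Y = _blocks(M)
    X0 = np.delete(X, tested, axis=1)

    def residual_scatter(design: np.ndarray) -> np.ndarray:
        # residual maker applied to every (point, coord) response at once
        Q, _ = np.linalg.qr(design)
        flat = Y.reshape(n, -1)
        resid = flat - Q @ (Q.T @ flat)
        R = resid.reshape(n, -1, 3)
        return np.einsum("npi,npj->pij", R, R)

    S1 = residual_scatter(X) / n
    S0 = residual_scatter(X0) / n
    S1 = _regularize(S1)
    S0 = _regularize(S0)
    stat = n * (np.linalg.slogdet(S0)[1] - np.linalg.slogdet(S1)[1])
    stat = np.maximum(stat, 0.0)
    return PointwiseStatField(stat, "lrt", float(stat.max()))


def max_stat_permutation(
    M: np.ndarray,
    values,
    stat: str = "t2",
    n_perm: int = 1000,
    seed: int = 0,
    covariates: np.ndarray | None = None,
) -> tuple[PointwiseStatField, PermutationTestResult]:
    """Family-wise-error-controlled permutation test of the maximum statistic.

    ``values`` holds the group labels (``stat="t2"``) or the tested covariate
    (``stat="lrt"``, design = intercept + optional covariates + tested
    column).  Labels are permuted with a seeded generator and
    ``p = (1 + #{perm max >= observed max}) / (n_perm + 1)``.  Per-point
    empirical p-values (against each point's own permutation null) are
    attached to the returned field for projection onto the template.
    """
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    values = np.asarray(values)
    if len(np.unique(values)) < 2:
        raise ValueError("constant labels/covariate cannot be tested")
    rng = np.random.default_rng(seed)
    M = np.asarray(M, dtype=float)
    n = len(M)

    if stat == "t2":
        X = _blocks(M)
        groups = np.unique(values)
        if len(groups) != 2:
            raise ValueError("t2 permutation test needs two groups")
        base_mask = values == groups[0]
        masks = np.empty((n_perm + 1, n), dtype=bool)
        masks[0] = base_mask
        for b in range(n_perm):
            masks[b + 1] = base_mask[rng.permutation(n)]
        # chunk the batched solve to bound memory
        all_t2 = np.vstack(
            [_batched_max_t2(X, masks[i : i + 64]) for i in range(0, len(masks), 64)]
        )
        observed_field = all_t2[0]
        perm_fields = all_t2[1:]
        name = "t2"
    elif stat == "lrt":
        def build_design(v):
            cols = [np.ones(n)]
            if covariates is not None:
                cov = np.atleast_2d(np.asarray(covariates, dtype=float))
                cols.extend(cov.T if cov.shape[0] == n else cov)
            cols.append(np.asarray(v, dtype=float))
            return np.column_stack(cols)

        tested = [-1 + build_design(values).shape[1]]
        observed_field = regression_lrt_field(M, build_design(values), tested).values
        perm_fields = np.empty((n_perm, len(observed_field)))
        for b in range(n_perm):
            perm_fields[b] = regression_lrt_field(
                M, build_design(np.asarray(values)[rng.permutation(n)]), tested
            ).values
        name = "lrt"
    else:
        raise ValueError(f"unknown statistic {stat!r}")

    observed_max = float(observed_field.max())
    perm_max = perm_fields.max(axis=1)
    p = (1.0 + float(np.sum(perm_max >= observed_max - 1e-12))) / (n_perm + 1.0)
    point_p = (1.0 + (perm_fields >= observed_field[None] - 1e-12).sum(axis=0)) / (
        n_perm + 1.0
    )
    field_out = PointwiseStatField(observed_field, name, observed_max, point_p)
    return field_out, PermutationTestResult(p, n_perm, seed, perm_max)


def age_effect_model(M: np.ndarray, ga_weeks) -> tuple[np.ndarray, callable]:
    """Linear age trend of the momenta.

    Per-coordinate least squares ``M ~ b0 + ga * b1``; returns ``b1`` reshaped
    as a momenta field (n_cp, 3) and a predictor ``m_hat(ga)`` whose output can
    be used to warp the template to age-extreme morphologies.
    """
    ga = np.asarray(ga_weeks, dtype=float)
    if np.ptp(ga) == 0:
        raise ValueError("gestational age is constant")
    M = np.asarray(M, dtype=float)
    X = np.column_stack([np.ones(len(ga)), ga])
    beta, *_ = np.linalg.lstsq(X, M, rcond=None)
    b0, b1 = beta

    def predict(ga_value: float) -> np.ndarray:
        return (b0 + ga_value * b1).reshape(-1, 3)

    return b1.reshape(-1, 3), predict


def divergence_field(cps, a, lambda_V: float, query_points: np.ndarray) -> np.ndarray:
    """Analytic divergence of the momentum field at the query points.

    ``div m(x) = sum_i (-2 / lambda_V^2) K(x, c_i) (x - c_i) . a_i``.
    """
    c = cps.points if isinstance(cps, ControlPointSet) else np.asarray(cps, float).reshape(-1, 3)
    vec = a.vectors if isinstance(a, Momenta) else np.asarray(a, float).reshape(-1, 3)
    q = np.asarray(query_points, dtype=float).reshape(-1, 3)
    K = gaussian_kernel(q, c, lambda_V)
    # (x - c_i) . a_i expanded: x . a_i - c_i . a_i
    xa = q @ vec.T  # (nq, nc)
    ca = np.einsum("ci,ci->c", c, vec)  # (nc,)
    return (-2.0 / lambda_V**2) * np.einsum("qc,qc->q", K, xa - ca[None, :])
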