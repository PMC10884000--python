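"""Standardised shape scores for individual subjects.

Both scores compare a subject's momentum field, evaluated at every cell
center of the template mesh, against its distribution over the control (AGA)
cohort.  With per-cell control mean ``m_bar`` and covariance ``Sigma_bar``:

* deformation score ``z_d = (m - m_bar)^T Sigma_bar^{-1} (m - m_bar)`` —
  a Mahalanobis norm of the full 3-D deviation, chi-squared with 3 degrees of
  freedom under a Gaussian null (95% bound 7.8);
* orthogonal score ``z_o = (m - m_bar) . n / sigma_n`` — the deviation along
  the cell normal in control-SD units, standard normal under the null with
  the usual [-2, +2] 95% interval.  Positive values are outward of the mean.

``sigma_n^2 = n^T Sigma_bar n`` algebraically, which gives the projection
bound ``z_o^2 <= z_d`` wherever both are defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kernel import gaussian_kernel, register
from .mesh import SurfaceMesh, cell_geometry
from .stats import RIDGE_COND_LIMIT, RIDGE_GAMMA

__all__ = [
    "ScoreModel",
    "ScoreField",
    "fit_score_model",
    "momentum_field_at_cells",
    "deformation_score",
    "orthogonal_score",
    "deformation_score_from_field",
    "orthogonal_score_from_field",
    "score_new_subject",
]


@dataclass
class ScoreModel:
    """Reference distribution of the control cohort at template cell centers."""

    points: np.ndarray  # (m, 3) template cell centers
    normals: np.ndarray  # (m, 3) unit cell normals
    mean: np.ndarray  # (m, 3) control mean momentum field
    covariance: np.ndarray  # (m, 3, 3), divisor N-1
    sigma_n: np.ndarray  # (m,) SD of the normal projection, divisor N-1
    n_controls: int
    kernel_matrix: np.ndarray  # (m, n_cp) K(x, c_i) for fast field evaluation

    @property
    def n_cells(self) -> int:
        return len(self.points)


@dataclass
class ScoreField:
    """Per-cell scores for one subject; NaN marks flagged-missing cells."""

    z_d: np.ndarray
    z_o: np.ndarray
    subject_id: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_index": np.arange(len(self.z_d)),
                "z_d": self.z_d,
                "z_o": self.z_o,
                "flagged": ~(np.isfinite(self.z_d) & np.isfinite(self.z_o)),
            }
        )


def momentum_field_at_cells(model: ScoreModel, subject_momenta: np.ndarray) -> np.ndarray:
    a = np.asarray(subject_momenta, dtype=float).reshape(-1, 3)
    return model.kernel_matrix @ a


def fit_score_model(atlas, control_ids) -> ScoreModel:
    """Estimate the per-cell reference distribution from control subjects.

    Evaluates every control's momentum field at the template cell centers and
    records the mean, the 3x3 covariance and the SD of the normal projection
    (both with divisor N-1).
    """
    control_ids = list(control_ids)
    idx = [atlas.subject_ids.index(cid) for cid in control_ids]
    if len(idx) < 5:
        raise ValueError("score model needs at least 5 control subjects")
    centers, normals, _ = cell_geometry(atlas.template)
    K = gaussian_kernel(centers, atlas.cps.points, atlas.config.lambda_V)
    fields = np.stack([K @ atlas.momenta[i].vectors for i in idx])  # (N, m, 3)
    N = len(idx)
    mean = fields.mean(axis=0)
    centered = fields - mean
    cov = np.einsum("nmi,nmj->mij", centered, centered) / (N - 1)
    proj = np.einsum("nmi,mi->nm", centered, normals)
    sigma_n = np.sqrt((proj**2).sum(axis=0) / (N - 1))
    return ScoreModel(centers, normals, mean, cov, sigma_n, N, K)


def _inverse_with_ridge(cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell inverse covariance via symmetric eigendecomposition.

    Cells whose covariance is ill-conditioned get the shared ridge policy;
    cells that stay singular even then are flagged (mask False).
    """
    w, V = np.linalg.eigh(cov)
    bad = (w[:, 0] <= 0) | (w[:, -1] > RIDGE_COND_LIMIT * np.maximum(w[:, 0], 1e-300))
    if np.any(bad):
        tr = np.clip(w.sum(axis=1), 0.0, None)
        cov = cov.copy()
        cov[bad] += (RIDGE_GAMMA * tr / 3.0)[bad, None, None] * np.eye(3)
        w, V = np.linalg.eigh(cov)
    # cells singular even after the ridge (e.g. zero control variance) are flagged
    ok = w[:, 0] > 1e-12 * np.maximum(w[:, -1], 0) + 0.0
    ok &= w[:, 0] > 0
    w_safe = np.where(w > 0, w, 1.0)
    inv = np.einsum("mij,mj,mkj->mik", V, 1.0 / w_safe, V)
    return inv, ok


def deformation_score_from_field(model: ScoreModel, m_at_cells: np.ndarray) -> np.ndarray:
    """``z_d`` from momentum vectors already evaluated at the cell centers.

    ``m_at_cells`` may be (m, 3) for one subject or (n, m, 3) for a batch.
    Cells with singular covariance (after the ridge) come back as NaN.
    """
    inv, ok = _inverse_with_ridge(model.covariance)
    d = np.asarray(m_at_cells, dtype=float) - model.mean
    z = np.einsum("...mi,mij,...mj->...m", d, inv, d)
    z = np.where(ok, z, np.nan)
    return np.maximum(z, 0.0, where=np.isfinite(z), out=z)


def orthogonal_score_from_field(model: ScoreModel, m_at_cells: np.ndarray) -> np.ndarray:
    """``z_o`` from momentum vectors already evaluated at the cell centers."""
    d = np.asarray(m_at_cells, dtype=float) - model.mean
    proj = np.einsum("...mi,mi->...m", d, model.normals)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = proj / model.sigma_n
    return np.where(model.sigma_n > 0, z, np.nan)


def deformation_score(model: ScoreModel, subject_momenta: np.ndarray) -> np.ndarray:
    """Per-cell deformation score of one subject's momenta (non-negative)."""
    return deformation_score_from_field(model, momentum_field_at_cells(model, subject_momenta))


def orthogonal_score(model: ScoreModel, subject_momenta: np.ndarray) -> np.ndarray:
    """Per-cell signed orthogonal score of one subject's momenta."""
    return orthogonal_score_from_field(model, momentum_field_at_cells(model, subject_momenta))


def score_new_subject(
    atlas,
    model: ScoreModel,
    mesh: SurfaceMesh,
    landmarks=None,
    reference_landmarks=None,
    register_opts: dict | None = None,
) -> tuple[ScoreField, np.ndarray]:
    """Register a preprocessed mesh to the template and score it.

    The mesh must already be size-normalised.  If ``landmarks`` (the subject's)
    and ``reference_landmarks`` (the template's) are given, the mesh is first
    rigidly aligned to the template frame; otherwise it must already be
    aligned.  Returns the score field and the fitted momenta.
    """
    if landmarks is not None:
        from .mesh import icp_align, landmark_align

        if reference_landmarks is None:
            raise ValueError("reference_landmarks required when landmarks are given")
        t = landmark_align(landmarks, reference_landmarks)
        t = icp_align(mesh, atlas.template, max_iter=10, initial=t)
        mesh = mesh.transformed(t)
    momenta, _ = register(atlas.template, mesh, atlas.cps, atlas.config, register_opts)
    zd = deformation_score(model, momenta.vectors)
    zo = orthogonal_score(model, momenta.vectors)
    return ScoreField(zd, zo, mesh.subject_id), momenta.vectors
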