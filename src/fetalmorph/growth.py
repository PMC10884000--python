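"""Face-size surrogate, quantile growth curve and size normalisation.

The dominant change of the fetal face between 24 and 34 gestational weeks is
growth.  To study shape rather than size, each mesh is rescaled to the size
predicted at a reference age (29 weeks) by a quadratic growth curve fitted by
quantile regression to a point-cloud size surrogate.

The surrogate is ``2 * sqrt(pi) * (l1 * l2)**0.25`` where ``l1 >= l2`` are the
two leading eigenvalues of the vertex covariance: the square root of the area
of the ellipse whose semi-axes are two standard deviations along the two
principal in-plane directions.  The constant is cosmetic — rescaling uses only
ratios of the surrogate, so it cancels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import hstack, identity, csr_matrix

from .mesh import DegenerateGeometryError, SurfaceMesh

__all__ = ["GrowthCurve", "face_size", "fit_growth_curve", "rescale_mesh"]

DEFAULT_QUANTILES = (0.05, 0.5, 0.95)
GA_RANGE = (24.0, 34.0)


@dataclass
class GrowthCurve:
    """Per-quantile polynomial coefficients of size (mm) versus age (weeks).

    ``coefficients[tau]`` holds ``(b0, b1, ..., b_degree)`` for
    ``size(ga) = b0 + b1*ga + ... ``.  Raw coefficients are preserved;
    :meth:`evaluate` repairs quantile crossing by sorting the predicted values
    at each evaluation point.
    """

    coefficients: dict[float, np.ndarray]
    reference_ga: float = 29.0
    quantiles: tuple[float, ...] = DEFAULT_QUANTILES

    def evaluate(self, ga, tau: float = 0.5) -> np.ndarray | float:
        ga_arr = np.atleast_1d(np.asarray(ga, dtype=float))
        taus = sorted(self.coefficients)
        raw = np.vstack([np.polyval(self.coefficients[t][::-1], ga_arr) for t in taus])
        repaired = np.sort(raw, axis=0)
        values = repaired[taus.index(tau)]
        return float(values[0]) if np.isscalar(ga) else values

    def median(self, ga) -> np.ndarray | float:
        return self.evaluate(ga, 0.5)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "reference_ga": self.reference_ga,
            "quantiles": list(self.quantiles),
            "coefficients": {str(t): c.tolist() for t, c in self.coefficients.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GrowthCurve":
        payload = json.loads(Path(path).read_text())
        return cls(
            coefficients={float(t): np.array(c) for t, c in payload["coefficients"].items()},
            reference_ga=payload["reference_ga"],
            quantiles=tuple(payload["quantiles"]),
        )


def face_size(mesh: SurfaceMesh | np.ndarray) -> float:
    """Point-cloud size surrogate of an open face mesh (mm).

    Centre the vertices, take the two leading eigenvalues ``l1 >= l2`` of the
    3x3 covariance (divisor n-1) and return ``2*sqrt(pi)*(l1*l2)**0.25``.
    Scales exactly linearly with the mesh and is rotation invariant.
    """
    pts = mesh.vertices if isinstance(mesh, SurfaceMesh) else np.asarray(mesh, float)
    if len(pts) < 3:
        raise DegenerateGeometryError("face_size needs at least 3 vertices")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / (len(pts) - 1)
    eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    l1, l2 = eigvals[0], eigvals[1]
    if l2 <= 1e-12 * max(l1, 1.0):
        raise DegenerateGeometryError("vertex cloud is (near-)collinear")
    return float(2.0 * np.sqrt(np.pi) * (l1 * l2) ** 0.25)


def _pinball_lp(X: np.ndarray, y: np.ndarray, tau: float) -> np.ndarray:
    """Exact quantile regression: minimise the pinball loss as a linear program."""
    n, p = X.shape
    # variables: beta+ (p), beta- (p), u+ (n), u- (n)
    cost = np.concatenate([np.zeros(2 * p), tau * np.ones(n), (1 - tau) * np.ones(n)])
    A_eq = hstack([csr_matrix(X), csr_matrix(-X), identity(n), -identity(n)], format="csr")
    res = linprog(cost, A_eq=A_eq, b_eq=y, bounds=[(0, None)] * (2 * p + 2 * n), method="highs")
    if not res.success:
        raise RuntimeError(f"quantile regression LP failed: {res.message}")
    return res.x[:p] - res.x[p : 2 * p]


def fit_growth_curve(
    sizes: np.ndarray,
    ga_weeks: np.ndarray,
    quantiles: tuple[float, ...] = DEFAULT_QUANTILES,
    degree: int = 2,
    reference_ga: float = 29.0,
) -> GrowthCurve:
    """Fit polynomial quantile-regression curves of size against gestational age.

    Each quantile minimises the pinball loss, solved exactly as a linear
    program; at tau = 0.5 the fraction of non-positive residuals is within
    ``1/n`` of 0.5 by LP optimality.
    """
    sizes = np.asarray(sizes, dtype=float).ravel()
    ga = np.asarray(ga_weeks, dtype=float).ravel()
    if len(sizes) != len(ga):
        raise ValueError("sizes and ga_weeks must have the same length")
    if len(sizes) < 10:
        raise ValueError("growth-curve fit needs at least 10 observations")
    if ga.min() < GA_RANGE[0] - 1e-9 or ga.max() > GA_RANGE[1] + 1e-9:
        warnings.warn("gestational ages outside the 24-34 week modelling range")
    X = np.vander(ga, degree + 1, increasing=True)
    if np.linalg.matrix_rank(X) < degree + 1:
        raise ValueError("rank-deficient design: gestational ages do not span the model")
    coefficients = {float(tau): _pinball_lp(X, sizes, tau) for tau in quantiles}
    return GrowthCurve(coefficients, reference_ga=reference_ga, quantiles=tuple(quantiles))


def rescale_mesh(mesh: SurfaceMesh, ga: float, curve: GrowthCurve) -> SurfaceMesh:
    """Isotropically rescale a mesh to the reference-age median size.

    Scales about the vertex centroid by
    ``f = median(reference_ga) / median(ga)``; ``face_size`` of the output is
    exactly ``f`` times that of the input.
    """
    if not GA_RANGE[0] <= ga <= GA_RANGE[1]:
        warnings.warn(f"gestational age {ga} outside the 24-34 week modelling range")
    denom = curve.median(ga)
    if denom <= 0:
        raise ValueError(f"median growth curve non-positive at ga={ga}")
    f = curve.median(curve.reference_ga) / denom
    centroid = mesh.vertices.mean(axis=0)
    return SurfaceMesh(
        centroid + f * (mesh.vertices - centroid), mesh.triangles.copy(), mesh.subject_id
    )
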