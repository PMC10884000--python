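"""Gaussian-kernel control-point deformation model.

A deformation is parameterised by 3-D momentum vectors ``a_i`` attached to
control points ``c_i``.  The velocity field is the kernel sum
``v(x) = sum_i K(x, c_i) a_i`` with the Gaussian kernel
``K(x, y) = exp(-||x - y||^2 / lambda_V^2)`` (no factor 2 in the exponent;
this convention is used everywhere in the package).  With one time step the
deformation is a single displacement by the field; with more steps the
point-kernel Hamiltonian system is integrated, giving a diffeomorphic flow.

Surfaces are compared with a varifold metric: orientation-insensitive
(normals enter squared), so inconsistent triangle winding does not bias the
data term.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from .mesh import SurfaceMesh, cell_geometry

__all__ = [
    "KernelConfig",
    "ControlPointSet",
    "Momenta",
    "RegistrationDiverged",
    "gaussian_kernel",
    "kernel",
    "momentum_field",
    "momenta_regularizer",
    "shoot",
    "warp_mesh",
    "warp_points",
    "varifold_distance",
    "register",
    "save_momenta",
    "load_momenta",
]


@dataclass(frozen=True)
class KernelConfig:
    """Model parameters: deformation stiffness ``lambda_V`` and data-term
    resolution ``lambda_W`` (both mm, default 7), number of integration steps
    and the data-term weight ``noise_std`` (mm)."""

    lambda_V: float = 7.0
    lambda_W: float = 7.0
    n_time_steps: int = 1
    noise_std: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda_V <= 0 or self.lambda_W <= 0:
            raise ValueError("kernel widths must be positive")
        if self.n_time_steps < 1:
            raise ValueError("n_time_steps must be >= 1")


class ControlPointSet:
    """Spatial anchors of the deformation parameterisation."""

    def __init__(self, points: np.ndarray):
        self.points = np.asarray(points, dtype=float).reshape(-1, 3)
        if len(self.points) > 1:
            d = cdist(self.points, self.points)
            np.fill_diagonal(d, np.inf)
            if d.min() == 0:
                raise ValueError("control points must be pairwise distinct")

    def __len__(self) -> int:
        return len(self.points)


class Momenta:
    """Per-subject momentum vectors, one 3-D vector per control point."""

    def __init__(self, vectors: np.ndarray):
        self.vectors = np.asarray(vectors, dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.vectors)

    @property
    def flat_dimension(self) -> int:
        return 3 * len(self.vectors)


class RegistrationDiverged(RuntimeError):
    def __init__(self, message: str, energy_trace: list[float]):
        super().__init__(message)
        self.energy_trace = energy_trace


def gaussian_kernel(x: np.ndarray, y: np.ndarray, sigma: float) -> np.ndarray:
    """Kernel matrix ``exp(-||x_i - y_j||^2 / sigma^2)``."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    return np.exp(-cdist(x, y, "sqeuclidean") / sigma**2)


def kernel(x: np.ndarray, y: np.ndarray, sigma: float) -> float:
    """Scalar Gaussian kernel between two points."""
    x = np.asarray(x, dtype=float).reshape(3)
    y = np.asarray(y, dtype=float).reshape(3)
    return float(np.exp(-np.dot(x - y, x - y) / sigma**2))


def _as_points(obj) -> np.ndarray:
    return obj.points if isinstance(obj, ControlPointSet) else np.asarray(obj, float).reshape(-1, 3)


def _as_vectors(obj) -> np.ndarray:
    return obj.vectors if isinstance(obj, Momenta) else np.asarray(obj, float).reshape(-1, 3)


def momentum_field(
    query_points: np.ndarray, cps, a, lambda_V: float
) -> np.ndarray:
    """Evaluate ``m(x) = sum_i K(x, c_i) a_i`` at each query point; linear in ``a``."""
    q = np.asarray(query_points, dtype=float).reshape(-1, 3)
    c = _as_points(cps)
    vec = _as_vectors(a)
    return gaussian_kernel(q, c, lambda_V) @ vec


def momenta_regularizer(cps, a, lambda_V: float) -> float:
    """RKHS norm ``sum_ij a_i^T K(c_i, c_j) a_j`` of the deformation."""
    c = _as_points(cps)
    vec = _as_vectors(a)
    K = gaussian_kernel(c, c, lambda_V)
    return float(np.sum((K @ vec) * vec))


def shoot(cps, a, config: KernelConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    """Euler-integrate the point-kernel Hamiltonian system.

    Dynamics: ``dc_i/dt = dH/da_i = sum_j K(c_i,c_j) a_j`` and
    ``da_i/dt = -dH/dc_i = (2/lambda_V^2) sum_j K(c_i,c_j) (a_i . a_j)(c_i - c_j)``
    for the Hamiltonian ``H = 0.5 sum_ij (a_i . a_j) K(c_i, c_j)`` with the
    ``exp(-r^2/sigma^2)`` kernel, integrated with step ``1/n_time_steps``.
    Returns the trajectory ``[(c(0), a(0)), ..., (c(1), a(1))]``; with one
    step this degenerates to a single displacement.
    """
    c = _as_points(cps).copy()
    vec = _as_vectors(a).copy()
    dt = 1.0 / config.n_time_steps
    trajectory = [(c.copy(), vec.copy())]
    for _ in range(config.n_time_steps):
        K = gaussian_kernel(c, c, config.lambda_V)
        dc = K @ vec
        dots = vec @ vec.T  # a_i . a_j
        w = K * dots
        # sum_j w_ij (c_i - c_j)
        da = (2.0 / config.lambda_V**2) * (c * w.sum(axis=1)[:, None] - w @ c)
        c = c + dt * dc
        vec = vec + dt * da
        trajectory.append((c.copy(), vec.copy()))
    return trajectory


def warp_points(points: np.ndarray, cps, a, config: KernelConfig) -> np.ndarray:
    """Transport points along the time-varying velocity field of the flow."""
    x = np.asarray(points, dtype=float).reshape(-1, 3).copy()
    dt = 1.0 / config.n_time_steps
    for c_t, a_t in shoot(cps, a, config)[:-1]:
        x = x + dt * (gaussian_kernel(x, c_t, config.lambda_V) @ a_t)
    return x


def warp_mesh(mesh: SurfaceMesh, cps, a, config: KernelConfig) -> SurfaceMesh:
    """Warp mesh vertices by the deformation; topology is unchanged."""
    return SurfaceMesh(
        warp_points(mesh.vertices, cps, a, config), mesh.triangles.copy(), mesh.subject_id
    )


# ---------------------------------------------------------------------------
# Varifold metric


def _varifold_repr(mesh: SurfaceMesh) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    centers, normals, areas = cell_geometry(mesh)
    return centers, normals, areas


def _varifold_inner(ca, ua, sa, cb, ub, sb, lambda_W: float) -> float:
    K = gaussian_kernel(ca, cb, lambda_W)
    dots = ua @ ub.T
    return float(np.sum(K * dots**2 * np.outer(sa, sb)))


def varifold_distance(mesh_a: SurfaceMesh, mesh_b: SurfaceMesh, lambda_W: float) -> float:
    """Squared varifold distance ``<A,A> - 2<A,B> + <B,B>``.

    ``<A,B> = sum_pq K(x_p, x_q; lambda_W) (u_p . u_q)^2 s_p s_q`` over cell
    centers ``x``, unit normals ``u`` and areas ``s``.  Symmetric,
    non-negative, zero iff the two cell measures coincide, and invariant to
    triangle winding (normals enter squared).
    """
    if mesh_a.n_triangles == 0 or mesh_b.n_triangles == 0:
        raise ValueError("varifold distance requires non-empty meshes")
    ca, ua, sa = _varifold_repr(mesh_a)
    cb, ub, sb = _varifold_repr(mesh_b)
    return (
        _varifold_inner(ca, ua, sa, ca, ua, sa, lambda_W)
        - 2.0 * _varifold_inner(ca, ua, sa, cb, ub, sb, lambda_W)
        + _varifold_inner(cb, ub, sb, cb, ub, sb, lambda_W)
    )


def _area_normals(V: np.ndarray, F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a, b, c = V[F[:, 0]], V[F[:, 1]], V[F[:, 2]]
    return (a + b + c) / 3.0, 0.5 * np.cross(b - a, c - a)


def _varifold_value_grad_half(
    x: np.ndarray, N: np.ndarray, y: np.ndarray, M: np.ndarray, lambda_W: float
) -> tuple[float, np.ndarray, np.ndarray]:
    """Value and gradient wrt (x, N) of ``<A,B>`` written with area-normals.

    ``<A,B> = sum_pq k(x_p,y_q) (N_p . M_q)^2 / (|N_p| |M_q|)``.
    """
    s = np.linalg.norm(N, axis=1)
    t = np.linalg.norm(M, axis=1)
    K = gaussian_kernel(x, y, lambda_W)
    dots = N @ M.T
    C = K * dots**2 / np.outer(s, t)
    value = float(C.sum())
    row = C.sum(axis=1)
    grad_x = (-2.0 / lambda_W**2) * (x * row[:, None] - C @ y)
    grad_N = (2.0 * (K * dots / np.outer(s, t))) @ M - (row / s**2)[:, None] * N
    return value, grad_x, grad_N


def varifold_distance_gradient(
    V: np.ndarray, F: np.ndarray, target: SurfaceMesh, lambda_W: float
) -> tuple[float, np.ndarray]:
    """Squared varifold distance to ``target`` and its gradient wrt vertices ``V``."""
    x, N = _area_normals(V, F)
    tv = target.vertices
    y, M = _area_normals(tv, target.triangles)
    vaa, gx_aa, gN_aa = _varifold_value_grad_half(x, N, x, N, lambda_W)
    vab, gx_ab, gN_ab = _varifold_value_grad_half(x, N, y, M, lambda_W)
    vbb = _varifold_value_grad_half(y, M, y, M, lambda_W)[0]
    value = vaa - 2.0 * vab + vbb
    gx = 2.0 * gx_aa - 2.0 * gx_ab  # <A,A> hits both slots -> factor 2
    gN = 2.0 * gN_aa - 2.0 * gN_ab
    return value, _scatter_vertex_grad(V, F, gx, gN)


# ---------------------------------------------------------------------------
# Registration


def _scatter_vertex_grad(
    V: np.ndarray, F: np.ndarray, gx: np.ndarray, gN: np.ndarray
) -> np.ndarray:
    """Accumulate per-triangle (centroid, area-normal) gradients onto vertices."""
    grad = np.zeros_like(V)
    i, j, k = F[:, 0], F[:, 1], F[:, 2]
    third = gx / 3.0
    np.add.at(grad, i, third)
    np.add.at(grad, j, third)
    np.add.at(grad, k, third)
    np.add.at(grad, i, 0.5 * np.cross(V[j] - V[k], gN))
    np.add.at(grad, j, 0.5 * np.cross(V[k] - V[i], gN))
    np.add.at(grad, k, 0.5 * np.cross(V[i] - V[j], gN))
    return grad


def registration_energy_grad(
    template: SurfaceMesh,
    target: SurfaceMesh,
    cps,
    a_flat: np.ndarray,
    config: KernelConfig,
) -> tuple[float, np.ndarray]:
    """Energy ``E(a) = d_W(warp(T,a), target)/noise_std^2 + a^T K_V a`` and its
    gradient, analytic for the single-step displacement model."""
    fun = _make_registration_objective(template, target, cps, config)
    return fun(np.asarray(a_flat, dtype=float).ravel())


def _make_registration_objective(
    template: SurfaceMesh, target: SurfaceMesh, cps, config: KernelConfig
):
    """Closure computing energy + analytic gradient with cached kernel matrices."""
    c = _as_points(cps)
    V0, F = template.vertices, template.triangles
    K_vc = gaussian_kernel(V0, c, config.lambda_V)
    K_cc = gaussian_kernel(c, c, config.lambda_V)
    y, M = _area_normals(target.vertices, target.triangles)
    vbb = _varifold_value_grad_half(y, M, y, M, config.lambda_W)[0]
    inv_noise2 = 1.0 / config.noise_std**2

    def fun(a_flat: np.ndarray) -> tuple[float, np.ndarray]:
        a = a_flat.reshape(-1, 3)
        warped = V0 + K_vc @ a
        x, N = _area_normals(warped, F)
        vaa, gx_aa, gN_aa = _varifold_value_grad_half(x, N, x, N, config.lambda_W)
        vab, gx_ab, gN_ab = _varifold_value_grad_half(x, N, y, M, config.lambda_W)
        data = vaa - 2.0 * vab + vbb
        grad_v = _scatter_vertex_grad(
            warped, F, 2.0 * gx_aa - 2.0 * gx_ab, 2.0 * gN_aa - 2.0 * gN_ab
        )
        reg = float(np.sum((K_cc @ a) * a))
        energy = data * inv_noise2 + reg
        grad_a = K_vc.T @ grad_v * inv_noise2 + 2.0 * K_cc @ a
        return energy, grad_a.ravel()

    return fun


def register(
    template: SurfaceMesh,
    target: SurfaceMesh,
    cps,
    config: KernelConfig,
    optimizer_opts: dict | None = None,
    a_init: np.ndarray | None = None,
) -> tuple[Momenta, float]:
    """Fit momenta deforming ``template`` onto ``target``.

    Minimises the varifold data term weighted by ``1/noise_std^2`` plus the
    RKHS regulariser by L-BFGS with analytic gradients (single-step
    displacement model).  Returns the momenta and the final energy.
    """
    opts = {"maxiter": 150, "gtol": 1e-6}
    opts.update(optimizer_opts or {})
    c = _as_points(cps)
    x0 = (
        np.zeros(3 * len(c))
        if a_init is None
        else np.asarray(a_init, dtype=float).ravel().copy()
    )
    trace: list[float] = []
    if config.n_time_steps != 1:
        # finite-difference gradients through the full geodesic flow
        cfg = config

        def fun(a_flat):
            warped = warp_mesh(template, c, a_flat.reshape(-1, 3), cfg)
            data = varifold_distance(warped, target, cfg.lambda_W)
            e = data / cfg.noise_std**2 + momenta_regularizer(
                c, a_flat.reshape(-1, 3), cfg.lambda_V
            )
            trace.append(float(e))
            if not np.isfinite(e):
                raise RegistrationDiverged("registration energy became non-finite", trace)
            return e

        jac = None
    else:
        objective = _make_registration_objective(template, target, c, config)

        def fun(a_flat):
            e, g = objective(a_flat)
            trace.append(float(e))
            if not np.isfinite(e):
                raise RegistrationDiverged("registration energy became non-finite", trace)
            return e, g

        jac = True

    res = minimize(
        fun,
        x0,
        jac=jac,
        method="L-BFGS-B",
        options={"maxiter": opts["maxiter"], "gtol": opts["gtol"]},
    )
    if not np.isfinite(res.fun):
        raise RegistrationDiverged("registration diverged", trace)
    return Momenta(res.x.reshape(-1, 3)), float(res.fun)


# ---------------------------------------------------------------------------
# Serialization: delimited text matrix with a JSON header line


def save_momenta(path: str | Path, cps, momenta_list: list, config: KernelConfig) -> None:
    c = _as_points(cps)
    header = json.dumps(
        {
            "lambda_V": config.lambda_V,
            "lambda_W": config.lambda_W,
            "n_time_steps": config.n_time_steps,
            "n_control_points": len(c),
            "n_subjects": len(momenta_list),
        }
    )
    blocks = [c] + [_as_vectors(m) for m in momenta_list]
    body = "\n".join(
        " ".join(f"{v:.17g}" for v in row) for block in blocks for row in block
    )
    Path(path).write_text(f"# {header}\n{body}\n")


def load_momenta(path: str | Path) -> tuple[ControlPointSet, list[Momenta], KernelConfig]:
    lines = Path(path).read_text().splitlines()
    meta = json.loads(lines[0].lstrip("# "))
    rows = np.array([[float(v) for v in ln.split()] for ln in lines[1:] if ln.strip()])
    n_cp = meta["n_control_points"]
    cps = ControlPointSet(rows[:n_cp])
    momenta = [
        Momenta(rows[n_cp * (k + 1) : n_cp * (k + 2)]) for k in range(meta["n_subjects"])
    ]
    config = KernelConfig(
        lambda_V=meta["lambda_V"],
        lambda_W=meta["lambda_W"],
        n_time_steps=meta["n_time_steps"],
    )
    return cps, momenta, config
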