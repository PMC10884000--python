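"""Shape-atlas estimation: template + per-subject momenta.

The atlas alternates per-subject registrations of the current template with a
gradient update of the template vertices against the summed varifold data
terms, so the total energy is non-increasing over outer iterations.  Control
points start on a regular grid over the population bounding box and are
filtered after fitting by their across-subject momenta variance: grid points
far from every face carry essentially no momenta and are inert.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
from scipy.optimize import minimize

from .kernel import (
    ControlPointSet,
    KernelConfig,
    Momenta,
    gaussian_kernel,
    load_momenta,
    register,
    save_momenta,
    varifold_distance_gradient,
    warp_mesh,
)
from .mesh import (
    SurfaceMesh,
    closest_point_on_surface,
    read_mesh,
    remesh_isotropic,
    write_mesh,
)

__all__ = [
    "AtlasModel",
    "init_control_points",
    "initial_template",
    "estimate_atlas",
    "filter_control_points",
    "reconstruction_error",
    "aic_model_selection",
]


@dataclass
class AtlasModel:
    """Fitted atlas: template mesh, control points, kernel configuration and
    one momenta vector set per subject."""

    template: SurfaceMesh
    cps: ControlPointSet
    config: KernelConfig
    momenta: list[Momenta]
    subject_ids: list[str]
    energy_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.momenta) != len(self.subject_ids):
            raise ValueError("one momenta set per subject required")
        for m in self.momenta:
            if len(m) != len(self.cps):
                raise ValueError("momenta length must match control-point count")

    def momenta_matrix(self) -> np.ndarray:
        """Subjects x D matrix with D = 3 * n_control_points."""
        return np.array([m.vectors.ravel() for m in self.momenta])

    def reconstruct(self, index: int) -> SurfaceMesh:
        return warp_mesh(self.template, self.cps, self.momenta[index], self.config)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_mesh(self.template, out / "template.ply")
        save_momenta(out / "momenta.txt", self.cps, self.momenta, self.config)
        (out / "model.json").write_text(
            json.dumps(
                {
                    "subject_ids": self.subject_ids,
                    "noise_std": self.config.noise_std,
                    "energy_trace": self.energy_trace,
                }
            )
        )

    @classmethod
    def load(cls, in_dir: str | Path) -> "AtlasModel":
        src = Path(in_dir)
        meta = json.loads((src / "model.json").read_text())
        cps, momenta, config = load_momenta(src / "momenta.txt")
        config = KernelConfig(
            lambda_V=config.lambda_V,
            lambda_W=config.lambda_W,
            n_time_steps=config.n_time_steps,
            noise_std=meta.get("noise_std", 1.0),
        )
        return cls(
            template=read_mesh(src / "template.ply"),
            cps=cps,
            config=config,
            momenta=momenta,
            subject_ids=meta["subject_ids"],
            energy_trace=meta.get("energy_trace", []),
        )


def init_control_points(meshes, spacing_mm: float) -> ControlPointSet:
    """Regular grid over the union bounding box, padded by one spacing.

    Per axis of extent ``L`` the grid has ``floor(L / spacing) + 3`` points
    starting one spacing below the box minimum, so the box plus one pad step
    on each side is covered.  Deterministic in its inputs.
    """
    if spacing_mm <= 0:
        raise ValueError("spacing_mm must be positive")
    meshes = list(meshes)
    los = np.min([m.bounds()[0] for m in meshes], axis=0)
    his = np.max([m.bounds()[1] for m in meshes], axis=0)
    axes = []
    for d in range(3):
        n = int(np.floor((his[d] - los[d]) / spacing_mm + 1e-9)) + 3
        axes.append(los[d] - spacing_mm + spacing_mm * np.arange(n))
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return ControlPointSet(np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]))


def initial_template(
    meshes: list[SurfaceMesh],
    sizes: np.ndarray | None = None,
    smoothing_iterations: int = 10,
    smoothing_lambda: float = 0.5,
    remesh_target_mm: float | None = None,
) -> SurfaceMesh:
    """Reproducible surrogate for a manually smoothed initial template.

    Picks the subject whose size surrogate is closest to the population
    median, applies Laplacian smoothing and, optionally, isotropic remeshing.
    """
    from .growth import face_size

    if sizes is None:
        sizes = np.array([face_size(m) for m in meshes])
    pick = int(np.argmin(np.abs(sizes - np.median(sizes))))
    base = meshes[pick]
    tm = base.to_trimesh()
    smoothed = trimesh.smoothing.filter_laplacian(
        tm, lamb=smoothing_lambda, iterations=smoothing_iterations, volume_constraint=False
    )
    template = SurfaceMesh(np.asarray(smoothed.vertices), np.asarray(smoothed.faces), "template")
    if remesh_target_mm is not None:
        template = remesh_isotropic(template, remesh_target_mm)
    return template


def _template_data_energy_grad(
    V: np.ndarray,
    F: np.ndarray,
    cps: np.ndarray,
    momenta: list[Momenta],
    meshes: list[SurfaceMesh],
    config: KernelConfig,
) -> tuple[float, np.ndarray]:
    """Summed varifold data terms and gradient wrt template vertices."""
    total = 0.0
    grad = np.zeros_like(V)
    K_vc = gaussian_kernel(V, cps, config.lambda_V)
    for m, target in zip(momenta, meshes):
        a = m.vectors
        warped = V + K_vc @ a
        val, g_w = varifold_distance_gradient(warped, F, target, config.lambda_W)
        total += val / config.noise_std**2
        g_w = g_w / config.noise_std**2
        # chain through x' = x + sum_i K(x, c_i) a_i
        coef = (-2.0 / config.lambda_V**2) * K_vc  # (n_v, n_cp)
        ag = g_w @ a.T  # (n_v, n_cp): a_i . g_v
        w = coef * ag
        grad += g_w + V * w.sum(axis=1)[:, None] - w @ cps
    return total, grad


def estimate_atlas(
    meshes: list[SurfaceMesh],
    cps: ControlPointSet,
    config: KernelConfig,
    init_template: SurfaceMesh,
    n_outer_iters: int = 4,
    template_update_iters: int = 10,
    register_opts: dict | None = None,
    update_template: bool = True,
) -> AtlasModel:
    """Alternating template/momenta estimation of the shape atlas.

    Each outer iteration registers the current template to every subject
    (warm-started from the previous momenta), then updates the template
    vertices by a few L-BFGS steps on the summed data terms.  The recorded
    total energy is non-increasing across outer iterations.
    """
    if len(meshes) < 2:
        raise ValueError("atlas estimation needs at least 2 meshes")
    subject_ids = [m.subject_id or f"subject{i}" for i, m in enumerate(meshes)]
    template = init_template.copy()
    n_cp = len(cps)
    momenta = [Momenta(np.zeros((n_cp, 3))) for _ in meshes]
    trace: list[float] = []
    if n_outer_iters == 0:
        return AtlasModel(template, cps, config, momenta, subject_ids, trace)
    for outer in range(n_outer_iters):
        energies = []
        new_momenta = []
        for m, target in zip(momenta, meshes):
            fitted, energy = register(
                template, target, cps, config, optimizer_opts=register_opts,
                a_init=m.vectors,
            )
            new_momenta.append(fitted)
            energies.append(energy)
        momenta = new_momenta
        total = float(np.sum(energies))
        if not np.isfinite(total):
            raise RuntimeError(f"atlas estimation diverged; energy trace: {trace}")
        trace.append(total)
        if update_template and outer < n_outer_iters - 1:
            F = template.triangles

            def fun(v_flat):
                val, grad = _template_data_energy_grad(
                    v_flat.reshape(-1, 3), F, cps.points, momenta, meshes, config
                )
                return val, grad.ravel()

            res = minimize(
                fun,
                template.vertices.ravel(),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": template_update_iters},
            )
            template = SurfaceMesh(res.x.reshape(-1, 3), F.copy(), "template")
    return AtlasModel(template, cps, config, momenta, subject_ids, trace)


def filter_control_points(atlas: AtlasModel, rel_var_threshold: float = 1e-4) -> AtlasModel:
    """Drop control points with almost no across-subject momenta variance.

    A point is kept iff its momenta variance (summed over the 3 coordinates)
    is at least ``rel_var_threshold`` times the maximum point variance;
    momenta columns are dropped consistently.
    """
    M = np.array([m.vectors for m in atlas.momenta])  # (n_subj, n_cp, 3)
    var = M.var(axis=0, ddof=1).sum(axis=1)
    if var.max() <= 0:
        raise ValueError("control-point filtering removed every point (no momenta variance)")
    keep = var >= rel_var_threshold * var.max()
    if not keep.any():
        raise ValueError("control-point filtering removed every point")
    cps = ControlPointSet(atlas.cps.points[keep])
    momenta = [Momenta(m.vectors[keep]) for m in atlas.momenta]
    return AtlasModel(
        atlas.template, cps, atlas.config, momenta, list(atlas.subject_ids),
        list(atlas.energy_trace),
    )


def _point_to_surface(points: np.ndarray, mesh: SurfaceMesh) -> np.ndarray:
    return closest_point_on_surface(mesh, points)[1]


def reconstruction_error(
    atlas: AtlasModel, meshes: list[SurfaceMesh]
) -> tuple[np.ndarray, dict]:
    """Mean point-to-surface distance of each warped template to its subject.

    Returns the per-subject mean distances (mm) and a summary dict.
    """
    errors = []
    for i, target in enumerate(meshes):
        warped = atlas.reconstruct(i)
        errors.append(float(_point_to_surface(warped.vertices, target).mean()))
    errors = np.array(errors)
    return errors, {"mean": float(errors.mean()), "max": float(errors.max())}


def aic_model_selection(
    meshes: list[SurfaceMesh],
    candidate_lambda_Ws: list[float],
    config: KernelConfig,
    init_template: SurfaceMesh,
    control_spacing: float | None = None,
    n_outer_iters: int = 2,
    rel_var_threshold: float = 1e-4,
) -> pd.DataFrame:
    """Rank data-term resolutions by the Akaike information criterion.

    For each candidate ``lambda_W`` an atlas is fitted, control points are
    filtered, and AIC = 2k - 2 ln(L) is computed with k = 3 x (retained
    control points) and ln(L) from an isotropic zero-mean Gaussian model of
    the vertex point-to-surface residuals (sigma estimated by ML).
    """
    if len(candidate_lambda_Ws) < 2:
        raise ValueError("need at least two candidate lambda_W values")
    rows = []
    for lam_w in candidate_lambda_Ws:
        cfg = KernelConfig(
            lambda_V=config.lambda_V,
            lambda_W=lam_w,
            n_time_steps=config.n_time_steps,
            noise_std=config.noise_std,
        )
        cps = init_control_points(meshes, control_spacing or cfg.lambda_V)
        fitted = estimate_atlas(meshes, cps, cfg, init_template, n_outer_iters=n_outer_iters)
        fitted = filter_control_points(fitted, rel_var_threshold)
        residuals = np.concatenate(
            [
                _point_to_surface(fitted.reconstruct(i).vertices, target)
                for i, target in enumerate(meshes)
            ]
        )
        n = len(residuals)
        sigma2 = max(float(np.mean(residuals**2)), 1e-12)
        log_lik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
        k = 3 * len(fitted.cps)
        rows.append(
            {
                "lambda_W": lam_w,
                "n_control_points": len(fitted.cps),
                "k": k,
                "log_likelihood": log_lik,
                "aic": 2 * k - 2 * log_lik,
            }
        )
    return pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
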