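"""Synthetic face-like mesh populations with known ground truth.

The generator emulates the statistical structure assumed by the shape model:
an open face-like template surface, smooth inter-subject shape variation
spanned by a few latent momenta modes, a linear gestational-age effect on
shape, isotropic size growth following a quadratic curve over 24-34 weeks, an
optional growth-restricted (FGR-like) subgroup with reduced size and a
localised shape offset, and vertex-level measurement noise.

Shape effects are injected in momenta space — the model's own
parameterisation — so downstream recovery tests have a well-defined truth.
All randomness flows from one seed; per-subject sub-streams are derived by
counter so populations are reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .growth import face_size
from .kernel import ControlPointSet, KernelConfig, Momenta, gaussian_kernel, warp_points
from .mesh import LandmarkSet, SurfaceMesh, cell_geometry, write_landmarks, write_mesh

__all__ = [
    "FaceFeatureParams",
    "SyntheticPopulationSpec",
    "PopulationSample",
    "make_template_face",
    "sample_population",
    "write_population",
]


@dataclass(frozen=True)
class FaceFeatureParams:
    """Analytic feature layout of the template face (mm, in the u-v plane).

    u runs left-right, v bottom-top; the surface is a half-ellipsoid dome
    looking towards +z with a nose bump, a lip ridge and two eye depressions.
    """

    half_width: float = 32.0
    half_height: float = 38.0
    depth: float = 25.0
    nose_center: tuple[float, float] = (0.0, -4.0)
    nose_amplitude: float = 6.0
    nose_sigma: float = 5.0
    eye_centers: tuple[tuple[float, float], ...] = ((-11.0, 8.0), (11.0, 8.0))
    eye_amplitude: float = -2.5
    eye_sigma: float = 4.0
    lip_center: tuple[float, float] = (0.0, -16.0)
    lip_amplitude: float = 2.0
    lip_sigma_u: float = 9.0
    lip_sigma_v: float = 2.5


def _surface_height(u: np.ndarray, v: np.ndarray, p: FaceFeatureParams) -> np.ndarray:
    r2 = (u / p.half_width) ** 2 + (v / p.half_height) ** 2
    z = p.depth * np.sqrt(np.clip(1.0 - r2, 0.0, None))
    z = z + p.nose_amplitude * np.exp(
        -((u - p.nose_center[0]) ** 2 + (v - p.nose_center[1]) ** 2) / (2 * p.nose_sigma**2)
    )
    for eu, ev in p.eye_centers:
        z = z + p.eye_amplitude * np.exp(
            -((u - eu) ** 2 + (v - ev) ** 2) / (2 * p.eye_sigma**2)
        )
    z = z + p.lip_amplitude * np.exp(
        -((u - p.lip_center[0]) ** 2) / (2 * p.lip_sigma_u**2)
        - ((v - p.lip_center[1]) ** 2) / (2 * p.lip_sigma_v**2)
    )
    return z


def make_template_face(
    u_res: int = 32, v_res: int = 36, feature_params: FaceFeatureParams | None = None
) -> tuple[SurfaceMesh, LandmarkSet]:
    """Deterministic open parametric face surface plus its four landmarks.

    The surface is z(u, v) over an oval patch; landmark points sit at the
    analytic feature centres (eye depressions, nose bump, lip ridge midpoint).
    Identical inputs give bit-identical meshes.
    """
    if u_res < 8 or v_res < 8:
        raise ValueError("u_res and v_res must be >= 8")
    p = feature_params or FaceFeatureParams()
    for cu, cv in (p.nose_center, p.lip_center) + tuple(p.eye_centers):
        if abs(cu) >= p.half_width or abs(cv) >= p.half_height:
            raise ValueError(f"feature centre ({cu}, {cv}) outside the surface domain")
    u = np.linspace(-p.half_width, p.half_width, u_res)
    v = np.linspace(-p.half_height, p.half_height, v_res)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    zz = _surface_height(uu, vv, p)
    inside = (uu / p.half_width) ** 2 + (vv / p.half_height) ** 2 <= 1.0 + 1e-12

    index = -np.ones((u_res, v_res), dtype=np.int64)
    verts = []
    for i in range(u_res):
        for j in range(v_res):
            if inside[i, j]:
                index[i, j] = len(verts)
                verts.append((uu[i, j], vv[i, j], zz[i, j]))
    faces = []
    for i in range(u_res - 1):
        for j in range(v_res - 1):
            a, b = index[i, j], index[i + 1, j]
            c, d = index[i + 1, j + 1], index[i, j + 1]
            # CCW in (u, v) so normals point towards +z
            if a >= 0 and b >= 0 and c >= 0:
                faces.append((a, b, c))
            if a >= 0 and c >= 0 and d >= 0:
                faces.append((a, c, d))
    mesh = SurfaceMesh(np.array(verts), np.array(faces, dtype=np.int64), subject_id="template")

    def at(cu: float, cv: float) -> np.ndarray:
        return np.array([cu, cv, _surface_height(np.array(cu), np.array(cv), p)])

    landmarks = LandmarkSet(
        left_eye=at(*p.eye_centers[0]),
        right_eye=at(*p.eye_centers[1]),
        nose=at(*p.nose_center),
        lip_midpoint=at(*p.lip_center),
    )
    return mesh, landmarks


@dataclass
class SyntheticPopulationSpec:
    """Study conditions of a synthetic cohort.

    ``growth_coeffs = (g0, g1, g2)`` defines the true median size curve
    ``g*(ga) = g0 * (1 + g1*(ga-29) + g2*(ga-29)^2)`` in surrogate-size mm.
    ``mode_sds`` are the per-mode momenta standard deviations (mm),
    ``age_effect_scale`` the momenta drift per week (mm/week) along a fixed
    unit field, and the group parameters describe the FGR-like subgroup
    (smaller overall size plus a localised momenta offset).
    """

    n_subjects: int = 135
    ga_range: tuple[float, float] = (24.0, 34.0)
    growth_coeffs: tuple[float, float, float] = (60.0, 0.035, -0.0006)
    n_modes: int = 2
    mode_sds: tuple[float, ...] = (3.0, 1.0)
    age_effect_scale: float = 0.25
    group_fraction: float = 0.0
    group_size_factor: float = 0.85
    group_offset_scale: float = 2.0
    vertex_noise_sd: float = 0.2
    size_noise_sd: float = 0.03
    seed: int = 0
    lambda_V: float = 7.0
    control_spacing_mm: float = 14.0
    template_resolution: tuple[int, int] = (32, 36)

    def __post_init__(self) -> None:
        if not 0.0 <= self.group_fraction <= 1.0:
            raise ValueError("group_fraction must lie in [0, 1]")
        if any(sd < 0 for sd in self.mode_sds):
            raise ValueError("mode_sds must be non-negative")
        if len(self.mode_sds) != self.n_modes:
            raise ValueError("mode_sds must have length n_modes")
        t = np.linspace(self.ga_range[0], self.ga_range[1], 101) - 29.0
        g0, g1, g2 = self.growth_coeffs
        if np.any(g0 * (1 + g1 * t + g2 * t**2) <= 0):
            raise ValueError("growth curve must stay positive over ga_range")

    def true_size_curve(self, ga) -> np.ndarray | float:
        g0, g1, g2 = self.growth_coeffs
        t = np.asarray(ga, dtype=float) - 29.0
        out = g0 * (1 + g1 * t + g2 * t**2)
        return float(out) if np.isscalar(ga) else out


@dataclass
class PopulationTruth:
    """Everything the generator knows: template, control grid, latent fields
    and the exact per-subject momenta before any vertex noise."""

    template: SurfaceMesh
    template_landmarks: LandmarkSet
    cps: ControlPointSet
    config: KernelConfig
    mode_fields: np.ndarray  # (n_modes, n_cp, 3), orthonormal in flattened space
    age_field: np.ndarray  # (n_cp, 3), unit norm
    group_field: np.ndarray  # (n_cp, 3), unit norm
    momenta: np.ndarray  # (n_subjects, n_cp * 3)
    template_size: float


@dataclass
class PopulationSample:
    meshes: list[SurfaceMesh]
    landmarks: list[LandmarkSet]
    metadata: pd.DataFrame
    truth: PopulationTruth


def _control_grid(mesh: SurfaceMesh, spacing: float) -> np.ndarray:
    from .atlas import init_control_points

    return init_control_points([mesh], spacing).points


def _latent_fields(
    cps: np.ndarray, n_fields: int, lambda_V: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth orthonormal vector fields on the control grid.

    White noise on the grid is smoothed with the lambda_V Gaussian kernel
    (same smoothness class as the deformation model) and Gram-Schmidt
    orthonormalised in the flattened momenta space.
    """
    n_cp = len(cps)
    if 3 * n_cp < n_fields:
        raise ValueError("more latent fields requested than grid capacity")
    K = gaussian_kernel(cps, cps, lambda_V)
    fields = []
    for _ in range(n_fields):
        raw = (K @ rng.standard_normal((n_cp, 3))).ravel()
        for prev in fields:
            raw = raw - (raw @ prev) * prev
        norm = np.linalg.norm(raw)
        if norm < 1e-12:
            raise RuntimeError("degenerate latent field draw")
        fields.append(raw / norm)
    return np.array(fields).reshape(n_fields, n_cp, 3)


def _vertex_normals(mesh: SurfaceMesh) -> np.ndarray:
    _, normals, areas = cell_geometry(mesh)
    out = np.zeros_like(mesh.vertices)
    w = normals * areas[:, None]
    for k in range(3):
        np.add.at(out, mesh.triangles[:, k], w)
    norms = np.linalg.norm(out, axis=1)
    return out / np.where(norms > 0, norms, 1.0)[:, None]


def sample_population(spec: SyntheticPopulationSpec) -> PopulationSample:
    """Draw a population of face meshes with recorded ground truth.

    Per subject: ga ~ Uniform(ga_range); momenta
    ``m = sum_k w_k B_k + (ga-29)*age_effect_scale*B_age``
    (plus ``group_offset_scale*B_grp`` for FGR subjects) with
    ``w_k ~ N(0, mode_sds^2)``; the template is warped by ``m``, isotropically
    scaled so its size surrogate equals the recorded true size
    ``g*(ga) * lognormal-noise * (group_size_factor if FGR)``, and vertices are
    displaced along their normals by ``N(0, vertex_noise_sd^2)``.
    """
    template, template_lm = make_template_face(*spec.template_resolution)
    cps_arr = _control_grid(template, spec.control_spacing_mm)
    cps = ControlPointSet(cps_arr)
    config = KernelConfig(lambda_V=spec.lambda_V, lambda_W=spec.lambda_V, n_time_steps=1)

    field_rng = np.random.default_rng([spec.seed, 2**20])
    fields = _latent_fields(cps_arr, spec.n_modes + 2, spec.lambda_V, field_rng)
    mode_fields = fields[: spec.n_modes]
    age_field = fields[spec.n_modes]
    group_field = fields[spec.n_modes + 1]

    template_size = face_size(template)
    n_cp = len(cps_arr)
    meshes: list[SurfaceMesh] = []
    landmark_sets: list[LandmarkSet] = []
    rows = []
    momenta = np.zeros((spec.n_subjects, 3 * n_cp))
    for i in range(spec.n_subjects):
        rng = np.random.default_rng([spec.seed, i])
        ga = rng.uniform(*spec.ga_range)
        is_fgr = rng.uniform() < spec.group_fraction
        w = rng.standard_normal(spec.n_modes) * np.asarray(spec.mode_sds)
        m = np.tensordot(w, mode_fields, axes=1)
        m = m + (ga - 29.0) * spec.age_effect_scale * age_field
        if is_fgr:
            m = m + spec.group_offset_scale * group_field
        momenta[i] = m.ravel()

        size_noise = float(np.exp(rng.normal(0.0, spec.size_noise_sd)))
        true_size = spec.true_size_curve(ga) * size_noise
        if is_fgr:
            true_size *= spec.group_size_factor

        verts = warp_points(template.vertices, cps_arr, m, config)
        lm_pts = warp_points(template_lm.as_array(), cps_arr, m, config)
        mesh = SurfaceMesh(verts, template.triangles.copy(), subject_id=f"subj{i:04d}")
        scale = true_size / face_size(mesh)
        center = verts.mean(axis=0)
        verts = center + scale * (verts - center)
        lm_pts = center + scale * (lm_pts - center)
        if spec.vertex_noise_sd > 0:
            noisy = SurfaceMesh(verts, template.triangles.copy())
            normals = _vertex_normals(noisy)
            verts = verts + normals * rng.normal(0.0, spec.vertex_noise_sd, len(verts))[:, None]
        meshes.append(SurfaceMesh(verts, template.triangles.copy(), subject_id=f"subj{i:04d}"))
        landmark_sets.append(LandmarkSet(*lm_pts))
        row = {
            "id": f"subj{i:04d}",
            "ga_weeks": ga,
            "group": "FGR" if is_fgr else "AGA",
            "true_size": true_size,
        }
        row.update({f"true_mode_w{k + 1}": w[k] for k in range(spec.n_modes)})
        rows.append(row)

    truth = PopulationTruth(
        template=template,
        template_landmarks=template_lm,
        cps=cps,
        config=config,
        mode_fields=mode_fields,
        age_field=age_field,
        group_field=group_field,
        momenta=momenta,
        template_size=template_size,
    )
    return PopulationSample(meshes, landmark_sets, pd.DataFrame(rows), truth)


def write_population(sample: PopulationSample, out_dir: str | Path) -> None:
    """Write meshes (PLY), landmarks (CSV), metadata (CSV) and truth arrays."""
    out = Path(out_dir)
    (out / "meshes").mkdir(parents=True, exist_ok=True)
    (out / "landmarks").mkdir(exist_ok=True)
    for mesh, lm in zip(sample.meshes, sample.landmarks):
        write_mesh(mesh, out / "meshes" / f"{mesh.subject_id}.ply")
        write_landmarks(lm, out / "landmarks" / f"{mesh.subject_id}.csv")
    sample.metadata.to_csv(out / "metadata.csv", index=False)
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    write_mesh(sample.truth.template, truth_dir / "template.ply")
    write_landmarks(sample.truth.template_landmarks, truth_dir / "template_landmarks.csv")
    np.savetxt(truth_dir / "control_points.txt", sample.truth.cps.points)
    np.savetxt(truth_dir / "momenta.txt", sample.truth.momenta)
    np.savetxt(truth_dir / "age_field.txt", sample.truth.age_field)
    np.savetxt(truth_dir / "group_field.txt", sample.truth.group_field)
    np.savetxt(
        truth_dir / "mode_fields.txt",
        sample.truth.mode_fields.reshape(len(sample.truth.mode_fields), -1),
    )
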