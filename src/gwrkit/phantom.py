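"""Cortical shell phantoms: synthetic white/pial surface pairs with a
matching voxelized T1-like intensity volume, and cohorts of such subjects
with controlled group effects.

The phantom is a radially perturbed sphere, not a brain: every acceptance
property (shell volumes, sampling depths, thickness) has a closed form on
it.  The white surface is an icosphere of radius R; the pial surface shares
its vertex indexing, each vertex pushed outward along the radius by a smooth
angular thickness field

    t(u) = t0 + a * P2(u_z),        P2(z) = (3 z^2 - 1) / 2,

with u the unit direction of the vertex.  Voxels are labeled by radius
(white matter inside R, gray matter in the ribbon, CSF outside), optionally
multiplied by a smooth separable half-period cosine bias field spanning
1 +/- bias_amplitude across the field of view, then perturbed by additive
i.i.d. Gaussian noise (Rician noise is deliberately not modeled).

Cohorts emulate a two-group case-control design: patients receive
fractional WM/GM intensity reductions and/or an absolute thickness
reduction inside a geodesic disc ("patch") of the surface, plus per-subject
global thickness jitter and a global intensity scale factor emulating
scanner gain; controls receive only the jitter.  Ground truth (true
thickness, patch mask, applied effects) is returned so every downstream
stage has a recovery target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh as _trimesh

from .io import VolumeGrid
from .mesh import TriangleMesh, VertexMap, geodesic_distances
from .records import SubjectRecord

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "CohortResult",
    "build_shell_phantom",
    "generate_cohort",
    "icosphere",
]


class PhantomError(ValueError):
    """Raised for unsatisfiable phantom specifications."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue intensities and degradations of one shell phantom.

    Intensities are in arbitrary units with the T1 ordering WM > GM > CSF.
    ``thickness_base``/``thickness_amplitude`` are mm; the amplitude scales
    the fixed P2 angular pattern.  ``bias_amplitude`` is the fractional
    excursion of the multiplicative bias field.  ``margin`` is padding (mm)
    between the outermost pial radius and the volume boundary.
    """

    white_radius: float = 50.0
    thickness_base: float = 3.0
    thickness_amplitude: float = 0.5
    intensity_wm: float = 110.0
    intensity_gm: float = 80.0
    intensity_csf: float = 40.0
    noise_sd: float = 6.0
    bias_amplitude: float = 0.0
    voxel_size: float = 1.5
    subdivision: int = 5
    margin: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.intensity_wm > self.intensity_gm > self.intensity_csf):
            raise PhantomError("need T1-like ordering intensity_wm > intensity_gm > intensity_csf")
        if self.white_radius <= 0 or self.voxel_size <= 0:
            raise PhantomError("white_radius and voxel_size must be positive")
        if self.min_thickness <= 0:
            raise PhantomError("thickness field must be positive everywhere")
        if self.voxel_size > self.min_thickness:
            raise PhantomError(
                f"voxel_size {self.voxel_size} mm exceeds minimum thickness "
                f"{self.min_thickness:.2f} mm: ribbon unresolvable"
            )
        if self.noise_sd < 0 or self.bias_amplitude < 0:
            raise PhantomError("noise_sd and bias_amplitude must be non-negative")

    @property
    def min_thickness(self) -> float:
        # P2 ranges over [-1/2, 1]
        return self.thickness_base - abs(self.thickness_amplitude)


def icosphere(subdivision: int, radius: float) -> TriangleMesh:
    """Outward-wound icosphere (trimesh construction, deterministic)."""
    m = _trimesh.creation.icosphere(subdivisions=subdivision, radius=radius)
    return TriangleMesh(np.asarray(m.vertices, dtype=np.float64), np.asarray(m.faces))


def _p2(z: np.ndarray) -> np.ndarray:
    return 0.5 * (3.0 * z * z - 1.0)


def thickness_field(spec: PhantomSpec, directions: np.ndarray) -> np.ndarray:
    """Angular thickness (mm) at unit directions (n, 3)."""
    return spec.thickness_base + spec.thickness_amplitude * _p2(directions[:, 2])


def _bias_field(shape: tuple[int, int, int], amplitude: float) -> np.ndarray:
    if amplitude == 0:
        return np.ones(shape)
    axes = [np.cos(np.pi * np.arange(n) / (n - 1)) for n in shape]
    return 1.0 + amplitude * (
        axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
    )


def _volume_grid(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel-center coordinate arrays (1D per axis) and the affine."""
    extent = spec.white_radius + spec.thickness_base + abs(spec.thickness_amplitude) + spec.margin
    n = int(np.ceil(2 * extent / spec.voxel_size)) + 1
    coords = (np.arange(n) - (n - 1) / 2.0) * spec.voxel_size
    affine = np.diag([spec.voxel_size] * 3 + [1.0])
    affine[:3, 3] = coords[0]
    return coords, np.array([n, n, n]), affine


def _label_volume(
    spec: PhantomSpec,
    *,
    thickness_offset: float = 0.0,
    effect_wm: float = 0.0,
    effect_gm: float = 0.0,
    effect_thickness: float = 0.0,
    patch_axis: np.ndarray | None = None,
    patch_cos: float = -2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free tissue intensity volume (and its affine).

    Patch effects apply to voxels whose direction from the center lies within
    the cone ``dot(direction, patch_axis) >= patch_cos`` (the volumetric
    counterpart of a geodesic disc on the near-spherical surface).
    """
    coords, _, affine = _volume_grid(spec)
    x = coords[:, None, None]
    y = coords[None, :, None]
    z = coords[None, None, :]
    r = np.sqrt(x * x + y * y + z * z)
    with np.errstate(invalid="ignore", divide="ignore"):
        uz = np.where(r > 0, z / np.where(r > 0, r, 1.0), 0.0)
    thick = spec.thickness_base + spec.thickness_amplitude * _p2(uz) + thickness_offset
    if patch_axis is not None:
        ux = np.where(r > 0, x / np.where(r > 0, r, 1.0), 0.0)
        uy = np.where(r > 0, y / np.where(r > 0, r, 1.0), 0.0)
        in_patch = (ux * patch_axis[0] + uy * patch_axis[1] + uz * patch_axis[2]) >= patch_cos
    else:
        in_patch = np.ones(r.shape, dtype=bool)
    thick = thick - effect_thickness * in_patch
    wm_int = spec.intensity_wm * (1.0 - effect_wm * in_patch)
    gm_int = spec.intensity_gm * (1.0 - effect_gm * in_patch)
    vol = np.full(r.shape, spec.intensity_csf, dtype=np.float64)
    wm = r < spec.white_radius
    gm = ~wm & (r < spec.white_radius + thick)
    vol[wm] = np.broadcast_to(wm_int, vol.shape)[wm]
    vol[gm] = np.broadcast_to(gm_int, vol.shape)[gm]
    return vol, affine


def _degrade(vol: np.ndarray, spec: PhantomSpec, rng: np.random.Generator, scale: float = 1.0) -> np.ndarray:
    out = vol * scale * _bias_field(vol.shape, spec.bias_amplitude)
    if spec.noise_sd > 0:
        out = out + rng.normal(0.0, spec.noise_sd, size=vol.shape)
    return out


def _surfaces(
    spec: PhantomSpec,
    *,
    thickness_offset: float = 0.0,
    effect_thickness: float = 0.0,
    patch_vertices: np.ndarray | None = None,
) -> tuple[TriangleMesh, TriangleMesh, VertexMap]:
    white = icosphere(spec.subdivision, spec.white_radius)
    u = white.vertices / np.linalg.norm(white.vertices, axis=1, keepdims=True)
    t = thickness_field(spec, u) + thickness_offset
    if patch_vertices is not None:
        t = t - effect_thickness * patch_vertices
    if (t <= 0).any():
        raise PhantomError("thickness non-positive after offsets/effects")
    pial = TriangleMesh(white.vertices + u * t[:, None], white.faces)
    return white, pial, VertexMap(t, name="true_thickness")


def build_shell_phantom(
    spec: PhantomSpec,
) -> tuple[TriangleMesh, TriangleMesh, VolumeGrid, VertexMap]:
    """Build one phantom: (white, pial, volume, true radial thickness).

    Reproducible: identical spec (including seed) gives bit-identical output.
    """
    white, pial, true_t = _surfaces(spec)
    vol, affine = _label_volume(spec)
    rng = np.random.default_rng(spec.seed)
    vol = _degrade(vol, spec, rng)
    return white, pial, VolumeGrid(vol, affine), true_t


@dataclass(frozen=True)
class CohortSpec:
    """A two-group phantom cohort and its induced group effects.

    ``effect_wm``/``effect_gm`` are fractional intensity reductions in
    patients, ``effect_thickness`` an absolute mm reduction, all confined to
    the geodesic disc of ``patch_radius_mm`` around ``patch_center_vertex``
    (None radius = whole surface).  ``thickness_jitter_sd`` (mm) is a global
    per-subject thickness offset; ``intensity_scale_sd`` a per-subject
    multiplicative gain (mean 1) the GWR should be invariant to.
    ``covariate_distributions`` maps covariate name to
    ``{group: (mean, sd)}``; patient-only covariates simply omit 'control'.
    """

    n_per_group: int = 18
    effect_wm: float = 0.0
    effect_gm: float = 0.0
    effect_thickness: float = 0.0
    patch_center_vertex: int = 0
    patch_radius_mm: float | None = 25.0
    thickness_jitter_sd: float = 0.15
    intensity_scale_sd: float = 0.02
    covariate_distributions: dict = field(default_factory=lambda: DEFAULT_COVARIATES)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise PhantomError("need at least 2 subjects per group")
        for e in (self.effect_wm, self.effect_gm, self.effect_thickness):
            if not np.isfinite(e):
                raise PhantomError("effects must be finite")
        if self.patch_radius_mm is not None and self.patch_radius_mm < 0:
            raise PhantomError("patch radius must be >= 0")


# Group means/SDs follow a matched case-control design: ~48 vs ~50 years of
# age, ~12.5 vs ~13 years of education; antipsychotic dosage in
# chlorpromazine-equivalent mg, illness duration in years and a unitless
# symptom-severity score exist for patients only.
DEFAULT_COVARIATES: dict = {
    "age": {"patient": (48.1, 11.3), "control": (49.8, 7.0)},
    "education": {"patient": (12.3, 2.6), "control": (13.2, 1.7)},
    "dosage": {"patient": (660.9, 479.1)},
    "duration": {"patient": (25.2, 9.8)},
    "symptom_severity": {"patient": (40.0, 10.0)},
}


@dataclass
class CohortResult:
    """Cohort plus generator ground truth for recovery checks."""

    subjects: list[SubjectRecord]
    white: TriangleMesh
    patch_mask: np.ndarray  # bool per vertex (geodesic disc on white surface)
    true_effects: dict[str, float]
    pspec: PhantomSpec
    cspec: CohortSpec


def patch_vertex_mask(white: TriangleMesh, center_vertex: int, radius_mm: float | None) -> np.ndarray:
    if radius_mm is None:
        return np.ones(white.n_vertices, dtype=bool)
    d = geodesic_distances(white, center_vertex)
    return d <= radius_mm


def generate_cohort(pspec: PhantomSpec, cspec: CohortSpec) -> CohortResult:
    """Generate a two-group cohort of shell phantoms with patch-confined effects.

    Patients get the configured intensity/thickness effects inside the patch;
    controls are unaffected draws from the same base phantom.  All surfaces
    share the white icosphere's vertex indexing, so per-vertex maps are
    directly comparable across subjects.  Per-subject randomness (covariates,
    jitter, gain, voxel noise) derives deterministically from ``cspec.seed``.
    """
    white = icosphere(pspec.subdivision, pspec.white_radius)
    mask = patch_vertex_mask(white, cspec.patch_center_vertex, cspec.patch_radius_mm)
    axis = white.vertices[cspec.patch_center_vertex]
    axis = axis / np.linalg.norm(axis)
    if cspec.patch_radius_mm is None:
        patch_cos = -2.0
    else:
        # geodesic disc radius -> cone half-angle on the sphere
        patch_cos = float(np.cos(min(cspec.patch_radius_mm / pspec.white_radius, np.pi)))

    ss = np.random.SeedSequence(cspec.seed)
    child_seeds = ss.spawn(2 * cspec.n_per_group)
    subjects: list[SubjectRecord] = []
    for i in range(2 * cspec.n_per_group):
        group = "patient" if i < cspec.n_per_group else "control"
        rng = np.random.default_rng(child_seeds[i])
        dt = rng.normal(0.0, cspec.thickness_jitter_sd)
        gain = rng.normal(1.0, cspec.intensity_scale_sd)
        covs: dict[str, float] = {}
        for name, dists in cspec.covariate_distributions.items():
            if group in dists:
                mean, sd = dists[group]
                covs[name] = float(rng.normal(mean, sd))
            else:
                covs[name] = float("nan")
        is_pat = group == "patient"
        _, pial, true_t = _surfaces(
            pspec,
            thickness_offset=dt,
            effect_thickness=cspec.effect_thickness if is_pat else 0.0,
            patch_vertices=mask if is_pat else None,
        )
        vol, affine = _label_volume(
            pspec,
            thickness_offset=dt,
            effect_wm=cspec.effect_wm if is_pat else 0.0,
            effect_gm=cspec.effect_gm if is_pat else 0.0,
            effect_thickness=cspec.effect_thickness if is_pat else 0.0,
            patch_axis=axis,
            patch_cos=patch_cos,
        )
        vol = _degrade(vol, pspec, rng, scale=gain)
        subjects.append(
            SubjectRecord(
                subject_id=f"{group[:3]}{i % cspec.n_per_group:03d}",
                group=group,
                covariates=covs,
                volume=VolumeGrid(vol, affine),
                white=white,
                pial=pial,
                maps={"true_thickness": true_t},
            )
        )
    true_effects = {
        "effect_wm": cspec.effect_wm,
        "effect_gm": cspec.effect_gm,
        "effect_thickness": cspec.effect_thickness,
    }
    return CohortResult(subjects, white, mask, true_effects, pspec, cspec)


def null_cohort_spec(seed: int, n_per_group: int = 6) -> CohortSpec:
    """A cohort with every group effect zero (exchangeable groups)."""
    return CohortSpec(
        n_per_group=n_per_group,
        effect_wm=0.0,
        effect_gm=0.0,
        effect_thickness=0.0,
        seed=seed,
    )
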