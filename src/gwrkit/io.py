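"""Readers and writers for the formats the pipeline touches.

Volumes are NIfTI-1 (via nibabel), surfaces are FreeSurfer binary triangle
files or GIfTI, per-vertex scalar maps are FreeSurfer "curv" (new format,
magic 0xFFFFFF) or CSV, and subject covariates are a CSV table.

Conventions: world coordinates are RAS millimetres as given by the NIfTI
affine, voxel indices are 0-based, and the affine maps the voxel *center* to
world.  FreeSurfer surface coordinates are taken to be in the volume's world
frame already; when a surface file carries the optional volume-geometry
footer, its c_ras translation is applied so real FreeSurfer surfaces land in
scanner RAS.  Missing per-vertex values are NaN in curv files and empty
cells in CSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from nibabel.freesurfer import io as fsio

from .mesh import MeshError, TriangleMesh, VertexMap

__all__ = [
    "VolumeGrid",
    "CovariateTable",
    "read_volume",
    "write_volume",
    "read_surface",
    "write_surface",
    "read_vertex_map",
    "write_vertex_map",
    "read_covariates",
    "write_covariates",
]

NUISANCE_COLUMNS = ("age", "education", "dosage", "duration", "symptom_severity")


class FormatError(ValueError):
    """Raised when a file does not conform to its declared format."""


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D scalar field plus the 4x4 affine mapping voxel ijk to world mm."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=np.float64)
        a = np.asarray(self.affine, dtype=np.float64)
        if d.ndim != 3 or min(d.shape) < 2:
            raise FormatError(f"volume must be 3D with every axis >= 2, got {d.shape}")
        if a.shape != (4, 4):
            raise FormatError(f"affine must be 4x4, got {a.shape}")
        if abs(np.linalg.det(a[:3, :3])) < 1e-12:
            raise FormatError("affine is singular")
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "affine", a)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm points (n, 3) to continuous voxel coordinates (n, 3)."""
        inv = np.linalg.inv(self.affine)
        p = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return p @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(ijk, dtype=np.float64))
        return p @ self.affine[:3, :3].T + self.affine[:3, 3]


def read_volume(path: str | Path) -> VolumeGrid:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several header error types
        raise FormatError(f"cannot parse NIfTI file {path}: {exc}") from exc
    if img.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got {img.ndim}D")
    return VolumeGrid(np.asanyarray(img.dataobj), img.affine)


def write_volume(vol: VolumeGrid, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), vol.affine), str(path))


def _surface_dialect(path: Path) -> str:
    if path.suffix == ".gii" or path.name.endswith(".surf.gii"):
        return "gifti"
    return "freesurfer_binary"


def read_surface(path: str | Path, dialect: str | None = None) -> TriangleMesh:
    """Read a triangle surface; dialect inferred from the extension when None."""
    path = Path(path)
    dialect = dialect or _surface_dialect(path)
    if dialect == "gifti":
        img = nib.load(str(path))
        if not isinstance(img, nib.gifti.GiftiImage):
            raise FormatError(f"{path} is not a GIfTI file")
        coords = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")
        tris = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")
        if not coords or not tris:
            raise FormatError(f"{path}: GIfTI surface needs POINTSET and TRIANGLE arrays")
        verts, faces = coords[0].data, tris[0].data
    elif dialect == "freesurfer_binary":
        try:
            # surfaces we write carry no volume-geometry footer; nibabel
            # warns about that, which is expected rather than actionable
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                verts, faces, meta = fsio.read_geometry(str(path), read_metadata=True)
        except ValueError:
            try:
                verts, faces = fsio.read_geometry(str(path))
                meta = {}
            except ValueError as exc:
                raise FormatError(f"{path}: not a FreeSurfer triangle file: {exc}") from exc
        if "cras" in meta:  # volume-geometry footer: shift into scanner RAS
            verts = verts + np.asarray(meta["cras"])
    else:
        raise FormatError(f"unknown surface dialect {dialect!r}")
    try:
        return TriangleMesh(np.asarray(verts, dtype=np.float64), np.asarray(faces))
    except MeshError as exc:
        raise FormatError(f"{path}: invalid surface: {exc}") from exc


def write_surface(mesh: TriangleMesh, path: str | Path, dialect: str | None = None) -> None:
    path = Path(path)
    dialect = dialect or _surface_dialect(path)
    if dialect == "gifti":
        img = nib.gifti.GiftiImage(
            darrays=[
                nib.gifti.GiftiDataArray(
                    mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
                ),
                nib.gifti.GiftiDataArray(
                    mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
                ),
            ]
        )
        nib.save(img, str(path))
    elif dialect == "freesurfer_binary":
        fsio.write_geometry(str(path), mesh.vertices, mesh.faces)
    else:
        raise FormatError(f"unknown surface dialect {dialect!r}")


def _map_dialect(path: Path) -> str:
    return "csv" if path.suffix == ".csv" else "curv"


def read_vertex_map(
    path: str | Path,
    dialect: str | None = None,
    mesh: TriangleMesh | None = None,
    name: str = "",
) -> VertexMap:
    """Read a per-vertex scalar map; validates length against ``mesh`` if given."""
    path = Path(path)
    dialect = dialect or _map_dialect(path)
    if dialect == "curv":
        try:
            values = fsio.read_morph_data(str(path))
        except ValueError as exc:
            raise FormatError(f"{path}: not a curv file: {exc}") from exc
    elif dialect == "csv":
        col = pd.read_csv(path)["value"]
        values = col.to_numpy(dtype=np.float64)
    else:
        raise FormatError(f"unknown vertex-map dialect {dialect!r}")
    if mesh is not None and len(values) != mesh.n_vertices:
        raise FormatError(
            f"{path}: map has {len(values)} values but mesh has {mesh.n_vertices} vertices"
        )
    return VertexMap(values, name=name or path.stem)


def write_vertex_map(vmap: VertexMap, path: str | Path, dialect: str | None = None) -> None:
    path = Path(path)
    dialect = dialect or _map_dialect(path)
    if dialect == "curv":
        fsio.write_morph_data(str(path), vmap.values.astype(np.float32))
    elif dialect == "csv":
        pd.DataFrame({"vertex": np.arange(len(vmap)), "value": vmap.values}).to_csv(
            path, index=False
        )
    else:
        raise FormatError(f"unknown vertex-map dialect {dialect!r}")


@dataclass
class CovariateTable:
    """Per-subject covariates: id, group ('patient'/'control'), nuisance columns.

    Dosage, illness duration and symptom severity are only meaningful for
    patients; controls may carry NaN there (the GLM recodes them, see
    :mod:`gwrkit.glm`).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        for col in ("subject_id", "group"):
            if col not in df.columns:
                raise FormatError(f"covariate table lacks required column {col!r}")
        if df["subject_id"].duplicated().any():
            raise FormatError("duplicate subject_id in covariate table")
        bad = ~df["group"].isin(["patient", "control"])
        if bad.any():
            raise FormatError(f"unknown group labels: {sorted(df.loc[bad, 'group'].unique())}")
        for col in df.columns.difference(["subject_id", "group"]):
            df[col] = pd.to_numeric(df[col], errors="raise")
        self.frame = df

    @property
    def subjects(self) -> list[str]:
        return self.frame["subject_id"].tolist()

    def row(self, subject_id: str) -> pd.Series:
        return self.frame.set_index("subject_id").loc[subject_id]


def read_covariates(path: str | Path) -> CovariateTable:
    return CovariateTable(pd.read_csv(path))


def write_covariates(table: CovariateTable, path: str | Path) -> None:
    table.frame.to_csv(path, index=False)
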