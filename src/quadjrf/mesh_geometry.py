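"""Attachment-site mesh geometry and skull landmarks.

Triangulated surfaces of jaw muscle attachment sites are the geometric input
to muscle force reconstruction: each site contributes an area (a frustum face)
and a surface centroid (one end of the muscle's line of action), and its
vertices carry distributed loads in the statics stage.  This module also
computes the quadrate "structural axis", the ventral-articular-surface to
otic-condyle direction against which joint reaction forces are compared.

The global anatomical frame is x mediolateral (+x = animal's left),
y dorsoventral (+y = dorsal), z rostrocaudal (+z = rostral).  All distances
are in mm, areas in mm².
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .errors import DegenerateSiteError, LandmarkError, MeshFormatError, ZeroVectorError

__all__ = [
    "TriMesh",
    "AttachmentSite",
    "LandmarkSet",
    "LANDMARK_NAMES",
    "load_mesh",
    "site_area",
    "site_centroid",
    "nodal_area_weights",
    "quadrate_axis",
    "read_landmarks",
    "write_landmarks",
]

#: Controlled vocabulary for landmark names (sides spelled out).
LANDMARK_NAMES = (
    "quadrate_ventral_left",
    "quadrate_ventral_right",
    "quadrate_dorsal_left",
    "quadrate_dorsal_right",
    "joint_left",
    "joint_right",
    "bite_rostral_left",
    "bite_rostral_right",
    "bite_caudal_left",
    "bite_caudal_right",
)


@dataclass
class TriMesh:
    """A triangulated surface: ``vertices`` (n, 3) mm, ``faces`` (m, 3) int."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.all(np.isfinite(self.vertices)):
            raise MeshFormatError("mesh contains non-finite vertex coordinates")
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise MeshFormatError(
                f"face index {self.faces.max()} out of range for "
                f"{len(self.vertices)} vertices"
            )
        if self.faces.size and self.faces.min() < 0:
            raise MeshFormatError("negative face index")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangle_areas(self) -> np.ndarray:
        """Per-face areas as half cross-product magnitudes (mm²)."""
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def face_centroids(self) -> np.ndarray:
        v = self.vertices
        return v[self.faces].mean(axis=1)


@dataclass
class AttachmentSite:
    """A named muscle attachment surface with cached area and centroid."""

    name: str
    mesh: TriMesh
    area: float = field(init=False)
    centroid: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.area = site_area(self)
        self.centroid = site_centroid(self)


# AttachmentSite.__post_init__ calls site_area before `area` exists, so the
# free functions below take either a site or a bare mesh.
def _mesh_of(site) -> TriMesh:
    return site.mesh if isinstance(site, AttachmentSite) else site


def load_mesh(path, fmt: str | None = None) -> TriMesh:
    """Load an STL (ASCII or binary), OBJ or PLY surface.

    Vertex order is preserved and duplicate vertices are *not* merged, so
    per-site node counts (and hence load distribution) match the file.
    Pass ``merge_tolerance`` via :func:`merge_vertices` explicitly if needed.
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"mesh file not found: {path}")
    file_type = (fmt or path.suffix.lstrip(".")).lower()
    if file_type not in {"stl", "obj", "ply"}:
        raise MeshFormatError(f"unsupported mesh format: {file_type!r}")
    try:
        tm = trimesh.load_mesh(str(path), file_type=file_type, process=False)
    except Exception as exc:  # trimesh raises heterogeneous types
        raise MeshFormatError(f"cannot parse {path} as {file_type}: {exc}") from exc
    if isinstance(tm, trimesh.Scene):
        geoms = list(tm.geometry.values())
        if not geoms:
            raise MeshFormatError(f"{path}: no geometry found")
        tm = trimesh.util.concatenate(geoms)
    if tm.vertices.size == 0 or tm.faces.size == 0:
        raise MeshFormatError(f"{path}: empty mesh")
    return TriMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def merge_vertices(mesh: TriMesh, tolerance: float = 1e-8) -> TriMesh:
    """Merge vertices closer than ``tolerance`` (off by default everywhere)."""
    tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    tm.merge_vertices(merge_tex=True, merge_norm=True, digits_vertex=max(
        0, int(round(-np.log10(max(tolerance, 1e-12))))))
    return TriMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def site_area(site) -> float:
    """Total surface area (mm²): sum of half cross-product magnitudes."""
    mesh = _mesh_of(site)
    if mesh.n_faces < 1:
        raise DegenerateSiteError("site has no faces")
    total = float(mesh.triangle_areas().sum())
    if total <= 0.0:
        raise DegenerateSiteError("site has zero total area (all faces degenerate)")
    return total


def site_centroid(site, method: str = "surface") -> np.ndarray:
    """Centroid of the attachment surface.

    ``method='surface'`` (default) is the area-weighted mean of face
    centroids — the centroid of the lamina.  ``method='vertex'`` is the
    unweighted vertex mean, provided for comparison with workflows that
    average mesh nodes directly.
    """
    mesh = _mesh_of(site)
    if method == "vertex":
        return mesh.vertices.mean(axis=0)
    if method != "surface":
        raise ValueError(f"unknown centroid method: {method!r}")
    areas = mesh.triangle_areas()
    total = areas.sum()
    if total <= 0.0:
        raise DegenerateSiteError("site has zero total area")
    return (mesh.face_centroids() * areas[:, None]).sum(axis=0) / total


def nodal_area_weights(site) -> np.ndarray:
    """Per-vertex area weights (mm²): one third of each incident face's area.

    Weights sum to the site area exactly (up to float round-off); they are the
    basis for distributing a muscle's force over its attachment nodes without
    concentrating it at a single point.
    """
    mesh = _mesh_of(site)
    areas = mesh.triangle_areas()
    w = np.zeros(mesh.n_vertices)
    for k in range(3):
        np.add.at(w, mesh.faces[:, k], areas / 3.0)
    return w


def quadrate_axis(ventral: np.ndarray, dorsal: np.ndarray) -> np.ndarray:
    """Unit structural axis of the quadrate, ventral articular surface → otic condyle."""
    ventral = np.asarray(ventral, dtype=float)
    dorsal = np.asarray(dorsal, dtype=float)
    d = dorsal - ventral
    norm = np.linalg.norm(d)
    if norm == 0.0:
        raise ZeroVectorError("ventral and dorsal quadrate landmarks coincide")
    return d / norm


@dataclass
class LandmarkSet:
    """Named skull landmarks (mm) in the global anatomical frame."""

    points: dict

    def __post_init__(self) -> None:
        clean = {}
        for name, p in self.points.items():
            p = np.asarray(p, dtype=float).reshape(3)
            if not np.all(np.isfinite(p)):
                raise LandmarkError(f"landmark {name!r} has non-finite coordinates")
            clean[name] = p
        self.points = clean

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.points[name]
        except KeyError:
            raise LandmarkError(f"missing landmark {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def require(self, names) -> None:
        missing = [n for n in names if n not in self.points]
        if missing:
            raise LandmarkError(f"missing landmarks: {', '.join(missing)}")

    def axis(self, side: str) -> np.ndarray:
        """Quadrate structural axis for ``side`` ('left' or 'right')."""
        return quadrate_axis(
            self[f"quadrate_ventral_{side}"], self[f"quadrate_dorsal_{side}"]
        )


def read_landmarks(path, strict_vocabulary: bool = True) -> LandmarkSet:
    """Read a landmark CSV with header ``name,x,y,z`` (mm)."""
    path = Path(path)
    points = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        expected = {"name", "x", "y", "z"}
        if reader.fieldnames is None or not expected.issubset(reader.fieldnames):
            raise LandmarkError(
                f"{path}: landmark CSV must have header name,x,y,z "
                f"(got {reader.fieldnames})"
            )
        for row in reader:
            name = row["name"].strip()
            if strict_vocabulary and name not in LANDMARK_NAMES:
                raise LandmarkError(
                    f"{path}: unknown landmark name {name!r}; "
                    f"expected one of {', '.join(LANDMARK_NAMES)}"
                )
            try:
                points[name] = [float(row[c]) for c in ("x", "y", "z")]
            except ValueError as exc:
                raise LandmarkError(f"{path}: bad coordinate for {name!r}: {exc}")
    if not points:
        raise LandmarkError(f"{path}: no landmarks found")
    return LandmarkSet(points)


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "x", "y", "z"])
        for name, p in landmarks.points.items():
            writer.writerow([name, repr(float(p[0])), repr(float(p[1])), repr(float(p[2]))])
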