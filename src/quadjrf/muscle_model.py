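"""Muscle volume, PCSA, force and orientation from attachment geometry.

Each jaw muscle is modeled as a frustum whose two faces are the origin and
insertion attachment areas.  Fascicle length is the origin-to-insertion
centroid chord scaled by a relative fascicle length fraction; physiological
cross-sectional area is volume over fascicle length with pennation
correction, and force is PCSA times specific tension (default 30 N/cm²).
The muscle's line of action is the insertion→origin centroid vector, and the
scalar force is distributed over the attachment-site vertices in proportion
to their nodal area weights, each nodal load pointing at the opposite
attachment's centroid so no artificial point load is created.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateDirectionError, DegenerateMuscleError
from .mesh_geometry import AttachmentSite, nodal_area_weights

__all__ = [
    "MUSCLE_NAMES",
    "DEFAULT_SPECIFIC_TENSION",
    "default_muscle_table",
    "read_muscle_table",
    "MuscleSpec",
    "MuscleForce",
    "fascicle_length",
    "frustum_volume",
    "pcsa",
    "muscle_force_magnitude",
    "muscle_vector",
    "distribute_force",
    "build_muscle_force",
]

#: Jaw muscles of the crocodylian adductor chamber plus the depressor.
MUSCLE_NAMES = (
    "mAMES",  # adductor mandibulae externus superficialis
    "mAMEM",  # adductor mandibulae externus medialis
    "mAMEP",  # adductor mandibulae externus profundus
    "mAMP",   # adductor mandibulae posterior
    "mPSTs",  # pseudotemporalis superficialis
    "mPTd",   # pterygoideus dorsalis
    "mPTv",   # pterygoideus ventralis
    "mDM",    # depressor mandibulae
)

#: Maximal isometric stress of vertebrate skeletal muscle, N/cm².
DEFAULT_SPECIFIC_TENSION = 30.0

# PLACEHOLDER architecture table.  Relative fascicle length and pennation for
# crocodylian jaw muscles are specimen-level dissection quantities not bundled
# here; these are order-of-magnitude defaults for synthetic work and MUST be
# overridden with measured values for any real specimen.
_DEFAULT_ARCHITECTURE = {
    # muscle: (rel_fascicle_length, pennation_deg)
    "mAMES": (0.55, 15.0),
    "mAMEM": (0.50, 20.0),
    "mAMEP": (0.50, 20.0),
    "mAMP": (0.45, 25.0),
    "mPSTs": (0.55, 15.0),
    "mPTd": (0.40, 20.0),
    "mPTv": (0.40, 20.0),
    "mDM": (0.60, 10.0),
}


def default_muscle_table(sides=("left", "right")) -> pd.DataFrame:
    """Placeholder per-muscle parameter table (override for real specimens)."""
    rows = [
        {
            "muscle": m,
            "side": s,
            "rel_fascicle_length": _DEFAULT_ARCHITECTURE[m][0],
            "pennation_deg": _DEFAULT_ARCHITECTURE[m][1],
            "specific_tension": DEFAULT_SPECIFIC_TENSION,
        }
        for m in MUSCLE_NAMES
        for s in sides
    ]
    return pd.DataFrame(rows)


def read_muscle_table(path) -> pd.DataFrame:
    """Read the per-muscle parameter CSV.

    Required columns: ``muscle,side,rel_fascicle_length,pennation_deg,
    specific_tension``.
    """
    df = pd.read_csv(Path(path))
    required = {
        "muscle",
        "side",
        "rel_fascicle_length",
        "pennation_deg",
        "specific_tension",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"muscle table missing columns: {sorted(missing)}")
    bad = df[
        (df.rel_fascicle_length <= 0)
        | (df.rel_fascicle_length > 1)
        | (df.pennation_deg < 0)
        | (df.pennation_deg >= 90)
        | (df.specific_tension <= 0)
    ]
    if len(bad):
        raise ValueError(f"muscle table rows violate parameter bounds:\n{bad}")
    return df


@dataclass
class MuscleSpec:
    """Per-muscle parameters joined with its two attachment sites."""

    name: str
    side: str
    origin: AttachmentSite
    insertion: AttachmentSite
    rel_fascicle_length: float
    pennation_deg: float
    specific_tension: float = DEFAULT_SPECIFIC_TENSION

    def __post_init__(self) -> None:
        if not 0 < self.rel_fascicle_length <= 1:
            raise ValueError("rel_fascicle_length must be in (0, 1]")
        if not 0 <= self.pennation_deg < 90:
            raise ValueError("pennation_deg must be in [0, 90)")
        if self.specific_tension <= 0:
            raise ValueError("specific_tension must be positive")


@dataclass
class MuscleForce:
    """Resolved muscle force: scalars, line of action, and nodal loads."""

    spec: MuscleSpec
    fascicle_length_mm: float
    volume_mm3: float
    pcsa_cm2: float
    force_N: float
    vector: np.ndarray
    unit_vector: np.ndarray
    node_loads: list = field(default_factory=list)  # [(point mm, force 3-vec N)]


def fascicle_length(origin_centroid, insertion_centroid, rel_lf: float) -> float:
    """Absolute fascicle length (mm): centroid chord × relative fraction."""
    if not 0 < rel_lf <= 1:
        raise ValueError("rel_lf must be in (0, 1]")
    chord = float(
        np.linalg.norm(np.asarray(origin_centroid) - np.asarray(insertion_centroid))
    )
    if chord == 0.0:
        raise DegenerateMuscleError("origin and insertion centroids coincide")
    return chord * rel_lf


def frustum_volume(a_or: float, a_ins: float, l_f: float) -> float:
    """Volume (mm³) of a frustum with faces ``a_or``/``a_ins`` and height ``l_f``.

    V = l_f/3 · (A_or + A_ins + √(A_or·A_ins)); reduces to a prism for equal
    faces and a cone when one face vanishes.
    """
    if a_or < 0 or a_ins < 0:
        raise ValueError("areas must be non-negative")
    if a_or == 0 and a_ins == 0:
        raise ValueError("at least one face area must be positive")
    if l_f <= 0:
        raise ValueError("fascicle length must be positive")
    return (l_f / 3.0) * (a_or + a_ins + math.sqrt(a_or * a_ins))


def pcsa(volume_mm3: float, l_f: float, pennation_deg: float) -> float:
    """Physiological cross-sectional area in cm²: (V/l_f)·cosθ / 100."""
    if volume_mm3 < 0:
        raise ValueError("volume must be non-negative")
    if l_f <= 0:
        raise ValueError("fascicle length must be positive")
    area_mm2 = (volume_mm3 / l_f) * math.cos(math.radians(pennation_deg))
    return area_mm2 / 100.0  # mm² → cm²


def muscle_force_magnitude(pcsa_cm2: float, specific_tension: float) -> float:
    """Maximal isometric force (N) = PCSA (cm²) × specific tension (N/cm²)."""
    if pcsa_cm2 < 0 or specific_tension < 0:
        raise ValueError("inputs must be non-negative")
    return pcsa_cm2 * specific_tension


def muscle_vector(origin_centroid, insertion_centroid) -> np.ndarray:
    """Origin − insertion centroid: the pull direction on the mandible."""
    v = np.asarray(origin_centroid, float) - np.asarray(insertion_centroid, float)
    if np.linalg.norm(v) == 0.0:
        raise DegenerateMuscleError("origin and insertion centroids coincide")
    return v


def distribute_force(
    site: AttachmentSite, total_force_N: float, target_centroid
) -> list:
    """Spread a scalar muscle force over a site's vertices.

    Vertex *i* carries magnitude ``total_force·w_i/Σw`` (w = nodal area
    weights), directed from the vertex toward ``target_centroid`` (the
    opposite attachment's centroid).  Scalar force is conserved exactly; the
    net vector converges to the single-point force as the target recedes.
    """
    target = np.asarray(target_centroid, dtype=float)
    w = nodal_area_weights(site)
    w = w / w.sum()
    loads = []
    for vertex, wi in zip(site.mesh.vertices, w):
        d = target - vertex
        norm = np.linalg.norm(d)
        if norm == 0.0:
            raise DegenerateDirectionError(
                f"target centroid coincides with a vertex of site {site.name!r}"
            )
        loads.append((vertex.copy(), (total_force_N * wi / norm) * d))
    return loads


def build_muscle_force(spec: MuscleSpec, load_side: str = "origin") -> MuscleForce:
    """Run the full per-muscle chain: areas → volume → PCSA → force → loads.

    ``load_side`` selects which attachment receives the distributed loads
    ('origin' loads the cranium-side site toward the insertion centroid;
    'insertion' the reverse, for mandible-loading workflows).
    """
    if load_side not in ("origin", "insertion"):
        raise ValueError("load_side must be 'origin' or 'insertion'")
    l_f = fascicle_length(
        spec.origin.centroid, spec.insertion.centroid, spec.rel_fascicle_length
    )
    vol = frustum_volume(spec.origin.area, spec.insertion.area, l_f)
    area_cm2 = pcsa(vol, l_f, spec.pennation_deg)
    force = muscle_force_magnitude(area_cm2, spec.specific_tension)
    vec = muscle_vector(spec.origin.centroid, spec.insertion.centroid)
    unit = vec / np.linalg.norm(vec)
    if load_side == "origin":
        loads = distribute_force(spec.origin, force, spec.insertion.centroid)
    else:
        loads = distribute_force(spec.insertion, force, spec.origin.centroid)
    return MuscleForce(
        spec=spec,
        fascicle_length_mm=l_f,
        volume_mm3=vol,
        pcsa_cm2=area_cm2,
        force_N=force,
        vector=vec,
        unit_vector=unit,
        node_loads=loads,
    )
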