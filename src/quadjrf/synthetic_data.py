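"""Synthetic skull specimens and clades for end-to-end pipeline testing.

Real inputs to the pipeline are specimen-specific 3D models that cannot be
bundled; this module generates geometrically simple stand-ins with the same
statistical structure.  A single ``flattening`` parameter φ ∈ [0, 1] drives a
smooth rotation of the quadrate structural axis from dorsoventral (φ = 0,
early-suchian-like tall skulls) toward an oblique rostrodorsal direction
with a growing mediolateral component (φ = 1, extant-crocodylian-like flat
skulls).  Muscle attachment patches are placed so the summed muscle
resultant on each side makes a controllable angle δ with that side's
quadrate axis, so the expected axis/JRF correspondence is known by
construction.  Clades are pure-birth trees on which φ evolves by Brownian
motion (reflected into [0, 1]), giving PGLS a known generative signal to
recover.

Attachment patches are small planar quads (two triangles), so areas and
centroids are closed-form.  All randomness flows from one integer seed.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import yaml

from .errors import GenerationError
from .mesh_geometry import AttachmentSite, LandmarkSet, TriMesh
from .muscle_model import MUSCLE_NAMES, default_muscle_table
from .phylo_comparative import Phylo, simulate_brownian

__all__ = [
    "SkullParams",
    "SyntheticSpecimen",
    "SyntheticClade",
    "make_specimen",
    "make_clade",
    "pure_birth_tree",
    "write_specimen",
    "write_clade",
    "quadrate_axis_direction",
    "muscle_pull_direction",
]

# Sagittal and transverse rotation of the quadrate axis at full flattening.
_MAX_SAGITTAL_DEG = 50.0
_MAX_TRANSVERSE_DEG = 25.0

# Per-muscle layout at reference scale (skull length 300 mm, jaw width
# 160 mm): rostral offset of the insertion (mm), its ventral depth (mm),
# a muscle-length factor, and origin patch area (mm²).  The pterygoideus
# complex carries the largest attachments, as in crocodylians.
_MUSCLE_LAYOUT = {
    "mAMES": (18.0, -30.0, 0.95, 180.0),
    "mAMEM": (24.0, -28.0, 0.90, 120.0),
    "mAMEP": (30.0, -26.0, 1.00, 160.0),
    "mAMP": (10.0, -24.0, 0.80, 200.0),
    "mPSTs": (36.0, -28.0, 1.05, 90.0),
    "mPTd": (48.0, -32.0, 1.20, 260.0),
    "mPTv": (42.0, -36.0, 1.15, 300.0),
    "mDM": (-14.0, -20.0, 0.70, 110.0),
}
_INSERTION_AREA_FRACTION = 0.6
_REF_LENGTH = 300.0
_REF_WIDTH = 160.0


@dataclass
class SkullParams:
    """Generative parameters for one synthetic skull."""

    flattening: float = 0.5  # φ: 0 = tall dorsoventral quadrate, 1 = flat oblique
    skull_length: float = 300.0  # joint line to snout tip, mm
    jaw_width: float = 160.0  # distance between jaw joints, mm
    quadrate_length: float = 45.0  # ventral articular surface to otic condyle, mm
    axis_offset_deg: float = 20.0  # δ: angle between muscle resultant and axis
    gape_deg: float = 5.0  # recorded; geometry is generated already posed
    patch_scale: float = 1.0  # multiplies all attachment areas
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.flattening <= 1.0:
            raise ValueError("flattening must be in [0, 1]")
        if self.axis_offset_deg < 0:
            raise ValueError("axis_offset_deg must be >= 0")
        if min(self.skull_length, self.jaw_width, self.quadrate_length) <= 0:
            raise ValueError("lengths must be positive")
        if self.patch_scale <= 0:
            raise ValueError("patch_scale must be positive")


@dataclass
class SyntheticSpecimen:
    """A generated specimen: sites, landmarks, truth, and provenance."""

    specimen_id: str
    sites: dict  # {(muscle, side, 'origin'|'insertion'): AttachmentSite}
    landmarks: LandmarkSet
    true_axes: dict  # {'left': unit vec, 'right': unit vec}
    true_muscle_direction: dict  # per-side pull direction (insertion→origin)
    muscle_table: "pd.DataFrame"
    params: SkullParams


@dataclass
class SyntheticClade:
    """A pure-birth clade of synthetic specimens with Brownian flattening."""

    phylo: Phylo
    specimens: dict  # {tip label: SyntheticSpecimen}
    flattening: dict  # {tip label: φ}
    provenance: dict


def _side_sign(side: str) -> float:
    if side == "left":
        return 1.0
    if side == "right":
        return -1.0
    raise ValueError("side must be 'left' or 'right'")


def quadrate_axis_direction(flattening: float, side: str) -> np.ndarray:
    """Unit quadrate axis (ventral → dorsal) as a smooth function of φ.

    At φ = 0 the axis is (0, 1, 0); as φ grows it tilts rostrally in the
    sagittal plane (up to 50°) and medially in the transverse plane (up to
    25°), so the dorsoventral component falls monotonically while the
    rostrocaudal and |mediolateral| components rise.
    """
    theta_s = np.radians(_MAX_SAGITTAL_DEG * flattening)
    theta_m = np.radians(_MAX_TRANSVERSE_DEG * flattening)
    sx = _side_sign(side)
    # dorsal condyle migrates medially: x points toward the midline
    return np.array(
        [
            -sx * np.sin(theta_m),
            np.cos(theta_m) * np.cos(theta_s),
            np.cos(theta_m) * np.sin(theta_s),
        ]
    )


def _rodrigues(v: np.ndarray, k: np.ndarray, angle_rad: float) -> np.ndarray:
    k = k / np.linalg.norm(k)
    return (
        v * np.cos(angle_rad)
        + np.cross(k, v) * np.sin(angle_rad)
        + k * np.dot(k, v) * (1.0 - np.cos(angle_rad))
    )


def muscle_pull_direction(axis: np.ndarray, offset_deg: float) -> np.ndarray:
    """Direction of the summed muscle pull (insertion → origin).

    The quadrate axis rotated by exactly ``offset_deg`` away from rostral
    within the plane spanned by the axis and the rostrocaudal direction, so
    the resultant-vs-axis angle is ``offset_deg`` by construction.
    """
    if offset_deg == 0.0:
        return axis.copy()
    k = np.cross(axis, np.array([0.0, 0.0, 1.0]))
    norm = np.linalg.norm(k)
    if norm < 1e-9:
        # axis ≈ rostrocaudal (never reached for φ ∈ [0,1]); fall back to x̂
        k = np.array([1.0, 0.0, 0.0])
    m = _rodrigues(axis, k, -np.radians(offset_deg))
    return m / np.linalg.norm(m)


def _patch_quad(centroid: np.ndarray, normal: np.ndarray, area: float) -> TriMesh:
    """A planar square patch of exact ``area`` centered on ``centroid``."""
    normal = normal / np.linalg.norm(normal)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    h = 0.5 * np.sqrt(area)
    verts = np.array(
        [
            centroid - h * u - h * v,
            centroid + h * u - h * v,
            centroid + h * u + h * v,
            centroid - h * u + h * v,
        ]
    )
    faces = np.array([[0, 1, 2], [0, 2, 3]])
    return TriMesh(verts, faces)


def make_specimen(params: SkullParams, specimen_id: str = "synthetic") -> SyntheticSpecimen:
    """Build one synthetic specimen from its parameters (deterministic)."""
    L, W = params.skull_length, params.jaw_width
    phi = params.flattening
    zscale = L / _REF_LENGTH
    xscale = W / _REF_WIDTH
    ascale = params.patch_scale * zscale**2

    landmarks = {}
    sites = {}
    true_axes = {}
    true_dir = {}
    # rostral bite migrates slightly rostrally as the skull flattens
    z_rostral = L * (0.65 + 0.10 * phi)
    z_caudal = L * 0.18
    tooth_x = 0.55 * W / 2.0

    for side in ("left", "right"):
        sx = _side_sign(side)
        joint = np.array([sx * W / 2.0, 0.0, 0.0])
        axis = quadrate_axis_direction(phi, side)
        pull = muscle_pull_direction(axis, params.axis_offset_deg)
        true_axes[side] = axis
        true_dir[side] = pull
        landmarks[f"joint_{side}"] = joint
        landmarks[f"quadrate_ventral_{side}"] = joint
        landmarks[f"quadrate_dorsal_{side}"] = joint + params.quadrate_length * axis
        landmarks[f"bite_rostral_{side}"] = np.array(
            [sx * tooth_x, -5.0 * zscale, z_rostral]
        )
        landmarks[f"bite_caudal_{side}"] = np.array(
            [sx * tooth_x, -5.0 * zscale, z_caudal]
        )

        for muscle in MUSCLE_NAMES:
            z_off, y_ins, len_factor, origin_area = _MUSCLE_LAYOUT[muscle]
            a_or = origin_area * ascale
            a_ins = a_or * _INSERTION_AREA_FRACTION
            length = 0.22 * L * len_factor
            if length <= np.sqrt(2.0 * max(a_or, a_ins)):
                raise GenerationError(
                    f"{muscle}: patch larger than the muscle is long "
                    "(reduce patch_scale or enlarge the skull)"
                )
            c_ins = np.array(
                [sx * 0.40 * W / 2.0, y_ins * zscale, z_off * zscale]
            )
            c_or = c_ins + length * pull
            sites[(muscle, side, "origin")] = AttachmentSite(
                name=f"{muscle}_{side}_origin", mesh=_patch_quad(c_or, pull, a_or)
            )
            sites[(muscle, side, "insertion")] = AttachmentSite(
                name=f"{muscle}_{side}_insertion",
                mesh=_patch_quad(c_ins, pull, a_ins),
            )

    return SyntheticSpecimen(
        specimen_id=specimen_id,
        sites=sites,
        landmarks=LandmarkSet(landmarks),
        true_axes=true_axes,
        true_muscle_direction=true_dir,
        muscle_table=default_muscle_table(),
        params=params,
    )


def pure_birth_tree(n_taxa: int, birth_rate: float = 1.0, seed: int = 0) -> Phylo:
    """A seeded pure-birth (Yule) tree scaled to unit root-to-tip depth."""
    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3")
    rng = _random.Random(seed)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=rng,
    )
    # The simulation stops exactly at the nth speciation, leaving zero-length
    # terminal branches (and a singular Brownian covariance); let the clade
    # age by one more waiting time, which keeps it ultrametric.
    extra = rng.expovariate(birth_rate * n_taxa)
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"t{i + 1}"
        leaf.edge.length = leaf.edge.length + extra
    phylo = Phylo(tree)
    depth = max(phylo.depths()[leaf] for leaf in tree.leaf_node_iter())
    for node in tree.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length = node.edge.length / depth
    return Phylo(tree)


def make_clade(
    n_taxa: int = 11,
    birth_rate: float = 1.0,
    brownian_rate: float = 0.35,
    base_params: SkullParams | None = None,
    seed: int = 0,
    root_flattening: float = 0.15,
) -> SyntheticClade:
    """Generate a pure-birth clade whose flattening evolves by Brownian motion.

    The tree is scaled to unit root-to-tip depth; ``brownian_rate`` is the
    standard deviation of φ change per unit depth, reflected into [0, 1].
    Each tip receives a specimen built from ``base_params`` with its own φ.
    """
    if base_params is None:
        base_params = SkullParams()
    ss = np.random.SeedSequence(seed)
    tree_seed, bm_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    phylo = pure_birth_tree(n_taxa, birth_rate=birth_rate, seed=tree_seed)
    tree = phylo.tree

    flattening = simulate_brownian(
        phylo, rate=brownian_rate, seed=bm_seed, root_value=root_flattening,
        bounds=(0.0, 1.0),
    )
    specimens = {}
    for tip, phi in flattening.items():
        p = SkullParams(
            flattening=float(phi),
            skull_length=base_params.skull_length,
            jaw_width=base_params.jaw_width,
            quadrate_length=base_params.quadrate_length,
            axis_offset_deg=base_params.axis_offset_deg,
            gape_deg=base_params.gape_deg,
            patch_scale=base_params.patch_scale,
            seed=seed,
        )
        specimens[tip] = make_specimen(p, specimen_id=tip)
    provenance = {
        "seed": seed,
        "n_taxa": n_taxa,
        "birth_rate": birth_rate,
        "brownian_rate": brownian_rate,
        "root_flattening": root_flattening,
        "axis_offset_deg": base_params.axis_offset_deg,
        "note": (
            "muscle resultants track the quadrate axis at axis_offset_deg by "
            "construction; axis components are smooth monotone maps of the "
            "Brownian flattening trait"
        ),
    }
    return SyntheticClade(
        phylo=phylo, specimens=specimens, flattening=flattening, provenance=provenance
    )


def _export_stl_ascii(mesh: TriMesh, path: Path) -> None:
    import trimesh as _trimesh

    tm = _trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    path.write_bytes(tm.export(file_type="stl_ascii").encode())


def write_specimen(spec: SyntheticSpecimen, directory, force: bool = False) -> dict:
    """Write one specimen as STL sites + landmark/muscle CSVs + provenance YAML.

    Returns the file map. Refuses to overwrite existing files unless
    ``force`` is set.
    """
    from .mesh_geometry import write_landmarks

    directory = Path(directory)
    sites_dir = directory / "sites"
    sites_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    for (muscle, side, role), site in spec.sites.items():
        path = sites_dir / f"{muscle}_{side}_{role}.stl"
        if path.exists() and not force:
            raise FileExistsError(f"{path} exists (use force=True to overwrite)")
        _export_stl_ascii(site.mesh, path)
        files[(muscle, side, role)] = path
    lm_path = directory / "landmarks.csv"
    mt_path = directory / "muscles.csv"
    meta_path = directory / "specimen.yaml"
    for path in (lm_path, mt_path, meta_path):
        if path.exists() and not force:
            raise FileExistsError(f"{path} exists (use force=True to overwrite)")
    write_landmarks(spec.landmarks, lm_path)
    spec.muscle_table.to_csv(mt_path, index=False)
    meta = {
        "specimen_id": spec.specimen_id,
        "params": {
            "flattening": spec.params.flattening,
            "skull_length": spec.params.skull_length,
            "jaw_width": spec.params.jaw_width,
            "quadrate_length": spec.params.quadrate_length,
            "axis_offset_deg": spec.params.axis_offset_deg,
            "gape_deg": spec.params.gape_deg,
            "patch_scale": spec.params.patch_scale,
            "seed": spec.params.seed,
        },
        "true_axes": {s: [float(c) for c in v] for s, v in spec.true_axes.items()},
    }
    meta_path.write_text(yaml.safe_dump(meta, sort_keys=True))
    return files


def write_clade(clade: SyntheticClade, directory, seed: int | None = None,
                force: bool = False) -> Path:
    """Write a ready-to-run clade directory (specimens/, tree.newick, config.yaml)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spec_entries = []
    for tip in clade.phylo.tip_labels:
        spec = clade.specimens[tip]
        spec_dir = directory / "specimens" / tip
        write_specimen(spec, spec_dir, force=force)
        spec_entries.append(
            {
                "id": tip,
                "landmarks": f"specimens/{tip}/landmarks.csv",
                "muscle_table": f"specimens/{tip}/muscles.csv",
                "sites_dir": f"specimens/{tip}/sites",
            }
        )
    tree_path = directory / "tree.newick"
    if tree_path.exists() and not force:
        raise FileExistsError(f"{tree_path} exists (use force=True to overwrite)")
    tree_path.write_text(
        clade.phylo.tree.as_string(schema="newick", suppress_rooting=True)
    )
    config = {
        "seed": int(clade.provenance["seed"] if seed is None else seed),
        "null_size": 1350,
        "n_resamples": 10000,
        "bite_positions": ["rostral", "caudal"],
        "bite_sides": ["left"],
        "load_side": "origin",
        "include_mDM": True,
        "centroid_method": "surface",
        "pool_sides_in_variance_test": True,
        "tree": "tree.newick",
        "output_dir": "results",
        "specimens": spec_entries,
    }
    cfg_path = directory / "config.yaml"
    if cfg_path.exists() and not force:
        raise FileExistsError(f"{cfg_path} exists (use force=True to overwrite)")
    cfg_path.write_text(yaml.safe_dump(config, sort_keys=False))
    (directory / "provenance.yaml").write_text(
        yaml.safe_dump(clade.provenance, sort_keys=True)
    )
    return directory
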