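"""Pipeline orchestration: config, stages, and tabular outputs.

Stages run in order — muscles (force reconstruction per specimen), jrf
(static reactions per bite scenario), compare (similarity statistics and
Monte-Carlo tests), pgls (phylogenetic regressions and ancestral states) —
each writing one or two CSV/JSON files into the output directory.  All
floating output is formatted to 12 significant digits, so identical
(config, seed) reruns produce identical files.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from .jrf_statics import BiteScenario, bite_force, jrf_unit_vector, solve_reactions
from .mesh_geometry import (
    AttachmentSite,
    LANDMARK_NAMES,
    load_mesh,
    read_landmarks,
)
from .muscle_model import (
    MUSCLE_NAMES,
    MuscleSpec,
    build_muscle_force,
    read_muscle_table,
)
from .phylo_comparative import (
    ancestral_correlation,
    ancestral_states,
    brownian_covariance,
    internal_state_values,
    pgls_fit,
    read_newick,
)
from .similarity_stats import (
    angle_deg,
    dot_similarity,
    individual_match_test,
    random_unit_vectors,
    sample_mean_test,
    variance_ratio_test,
)

__all__ = ["RunConfig", "load_config", "validate_config", "run_pipeline"]

STAGES = ("muscles", "jrf", "compare", "pgls")
_FLOAT_FMT = "%.12g"

_KNOWN_KEYS = {
    "seed",
    "null_size",
    "n_resamples",
    "bite_positions",
    "bite_sides",
    "load_side",
    "include_mDM",
    "centroid_method",
    "pool_sides_in_variance_test",
    "tree",
    "output_dir",
    "specimens",
}
_KNOWN_SPECIMEN_KEYS = {"id", "landmarks", "muscle_table", "sites_dir", "sites"}


@dataclass
class SpecimenEntry:
    specimen_id: str
    landmarks: Path
    muscle_table: Path
    sites_dir: Path | None = None
    sites: dict | None = None  # explicit {(muscle, side, role): path}


@dataclass
class RunConfig:
    """Validated run configuration (paths resolved against the config dir)."""

    base_dir: Path
    specimens: list
    seed: int = 0
    null_size: int = 1350
    n_resamples: int = 10_000
    bite_positions: tuple = ("rostral", "caudal")
    bite_sides: tuple = ("left",)
    load_side: str = "origin"
    include_mDM: bool = True
    centroid_method: str = "surface"
    pool_sides_in_variance_test: bool = True
    tree: Path | None = None
    output_dir: Path = field(default_factory=lambda: Path("results"))
    raw: dict = field(default_factory=dict)


def _site_path(entry: SpecimenEntry, muscle: str, side: str, role: str) -> Path:
    if entry.sites is not None and (muscle, side, role) in entry.sites:
        return entry.sites[(muscle, side, role)]
    if entry.sites_dir is not None:
        return entry.sites_dir / f"{muscle}_{side}_{role}.stl"
    raise ConfigError(
        f"specimen {entry.specimen_id}: no site path for {muscle} {side} {role}"
    )


def load_config(path) -> RunConfig:
    """Parse and structurally validate a YAML/JSON run configuration."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    base = path.parent
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown keys: {sorted(unknown)}")
    if "specimens" not in raw or not raw["specimens"]:
        raise ConfigError(f"{path}: 'specimens' list is required")
    entries = []
    for i, s in enumerate(raw["specimens"]):
        bad = set(s) - _KNOWN_SPECIMEN_KEYS
        if bad:
            raise ConfigError(f"{path}: specimen #{i}: unknown keys {sorted(bad)}")
        sites = None
        if "sites" in s:
            sites = {}
            for muscle, sides in s["sites"].items():
                for side, roles in sides.items():
                    for role, p in roles.items():
                        sites[(muscle, side, role)] = base / p
        entries.append(
            SpecimenEntry(
                specimen_id=str(s["id"]),
                landmarks=base / s["landmarks"],
                muscle_table=base / s["muscle_table"],
                sites_dir=(base / s["sites_dir"]) if "sites_dir" in s else None,
                sites=sites,
            )
        )
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError(f"{path}: seed must be an integer")
    cfg = RunConfig(
        base_dir=base,
        specimens=entries,
        seed=seed,
        null_size=int(raw.get("null_size", 1350)),
        n_resamples=int(raw.get("n_resamples", 10_000)),
        bite_positions=tuple(raw.get("bite_positions", ("rostral", "caudal"))),
        bite_sides=tuple(raw.get("bite_sides", ("left",))),
        load_side=str(raw.get("load_side", "origin")),
        include_mDM=bool(raw.get("include_mDM", True)),
        centroid_method=str(raw.get("centroid_method", "surface")),
        pool_sides_in_variance_test=bool(
            raw.get("pool_sides_in_variance_test", True)
        ),
        tree=(base / raw["tree"]) if raw.get("tree") else None,
        output_dir=base / raw.get("output_dir", "results"),
        raw=raw,
    )
    for pos in cfg.bite_positions:
        if pos not in ("rostral", "caudal"):
            raise ConfigError(f"bad bite position {pos!r}")
    for side in cfg.bite_sides:
        if side not in ("left", "right"):
            raise ConfigError(f"bad bite side {side!r}")
    if cfg.load_side not in ("origin", "insertion"):
        raise ConfigError("load_side must be 'origin' or 'insertion'")
    return cfg


def validate_config(path, stages=STAGES) -> list:
    """Return a list of problems (empty = clean): missing files, bad names."""
    problems = []
    try:
        cfg = load_config(path)
    except ConfigError as exc:
        return [str(exc)]
    for entry in cfg.specimens:
        for p in (entry.landmarks, entry.muscle_table):
            if not p.exists():
                problems.append(f"{entry.specimen_id}: missing file {p}")
        if entry.landmarks.exists():
            try:
                lm = read_landmarks(entry.landmarks)
                needed = [
                    f"{stem}_{side}"
                    for stem in (
                        "quadrate_ventral",
                        "quadrate_dorsal",
                        "joint",
                    )
                    for side in ("left", "right")
                ] + [
                    f"bite_{pos}_{side}"
                    for pos in cfg.bite_positions
                    for side in cfg.bite_sides
                ]
                missing = [n for n in needed if n not in lm]
                if missing:
                    problems.append(
                        f"{entry.specimen_id}: landmarks missing {missing}"
                    )
            except Exception as exc:
                problems.append(f"{entry.specimen_id}: {exc}")
        for muscle in MUSCLE_NAMES:
            for side in ("left", "right"):
                for role in ("origin", "insertion"):
                    try:
                        p = _site_path(entry, muscle, side, role)
                    except ConfigError as exc:
                        problems.append(str(exc))
                        continue
                    if not p.exists():
                        problems.append(
                            f"{entry.specimen_id}: missing site file {p}"
                        )
    if "pgls" in stages:
        if cfg.tree is None:
            problems.append("pgls stage requested but no tree configured")
        elif not cfg.tree.exists():
            problems.append(f"missing tree file {cfg.tree}")
    return problems


@dataclass
class LoadedSpecimen:
    entry: SpecimenEntry
    landmarks: object
    muscle_table: pd.DataFrame
    sites: dict


def _load_specimen(entry: SpecimenEntry) -> LoadedSpecimen:
    landmarks = read_landmarks(entry.landmarks)
    table = read_muscle_table(entry.muscle_table)
    sites = {}
    for _, row in table.iterrows():
        muscle, side = row["muscle"], row["side"]
        for role in ("origin", "insertion"):
            p = _site_path(entry, muscle, side, role)
            sites[(muscle, side, role)] = AttachmentSite(
                name=f"{muscle}_{side}_{role}", mesh=load_mesh(p)
            )
    return LoadedSpecimen(entry, landmarks, table, sites)


def _muscle_forces(spec: LoadedSpecimen, cfg: RunConfig) -> dict:
    """{(muscle, side): MuscleForce} for one specimen."""
    out = {}
    for _, row in spec.muscle_table.iterrows():
        muscle, side = row["muscle"], row["side"]
        if muscle == "mDM" and not cfg.include_mDM:
            continue
        ms = MuscleSpec(
            name=muscle,
            side=side,
            origin=spec.sites[(muscle, side, "origin")],
            insertion=spec.sites[(muscle, side, "insertion")],
            rel_fascicle_length=float(row["rel_fascicle_length"]),
            pennation_deg=float(row["pennation_deg"]),
            specific_tension=float(row["specific_tension"]),
        )
        out[(muscle, side)] = build_muscle_force(ms, load_side=cfg.load_side)
    return out


def stage_muscles(specimens: dict, cfg: RunConfig):
    """Compute all muscle forces; returns (forces, muscles dataframe)."""
    forces = {sid: _muscle_forces(spec, cfg) for sid, spec in specimens.items()}
    rows = []
    for sid, per_muscle in forces.items():
        for (muscle, side), mf in per_muscle.items():
            oc, ic = mf.spec.origin.centroid, mf.spec.insertion.centroid
            rows.append(
                {
                    "specimen": sid,
                    "muscle": muscle,
                    "side": side,
                    "origin_area_mm2": mf.spec.origin.area,
                    "insertion_area_mm2": mf.spec.insertion.area,
                    "origin_cx": oc[0], "origin_cy": oc[1], "origin_cz": oc[2],
                    "insertion_cx": ic[0], "insertion_cy": ic[1], "insertion_cz": ic[2],
                    "fascicle_length_mm": mf.fascicle_length_mm,
                    "volume_mm3": mf.volume_mm3,
                    "pcsa_cm2": mf.pcsa_cm2,
                    "force_N": mf.force_N,
                    "vx": mf.vector[0], "vy": mf.vector[1], "vz": mf.vector[2],
                    "ux": mf.unit_vector[0], "uy": mf.unit_vector[1],
                    "uz": mf.unit_vector[2],
                }
            )
    return forces, pd.DataFrame(rows)


def stage_jrf(specimens: dict, forces: dict, cfg: RunConfig):
    """Solve every bite scenario; returns (orientation rows, jrf dataframe)."""
    jrf_rows = []
    pairs = []  # dict rows with v_Q / v_JRF per specimen, position, role
    for sid, spec in specimens.items():
        loads = [
            (p, f)
            for mf in forces[sid].values()
            for p, f in mf.node_loads
        ]
        for pos in cfg.bite_positions:
            for bite_side in cfg.bite_sides:
                other = "right" if bite_side == "left" else "left"
                scenario = BiteScenario(
                    bite_side=bite_side,
                    bite_position=pos,
                    bite_point=spec.landmarks[f"bite_{pos}_{bite_side}"],
                    joint_W=spec.landmarks[f"joint_{bite_side}"],
                    joint_B=spec.landmarks[f"joint_{other}"],
                    applied_loads=loads,
                )
                sol = solve_reactions(scenario)
                bf_mag, bf_unit = bite_force(sol)
                row = {
                    "specimen": sid,
                    "bite_position": pos,
                    "bite_side": bite_side,
                    "bite_force_N": bf_mag,
                    "force_residual": sol.force_residual,
                    "moment_residual": sol.moment_residual,
                }
                for tag, r in (("W", sol.r_W), ("B", sol.r_B), ("bite", sol.r_bite)):
                    row[f"r{tag}_x"], row[f"r{tag}_y"], row[f"r{tag}_z"] = r
                    row[f"r{tag}_mag"] = float(np.linalg.norm(r))
                jrf_rows.append(row)
                for role, joint, anat_side in (
                    ("working", "W", bite_side),
                    ("balancing", "B", other),
                ):
                    v_jrf = jrf_unit_vector(sol, joint)
                    v_q = spec.landmarks.axis(anat_side)
                    pairs.append(
                        {
                            "specimen": sid,
                            "bite_position": pos,
                            "bite_side": bite_side,
                            "role": role,
                            "v_Q": v_q,
                            "v_JRF": v_jrf,
                        }
                    )
    return pairs, pd.DataFrame(jrf_rows)


def stage_compare(pairs: list, cfg: RunConfig):
    """Similarity stats: per-pair tests plus per-group resampled mean tests."""
    null = random_unit_vectors(cfg.null_size, seed=cfg.seed)
    sim_rows = []
    for pr in pairs:
        d = dot_similarity(pr["v_Q"], pr["v_JRF"])
        sim_rows.append(
            {
                "specimen": pr["specimen"],
                "bite_position": pr["bite_position"],
                "bite_side": pr["bite_side"],
                "role": pr["role"],
                "dot": d,
                "angle_deg": angle_deg(d),
                "match_proportion": individual_match_test(
                    pr["v_Q"], pr["v_JRF"], null
                ),
            }
        )
    sim_df = pd.DataFrame(sim_rows)
    groups = {}
    for i, ((pos, role), g) in enumerate(
        sorted(sim_df.groupby(["bite_position", "role"]))
    ):
        dots = g["dot"].to_numpy()
        p, means = sample_mean_test(
            dots, null, n_resamples=cfg.n_resamples, seed=cfg.seed + 1 + i
        )
        groups[f"{pos}_{role}"] = {
            "n": int(len(dots)),
            "observed_mean_dot": float(dots.mean()),
            "observed_mean_angle_deg": float(g["angle_deg"].mean()),
            "p": float(p),
            "n_resamples": int(cfg.n_resamples),
            "resample_mean_of_means": float(means.mean()),
            "resample_sd_of_means": float(means.std(ddof=1)),
        }
    # F-test of dot-product variances, caudal vs rostral
    variance = None
    if {"rostral", "caudal"} <= set(sim_df["bite_position"]):
        if cfg.pool_sides_in_variance_test:
            rostral = sim_df.query("bite_position == 'rostral'")["dot"]
            caudal = sim_df.query("bite_position == 'caudal'")["dot"]
            f_stat, p_val, numerator = variance_ratio_test(rostral, caudal)
            variance = {
                "pooled_sides": True,
                "F": f_stat,
                "p": p_val,
                "numerator": numerator,
            }
        else:
            variance = {"pooled_sides": False, "per_role": {}}
            for role in ("working", "balancing"):
                rostral = sim_df.query(
                    "bite_position == 'rostral' and role == @role"
                )["dot"]
                caudal = sim_df.query(
                    "bite_position == 'caudal' and role == @role"
                )["dot"]
                f_stat, p_val, numerator = variance_ratio_test(rostral, caudal)
                variance["per_role"][role] = {
                    "F": f_stat,
                    "p": p_val,
                    "numerator": numerator,
                }
    report = {
        "null_size": int(cfg.null_size),
        "seed": int(cfg.seed),
        "groups": groups,
        "variance_test": variance,
    }
    return sim_df, report


def stage_pgls(pairs: list, cfg: RunConfig):
    """Component-wise PGLS of JRF direction on quadrate axis, plus ancestry."""
    if cfg.tree is None:
        raise ConfigError("pgls stage requires a tree")
    phylo = read_newick(cfg.tree)
    rows = []
    anc_rows = []
    corr_rows = []
    by_group = {}
    for pr in pairs:
        by_group.setdefault((pr["bite_position"], pr["role"]), {})[
            pr["specimen"]
        ] = pr
    components = ("x", "y", "z")
    for (pos, role), group in sorted(by_group.items()):
        labels = [t for t in phylo.tip_labels if t in group]
        if len(labels) != phylo.n_tips or len(labels) < 3:
            raise ConfigError(
                f"pgls: specimens for {pos}/{role} do not match the tree tips"
            )
        C = brownian_covariance(phylo, order=labels)
        for ci, comp in enumerate(components):
            x = np.array([group[t]["v_Q"][ci] for t in labels])
            y = np.array([group[t]["v_JRF"][ci] for t in labels])
            fit = pgls_fit(x, y, C)
            rows.append(
                {
                    "bite_position": pos,
                    "role": role,
                    "component": comp,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "slope_se": fit.slope_se,
                    "t": fit.t_slope,
                    "p": fit.p_slope,
                    "df": fit.df,
                    "sigma2": fit.sigma2,
                }
            )
            sx = ancestral_states(phylo, dict(zip(labels, x)))
            sy = ancestral_states(phylo, dict(zip(labels, y)))
            ix = internal_state_values(phylo, sx)
            iy = internal_state_values(phylo, sy)
            corr_rows.append(
                {
                    "bite_position": pos,
                    "role": role,
                    "component": comp,
                    "ancestral_r": ancestral_correlation(ix, iy),
                }
            )
            for node in sx:
                anc_rows.append(
                    {
                        "bite_position": pos,
                        "role": role,
                        "component": comp,
                        "node": node,
                        "axis_state": sx[node],
                        "jrf_state": sy[node],
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(anc_rows), pd.DataFrame(corr_rows)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def run_pipeline(cfg: RunConfig, stages=STAGES, log=None) -> Path:
    """Execute the requested stages in order and write outputs.

    Returns the output directory.  Earlier stages are always recomputed in
    memory (they are cheap and deterministic); only the files of requested
    stages are written.
    """
    def _log(msg: str) -> None:
        if log is not None:
            print(msg, file=log)

    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    _log(f"loading {len(cfg.specimens)} specimens")
    specimens = {e.specimen_id: _load_specimen(e) for e in cfg.specimens}

    _log("stage muscles")
    forces, muscles_df = stage_muscles(specimens, cfg)
    if "muscles" in stages:
        _write_csv(muscles_df, out / "muscles.csv")
    if set(stages) <= {"muscles"}:
        _write_manifest(cfg, out, stages)
        return out

    _log("stage jrf")
    pairs, jrf_df = stage_jrf(specimens, forces, cfg)
    if "jrf" in stages:
        _write_csv(jrf_df, out / "jrf.csv")

    if "compare" in stages or "pgls" in stages:
        if "compare" in stages:
            _log("stage compare")
            sim_df, report = stage_compare(pairs, cfg)
            _write_csv(sim_df, out / "similarity.csv")
            (out / "sample_test.json").write_text(
                json.dumps(report, indent=2, sort_keys=True)
            )
        if "pgls" in stages:
            _log("stage pgls")
            pgls_df, anc_df, corr_df = stage_pgls(pairs, cfg)
            _write_csv(pgls_df, out / "pgls.csv")
            _write_csv(anc_df, out / "ancestral.csv")
            _write_csv(corr_df, out / "ancestral_corr.csv")
    _write_manifest(cfg, out, stages)
    return out


def _write_manifest(cfg: RunConfig, out: Path, stages) -> None:
    canonical = yaml.safe_dump(cfg.raw, sort_keys=True)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "stages": list(stages),
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
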