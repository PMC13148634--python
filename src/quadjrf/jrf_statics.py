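"""Rigid-body statics for unilateral bites: joint and bite reactions.

The cranium is treated as a rigid body supported at three points — the
working-side jaw joint, the balancing-side jaw joint, and the tip of the
biting tooth — and loaded by the distributed muscle forces.  Static
equilibrium (ΣF = 0, ΣM = 0) gives six equations for nine unknown reaction
components, a three-fold indeterminacy that is resolved by the minimum-norm
solution: among all equilibrium-feasible reaction triples, the one with the
smallest summed squared magnitudes, obtained from the Moore–Penrose
pseudoinverse of the 6×9 equilibrium matrix.  Reactions are point forces on
the cranium; no reaction moments are carried.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SingularConfigurationError, UnstableOrientationError, ZeroVectorError

__all__ = [
    "BiteScenario",
    "ReactionSolution",
    "solve_reactions",
    "jrf_unit_vector",
    "bite_force",
]

#: Reactions smaller than this fraction of the total applied load are
#: considered orientation-unstable.
ORIENTATION_TOLERANCE = 1e-9


def _skew(p: np.ndarray) -> np.ndarray:
    """Matrix S with S @ v = p × v."""
    x, y, z = p
    return np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])


@dataclass
class BiteScenario:
    """A unilateral static bite: three support points plus applied loads."""

    bite_side: str  # working side: 'left' | 'right'
    bite_position: str  # 'rostral' | 'caudal'
    bite_point: np.ndarray
    joint_W: np.ndarray  # working-side jaw joint
    joint_B: np.ndarray  # balancing-side jaw joint
    applied_loads: list  # [(point mm, force 3-vector N)]

    def __post_init__(self) -> None:
        if self.bite_side not in ("left", "right"):
            raise ValueError("bite_side must be 'left' or 'right'")
        if self.bite_position not in ("rostral", "caudal"):
            raise ValueError("bite_position must be 'rostral' or 'caudal'")
        self.bite_point = np.asarray(self.bite_point, dtype=float).reshape(3)
        self.joint_W = np.asarray(self.joint_W, dtype=float).reshape(3)
        self.joint_B = np.asarray(self.joint_B, dtype=float).reshape(3)
        if not self.applied_loads:
            raise ValueError("applied_loads must be non-empty")
        self.applied_loads = [
            (np.asarray(p, float).reshape(3), np.asarray(f, float).reshape(3))
            for p, f in self.applied_loads
        ]


@dataclass
class ReactionSolution:
    """Minimum-norm equilibrium reactions and their residuals."""

    scenario: BiteScenario
    r_W: np.ndarray
    r_B: np.ndarray
    r_bite: np.ndarray
    force_residual: float
    moment_residual: float
    total_applied: float = field(default=0.0)


def _collinear(p1, p2, p3, rtol: float = 1e-12) -> bool:
    cross = np.cross(p2 - p1, p3 - p1)
    scale = max(np.linalg.norm(p2 - p1) * np.linalg.norm(p3 - p1), 1.0)
    return np.linalg.norm(cross) <= rtol * scale


def solve_reactions(scenario: BiteScenario) -> ReactionSolution:
    """Solve ΣF = 0, ΣM = 0 for the three support reactions (minimum norm)."""
    pw, pb, pt = scenario.joint_W, scenario.joint_B, scenario.bite_point
    if _collinear(pw, pb, pt):
        raise SingularConfigurationError(
            "joint and bite constraint points are collinear"
        )
    # Equilibrium about the centroid of the support points (conditioning).
    ref = (pw + pb + pt) / 3.0
    A = np.zeros((6, 9))
    for k, p in enumerate((pw, pb, pt)):
        A[0:3, 3 * k : 3 * k + 3] = np.eye(3)
        A[3:6, 3 * k : 3 * k + 3] = _skew(p - ref)
    f_sum = np.zeros(3)
    m_sum = np.zeros(3)
    for p, f in scenario.applied_loads:
        f_sum += f
        m_sum += np.cross(p - ref, f)
    b = np.concatenate([-f_sum, -m_sum])
    x = np.linalg.pinv(A) @ b
    r_w, r_b, r_t = x[0:3], x[3:6], x[6:9]

    residual = A @ x - b
    total_applied = sum(np.linalg.norm(f) for _, f in scenario.applied_loads)
    lever = max(
        np.linalg.norm(p - ref) for p in (pw, pb, pt)
    )
    return ReactionSolution(
        scenario=scenario,
        r_W=r_w,
        r_B=r_b,
        r_bite=r_t,
        force_residual=float(np.linalg.norm(residual[:3])),
        moment_residual=float(np.linalg.norm(residual[3:])),
        total_applied=float(total_applied) if total_applied else 0.0,
    )


def jrf_unit_vector(solution: ReactionSolution, joint: str) -> np.ndarray:
    """Unit direction of the reaction acting on the cranium at a jaw joint.

    ``joint`` is 'W' (working) or 'B' (balancing).  With muscles pulling the
    cranium ventrally toward the mandible, the joint reaction points
    dorsally through the quadrate, so pure axial compression of the quadrate
    gives a dot product of +1 against its ventral→dorsal structural axis.
    """
    if joint not in ("W", "B"):
        raise ValueError("joint must be 'W' or 'B'")
    r = solution.r_W if joint == "W" else solution.r_B
    mag = np.linalg.norm(r)
    if mag <= ORIENTATION_TOLERANCE * max(solution.total_applied, 1e-300):
        raise UnstableOrientationError(
            f"{joint}-side reaction magnitude {mag:.3g} N is too small for a "
            "stable orientation"
        )
    return r / mag


def bite_force(solution: ReactionSolution):
    """Bite reaction magnitude (N) and unit direction (None when zero)."""
    mag = float(np.linalg.norm(solution.r_bite))
    if mag == 0.0:
        return 0.0, None
    return mag, solution.r_bite / mag
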