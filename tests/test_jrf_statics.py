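import numpy as np
import pytest
from scipy.linalg import null_space
from scipy.optimize import minimize

from quadjrf.errors import SingularConfigurationError, UnstableOrientationError
from quadjrf.jrf_statics import (
    BiteScenario,
    bite_force,
    jrf_unit_vector,
    solve_reactions,
)


def _scenario(loads, bite=(0.0, 0.0, 200.0), jw=(80.0, 0.0, 0.0), jb=(-80.0, 0.0, 0.0)):
    return BiteScenario(
        bite_side="left",
        bite_position="rostral",
        bite_point=bite,
        joint_W=jw,
        joint_B=jb,
        applied_loads=loads,
    )


def _equilibrium_matrix(scenario):
    def skew(p):
        x, y, z = p
        return np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]], dtype=float)

    A = np.zeros((6, 9))
    for k, p in enumerate((scenario.joint_W, scenario.joint_B, scenario.bite_point)):
        A[0:3, 3 * k: 3 * k + 3] = np.eye(3)
        A[3:6, 3 * k: 3 * k + 3] = skew(p)
    return A


class TestSolveReactions:
    def test_load_at_bite_point_directly_opposed(self):
        sol = solve_reactions(_scenario([((0.0, 0.0, 200.0), (0.0, -100.0, 0.0))]))
        assert np.allclose(sol.r_bite, [0.0, 100.0, 0.0], atol=1e-9)
        assert np.allclose(sol.r_W, 0.0, atol=1e-9)
        assert np.allclose(sol.r_B, 0.0, atol=1e-9)

    def test_midspan_lever_balance(self):
        # joints at (±w,0,0), bite at (0,0,L), load −Fŷ at (0,0,L/2):
        # the minimum-norm equilibrium gives F/2 at the bite, F/4 per joint.
        F = 100.0
        sol = solve_reactions(_scenario([((0.0, 0.0, 100.0), (0.0, -F, 0.0))]))
        assert np.allclose(sol.r_bite, [0.0, F / 2.0, 0.0], atol=1e-8)
        assert np.allclose(sol.r_W, [0.0, F / 4.0, 0.0], atol=1e-8)
        assert np.allclose(sol.r_B, [0.0, F / 4.0, 0.0], atol=1e-8)

    def test_zero_magnitude_load_gives_zero_reactions(self):
        sol = solve_reactions(_scenario([((10.0, 5.0, 50.0), (0.0, 0.0, 0.0))]))
        for r in (sol.r_W, sol.r_B, sol.r_bite):
            assert np.allclose(r, 0.0)

    def test_collinear_supports_rejected(self):
        with pytest.raises(SingularConfigurationError):
            solve_reactions(
                _scenario(
                    [((0.0, 0.0, 0.0), (0.0, -1.0, 0.0))],
                    bite=(0.0, 0.0, 160.0),
                    jw=(0.0, 0.0, 0.0),
                    jb=(0.0, 0.0, 80.0),
                )
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_equilibrium_residuals_relative(self, seed):
        rng = np.random.default_rng(seed)
        loads = [
            (rng.uniform(-100, 100, 3), rng.uniform(-50, 50, 3)) for _ in range(40)
        ]
        sol = solve_reactions(_scenario(loads))
        total = sum(np.linalg.norm(f) for _, f in loads)
        lever = 300.0
        assert sol.force_residual <= 1e-9 * total
        assert sol.moment_residual <= 1e-9 * total * lever

    def test_linearity_in_loads(self):
        rng = np.random.default_rng(7)
        la = [(rng.uniform(-50, 50, 3), rng.uniform(-20, 20, 3)) for _ in range(5)]
        lb = [(rng.uniform(-50, 50, 3), rng.uniform(-20, 20, 3)) for _ in range(5)]
        sa = solve_reactions(_scenario(la))
        sb = solve_reactions(_scenario(lb))
        sab = solve_reactions(_scenario(la + lb))
        assert np.allclose(sab.r_W, sa.r_W + sb.r_W, atol=1e-8)
        assert np.allclose(sab.r_bite, sa.r_bite + sb.r_bite, atol=1e-8)

    def test_bilateral_symmetry_mirrors_reactions(self):
        # symmetric geometry and loads, midline bite: r_W is the x-mirror of r_B
        loads = [
            ((60.0, -20.0, 30.0), (-5.0, -40.0, 10.0)),
            ((-60.0, -20.0, 30.0), (5.0, -40.0, 10.0)),
        ]
        sol = solve_reactions(_scenario(loads))
        mirror = np.array([-1.0, 1.0, 1.0])
        assert np.allclose(sol.r_W, sol.r_B * mirror, atol=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_minimum_norm_against_optimization_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        loads = [(rng.uniform(-80, 80, 3), rng.uniform(-30, 30, 3)) for _ in range(8)]
        scenario = _scenario(loads)
        sol = solve_reactions(scenario)
        x = np.concatenate([sol.r_W, sol.r_B, sol.r_bite])
        A = _equilibrium_matrix(scenario)
        N = null_space(A)
        assert N.shape[1] == 3  # three-fold static indeterminacy

        # minimize ‖x0 + N a‖² over null-space coordinates a
        def cost(a):
            return np.sum((x + N @ a) ** 2)

        res = minimize(cost, np.zeros(N.shape[1]), method="BFGS")
        assert res.fun >= np.sum(x**2) - 1e-6 * max(np.sum(x**2), 1.0)
        assert np.linalg.norm(res.x) < 1e-4 * max(np.linalg.norm(x), 1.0)


def _solution_with(r_W, r_B=(0.0, 0.0, 0.0)):
    from quadjrf.jrf_statics import ReactionSolution

    scenario = _scenario([((0.0, 0.0, 0.0), (0.0, -1.0, 0.0))])
    return ReactionSolution(
        scenario=scenario,
        r_W=np.asarray(r_W, float),
        r_B=np.asarray(r_B, float),
        r_bite=np.zeros(3),
        force_residual=0.0,
        moment_residual=0.0,
        total_applied=1.0,
    )


class TestJrfUnitVector:
    def test_axis_aligned(self):
        v = jrf_unit_vector(_solution_with([0.0, 200.0, 0.0]), "W")
        assert np.allclose(v, [0.0, 1.0, 0.0], atol=1e-12)

    def test_three_four_five(self):
        v = jrf_unit_vector(_solution_with([30.0, 40.0, 0.0]), "W")
        assert np.allclose(v, [0.6, 0.8, 0.0], atol=1e-12)

    def test_near_zero_reaction_flagged(self):
        sol = solve_reactions(_scenario([((0.0, 0.0, 200.0), (0.0, -100.0, 0.0))]))
        with pytest.raises(UnstableOrientationError):
            jrf_unit_vector(sol, "W")

    def test_compression_positive_convention(self):
        # ventral pull at the joints → reaction on the cranium points dorsally,
        # i.e. positive dot with a ventral→dorsal quadrate axis
        loads = [
            ((80.0, -10.0, 5.0), (0.0, -100.0, -20.0)),
            ((-80.0, -10.0, 5.0), (0.0, -100.0, -20.0)),
        ]
        sol = solve_reactions(_scenario(loads))
        axis = np.array([0.0, 1.0, 0.0])
        assert np.dot(jrf_unit_vector(sol, "W"), axis) > 0
        assert np.dot(jrf_unit_vector(sol, "B"), axis) > 0


class TestBiteForce:
    def test_lever_example_magnitude(self):
        F = 100.0
        sol = solve_reactions(_scenario([((0.0, 0.0, 100.0), (0.0, -F, 0.0))]))
        mag, unit = bite_force(sol)
        assert mag == pytest.approx(F / 2.0, rel=1e-9)
        assert np.allclose(unit, [0.0, 1.0, 0.0], atol=1e-9)

    def test_zero_loads_zero_bite_force(self):
        sol = solve_reactions(_scenario([((1.0, 2.0, 3.0), (0.0, 0.0, 0.0))]))
        mag, unit = bite_force(sol)
        assert mag == 0.0
        assert unit is None

    def test_magnitude_invariant_under_rotation(self):
        rng = np.random.default_rng(3)
        q, r = np.linalg.qr(rng.standard_normal((3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        loads = [(rng.uniform(-80, 80, 3), rng.uniform(-30, 30, 3)) for _ in range(6)]
        plain = solve_reactions(_scenario(loads))
        rotated = BiteScenario(
            bite_side="left",
            bite_position="rostral",
            bite_point=q @ np.array([0.0, 0.0, 200.0]),
            joint_W=q @ np.array([80.0, 0.0, 0.0]),
            joint_B=q @ np.array([-80.0, 0.0, 0.0]),
            applied_loads=[(q @ p, q @ f) for p, f in loads],
        )
        rot = solve_reactions(rotated)
        assert bite_force(rot)[0] == pytest.approx(bite_force(plain)[0], rel=1e-9)


class TestCaudalVsRostral:
    def test_caudal_bite_raises_bite_share_and_lowers_working_jrf(self, small_clade):
        """Moving the bite caudally (shorter outlever) raises bite reaction and
        lowers the working-side joint reaction on extant-like geometry."""
        from quadjrf.muscle_model import MuscleSpec, build_muscle_force

        spec = small_clade.specimens[
            max(small_clade.flattening, key=small_clade.flattening.get)
        ]
        loads = []
        for _, row in spec.muscle_table.iterrows():
            ms = MuscleSpec(
                name=row["muscle"],
                side=row["side"],
                origin=spec.sites[(row["muscle"], row["side"], "origin")],
                insertion=spec.sites[(row["muscle"], row["side"], "insertion")],
                rel_fascicle_length=row["rel_fascicle_length"],
                pennation_deg=row["pennation_deg"],
                specific_tension=row["specific_tension"],
            )
            loads.extend(build_muscle_force(ms).node_loads)
        sols = {}
        for pos in ("rostral", "caudal"):
            scenario = BiteScenario(
                bite_side="left",
                bite_position=pos,
                bite_point=spec.landmarks[f"bite_{pos}_left"],
                joint_W=spec.landmarks["joint_left"],
                joint_B=spec.landmarks["joint_right"],
                applied_loads=loads,
            )
            sols[pos] = solve_reactions(scenario)
        assert bite_force(sols["caudal"])[0] > bite_force(sols["rostral"])[0]
        assert np.linalg.norm(sols["caudal"].r_W) < np.linalg.norm(sols["rostral"].r_W)
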