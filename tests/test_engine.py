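"""Tree solver, diffusion stepping, reaction stepping, operator splitting."""

import math

import numpy as np
import pytest

import dendrochem as dc
from dendrochem.scenarios import random_tree_morphology


def tree_system(seed, n_sections=None, dt=None):
    """A random diffusion tree matrix plus the model that produced it."""
    rng = np.random.default_rng(seed)
    if n_sections is None:
        n_sections = int(rng.integers(1, 20))
    morph = random_tree_morphology(seed, n_sections=n_sections)
    region = dc.Region(morph.sections, name="all")
    s = dc.Species(region, d=float(rng.uniform(0.1, 3.0)), name="s",
                   initial=1.0)
    model = dc.Model(species=[s])
    model.initialize()
    if dt is None:
        dt = float(rng.uniform(0.01, 1.0))
    return dc.assemble_diffusion(model, s, region, dt=dt), model, s, region


class TestTreeMatrix:
    def test_two_segment_coupling(self):
        """g = D·A/Δx between adjacent interior segment centers."""
        morph = dc.Morphology()
        sec = morph.create_section("c", L=1.0, diam=2.0, nseg=2)
        region = dc.Region([sec], name="r")
        s = dc.Species(region, d=1.0, name="s", initial=0.0)
        model = dc.Model(species=[s])
        model.initialize()
        dt = 0.125
        tm = dc.assemble_diffusion(model, s, region, dt=dt)
        dense = tm.to_dense()
        # map global state indices to the local tree-ordered rows
        local = {g: k for k, g in enumerate(tm.indices)}
        i0, i1 = (local[n.index] for n in s.nodes)
        # entries are -dt*g in the volume rows; A = pi, dx = 0.5 -> g = 2*pi
        assert dense[i0, i1] == pytest.approx(-dt * 2 * math.pi, rel=1e-12)
        assert dense[i1, i0] == pytest.approx(-dt * 2 * math.pi, rel=1e-12)

    def test_zero_diffusion_gives_diagonal_matrix(self):
        morph = dc.Morphology()
        sec = morph.create_section("c", L=1.0, diam=1.0, nseg=4)
        region = dc.Region([sec], name="r")
        s = dc.Species(region, d=0.0, name="s", initial=0.0)
        model = dc.Model(species=[s])
        model.initialize()
        dense = dc.assemble_diffusion(model, s, region, dt=0.1).to_dense()
        assert np.count_nonzero(dense - np.diag(np.diag(dense))) == 0

    def test_junction_rows_sum_to_zero(self, y_morphology):
        region = dc.Region(y_morphology.sections, name="all")
        s = dc.Species(region, d=1.0, name="s", initial=0.0)
        model = dc.Model(species=[s])
        model.initialize()
        tm = dc.assemble_diffusion(model, s, region, dt=0.2)
        dense = tm.to_dense()
        jrows = np.nonzero(tm.is_junction)[0]
        assert len(jrows) == 4  # 2 free ends per branch point topology
        assert np.max(np.abs(dense[jrows].sum(axis=1))) < 1e-12
        # the shared branch junction couples to all three sections
        degrees = sorted(np.count_nonzero(dense[j]) - 1 for j in jrows)
        assert degrees == [1, 1, 1, 3]

    def test_matrix_is_asymmetric_with_unequal_volumes(self, y_morphology):
        region = dc.Region(y_morphology.sections, name="all")
        s = dc.Species(region, d=1.0, name="s", initial=0.0)
        model = dc.Model(species=[s])
        model.initialize()
        dense = dc.assemble_diffusion(model, s, region, dt=0.2).to_dense()
        assert np.max(np.abs(dense - dense.T)) > 1e-12


class TestTreeSolve:
    def test_identity(self):
        tm = dc.TreeMatrix(parent=[-1, 0, 0], diag=[1.0, 1.0, 1.0],
                           lower=[0.0, 0.0, 0.0], upper=[0.0, 0.0, 0.0])
        rhs = np.array([3.0, -1.0, 2.5])
        assert np.array_equal(dc.tree_solve(tm, rhs), rhs)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_dense_oracle(self, seed):
        tm, *_ = tree_system(seed)
        rng = np.random.default_rng(10_000 + seed)
        b = rng.normal(size=tm.n)
        x = dc.tree_solve(tm, b)
        x_dense = np.linalg.solve(tm.to_dense(), b)
        assert np.max(np.abs(x - x_dense)) < 1e-10

    def test_operation_count_linear_in_n(self):
        """Elimination work on a chain grows linearly: 10x nodes, ~10x ops."""
        counts = {}
        for nseg in (100, 1000):
            morph = dc.Morphology()
            sec = morph.create_section("c", L=float(nseg), diam=1.0, nseg=nseg)
            region = dc.Region([sec], name="r")
            s = dc.Species(region, d=1.0, name="s", initial=0.0)
            model = dc.Model(species=[s])
            model.initialize()
            tm = dc.assemble_diffusion(model, s, region, dt=0.1)
            dc.tree_solve(tm, np.ones(tm.n))
            counts[nseg] = tm.last_op_count
        ratio = counts[1000] / counts[100]
        assert 9.0 <= ratio <= 11.0

    def test_singularity_names_the_node(self):
        tm = dc.TreeMatrix(parent=[-1, 0], diag=[1.0, 0.0],
                           lower=[0.0, 1.0], upper=[0.0, 1.0])
        with pytest.raises(dc.SingularMatrixError, match="node 1"):
            dc.tree_solve(tm, np.ones(2))


class TestDiffusionStep:
    def test_uniform_concentration_is_fixed_point(self):
        _, model, s, _ = tree_system(5, n_sections=10, dt=0.3)
        before = model.gather()
        for _ in range(10):
            model.diffusion_step(0.3)
        assert np.max(np.abs(model.gather() - before)) < 1e-14

    def test_mass_conserved_1000_steps(self, rng):
        morph = random_tree_morphology(11, n_sections=12)
        region = dc.Region(morph.sections, name="all")
        s = dc.Species(region, d=0.8, name="s",
                       initial=lambda n: float(rng.uniform(0.0, 2.0)))
        model = dc.Model(species=[s])
        model.initialize()
        vols = np.array([n.volume for n in s.nodes])
        idx = np.array([n.index for n in s.nodes])
        mass0 = vols @ model.state[idx]
        for _ in range(1000):
            model.diffusion_step(0.05)
        mass1 = vols @ model.state[idx]
        assert abs(mass1 - mass0) <= 1e-10 * abs(mass0)

    def test_two_box_implicit_euler_closed_form(self):
        """Equal boxes approach the mean at the rate 1/(1 + 2 g dt / V)."""
        morph = dc.Morphology()
        sec = morph.create_section("c", L=2.0, diam=2.0, nseg=2)
        region = dc.Region([sec], name="r")
        s = dc.Species(region, d=1.0, name="s",
                       initial=lambda n: 1.0 if n.x < 0.5 else 0.0)
        model = dc.Model(species=[s])
        model.initialize()
        idx = [n.index for n in s.nodes]
        V = s.nodes[0].volume
        g = 1.0 * math.pi / 1.0  # D*A/dx
        factor = 1.0 / (1.0 + 2 * g * 0.3 / V)
        diff = 1.0
        for _ in range(5):
            model.diffusion_step(0.3)
            diff *= factor
            got = model.state[idx[0]] - model.state[idx[1]]
            assert got == pytest.approx(diff, rel=1e-12)

    def test_non_negativity_preserved(self, rng):
        """Implicit Euler on the diffusion M-matrix keeps states >= 0."""
        morph = random_tree_morphology(3, n_sections=8)
        region = dc.Region(morph.sections, name="all")
        s = dc.Species(region, d=2.0, name="s",
                       initial=lambda n: float(rng.uniform(0.0, 1.0)))
        model = dc.Model(species=[s])
        model.initialize()
        for _ in range(50):
            model.diffusion_step(5.0)
            assert np.min(model.state) >= -1e-15


class TestReactionStep:
    @pytest.fixture
    def point_region(self):
        morph = dc.Morphology()
        sec = morph.create_section("s", 1.0, 1.0, 1)
        return dc.Region([sec], name="r")

    def test_linear_decay_exact(self, point_region):
        s = dc.Species(point_region, name="s", initial=1.0)
        model = dc.Model(species=[s], reactions=[dc.Rate(s, -3.0 * s)])
        model.initialize()
        model.reaction_step(0.4)
        assert s.nodes[0].concentration == pytest.approx(
            1.0 / (1.0 + 3.0 * 0.4), rel=1e-15
        )

    def test_stiff_decay_stable_and_positive(self, point_region):
        s = dc.Species(point_region, name="s", initial=1.0)
        model = dc.Model(species=[s], reactions=[dc.Rate(s, -1e6 * s)])
        model.initialize()
        model.reaction_step(1.0)  # k*dt = 1e6
        c = s.nodes[0].concentration
        assert 0.0 < c < 1e-5

    def test_first_order_error_decay(self, point_region):
        """One linearized implicit step on 2H+O<->W converges at first order
        against a fine-step reference."""
        def one_macro_step(n_sub):
            H = dc.Species(point_region, name="H", initial=0.6)
            O = dc.Species(point_region, name="O", initial=0.4)
            W = dc.Species(point_region, name="W", initial=0.05)
            rxn = dc.Reaction(2 * H + O, W, 4.0, 1.0)
            model = dc.Model(species=[H, O, W], reactions=[rxn])
            model.initialize()
            for _ in range(n_sub):
                model.reaction_step(0.2 / n_sub)
            return np.array([a.nodes[0].concentration for a in (H, O, W)])

        reference = one_macro_step(4096)
        errors = [
            np.max(np.abs(one_macro_step(n) - reference)) for n in (1, 2, 4, 8)
        ]
        orders = np.log2(np.array(errors[:-1]) / np.array(errors[1:]))
        assert np.all(orders > 0.8) and np.all(orders < 1.3)


class TestAdvance:
    def test_without_reactions_equals_diffusion_step(self):
        _, model_a, s, region = tree_system(9, n_sections=6, dt=0.2)
        _, model_b, s2, _ = tree_system(9, n_sections=6, dt=0.2)
        model_a.advance(0.2)
        model_b.diffusion_step(0.2)
        assert np.array_equal(model_a.gather(), model_b.gather())

    def test_without_diffusion_equals_reaction_step(self):
        morph = dc.Morphology()
        sec = morph.create_section("s", 1.0, 1.0, 3)
        region = dc.Region([sec], name="r")

        def build():
            s = dc.Species(region, d=0.0, name="s", initial=1.0)
            model = dc.Model(species=[s], reactions=[dc.Rate(s, -2.0 * s)])
            model.initialize()
            return model

        a, b = build(), build()
        a.advance(0.1)
        b.reaction_step(0.1)
        assert np.array_equal(a.gather(), b.gather())

    def test_time_advances(self):
        _, model, *_ = tree_system(2, n_sections=3, dt=0.5)
        model.advance(0.5)
        model.advance(0.25)
        assert model.t == pytest.approx(0.75)


class TestMethodOfLinesContract:
    def test_gamma_zero_returns_rhs(self):
        _, model, *_ = tree_system(4, n_sections=5)
        b = np.random.default_rng(0).normal(size=len(model.state))
        assert np.array_equal(model.approx_jacobian_solve(0.0, b), b)

    def test_pure_diffusion_solve_is_exact(self):
        """With a single split component the approximate solve is exact on
        the volume rows of (I - γJ)."""
        _, model, s, region = tree_system(6, n_sections=7)
        gamma = 0.37
        rng = np.random.default_rng(1)
        b = rng.normal(size=len(model.state))
        x = model.approx_jacobian_solve(gamma, b)
        import scipy.sparse as sp

        n = len(model.state)
        residual = (sp.identity(n) - gamma * model.full_jacobian()) @ x - b
        vol = np.ones(n, bool)
        for block in model._blocks:
            vol[block.global_idx[block.is_junction]] = False
        assert np.max(np.abs(residual[vol])) < 1e-10

    def test_adaptive_matches_fine_fixed_step(self):
        """Cross-method agreement on a small bistable cable."""
        common = dict(alpha=0.25, L=100.0, dx=4.0, seed_width=30.0, T=50.0,
                      snapshot_times=[0.0, 50.0])
        adaptive = dc.run_bistable(dc.BistableScenario(**common))
        fixed = dc.run_bistable(dc.BistableScenario(dt=0.001, **common))
        gap = np.max(np.abs(adaptive.concentrations[-1]
                            - fixed.concentrations[-1]))
        assert gap < 1e-3

    def test_rhs_full_matches_split_steps_at_small_dt(self):
        """advance(dt) ≈ c + dt·rhs_full(c) to O(dt²) per step."""
        _, model, s, region = tree_system(8, n_sections=4)
        c0 = model.gather()
        rhs = model.rhs_full(c0)
        dt = 1e-5
        model.advance(dt)
        seg = np.ones(len(c0), bool)
        for block in model._blocks:
            seg[block.global_idx[block.is_junction]] = False
        one_step = model.gather()
        assert np.max(np.abs(one_step - (c0 + dt * rhs))[seg]) < 1e-8


class TestCheckpoint:
    def test_state_roundtrip(self, tmp_path):
        _, model, *_ = tree_system(12, n_sections=4)
        rng = np.random.default_rng(2)
        model.scatter(rng.uniform(0.0, 1.0, size=len(model.state)))
        path = str(tmp_path / "state.csv")
        model.save_state(path)
        saved = model.gather()
        model.scatter(np.zeros(len(saved)))
        model.load_state(path)
        assert np.array_equal(model.gather(), saved)
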