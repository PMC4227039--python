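import numpy as np
import pytest
from scipy import stats

from mutsphere import mutmap, nullsim, synthetic
from mutsphere.nullsim import analyze, build_matrix, default_grid, p_value, simulate_null
from mutsphere.spherescan import best_spheres


def fixture_tally(spec):
    model, _ = synthetic.make_structure(spec)
    records = synthetic.make_mutations(spec, model)
    mapping = mutmap.reconcile(model.sequence, model, mode="structure_numbering")
    return model, mutmap.tally(mutmap.filter_mutations(records), mapping, model)


@pytest.fixture(scope="module")
def small_case():
    spec = synthetic.FixtureSpec(
        geometry="random_coil", N=25, background=20, seed=42
    )
    return fixture_tally(spec)


class TestSimulateNull:
    def test_totals_conserved(self, small_case):
        model, tally = small_case
        sims = simulate_null(model, tally, seed=1, T=50)
        assert sims.shape == (50, model.N)
        assert (sims.sum(axis=1) == tally.total).all()
        assert (sims >= 0).all()

    def test_single_residue_structure(self):
        spec = synthetic.FixtureSpec(geometry="linear", N=1, seed=0)
        model, _ = synthetic.make_structure(spec)
        tally = mutmap.MutationTally(
            counts={1: 4}, structure_counts=np.array([4])
        )
        sims = simulate_null(model, tally, seed=3, T=10)
        assert (sims == 4).all()

    def test_deterministic_given_seed(self, small_case):
        model, tally = small_case
        a = simulate_null(model, tally, seed=9, T=20)
        b = simulate_null(model, tally, seed=9, T=20)
        c = simulate_null(model, tally, seed=10, T=20)
        np.testing.assert_array_equal(a, b)
        assert (a != c).any()

    def test_uniform_law(self):
        # 2000 simulations of 100 mutations over 20 residues: mean count 5
        spec = synthetic.FixtureSpec(geometry="linear", N=20, background=100, seed=5)
        model, tally = fixture_tally(spec)
        sims = simulate_null(model, tally, seed=11, T=2000)
        observed = sims.sum(axis=0)
        chi2 = stats.chisquare(observed)
        assert chi2.pvalue > 0.001
        assert np.allclose(sims.mean(axis=0), 5.0, atol=0.5)

    def test_weights_hook_validates(self, small_case):
        model, tally = small_case
        with pytest.raises(ValueError):
            simulate_null(model, tally, seed=0, T=5, weights=np.ones(3))


class TestBuildMatrix:
    def test_observed_row_matches_best_spheres(self, small_case):
        model, tally = small_case
        grid = default_grid(radii=(2.0, 5.0))
        m = build_matrix(model, tally, grid=grid, T=50, seed=2)
        for j, (s, r) in enumerate(m.grid):
            assert m.X[0, j] == best_spheres(model, tally, s, r).covered

    def test_constant_column_excluded(self):
        # single residue: every sphere covers everything, sigma == 0
        spec = synthetic.FixtureSpec(geometry="linear", N=1, seed=0)
        model, _ = synthetic.make_structure(spec)
        tally = mutmap.MutationTally(counts={1: 5}, structure_counts=np.array([5]))
        m = build_matrix(model, tally, grid=[(1, 3.0)], T=30, seed=4)
        assert not m.included.any()
        res = p_value(m)
        assert res.degenerate and res.p_value == 1.0

    def test_single_cell_grid(self, small_case):
        model, tally = small_case
        m = build_matrix(model, tally, grid=[(2, 4.0)], T=80, seed=6)
        if m.included[0]:
            expected = (m.X[:, 0] - m.mu[0]) / m.sigma[0]
            np.testing.assert_allclose(m.Z, expected)

    def test_infeasible_cells_excluded_everywhere(self):
        spec = synthetic.FixtureSpec(geometry="linear", N=3, background=6, seed=8)
        model, tally = fixture_tally(spec)
        # N=3 linear chain spans 7.6 Å: three spheres of r=4 cannot be
        # pairwise 8 Å apart
        m = build_matrix(model, tally, grid=[(1, 4.0), (3, 4.0)], T=40, seed=1)
        assert not m.included[1]

    def test_blank_tally_rejected(self):
        spec = synthetic.FixtureSpec(geometry="linear", N=10, seed=0)
        model, _ = synthetic.make_structure(spec)
        t = mutmap.MutationTally(counts={2: 1}, structure_counts=np.eye(10, dtype=int)[1])
        with pytest.raises(ValueError):
            build_matrix(model, t, T=10, seed=0)


class TestPValue:
    def test_floor_report(self, small_case):
        model, tally = small_case
        m = build_matrix(model, tally, grid=default_grid(radii=(3.0,)), T=40, seed=3)
        m.Z[0] = m.Z[1:].max() + 10.0  # force the observed statistic on top
        res = p_value(m)
        assert res.p_floor and res.p_value == 0.0
        assert res.p_text == "<2.50E-02"  # 1/T at T=40

    def test_floor_text_at_t1000(self):
        assert f"<{1.0 / 1000:.2E}" == "<1.00E-03"

    def test_observed_at_bottom_gives_p_one(self, small_case):
        model, tally = small_case
        m = build_matrix(model, tally, grid=default_grid(radii=(3.0,)), T=40, seed=3)
        m.Z[0] = m.Z[1:].min() - 10.0
        res = p_value(m)
        assert res.p_value == 1.0 and not res.p_floor

    def test_ties_count_against_significance(self, small_case):
        model, tally = small_case
        m = build_matrix(model, tally, grid=default_grid(radii=(3.0,)), T=40, seed=3)
        m.Z[:] = 1.0
        assert p_value(m).p_value == 1.0

    def test_invariant_under_simulation_relabeling(self, small_case):
        model, tally = small_case
        m = build_matrix(model, tally, grid=default_grid(radii=(2.0, 5.0)), T=60, seed=13)
        p_before = p_value(m).p_value
        rng = np.random.default_rng(0)
        perm = rng.permutation(m.T) + 1
        m.Z[1:] = m.Z[perm]
        m.X[1:] = m.X[perm]
        assert p_value(m).p_value == p_before

    def test_best_cell_prefers_smaller_s_then_r(self, small_case):
        model, tally = small_case
        m = build_matrix(
            model, tally, grid=default_grid(radii=(3.0, 6.0)), T=60, seed=21
        )
        res = p_value(m)
        inc = np.flatnonzero(m.included)
        std0 = (m.X[0, inc] - m.mu[inc]) / m.sigma[inc]
        winners = [m.grid[j] for j, v in zip(inc, std0) if v == std0.max()]
        assert res.best_cell == min(winners)

    def test_hotspot_covered_consistency(self, small_case):
        model, tally = small_case
        res = analyze(model, tally, grid=default_grid(radii=(2.0, 5.0)), T=60, seed=5)
        j = res.per_cell[res.best_cell]
        assert res.hotspots.covered == j.covered


class TestDeterminism:
    def test_identical_inputs_identical_result(self, small_case):
        model, tally = small_case
        grid = default_grid(radii=(2.0, 4.0, 6.0))
        a = analyze(model, tally, grid=grid, T=100, seed=77)
        b = analyze(model, tally, grid=grid, T=100, seed=77)
        assert a.to_dict(model) == b.to_dict(model)
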