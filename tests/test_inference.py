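"""Monte-Carlo direct search: sampling, objective, compass polling,
ensembles and consensus distillation."""

import numpy as np
import pytest

from glvnet import (
    NoAdmissibleNetworkError,
    SearchConfig,
    SolutionEnsemble,
    consensus_network,
    direct_search,
    equilibrium_residual,
    infer_ensemble,
    objective,
    sample_initial_matrix,
    CommunityModel,
    assess_stability,
)
from glvnet.inference import Solution


def small_config(**kw):
    base = dict(n_restarts=8, max_iters=4000, seed=3)
    base.update(kw)
    return SearchConfig(**base)


class TestSearchConfig:
    @pytest.mark.parametrize(
        "field, value",
        [
            ("n_restarts", 0),
            ("step_contract", 1.0),
            ("step_tol", 0.5),  # >= step_init
            ("sparsity_weight", -1e-3),
            ("subsample_fraction", 0.0),
        ],
    )
    def test_invalid_values_rejected(self, field, value):
        with pytest.raises(ValueError):
            SearchConfig(**{field: value})


class TestSampleInitialMatrix:
    def test_seeded_determinism(self):
        a = sample_initial_matrix(np.random.default_rng(5), 4, 0.5)
        b = sample_initial_matrix(np.random.default_rng(5), 4, 0.5)
        np.testing.assert_array_equal(a, b)

    def test_diagonal_nonpositive_and_offdiag_symmetric(self):
        rng = np.random.default_rng(0)
        draws = np.stack(
            [sample_initial_matrix(rng, 3, 0.5) for _ in range(1000)]
        )
        diag = draws[:, np.arange(3), np.arange(3)]
        assert np.all(diag <= 0)
        off = draws[:, ~np.eye(3, dtype=bool)]
        # uniform on [-s, s]: mean 0 within 3 standard errors
        se = 0.5 / np.sqrt(3) / np.sqrt(off.size)
        assert abs(off.mean()) < 3 * se


class TestObjective:
    def test_stable_unpenalised_matrix_scores_zero(self):
        cfg = small_config(sparsity_weight=0.0, stability_margin=0.0)
        assert objective([[-1.0]], [1.0], cfg) == 0.0

    def test_unstable_matrix_pays_squared_hinge(self):
        cfg = small_config(sparsity_weight=0.0, stability_margin=0.0)
        assert objective([[1.0]], [1.0], cfg) == pytest.approx(1.0)

    def test_sparsity_term_decomposes(self):
        cfg = small_config(sparsity_weight=0.1, stability_margin=0.0)
        A = [[-1.0, 0.3], [-0.2, -1.0]]  # stable, off-diag l1 = 0.5
        assert objective(A, [0.5, 0.5], cfg) == pytest.approx(0.1 * 0.5)

    def test_rejects_boundary_equilibrium(self):
        with pytest.raises(ValueError, match="interior"):
            objective([[-1.0]], [0.0], small_config())


class TestDirectSearch:
    def test_quadratic_one_dim(self):
        cfg = small_config(step_tol=1e-4)
        f = lambda A: (A[0, 0] - 3.0) ** 2
        A_star, f_star = direct_search(f, np.zeros((1, 1)), cfg)
        assert abs(A_star[0, 0] - 3.0) < 1e-3

    def test_rosenbrock_improves_monotonically(self):
        def rosen(A):
            x, y = A[0, 0], A[0, 1]
            return (1 - x) ** 2 + 100 * (y - x * x) ** 2

        A0 = np.array([[-1.0, 1.0]])
        cfg = small_config(max_iters=20000, step_tol=1e-5)
        A_star, f_star, trace = direct_search(rosen, A0, cfg,
                                              return_trace=True)
        assert f_star < rosen(A0)
        assert all(b <= a + 1e-15 for a, b in zip(trace, trace[1:]))

    def test_constant_objective_returns_start(self):
        cfg = small_config()
        A0 = np.array([[0.5, -0.2], [0.1, -0.8]])
        A_star, f_star = direct_search(lambda A: 7.0, A0, cfg)
        np.testing.assert_array_equal(A_star, A0)
        assert f_star == 7.0

    def test_non_finite_polls_are_skipped(self):
        def f(A):
            if A[0, 0] > 0.5:
                return np.inf
            return (A[0, 0] - 3.0) ** 2

        cfg = small_config(step_tol=1e-4)
        A_star, _ = direct_search(f, np.zeros((1, 1)), cfg)
        assert A_star[0, 0] <= 0.5  # pinned at the barrier


class TestInferEnsemble:
    def test_one_dim_accepted_solutions_self_limit(self):
        ens = infer_ensemble([1.0], small_config())
        assert len(ens.accepted) >= 1
        for sol in ens.accepted:
            assert sol.A[0, 0] < 0

    def test_accepted_solutions_satisfy_both_constraints(self):
        y_bar = np.array([0.3, 0.5, 0.2])
        ens = infer_ensemble(y_bar, small_config())
        for sol in ens.accepted:
            model = CommunityModel(ens.taxa, sol.r, sol.A)
            assert np.max(np.abs(equilibrium_residual(model, y_bar))) < 1e-8
            report = assess_stability(model, y_bar,
                                      ens.config.stability_margin)
            assert report.stable

    def test_seeded_byte_identical_ensembles(self):
        y_bar = [0.4, 0.6]
        e1 = infer_ensemble(y_bar, small_config())
        e2 = infer_ensemble(y_bar, small_config())
        assert e1.to_json() == e2.to_json()

    def test_multiple_distinct_solutions_exist(self):
        # the inverse problem is underdetermined: restarts reach
        # genuinely different admissible matrices
        cfg = small_config(n_restarts=10)
        ens = infer_ensemble([0.3, 0.3, 0.4], cfg)
        accepted = ens.accepted
        assert len(accepted) >= 2
        diffs = [
            np.max(np.abs(a.A - b.A))
            for i, a in enumerate(accepted)
            for b in accepted[i + 1:]
        ]
        assert max(diffs) > 10 * cfg.step_tol

    def test_no_admissible_solution_error_carries_best(self):
        # diagonal forced positive via init and constraint off, margin
        # impossible to satisfy within the eval budget
        cfg = SearchConfig(
            n_restarts=2, max_iters=3, step_init=1e-4, step_tol=5e-5,
            diag_constraint=False, stability_margin=10.0, seed=0,
        )
        with pytest.raises(NoAdmissibleNetworkError) as exc:
            infer_ensemble([1.0], cfg)
        assert np.isfinite(exc.value.best_objective)

    def test_json_round_trip(self):
        ens = infer_ensemble([0.4, 0.6], small_config(n_restarts=3))
        back = SolutionEnsemble.from_json(ens.to_json())
        assert back.to_json() == ens.to_json()


def make_ensemble(matrices, taxa=("t1", "t2"), y_bar=(0.5, 0.5)):
    sols = tuple(
        Solution(
            A=np.asarray(m, dtype=float),
            r=-np.asarray(m) @ np.asarray(y_bar),
            objective=0.0,
            spectral_abscissa=-0.1,
            accepted=True,
            restart_index=i,
        )
        for i, m in enumerate(matrices)
    )
    return SolutionEnsemble(
        solutions=sols,
        y_bar=np.asarray(y_bar, dtype=float),
        taxa=taxa,
        config=SearchConfig(n_restarts=len(sols)),
    )


class TestConsensusNetwork:
    def test_unanimous_edge_orientation(self):
        # a_21 = +0.5: taxon 1 facilitates taxon 2 -> edge t1 -> t2
        m = [[-1.0, 0.0], [0.5, -1.0]]
        net = consensus_network(make_ensemble([m, m, m]))
        assert len(net.edges) == 1
        e = net.edges[0]
        assert (e.source, e.target, e.sign) == ("t1", "t2", 1)
        assert e.weight == pytest.approx(0.5)
        assert e.support == 1.0

    def test_split_signs_fail_support(self):
        m_pos = [[-1.0, 0.0], [0.5, -1.0]]
        m_neg = [[-1.0, 0.0], [-0.5, -1.0]]
        net = consensus_network(
            make_ensemble([m_pos, m_neg] * 5), sign_support=0.9
        )
        assert net.edges == ()

    def test_weak_median_excluded_by_strength_floor(self):
        m = [[-1.0, 0.0], [0.02, -1.0]]
        net = consensus_network(make_ensemble([m] * 4), strength_floor=0.05)
        assert net.edges == ()

    def test_diagonal_reported_as_self_limitation(self):
        m = [[-1.0, 0.0], [0.5, -0.7]]
        net = consensus_network(make_ensemble([m] * 3))
        assert net.self_limitation == {"t1": -1.0, "t2": -0.7}

    def test_requires_accepted_solutions(self):
        ens = make_ensemble([[[-1.0, 0.0], [0.5, -1.0]]])
        object.__setattr__(
            ens, "solutions",
            tuple(
                Solution(s.A, s.r, s.objective, s.spectral_abscissa,
                         False, s.restart_index)
                for s in ens.solutions
            ),
        )
        with pytest.raises(ValueError, match="no accepted"):
            consensus_network(ens)
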