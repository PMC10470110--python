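import numpy as np
import pytest
from oracles import dense_mme, dense_sigma_inverse, random_pedigree

from pentagen import (
    ParameterError,
    PedigreeError,
    PedigreeFrame,
    agg_inverse_times,
    build_a_inverse,
    build_ssmodel,
    inbreeding_coefficients,
    mme_operator_times,
    pcg_solve,
    sigma_inverse_times,
    solve_ssSNPBLUP,
    tabular_relationship_matrix,
)


class TestPedigreeFrame:
    def test_cycle_detection(self):
        # 0 -> 1 -> 0 through parentage is impossible to order
        with pytest.raises(PedigreeError):
            PedigreeFrame(sire=[1, 0], dam=[-1, -1], genotyped=[False, False])

    def test_out_of_order_pedigree_is_reordered_with_warning(self, caplog):
        # offspring (index 0) listed before its sire (index 1)
        with caplog.at_level("WARNING", logger="pentagen"):
            ped = PedigreeFrame(sire=[1, -1], dam=[-1, -1], genotyped=[False, False])
        assert ped.order.tolist() == [1, 0]
        assert "topological order" in caplog.text

    def test_from_table_resolves_string_ids(self):
        ped = PedigreeFrame.from_table(
            ["a", "b", "c"], ["0", "0", "a"], ["0", "0", "b"], genotyped=[0, 0, 1]
        )
        assert ped.sire.tolist() == [-1, -1, 0]
        assert ped.dam.tolist() == [-1, -1, 1]


class TestInbreeding:
    def test_founders_have_zero_inbreeding(self):
        ped = PedigreeFrame(sire=[-1] * 3, dam=[-1] * 3, genotyped=[False] * 3)
        assert np.array_equal(inbreeding_coefficients(ped), np.zeros(3))

    def test_full_sib_mating_offspring(self):
        #   0 x 1 -> 2, 3 ; 2 x 3 -> 4
        ped = PedigreeFrame(
            sire=[-1, -1, 0, 0, 2], dam=[-1, -1, 1, 1, 3], genotyped=[False] * 5
        )
        assert inbreeding_coefficients(ped)[4] == pytest.approx(0.25)

    def test_parent_offspring_mating(self):
        ped = PedigreeFrame(sire=[-1, -1, 0, 0], dam=[-1, -1, 1, 2], genotyped=[False] * 4)
        assert inbreeding_coefficients(ped)[3] == pytest.approx(0.25)


class TestAInverse:
    def test_single_founder(self):
        ped = PedigreeFrame(sire=[-1], dam=[-1], genotyped=[True])
        assert build_a_inverse(ped).full().toarray() == pytest.approx(np.array([[1.0]]))

    def test_unrelated_parents_with_offspring(self):
        ped = PedigreeFrame(sire=[-1, -1, 0], dam=[-1, -1, 1], genotyped=[False] * 3)
        expected = np.array([[1.5, 0.5, -1.0], [0.5, 1.5, -1.0], [-1.0, -1.0, 2.0]])
        assert build_a_inverse(ped).full().toarray() == pytest.approx(expected)

    @pytest.mark.parametrize("n,seed", [(50, 0), (200, 1), (500, 2)])
    def test_henderson_inverse_times_tabular_a_is_identity(self, n, seed):
        ped = random_pedigree(n, np.random.default_rng(seed))
        A = tabular_relationship_matrix(ped)
        prod = build_a_inverse(ped, use_inbreeding=True).full() @ A
        assert np.abs(prod - np.eye(n)).max() <= 1e-8

    def test_non_inbred_alphas_invert_a_of_inbreeding_free_pedigree(self):
        # one generation from unrelated founders: no inbreeding anywhere
        ped = PedigreeFrame(
            sire=[-1, -1, -1, -1, 0, 0, 2], dam=[-1, -1, -1, -1, 1, 3, 3],
            genotyped=[False] * 7,
        )
        A = tabular_relationship_matrix(ped)
        prod = build_a_inverse(ped, use_inbreeding=False).full() @ A
        assert np.abs(prod - np.eye(7)).max() <= 1e-12


class TestPartitionedAggInverse:
    def test_matches_dense_inverse_of_genotyped_submatrix(self):
        rng = np.random.default_rng(3)
        ped = random_pedigree(120, rng)
        ainv = build_a_inverse(ped)
        A = tabular_relationship_matrix(ped)
        Agg = A[np.ix_(ainv.geno_idx, ainv.geno_idx)]
        v = rng.standard_normal(ainv.n_gen)
        assert np.abs(agg_inverse_times(ainv, v) - np.linalg.solve(Agg, v)).max() <= 1e-8

    def test_fully_genotyped_pedigree_reduces_to_agg_block(self):
        ped = PedigreeFrame(sire=[-1, -1, 0], dam=[-1, -1, 1], genotyped=[True] * 3)
        ainv = build_a_inverse(ped)
        v = np.array([1.0, -2.0, 0.5])
        assert np.allclose(agg_inverse_times(ainv, v), ainv.agg @ v)

    def test_zero_vector_maps_to_zero(self):
        ped = random_pedigree(40, np.random.default_rng(4))
        ainv = build_a_inverse(ped)
        assert not agg_inverse_times(ainv, np.zeros(ainv.n_gen)).any()


class TestMatrixFreeOperators:
    def test_sigma_inverse_matches_dense_assembly(self, desk_model):
        study, model, ainv = desk_model
        dense = dense_sigma_inverse(
            study.pedigree, study.genotypes, model.p, model.w, model.sigma2_u
        )
        rng = np.random.default_rng(5)
        v = rng.standard_normal(dense.shape[0])
        got = sigma_inverse_times(model, ainv, v)
        ref = dense @ v
        assert np.linalg.norm(got - ref) / np.linalg.norm(ref) <= 1e-8

    def test_sigma_inverse_of_zero_is_zero(self, desk_model):
        _, model, ainv = desk_model
        n = model.n_non + model.n_gen + model.n_snps
        assert not sigma_inverse_times(model, ainv, np.zeros(n)).any()

    def test_mme_operator_matches_dense_assembly(self, desk_model):
        study, model, ainv = desk_model
        C, _ = dense_mme(
            study.pedigree, study.genotypes, model.p, model.y,
            model.X, model.W_n, model.W_g, model.w, model.sigma2_u, model.sigma2_e,
        )
        rng = np.random.default_rng(6)
        theta = rng.standard_normal(model.n_unknowns)
        got = mme_operator_times(model, ainv, theta)
        ref = C @ theta
        assert np.linalg.norm(got - ref) / np.linalg.norm(ref) <= 1e-8

    def test_residual_variance_scales_only_the_precision_term(self, desk_model):
        study, model, ainv = desk_model
        import dataclasses

        theta = np.random.default_rng(7).standard_normal(model.n_unknowns)
        base = mme_operator_times(model, ainv, theta)
        doubled = mme_operator_times(
            dataclasses.replace(model, sigma2_e=2 * model.sigma2_e), ainv, theta
        )
        diff = doubled - base
        # the T'T part is unchanged, so diff is exactly the sigma_e^2 * Sigma^-1 term
        sigma_term = model.sigma2_e * sigma_inverse_times(model, ainv, theta[model.n_fixed :])
        assert np.allclose(diff[model.n_fixed :], sigma_term)
        assert np.allclose(diff[: model.n_fixed], 0.0)

    def test_invalid_w_rejected(self, desk_model):
        import dataclasses

        _, model, _ = desk_model
        with pytest.raises(ParameterError):
            dataclasses.replace(model, w=1.0)


class TestPCG:
    def test_identity_operator_converges_in_one_iteration(self):
        rhs = np.array([3.0, -1.0, 2.0])
        x, iters, hist, converged = pcg_solve(lambda v: v, rhs, np.ones(3))
        assert converged and iters == 1
        assert np.allclose(x, rhs)

    def test_two_by_two_closed_form(self):
        A = np.array([[4.0, 1.0], [1.0, 3.0]])
        x, _, hist, converged = pcg_solve(lambda v: A @ v, np.array([1.0, 2.0]), np.diag(A))
        assert converged
        assert np.allclose(x, [1.0 / 11.0, 7.0 / 11.0], atol=1e-12)
        assert hist[-1] < hist[0] or hist.size == 1

    def test_zero_rhs_returns_zero(self):
        x, iters, _, converged = pcg_solve(lambda v: v, np.zeros(4), np.ones(4))
        assert converged and iters == 0 and not x.any()


class TestSolver:
    def test_zero_records_give_zero_solution(self, desk_model):
        import dataclasses

        _, model, ainv = desk_model
        res = solve_ssSNPBLUP(dataclasses.replace(model, y=np.zeros_like(model.y)), ainv)
        assert not res.x.any() and res.converged

    def test_solution_matches_dense_direct_solve(self, desk_model):
        study, model, ainv = desk_model
        C, rhs = dense_mme(
            study.pedigree, study.genotypes, model.p, model.y,
            model.X, model.W_n, model.W_g, model.w, model.sigma2_u, model.sigma2_e,
        )
        ref = np.linalg.solve(C, rhs)
        res = solve_ssSNPBLUP(model, ainv)
        assert res.converged
        for got, exp in zip(
            (res.b, res.u_n, res.u_g, res.g),
            (ref[: model.n_fixed], *np.split(ref[model.n_fixed :],
             [model.n_non, model.n_non + model.n_gen])),
        ):
            assert np.linalg.norm(got - exp) / np.linalg.norm(exp) <= 1e-5

    def test_final_residual_below_first_and_tolerance(self, desk_model):
        _, model, ainv = desk_model
        res = solve_ssSNPBLUP(model, ainv)
        assert res.residual_history[-1] < res.residual_history[0]
        assert res.residual_history[-1] < 1e-13

    def test_tightening_tolerance_does_not_move_solution(self):
        from pentagen import SimulationConfig, simulate_study

        study = simulate_study(SimulationConfig(seed=31))  # 400 animals, 1000 SNPs
        model, ainv = build_ssmodel(
            study.pedigree, study.genotypes, study.y, study.record_animal,
            study.fixed_codes, w=study.config.w,
        )
        loose = solve_ssSNPBLUP(model, ainv, tol=1e-10)
        tight = solve_ssSNPBLUP(model, ainv, tol=1e-13)
        assert np.linalg.norm(loose.x - tight.x) / np.linalg.norm(tight.x) < 1e-5

    def test_recovery_beats_permuted_phenotype_control(self):
        from pentagen import SimulationConfig, simulate_study

        study = simulate_study(SimulationConfig(n_founders=80, n_generations=4,
                                                n_snps=300, seed=21))
        model, ainv = build_ssmodel(
            study.pedigree, study.genotypes, study.y, study.record_animal,
            study.fixed_codes, w=study.config.w,
        )
        res = solve_ssSNPBLUP(model, ainv, tol=1e-10)
        uhat = np.empty(study.pedigree.n_animals)
        uhat[ainv.nong_idx] = res.u_n
        uhat[ainv.geno_idx] = res.u_g
        corr = np.corrcoef(uhat, study.true_u)[0, 1]

        perm = np.random.default_rng(0).permutation(model.y.size)
        import dataclasses

        res0 = solve_ssSNPBLUP(dataclasses.replace(model, y=model.y[perm]), ainv, tol=1e-10)
        uhat0 = np.empty(study.pedigree.n_animals)
        uhat0[ainv.nong_idx] = res0.u_n
        uhat0[ainv.geno_idx] = res0.u_g
        corr0 = np.corrcoef(uhat0, study.true_u)[0, 1]
        assert corr > 0
        assert corr > corr0
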