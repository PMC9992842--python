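import shutil
import subprocess

import numpy as np
import pytest

from gngflux import (ContributionModel, ContributionSystem, NormalizedLabeling,
                     build_system, interconversion_contributions,
                     monte_carlo_errors, solve_contributions)
from oracles import grid_nnls_objective


def _nl(metabolite, tracer, value, se=0.0):
    return NormalizedLabeling(metabolite=metabolite, tracer=tracer, value=value, se=se)


def _full_set(cross, product_L, substrates=("lactate", "glycerol", "alanine"),
              product="glucose"):
    out = []
    for t in substrates:
        for s in substrates:
            if s != t:
                out.append(_nl(s, t, cross.get((s, t), 0.0)))
        out.append(_nl(product, t, product_L[t]))
    return out


class TestBuildSystem:
    def test_no_interconversion_gives_identity(self):
        nls = _full_set({}, {"lactate": 0.3, "glycerol": 0.1, "alanine": 0.05})
        system = build_system(nls)
        np.testing.assert_allclose(system.M, np.eye(3))
        np.testing.assert_allclose(system.L, [0.3, 0.1, 0.05])

    def test_cross_labelings_placed_in_tracer_rows(self):
        nls = _full_set({("glycerol", "lactate"): 0.5, ("lactate", "glycerol"): 0.2},
                        {"lactate": 0.4, "glycerol": 0.3, "alanine": 0.1})
        system = build_system(nls)
        np.testing.assert_allclose(
            system.M, [[1, 0.5, 0], [0.2, 1, 0], [0, 0, 1]])

    def test_unit_diagonal(self):
        nls = _full_set({("glycerol", "lactate"): 0.3},
                        {"lactate": 0.4, "glycerol": 0.3, "alanine": 0.1})
        np.testing.assert_array_equal(np.diag(build_system(nls).M), [1, 1, 1])

    def test_missing_measurement_named(self):
        nls = _full_set({}, {"lactate": 0.3, "glycerol": 0.1, "alanine": 0.05})
        nls = [n for n in nls if not (n.metabolite == "alanine" and n.tracer == "lactate")]
        with pytest.raises(ValueError, match="L_alanine<-lactate"):
            build_system(nls)


class TestSolveContributions:
    def test_identity_system(self):
        system = ContributionSystem(("a", "b", "c"), np.eye(3), np.zeros((3, 3)),
                                    "glucose", np.array([0.3, 0.1, 0.05]), np.zeros(3))
        res = solve_contributions(system)
        np.testing.assert_allclose(res.f, [0.3, 0.1, 0.05], atol=1e-12)
        assert res.residual == pytest.approx(0.0, abs=1e-12)

    def test_worked_interior_solution(self, worked_system):
        res = solve_contributions(worked_system)
        np.testing.assert_allclose(res.f, [0.277778, 0.244444, 0.1], atol=1e-6)

    def test_active_constraint_matches_grid_oracle(self):
        # unconstrained solution has a negative component here
        M = np.array([[1.0, 0.9], [0.9, 1.0]])
        L = np.array([0.1, 0.5])
        unconstrained = np.linalg.solve(M, L)
        assert unconstrained.min() < 0
        system = ContributionSystem(("a", "b"), M, np.zeros((2, 2)),
                                    "glucose", L, np.zeros(2))
        res = solve_contributions(system)
        assert np.all(res.f >= 0)
        grid_min = grid_nnls_objective(M, L, coarse_step=0.01, fine_step=1e-3)
        assert res.residual <= grid_min + 1e-6

    def test_interior_solution_equals_unconstrained(self, worked_system):
        res = solve_contributions(worked_system)
        np.testing.assert_allclose(
            res.f, np.linalg.solve(worked_system.M, worked_system.L), atol=1e-9)

    def test_nonfinite_rejected(self):
        M = np.eye(2); M[0, 1] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            solve_contributions(ContributionSystem(
                ("a", "b"), M, np.zeros((2, 2)), "p", np.zeros(2), np.zeros(2)))

    def test_singular_system_warns_but_solves(self):
        M = np.array([[1.0, 1.0], [1.0, 1.0]])
        system = ContributionSystem(("a", "b"), M, np.zeros((2, 2)),
                                    "p", np.array([0.5, 0.5]), np.zeros(2))
        with pytest.warns(RuntimeWarning, match="near-singular"):
            res = solve_contributions(system)
        assert np.all(res.f >= 0)
        assert res.residual == pytest.approx(0.0, abs=1e-9)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        nls = _full_set(
            {("glycerol", "lactate"): 0.2, ("alanine", "lactate"): 0.25,
             ("lactate", "glycerol"): 0.05, ("alanine", "glycerol"): 0.03,
             ("lactate", "alanine"): 0.3, ("glycerol", "alanine"): 0.02},
            {"lactate": 0.45, "glycerol": 0.32, "alanine": 0.15})
        order1 = ("lactate", "glycerol", "alanine")
        order2 = ("alanine", "lactate", "glycerol")
        f1 = solve_contributions(build_system(nls, substrates=order1)).params
        f2 = solve_contributions(build_system(nls, substrates=order2)).params
        for s in order1:
            assert f1[s] == pytest.approx(f2[s], abs=1e-12)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
def test_solver_matches_r_lsqnonneg(worked_system):
    """Cross-check the NNLS solve against R's pracma::lsqnonneg."""
    M, L = worked_system.M, worked_system.L
    code = (
        "suppressMessages(library(pracma));"
        f"M <- matrix(c({','.join(map(str, M.T.ravel()))}), {M.shape[0]}, {M.shape[1]});"
        f"L <- c({','.join(map(str, L))});"
        "cat(sprintf('%.15g', lsqnonneg(M, L)$x), sep=',')"
    )
    out = subprocess.run(["Rscript", "-e", code], capture_output=True, text=True,
                         check=True)
    r_f = np.array([float(v) for v in out.stdout.strip().split(",")])
    res = solve_contributions(worked_system)
    np.testing.assert_allclose(res.f, r_f, atol=1e-8)


class TestMonteCarlo:
    def test_zero_ses_give_zero_f_se(self, worked_system):
        res = monte_carlo_errors(worked_system, n_mc=100, seed=1)
        np.testing.assert_array_equal(res.f_se, [0.0, 0.0, 0.0])
        np.testing.assert_allclose(res.f_mc_mean, res.f, atol=1e-12)

    def test_default_replicate_count_is_100(self, worked_system):
        assert monte_carlo_errors(worked_system, seed=0).n_mc == 100

    def test_deterministic_given_seed(self, worked_system):
        system = ContributionSystem(
            worked_system.substrates, worked_system.M,
            np.full((3, 3), 0.02) * (1 - np.eye(3)), worked_system.product,
            worked_system.L, np.full(3, 0.02))
        r1 = monte_carlo_errors(system, n_mc=100, seed=11)
        r2 = monte_carlo_errors(system, n_mc=100, seed=11)
        np.testing.assert_array_equal(r1.f_se, r2.f_se)
        r3 = monte_carlo_errors(system, n_mc=100, seed=12)
        assert not np.array_equal(r1.f_se, r3.f_se)

    def test_f_se_scales_linearly_with_input_ses(self, worked_system):
        def with_se(scale):
            return ContributionSystem(
                worked_system.substrates, worked_system.M,
                scale * 0.01 * (1 - np.eye(3)), worked_system.product,
                worked_system.L, np.full(3, scale * 0.01))
        se1 = monte_carlo_errors(with_se(1.0), n_mc=10_000, seed=3).f_se
        se2 = monte_carlo_errors(with_se(2.0), n_mc=10_000, seed=4).f_se
        np.testing.assert_allclose(se2 / se1, 2.0, rtol=0.1)

    def test_convergence_100_vs_10000(self, worked_system):
        system = ContributionSystem(
            worked_system.substrates, worked_system.M,
            0.02 * (1 - np.eye(3)), worked_system.product,
            worked_system.L, np.full(3, 0.02))
        se_small = monte_carlo_errors(system, n_mc=100, seed=5).f_se
        se_big = monte_carlo_errors(system, n_mc=10_000, seed=6).f_se
        np.testing.assert_allclose(se_small, se_big, rtol=0.3)


class TestInterconversion:
    def _nls(self):
        return _full_set(
            {("glycerol", "lactate"): 0.1, ("alanine", "lactate"): 0.25,
             ("lactate", "glycerol"): 0.05, ("alanine", "glycerol"): 0.03,
             ("lactate", "alanine"): 0.3, ("glycerol", "alanine"): 0.02},
            {"lactate": 0.45, "glycerol": 0.32, "alanine": 0.15})

    def test_default_product_reproduces_plain_solve(self):
        nls = self._nls()
        res = interconversion_contributions(nls, product="glucose", n_mc=10, seed=0)
        plain = solve_contributions(build_system(nls))
        np.testing.assert_allclose(res.f, plain.f, atol=1e-12)

    def test_identity_system_returns_product_labelings(self):
        nls = _full_set({}, {"lactate": 0.3, "glycerol": 0.1, "alanine": 0.05},
                        product="pyruvate")
        res = interconversion_contributions(nls, product="pyruvate", n_mc=5, seed=0)
        np.testing.assert_allclose(res.f, [0.3, 0.1, 0.05], atol=1e-12)

    def test_substrate_product_reduces_system_and_matches_grid(self):
        # lactate as product: 2x2 system over glycerol/alanine
        nls = [
            _nl("alanine", "glycerol", 0.03), _nl("glycerol", "alanine", 0.02),
            _nl("lactate", "glycerol", 0.6), _nl("lactate", "alanine", 0.7),
        ]
        res = interconversion_contributions(nls, product="lactate", n_mc=5, seed=0)
        assert res.substrates == ("glycerol", "alanine")
        M = np.array([[1, 0.03], [0.02, 1]])
        L = np.array([0.6, 0.7])
        grid_min = grid_nnls_objective(M, L, coarse_step=0.01, fine_step=1e-3)
        assert res.residual <= grid_min + 1e-6

    def test_missing_product_errors(self):
        nls = _full_set({}, {"lactate": 0.3, "glycerol": 0.1, "alanine": 0.05})
        with pytest.raises(ValueError, match="pyruvate"):
            interconversion_contributions(nls, product="pyruvate", n_mc=5, seed=0)


class TestContributionModelAPI:
    def test_from_dataframe_fit_summary(self):
        import pandas as pd

        rows = [(n.metabolite, n.tracer, n.value, 0.01)
                for n in _full_set(
                    {("glycerol", "lactate"): 0.2},
                    {"lactate": 0.45, "glycerol": 0.3, "alanine": 0.1})]
        df = pd.DataFrame(rows, columns=["metabolite", "tracer", "value", "se"])
        model = ContributionModel.from_dataframe(df)
        res = model.fit(n_mc=50, seed=2)
        assert set(res.params.index) == {"lactate", "glycerol", "alanine"}
        assert np.all(res.bse.to_numpy() > 0)
        text = res.summary()
        assert "glucose" in text and "lactate" in text and "Monte Carlo" in text
        frame = res.to_frame()
        assert {"fraction", "se", "mc_mean"} <= set(frame.columns)
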