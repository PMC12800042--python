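"""Linearization, characteristic quantities, Hurwitz and Matignon criteria."""

import numpy as np
import pytest

from crcdyn import (default_parameters, jacobian, eigenvalues,
                    block_characteristic_coeffs, hurwitz_determinants,
                    matignon_classify, assess_equilibrium,
                    tumor_free_equilibrium, find_coexistence,
                    DrawSpec, draw_parameters, rhs_base)


def fd_jacobian(params, state, variant="base", step=1e-6):
    """Central finite-difference oracle for the linearization."""
    from crcdyn.model import rhs_for_variant
    rhs = rhs_for_variant(variant)
    state = np.asarray(state, dtype=float)
    J = np.empty((5, 5))
    for j in range(5):
        e = np.zeros(5)
        e[j] = step
        J[:, j] = (rhs(state + e, params) - rhs(state - e, params)) / (2 * step)
    return J


class TestJacobian:
    def test_matches_finite_differences(self, rng):
        params_list = draw_parameters(DrawSpec(seed=101, n=10))
        for p in params_list:
            for _ in range(10):
                state = rng.uniform(0.5, 50.0, size=5)
                J = jacobian(p, state, mode="correct")
                Jfd = fd_jacobian(p, state)
                scale = np.maximum(np.abs(Jfd), 1e-3)
                assert np.max(np.abs(J - Jfd) / scale) < 1e-5

    def test_extended_matches_finite_differences(self, app3_params, rng):
        for _ in range(20):
            state = rng.uniform(0.5, 50.0, size=5)
            J = jacobian(app3_params, state, mode="correct", variant="extended")
            Jfd = fd_jacobian(app3_params, state, variant="extended")
            scale = np.maximum(np.abs(Jfd), 1e-3)
            assert np.max(np.abs(J - Jfd) / scale) < 1e-5

    def test_decay_entry_at_tumor_free(self):
        p = default_parameters(u1=0.0)
        rep = tumor_free_equilibrium(p)
        J = jacobian(p, rep.as_array(), mode="correct")
        assert J[4, 4] == -1.0  # -vartheta with the default decay rate

    def test_cross_entry_vanishes_at_zero_tumor(self, app1i_params):
        J = jacobian(app1i_params, [0.0, 1.0, 1.0, 1.0, 0.2])
        assert J[0, 1] == 0.0

    def test_verbatim_disagrees_at_documented_entries(self, app1i_params):
        """The printed linearization differs from the derivative oracle at
        (1,1), (2,1), (3,1) (squared saturation constants) and (4,5)
        ((1-P) in place of b/(b+P) numerator), and only there at T=0."""
        rep = tumor_free_equilibrium(app1i_params)
        state = rep.as_array()
        Jv = jacobian(app1i_params, state, mode="paper_verbatim")
        Jfd = fd_jacobian(app1i_params, state)
        diff = np.abs(Jv - Jfd)
        disagree = {(0, 0), (1, 0), (2, 0), (3, 4)}
        for idx in disagree:
            assert diff[idx] > 1e-4, f"expected disagreement at {idx}"
        agree_mask = np.ones((5, 5), dtype=bool)
        for idx in disagree:
            agree_mask[idx] = False
        assert np.max(diff[agree_mask]) < 1e-6

    def test_verbatim_extended_unavailable(self, app3_params):
        with pytest.raises(ValueError):
            jacobian(app3_params, np.ones(5), mode="paper_verbatim",
                     variant="extended")


class TestEigenvalues:
    def test_tumor_free_spectrum_closed_form(self, app1i_params):
        p = app1i_params
        rep = tumor_free_equilibrium(p)
        eigs = np.sort(eigenvalues(jacobian(p, rep.as_array())).real)
        c_star = rep.as_array()[3]
        expected = np.sort([
            -(p.beta2 + p.d1),                      # -0.508
            -(p.beta3 + p.d2),                      # -0.4008
            -p.vartheta,                            # -1
            p.g1 - p.u3 - p.omega * c_star / p.s4,  # tumor eigenvalue
            -(p.beta4 + p.d3 - p.u2
              - p.delta * 0.2 / (p.b + 0.2)),       # CD4 eigenvalue
        ])
        assert np.allclose(eigs, expected, atol=1e-10)
        assert eigs[1] == pytest.approx(-0.508, abs=1e-10)
        assert np.any(np.abs(eigs + 0.4199) < 1e-3)  # tumor eigenvalue

    def test_diagonal_matrix(self):
        assert np.allclose(np.sort(eigenvalues(np.diag([1., 2, 3, 4, 5]))),
                           [1, 2, 3, 4, 5])


class TestBlockCoefficients:
    def test_diagonal_block(self):
        J = np.zeros((5, 5))
        J[0, 0], J[1, 1], J[2, 2], J[3, 3] = 1.0, 2.0, 3.0, 4.0
        r1, r2, r3, r4 = block_characteristic_coeffs(J)
        assert r1 == 10.0 and r4 == 24.0

    def test_matches_char_poly_on_sparsity_pattern(self, rng):
        for _ in range(100):
            J = np.zeros((5, 5))
            vals = rng.normal(size=10)
            (J[0, 0], J[0, 1], J[0, 3], J[1, 0], J[1, 1],
             J[2, 0], J[2, 2], J[3, 2], J[3, 3], J[3, 4]) = vals
            J[4, 4] = -1.0
            r1, r2, r3, r4 = block_characteristic_coeffs(J)
            c = np.poly(J[:4, :4])  # [1, c1, c2, c3, c4]
            assert np.allclose([c[1], c[2], c[3], c[4]],
                               [-r1, r2, r3, r4], atol=1e-9)

    def test_fig2_coexistence_r4_positive(self, fig2_params):
        rep = [r for r in find_coexistence(fig2_params) if r.exists][0]
        J = jacobian(fig2_params, rep.as_array())
        _, _, _, r4 = block_characteristic_coeffs(J)
        assert r4 > 0


class TestHurwitz:
    def test_all_roots_minus_one(self):
        # frozen from the oracle: R = coefficients of det(lI - diag(-1)*4)
        c = np.poly(np.diag([-1.0, -1, -1, -1]))
        R = (-c[1], c[2], c[3], c[4])
        assert R == (-4.0, 6.0, 4.0, 1.0)
        h1, h2, h3, h4 = hurwitz_determinants(R)
        assert (h1, h2, h3, h4) == (4.0, 20.0, 64.0, 64.0)
        assert all(h > 0 for h in (h1, h2, h3, h4))

    def test_zero_r1_marginal(self):
        h1, _, _, _ = hurwitz_determinants((0.0, 1.0, -1.0, 1.0))
        assert h1 == 0.0

    def test_h4_identity(self, rng):
        for _ in range(50):
            R = rng.normal(size=4)
            _, _, h3, h4 = hurwitz_determinants(R)
            if h3 != 0:
                assert h4 / h3 == pytest.approx(R[3], rel=1e-12)

    def test_agreement_with_spectrum_on_random_draws(self, rng):
        """Positivity of H1..H4 iff the 4x4 block spectrum lies in the open
        left half-plane, on 200 seeded draws away from marginality."""
        from crcdyn.stability import _block_spectrum
        checked = 0
        for p in draw_parameters(DrawSpec(seed=20260921, n=200)):
            reps = [tumor_free_equilibrium(p)]
            reps += find_coexistence(p, scan_points=2000)
            for rep in reps:
                if not rep.exists:
                    continue
                J = jacobian(p, rep.as_array())
                block_eigs = _block_spectrum(J)
                if np.min(np.abs(block_eigs.real)) < 1e-6:
                    continue
                H = hurwitz_determinants(block_characteristic_coeffs(J))
                assert (all(h > 0 for h in H)
                        == bool(np.all(block_eigs.real < 0)))
                checked += 1
        assert checked >= 200


class TestMatignon:
    def test_real_negative_always_stable(self):
        for alpha in (0.3, 0.7, 1.0):
            cls, margin = matignon_classify([-1.0, -0.5, -2.0], alpha)
            assert cls == "stable" and margin > 0

    def test_positive_real_unstable(self):
        cls, _ = matignon_classify([0.1, -1.0], 0.9)
        assert cls == "unstable"

    def test_sector_boundary_pair(self):
        lam = 2.0 * np.exp(1j * 0.8 * np.pi / 2)
        pair = [lam, np.conj(lam)]
        assert matignon_classify(pair, 0.9)[0] == "unstable"
        assert matignon_classify(pair, 0.7)[0] == "stable"

    def test_zero_eigenvalue_marginal(self):
        assert matignon_classify([0.0, -1.0], 0.9)[0] == "marginal"

    def test_reduces_to_half_plane_at_alpha_one(self):
        assert matignon_classify([-1e-3 + 5j, -1.0], 1.0)[0] == "stable"
        assert matignon_classify([1e-3 + 5j, -1.0], 1.0)[0] == "unstable"

    def test_monotone_in_alpha_when_stable_at_one(self, rng):
        for p in draw_parameters(DrawSpec(seed=55, n=50)):
            rep = tumor_free_equilibrium(p)
            if not rep.exists:
                continue
            eigs = eigenvalues(jacobian(p, rep.as_array()))
            if matignon_classify(eigs, 1.0)[0] == "stable":
                for alpha in (0.2, 0.5, 0.8, 0.95):
                    assert matignon_classify(eigs, alpha)[0] == "stable"


class TestAssess:
    def test_app1i_tumor_free_stable(self, app1i_params):
        rep = tumor_free_equilibrium(app1i_params)
        st = assess_equilibrium(app1i_params, rep, alpha=0.9)
        assert st.classification == "stable"
        assert st.theorem_conditions["lambda4_negative"]
        assert st.theorem_conditions["lambda5_negative"]
        assert st.matignon_margin > 0

    def test_fig2_coexistence_stable(self, fig2_params):
        rep = [r for r in find_coexistence(fig2_params) if r.exists][0]
        st = assess_equilibrium(fig2_params, rep, alpha=0.9)
        assert st.classification == "stable"
        assert st.hurwitz_all_positive
        assert st.theorem_conditions["hurwitz_matches_spectrum"]

    def test_uncontrolled_tumor_unstable(self):
        p = default_parameters(u1=0.2, u2=0.0, u3=0.0, omega=0.0, beta1=0.0)
        rep = tumor_free_equilibrium(p)
        st = assess_equilibrium(p, rep, alpha=0.9)
        assert st.classification == "unstable"
        assert not st.theorem_conditions["lambda4_negative"]

    def test_json_round_trip(self, app1i_params):
        import json
        rep = tumor_free_equilibrium(app1i_params)
        st = assess_equilibrium(app1i_params, rep, alpha=0.9)
        payload = json.loads(st.to_json())
        assert payload["classification"] == "stable"
        assert len(payload["jacobian"]) == 5
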