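"""Scheme construction, mass-action compilation and conservation laws."""

import numpy as np
import pytest

from tdtkinetics.mechanisms import (
    Mechanism,
    MissingRateError,
    RateParameters,
    UndefinedEquilibriumError,
    build_scheme,
    conserved_moieties,
    derive_rhs,
    equilibrium_summary,
)
from tdtkinetics.transient import simulate_concentrations

ALL_SCHEMES = ["scheme1", "scheme2", "scheme3"]


def random_params(rng, scheme: str) -> RateParameters:
    k = 10.0 ** rng.uniform(-1.5, 1.0, 6)
    return RateParameters(
        k1=k[0], k_minus1=k[1], k2=k[2], k_minus2=k[3],
        kpol=None if scheme == "scheme2" else k[4],
        kt=k[5] if scheme == "scheme3" else None,
    )


class TestBuildScheme:
    def test_scheme2_has_four_species_two_reversible_reactions(self):
        m = build_scheme("scheme2")
        assert len(m.species) == 4
        assert len(m.reactions) == 2
        assert all(r.k_rev is not None for r in m.reactions)

    def test_scheme1_has_exactly_one_irreversible_reaction_in_cycle_one(self):
        m = build_scheme("scheme1")
        irreversible = [r for r in m.reactions if r.k_rev is None]
        assert len(irreversible) == 1
        assert irreversible[0].k_fwd == "kpol"
        assert irreversible[0].products == ("ED1",)

    def test_scheme3_without_second_cycle_terminates_at_extended_complex(self):
        m = build_scheme("scheme3", second_cycle=False)
        assert "ED1" in m.species_names
        assert "ED2" not in m.species_names
        # nothing consumes ED1
        assert all("ED1" not in r.reactants for r in m.reactions)

    def test_unknown_scheme_rejected_with_valid_names(self):
        with pytest.raises(ValueError, match="scheme1.*scheme2.*scheme3"):
            build_scheme("scheme9")

    def test_independent_second_cycle_constants(self):
        m = build_scheme("scheme3", shared_second_cycle=False)
        assert "k1_2" in m.rate_names()
        p = RateParameters(
            k1=1, k_minus1=1, k2=1, k_minus2=1, kpol=1, kt=1,
            extra={"k1_2": 2, "k_minus1_2": 2, "k2_2": 2, "k_minus2_2": 2,
                   "kpol_2": 2, "kt_2": 2},
        )
        derive_rhs(m, p)  # all constants resolvable

    @pytest.mark.parametrize("scheme", ALL_SCHEMES)
    def test_config_round_trip(self, scheme):
        m = build_scheme(scheme, second_cycle_conformational=(scheme == "scheme1"))
        m2 = Mechanism.from_config(m.to_config())
        assert m2.species_names == m.species_names
        assert [(r.reactants, r.products, r.k_fwd, r.k_rev) for r in m2.reactions] == [
            (r.reactants, r.products, r.k_fwd, r.k_rev) for r in m.reactions
        ]

    def test_custom_mechanism_config_round_trip(self):
        m = build_scheme("scheme2")
        cfg = m.to_config()
        cfg_custom = Mechanism(name="mine", species=m.species, reactions=m.reactions).to_config()
        m2 = Mechanism.from_config(cfg_custom)
        assert m2.name == "mine"
        assert m2.species_names == m.species_names


class TestDeriveRhs:
    def test_null_dynamics_at_zero_rates(self):
        m = build_scheme("scheme2")
        f = derive_rhs(m, RateParameters(0, 0, 0, 0))
        c = np.array([1.0, 2.0, 0.5, 0.3])
        assert np.all(f(c) == 0)

    def test_single_bimolecular_flux(self):
        m = build_scheme("scheme2")
        f = derive_rhs(m, RateParameters(k1=1.0, k_minus1=0, k2=0, k_minus2=0))
        c = np.zeros(4)
        c[m.index("E")] = 1.0
        c[m.index("N")] = 1.0
        dc = f(c)
        assert dc[m.index("X1")] == pytest.approx(1.0)
        assert dc[m.index("E")] == pytest.approx(-1.0)
        assert dc[m.index("N")] == pytest.approx(-1.0)

    def test_missing_rate_constant_named_in_error(self):
        m = build_scheme("scheme1")
        with pytest.raises(MissingRateError, match="kpol"):
            derive_rhs(m, RateParameters(1, 1, 1, 1))  # no kpol

    def test_jacobian_matches_finite_differences(self, rng):
        m = build_scheme("scheme3")
        f = derive_rhs(m, random_params(rng, "scheme3"))
        c = rng.uniform(0.1, 2.0, len(m.species))
        J = f.jac_ivp(0.0, c)
        eps = 1e-7
        for j in range(c.size):
            dc = np.zeros_like(c)
            dc[j] = eps
            fd = (f(c + dc) - f(c - dc)) / (2 * eps)
            assert np.allclose(J[:, j], fd, atol=1e-5)


class TestConservedMoieties:
    def test_scheme2_enzyme_moiety(self):
        m = build_scheme("scheme2")
        moieties = dict(conserved_moieties(m))
        assert moieties["enzyme"] == {"E": 1, "X1": 1, "X2": 1}

    def test_scheme3_nucleotide_moiety_counts_incorporated_residues(self):
        m = build_scheme("scheme3")
        nuc = dict(conserved_moieties(m))["nucleotide"]
        assert nuc["ED1"] == 1
        assert nuc["ED2"] == 2
        assert nuc["C1b"] == 2  # one incorporated + one bound

    @pytest.mark.parametrize("scheme", ALL_SCHEMES)
    def test_moieties_annihilate_rhs_at_random_states(self, scheme, rng):
        """Conservation is analytic: inner products vanish to 1e-12."""
        m = build_scheme(scheme)
        for _ in range(100):
            p = random_params(rng, scheme)
            f = derive_rhs(m, p)
            c = rng.uniform(0.0, 5.0, len(m.species))
            dc = f(c)
            for _, weights in conserved_moieties(m):
                w = np.array([weights.get(s, 0) for s in m.species_names], float)
                assert abs(float(w @ dc)) < 1e-12 * max(1.0, np.max(np.abs(dc)))


class TestEquilibriumSummary:
    def test_unit_case(self):
        s = equilibrium_summary(RateParameters(1, 1, 1, 1))
        assert s.K1 == 1.0 and s.K2 == 1.0
        assert s.Kd_total == pytest.approx(0.5)

    def test_one_step_limit(self):
        s = equilibrium_summary(RateParameters(k1=2.0, k_minus1=1.0, k2=0.0, k_minus2=1.0))
        assert s.K2 == 0.0
        assert s.Kd_total == pytest.approx(1.0 / 2.0)

    def test_zero_reverse_rate_rejected(self):
        with pytest.raises(UndefinedEquilibriumError):
            equilibrium_summary(RateParameters(1, 0, 1, 1))

    def test_product_convention_flag(self):
        p = RateParameters(k1=2.0, k_minus1=1.0, k2=4.0, k_minus2=1.0)
        exact = equilibrium_summary(p)
        prod = equilibrium_summary(p, convention="product")
        assert exact.Kd_total == pytest.approx(1.0 / (2.0 * 5.0))
        assert prod.Kd_total == pytest.approx(1.0 / (2.0 * 4.0))

    def test_matches_steady_state_integration(self, rng):
        """Kd_total predicts the equilibrium bound fraction of scheme2."""
        m = build_scheme("scheme2")
        for _ in range(20):
            p = RateParameters(*(10.0 ** rng.uniform(-1, 1, 4)))
            kd = equilibrium_summary(p).Kd_total
            e0, n0 = 1.0, 2.0
            # analytic equilibrium: (e0-b)(n0-b) = kd*b
            coeffs = [1.0, -(e0 + n0 + kd), e0 * n0]
            b_pred = min(np.roots(coeffs).real)
            slowest = min(p.k_minus1, p.k2 if p.k2 > 0 else np.inf, p.k_minus2)
            t_end = 200.0 / min(slowest, p.k1 * n0)
            c = simulate_concentrations(m, p, {"E": e0, "N": n0}, np.array([t_end]))[-1]
            b_sim = c[m.index("X1")] + c[m.index("X2")]
            assert b_sim == pytest.approx(b_pred, rel=1e-3)
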