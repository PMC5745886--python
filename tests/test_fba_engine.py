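"""Lexicographic FBA engine tests, including the exhaustive
vertex-enumeration oracle on small toy networks."""

import itertools

import numpy as np
import pytest

from gutbiofilm.fba_engine import (
    KineticBound,
    LexicographicSolver,
    default_kinetics,
    mm_bound,
    solve_lexicographic,
)
from gutbiofilm.media import TRANSPORTED, TRANSPORTED_INDEX
from gutbiofilm.reduced_models import Reaction, ReducedMetabolicNetwork


# ---------------------------------------------------------------------------
# Michaelis-Menten bounds

@pytest.mark.parametrize("conc, vmax, km, expected", [
    (0.5, 10.0, 0.5, 5.0),     # carbohydrate half-saturation
    (0.0, 10.0, 0.5, 0.0),
    (0.003, 20.0, 0.003, 10.0),  # oxygen half-saturation
    (1e-13, 10.0, 0.5, 0.0),   # below the clipping threshold
])
def test_mm_bound_values(conc, vmax, km, expected):
    assert mm_bound(conc, vmax, km) == pytest.approx(expected)


def test_mm_bound_monotone_and_capped():
    concs = np.linspace(0, 50, 200)
    vals = [mm_bound(c, 10.0, 0.5) for c in concs]
    assert all(b >= a for a, b in zip(vals, vals[1:]))
    assert vals[-1] <= 10.0


def test_mm_bound_rejects_negative_concentration():
    with pytest.raises(ValueError, match="negative concentration"):
        mm_bound(-1e-3, 10.0, 0.5)


def test_kinetic_bound_validation():
    with pytest.raises(ValueError):
        KineticBound("glucose", -1.0, 0.5)
    with pytest.raises(ValueError):
        KineticBound("glucose", 10.0, 0.0)
    kb = default_kinetics()["o2"]
    assert (kb.v_max, kb.K_m) == (20.0, 0.003)


# ---------------------------------------------------------------------------
# toy networks

def toy_network(reactions, objective="BIOMASS"):
    mets = {}
    for r in reactions:
        for m in r.stoichiometry:
            mets[m] = "exchange" if m.endswith("_e") else "internal"
    if not any(r.id == "ATPM" for r in reactions):
        reactions = reactions + [Reaction("ATPM", {"atp_c": -1.0},
                                          lower_bound=0.0)]
        mets.setdefault("atp_c", "internal")
    return ReducedMetabolicNetwork(
        species_id="Bt", metabolites=mets, reactions=list(reactions),
        objective_reaction_id=objective, atpm_reaction_id="ATPM")


def single_path_network():
    """EX_glucose(lb -10) -> biomass at yield 0.1; optimum is mu=1."""
    return toy_network([
        Reaction("EX_glucose", {"glucose_e": -1.0}, lower_bound=-1000.0,
                 upper_bound=0.0),
        Reaction("T_glc", {"glucose_e": -1.0, "g_c": 1.0}),
        Reaction("BIOMASS", {"g_c": -10.0}),
    ])


def alternate_secretion_network():
    """Two equal-optimum secretion routes; lexicographic order decides."""
    return toy_network([
        Reaction("EX_glucose", {"glucose_e": -1.0}, lower_bound=-1000.0,
                 upper_bound=0.0),
        Reaction("T_glc", {"glucose_e": -1.0, "g_c": 1.0}),
        Reaction("BIOMASS", {"g_c": -2.0, "w_c": 1.0}),
        Reaction("R_ac", {"w_c": -1.0, "acetate_e": 2.0}),
        Reaction("R_but", {"w_c": -1.0, "butyrate_e": 1.0}),
        Reaction("EX_acetate", {"acetate_e": -1.0}),
        Reaction("EX_butyrate", {"butyrate_e": -1.0}),
    ])


def capped_atpm_network():
    return toy_network([
        Reaction("EX_glucose", {"glucose_e": -1.0}, lower_bound=-1000.0,
                 upper_bound=0.0),
        Reaction("T_glc", {"glucose_e": -1.0, "atp_c": 2.0, "g_c": 0.5}),
        Reaction("ATPM", {"atp_c": -1.0}, lower_bound=3.0),
        Reaction("BIOMASS", {"g_c": -1.0}),
    ])


def test_single_path_optimum_by_hand():
    sol = solve_lexicographic(single_path_network(), {"glucose": 10.0})
    assert sol.growth_rate == pytest.approx(1.0)
    assert sol.exchange_fluxes["glucose"] == pytest.approx(-10.0)


def test_alternate_optima_resolved_by_order_reproducibly():
    net = alternate_secretion_network()
    for _ in range(3):
        sol = solve_lexicographic(net, {"glucose": 10.0})
        # acetate precedes butyrate in the canonical order, so the
        # acetate route carries the full degenerate flux
        assert sol.exchange_fluxes["acetate"] == pytest.approx(10.0)
        assert sol.exchange_fluxes["butyrate"] == pytest.approx(0.0)
    # reversing the secondary objectives flips the route, not the growth
    order = [("BIOMASS", "max"), ("EX_butyrate", "max"),
             ("EX_acetate", "max"), ("EX_glucose", "max")]
    sol2 = solve_lexicographic(net, {"glucose": 10.0}, objective_order=order)
    assert sol2.exchange_fluxes["butyrate"] == pytest.approx(5.0)
    assert sol2.exchange_fluxes["acetate"] == pytest.approx(0.0)
    assert sol2.growth_rate == pytest.approx(
        solve_lexicographic(net, {"glucose": 10.0}).growth_rate)


def test_unsatisfiable_atpm_reports_infeasible_with_zero_fluxes():
    sol = solve_lexicographic(capped_atpm_network(), {"glucose": 0.0})
    assert not sol.feasible
    assert sol.growth_rate == 0.0
    assert all(v == 0.0 for v in sol.exchange_fluxes.values())


def test_uptake_respects_kinetic_bound():
    sol = solve_lexicographic(single_path_network(), {"glucose": 3.7})
    assert abs(sol.exchange_fluxes["glucose"]) <= 3.7 + 1e-9


def test_determinism_bit_identical():
    net = alternate_secretion_network()
    solver = LexicographicSolver(net)
    results = [solver.solve({"glucose": 7.3}) for _ in range(5)]
    first = results[0]
    for r in results[1:]:
        assert r.growth_rate == first.growth_rate
        assert r.exchange_fluxes == first.exchange_fluxes


def test_objective_order_must_start_with_biomass():
    net = single_path_network()
    with pytest.raises(ValueError, match="biomass"):
        LexicographicSolver(net, objective_order=[("EX_glucose", "max")])


# ---------------------------------------------------------------------------
# exhaustive vertex-enumeration oracle (tests/oracles.py)

from oracles import lexicographic_oracle  # noqa: E402


@pytest.mark.parametrize("factory, bounds", [
    (single_path_network, {"glucose": 10.0}),
    (single_path_network, {"glucose": 2.5}),
    (alternate_secretion_network, {"glucose": 10.0}),
    (alternate_secretion_network, {"glucose": 1.0}),
    (capped_atpm_network, {"glucose": 10.0}),
])
def test_lexicographic_matches_vertex_enumeration(factory, bounds):
    net = factory()
    oracle = lexicographic_oracle(net, bounds)
    assert oracle is not None
    sol = solve_lexicographic(net, bounds)
    idx = {r.id: j for j, r in enumerate(net.reactions)}
    for met in net.exchanged_metabolites:
        assert sol.exchange_fluxes[met] == pytest.approx(
            oracle[idx[f"EX_{met}"]], abs=1e-6), met
    assert sol.growth_rate == pytest.approx(
        oracle[idx[net.objective_reaction_id]], abs=1e-6)


def test_reduced_model_growth_invariant_under_secondary_order():
    """Perturbing the order of objectives after the first never changes
    the growth rate (lexicographic consistency)."""
    from gutbiofilm.reduced_models import build_reduced_model

    net = build_reduced_model("Ec")
    base = LexicographicSolver(net)
    bounds = {m: 5.0 for m in base.consumables}
    reference = base.solve(bounds).growth_rate
    reordered = [base.objective_order[0]] + base.objective_order[:0:-1]
    flipped = LexicographicSolver(net, objective_order=reordered)
    assert flipped.solve(bounds).growth_rate == pytest.approx(
        reference, abs=1e-9)


# ---------------------------------------------------------------------------
# property tests

from hypothesis import given, settings  # noqa: E402
from hypothesis import strategies as st  # noqa: E402


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.lists(st.floats(0.0, 10.0, allow_nan=False),
                min_size=15, max_size=15))
def test_feasible_solutions_respect_bounds_property(bound_values):
    """For arbitrary bound vectors, every uptake stays within its
    kinetic bound and growth is non-negative (Ec reduced model)."""
    from gutbiofilm.reduced_models import build_reduced_model

    net = build_reduced_model("Ec")
    solver = _property_solver_cache.setdefault(
        "Ec", LexicographicSolver(net))
    bounds = dict(zip(solver.consumables, bound_values))
    sol = solver.solve(bounds)
    assert sol.growth_rate >= 0.0
    if sol.feasible:
        for met, b in bounds.items():
            assert sol.exchange_fluxes[met] >= -round(b, 4) - 1e-6, met


_property_solver_cache: dict = {}
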