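"""Minimal-adjustment QP against a dense KKT oracle; chain invariants."""

import numpy as np
import pandas as pd
import pytest

from phaseflux.fba import amino_acid_exchange_map, phase_medium, run_phase_fba, \
    stoichiometric_arrays
from phaseflux.moma import MomaError, compare_methods, moma_step, run_moma_chain
from phaseflux.synth import make_toy_model


def kkt_projection(S, ref):
    """Closed-form minimizer of ||v - ref||^2 s.t. S v = 0 (bounds slack).

    v* = ref - S^T (S S^T)^+ S ref  (Euclidean projection onto the null space).
    """
    pinv = np.linalg.pinv(S @ S.T)
    return ref - S.T @ (pinv @ (S @ ref))


def test_step_returns_reference_when_bounds_unchanged(toy_model, params, fba):
    ref = fba.fluxes["P3"]
    flux, dist = moma_step(toy_model, params.uf.loc[3].to_dict(), ref)
    assert dist == pytest.approx(0.0, abs=1e-5)
    assert np.allclose(flux, ref, atol=1e-4)


def test_zero_reference_yields_zero_vector(toy_model, params):
    ref = pd.Series(0.0, index=[r.id for r in toy_model.reactions])
    flux, dist = moma_step(toy_model, params.uf.loc[2].to_dict(), ref)
    assert dist == pytest.approx(0.0, abs=1e-6)
    assert np.allclose(flux, 0.0, atol=1e-6)


def test_step_matches_dense_kkt_oracle(toy_model, params):
    """With wide bounds the QP equals the closed-form null-space projection."""
    model = toy_model.copy()
    for rxn in model.reactions:
        rxn.bounds = (-50.0, 50.0)  # keep every box constraint slack
    rng = np.random.default_rng(0)
    S, _, _, order = stoichiometric_arrays(model)
    # a reference near the null space so the projection stays interior
    base = kkt_projection(S, rng.normal(scale=0.5, size=len(order)))
    ref = pd.Series(base + rng.normal(scale=0.05, size=len(order)), index=order)
    uptake = {aa: 50.0 for aa in params.amino_acids}
    flux, dist = moma_step(model, uptake, ref)
    expected = kkt_projection(S, ref.to_numpy())
    assert np.abs(expected).max() < 49.0  # oracle itself respects the box
    assert np.allclose(flux.to_numpy(), expected, atol=1e-5)
    assert dist == pytest.approx(np.linalg.norm(expected - ref.to_numpy()), abs=1e-5)


def test_step_satisfies_steady_state_and_bounds(toy_model, params, fba):
    S, _, _, order = stoichiometric_arrays(toy_model)
    emap = amino_acid_exchange_map(toy_model, params.amino_acids)
    flux, _ = moma_step(toy_model, params.uf.loc[4].to_dict(), fba.fluxes["P3"])
    assert np.abs(S @ flux.reindex(order).to_numpy()).max() < 1e-6
    with phase_medium(toy_model, params.uf.loc[4].to_dict(), emap) as m:
        _, lb, ub, _ = stoichiometric_arrays(m)
    v = flux.reindex(order).to_numpy()
    assert (v >= lb - 1e-8).all() and (v <= ub + 1e-8).all()


class TestChain:
    def test_length_is_phases_minus_one(self, chain, params):
        assert len(chain.fluxes.phases) == len(params.phases) - 1
        assert len(chain.distances) == len(params.phases) - 1

    def test_identical_media_give_zero_distances(self, toy_model, params):
        import copy

        frozen = copy.deepcopy(params)
        for p in frozen.phases:
            frozen.uf.loc[p] = frozen.uf.loc[frozen.phases[0]]
        chain = run_moma_chain(toy_model, frozen)
        assert (chain.distances < 1e-5).all()

    def test_moma_is_minimal_among_feasible_phase_solutions(
        self, toy_model, params, fba, chain
    ):
        """The adjustment never exceeds the FBA solution's distance."""
        phases = params.phases
        for prev, cur in zip(phases[:-1], phases[1:]):
            if prev == phases[0]:
                ref = fba.fluxes[f"P{prev}"]
            else:
                ref = chain.fluxes.fluxes[f"P{prev}"]
            d_moma = chain.distances[f"P{prev}->P{cur}"]
            d_fba = np.linalg.norm(fba.fluxes[f"P{cur}"] - ref)
            assert d_moma <= d_fba + 1e-6

    def test_moma_biomass_never_exceeds_fba_optimum(self, fba, chain):
        for p in chain.fluxes.phases:
            assert chain.fluxes.objective[p] <= fba.objective[p] + 1e-9

    def test_major_switch_dominates_quiet_transitions(self, chain, scenario):
        """The planted three-substrate switch forces the largest adjustment
        among transitions with no depletion or accumulation event."""
        t_major = scenario.major_switch_transition
        events = set(scenario.depletion_schedule.values())
        if scenario.accumulation_phase is not None:
            events |= {scenario.accumulation_phase - 1, scenario.accumulation_phase}
        d_major = chain.distances[f"P{t_major}->P{t_major + 1}"]
        for label, d in chain.distances.items():
            t = int(label.split("->")[0][1:])
            if t not in events:
                assert d_major > d, label

    def test_l1_variant_feasible(self, toy_model, params, fba):
        chain = run_moma_chain(toy_model, params, fba_fluxes=fba, metric="l1")
        S, _, _, order = stoichiometric_arrays(toy_model)
        for p in chain.fluxes.phases:
            v = chain.fluxes.fluxes[p].reindex(order).to_numpy()
            assert np.abs(S @ v).max() < 1e-6

    def test_single_phase_rejected(self, toy_model, params):
        import copy

        short = copy.deepcopy(params)
        short.table = short.table.iloc[:1]
        short.uf = short.uf.iloc[:1]
        with pytest.raises(MomaError):
            run_moma_chain(toy_model, short)


class TestCompareMethods:
    def test_identical_matrices_fully_shared(self, fba, toy_model):
        out = compare_methods(fba, fba, toy_model)
        per = out["per_phase"]
        assert (per["n_shared"] == per["n_active_FBA"]).all()
        assert (per["n_shared"] == per["n_active_MOMA"]).all()

    def test_shared_bounded_by_each_method(self, fba, chain, toy_model):
        per = compare_methods(fba, chain.fluxes, toy_model)["per_phase"]
        assert (per["n_shared"] <= per["n_active_FBA"]).all()
        assert (per["n_shared"] <= per["n_active_MOMA"]).all()

    def test_seed_phase_excluded_from_comparison(self, fba, chain, toy_model):
        per = compare_methods(fba, chain.fluxes, toy_model)["per_phase"]
        assert "P1" not in per.index

    def test_subsystem_fractions_sum_to_at_most_one(self, fba, chain, toy_model):
        sub = compare_methods(fba, chain.fluxes, toy_model)["per_subsystem"]
        total = sub[["frac_fba_only", "frac_moma_only", "frac_both"]].sum(axis=1)
        assert (total <= 1.0 + 1e-9).all()

    def test_mismatched_reaction_sets_rejected(self, fba, chain, toy_model):
        clipped = fba.fluxes.iloc[:-1]
        from phaseflux.fba import FluxMatrix

        bad = FluxMatrix(fluxes=clipped, objective=fba.objective)
        with pytest.raises(MomaError):
            compare_methods(bad, chain.fluxes, toy_model)


def test_moma_predicts_at_least_as_many_active_reactions_early(
    fba, chain, toy_model
):
    """Minimal adjustment retains previously active routes, widening the
    active network relative to fresh per-phase optimisation."""
    per = compare_methods(fba, chain.fluxes, toy_model)["per_phase"]
    early = per.iloc[: max(3, len(per) // 2)]
    assert (early["n_active_MOMA"] >= early["n_active_FBA"]).all()
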