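"""Nutritional-MOMA: minimal metabolic adjustment across nutrient transitions.

Canonical MOMA finds, for a perturbed model, the feasible flux vector closest
(in squared Euclidean distance) to a reference flux distribution.  Here the
perturbation is not a gene knockout but a *nutrient shift*: at each transition
the previous phase's flux distribution is the "wild-type" reference and the
current phase's uptake bounds define the "mutant" feasible set,

    minimize  || v - v_ref ||_2^2
    s.t.      S v = 0,   lb_P <= v <= ub_P.

No biomass floor is imposed — growth emerges from the minimal adjustment, so
the predicted biomass flux may be sub-optimal relative to FBA.  Chaining the
step over phases P1 -> P2 -> ... (each solution becoming the next reference,
seeded by the FBA solution of the first phase) yields a flux matrix with one
column fewer than FBA's, covering the transitions of the growth curve.

The quadratic program is solved with OSQP on the sparse stoichiometric
matrix; an L1 (least absolute adjustment) variant via linear programming is
available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from cobra import Model

from .fba import ACTIVITY_TOL, FluxMatrix, amino_acid_exchange_map, phase_medium, \
    stoichiometric_arrays
from .model import biomass_reaction_id

__all__ = ["MomaError", "MomaChain", "moma_step", "run_moma_chain", "compare_methods"]

_OSQP_SETTINGS = dict(
    eps_abs=1e-10, eps_rel=1e-10, max_iter=200000, polishing=True, verbose=False
)


class MomaError(Exception):
    pass


def _qp_min_adjust(S, lb, ub, ref):
    import osqp

    n = S.shape[1]
    P = sp.eye(n, format="csc") * 2.0
    q = -2.0 * ref
    A = sp.vstack([sp.csc_matrix(S), sp.eye(n, format="csc")], format="csc")
    l = np.concatenate([np.zeros(S.shape[0]), lb])
    u = np.concatenate([np.zeros(S.shape[0]), ub])
    prob = osqp.OSQP()
    prob.setup(P, q, A, l, u, **_OSQP_SETTINGS)
    res = prob.solve(raise_error=False)
    status = res.info.status
    if "solved" not in status:
        raise MomaError(f"quadratic program not solved: status {status!r}")
    v = np.asarray(res.x)
    # project tiny constraint violations back into the box
    return np.clip(v, lb, ub)


def _lp_min_adjust(S, lb, ub, ref):
    from scipy.optimize import linprog

    n = S.shape[1]
    # variables [v, t]; minimize sum t, t >= |v - ref|
    c = np.concatenate([np.zeros(n), np.ones(n)])
    I = sp.eye(n)
    A_ub = sp.vstack([sp.hstack([I, -I]), sp.hstack([-I, -I])], format="csc")
    b_ub = np.concatenate([ref, -ref])
    A_eq = sp.hstack([sp.csc_matrix(S), sp.csc_matrix((S.shape[0], n))], format="csc")
    bounds = [(lo, hi) for lo, hi in zip(lb, ub)] + [(0, None)] * n
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=np.zeros(S.shape[0]),
                  bounds=bounds, method="highs")
    if not res.success:
        raise MomaError(f"L1 adjustment LP failed: {res.message}")
    return np.clip(res.x[:n], lb, ub)


def moma_step(
    model: Model,
    uptake: dict[str, float],
    reference: pd.Series,
    exchange_map: dict[str, str] | None = None,
    metric: str = "euclidean",
) -> tuple[pd.Series, float]:
    """Minimal-adjustment flux vector for one phase given a reference.

    ``uptake`` maps amino acids to the phase's uptake-flux bounds; the mapped
    exchanges get ``lower_bound = -UF`` while all other bounds come from the
    model.  Returns ``(flux vector, Euclidean adjustment distance)`` — the
    distance is reported as the L2 norm for either metric.
    """
    emap = exchange_map or amino_acid_exchange_map(model, sorted(uptake))
    with phase_medium(model, uptake, emap) as m:
        S, lb, ub, order = stoichiometric_arrays(m)
    ref = reference.reindex(order)
    if ref.isna().any():
        missing = list(ref.index[ref.isna()])[:5]
        raise MomaError(f"reference vector lacks reactions, e.g. {missing}")
    refv = ref.to_numpy(dtype=float)
    solver = _qp_min_adjust if metric == "euclidean" else _lp_min_adjust
    if metric not in ("euclidean", "l1"):
        raise MomaError(f"unknown adjustment metric {metric!r}")
    v = solver(S, lb, ub, refv)
    flux = pd.Series(v, index=order)
    return flux, float(np.linalg.norm(v - refv))


@dataclass
class MomaChain:
    """Flux matrix from chained minimal-adjustment steps plus distances."""

    fluxes: FluxMatrix  # method "nMOMA", columns P2..Pn
    distances: pd.Series  # index "P1->P2", ...
    reference_phase: str  # the FBA-seeded first phase (not a column)


def run_moma_chain(
    model: Model,
    params,
    fba_fluxes: FluxMatrix | None = None,
    metric: str = "euclidean",
    exchange_overrides: dict[str, str] | None = None,
) -> MomaChain:
    """Chain minimal-adjustment steps over the parameterized phases.

    The FBA solution of the first phase seeds the chain; each step's solution
    becomes the next reference.  The resulting matrix has one column per
    phase from the second onwards (nine columns for a ten-phase window).
    """
    from .fba import run_phase_fba

    phases = params.phases
    if len(phases) < 2:
        raise MomaError("need at least two phases for a transition chain")
    emap = amino_acid_exchange_map(model, params.amino_acids, exchange_overrides)
    if fba_fluxes is None or f"P{phases[0]}" not in fba_fluxes.phases:
        fba_fluxes = run_phase_fba(model, params, phases=[phases[0]],
                                   exchange_overrides=exchange_overrides)
    ref = fba_fluxes.fluxes[f"P{phases[0]}"]
    bio = biomass_reaction_id(model)
    cols, objs, dists = {}, {}, {}
    for prev, cur in zip(phases[:-1], phases[1:]):
        label = f"P{cur}"
        uptake = params.uf.loc[cur].to_dict()
        try:
            flux, dist = moma_step(model, uptake, ref, exchange_map=emap, metric=metric)
        except MomaError as exc:
            raise MomaError(f"chain aborted at transition P{prev}->P{cur}: {exc}") from exc
        cols[label] = flux
        objs[label] = float(flux[bio])
        dists[f"P{prev}->P{cur}"] = dist
        ref = flux
    fm = FluxMatrix(
        fluxes=pd.DataFrame(cols), objective=pd.Series(objs), method="nMOMA"
    )
    return MomaChain(fluxes=fm, distances=pd.Series(dists), reference_phase=f"P{phases[0]}")


def compare_methods(
    fba: FluxMatrix,
    moma: FluxMatrix,
    model: Model,
    tol: float = ACTIVITY_TOL,
) -> dict[str, pd.DataFrame]:
    """Active-set agreement between FBA and nutritional-MOMA predictions.

    Over the phases present in both matrices (the FBA-only seed phase is
    excluded): per-phase counts of active reactions under each method and
    their intersection, and per-subsystem fractions active under FBA only,
    MOMA only, or both.
    """
    if set(fba.fluxes.index) != set(moma.fluxes.index):
        raise MomaError("flux matrices cover different reaction sets")
    common = [p for p in fba.phases if p in moma.phases]
    if not common:
        raise MomaError("no common phases to compare")
    act_f = fba.active(tol)[common]
    act_m = moma.active(tol).reindex(fba.fluxes.index)[common]
    per_phase = pd.DataFrame(
        {
            "n_active_FBA": act_f.sum(axis=0),
            "n_active_MOMA": act_m.sum(axis=0),
            "n_shared": (act_f & act_m).sum(axis=0),
        }
    )
    sub = pd.Series({r.id: (r.subsystem or "unassigned") for r in model.reactions})
    sub = sub.reindex(act_f.index).fillna("unassigned")
    rows = []
    for subsystem, idx in act_f.groupby(sub).groups.items():
        nf = act_f.loc[idx]
        nm = act_m.loc[idx]
        n = len(idx)
        for p in common:
            both = (nf[p] & nm[p]).sum()
            rows.append(
                {
                    "subsystem": subsystem,
                    "phase": p,
                    "n_reactions": n,
                    "frac_fba_only": (nf[p] & ~nm[p]).sum() / n,
                    "frac_moma_only": (nm[p] & ~nf[p]).sum() / n,
                    "frac_both": both / n,
                }
            )
    return {"per_phase": per_phase, "per_subsystem": pd.DataFrame(rows)}
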