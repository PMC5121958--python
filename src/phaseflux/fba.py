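"""Phase-wise flux balance analysis and flux variability analysis.

Each growth phase is a medium: the amino-acid exchange reactions are bounded
below by minus the phase's uptake flux (uptake is negative by convention),
salt exchanges stay open, and biomass formation is maximized.  The result is
a reaction x phase *flux matrix*, the object every downstream analysis
(transition classification, nutritional-MOMA comparison, covariation
clustering) consumes.

FVA at a fixed fraction of the phase optimum yields per-reaction admissible
ranges ``[f_min, f_max]``; the span ``v = f_max / f_min`` splits the network
into *fixed* (v = 1) and *flexible* (v != 1) parts.  When ``f_min`` is 0 the
ratio is undefined; the fixed/flexible call then falls back to
``f_max - f_min`` against the tolerance and the span is reported as NaN.
"""

from __future__ import annotations

from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cobra import Model
from cobra.flux_analysis import flux_variability_analysis
from cobra.util.array import create_stoichiometric_matrix

from .model import exchange_reaction_ids

__all__ = [
    "FluxMatrix",
    "FvaResult",
    "PhaseFbaError",
    "ACTIVITY_TOL",
    "amino_acid_exchange_map",
    "phase_medium",
    "run_phase_fba",
    "minimal_media_screen",
    "run_phase_fva",
    "stoichiometric_arrays",
]

#: |v| above this (mmol gDW^-1 h^-1) counts as "carrying flux" pipeline-wide
ACTIVITY_TOL = 1e-9

STEADY_STATE_TOL = 1e-6


class PhaseFbaError(Exception):
    pass


@dataclass
class FluxMatrix:
    """Reaction x phase flux values plus the per-phase objective.

    ``method`` is ``"FBA"`` or ``"nMOMA"``.  ``normalized`` marks a matrix
    whose columns were divided by the predicted growth rate; activity tests
    then rescale the tolerance by 1/mu so active sets are preserved.
    """

    fluxes: pd.DataFrame  # index: reaction ids; columns: phase labels
    objective: pd.Series  # per-phase predicted biomass flux (mu_pred)
    method: str = "FBA"
    normalized: bool = False
    infeasible_phases: list[str] = field(default_factory=list)

    @property
    def phases(self) -> list[str]:
        return list(self.fluxes.columns)

    def activity_tolerances(self, tol: float = ACTIVITY_TOL) -> pd.Series:
        """Per-column activity threshold (tol, or tol/mu for normalized)."""
        if not self.normalized:
            return pd.Series(tol, index=self.fluxes.columns)
        mu = self.objective.reindex(self.fluxes.columns)
        scaled = tol / mu.where(mu > 0)
        return scaled.fillna(tol)

    def active(self, tol: float = ACTIVITY_TOL) -> pd.DataFrame:
        return self.fluxes.abs().gt(self.activity_tolerances(tol), axis=1)

    def write_tsv(self, path: str | Path) -> None:
        out = self.fluxes.copy()
        out.loc["__objective__"] = self.objective.reindex(out.columns)
        out.index.name = "reaction"
        out.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def read_tsv(cls, path: str | Path, method: str = "FBA") -> "FluxMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        obj = df.loc["__objective__"]
        return cls(fluxes=df.drop(index="__objective__"), objective=obj, method=method)


def stoichiometric_arrays(model: Model) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Dense S matrix plus bound vectors and the reaction-id order."""
    S = create_stoichiometric_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    return S, lb, ub, [r.id for r in model.reactions]


# ---------------------------------------------------------------------------
# Media handling
# ---------------------------------------------------------------------------

def amino_acid_exchange_map(
    model: Model, amino_acids: list[str], overrides: dict[str, str] | None = None
) -> dict[str, str]:
    """Map each amino-acid name to its exchange reaction id.

    Convention: the exchange is the single-metabolite reaction whose
    metabolite id starts with the amino-acid name (e.g. ``aa1`` ->
    ``EX_aa1_e`` on ``aa1_e``).  ``overrides`` wins where given; an amino acid
    with no exchange raises.
    """
    overrides = overrides or {}
    exchanges = exchange_reaction_ids(model)
    by_met = {}
    for rid in exchanges:
        met = next(iter(model.reactions.get_by_id(rid).metabolites))
        by_met[met.id] = rid
    mapping = {}
    for aa in amino_acids:
        if aa in overrides:
            mapping[aa] = overrides[aa]
            continue
        hits = [rid for mid, rid in by_met.items()
                if mid == aa or mid.startswith(aa + "_")]
        if len(hits) != 1:
            raise PhaseFbaError(
                f"cannot map amino acid {aa!r} to a unique exchange reaction "
                f"(candidates: {sorted(hits)})"
            )
        mapping[aa] = hits[0]
    return mapping


@contextmanager
def phase_medium(model: Model, uptake: dict[str, float], exchange_map: dict[str, str]):
    """Temporarily impose a phase's amino-acid uptake bounds.

    Every mapped exchange gets ``lower_bound = -UF`` (zero closes it); salt
    and secretion bounds are left as the model defines them.
    """
    with model:
        for aa, rid in exchange_map.items():
            model.reactions.get_by_id(rid).lower_bound = -abs(uptake.get(aa, 0.0))
        yield model


# ---------------------------------------------------------------------------
# FBA / FVA
# ---------------------------------------------------------------------------

def _check_steady_state(model: Model, flux: pd.Series) -> float:
    S, _, _, order = stoichiometric_arrays(model)
    resid = float(np.abs(S @ flux.reindex(order).to_numpy()).max())
    if resid > STEADY_STATE_TOL:
        raise PhaseFbaError(f"steady-state residual {resid:.2e} exceeds tolerance")
    return resid


def run_phase_fba(
    model: Model,
    params,
    phases: list[int] | None = None,
    exchange_overrides: dict[str, str] | None = None,
) -> FluxMatrix:
    """One FBA per phase under that phase's uptake bounds.

    ``params`` is a :class:`~phaseflux.parameterization.PhaseParameterization`.
    Infeasible phases are recorded and contribute an all-zero column.
    """
    phases = list(phases) if phases is not None else params.phases
    emap = amino_acid_exchange_map(model, params.amino_acids, exchange_overrides)
    cols, objs, infeasible = {}, {}, []
    for p in phases:
        label = f"P{p}"
        uptake = params.uf.loc[p].to_dict()
        with phase_medium(model, uptake, emap) as m:
            sol = m.optimize()
            if sol.status != "optimal":
                infeasible.append(label)
                cols[label] = pd.Series(0.0, index=[r.id for r in model.reactions])
                objs[label] = 0.0
                continue
            _check_steady_state(m, sol.fluxes)
            cols[label] = sol.fluxes
            objs[label] = float(sol.objective_value)
    fm = FluxMatrix(
        fluxes=pd.DataFrame(cols),
        objective=pd.Series(objs),
        method="FBA",
        infeasible_phases=infeasible,
    )
    return fm


def minimal_media_screen(
    model: Model,
    amino_acids: list[str],
    uptake: float = 1.0,
    nitrogen_exchange: str | None = "EX_nh4_e",
    exchange_overrides: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Growth rate on each single-amino-acid minimal medium.

    Each amino acid in turn is the sole carbon *and* nitrogen source at the
    given uptake rate (default 1 mmol gDW^-1 h^-1): all other amino-acid
    exchanges are closed and, when ``nitrogen_exchange`` names a reaction,
    its uptake is closed too (secretion stays open).  Salts remain open.
    Returns a frame ranked by growth rate; amino acids without an exchange
    get NaN.
    """
    rows = []
    try:
        emap = amino_acid_exchange_map(model, amino_acids, exchange_overrides)
    except PhaseFbaError:
        emap = {}
        for aa in amino_acids:
            try:
                emap.update(amino_acid_exchange_map(model, [aa], exchange_overrides))
            except PhaseFbaError:
                emap[aa] = None
    for aa in amino_acids:
        rid = emap.get(aa)
        if rid is None:
            rows.append((aa, np.nan))
            continue
        with model:
            for other in emap.values():
                if other is not None:
                    model.reactions.get_by_id(other).lower_bound = 0.0
            if nitrogen_exchange and nitrogen_exchange in model.reactions:
                model.reactions.get_by_id(nitrogen_exchange).lower_bound = 0.0
            model.reactions.get_by_id(rid).lower_bound = -abs(uptake)
            mu = model.slim_optimize(error_value=0.0)
            rows.append((aa, max(float(mu), 0.0)))
    out = pd.DataFrame(rows, columns=["amino_acid", "growth_rate"])
    return out.sort_values(
        by=["growth_rate", "amino_acid"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)


@dataclass
class FvaResult:
    """Per-reaction, per-phase FVA bounds and the fixed/flexible split."""

    minimum: pd.DataFrame  # reaction x phase
    maximum: pd.DataFrame
    span: pd.DataFrame  # f_max / f_min, NaN where f_min ~ 0
    fixed: pd.DataFrame  # bool: f_max - f_min <= tol

    def n_flexible(self) -> pd.Series:
        return (~self.fixed).sum(axis=0)

    def write_tsv(self, path: str | Path) -> None:
        long = pd.concat(
            {"f_min": self.minimum, "f_max": self.maximum, "span": self.span},
            axis=1,
        )
        long.columns = [f"{a}:{b}" for a, b in long.columns]
        long.index.name = "reaction"
        long.to_csv(path, sep="\t", float_format="%.10g")


def run_phase_fva(
    model: Model,
    params,
    phases: list[int] | None = None,
    optimality_fraction: float = 1.0,
    tol: float = ACTIVITY_TOL,
    exchange_overrides: dict[str, str] | None = None,
) -> FvaResult:
    """FVA per phase at ``optimality_fraction`` of the biomass optimum."""
    phases = list(phases) if phases is not None else params.phases
    emap = amino_acid_exchange_map(model, params.amino_acids, exchange_overrides)
    mins, maxs = {}, {}
    for p in phases:
        label = f"P{p}"
        uptake = params.uf.loc[p].to_dict()
        with phase_medium(model, uptake, emap) as m:
            fva = flux_variability_analysis(
                m, fraction_of_optimum=optimality_fraction, processes=1
            )
        mins[label] = fva["minimum"]
        maxs[label] = fva["maximum"]
    minimum, maximum = pd.DataFrame(mins), pd.DataFrame(maxs)
    with np.errstate(divide="ignore", invalid="ignore"):
        span = maximum / minimum
    span = span.where(minimum.abs() > tol)
    fixed = (maximum - minimum).abs() <= tol
    return FvaResult(minimum=minimum, maximum=maximum, span=span, fixed=fixed)
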