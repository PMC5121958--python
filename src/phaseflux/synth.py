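"""Synthetic toy models and fed-batch growth curves.

The generator emulates the statistical structure of a fed-batch growth
experiment on a complex amino-acid medium: hierarchical (sequential) substrate
depletion, a monotonically non-increasing growth rate, a trailing window with
no growth and no uptake, and an occasional transient concentration increase
(nutrient accumulation).  Together with :func:`make_toy_model` it lets the
whole pipeline run end-to-end with no external data.

Defaults define the reference scenario used throughout the test-suite and the
examples: six amino acids over twelve one-hour phases, a planted *major
switch* at which three amino acids deplete simultaneously (the transition
P3 -> P4), single depletions later, one amino acid accumulating transiently,
a constant planted yield of 0.4 g biomass per g substrate, and the
biomass-per-OD calibration anchor (1.28 g dry weight, OD 3.8, 1.4 l).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from cobra import Model, Metabolite, Reaction

from .parameterization import Calibration, GrowthCurve, biomass_per_od

__all__ = ["SyntheticScenario", "make_toy_model", "make_growth_curve", "DEFAULT_MW"]

# real amino-acid molar weights (g/mol), cycled over synthetic amino acids;
# light ones first so the preferred, early-depleted substrates are molar-rich
DEFAULT_MW = (75.07, 89.09, 105.09, 131.17, 133.10, 147.13, 155.15, 181.19, 115.13, 204.23)

_DEFAULT_MU = (0.30, 0.28, 0.26, 0.20, 0.18, 0.15, 0.12, 0.10, 0.07, 0.04, 0.0, 0.0)


def _default_schedule(n_aa: int, n_phases: int) -> dict[str, int]:
    """Staggered depletion with a major switch: aa1-aa3 all end at phase 3."""
    last_fed = n_phases - 2  # trailing two phases have no uptake
    sched = {}
    for k in range(1, n_aa + 1):
        if k <= min(3, n_aa - 1):
            sched[f"aa{k}"] = min(3, last_fed)
        else:
            # later, single depletions spread towards the end of the window
            step = max(1, (last_fed - 4) // max(1, n_aa - 3))
            sched[f"aa{k}"] = min(last_fed, 4 + (k - 3) * step + (k == n_aa) * last_fed)
    sched[f"aa{n_aa}"] = last_fed  # one substrate persists to the end (Glu-like)
    return sched


@dataclass
class SyntheticScenario:
    """Parameters of a synthetic fed-batch experiment."""

    n_amino_acids: int = 6
    n_phases: int = 12
    depletion_schedule: dict[str, int] | None = None
    growth_rate_profile: tuple[float, ...] | None = None
    planted_yield: float = 0.4
    noise_sd: float = 0.0
    accumulation_aa: str | None = "aa5"
    accumulation_phase: int | None = 3
    od_start: float = 0.15
    calibration: Calibration = field(
        default_factory=lambda: Calibration(dry_weight_g=1.28, od_ref=3.8, volume_l=1.4)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_amino_acids < 2:
            raise ValueError("need at least two amino acids")
        if self.n_phases < 3:
            raise ValueError("need at least three phases")
        if self.depletion_schedule is None:
            self.depletion_schedule = _default_schedule(self.n_amino_acids, self.n_phases)
        if self.growth_rate_profile is None:
            if self.n_phases == len(_DEFAULT_MU):
                self.growth_rate_profile = _DEFAULT_MU
            else:  # resample the non-increasing reference profile
                x = np.linspace(0, 1, self.n_phases)
                xp = np.linspace(0, 1, len(_DEFAULT_MU))
                self.growth_rate_profile = tuple(np.interp(x, xp, _DEFAULT_MU))
        if len(self.growth_rate_profile) != self.n_phases:
            raise ValueError("growth_rate_profile length must equal n_phases")
        if any(m < 0 for m in self.growth_rate_profile):
            raise ValueError("growth rates must be non-negative")
        for aa, p in self.depletion_schedule.items():
            if not (1 <= p <= self.n_phases):
                raise ValueError(f"depletion phase {p} for {aa!r} outside 1..{self.n_phases}")

    @property
    def amino_acids(self) -> list[str]:
        return [f"aa{k}" for k in range(1, self.n_amino_acids + 1)]

    @property
    def mw(self) -> dict[str, float]:
        return {
            aa: DEFAULT_MW[k % len(DEFAULT_MW)] for k, aa in enumerate(self.amino_acids)
        }

    @property
    def major_switch_transition(self) -> int:
        """Transition index T at which the most amino acids deplete at once."""
        counts: dict[int, int] = {}
        for p in self.depletion_schedule.values():
            counts[p] = counts.get(p, 0) + 1
        return max(sorted(counts), key=lambda p: counts[p])


# ---------------------------------------------------------------------------
# Toy metabolic model
# ---------------------------------------------------------------------------

def make_toy_model(n_amino_acids: int = 6, seed: int = 0) -> Model:
    """A small, feasible amino-acid economy around a TCA-like cycle.

    Per amino acid: an exchange, a transporter, a degradation route into the
    2-oxoglutarate hub (releasing NH4) and a biosynthetic route back (costing
    ATP), so every amino acid can be either imported or synthesized.  A cyclic
    three-step TCA-like subsystem regenerates the hub carbon (the emitted CO2
    is re-fixed by a carboxylation step) while producing ATP from O2.  Salts
    (NH4, O2, phosphate) have open exchanges; biomass consumes every amino
    acid plus ATP and phosphate.  Each internal reaction carries a GPR over
    synthetic gene ids and a subsystem label.  Construction is deterministic
    given ``seed`` (which only varies the synthetic gene-id tags).
    """
    if n_amino_acids < 2:
        raise ValueError("need at least two amino acids")
    rng = np.random.default_rng(seed)
    tag = lambda: rng.integers(100, 1000)  # noqa: E731

    model = Model(f"toy{n_amino_acids}")
    aas = [f"aa{k}" for k in range(1, n_amino_acids + 1)]

    def met(mid: str) -> Metabolite:
        return Metabolite(mid, compartment=mid.rsplit("_", 1)[-1])

    akg, succ, oaa = met("akg_c"), met("succ_c"), met("oaa_c")
    atp, co2, co2e = met("atp_c"), met("co2_c"), met("co2_e")
    nh4e, nh4 = met("nh4_e"), met("nh4_c")
    o2e, o2 = met("o2_e"), met("o2_c")
    pie, pi = met("pi_e"), met("pi_c")

    rxns: list[Reaction] = []

    def add(rid, stoich, lb, ub, gpr="", subsystem=""):
        r = Reaction(rid)
        r.bounds = (lb, ub)
        r.subsystem = subsystem
        rxns.append((r, stoich, gpr))
        return r

    for aa in aas:
        e, c = met(f"{aa}_e"), met(f"{aa}_c")
        add(f"EX_{aa}_e", {e: -1}, 0, 1000, subsystem="exchange")
        add(f"TR_{aa}", {e: -1, c: 1}, 0, 1000,
            gpr=f"g{tag()}_tr_{aa}", subsystem="amino acid transport")
        deg_gpr = (f"g{tag()}_deg_{aa}_1 and g{tag()}_deg_{aa}_2"
                   if int(aa[2:]) % 2 == 0 else f"g{tag()}_deg_{aa}")
        add(f"DEG_{aa}", {c: -1, akg: 1, nh4: 1}, 0, 1000,
            gpr=deg_gpr, subsystem=f"{aa} degradation")
        syn_gpr = (f"g{tag()}_syn_{aa}_1 or g{tag()}_syn_{aa}_2"
                   if int(aa[2:]) % 3 == 0 else f"g{tag()}_syn_{aa}")
        add(f"SYN_{aa}", {akg: -1, nh4: -1, atp: -1, c: 1}, 0, 1000,
            gpr=syn_gpr, subsystem=f"{aa} biosynthesis")

    add("TCA1", {akg: -1, o2: -1, succ: 1, co2: 1, atp: 2}, 0, 1000,
        gpr=f"g{tag()}_tca1_a and g{tag()}_tca1_b", subsystem="TCA cycle")
    add("TCA2", {succ: -1, o2: -1, oaa: 1, atp: 1}, 0, 1000,
        gpr=f"g{tag()}_tca2", subsystem="TCA cycle")
    add("TCA3", {oaa: -1, co2: -1, akg: 1}, -1000, 1000,
        gpr=f"g{tag()}_tca3_a or g{tag()}_tca3_b", subsystem="TCA cycle")

    add("EX_nh4_e", {nh4e: -1}, -1000, 1000, subsystem="exchange")
    add("TR_nh4", {nh4e: -1, nh4: 1}, -1000, 1000,
        gpr=f"g{tag()}_trnh4", subsystem="inorganic transport")
    add("EX_o2_e", {o2e: -1}, -1000, 1000, subsystem="exchange")
    add("TR_o2", {o2e: -1, o2: 1}, 0, 1000,
        gpr=f"g{tag()}_tro2", subsystem="inorganic transport")
    add("EX_pi_e", {pie: -1}, -1000, 1000, subsystem="exchange")
    add("TR_pi", {pie: -1, pi: 1}, 0, 1000,
        gpr=f"g{tag()}_trpi", subsystem="inorganic transport")
    add("EX_co2_e", {co2e: -1}, -1000, 1000, subsystem="exchange")
    add("TR_co2", {co2: -1, co2e: 1}, -1000, 1000, subsystem="inorganic transport")

    # lower-numbered (preferred, early-depleted) amino acids are minor biomass
    # components: while fed at high molar rates their supply exceeds demand,
    # so their biosynthetic routes stay off until the depletion transition
    bm = {
        met(f"{aa}_c"): (-0.2 if k < n_amino_acids // 2 else -1.2)
        for k, aa in enumerate(aas)
    }
    bm[atp] = -2.0
    bm[pi] = -0.1
    add("BIOMASS", bm, 0, 1000, subsystem="biomass")

    reactions = [r for r, _, _ in rxns]
    model.add_reactions(reactions)
    # resolve duplicate Metabolite objects by id through the model registry
    for r, stoich, gpr in rxns:
        rxn = model.reactions.get_by_id(r.id)
        resolved = {}
        for m, c in stoich.items():
            if m.id not in model.metabolites:
                model.add_metabolites([m])
            resolved[model.metabolites.get_by_id(m.id)] = c
        rxn.add_metabolites(resolved)
        rxn.gene_reaction_rule = gpr
    model.objective = "BIOMASS"
    return model


# ---------------------------------------------------------------------------
# Growth curve
# ---------------------------------------------------------------------------

def make_growth_curve(scenario: SyntheticScenario) -> GrowthCurve:
    """Simulate a fed-batch curve consistent with the scenario's planted yield.

    OD grows exponentially at the per-phase rate; each phase's total mass
    consumption is ``delta_biomass / planted_yield``, shared among the
    still-available amino acids with fixed heterogeneous weights; each amino
    acid's starting concentration is exactly its cumulative consumption, so it
    reaches zero at its scheduled depletion phase.  One amino acid (if
    configured) receives a transient concentration bump at a single time
    point, which downstream parameterization must clamp to zero consumption.
    """
    sc = scenario
    aas = sc.amino_acids
    n = sc.n_phases
    rng = np.random.default_rng(sc.seed)

    mu = np.asarray(sc.growth_rate_profile)
    od = np.empty(n + 1)
    od[0] = sc.od_start
    for i in range(1, n + 1):
        od[i] = od[i - 1] * np.exp(mu[i - 1])
    bpo = biomass_per_od(sc.calibration)
    delta_b = np.diff(od) * bpo  # g/l per phase
    total_mass = delta_b / sc.planted_yield

    # preferred (early-depleted) substrates are consumed at several-fold the
    # rate of the others, keeping their supply above biomass demand while fed
    # so their biosynthetic routes only switch on at the depletion transition
    weights = {aa: (3.0 if k < len(aas) // 2 else 1.0) for k, aa in enumerate(aas)}
    consumed = np.zeros((n, len(aas)))  # g/l consumed in phase i by aa j
    for i in range(1, n + 1):
        active = [aa for aa in aas if sc.depletion_schedule[aa] >= i]
        if not active or total_mass[i - 1] <= 0:
            continue
        wsum = sum(weights[aa] for aa in active)
        for j, aa in enumerate(aas):
            if aa in active:
                consumed[i - 1, j] = total_mass[i - 1] * weights[aa] / wsum

    c0 = consumed.sum(axis=0)  # exact exhaustion at the depletion phase
    mass_traj = np.vstack([c0, c0 - np.cumsum(consumed, axis=0)])
    mass_traj = np.maximum(mass_traj, 0.0)

    if sc.accumulation_aa is not None and sc.accumulation_phase is not None:
        if sc.accumulation_phase >= sc.n_phases:
            raise ValueError("accumulation phase must precede the final phase")
        j = aas.index(sc.accumulation_aa)
        p = sc.accumulation_phase
        bump = 1.5 * consumed[p - 1, j] + 0.05 * c0[j]
        mass_traj[p, j] += bump  # single elevated time point -> clamped delta

    if sc.noise_sd > 0:
        noise = 1.0 + sc.noise_sd * rng.standard_normal(mass_traj.shape)
        mass_traj = np.maximum(mass_traj * noise, 0.0)

    mw = sc.mw
    data = pd.DataFrame({"time_h": np.arange(n + 1, dtype=float), "OD": od})
    data["mu_per_h"] = np.append(mu, 0.0)[: n + 1]
    for j, aa in enumerate(aas):
        data[aa] = mass_traj[:, j] / (mw[aa] * 1e-3)  # back to mM

    return GrowthCurve(data=data, mw=dict(mw), calibration=sc.calibration)
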