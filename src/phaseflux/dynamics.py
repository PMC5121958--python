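"""Classification of per-transition flux behaviour and rewiring summaries.

Given a flux matrix over consecutive growth phases, each transition
``T: P_i -> P_{i+1}`` partitions the reactions active in either phase into

* ``reversed``   — flux sign flips with both magnitudes above tolerance;
* ``increased``  — |v| grows by more than the change tolerance (not reversed);
* ``decreased``  — |v| shrinks by more than the change tolerance (not reversed);
* ``unchanged``  — everything else.

``turned_on`` / ``turned_off`` track the activity change (crossing the
activity tolerance) and are subsets of increased / decreased respectively.
Because a monotonically declining growth rate drags many fluxes down at every
single transition, the *adjusted* decreasing set removes those consistent
decliners, isolating genuine substrate-switching responses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from cobra import Model

from .fba import ACTIVITY_TOL, FluxMatrix

__all__ = [
    "CHANGE_TOL",
    "ActivitySummary",
    "TransitionReport",
    "activity_summary",
    "classify_transition",
    "classify_all_transitions",
    "adjust_decreasing",
    "normalize_by_growth",
    "pathway_activity",
]

#: minimal |Delta|v|| (mmol gDW^-1 h^-1) counting as a change in flux
CHANGE_TOL = 1e-6


@dataclass
class ActivitySummary:
    per_phase: pd.Series  # active-reaction count per phase
    ever_active: set[str]
    never_active: set[str]
    mean_active: float  # excluding the trailing all-off phases
    sd_active: float


def activity_summary(fluxes: FluxMatrix, tol: float = ACTIVITY_TOL) -> ActivitySummary:
    """Active counts per phase and the ever/never-active partition.

    The mean and standard deviation exclude trailing phases in which every
    reaction is off (the end of the growth curve where the model predicts a
    fully silent network).
    """
    act = fluxes.active(tol)
    per_phase = act.sum(axis=0)
    ever = set(act.index[act.any(axis=1)])
    never = set(act.index) - ever
    counts = per_phase.to_numpy(dtype=float)
    keep = len(counts)
    while keep > 1 and counts[keep - 1] == 0:
        keep -= 1
    used = counts[:keep]
    return ActivitySummary(
        per_phase=per_phase,
        ever_active=ever,
        never_active=never,
        mean_active=float(used.mean()),
        sd_active=float(used.std(ddof=1)) if len(used) > 1 else 0.0,
    )


@dataclass
class TransitionReport:
    transition: str  # e.g. "P3->P4"
    increased: set[str]
    decreased: set[str]
    reversed: set[str]
    turned_on: set[str]
    turned_off: set[str]
    unchanged: set[str]
    adjusted_decreased: set[str] | None = None

    @property
    def n_changing(self) -> int:
        return len(self.increased) + len(self.decreased) + len(self.reversed)

    def counts(self) -> dict[str, int]:
        d = {
            "increased": len(self.increased),
            "decreased": len(self.decreased),
            "reversed": len(self.reversed),
            "turned_on": len(self.turned_on),
            "turned_off": len(self.turned_off),
            "unchanged": len(self.unchanged),
            "changing": self.n_changing,
        }
        if self.adjusted_decreased is not None:
            d["adjusted_decreased"] = len(self.adjusted_decreased)
        return d


def classify_transition(
    fluxes: FluxMatrix,
    transition: int,
    tol: float = ACTIVITY_TOL,
    change_tol: float = CHANGE_TOL,
) -> TransitionReport:
    """Classify every reaction active in phase ``transition`` or the next one."""
    cols = fluxes.phases
    if not (0 <= transition < len(cols) - 1):
        raise IndexError(f"transition {transition} out of range for {cols}")
    a, b = cols[transition], cols[transition + 1]
    tols = fluxes.activity_tolerances(tol)
    va, vb = fluxes.fluxes[a], fluxes.fluxes[b]
    act_a, act_b = va.abs() > tols[a], vb.abs() > tols[b]
    either = act_a | act_b

    inc, dec, rev, on, off, unch = set(), set(), set(), set(), set(), set()
    for rid in fluxes.fluxes.index[either]:
        x, y = va[rid], vb[rid]
        if act_a[rid] and act_b[rid] and np.sign(x) != np.sign(y):
            rev.add(rid)
            continue
        d = abs(y) - abs(x)
        if d > change_tol:
            inc.add(rid)
        elif d < -change_tol:
            dec.add(rid)
        else:
            unch.add(rid)
        if not act_a[rid] and act_b[rid]:
            on.add(rid)
        elif act_a[rid] and not act_b[rid]:
            off.add(rid)
    return TransitionReport(
        transition=f"{a}->{b}",
        increased=inc,
        decreased=dec,
        reversed=rev,
        turned_on=on,
        turned_off=off,
        unchanged=unch,
    )


def classify_all_transitions(
    fluxes: FluxMatrix, tol: float = ACTIVITY_TOL, change_tol: float = CHANGE_TOL
) -> list[TransitionReport]:
    reports = [
        classify_transition(fluxes, t, tol=tol, change_tol=change_tol)
        for t in range(len(fluxes.phases) - 1)
    ]
    return adjust_decreasing(reports)


def adjust_decreasing(reports: list[TransitionReport]) -> list[TransitionReport]:
    """Remove consistent decliners from every transition's decreased set.

    A *consistent decliner* decreases at every transition in which it is
    active (in either flanking phase) and decreases at least once — the
    signature of a flux merely tracking the declining growth rate rather than
    responding to a substrate switch.  Populates ``adjusted_decreased``.
    """
    candidates = set().union(*(r.decreased for r in reports)) if reports else set()
    consistent = set()
    for rid in candidates:
        ok = True
        for r in reports:
            involved = (
                rid in r.increased or rid in r.decreased or rid in r.reversed
                or rid in r.unchanged
            )
            if involved and rid not in r.decreased:
                ok = False
                break
        if ok:
            consistent.add(rid)
    for r in reports:
        r.adjusted_decreased = r.decreased - consistent
    return reports


def normalize_by_growth(fluxes: FluxMatrix) -> FluxMatrix:
    """Express each phase's fluxes as a fraction of its predicted growth rate.

    Columns with zero predicted growth are left as-is (all zero downstream of
    the FBA convention) and flagged via ``infeasible_phases`` untouched.
    """
    mu = fluxes.objective.reindex(fluxes.fluxes.columns)
    scale = mu.where(mu > 0)
    normed = fluxes.fluxes.div(scale, axis=1).fillna(fluxes.fluxes)
    zero_growth = [c for c in fluxes.fluxes.columns if not (mu[c] > 0)]
    normed[zero_growth] = fluxes.fluxes[zero_growth]
    return FluxMatrix(
        fluxes=normed,
        objective=fluxes.objective.copy(),
        method=fluxes.method,
        normalized=True,
        infeasible_phases=list(fluxes.infeasible_phases),
    )


def pathway_activity(
    fluxes: FluxMatrix, model: Model, tol: float = ACTIVITY_TOL
) -> pd.DataFrame:
    """Active-reaction counts per subsystem (pathway) per phase.

    Reactions without a subsystem label aggregate under ``"unassigned"``.
    """
    sub = pd.Series(
        {r.id: (r.subsystem or "unassigned") for r in model.reactions}, name="subsystem"
    )
    act = fluxes.active(tol)
    sub = sub.reindex(act.index).fillna("unassigned")
    out = act.groupby(sub).sum()
    out.index.name = "subsystem"
    return out


def write_transition_reports(reports: list[TransitionReport], path: str | Path) -> None:
    doc = [
        {
            "transition": r.transition,
            **{k: sorted(getattr(r, k)) for k in
               ("increased", "decreased", "reversed", "turned_on", "turned_off", "unchanged")},
            "adjusted_decreased": sorted(r.adjusted_decreased)
            if r.adjusted_decreased is not None else None,
        }
        for r in reports
    ]
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def transition_summary(reports: list[TransitionReport]) -> pd.DataFrame:
    """Count table per transition (the data series behind rewiring plots)."""
    return pd.DataFrame([r.counts() for r in reports],
                        index=[r.transition for r in reports])
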