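"""Per-phase uptake parameterization of a fed-batch growth curve.

A growth experiment on a complex medium (a mixture of amino acids serving as
carbon and energy sources) is divided into one-hour *phases*.  Phase ``i``
spans ``[t_{i-1}, t_i]``; the growth rate ``GR_i`` and the concentration
vector entering the uptake formula are taken at the phase start ``t_{i-1}``.

From optical density (OD), growth rate (mu, h^-1) and per-amino-acid molar
concentrations the module derives, per phase:

* ``delta_biomass_i`` (g/l) via a biomass-per-OD calibration;
* ``delta_conc[aa][i]`` (g/l) — the mass of each amino acid consumed, clamped
  at 0 when a concentration rises hour-to-hour (nutrient accumulation);
* ``yield_i = delta_biomass_i / sum_aa delta_conc[aa][i]`` (g biomass per g
  substrate carbon);
* the uptake flux bound for each amino acid::

      UF_aa^i = (conc_aa^i / sum_a conc_a^i) * (GR_i / yield_i)
                / (MW_aa * 1e-3)                      [mmol gDW^-1 h^-1]

  with the concentration ratio on mass concentrations (g/l), then multiplied
  by a per-phase scale constant.  By default the scale constant normalizes
  each phase's total carbon-mass uptake flux to a common reference so phases
  are comparable; explicit constants may be supplied instead.

Amino acids not consumed in a phase (``delta_conc = 0``) get ``UF = 0``.
Trailing phases with no growth and no uptake are dropped from the modelled
window by :func:`select_phases`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Calibration",
    "GrowthCurve",
    "PhaseParameterization",
    "ParameterizationError",
    "biomass_per_od",
    "compute_deltas",
    "compute_yield",
    "compute_uptake_fluxes",
    "select_phases",
    "parameterize",
]

_META_COLS = ("time_h", "OD", "mu_per_h")


class ParameterizationError(Exception):
    pass


@dataclass(frozen=True)
class Calibration:
    """Anchor converting optical density into dry-weight concentration."""

    dry_weight_g: float
    od_ref: float
    volume_l: float


def biomass_per_od(calibration: Calibration) -> float:
    """g/l of dry biomass per OD unit: ``dry_weight / (OD_ref * volume)``."""
    c = calibration
    if c.dry_weight_g <= 0 or c.od_ref <= 0 or c.volume_l <= 0:
        raise ParameterizationError(f"non-positive calibration values: {c}")
    return c.dry_weight_g / (c.od_ref * c.volume_l)


@dataclass
class GrowthCurve:
    """Time-indexed OD, growth rate and molar amino-acid concentrations.

    ``data`` holds one row per time point (``time_h``, ``OD``, ``mu_per_h``
    and one mM-concentration column per amino acid).  ``mu_per_h`` at row
    ``t`` is the growth rate over the hour starting at ``t``.
    """

    data: pd.DataFrame
    mw: dict[str, float]
    calibration: Calibration

    def __post_init__(self) -> None:
        missing = [c for c in _META_COLS if c not in self.data.columns]
        if missing:
            raise ParameterizationError(f"growth curve lacks columns {missing}")
        for aa in self.amino_acids:
            if aa not in self.mw:
                raise ParameterizationError(f"no molar weight for amino acid {aa!r}")
            if self.mw[aa] <= 0:
                raise ParameterizationError(f"non-positive MW for {aa!r}")
        t = self.data["time_h"].to_numpy()
        if not np.all(np.diff(t) > 0):
            raise ParameterizationError("time points must be strictly increasing")
        if (self.data[list(self.amino_acids)].to_numpy() < 0).any():
            raise ParameterizationError("negative concentration in growth curve")

    @property
    def amino_acids(self) -> list[str]:
        return [c for c in self.data.columns if c not in _META_COLS]

    @property
    def n_phases(self) -> int:
        return len(self.data) - 1

    def mass_conc(self) -> pd.DataFrame:
        """Mass concentrations (g/l) per time point: mM * MW * 1e-3."""
        aas = self.amino_acids
        mw = pd.Series({aa: self.mw[aa] for aa in aas})
        return self.data[aas] * mw * 1e-3

    # -- persistence --------------------------------------------------------

    def write(self, csv_path: str | Path, meta_path: str | Path | None = None) -> None:
        csv_path = Path(csv_path)
        self.data.to_csv(csv_path, index=False, float_format="%.10g")
        meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".meta.json")
        meta = {
            "mw": {aa: self.mw[aa] for aa in sorted(self.mw)},
            "calibration": {
                "dry_weight_g": self.calibration.dry_weight_g,
                "od_ref": self.calibration.od_ref,
                "volume_l": self.calibration.volume_l,
            },
        }
        meta_path.write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")

    @classmethod
    def read(cls, csv_path: str | Path, meta_path: str | Path | None = None) -> "GrowthCurve":
        csv_path = Path(csv_path)
        meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".meta.json")
        data = pd.read_csv(csv_path)
        meta = json.loads(meta_path.read_text())
        cal = Calibration(**meta["calibration"])
        return cls(data=data, mw=dict(meta["mw"]), calibration=cal)


# ---------------------------------------------------------------------------
# Deltas and yields
# ---------------------------------------------------------------------------

def compute_deltas(curve: GrowthCurve) -> pd.DataFrame:
    """Per-phase biomass increment and clamped substrate consumption (g/l).

    Returns a frame indexed by phase 1..n with a ``delta_biomass`` column and
    one column per amino acid.  Consumption is ``max(0, c(t_{i-1}) - c(t_i))``
    on mass concentrations: an hour-to-hour rise (nutrient accumulation)
    counts as zero consumption.
    """
    if len(curve.data) < 2:
        raise ParameterizationError("need at least two time points")
    bpo = biomass_per_od(curve.calibration)
    biomass = curve.data["OD"].to_numpy() * bpo
    mass = curve.mass_conc().to_numpy()
    phases = np.arange(1, len(curve.data))
    out = pd.DataFrame(index=pd.Index(phases, name="phase"))
    out["delta_biomass"] = np.diff(biomass)
    consumed = np.maximum(0.0, mass[:-1] - mass[1:])
    for j, aa in enumerate(curve.amino_acids):
        out[aa] = consumed[:, j]
    return out


def compute_yield(deltas: pd.DataFrame, tol: float = 1e-12) -> pd.Series:
    """Per-phase yield: biomass increment over total substrate mass consumed.

    Phases with no biomass increase get yield 0; a phase with biomass gain but
    zero total consumption is unparameterizable and gets NaN.
    """
    aas = [c for c in deltas.columns if c != "delta_biomass"]
    total = deltas[aas].sum(axis=1)
    db = deltas["delta_biomass"]
    y = pd.Series(0.0, index=deltas.index, name="yield")
    ok = total > tol
    y[ok] = db[ok] / total[ok]
    y[(~ok) & (db > tol)] = np.nan
    y[y < 0] = 0.0
    return y


def compute_uptake_fluxes(
    curve: GrowthCurve,
    yields: pd.Series,
    deltas: pd.DataFrame,
    scaling: str | Sequence[float] = "normalize",
    target_mass_flux: float = 1.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Uptake-flux bounds (mmol gDW^-1 h^-1) per amino acid and phase.

    ``scaling`` is ``"normalize"`` (per-phase constant bringing the total
    carbon-mass uptake flux to ``target_mass_flux`` g gDW^-1 h^-1),
    ``"none"`` (all constants 1), or an explicit sequence of per-phase
    constants.  Returns ``(UF frame, scale constants)``.
    """
    aas = curve.amino_acids
    mw = np.array([curve.mw[aa] for aa in aas])
    mass = curve.mass_conc().to_numpy()
    mu = curve.data["mu_per_h"].to_numpy()
    phases = deltas.index.to_numpy()
    uf = pd.DataFrame(0.0, index=deltas.index, columns=aas)
    unparameterizable: list[int] = []
    for i in phases:
        start = i - 1  # row at phase start
        conc = mass[start]
        gr = mu[start]
        if gr <= 0:
            continue
        y = yields.loc[i]
        if not np.isfinite(y) or y <= 0:
            unparameterizable.append(int(i))
            continue
        total = conc.sum()
        if total <= 0:
            continue
        frac = conc / total
        row = frac * (gr / y) / (mw * 1e-3)
        # formula uses concentrations; the consumption clamp decides activity
        row[deltas.loc[i, aas].to_numpy() <= 0] = 0.0
        uf.loc[i] = row
    if unparameterizable:
        raise ParameterizationError(
            f"phases {unparameterizable} have growth but zero/undefined yield; "
            "cannot derive uptake fluxes"
        )
    if isinstance(scaling, str):
        if scaling == "none":
            scales = pd.Series(1.0, index=deltas.index, name="scale")
        elif scaling == "normalize":
            mass_flux = (uf * mw * 1e-3).sum(axis=1)
            scales = pd.Series(
                np.where(mass_flux > 0, target_mass_flux / mass_flux.replace(0, np.nan), 1.0),
                index=deltas.index,
                name="scale",
            ).fillna(1.0)
        else:
            raise ParameterizationError(f"unknown scaling mode {scaling!r}")
    else:
        scales = pd.Series(list(scaling), index=deltas.index, name="scale", dtype=float)
    return uf.mul(scales, axis=0), scales


def select_phases(
    curve: GrowthCurve, deltas: pd.DataFrame, tol: float = 1e-9
) -> list[int]:
    """Drop trailing phases with neither growth nor substrate uptake.

    Only a contiguous tail is removed (a dead phase in the middle of the
    experiment is retained).  Raises if nothing remains.
    """
    aas = curve.amino_acids
    mu = curve.data["mu_per_h"].to_numpy()
    alive = []
    for i in deltas.index:
        dead = mu[i - 1] <= tol and deltas.loc[i, aas].sum() <= tol
        alive.append(not dead)
    last = max((k for k, a in enumerate(alive) if a), default=None)
    if last is None:
        raise ParameterizationError("all phases are growthless with no uptake")
    return list(deltas.index[: last + 1])


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

@dataclass
class PhaseParameterization:
    """Per-phase growth rate, yield, scale constant and uptake-flux bounds."""

    table: pd.DataFrame  # index: phase; columns GR, yield, delta_biomass, scale
    uf: pd.DataFrame  # index: phase; one column per amino acid
    mw: dict[str, float] = field(default_factory=dict)

    @property
    def phases(self) -> list[int]:
        return list(self.table.index)

    @property
    def amino_acids(self) -> list[str]:
        return list(self.uf.columns)

    def write_tsv(self, path: str | Path) -> None:
        out = self.table.join(self.uf.add_prefix("UF_"))
        out.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PhaseParameterization":
        df = pd.read_csv(path, sep="\t", index_col=0)
        ufcols = [c for c in df.columns if c.startswith("UF_")]
        uf = df[ufcols].rename(columns=lambda c: c[3:])
        return cls(table=df.drop(columns=ufcols), uf=uf)


def parameterize(
    curve: GrowthCurve,
    scaling: str | Sequence[float] = "normalize",
    target_mass_flux: float = 1.0,
    restrict: bool = True,
) -> PhaseParameterization:
    """Full parameterization: deltas, yields, uptake fluxes, phase selection."""
    deltas = compute_deltas(curve)
    yields = compute_yield(deltas)
    uf, scales = compute_uptake_fluxes(
        curve, yields, deltas, scaling=scaling, target_mass_flux=target_mass_flux
    )
    mu = pd.Series(
        curve.data["mu_per_h"].to_numpy()[:-1], index=deltas.index, name="GR"
    )
    table = pd.DataFrame(
        {
            "GR": mu,
            "yield": yields,
            "delta_biomass": deltas["delta_biomass"],
            "scale": scales,
        }
    )
    if restrict:
        keep = select_phases(curve, deltas)
        table = table.loc[keep]
        uf = uf.loc[keep]
    return PhaseParameterization(
        table=table, uf=uf, mw={aa: curve.mw[aa] for aa in curve.amino_acids}
    )
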