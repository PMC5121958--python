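"""Turn the growth curve into per-phase yields and uptake-flux bounds."""

from phaseflux import (
    Calibration,
    SyntheticScenario,
    biomass_per_od,
    make_growth_curve,
    parameterize,
)

bpo = biomass_per_od(Calibration(dry_weight_g=1.28, od_ref=3.8, volume_l=1.4))
print(f"biomass per OD unit from the calibration anchor: {bpo:.4f} g/l")

curve = make_growth_curve(SyntheticScenario(seed=1))
params = parameterize(curve)

print(f"\nmodelled phases (trailing dead phases dropped): {params.phases}")
print("\nper-phase growth rate, yield and scale constant:")
print(params.table.round(4).to_string())
print("\nuptake-flux bounds (mmol/gDW/h) per amino acid:")
print(params.uf.round(3).to_string())
print()
print("A zero column entry means the substrate was depleted or transiently")
print("accumulating in that phase (consumption clamped to zero); the scale")
print("constant normalizes each phase's total mass uptake to 1 g/gDW/h so")
print("fluxes are comparable across phases.")
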