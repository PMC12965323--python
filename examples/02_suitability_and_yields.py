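"""Classify multiple-cropping suitability and build annual yield tables.

A cell supports multiple cropping under a water regime when at least
nine months have grass GPP above 100 g C m^-2 (about 2.2 t DM/ha).  The
off-season yield of each crop scales its main-season yield by the
off/main-season ratio of grass GPP, dampened by 25% for turnaround
losses; annual multiple-cropping yield is main + off-season.
"""

from multicrop import (
    build_yield_table,
    calibrate_yields,
    classify_suitability,
    generate_world,
    gpp_threshold_in_dm,
)

world = generate_world(seed=1, n_cells=100, n_basins=6)

print(f"GPP threshold in dry matter: {gpp_threshold_in_dm(100.0, 0.45):.2f} t DM/ha")

suitable = classify_suitability(world.gpp)
n_rf = int(suitable.sel(regime="rainfed").sum())
n_ir = int(suitable.sel(regime="irrigated").sum())
print(f"suitable cells: {n_rf} rainfed, {n_ir} irrigated (of {world.n_cells})")
# Irrigated suitability always contains rainfed suitability: irrigation
# removes the dry-season water limitation, never the thermal one.

table = build_yield_table(world, suitable)
table, factors = calibrate_yields(table, world, world.reported_yield)
mean_single = float(table["y_annual_single"].mean())
mean_mc = float(table["y_annual_mc"].mean())
print(f"mean annual yield: single {mean_single:.2f} t DM/ha, "
      f"multiple cropping {mean_mc:.2f} t DM/ha")
print("country calibration factors (reported / modeled):")
print(factors.round(3).to_string())
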