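"""Heat stress index for single days and for a gridded climate field.

The HSI is the NWS heat index expressed in degC: Steadman's simple formula
on mild days, the Rothfusz regression with humidity adjustments on hot ones.
"""

import heatrisk as hr

for t, rh in [(26.0, 50.0), (35.56, 50.0), (38.0, 10.0), (28.0, 90.0)]:
    v = hr.heat_index_point(t, rh)
    print(f"T={t:5.2f} degC  RH={rh:4.0f}%  ->  HSI={v.hsi:6.2f} degC  ({v.branch.value})")

# a month of gridded synthetic climate -> HSI field
grid = hr.GridDef(30.0, 30.5, 110.0, 110.5)
clim = hr.gen_climate(grid, hr.SCENARIOS["ssp245"], (2010, 2010), seed=1)
hsi = hr.hsi_grid(clim)
july = hsi.sel(time="2010-07")
print(f"\nJuly 2010 HSI over a 2x2 grid: mean {float(july.mean()):.1f} degC, "
      f"max {float(july.max()):.1f} degC")
print("Humid heat reads hotter than dry heat at the same temperature —")
print("compare the 38 degC/10% row (dry adjustment) with the humid rows above.")
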