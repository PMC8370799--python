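"""Terrain indices from a bathymetry grid, and export flux from NPP.

Derives slope (Horn), terrain ruggedness (Wilson TRI) and topographic
position (TPI) from a synthetic 1 m bathymetry grid, and converts a
monthly surface NPP series into depth-attenuated export flux at the
seafloor.
"""

import numpy as np

from seepbef import (
    annual_npp, export_flux, generate_bathymetry, slope_grid, tpi_grid, tri_grid,
)

grid = generate_bathymetry(40, 40, cell_size_m=1.0, roughness=2.0, seed=7)
print(f"depth range: {grid.values.min():.1f} - {grid.values.max():.1f} m")
print(f"median slope: {np.median(slope_grid(grid).values):.2f} deg")
print(f"median TRI:   {np.median(tri_grid(grid).values):.3f} m  (local relief)")
print(f"TPI spread:   {tpi_grid(grid).values.std():.3f} m  "
      "(+ = local high, - = local depression)")

monthly = 350 + 150 * np.sin(2 * np.pi * (np.arange(12) - 2) / 12)
npp_year = annual_npp(monthly)
print(f"\nannual NPP: {npp_year:.0f} mg C m^-2 yr^-1")
for depth in (400, 1000, 1900):
    f = export_flux(npp_year, depth, prd=0.4, rld=400.0, prr=0.01)
    print(f"export flux at {depth:>4} m: {f:7.1f} mg C m^-2 yr^-1 "
          f"({100 * f / npp_year:.1f}% of surface production)")
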