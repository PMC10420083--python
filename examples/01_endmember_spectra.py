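"""Build a flower/leaf/soil endmember library and resample it to sensor bands.

The printed 6x3 matrix is the linear-mixing matrix E: one row per UAV band
(490/550/670/720/800/900 nm), one column per endmember (FL, LF, SL).  Note
the flowering-canopy signature: the FL column exceeds LF in the green and
red rows but falls below it in the NIR rows.
"""

import numpy as np

from rapeyield import build_endmember_matrix, generate_endmember_library, uav6

library = generate_endmember_library(seed=1)
sensor = uav6()
E = build_endmember_matrix(library, sensor)

print("band (nm)   FL      LF      SL")
for band, row in zip(sensor.bands, E.values):
    print(f"{band.center_nm:7.0f}   " + "  ".join(f"{v:.4f}" for v in row))

green, red, nir = (sensor.band_index(r) for r in ("green", "red", "nir1"))
print(f"\nflower brighter than leaf in green? {E.values[green, 0] > E.values[green, 1]}")
print(f"flower brighter than leaf in red?   {E.values[red, 0] > E.values[red, 1]}")
print(f"flower darker than leaf in NIR?     {E.values[nir, 0] < E.values[nir, 1]}")
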