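"""Physical constants and unit conversion factors.

All geometric quantities are stored in nanometres throughout the package;
conversion to SI happens only inside physics formulas (Stokes-Einstein,
the flow solver).  Velocities are exposed in um/s, the unit the capillary
literature uses.
"""

BOLTZMANN_J_PER_K = 1.380649e-23

NM_PER_M = 1e9
M_PER_NM = 1e-9

UM_S_PER_M_S = 1e6  # m/s -> um/s
M_S_PER_UM_S = 1e-6

NM3_PER_UM3 = 1e9
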