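"""The pH-sensor net-charge switch, from tabulated macroscopic pKa values.

Reconstructs the expected net charge of the ten residues at the cytoplasmic
funnel entrance of NhaA (eight titratable sites at their tabulated
macroscopic pKa's plus two arginines fixed at +1) as a function of pH,
assuming independent-site titration.  The charge falls from a positive
plateau at acidic pH to a negative one at basic pH; the zero crossing marks
the electrostatic switch that lets the funnel attract a sodium ion.
"""

import numpy as np

from cphmc import find_sign_switch_ph, reconstruct_net_charge
from cphmc.nhaa import FIXED_ARGININES, NHAA_PKA_TABLE, PH_SENSOR_SITES

table = {name: NHAA_PKA_TABLE[name] for name in PH_SENSOR_SITES}

for ph in (3.5, 5.0, 6.5, 7.0, 8.0, 9.5):
    q = reconstruct_net_charge(table, FIXED_ARGININES, ph)
    print(f"pH {ph:4.1f}  net charge {q:+.2f} e")

grid = np.arange(3.5, 9.5001, 0.05)
charge = reconstruct_net_charge(table, FIXED_ARGININES, grid)
switch = find_sign_switch_ph(grid, charge)
print(f"\nsign switch at pH {switch:.2f}")
print("(+ at acidic pH repels cations; the switch to - near neutral pH "
      "coincides with the transporter's activation range)")
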