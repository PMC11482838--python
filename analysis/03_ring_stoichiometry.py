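"""Concentric-ring stoichiometry and symmetry-mismatch registration.

Three pieces of arithmetic that tie the disk lattice together:
17 asymmetric units x 3 protomers = 51 first-ring protomers; the
circumference-ratio model predicts +11 protomers per concentric ring when
the radial pitch is 11 arc widths / 2 pi; and a 51-protomer ring against a
C17 scaffold contacts every third protomer at 17 sites, while a 26-fold
ring is incommensurate with C17.
"""

import os

import numpy as np
import pandas as pd

from motorsym.rings import predict_ring_counts, register, ring_from_asymmetric_unit

os.makedirs("results", exist_ok=True)

n1 = ring_from_asymmetric_unit(17, 3)
print(f"17 asymmetric units x 3 protomers = {n1} first-ring protomers")

r1 = 400.0
w = 2 * np.pi * r1 / n1
dr = 11 * w / (2 * np.pi)
radii = [r1 + k * dr for k in range(10)]
counts, increments = predict_ring_counts(n1, r1, radii)
pd.DataFrame({"ring": range(1, 11), "radius_A": radii, "protomers": counts}).to_csv(
    "results/ring_counts.csv", index=False
)
print(f"ring counts over 10 rings: {counts}")
print(f"increments: {sorted(set(increments))} (radial pitch {dr:.2f} Å, arc width {w:.2f} Å)")

rows = []
for n_ring, n_scaf in [(51, 17), (26, 17), (38, 17)]:
    reg = register(n_ring, n_scaf)
    rows.append(
        dict(n_ring=n_ring, n_scaffold=n_scaf, period=reg.period,
             contacts=reg.contacts, incommensurate=reg.incommensurate)
    )
    tag = "incommensurate" if reg.incommensurate else f"every {reg.period}th protomer, {reg.contacts} contacts"
    print(f"register({n_ring}, C{n_scaf}): {tag}")
pd.DataFrame(rows).to_csv("results/registration.csv", index=False)
print("tables -> results/ring_counts.csv, results/registration.csv")
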