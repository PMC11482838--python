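"""Count rotational dwell positions from simulated bead trajectories.

Simulates a 26-dwell stepping motor at several de-energization levels
(emulating a CCCP titration), runs each trace through the full pipeline
(ellipse fit, angle extraction, occupancy-weighted circular KDE, weighted
power spectrum, harmonic argmax), and checks that the dwell phase is
invariant across conditions.
"""

import os

import pandas as pd

from motorsym.bead import (
    circular_kde,
    count_steps,
    count_steps_from_trajectory,
    fit_ellipse,
    phase_invariance,
    step_spectrum,
    to_angle,
)
from motorsym.beadsim import BeadSimSpec, simulate_bead

os.makedirs("results", exist_ok=True)
os.makedirs("scratch", exist_ok=True)

conditions = [(1.0, "cccp_0uM"), (0.5, "cccp_1uM"), (0.2, "cccp_5uM")]
traces, densities, rows = [], [], []
for factor, label in conditions:
    spec = BeadSimSpec(n_dwells=26, deenergization_factor=factor,
                       duration=30.0, seed=20231009)
    traj = simulate_bead(spec, condition=label)
    traj.to_csv(f"scratch/trace_{label}.csv")
    call, spectrum, trace = count_steps_from_trajectory(traj)
    traces.append(trace)
    densities.append(circular_kde(trace))
    rows.append(dict(condition=label, deenergization=factor,
                     revolutions=trace.revolutions, n_steps=call.n,
                     confidence=call.confidence))
    print(f"{label:10s} ({trace.revolutions:6.1f} rev): {call.n} dwell positions "
          f"(confidence {call.confidence:.0f})")

combined = step_spectrum(traces)
pooled = count_steps(combined)
phase = phase_invariance(densities, n_dwells=pooled.n or 26)
print(f"pooled spectrum over {len(traces)} traces: {pooled.n} dwell positions")
print(f"phase invariance across conditions: max lag {phase.max_lag:.4f} rad "
      f"(< pi/{phase.n_dwells} = {3.141592653589793 / phase.n_dwells:.4f}) -> "
      f"{'phase-invariant' if phase.passes else 'phase shift detected'}")

pd.DataFrame(rows).to_csv("results/bead_calls.csv", index=False)
pd.DataFrame({"m": combined.m, "power": combined.power}).to_csv(
    "results/bead_spectrum.csv", index=False
)
print("tables -> results/bead_calls.csv, results/bead_spectrum.csv")
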