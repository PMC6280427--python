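#!/usr/bin/env python
"""Simulate the study system: tracked shearwaters, a VMS-monitored fleet,
and on-board accelerometers, with complete planted ground truth.

Writes the GPS and native-VMS streams plus a truth summary under
results/analysis/.  The 25 Hz accelerometer streams are synthesised on
demand by the later stages from the same seed (they are deterministic),
so this driver stays light on disk.
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from vesselbird.geo import write_bird_gps, write_vessel_pings
from vesselbird.simulate import SimConfig, SimDataset

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "analysis")
SEED = 1


def main():
    os.makedirs(OUT, exist_ok=True)
    cfg = SimConfig(seed=SEED)
    sim = SimDataset(cfg)
    write_bird_gps(sim.fixes, os.path.join(OUT, "bird_gps.csv"))
    write_vessel_pings(sim.native_pings, os.path.join(OUT, "vms_native.csv"))
    sim.truth.trips.to_csv(os.path.join(OUT, "truth_trips.csv"), index=False)
    print(f"simulated {cfg.n_birds} birds x {cfg.days} days with "
          f"{cfg.n_vessels} vessels (seed {SEED})")
    print(f"  {len(sim.fixes)} GPS fixes, {len(sim.native_pings)} native pings")
    print(f"  planted: {len(sim.truth.trips)} complete trips, "
          f"{len(sim.truth.diversions)} vessel attendances, "
          f"{len(sim.truth.interactions)} interaction events, "
          f"true interaction distance {sim.truth.true_interaction_km} km")


if __name__ == "__main__":
    main()
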