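#!/usr/bin/env python
"""Supervised ligand entrance through the widest gate.

Starts the ligand in the membrane just outside the widened TM1–TM7 gate,
tail first, and runs distance-supervised dynamics: unbiased slices that
are kept only if the ligand–pocket distance improves, otherwise restarted
from the checkpoint with fresh velocities (tabu seeds).  The run then
switches to plain dynamics to confirm the entered pose is stable, the
standard endgame of supervised entrance protocols.

Writes the attempt log, distance series and energy profile to
results/sumd_entrance/; the full trajectory goes under scratch/
(regenerable by re-running this script).
"""

import shutil
from pathlib import Path

import numpy as np

from ligandpath import switch_to_plain_md, widened_layout
from ligandpath.pipeline import RunConfig, SMDParams, SuMDParams, run_sumd
from ligandpath.sumd import ligand_site_distance

OUT = Path("results/sumd_entrance")
RUNDIR = Path("scratch/sumd_entrance")


def main() -> None:
    cfg = RunConfig(
        layout=widened_layout(),
        sumd=SuMDParams(arrival_radius=4.0, slice_length=100, epsilon=0.1,
                        max_consecutive_rejects=100, max_total_steps=400_000,
                        start_site="outside_gate", start_direction="TM1-TM7",
                        orientation="tail_first"),
        seed=11, outdir=str(RUNDIR))
    result = run_sumd(cfg, make_plots=False)
    OUT.mkdir(parents=True, exist_ok=True)
    for name in ("attempt_log.csv", "distance_series.csv",
                 "energy_profile.csv", "manifest.json"):
        shutil.copy(RUNDIR / name, OUT / name)
    print(f"termination: {result.termination} after {result.total_steps} steps "
          f"({result.restart_count} restarts, "
          f"{int(result.attempts['accepted'].sum())} accepted slices)")
    print(f"ligand–pocket distance: {result.distances[0]:.2f} Å -> "
          f"{result.distances[-1]:.2f} Å")

    if result.termination == "arrived":
        traj = switch_to_plain_md(result, 5000, seed=99)
        n0 = result.trajectory.n_frames
        d = [ligand_site_distance(result.system, f, cfg.sumd.site_center
                                  or (0, 0, 0))
             for f in traj.frames[n0:]]
        verdict = ("remains inside the helix ring"
                   if max(d) < result.system.layout.helix_radius
                   else "wanders back into the gate channel")
        print(f"plain-MD continuation (50 ps): ligand–pocket distance spans "
              f"{min(d):.2f}–{max(d):.2f} Å — {verdict}")


if __name__ == "__main__":
    main()
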