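#!/usr/bin/env python
"""Generate the study's synthetic datasets and write them to results/data/.

Produces, with known ground truth:
  * four NIR concentration series (GSH, GSSG, NADH, NAD+; 1-10 mM,
    25 replicates per level) as spectra CSVs with ground-truth sidecars;
  * the paired GSH:GSSG mixture series (1:4.5 ... 9:0.5 mM);
  * one thiol-like and one disulfide-like solvation trajectory
    (XYZ + topology JSON + hydrogen-bond schedule CSV).
"""

import argparse
from pathlib import Path

from aquaredox import spectra_core as core
from aquaredox import synthetic_spectra as synth
from aquaredox import synthetic_trajectory as straj


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    for i, name in enumerate(("GSH", "GSSG", "NADH", "NAD+")):
        design = synth.ExperimentDesign(
            analytes=(synth.SIGNATURES[name],), seed=args.seed + i)
        sset, truth = synth.generate_spectra_set(design)
        tag = name.replace("+", "plus")
        core.write_spectra_table(sset, out / f"series_{tag}.csv")
        truth.per_sample.to_csv(out / f"series_{tag}.truth.csv", index=False)
        print(f"{name}: {sset.n_samples} spectra x {sset.n_channels} channels")

    mix, Y = synth.generate_mixture_set(seed=args.seed + 10)
    core.write_spectra_table(mix, out / "mixtures_GSH_GSSG.csv")
    print(f"mixtures: {mix.n_samples} spectra, "
          f"GSH {Y[:, 0].min():g}-{Y[:, 0].max():g} mM paired with "
          f"GSSG {Y[:, 1].min():g}-{Y[:, 1].max():g} mM")

    for kind, seed_off in (("thiol", 20), ("disulfide", 21)):
        traj, sched = straj.generate_solvation_trajectory(
            kind, n_waters=200, n_frames=500, seed=args.seed + seed_off)
        straj.write_xyz(traj, out / f"{kind}.xyz")
        straj.write_topology(traj, out / f"{kind}.topology.json")
        straj.write_schedule(sched, out / f"{kind}.schedule.csv")
        print(f"{kind}: {traj.n_frames} frames, {traj.topology.n_atoms} atoms, "
              f"{len(sched.intervals)} scheduled H-bond intervals")


if __name__ == "__main__":
    main()
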