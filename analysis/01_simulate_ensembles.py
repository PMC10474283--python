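"""Generate the synthetic study ensembles with known ground truth.

Produces the four inputs every later stage consumes: the two-state
hinge trajectory (85°/118°, weights 0.7/0.3, 2000 frames over 500 ns),
a 60%-bound ligand trajectory, a half-occupied hydration site, and a
membrane-anchored system.  Ensembles are written in the multi-frame
XYZ dialect under results/data/ together with their ground truth.
"""

from pathlib import Path

import numpy as np

import hingescape as hs
from hingescape.synthetic import (
    HingeEnsembleSpec,
    hinge_topology,
    make_anchor_foot_protein,
    make_hinge_ensemble,
    make_hydrated_site,
    make_ligand_trajectory,
    make_membrane_system,
)

SEED = 0
OUT = Path(__file__).resolve().parents[1] / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)


def save(name, ens):
    (OUT / f"{name}.xyz").write_text(hs.write_xyz(ens))
    print(f"  wrote {name}.xyz: {ens.n_frames} frames × {ens.n_atoms} atoms")


print("Hinge ensemble (closed 85° / open 118°, weights 0.7/0.3):")
ens, truth = make_hinge_ensemble(HingeEnsembleSpec(seed=SEED))
save("hinge", ens)
rows = ["# frame\tstate\tangle_deg"] + [
    f"{i}\t{s}\t{a:.4f}" for i, (s, a) in
    enumerate(zip(truth.state_labels, truth.angles))]
(OUT / "hinge_truth.tsv").write_text("\n".join(rows) + "\n")
counts = np.bincount(truth.state_labels)
print(f"  drawn state fractions: {counts[0]/len(truth.state_labels):.3f} closed, "
      f"{counts[1]/len(truth.state_labels):.3f} open")

print("Ligand trajectory (bound in 60% of frames):")
top = hinge_topology()
lig, ltruth = make_ligand_trajectory(top, 0.6, n_frames=100, seed=SEED)
save("ligand", lig)
print(f"  designated residue: {ltruth.designated_residue}")

print("Hydration site (occupancy 0.5):")
wet, wtruth = make_hydrated_site(top, 0.5, n_frames=40, seed=SEED)
save("water", wet)

print("Membrane system (LEU/SER foot anchors):")
mem, mtruth = make_membrane_system(make_anchor_foot_protein(), {1, 2},
                                   n_frames=20, seed=SEED)
save("membrane", mem)
print("Done; later stages read results/data/*.xyz")
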