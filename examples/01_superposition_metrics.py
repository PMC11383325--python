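"""RMSD, per-domain RMSD and RMSF on a synthetic two-domain ensemble.

Builds a 50-residue Cα helix, samples an anticorrelated two-domain Gaussian
ensemble, and prints the deviation/fluctuation metrics.  The planted
per-residue fluctuation is 0.08 nm, so the RMSF column should hover there.
"""

import numpy as np

import ensemblekit as ek

base = ek.make_toy_structure(50, "ideal-helix")
spec = ek.FactorModelSpec(
    residues_per_domain=(25, 25),
    factor_correlation=np.array([[1.0, -0.8], [-0.8, 1.0]]),
    n_frames=1000, seed=11)
traj, truth = ek.sample_ensemble(spec, base)
dmap = spec.domain_map()

series = ek.rmsd_series(traj, fit_selection=ek.AtomSelection.ca())
print(f"RMSD(t) vs frame 1: mean {series.values.mean():.3f} nm, "
      f"max {series.values.max():.3f} nm")
# each frame is an independent Gaussian draw, so RMSD fluctuates around a
# plateau instead of drifting like a real trajectory would

for name in dmap.names:
    dom = ek.domain_rmsd_series(traj, None, dmap, name)
    print(f"domain {name}: local RMSD mean {dom.values.mean():.3f} nm "
          "(internal deformation only; rigid-body motion removed)")

res_ids, rmsf = ek.rmsf_per_residue(traj, superpose=False)
print(f"RMSF: mean {rmsf.mean():.4f} nm (planted sigma = "
      f"{truth.rmsf.mean():.4f} nm), max |error| "
      f"{np.abs(rmsf - truth.rmsf).max():.4f} nm")

matrix = ek.pairwise_rmsd_matrix(traj, fit_selection=ek.AtomSelection.ca(),
                                 stride=100)
print(f"all-to-all RMSD matrix ({matrix.shape[0]} frames): "
      f"off-diagonal mean {matrix[np.triu_indices_from(matrix, 1)].mean():.3f} nm")
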