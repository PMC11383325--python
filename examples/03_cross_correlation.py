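"""Dynamic cross-correlation and domain coupling scores.

The generator plants an inter-domain correlation of −0.8; the estimated
DCCM inter-domain block should average close to that, and the accumulated
domain score matrix shows the same coupling at domain resolution.
"""

import numpy as np

import ensemblekit as ek

base = ek.make_toy_structure(50, "ideal-helix")
spec = ek.FactorModelSpec(
    residues_per_domain=(25, 25),
    factor_correlation=np.array([[1.0, -0.8], [-0.8, 1.0]]),
    n_frames=5000, seed=37)
traj, truth = ek.sample_ensemble(spec, base)
dmap = spec.domain_map()

cov = ek.build_covariance(traj, superpose=False)
dccm = ek.compute_dccm(cov)
inter = dccm.matrix[:25, 25:]
print(f"mean inter-domain correlation {inter.mean():.3f} (planted -0.800)")

scores = ek.residue_scores(dccm, dmap)
r1 = int(dccm.residue_ids[0])
print(f"residue {r1}: total score {scores.cs_total(r1):.2f} = "
      f"intra {scores.cs_intra(r1):.2f} + inter(B) {scores.cs_inter(r1, 'B'):.2f}")

for norm in ("raw-sum", "per-residue-pair"):
    dsm = ek.domain_score_matrix(scores, dmap, normalization=norm)
    print(f"domain score matrix ({norm}):")
    print(dsm.to_frame().round(3).to_string())
# raw sums scale with domain size (25x25 pairs); the per-pair entries are
# mean correlations and land near the planted ±0.8 / 1.0 block values
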