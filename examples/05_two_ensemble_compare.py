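"""Wild-type-vs-mutant style comparison of two synthetic ensembles.

Two ensembles with different planted inter-domain couplings (−0.8 vs −0.3)
are written to disk, analysed with identical settings, and differenced.
The DCCM difference map's inter-domain block should average ≈ −0.5.
"""

import tempfile
from pathlib import Path

import numpy as np

import ensemblekit as ek
from ensemblekit.domains import write_domain_map
from ensemblekit.reporting import RunConfig, run_compare

workdir = Path(tempfile.mkdtemp(prefix="ensemblekit_compare_"))
base = ek.make_toy_structure(50, "ideal-helix", with_backbone=True,
                             with_polar_hydrogens=True)
configs = []
for label, seed, r12 in (("WT", 1, -0.8), ("MT", 2, -0.3)):
    spec = ek.FactorModelSpec(
        residues_per_domain=(25, 25),
        factor_correlation=np.array([[1.0, r12], [r12, 1.0]]),
        n_frames=500, seed=seed)
    traj, _ = ek.sample_ensemble(spec, base)
    d = workdir / label.lower()
    d.mkdir()
    ek.write_structure(base, d / "structure.pdb")
    ek.write_trajectory(traj, d / "trajectory.xyz", dialect="xyz-table")
    write_domain_map(spec.domain_map(), d / "domains.yaml")
    configs.append(RunConfig(
        structure=str(d / "structure.pdb"),
        trajectory=str(d / "trajectory.xyz"),
        trajectory_dialect="xyz-table",
        domain_map=str(d / "domains.yaml"),
        out_dir=str(d / "out"), label=label, superpose=False,
        hbond_stride=10, sasa_stride=50))

report = run_compare(configs[0], configs[1], out_dir=workdir / "cmp")
print(f"outputs under {report.out_dir}")
for result in report.results:
    print(f"  {result.label}: {len(result.manifest['files'])} files")
diff = report.diff_tables["dccm"].matrix
print(f"DCCM difference inter-domain mean {diff[:25, 25:].mean():.3f} "
      "(planted -0.8 minus -0.3 = -0.5)")
print("paired RMSF head:")
print(report.diff_tables["rmsf"].head(3).round(4).to_string(index=False))
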