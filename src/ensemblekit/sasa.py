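"""Solvent-accessible surface area by Shrake–Rupley point sampling.

Each atom is expanded by the probe radius and covered with a deterministic
golden-spiral point set; points inside any neighbouring expanded sphere are
inaccessible.  The atom's accessible area is ``4π(r+r_probe)²`` times its
accessible point fraction; per-residue areas are sums over the residue's
atoms and add up to the total exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import UnknownElementError
from .structure import AtomSelection, StructureModel, TrajectoryEnsemble
from .superpose import MetricSeries

#: van der Waals radii (nm) used for SASA
VDW_RADII_NM = {
    "H": 0.110,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "S": 0.180,
    "P": 0.180,
}

DEFAULT_PROBE_RADIUS = 0.14   # nm, water probe
DEFAULT_N_POINTS = 960


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral unit sphere points, shape (n, 3)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def atom_radii(structure: StructureModel, indices: np.ndarray) -> np.ndarray:
    radii = np.empty(len(indices))
    for k, i in enumerate(indices):
        el = str(structure.elements[i])
        if el not in VDW_RADII_NM:
            raise UnknownElementError(
                f"no van der Waals radius for element {el!r} "
                f"(atom serial {int(structure.serials[i])}, "
                f"name {structure.atom_names[i]})"
            )
        radii[k] = VDW_RADII_NM[el]
    return radii


def sasa_frame(coords: np.ndarray, structure: StructureModel,
               probe_radius: float = DEFAULT_PROBE_RADIUS,
               n_sphere_points: int = DEFAULT_N_POINTS,
               selection: AtomSelection | None = None):
    """SASA of one frame: ``(total_nm2, per_residue, per_atom)``.

    ``per_residue`` is a pandas Series indexed by residue id; per-residue
    areas sum to the total by construction.  Heavy atoms are used by default.
    """
    coords = np.asarray(coords, dtype=float)
    idx = (selection or AtomSelection.heavy()).indices(structure)
    pos = coords[idx]
    radii = atom_radii(structure, idx) + probe_radius
    unit = sphere_points(n_sphere_points)
    tree = cKDTree(pos)
    areas = np.empty(len(idx))
    tol = 1e-12   # nm²; points exactly on a neighbour surface tie-break by index
    for k in range(len(idx)):
        pts = pos[k] + radii[k] * unit
        cand = np.asarray(tree.query_ball_point(pos[k], radii[k] + radii.max()),
                          dtype=int)
        cand = cand[cand != k]
        nb = cand[np.linalg.norm(pos[cand] - pos[k], axis=1)
                  < radii[k] + radii[cand]] if len(cand) else cand
        if len(nb) == 0:
            areas[k] = 4.0 * np.pi * radii[k] ** 2
            continue
        nb_pos = pos[nb]
        d2 = (np.sum(pts ** 2, axis=1)[:, None] - 2.0 * (pts @ nb_pos.T)
              + np.sum(nb_pos ** 2, axis=1)[None, :])
        r2 = radii[nb] ** 2
        occluded = d2 < r2 - tol
        lower = nb < k   # surface-degenerate points belong to the lower index
        if lower.any():
            occluded[:, lower] |= np.abs(d2[:, lower] - r2[lower]) <= tol
        accessible = ~occluded.any(axis=1)
        areas[k] = 4.0 * np.pi * radii[k] ** 2 * accessible.sum() / n_sphere_points
    res_of = structure.res_ids[idx]
    per_residue = pd.Series(areas).groupby(res_of).sum()
    per_residue.index.name = "residue"
    per_atom = pd.Series(areas, index=idx)
    return float(areas.sum()), per_residue, per_atom


def sasa_series(trajectory: TrajectoryEnsemble,
                probe_radius: float = DEFAULT_PROBE_RADIUS,
                n_sphere_points: int = DEFAULT_N_POINTS,
                selection: AtomSelection | None = None):
    """Total SASA per frame plus a (frame × residue) per-residue table."""
    structure = trajectory.sub_structure()
    totals = np.empty(trajectory.n_frames)
    residue_rows = []
    for k in range(trajectory.n_frames):
        total, per_res, _ = sasa_frame(trajectory.frames[k], structure,
                                       probe_radius, n_sphere_points, selection)
        totals[k] = total
        residue_rows.append(per_res)
    per_residue = pd.DataFrame(residue_rows)
    per_residue.insert(0, "time_ps", trajectory.times)
    series = MetricSeries(times=trajectory.times, values=totals, label="sasa_total")
    return series, per_residue
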