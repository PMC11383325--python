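"""Geometric hydrogen-bond detection, occupancy tables, count series.

A donor–hydrogen–acceptor triple is a hydrogen bond in a frame when the
donor–acceptor distance is within the cutoff *and* the hydrogen–donor–
acceptor angle (deviation from D–H···A linearity measured at the donor) is
within the angular cutoff.  Defaults (0.35 nm, 30°, N/O donors and
acceptors) are the conventional geometric criteria of MD analysis tools.

Occupancy is the percentage of frames in which a given triple is bonded;
tables keep rows above a strict threshold (default > 10 % of frames) in the
``R160(HN)-R156(O)`` donor(atom)–acceptor(atom) labelling convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import MissingHydrogensError
from .structure import AtomSelection, StructureModel, TrajectoryEnsemble
from .superpose import MetricSeries

log = logging.getLogger(__name__)

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}

#: covalent H–donor assignment cutoff (nm)
COVALENT_H_CUTOFF = 0.12


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criteria."""

    max_da_distance: float = 0.35          # nm, donor–acceptor
    max_hda_angle: float = 30.0            # degrees, at the donor
    donor_elements: frozenset = field(default_factory=lambda: frozenset({"N", "O"}))
    acceptor_elements: frozenset = field(default_factory=lambda: frozenset({"N", "O"}))

    def __post_init__(self):
        if self.max_da_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0 < self.max_hda_angle <= 90:
            raise ValueError("angle cutoff must lie in (0, 90] degrees")


@dataclass
class HBondOccupancyTable:
    """Occupancy-filtered table of donor–hydrogen–acceptor triples."""

    table: pd.DataFrame                # columns below, sorted by occupancy desc
    n_frames: int
    min_occupancy_percent: float

    # columns: donor, hydrogen, acceptor, occupancy_percent, n_frames_observed


def _residue_atom_label(structure: StructureModel, atom_index: int) -> str:
    res_name = structure.res_names[atom_index]
    one = _THREE_TO_ONE.get(str(res_name).upper(), "X")
    return f"{one}{int(structure.res_ids[atom_index])}({structure.atom_names[atom_index]})"


def assign_hydrogen_donors(structure: StructureModel,
                           criteria: HBondCriteria | None = None,
                           coords: np.ndarray | None = None) -> dict[int, int]:
    """Map hydrogen atom index → covalently-bound donor heavy atom index.

    A hydrogen is bound to the nearest donor-element atom within
    ``COVALENT_H_CUTOFF``; hydrogens with two candidate donors within the
    cutoff are assigned to the nearest and logged.  Raises
    :class:`MissingHydrogensError` when the structure has no hydrogens.
    """
    criteria = criteria or HBondCriteria()
    coords = structure.coords if coords is None else np.asarray(coords)
    h_idx = np.flatnonzero(np.asarray([e == "H" for e in structure.elements]))
    if len(h_idx) == 0:
        raise MissingHydrogensError(
            "structure contains no hydrogens; H-bond analysis needs explicit "
            "hydrogens bonded to donors"
        )
    donor_idx = np.flatnonzero(
        np.asarray([e in criteria.donor_elements for e in structure.elements]))
    if len(donor_idx) == 0:
        return {}
    tree = cKDTree(coords[donor_idx])
    out: dict[int, int] = {}
    for h in h_idx:
        near = tree.query_ball_point(coords[h], COVALENT_H_CUTOFF)
        if not near:
            continue
        dists = np.linalg.norm(coords[donor_idx[near]] - coords[h], axis=1)
        if len(near) > 1:
            log.debug("hydrogen %s has %d candidate donors; using nearest",
                      _residue_atom_label(structure, h), len(near))
        out[int(h)] = int(donor_idx[near[int(np.argmin(dists))]])
    return out


def detect_hbonds_frame(coords: np.ndarray, structure: StructureModel,
                        criteria: HBondCriteria | None = None,
                        selection: AtomSelection | None = None,
                        _donor_of_h: dict[int, int] | None = None) -> set:
    """Hydrogen bonds in one frame as ``{(donor, hydrogen, acceptor), ...}``.

    Indices are atom indices into ``structure``.  ``selection`` restricts
    participating atoms (all atoms by default; solvent exclusion is done by
    selecting the protein).
    """
    criteria = criteria or HBondCriteria()
    coords = np.asarray(coords, dtype=float)
    sel_mask = (selection or AtomSelection.all()).mask(structure)
    donor_of_h = _donor_of_h if _donor_of_h is not None else \
        assign_hydrogen_donors(structure, criteria)
    acceptor_idx = np.flatnonzero(np.asarray(
        [e in criteria.acceptor_elements for e in structure.elements]) & sel_mask)
    if len(acceptor_idx) == 0:
        return set()
    tree = cKDTree(coords[acceptor_idx])
    cos_cut = np.cos(np.deg2rad(criteria.max_hda_angle))
    found = set()
    for h, d in donor_of_h.items():
        if not (sel_mask[h] and sel_mask[d]):
            continue
        near = tree.query_ball_point(coords[d], criteria.max_da_distance)
        for a_local in near:
            a = int(acceptor_idx[a_local])
            if a == d:
                continue
            v_h = coords[h] - coords[d]
            v_a = coords[a] - coords[d]
            na = np.linalg.norm(v_a)
            nh = np.linalg.norm(v_h)
            if na == 0 or nh == 0:
                continue
            if np.dot(v_h, v_a) / (na * nh) >= cos_cut:
                found.add((int(d), int(h), a))
    return found


def _iter_frame_bonds(trajectory: TrajectoryEnsemble,
                      criteria: HBondCriteria | None,
                      selection: AtomSelection | None):
    structure = trajectory.sub_structure()
    criteria = criteria or HBondCriteria()
    donor_of_h = assign_hydrogen_donors(structure, criteria)
    for k in range(trajectory.n_frames):
        yield detect_hbonds_frame(trajectory.frames[k], structure, criteria,
                                  selection, _donor_of_h=donor_of_h)


def occupancy_table(trajectory: TrajectoryEnsemble,
                    criteria: HBondCriteria | None = None,
                    selection: AtomSelection | None = None,
                    min_occupancy_percent: float = 10.0) -> HBondOccupancyTable:
    """Per-triple occupancy over all frames, filtered strictly above threshold.

    Rows are sorted by descending occupancy (ties broken by label) and
    labelled ``X123(ATOM)`` per participant.
    """
    structure = trajectory.sub_structure()
    counts: dict[tuple, int] = {}
    for bonds in _iter_frame_bonds(trajectory, criteria, selection):
        for triple in bonds:
            counts[triple] = counts.get(triple, 0) + 1
    f = trajectory.n_frames
    rows = []
    for (d, h, a), n in counts.items():
        occ = 100.0 * n / f
        if occ > min_occupancy_percent:
            rows.append({
                # donor carries the hydrogen name: R160(HN)-R156(O) convention
                "donor": _residue_atom_label(structure, h),
                "hydrogen": structure.atom_names[h],
                "acceptor": _residue_atom_label(structure, a),
                "occupancy_percent": occ,
                "n_frames_observed": n,
            })
    table = pd.DataFrame(
        rows, columns=["donor", "hydrogen", "acceptor",
                       "occupancy_percent", "n_frames_observed"])
    if len(table):
        table = table.sort_values(
            ["occupancy_percent", "donor", "acceptor"],
            ascending=[False, True, True]).reset_index(drop=True)
    return HBondOccupancyTable(table=table, n_frames=f,
                               min_occupancy_percent=min_occupancy_percent)


def average_occupancy_tables(tables: list[HBondOccupancyTable],
                             min_occupancy_percent: float = 10.0) -> HBondOccupancyTable:
    """Average per-trajectory occupancies over replicate tables.

    Triples absent from a replicate contribute zero to its average (the
    alternative — pooling frames — is obtained by concatenating trajectories
    before calling :func:`occupancy_table`).
    """
    if not tables:
        raise ValueError("no tables to average")
    acc: dict[tuple, list[float]] = {}
    meta: dict[tuple, dict] = {}
    for t in tables:
        for _, row in t.table.iterrows():
            key = (row["donor"], row["hydrogen"], row["acceptor"])
            acc.setdefault(key, []).append(row["occupancy_percent"])
            meta[key] = {"donor": key[0], "hydrogen": key[1], "acceptor": key[2]}
    n_rep = len(tables)
    rows = []
    for key, vals in acc.items():
        occ = sum(vals) / n_rep
        if occ > min_occupancy_percent:
            rows.append({**meta[key], "occupancy_percent": occ,
                         "n_frames_observed": int(round(
                             occ / 100 * sum(t.n_frames for t in tables) / n_rep))})
    table = pd.DataFrame(
        rows, columns=["donor", "hydrogen", "acceptor",
                       "occupancy_percent", "n_frames_observed"])
    if len(table):
        table = table.sort_values(
            ["occupancy_percent", "donor", "acceptor"],
            ascending=[False, True, True]).reset_index(drop=True)
    return HBondOccupancyTable(
        table=table, n_frames=sum(t.n_frames for t in tables),
        min_occupancy_percent=min_occupancy_percent)


def hbond_count_series(trajectory: TrajectoryEnsemble,
                       criteria: HBondCriteria | None = None,
                       selection: AtomSelection | None = None) -> MetricSeries:
    """Total hydrogen-bond number per frame (integer-valued series)."""
    values = np.array([len(b) for b in
                       _iter_frame_bonds(trajectory, criteria, selection)],
                      dtype=float)
    return MetricSeries(times=trajectory.times, values=values, label="hbond_count")
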