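"""Fixed-column PDB and plain xyz-table readers/writers.

The mandatory trajectory dialect is multi-model PDB; a whitespace-delimited
``frame atom x y z`` table (nm) is supported for light-weight fixtures.
Diagnostics are part of the contract: parse errors name the offending
1-based line number, trajectory atom-count mismatches name the frame.

Å→nm conversion happens here and nowhere else.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .errors import EmptyInputError, FrameMismatchError, ParseError
from .structure import StructureModel, TrajectoryEnsemble

log = logging.getLogger(__name__)

ANGSTROM_PER_NM = 10.0


def _parse_atom_record(line: str, lineno: int):
    """Parse one ATOM/HETATM record (PDB fixed columns) → field tuple."""
    if len(line.rstrip("\n")) < 54:
        raise ParseError(
            "ATOM/HETATM record shorter than 54 columns (malformed column widths)",
            lineno,
        )
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16]
        res_name = line[17:20].strip()
        chain_id = line[21].strip() or "A"
        res_id = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise ParseError(f"malformed ATOM/HETATM record ({exc})", lineno) from None
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # fall back on the standard name-column convention
        element = name[:1] if name[:1].isalpha() else name[1:2]
    return serial, name, altloc, res_name, chain_id, res_id, icode, x, y, z, element


def _records_to_structure(records, title: str) -> StructureModel:
    if not records:
        raise EmptyInputError("no ATOM/HETATM records found")
    serials, names, elements, res_ids, res_names, chains, xyz = [], [], [], [], [], [], []
    for serial, name, _alt, res_name, chain, res_id, _ic, x, y, z, element in records:
        serials.append(serial)
        names.append(name)
        elements.append(element)
        res_ids.append(res_id)
        res_names.append(res_name)
        chains.append(chain)
        xyz.append((x, y, z))
    coords = np.asarray(xyz, dtype=float) / ANGSTROM_PER_NM
    return StructureModel(
        serials=serials, atom_names=names, elements=elements,
        res_ids=res_ids, res_names=res_names, chain_ids=chains,
        coords=coords, title=title,
    )


def _scan_pdb_models(path):
    """Yield (model_number, records) per MODEL block; also returns title.

    Files without MODEL cards yield a single block numbered 1.
    """
    title = ""
    models: list[tuple[int, list]] = []
    current: list = []
    current_number = 1
    seen_model_card = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "TITLE ":
                title = (title + " " + line[10:].strip()).strip()
            elif rec == "MODEL ":
                if seen_model_card and current:
                    models.append((current_number, current))
                    current = []
                seen_model_card = True
                try:
                    current_number = int(line.split()[1])
                except (IndexError, ValueError):
                    current_number = len(models) + 1
            elif rec in ("ATOM  ", "HETATM"):
                fields = _parse_atom_record(line, lineno)
                if fields[6]:  # insertion code
                    raise ParseError(
                        f"insertion code {fields[6]!r} on residue {fields[5]} "
                        "not supported (simulation-derived PDBs do not use them)",
                        lineno,
                    )
                if fields[2] not in (" ", "", "A"):
                    continue  # keep altLoc blank or 'A' only
                current.append(fields)
            elif rec == "ENDMDL":
                if current:
                    models.append((current_number, current))
                    current = []
    if current:
        models.append((current_number, current))
    return title, models


def read_structure(path, dialect: str = "pdb", chain: str | None = None) -> StructureModel:
    """Read a reference structure from a fixed-column PDB file.

    Multi-MODEL files contribute MODEL 1 only (a warning is logged).  The
    single-chain assumption is enforced: multi-chain files require an
    explicit ``chain`` argument.
    """
    if dialect != "pdb":
        raise ValueError(f"unsupported structure dialect {dialect!r}")
    title, models = _scan_pdb_models(path)
    if not models:
        raise EmptyInputError(f"{path}: no ATOM/HETATM records found")
    if len(models) > 1:
        log.warning("%s: %d MODEL blocks; using MODEL 1 only", path, len(models))
        warnings.warn(f"{path}: multiple MODEL blocks, using MODEL 1 only",
                      stacklevel=2)
    structure = _records_to_structure(models[0][1], title)
    chains = sorted(set(structure.chain_ids))
    if chain is not None:
        keep = np.flatnonzero(structure.chain_ids == chain)
        if len(keep) == 0:
            raise ParseError(f"{path}: no atoms with chain id {chain!r}")
        structure = structure.subset(keep)
    elif len(chains) > 1:
        raise ParseError(
            f"{path}: multiple chains {chains}; pass an explicit chain id"
        )
    return structure


def read_trajectory(path, structure: StructureModel,
                    dialect: str = "multimodel-pdb",
                    dt_ps: float = 1.0,
                    selection=None) -> TrajectoryEnsemble:
    """Read a trajectory against a reference ``structure``.

    ``multimodel-pdb`` frames must carry exactly the structure's atom count;
    ``xyz-table`` rows are ``frame atom x y z`` with coordinates already in
    nm and atom count equal to the structure's (or to ``selection``'s when an
    :class:`AtomSelection` is given).  Frame times absent from both dialects
    are synthesised as ``dt_ps * frame_index``.
    """
    atom_indices = np.arange(structure.n_atoms) if selection is None \
        else selection.indices(structure)
    expected = len(atom_indices)
    if dialect == "multimodel-pdb":
        _title, models = _scan_pdb_models(path)
        if not models:
            raise EmptyInputError(f"{path}: no frames found")
        frames = []
        for k, (_num, records) in enumerate(models):
            if len(records) != expected:
                raise FrameMismatchError(k, expected, len(records))
            frames.append([(r[7], r[8], r[9]) for r in records])
        coords = np.asarray(frames, dtype=float) / ANGSTROM_PER_NM
    elif dialect == "xyz-table":
        try:
            table = np.loadtxt(path, ndmin=2, comments="#")
        except ValueError as exc:
            raise ParseError(f"{path}: malformed xyz-table ({exc})") from None
        if table.size == 0:
            raise EmptyInputError(f"{path}: empty xyz-table")
        if table.shape[1] != 5:
            raise ParseError(f"{path}: xyz-table needs 5 columns (frame atom x y z)")
        frame_ids = table[:, 0].astype(int)
        uniq = np.unique(frame_ids)
        coords = np.empty((len(uniq), expected, 3), dtype=float)
        for k, f in enumerate(uniq):
            rows = table[frame_ids == f]
            if rows.shape[0] != expected:
                raise FrameMismatchError(k, expected, rows.shape[0])
            order = np.argsort(rows[:, 1], kind="stable")
            coords[k] = rows[order, 2:5]
    else:
        raise ValueError(f"unsupported trajectory dialect {dialect!r}")
    times = dt_ps * np.arange(coords.shape[0], dtype=float)
    return TrajectoryEnsemble(
        structure=structure,
        atom_indices=atom_indices,
        frames=coords,
        times=times,
    )


def _format_atom_line(serial, name, res_name, chain, res_id, xyz_ang, element):
    # names shorter than 4 characters start in column 14 by convention
    name_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    return (
        f"ATOM  {serial:>5d} {name_field} {res_name:>3s} {chain:1s}{res_id:>4d}    "
        f"{xyz_ang[0]:8.3f}{xyz_ang[1]:8.3f}{xyz_ang[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}\n"
    )


def write_structure(structure: StructureModel, path) -> None:
    """Write a StructureModel as a single-model fixed-column PDB (Å)."""
    with open(path, "w") as fh:
        if structure.title:
            fh.write(f"TITLE     {structure.title}\n")
        for i in range(structure.n_atoms):
            fh.write(_format_atom_line(
                int(structure.serials[i]), structure.atom_names[i],
                structure.res_names[i], structure.chain_ids[i],
                int(structure.res_ids[i]),
                structure.coords[i] * ANGSTROM_PER_NM,
                structure.elements[i],
            ))
        fh.write("END\n")


def write_trajectory(trajectory: TrajectoryEnsemble, path,
                     dialect: str = "multimodel-pdb") -> None:
    """Write a trajectory in the multi-model PDB or xyz-table dialect."""
    sub = trajectory.sub_structure()
    if dialect == "multimodel-pdb":
        with open(path, "w") as fh:
            if sub.title:
                fh.write(f"TITLE     {sub.title}\n")
            for k in range(trajectory.n_frames):
                fh.write(f"MODEL     {k + 1:>4d}\n")
                ang = trajectory.frames[k] * ANGSTROM_PER_NM
                for i in range(sub.n_atoms):
                    fh.write(_format_atom_line(
                        int(sub.serials[i]), sub.atom_names[i], sub.res_names[i],
                        sub.chain_ids[i], int(sub.res_ids[i]), ang[i],
                        sub.elements[i],
                    ))
                fh.write("ENDMDL\n")
            fh.write("END\n")
    elif dialect == "xyz-table":
        with open(path, "w") as fh:
            fh.write("# frame atom x_nm y_nm z_nm\n")
            for k in range(trajectory.n_frames):
                for i in range(trajectory.n_atoms):
                    x, y, z = trajectory.frames[k, i]
                    fh.write(f"{k} {i} {x:.6f} {y:.6f} {z:.6f}\n")
    else:
        raise ValueError(f"unsupported trajectory dialect {dialect!r}")
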