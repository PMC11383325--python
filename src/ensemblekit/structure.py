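"""Structure and trajectory containers plus atom selections.

Coordinates are stored in **nanometres** throughout the package; ångströms
appear only at file-format boundaries.  Residue numbering is 1-based and
intervals are closed, matching the residue labels used in structural biology
(e.g. R160, D868).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import EmptyInputError, SelectionError

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class StructureModel:
    """All-atom model of a (single-chain) molecule, the fitting reference.

    Fields are parallel arrays over atoms; ``coords`` is ``(n_atoms, 3)`` in nm.
    """

    serials: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    chain_ids: np.ndarray
    coords: np.ndarray
    title: str = ""

    def __post_init__(self):
        self.serials = np.asarray(self.serials, dtype=int)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.res_names = np.asarray(self.res_names, dtype=object)
        self.chain_ids = np.asarray(self.chain_ids, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        n = self.coords.shape[0]
        if n == 0:
            raise EmptyInputError("structure contains zero atoms")
        if self.coords.shape != (n, 3):
            raise ValueError("coords must have shape (n_atoms, 3)")
        if len(np.unique(self.serials)) != n:
            raise ValueError("atom serials must be unique")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def residue_ids(self) -> np.ndarray:
        """Unique residue indices in order of first appearance."""
        _, first = np.unique(self.res_ids, return_index=True)
        return self.res_ids[np.sort(first)]

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    def subset(self, indices: np.ndarray, title: str | None = None) -> "StructureModel":
        """New StructureModel restricted to ``indices`` (structure order kept)."""
        idx = np.asarray(indices, dtype=int)
        return StructureModel(
            serials=self.serials[idx],
            atom_names=self.atom_names[idx],
            elements=self.elements[idx],
            res_ids=self.res_ids[idx],
            res_names=self.res_names[idx],
            chain_ids=self.chain_ids[idx],
            coords=self.coords[idx],
            title=self.title if title is None else title,
        )

    def with_coords(self, coords: np.ndarray, title: str | None = None) -> "StructureModel":
        out = replace(self, coords=np.asarray(coords, dtype=float))
        if title is not None:
            out.title = title
        return out


@dataclass(frozen=True)
class AtomSelection:
    """Deterministic predicate over a structure's atoms.

    Build via the factory classmethods and combine with ``&``::

        sel = AtomSelection.ca() & AtomSelection.residue_range(2, 4)
    """

    kind: str
    name: str | None = None
    start: int | None = None
    stop: int | None = None
    domain_map: object = None
    parts: tuple = field(default=())

    # -- factories ---------------------------------------------------------
    @classmethod
    def ca(cls) -> "AtomSelection":
        return cls(kind="ca")

    @classmethod
    def backbone(cls) -> "AtomSelection":
        """Backbone heavy atoms N, CA, C, O."""
        return cls(kind="backbone")

    @classmethod
    def heavy(cls) -> "AtomSelection":
        """All non-hydrogen atoms."""
        return cls(kind="heavy")

    @classmethod
    def all(cls) -> "AtomSelection":
        return cls(kind="all")

    @classmethod
    def residue_range(cls, start: int, stop: int) -> "AtomSelection":
        """Closed residue interval [start, stop], 1-based."""
        return cls(kind="range", start=int(start), stop=int(stop))

    @classmethod
    def domain(cls, name: str, domain_map) -> "AtomSelection":
        return cls(kind="domain", name=name, domain_map=domain_map)

    @classmethod
    def from_name(cls, name: str) -> "AtomSelection":
        try:
            return {"ca": cls.ca, "backbone": cls.backbone,
                    "heavy": cls.heavy, "all": cls.all}[name.lower()]()
        except KeyError:
            raise SelectionError(f"unknown selection name {name!r}") from None

    def __and__(self, other: "AtomSelection") -> "AtomSelection":
        return AtomSelection(kind="and", parts=(self, other))

    # -- evaluation --------------------------------------------------------
    def mask(self, structure: StructureModel) -> np.ndarray:
        names = structure.atom_names
        if self.kind == "ca":
            return np.array([n == "CA" for n in names], dtype=bool)
        if self.kind == "backbone":
            return np.array([n in BACKBONE_ATOMS for n in names], dtype=bool)
        if self.kind == "heavy":
            return np.array([e != "H" for e in structure.elements], dtype=bool)
        if self.kind == "all":
            return np.ones(structure.n_atoms, dtype=bool)
        if self.kind == "range":
            return (structure.res_ids >= self.start) & (structure.res_ids <= self.stop)
        if self.kind == "domain":
            residues = self.domain_map.residues(self.name)  # raises UnknownDomainError
            return np.isin(structure.res_ids, residues)
        if self.kind == "and":
            m = np.ones(structure.n_atoms, dtype=bool)
            for p in self.parts:
                m &= p.mask(structure)
            return m
        raise SelectionError(f"unknown selection kind {self.kind!r}")

    def indices(self, structure: StructureModel) -> np.ndarray:
        """Ordered atom indices (structure order); never reorders atoms."""
        return np.flatnonzero(self.mask(structure))


def select_atoms(structure: StructureModel, selection: AtomSelection) -> np.ndarray:
    """Ordered indices of ``selection`` applied to ``structure``."""
    return selection.indices(structure)


@dataclass
class TrajectoryEnsemble:
    """Ordered coordinate frames for a fixed atom subset of a structure.

    ``frames`` is ``(F, n_atoms, 3)`` in nm; ``times`` in ps, strictly
    increasing; ``atom_indices`` maps trajectory atoms into ``structure``.
    """

    structure: StructureModel
    atom_indices: np.ndarray
    frames: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        self.atom_indices = np.asarray(self.atom_indices, dtype=int)
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (F, n_atoms, 3)")
        if self.frames.shape[0] < 1:
            raise EmptyInputError("trajectory must contain at least one frame")
        if self.frames.shape[1] != len(self.atom_indices):
            raise ValueError("frame atom count does not match atom_indices")
        if len(self.times) != self.frames.shape[0]:
            raise ValueError("times length must equal number of frames")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def local_indices(self, selection: AtomSelection) -> np.ndarray:
        """Positions (into the frame atom axis) of ``selection``'s atoms.

        Raises :class:`SelectionError` if the selection is empty on the
        trajectory's atom set.
        """
        structure_idx = selection.indices(self.structure)
        pos_of = {int(a): i for i, a in enumerate(self.atom_indices)}
        local = [pos_of[int(a)] for a in structure_idx if int(a) in pos_of]
        if not local:
            raise SelectionError("selection matches no atoms in trajectory")
        return np.asarray(local, dtype=int)

    def sub_structure(self) -> StructureModel:
        """Structure restricted to the trajectory's atoms."""
        return self.structure.subset(self.atom_indices)

    def strided(self, stride: int) -> "TrajectoryEnsemble":
        if stride < 1:
            raise ValueError("stride must be >= 1")
        return TrajectoryEnsemble(
            structure=self.structure,
            atom_indices=self.atom_indices,
            frames=self.frames[::stride],
            times=self.times[::stride],
        )
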