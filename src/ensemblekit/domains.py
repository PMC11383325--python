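"""Named residue-range domain maps.

A domain map assigns closed, 1-based residue intervals to named structural
domains (e.g. the 12-domain Cas12b scheme: PI, BH, REC1-I/II, REC2,
OBD-I/II, RuvC-I/II/III, UK-I/II).  Intervals must be disjoint within and
across domains; unassigned residues are allowed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import DomainBoundsError, DomainOverlapError, UnknownDomainError
from .structure import StructureModel

#: Domain names of the 12-domain Cas12b decomposition (residue ranges are
#: structure-specific and therefore user-supplied).
DOMAIN_SCHEME_12 = (
    "PI", "BH", "REC1-I", "REC1-II", "REC2", "OBD-I", "OBD-II",
    "RuvC-I", "RuvC-II", "RuvC-III", "UK-I", "UK-II",
)


@dataclass
class DomainMap:
    """Ordered mapping domain name → list of closed residue intervals."""

    entries: list[tuple[str, list[tuple[int, int]]]]
    palette_order: tuple[str, ...] = field(default=())

    def __post_init__(self):
        names = [name for name, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate domain names")
        if not self.palette_order:
            self.palette_order = tuple(names)
        self._validate_disjoint()

    def _validate_disjoint(self):
        owner: dict[int, str] = {}
        for name, ranges in self.entries:
            for start, stop in ranges:
                if stop < start:
                    raise ValueError(f"domain {name}: empty interval [{start}, {stop}]")
                for r in range(start, stop + 1):
                    if r in owner:
                        raise DomainOverlapError(
                            f"residue {r} assigned to both {owner[r]!r} and {name!r}"
                        )
                    owner[r] = name
        self._owner = owner

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.entries)

    def residues(self, name: str) -> np.ndarray:
        """Sorted residue indices of domain ``name``."""
        for dom, ranges in self.entries:
            if dom == name:
                out = np.concatenate(
                    [np.arange(a, b + 1) for a, b in ranges]
                ) if ranges else np.empty(0, dtype=int)
                return np.sort(out.astype(int))
        raise UnknownDomainError(f"unknown domain {name!r}")

    def domain_of(self, res_id: int) -> str | None:
        """Domain owning residue ``res_id``, or None if unassigned."""
        return self._owner.get(int(res_id))

    def validate_against(self, structure: StructureModel) -> None:
        lo = int(structure.res_ids.min())
        hi = int(structure.res_ids.max())
        for name, ranges in self.entries:
            for start, stop in ranges:
                if start < lo or stop > hi:
                    raise DomainBoundsError(
                        f"domain {name}: interval [{start}, {stop}] outside "
                        f"structure residue span [{lo}, {hi}]"
                    )

    def to_dict(self) -> dict:
        return {name: [list(r) for r in ranges] for name, ranges in self.entries}


def domain_map_from_dict(data: dict) -> DomainMap:
    """Build a DomainMap from ``{name: [[start, stop], ...]}`` (order kept)."""
    entries = []
    for name, ranges in data.items():
        if ranges and isinstance(ranges[0], int):
            ranges = [ranges]  # allow a bare [start, stop]
        entries.append(
            (str(name), [(int(a), int(b)) for a, b in ranges])
        )
    return DomainMap(entries=entries)


def load_domain_map(path, structure: StructureModel | None = None) -> DomainMap:
    """Load a domain map from a YAML/JSON config file.

    The config is a mapping ``name -> list of [start, stop]`` pairs, optionally
    nested under a top-level ``domains:`` key.  When a structure is given the
    map is validated against its residue span.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or not data:
        raise ValueError(f"{path}: domain map config must be a non-empty mapping")
    if "domains" in data and isinstance(data["domains"], dict):
        data = data["domains"]
    dmap = domain_map_from_dict(data)
    if structure is not None:
        dmap.validate_against(structure)
    return dmap


def write_domain_map(dmap: DomainMap, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"domains": dmap.to_dict()}, fh, sort_keys=False)
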