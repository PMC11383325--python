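"""Synthetic structures and Gaussian conformational ensembles with exact truth.

The factor model plants per-residue fluctuation amplitudes and domain–domain
correlations with closed-form covariance, DCCM, spectrum and RMSF: residue i
of domain d moves one-dimensionally along a unit direction u_i,

    r_i(t) = r_i0 + sigma_i * (rho_d f_d(t) + sqrt(1 - rho_d^2) eps_i(t)) * u_i,

with f ~ correlated standard normals (correlation matrix R across domains)
and eps iid standard normal.  The planted cross-correlation between residues
i in domain a and j in domain b (i ≠ j) is ``rho_a rho_b R_ab (u_i · u_j)``
and the planted RMSF is ``sigma_i`` exactly.  Anticorrelated two-domain
defaults emulate, qualitatively, the large-scale counter-motion of structural
domains seen in Cas-protein ensembles (e.g. the REC-lobe open/close motion);
they are an analogy for testing, not a physical simulation.

Frames are generated in a common laboratory frame (already superposed);
optional per-frame rigid-body jitter exercises the superposition machinery.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .domains import DomainMap, domain_map_from_dict, write_domain_map
from .pdbio import write_structure, write_trajectory
from .structure import StructureModel, TrajectoryEnsemble

# ideal backbone internal coordinates (nm / degrees)
_BOND_N_CA = 0.1458
_BOND_CA_C = 0.1525
_BOND_C_N = 0.1329
_BOND_C_O = 0.1231
_BOND_N_H = 0.1010
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7
_ANGLE_CA_C_O = 120.8
_ANGLE_C_N_H = 119.5

HELIX_PHI_PSI = (-57.0, -47.0)
EXTENDED_PHI_PSI = (-135.0, 135.0)
CA_CA_EXTENDED_NM = 0.38
HELIX_RISE_NM = 0.15          # rise per residue along the helix axis
HELIX_RADIUS_NM = 0.23
HELIX_TWIST_DEG = 100.0       # 3.6 residues per turn


def _nerf(a, b, c, bond, angle_deg, torsion_deg):
    """Place the next atom from three predecessors and internal coordinates."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(angle),
                  bond * np.sin(angle) * np.cos(torsion),
                  bond * np.sin(angle) * np.sin(torsion)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def make_toy_structure(n_residues: int, geometry: str = "extended",
                       with_backbone: bool = False,
                       with_polar_hydrogens: bool = False) -> StructureModel:
    """Deterministic poly-alanine toy chain (Cα-only or full backbone).

    ``geometry`` is ``'extended'`` or ``'ideal-helix'``.  Cα-only extended
    chains place consecutive Cα exactly 0.38 nm apart on a line; Cα-only
    helices follow the parametric α-helix (0.15 nm rise, 100° twist per
    residue).  With ``with_backbone`` the N/CA/C/O backbone is built from
    ideal internal coordinates at α-helical (−57°, −47°) or β-extended
    (−135°, 135°) torsions, and ``with_polar_hydrogens`` adds the amide
    hydrogen (named HN) on residues 2..n, giving genuine i→i+4 N–H···O
    hydrogen bonds in the helix.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    if geometry not in ("extended", "ideal-helix"):
        raise ValueError(f"unknown geometry {geometry!r}")
    if not with_backbone:
        if geometry == "extended":
            ca = np.column_stack([
                CA_CA_EXTENDED_NM * np.arange(n_residues),
                np.zeros(n_residues), np.zeros(n_residues)])
        else:
            t = np.deg2rad(HELIX_TWIST_DEG) * np.arange(n_residues)
            ca = np.column_stack([
                HELIX_RADIUS_NM * np.cos(t),
                HELIX_RADIUS_NM * np.sin(t),
                HELIX_RISE_NM * np.arange(n_residues)])
        n = n_residues
        return StructureModel(
            serials=np.arange(1, n + 1),
            atom_names=["CA"] * n, elements=["C"] * n,
            res_ids=np.arange(1, n + 1), res_names=["ALA"] * n,
            chain_ids=["A"] * n, coords=ca,
            title=f"toy {geometry} CA-only ({n} residues)",
        )

    phi, psi = HELIX_PHI_PSI if geometry == "ideal-helix" else EXTENDED_PHI_PSI
    omega = 180.0
    n_pos = [np.array([0.0, 0.0, 0.0])]
    ca_pos = [np.array([_BOND_N_CA, 0.0, 0.0])]
    ang = np.deg2rad(_ANGLE_N_CA_C)
    c_pos = [ca_pos[0] + _BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])]
    for i in range(1, n_residues):
        n_i = _nerf(n_pos[-1], ca_pos[-1], c_pos[-1], _BOND_C_N, _ANGLE_CA_C_N, psi)
        ca_i = _nerf(ca_pos[-1], c_pos[-1], n_i, _BOND_N_CA, _ANGLE_C_N_CA, omega)
        c_i = _nerf(c_pos[-1], n_i, ca_i, _BOND_CA_C, _ANGLE_N_CA_C, phi)
        n_pos.append(n_i)
        ca_pos.append(ca_i)
        c_pos.append(c_i)

    serials, names, elements, res_ids, coords = [], [], [], [], []
    serial = 1
    for i in range(n_residues):
        atoms = [("N", "N", n_pos[i]), ("CA", "C", ca_pos[i]), ("C", "C", c_pos[i])]
        # carbonyl O anti to the next N across the peptide plane
        o_i = _nerf(n_pos[i], ca_pos[i], c_pos[i], _BOND_C_O, _ANGLE_CA_C_O,
                    psi + 180.0)
        atoms.append(("O", "O", o_i))
        if with_polar_hydrogens and i >= 1:
            h_i = _nerf(ca_pos[i - 1], c_pos[i - 1], n_pos[i], _BOND_N_H,
                        _ANGLE_C_N_H, 0.0)
            atoms.append(("HN", "H", h_i))
        for name, element, pos in atoms:
            serials.append(serial)
            names.append(name)
            elements.append(element)
            res_ids.append(i + 1)
            coords.append(pos)
            serial += 1
    return StructureModel(
        serials=serials, atom_names=names, elements=elements,
        res_ids=res_ids, res_names=["ALA"] * len(serials),
        chain_ids=["A"] * len(serials), coords=np.asarray(coords),
        title=f"toy {geometry} backbone ({n_residues} residues)",
    )


@dataclass
class FactorModelSpec:
    """Parameters of the planted-correlation Gaussian factor model."""

    residues_per_domain: tuple[int, ...] = (25, 25)
    sigma: float | np.ndarray = 0.08            # nm per-residue fluctuation
    rho: float | np.ndarray = 1.0               # per-domain factor loading
    factor_correlation: np.ndarray | None = None  # DxD PSD, unit diagonal
    directions: str | np.ndarray = "common-x"   # 'common-x' | 'random' | (N,3)
    n_frames: int = 5000
    seed: int = 1234
    rigid_jitter: bool = False
    jitter_translation_nm: float = 0.5
    dt_ps: float = 1.0
    domain_names: tuple[str, ...] = field(default=())

    def __post_init__(self):
        self.residues_per_domain = tuple(int(n) for n in self.residues_per_domain)
        if not self.domain_names:
            self.domain_names = tuple(
                chr(ord("A") + d) for d in range(self.n_domains))
        if len(self.domain_names) != self.n_domains:
            raise ValueError("domain_names length must equal number of domains")

    @property
    def n_domains(self) -> int:
        return len(self.residues_per_domain)

    @property
    def n_residues(self) -> int:
        return int(sum(self.residues_per_domain))

    def domain_of_residue(self) -> np.ndarray:
        """Domain index (0-based) of each residue, residues in chain order."""
        return np.repeat(np.arange(self.n_domains), self.residues_per_domain)

    def domain_map(self) -> DomainMap:
        ranges = {}
        start = 1
        for name, n in zip(self.domain_names, self.residues_per_domain):
            ranges[name] = [[start, start + n - 1]]
            start += n
        return domain_map_from_dict(ranges)

    def resolve(self):
        """Concrete (sigma_i, rho_d, R, u_i) arrays; deterministic per seed."""
        n, d = self.n_residues, self.n_domains
        sigma = np.broadcast_to(np.asarray(self.sigma, dtype=float), (n,)).copy()
        if np.any(sigma <= 0):
            raise ValueError("sigma must be positive")
        rho = np.broadcast_to(np.asarray(self.rho, dtype=float), (d,)).copy()
        if np.any((rho < 0) | (rho > 1)):
            raise ValueError("rho must lie in [0, 1]")
        r = np.eye(d) if self.factor_correlation is None \
            else np.asarray(self.factor_correlation, dtype=float)
        if r.shape != (d, d) or np.abs(r - r.T).max() > 1e-12 \
                or np.abs(np.diag(r) - 1).max() > 1e-12:
            raise ValueError("factor correlation must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(r).min() < -1e-10:
            raise ValueError("factor correlation matrix is not positive semidefinite")
        if isinstance(self.directions, str):
            if self.directions == "common-x":
                u = np.tile(np.array([1.0, 0.0, 0.0]), (n, 1))
            elif self.directions == "random":
                rng = np.random.default_rng(
                    np.random.SeedSequence([self.seed, 7]))
                v = rng.standard_normal((n, 3))
                u = v / np.linalg.norm(v, axis=1, keepdims=True)
            else:
                raise ValueError(f"unknown directions mode {self.directions!r}")
        else:
            u = np.asarray(self.directions, dtype=float)
            if u.shape != (n, 3) or np.abs(
                    np.linalg.norm(u, axis=1) - 1).max() > 1e-9:
                raise ValueError("directions must be (N, 3) unit vectors")
        return sigma, rho, r, u

    def to_dict(self) -> dict:
        sigma, rho, r, u = self.resolve()
        return {
            "residues_per_domain": list(self.residues_per_domain),
            "sigma": sigma.tolist(),
            "rho": rho.tolist(),
            "factor_correlation": r.tolist(),
            "directions": (self.directions if isinstance(self.directions, str)
                           else u.tolist()),
            "n_frames": self.n_frames,
            "seed": self.seed,
            "rigid_jitter": self.rigid_jitter,
            "jitter_translation_nm": self.jitter_translation_nm,
            "dt_ps": self.dt_ps,
            "domain_names": list(self.domain_names),
        }


@dataclass
class PlantedTruth:
    """Closed-form ground truth of a factor model over the Cα atoms."""

    covariance: np.ndarray      # (3N, 3N) nm²
    dccm: np.ndarray            # (N, N)
    eigenvalues: np.ndarray     # nonincreasing, nm²
    rmsf: np.ndarray            # (N,) nm

    @property
    def trace(self) -> float:
        return float(np.trace(self.covariance))


def planted_truth(spec: FactorModelSpec) -> PlantedTruth:
    """Exact covariance, DCCM, spectrum and RMSF of the factor model."""
    sigma, rho, r, u = spec.resolve()
    dom = spec.domain_of_residue()
    n = spec.n_residues
    k = rho[dom][:, None] * rho[dom][None, :] * r[np.ix_(dom, dom)]
    np.fill_diagonal(k, 1.0)
    scalar_cov = np.outer(sigma, sigma) * k
    cov = np.einsum("ij,ia,jb->iajb", scalar_cov, u, u).reshape(3 * n, 3 * n)
    dccm = k * (u @ u.T)
    np.fill_diagonal(dccm, 1.0)
    vals = np.linalg.eigvalsh(cov)[::-1]
    return PlantedTruth(covariance=cov, dccm=dccm,
                        eigenvalues=np.clip(vals, 0.0, None), rmsf=sigma.copy())


def _random_rotation(rng) -> np.ndarray:
    """Uniform random rotation matrix from a normalised quaternion."""
    q = rng.standard_normal(4)
    w, x, y, z = q / np.linalg.norm(q)
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def sample_ensemble(spec: FactorModelSpec,
                    base: StructureModel) -> tuple[TrajectoryEnsemble, PlantedTruth]:
    """Sample the factor-model ensemble on a base structure.

    Every atom of residue i is displaced by the residue's scalar amplitude
    along u_i (rigid per-residue translation), so Cα statistics follow the
    planted truth exactly.  Sampling is bit-exact reproducible per seed.
    """
    if base.n_residues != spec.n_residues:
        raise ValueError(
            f"base structure has {base.n_residues} residues, "
            f"spec wants {spec.n_residues}")
    sigma, rho, r, u = spec.resolve()
    dom = spec.domain_of_residue()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 11]))
    f = spec.n_frames
    n = spec.n_residues
    w, v = np.linalg.eigh(r)
    sqrt_r = v @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ v.T
    factors = rng.standard_normal((f, spec.n_domains)) @ sqrt_r.T
    eps = rng.standard_normal((f, n))
    amp = sigma * (rho[dom] * factors[:, dom] + np.sqrt(1 - rho[dom] ** 2) * eps)
    disp = amp[:, :, None] * u[None, :, :]           # (F, N, 3)

    res_index = np.searchsorted(base.residue_ids, base.res_ids)
    frames = base.coords[None, :, :] + disp[:, res_index, :]
    if spec.rigid_jitter:
        for t in range(f):
            rot = _random_rotation(rng)
            shift = spec.jitter_translation_nm * rng.standard_normal(3)
            frames[t] = frames[t] @ rot.T + shift
    traj = TrajectoryEnsemble(
        structure=base,
        atom_indices=np.arange(base.n_atoms),
        frames=frames,
        times=spec.dt_ps * np.arange(f, dtype=float),
    )
    return traj, planted_truth(spec)


def make_breathing_dimer(n_frames: int = 5, bound_fraction: float = 0.6,
                         dt_ps: float = 1.0) -> TrajectoryEnsemble:
    """Two-residue fixture whose single N–H···O bond is scripted on/off.

    The first ``round(bound_fraction * n_frames)`` frames place the acceptor
    oxygen collinear with the donor N–H at 0.30 nm (a textbook hydrogen
    bond); the remaining frames move it to 0.45 nm, outside the distance
    cutoff.  Occupancy is therefore exactly the scripted fraction.
    """
    if not 0 <= bound_fraction <= 1:
        raise ValueError("bound_fraction must lie in [0, 1]")
    structure = StructureModel(
        serials=[1, 2, 3, 4, 5],
        atom_names=["N", "HN", "CA", "CA", "O"],
        elements=["N", "H", "C", "C", "O"],
        res_ids=[1, 1, 1, 2, 2],
        res_names=["GLY", "GLY", "GLY", "GLY", "GLY"],
        chain_ids=["A"] * 5,
        coords=np.array([
            [0.000, 0.000, 0.0],
            [0.101, 0.000, 0.0],       # H on the N, along +x
            [-0.070, 0.130, 0.0],
            [0.450, 0.130, 0.0],
            [0.300, 0.000, 0.0],       # acceptor O, collinear N-H...O
        ]),
        title="breathing dimer",
    )
    n_bound = int(round(bound_fraction * n_frames))
    frames = np.tile(structure.coords, (n_frames, 1, 1))
    frames[n_bound:, 4, 0] = 0.450   # broken: N...O = 0.45 nm > cutoff
    return TrajectoryEnsemble(
        structure=structure,
        atom_indices=np.arange(5),
        frames=frames,
        times=dt_ps * np.arange(n_frames, dtype=float),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture_suite(output_dir, n_residues: int = 50, n_frames: int = 120,
                        seed: int = 2024) -> dict[str, str]:
    """Write the canonical test fixture set; idempotent per (args, seed).

    Emits a helical backbone structure with polar hydrogens, a sampled
    two-domain anticorrelated ensemble in both trajectory dialects, the
    domain map, the factor-model spec (JSON) and a SHA-256 manifest.
    Returns ``{filename: checksum}``.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    half = n_residues // 2
    spec = FactorModelSpec(
        residues_per_domain=(half, n_residues - half),
        factor_correlation=np.array([[1.0, -0.8], [-0.8, 1.0]]),
        n_frames=n_frames, seed=seed,
    )
    base = make_toy_structure(n_residues, "ideal-helix", with_backbone=True,
                              with_polar_hydrogens=True)
    traj, _truth = sample_ensemble(spec, base)
    write_structure(base, out / "structure.pdb")
    write_trajectory(traj, out / "trajectory.pdb", dialect="multimodel-pdb")
    write_trajectory(traj, out / "trajectory.xyz", dialect="xyz-table")
    write_domain_map(spec.domain_map(), out / "domains.yaml")
    with open(out / "factor_spec.json", "w") as fh:
        json.dump(spec.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    names = ["structure.pdb", "trajectory.pdb", "trajectory.xyz",
             "domains.yaml", "factor_spec.json"]
    checksums = {name: _sha256(out / name) for name in names}
    with open(out / "MANIFEST.sha256", "w") as fh:
        for name in names:
            fh.write(f"{checksums[name]}  {name}\n")
    return checksums
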