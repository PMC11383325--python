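"""Essential dynamics: Cα covariance, eigen-decomposition, projections, modes.

The positional covariance of the Cα atoms is built after least-squares
fitting every frame to a reference on the backbone, taken about the
ensemble-mean structure (which makes it positive semidefinite and ties
projection variances to eigenvalues).  Diagonalising it yields the
principal components; motion along the leading component is the protein's
"essential dynamics".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientFramesError
from .structure import AtomSelection, StructureModel, TrajectoryEnsemble
from .superpose import fit_frames


@dataclass
class CovarianceModel:
    """3N×3N positional covariance of N analysis atoms (nm²) + fit context."""

    mean_coords: np.ndarray          # (N, 3) nm, ensemble mean after fitting
    matrix: np.ndarray               # (3N, 3N) nm²
    structure: StructureModel        # trajectory sub-structure the fit used
    analysis_indices: np.ndarray     # into the trajectory atom axis
    fit_selection: AtomSelection | None   # None: frames were used unfitted
    reference_coords: np.ndarray     # full trajectory-atom reference (n, 3)
    n_frames_used: int

    @property
    def n_atoms(self) -> int:
        return self.mean_coords.shape[0]

    @property
    def residue_ids(self) -> np.ndarray:
        return self.structure.res_ids[self.analysis_indices]

    @property
    def trace(self) -> float:
        return float(np.trace(self.matrix))

    def block(self, i: int, j: int) -> np.ndarray:
        """The 3×3 covariance block of analysis atoms i, j."""
        return self.matrix[3 * i:3 * i + 3, 3 * j:3 * j + 3]


@dataclass
class EigenDecomposition:
    """Sorted spectrum of a CovarianceModel."""

    eigenvalues: np.ndarray          # nonincreasing, nm²
    eigenvectors: np.ndarray         # (3N, 3N), column k ↔ eigenvalue k
    sign_convention: str = "largest-component-positive"

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    def mode(self, k: int) -> np.ndarray:
        """Eigenvector k reshaped to per-atom 3-vectors."""
        return self.eigenvectors[:, k].reshape(-1, 3)


@dataclass
class ProjectionSeries:
    """Per-frame coordinates (nm) along selected principal components."""

    times: np.ndarray
    coords: np.ndarray               # (F, k)
    pc_indices: tuple[int, ...]

    def to_frame(self) -> pd.DataFrame:
        data = {"time_ps": self.times}
        for j, pc in enumerate(self.pc_indices):
            data[f"pc{pc + 1}"] = self.coords[:, j]
        return pd.DataFrame(data)


def build_covariance(trajectory: TrajectoryEnsemble,
                     reference: StructureModel | np.ndarray | None = None,
                     fit_selection: AtomSelection | None = None,
                     analysis_selection: AtomSelection | None = None,
                     superpose: bool = True) -> CovarianceModel:
    """Covariance of the analysis atoms (Cα by default) after backbone fitting.

    Every frame is superposed onto the reference (trajectory frame 1 by
    default) over ``fit_selection``; the unweighted covariance of the
    analysis coordinates is then taken about their ensemble mean with 1/F
    normalisation.  ``superpose=False`` skips the fit for ensembles already
    expressed in a common laboratory frame (superposition projects out
    rigid-body modes, which also removes any collective drift a generator
    may have planted deliberately).
    """
    if trajectory.n_frames < 2:
        raise InsufficientFramesError("covariance needs at least 2 frames")
    fit_selection = fit_selection or AtomSelection.backbone()
    analysis_selection = analysis_selection or AtomSelection.ca()
    if superpose:
        fitted = fit_frames(trajectory, reference, fit_selection)
    else:
        fitted = trajectory.frames
    idx = trajectory.local_indices(analysis_selection)
    x = fitted[:, idx].reshape(trajectory.n_frames, -1)      # (F, 3N)
    mean = x.mean(axis=0)
    dx = x - mean
    cov = dx.T @ dx / trajectory.n_frames
    cov = 0.5 * (cov + cov.T)
    from .superpose import _reference_coords  # shared default-reference rule
    ref = _reference_coords(trajectory, reference)
    return CovarianceModel(
        mean_coords=mean.reshape(-1, 3),
        matrix=cov,
        structure=trajectory.sub_structure(),
        analysis_indices=idx,
        fit_selection=fit_selection if superpose else None,
        reference_coords=ref,
        n_frames_used=trajectory.n_frames,
    )


def eigendecompose(cov: CovarianceModel | np.ndarray,
                   symmetry_tol: float = 1e-9) -> EigenDecomposition:
    """Spectrum of the covariance, sorted nonincreasing, deterministic signs.

    Eigenvalues inside a small negative tolerance band (numerical PSD
    violations) are clipped to zero; larger violations raise.  Each
    eigenvector's sign is fixed so that its largest-magnitude component is
    positive, which makes output reproducible across BLAS implementations.
    """
    matrix = cov.matrix if isinstance(cov, CovarianceModel) else np.asarray(cov)
    scale = max(float(np.abs(matrix).max()), 1.0)
    if np.abs(matrix - matrix.T).max() > symmetry_tol * scale:
        raise ValueError("covariance matrix is asymmetric beyond tolerance")
    matrix = 0.5 * (matrix + matrix.T)
    vals, vecs = np.linalg.eigh(matrix)
    order = np.argsort(vals, kind="stable")[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    neg_tol = 1e-9 * max(float(np.trace(matrix)), 1.0)
    if vals.min() < -neg_tol:
        raise ValueError(
            f"covariance not positive semidefinite (min eigenvalue {vals.min():.3e})"
        )
    vals = np.clip(vals, 0.0, None)
    for k in range(vecs.shape[1]):
        j = int(np.argmax(np.abs(vecs[:, k])))
        if vecs[j, k] < 0:
            vecs[:, k] = -vecs[:, k]
    return EigenDecomposition(eigenvalues=vals, eigenvectors=vecs)


def project_coords(cov: CovarianceModel, eig: EigenDecomposition,
                   coords: np.ndarray, pcs) -> np.ndarray:
    """Project analysis-atom coordinates (…, N, 3) onto selected modes."""
    pcs = tuple(int(p) for p in pcs)
    for p in pcs:
        if not 0 <= p < eig.n_modes:
            raise IndexError(f"principal component index {p} out of range")
    flat = np.asarray(coords, dtype=float).reshape(*coords.shape[:-2], -1)
    centered = flat - cov.mean_coords.reshape(-1)
    return centered @ eig.eigenvectors[:, list(pcs)]


def project_trajectory(trajectory: TrajectoryEnsemble, cov: CovarianceModel,
                       eig: EigenDecomposition,
                       pcs=(0, 1)) -> ProjectionSeries:
    """Per-frame projections onto selected PCs (PC1/PC2 by default).

    Frames are fitted with the covariance model's own fit selection and
    reference, so projecting the trajectory that built the covariance
    reproduces the eigenvalue/variance identity.  A covariance built with
    ``superpose=False`` projects raw frames.
    """
    if cov.fit_selection is None:
        fitted = trajectory.frames
    else:
        fitted = fit_frames(trajectory, cov.reference_coords, cov.fit_selection)
    coords = fitted[:, cov.analysis_indices]
    proj = project_coords(cov, eig, coords, pcs)
    return ProjectionSeries(times=trajectory.times, coords=proj,
                            pc_indices=tuple(int(p) for p in pcs))


def export_mode_endpoints(cov: CovarianceModel, eig: EigenDecomposition,
                          pc: int = 0, amplitude: float = 2.0):
    """Mean structure displaced ±amplitude·√λ along a mode, plus arrow table.

    Returns ``(plus, minus, arrows)`` where the snapshots are CA-only
    StructureModels and ``arrows`` is a DataFrame of per-residue displacement
    vectors (nm) from the −amplitude to the +amplitude endpoint, suitable for
    porcupine-style rendering.
    """
    if not 0 <= pc < eig.n_modes:
        raise IndexError(f"principal component index {pc} out of range")
    disp = amplitude * np.sqrt(eig.eigenvalues[pc]) * eig.mode(pc)
    base = cov.structure.subset(cov.analysis_indices)
    plus = base.with_coords(cov.mean_coords + disp, title=f"PC{pc + 1} +{amplitude}sd")
    minus = base.with_coords(cov.mean_coords - disp, title=f"PC{pc + 1} -{amplitude}sd")
    arrows = pd.DataFrame({
        "residue": cov.residue_ids,
        "dx_nm": 2 * disp[:, 0],
        "dy_nm": 2 * disp[:, 1],
        "dz_nm": 2 * disp[:, 2],
        "norm_nm": 2 * np.linalg.norm(disp, axis=1),
    })
    return plus, minus, arrows
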