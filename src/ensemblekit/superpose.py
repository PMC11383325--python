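"""Least-squares rigid-body superposition and deviation/fluctuation metrics.

Implements the Kabsch algorithm (SVD route, reflections excluded) and the
standard ensemble metrics built on it: RMSD time series against a reference
frame, per-domain RMSD with a *local* fit to the domain's own initial
backbone, per-residue RMSF about the ensemble mean, and the all-to-all RMSD
matrix used to assess sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FitDegenerateError, InsufficientFramesError, SelectionError
from .structure import AtomSelection, StructureModel, TrajectoryEnsemble


@dataclass
class SuperpositionResult:
    """Optimal proper rotation + translation: ``x' = rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd_after_fit: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class MetricSeries:
    """Per-frame scalar metric with time stamps (ps)."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("metric values must be finite")


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray,
               weights: np.ndarray | None = None) -> SuperpositionResult:
    """Weighted least-squares optimal superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation (det = +1; reflections excluded) and
    translation minimising the weighted sum of squared distances, plus the
    RMSD after the fit.  Raises :class:`FitDegenerateError` for fewer than
    three atoms or (near-)collinear geometry, where the rotation is not
    uniquely determined.
    """
    x = np.asarray(mobile, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("mobile and reference must both have shape (n, 3)")
    n = x.shape[0]
    if n < 3:
        raise FitDegenerateError(f"superposition needs >= 3 atoms, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()
    cx = w @ x
    cy = w @ y
    xc = x - cx
    yc = y - cy
    # collinearity check on the weighted mobile cloud
    sv = np.linalg.svd(xc * np.sqrt(w)[:, None], compute_uv=False)
    if sv[1] <= 1e-12 * max(sv[0], 1.0):
        raise FitDegenerateError("atoms are collinear; rotation is underdetermined")
    h = (xc * w[:, None]).T @ yc
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cy - rot @ cx
    fitted = xc @ rot.T + cy
    rmsd = float(np.sqrt(np.sum(w * np.sum((fitted - y) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd_after_fit=rmsd)


def _reference_coords(trajectory: TrajectoryEnsemble,
                      reference: StructureModel | np.ndarray | None) -> np.ndarray:
    """Reference coordinates in trajectory atom order (default: frame 1)."""
    if reference is None:
        return trajectory.frames[0]
    if isinstance(reference, StructureModel):
        return reference.coords[trajectory.atom_indices]
    ref = np.asarray(reference, dtype=float)
    if ref.shape != trajectory.frames[0].shape:
        raise ValueError("reference coordinates do not match trajectory atoms")
    return ref


def fit_frames(trajectory: TrajectoryEnsemble,
               reference: StructureModel | np.ndarray | None = None,
               fit_selection: AtomSelection | None = None) -> np.ndarray:
    """All frames rigidly fitted onto the reference over ``fit_selection``.

    Fitting defaults to the backbone of trajectory frame 1 — the first frame
    of the trajectory is the conventional reference.  Returns an
    ``(F, n_atoms, 3)`` array of transformed frames.
    """
    fit_selection = fit_selection or AtomSelection.backbone()
    fit_idx = trajectory.local_indices(fit_selection)
    ref = _reference_coords(trajectory, reference)[fit_idx]
    out = np.empty_like(trajectory.frames)
    for k in range(trajectory.n_frames):
        res = kabsch_fit(trajectory.frames[k, fit_idx], ref)
        out[k] = res.apply(trajectory.frames[k])
    return out


def rmsd_series(trajectory: TrajectoryEnsemble,
                reference: StructureModel | np.ndarray | None = None,
                fit_selection: AtomSelection | None = None,
                measure_selection: AtomSelection | None = None,
                label: str = "rmsd") -> MetricSeries:
    """RMSD(t) after fitting each frame to the reference.

    Both the fit and the measurement default to backbone atoms, and the
    reference defaults to trajectory frame 1.
    """
    fit_selection = fit_selection or AtomSelection.backbone()
    measure_selection = measure_selection or fit_selection
    fit_idx = trajectory.local_indices(fit_selection)
    meas_idx = trajectory.local_indices(measure_selection)
    if len(fit_idx) == 0 or len(meas_idx) == 0:
        raise SelectionError("empty selection")
    ref = _reference_coords(trajectory, reference)
    values = np.empty(trajectory.n_frames)
    for k in range(trajectory.n_frames):
        res = kabsch_fit(trajectory.frames[k, fit_idx], ref[fit_idx])
        moved = res.apply(trajectory.frames[k, meas_idx])
        values[k] = np.sqrt(np.mean(np.sum((moved - ref[meas_idx]) ** 2, axis=1)))
    return MetricSeries(times=trajectory.times, values=values, label=label)


def domain_rmsd_series(trajectory: TrajectoryEnsemble,
                       reference: StructureModel | np.ndarray | None,
                       domain_map, domain: str) -> MetricSeries:
    """Per-domain RMSD(t) with fit *and* measurement local to the domain.

    Each frame's domain backbone is fitted to the domain's own initial
    backbone structure, so the series reports internal deformation of the
    domain, not its rigid-body motion relative to the rest of the protein.
    """
    sel = AtomSelection.domain(domain, domain_map) & AtomSelection.backbone()
    return rmsd_series(trajectory, reference, fit_selection=sel,
                       measure_selection=sel, label=f"rmsd[{domain}]")


def rmsf_per_residue(trajectory: TrajectoryEnsemble,
                     reference: StructureModel | np.ndarray | None = None,
                     fit_selection: AtomSelection | None = None,
                     atom_mode: str = "CA",
                     superpose: bool = True):
    """Per-residue RMSF (nm) about the ensemble-mean position.

    Frames are first fitted to the reference (backbone fit by default); the
    fluctuation of each residue is then taken about its mean over the fitted
    ensemble: ``RMSF_i = sqrt(<|r_i - <r_i>|^2>)``.  ``atom_mode='CA'`` uses
    the Cα atom; ``'backbone-mean'`` averages the mean-square fluctuation
    over the residue's backbone atoms before taking the root.
    ``superpose=False`` skips fitting for frames already in a common frame.

    Returns ``(residue_ids, rmsf_values)``.
    """
    if trajectory.n_frames < 2:
        raise InsufficientFramesError("RMSF needs at least 2 frames")
    if atom_mode not in ("CA", "backbone-mean"):
        raise ValueError(f"unknown atom_mode {atom_mode!r}")
    fitted = fit_frames(trajectory, reference, fit_selection) if superpose \
        else trajectory.frames
    sel = AtomSelection.ca() if atom_mode == "CA" else AtomSelection.backbone()
    idx = trajectory.local_indices(sel)
    sub = trajectory.sub_structure()
    res_of_atom = sub.res_ids[idx]
    coords = fitted[:, idx]                       # (F, m, 3)
    msf_atom = np.mean(np.sum((coords - coords.mean(axis=0)) ** 2, axis=2), axis=0)
    residue_ids = sub.residue_ids
    rmsf = np.empty(len(residue_ids))
    for r, res in enumerate(residue_ids):
        mask = res_of_atom == res
        if not np.any(mask):
            rmsf[r] = np.nan
        else:
            rmsf[r] = np.sqrt(np.mean(msf_atom[mask]))
    return residue_ids, rmsf


def pairwise_rmsd_matrix(trajectory: TrajectoryEnsemble,
                         fit_selection: AtomSelection | None = None,
                         measure_selection: AtomSelection | None = None,
                         stride: int = 1) -> np.ndarray:
    """All-to-all RMSD matrix: entry (k, l) fits frame l onto frame k.

    Symmetric with zero diagonal when fit and measurement selections agree
    (the default).
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    fit_selection = fit_selection or AtomSelection.backbone()
    measure_selection = measure_selection or fit_selection
    fit_idx = trajectory.local_indices(fit_selection)
    meas_idx = trajectory.local_indices(measure_selection)
    frames = trajectory.frames[::stride]
    fp = frames.shape[0]
    out = np.zeros((fp, fp))
    for k in range(fp):
        for l in range(k + 1, fp):
            res = kabsch_fit(frames[l, fit_idx], frames[k, fit_idx])
            moved = res.apply(frames[l, meas_idx])
            val = np.sqrt(np.mean(np.sum((moved - frames[k, meas_idx]) ** 2, axis=1)))
            out[k, l] = out[l, k] = val
    return out
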