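"""Dynamic cross-correlation and domain coupling scores.

The DCCM entry for residues i, j is the normalised covariance of their Cα
displacement vectors,

    CC_ij = <Δr_i · Δr_j> / (<|Δr_i|²> <|Δr_j|²>)^(1/2),

computed from the 3×3 blocks of the PCA covariance matrix (Δr is the
displacement from the ensemble-mean position after least-squares fitting).
Per-residue cross-correlation scores sum the off-diagonal row,

    Cs_i = Σ_{j≠i} CC_ij,

split into an intra-domain part (j in residue i's own domain) and
inter-domain parts per partner domain; accumulating Cs over a domain's
residues gives the domain–domain coupling matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .domains import DomainMap
from .errors import UndefinedCorrelationError
from .essential import CovarianceModel


@dataclass
class DCCMatrix:
    """N×N residue–residue correlation matrix, values in [−1, 1]."""

    matrix: np.ndarray
    residue_ids: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        n = len(self.residue_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("DCCM shape does not match residue ids")

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.residue_ids,
                            columns=self.residue_ids)


@dataclass
class ResidueScoreTable:
    """Per-residue total / intra-domain / inter-domain correlation scores."""

    table: pd.DataFrame              # index residue, columns below
    domain_names: tuple[str, ...]

    # columns: domain, cs_total, cs_intra, inter:<name> per domain

    def cs_total(self, residue: int) -> float:
        return float(self.table.loc[residue, "cs_total"])

    def cs_intra(self, residue: int) -> float:
        return float(self.table.loc[residue, "cs_intra"])

    def cs_inter(self, residue: int, domain: str) -> float:
        return float(self.table.loc[residue, f"inter:{domain}"])


@dataclass
class DomainScoreMatrix:
    """D×D accumulated cross-correlation scores between domains."""

    matrix: np.ndarray
    domain_names: tuple[str, ...]
    normalization: str = "raw-sum"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.domain_names),
                            columns=list(self.domain_names))


def compute_dccm(cov: CovarianceModel) -> DCCMatrix:
    """DCCM from the 3×3 blocks of a Cα covariance matrix.

    ``<Δr_i·Δr_j>`` is the trace of block (i, j); normalisation uses the
    per-residue self-variances.  A residue with zero self-variance has no
    defined correlation and raises :class:`UndefinedCorrelationError`.
    """
    n = cov.n_atoms
    c4 = cov.matrix.reshape(n, 3, n, 3)
    inner = np.einsum("iaja->ij", c4)
    self_var = np.diag(inner).copy()
    res_ids = cov.residue_ids
    bad = np.flatnonzero(self_var <= 0)
    if len(bad):
        raise UndefinedCorrelationError(
            f"residue {int(res_ids[bad[0]])} has zero self-variance; "
            "correlation undefined"
        )
    cc = inner / np.sqrt(np.outer(self_var, self_var))
    cc = 0.5 * (cc + cc.T)
    return DCCMatrix(matrix=cc, residue_ids=res_ids)


def residue_scores(dccm: DCCMatrix, domain_map: DomainMap) -> ResidueScoreTable:
    """Per-residue cross-correlation scores: total, intra- and inter-domain.

    Residues not covered by the domain map get ``cs_total`` only (intra and
    inter entries are NaN).  For covered residues
    ``cs_intra + Σ_b cs_inter[b] = cs_total`` holds by construction.
    """
    res_ids = dccm.residue_ids
    m = dccm.matrix - np.diag(np.diag(dccm.matrix))    # exclude self-term
    names = domain_map.names
    dom_of = np.array([domain_map.domain_of(r) for r in res_ids], dtype=object)
    col_mask = {name: dom_of == name for name in names}
    data = {
        "domain": dom_of,
        "cs_total": m.sum(axis=1),
    }
    per_domain = {name: m[:, col_mask[name]].sum(axis=1) for name in names}
    intra = np.full(len(res_ids), np.nan)
    inter = {name: np.full(len(res_ids), np.nan) for name in names}
    for i, dom in enumerate(dom_of):
        if dom is None:
            continue
        intra[i] = per_domain[dom][i]
        for name in names:
            if name != dom:
                inter[name][i] = per_domain[name][i]
    data["cs_intra"] = intra
    for name in names:
        data[f"inter:{name}"] = inter[name]
    table = pd.DataFrame(data, index=res_ids)
    table.index.name = "residue"
    return ResidueScoreTable(table=table, domain_names=tuple(names))


def domain_score_matrix(scores: ResidueScoreTable, domain_map: DomainMap,
                        normalization: str = "raw-sum") -> DomainScoreMatrix:
    """Accumulate per-residue scores into a D×D domain coupling matrix.

    Off-diagonal entry (a, b) sums ``cs_inter[b]`` over residues of domain a;
    the diagonal sums intra-domain scores.  ``raw-sum`` (default) reports the
    accumulated sums, which scale with domain size; ``per-residue-pair``
    divides each entry by its number of contributing ordered residue pairs,
    giving a size-independent mean correlation.
    """
    if normalization not in ("raw-sum", "per-residue-pair"):
        raise ValueError(f"unknown normalization {normalization!r}")
    names = scores.domain_names
    t = scores.table
    d = len(names)
    out = np.zeros((d, d))
    counts = np.zeros((d, d))
    sizes = {name: int((t["domain"] == name).sum()) for name in names}
    for a, name_a in enumerate(names):
        rows = t[t["domain"] == name_a]
        out[a, a] = np.nansum(rows["cs_intra"].to_numpy()) if len(rows) else 0.0
        counts[a, a] = max(sizes[name_a] * (sizes[name_a] - 1), 1)
        for b, name_b in enumerate(names):
            if a == b:
                continue
            out[a, b] = np.nansum(rows[f"inter:{name_b}"].to_numpy()) if len(rows) else 0.0
            counts[a, b] = max(sizes[name_a] * sizes[name_b], 1)
    out = 0.5 * (out + out.T)
    if normalization == "per-residue-pair":
        out = out / counts
    return DomainScoreMatrix(matrix=out, domain_names=tuple(names),
                             normalization=normalization)


def dccm_difference(d1: DCCMatrix, d2: DCCMatrix) -> DCCMatrix:
    """Entrywise d1 − d2 (values in [−2, 2]); residue maps must agree."""
    if d1.matrix.shape != d2.matrix.shape or not np.array_equal(
            d1.residue_ids, d2.residue_ids):
        raise ValueError("DCCMs have different residues; cannot difference")
    return DCCMatrix(matrix=d1.matrix - d2.matrix, residue_ids=d1.residue_ids)
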