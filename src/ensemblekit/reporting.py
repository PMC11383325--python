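"""Run configuration, single-ensemble analysis runs, and paired comparisons.

``run_single`` executes a requested subset of analyses on one ensemble and
writes deterministic, checksummed outputs; ``run_compare`` runs two
ensembles with identical settings (the wild-type-vs-mutant or low-vs-high
temperature pattern) and emits paired tables and difference maps.

Numeric CSV output uses 6 significant digits; occupancies are printed to one
decimal.  Manifests list every written file with its SHA-256 checksum, so
identical (config, input, seed) triples give byte-identical output trees.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correlation import compute_dccm, dccm_difference, domain_score_matrix, residue_scores
from .domains import load_domain_map
from .errors import ComparisonIncompatibleError
from .essential import build_covariance, eigendecompose, export_mode_endpoints, project_trajectory
from .hbonds import HBondCriteria, hbond_count_series, occupancy_table
from .pdbio import read_structure, read_trajectory, write_structure
from .sasa import sasa_series
from .structure import AtomSelection
from .superpose import domain_rmsd_series, pairwise_rmsd_matrix, rmsd_series, rmsf_per_residue

log = logging.getLogger(__name__)

ALL_ANALYSES = ("rmsd", "rmsf", "rmsd-matrix", "pca", "dccm",
                "domain-scores", "hbonds", "sasa")

FLOAT_FORMAT = "%.6g"


@dataclass
class RunConfig:
    """Validated settings of one analysis run."""

    structure: str
    trajectory: str
    out_dir: str
    domain_map: str | None = None
    trajectory_dialect: str = "multimodel-pdb"
    label: str = "ensemble"
    fit_selection: str = "backbone"
    superpose: bool = True
    stride: int = 1                      # frame stride applied at load time
    dt_ps: float = 1.0
    pca_modes: int = 2
    mode_amplitude: float = 2.0
    rmsd_matrix_max_frames: int = 100
    hbond_stride: int = 10
    sasa_stride: int = 10
    min_occupancy_percent: float = 10.0
    hbond_distance_nm: float = 0.35
    hbond_angle_deg: float = 30.0
    sasa_probe_radius_nm: float = 0.14
    sasa_n_points: int = 960
    seed: int | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def validate(self) -> None:
        for p in (self.structure, self.trajectory, self.domain_map):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config references missing path: {p}")
        for name in ("stride", "hbond_stride", "sasa_stride"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        AtomSelection.from_name(self.fit_selection)

    def canonical_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    def sha256(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()


@dataclass
class RunResult:
    """Outputs and in-memory artifacts of one run_single call."""

    label: str
    out_dir: Path
    manifest: dict
    artifacts: dict = field(default_factory=dict)


@dataclass
class ComparisonReport:
    """Paired analysis of two ensembles under identical settings."""

    labels: tuple[str, str]
    results: tuple[RunResult, RunResult]
    diff_tables: dict
    manifest: dict
    out_dir: Path


def _sha256_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _OutputTracker:
    def __init__(self, out_dir: Path):
        self.out_dir = Path(out_dir)
        self.out_dir.mkdir(parents=True, exist_ok=True)
        self.files: list[str] = []

    def path(self, name: str) -> Path:
        self.files.append(name)
        return self.out_dir / name

    def write_table(self, df: pd.DataFrame, name: str, sep: str = ",",
                    index: bool = False, float_format: str = FLOAT_FORMAT):
        df.to_csv(self.path(name), sep=sep, index=index,
                  float_format=float_format)

    def checksums(self) -> dict[str, str]:
        return {name: _sha256_file(self.out_dir / name) for name in self.files}


def _series_frame(series, value_name: str) -> pd.DataFrame:
    return pd.DataFrame({"time_ps": series.times, value_name: series.values})


def _safe_name(domain: str) -> str:
    return "".join(c if c.isalnum() or c in "-_" else "_" for c in domain)


def run_single(config: RunConfig, analyses=None) -> RunResult:
    """Run the requested analyses (all by default) and write their outputs.

    The manifest (written last) lists every output file with its SHA-256
    checksum plus a provenance block: config hash, package version, seed.
    """
    analyses = list(analyses) if analyses is not None else list(ALL_ANALYSES)
    unknown = set(analyses) - set(ALL_ANALYSES)
    if unknown:
        raise ValueError(f"unknown analyses: {sorted(unknown)}")
    config.validate()
    t0 = time.time()

    structure = read_structure(config.structure)
    dmap = load_domain_map(config.domain_map, structure) if config.domain_map else None
    traj = read_trajectory(config.trajectory, structure,
                           dialect=config.trajectory_dialect, dt_ps=config.dt_ps)
    if config.stride > 1:
        traj = traj.strided(config.stride)
    fit_sel = AtomSelection.from_name(config.fit_selection)
    tracker = _OutputTracker(Path(config.out_dir))
    artifacts: dict = {}

    def covariance():
        if "cov" not in artifacts:
            artifacts["cov"] = build_covariance(
                traj, fit_selection=fit_sel, superpose=config.superpose)
        return artifacts["cov"]

    if "rmsd" in analyses:
        series = rmsd_series(traj, fit_selection=fit_sel)
        artifacts["rmsd"] = series
        tracker.write_table(_series_frame(series, "rmsd_nm"), "rmsd.csv")
        if dmap is not None:
            for name in dmap.names:
                dom_series = domain_rmsd_series(traj, None, dmap, name)
                tracker.write_table(
                    _series_frame(dom_series, "rmsd_nm"),
                    f"rmsd_{_safe_name(name)}.csv")
        log.info("[%s] rmsd done (%.1fs)", config.label, time.time() - t0)

    if "rmsf" in analyses:
        res_ids, rmsf = rmsf_per_residue(traj, fit_selection=fit_sel,
                                         superpose=config.superpose)
        artifacts["rmsf"] = (res_ids, rmsf)
        tracker.write_table(
            pd.DataFrame({"residue": res_ids, "rmsf_nm": rmsf}), "rmsf.csv")
        log.info("[%s] rmsf done (%.1fs)", config.label, time.time() - t0)

    if "rmsd-matrix" in analyses:
        stride = max(1, math.ceil(traj.n_frames / config.rmsd_matrix_max_frames))
        matrix = pairwise_rmsd_matrix(traj, fit_selection=fit_sel, stride=stride)
        times = traj.times[::stride]
        df = pd.DataFrame(matrix, index=times, columns=times)
        df.index.name = "time_ps"
        tracker.write_table(df, "rmsd_matrix.csv", index=True)
        log.info("[%s] rmsd-matrix done (%.1fs)", config.label, time.time() - t0)

    if "pca" in analyses:
        cov = covariance()
        eig = eigendecompose(cov)
        artifacts["eig"] = eig
        total = eig.eigenvalues.sum() or 1.0
        tracker.write_table(pd.DataFrame({
            "mode": np.arange(1, eig.n_modes + 1),
            "eigenvalue_nm2": eig.eigenvalues,
            "cumulative_fraction": np.cumsum(eig.eigenvalues) / total,
        }), "eigenvalues.csv")
        tracker.write_table(pd.DataFrame(
            {"quantity": ["covariance_trace_nm2", "n_frames"],
             "value": [cov.trace, cov.n_frames_used]}), "pca_summary.csv")
        pcs = tuple(range(min(config.pca_modes, eig.n_modes)))
        proj = project_trajectory(traj, cov, eig, pcs=pcs)
        tracker.write_table(proj.to_frame(), "projection.csv")
        plus, minus, arrows = export_mode_endpoints(
            cov, eig, pc=0, amplitude=config.mode_amplitude)
        write_structure(plus, tracker.path("pc1_plus.pdb"))
        write_structure(minus, tracker.path("pc1_minus.pdb"))
        tracker.write_table(arrows, "pc1_arrows.tsv", sep="\t")
        log.info("[%s] pca done (%.1fs)", config.label, time.time() - t0)

    if "dccm" in analyses or "domain-scores" in analyses:
        dccm = compute_dccm(covariance())
        artifacts["dccm"] = dccm
        if "dccm" in analyses:
            df = dccm.to_frame()
            df.index.name = "residue"
            tracker.write_table(df, "dccm.csv", index=True)
            log.info("[%s] dccm done (%.1fs)", config.label, time.time() - t0)

    if "domain-scores" in analyses:
        if dmap is None:
            raise ValueError("domain-scores requires a domain map")
        scores = residue_scores(artifacts["dccm"], dmap)
        artifacts["scores"] = scores
        tracker.write_table(scores.table, "residue_scores.csv", index=True)
        for norm, fname in (("raw-sum", "domain_scores.csv"),
                            ("per-residue-pair", "domain_scores_per_pair.csv")):
            dsm = domain_score_matrix(scores, dmap, normalization=norm)
            if norm == "raw-sum":
                artifacts["domain_scores"] = dsm
            df = dsm.to_frame()
            df.index.name = f"domain[{norm}]"
            tracker.write_table(df, fname, index=True)
        log.info("[%s] domain-scores done (%.1fs)", config.label, time.time() - t0)

    if "hbonds" in analyses:
        criteria = HBondCriteria(max_da_distance=config.hbond_distance_nm,
                                 max_hda_angle=config.hbond_angle_deg)
        htraj = traj.strided(config.hbond_stride)
        occ = occupancy_table(htraj, criteria,
                              min_occupancy_percent=config.min_occupancy_percent)
        artifacts["hbond_occupancy"] = occ
        table = occ.table.copy()
        table["occupancy_percent"] = table["occupancy_percent"].map(
            lambda v: f"{v:.1f}")
        tracker.write_table(table, "hbond_occupancy.tsv", sep="\t")
        counts = hbond_count_series(htraj, criteria)
        artifacts["hbond_counts"] = counts
        tracker.write_table(_series_frame(counts, "hbond_count"),
                            "hbond_counts.csv")
        log.info("[%s] hbonds done (%.1fs)", config.label, time.time() - t0)

    if "sasa" in analyses:
        straj = traj.strided(config.sasa_stride)
        series, per_res = sasa_series(
            straj, probe_radius=config.sasa_probe_radius_nm,
            n_sphere_points=config.sasa_n_points)
        artifacts["sasa"] = series
        tracker.write_table(_series_frame(series, "sasa_total_nm2"), "sasa.csv")
        tracker.write_table(per_res, "sasa_per_residue.csv")
        log.info("[%s] sasa done (%.1fs)", config.label, time.time() - t0)

    manifest = {
        "label": config.label,
        "package_version": __version__,
        "config_sha256": config.sha256(),
        "seed": config.seed,
        "analyses": analyses,
        "files": tracker.checksums(),
    }
    with open(tracker.out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    log.info("[%s] run complete: %d files (%.1fs)",
             config.label, len(manifest["files"]), time.time() - t0)
    return RunResult(label=config.label, out_dir=tracker.out_dir,
                     manifest=manifest, artifacts=artifacts)


def _check_compatible(a: RunConfig, b: RunConfig):
    sa = read_structure(a.structure)
    sb = read_structure(b.structure)
    if sa.n_residues != sb.n_residues:
        raise ComparisonIncompatibleError(
            f"residue counts differ: {sa.n_residues} vs {sb.n_residues}")
    if (a.domain_map is None) != (b.domain_map is None):
        raise ComparisonIncompatibleError("only one config has a domain map")
    if a.domain_map and b.domain_map:
        da = load_domain_map(a.domain_map).to_dict()
        db = load_domain_map(b.domain_map).to_dict()
        if da != db:
            raise ComparisonIncompatibleError("domain maps differ")


def run_compare(config_a: RunConfig, config_b: RunConfig,
                labels: tuple[str, str] | None = None,
                analyses=None, out_dir=None) -> ComparisonReport:
    """Analyse two ensembles with identical settings and difference them.

    Writes each ensemble's full output tree under its label, then paired
    RMSF/RMSD tables and DCCM / domain-score difference maps under ``diff/``,
    plus a top-level manifest covering everything.
    """
    labels = labels or (config_a.label, config_b.label)
    if labels[0] == labels[1]:
        labels = (labels[0] + "_a", labels[1] + "_b")
    _check_compatible(config_a, config_b)
    out = Path(out_dir) if out_dir else Path(config_a.out_dir).parent / "comparison"
    results = []
    for cfg, lab in zip((config_a, config_b), labels):
        cfg.label = lab
        cfg.out_dir = str(out / lab)
        results.append(run_single(cfg, analyses))
    ra, rb = results

    tracker = _OutputTracker(out / "diff")
    diff_tables: dict = {}
    if "dccm" in ra.artifacts and "dccm" in rb.artifacts:
        diff = dccm_difference(ra.artifacts["dccm"], rb.artifacts["dccm"])
        diff_tables["dccm"] = diff
        df = diff.to_frame()
        df.index.name = "residue"
        tracker.write_table(df, f"dccm_{labels[0]}_minus_{labels[1]}.csv",
                            index=True)
    if "domain_scores" in ra.artifacts and "domain_scores" in rb.artifacts:
        dm = (ra.artifacts["domain_scores"].to_frame()
              - rb.artifacts["domain_scores"].to_frame())
        diff_tables["domain_scores"] = dm
        dm.index.name = "domain"
        tracker.write_table(dm, f"domain_scores_{labels[0]}_minus_{labels[1]}.csv",
                            index=True)
    if "rmsf" in ra.artifacts and "rmsf" in rb.artifacts:
        (res_a, va), (res_b, vb) = ra.artifacts["rmsf"], rb.artifacts["rmsf"]
        paired = pd.DataFrame({
            "residue": res_a,
            f"rmsf_nm[{labels[0]}]": va,
            f"rmsf_nm[{labels[1]}]": np.interp(res_a, res_b, vb) if
            not np.array_equal(res_a, res_b) else vb,
        })
        paired["difference_nm"] = (paired.iloc[:, 1] - paired.iloc[:, 2])
        diff_tables["rmsf"] = paired
        tracker.write_table(paired, "rmsf_paired.csv")
    if "rmsd" in ra.artifacts and "rmsd" in rb.artifacts:
        sa, sb = ra.artifacts["rmsd"], rb.artifacts["rmsd"]
        n = min(len(sa.values), len(sb.values))
        paired = pd.DataFrame({
            "time_ps": sa.times[:n],
            f"rmsd_nm[{labels[0]}]": sa.values[:n],
            f"rmsd_nm[{labels[1]}]": sb.values[:n],
        })
        diff_tables["rmsd"] = paired
        tracker.write_table(paired, "rmsd_paired.csv")

    manifest = {
        "labels": list(labels),
        "package_version": __version__,
        "config_sha256": {labels[0]: config_a.sha256(),
                          labels[1]: config_b.sha256()},
        "runs": {r.label: r.manifest["files"] for r in results},
        "diff_files": tracker.checksums(),
    }
    with open(out / "comparison_manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return ComparisonReport(labels=labels, results=(ra, rb),
                            diff_tables=diff_tables, manifest=manifest,
                            out_dir=out)
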