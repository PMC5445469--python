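"""Job orchestration: parse a driver config, run cPCA/dpPCA, write outputs.

A job is described by a flat ``key = value`` text config (comments with
'#').  Required keys name the input (``pdb_list`` — a text file of PDB
paths in frame order — or ``coordinate_matrix``); everything else has
defaults.  Recognised keys:

    pdb_list / coordinate_matrix   input (one required)
    selection        "all" or e.g. "A:1-50,B:12,B:20-25"   (default all)
    reference_index  integer (default 0)
    pca              cpca | dppca | both                   (default cpca)
    matrices         comma list from Q,R,P                 (default Q,R,P)
    modes_retained   integer (default 20)
    zscore_cutoff    decimal; <= 0 disables                (default 0)
    outlier_mode     zscore_replace | rmsd_frame_drop | off
    pair_list        residue-pair file (required for dpPCA)
    fes_modes        e.g. "1,2" -> write an FES over those PCs (optional)
    fes_temperature  Kelvin (default 300)
    animate_modes    e.g. "1:0" = k0:window -> Q/R/P mode animations (optional)
    out_dir          output directory (default essdyn_out)
    seed             integer, recorded in the log (default 0)

Unknown keys warn rather than fail.  The run log records every stage with
counts; all numeric output files are deterministic for a fixed config.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import io as sio
from .alignment import align_trajectory, residue_rmsf
from .animation import AnimationSpec, write_animation
from .distances import distance_matrix, pair_list_from_file
from .fes import free_energy_surface
from .outliers import rmsd_frame_drop, zscore_replace
from .pca import (
    ModeSet,
    eigendecompose,
    matrix_bundle,
    mean_center,
    mode_msf,
    project,
)

__all__ = ["JobConfig", "parse_config", "serialize_config", "run_job", "run_batch"]

_DEFAULTS = {
    "selection": "all",
    "reference_index": 0,
    "pca": "cpca",
    "matrices": "Q,R,P",
    "modes_retained": 20,
    "zscore_cutoff": 0.0,
    "outlier_mode": "zscore_replace",
    "fes_temperature": 300.0,
    "out_dir": "essdyn_out",
    "seed": 0,
}


@dataclass
class JobConfig:
    pdb_list: str | None = None
    coordinate_matrix: str | None = None
    selection: str = "all"
    reference_index: int = 0
    pca: str = "cpca"  # cpca | dppca | both
    matrices: tuple[str, ...] = ("Q", "R", "P")
    modes_retained: int = 20
    zscore_cutoff: float = 0.0
    outlier_mode: str = "zscore_replace"
    pair_list: str | None = None
    fes_modes: tuple[int, int] | None = None
    fes_temperature: float = 300.0
    animate_modes: tuple[int, int] | None = None  # (k0, w)
    out_dir: str = "essdyn_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.modes_retained < 1:
            raise ValueError("modes_retained must be >= 1")
        if self.pca not in ("cpca", "dppca", "both"):
            raise ValueError(f"unknown pca kind {self.pca!r}")
        bad = [mk for mk in self.matrices if mk not in ("Q", "R", "P")]
        if bad:
            raise ValueError(f"unknown matrix kind(s) {bad}")
        if self.pdb_list is None and self.coordinate_matrix is None:
            raise ValueError("missing required key: pdb_list or coordinate_matrix")
        if self.pca in ("dppca", "both") and self.pair_list is None:
            raise ValueError("dpPCA requested but no pair_list given")


def parse_selection(spec: str) -> sio.ResidueSelection | str:
    """Parse "A:1-50,B:12" into a ResidueSelection; "all" passes through."""
    spec = spec.strip()
    if spec.lower() == "all":
        return "all"
    entries: list[tuple[str, int]] = []
    for part in spec.split(","):
        part = part.strip()
        chain, _, resspec = part.partition(":")
        if not resspec:
            raise ValueError(f"bad selection element {part!r} (expected chain:res)")
        if "-" in resspec:
            lo, hi = resspec.split("-")
            entries += [(chain, r) for r in range(int(lo), int(hi) + 1)]
        else:
            entries.append((chain, int(resspec)))
    return sio.ResidueSelection(tuple(entries))


def parse_config(path: str | Path) -> JobConfig:
    """Parse a flat key = value driver file into a validated JobConfig."""
    raw: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if "=" not in stripped:
            raise ValueError(f"{path}: line {lineno} is not 'key = value'")
        key, _, value = stripped.partition("=")
        raw[key.strip()] = value.strip()

    known = set(JobConfig.__dataclass_fields__)
    for key in raw:
        if key not in known:
            warnings.warn(f"{path}: unknown config key {key!r} ignored")

    def get(key, cast=str, default=None):
        if key in raw:
            return cast(raw[key])
        return _DEFAULTS.get(key, default)

    def pair_of_ints(value: str) -> tuple[int, int]:
        a, b = value.replace(":", ",").split(",")
        return int(a), int(b)

    return JobConfig(
        pdb_list=raw.get("pdb_list"),
        coordinate_matrix=raw.get("coordinate_matrix"),
        selection=get("selection"),
        reference_index=get("reference_index", int),
        pca=get("pca"),
        matrices=tuple(s.strip() for s in get("matrices").split(",")),
        modes_retained=get("modes_retained", int),
        zscore_cutoff=get("zscore_cutoff", float),
        outlier_mode=get("outlier_mode"),
        pair_list=raw.get("pair_list"),
        fes_modes=pair_of_ints(raw["fes_modes"]) if "fes_modes" in raw else None,
        fes_temperature=get("fes_temperature", float),
        animate_modes=(
            pair_of_ints(raw["animate_modes"]) if "animate_modes" in raw else None
        ),
        out_dir=get("out_dir"),
        seed=get("seed", int),
    )


def serialize_config(config: JobConfig, path: str | Path) -> None:
    lines = []
    for key, value in asdict(config).items():
        if value is None:
            continue
        if isinstance(value, tuple):
            value = ",".join(str(v) for v in value)
        lines.append(f"{key} = {value}")
    Path(path).write_text("\n".join(lines) + "\n")


def _write_matrix(path: Path, M: np.ndarray, header: str) -> None:
    sio.write_coordinate_matrix(path, np.atleast_2d(M), header=header)


def _write_vector(path: Path, v: np.ndarray, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        for x in np.asarray(v).ravel():
            fh.write(f"{x:.12e}\n")


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.lines: list[str] = ["# run log"]
        self.t0 = time.perf_counter()

    def stage(self, message: str) -> None:
        dt = time.perf_counter() - self.t0
        self.lines.append(f"[{dt:9.3f}s] {message}")
        self.path.write_text("\n".join(self.lines) + "\n")


def _analyze(
    data: np.ndarray,
    config: JobConfig,
    out: Path,
    log: _RunLog,
    cartesian: bool,
    labels=None,
    mean_structure: np.ndarray | None = None,
) -> dict[str, ModeSet]:
    """Outlier-treat, centre, build Q/R/P, decompose, project; write files."""
    kind_name = "cPCA" if cartesian else "dpPCA"
    if config.outlier_mode == "zscore_replace" and config.zscore_cutoff > 0:
        data, report = zscore_replace(data, config.zscore_cutoff)
        log.stage(
            f"{kind_name}: z-score outlier replacement, cutoff "
            f"{config.zscore_cutoff}: {report.replaced_count} cells replaced"
        )
        (out / "outlier_report.txt").write_text(report.to_text())
    centered, means = mean_center(data)
    bundle = matrix_bundle(centered, cartesian=cartesian)
    k = min(config.modes_retained, data.shape[0])
    mode_sets: dict[str, ModeSet] = {}
    matrices = {"Q": bundle.Q, "R": bundle.R, "P": bundle.P}
    inverses = {
        "Q": ("inverse_covariance", bundle.inverse_covariance),
        "R": ("precision", bundle.precision),
        "P": ("anti_image", bundle.anti_image),
    }
    reduced = {"Q": bundle.reduced_Q, "R": bundle.reduced_R, "P": bundle.reduced_P}
    for mk in config.matrices:
        M = matrices[mk]
        modes = eigendecompose(M, k=k, matrix_kind=mk)
        mode_sets[mk] = modes
        _write_matrix(out / f"{mk}_matrix.txt", M, f"{mk} matrix ({kind_name})")
        inv_name, inv = inverses[mk]
        _write_matrix(out / f"{mk}_{inv_name}.txt", inv, f"{inv_name} ({mk}^-1)")
        if cartesian and reduced[mk] is not None:
            _write_matrix(
                out / f"reduced_{mk}.txt",
                reduced[mk],
                f"reduced (residue-level block-trace) {mk} matrix",
            )
        _write_vector(
            out / f"{mk}_eigenvalues.txt",
            modes.eigenvalues_full,
            f"all eigenvalues of {mk}, descending; trace={modes.trace:.8e}; "
            f"sample (n-1) covariance normalisation",
        )
        _write_matrix(
            out / f"{mk}_top_eigenvectors.txt",
            modes.eigenvectors,
            f"top {modes.k_retained} eigenvectors of {mk} (columns)",
        )
        weighted_ok = bool(np.all(modes.eigenvalues > 0))
        proj = project(centered, modes, weighted=weighted_ok)
        _write_matrix(
            out / f"{mk}_pcs.txt", proj.pcs, f"unweighted PCs of {mk} (modes x frames)"
        )
        if weighted_ok:
            _write_matrix(
                out / f"{mk}_pcs_weighted.txt",
                proj.pcs_weighted,
                f"weighted (unit-variance) PCs of {mk}",
            )
        if cartesian:
            for weighted in (False, True):
                tag = "weighted" if weighted else "unweighted"
                msf = mode_msf(modes, weighted=weighted)
                _write_matrix(
                    out / f"{mk}_msf_{tag}.txt",
                    msf,
                    f"per-residue {tag} MSF of top {mk} modes (modes x residues)",
                )
                _write_matrix(
                    out / f"{mk}_rmsf_{tag}.txt",
                    np.sqrt(msf),
                    f"per-residue {tag} RMSF of top {mk} modes",
                )
        log.stage(
            f"{kind_name}/{mk}: trace={modes.trace:.6g} "
            f"condition_number={modes.condition_number:.6g} rank={modes.rank} "
            f"eigenvalues>1: {modes.n_eigenvalues_gt_one}"
        )
        if config.fes_modes is not None and mk == "Q":
            i, j = config.fes_modes
            pts = np.column_stack([proj.pcs[i - 1], proj.pcs[j - 1]])
            grid = free_energy_surface(pts, temperature=config.fes_temperature)
            grid.to_text(out / f"fes_pc{i}_pc{j}.txt")
            log.stage(f"{kind_name}: FES over PC{i}/PC{j} written")
        if (
            cartesian
            and config.animate_modes is not None
            and mean_structure is not None
        ):
            k0, w = config.animate_modes
            spec = AnimationSpec(k0=k0, w=w, matrix_kind=mk)
            write_animation(out, mean_structure.reshape(-1), modes, spec, labels)
            log.stage(f"{kind_name}/{mk}: animation modes {k0}..{k0 + w} written")
    return mode_sets


def run_job(config: JobConfig) -> Path:
    """Run a full job; returns the output directory.

    Stages: read -> align (cPCA) -> outlier treatment -> Q/R/P PCA ->
    projections -> MSF/RMSF -> reduced matrices -> optional FES/animation.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out / "run_log.txt")
    log.stage(f"job started (seed {config.seed})")
    serialize_config(config, out / "job_config.txt")

    selection = parse_selection(config.selection)
    if config.pdb_list is not None:
        paths = [
            p
            for p in Path(config.pdb_list).read_text().splitlines()
            if p.strip() and not p.startswith("#")
        ]
        traj = sio.read_pdb_frames(
            paths,
            selection,
            reference_index=config.reference_index,
            log_path=out / "pdb_read.log",
        )
    else:
        traj = sio.read_coordinate_matrix(
            config.coordinate_matrix, reference_index=config.reference_index
        )
    log.stage(
        f"read {traj.n_frames} frames x {traj.n_residues} residues "
        f"({traj.data.shape[0]} Cartesian variables)"
    )

    results = {}
    if config.pca in ("cpca", "both"):
        cdir = out / "cPCA"
        cdir.mkdir(exist_ok=True)
        aligned = align_trajectory(traj)
        if config.outlier_mode == "rmsd_frame_drop" and config.zscore_cutoff > 0:
            aligned, report = rmsd_frame_drop(aligned, config.zscore_cutoff)
            (cdir / "outlier_report.txt").write_text(report.to_text())
            log.stage(f"cPCA: dropped {report.replaced_count} RMSD-outlier frames")
        rmsf = residue_rmsf(aligned)
        sio.write_coordinate_matrix(
            cdir / "aligned_coordinates.txt", aligned.data, header="aligned 3m x n"
        )
        _write_vector(cdir / "rmsd_per_frame.txt", aligned.rmsd_per_frame,
                      "RMSD to reference per frame (A)")
        _write_vector(cdir / "rmsf_per_residue.txt", rmsf,
                      "trajectory RMSF per residue (A)")
        mean_struct = aligned.mean_structure
        sio.write_ca_pdb(
            cdir / "mean_structure_rmsf_bfactors.pdb",
            mean_struct,
            aligned.labels,
            bfactors=rmsf,
        )
        log.stage("cPCA: alignment and RMSD/RMSF written")
        results["cpca"] = _analyze(
            aligned.data,
            config,
            cdir,
            log,
            cartesian=True,
            labels=aligned.labels,
            mean_structure=mean_struct,
        )
    if config.pca in ("dppca", "both"):
        ddir = out / "dpPCA"
        ddir.mkdir(exist_ok=True)
        sel = (
            selection
            if isinstance(selection, sio.ResidueSelection)
            else sio.ResidueSelection(tuple(traj.labels))
        )
        pairs = pair_list_from_file(config.pair_list, sel)
        D = distance_matrix(traj, pairs)
        sio.write_coordinate_matrix(
            ddir / "distance_matrix.txt", D, header="pair distances (A), pairs x frames"
        )
        log.stage(f"dpPCA: {len(pairs)} pair distances over {D.shape[1]} frames")
        results["dppca"] = _analyze(D, config, ddir, log, cartesian=False)
    log.stage("job finished")
    return out


def run_batch(config_paths: list[str | Path]) -> list[Path]:
    """Run several driver files in sequence, each with its own output tree."""
    return [run_job(parse_config(p)) for p in config_paths]
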