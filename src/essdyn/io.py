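"""Structure and matrix I/O.

Reads ordered sets of single-frame PDB files (or one multi-model PDB) into a
coordinate ``Trajectory`` at the coarse-grained level of alpha carbons, and
round-trips plain-text coordinate matrices.  Also writes CA-trace PDB files
and replaces B-factor columns in an existing PDB with per-residue values
(e.g. RMSF) without touching any other column.

Conventions: ATOM records only; altloc '' preferred, then 'A'; for duplicate
insertion codes on one residue number only the first is kept (with a
warning); residue numbering is the PDB's own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser

__all__ = [
    "ResidueSelection",
    "Trajectory",
    "read_pdb_frames",
    "read_coordinate_matrix",
    "write_coordinate_matrix",
    "write_pdb_bfactors",
    "write_ca_pdb",
]


@dataclass(frozen=True)
class ResidueSelection:
    """Ordered residue selection; entry order defines variable order downstream.

    Entries are ``(chain_id, residue_number)`` pairs.  The selection need not
    be contiguous and may span chains.
    """

    entries: tuple[tuple[str, int], ...]
    contiguous: bool = False

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("ResidueSelection must contain at least one residue")
        if len(set(self.entries)) != len(self.entries):
            raise ValueError("duplicate (chain, residue) pairs in selection")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __contains__(self, item) -> bool:
        return item in self.entries


@dataclass
class Trajectory:
    """A variables x frames coordinate matrix with residue labels.

    For Cartesian trajectories rows are interleaved per residue
    (x1, y1, z1, x2, ...), so the row count is 3m for m residues.  Units Å.
    """

    data: np.ndarray
    labels: list[tuple[str, int]]
    frame_ids: list[str] = field(default_factory=list)
    reference_index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("trajectory data must be 2-D (variables x frames)")
        if self.data.shape[0] != 3 * len(self.labels):
            raise ValueError(
                f"row count {self.data.shape[0]} != 3 x {len(self.labels)} residues"
            )
        if not self.frame_ids:
            self.frame_ids = [f"frame_{i}" for i in range(self.n_frames)]
        if len(self.frame_ids) != self.n_frames:
            raise ValueError("frame_ids length must equal frame count")
        if not (0 <= self.reference_index < self.n_frames):
            raise ValueError("reference_index out of range")

    @property
    def n_residues(self) -> int:
        return len(self.labels)

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    def frame(self, t: int) -> np.ndarray:
        """Coordinates of frame ``t`` as an (m, 3) array."""
        return self.data[:, t].reshape(-1, 3)

    @property
    def reference(self) -> np.ndarray:
        return self.frame(self.reference_index)


_parser = PDBParser(QUIET=True)


def _ca_atom(residue):
    atom = residue["CA"]
    if atom.is_disordered():
        ids = atom.disordered_get_id_list()
        pick = "A" if "A" in ids else ids[0]
        atom = atom.disordered_get(pick)
    return atom


def _frame_residues(model, path):
    """Map (chain, resnum) -> residue for ATOM residues with a CA atom."""
    seen: dict[tuple[str, int], object] = {}
    order: list[tuple[str, int]] = []
    for chain in model:
        for residue in chain:
            hetfield, resseq, icode = residue.id
            if hetfield != " " or "CA" not in residue:
                continue
            key = (chain.id, resseq)
            if key in seen:
                warnings.warn(
                    f"{path}: duplicate residue {chain.id}:{resseq} "
                    f"(insertion code {icode!r}); keeping first occurrence"
                )
                continue
            seen[key] = residue
            order.append(key)
    return seen, order


def read_pdb_frames(
    paths: Sequence[str | Path],
    selection: ResidueSelection | str = "all",
    reference_index: int = 0,
    log_path: str | Path | None = None,
) -> Trajectory:
    """Read an ordered set of PDB files (one frame each, or multi-model) into
    a CA trajectory.

    Frame order equals path order (model order within multi-model files).
    With ``selection="all"`` the selection is taken from the first frame in
    file order; otherwise variable order follows the selection's entry order
    regardless of record order in the files.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no input PDB files")

    columns: list[np.ndarray] = []
    frame_ids: list[str] = []
    labels: list[tuple[str, int]] | None = (
        list(selection.entries) if isinstance(selection, ResidueSelection) else None
    )
    log_lines: list[str] = []

    for path in paths:
        structure = _parser.get_structure(path.stem, str(path))
        models = list(structure)
        for model in models:
            seen, order = _frame_residues(model, path)
            if labels is None:
                labels = order
                if not labels:
                    raise ValueError(f"{path}: no CA atoms found")
            coords = np.empty((len(labels), 3))
            for i, (ch, res) in enumerate(labels):
                if (ch, res) not in seen:
                    raise ValueError(
                        f"{path}: missing CA atom for chain {ch} residue {res}"
                    )
                # PDB carries 3 decimals; round the parser's float32 back to them
                coords[i] = np.round(
                    np.asarray(_ca_atom(seen[(ch, res)]).get_coord(), dtype=float), 3
                )
            columns.append(coords.reshape(-1))
            fid = path.name if len(models) == 1 else f"{path.name}:model{model.id}"
            frame_ids.append(fid)
            log_lines.append(f"{len(frame_ids):6d}  {fid}")

    if log_path is not None:
        Path(log_path).write_text(
            "# PDB frames read, in order\n" + "\n".join(log_lines) + "\n"
        )

    data = np.column_stack(columns)
    return Trajectory(data, labels, frame_ids, reference_index)


def write_coordinate_matrix(
    path: str | Path, data: np.ndarray | Trajectory, header: str | None = None
) -> None:
    """Write a variables x frames matrix as space-delimited scientific text
    (18 significant digits, lossless float64 round-trip)."""
    if isinstance(data, Trajectory):
        data = data.data
    data = np.atleast_2d(np.asarray(data, dtype=float))
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for row in data:
            fh.write(" ".join(f"{v:.17e}" for v in row) + "\n")


def read_coordinate_matrix(
    path: str | Path,
    labels: list[tuple[str, int]] | None = None,
    reference_index: int = 0,
    cartesian: bool = True,
) -> Trajectory | np.ndarray:
    """Read a whitespace-delimited numeric matrix (rows = variables,
    columns = frames); lines starting with '#' are comments.

    Returns a ``Trajectory`` when ``cartesian`` is true (row count must be
    divisible by 3), otherwise the bare matrix.
    """
    rows: list[list[float]] = []
    width: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            values = [float(tok) for tok in stripped.split()]
            if width is None:
                width = len(values)
            elif len(values) != width:
                raise ValueError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(values)} values, expected {width})"
                )
            rows.append(values)
    if not rows:
        raise ValueError(f"{path}: empty coordinate matrix")
    data = np.array(rows)
    if not cartesian:
        return data
    if data.shape[0] % 3 != 0:
        raise ValueError(
            f"{path}: {data.shape[0]} rows not divisible by 3 (Cartesian mode)"
        )
    m = data.shape[0] // 3
    if labels is None:
        labels = [("A", i + 1) for i in range(m)]
    return Trajectory(data, labels, reference_index=reference_index)


def write_pdb_bfactors(
    template_path: str | Path,
    values: Sequence[float],
    out_path: str | Path,
    selection: ResidueSelection | None = None,
) -> None:
    """Replace B-factor columns (61-66) of ATOM records with per-residue values.

    All other columns are preserved byte-exact.  One value per selected
    residue; values must be >= 0 and are clamped (with a warning) to the
    999.99 representable in the fixed-width %6.2f field.
    """
    values = list(values)
    if any(v < 0 for v in values):
        raise ValueError("B-factor values must be non-negative")
    template_path = Path(template_path)

    if selection is None:
        # derive selection from the template, in record order
        structure = _parser.get_structure("tpl", str(template_path))
        _, order = _frame_residues(next(iter(structure)), template_path)
        keys = order
    else:
        keys = list(selection.entries)
    if len(values) != len(keys):
        raise ValueError(f"{len(values)} values for {len(keys)} selected residues")
    value_by_res = dict(zip(keys, values))

    out_lines = []
    for line in template_path.read_text().splitlines(keepends=True):
        if line.startswith("ATOM") and len(line) >= 66:
            chain = line[21]
            try:
                resseq = int(line[22:26])
            except ValueError:
                out_lines.append(line)
                continue
            key = (chain, resseq)
            if key in value_by_res:
                v = value_by_res[key]
                if v > 999.99:
                    warnings.warn(f"B-factor {v} clamped to 999.99 for {key}")
                    v = 999.99
                line = line[:60] + f"{v:6.2f}" + line[66:]
        out_lines.append(line)
    Path(out_path).write_text("".join(out_lines))


def write_ca_pdb(
    path: str | Path,
    frames: np.ndarray | Iterable[np.ndarray],
    labels: Sequence[tuple[str, int]],
    bfactors: Sequence[float] | None = None,
) -> None:
    """Write a CA-trace PDB.  ``frames`` is one (m, 3) array or an iterable of
    them; multiple frames are written as MODEL/ENDMDL blocks."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3 or frames.shape[1] != len(labels) or frames.shape[2] != 3:
        raise ValueError("frames must have shape (n_frames, m, 3)")
    b = np.zeros(len(labels)) if bfactors is None else np.asarray(bfactors, float)
    multi = frames.shape[0] > 1
    with open(path, "w") as fh:
        for imodel, coords in enumerate(frames, start=1):
            if multi:
                fh.write(f"MODEL     {imodel:4d}\n")
            for serial, ((chain, resnum), (x, y, z), bf) in enumerate(
                zip(labels, coords, b), start=1
            ):
                fh.write(
                    f"ATOM  {serial:5d}  CA  ALA {chain:1s}{resnum:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{min(bf, 999.99):6.2f}"
                    f"           C\n"
                )
            fh.write("TER\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")
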