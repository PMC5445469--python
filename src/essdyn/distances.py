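"""Internal-coordinate (distance-pair) data matrices for dpPCA.

A user selects residue pairs; the CA-CA Euclidean distance of each pair in
each frame forms the variables x frames matrix.  Because internal distances
are invariant under rigid translations and rotations, no alignment step is
performed or needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import ResidueSelection, Trajectory

__all__ = ["PairList", "distance_matrix", "pair_list_from_file"]

Residue = tuple[str, int]


def _canonical(a: Residue, b: Residue) -> tuple[Residue, Residue]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class PairList:
    """Ordered residue pairs; order defines dpPCA variable order.

    Pairs are unordered internally ((a, b) == (b, a)) and canonicalised by
    chain then residue number.
    """

    pairs: tuple[tuple[Residue, Residue], ...]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("pair list is empty")
        canon = [_canonical(a, b) for a, b in self.pairs]
        for a, b in canon:
            if a == b:
                raise ValueError(f"self-pair {a} not allowed")
        if len(set(canon)) != len(canon):
            raise ValueError("duplicate unordered residue pair")
        object.__setattr__(self, "pairs", tuple(canon))

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


def distance_matrix(traj: Trajectory, pairs: PairList) -> np.ndarray:
    """CA-CA distances (Å) of each pair in each frame: n_pairs x n_frames.

    Raw, unaligned coordinates are acceptable.  Warns if any distance is
    below 1e-6 Å (coincident atoms give a zero-variance variable).
    """
    index = {lab: i for i, lab in enumerate(traj.labels)}
    rows = []
    for a, b in pairs:
        for member in (a, b):
            if member not in index:
                raise ValueError(f"pair member {member} not in trajectory selection")
        ia, ib = index[a], index[b]
        xa = traj.data[3 * ia : 3 * ia + 3, :]
        xb = traj.data[3 * ib : 3 * ib + 3, :]
        rows.append(np.sqrt(((xa - xb) ** 2).sum(axis=0)))
    D = np.vstack(rows)
    if (D < 1e-6).any():
        warnings.warn("coincident atoms in a residue pair: zero-variance risk")
    return D


def pair_list_from_file(
    path: str | Path, selection: ResidueSelection | None = None
) -> PairList:
    """Read a pair list: one pair per line, ``chain res chain res``.

    Lines starting with '#' are comments.  Errors carry the offending line
    number; with a selection given, every member must belong to it.
    """
    pairs: list[tuple[Residue, Residue]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if len(tokens) != 4:
                raise ValueError(
                    f"{path}: malformed pair at line {lineno}: {stripped!r} "
                    "(expected: chain res chain res)"
                )
            try:
                a = (tokens[0], int(tokens[1]))
                b = (tokens[2], int(tokens[3]))
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-integer residue number at line {lineno}"
                ) from exc
            if selection is not None:
                for member in (a, b):
                    if member not in selection:
                        raise ValueError(
                            f"{path}: line {lineno}: residue {member} "
                            "not in the analysis selection"
                        )
            pairs.append((a, b))
    return PairList(tuple(pairs))
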