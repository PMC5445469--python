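"""Trajectory pooling for comparative PCA.

Multiple trajectories sharing the same variable space are concatenated
column-wise into one augmented data matrix so a single joint PCA describes
all systems at once.  For Cartesian pooling every frame of every source is
first superposed onto one common reference (the first source's reference
frame), since a joint covariance needs a shared coordinate frame; distance
pooling needs no alignment.  The pooled matrix is centred with the pooled
grand mean, so a displacement between systems remains visible as signal in
the joint PCs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import AlignedTrajectory, optimal_superposition
from .io import Trajectory
from .pca import ModeSet, mean_center, project

__all__ = ["PooledTrajectory", "pool", "per_block_projections"]


@dataclass
class PooledTrajectory:
    """Concatenated d x (sum n_i) data matrix with per-column source labels."""

    data: np.ndarray
    block_labels: list[str]  # source id per frame column
    offsets: list[int]  # start column of each source
    labels: list[tuple[str, int]] | None = None
    mode: str = "cartesian"  # cartesian | distance

    @property
    def sources(self) -> list[str]:
        seen = dict.fromkeys(self.block_labels)
        return list(seen)

    def block(self, source: str) -> np.ndarray:
        mask = [lab == source for lab in self.block_labels]
        return self.data[:, np.asarray(mask)]


def _aligned_to_common_reference(trajs: list[Trajectory]) -> np.ndarray:
    ref = trajs[0].reference
    ref = ref - ref.mean(axis=0)
    cols = []
    for traj in trajs:
        for t in range(traj.n_frames):
            x = traj.frame(t)
            x = x - x.mean(axis=0)
            R, _ = optimal_superposition(x, ref)
            cols.append((x @ R.T).reshape(-1))
    return np.column_stack(cols)


def pool(
    trajs: list[Trajectory] | list[np.ndarray],
    mode: str = "cartesian",
    source_ids: list[str] | None = None,
) -> PooledTrajectory:
    """Pool trajectories (Cartesian) or distance matrices into one dataset.

    Cartesian inputs are ``Trajectory`` objects with identical residue
    selections; every frame is aligned to the first trajectory's reference
    before concatenation.  Distance inputs are n_pairs x n_frames matrices
    built from identical pair lists.
    """
    if not trajs:
        raise ValueError("nothing to pool")
    if source_ids is None:
        source_ids = [f"source_{i}" for i in range(len(trajs))]
    if len(source_ids) != len(trajs):
        raise ValueError("one source id per trajectory required")

    if mode == "cartesian":
        if not all(isinstance(t, Trajectory) for t in trajs):
            raise TypeError("cartesian pooling expects Trajectory inputs")
        labels0 = trajs[0].labels
        for sid, t in zip(source_ids, trajs):
            if t.labels != labels0:
                raise ValueError(
                    f"variable mismatch: source {sid!r} has a different "
                    "residue selection than the first source"
                )
        data = _aligned_to_common_reference(list(trajs))
        counts = [t.n_frames for t in trajs]
        res_labels = list(labels0)
    elif mode == "distance":
        mats = [np.asarray(t, dtype=float) for t in trajs]
        d0 = mats[0].shape[0]
        for sid, mat in zip(source_ids, mats):
            if mat.shape[0] != d0:
                raise ValueError(
                    f"variable mismatch: source {sid!r} has {mat.shape[0]} "
                    f"pairs, expected {d0} (pair lists must be identical)"
                )
        data = np.column_stack(mats)
        counts = [mat.shape[1] for mat in mats]
        res_labels = None
    else:
        raise ValueError(f"unknown pooling mode {mode!r}")

    block_labels = [
        sid for sid, c in zip(source_ids, counts) for _ in range(c)
    ]
    offsets = [int(x) for x in np.concatenate([[0], np.cumsum(counts)[:-1]])]
    return PooledTrajectory(data, block_labels, offsets, res_labels, mode)


def per_block_projections(
    pooled: PooledTrajectory, modes: ModeSet
) -> dict[str, np.ndarray]:
    """PC time series per source block (grand-mean-centred, unweighted).

    Returns ``{source_id: k x n_i}``; per-system spread statistics (e.g.
    score variance per PC) follow directly.
    """
    centered, _ = mean_center(pooled.data)
    proj = project(centered, modes, weighted=False)
    out: dict[str, np.ndarray] = {}
    labels = np.asarray(pooled.block_labels)
    for source in pooled.sources:
        out[source] = proj.pcs[:, labels == source]
    return out
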