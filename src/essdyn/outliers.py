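"""Outlier treatment ahead of covariance estimation.

Outliers skew Q, R and P toward rare large excursions and inflate condition
numbers.  The primary treatment replaces, per variable and per frame, any
value whose |z-score| exceeds a user cutoff with that variable's mean; an
alternative drops whole conformations whose RMSD to the reference is an
outlier.  Both are single-pass: means and standard deviations are computed
once, before any replacement.  A cutoff <= 0 disables processing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .alignment import AlignedTrajectory

__all__ = ["OutlierReport", "zscore_replace", "rmsd_frame_drop"]


@dataclass(frozen=True)
class OutlierReport:
    cutoff: float
    replaced_count: int
    replaced_fraction: float
    per_variable_counts: tuple[int, ...]
    mode: str  # zscore_replace | rmsd_frame_drop | off

    def to_text(self) -> str:
        lines = [
            f"# outlier treatment: {self.mode}",
            f"# cutoff: {self.cutoff}",
            f"# replaced/removed: {self.replaced_count}",
            f"# fraction: {self.replaced_fraction:.6g}",
            "# per-variable counts:",
        ]
        lines += [f"{i} {c}" for i, c in enumerate(self.per_variable_counts)]
        return "\n".join(lines) + "\n"


def zscore_replace(
    data: np.ndarray, cutoff: float
) -> tuple[np.ndarray, OutlierReport]:
    """Replace per-variable outliers by the variable's pre-pass mean.

    A cell x of variable v is an outlier when |x - mu_v| > cutoff * sd_v,
    with mu_v and sd_v (sample, n-1 denominator) computed over frames before
    any replacement.  Variables with sd 0 are skipped.  ``cutoff <= 0``
    disables the treatment and returns the data unchanged.
    """
    data = np.asarray(data, dtype=float)
    d, n = data.shape
    if cutoff <= 0:
        report = OutlierReport(cutoff, 0, 0.0, tuple([0] * d), "off")
        return data.copy(), report
    if n < 2:
        raise ValueError("z-score treatment requires at least 2 frames")
    mu = data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        flagged = np.abs(data - mu) > cutoff * sd
    flagged &= sd > 0  # zero-variance variables are skipped
    out = np.where(flagged, mu, data)
    per_var = flagged.sum(axis=1)
    total = int(per_var.sum())
    report = OutlierReport(
        cutoff, total, total / (d * n), tuple(int(c) for c in per_var), "zscore_replace"
    )
    return out, report


def rmsd_frame_drop(
    traj: AlignedTrajectory, cutoff: float
) -> tuple[AlignedTrajectory, OutlierReport]:
    """Drop frames whose RMSD-to-reference z-score exceeds the cutoff.

    Surviving frame order is preserved.  ``cutoff <= 0`` disables the
    treatment.  Raises if every frame would be removed.
    """
    rmsd = np.asarray(traj.rmsd_per_frame, dtype=float)
    n = rmsd.size
    if cutoff <= 0:
        report = OutlierReport(cutoff, 0, 0.0, (0,), "off")
        return traj, report
    sd = rmsd.std(ddof=1)
    if sd == 0:
        keep = np.ones(n, dtype=bool)
    else:
        keep = np.abs(rmsd - rmsd.mean()) <= cutoff * sd
    if not keep.any():
        raise ValueError("RMSD outlier cutoff removed every frame")
    dropped = int(n - keep.sum())
    report = OutlierReport(cutoff, dropped, dropped / n, (dropped,), "rmsd_frame_drop")
    idx = np.nonzero(keep)[0]
    new_ref = int(np.searchsorted(idx, traj.reference_index))
    if traj.reference_index not in idx:
        new_ref = 0
    subset = _dc_replace(
        traj,
        data=traj.data[:, keep],
        frame_ids=[traj.frame_ids[i] for i in idx],
        reference_index=new_ref,
        rmsd_per_frame=rmsd[keep],
    )
    return subset, report
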