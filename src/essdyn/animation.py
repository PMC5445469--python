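"""Pseudo-trajectories animating PC modes.

Essential motion over a window of modes k0..k0+w is synthesised as

    X(tau) = X_ref + sum_k A_k sin(omega_k tau) V_k

with amplitude and frequency tied to the eigenvalue: for Q- and R-modes
A_k = C sqrt(lambda_k) and omega_k = B sqrt(1/lambda_k) (large-variance
modes move far and slowly); for P-modes the scalings invert,
A_k = C sqrt(1/lambda_k) and omega_k = B sqrt(lambda_k).  B and C set the
time and space scales; by default C is chosen so the largest peak
displacement in the window is 2 Å, and tau covers one full period of the
slowest mode in the window.

Frames are written as a MODEL/ENDMDL PDB plus PyMOL scripts to load and
play the movie and to colour residues by the animated modes' RMSF
(blue -> red for low -> high).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import write_ca_pdb
from .pca import ModeSet, mode_msf

__all__ = ["AnimationSpec", "mode_amplitudes_frequencies", "synthesize_frames",
           "write_animation", "write_viewer_scripts"]


@dataclass(frozen=True)
class AnimationSpec:
    """Window of modes to animate; ``k0`` is 1-based, window size ``w >= 0``
    animates modes k0..k0+w."""

    k0: int = 1
    w: int = 0
    B: float = 1.0
    C: float | None = None  # None: scale largest peak displacement to 2 Å
    frames_per_cycle: int = 40
    matrix_kind: str = "Q"

    def __post_init__(self) -> None:
        if self.k0 < 1 or self.w < 0:
            raise ValueError("require k0 >= 1 and w >= 0")
        if self.B <= 0 or (self.C is not None and self.C <= 0):
            raise ValueError("B and C must be positive")


def mode_amplitudes_frequencies(
    eigenvalues: np.ndarray, matrix_kind: str, B: float, C: float
) -> tuple[np.ndarray, np.ndarray]:
    """A_k and omega_k for the given eigenvalues under the Q/R or P rules."""
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("zero eigenvalue in animation window: amplitude/"
                         "frequency undefined")
    if matrix_kind in ("Q", "R"):
        return C * np.sqrt(lam), B * np.sqrt(1.0 / lam)
    if matrix_kind == "P":
        return C * np.sqrt(1.0 / lam), B * np.sqrt(lam)
    raise ValueError(f"unknown matrix kind {matrix_kind!r}")


def synthesize_frames(
    ref: np.ndarray,
    modes: ModeSet,
    spec: AnimationSpec,
    n_frames: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesise animation frames about ``ref`` (a 3m vector or (m, 3)).

    Returns ``(frames, taus)`` with frames (n_frames, 3m); ``taus`` spans
    one full cycle of the slowest mode in the window.
    """
    ref = np.asarray(ref, dtype=float).ravel()
    if ref.size != modes.d:
        raise ValueError("reference dimension does not match modes")
    if modes.d % 3:
        raise ValueError("animation requires Cartesian modes")
    lo, hi = spec.k0 - 1, spec.k0 + spec.w
    if hi > modes.k_retained:
        raise ValueError("animation window exceeds retained modes")
    lam = modes.eigenvalues[lo:hi]
    V = modes.eigenvectors[:, lo:hi]
    C = spec.C
    if C is None:
        # peak displacement of the largest-amplitude mode = 2 Å
        A1, _ = mode_amplitudes_frequencies(lam, spec.matrix_kind, spec.B, 1.0)
        C = 2.0 / A1.max()
    A, omega = mode_amplitudes_frequencies(lam, spec.matrix_kind, spec.B, C)
    n_frames = spec.frames_per_cycle if n_frames is None else n_frames
    period = 2 * np.pi / omega.min()
    taus = np.linspace(0.0, period, n_frames, endpoint=False)
    frames = ref[None, :] + np.sin(np.outer(taus, omega)) @ (A[:, None] * V.T)
    return frames, taus


def write_animation(
    out_dir: str | Path,
    ref: np.ndarray,
    modes: ModeSet,
    spec: AnimationSpec,
    labels: list[tuple[str, int]],
) -> Path:
    """Write the animated PDB, viewer scripts and a metadata file.

    Returns the path of the multi-model PDB.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames, taus = synthesize_frames(ref, modes, spec)
    name = f"animation_{spec.matrix_kind}_modes_{spec.k0}_to_{spec.k0 + spec.w}"
    pdb_path = out_dir / f"{name}.pdb"
    msf = mode_msf(
        ModeSet(
            eigenvectors=modes.eigenvectors[:, spec.k0 - 1 : spec.k0 + spec.w],
            eigenvalues=modes.eigenvalues[spec.k0 - 1 : spec.k0 + spec.w],
            matrix_kind=spec.matrix_kind,
            trace=modes.trace,
            condition_number=modes.condition_number,
            k_retained=spec.w + 1,
        ),
        weighted=True,
    ).sum(axis=0)
    rmsf = np.sqrt(msf)
    write_ca_pdb(pdb_path, frames.reshape(len(frames), -1, 3), labels, bfactors=rmsf)
    write_viewer_scripts(pdb_path, rmsf, labels, out_dir, name)
    meta = out_dir / f"{name}_metadata.txt"
    meta.write_text(
        f"matrix_kind {spec.matrix_kind}\nk0 {spec.k0}\nw {spec.w}\n"
        f"B {spec.B}\nC {spec.C if spec.C is not None else 'auto(2A peak)'}\n"
        f"frames {len(frames)}\n"
    )
    return pdb_path


def write_viewer_scripts(
    pdb_path: str | Path,
    rmsf: np.ndarray,
    labels: list[tuple[str, int]],
    out_dir: str | Path,
    name: str,
) -> tuple[Path, Path]:
    """Emit PyMOL scripts: one loading and playing the frames in order, one
    colouring residues blue -> red by per-mode RMSF.  Output is byte-stable
    for fixed input (no timestamps)."""
    out_dir = Path(out_dir)
    pdb_path = Path(pdb_path)
    play = out_dir / f"{name}_play.pml"
    play.write_text(
        f"load {pdb_path.name}, movie\n"
        "set all_states, off\n"
        "mplay\n"
    )
    color = out_dir / f"{name}_color_by_rmsf.pml"
    rmsf = np.asarray(rmsf, dtype=float)
    lo, hi = float(rmsf.min()), float(rmsf.max())
    span = hi - lo if hi > lo else 1.0
    lines = [f"load {pdb_path.name}, movie", "hide everything", "show cartoon"]
    for (chain, resnum), v in zip(labels, rmsf):
        frac = (v - lo) / span  # 0 -> blue, 1 -> red
        r, b = frac, 1.0 - frac
        cname = f"rmsf_{chain}_{resnum}"
        lines.append(f"set_color {cname}, [{r:.4f}, 0.0000, {b:.4f}]")
        lines.append(f"color {cname}, chain {chain} and resi {resnum}")
    color.write_text("\n".join(lines) + "\n")
    return play, color
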