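# Methods

## Trajectory model and alignment

A conformational ensemble is represented as a matrix of 3*m* Cartesian
variables (x, y, z interleaved per residue, Å) over *n* frames, at the
coarse-grained level of one CA atom per selected residue. The residue
selection is an ordered list of (chain, residue-number) pairs; its order,
not the PDB record order, defines the variable order everywhere
downstream.

Internal motion is isolated by superposing every frame onto a
user-designated reference frame: each frame's unweighted CA centroid is
translated to the origin and the frame is rotated by the proper rotation
minimising the least-squares displacement to the likewise-centred
reference. The rotation is obtained from the leading eigenvector of the
4×4 quaternion key matrix built from the 3×3 coordinate cross-covariance;
this is algebraically exact (no iteration) and always proper
(det R = +1). Degenerate configurations — fewer than 3 atoms, or
collinear CA traces, for which the optimal rotation is not unique — are
rejected. Ties in the leading eigenvalue are broken deterministically.
Alignment is single-pass against the chosen reference; no iterative
mean-structure realignment is performed.

A consequence worth stating explicitly: exact centring removes 3 degrees
of freedom, and the stationarity condition of the optimal rotation imposes
3 more linear constraints (Σᵢ refᵢ × xᵢ = 0) that are identical for every
frame. Aligned frames therefore live in a fixed (3*m* − 6)-dimensional
subspace and the Cartesian covariance matrix is *exactly* rank-deficient
by 6, not merely approximately. All full-space inverses in the Cartesian
pipeline (inverse covariance, precision, anti-image) are therefore
computed as eigendecomposition-based pseudo-inverses restricted to the
non-trivial subspace; the strict-inverse route (which raises on singular
input) remains available and is the default for distance-pair data, which
is generically full rank.

## Outlier treatment

Covariance estimates are sensitive to rare large excursions. The primary
treatment is per-variable z-score replacement: with mean μᵥ and *sample*
(n − 1) standard deviation σᵥ computed per variable over frames *before
any replacement*, every cell with |x − μᵥ| > c·σᵥ is replaced by μᵥ. The
pass is single (no iterative re-flagging), variables with σᵥ = 0 are
skipped, and a cutoff c ≤ 0 disables the treatment entirely — a literal
cutoff of 0 would replace every cell, which cannot be meant. Replacement
can only shrink per-variable variance, and on spiked fixtures it
demonstrably lowers the condition number of Q. The common alternative —
dropping whole conformations whose RMSD-to-reference z-score exceeds the
cutoff — is provided as an option; it preserves surviving frame order.
For cPCA the z-scores operate on aligned coordinates, for dpPCA on
distances, i.e. always on the PCA variables themselves.

## The Q / R / P circle

From the row-centred data A′:

- Q = A′(A′)ᵀ/(n − 1). The sample denominator is a deliberate choice: it
  gives eigenvalues and trace the units of variance (Å²) so that
  trace(Q) equals the summed per-residue mean squared fluctuation;
  eigenvectors are unaffected by the normalisation. The denominator is
  recorded in output headers.
- R_ij = Q_ij/√(Q_ii Q_jj); zero-variance variables are a hard error
  naming the variable.
- P_ij = −Ω_ij/√(Ω_ii Ω_jj) with Ω = Q⁻¹ (unit diagonal imposed) — the
  standard negative-normalised convention, so that P has the same sign
  semantics as R.
- R⁻¹ is labelled the precision matrix and P⁻¹ the anti-image matrix;
  Q⁻¹ is labelled the inverse covariance. All three are written with
  explicit labels, covering both common naming conventions.

Eigendecomposition uses a dense symmetric solver, sorts descending, and
fixes the sign of each eigenvector so its largest-magnitude component
(lowest index on ties) is positive, making outputs reproducible and mode
files comparable across runs. The trace (sum of all eigenvalues), the
condition number (λ_max/λ_min over eigenvalues counted non-zero), the
rank, and the count of R-eigenvalues > 1 (the significance rule for
correlated modes) are recorded. Eigenvalues below 1e−9·λ_max count as
zero for rank reporting. Within a degenerate eigenvalue cluster the
individual vectors are basis-dependent (solver order is kept after
sorting); subspace metrics are invariant to this.

Reduced m × m residue-level matrices take the trace of each 3×3
inter-residue block; reduced R and P can optionally be renormalised to
unit diagonal (off by default — the block-trace form is the primary
definition, and the reduced covariance is never renormalised).

Displacement vectors are DV(t) = aligned frame − mean aligned structure,
identical to the centred columns. Unweighted PCs are Vₖᵀ·DV(t) (variance
λₖ); weighted PCs divide by √λₖ (unit variance) and require λₖ > 0.
Per-mode, per-residue MSF sums the squared x, y, z components of the
eigenvector (so it sums to 1 over residues); the weighted form multiplies
by λₖ. Per-residue MSF is undefined for distance-pair modes (no residue
mapping) and raises.

## Distance-pair PCA

Variables are CA–CA Euclidean distances of an ordered user list of
residue pairs (unordered internally, canonicalised by chain then residue
number; self-pairs and duplicates rejected). Distances are invariant
under rigid motion, so dpPCA runs on raw coordinates with no alignment —
the invariance is asserted to 1e−10 Å in tests. The covariance dimension
equals the pair count.

## Subspace similarity

Cumulative overlap CO(v, B) = √Σₖ(v·bₖ)²; RMSIP = √((1/k)ΣᵢΣⱼ(uᵢ·vⱼ)²)
for equal retained dimension (mismatched mode sets are compared at
min(k₁, k₂) with a warning, never silently); principal angles are
arccos of the singular values of UᵀV, clamped to [0, 1] before arccos to
suppress 1 + ε rounding, reported ascending in degrees (4 decimals in
files). The CO formula variant is stated in output headers since several
normalisations circulate. RMSIP and PA are linked by RMSIP²·k = Σcos²θᵢ,
which the tests assert to 1e−10. Angles ≤ 30° are counted as high
similarity per the field's convention, and an RMSIP curve over k = 1..k
supports "how many modes capture the essential dynamics" analyses.

## Free-energy surfaces

The density of n points over two chosen PCs is estimated by a separable
Gaussian KDE with diagonal bandwidths, Silverman's per-axis rule
h = σ·n^(−1/6) by default (overridable). The grid is 100 × 100 spanning
the data range padded by 3 bandwidths, so the tails fall inside the grid
and the Riemann sum of the density is 1 within 2%. The surface is
ΔG = −k_BT ln(p/p_max), exactly 0 at the density maximum; cells with
p < 1e−12·p_max are masked to +∞. Output carries both k_BT and kcal/mol
columns (default T = 300 K, k_B = 0.0019872041 kcal mol⁻¹ K⁻¹); the
temperature and bandwidths are recorded in the file header.

## Mode animation

X(τ) = ref + Σₖ Aₖ sin(ωₖτ) Vₖ over modes k₀..k₀+w, with Aₖ = C√λₖ,
ωₖ = B√(1/λₖ) for Q and R mode sets and the inverted scalings
Aₖ = C√(1/λₖ), ωₖ = B√λₖ for P. By default C is set so the largest peak
displacement in the window is 2 Å and the τ grid covers exactly one
period of the slowest mode (40 frames); faster modes complete non-integer
cycles, which the superposition form implies. Zero eigenvalues in the
window are an error (frequency and amplitude undefined). The animation
centre is the mean aligned structure, consistent with the DV definition.
Frames are written as a MODEL/ENDMDL PDB; PyMOL scripts (load/play and
colour-by-RMSF, blue → red for low → high) are emitted as plain text with
no timestamps, so outputs are byte-stable.

## Pooling

Trajectories sharing a variable space are concatenated column-wise. For
Cartesian pooling every frame of every source is aligned to one common
reference — the first source's reference frame — because a joint
covariance requires a shared coordinate frame; for distance pooling no
alignment is needed and identical pair lists are enforced. The pooled
matrix is centred with the pooled grand mean rather than per-block means:
a displacement between systems is exactly the comparative signal joint
PCA is meant to expose. Both choices are recorded in output headers.
Per-block PC score tables support per-system spread statistics.

## Driver and outputs

A flat `key = value` config (defaults: k = 20 retained modes, outlier
treatment disabled, all of Q, R, P) drives read → align (cPCA only) →
outlier treatment → PCA → projections → MSF/RMSF → reduced matrices →
optional FES and animation. Every numeric output is plain text written at
full float64 precision (18 significant digits, lossless round-trip
through the package's own readers); the run log records each stage with
counts and the diagnostics above. Unknown config keys warn rather than
fail. For a fixed config the numeric outputs are byte-identical across
reruns.

## Synthetic fixtures and what they do (and do not) show

The generator plants orthonormal internal modes with chosen eigenvalues
on toy CA traces (ideal α-helix geometry, extended zig-zag, or a random
walk, all at ~3.8 Å spacing) and samples Gaussian frames
x(t) = ref + Σⱼ√λⱼ zⱼₜ vⱼ, optionally contaminated per frame with random
rigid rotations (≤ 30°) and translations (≤ 5 Å). The six rigid-body
generators (3 unit translations, 3 centred infinitesimal rotation fields
rᵢ × ê, jointly orthonormalised) are exposed so planted modes can be
projected orthogonal to the trivial subspace, which makes the 3m − 6
rank structure exactly testable. Default planted spectra used throughout
the tests are (9, 4, 1) Å² at n = 5000 frames for parameter recovery, a
3-variable chain model with coupling 0.7 at n = 10⁴ for
conditional-independence recovery, and a 70/30 two-cluster mixture at
n = 5000 for the free-energy-basin gap; these sizes keep every check
well inside sampling tolerance while running in seconds.

Gaussian, harmonic-like sampling matches exactly the second-moment
structure PCA estimates — so passing tests show the estimators, the
alignment and the bookkeeping are correct. They do not show anything
about anharmonicity, multi-basin kinetics, solvent memory or sampling
convergence of real molecular dynamics; conclusions about a real system
still require the usual convergence diagnostics (e.g. cosine content of
PC1) on real data.

## Known limitations

- CA-only, ATOM-record-only parsing; altloc '' or 'A' is taken and only
  the first insertion-code duplicate is kept (with a warning). These are
  conventions, stated here, not reproductions of any particular tool.
- Single-reference alignment; no mass-weighting, no iterative mean
  realignment.
- Full dense eigendecomposition: memory O(d²), time O(d³); fine for
  thousands of variables, not for all-atom covariances of large systems.
- KDE bandwidth is fixed per axis (no adaptive bandwidth); FES is 2-D
  only.
- No automatic pair selection for dpPCA; the pair list is the user's
  scientific choice.
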