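# essdyn

Essential dynamics analysis of protein trajectories: Cartesian and
distance-pair principal component analysis with the full circle of
multivariate statistics — covariance, correlation and partial-correlation
mode sets, their precision/anti-image inverses, subspace similarity
metrics, free-energy landscapes, trajectory pooling and PC-mode animation.

## Who this is for

Anyone with an ensemble of protein conformations (molecular dynamics
frames, NMR models, Monte-Carlo snapshots) who wants to extract and
*compare* the collective motions that dominate it: which few modes carry
the motion, whether a mutant moves like the native, whether two
trajectories explore the same conformational basins.

## The model

A trajectory of *n* frames over *m* selected alpha carbons is a 3*m* × *n*
matrix *A*. Each frame is translated to put its centroid at the origin and
rotated onto a reference structure by quaternion least squares (the
rotation minimising the RMSD). After mean-centring the rows to *A*′, the
engine builds

- **Q** = *A*′(*A*′)ᵀ / (*n* − 1) — the covariance matrix (Å²), whose top
  eigenvectors are the essential modes and whose trace is the total
  fluctuation;
- **R** — the correlation matrix (Q normalised), which finds correlated
  motion regardless of amplitude; modes with eigenvalue > 1 flag
  statistically significant correlation;
- **P** — the partial-correlation matrix (the negative-normalised inverse
  of Q), measuring *direct* coupling between two variables with all others
  held fixed;

plus their inverses (precision, anti-image) and residue-level *m* × *m*
reduced forms Q̃ⱼₖ = Q<sub>xj,xk</sub> + Q<sub>yj,yk</sub> + Q<sub>zj,zk</sub>.
Because aligned frames lose exactly 6 rigid-body degrees of freedom, Q has
3*m* − 6 non-trivial eigenvalues; the trivial subspace is handled by a
rank-aware pseudo-inverse.

Variables can instead be CA–CA distances of user-selected residue pairs
(**dpPCA**), which are invariant under rigid motion and therefore need no
alignment at all.

Mode subspaces are compared by cumulative overlap, RMSIP and principal
angles (≤ 30° conventionally counts as high similarity); free-energy
surfaces ΔG = −k\_BT ln(p/p\_max) are estimated over any two PCs by
Gaussian kernel density estimation; and essential motion is animated as
X(τ) = Σₖ Aₖ sin(ωₖτ) Vₖ with amplitude/frequency tied to the eigenvalues.

## Worked example

`examples/cartesian_pca.py` plants three internal modes with eigenvalues
(9, 4, 1) Å² on a 20-residue helix, scrambles every frame with a random
rigid rotation and translation, and runs the full alignment + PCA pipeline:

```
planted eigenvalues (A^2):   [9. 4. 1.]
recovered eigenvalues (A^2): [9.037 3.975 1.016]
trace of Q (A^2):            14.028
principal angles to planted subspace (deg): [0. 0. 0.]
```

The recovered spectrum matches the planted variances to ~1% at n = 2000
frames, and the zero principal angles show the essential subspace itself
was recovered exactly despite the rigid-body contamination. The other
scripts in `examples/` walk through dpPCA invariance, partial vs marginal
correlations, subspace comparison, free-energy basins, pooling and mode
animation the same way; each prints the numbers it computes and what they
mean.

There is also a thin CLI mirroring the library:

```bash
essdyn cpca driver.txt      # full job from a flat key = value config
essdyn subspace A_vecs.txt B_vecs.txt --out report.txt
essdyn fes Q_pcs.txt --modes 1,2 --out fes.txt
```

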