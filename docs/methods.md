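# Methods

## The model

Both variants in this package are constrained Gaussian mixtures. A
latent surface carries K sample points ("nodes") `u_k`; an RBF network
maps them into data space,

    y(u) = W Φ(u) + x̄,      Φ_l(u) = exp(−d(u, c_l)² / 2w²),

with L basis centers `c_l` sharing one width `w`, weights `W ∈ R^{D×L}`,
and the data mean `x̄` added back after fitting in centered coordinates.
Each mapped node carries an isotropic density
`(β/π)^{D/2} exp(−β‖x − y_k‖²)` — a normal with variance `1/(2β)` per
dimension — and the mixture uses uniform `1/K` priors, so

    log p(x) = log[ (1/K) Σ_k (β/π)^{D/2} exp(−β‖x − y_k‖²) ].

GTM formulations often state the mixture density only up to
proportionality; we fix the constant to the proper normal density
because the headline use of the likelihood is *cross-model comparison*:
the flat and spherical variants are scored by the identical code path,
which never inspects the latent geometry, only the mapped node
positions. Likelihoods are reported as means per point so that frame
and validation sets of different sizes are comparable.

The two variants differ only in latent geometry:

* **sphere** — nodes and RBF centers are two independent Fibonacci
  spirals (`θ_i = arccos(1 − 2i/N)`, `φ_i = 2π·frac(φ_g·i)`,
  `φ_g = (√5+1)/2`, i = 1..N, literal index convention: i = N is the
  exact south pole); `d` is the geodesic (great-circle) angle.
* **flat** — nodes on a regular k×k lattice over [−1, 1]², centers on a
  coarser lattice; `d` is Euclidean. This is the classical-GTM
  comparator; node and center counts must be perfect squares.

The nodes and RBF centers are independent grids of independent sizes:
nothing links them, and typical configurations use many more nodes than
centers (the centers set the model's degrees of freedom m, the nodes
only discretize the manifold).

## Fitting

EM on the (mean) log-likelihood:

* E-step: responsibilities `r_nk = softmax_k(−β‖x_n − y_k‖²)`, computed
  with shifted exponentials; the likelihood itself uses log-sum-exp.
* M-step: `(ΦᵀGΦ + (l/β)I) W_newᵀ = ΦᵀRᵀX_c` with `G = diag(Σ_n r_nk)`
  and `X_c` the centered data, solved by Cholesky factorization;
  a singular unregularized system raises an error advising a larger
  `l`. Then `β_new = N·D / (2 Σ_nk r_nk‖x_n − y_k^new‖²)` — the exact
  maximizer for the `exp(−βd²)` convention (no ½ factor).
* Convergence: relative change of mean log-likelihood below `tol`
  (default 1e-5) or `max_iter` (default 500).

The ridge penalty is a Tikhonov term on the sum-form normal equations,
the standard GTM MAP treatment; consequently the *effective per-point*
smoothing of a fixed `l` weakens as N grows. The alternative — scaling
the penalty with N — would make the conventional working range of `l`
(roughly 0.3–100, default 1) collapse the manifold at realistic dataset
sizes, so the sum form is used. With `l = 0` every quantity in the fit
is exactly invariant under duplicating the dataset, and EM monotonicity
is guaranteed (and tested); with `l > 0` the penalized update can in
principle trade a little likelihood for smoothness, though in practice
the traces in the test suite are monotone at all `l` used.

No randomness enters fitting anywhere, so a fit is bit-for-bit
reproducible given data and configuration.

### Initialization

Spherical fits start from a PCA-aligned ellipsoid: for the node with
unit-sphere direction (a, b, c),

    t_k = x̄ + s·[ a·PC1 + (λ2/λ1)·b·PC2 + (λ3/λ1)·c·PC3 ],

using eigenvalue (variance) ratios rather than their square roots; the
alternative √λ convention would give a fatter initial ellipsoid but is
corrected by EM within a few iterations either way. The relative axis
lengths are paired to the components in variance order — the only
order-preserving choice. The absolute scale is never stated
either; we use `s = 2√λ1` so the major semi-axis spans two standard
deviations of the data along PC1 (~95% of a Gaussian cloud). `W` is the
ridge least-squares solution mapping nodes to targets (the M-step
solver with an identity responsibility pairing; a tiny jitter keeps the
Gram matrix factorizable when `l = 0`). Flat fits use the analogous PCA
plane spanned by the first two components at 2√λ per axis. PCA uses
the population covariance and a deterministic sign convention (each
component's largest-magnitude entry positive). `β₀` is 1 / (mean
squared distance of the data to the nearest initial mapped node) —
scale-free and deterministic. Initialization demands D ≥ 3 (sphere) or
D ≥ 2 (flat); lower-dimensional data should be padded or fitted flat.

### Hyperparameters

| parameter | meaning | units | default |
|---|---|---|---|
| K (`n_nodes`) | mixture size / manifold resolution | count | 500 (22² flat) |
| m (`n_rbf`) | RBF centers = model capacity | count | 80 |
| w (`width`) | shared RBF width | radians (sphere), latent units (flat) | 0.2 |
| l (`reg`) | ridge coefficient | dimensionless | 1.0 |

`w` should be comparable to the RBF center spacing (≈ √(4π/m) on the
sphere): much smaller values leave inter-center nodes mapping to the
data mean (wasted mixture mass), much larger ones make the basis
collinear. The `parameter_scan` helper reproduces the standard
selection procedure: fit on a frame set per (m, l, w), pick the
configuration maximizing validation likelihood (ties: frame likelihood,
then smaller m).

## Projections and meshes

Each point's responsibility vector is collapsed to its center of mass
over the unit-sphere node positions and renormalized onto the sphere.
If the center of mass nearly vanishes (‖c‖ < 1e-6, an antipodally
balanced pattern) the point is flagged and placed at its arg-max node,
ties to the lowest index. The equirectangular image uses azimuth φ as x
and polar angle θ as y, in the latent frame inherited from the
PCA-aligned initialization (no post-fit re-rotation). "Adjacent on the
map sphere" is operationalized as the convex hull of the unit-sphere
node positions — the spherical Delaunay triangulation, deterministic
given the grid — which also provides the manifold mesh (vertices are
the mapped nodes for 3D data, the map-sphere nodes otherwise) and the
node graph used by the cluster-connectivity diagnostic (flat grids use
the 4-neighbor lattice graph there).

## Synthetic data

The generators emulate the statistical structure of the method's two
use cases without any quantum-chemistry or descriptor software:

* `make_p_orbital` — two signed isotropic Gaussian lobes (separation
  2 Å, width 0.5 Å): the two-lobed, nodal-plane shape of a p-type
  orbital such as a water HOMO.
* `make_ring_density` — six Gaussian sites on a 1.4 Å ring (benzene
  bond-length scale), C₆-symmetric in distribution.
* `make_spherical_shell` — uniform directions × radius 1 + isotropic
  noise (default 0.05): data with exactly the topology the spherical
  manifold assumes.
* `make_chemspace` — cluster centers on a closed unit 2-sphere (or a
  bounded sheet) embedded in D dimensions by a random orthonormal map,
  plus isotropic noise (default 0.1): an enumerated library's families
  of structural analogues living near a curved 2-surface in descriptor
  space. Defaults n=2000, D=20, 8 clusters.
* `sample_scalar_field` — draws positions from a cube-file field by
  voxel-categorical sampling (probability ∝ value for densities,
  ∝ value² for signed orbital amplitudes — the Born rule; the sampling
  law for orbitals is our choice, as is the voxel-categorical scheme,
  which is exact only at voxel resolution but deterministic given the
  seed). Orbital mode labels points by amplitude sign.

What these do *not* emulate: real orbital shapes (no cusps, no
exponential decay, no symmetry beyond what is constructed), correlated
or sparse fragment-count descriptors, and cluster populations of an
actual enumerated library. A passing suite therefore shows that the
algorithm behaves correctly on data with the *assumed geometry and
topology*, not that any particular chemistry result is reproduced.

## Numerical choices and limitations

* Geodesic dot products are clamped to [−1, 1]; equirectangular azimuth
  is canonicalized to 0 at the poles.
* The M-step solve is a Cholesky factorization; failure raises a
  numerical error rather than silently regularizing.
* Exact-overlap degeneracy (all data on the manifold) caps β at 10⁶×
  its previous value instead of dividing by zero.
* Text writers emit 17-significant-digit floats in fixed column order:
  outputs are byte-deterministic and round-trip exactly.
* Problem sizes in the test suite and the reproduction script (2000
  points, K ≤ 500, m ≤ 120, ≤ 200 EM iterations, 5–10 seeds per
  stochastic claim) are chosen so the whole pipeline runs on a laptop
  in minutes; all of them can be scaled up through the same interfaces.
* Known limitations: no per-node variances or anisotropic
  (normal/parallel) manifold distances; no minibatch EM; flat grids
  require perfect-square node/center counts; multi-orbital cube files
  (more than one field) are rejected rather than split.
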