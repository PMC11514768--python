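# Methods

This note documents the models, numerical choices and limitations of
patellamorph, in the package's own terms. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself compute.

## Thin-plate splines and bending energy (`tps`)

The 3D TPS interpolant uses the kernel U(r) = −r (the 3D fundamental
solution is linear in distance; the sign is chosen so the bending-energy
quadratic form is positive semidefinite directly, matching the convention of
the standard R morphometrics tools — the +r convention gives the same
interpolant and the same energies up to the documented sign of the kernel
block). The system

L [W | A]ᵀ = [V | 0]ᵀ,  L = [[K, P], [Pᵀ, 0]],  K_ij = U(‖xᵢ − xⱼ‖), P = [1 | x]

is solved by LU with a relative pivot threshold of 1e-12; configurations
failing it (coincident landmarks) are rejected, never regularised — exact
interpolation is part of the sliding contract. The bending-energy matrix B is
the upper-left k×k block of L⁻¹; its null space contains the constant vector
and the three coordinate columns of the reference, so affine maps cost
nothing. Energies are reported in this conventional unnormalised form
(only ratios and minimisers matter downstream); under a joint scaling of both
configurations by s the energy scales as s¹ in 3D, which the tests verify
against a finite-difference quadrature of the warp's second derivatives.

## Sliding semilandmarks (`sliding`)

Curve points may move along the chord through their curve neighbours
(one-sided at free endpoints); surface points within the tangent plane of
their nearest mesh triangle. With T mapping the stacked tangential offsets t
to coordinate perturbations, minimising (y₀ + T t)ᵀ(I₃ ⊗ B)(y₀ + T t) is one
linear solve per specimen — all sliding coordinates simultaneously, not
per-landmark greedy. After solving, curve points are re-projected onto the
original curve polyline and surface points onto the mesh (closest point), so
slid points always lie on their carrier geometry. Re-projection is a
second-order correction but not exactly energy-neutral; if it ever overshoots
the pass's energy budget the step is halved until the energy is non-increasing
(worst case: the identity step). Anatomical landmarks are copied through
bitwise.

The full protocol is one pass against the template followed by
`n_consensus_iterations` (default 4) passes against the recomputed Procrustes
consensus, the consensus being rescaled to the mean centroid size so TPS and
meshes stay commensurate. Mean bending energy per pass is logged and stored in
the output provenance. Curve endpoints are fixed only where they coincide with
an anatomical landmark (within 1e-8 of scale); a `fixed_ids` escape hatch pins
arbitrary points. Everything in this module is deterministic.

Template projection fits the TPS on the anatomical + curve anchors, warps the
template's surface points, and relaxes them onto the specimen mesh by
closest-point projection (exact, via a centroid kd-tree with a radius bound
that cannot miss the true nearest triangle).

## Superimposition (`procrustes`)

GPA centres, scales to unit centroid size (sizes are kept alongside, since all
allometry uses log CS), and iteratively rotates to the running consensus until
the consensus RMS change is < 1e-10 (cap 100 iterations, warning on cap). Only
proper rotations are used; chirality is handled exclusively by the explicit
`mirror` step, as in the protocol where left bones were mirrored before
analysis. The reported consensus is the plain mean of the aligned
configurations. `procrustes_distance` is the partial Procrustes distance
(centre, unit-scale, optimal rotation, root-sum-of-squares). Species mean
shapes are per-species means of the first GPA's aligned coordinates, to be
superimposed again (two-step GPA) before ordination or signal tests.

## Ordination (`ordination`)

PCA is the SVD of the centred flattened residuals; eigenvector signs are fixed
(largest-magnitude loading positive) so scores and theoretical shapes are
reproducible across BLAS builds. Theoretical shapes are consensus +
score·eigenvector. Mesh warping carries the template mesh through the TPS
fitted on template → target landmarks; colour-map exports offer signed
(normal-projected) and magnitude per-vertex deformation. NJ is Saitou–Nei on
Euclidean distances over all PC axes (an option restricts to the first m);
negative branch lengths are clamped to zero with the deficit moved to the
sister branch, preserving the joined pair's path length. The tests cross-check
NJ against scikit-bio's implementation and against exact additive metrics.

## Inference (`stats`)

* Pearson tests report r, t = r·√(df/(1−r²)), df = n−2 and the two-sided t
  p-value.
* PERMANOVA uses sequential (Type-I) sums of squares via nested hat matrices
  on the Euclidean geometry of PC scores, pseudo-F per term, and free row
  permutation with p = (1+b)/(1+m); an exhaustive `permutation_set` switches
  to the exact convention b/m. Specimens missing a level in any tested factor
  are excluded listwise first (count recorded); the pipeline maps unknown sex
  to missing. Defaults: 999 permutations.
* Procrustes ANOVA regresses the flattened aligned coordinates on one
  covariate; because Procrustes and tangent-space Euclidean sums of squares
  coincide, its R² equals the multivariate OLS R² (asserted to 1e-8 in the
  tests). Inference is residual randomization under the reduced
  (intercept-only) model, 1000 permutations by default; the effect size is
  Z = (log F_obs − mean log F_perm)/sd(log F_perm). Fitted shapes at the
  covariate extremes feed the deformation-map workflow.
* Significance: p ≤ 0.05 flagged significant, 0.05 < p ≤ 0.10 marginal.

## Phylogenetic signal (`phylo`)

The Brownian covariance C holds shared root-to-MRCA path lengths. K is the
observed MSE₀/MSE ratio (about the GLS phylogenetic mean, with and without
C⁻¹ weighting) over its Brownian expectation (tr C − N/ΣC⁻¹)/(N−1); K_mult
sums the quadratic forms over trait columns and reduces exactly to K for one
column. p-values permute trait rows across tips (default 1000). Tip/species
matching trims, casefolds and converts spaces to underscores. Simulation draws
tip values with covariance rate·C via an eigendecomposition square root
(robust to zero eigenvalues on star-like trees).

## Synthetic world (`synthetic`)

The generator emulates the *statistical* structure of the study, not patellar
anatomy:

* **Template.** A deformed ellipsoid (icosphere, subdivision 3): semi-axes
  1.15/0.90/0.62 (proximodistal/mediolateral/craniocaudal), a taper that
  narrows the distal apex, and a Gaussian medial bump whose amplitude is the
  `medial_angle` parameter in [0, 1] — 0 a symmetric "tapir-like" bone, →1 an
  asymmetric "rhino/equid-like" bone. The scheme is the real one: 6 anatomical
  points (drifting medially with the angle so the angle-0 scheme is
  mirror-symmetric with a known landmark pairing), a 52-point medial-ridge
  curve and 51-point articular-margin loop, and 461 mirror-paired quasi-uniform
  surface points, all snapped onto the mesh.
* **Shape basis.** 20 smooth Gaussian-bump displacement modes (+1 allometric,
  +1 dimorphism direction), orthonormalised and projected clear of the seven
  similarity motions; built from a fixed structural seed so they are part of
  the stated world, not of any particular draw.
* **Species and specimens.** Species means = clade-specific template
  (medial angle per family) + Brownian scores on the bundled cladogram in the
  mode basis. Specimens add β·(log S − mean)·v_allo, an optional sex offset,
  iid noise, a random rigid motion and their own scale, with
  log S ∼ N(log CS_template + (log BM_species − log median BM)/3, size_log_sd)
  — centroid size tracking the cube root of body mass. β is calibrated so that
  when noise is the only other within-species effect the expected
  shape-on-size R² equals `allometry_fraction`
  (β² = ρ/(1−ρ) · 3k·σ²_noise / Var(log S)); Brownian and clade components add
  further variance on top, so whole-sample R² exceeds ρ exactly as interspecific
  data exceed within-species allometry.
* **Defaults** are the package's one-time realism choices: bm_rate 1e-3 per
  Myr per mode, noise_sd 2e-3 (template units; template CS ≈ 17), medial
  angles 0.72/0.60/0.35 for rhinos/equids/tapirs, size_log_sd 0.12,
  allometry_fraction 0.12 (the published rhino allometric share), body masses
  from the study-design table. They yield PC1 ≈ 0.45–0.55, PC2 ≈ 0.25–0.35,
  species R² ≈ 0.99 and whole-sample allometric R² ≈ 0.2–0.3 — the qualitative
  regime of the real data (strong species structure, moderate allometry).
* **Meshes** (TPS warps of the template mesh per specimen) are generated only
  on request: they are needed by projection/sliding, not by the statistics,
  and dominate runtime.
* **Repeatability protocol.** n_specimens base shapes separated by
  `specimen_separation` (default 10× the jitter), each digitized
  n_digitizations times with iid jitter on the anatomical landmarks.

What a green test does *not* establish: the generator has no scan artifacts,
no missing landmarks, no within-species Brownian structure, no correlated
digitization error, and its meshes are warped copies of one shell — so tests
validate the estimators and the protocol, not robustness to real scan
pathology.

## Pipeline (`pipeline`)

`run_pipeline(RunConfig)` chains mirror → project → slide → GPA → PCA → NJ →
Pearson → PERMANOVAs → Procrustes ANOVAs → species means → K/K_mult →
theoretical shapes and deformation maps, writing every statistic to CSV/JSON/
Newick/PLY artifacts (seeds and permutation counts in the headers) and a
report that indexes them. Phylogenetic signal runs only on unfiltered
(all-perissodactyl) samples, matching the protocol's restriction of signal
tests to the full species set; family-filtered runs (e.g. rhinos only) skip
it. Exclusion lists (unknown sex, missing femoral circumference) are applied
listwise per analysis and counted in the outputs.

## Known fixture caveats

* The study-design table's printed sex marginals (29 M / 17 F / 19 unknown)
  sum to 65, not 54; the bundled fixture transcribes the 54 per-row values
  (25 M / 12 F / 17 U) and leaves the discrepancy documented rather than
  repaired.
* The cladogram fixture's branch lengths are round Myr values consistent with
  the cited epochs (rhino crown ≈ 30 Ma, tapir crown ≈ 23 Ma, *Equus* crown
  ≈ 4.5 Ma, ceratomorph–hippomorph split ≈ 56 Ma), not a published matrix;
  everything depending on the tree uses this fixture.
* Classic TPS files are read-only (the long CSV is canonical; class/curve
  annotations do not fit TPS); PLY is ascii-only in both directions.
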