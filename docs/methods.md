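# Methods

## The reconstruction problem

Standard CT acquires one sinogram with one polychromatic spectrum. The
post-log datum of ray j follows the nonlinear (beam-hardening) model

    g_j(b') = -ln SUM_m q_jm exp( -SUM_k mu_km t_jk ),       t_jk = [A b_k]_j,

where `q_jm` is the normalized effective spectrum on M energy bins, `mu_km`
the mass attenuation coefficient (cm^2/g) of basis material k at bin m, `A`
the discrete fan-beam x-ray transform (intersection lengths, cm), and `b_k`
the basis image of material k in g/cm^3. Recovering K >= 3 basis images from
a single sinogram is severely ill-posed. Two structural priors restore
well-posedness:

* **Basis regions.** The image array is partitioned into L regions; region l
  is assumed to contain a known set Phi_l of at most two materials, and each
  region's set is unique. The unknowns shrink to the congregated
  basis-region vector b' with N_b = SUM_l K_l I_l <= 2I entries (blocks
  ordered by region, then by material within the region). Basis images,
  virtual monochromatic images (VMIs) f_m = SUM_k mu_km b_k, and the data
  model are all linear re-expressions of b'.
* **Volume conservation (VC).** In each designated two-material region,
  per-pixel volume fractions must sum to one:
  SUM_{k in Phi_l} b'_lk / rho_k = 1. This adds SUM I_lc exact constraints
  that augment the single-spectrum data.

The reconstruction is posed as a constrained program: minimize
`1/2 || (g - Delta g) - H(bbar') b' ||^2` subject to isotropic-TV bounds on
two VMIs (`TV(f'_50keV) <= gamma_1`, `TV(f'_100keV) <= gamma_2`), the VC
equalities, and `b' >= 0`. Here `H(bbar')` is the Jacobian of the data model
at an expansion point — a projection weighted by per-ray effective
attenuation `w_jk = SUM_m mu_km N_jm / SUM_m N_jm` — and
`Delta g = g'(b') - H(bbar') b'` is the exact nonlinear remainder, so the
model identity `g' = H b' + Delta g` holds to machine precision by
construction. For a monochromatic spectrum `w_jk = mu_k` exactly and
`Delta g = 0`.

## Solvers

`pd` is a diagonally preconditioned Chambolle-Pock-type primal-dual
algorithm for the convexified program (H and the nonlinearity offset held
fixed). `dncpd` relinearizes after every primal update: it recomputes
`Delta g` (at the previous expansion point), refreshes the effective weights
of H, and refreshes the data-dual steps `Sigma_u` and primal steps `T` from
the new |H| row/column sums; all other dual steps stay those of the zero
expansion point. With M = 1 the two algorithms coincide iterate for iterate
(bitwise, by construction of the weight computation), which is tested.

Balancing scalars are `nu = ||H(0)||_2`, `alpha_i = ||H(0)||_2 / ||grad
U_mi||_2`, `beta_lc = ||H(0)||_2 / ||V_lc||_2` (V-norms are closed-form
since V rows are disjoint). Step sizes follow the absolute row/column sums
of the stacked operator `K = [H; a1 grad U_m1; a2 grad U_m2; nu I;
{b_lc V_lc}]`: `sigma = rho_pc / (|K| 1)`, `tau = 1 / (rho_pc |K^T| 1)`,
with zero rows/columns assigned zero steps. Norm estimates use seeded power
iteration (100 iterations or relative change < 1e-6).

### Numerical choices

* **Gradient / TV.** Forward differences with replicate boundary; isotropic
  per-pixel magnitude; `grad_adjoint` is the exact matrix adjoint
  (dot-product tested). The |grad| column sums needed for `tau` come from
  the stencil analytically.
* **TV dual prox.** The gradient-domain dual step is the prox, in the
  Sigma-weighted metric, of the conjugate of the TV-ball indicator. For a
  per-pixel diagonal Sigma this is a weighted magnitude clipping: magnitudes
  |v'| are clipped to the water-filling threshold t solving
  `SUM_i (|v'_i| - t)_+ / sigma_i = alpha * gamma`; for uniform sigma this
  reduces exactly to the `POL1B` (l1-ball projection) form. `POL1B` itself
  is the O(N log N) sort-and-threshold simplex projection, checked against
  a brute-force QP.
* **Per-pixel sigma for the gradient duals.** The two gradient components of
  a pixel share `sigma = rho_pc / (rowsum_x + rowsum_y)`, which is never
  larger than the per-component row-sum rule, so the diagonal-preconditioner
  step condition still holds while keeping the per-pixel magnitude algebra
  well defined.
* **Underflow.** The log-sum over energy bins is a shifted log-sum-exp, so
  long metal paths cannot underflow; effective weights are computed from
  normalized bin probabilities (this also makes the monochromatic weights
  exactly equal to mu, giving the bitwise pd/dncpd equivalence).
* **Divisions.** All `sigma/(1+sigma)` and `v'/|v'|` operations are
  elementwise with 0/0 := 0.
* **rho_pc.** Exposed with default 1.0. The shipped reduced-scale studies
  pass 0.3, selected by a design-time sweep (0.1–10) in which 0.3 gave
  uniformly faster decay of the data-residual, feasibility, and truth-error
  metrics on this problem class.

### Convergence metrics and stopping

Six normalized metrics are recorded per iteration: relative data residual
`||(g - Delta g) - H b'|| / ||g||`; two TV feasibility gaps
`max(0, TV - gamma)/gamma`; per-VC-region residual RMS
`||VC_lc(b')||_2 / sqrt(I_lc)`; relative nonnegativity violation; relative
primal change; and, when a truth is supplied, the basis-image nRMSE
`||b - b_truth|| / ||b_truth||`. Iteration stops when every enabled metric
is below its tolerance (default 1e-6) or at `max_iters`.

## The x-ray transform

Ray weights are exact ray-pixel intersection lengths from a Siddon
traversal, making the operator nonnegative with exactly matched
forward/adjoint and absolute row/column sums equal to plain applications to
ones. Conventions (the model is agnostic; these are fixed package
conventions): pixel-centered grid, rotation center at the image center, the
source at angle theta counter-clockwise from +x at distance `sor`, first
view at theta = 0, detector coordinate increasing along `(-sin, cos) theta`;
flat (equispaced, cm) or curved (equiangular, rad) detectors. Rays missing
the grid are kept as zero rows so J = n_views x n_bins always; their dual
steps are zero. The sparse rows are built lazily and cached, so declaring a
clinical-scale geometry is free and only actual projection pays memory.

## Synthetic data

`make_chest_like` builds a chest-like phantom: water body ellipse, air
lungs, cortical-bone spine and ribs (region water/bone = bone dilated by 2
px), iodine-solution vessels at 20/10/5 mg/ml (region water/iodine),
a titanium implant (single-material region), and, in the full scheme, a
stainless-steel needle with an air margin (region air/steel). Water spans
the first three regions; the VC constraint applies to every two-material
region. `make_de_disk` builds a water disk with 7 iodine (2–20 mg/ml) and 7
calcium (50–600 mg/ml) solution inserts plus 8 air holes, in three regions
(water/calcium, water/iodine, air/water). Insert concentrations map to
volume fractions of the reference-concentration basis (c/c_ref), so every
truth pixel satisfies VC exactly and the iodine-concentration calibration
`c = (c_ref / rho_ref) * b` is anchored by construction.

Noise is Poisson on transmitted counts, `N ~ Poisson(N0 exp(-g))`, then
`g = ln(N0/N)` with zero counts clamped to one and logged. Scatter, bowtie
and spectrum-estimation errors of real scanners are NOT simulated, so
passing tests demonstrate correct inversion of the stated model and
stability to photon noise — not robustness to real-data inconsistencies.

Mass-attenuation fixtures are small CSV surrogates transcribed from
standard references (water, air, cortical bone, adipose, titanium, steel,
20 mg/ml iodine solution, 600 mg/ml calcium solution), log-log interpolated
onto the working grid (default 1-keV bins over 10–150 keV; iodine carries
extra tabulation at its K-edge). The shipped "80 kV"/"140 kV" spectra are
tabulated toy shapes. No NIST/XCOM fidelity is claimed and no test depends
on it — only on internal consistency.

## Study configurations and observed behavior

The canonical studies (module `polybasis.studies`) run on one CPU in
minutes: a 96x96 chest phantom (5 materials / 4 regions, the full scheme
minus the steel needle), 180 views x 128 bins, a 20-bin spectrum on 20–115
keV; and a 96x96 DE disk with the full insert layout. TV bounds are the
truth-VMI TVs at 50 and 100 keV.

On noiseless, model-consistent data the dNCPD run reaches basis-image nRMSE
~5e-4 within ~2000 iterations; TV gaps, nonnegativity and primal change
fall below 1e-5–1e-8; iodine concentrations are recovered within 0.005
mg/ml at 2–20 mg/ml; with Poisson noise at N0 = 1e5 the solver is stable
with nRMSE ~2e-2. Two metrics converge much more slowly at this sampling
density (~2.5 rays per pixel): the data residual and the air/water-region
VC RMS plateau near 1e-4 over thousands of iterations. The same plateau
appears in the monochromatic convex benchmark solved by plain PD, so it is
a conditioning property, not a defect of the dynamic relinearization: the
VC row of an air/water region has entries (1/rho_air, 1/rho_water) ≈
(833, 1), and wherever nonnegativity pins the air value at a material
boundary, the residual can only decay through the 800x-weaker water
coupling. Denser ray sampling (the clinical-scale geometries the model
targets) strengthens the data term at exactly those pixels; at desk scale
we report the plateau rather than hide it.

## Known limitations

* Convergence of the dynamically relinearized solver is empirical; no
  global guarantee exists for the non-convex program (the convexified
  program's PD solver is oracle-verified against an independent QP solver).
* Basis regions are inputs; no automatic segmentation from a prior
  reconstruction is provided.
* 2-D fan beam only; no scatter, bowtie, detector response, or vendor raw
  formats; per-ray spectra are supported by the data model but no generator
  produces them.
* The trust-constr oracle for the convex check requires TV bounds slack at
  the optimum (nonsmooth active TV defeats SQP-type solvers); the TV prox
  is therefore oracle-tested separately at the operator level.
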