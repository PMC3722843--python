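# Methods

## Model and assumptions

The imaging domain is the 2-D cross-section of a cylindrical saline tank:
a disk of radius R (normalized to 1 for the single-anomaly study, 0.07 m
for the tank studies) with real, isotropic, piecewise-constant
conductivity.  Complex conductivity, multi-frequency data and the third
dimension are out of scope; the internal probe's insulated shaft is not
modelled — only its exposed tip appears, as a circular hole of radius
0.125/7 · R (a 0.25 cm diameter probe in a 14 cm tank).

**Electrode model.** Gap (shunt-free) model: an injected current I spreads
uniformly over the electrode arc (Neumann data ±I/|ℰ|), and the electrode
voltage is the arc-average of the potential.  Contact impedance and the
shunting of the complete electrode model are deliberately omitted; they
affect absolute voltages far more than the time-difference data this
package works with.  The additive potential constant is fixed by a
zero-mean gauge over mesh nodes (differences are gauge-independent).

**Protocols.** Surface electrodes are driven and measured in adjacent
pairs, all E² combinations retained.  With an internal electrode the drive
set is augmented with probe-to-surface injections while the measurement
set stays on the surface ring (2E × E data).  Two facts motivate leaving
probe *measurements* out of the default: (i) by reciprocity,
surface-drive/probe-measurement data are numerically identical to the
probe-drive/surface-measurement data already collected; (ii) rows in which
both the drive and the measurement involve the 1.25 mm current-carrying
probe produce sensitivity columns that are nearly radial functions of the
distance to the probe — in our simulations their mean ROI/outside
cross-correlation is ≈ 0.30 versus ≈ 0.10 for surface data, i.e. they
actively blur the distinction the ROI filter relies on.  The full cross
product remains available as the `internal_augmented_full` scheme.

**Sign convention.** The first-order perturbation identity is
δV_{j,k} = −∫ δγ ∇u^j·∇w^k dr; the minus sign is kept in both the
sensitivity matrix and the simulated difference data (the two must share
the convention; the Jacobian oracle test pins it down).

## Discretization

* **Mesh.** Structured point placement — a boundary ring conforming to
  every electrode arc endpoint (arcs refined 2× relative to the bulk),
  staggered graded rings around the probe hole, concentric interior rings
  at the target spacing — triangulated with Delaunay, after which
  triangles inside the hole are removed.  Interior ring angles carry a
  deterministic jitter of 3% of the local spacing: exactly concentric
  rings produce co-circular quadruples whose Delaunay diagonals are
  arbitrary; the jitter makes the triangulation generic while leaving mesh
  quality untouched.  Conformity (every marked electrode edge is a mesh
  edge, ≥ 2 edges per electrode) is verified at build time.  Default edge
  lengths: 0.06 on the unit disk (~1 800 elements), 4 mm in the 7 cm tank
  (~2 200 elements) — several elements across the 1 cm objects; the
  four-anomaly localization result was checked to be stable under
  refinement to 3 mm.
* **Forward solves.** The pure-Neumann stiffness matrix is augmented with
  a mean-value Lagrange multiplier and factorized once (sparse LU) per
  conductivity; all drives and adjoint measurement fields reuse the
  factorization.
* **Pixels.** A square lattice clipped to the disk, 32 pixels per
  diameter by default, pixels ordered row-major with ROI pixels re-indexed
  first.  Triangle-to-pixel integration uses centroid binning; exact
  polygon clipping would change pixel integrals by less than the FEM error
  at this scale.  Rim lattice cells whose centre falls outside the disk
  are not pixels; triangles binned to them contribute to no column (on the
  48-pixel validation grid the partition covers every triangle, and the
  row-sum identity Σₙ S[m,n] = −V_m/σ holds to machine precision).

## The ROI and the filter

The ROI is the disk centred on the internal electrode with radius 5/6 of
the distance to the nearest surface-electrode centre.  (For probes within
0.7 R of the centre this disk stays strictly inside the domain; very
close to the rim the nearest electrode *centre* can be farther away than
the boundary itself and the 5/6 rule can spill over — no registered
scenario is in that regime.)

Each filter column solves the strictly convex quadratic
min_φ Σ_{pⱼ∉D} |sⱼ·φ|² + α‖φ − sₖ‖², by the normal equations
(S_out S_outᵀ + αI)φ = αsₖ, one Cholesky factorization of the
(J·K)×(J·K) Gram operator for all R columns.  α trades outside
suppression (small α) against fidelity to the ROI columns (large α); the
default α = 10⁻² · ‖S_out‖₂² makes the two terms dimensionally comparable
and is homogeneous of degree 2 in the data scale, so the filter is
invariant under rescaling of S.  The α → ∞ limit returns S_D itself; the
α → 0 limit projects the ROI columns onto the null space of S_outᵀ.

## Reconstruction and metrics

Both the conventional system S δγ = δV and the localized system
(ΦᵀS_D) δγ_D = ΦᵀδV are inverted by truncated SVD.  The truncation level
is relative to the largest singular value (dimensionless, comparable
across configurations).  The default for noiseless simulated runs is
10⁻³ — with noiseless data the truncation only needs to guard against the
linearization/binning inconsistency of the model, and 0.1% of σ_max
retains ≈ 20 of the ≈ 150 localized components.  Noisy runs should raise
it or use the contrast-targeted search.

* **Contrast** is the mean image value over the true anomaly footprint
  minus the mean over the background (the complement of the 2×-dilated
  footprint); the definition is deliberately simple and swappable.
* **Threshold search** bisects the relative truncation level on [0, 1]
  until the contrast meets a target within a relative tolerance,
  returning the closest bracketing threshold with a flag when the target
  is unattainable.  The contrast-vs-threshold curve is piecewise constant
  (one step per retained singular value), so results are reported both as
  the relative threshold and as the retained rank.  In our noiseless
  simulations the internal-electrode configurations reach a common target
  contrast with *fewer* retained singular components (ranks 73/67 versus
  88 for the surface-only model) — the configuration is better conditioned
  for in-ROI targets — while their *relative* thresholds are higher; the
  rank is the robust figure of merit.
* **Localization** detects strict 8-neighbour extrema of the 3×3
  mean-smoothed image (polarity chosen from the dominant sign of the
  image, since conductivity drops give troughs), ties broken by pixel
  index, and matches extrema to true centres greedily by distance.
* **Cross-correlation** μ(j) averages |sᵢ·sⱼ|/(‖sᵢ‖‖sⱼ‖) over outside
  pixels i for each ROI pixel j; zero columns (degenerate rim pixels) are
  excluded from the average.
* **Outside-anomaly influence** reports ‖δVᵢ − δV_ref‖ and
  ‖Φᵀ(δVᵢ − δV_ref)‖, normalized by the reference norms, for scenarios
  that add an anomaly outside the ROI.

## What the synthetic phantoms do and do not show

The generator reproduces the study conditions exactly as printed: the
normalized single anomaly (2 S/m, diameter 0.1428, centre (0.8, 0), 1 S/m
background), the four-anomaly tank (0.029 S/m objects, 1 cm diameter, in
0.0418 S/m saline, probe at (3.5, 0) cm — the duplicated fourth
coordinate in the source description is restored to (5, +1.5) cm by
symmetry with the experimental carrot layout), the four-carrot layout and
the radish/potato cases in 0.042 S/m saline.  Default runs are noiseless
(the studies' simulated noise level is unstated); Gaussian measurement
noise at a chosen SNR is available per config.

Simulated data are produced by the same FEM machinery that builds the
sensitivity matrix (on the same mesh), so these experiments probe the
linearization and the filter, not modelling error: they say nothing about
contact impedance, electrode-position uncertainty, 3-D current spreading,
or hardware noise spectra — the dominant error sources in bench data.
The in-silico radish/potato influence study mirrors the physical
experiment's geometry but not its measured values.

## Known limitations

* 2-D only; the probe shaft and the tank's z-extent are not modelled.
* The filter suppresses the *linear* out-of-ROI response; second-order
  contributions of large outside anomalies pass through attenuated, not
  eliminated (visible as the growing filtered influence ratio as the
  potato approaches the ROI).
* Centroid binning leaves a thin uncovered rim at coarse pixel sizes;
  affected pixels are logged.
* `threshold_search` assumes a monotone-trend contrast curve when picking
  the bisection side; for strongly non-monotone curves it still returns
  the best evaluated threshold, flagged as non-converged.
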