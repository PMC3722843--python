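# eitroi — local region-of-interest EIT imaging with an internal electrode

Electrical impedance tomography (EIT) reconstructs the conductivity change
inside a body from current/voltage measurements on surface electrodes.
Surface measurements are notoriously insensitive to deep, localized
targets — a problem for applications such as monitoring radio-frequency
ablation of liver tumours or cardiac interventions, where the clinically
interesting change happens in a small region around a probe that is
*already inside* the body.  `eitroi` implements a local region-of-interest
(ROI) imaging method that exploits such an internal electrode:

1. **Forward model.** The potential satisfies ∇·(σ∇u) = 0 on a 2-D disk
   with gap-model (shunt-free) electrodes; the internal probe is a small
   circular hole with its own boundary marker.  The model is discretized
   with P1 finite elements on an unstructured triangle mesh and driven by
   adjacent-pair surface injections plus probe-to-surface injections,
   giving the data vector δV of time-difference EIT.
2. **Sensitivity matrix.** The linearized system S δγ = δV with
   S[(j,k), n] = −∫_{qₙ} ∇u^j · ∇w^k dr on a pixel grid, computed by the
   adjoint (reciprocity) formulation.  With an ROI D (a disk around the
   probe with radius 5/6 of the distance to the nearest surface
   electrode), the columns split into S = [S_D | S_out].
3. **ROI filter (the core method).** For each ROI pixel k, a filter column
   φₖ = argmin_φ Σ_{pⱼ∉D} |sⱼ·φ|² + α‖φ − sₖ‖², i.e. φₖ stays parallel to
   the ROI sensitivity column while suppressing coupling to everything
   outside.  The closed-form minimizer solves
   (S_out S_outᵀ + αI) φₖ = α sₖ — one Cholesky factorization for the
   whole filter Φ = (φ₁ … φ_R).
4. **Reconstruction.** Truncated SVD of the conventional system S δγ = δV
   and of the localized system (Φᵀ S_D) δγ_D = Φᵀ δV, with the truncation
   level expressed relative to the largest singular value, plus the
   diagnostics used to compare electrode configurations: cross-correlation
   μ between ROI and outside columns, spectral-norm ratios ‖A_in‖/‖A‖,
   contrast-targeted threshold search, leakage, and outside-anomaly
   influence tables.

Everything runs on built-in simulated phantoms (no external data): a
normalized single-anomaly tank, a four-anomaly simulation in a 14 cm tank,
and the four-carrot / radish-potato experiment layouts, under three
electrode configurations (Model 0: 16 equidistant surface electrodes;
Model 1: plus an internal electrode; Model 2: internal electrode with
surface electrodes clustered towards the ROI).

## Worked example

Run the four-anomaly simulation end to end (forward data, sensitivity
matrix, ROI filter, both reconstructions, metrics):

```bash
cat > run.json <<'JSON'
{
  "scenario": "model2_four_anomaly_sim",
  "outdir": "four_anomaly_run"
}
JSON
eitroi run --config run.json
```

which prints (abridged):

```json
{
  "scenario": "model2_four_anomaly_sim",
  "n_data": 512,
  "n_pixels": 812,
  "n_roi_pixels": 148,
  "alpha": 1144.3484916533764,
  "mu_mean": 0.08362645421009521,
  "norm_ratio_S": [0.2001123679260645, 0.9998455158448846],
  "norm_ratio_filtered": [0.9272681122610215, 0.3902634085555112],
  "local_rank": 21,
  "local_localization_error": [0.004697905118241539, 0.004697905118241532,
                               0.0004419417382416024, 0.0004419417382415975]
}
```

Reading the numbers: the raw sensitivity matrix concentrates only 20% of
its spectral norm on the 148 ROI pixels (`norm_ratio_S`), while after
filtering 93% of the norm sits on the ROI and the outside coupling drops
to 0.39 (`norm_ratio_filtered`) — the filter has localized the linear
system.  The local reconstruction then recovers all four 1 cm objects with
centre errors below 4.7 mm (half an object diameter;
`local_localization_error`, in metres).  The artifact bundle (mesh, data
vectors, matrices, images, manifest) is written to `four_anomaly_run/` as
plain-text CSV/JSON; rerunning the same config reproduces it byte for
byte.

`eitroi scenario list` shows the registered phantoms, and `simulate`,
`sens`, `filter`, `recon`, `metrics` run the pipeline stage by stage.

## Layout

```
src/eitroi/geometry.py        disk domain, layouts, ROI rule, mesh, pixel grid
src/eitroi/forward.py         P1 FEM solver, protocols, data vectors, noise
src/eitroi/sensitivity.py     Jacobian, ROI partition, mu, norm ratios
src/eitroi/roi_filter.py      filter construction and application
src/eitroi/reconstruction.py  TSVD, threshold search, metrics
src/eitroi/phantoms.py        scenario registry
src/eitroi/pipeline.py, cli.py  run driver and CLI
docs/methods.md               model assumptions, parameters, limitations
```
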