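# arcplan

Inverse planning and delivery evaluation for dynamic-arc radiotherapy with a
multileaf collimator (MLC), exercised on synthetic water phantoms.

The package covers the full planning chain for a robotic delivery device that
sweeps a fixed non-coplanar arc trajectory (control points every 5°) or visits
a static body path:

- **machine model** (`arcplan.machine`) — MLC geometry (paired 7.7 mm fluence
  rows), delivery constraints (min field width/length, opposing-leaf rule,
  50 mm leaf travel per interval derived from 33 mm/s × 1.5 s), arc and
  body-path trajectory fixtures (104-node / 110-node defaults), and an
  idempotent constraint projection `apply_mlc_constraints`.
- **phantom fixtures** (`arcplan.phantom`) — 300×300×200 mm water box with a
  60 mm spherical PTV, plus two-control-point demonstration plans
  (`semicircle_pair`, `crescent_pair`) for the motion-artifact illustrations.
- **dose engine** (`arcplan.dose`) — simplified divergent beamlet kernel
  (inverse square × build-up/attenuation depth dose × erf lateral profile),
  sparse per-node dose-influence matrices with 0.015 %-of-column-max
  truncation, and linear dose accumulation `D_i = Σ_j d_ij w_j`.
- **fluence optimizer** (`arcplan.fluence`) — quadratic under/over-dose DVH
  objective and a projected low-memory quasi-Newton (L-BFGS two-loop) driver
  with backtracking line search; arc plans optimize fluence at every third
  node (15° spacing).
- **sequencer** (`arcplan.sequencing`) — reducing-level (Xia–Verhey style)
  decomposition; arc mode sequences each fluence map into 3 apertures and
  redistributes two to the ±5° neighbour nodes; static mode allocates a global
  aperture budget (110) greedily across nodes.
- **motion model + DAO** (`arcplan.motion`) — effective fluence of the moving
  aperture between control points (linear ramps; exact bixel averages), the
  partial-bixel static aperture fluence, and direct aperture optimization of
  leaf positions and MU under the delivery constraints, with dose evaluated
  through either the discrete or the effective-fluence model.
- **evaluation** (`arcplan.evaluate`) — interpolated recalculation (5 nodes ×
  20 apertures per interval → 0.05° effective resolution), DVH, conformity
  index, clinical-goal checks, and delivery-time models for dynamic
  (`max(60·MU/D, 1.5 s)` per interval) and step-and-shoot (3.5 s per segment,
  1.5 s for zero-MU nodes) delivery.
- **I/O + pipeline** (`arcplan.io`, `arcplan.pipeline`, `arcplan.cli`) —
  versioned plan JSON schema, NIfTI volumes, DVH/trajectory CSV, and a YAML
  configured end-to-end workflow for schemes CKA1–CKA5 (dynamic arc with
  different dose-calculation variants) and CKSB (step-and-shoot).

## CLI

```bash
arcplan phantom --spacing 2.5 --out phantom.nii.gz
arcplan demo --kind semicircle_pair --out-dir demo_out
arcplan optimize config.yaml
arcplan recalc plan.json --n-nodes 5 --n-apertures 20 --out dose.nii.gz
arcplan evaluate dose.nii.gz --prescription 10 --out report.json
```

Minimal pipeline config:

```yaml
seed: 1
scheme: CKA4            # CKA1..CKA5 | CKSB
prescription_gy: 10.0
output_dir: out
phantom: {spacing: 5.0, ptv_diameter: 60.0}
trajectory: {kind: arc, n_arcs: 1, nodes_per_arc: [36], spacing: 5.0}
fluence_iterations: 40
dao_iterations: 40
goals:
  - [PTV, "D95%", 10.0]
```

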