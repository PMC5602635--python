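# thrombovol

Thrombus volumetry for microfluidic flow-chamber experiments, two independent
ways: **optical thresholding** of confocal z-stacks and **electrical impedance
inversion** through a conduction model of the sensing channel — plus real-time
classification of impedance traces during the perfusion.

## The problem

Whole blood perfused over a collagen-coated surface at arteriolar shear
(γ = 6Q/wh² = 1500 s⁻¹ for Q = 75 µl/min in a 500 × 100 µm channel) forms
platelet aggregates — thrombi — whose volume is the readout of hemostatic
function. The reference measurement is confocal microscopy: a z-stack of
8-bit fluorescence planes (mepacrine-labelled platelets, 512 × 512 px at
0.33 µm/px, z-step Δz = 0.5 µm) acquired at the end of a 300 s perfusion.
A biosensor with two coplanar u-shaped gold microelectrodes on the channel
floor measures the impedance magnitude |Z| at 150 kHz at the same time:
platelet membranes are insulating there, so aggregation raises |Z|.

This package implements the full analysis toolchain on either data stream:

- **Optical thresholding (OT).** Per plane *i*, the covered area is
  `A_i(Thr) = #{pixels ≥ Thr} · f²` and `V_OT = Δz · Σ A_i`. The threshold is
  selected automatically: sweeping Thr from 0 to the stack maximum yields a
  volume curve `V_OT(Thr)` and a maximum-height curve `H_max(Thr)`; the
  selected Thr is the largest threshold at which the height curve still
  attains its plateau — the saturation point of the height curve, i.e. the
  elbow of the volume curve. Uncertainty is propagated from the threshold
  identification error, `u(V_OT) = |dV/dThr| · δThr/√3`, with δThr = 3.
- **Impedance inversion (IM).** Thrombus height is modelled as proportional
  to the 2D fluorescence intensity, `h(x,y) = k · I(x,y)`, with one scale
  factor k for the whole image. A finite-volume conduction solve
  (∇·(σ∇φ) = 0, harmonic-mean face conductances, Dirichlet electrodes,
  σ_thrombus = σ_blood/8) predicts |Z| for any k; |Z| is strictly increasing
  in k, so k is recovered by bisection against the measured |Z| and
  `V_IM = f² Σ min(k·I, h)`. The same height field exports a watertight STL/OBJ
  surface.
- **Real-time monitoring.** ΔZ(%) — the relative rise of |Z| over its
  thrombus-free baseline — classifies blood behaviour into four groups by the
  final value at 300 s (<10, 10–20, 20–40, ≥40 %), with the 10 %-crossing time
  (bounds 240/180/120 s) as a consistency check and early predictor; sudden
  monotone ΔZ falls are reported as detachment (embolization) events.
- **Synthetic fixtures.** Seed-deterministic generators for thrombus height
  fields (pyramids/frusta/domes over an optional mural adhesion carpet),
  rendered noisy z-stacks, intensity-projection images, forward-modelled
  impedance readings, and logistic ΔZ traces for all four groups — every
  estimator is testable against exact ground truth without any external data.

## Worked example

Generate one synthetic experiment and run the full pipeline on it:

```sh
thrombovol simulate --out-dir demo --seed 42 --n-thrombi 4
thrombovol run --stack demo/stack.tif --image demo/projection.png \
               --trace demo/trace.csv --z-measured 5936.3
```

Output (abridged):

```json
{
  "monitor": {
    "classification": {
      "group": 3,
      "final_delta_z_pct": 30.42,
      "crossing_time_10pct_s": 161.5,
      "consistent": true
    },
    "detachment_events": []
  },
  "optical": {
    "n_planes": 54,
    "h_zstack_um": 26.5,
    "selected_threshold": 29,
    "v_ot_um3": 11773.2,
    "u_v_ot_relative": 0.15
  },
  "impedance_volume": {
    "scale_factor_um_per_intensity": 0.1001,
    "v_im_um3": 11404.2,
    "iterations": 13,
    "residual": 5.9e-06
  },
  "compatibility": { "difference_um3": 368.9, "tolerance_um3": 4204.4, "compatible": true }
}
```

Reading it: the trace crossed 10 % at 161 s and ended at 30.4 % → group 3
(strong aggregation), consistent with its crossing time. The stack's automatic
threshold landed at 29 (just above the noise floor) giving V_OT ≈ 11 773 µm³;
the inversion recovered the generative scale factor 0.1 µm/intensity to 0.1 %
and V_IM ≈ 11 404 µm³. The generator's ground truth was 11 392 µm³
(11 757 µm³ after voxelization onto the z-grid), and the two estimates are
metrologically compatible under their 15 %/10 % uncertainties.

Every subcommand (`simulate`, `ot-volume`, `fuseit`, `classify`,
`detect-events`, `compare`, `run`) is a thin wrapper over the library —
`thrombovol <cmd> --help` lists the options, and everything is callable from
Python (`thrombovol.analyze_stack`, `thrombovol.invert_scale_factor`, …).

## Layout

```
src/thrombovol/
  volumetry.py    z-stacks, threshold curves, automatic selection, u(V_OT)
  conduction.py   channel/electrode geometry, voxel fields, |Z| solver
  inversion.py    scale-factor bisection, V_IM, 3D meshes, V_OT/V_IM comparison
  monitor.py      ΔZ traces, 4-group classification, prediction, detachment
  synthetic.py    ground-truth fixture generators
  io.py           TIFF/PNG stacks, trace CSVs, validated run configuration
  pipeline.py     end-to-end orchestration with stage-tagged errors
  cli.py          umbrella command-line interface
docs/methods.md   model assumptions, numerical choices, limitations
```
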