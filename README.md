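# ivs-hemoflow

Desk-scale computational hemodynamics of the uteroplacental inflow region:
what happens to maternal blood as it leaves a uterine spiral artery and
enters the intervillous space (IVS) of the placenta — and how that changes
when the artery's terminal segment fails to remodel, the root lesion
postulated for intrauterine growth retardation (IUGR) and preeclampsia.

The package is aimed at placental physiologists and biofluid modellers who
want a reproducible, fully synthetic version of this flow problem: every
input (geometry, inflow, fluid) is generated by code, so simulations are
deterministic under seeds and contain no patient data.

## What it computes

1. **Synthetic morphological stage** — a labeled voxel grid (default
   3000 × 4400 µm planar; 3-D builder included): a spiralized artery
   (lumen 340 µm) rising through a basal zone into a villous-obstructed
   IVS, with either a **dilated** (gentle funnel, remodeled) or
   **undilated** opening, and a porosity-controlled random villous packing.
2. **Doppler-derived inflow** — uterine-artery velocity waveforms
   (normal / IUGR / notched IUGR-PE templates, or imported CSV traces)
   converted by the standard chain

   Q_AU(t) = v(t)·π(d_AU/2)², d_AU = 3.0 mm;
   q_SA(t) = (Q_left + Q_right)/n, n = 130 spiral arteries;
   v_in(t) = q_SA(t)/π(d_in/2)², d_in = 0.34 mm,

   calibrated so the cycle-mean spiral-artery flows equal
   0.031 / 0.027 / 0.017 ml/s for the three clinical scenarios.
3. **Incompressible Navier–Stokes** — staggered (MAC) finite volumes with
   pressure projection on the voxel mask; no-slip walls, slip sides,
   zero-traction top, plug pulsatile inflow; blood Newtonian with
   μ = 6 mPa·s, ρ = 1.055 g/cm³.
4. **Hemodynamic statistics** — entry-jet peak velocity and onset, wall
   shear stress τ = μ ∂u_t/∂n on villous and arterial surfaces (true-surface
   two-probe evaluation), segmented pressure drops (artery / opening / IVS,
   in mmHg), streamline and pathline classification with vortex-shunt
   fractions, the reversed-flow (dead-volume) share of the entry pocket,
   iso-pressure contours at 0.05 mmHg spacing, and the critical steady flow
   Q\* above which the entry vortex appears.

`docs/methods.md` describes the model, its assumptions, the numerical
choices and the planar-geometry caveats in detail.

## Worked example

```python
from ivs_hemoflow import ScenarioConfig, run_scenario, compare_scenarios

bundles = [run_scenario(ScenarioConfig(name=n, preset="coarse", n_cycles=2))
           for n in ("normal", "iugr", "iugr_pe")]
report = compare_scenarios(bundles)
for b in bundles:
    m = b.metrics
    print(f"{m['scenario']:8s} q̄={m['q_sa_cycle_mean_ml_s']:.3f} ml/s  "
          f"jet={m['jet_peak_velocity_cm_s']:5.1f} cm/s  "
          f"vortex={m['recirc_fraction_peak_pct']:4.1f}%  "
          f"Δp={m['dp_total_mmhg']:4.1f} mmHg  "
          f"steepness={m['dp_opening_steepness_mmhg_per_mm']:6.3f} mmHg/mm")
```

prints (coarse preset, default seeds):

```
normal   q̄=0.031 ml/s  jet= 76.3 cm/s  vortex=18.3%  Δp=40.1 mmHg  steepness= 0.029 mmHg/mm
iugr     q̄=0.027 ml/s  jet=112.1 cm/s  vortex=31.0%  Δp=48.7 mmHg  steepness= 5.842 mmHg/mm
iugr_pe  q̄=0.017 ml/s  jet=112.0 cm/s  vortex=31.0%  Δp=48.7 mmHg  steepness= 5.834 mmHg/mm
```

Reading: the three inlets carry similar systolic peaks, but the undilated
opening of the pathological cases fires a ~1.5× faster jet into the IVS
entry pocket, reverses ~31% of the pocket into a recirculating "dead
volume" at peak systole (vs ~18% transiently for the remodeled funnel), and
concentrates its pressure drop into the opening two orders of magnitude more
steeply. Bisection on steady solves places the vortex-onset threshold of the
undilated stage at Q\* ≈ 0.024 ml/s — inside the physiologic range — while
the dilated stage has none over the same bracket.

A thin CLI wraps the same calls:

```bash
ivs-hemoflow run --scenario iugr --out runs/iugr      # fields + metrics + VTK
ivs-hemoflow compare --out report/                    # all three + ratio table
ivs-hemoflow waveform-synth --profile iugr_pe --out wave.csv
ivs-hemoflow cohort                                   # clinical-table morphometrics
```

Outputs are CSV metrics, JSON reports and legacy-ASCII VTK files (stage
labels, velocity/pressure snapshots, streamlines, isobars) readable in
ParaView.

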