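# angionorm

A 2-D simulator of coupled tumor growth, angiogenesis, interstitial fluid
pressure (IFP) and drug transport, with a treatment-scheduling engine for
combinations of antiangiogenic agents and liposomal chemotherapy.

The model couples:

* **growth dynamics** — reaction–diffusion tumor cells (logistic growth,
  vessel-assisted proliferation, drug kill) and a bistable vessel-density
  field with angiogenesis couplings and an antiangiogenic kill term;
* **interstitial fluid** — a Darcy/Starling elliptic IFP solve with dynamic
  vessel-wall leakiness switching (vessels with density above 1 are leaky;
  normalization restores normal wall conductivity) and lymphatic suppression
  inside the tumor, plus a modified-Bessel analytic oracle for radially
  symmetric disc tumors;
* **drug transport** — exponential bolus plasma pharmacokinetics and
  quasi-steady tissue fields: a diffusion-dominated antiangiogenic agent and
  a convection-dominated liposomal drug (upwinded interstitial convection,
  one-way transvascular extravasation weighted by `1 − σ_d` from the
  pore-exclusion formula);
* **treatment scheduling** — the reference regimens (antiangiogenic alone,
  chemotherapy alone on days 23/25/27, lead-in and concurrent combinations),
  dose tapering, antiangiogenic dose calibration to a target microvascular
  density (MVD) reduction, and growth-rate calibration to the day-30 control
  radius;
* **metrics** — masked spatial averages (interior region `n > 1`, whole
  tumor `n > 0.1`), equivalent-disc tumor radius, MVD reduction,
  extravasation and exposure summaries, and case-comparison reports.

## Command line

```bash
angionorm config --dump                     # print the full default TOML config
angionorm grow  --config cfg.toml --out control.h5
angionorm treat --config cfg.toml --case case3 --resume control.h5 --out run.h5
angionorm calibrate growth --config cfg.toml
angionorm calibrate dose   --config cfg.toml --case case3
angionorm compare --cases case1,case2,case3,case4 --report report.csv
```

Field snapshots are stored in HDF5 (`SnapshotStore`), per-sample metrics as
CSV next to the snapshot file. Configuration is TOML (canonical) or YAML;
unknown keys are rejected and derived transport quantities (λ_b = L_p·S/V,
effective microvascular pressures, the reflection coefficient σ_d) are
always computed from the primary entries.

## Notes on defaults

All transport parameters follow the published tumor/normal table values.
The growth-rate constants are not published; the shipped defaults are
calibration choices (config-overridable) that reproduce a 13.5 mm radius at
day 30 from a 0.2 mm Gaussian seed together with the expected control
phenomenology: a leaky vascular rim, vessel-depleted core, and an interior
IFP plateau near the effective microvascular pressure that collapses within
~2 mm outside the tumor rim. Use odd grid node counts so the domain center
(where the seed sits) is a grid node.
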