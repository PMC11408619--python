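# riboforce

Analysis of single-molecule **magnetic force spectroscopy (MFS)**
experiments on riboswitch aptamers, for biophysicists studying how small
molecules stabilize RNA structure.  In an MFS experiment an RNA aptamer is
tethered between a surface and a paramagnetic bead; ramping the force up
and down makes the structure unfold and refold as abrupt jumps in bead
height, while holding the force constant lets it hop between the two
states.  A ligand can change this picture in two mechanistically distinct
ways: a **thermodynamic** binder (like the cognate PreQ₁ metabolite of
PreQ₁ riboswitches) locks the aptamer into a stable pseudoknot that only
ruptures at much higher force, while a **kinetic** stabilizer (like
synthetic xanthone ligands) merely slows unfolding of the existing fold,
subtly shifting the rupture-force peak.  `riboforce` implements the full
analysis that separates these signatures, plus the accompanying bulk-assay
fits.

## What it does

- **Trace model and I/O** (`trace_model`): validated time/extension/force
  containers, CSV and HDF5 round-trips.
- **Synthetic data** (`synthetic_data`): a Bell-kinetics two-state
  simulator (per-sample discretized ramps, exact Gillespie dwells) with
  both ligand modes, per-molecule heterogeneity and ground truth — every
  pipeline stage is testable without instrument data.
- **Ramp pipeline** (`ramp_analysis`): Brownian-noise QC, cycle
  segmentation, jump detection by density clustering (HDBSCAN) with an
  independent changepoint oracle, the analyzable-structure filter
  (5–15 pN, 10–25 nm, > 20 cycles, > 80 % unfolding), per-bead control
  normalization, the high-force cycle fraction against the control 95th
  percentile, and the saturation fit
  *y = (u + b·x/K_D)/(1 + x/K_D)* for EC₅₀.
- **Constant-force pipeline** (`dwell_analysis`): artifact screening, a
  two-state Viterbi state assigner, dwell extraction with censoring,
  exponential-mixture MLE (EM, 1–3 components) with BIC order selection,
  control-normalized log-rate aggregation across molecules, and pseudoknot
  occupancy versus concentration.
- **Dose-response fits** (`dose_response`): one-site total binding (K_D),
  transcription-termination efficiency T/(T+RT) and its T₅₀ curve.
- **CLI** (`riboforce simulate|ramp|dwell|fit|run`): YAML-configured,
  seeded, bit-reproducible runs with manifest and exclusion logs.

## Worked example

Simulate a small cohort with a kinetic-stabilizer ligand (K_D 560 µM, so
the half-maximal force shift sits near 400 µM) and run the ramp pipeline:

```python
import numpy as np
from riboforce import synthetic_data as sd, ramp_analysis as ra

model = sd.KineticModel(ligand_mode="kinetic_stabilizer", K_D_ligand=560e-6,
                        stabilization_factor=2.0, fold_enhancement_factor=2.0)
protocol = sd.ProtocolParams(n_cycles=50)           # 1-25 pN at 2 pN/s, 30 Hz
concs = [0.0, 100e-6, 400e-6, 1600e-6]              # molar; 0 = control (DMSO)
traces, _ = sd.simulate_ramp_cohort(model, protocol, concs, n_beads=6, rng=7)

result = ra.analyze_ramp_cohort(traces)
resp, fit = ra.ramp_dose_response(result["normalized"], "unfold", rng=7)
```

Output:

```
selected molecules: 6 of 6
control median unfolding force: 9.0 pN, size: 18.2 nm
c =       0 uM   median normalized force = 1.000
c =     100 uM   median normalized force = 1.039
c =     400 uM   median normalized force = 1.056
c =    1600 uM   median normalized force = 1.104
EC50 = 422 uM  (u = 1.005, b = 1.126)
```

Reading this: all six molecules pass the analyzable-structure filter; the
control unfolds around 9 pN with an ~18 nm step, inside the selection
windows.  Normalized rupture forces rise with ligand concentration toward
a ~10 % saturating shift — the kinetic-stabilizer fingerprint (one peak,
shifted) — and the hyperbolic fit reads off an EC₅₀ of ~420 µM against the
planted half-effect of ~400 µM (a six-molecule cohort leaves a few
10 % of sampling scatter on this number; see `docs/methods.md`).

## Documentation

`docs/methods.md` describes the kinetic model, every pipeline stage with
its defaults and units, what the synthetic-data generator does and does
not emulate, and the numerical choices (tolerances, initialization,
tie-breaks, degenerate inputs).
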