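# datnorm

Striatal specific-binding-ratio (SBR) quantification, striatal-phantom
cross-calibration, and normative modeling for dopamine-transporter (DAT)
SPECT — with a digital phantom and synthetic-cohort simulator so the whole
pipeline runs and is tested without any clinical data.

## The problem

[123I]FP-CIT SPECT measures dopamine-transporter density in the striatum.
Whether a scan is "normal" is judged against a reference database of
healthy controls — but multicenter databases mix scanners, collimators and
reconstruction conditions (with/without attenuation correction by the
Chang method or CT, with/without scatter correction), and raw quantitative
outcomes are not comparable across systems. This package implements the
harmonization pipeline such databases use:

1. **Southampton SBR.** With an intentionally oversized striatal VOI that
   captures all striatal counts,

   `SBR = (C_StrVOI − C_bg/vox · N_StrVOI) / (C_bg/vox · V_str)`

   where `C_StrVOI` is the total count in the striatal VOI, `N_StrVOI` its
   voxel count, `C_bg/vox` the per-voxel count of a reference region (a
   44 mm axial slab at the striatal level, minus the striatal VOIs), and
   `V_str` a standard striatal volume (11.2 mL) in voxel units. Adding
   pure-background voxels to the VOI leaves the estimate unchanged, which
   makes it insensitive to VOI shape, partial-volume blur and scanner
   resolution. The asymmetry index is `AI = |R − L| / (R + L) × 200`.

2. **Phantom cross-calibration.** A striatal phantom filled at known
   striatum:background concentration ratios (8:1, 6:1, 4:1, 3:1, uniform)
   has ground-truth SBR = ratio − 1. Regressing measured on true SBR per
   (scanner, reconstruction condition) gives a near-perfect line; applying
   its inverse maps any subject's measured SBR onto the common true scale.

3. **Normative layer.** Multiple regression of the average striatal SBR on
   age, scan start time (hours post injection) and sex, e.g.

   `SBR = 10.610 − 0.063·age + 0.263·start + 0.461·1[female]`,

   with t-based 95% confidence and prediction intervals, decade × sex
   summary tables, ICC(2,1) agreement between reconstruction conditions,
   Type-III ANOVA effect tests, and z-scoring of new subjects.

Because the underlying clinical scans are not redistributable, the
`phantom`/`scanner`/`cohort` modules provide a fully synthetic stand-in
with known ground truth: a digital striatal phantom (two 11.2 mL mirrored
ellipsoidal compartments in a head-sized background), an abstract scanner
model (PSF blur + per-condition affine SBR bias + Poisson counting noise),
and a cohort generator that draws subjects from the published normative
model.

## Worked example

```python
from datnorm import build_phantom_spec, rasterize_phantom, quantify

spec = build_phantom_spec(8.0, 4.0, background_conc=5.0)  # 8:1 right, 4:1 left
vol = rasterize_phantom(spec, voxel_size=2.0)
m = quantify(vol)
print(m.sbr_right, m.sbr_left, m.ai)
```

prints `7.0 3.0 80.0`: the noise-free digital phantom recovers the
ground-truth SBR (ratio − 1) exactly, and the asymmetry index
|7 − 3|/10 × 200 = 80.

The full simulated study is the numbered scripts under `analysis/`
(phantoms → calibration → cohort → harmonization → normative models →
consistency checks). Running them in order prints, among other things:

```
mean measured average SBR by condition (before calibration):
CTACNOSC  6.70   CTACSC 10.70   ChangACNOSC 7.55   ChangACSC 10.92   NOACNOSC 5.75

  condition  mean_original  mean_calibrated  icc_original  icc_calibrated
     CTACSC         10.704            8.918         0.183           0.925
  ChangACSC         10.920            8.268         0.173           0.961
```

— the ~2× spread of raw SBR across reconstruction conditions collapses
after calibration, and agreement with the uncorrected condition (ICC)
rises sharply, which is the point of the phantom harmonization. The
normative fit on the same calibrated cohort recovers the generating age
coefficient (−0.069 ± 0.005 vs −0.063) and the ~6–7% SBR decline per
decade.

A `datnorm` CLI wraps the same steps
(`simulate-phantom`, `simulate-cohort`, `quantify`, `calibrate-fit`,
`calibrate-apply`, `normative-fit`, `normative-report`,
`normative-compare`, `run-all`).

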