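# polcurve

Simulation and analysis of membrane bending at clathrin-coated pits as seen
by polarized total internal reflection fluorescence (pol-TIRF) microscopy.

## The problem

Clathrin-mediated endocytosis pulls flat plasma membrane into ~100 nm
vesicles, but when the membrane actually bends relative to clathrin
assembly distinguishes competing structural models: does curvature grow as
the coat assembles (constant curvature), or does a flat clathrin lattice
form first and bend later (constant area)? pol-TIRF encodes membrane
orientation into the ratio of images taken with excitation polarized
perpendicular (P) and parallel (S) to the coverslip: the membrane dye DiI
holds its dipole at a tilt β from the membrane plane, so flat membrane
gives

    P/S = cos²β / (½ sin²β) = 2 cot²β   (≈ 0.26 at β = 70°)

while vertical membrane — the wall of a forming pit — raises P. `polcurve`
provides, for people building or analyzing such experiments:

* **membrane geometry** — discretized surfaces of both bending models at
  any morphological stage, with exact area bookkeeping;
* **polarized optics** — the evanescent-field excitation model
  (e^(−z/d) decay, d = 100 nm), per-element P/S weights, Gaussian PSF
  (FWHM 211 nm), photon-additive downsampling to 125 nm pixels, and
  Poisson noise;
* **movie synthesis** — ground-truth-labelled multi-channel time-lapse
  movies (clathrin, P, S, dynamin) of endocytic events in three bending
  classes plus abortive structures;
* **event analysis** — bias calibration, fiducial-based channel
  registration, spot tracking, onset detection, event filtering,
  classification into bending classes, and lifetime/lag statistics.

## Worked example

```sh
python examples/classify_events.py
```

generates a 60-event synthetic movie at realistic photon counts, runs the
full pipeline, and prints:

```
events generated: 60, tracks kept: 57
classification accuracy vs ground truth: 93.0%

recovered class counts: {'class3': 24, 'class1': 19, 'class2': 14}
clathrin lifetime: class 1 77 s vs class 2/3 120 s (generator: 80 vs 108 s)
bending lag (class 2/3 minus class 1): 25.6 s (generator: 25.5 s)
lifetime difference test p = 1.89e-03 (class 1 events are shorter-lived)
```

Reading the numbers: class-1 events (membrane bends while clathrin
assembles) are recovered as shorter-lived than class-2/3 events (bending
delayed until after partial or complete assembly); the extra ~25 s the
delayed classes spend flat is recovered as the difference in the
clathrin-to-bending onset lag; and the Mann–Whitney test confirms the
lifetime split. Other examples: `beta_calibration.py` (the 0.26 ↔ 70°
closed loop), `bending_signatures.py` (per-stage clathrin and P/S signals
of both models), `synthetic_movie.py` (write a labelled TIFF movie),
`snr_robustness.py` (detection across noise levels).

A thin CLI wraps the same functions:

```sh
polcurve simulate --model class2 --stages 10 -o stages.tif
polcurve render-movie --seed 1 -o movie.tif
polcurve analyze movie.tif --bias dark.tif -o results/
polcurve calibrate-beta movie.tif
```

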