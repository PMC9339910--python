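# polstim

Computational toolkit for a dual-projector polarised-light stimulation
display and the electrophysiology analyses built around it:

- **frame_codec** — encodes per-pixel intensity / degree-of-linear-
  polarisation (DoLP) commands into paired 4-bit greyscale channels for
  the polarised and non-polarised projectors, packs six greyscale
  subframes into each 24-bit video frame (60 Hz video → 360 Hz pattern
  rate), and generates stimulus protocols: a circular dot revolving on a
  circular path and a 20×20 grid of briefly flashed squares.
- **calibration** — fits the sinusoidal polariser-angle dependence of
  each projector LED's luminance, selects the lowest uncalibrated
  luminance as the common target, and equalises every LED to it by
  iterative current adjustment, producing per-angle lookup tables.
- **polarimetry** — Stokes parameters (S0–S2), angle of polarisation
  (AoP) and DoLP maps from four analyser-angle images, RGGB Bayer
  channel extraction, DoLP-weighted AoP rendering, and the synthetic
  inverse (scene → four-image stack) used for round-trip validation.
- **rf_photoreceptor** — photoreceptor receptive-field maps from
  intracellular voltage traces and a grid schedule, spline/Gaussian
  display refinement, per-cell normalisation, binary-mask centroids,
  centroid-aligned averaging, polarisation tuning curves and
  polarisation-sensitivity (PS) ratios.
- **lms_lpd** — local preferred direction (LPD, latency-corrected via
  the clockwise/counter-clockwise resultant) and local motion
  sensitivity (LMS, preferred-minus-anti-preferred sector rate
  difference) from spike trains, contrast and AoP tuning curves with
  within-animal-first averaging, and bicubic vector-field
  interpolation.
- **simulators** — ground-truth generators: a photodiode reading a
  simulated projector light path, a polarisation-sensitive
  photoreceptor (photon-capture model, Gaussian spatial receptive
  field, Naka–Rushton nonlinearity), and a direction-tuned spiking
  neuron (cosine tuning, contrast-squared gain, latency, inhomogeneous
  Poisson spiking by thinning).

## CLI

All pipelines are exposed through one entry point:

```sh
polstim stimgen --config protocol.yaml --out out/          # protocols
polstim calibrate --simulated --out out/cal/               # LED LUTs
polstim polarimetry --i0 a.tif --i45 b.tif --i90 c.tif \
        --i135 d.tif --out out/pol/                        # AoP/DoLP maps
polstim --seed 3 simulate --kind photoreceptor --config sim.yaml --out out/sim/
polstim rfmap --trace out/sim/photoreceptor_trace \
        --schedule out/sim/grid_schedule.csv --out out/rf/
polstim --seed 5 simulate --kind h1 --out out/h1/
polstim lmsmap --spikes-cw out/h1/spikes_cw.csv \
        --spikes-ccw out/h1/spikes_ccw.csv --out out/lms/
```

Angles are stored in degrees and times in seconds; CSV files carry
header rows, maps are written as 32-bit float TIFF, and every output is
accompanied by a `*.provenance.json` record (inputs, parameters, seed,
version) sufficient to reproduce it.

## Conventions

- AoP is reported in (−90, 90] with 0 deg on the analyser's 0-deg axis;
  the period is 180 deg.
- Azimuth is positive toward the right visual field, elevation positive
  dorsal; the dot's position angle is 0 deg at the rightmost point of
  its path and counter-clockwise positive.
- The −1/0/+1 contrast scale is the difference of normalised object and
  background intensities (historically labelled "Weber contrast"; the
  classical Weber formula cannot reach +1 on a dark background).
- Bit packing: subframe *i* occupies bits [4*i*, 4*i*+4) of the 24-bit
  word read in B, R, G byte order, least-significant bit first; the
  pack/unpack round trip is the tested contract.
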