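# lightsweep

Simulation and analysis of **fast volume-scanning light-sheet calcium
imaging**, for cellular neuroscientists and microscope builders who want to
prototype or validate the acquisition scheme and its event-detection
analysis without hardware.

Dendrites meander through brain tissue in all three dimensions, so a
single-plane light-sheet movie keeps only short segments in focus. The
scheme modelled here sweeps the illumination sheet (galvo mirror) and the
detection focal plane (electrically tunable lens) with synchronized sine
drives

    z(t) = z₀ + A·sin(2π f t + φ),    f = 50 Hz, 2A = 20 µm,

and locks the camera exposure to one full period (20 ms), so each frame is
an average intensity projection of a whole Z sweep: an XYT movie at 50
volumes/s with an effective sheet thickness of the sweep depth. The package
provides:

* **phantom** — synthetic dendrites (smoothed random-walk tube) carrying a
  structural dye and a Ca²⁺ indicator, with ground-truth transients
  ΔF/F(t) = b·t·e^(−c·t) whose amplitude attenuates as e^(−d/λ) and whose
  onset is delayed with distance d along the dendrite;
* **acquisition** — the optical forward model (Gaussian sheet and
  depth-of-field profiles, per-exposure sweep integration, shot/read noise)
  in volume-scan, single-plane and stage-stepped structural modes, written
  as multi-page TIFF + JSON sidecar;
* **calibration** — in-silico recovery of the phase difference P that
  compensates the tunable lens's response lag, by maximising normalised
  variance (var/mean²) on a bead phantom;
* **traces** — ROI mean-intensity extraction, exponential background
  subtraction (p + q·e^(−rt)), ΔF/F conversion;
* **events** — candidate nomination, rise/decay fitting
  a + b·(t−t_on)·e^(−c·(t−t_on)), and the acceptance rule: an event is kept
  only if its fitted amplitude b/(c·e) strictly exceeds the RMS of the 1 s
  of baseline preceding it;
* **pipeline / CLI** — YAML-configured end-to-end runs with a single seed.

## Worked example

The packaged demo simulates one strong transient (peak ΔF/F 0.8 at
arclength 30 µm, c = 8 s⁻¹, spatial spread λ = 6 µm) on a meandering
dendrite, volume-scans it for 6 s at 50 volumes/s, then runs the full
detection chain:

```sh
$ lightsweep demo --seed 0 --out demo_run
accepted events: 6
precision=1.000 recall=0.545
outputs in demo_run/
```

Six ROIs along the dendrite yield accepted events; all six match ground
truth (precision 1.000). Recall is 0.545 because the ground-truth table
lists the event at *every* ROI, including distant ones where the
attenuated amplitude legitimately fails the amplitude-vs-noise criterion —
exactly the behaviour the acceptance rule is for. The fitted amplitudes in
`demo_run/detected_events.csv` trace the spatial attenuation, e.g.:

| ROI arclength (µm) | distance from origin | fitted amplitude (ΔF/F) |
|---|---|---|
| 30 | 0 µm  | 0.76 |
| 26 | 4 µm  | 0.40 |
| 22 | 8 µm  | 0.23 |
| 18 | 12 µm | 0.17 |

against a ground-truth peak of 0.8 and e-folding length of 6 µm. The phase
calibration can be exercised on its own; with a simulated 2 ms lens lag at
50 Hz the compensating phase 2π·50·0.002 ≈ 0.63 rad is recovered to the
grid resolution:

```sh
$ lightsweep calibrate --lag-ms 2 --out cal.json
optimal phase 0.5236 rad -> cal.json
```

Other subcommands: `simulate`, `detect`, `report`,
`config --show-defaults`. Exit codes: 0 success, 2 config error, 3 data
error.

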