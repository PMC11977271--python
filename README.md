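# discsense

Simulation and signal processing for low-cost optical sensing on electrified
lab-on-a-disc (eLOD) platforms.

Centrifugal microfluidic discs move fluids with spin instead of pumps, but
watching what happens on a spinning disc normally takes a stroboscope or
high-speed camera. An alternative instrument class watches the channel with
an array of light-dependent resistors (LDRs) behind cone-shaped waveguides
whose sub-millimeter apertures (diameter *D*₁ = 0.2–1 mm, 0.3 mm gaps)
restrict each sensor's view to a spot on the channel. Droplets, two-phase
interfaces and sedimenting red-blood-cell (RBC) columns cast shadows and
absorb light, modulating each sensor's normalized light intensity
LI ∈ [0, 1]; the timing and pattern of those modulations carry the
measurement.

`discsense` provides both directions of that sensing chain for engineers and
diagnostics researchers working with such devices:

* **Forward models** — per-sensor LI from Beer–Lambert attenuation
  (T = 10⁻ᵏʰ), circle–circle aperture occlusion, LED calibration, cone tilt
  and first-order LDR lag (`optics`); droplet transport in the rotating
  channel from the force balance
  *m* d*v*/d*t* = Δρ·*V*·ω²*r* − 18µ*V·v*/(d²·H(κ)), with the
  Hadamard–Rybczynski mobility H(κ) = (1+κ)/(⅔+κ) (`dynamics`); and
  two-front Kynch/Richardson–Zaki kinematics of RBC–plasma separation with
  sedimentation index SI = (d₀ − d₁)/d₀ (`sedimentation`).
* **Inverse computations** — the instrument's 5% detection rule, droplet
  event detection and counting, time-of-flight velocimetry (v = pitch/Δt
  between apertures), interface localization and sample-volume monitoring,
  and RBC-deformability classification by counting enabled sensors
  (`detection`).
* **Ground-truthed synthetic scenarios** (`synthetic`), trace CSV / YAML /
  JSON I/O (`io`), and a `discsense` command-line interface (`cli`).

## Worked example

Simulate a droplet pass at each rotation speed of the velocimetry experiment
and recover the velocities from the rendered sensor signals:

```python
from discsense import io
report = io.run_pipeline("fig2e", seed=0)
print(report["velocities"])
```

```
{'64':  {'estimated_mm_s': 0.9093,  'ground_truth_mm_s': 0.9097,  'n_events': [1, 1, 1]},
 '95':  {'estimated_mm_s': 2.0062,  'ground_truth_mm_s': 2.0043,  'n_events': [1, 1, 1]},
 '170': {'estimated_mm_s': 6.4271,  'ground_truth_mm_s': 6.4179,  'n_events': [1, 1, 1]},
 '240': {'estimated_mm_s': 12.7208, 'ground_truth_mm_s': 12.7907, 'n_events': [1, 1, 1]}}
```

Each 1 mm water droplet in 75 cP blue-dyed oil produces one LI peak per
aperture; dividing the 1.3 mm aperture pitch by the inter-peak delay
recovers the simulated velocity to well under 1% despite σ = 0.005 LI noise.
The same pipeline runs the deformability assay — sedimentation traces for
normal and glutaraldehyde-stiffened RBC samples, classified by counting
sensors still seeing plasma at the read time:

```python
print({k: (v["label"], v["count_at_read"])
       for k, v in io.run_pipeline("fig4", seed=0)["calls"].items()})
# {'normal': ('normal', 2), 'GA_0.01': ('GA_0.01', 1), 'GA_0.02': ('GA_0.02', 0)}
```

reproducing the 2 / 1 / 0 enabled-sensor ordering of the graded samples.
The equivalent shell commands:

```
discsense run fig2e --seed 0 --out report.json
discsense simulate-sedimentation --label GA_0.02 --out sed.csv
discsense classify sed.csv --protocol four_class
```

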