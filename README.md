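# antagonav

Simulation and analysis pipeline for volatile-pheromone chemotaxis by
*Caenorhabditis elegans* males, who navigate with two spatially separated,
functionally antagonistic detectors: gradient-sensing head neurons (AWA)
that promote forward movement, and threshold-sensing male-specific tail
neurons (PHD) that promote reversals and slowing. Because a volatile cue on
a lab plate forms a fast-moving, shallow gradient, the relative
concentration difference along a ~1 mm body is almost always negligible —
so the model compares detector *response properties*, not concentrations at
two body ends.

The package is aimed at computational neuroethologists who want to simulate
and analyse this navigation strategy end to end:

* **`plume_field`** — conservative finite-volume solver for volatile
  transport in a two-layer circular arena (4 mm air, D = 1.6 mm²/s, over
  9 mm agar, D = 10⁻³ mm²/s; no-flux walls; droplet source on the lid),
  plus the along-body contrast statistic |C(head) − C(tail)| / C(body).
* **`navigator`** — agent-based run-and-tumble worms with internal
  confidence variables
  dQ^H/dt = −k₁Q^H + k₂f_H(C, Ċ), dQ^T/dt = −k₁Q^T + k₂f_T(C)
  (k₁ = 1/60 s⁻¹, k₂ = 1 s⁻¹, Q clamped to [−1, 1]) driving speed
  U = max(0, U₀ + U₁(Q^H − Q^T + η)) and tumble rate
  γ = γ₀ e^{−λ_K (Q^H − Q^T)} with γ₀ = 0.067 s⁻¹, U₀ = 0.064 mm/s,
  U₁ = 0.03 mm/s, rotational diffusivity D_R = 0.02 rad²/s, plus
  perfectly-accurate taxis turns gated by concentration and a sensed
  decrease. Detectors can be disabled per condition
  (`both`/`head_only`/`tail_only`/`none`).
* **`traj_metrics`** — speed series and stimulation-locked power spectra,
  2-s-window behavioural motif classification (four/six motifs),
  chemotaxis indices C.I. = (E − C)/(E + C + N), cohort summaries
  (success curves, ⟨x⟩, per-worm maximum source distance).
* **`calcium_metrics`** — two-channel ΔR/R₀ with Savitzky–Golay filtering
  (order 1, window 13), sign-restricted AUC dose analysis, Pearson
  correlation screening (cutoff 0.55), unit-interval normalisation, and the
  linear head/tail → command-neuron decomposition.
* **`turn_design`** — optimal second-sampling-angle analysis: a least-squares
  gradient estimate from two noisy directional-derivative samples, and the
  turn angle that minimises the uncertainty of the estimated gradient
  direction.
* **`synthetic_data`** — seeded generators for every input the analyses
  need (fast/slow calcium responder cohorts, stimulation-locked speed
  traces, circuit triplets, endpoint counts, analytic toy fields).

## Worked example

Dominant spectral peak of a stimulation-locked speed trace (12.5 s light-on
/ 7.5 s light-off, a 20-s cycle):

```python
from antagonav.synthetic_data import StimProtocol, gen_periodic_speed
from antagonav.traj_metrics import power_spectrum

series = gen_periodic_speed(StimProtocol(12.5, 7.5, 8),
                            response_gain=0.5, noise_sd=0.1, seed=7)
_, _, peak, strength = power_spectrum(series)
print(f"dominant peak {peak:.3f} Hz, strength {strength:.1f}")
```

prints `dominant peak 0.050 Hz, strength 30.0` — the response locks to the
20-s stimulation cycle (1/20 s = 0.05 Hz) and stands ~30× above the local
spectral background on the amplitude scale.

Cohorts on the simulated 8-cm arena (1000 worms each, 30 min):

```python
from antagonav.arena import standard_field_slice, field_scaled_params
from antagonav.navigator import run_cohort
import numpy as np

slc = standard_field_slice()
params = field_scaled_params(slc)
for cond in ["head_only", "tail_only", "none"]:
    res = run_cohort(1000, cond, slc, 1800.0, dt=0.1, params=params, seed=42)
    print(cond, f"{100 * np.mean(~np.isnan(res.capture_times)):.1f}%")
```

prints `head_only 100.0%`, `tail_only 15.8%`, `none 4.7%`: taxis turns from
the head detector make source-finding nearly certain; the tail detector
alone still multiplies the blind-search success severalfold by driving
faster, straighter excursions (sprints) once the plate fills with pheromone.

The same things are available from a shell:

```bash
antagonav turnopt --grid-deg 0.5 --out curve.csv
# optimal turn angle: 121.0 deg (curve in curve.csv)
antagonav field --plate-diameter 80 --source-x -15 --duration 1800 --out field.npz
antagonav simulate --field field.npz --condition none --n 1000 --seed 42 --out cohort.h5
antagonav analyze-traj cohort.h5 --out summary.json
```

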