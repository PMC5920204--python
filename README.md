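# doppleroct

Extended-dynamic-range Doppler optical coherence tomography by complex
regression, with the conventional two-point comparator, a calibrated
flow-phantom simulator, and the minimum-detectable-velocity evaluation
protocol.

## The problem

Doppler OCT converts the phase shift θ between A-lines into axial
velocity, v = θ·λ₀/(4π·n·ΔT). The two-point (adjacent A-line) method is
boxed in from both sides: the system phase stability sets the floor and
phase wrapping at ±π sets the ceiling. At λ₀ = 1315 nm, n = 1.38,
ΔT = 594 ns and a 0.096-rad stability floor that is 12.25–401.05 mm/s —
too narrow for samples like developing embryonic hearts, whose blood
velocities span from ~100 μm/s near vessel walls to hundreds of mm/s.

With MHz A-line rates, B-scans can be sampled densely enough that ~64
consecutive A-lines interrogate effectively the same location. The
**complex-regression** estimator exploits this: for a window of m
complex samples it searches θ ∈ (−π, π] (1-mrad grid) for the value
that, after derotating the k-th sample by kθ, minimizes the standard
deviation of the realigned points. Working in polar coordinates, the
accumulated phase Δφ = (m−1)θ simply circles the origin, so the total
shift may exceed 2π without wrapping — the ceiling stays at the
two-point value while the floor improves (m−1)-fold, to ~194 μm/s for
m = 64. Because derotation preserves moduli, minimizing the dispersion
is exactly equivalent to maximizing |Σₖ sₖe^{−ikθ}|, which is how the
fast path computes it (the literal dispersion search is kept as a
cross-check). The estimator weights by amplitude, like the Kasai
autocorrelation estimator `arg Σ s₍ₖ₊₁₎s̄ₖ` it is compared against.

The package is aimed at researchers who want to reproduce, stress or
extend these dynamic-range results without an instrument: the phantom
module simulates a 300-μm capillary flow phantom with SNR-dependent
phase noise calibrated so a static sample shows exactly the 0.096-rad
adjacent-pair phase std.

## Worked example

```python
import numpy as np
from doppleroct import (DopplerConfig, EstimatorSpec, PhantomSpec,
                        conventional_range, detection_report, simulate_mscan)
from doppleroct.evaluation import window_velocities
from doppleroct.phantom import centerline_depth_index

config = DopplerConfig()
rng = conventional_range(config)
print(f"two-point range: {rng.v_min*1e3:.2f} - {rng.v_max*1e3:.2f} mm/s")

report = detection_report(EstimatorSpec("complex_regression", 64), "high", config)
print(f"regression floor: {report.theoretical_floor_mps*1e6:.0f} um/s, "
      f"grid minimum: {report.grid_minimum_mps*1e6:.0f} um/s")

spec = PhantomSpec(axial_velocity_mps=374e-6, seed=42, n_alines=2000, n_depth=32)
scan = simulate_mscan(spec, config)
v = window_velocities(scan, EstimatorSpec("complex_regression", 64),
                      centerline_depth_index(spec), config=config)
print(f"{v.size} windows: mean {np.mean(v)*1e6:.0f} um/s "
      f"(normalized {np.mean(v)/374e-6:.3f})")
```

prints

```
two-point range: 12.26 - 401.05 mm/s
regression floor: 195 um/s, grid minimum: 374 um/s
31 windows: mean 387 um/s (normalized 1.035)
```

The first line is the conventional two-point dynamic range at the
default acquisition constants. The second converts the same phase floor
through the 63-interval regression window (~194 μm/s) and snaps it to
the smallest velocity of the 18-value logarithmic test grid at or above
it. The third simulates flow *at* that grid velocity — 30× below the
two-point floor — and recovers it within 3.5% from 31 windows of a
2,000-A-line scan.

The same operations are available from the shell:

```
doppleroct simulate --velocity 0.000374 --n-alines 2000 --n-depth 32 \
    --seed 42 --out scan.h5
doppleroct doppler scan.h5 --estimator cmpreg --window 64 --out velocity.csv
doppleroct report --estimator cnv5 --snr low --out report.json
```

Every run writes a JSON manifest (config, seed, version) beside its
outputs; rerunning with the same manifest settings reproduces results
bit for bit.

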