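# melanotrack

Trajectory analysis and spatial quantification for intracellular organelle
transport, built around 2D single-particle tracking of pigmented melanosomes
in cultured melanocytes (brightfield video at one frame per 0.5 s over
5 minutes — 601 frames — with a 0.16 μm pixel), and applicable to any tracked
cargo recorded as (track, frame, x, y) tables.

Melanosomes are carried along microtubules by kinesin (outward, centrifugal)
and dynein (inward, centripetal) motors; perturbing one side of this
tug-of-war changes how far, how directedly and how often organelles move, and
where they accumulate in the cell. The package quantifies exactly that, from
tracked coordinates:

* **Kinematic descriptors** — total travelled distance (sum of per-frame step
  lengths), Euclidean (start-to-end) distance, average distance per frame and
  velocity, pause fraction (steps whose pixel-quantized displacement is zero,
  i.e. movement below the 0.16 μm resolution), and net centrifugal/centripetal
  direction relative to the nucleus.
* **MSD exponent analysis** — the time-averaged mean-square displacement
  MSD(τ) = ⟨[r(t+τ) − r(t)]²⟩ fitted with the power law b·τ^α by log–log
  least squares. α is the motion descriptor: α ≈ 1 for diffusion
  (MSD = 4Dτ in 2D), α → 2 for directed transport (MSD = V²τ²), α < 1 for
  tethered/confined or noise-dominated motion. Population α distributions are
  compared with the two-sided rank-sum test.
* **Directional / non-directional classification** — each trajectory's second
  moments of displacement at a short and a long lag (μ2S, μ2L) are compared
  against slope-1 frontier lines in the log10 plane, calibrated once from
  quantiles of a simulated Brownian reference and then applied unchanged to
  every population; tracks between the two frontiers form the uncertainty
  band, reported as a directional-count range.
* **Perinuclear quantification** — particles ≥ 150 nm counted inside the band
  extending 2 μm outward from the nucleus border, clipped to the cell outline,
  normalized by the band's area.
* **A seeded simulator** of the elementary motion processes (Brownian,
  directed, drift+diffusion, Ornstein–Uhlenbeck tethering, reflected
  confinement) with Gaussian localization noise and pixel quantization, used
  for classifier calibration and for testing every stage against closed-form
  laws.

## Worked example

```python
import numpy as np
from melanotrack import (
    AcquisitionSettings, MotionClassifier, alpha_distribution, compare_alpha,
    generate_population, summarize_population, wt_like_spec, knockdown_like_spec,
)

settings = AcquisitionSettings()          # 0.5 s/frame, 601 frames, 0.16 um pixel
control = generate_population(wt_like_spec(), settings, seed=10)
depleted = generate_population(knockdown_like_spec(), settings, seed=11)

for label, pop in [("control", control), ("depleted", depleted)]:
    desc = summarize_population(pop)
    print(f"{label}: total {desc['total_distance_um'].mean():.1f} um, "
          f"euclidean {desc['euclidean_distance_um'].mean():.1f} um, "
          f"paused {desc['pause_fraction'].mean():.0%} of steps")

a_ctrl = alpha_distribution(control, "control")
a_depl = alpha_distribution(depleted, "depleted")
res = compare_alpha(a_ctrl, a_depl)
print(f"median alpha: {np.median(a_ctrl.alphas):.2f} vs "
      f"{np.median(a_depl.alphas):.2f} (rank-sum p = {res.p_value:.2g})")

clf = MotionClassifier.calibrate(settings, n_reference=2000, seed=12)
for label, pop in [("control", control), ("depleted", depleted)]:
    c = clf.count_directional(pop)
    lo, hi = c.directional_range
    print(f"{label}: {lo}-{hi} directional trajectories out of {c.n_total}")
```

prints

```
control: total 12.7 um, euclidean 2.8 um, paused 84% of steps
depleted: total 17.2 um, euclidean 11.0 um, paused 78% of steps
median alpha: 1.02 vs 1.83 (rank-sum p = 5.3e-07)
control: 17-46 directional trajectories out of 75
depleted: 46-57 directional trajectories out of 75
```

The two presets emulate a control-like population (75 tracks, mostly
diffusive with a small directed minority) and a retrograde-motor-depleted one
(a directed majority): the depleted population travels farther, pauses less,
its α distribution is right-shifted, and far more of its trajectories fall on
the directional side of the shared Brownian-calibrated frontiers — with the
intermediate band giving each count as a range rather than a single number.

The same analyses are available from the shell on any track table:

```bash
melanotrack simulate --process brownian --d 0.01 --count 75 --seed 1 --out tracks.csv
melanotrack descriptors --tracks tracks.csv --out descriptors.csv
melanotrack msd --tracks tracks.csv
melanotrack classify calibrate --out frontiers.json
melanotrack classify run --frontiers frontiers.json --tracks tracks.csv
melanotrack report --config config.yaml --out report/
```

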