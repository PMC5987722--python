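# rdomainscope

Quantitative analysis of **replication domains (RDs)** — the ~150-nm,
~500-kbp structural units of chromosomes — from correlative confocal and
STORM (single-molecule localization) imaging, for microscopists and
chromatin biophysicists who pulse-label co-replicating DNA and want the
full measurement chain in one tested package:

- **STORM quality control** — photon-count gating of the localization
  event list, correlation-based lateral drift correction in temporal
  blocks, count-histogram rendering at 10-nm pixels, and a Fourier ring
  correlation (FRC) resolution gate (3σ criterion, images worse than
  50 nm rejected).
- **Confocal–STORM overlay** — the 3D confocal stack is rescaled to the
  STORM grid, turned into moving 5-slice sum projections, each is
  rigid-registered (rotation + translation, normalized cross-correlation)
  against the STORM image, and the best-correlating z-window selects the
  in-focus region; per-territory ROI polygons crop the rest.
- **Domain ultrastructure** — Perona–Malik and median filtering, peak
  detection by grayscale dilation (4-px disc), DBSCAN clustering of the
  detected co-replicating stretches (MinPts = 2, Eps = 14 px ≙ 140 nm),
  and per-cluster morphometrics: stretches/RD, intra-RD nearest-neighbor
  distances (NND), horizontal Feret diameter, convex hull, solitary
  fraction.
- **Inter-domain spacing** — 3D particle detection (threshold,
  26-connected components, intensity-weighted centroids) in dual-color
  stacks and directed cross-channel NNDs as a function of the pulse
  interval Δt.
- **Mechanical coupling** — per-step correlation angle
  α = arccos(u·v/|u||v|) between the displacement vectors of paired RD
  trajectories (0° = fully coupled, mean 90° = uncoupled), the ⟨α⟩-vs-
  distance profile, and the coupling transition point (d\*, α\*) as the
  intersection of two regression lines fitted below 400 nm and above
  600 nm.
- **Combing calibration** — λDNA stretching-rate fit (kb/µm) and
  comet-length conversion to kbp, plus the fork-yield consistency
  arithmetic (forks × speed × duration).
- **Synthetic data** — a generator that emulates all of the above inputs
  (clustered emitter scenes, blinking event lists with drift, confocal
  PSF renderings, Δt-dependent dual-color scenes, coupled trajectory
  pairs, combed fibers) with retained ground truth, so every stage is
  verifiable end to end.

## Worked example

Run the whole synthetic chain with one command:

```sh
rdomainscope run --seed 7
```

or from Python:

```python
import rdomainscope as rds

cfg = rds.validate_config({"imaging": {"loc_precision_sigma": 8.0},
                           "run": {"seed": 7}})
report = rds.run_pipeline(cfg)
print(report["stages"])
```

which prints (abridged):

```
clustering: median_stretches_per_rd 5.0, median_intra_nnd_nm 60.8,
            median_feret_nm 105.0, solitary_fraction 0.158
spacing:    delta_t_min 60.0, median_nnd_nm 316.9  (n_pairs 16)
coupling:   transition_distance_nm 574.9, transition_alpha_deg 88.1
```

Reading: the STORM images passed the drift and FRC gates; DBSCAN finds a
median of 5 stretches per recovered domain (the generator's count law has
median 4 including single-stretch domains, which a MinPts = 2 clustering
necessarily reports as solitary — see `docs/methods.md`), stretches sit
~61 nm apart, domains extend ~105 nm along x; dual-color domains pulsed
60 min apart sit ~300 nm from each other; and motion correlation is lost
near ~550 nm at an angle close to the 90° of independent motion.

Per-stage CLI subcommands (`simulate`, `qc`, `overlay`, `cluster`,
`spacing`, `coupling`, `combing`) operate on CSV/TIFF/YAML files; run
`rdomainscope <cmd> --help` for their options.

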