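# synapsekit

Quantitative analysis of receptor organization and dynamics within the T cell
immunological synapse, for researchers imaging synapses on supported lipid
bilayers (SLBs) with TIRF microscopy. When a T cell engages an activating
surface, the contact organizes into concentric supramolecular activation
clusters — the TCR-rich cSMAC, the adhesion (LFA-1/ICAM1) pSMAC, and the
actin-rich dSMAC — and membrane receptors such as GPCRs redistribute across
these zones over minutes while individual molecules diffuse, get transported
centripetally, or become confined. `synapsekit` implements the image- and
trajectory-analysis used to quantify that behavior, plus a synthetic-data
generator so every stage can be validated against known ground truth without
any raw microscopy data.

## What it computes

- **Segmentation** — the contact footprint from the IRM channel (contact =
  dark), partitioned into cSMAC / pSMAC / dSMAC from UCHT1 and ICAM1
  enrichment (Otsu thresholds, largest connected component for the cSMAC).
- **Radial profiles and enrichment** — rotational radial averages (mean
  projection over 359 rotations, with an equivalent annular fast path),
  min-max-normalized cross-section profiles, and the per-region enrichment
  index E_r = (intensity fraction of region r) / (area fraction of region r),
  with a one-sample two-tailed t-test against E = 1. Colocalization is a
  thresholded Pearson correlation restricted to pixels above threshold in
  either channel.
- **Single-particle tracking** — difference-of-Gaussians spot detection
  (0.5 um spot diameter) with sub-pixel centroid refinement, two-pass LAP
  linking (1 um max link distance, 1 um / 1 frame gap closing), and a
  30-frame (1.5 s at 50 ms/frame) track-length filter.
- **Diffusion classification** — per-track time-averaged MSD, anomalous
  exponent alpha (log-log slope over the first 10 lags), short-lag
  D = MSD(tau_1)/(4 tau_1), mean speed; tracks labeled confined
  (alpha < 0.7), active (alpha > 1.3), or normal.
- **Region dynamics** — per-frame region assignment, occupancy (>= 3 frames
  in a region), normalized distance-to-center series (start = 1) with
  regression slopes, and run-collapsed region-transition summaries.
- **Intensity ratios** — distal/basal membrane ratios from confocal z-stacks
  (3 x 3 um box at the synapse center) and outside/inside ratios of
  cell-vesicle contact profiles.
- **Screen statistics** — responses normalized so the reference (CD19)
  control's maximum baseline-subtracted response is 100, four-parameter
  logistic fits R(c) = Bottom + (Top − Bottom) / (1 + 10^((logEC50 −
  log10 c)·Hill)), Emax at the highest dose, and whole-curve comparison by
  the extra sum-of-squares F test.

The simulator (`synapsekit.simulate`) generates concentric synapse
geometries, four-channel images with Poisson noise, Gaussian-PSF spot movies,
trajectories under normal / active (center-drifting) / confined (reflecting
corral) diffusion, and 4PL-shaped superantigen dose-response screens — all
seeded and bit-reproducible.

## Worked example

```python
import synapsekit as sk
from synapsekit import diffusion, dynamics, profiles, screen, simulate

geometry = sk.SynapseGeometry()  # 12.8 um field; cSMAC 1.5 / pSMAC 3.5 / contact 5.0 um
image = simulate.render_synapse_channels(geometry, noise="poisson", seed=7)
partition = sk.segment_synapse(image)
enrich = profiles.enrichment_index(image["receptor"], partition)

tracks = simulate.simulate_trackset(geometry, (0.6, 0.2, 0.2), 200, n_frames=100, seed=7)
labels = diffusion.classify_trackset(tracks)
occ = dynamics.occupancy(tracks, partition)

ds = simulate.simulate_screen_dataset(seed=7)
summary = screen.screen_summary(screen.normalize_screen(ds))
```

This prints (seed 7):

```
contact center (um): (6.4, 6.4)
areas (um^2): {'dSMAC': 40.1, 'pSMAC': 31.4, 'cSMAC': 7.2}
receptor enrichment: {'dSMAC': 1.23, 'pSMAC': 0.84, 'cSMAC': 0.4}
mode fractions: {'normal': 0.8, 'confined': 0.2}
occupancy (>=3 frames): {'dSMAC': 0.65, 'pSMAC': 0.65, 'cSMAC': 0.23}
target   emax  log_ec50  p_value
  CD19 99.678     0.000      1.0
 CXCR4 62.866     1.033      0.0
```

Reading the numbers: the segmented SMAC areas match the generator's annuli;
the dSMAC-biased receptor profile yields enrichment above 1 distally and
depletion centrally (1 = no enrichment); the MSD-exponent rule recovers the
confined fraction exactly but files slowly-drifting active tracks under
normal diffusion (see `docs/methods.md` for why); most tracks touch the
outer zones while few reach the cSMAC; and the simulated CXCR4 knockout
shows the expected reduced Emax and right-shifted logEC50 relative to the
CD19 control, flagged by the extra sum-of-squares F test.

A command-line interface mirrors the library:

```bash
synapsekit simulate image --seed 1 --out synapse.tif
synapsekit segment --image synapse.tif --out-labels labels.tif --out-summary regions.json
synapsekit profile enrichment --image synapse.tif --out enrichment.csv
synapsekit simulate tracks --seed 1 --out tracks.csv
synapsekit classify --tracks tracks.csv --out modes.csv
```

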