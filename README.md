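# eltether

Quantification of ER–endolysosome tethering and endolysosome behaviour from
fluorescence microscopy and electron microscopy data.

Endolysosomes (ELs — late endosomes and lysosomes) form membrane contact
sites with the endoplasmic reticulum: regions where the two membranes are
apposed within ~30 nm without fusing. Tethering at these sites restrains EL
motility and keeps ELs in the perinuclear region; losing the tether makes
ELs faster and more peripheral. `eltether` implements, as one tested
pipeline, the image-analysis procedures used to quantify this biology:

- **Sub-pixel puncta detection** — band-pass filtering plus least-squares
  fitting of pixel-integrated 2-D Gaussians (with a two-component fit for
  near-neighbour spots), and thresholding of bright tether-protein
  *accumulations* above the dimmer reticular ER signal.
- **Trajectory linking** — Hungarian frame-to-frame assignment with gap
  closing.
- **Moment-scaling-spectrum (MSS) motion classification** — displacement
  moments μ_ν(δ) of orders ν = 0…6 scale as δ^γ_ν; the slope *S* of γ_ν
  versus ν is 0 for stalled, 0.5 for Brownian and 1 for ballistic motion.
  Tracks are labelled confined / free / directed against a Brownian null
  band calibrated by Monte-Carlo simulation at the acquisition's track
  length, frame interval and localization noise; free + directed are pooled
  as the "motile" fraction.
- **Contact persistence** — co-occurrence of an accumulation and an EL
  object must persist ≥ 10 s to count as a true contact (≥ 2 consecutive
  slices for fixed-cell z-stacks).
- **Peripheral dispersal** — the cell outline is shrunk inward in 2 µm steps
  into five shells; the peripheral fraction is thresholded EL signal in the
  outer three shells over the whole-cell signal.
- **EM contact fraction** — from traced serial-section contours, the percent
  of EL membrane perimeter within ≤ 30 nm of ER membrane, summed across
  sections before dividing, averaged per cell.
- **PLA dot counting** — threshold, watershed splitting of touching dots,
  and a ≥ 5 px size filter, per cell.
- **ER association** — the fraction of 10 followed frames (2.4 s interval)
  in which ER signal appears inside the EL mask, as a percentage.

Because the raw recordings behind such studies are rarely deposited, the
package ships a first-class synthetic-scene generator
(`eltether.synthetic`): trajectories with confined (reflected Brownian),
free and directed kinetics; rendered movies with a reticular ER background,
Poisson/read noise and planted contact dwells; dispersal stills with known
peripheral fractions; EM circle/line geometries with closed-form contact
percentages; and PLA dot layouts with exact pixel areas. Every analysis
stage is validated against this ground truth.

## Worked example

Simulate a three-class movie (10 fps, 0.1 µm/px), detect, link and classify
it in one command:

```sh
eltether all --seed 7 --out run --n-frames 120
```

```
wrote run/movie.tif (18 particles, 120 frames)
2159 detections -> run/detections.csv
18 tracks -> run/tracks.csv
18 tracks classified -> run/mss.csv
end-to-end report in run
```

The scene plants six particles per motion class. `run/motion_summary.json`
then reads:

```json
{
  "counts": {"confined": 7, "free": 6, "directed": 5, "unclassified": 0},
  "free_plus_directed": 0.611,
  "motile_to_confined_ratio": 1.571
}
```

All 18 planted particles were recovered as tracks; at this short track
length (120 frames) one free/directed track lands on the confined side of
the calibrated Brownian band, so the recovered composition is 7/6/5 against
the planted 6/6/6. The motile fraction (free + directed pooled, 0.611
vs. planted 0.667) and the motile-to-confined ratio are the two numbers used
to compare conditions. Longer recordings sharpen the classification; the
same library calls are available programmatically via
`eltether.mss.compute_mss`, `calibrate_thresholds` and `classify_motion`.

Every run directory also contains `resolved_config.yaml` and `run_log.json`
(package version, seed, per-stage counts), so a run can be audited and
regenerated exactly.

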