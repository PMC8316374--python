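# Methods

This note documents the models, parameter choices and numerical decisions
behind each analysis stage, what the synthetic-data generator does and does
not emulate, and the known limitations.

## Coordinate and unit conventions

Images are `(t, c, y, x)` arrays with 0-based pixel indices, x = column,
y = row, and pixel centres at integer coordinates. Physical positions are
pixels × `pixel_size_um`; trajectory analysis works in µm and seconds. EM
contours are in nanometres. Durations count both endpoint frames: an object
visible in frames `start…end` lasted `(end − start + 1)·Δt`, so a
single-frame appearance has duration Δt, not zero.

## Synthetic scenes

The generator exists because each analysis stage needs inputs with known
ground truth.

**Trajectories.** Free motion is 2-D Brownian with per-axis increment
variance `2·D·dt`. Directed motion adds a constant drift `v·dt` in a fixed
random direction. Confined motion is Brownian *reflected* at the boundary of
a disc of radius `R_c` (radial reflection `r → 2R_c − r`, iterated):
hard confinement rather than an Ornstein–Uhlenbeck spring, because it gives
a clean MSS-slope separation and a testable bound (no true position ever
exceeds `R_c`). Localization noise (default σ = 0.02 µm, a typical
fitting error at moderate SNR) is added after reflection, so *observed*
positions may slightly exceed `R_c`; ground truth records the noiseless
path.

**Rendering.** Spots are pixel-integrated 2-D Gaussians (error-function
form), not point-sampled, so sub-pixel localization against rendered images
is unbiased by construction. The reticular ER background is the edge set of
a random Voronoi tessellation blurred by the PSF — a stand-in for the
peripheral ER tubule network that accumulation thresholding must reject.
Poisson photon noise and Gaussian read noise are applied last. Start
positions are chosen after simulating each trajectory so the whole path fits
in the frame with a PSF-sized margin; explicitly supplied start positions
that let a particle leave the frame raise an error naming the particle and
frame. Default acquisition parameters mirror live EL imaging: 10 fps for
motility scenes, 2.4 s intervals for ER-association scenes, background
100 counts and spot amplitude 100 (peak-SNR ≈ 10 under shot noise). Pixel
size 0.1 µm and PSF σ = 1.3 px are fixture choices, not measured values.

**Dispersal stills** place `round(target·n)` puncta uniformly in the
outer-three-shell region and the rest in the inner two shells, with a 4 px
erosion margin so PSF bleed stays within its region; the recorded true
fraction comes from the actual placement counts. **EM scenes** are
circle-ELs plus straight-line ER, with the closed-form contact percentage
`(acos(lo) − acos(hi))/π` for `cosθ` between `(d ± cutoff)/R`. **PLA
scenes** render each dot as exactly its requested pixel area (the `area`
nearest-to-centre pixels, deterministic tie-break), permitting touching
dots and flagging them.

What the generator does *not* emulate: photobleaching and blinking, 3-D
(defocus) effects, vesicle fission/fusion, motion blur within a frame, and
spatially varying background other than the reticular network. Passing
tests therefore demonstrate correctness of the measurement procedures on
well-posed scenes, not robustness to every real-data pathology.

## Puncta detection

Candidates are local maxima of a difference-of-Gaussians band-pass (σ and
3σ) above half of `min_amplitude`, corrected for the band-pass's peak
attenuation. `min_amplitude` defaults to 5× the robust background noise
(1.4826·MAD), with a fallback of 10% of the frame's dynamic range so that
(near-)noiseless frames do not degenerate to a zero threshold. Each
candidate is fit in a window of half-width `ceil(3.5σ)` with a
pixel-integrated Gaussian plus flat background by bounded least squares.
Two candidates sharing a window are fit jointly with two components; a lone
candidate whose single-component RMS residual exceeds `max_fit_residual`
(default 3× noise sd) is retried with a second component seeded at the
residual maximum and kept if it lowers the residual. Fits are capped at two
components per window — enough to resolve the near-neighbour pairs that
matter for linking while keeping the fit identifiable on small windows.

Accumulation thresholding removes the spatially structured background by
greyscale opening with a disk (radius 6 px, a rolling-ball equivalent) and
applies a percentile (default), Otsu or absolute threshold to the residual.
Percentile thresholds are taken over the *positive* residual intensities;
raising the level can never add mask pixels.

## Trajectory linking

Per frame pair, open tracks compete for new detections by Hungarian
assignment on squared displacement with a hard gate of
`max_disp_px · gap` (default 5 px per frame at 0.1 µm/px and 10 fps, which
caps speeds near 5 µm/s — generous for directed EL transport). Tracks
survive gaps up to `max_gap_frames` (default 2 in the pipeline
configuration) and must reach `min_track_len` (default 20 frames ≈ 2 s at
10 fps; shorter tracks give unstable moment fits). Ties resolve by
detection order, making linking deterministic. Merge/split events are out
of scope.

## MSS motion classification

For lags δ = k·dt up to a quarter of the track length
(`max_lag_fraction = 0.25`; longer lags have too few displacement pairs),
the moments μ_ν(δ) over orders ν = 0…6 are fit in log-log space; the MSS
slope S is the least-squares slope of γ_ν versus ν anchored at
(0, 0), since μ_0 ≡ 1 implies γ_0 = 0 analytically. For Brownian motion
S = 0.5 (γ_ν = ν/2); for ballistic motion S = 1 exactly; a perfectly
stationary track is a degenerate branch reported with S = 0 and classified
confined.

Class boundaries are not universal constants at finite track length, so
they are calibrated per acquisition: 500 Brownian tracks are simulated at
the acquisition's length, frame interval and localization noise, and the
2.5th/97.5th percentiles of their S distribution become `S_low`/`S_high`.
This fixes the free-class specificity at 95% by construction and adapts
automatically to shorter or noisier recordings.

Fit-quality gating uses *either* R² ≥ 0.8 on the order-2 log-log fit *or*
an RMS log-residual ≤ 0.25. The second gate exists because R² is
uninformative exactly where confinement shows: a saturated (flat) moment
curve has almost no variance for R² to explain, yet its small absolute
residuals mean γ ≈ 0 is measured reliably. Gating on R² alone would send
nearly all confined tracks to "unclassified".

Confined-immobile and confined-mobile are not split; a single confined
class is reported. The motility summaries pool free + directed and report
their proportion and the (free+directed)/confined ratio, flagged undefined
(None) when no track is confined.

## Contact analysis

"Appearing together" is ≥ 1 shared pixel between the accumulation mask and
an EL object mask — the thresholded-overlay reading, with no distance
criterion. Event identity follows EL mask overlap between consecutive
frames (ELs change shape, so centroid distance is the wrong key). The
default tolerates no dropout frames within an event (`max_gap_frames = 0`,
the strictest reading; configurable). An event is accepted when its
duration reaches `min_duration_s = 10`. Connected regions smaller than
4 px in either mask are discarded as shot-noise specks — a
diffraction-limited object covers ≥ ~10 px at these samplings. Z-stack
counting reuses the same logic with slice index in place of time and a
2-consecutive-slice persistence requirement.

ER association scores a followed EL over exactly 10 frames at 2.4 s: a
frame is positive when any suprathreshold ER pixel falls inside that
frame's EL mask, and the score is `positives/10 × 100`. Marker
co-occurrence labels each punctum with the exact subset of marker masks
containing its position; subset percentages sum to 100 by construction.

## Dispersal shells

Shells are built from the Euclidean distance transform of the cell mask
rather than iterated binary erosion, giving 2 µm bands independent of
structuring-element shape. Half a pixel is subtracted from the EDT because
it measures centre-to-centre distance while the outline runs along pixel
edges; on a uniform 10 µm disc this yields the closed-form fraction
(10² − 4²)/10² = 0.84 within discretization error. Shell k (k ≥ 2) takes
boundary distances in `((5−k)·2, (5−k+1)·2]` µm; shell 1 absorbs the
remainder, so the shells tile the mask exactly. Cells too thin for the
inner shells are returned with `thin-cell` / `empty-shell` QC flags instead
of raising — reproducible inclusion criteria replace the manual
"relatively round cells" selection. Per-shell signal is integrated
thresholded intensity by default; a thresholded-area mode is provided since
either reading is defensible.

## EM contact fraction

Membrane-to-membrane distance is curve-to-curve: the EL boundary is
resampled at ≤ 5 nm arc spacing, each sample's minimum distance to the
union of ER polylines is computed (shapely), and the contact length sums
the boundary arcs with distance ≤ 30 nm, locating threshold crossings
between samples by linear interpolation — halving the step changes the
result by < 0.5% on smooth fixtures. Per EL, perimeters and contact
lengths are summed across all sections before dividing ×100; per-section
percentages are never averaged. Per cell, the EL percentages are averaged
unweighted. Sections are treated independently (no 3-D interpolation),
mirroring per-section manual tracing. Note that a finite cutoff legitimately
counts small arcs of sides adjacent to a coincident contact (2× cutoff at a
right-angle corner); this is a property of the distance definition, not an
artefact.

## PLA counting

Binarize at an absolute threshold (Otsu fallback when none is configured —
the interactive thresholding of the original workflow is replaced by a
deterministic default), split touching blobs by watershed on the negated
Euclidean distance transform with EDT-peak markers, and keep 8-connected
components of ≥ 5 px. "5 pixels" is read as area (the particle-size
convention of binary particle analysis), recorded as a config default.
Removing the watershed can only merge, never split, so it can only lower
the count. Dots are assigned to cells by containment when cytoplasm masks
exist, else to the nearest nucleus centroid (generalized Voronoi; ties to
the lower cell id) — a deterministic stand-in for manual per-cell reading
when no cytoplasm stain is available.

## Problem sizes and tolerances

The validation suite uses: 500 Brownian tracks of 600 frames for the MSS
closed form (mean S within [0.45, 0.55]); 200 tracks per class of 300
frames for classification accuracy (≥ 90% per class); one rendered
600-frame, 30-particle movie at peak-SNR 10 for the end-to-end pipeline
(track purity ≥ 95%, label agreement ≥ 80%); 200 spots for localization
(RMSE ≤ 0.2 px, noiseless bias ≤ 0.05 px); a 10-dwell contact plan
(accepted count exact); planted dispersal fractions 0.1–0.9 (recovered
within 0.03, uniform disc within 0.01 of 0.84); EM fixtures against a
2×10⁵-point sampling oracle (within 1%); and exact PLA counts. These sizes
were chosen to make the Monte-Carlo checks statistically meaningful while
keeping the whole suite fast on a single CPU.

## Known limitations

- The detector fits at most two Gaussians per window; three-way overlaps
  lose spots (they reappear after separation and are bridged by gap
  closing).
- Percentile accumulation thresholds depend on the bright-pixel coverage of
  the scene; absolute thresholds are preferable when calibration is stable.
- The linker has no motion model (no velocity prediction), so two particles
  crossing within one frame displacement can swap identities.
- MSS classification assumes a single motion state per track; tracks that
  switch state mid-recording land between classes.
- Shell analysis is 2-D and boundary-centred; nucleus-centred or 3-D radial
  profiles are out of scope.
- EM measurements trust the traced contours; no membrane segmentation from
  raw micrographs is attempted.
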