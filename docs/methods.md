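# Methods

`mudrop` implements an AI-assisted control stack for electrowetting
digital-microfluidics (DMF) chips: a semantic-segmentation network that
recognizes the four morphological droplet states, a region-growing step that
turns masks into per-droplet observations, and feedback state machines that
use those observations to move, split, merge and dispense droplets — all
exercised against a built-in virtual device so the complete loop runs
without hardware.

## Droplet states and class encoding

A droplet is labeled by appearance: *unsplit* (a lone droplet), *splitting*
(an hourglass with a thin neck), *split* (a freshly divided pair roughly one
electrode width apart) and *merging* (two droplets in contact).  Masks use a
fixed encoding: 0 background, 1 unsplit, 2 splitting, 3 split, 4 merging.
Labels follow what a camera sees at that instant, not the droplets' history:
a pair that has fully coalesced is unsplit even if it merged a frame ago.
One observable consequence: a merging pair reads as a single connected
class-4 region while the silhouettes share a boundary, and may flicker to
two regions when the rasterized contact is a single diagonal pixel.

## The virtual device

The simulator stands in for chip + camera.  Geometry is a `rows x cols`
array of square electrodes (default 3x3, 32 px electrodes, 2 px gaps,
14 px margins: a 128x128 canvas).  Rendering composes flat-filled droplet
silhouettes (circle, rectangle, L-shape, triangle; five liquids including a
transparent one drawn as a background-tinted fill with a dark refraction
rim) over a uniform chip background with faint electrode outlines, adds
Gaussian sensor noise (sd 1.5 grey levels) and applies a linear brightness
factor.  The ground-truth mask is the exact rasterization, so pixel counts
measure volume directly.

Physics is a discrete update per camera frame, deliberately minimal — just
enough behavior to exercise feedback control:

- a droplet adjacent to exactly one energized electrode hops to it with
  probability `move_success_prob` (default 0.95); an approach toward another
  droplet stops where the liquid fronts meet;
- energizing both flanks of a droplet's electrode necks it into the
  splitting state; one frame later it either collapses to one side
  (probability `split_pull_prob`, default 0.1) or divides into halves
  `V*(1/2 ± delta)` with `delta ~ N(0, split_asymmetry_sd)` (default 0.04);
- touching droplets become a merging doublet and coalesce on the next frame
  (volume-weighted centroid, summed volume); deep overlap coalesces
  immediately;
- a reservoir droplet extends a liquid finger along energized electrodes,
  necks at a de-energized electrode between finger and reservoir, and breaks
  off a droplet whose volume is the covered footprint area times
  `(1 + eps)`, `eps ~ N(0, split_asymmetry_sd)`.

Volume is conserved exactly by move, split and merge.  The failure
probabilities are stated choices, not calibrated values — the reference
system documents the failure modes but not their rates.  One root seed
spawns separate physics and rendering streams
(`np.random.SeedSequence(seed).spawn(2)`), and physics draws follow a
documented order (reservoirs, splitting resolutions, moves; ascending
droplet id), so trajectories can be replayed exactly.

## Synthetic training distribution

`mudrop.synthetic` renders seeded scenes covering all four states (cycled so
counts balance), all colors and shapes, with droplet areas of 0.35–1.1
electrode areas.  Pair geometry mirrors the chip: split pairs sit 0.85–1.5
electrode widths apart edge-to-edge (the device parks halves on flanking
electrodes, two pitches center-to-center, which lands near the top of that
band), merging pairs overlap by 2 px, and droplets of unrelated groups stay
at least 2 electrode widths apart so the pair states remain geometrically
unambiguous.  The brightness factor of each frame is drawn uniformly from
[0.5, 1.5], emulating lab-to-lab illumination differences; sensor noise is
as above.

What the generator does **not** emulate: specular highlights, refraction
beyond a rim cue, motion blur, shadows, electrode wear, or the transient
wall-shape deformations of real droplets.  Passing tests therefore
demonstrate that the architecture, losses, extraction and control logic work
end-to-end and reproduce the reference system's quantitative behavior on a
clean but fully controlled distribution — not camera-ready performance on
real footage.

## Segmentation network

The encoder-decoder follows the reference design: four encoder blocks of
3x3/stride-1 convolutions with ReLU and 2x2 max pooling — two shallow
blocks with 2 conv layers, two deep blocks with 3 — widths doubling from 64
(scaled by `width_scale`); a decoder of four direct twofold-upsampling
stages (nearest-neighbor by default, bilinear as an option) with 8
convolution layers total and skip connections concatenating the
equal-resolution encoder features; and a final 1x1 convolution with 5
channels.  Exact per-block widths beyond "64 after the first block" are a
reconstruction (the original supplementary table is not public); widths
double per block.

Everything runs on a small numpy engine (channels-last im2col convolutions
lowered to BLAS GEMMs, explicit backprop) — no GPU framework is required.

Two trainability aids are deliberate additions for short CPU schedules, and
both are switchable: group normalization between each convolution and its
ReLU (`ModelSpec.normalization="none"` restores the plain stacks), and an
auxiliary per-pixel cross-entropy term added to the optimization objective
(`TrainingConfig.aux_ce_weight`, default 1.0).  Without them the
softmax+Dice objective needs roughly an order of magnitude more optimizer
steps to break per-pixel class ties than a single-CPU run can afford.  All
reported and recorded loss values are the pure Dice term.

### Loss

Dice loss `1 − 2|x∩y| / (|x|+|y|)` with a 1e-6 smoothing constant, averaged
over the foreground classes present in prediction or truth (background is
excluded: droplet scenes are overwhelmingly background, which is the usual
motivation for Dice).  Classes absent from both sides carry no signal and
are skipped.

### Training schedule

Adam under cosine annealing with warm restarts every 5 epochs.  The
defaults in `TrainingConfig` mirror the reference protocol (learning rate
1e-4 down to 1e-6, 30 epochs, full-peak restarts).  The desk-scale helper
(`desk_training_config`) keeps the optimizer and schedule shape but uses a
3e-3 → 3e-5 band, batch size 2 (maximizing optimizer steps per unit compute
on one core), a 0.7 per-cycle decay of the restart peak (full-peak restarts
repeatedly throw away a converged state late in a short schedule), and up
to 36 epochs with two stopping rules: converged (validation mIoU ≥ 0.985
twice in a row) or plateaued (best mIoU not improved by 0.003 within 10
epochs).  The weights of the best-validation-mIoU epoch are restored at the
end (`TrainingConfig.restore_best`), and `TrainingHistory.best_epoch`
records which epoch the returned network carries.  With two orders of
magnitude fewer steps than a GPU-scale run, the larger rate is what makes
the Dice objective converge at all — at 1e-4 the loss measurably never
leaves its initial plateau within this schedule.

The desk-scale model trains and infers at a working resolution of 64 px
(frames are rendered at 128x128 and resized); `predict` resizes any frame
to the working resolution, runs the network, upsamples the class scores
bilinearly back to the input size and takes the per-pixel argmax (ties to
the lowest class id), so masks come back at full frame resolution with
sub-pixel-smooth boundaries.  Full 512-px operation is supported by the
same code and is simply slower.

## Droplet extraction

The observation pipeline first applies a majority-class vote over every
connected *foreground* component (`majority_vote_refine`): a physical
droplet is one connected silhouette, touching droplets always share a class
(contact makes both merging), so relabeling each component by its majority
class removes stray in-droplet class fragments without ever mixing
distinct droplets — this is the "more accurate representation of the
droplet" the region-growing stage exists to provide.

`grow_regions` then aggregates connected same-class nonzero pixels (scipy
`ndimage.label` per class; 4-connectivity by default — the conservative
choice that keeps near-touching droplets separate; components are reported
in row-major seed order).  Components below `min_size` are dropped as
speckle; the observation pipeline ties the default to chip geometry (5% of
one electrode footprint) since the smallest controllable droplet is
comparable to an electrode.  Each region becomes an observation: state,
centroid, pixel count, bounding box, and the electrode whose footprint
contains the centroid (lowest index on a tie; nearest footprint center for
gap/margin centroids).

`volume_error` is the symmetric relative imbalance `|a−b|/(a+b)` of a pixel
count pair; the asymmetric alternative `|a−b|/max(a,b)` was considered and
rejected for order dependence.  Dispensed droplets are scored with the same
form against the target electrode footprint area (the chip's "unit size").

## Feedback control

Each manipulation is a state machine that issues an actuation pattern,
observes every camera frame, and corrects what it sees; the controller is
observation-only (device = `actuate`/`capture`, observer = frame →
observations), so the identical code drives the ground-truth observer or
the trained network.  Policy defaults: settle delay 3 frames, timeout 30
frames (one second at 30 fps), 5 retries per manipulation, 3 dispensing
restarts, 3% volume tolerance.

- *move*: single-electrode activations along a shortest Manhattan path (row
  moves first); a step observed to have failed re-activates the same
  electrode.
- *split*: both flanks energized, center off; an unsplit droplet observed on
  one flank (pull failure) is moved back and the split re-attempted; a
  splitting state that never resolves within the timeout also retries.
- *merge*: route one droplet into the other, wait for the merging doublet to
  coalesce, park the result.
- *dispense*: energize driving + dispensing electrodes until the liquid
  finger covers the target electrodes (checked pixel-exactly), then
  reservoir on / dispensing electrode off and wait for splitting → split
  within the timeout, else restart; accept when the pixel-count volume
  error against the target area is within tolerance.
- *closed-loop split*: after each successful split, compute the pair's
  volume error from pixel counts; beyond tolerance, re-merge, park one
  electrode over (bouncing back at the grid edge), re-split.  Every accepted
  pair is within tolerance by construction; with a 3% tolerance and 4%
  asymmetry roughly 10–30% of runs (depending on droplet size, which sets
  the pixel-count measurement noise) exhaust their 5 retries and are
  excluded and reported.

Trace legality is checked against the observer-level transition rules
(e.g. split never follows unsplit without splitting in between); entries
flagged as inferred (frames skipped between observations) may take two
elementary transitions at once.

## Evaluation protocols

- **Segmentation metrics** accumulate one 5x5 confusion matrix over all
  pixels.  mIoU averages `p_ii / (Σp_ij + Σp_ji − p_ii)` over the n+1
  classes including background; mPrecision and mRecall macro-average the
  per-class column/row ratios; mPA (per-class pixel accuracy) coincides
  with mRecall by construction — both are reported because both names are
  conventional.  Classes absent from prediction and truth are skipped.
- **Continuous error rate**: percentage of frames whose predicted state
  multiset (from region growing) differs from the ground-truth multiset,
  over recorded control footage (scripted move/split/re-merge sub-sessions
  cycling colors and shapes).
- **Brightness sweep**: every scenario frame's pixels are multiplied by a
  coefficient factor; a frame counts as state-correct (multisets equal),
  position-correct (one-to-one centroid matching within half an electrode
  side — the supplementary definition is not public, this is the documented
  stand-in) and overall-correct (both).  Mean ± SD over scenarios.
- **CV experiment**: n independent seeded splitting runs; open mode accepts
  the first successful split, closed mode runs the feedback loop.  The
  coefficient of variation (sample sd over mean, n−1) of all accepted half
  volumes is reported; runs that exhaust retries are excluded and counted.

## Problem sizes of the standard desk-scale run

400 training + 100 validation frames at 128x128 (seeded), model width scale
0.25 at working resolution 64, up to 36 training epochs (early-stopped on
convergence or plateau), a 2000-frame control video for the error rate,
8 scenarios x 6 frames for the brightness sweep, and 70 runs for the CV
experiment.  On one CPU core the whole acceptance run takes roughly
15–20 minutes, dominated by training.

## Known limitations

- The synthetic gap between generator and reality (above) is the main one:
  no claim is made about real-camera performance.
- The reservoir/dispensing physics assumes the 1-row strip layout with the
  reservoir at the highest index.
- No identity tracking across frames beyond nearest-centroid matching; no
  path planning with collision avoidance for more than two moving droplets.
- mPA equals mRecall under the per-class-accuracy definition used here; if
  the original work used a different supplementary definition the two could
  diverge there.
- The numpy engine is single-threaded and tuned for the desk-scale model;
  full-resolution (512 px) training is supported but impractically slow
  without a GPU framework.
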