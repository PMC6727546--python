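# Methods

This note documents the models, estimators and numerical choices behind
`myceliotrack`: what each stage assumes, which parameters matter, and what
the synthetic benchmark does and does not establish about real data.

## Image model and pre-processing

The input is a calibrated phase-contrast time lapse of one growth chamber:
dark filaments (hyphae) of roughly constant width on a bright background with
slowly varying illumination, additive sensor noise, and slow stage drift.
All length-like parameters are given in µm and converted to pixels through
the stack calibration, so one configuration transfers across magnifications.

**Drift compensation** is translation-only and integer-pixel: stage drift,
not rotation, is the artifact in chamber-based time lapses, and sub-pixel
resampling would smear the thin filaments. Each frame is aligned to the
previous registered frame by FFT cross-correlation of a *structure image* —
the background-corrected frame clipped to excursions darker than 4 robust
noise σ. Correlating raw frames fails subtly: sensor noise is fixed to the
camera, not the sample, so on nearly empty frames the correlation locks onto
the noise and reports arbitrary shifts. Two guards make the estimate safe:
frames with fewer than 30 structure pixels inherit the previous offset
(before germination there is nothing to align), and estimated shifts beyond
a quarter of the frame are rejected as implausible. One caveat is inherent:
for a field containing a single straight hypha, translation along the hypha
axis is unobservable; any branch point breaks the degeneracy.

**Background correction** subtracts a blurred illumination estimate
(Gaussian σ = `background_blur_um` / calibration, default 7.5 µm — roughly
an order of magnitude above the hyphal width). The blur is applied to a
median-prefiltered copy of the frame (window ≈ blur/2, computed at half
resolution for speed since the illumination field is smooth): the median
removes the filaments themselves from the estimate, so the correction does
not carry a halo of the foreground and is idempotent to well under 1 % of
the dynamic range at realistic noise levels.

## Segmentation

The default binarization is an adapted Niblack rule for dark-on-bright
filaments: a pixel is foreground iff

    x < m(w) + k · s(w)   and   x < m(w) − c_abs

with local mean m and standard deviation s over a window w (default 15 µm),
k = −0.6, and an absolute contrast floor c_abs. Plain Niblack fires on a
fixed fraction of pixels in texture-free regions regardless of content; the
floor suppresses that. Its default, 3× the robust noise σ estimated from the
frame's median absolute deviation, puts the per-pixel false positive rate
near 0.1 % (2σ would admit ≈2.3 %, visibly speckling empty frames) while a
filament at 5σ contrast is still detected with ≳95 % pixel recall. `otsu-
global` and `mean-local` are available for well-behaved or non-phase-contrast
data, and `--invert` flips the polarity.

Cleaning removes foreground speckles below `min_object_um2` (default 1 µm²)
and fills holes below `max_hole_um2` (0.5 µm²), with areas converted through
calibration². Between two speckle passes sits a morphological closing of
about one hyphal width (0.7 µm, square footprint): at realistic sampling a
hypha is only 1–2 px wide and single-pixel detection dropouts would otherwise
fragment it. Speckles are removed *before* closing so that closing cannot
weld isolated noise pixels into objects above the size threshold. Foreground
connectivity is 8-connected throughout, matching the skeleton convention —
with 4-connectivity a diagonal single-pixel filament decomposes into
singletons and is destroyed by the size filter.

## Skeleton graph

Cleaned masks are thinned with the Zhang–Suen algorithm (via scikit-image)
to a topology-preserving single-pixel skeleton. Terminal spurs shorter than
`skeleton_prune_um` (default 1.5 µm ≈ 2 hyphal widths) are pruned: they are
noise pixels that attached to a filament during closing, and they would
otherwise inflate tip and junction counts. Whole isolated segments are never
pruned; a final thinning pass removes the residual bump a pruned spur leaves
at its junction.

Skeleton pixels with one 8-neighbour are tips, with three or more are
junction pixels; thinning emits small junction blobs at crossings, so
adjacent junction pixels merge into one node at their centroid. Edges are
traced pixel-wise through the degree-2 chains; self-loops and parallel edges
are kept (they occur when hyphae touch), components that are pure cycles get
an anchor node at their lexicographically smallest pixel, and
junction–junction edges shorter than 2 px are contracted as thinning
artifacts. Every skeleton pixel belongs to exactly one edge interior or one
node — this conservation property is asserted in the tests.

Chain length is the sum of pixel-step distances (1 or √2). On staircase
rasterizations this overestimates the true curve length by up to ≈8 %, so
the recorded edge length uses coordinates smoothed by five iterations of an
endpoint-preserving three-point moving average — enough to bring a
4-connected 45° staircase within 0.5 % of its chord while leaving straight
chains untouched. Smoothing is a contraction: length is monotonically
non-increasing in the iteration count and bounded below by the endpoint
distance (property-tested).

## Tracking

Junctions keep their position under planar growth; tips advance. Matching
between consecutive frames is therefore nearest-neighbour within a
kind-specific radius: `junction_radius_um` (default 2 µm) and `tip_radius_um`
(default 10 µm). Candidate pairs are taken greedily in order of ascending
displacement (ties by node id), one-to-one; unmatched nodes stay unmatched,
and no gaps are bridged — a missed detection ends a track rather than
inventing a correspondence. Greedy matching can differ from the global
optimal assignment on adversarial geometries, but in the tracking regime
(node spacing well above the displacement scale) it equals the unique
optimum, which the tests verify against exhaustive enumeration. The tip
radius should be ~3× the expected per-frame tip advance; the default suits
the instrument-typical 10-min interval, while the synthetic benchmark (20-min
frames, tips up to ~10 µm/frame) is analyzed with 15 µm.

A track starts at each tip's first appearance. Its anchor is the nearest
junction in the component (preferring junctions matched into the next frame);
an unbranched germ tube has no junction, so the far end of the component
serves instead. Per frame the track records the shortest graph path (by
smoothed length) from anchor to tip; the hypha length is that path's length.
Because both free ends of an unbranched hypha are degree-1 nodes, naive
seeding creates two mirror tracks over the same path; the one whose tip
travels less — the stationary base — is dropped. A track ends when its tip
(or anchor) is unmatched, and two sanity checks act afterwards: if anchor and
tip fall into different components the track is truncated and marked
`excluded-disconnected`; if the length *drops* between frames by more than
max(1 µm, 10 % of the previous length) — the signature of a shortcut through
a merged adjacent hypha — it is truncated and marked `excluded-shortcut`.
Excluded tracks are kept in the output with their status. Tracks with fewer
than 3 time points, and tracks that never exceed `min_track_length_um`
(default 2 µm; spore-sized specks), are flagged and excluded from rate
fitting and summaries.

## Fits and derived metrics

All fits are ordinary least squares of y — or ln y for the logarithmic
transform — against time in hours. Non-positive values are dropped before
the log transform (no pseudo-count: an offset would bias rate estimates; the
dropped zeros are exactly the pre-germination frames). *Raw* fits use all
points; *optimized* fits select the widest contiguous window of at least 3
points whose R² exceeds 0.9, ties broken by higher R², then earlier start.
The search is exhaustive O(n²) with prefix sums and is verified against an
independent brute-force oracle. A zero-variance response gets R² = 0 and a
degenerate flag rather than NaN. One behaviour of the window rule is worth
knowing: if a series has a flat lag at a *positive* level followed by
exponential growth, windows spanning the kink can retain R² > 0.9, so the
widest window keeps part of the lag and the slope underestimates the
exponential rate. For mycelium length this does not arise — the lag is at
zero and is removed by the log transform.

The headline outputs per position are: the specific mycelium growth rate µ
(logarithmic-optimized slope of total length), the germination delay (start
timestamp of the earliest non-spurious track; the first frame with nonzero
length is emitted as a secondary estimate), and tip elongation rates
(per-track linear-optimized slopes of absolute length, summarised as
mean ± sample sd, n−1). Relative length (length minus the track minimum) is
fitted as well. The hyphal growth unit, total length divided by tip count,
is reported per frame and missing when no tip exists.

## Synthetic benchmark

The generator emulates what the pipeline must survive: germination after a
delay, per-tip elongation at rates drawn once per tip from a truncated normal
(defaults 16.33 ± 6.91 µm·h⁻¹), lateral branching, angular diffusion of the
growth direction, stage drift as an integer random walk, a smooth
illumination gradient, and Gaussian sensor noise added after the drift shift
(noise sits on the camera, not the sample). Branching is a Poisson process
per unit mycelium length — lateral branches along existing hyphae are the
dominant branching mode of mycelial bacteria — giving the deterministic mean
dynamics dL/dt = v̄N, dN/dt = βL, i.e. L ∝ sinh(µ_mech·τ) with
µ_mech = √(v̄β).

A finite observation window never sees the pure exponential: any log-linear
fit over the growth phase picks up the sinh transient and reads high. The
generator therefore defines its rate parameter `specific_rate_h` as the
*observable* specific growth rate — the slope the optimized-window
logarithmic fit returns on the noise-free mean curve over the configured
frame grid — and derives β by inverting that relation numerically at
construction. Ground truth and estimator then share one definition of µ, and
recovery tests measure the imaging pipeline rather than the gap between an
asymptotic parameter and a finite-window estimator.

Default rendering uses a 512² px field at 0.65 µm/px (a ~330 µm field), 60
frames at 20-min intervals, a 12-h germination delay, and hyphae of 1 µm
width drawn as 2-px strokes — the coverage a sub-resolution filament has
after optical blur. These sizes keep a full simulated study (simulation,
rendering, complete analysis, twenty replicates) within a few CPU-minutes;
the real instrument's 0.065 µm/px sampling would need 5000² px frames for
the same field. Tips never intersect by default (a tip halts on contact,
crude negative autotropism); `allow_overlap=True` disables avoidance, and a
two-spore scenario aims two germ tubes at each other with a sub-width lateral
offset to force the mask merge that the shortcut/connectivity exclusions must
catch. Ground truth records every segment's polyline, birth time, parent and
rate, per-frame totals, the drift schedule, and the first frame at which the
two lineages come within ~3 px (unresolvable for any gap-bridging
segmentation).

What passing the synthetic benchmark shows: the chain from raw drifting noisy
frames to growth rates is unbiased at the ~10 % level under the modelled
conditions, tracks follow the hyphae that produced them, and merge artifacts
are excluded rather than converted into spurious kinetics. What it does not
show: robustness to real phase-contrast halos, septation, focus drift,
chamber walls, or dense late-stage mycelium where most paths overlap —
parameters (contrast floor, radii, speckle sizes) will need preview-guided
adjustment on real data.

## Storage and determinism

One HDF5 archive holds, per position: the full materialised configuration
(JSON), drift offsets, timestamps, calibration, gzip'd masks and skeletons,
per-frame GraphML documents, the three result tables stored column-wise with
explicit column order, and the derived summary. Writes are atomic (assembled
at `<path>.tmp`, moved into place on success); a validator checks the layout
(`myceliotrack_layout = 1`) for completeness. Given the same stack and
configuration the tables are element-wise identical across runs and across
parallelism degrees: per-frame work is order-independent and collected by
frame index, and every random quantity in the synthetic module derives from
one seeded generator.
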