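# Methods

This note documents the models, algorithms and numerical choices behind
`septachain`, and what validation on the synthetic fixtures does and
does not establish.

## Coordinate and intensity conventions

Pixels are square; pixel centers sit at integer (column, row) indices;
x is the column direction, y the row direction; physical coordinates are
pixel coordinates × `pixel_size` (μm/px). Intensities are used exactly
as stored — no bit-depth rescaling — because comparisons across frames
and time points assume a common camera scale. The background of a frame
is estimated as its modal intensity (fullest of 256 histogram bins),
which is robust as long as background dominates the area; a constant
override is available for frames where it does not.

## Chain segmentation and axis tracing

Chains are dark in phase contrast. The phase channel is Gaussian
pre-smoothed (default 0.1 μm) and thresholded (Otsu by default, fixed
threshold available; foreground polarity is explicit config because
phase polarity varies between setups). Holes are filled; components
smaller than `min_area_um2` (default 1 μm²) are dropped; components
touching the frame border are dropped by default since partial chains
bias length statistics.

The axis is the longest path through the skeleton of the mask. Before
thinning, the mask is morphologically opened with a disk scaled to its
inscribed half-width (backing off, halving the radius, if the opening
would fragment the mask, as can happen for strongly bent chains). This
matters: thinning a flat-ended rod otherwise sprouts diagonal spurs at
the pole corners whose depth rivals the mask width, corrupting both the
path and any branch-based quality check. The longest path is found by a
double Dijkstra sweep over the 8-connected skeleton pixel graph with
Euclidean edge weights. Remaining off-path skeleton branches deeper
than `max(prune_um, 0.9 × estimated width)` disqualify the chain — such
branches indicate touching chains (a Y), which the method deliberately
does not attempt to separate. The path is smoothed by a moving average
(default 5 vertices) and both ends are extended along the local tangent
to the mask boundary so the poles are measured.

The phase-based chain diameter is the mean mask width perpendicular to
the axis, ray-marched at 0.2 μm stations excluding 0.5 μm at each pole.

## Straightening and axial profiles

Each channel is resampled bilinearly on a curvilinear grid: one column
per axial station (`round(axis_length / pixel_size)` columns), one row
per perpendicular offset across a band (default 1.6 μm ≈ cell diameter
plus margin; odd row count so the middle row samples the axis).
Bilinear interpolation, not nearest-neighbour, because septum peak
localization needs sub-pixel fidelity. Normals come from the smoothed
tangent, averaged over adjacent segments at vertices. Out-of-frame
sample points are filled with the modal background and their columns
flagged.

The axial profile averages the central rows (default 3): a thin stripe
sees little of the lateral membrane walls (≈ 0.5 μm off-axis) but the
full signal of septa, which cross the axis.

## Septum detection and cell splitting

Septa are local maxima of the axial membrane profile. The profile is
first smoothed with a 0.1 μm Gaussian (septa are wall-width features and
survive; single-sample noise spikes do not). Peaks qualify by
topographic prominence ≥ `min_prominence_frac` (default 0.15) of the
profile's dynamic range — a relative criterion, so detection is
invariant to affine intensity rescaling — with pairwise separation ≥
`min_cell_length_um` (default 1.0 μm; the taller of a conflicting pair
wins) and distance > `pole_margin_um` (default 0.25 μm) from both ends,
since pole membrane caps are not septa. Positions are refined by a
parabolic fit through the peak and its neighbours so cell lengths are
not quantized to the pixel grid.

Manual corrections are programmatic: additions (origin = `manual`) and
removals, from an API or a CSV edits file. An addition violating the
minimum separation is rejected with a report, never silently dropped.
`n` markers split a chain into `n + 1` cells partitioning
`(pole_margin, axis_length − pole_margin)` with half-open intervals, so
boundary columns are never counted twice and integrated fluorescence is
additive over the cells of a chain.

## Fluorescence capture

*Integrated mode*: raw sum over the cell's box (axial interval × a
centred band, default chain diameter + 0.3 μm) minus background × box
area. Background enters as a global term; clamping per pixel after
subtraction would bias dim cells upward. *Axis mode*: mean of the thin
axial profile over the interval minus background, excluding a 0.15 μm
guard at each interval end where the PSF mixes the neighbouring cells'
cytoplasmic signal — without the guard, a dim cell flanked by bright
neighbours reads several percent high. Axis mode is the mode of choice
when chains lie close together and boxes would overlap neighbours.

The membrane-based cell diameter is the distance between the two
outermost prominent peaks of the perpendicular membrane profile,
parabolic-refined, averaged over three stations around the cell
midpoint. This measurement inherits the systematic underestimation
quantified by the PSF simulation below and should be corrected
accordingly when absolute diameters matter.

Population summaries report histograms (default 40 bins; a shared bin
range across time points keeps panels comparable), the empirical CDF,
and per chain-length class (1–2, 3–4, ≥ 5 cells) the mean ± standard
deviation (not SEM) of member-cell fluorescence.

## Nucleoid-proxy measurement

The DAPI channel is smoothed (default σ 0.1 μm); local maxima qualify
when they rise at least `min_peak_frac` (default 0.2) of the way from
the modal background to the frame maximum — relative to range, hence
exposure-invariant — with minimum separation 0.5 μm (brighter wins).
Centers are refined by 1-D parabolic fits along each axis. The reporter
is sampled over pixels whose centers lie within a 0.66 μm-diameter
circle (81 pixels at 0.066 μm/px); a circle not fully inside the frame
disqualifies its ROI rather than biasing it by partial sampling. The
per-ROI mean is the headline statistic (the fixed circle makes mean and
integral proportional); both are reported.

Subpopulations are split at the minimum of a Gaussian KDE between the
two tallest density modes, falling back to the midpoint of the value
range when the density is unimodal. At least 10 values are required.

## PSF projection simulation

The membrane is a cylinder surface (diameter D₁, default length 5 μm)
carrying fluorescent points at 2000 points/μm² (Poisson count, uniform
over the surface, deterministic per seed). The default PSF is an
anisotropic 3-D Gaussian with lateral σ = 0.21 λ/NA and axial
σ = 0.66 λn/NA² at λ = 0.63 μm, NA = 1.3, n = 1.518 (σ_lat ≈ 0.102 μm,
σ_ax ≈ 0.37 μm). A point at defocus z contributes a 2-D Gaussian
widened to σ_lat·sqrt(1 + (z/σ_ax)²) carrying the in-plane energy
exp(−z²/2σ_ax²); points are binned into 0.02 μm depth slices and each
slice convolved once. A measured through-focus bead stack can be
supplied instead as tabulated per-depth kernels (nearest slice per
point). The focal plane defaults to the tube axis, matching how cells
are focused.

The measured diameter D₂ averages the two-peak distance of
perpendicular profiles over stations along the axis (anchor snapped to
the pixel grid to avoid bilinear softening for axis-aligned tubes; the
peak-distance primitive is shared with the membrane-based cell diameter
measurement). Under the default optics, D₂ ≈ 0.89–0.90 μm for
D₁ = 1.0 μm, and the bias decays for larger tubes. Two numerical limits
are worth knowing: (i) for a *vanishing* PSF the unblurred ring profile
has edge singularities, and the binned argmax localizes each peak only
to about one pixel, so D₂ is then accurate to the pixel scale, not
below; (ii) at the camera-scale grid (0.066 μm) pixel-lattice alignment
alone moves D₂ by ~0.5%, so sub-percent invariance properties are
checked on a finer simulation grid (0.033 μm) — the projection grid is
an internal parameter, not a camera property.

## Synthetic data generator

The generator emulates the imaging conditions the method targets:
0.066 μm/px sampling (a typical 100× objective with a 6.45 μm-pixel
camera — chosen, not measured), rods 1.0 μm wide with 3 μm cells,
membrane amplitude 150 a.u. over a 100 a.u. background, septum
amplitude 1.5× the lateral membrane signal, phase contrast with dark
cells (80 vs 200 a.u.), DAPI blobs of σ 0.15 μm (1–2 per cell at the
quarter/three-quarter or mid positions), and a per-cell reporter drawn
from a two-component Gaussian mixture (means 80/400 a.u., SDs 10% of
the mean, mixing fraction 0.5 by default). All painted amplitudes are
blurred with a 0.1 μm Gaussian and Gaussian read noise (σ 15 → SNR ≈ 10)
is added. Chains are placed with ≥ 4 px clearance, honouring the
method's requirement that chains not touch. Cocci fields place round
cells on a jittered grid, one nucleoid each.

Cells are painted with flat ends, so a chain's mask length equals its
centerline arc length and ground-truth axial positions are exact. Every
random draw is recorded: centerlines, septum positions, per-cell
amplitude, label and injected photon sum, nucleoid centers — so
detections are scored against truth, not against plausibility.

What the generator does **not** emulate: phase-contrast halo artifacts,
uneven illumination, staining heterogeneity along the membrane,
photobleaching, focus drift, and cell-shape irregularity. Passing the
fixture-based tests therefore demonstrates the correctness of the
measurement pipeline under controlled optics, not robustness to every
real-world imaging pathology; on real images the miss rate of septum
detection rises with poor membrane staining, which is exactly what the
scripted manual-correction path is for.

## Validation scales

The benchmark chain field uses 25 chains of 8–12 cells (~220 septa) at
the default noise level — large enough that detection rates and
distribution comparisons are statistically meaningful while a full
end-to-end run stays within seconds. The coccoid mixture uses 500 cells
with equal subpopulations, matching the scale at which a 3-standard-
error band on the recovered ratio is a meaningful test. Automatic
septum detection on these conditions misses ~0% of septa with ~1% false
positives; the noiseless fixture is recovered perfectly.

## Known limitations

* Touching or crossing chains are disqualified, not separated.
* Nucleoid ROIs are not assigned to parent cells; expression ratios are
  nucleoid-weighted (cells with two nucleoids count twice), which
  leaves distribution *shapes* essentially unchanged but is not a
  per-cell census.
* The KDE-valley classifier assumes at most two modes; overlapping
  mixtures (< ~4 combined SDs separation) will blur the threshold.
* The Gaussian 3-D PSF is a model; for quantitative work with a real
  instrument, supply a measured bead-stack as the tabulated PSF.
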