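# Methods

## Experimental setting being modeled

The pipeline targets time-lapse fluorescence microscopy of GFP-fusion
yeast strains held in shallow microfluidic observation chambers, one
strain per chamber, imaged every 5 minutes. Cells grow in rich medium
for a pre-stimulus window, then the medium is switched to one
containing KCl (conditions labeled 0, 0.2, 0.4, 0.8 M). Chambers start
with 20–50 cells and fill to hundreds; cells are continuously at risk
of being extruded ("washed out"), so only a subset of trajectories
spans the whole movie. All analysis times are minutes relative to the
stimulus (t = 0); the default grid is 30 min pre-stimulus + 420 min
post-stimulus at 5-min spacing (91 points), and a full 10-h
acquisition (180 min pre-stimulus) is available through the config.

## Per-cell readout

Protein concentration is read from the labeled cell region as the
whole-cell mean intensity for uniformly distributed, membrane-bound
and mitochondrial proteins, and as the mean of the ceil(0.1·n)
brightest pixels for nuclear proteins (stable descending sort, so
cutoff ties resolve deterministically). Regions under 10 px are
flagged low-quality but still reported. Background is estimated per
frame as the median of non-cell pixels (robust to bright debris);
frames with fewer than 100 background pixels reuse the previous
frame's estimate, and a first-frame shortfall is an error. Cell
identity across frames uses greedy nearest-centroid matching with a
10 px/frame displacement gate: pairs are accepted in order of
increasing distance; unmatched old ids terminate (truncation),
unmatched new regions (buds) get fresh ids. This is deliberately the
simplest tracker that supports the downstream statistics; it does no
lineage reconstruction.

## Photobleaching and normalization

Bleaching is modeled as a global mono-exponential: measured signal =
true signal × exp(−k·elapsed), elapsed counted from the first acquired
frame. k is fitted by linear regression of log(intensity) on elapsed
time using a non-responding control (a 0 M chamber when present, else
pooled pre-stimulus data); non-positive points are excluded, fewer
than 5 usable points is an error, and negative fitted rates are
clipped to 0 with a warning. Correction divides by exp(−k·elapsed).

Population profiles are per-time arithmetic means over the cells valid
at that time; time points with fewer than `min_cells` (default 10)
cells are flagged. Log₂ normalization subtracts the mean log₂ over the
baseline window (the 30 min before the stimulus, i.e. the initial half
hour of the display window) — equivalently, division by the geometric
mean of the window. The geometric mean is used deliberately: it makes
the baseline-window mean of the log₂ output exactly zero, which the
arithmetic mean does not for noisy baselines. For flat baselines the
two coincide.

## Protein screen

SNR is defined, per strain, as the mean background-subtracted cell
fluorescence over the pre-stimulus window divided by the standard
deviation of the background pixels — the conventional imaging
definition, stated here because the screen threshold (SNR > 7) is
meaningless without one. Fold change is the maximum over post-stimulus
times of max(F, 1/F) with F = 2^(log₂ value): direction-agnostic, so
down-regulated proteins (trough at 0.5× scores 2.0) pass the > 1.2
gate. Peak fold (not steady-state fold) is used. Both screen
inequalities are strict.

## Representative-cell statistics M1 and M2

With Sₜⁱ the trajectory of full-length cell i (N cells, T time points)
and S̄ₜ the per-time mean over all N cells (cell i included):

    M1ᵢ = (1/(N−1)) Σ_{j≠i} √[ (1/T) Σₜ ((Sₜⁱ − Sₜʲ)/S̄ₜ)² ]

the root-mean-square relative deviation between cells i and j,
averaged over the other N−1 cells. The representative cell is the
argmin of M1 (ties broken by lowest cell id, for bit-reproducibility).
Its series Srₜ is compared to the population mean by

    M2 = √[ (1/T) Σₜ ((Srₜ − S̄ₜ)/S̄ₜ)² ]

Both statistics are nonnegative, zero exactly when the compared series
coincide, invariant to relabeling of cells, and scale-free (the S̄ₜ
normalization cancels any common multiplicative factor — asserted by a
property test). They are computed on background- and bleach-corrected
raw intensities, not log₂ values, since the normalization by S̄ₜ
presumes positive intensities. Only full-length trajectories enter;
the population mean used by M2 is taken over those same cells so both
statistics share S̄ₜ.

A vectorized implementation is used throughout; independent
double-loop scalar transcriptions of both formulas live in the test
suite and the acceptance script and must agree to ≤ 1e-12.

Known limitation: because the representative cell is the *most
typical* cell, in a bursty strain it can be a cell that happened to
burst little or not at all, which attenuates M2 for that strain in a
minority of cohorts. Across simulated cohorts with one bursty strain
in ten, the bursty strain still attains the top M2 in ≥ 90% of runs.

## Dynamics-based clustering

Rows of the protein × time log₂ matrix are clustered agglomeratively
with Euclidean distance and average linkage, on the raw log₂ profiles
without row standardization — response magnitude is biologically
meaningful and should contribute to the distance. Missing points are
linearly interpolated when no gap exceeds 2 consecutive points;
longer gaps drop the row with a warning. The tree is cut either at an
explicit k or, by default, at the k ∈ {2..8} maximizing the mean
silhouette. On panels built from the four response archetypes the
selected k is 4. Module descriptions (peak time, net sign, adaptation
ratio peak→final) drive a rule-based label: up-fast-adapting,
up-slow-adapting, up-late-non-adapting, down, plus an extra
"unresponsive" label for flat modules, with configurable thresholds
(net |log₂| < 0.25 → unresponsive; return of ≥ 50% from peak toward
baseline → adapting; peak later than half the window → late).

## Synthetic-data generator

The generator emulates the statistical structure the analysis
assumes, not chamber physics or cell shape.

**Archetype fold curves.** Four classes: rapid-up-then-adapting,
down-regulated, slow-up-then-adapting, late-up-non-adapting. Each
curve is 1.0 before the stimulus, stays at 1.0 for a response delay,
ramps linearly (rate in fold/min) to the peak fold, then relaxes
exponentially toward the steady fold; adaptation rate 0 means the
curve holds its peak. The piecewise form is continuous and attains
the peak fold exactly at the analytic peak time, which the tests
exploit. Default parameters (delay, rate, peak, adaptation, steady
per class) are free configuration values chosen to give four
well-separated shapes on the 7.5-h window — peak times ≈ 30, 60, 130
and 250 min; they are not fits to any experimental curve.

**Per-cell variability.** Response delay jitter (Gaussian, sd 4 min),
production-rate and steady-level log-normal variation (CV 0.2 and
0.1), baseline brightness log-normal variation (CV 0.1).

**Bursts.** In strains flagged bursty, each cell receives
Poisson-timed Gaussian bumps after its response peak (rate 0.006/min,
amplitude ~ N(0.8, 0.2) fold, width 12 min), independent across
cells. Because burst times are asynchronous, bursts largely cancel in
the population mean while persisting in individual cells — exactly
the regime in which M2 separates bursty from non-bursty strains. No
quantitative burst statistics exist to calibrate against, so these
are configuration values, not estimates.

**Cohort dynamics.** Initial cell count uniform in 20–50 (or fixed),
per-frame washout hazard 0.004 (≈ 70% of initial cells survive 91
frames, leaving tens of full-length trajectories per chamber, and
> 30 when the chamber starts near the top of the loading range),
division rate 0.004/cell/min producing late-born (non-full-length)
cells.

**Signal model.** value = baseline × fold(t) × exp(−0.001·elapsed) +
background 50 a.u. + Gaussian noise (sd 3 a.u.), baseline 200 a.u.
Identical seed and config reproduce bit-identical output.

**Rendering.** Cells are placed as non-overlapping disks (radius 6 px
in a 192×192 frame by default); uniform-mode cells are filled with
the trajectory value, nuclear-mode cells put the trajectory value in
a 10%-of-pixels sub-region and a quarter of it in the cytoplasm, so
the matching readout rule returns the input exactly. Background
pixels carry the background level plus noise. In-memory stacks are
float64; TIFF export quantizes fluorescence to 16-bit, which the
image-based round-trip tests account for.

**What passing tests do and do not show.** The generator reproduces
the features the statistics rely on (archetype shapes, asynchronous
bursts, truncation, bleaching, additive noise) but not segmentation
errors, cell crowding/overlap, focus drift, uneven illumination, or
motile cells — so green tests validate the analysis logic and its
numerics, not robustness to real-microscopy artifacts. Mask quality
is taken as given (mask generation is upstream of this package).

## Numerical and design choices

- Tie-breaks are deterministic everywhere: argmin ties → lowest cell
  id; tracker assignment ties → lowest previous id; M2 ranking ties →
  strain name.
- Bleach-fit rates with |k| < 1e-12 are treated as exactly 0.
- The baseline window is closed on the left and open at the stimulus.
- S̄ₜ in M1 includes the cell under evaluation; excluding it changes
  scores only at O(1/N) and would break the shared-S̄ₜ relationship
  with M2.
- Problem sizes in the tests and the acceptance script (40-strain
  panels, 91-point grids, chambers of a few tens of cells, 20-seed
  repetitions) mirror one chip experiment at desk scale; they are the
  package's default study conditions, not tuned quantities.
- The command-line interface is a thin wrapper over `run_pipeline`;
  all behavior is available as library calls, and each stage writes
  seed- and config-hash-stamped CSV artifacts so runs are auditable.
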