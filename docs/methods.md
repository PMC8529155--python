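# Methods

## Problem and model

A lung tumor treated with fiducial-tracking SABR is followed indirectly:
the machine tracks implanted gold seeds, and any desynchronization
between tumor and seeds becomes a geometric miss unless covered by a
margin.  Given the tumor motion trace **u**_T (per-phase 3D displacement
relative to the 0% respiratory phase) and the traces of the N_F
fiducials, every non-empty subset S of markers is scored by

    f(S) = sqrt( (1 / 3P) · Σ_phases Σ_axes (u_T − u_S)² ),

where u_S is the per-phase arithmetic mean of the member traces and P
the phase count.  The optimum S* = argmin f(S) is found by exhaustive
enumeration (2^N_F − 1 subsets; N_F ≤ 6 clinically, hard cap 12).  The
ITV_tracking margin of S* is reported per axis (R-L, A-P, I-S) as the
maximum absolute per-phase discrepancy — the margin must cover the
worst-phase excursion, and three directional margins are what treatment
planning consumes.  Two choices here were genuinely open:

* *Norm pooling.*  f(S) pools phases and axes into one RMS (division by
  3P).  Any monotone variant yields the same argmin; only the reported
  magnitude of f depends on it.
* *Margin norm.*  A single Euclidean norm per lesion cannot populate
  three directional margin columns; the per-axis worst-phase rule is the
  smallest axis-aligned box that covers the residual discrepancy at
  every phase.

Ties in f are broken toward fewer markers, then smaller mean
GTV-to-marker distance (when marker/tumor positions are supplied), then
lexicographic id order — fewer tracked markers means less imaging burden,
and nearer markers are better motion surrogates.

Displacements, not absolute positions, enter f: a static spatial offset
between tumor and marker is irrelevant to tracking fidelity, and f built
on positions would not vanish for a perfectly synchronized distant
marker.

## Synthetic phantom

`generate_phantom` renders an n-phase 4D CT (default ten phases, 1 × 1 ×
3 mm voxels, slice axis I-S) of uniform lung-density background
(−750 HU) containing gold-seed capsules (default 1 mm diameter × 3 mm
length, 3000 HU, long axis I-S) and optionally a spherical soft-tissue
GTV insert.  Phase k samples each object's motion model at t = k·τ/n; the
cos⁴ model displaces an object by b·(1 − cos⁴(π(φ + lag))) per axis
relative to phase 0, so phases 0 and n/2 hit the extremes and the
peak-to-peak of the ten-phase trace equals b exactly.  The per-axis
amplitude vector and fractional phase lag generalize the physical
phantom's one-axis motion so that desynchronized target–marker
configurations can be constructed for the margin framework.

Rendering uses a smooth point-spread falloff rather than binary voxel
membership: a voxel's intensity is bg + (hu − bg)·exp(−½[(d_r/σ_r)² +
(d_z/σ_z)²]), with d_r and d_z the in-plane and axial distances outside
the seed envelope and σ = (0.8, 0.8, 2.0) mm by default.  This emulates
the scanner PSF, the ~3 mm slice profile, and the metal bloom that makes
a sub-voxel gold seed visible across neighbouring voxels on real CT.  It
is also what makes sub-voxel tracking possible at all: rendered
intensities vary continuously with object position, whereas a binary
voxel-center rendering quantizes all displacement information to the
grid (and can make a 1 × 3 mm capsule vanish entirely between voxel
centers).  Consequently the above-threshold footprint of a seed straddles
two or three slices depending on its sub-slice position, so the
marker voxel count varies within a bounded band across phases rather
than being constant.

What the phantom does *not* model: CT physics (beam hardening, streaks),
4D-CT sorting artifacts, irregular breathing, tissue texture, and the
hardware slippage of physical motion stages (a stage programmed to 20 mm
that moves ≈19 mm).  Tests passing on this phantom therefore demonstrate
the correctness of the estimator chain on clean, well-posed inputs — not
robustness to clinical image quality, which in the package is probed
only by the additive-noise cases (σ up to 20 HU).

## Detection

Voxels above 1500 HU (far above any thoracic tissue) are grouped into
26-connected components; components smaller than 2 voxels are discarded
as noise.  Centroids are intensity-weighted means of member voxel-center
world coordinates, giving sub-voxel stability; detections are numbered
superior → inferior, with optional R/L labelling about a mid-sagittal
x coordinate to match the clinical R1/R2/L1 convention.

## Template tracking

For each detected marker a template box (default 4 × 4 × 10 mm, long
axis I-S, the dominant motion direction) is centred on the phase-0
centroid.  For a candidate translation t, the target phase is sampled
trilinearly at the template points shifted by t and compared with the
reference samples by mutual information — the standard similarity for
this registration family, robust to intensity scaling:

    MI = Σ_ij p(i,j) log2[ p(i,j) / (p(i) p(j)) ]

over a joint histogram with equal-width bins and per-signal [min, max]
ranges; constant signals give exactly 0.  Estimator parameters matter at
this template size: the box holds only ~75 voxels on a 1 × 1 × 3 mm
lattice, far too few joint-histogram samples.  The template is therefore
sampled on a 1 mm sub-voxel lattice (~275 points, reference trilinearly
interpolated) and the default bin count is 16, keeping bins² below the
sample count.  Coarser settings (lattice sampling, 32 bins) were measured
to degrade the MI landscape into sampling noise with tracking errors
above 1 mm.

The search is exhaustive on a 1.0 mm translation grid within the search
radius (default 15 mm per axis — it must cover the expected motion, and
should be raised for amplitudes near or above it), then refined on 0.5
and 0.25 mm grids within one previous step of the running optimum.
Exact MI ties are broken by smallest Euclidean norm, then lexicographic
(x, y, z), so the identity is preferred on symmetric landscapes.  Pure
translation only: the seed is rigid and small, and rotations are not
observable at this scale.  Each non-reference phase is matched
independently against phase 0; a failed phase (e.g. search window
leaving the volume) is flagged on the trajectory and tracking continues.

Measured on noise-free phantoms (3 mm slices), the tracked traces agree
with the analytic cos⁴ ground truth to ≤ 0.25 mm for programmed
amplitudes of 5–20 mm, independent of where the seed rests relative to
the slice grid; with 20 HU additive noise the error stays ≤ 0.5 mm.

## Log analysis

Treatment logs are a generic delimited table (time_s, x_mm, y_mm, z_mm,
fraction_id); the proprietary vendor log dialect is out of scope.  Per
axis, the position signal is segmented into breathing cycles at
successive maxima with prominence ≥ 1 mm; each cycle contributes
max − min, and the fraction amplitude is the mean over cycles — robust
to baseline drift, unlike a global range (both alternatives, global
range and 5–95 percentile span, are exposed).  An axis whose total range
is below the prominence floor is reported with its (sub-millimetre)
range and zero cycles; a trace with no cyclic axis at all is rejected.
At least two complete cycles (three detected maxima) are required.

Pre- vs in-treatment amplitudes are compared with a paired two-tailed
t-test: d = during − pre, t = mean(d)/(sd(d)/√n) with sample sd, p from
Student's t with n − 1 degrees of freedom.  Zero-variance differences
are reported, not errored: identical pairs give t = 0, p = 1; an exact
constant nonzero difference is flagged degenerate with p = 0.

## Cohort fixtures

The packaged CSVs transcribe the published study cohort: per-patient
lesion/fiducial/plan counts (17 patients) and per-lesion optimal marker
sets, per-axis margins and GTV-to-marker distances (42 lesions).
`summarize_margins` reproduces the published per-axis margin mean/SD at
one-decimal rounding with sample SD (n − 1; at n = 42 the n vs n − 1
choice survives the rounding, verified in tests).  The distance summary
is reproduced by averaging distances *within* each lesion first and then
across the 42 lesions; the flat average over all 59 distance entries
does not match the published 59.3 ± 24.6 mm, so the per-lesion
aggregation is the documented choice.

## Numerical and interface choices

* World axes x = R-L, y = A-P, z = I-S, millimetres; world = origin +
  index·spacing, 0-based indices.  Volumes are NIfTI with a diagonal
  affine (nibabel); traces and trajectories are plain CSV, round-tripped
  at 10⁻⁶ mm.
* All randomness (phantom noise) flows through one `numpy` generator
  seeded from the spec; noise-free phantoms are bit-identical across
  runs regardless of seed.
* Problem sizes in tests and the acceptance script (64 × 64 × 50 voxel
  grids, one to three markers) were chosen as the smallest grids that
  hold the 4 × 4 × 10 mm template plus a search window covering 20 mm
  motion; they keep a full tracking run at tens of seconds on one CPU.
* Degenerate inputs are defined, not special-cased ad hoc: empty
  detection lists are valid results, MI of constant signals is 0, a
  single-lesion margin summary reports SD 0 with a flag.

## Known limitations

* The phantom's clean background makes MI tracking easier than on
  textured lung anatomy; the reported sub-voxel accuracies are upper
  bounds on clinical performance.
* Physical-phantom biases (4D-CT motion underestimation of 0.5–1.8 mm
  from real acquisitions) arise from scanner physics and stage slippage
  and are deliberately not emulated.
* The margin framework assumes the simulation-time synchronization
  persists through treatment; the log-analysis module quantifies, but
  the margins do not automatically absorb, intrafraction amplitude
  changes.
* Subset enumeration is exponential and capped at 12 markers; clinical
  counts (≤ 6) enumerate in microseconds.
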