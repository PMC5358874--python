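# Methods

This note documents the models and procedures the package implements, the
choices made where several defensible options existed, and what the
synthetic world does and does not emulate.

## The analysis problem

Gravid sea turtles (the motivating case is the Kemp's ridley, *Lepidochelys
kempii*, in the western Gulf of Mexico) spend the weeks between successive
nesting emergences in restricted nearshore waters. Quantifying that
inter-nesting habitat from Argos satellite telemetry requires a chain of
steps — cleaning error-prone fixes, separating restricted inter-nesting
movement from directed migration, estimating home ranges, testing site
fidelity, and overlaying anthropogenic threats — each with conventions that
materially affect the result. The package implements the full chain as a
reusable, seeded, testable library.

## Track filtering

Fixes are cleaned in a fixed order: reject location class Z (no usable
accuracy estimate); clip to the mapped study area; drop fixes more than
1 km inland (positions slightly on land are retained because Argos error
routinely displaces genuinely nearshore fixes — the 1-km tolerance
preserves the spatial structure of coastal tracks); drop fixes at depths
greater than 100 m (biologically implausible for an inter-nesting female
on the shelf); drop fixes implying swim speeds above 5 km/h. Thresholds
are applied with strict inequality, so boundary values (exactly 100 m,
exactly 5 km/h) are retained.

The speed filter is a forward pass from the last retained fix: the first
fix is always kept, and each later fix is kept only if the great-circle
speed from the previously retained fix is within the cap. This is the
simplest deterministic variant; it guarantees the output contains no
consecutive pair violating the cap, and it is idempotent. A separate
turning-angle filter (drop interior fixes with angles sharper than 25
degrees) is intended for display tracks only: genuinely restricted
movement produces sharp angles, so this rule is never part of the
analysis chain.

All distances are haversine great-circle distances on a sphere of radius
6371.0 km. "Straight-line distance" throughout means great-circle.

## Switching state-space model (DCRWS)

Behavioural classification uses a two-state switching first-difference
correlated random walk fitted in a track-local azimuthal equidistant
projection. With positions x_t on a regular 8-hour grid and
d_t = x_t − x_{t−1}:

    d_t | d_{t−1}, b_t ~ N( γ_{b_t} R(θ_{b_t}) d_{t−1},  σ_{b_t}² I )

where b_t ∈ {migration, inter-nesting} follows a two-state Markov chain
with row-stochastic transition matrix A, γ ∈ [0,1] is move persistence,
θ a mean turn per step, and R(θ) a rotation. An Argos fix observed at
fraction w of interval [t_j, t_{j+1}) measures (1−w)x_j + w x_{j+1} plus
isotropic Gaussian error whose scale is the fix's location-class accuracy
(defaults: LC3 0.25, LC2 0.5, LC1 1.5, LC0 5, A 8, B 15 km; configurable).

One deliberate extension: the process scale σ is per-mode rather than
shared. Restricted inter-nesting movement differs from migration in
displacement magnitude as well as persistence, and a shared scale
measurably degrades state recovery when the modes differ in step size
(oracle classification accuracy on noise-free paths drops from ~0.94 to
~0.89 at the default mode scales). The per-mode scale is the standard
remedy and costs one extra parameter.

Inference is MCMC with exact conditional draws wherever the model is
conjugate:

* **Positions.** Given modes and parameters the model is jointly Gaussian
  in the full position path, with a banded precision matrix (each process
  term couples three consecutive grid points; each observation couples
  two). The whole path is drawn exactly per iteration by a banded Cholesky
  factorization — no per-position random-walk updates and no tuning.
* **Modes.** Exact forward-filter backward-sample over the two-state
  chain.
* **Switch probabilities.** Conjugate Beta(1,1) updates from transition
  counts.
* **γ, θ, σ.** Random-walk Metropolis with uniform priors on γ (0,1) and
  θ (−π, π), and half-normal priors on each σ scaled by the empirical
  step-difference SD.

Mode labels are made identifiable post hoc: every stored draw is
relabelled so migration carries the larger γ (directed movement is the
more persistent mode). The posterior mean mode index b̂ ∈ [1,2] is
binarized at 1.5 (strictly above → inter-nesting); an optional
(1.25, 1.75) band labels intermediate states "uncertain". The cutoff is a
convention, not an estimate — the posterior b̂ is retained in the output.

Defaults mirror the study design this reimplements: two independent
chains, 10,000 posterior iterations after 7,000 burn-in, thinned by five,
states every 8 hours. Tests and the acceptance script use shorter chains
(typically 1,500 after 800) at 75–200-step problem sizes; all convergence
claims are re-checked at those settings via split R-hat on γ, σ and the
diagonal of A, with failure declared above 1.1. Tracks with fewer than 20
fixes or spanning fewer than 10 grid steps are declared not robust and
fall back to heuristic segmentation — the operationalization of a
qualitative robustness judgement; with it, a fraction of unbalanced or
sparse tracks fails by design rather than returning silent estimates.

## Inter-nesting segmentation

An inter-nesting period is a maximal run of consecutive inter-nesting
labeled fixes. A final inter-nesting run that follows the last migration
bout and sits beyond a configurable radius (default 50 km) of the
deployment site is excluded as foraging (no return toward the nesting
region). Everything is truncated at the 31 August season end (inclusive).

The heuristic fallback starts the period at the first valid fix and ends
it on the last fix before detected departure. Departure — judged visually
in the original workflow — is made explicit: the first day whose mean net
displacement from the deployment site exceeds 50 km at the end of at
least 3 strictly increasing days, backtracked through days gaining at
least 5 km/day. The 5 km/day backtrack rate separates migration spin-up
from resident wandering (which gains and loses a few km/day); with it the
detector lands within one day of a known departure in over 90% of seeded
fixture runs. Tracks that never leave the nesting-site radius receive the
29 June default end date of the nesting year.

## Home-range estimation

All estimators work in a Lambert azimuthal equal-area projection centred
on the input points, so areas are exact and invariant (to well under 1%)
to the centring choice.

* **MCP (100%).** Convex hull of the filtered fixes; eligible from five
  locations.
* **α-Hull.** Delaunay triangulation of the fixes; a triangle is kept iff
  the mean of its three edge lengths is at most α times the mean edge
  length of the triangulation, with α = 1.5 by default. The global mean
  counts each shared edge once (a per-triangle counting variant is behind
  a flag; the choice is a convention the source workflow leaves open). As
  α → ∞ the union of kept triangles is exactly the MCP.
* **KDE.** Bivariate Gaussian kernel with one scalar bandwidth chosen by
  least-squares cross-validation over 100 log-spaced candidates in
  [0.05, 2] × the normal-reference bandwidth σ n^(−1/6); a minimum on the
  grid boundary (the classic LSCV failure mode) falls back to the
  reference bandwidth with a warning. Input is mean daily locations
  (daily arithmetic means in the projection), eligible from 20 days. If
  the x/y standard-deviation ratio falls outside (0.5, 2) the coordinates
  are standardized per axis before estimation and the result mapped back
  — the "rescale" treatment for strongly shore-parallel point sets. The
  utilization distribution is evaluated on a grid of resolution h/4
  extending 3h beyond the points and normalized to unit mass; the 95%
  (home range) and 50% (core area) regions are percent-volume contours —
  the smallest regions holding that share of mass — extracted as closed
  contour polygons with even-odd nesting.

Centroids of any polygon set are area-weighted in the equal-area
projection.

## Site-fidelity test

The spread statistic r² is the mean squared distance of relocations about
their arithmetic mean centre, in km² (the successive-displacement variant
is available behind a flag; the source phrase is ambiguous and the
about-centre reading is the common one). Each track is compared with 100
replicate correlated random walks that reuse its own step lengths and
turning angles in independently shuffled order (independent shuffling
breaks any length–angle coupling, the stronger null), start at the
observed start point with a uniform random initial heading, and are
confined to the shallow-shelf region (ocean within the 100-m isobath plus
the 1-km coastal strip). A step leaving the region has its (length, turn)
pair re-drawn from the remaining pool up to 100 times, after which the
replicate restarts (10 restarts by default — raiseable for heavily
constrained geometries, where the extra restarts are simply more
rejection sampling); re-draw counts are reported so constrained
geometries are visible.

p is the fraction of replicates whose r² is at least the observed r²
(ties count toward the null — the conservative direction), and fidelity
is declared when p > 0.95, i.e. at least 96 of 100 walks spread more than
the turtle did. Under an exchangeable null (a track generated by the same
shuffled-step process) p is uniform on {0, 0.01, …, 1}, giving a nominal
~5% false-positive rate, which the calibration suite verifies.

## Habitat metrics and threat overlay

Centroid depth is a bilinear bathymetry sample (positive down; a land
sentinel and a flag mark the occasional centroid displaced onto land by
nearshore location error); centroid distance to land is the minimum
distance to the coastline geometry. Total distance moved (TDM) sums
great-circle distances over successive filtered fixes; TDM/day divides by
the period's inclusive day count.

Occupancy uses 10 × 10 km cells axis-aligned in the environment's
equal-area frame. Turtle-days: each turtle-day credits every cell holding
at least one of that day's fixes (a single-cell-per-day variant assigns
the day's mean location and conserves totals exactly). Turtle counts per
home-range method merge each turtle's polygons first, so a turtle counts
at most once per cell regardless of how many periods it had.

Habitat-category structure is tested with χ² = Σ (Oᵢ−Eᵢ)²/Eᵢ against an
even distribution (Eᵢ = total/k, df = k−1), with distance categories
<5, 5–9.9, …, ≥30 km and depth categories ≤15, 15–24, 25–34, 35–49,
≥50 m read as half-open intervals. Nest-site fidelity is a mean
successive-nest distance of at most 13.5 km (boundary inclusive).
Cohort comparisons delegate to standard routines: Mann-Whitney U,
Kruskal-Wallis, Pearson correlation (scipy), with Dunn's rank-based
all-pairwise z test (Bonferroni-adjusted) implemented in-package.

Threat overlap counts platforms active on a required reference date
(removal date after that date, or none) within a 15-km great-circle
radius of each centroid — point-to-point distance rather than projected
polygon buffers, equivalent at these radii — and reports the trawl
effort-days of the partition cell containing each centroid (None, with a
warning, outside coverage; overlapping cells are rejected because the
layer must be a partition).

## The synthetic world

The generator exists so every stage can be tested against known truth
without external data. It emulates: a north-south coastline (meridional
line with a sinusoidal perturbation, amplitude 8 km, wavelength 120 km by
default; amplitude 0 gives an exact linear depth ramp for closed-form
checks); a shelf whose depth grows at 2 m/km with distance from shore, so
the 100-m isobath sits 50 km out; two-mode switching CRW trajectories
confined to the ocean (steps leaving it are re-drawn, with the persistent
component progressively damped past half the re-draw budget — the animal
turns along the coast rather than the simulation failing); duty-cycled
Argos observation (6 h on / 6 h off, Poisson fix counts per on-window at
2 per window) with location classes drawn from a configurable mix and
isotropic per-class Gaussian error; nesting emergences on configured day
offsets when the turtle is within 3 km of shore; and threat layers
(platforms with removal dates; an effort-polygon tiling of the shelf).

Default movement: migration γ 0.85 with 4 km process scale per 8-h step
(roughly 20–25 km/day sustained), inter-nesting γ 0.15 with 2 km scale —
restricted wandering of a few km/day, matching the reported inter-nesting
movement rates of hard-shelled turtles. The default class mix includes
realistic shares of the poor classes (A, B ~44%, Z 4%); the recovery
experiments use a modern Kalman-era mix weighted toward classes 3–1,
which is the data quality on which state recovery at the 0.9-accuracy
level is attainable.

What it does not emulate: currents and oceanography, tides, real
coastline geometry, diel behaviour, tag failure and duty-cycle drift,
non-isotropic (ellipse) Argos errors, and the length-biased detectability
of real Argos passes. Passing tests therefore demonstrate correctness of
the algorithms under a controlled data-generating process, not field
performance on real tags.

Determinism: every stochastic component derives from one seed through a
per-turtle `numpy` SeedSequence, so identical configurations reproduce
byte-identical pipeline outputs; per-turtle streams survive cohort
reordering.

## Problem sizes

The shipped tests and the acceptance script run the model chain at
reduced sizes chosen to exercise every code path at full fidelity:
200-step tracks and 2 × 2,300-iteration chains for recovery experiments,
10–20 replicate fits, 100–200 seeded runs for fidelity calibration, and
5-turtle cohorts for the end-to-end determinism check. These sizes are
the package's own test design; all configured defaults remain the full
study settings.

## Known limitations

* The SSM assumes isotropic, known observation scales per location class;
  a t-distributed error option exists in the generator but the fitter is
  Gaussian.
* Mode classification near switches is intrinsically uncertain at 8-h
  resolution; accuracy claims are medians over whole tracks.
* LSCV is known to undersmooth clustered data; the boundary fallback
  mitigates but does not remove this.
* The heuristic departure detector assumes migration displaces the animal
  monotonically over several days; slow or coast-following departures can
  be dated a day or two late.
* The trailing-foraging exclusion keys on distance from the deployment
  site; a turtle foraging near its nesting beach would not be excluded.
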