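# internesting

Inter-nesting movement and habitat-use analysis for satellite-tracked sea
turtles.

Female sea turtles nesting several times in a season spend the intervening
weeks in restricted nearshore waters. Where exactly, how much space they
use, and how that space overlaps shrimp-trawling grounds and oil and gas
platforms are the questions this package answers from Argos telemetry, the
way movement ecologists answer them for the Kemp's ridley (*Lepidochelys
kempii*) cohort nesting along the western Gulf of Mexico:

* **Track cleaning** — reject location class Z, drop fixes more than 1 km
  inland, deeper than 100 m, or implying swim speeds above 5 km/h, plus a
  25-degree turning-angle filter for display tracks.
* **Behavioural classification** — a two-state switching first-difference
  correlated random walk state-space model (DCRWS), fitted by MCMC,
  estimating position and mode (restricted inter-nesting vs. directed
  migration) every 8 hours:
  `d_t | d_{t-1}, b_t ~ N(γ_b R(θ_b) d_{t-1}, σ_b² I)` with a two-state
  Markov chain on b and per-location-class observation error.
* **Segmentation** — maximal runs of inter-nesting locations become
  inter-nesting periods (31 August season end; a heuristic
  departure-detection fallback with the 29 June default end for tracks
  that never leave the nesting area).
* **Home ranges** — 100% minimum convex polygon, α-Hull (Delaunay triangle
  pruning at α = 1.5) and kernel density estimation with an LSCV bandwidth
  (95% home range, 50% core area, mean daily locations, ≥ 20-day rule,
  SD-ratio rescaling).
* **Site fidelity** — Monte-Carlo comparison of each track's mean squared
  distance r² against 100 correlated random walks built from its own
  shuffled steps, constrained to the shallow shelf; fidelity at p > 0.95.
* **Habitat and threats** — centroid depth and distance to shore,
  total distance moved, 10 × 10 km turtle-day and turtle-count grids,
  χ² tests against even habitat-category use, nest-site fidelity
  (≤ 13.5 km rule), and platform/trawl-effort overlap within 15 km
  buffers.
* **A ground-truthed synthetic world** — shelf bathymetry, duty-cycled
  Argos observation with class-dependent error, plantable labeled
  outliers, and threat layers, so every stage is testable end to end
  without external data.

## Worked example

`examples/03_home_ranges.py` builds a 30-day restricted-movement period
(three fixes per day scattered ~4 km around a site) and estimates its home
range three ways:

```
MCP (100%):             214.8 km^2
alpha-Hull (a=1.5):     144.7 km^2 (11.2% of triangles pruned)
KDE 95% home range:      88.0 km^2 (h = 1.17 km by LSCV)
KDE 50% core area:       23.4 km^2
```

The α-Hull trims sparse outlying triangles so it is never larger than the
MCP; the 50% KDE core is the tight nucleus of daily use. Site fidelity on
two contrasting tracks (`examples/04_site_fidelity.py`):

```
resident:  r^2 =     9.8 km^2, p = 1.00, fidelity = True
transect:  r^2 =   744.7 km^2, p = 0.00, fidelity = False
```

A resident's spread (r², mean squared distance about the track centre) is
smaller than every one of its 100 reshuffled random walks (p = 1.00 means
all replicates spread at least as much); a directed transect spreads more
than all of them. And fitting the state-space model to a simulated
two-mode track (`examples/02_fit_behavior_ssm.py`, truth γ = 0.85
migration / 0.15 inter-nesting, process scales 4 and 2 km):

```
converged: True | R-hat: {'gamma_migration': 0.999, ...}
            parameter     mean       sd
      gamma_migration 0.910308 0.045895
   gamma_internesting 0.157662 0.090753
   sigma_migration_km 4.031091 0.282121
sigma_internesting_km 1.983730 0.281283
states labeled inter-nesting: 0.435 | true fraction: 0.4
```

The other examples cover simulation + filtering (`01`) and the full
pipeline with its summary tables (`05`).

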