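# Methods

`condensates` bundles three computational methods around one biological
question: how macromolecular crowding drives the stress kinase ASK3 into
liquid-like condensates when a cell shrinks under hyperosmotic stress, and
how those condensates dissolve and exchange material when volume recovers.
The package contains (i) a lattice kinetic Monte Carlo model of
crowding-driven clustering, (ii) a FRAP-rate quantification pipeline for
fast-moving condensates tracked as particles, and (iii) condensate
count/size/amount quantification for fluorescence images. Synthetic-data
generators with known ground truth make every pipeline testable without
microscopy data.

## 1. The lattice model

### State and moves

Molecules live on a bounded `width x height` square lattice with at most
one molecule per square. Two species exist: **ASK3 units** (the clustering
protein) and **obstacles** (virtually integrated crowder macromolecules —
one obstacle square stands for the averaged motion of many molecules).
One iteration of the rejection kinetic Monte Carlo (rKMC) loop:

1. pick a molecule uniformly at random from the union population;
2. pick one of its four von Neumann neighbour squares uniformly;
3. classify the move and look up its rate constant `k`;
4. draw `r ~ U[0, 1)` and accept iff `k > r` (classes that deterministically
   stay in place skip the draw).

Move classes and rates:

| class | condition | rate |
| --- | --- | --- |
| free ASK3 diffusion | empty destination, no contact lost | `k1 = 1` |
| penalized ASK3 move | empty destination, `n_lost > 0` | `k3 = A exp(-n_lost dE/theta)` |
| obstacle diffusion | empty destination | `k5 = 0.01` |
| exchange/vibration | ASK3 onto ASK3 | stay (dummy `k2`) |
| reflection | off-grid, or onto an obstacle / ASK3-onto-obstacle mix | stay (dummy `k4`, `k6`, `k7`) |

`n_lost` is the net number of ASK3–ASK3 nearest-neighbour contacts broken:
`max(0, contacts(origin) − contacts(destination, mover excluded))`; moves
that gain contacts count as free. This is a Metropolis-style penalty with
contact energy `dE/theta = 1` (in units of the thermal scale), so clusters
are cohesive but dynamic: detaching one contact succeeds ~37% of the time.
With defaults `A = 1` and `dE/theta = 1`, `k3(0) = 1 = k1` — surface
diffusion along a cluster is as fast as free diffusion. Note that at
`dE/theta = 1` the two-dimensional lattice gas is above its demixing
point, so clusters stay modest (~6–20 units) and exchange molecules
constantly, which is exactly the liquid-like, reversible regime the
biology calls for; the interesting behaviour comes from density (grid
size) and obstacles, not from deep quenching.

Boundaries are hard walls (out-of-bounds proposals are reflections), not
periodic: the grid boundary *is* the model's stand-in for the cell
boundary, and shrinking/expanding it is the experimental variable.

### Randomness

All randomness derives from one integer seed through
`numpy.random.SeedSequence.spawn`: one child stream each for initial
placement, target choice, direction choice and acceptance draws. Per
iteration exactly one target draw and one direction draw are consumed,
plus one acceptance draw when (and only when) a rate comparison occurs —
so trajectories are bit-reproducible from the seed, and the streams can be
buffered for speed (~0.4 µs/step in pure Python). `step()` (one readable
iteration) and the buffered inner loop used by `run()` are asserted
trajectory-identical in the test suite.

### Cluster statistics

A **cluster** is a 4-connected component of ASK3-occupied squares with at
least 6 units (`scipy.ndimage.label` with the cross-shaped structuring
element; the threshold mimics the confocal resolution limit — smaller
groups would be invisible). Per snapshot we report the cluster count and
the mean size over qualifying clusters; when none qualifies the mean size
is recorded as 0 (the value a microscopy field with no visible condensate
would contribute). Across replicates, summaries are mean ± SEM
(`sd/sqrt(n)`). Simulation time is quoted as `t` = 10^5 iteration steps.

## 2. The in-silico experiments

Both experiments use 500 ASK3 units and 1500 obstacles (occupancies 3.5%
and 10.4% at 120×120) and change **only the grid size**, the model's proxy
for osmotic volume change.

**Shrink sweep.** Fresh random initialisation per grid size and replicate,
5×10^6 steps, final-snapshot statistics. The full-scale preset sweeps
grids 50–120 with 18 replicates. The expected shape is non-monotone:
shrinking the grid raises both count and size (higher density nucleates
and feeds more clusters), but near jamming the obstacle matrix — which
percolates below ~52 squares at these numbers — fragments free space and
arrests coarsening, so count keeps rising while mean size falls. The desk
preset extends the sweep down to 45×45 (2025 squares for 2000 molecules,
~99% occupancy), where this kinetic arrest is resolvable with few
replicates: mean size ≈ 8.2 at 45 versus ≈ 8.9 at the 48–53 peak versus
≈ 0 at 120. Within the 50–120 range alone the downturn exists but is
shallow (≈ 0.3 units between 50 and the peak), needing far more
replicates to resolve.

**Expansion reversal.** Equilibrate at 55×55 for 5×10^6 steps, enlarge the
grid to 120×120 with molecules keeping their coordinates (the original
block sits in the corner; with hard walls any anchor is
translation-equivalent), then follow cluster statistics. Clusters dissolve
— count decays from ~18 toward the large-grid steady state — while the
mean size of the *surviving* clusters transiently overshoots its value at
the expansion instant: small clusters evaporate first, biasing the mean
upward before the large ones shrink too. The full-scale preset runs phase
2 for 35×10^6 steps; the desk preset stops at 2×10^7 steps (count has
fallen to ~6 by then), with 6 replicates recorded every 10^6 steps. At
this scale the overshoot itself is robust across seeds but its position
within phase 2 fluctuates, so tests assert its existence over the whole
dissolution window rather than its timing.

**No-obstacle control.** The sweep with `n_obstacles = 0`: mean size then
rises monotonically as the grid shrinks (10.6 at 50×50 vs ~1.9 at 120×120
with 5×10^6 steps) — and is *larger* than with obstacles at the same grid,
showing that crowding both causes clustering at moderate density and caps
cluster growth at high density.

Replicate `r` on grid `g` of an experiment with base seed `s` uses the
stream `SeedSequence([s, g, r])`, so any single replicate can be re-run in
isolation.

## 3. FRAP-rate quantification

The assay bleaches a rectangle containing many condensates (they move too
fast for single-spot FRAP) and quantifies recovery from a spot-tracker
table (`track_id, frame, time_s, x, y, intensity`; TrackMate-style exports
map onto this via a column map). The first `n_before_frames = 5` frames
are the pre-bleach phase; the pipeline:

1. **Track filter** — keep tracks with ≥1 Before frame, ≥1 After frame
   and ≥ 25 frames total.
2. **Grouping** — bleached iff the mean Before-phase (x, y) lies inside
   the bleach rectangle (closed bounds; the mean is used for noise
   robustness).
3. **Self-normalisation** — `F_i(t)/F_i,Before` with `F_i,Before` the
   track's Before-phase mean intensity.
4. **False-positive removal** — a "bleached" track whose mean relative
   intensity over its first three After frames exceeds 0.85 (i.e. lost
   < 15%) is a detector artefact and is dropped. The three-frame window
   mirrors the `G_Min` search window.
5. **Quench correction** — `G_i(t)` divides each bleached trace by the
   non-bleached group mean at the same time point, removing any per-time
   global factor (acquisition photobleaching) *exactly*; time points with
   no non-bleached coverage are dropped and logged.
6. **FRAP rate** — `G(t)` averages the bleached `G_i(t)` (one virtual
   condensate per cell); `G_Min` is the minimum of `G(t)` over the first
   three After time points; `FRAP rate(t) = (G(t) − G_Min)/(1 − G_Min) ×
   100`, anchored at 0 at the `G_Min` time point and approaching
   100 × mobile fraction.
7. **Pooling cells** — per-cell final-time FRAP rates outside
   `[Q1 − 5·IQR, Q3 + 5·IQR]` (type-7 quartiles) are trimmed; fewer than
   four cells disables trimming with a warning. The final-time statistic
   is used because the plateau is the per-cell summary of interest.

Tracks with gaps are left gapped — group means use whichever tracks are
present at each time point; no interpolation, and output stays aligned to
the input After time points.

Degenerate inputs: a track with non-positive Before mean, a cell with no
bleached or no non-bleached track, and `G_Min ≥ 1` (no detectable bleach)
are hard errors, not silent omissions.

## 4. Image quantification

**Per-cell count/size** (live-cell readout): Gaussian smoothing
(`sigma = 1 px`) → local mean threshold over a 31-px window plus an offset
(10 intensity units) → restriction to the provided cell mask → connected
components → particles below `min_area = 4 px²` discarded. The local
threshold makes the detection invariant to image-wide additive offsets.
The cell mask is an input; deriving it from DIC images is out of scope.
Sizes are reported in px² (convert with pixel-size metadata if needed).

**In vitro amount**: per field, a large-scale Gaussian background estimate
(`bg_sigma = 20 px`, a rolling-ball-equivalent) is subtracted, particles
are detected, and their total intensity summed; the **sample amount** is
the mean over the (default five) fields. Amounts are divided by the
internal-standard sample's amount and, when comparing groups across
experiments, by the mean of the control samples.

The default detection parameters were calibrated once against the
synthetic spot generator (below), since the original pilot-derived values
are not published. At the generator's default contrast (amplitude 50× the
noise sd) detection is exact; the test suite demonstrates exact planted
counts across ≥ 20 random layouts.

## 5. Synthetic data

**FRAP tracks**: bleached/non-bleached condensates jitter (Brownian, 0.3
px/frame) around centres drawn inside/outside the bleach rectangle. The
expected relative intensity of a bleached track at time `Δt` after the
bleach is `(1 − d) + m·d·(1 − exp(−Δt/τ))` — bleach depth `d = 0.8`
(tracks typically lose ~80% on bleaching), mobile fraction `m = 0.5`
(recovery is partial for these condensates), recovery time constant
`τ = 20 s` — multiplied by a global quench `exp(−λt)`, `λ = 0.002/s`.
The bleach lands at the first After frame's timestamp, so `G_Min` equals
`1 − d` exactly in the noiseless case and the pipeline output reduces to
the closed form `100·m·(1 − exp(−Δt/τ))`. Gaussian noise (sd 0.02) is
added on the relative scale and shares the track's quench factor, so
quench invariance is exact at zero noise and holds to noise order
otherwise. Acquisition geometry follows the assay: 5 Before + 100 After
frames at 2.1 s, 12 bleached and 20 reference tracks. Single-exponential
recovery is a harness choice — the pipeline itself fits no model — so
passing tests certify the pipeline's algebra and filters, not any
diffusion model of real condensates.

**Spot images**: Gaussian spots (sigma 2 px, amplitude 100) on a flat
background (10) with Gaussian noise (sd 2), centres kept ≥ 14 px apart and
≥ 10 px from the border so planted count is well-defined. The generator
records the layout it actually placed. What these images do *not* emulate:
shot noise, uneven illumination, out-of-focus light, touching condensates
— exactness of recovered counts on them bounds algorithmic errors only.

**Lattice fixtures**: explicit placements for hand-checkable cluster and
move-classification cases.

## 6. Numerical and design notes

* Quartiles: linear interpolation (numpy default, type 7) everywhere.
* The IQR fence factor is 5 (extreme outliers only), far stricter than
  Tukey's 1.5.
* `mean_size` of a snapshot with no qualifying cluster is 0 and flagged by
  `n_clusters == 0`; time series stay defined.
* Boundary tie-breaks: the bleach rectangle and the IQR fences are closed
  intervals; "at least a 15% decrease" keeps a track at exactly 15%.
* The expansion driver rejects shrink requests — molecule relocation onto
  a smaller grid is undefined in this model.
* Problem sizes in the shipped desk presets (5×10^6-step sweeps at 24 or
  fewer replicates; 2×10^7-step expansions at 6 replicates) were chosen as
  the smallest runs that resolve the qualitative orderings above with
  clear margins; the full-scale presets reproduce the original protocol
  sizes.
* Known limitations: 2D square lattice only (no 3D, no off-lattice); no
  detailed-balance or free-energy analysis; obstacles are inert hard
  squares; the hyperosmotic grid-size range is configurable rather than
  hard-coded (its published definition sits in supplementary material not
  reproduced here); cluster "size" is units per cluster, not an
  imaging-convolved area.
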