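# Methods

## The model

`domreg` treats space control as a reachability question: a pitch cell is
dominated by a player at a given instant if, within a fixed time horizon,
that player is more likely to occupy it than any other player, and by
nobody if no player can plausibly occupy it at all. The pipeline has four
stages.

**Kinematics.** Raw trajectories are filtered with a zero-phase
(forward–backward) third-order Butterworth low-pass at 0.4 Hz, applied to
x and y independently. Forward–backward filtering doubles the effective
order but keeps positions aligned in time, which matters because movement
models pair each frame with its *future* positions at fixed lags. From the
filtered path we take, per frame: the displacement angle θd of the forward
step (two-argument arctangent, degrees in (−180, 180]); the speed v as the
central difference of position; and the tangential acceleration a as the
central difference of the speed series. The three stencils lose one frame
at the end (θd), one at each end (v) and two at each end (a); downstream
stages only use frames where all three are defined. θd uses a forward
difference while v and a are centred, so θd is effectively advanced by
half a frame relative to them (17 ms at 30 Hz) — all three are
nevertheless indexed to frame i, and at 30 Hz the misalignment is far
below the raster resolution. Steps shorter than 10⁻⁴ m have no meaningful
direction and are masked rather than rounded.

**Movement models.** Each valid frame with a full 3 s future window
contributes one *canonical segment*: the next 90 positions relative to
the current one, rotated by θr = 90° + |θd| (θd < 0) or 90° − θd
(θd ≥ 0) so the instantaneous movement direction maps onto +y, then
mirrored about the y axis (the x-negated copy of every sample is added) so
left and right curvature are represented equally. Segments are pooled
into half-open (speed, acceleration) bins — 0–10 m/s and −6 to 6 m/s² in
unit steps. Speeds ≥ 10 and |a| > 6 clamp into the outermost bin rather
than being dropped, so sprints stay represented. Each populated bin is a
movement model: an (S, 90, 2) cloud of reachable offsets per lag, exactly
symmetric in x by construction.

**Probability grids.** To score one player at one frame, the model for
their current (v, a) is rotated by −θr back to their heading, translated
to their position, and rasterized on the 680 × 1050 grid of 0.1 m cells
as a histogram with probability-density normalisation:
pr(i,j) = c(i,j)/(N·A) with A = 0.01 m². Rotation and translation act on
the sample points *before* rasterization, so no raster interpolation
error enters. Off-pitch samples count toward N but land in no cell. The
raster is smoothed with an isotropic Gaussian (σ = 20 cells = 2 m, kernel
truncated at 4σ, zero padding — reflective padding would fabricate reach
beyond the touchline), and values strictly below 0.001 are zeroed; a
value exactly at the floor survives.

**Dominance.** Per cell, the owner is the player with the strictly
greatest value; ties among positive values go deterministically to the
lowest player identifier (and are counted); cells where every player is
zero are free space. Maps are per-frame — no temporal smoothing. Areas
are cell counts × A, so player areas plus free space tile the pitch
exactly.

## Normalisation of the probability grids

Two readings of "probability values from 0 to 1" are supported:

- **density** (default): the 0.001 floor applies to the smoothed densities
  themselves (units 1/m²). A σ = 2 m kernel spreads unit mass so peak
  densities are well below 1, and the fixed floor acts as an absolute
  reachability cut that is *comparable across players*.
- **unit-max**: each grid is first rescaled to [0, 1] by its own maximum,
  and the floor becomes relative. This makes every player's peak equal
  regardless of how concentrated their model is, and — because a smoothed
  field only falls below 10⁻³ of its peak about 3.7σ (≈ 7.4 m) from its
  support — it inflates every region to a ≥ 170 m² footprint even for a
  stationary point model.

Measured on the default synthetic match (22 agents, 60 s), density mode
yields median player regions of ~115 m² with ~62% of the pitch free,
against ~210 m² and ~27% free for unit-max. Only density mode reproduces
the qualitative regime this method is about — small, capacity-limited
regions inside a mostly free pitch — so it is the default; unit-max
remains available via `ModelConfig(normalization="unit-max")`, and grids
built under different modes are refused in the same dominance comparison.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `cell_size` | 0.1 m | raster resolution; 680 × 1050 cells of 0.01 m² |
| `frame_rate` | 30 Hz | tracking rate; 3 s horizon = 90 lags |
| `horizon_s` | 3 s | maximal future window of the models |
| `cutoff_hz`, `filter_order` | 0.4 Hz, 3 | trajectory low-pass (configuration, not re-derived) |
| `sigma_cells` | 20 | Gaussian smoothing sd in *cells* (2 m); 20 m would smear a model across a third of the pitch |
| `threshold` | 0.001 | reachability floor (strictly-below rule) |
| `min_samples` | 200 | post-mirroring samples per lag for a bin to count as populated |
| `max_segments_per_cell` | 2000 | deterministic evenly-spaced cap on stored segments per bin |
| `cumulative` | True | horizon T uses the union of lags ≤ T |
| `stillness_floor` | 10⁻⁴ m | displacement below which θd is undefined |

A dominance map at horizon T uses the union of samples at all lags up to
T ("reached *before* T"); `cumulative=False` switches to the exact-lag
reading. Queries for an unpopulated (v, a) bin fall back to the nearest
populated bin by city-block distance in bin units, ties resolved toward
lower speed and then lower |a|, and the fallback is counted.

The per-bin segment cap bounds memory and query cost; it thins segments
evenly *before* mirroring, so mirror symmetry is exact regardless.
Beyond ~2000 segments (4000 samples per lag) the smoothed density is
visually and numerically stable, and the cap only engages for the most
crowded central bins.

## Evaluation protocols

**Accuracy.** At every evaluated frame t (a stride option trades frames
for speed; the default protocols here evaluate once or twice per second),
a dominance map at horizon T is built from all players with defined
states, and a player scores a hit iff the raster cell containing their
real position at t + T carries their label. Landing in free space or in
another player's region are both misses. Percent correct is reported per
player; across players we report mean, sd and a t-based 95% CI.
Evaluation on the library's own training data is detected by
player/frame overlap and triggers a warning.

**Pass windows.** Release-to-reception times of successful passes are
summarized by linear-interpolation percentiles; the implied model horizon
is the 95th percentile rounded up to the nearest 0.5 s.

**Area comparison.** Player-frame areas from the model (3 s horizon) and
from the clipped Voronoi tessellation of the same frames are compared
with a two-sided Wilcoxon rank-sum test — exact enumeration when either
sample has ≤ 20 observations, normal approximation otherwise — and the
Rosenthal effect size r = |Z|/√N with Cohen's labels (0.1/0.3/0.5). In
the exact branch, Z is recovered from the exact p-value through the
normal quantile so that r remains defined. Medians get bootstrap 95% CIs
(2000 seeded resamples); means get t-intervals. Voronoi polygon areas are
computed geometrically (shapely, clipped to the pitch rectangle), not by
raster counting, to keep the comparison free of discretisation bias;
coincident players are perturbed by 10⁻⁹ m.

## The synthetic match generator

No public tracking data accompanies the method, so the package ships a
seeded multi-agent generator whose envelopes match the method's input
space: 22 agents at 30 Hz on a 105 × 68 m pitch, speeds within 0–10 m/s,
per-frame accelerations clipped to ±6 m/s². The default behaviour is a
correlated random walk: an Ornstein–Uhlenbeck speed process (κ = 0.8 s⁻¹,
σ = 1.2 m s⁻¹ s⁻½) around a per-agent cruising speed drawn from 1–4.5 m/s,
with sprint episodes (2 per minute, 3–6 s, target 5.5–8.5 m/s) so the
upper speed bins are populated, wrapped-normal heading increments
(60°/s scale) and reflecting pitch boundaries. Pass events arrive at
11 per minute with lognormal reception delays parameterised to median
1.4 s and 95th percentile 3.2 s — the empirical shape of real pass-window
distributions. `stationary`, `uniform` (constant-velocity, heading chosen
to stay on the pitch) and `waypoint` behaviours support targeted tests.

What the generator does *not* emulate: formations, set pieces, coupled
team tactics, the ball (beyond an optional attractor drift), measurement
noise, or occlusion gaps. Consequently, passing tests demonstrate the
correctness and the qualitative behaviour of the pipeline — accuracy
decaying with horizon, model regions smaller than Voronoi regions, free
space dominating the pitch — not the numerical values a professional
match would produce.

## Numerical choices and degenerate inputs

- Probability pipelines run on a local window covering the sample support
  plus the kernel's truncation radius; since the truncated kernel is
  exactly zero beyond that radius, the embedded full-pitch grid is
  identical to a whole-raster computation (asserted in tests).
- Empty point sets, all-zero grids and empty datasets flow through as
  valid degenerate values (zero grids, all-free maps, empty libraries);
  querying an entirely empty library is an error.
- Grid cells are half-open, so every point maps to exactly one cell;
  positions off the pitch are clamped at ingest and counted.
- Trajectories too short for the filter warm-up (≤ 12 samples at the
  defaults) are rejected with the minimum length in the message; in
  dataset-level builds they simply contribute nothing.
- The constant-step check on timestamps tolerates 10⁻⁵ s so 6-decimal
  CSV round-trips pass while a dropped frame (33 ms) still fails.
- Determinism: library building is deterministic given data and config;
  serialization (npz + hash-validated JSON manifest) round-trips
  bit-exactly; the simulator is fully seeded (same seed ⇒ same bytes).

## Protocol sizes

The shipped evaluation protocols use 60 s matches, evaluation strides of
30–60 frames (one to two evaluations per second) and three seeds for the
directional checks; these sizes give stable medians and CIs for the
qualitative claims while keeping a full run in the minutes range on a
single CPU. All of them are parameters, not constants.

## Known limitations

- A 0.4 Hz positional cut-off strongly attenuates sprint dynamics; it is
  kept as the default because it is the method's stated preprocessing,
  but it is configurable.
- Bins are unconditioned on playing position or player identity; a bin
  inherits whatever mixture of contexts produced its samples.
- The exact-lag vs cumulative-union ambiguity matters at long horizons
  (cumulative unions concentrate mass near the origin); the cumulative
  reading is the default.
- Tie handling (lowest identifier) is deterministic but arbitrary; ties
  on smoothed continuous fields are measure-zero and counted.
- Voronoi areas are exact polygon areas while model areas are cell
  counts; at 0.1 m resolution the discretisation gap is < 1% (asserted
  against a raster oracle in tests).
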