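# domreg

Probabilistic **dominant regions** and **free space** from football player
tracking data.

A player's dominant region is the part of the pitch they can reach before
any other player within a time horizon. The classical answer — the Voronoi
cell around each player — ignores how players actually move and assigns
*every* point of the pitch to someone. `domreg` instead learns empirical
**movement models** from tracking data and resolves dominance
probabilistically, which leaves the unreachable majority of the pitch
explicitly unowned ("free space").

## Method

From each smoothed trajectory (zero-phase third-order Butterworth,
0.4 Hz cut-off) the instantaneous kinematics are computed per frame *i*:

- displacement angle θd(i) = atan2(y(i+1) − y(i), x(i+1) − x(i)),
- speed v(i) from central differences of position,
- tangential acceleration a(i) from central differences of v.

Every frame with a full future window contributes its next H = 90
positions (3 s at 30 Hz), translated to the origin and rotated by
θr (θr = 90° + |θd| for θd < 0, else 90° − θd) so the movement direction
is +y, then mirrored about the y axis. Samples are binned by
(v, a) into a 10 × 12 matrix (speeds 0–10 m/s, accelerations −6 to 6 m/s²
in unit steps); each populated bin is a movement model.

To score a frame, each player's model is rotated back to their current
heading, translated to their position, and rasterized on the 680 × 1050
pitch grid (0.1 m cells) as a probability density
pr(i,j) = c(i,j)/(N·A), smoothed with an isotropic Gaussian
(σ = 20 cells = 2 m), with densities below 0.001 zeroed. Per cell the
player with the strictly greatest value dominates; cells where every
player is zero are free space. Evaluation asks whether each player's
*real* position T ∈ {1, 2, 3} s later falls inside their own region, and
compares region areas against the clipped Voronoi baseline
(Wilcoxon rank-sum, Rosenthal effect size r = |Z|/√N).

## Worked example

```python
from domreg import DominantRegionModel, SimConfig, generate_match, region_areas

train, _ = generate_match(SimConfig(n_per_team=11, duration_s=60, seed=1))
est = DominantRegionModel().fit(train)          # learn movement models
print(est.n_models_)                            # populated (v, a) bins

match, _ = generate_match(SimConfig(n_per_team=11, duration_s=60, seed=101))
dmap = est.predict_frame(match, frame=900, horizon_s=3.0)
areas = region_areas(dmap)
print(round(areas.free_area))                   # free-space area, m^2
print(round(est.score(match, horizon_s=1.0), 3))  # fraction of correct 1 s predictions
```

prints (exact numbers depend on the seeds shown):

```
37
4173
0.969
```

i.e. the 60 s training match populates 37 of the 120 (speed, acceleration)
bins; at frame 900 about 4 200 m² of the 7 140 m² pitch is controlled by
nobody within 3 s; and 96.9% of the players' true positions one second
ahead fall inside their own predicted dominant region.

The same pipeline is scriptable from the shell:

```bash
domreg simulate --seed 1 --players 11 --duration 60 --out match/
domreg build-models --tracking match/tracking.csv --out library.npz
domreg evaluate --tracking match/tracking.csv --events match/events.csv \
    --library library.npz --stride 30 --out report.json
```

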