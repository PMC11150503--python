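# antforage

Tools for studying **collective foraging of ant colonies on hexagonal channel
arenas**: an agent-based generator of synthetic foraging trials, mutual-information
analysis of spatial occupancy, maximum-entropy ("spin-glass") colony replicas, and
in-silico food-detection efficiency experiments on those replicas.

The package is aimed at researchers in collective animal behavior and network
inference who want to (a) analyze node-occupancy tracking data from channel-lattice
arenas, or (b) explore how spatial pairwise correlations shape a colony's search
efficiency, without access to live colonies.

## The system and the models

A colony of *Aphaenogaster senilis*-like ants (~750 workers) forages on a Teflon
arena milled with hexagonal channels (5 cm edges): a 2 m x 2 m plate carries 572
hexagons whose vertices form 1240 decision nodes; each colony explores a 2 m x 1 m
half with 286 hexagons. Trials last 3 h, sampled at 2 Hz. Food (12 items on the
vertices of two hexagons) is placed either at fixed faces every trial
(**deterministic** condition, arena never cleaned so trail cues persist) or at
random faces (**stochastic** condition, arena cleaned). Each trial splits into
three phases at TP1 (first item discovered) and TP2 (last item collected):
exploration, exploitation (group recruitment of 3-5 nestmates per delivery,
5-10-fold activity rise), and relaxation (back to 5-10 resident ants).

**Occupancy and mutual information.** Node *i*'s occupancy is the binary
`I_i(t)` (1 if >= 1 ant is on the node at frame *t*). Spatiotemporal organization
is quantified by the pairwise mutual information

```
MI(I_i, I_j) = sum_{a,b} P_ij(a,b) log2[ P_ij(a,b) / (P_i(a) P_j(b)) ]
```

with plug-in empirical probabilities, its system average
`<MI> = 2/(N(N-1)) sum_{i<j} MI(I_i, I_j)`, nearest-neighbor MI maps over the
lattice, moving-window `<MI>(t)` series, and the signed lags T1, T2 between the
`<MI>` turning points and TP1/TP2.

**Maximum-entropy replicas.** The colony's "computational replica" is the
pairwise maximum-entropy distribution over spins `s_i = 2 I_i - 1`:

```
P(s) = exp[ beta ( sum_i h_i s_i + sum_{i<j} J_ij s_i s_j ) ] / Z
```

Fields `h` and couplings `J` are inferred at `beta = 1` from exploitation-phase
occupancy by node-wise logistic pseudolikelihood with L2 regularization, followed
by a Boltzmann-learning refinement of `h` that pins the replica's per-node mean
occupancies to the data. The **null replica** forces `J = 0` (occupancies without
spatial correlations); its `beta` is calibrated by bisection so both replicas have
the same overall occupancy. Replicas are sampled with Glauber (heat-bath)
dynamics; food-detection efficiency is the first-passage time (in sweeps, from the
all-empty state) until every food node has been occupied, summarized by survival
curves and the 90th-percentile detection time.

## Worked example

```python
import numpy as np
from antforage import (build_arena, place_food, SimConfig, simulate_trial,
                       binarize_tracks, transition_points, windowed_average_mi,
                       lag_times, train_replicas, percentile_time, run_experiment)

arena = build_arena(1000, 800, 50)
print(f"arena: {arena.n_faces} hexagons, {arena.n_nodes} decision nodes")

cfg = SimConfig(duration_s=3600)
scenario = place_food(arena, "deterministic", seed=1)
tracks, events = simulate_trial(arena, scenario, cfg, seed=1)
phases = transition_points(events, cfg.duration_s)
print(f"TP1 = {phases.TP1_s:.0f} s, TP2 = {phases.TP2_s:.0f} s")

occ = binarize_tracks(tracks, arena, n_frames=cfg.n_frames)
mi = windowed_average_mi(occ, window_s=300, step_s=60)
lags = lag_times(mi, phases)
print(f"<MI> peak {mi.values.max():.4f} bits; T1 = {lags.T1_s:+.0f} s, "
      f"T2 = {lags.T2_s:+.0f} s")

full, null, _ = train_replicas(arena, "deterministic", 3, cfg, seed=11)
res = run_experiment(full, lambda s: scenario, 200, 10_000, seed=5)
res0 = run_experiment(null, lambda s: scenario, 200, 10_000, seed=5)
print(f"P90 detection: J>0 {percentile_time(res):.0f} sweeps, "
      f"J=0 {percentile_time(res0):.0f} sweeps")
```

Output:

```
arena: 110 hexagons, 262 decision nodes
TP1 = 40 s, TP2 = 448 s
<MI> peak 0.0038 bits; T1 = +110 s, T2 = -178 s
P90 detection: J>0 68 sweeps, J=0 45 sweeps
```

Reading the numbers: the first item is found 40 s in and the last is delivered at
448 s; the windowed `<MI>` peaks after TP1 (T1 = +110 s, a delayed collective
response) and starts declining before collection ends (T2 = -178 s, anticipated).
Both replicas trained on this deterministic colony find their accustomed food
quickly, the uncoupled one slightly faster — under the familiar condition the
nest-to-food occupancy pattern alone suffices, and spatial correlations only pay
off when food moves somewhere unexpected (see `scenario_suite` and the
`p_mixture` / `radial` placements).

A `antforage` command-line interface wraps the stages
(`simulate`, `binarize`, `mi`, `fit`, `sample`, `gof`, `efficiency`, `run-all`);
`antforage run-all --seed 0 --out out/` executes the whole pipeline from a YAML
config and writes a manifest with per-stage seeds and artifact hashes.

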