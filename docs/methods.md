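# Methods

This note documents the models behind `antforage`, the choices made where the
design was genuinely open, and what the synthetic-data generator does and does
not establish about real colonies.

## Arena geometry

`build_arena(width_mm, height_mm, edge_mm)` tiles the box with regular
pointy-top hexagons: horizontal pitch `sqrt(3)*a`, vertical pitch `1.5*a`, rows
offset by half a hexagon width, all rows the same length, and only whole
hexagons kept. With `a = 50` mm this convention yields exactly 572 faces in a
2 m x 2 m box (1240 decision nodes) and 286 faces in a 2 m x 1 m half — the
published dimensions of the physical arena. The physical structure's
interior/peripheral split (1192 ternary Y-crossings, and N = 620 occupancy
nodes per half) is *not* reproduced by a clean honeycomb cut, whose boundary
contains more degree-2 vertices; those four integers are therefore stored as
dataset constants (for ingesting tracking data from that arena, where
`active_nodes` is data-driven) and geometry tests assert internal consistency
instead: Euler's formula `V - E + F = 1`, degree in {2, 3}, unit edge lengths.
Coordinates are mm from the lower-left corner; the nest defaults to the node
nearest the midpoint of the lower edge; node ids are 0-based and stable for
identical build parameters.

Food scenarios place 12 items on the vertices of two vertex-disjoint faces.
The deterministic pair defaults to the faces whose centers lie nearest 500 mm
from the nest on symmetric sides of the nest axis (the distance of the fixed
patches in the experimental layout); stochastic draws are uniform with the
second face redrawn among vertex-disjoint partners; `p_mixture` uses the
deterministic pair with probability `p`; `radial` restricts draws to faces
within `R` mm of the nest.

## Synthetic colony generator

The generator is a population-level emulator, not an individual-based model of
*A. senilis* cognition: the study conditions it must reproduce are 3-h trials
at 2 Hz, a ~750-strong colony of which a handful scout at a time, group
recruitment of 3-5 nestmates per delivery, a 5-10-fold activity rise after the
first discovery, relaxation to 5-10 resident ants with departure bursts, and
trail memory that persists across trials only in the deterministic condition.
Its micro-rules are the minimal mechanisms that produce those facts:

- **Emission.** Nest departures are Poisson, 0.025 /s while exploring;
  sorties give up after an exponential time (mean 250 s), giving a steady
  scouting population of ~6. The trial warm-starts at that steady state
  (memorylessness makes the residual give-up times exact). After TP1 the rate
  is multiplied by `recruit_speedup = 6`; after TP2 it returns to base with
  Poisson bursts (rate 1/900 s, 5 ants) superimposed — the measured relaxation
  population sits in the 5-10 band.
- **Movement.** One channel per 4 frames (2.5 cm/s). At each node the next
  channel is a softmax over log-weights: persistence (+1.2 unless turning
  back), trail attraction (`1.5 * log1p(trail score)`), and a thigmotaxis
  bonus (+0.3 for peripheral nodes).
- **Trails.** A per-node scalar, +1 per food-carrying traversal, exponential
  decay with 2 h half-life, multiplied by 0.5 between deterministic trials and
  zeroed between stochastic trials. This abstracts contact/visual/odor cues
  without pheromone chemistry.
- **Foraging.** A scout reaching an item handles it (exponential, mean 60 s),
  carries it home by shortest path (reinforcing the trail), and triggers a
  dispatch of 3-5 recruits toward the remaining food; recruits travel by
  shortest path with 10% per-step noise and give up quickly (mean 90 s) if
  the face is empty. TP2 is the delivery of the last item.
- **Randomness.** Streams are split per ant (keyed by ant id), so adding an
  ant cannot perturb the others' trajectories; identical seeds give
  byte-identical outputs.

What passing tests show — and do not show. The generator reproduces the
*population-level* statistical structure (phase ordering, activity rise band,
trail concentration under the deterministic condition, preconditioning of TP1
across trials). It does not model individual heterogeneity, load carriage,
energetics, or pheromone diffusion, and none of its micro-parameters are
estimates of real ant behavior; conclusions drawn downstream are about the
pipeline's methods, not about the species.

## Features and mutual information

Detections are snapped to the nearest node within 25 mm (half a channel) and
dropped otherwise; occupancy is binary per node and frame. Encounters count
each unordered pair within one body length (10 mm default) once per frame, no
debouncing. The MI estimator is the plug-in over the window's empirical 2x2
joints, in bits by default (the log base is configurable); zero-count cells
contribute zero, and an optional Miller-Madow correction is available but off
by default since raw averages are reported. `<MI>` averages the N(N-1)/2
unordered pairs (the ordered-pair reading would double every value, a pure
rescaling). The moving window defaults to 900 s with a 150 s step, both
configurable (analyses in the source literature used 15- and 20-min windows
interchangeably). Turning points for the lag times T1/T2 use a deliberately
simple rule — 3-point moving smooth, rise onset at the pre-peak minimum, fall
onset at the post-TP1 maximum — because no canonical rule exists; a monotone
series yields undefined markers.

## Maximum-entropy replicas

Inference is node-wise logistic pseudolikelihood at `beta = 1`: spin i's
conditional is logistic with intercept `2 h_i` and coefficients `2 J_ij`, so
each node is one penalized logistic regression (scikit-learn, lbfgs) and the
two directed coupling estimates are averaged. Numerical choices:

- **Penalty scale.** The L2 strength `lambda` (default 0.01) multiplies
  `||J_i.||^2` against the *per-frame mean* conditional log-likelihood
  (`C = 2/(lambda T)`), so regularization does not vanish as frames
  accumulate. An unscaled penalty left pooled colony fits with dense,
  order-1 couplings whose Glauber dynamics froze in the all-empty state.
  Optionally the fields can be penalized too (`penalize_h`), which trades
  per-node occupancy accuracy for tamer fields; it is off by default.
- **Field polish.** After the PL fit, `train_replicas` runs ~15 rounds of
  Boltzmann learning on `h` only (`h_i -= 0.4 (<s_i>_model - <s_i>_data)`,
  500 Glauber samples per round): the pseudolikelihood optimum's equilibrium
  can drift from the observed occupancies by a factor of 2-3, and matching
  them is precisely the goodness-of-fit the replica concept requires.
  Constant (never/always occupied) columns get closed-form fields from
  Laplace-smoothed means (pseudocount 1) and zero couplings.
- **Null model.** `J = 0` with `h_i = atanh(2 p_i - 1)/beta` exactly
  reproduces per-node means. Its `beta` is calibrated by bisection (tolerance
  0.005 occupancy) so that null and full replicas have equal overall
  occupancy — the fair-comparison device for efficiency experiments; on the
  synthetic colonies this lands near 0.9-1.05. `beta` is otherwise a pure
  post-fit temperature knob: scaling `(h, J)` by `c` and `beta` by `1/c`
  leaves the distribution invariant (asserted by enumeration), which is what
  justifies training at `beta = 1`.
- **Sampling.** Glauber heat-bath dynamics, one sweep = N single-site updates
  in uniformly re-shuffled order, numba-compiled; exact enumeration is the
  oracle up to N = 20.
- **Pairwise fraction.** On subsets of <= 10 nodes, the share of total
  multi-information captured by pairwise structure is
  `(sum_i H_i - H(P2)) / (sum_i H_i - H(P))` with `P2` the iterative
  proportional fit to all pair marginals (<= 200 IPF sweeps, tolerance 1e-8).
  It is exactly 1 for two nodes and 0 for the three-node parity distribution.

## Efficiency experiments

Detection runs start from the all-empty configuration (the metric counts
0 -> 1 transitions) and return the first sweep at which *all* food nodes have
been occupied; a first-node variant matches the alternative reading of the
metric and is a switch. Time is measured in sweeps only — no mapping to
seconds is attempted. Censoring at `max_sweeps` (default 10^4) is explicit;
survival curves count censored runs as beyond the cap, and percentiles are
nearest-rank over finite times, erroring rather than silently extrapolating
when the rank falls among censored runs. Suites compare the four replicas
(deterministic/stochastic x coupled/null) under their trained conditions, a
`p`-mixture grid (default {0, 0.5, 1}) and a radial grid (default {250, 550,
750} mm), with common random numbers across models so comparisons are paired.

## Problem sizes and a known desk-scale limitation

The packaged analyses run on a 1000 x 800 mm arena (110 faces, 262 nodes),
3600 s trials, three trials pooled per condition, 120-200 realizations per
efficiency cell — sizes chosen so the full pipeline runs in minutes on one
core while every phase of the dynamics is still present. At this scale the
comparative findings hold: replica occupancy falls monotonically with `beta`;
the deterministic-trained replica finds its accustomed food far faster than
the stochastic-trained one; its efficiency collapses as food placement is
randomized (`p -> 0`) while the stochastic replica degrades far less; and for
the deterministic pair the uncoupled replica's random-food survival decays
more slowly than the coupled one's.

One finding does **not** reproduce at this scale: for the *stochastic* pair,
the `J = 0` replica detects randomly placed food faster, not slower, than the
coupled replica. The reason is structural. On a few-hundred-node lattice the
synthetic stochastic colony's pooled exploitation coverage reaches essentially
every node (10th-percentile node occupancy ~1e-2), so the occupancy-matched
independent replica flips any food node within tens of sweeps, while a
correlated replica pays a nucleation/mixing cost from the empty start. The
advantage of spatial correlations requires the large-lattice regime — hundreds
of nodes that the colony essentially never visits, where an independent
replica is astronomically slow and only collectively organized activity
reaches cold regions. That regime needs the full 620-node half-arena and
correspondingly longer fits and runs. The corresponding test is kept, and
fails, as an honest record of this limitation.

## Degenerate inputs and tie-breaks

Empty track tables binarize to all-zero matrices; frames with zero ants are
excluded from per-capita occupancy; all-constant occupancy columns give zero
MI and closed-form fields; disconnected node pairs report infinite hop
distance; a radial food radius containing fewer than two vertex-disjoint faces
is an error rather than a silent fallback; event logs with a collection before
any discovery are rejected.
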