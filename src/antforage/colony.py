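"""Agent-based synthetic colony: foraging trials on the channel arena.

The generator is a population-level stand-in for a real colony.  It emulates
the statistical structure of foraging trials — three phases bounded by the
first food discovery (TP1) and the last food delivery (TP2), group
recruitment of 3-5 nestmates per successful scout, a 5-10 fold activity rise
during exploitation, relaxation to a handful of resident ants with departure
bursts, and trail memory that persists across trials under the deterministic
food condition but is wiped under the stochastic one.  Its individual-level
movement rules (softmax direction choice with persistence, trail attraction
and thigmotaxis) are minimal mechanisms producing those population facts,
not claims about real ant cognition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arena import FoodScenario, HexArena, place_food

__all__ = ["SimConfig", "simulate_trial", "simulate_series", "tracks_to_csv",
           "tracks_from_csv", "events_to_csv", "events_from_csv"]

TRACK_COLUMNS = ["frame", "ant_id", "node_id", "x_mm", "y_mm"]
EVENT_COLUMNS = ["time_s", "kind", "ant_id", "node_id"]
EVENT_KINDS = ("exit_nest", "enter_nest", "food_found", "food_collected",
               "recruit_dispatch")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic foraging trial.

    Defaults reproduce the study conditions: 3-hour trials sampled at 2 Hz,
    a colony of ~750 workers of which only a small scouting contingent is in
    the arena at a time, recruitment of 3-5 nestmates per delivery, an
    emission speed-up after TP1 tuned so arena population rises 5-10 fold,
    and relaxation back to 5-10 resident ants.
    """

    duration_s: float = 10800.0
    frame_rate_hz: float = 2.0
    colony_size: int = 750
    # nest departures per second while exploring; with ~250 s sorties this
    # keeps a steady scouting population of ~6 ants
    scout_emission_rate: float = 0.025
    recruit_count_range: tuple[int, int] = (3, 5)
    # emission multiplier after TP1; 6x emission plus recruit traffic yields
    # a 5-10 fold population rise at the exploitation peak
    recruit_speedup: float = 6.0
    relax_floor: tuple[int, int] = (5, 10)
    burst_rate: float = 1.0 / 900.0   # relaxation departure bursts per second
    burst_size: int = 5
    step_frames: int = 4              # frames per node-to-node move (2.5 cm/s)
    sortie_mean_s: float = 250.0      # mean give-up time of an unsuccessful sortie
    handling_time_s: float = 60.0     # mean time spent handling an item at the node
    recruit_patience_s: float = 90.0  # mean search time of a recruit at an empty face
    persistence_weight: float = 1.2   # log-weight against turning back
    trail_weight: float = 1.5         # alpha: log-weight per log(1+trail score)
    thigmotaxis_weight: float = 0.3   # log-weight bonus for peripheral nodes
    trail_decay: float = float(np.log(2) / 7200.0)  # per-s decay (2 h half-life)
    trail_carryover: float = 0.5      # inter-trial trail retention factor
    path_noise: float = 0.1           # per-step chance a directed ant strays
    trail_persistence: bool = True    # deterministic condition: keep trails
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.frame_rate_hz <= 0:
            raise ValueError("duration_s and frame_rate_hz must be positive")
        lo, hi = self.recruit_count_range
        if not (1 <= lo <= hi <= self.colony_size):
            raise ValueError("recruit_count_range must lie within [1, colony_size]")
        for name in ("scout_emission_rate", "recruit_speedup", "burst_rate",
                     "trail_decay", "path_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))


class _Ant:
    __slots__ = ("ant_id", "node", "prev", "mode", "path", "carrying",
                 "give_up_frame", "rng", "move_phase", "target_face",
                 "handle_until")

    def __init__(self, ant_id, node, rng, give_up_frame, move_phase):
        self.ant_id = ant_id
        self.node = node
        self.prev = -1
        self.mode = "explore"     # explore | goto | handle | home
        self.path = []            # remaining nodes to visit for goto/home
        self.carrying = False
        self.give_up_frame = give_up_frame
        self.rng = rng
        self.move_phase = move_phase
        self.target_face = -1
        self.handle_until = -1


def _softmax_choice(rng, options, logw):
    logw = logw - logw.max()
    w = np.exp(logw)
    return options[rng.choice(len(options), p=w / w.sum())]


def simulate_trial(
    arena: HexArena,
    scenario: FoodScenario,
    config: SimConfig,
    seed: int,
    trail_init: np.ndarray | None = None,
    return_trail: bool = False,
):
    """Run one foraging trial; returns (TrackTable, EventLog[, trail scores]).

    Identical ``(arena, scenario, config, seed)`` give bit-identical outputs.
    Random streams are split per ant (keyed by the ant's id) so that adding
    an ant does not perturb the trajectories of the others.
    """
    if scenario.food_nodes and not all(n in arena.graph for n in scenario.food_nodes):
        raise ValueError("food scenario does not match this arena")
    fps = config.frame_rate_hz
    n_frames = config.n_frames
    dt = 1.0 / fps
    if config.scout_emission_rate == 0 and config.duration_s > 0:
        warnings.warn("zero emission rate: the trial will produce an empty track")

    ev_rng = np.random.default_rng([seed, 0xE])  # emission / event stream
    trail = np.zeros(arena.n_nodes) if trail_init is None else trail_init.astype(float).copy()
    food_left = {n: scenario.items_per_node for n in scenario.food_nodes}
    items_total = scenario.total_items
    collected = 0
    tp1_seen = False
    exploitation_over = items_total == 0

    neighbors = [sorted(arena.graph.neighbors(i)) for i in range(arena.n_nodes)]
    peripheral = arena.is_peripheral
    nest = arena.nest_node
    decay_per_frame = np.exp(-config.trail_decay * dt)

    ants: list[_Ant] = []
    next_ant_id = 0
    pending_departures: list[tuple[int, str, int]] = []  # (frame, role, target_face)
    track_frames: list[int] = []
    track_ants: list[int] = []
    track_nodes: list[int] = []
    events: list[tuple[float, str, int, int]] = []
    dispatched_frames: set[int] = set()

    def spawn(frame, mode="explore", target_face=-1):
        nonlocal next_ant_id
        if len(ants) >= config.colony_size:
            return
        aid = next_ant_id
        next_ant_id += 1
        rng = np.random.default_rng([seed, 1, aid])
        give_up = frame + max(1, int(rng.exponential(config.sortie_mean_s) * fps))
        ant = _Ant(aid, nest, rng, give_up, frame % config.step_frames)
        if mode == "goto" and target_face >= 0:
            verts = arena.faces[target_face]
            tgt = verts[rng.integers(len(verts))]
            ant.mode = "goto"
            ant.target_face = target_face
            ant.path = arena.shortest_path(nest, tgt)[1:]
        ants.append(ant)
        events.append((frame * dt, "exit_nest", aid, nest))

    def emission_rate(frame):
        if not tp1_seen:
            return config.scout_emission_rate
        if not exploitation_over:
            return config.scout_emission_rate * config.recruit_speedup
        return config.scout_emission_rate  # relaxation floor traffic

    def pickup(ant, frame):
        nonlocal tp1_seen
        node = ant.node
        if food_left.get(node, 0) > 0 and not ant.carrying:
            food_left[node] -= 1
            ant.carrying = True
            tp1_seen = True
            events.append((frame * dt, "food_found", ant.ant_id, node))
            ant.mode = "handle"
            ant.handle_until = frame + max(
                1, int(ant.rng.exponential(config.handling_time_s) * fps))

    def step_ant(ant, frame):
        nonlocal collected, exploitation_over
        if ant.mode == "handle":
            if frame >= ant.handle_until:
                ant.mode = "home"
                ant.path = arena.shortest_path(ant.node, nest)[1:]
            return False
        if ant.mode == "explore":
            if frame >= ant.give_up_frame:
                ant.mode = "home"
                ant.path = arena.shortest_path(ant.node, nest)[1:]
                return False
            opts = neighbors[ant.node]
            logw = np.empty(len(opts))
            for k, o in enumerate(opts):
                logw[k] = (config.persistence_weight * (o != ant.prev)
                           + config.trail_weight * np.log1p(trail[o])
                           + config.thigmotaxis_weight * peripheral[o])
            nxt = _softmax_choice(ant.rng, opts, logw)
        else:
            if ant.mode == "goto" and ant.rng.random() < config.path_noise:
                opts = neighbors[ant.node]
                nxt = opts[ant.rng.integers(len(opts))]
                verts = arena.faces[ant.target_face]
                tgt = verts[ant.rng.integers(len(verts))]
                ant.path = arena.shortest_path(nxt, tgt)[1:]
            elif ant.path:
                nxt = ant.path.pop(0)
            else:
                nxt = ant.node
        ant.prev, ant.node = ant.node, nxt
        if ant.carrying:
            trail[nxt] += 1.0
        if ant.mode == "goto" and not ant.path:
            # reached the target face: search locally, but give up quickly
            # (recruits are followers, not scouts)
            ant.mode = "explore"
            ant.give_up_frame = frame + max(
                1, int(ant.rng.exponential(config.recruit_patience_s) * fps))
        pickup(ant, frame)
        if ant.mode == "home" and not ant.path and ant.node == nest:
            events.append((frame * dt, "enter_nest", ant.ant_id, nest))
            if ant.carrying:
                collected += 1
                events.append((frame * dt, "food_collected", ant.ant_id, nest))
                remaining = sum(food_left.values())
                if remaining > 0:
                    k = int(ev_rng.integers(config.recruit_count_range[0],
                                            config.recruit_count_range[1] + 1))
                    dframe = frame
                    while dframe in dispatched_frames:
                        dframe += 1
                    dispatched_frames.add(dframe)
                    candidates = [n for n, c in food_left.items() if c > 0]
                    tnode = candidates[int(ev_rng.integers(len(candidates)))]
                    tface = next(f for f, verts in enumerate(arena.faces)
                                 if tnode in verts and
                                 any(food_left.get(v, 0) > 0 for v in verts))
                    for _ in range(k):
                        events.append((dframe * dt, "recruit_dispatch", -1, tnode))
                        pending_departures.append((dframe + 1, "goto", tface))
                if collected >= items_total:
                    exploitation_over = True
            return True  # ant retires to the nest
        return False

    # warm start: the scouting population is assumed at its steady state
    # (emission rate x mean sortie time) when the nest is connected
    n0 = ev_rng.poisson(config.scout_emission_rate * config.sortie_mean_s)
    for _ in range(n0):
        spawn(0)

    burst_left = 0
    for frame in range(n_frames):
        trail *= decay_per_frame
        # nest emissions
        rate = emission_rate(frame)
        n_out = ev_rng.poisson(rate * dt)
        if exploitation_over and items_total > 0:
            if ev_rng.random() < config.burst_rate * dt:
                burst_left += config.burst_size
            if burst_left > 0 and frame % config.step_frames == 0:
                n_out += 1
                burst_left -= 1
        for _ in range(n_out):
            spawn(frame)
        while pending_departures and pending_departures[0][0] <= frame:
            _, role, tface = pending_departures.pop(0)
            spawn(frame, "goto", tface)
        pending_departures.sort(key=lambda t: t[0])
        # movement
        retired = []
        for ant in ants:
            if frame % config.step_frames == ant.move_phase:
                if step_ant(ant, frame):
                    retired.append(ant)
        for ant in retired:
            ants.remove(ant)
        # record detections
        for ant in ants:
            track_frames.append(frame)
            track_ants.append(ant.ant_id)
            track_nodes.append(ant.node)

    node_ids = np.asarray(track_nodes, dtype=np.int64)
    xy = arena.node_xy[node_ids] if len(node_ids) else np.empty((0, 2))
    tracks = pd.DataFrame({
        "frame": np.asarray(track_frames, dtype=np.int64),
        "ant_id": np.asarray(track_ants, dtype=np.int64),
        "node_id": node_ids,
        "x_mm": xy[:, 0] if len(node_ids) else np.array([]),
        "y_mm": xy[:, 1] if len(node_ids) else np.array([]),
    })
    evdf = pd.DataFrame(events, columns=EVENT_COLUMNS)
    evdf = evdf.sort_values("time_s", kind="stable").reset_index(drop=True)
    if return_trail:
        return tracks, evdf, trail
    return tracks, evdf


def simulate_series(
    arena: HexArena,
    condition: str,
    n_trials: int,
    config: SimConfig,
    seed: int,
    fixed_faces: tuple[int, int] | None = None,
):
    """Run a series of trials under one food condition.

    Under ``deterministic`` the food faces are identical in every trial and
    trail scores carry over (decayed by ``trail_carryover``) between trials;
    under ``stochastic`` fresh faces are drawn and trails are reset to zero
    each trial, emulating the cleaned arena.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    persist = condition == "deterministic" and config.trail_persistence
    out = []
    trail = np.zeros(arena.n_nodes)
    for t in range(n_trials):
        scen_seed = int(np.random.default_rng([seed, 2, t]).integers(2**31))
        if condition == "deterministic":
            scenario = place_food(arena, "deterministic", seed=scen_seed,
                                  fixed_faces=fixed_faces)
        else:
            scenario = place_food(arena, condition, seed=scen_seed)
        trial_seed = int(np.random.default_rng([seed, 3, t]).integers(2**31))
        init = trail * config.trail_carryover if persist else np.zeros(arena.n_nodes)
        tracks, events, trail = simulate_trial(
            arena, scenario, config, trial_seed, trail_init=init, return_trail=True)
        out.append((tracks, events, scenario))
        if not persist:
            trail = np.zeros(arena.n_nodes)
    return out


# -- CSV round trips -----------------------------------------------------

def tracks_to_csv(tracks: pd.DataFrame, path) -> None:
    tracks.to_csv(path, index=False)


def tracks_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"track table missing columns {sorted(missing)}")
    return df[TRACK_COLUMNS]


def events_to_csv(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False)


def events_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event log missing columns {sorted(missing)}")
    return df[EVENT_COLUMNS]
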