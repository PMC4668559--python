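"""Constrained 7x7 maze generation and the scene-choice navigation task.

A maze map is a 7x7 grid of path/wall squares surrounded by implicit walls.
Valid maps contain no dead ends, no cross roads, no 2x2 all-path ("white
patch") windows, no interior 2x2 all-wall ("black patch") windows and no
2x2 checker patterns, and their path squares form a single connected
component.

On every trial the navigator is placed at a random pose, moved three steps
(the third always forward), and must pick the upcoming scene -- the wall
status of the five squares visible from the post-move pose -- from two
options: the true scene and a distracter that differs in exactly one of the
three newly revealed forward view parts (forward-left, forward-center,
forward-right).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GRID_SIZE = 7

PATH = True
WALL = False

HEADINGS = ("N", "E", "S", "W")
MOVEMENTS = ("FWD", "TURN_L", "TURN_R")
VIEW_PARTS = ("FL", "FC", "FR")

#: unit steps per heading; row 0 is the top of the map, so North decreases row
_FWD_DELTA = {"N": (-1, 0), "E": (0, 1), "S": (1, 0), "W": (0, -1)}
_LEFT_OF = {"N": "W", "W": "S", "S": "E", "E": "N"}
_RIGHT_OF = {v: k for k, v in _LEFT_OF.items()}

#: the 12 binary status codes, in battery order
CODE_NAMES = (
    "up_fl", "up_fc", "up_fr",          # upcoming view parts
    "obs_left", "obs_right",            # observed view at post-move state
    "pos_upper", "pos_lower", "pos_left", "pos_right",
    "map1", "map2", "map3",
)

CODE_FAMILIES: Mapping[str, tuple[str, ...]] = {
    "UPCOMING": ("up_fl", "up_fc", "up_fr"),
    "OBSERVED": ("obs_left", "obs_right"),
    "POSITION": ("pos_upper", "pos_lower", "pos_left", "pos_right"),
    "MAP": ("map1", "map2", "map3"),
}

#: upcoming-view codes of the scene chosen on incorrect trials
CHOSEN_CODE_NAMES = ("ch_fl", "ch_fc", "ch_fr")


class MapGenerationError(RuntimeError):
    """Raised when constrained map search exhausts its retry budget."""


class TrialGenerationError(RuntimeError):
    """Raised when a trial set satisfying the balance criteria cannot be built."""


class InvalidMovementError(ValueError):
    """Raised on a forward move into a wall or off the grid."""


class DistracterInfeasibleError(RuntimeError):
    """Signal that no view part of this trial can be flipped legally."""


# ---------------------------------------------------------------------------
# map representation and constraint checking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    """One topographic-constraint violation: kind plus the offending coords."""

    kind: str
    coords: tuple[tuple[int, int], ...]


@dataclass
class MazeMap:
    """A 7x7 path/wall grid.  ``grid[r, c]`` is True for path squares."""

    map_id: int
    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.shape != (GRID_SIZE, GRID_SIZE):
            raise ValueError(f"grid must be {GRID_SIZE}x{GRID_SIZE}, got {self.grid.shape}")

    def is_path(self, row: int, col: int) -> bool:
        """Path status of a square; anything outside the grid is a wall."""
        if 0 <= row < GRID_SIZE and 0 <= col < GRID_SIZE:
            return bool(self.grid[row, col])
        return WALL

    @property
    def n_paths(self) -> int:
        return int(self.grid.sum())

    def to_text(self) -> str:
        return "\n".join(
            "".join("." if self.grid[r, c] else "#" for c in range(GRID_SIZE))
            for r in range(GRID_SIZE)
        )

    @classmethod
    def from_text(cls, text: str, map_id: int = 0) -> "MazeMap":
        rows = [line for line in text.strip().splitlines()]
        grid = np.array([[ch == "." for ch in row] for row in rows], dtype=bool)
        return cls(map_id=map_id, grid=grid)

    def to_json(self) -> str:
        return json.dumps({"map_id": self.map_id, "grid": self.grid.astype(int).tolist()})

    @classmethod
    def from_json(cls, text: str) -> "MazeMap":
        obj = json.loads(text)
        return cls(map_id=int(obj["map_id"]), grid=np.array(obj["grid"], dtype=bool))


def _path_neighbor_count(grid: np.ndarray) -> np.ndarray:
    """Number of path 4-neighbors of every square (outside counts as wall)."""
    padded = np.zeros((GRID_SIZE + 2, GRID_SIZE + 2), dtype=int)
    padded[1:-1, 1:-1] = grid.astype(int)
    return (
        padded[:-2, 1:-1] + padded[2:, 1:-1] + padded[1:-1, :-2] + padded[1:-1, 2:]
    )


def check_map_constraints(maze: MazeMap | np.ndarray) -> list[Violation]:
    """Check all topographic constraints; an empty list means a valid map.

    Kinds: ``NO_PATH``, ``DEAD_END``, ``CROSS_ROAD``, ``WHITE_PATCH``,
    ``BLACK_PATCH`` (interior windows only; the implicit wall surround is
    exempt), ``CHECKER`` and ``DISCONNECTED``.
    """
    grid = maze.grid if isinstance(maze, MazeMap) else np.asarray(maze, dtype=bool)
    if grid.shape != (GRID_SIZE, GRID_SIZE):
        raise ValueError(f"grid must be {GRID_SIZE}x{GRID_SIZE}, got {grid.shape}")

    violations: list[Violation] = []
    if not grid.any():
        violations.append(Violation("NO_PATH", ()))
        return violations

    ncount = _path_neighbor_count(grid)
    for r in range(GRID_SIZE):
        for c in range(GRID_SIZE):
            if grid[r, c]:
                if ncount[r, c] <= 1:
                    violations.append(Violation("DEAD_END", ((r, c),)))
                elif ncount[r, c] == 4:
                    violations.append(Violation("CROSS_ROAD", ((r, c),)))

    for r in range(GRID_SIZE - 1):
        for c in range(GRID_SIZE - 1):
            window = grid[r : r + 2, c : c + 2]
            cells = ((r, c), (r, c + 1), (r + 1, c), (r + 1, c + 1))
            if window.all():
                violations.append(Violation("WHITE_PATCH", cells))
            elif not window.any():
                violations.append(Violation("BLACK_PATCH", cells))
            elif window[0, 0] == window[1, 1] and window[0, 1] == window[1, 0] \
                    and window[0, 0] != window[0, 1]:
                violations.append(Violation("CHECKER", cells))

    # connectivity by flood fill over path squares
    seeds = np.argwhere(grid)
    seen = np.zeros_like(grid, dtype=bool)
    stack = [tuple(seeds[0])]
    seen[tuple(seeds[0])] = True
    while stack:
        r, c = stack.pop()
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < GRID_SIZE and 0 <= cc < GRID_SIZE and grid[rr, cc] and not seen[rr, cc]:
                seen[rr, cc] = True
                stack.append((rr, cc))
    stranded = np.argwhere(grid & ~seen)
    if len(stranded):
        violations.append(Violation("DISCONNECTED", tuple(map(tuple, stranded))))
    return violations




def _pattern_score(grid: np.ndarray) -> int:
    """Vectorized count of local pattern defects (no connectivity check):
    dead ends, cross roads, white/black patches and checkers."""
    ncount = _path_neighbor_count(grid)
    dead = int((grid & (ncount <= 1)).sum())
    cross = int((grid & (ncount == 4)).sum())
    a, b = grid[:-1, :-1], grid[:-1, 1:]
    c, d = grid[1:, :-1], grid[1:, 1:]
    white = int((a & b & c & d).sum())
    black = int((~a & ~b & ~c & ~d).sum())
    checker = int(((a == d) & (b == c) & (a != b)).sum())
    return dead + cross + white + black + checker


def _violation_score(grid: np.ndarray) -> int:
    """Vectorized total violation count (search objective): pattern defects
    plus a penalty per extra path component and a no-path penalty.

    The connectivity term only matters near convergence, so the (relatively
    expensive) component labeling is skipped while pattern defects remain.
    """
    if not grid.any():
        return GRID_SIZE * GRID_SIZE  # worst possible: force paths to appear
    score = _pattern_score(grid)
    if score > 2:
        return score
    n_components, _ = _ndimage_label(grid)
    return score + 3 * (n_components - 1)


def _ndimage_label(grid: np.ndarray) -> tuple[int, np.ndarray]:
    from scipy import ndimage

    labeled, n = ndimage.label(grid)
    return n, labeled


def generate_map(
    seed: int,
    map_id: int,
    symmetric: bool = False,
    max_restarts: int = 50,
    max_steps: int = 20000,
) -> MazeMap:
    """Search for a valid map by annealed stochastic local search.

    Starting from a random half-filled grid, single squares are flipped;
    flips that do not increase the total violation count are always accepted
    and worsening flips are accepted with a slowly cooling probability.  With
    ``symmetric=True`` the grid is kept invariant under 180-degree rotation
    (flips applied in point-symmetric pairs).  Deterministic given ``seed``
    and ``map_id``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, map_id, 0x6D617A65]))
    for _ in range(max_restarts):
        grid = rng.random((GRID_SIZE, GRID_SIZE)) < 0.5
        if symmetric:
            grid |= grid[::-1, ::-1]
        score = _violation_score(grid)
        for step in range(max_steps):
            if score == 0 and not check_map_constraints(grid):
                return MazeMap(map_id=map_id, grid=grid)
            temperature = max(0.05, 1.5 * (1.0 - step / max_steps))
            r, c = rng.integers(GRID_SIZE), rng.integers(GRID_SIZE)
            grid[r, c] = ~grid[r, c]
            if symmetric:
                grid[GRID_SIZE - 1 - r, GRID_SIZE - 1 - c] = grid[r, c]
            new_score = _violation_score(grid)
            if new_score <= score or rng.random() < np.exp((score - new_score) / temperature):
                score = new_score
            else:  # revert
                grid[r, c] = ~grid[r, c]
                if symmetric:
                    grid[GRID_SIZE - 1 - r, GRID_SIZE - 1 - c] = grid[r, c]
        if score == 0 and not check_map_constraints(grid):
            return MazeMap(map_id=map_id, grid=grid)
    raise MapGenerationError(
        f"no valid map found for seed={seed}, map_id={map_id} "
        f"after {max_restarts} restarts"
    )


#: in-process memo of selected study map sets (selection is expensive)
_STUDY_MAPS_CACHE: dict[tuple, list["MazeMap"]] = {}


def generate_study_maps(
    seed: int,
    n_maps: int = 3,
    symmetric: bool = False,
    min_bucket: int = 5,
    min_coverage: float = 0.60,
    max_candidates: int = 400,
) -> list[MazeMap]:
    """Generate maps rich enough to host a balanced scene-choice stimulus set.

    Valid random maps differ widely in how many squares can serve as legally
    flippable distracter targets.  Candidate maps are therefore screened:
    every (view part, path/wall status) bucket of legal state sequences must
    hold at least ``min_bucket`` entries, and the squares reachable as
    post-move positions must cover at least ``min_coverage`` of the path
    squares.  Returns ``n_maps`` maps relabeled with ids 1..n_maps.
    """
    cache_key = (seed, n_maps, symmetric, min_bucket, min_coverage)
    if cache_key in _STUDY_MAPS_CACHE:
        return [MazeMap(m.map_id, m.grid.copy()) for m in _STUDY_MAPS_CACHE[cache_key]]
    chosen: list[MazeMap] = []
    for k in range(max_candidates):
        maze = generate_map(seed=seed, map_id=1000 + k, symmetric=symmetric)
        flip_ok = _flip_feasible_cells(maze)
        if not (flip_ok & maze.grid).any() or not (flip_ok & ~maze.grid).any():
            continue  # cheap prefilter: need flippable squares of both statuses
        catalog = _trial_catalog(maze)
        if min(len(v) for v in catalog.values()) < min_bucket:
            continue
        cells = {(post.row, post.col) for v in catalog.values() for _, _, post in v}
        if len(cells) / maze.n_paths < min_coverage:
            continue
        maze.map_id = len(chosen) + 1
        _CATALOG_CACHE[(maze.map_id, maze.grid.tobytes())] = catalog
        chosen.append(maze)
        if len(chosen) == n_maps:
            _STUDY_MAPS_CACHE[cache_key] = [MazeMap(m.map_id, m.grid.copy())
                                            for m in chosen]
            return chosen
    raise MapGenerationError(
        f"only {len(chosen)} of {n_maps} sufficiently rich maps found in "
        f"{max_candidates} candidates (seed={seed})"
    )


# ---------------------------------------------------------------------------
# poses, movements and scene views
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Pose:
    """Position and body orientation on a map (0-based row/col, row 0 on top)."""

    row: int
    col: int
    heading: str

    def __post_init__(self) -> None:
        if self.heading not in HEADINGS:
            raise ValueError(f"heading must be one of {HEADINGS}")


@dataclass(frozen=True)
class SceneView:
    """Wall status (True = path) of the five squares visible from a pose."""

    left: bool
    right: bool
    fwd_left: bool
    fwd_center: bool
    fwd_right: bool

    def part(self, part: str) -> bool:
        return {"FL": self.fwd_left, "FC": self.fwd_center, "FR": self.fwd_right}[part]

    def with_part_flipped(self, part: str) -> "SceneView":
        fld = {"FL": "fwd_left", "FC": "fwd_center", "FR": "fwd_right"}[part]
        return dataclasses.replace(self, **{fld: not getattr(self, fld)})


def _relative_cells(pose: Pose) -> dict[str, tuple[int, int]]:
    """Grid coordinates of the five visible squares relative to a pose."""
    dr, dc = _FWD_DELTA[pose.heading]
    lr, lc = _FWD_DELTA[_LEFT_OF[pose.heading]]
    r, c = pose.row, pose.col
    return {
        "left": (r + lr, c + lc),
        "right": (r - lr, c - lc),
        "fwd_left": (r + dr + lr, c + dc + lc),
        "fwd_center": (r + dr, c + dc),
        "fwd_right": (r + dr - lr, c + dc - lc),
    }


def view_part_cell(pose: Pose, part: str) -> tuple[int, int]:
    """Map coordinates of one forward view part as seen from ``pose``."""
    cells = _relative_cells(pose)
    return {"FL": cells["fwd_left"], "FC": cells["fwd_center"], "FR": cells["fwd_right"]}[part]


def observe_scene(maze: MazeMap, pose: Pose) -> SceneView:
    """The five-square scene visible from a pose; off-grid squares are walls."""
    if not maze.is_path(pose.row, pose.col):
        raise ValueError(f"pose {pose} is not on a path square")
    cells = _relative_cells(pose)
    return SceneView(**{name: maze.is_path(*rc) for name, rc in cells.items()})


def apply_movement(pose: Pose, movement: str, maze: MazeMap) -> Pose:
    """Apply one movement: turns rotate in place, FWD advances one square."""
    if movement == "TURN_L":
        return dataclasses.replace(pose, heading=_LEFT_OF[pose.heading])
    if movement == "TURN_R":
        return dataclasses.replace(pose, heading=_RIGHT_OF[pose.heading])
    if movement == "FWD":
        dr, dc = _FWD_DELTA[pose.heading]
        nr, nc = pose.row + dr, pose.col + dc
        if not maze.is_path(nr, nc):
            raise InvalidMovementError(
                f"forward move from {pose} hits a wall or leaves the grid"
            )
        return Pose(nr, nc, pose.heading)
    raise ValueError(f"unknown movement {movement!r}")


def _effective_movements(maze: MazeMap, pose: Pose) -> list[str]:
    """Movements that change the observable state; turns are always legal."""
    out = ["TURN_L", "TURN_R"]
    dr, dc = _FWD_DELTA[pose.heading]
    if maze.is_path(pose.row + dr, pose.col + dc):
        out.insert(0, "FWD")
    return out


# ---------------------------------------------------------------------------
# trials
# ---------------------------------------------------------------------------

@dataclass
class Trial:
    """One scene-choice trial.

    Behavioral fields (``outcome``, ``chosen_part_value``, ``rt_z``) are filled
    by :func:`simulate_behavior`; ``outcome`` is one of CORRECT / INCORRECT /
    MISS.
    """

    trial_id: int
    session_id: int
    map_id: int
    initial_pose: Pose
    movements: tuple[str, str, str]
    delay_s: int
    post_pose: Pose
    correct_scene: SceneView
    distracter: SceneView
    flipped_part: str
    target_position: str  # screen slot of the correct option: UP or DOWN
    outcome: str | None = None
    rt_z: float | None = None

    @property
    def chosen_scene(self) -> SceneView | None:
        if self.outcome == "CORRECT":
            return self.correct_scene
        if self.outcome == "INCORRECT":
            return self.distracter
        return None

    @property
    def set_key(self) -> tuple:
        """Uniqueness key of the stimulus set underlying this trial."""
        return (
            self.map_id,
            (self.initial_pose.row, self.initial_pose.col, self.initial_pose.heading),
            self.movements,
            self.flipped_part,
        )


@dataclass
class LabelVector:
    """The 12 binary status codes of one trial (1 = positive)."""

    upcoming: tuple[int, int, int]
    observed: tuple[int, int]
    position: tuple[int, int, int, int]
    map_code: tuple[int, int, int]

    def to_array(self) -> np.ndarray:
        return np.array(self.upcoming + self.observed + self.position + self.map_code)

    def as_dict(self) -> dict[str, int]:
        return dict(zip(CODE_NAMES, self.to_array().tolist()))


def derive_trial_labels(trial: Trial, maps: Sequence[MazeMap]) -> LabelVector:
    """Derive all 12 binary codes from the post-move state of a trial.

    Position codes use the 7-square grid's middle row/column (index 3) as the
    boundary, so a middle-row pose is both upper and lower, and likewise for
    the middle column.
    """
    maze = next(m for m in maps if m.map_id == trial.map_id)
    scene = observe_scene(maze, trial.post_pose)
    r, c = trial.post_pose.row, trial.post_pose.col
    mid = GRID_SIZE // 2
    return LabelVector(
        upcoming=(int(scene.fwd_left), int(scene.fwd_center), int(scene.fwd_right)),
        observed=(int(scene.left), int(scene.right)),
        position=(int(r <= mid), int(r >= mid), int(c <= mid), int(c >= mid)),
        map_code=tuple(int(trial.map_id == m) for m in (1, 2, 3)),
    )


def make_distracter(
    maze: MazeMap,
    post_pose: Pose,
    correct_scene: SceneView,
    rng: np.random.Generator,
    part_weights: Mapping[str, float] | None = None,
) -> tuple[SceneView, str]:
    """Flip one feasible forward view part of the correct scene.

    A flip is feasible when the flipped square lies inside the grid and the
    map copy with that square flipped shows no new dead end, cross road,
    white/black patch or checker pattern.  ``part_weights`` biases the draw
    among feasible parts (used for counterbalancing).  Raises
    :class:`DistracterInfeasibleError` when no part can be flipped.
    """
    feasible = [p for p in VIEW_PARTS if distracter_feasible(maze, post_pose, p)]
    if not feasible:
        raise DistracterInfeasibleError(f"no feasible flip at pose {post_pose}")
    if part_weights is None:
        weights = np.ones(len(feasible))
    else:
        weights = np.array([max(part_weights.get(p, 0.0), 0.0) for p in feasible])
        if weights.sum() <= 0:
            weights = np.ones(len(feasible))
    part = feasible[rng.choice(len(feasible), p=weights / weights.sum())]
    return correct_scene.with_part_flipped(part), part


def distracter_feasible(maze: MazeMap, post_pose: Pose, part: str) -> bool:
    """Whether flipping ``part`` of the upcoming scene keeps the map clean."""
    r, c = view_part_cell(post_pose, part)
    if not (0 <= r < GRID_SIZE and 0 <= c < GRID_SIZE):
        return False  # the wall surround cannot be flipped
    flipped = maze.grid.copy()
    flipped[r, c] = ~flipped[r, c]
    return _pattern_score(flipped) == 0


@dataclass
class TaskConfig:
    """Stimulus-set generation parameters.

    Defaults reproduce the study design: 5 sessions of 64 trials, 60 of which
    have the analyzable 5 s delay (the remaining 4 carry 1 s / 3 s jitter
    delays), flipped view parts counterbalanced, and the wall rate of each
    target view part steered to ~0.5 by sampling against a balanced wall/path
    deck.
    """

    sessions: int = 5
    trials_per_session: int = 64
    delay5_per_session: int = 60
    coverage_min: float = 0.6
    max_trial_retries: int = 4000
    max_set_retries: int = 5


def generate_trial_set(
    maps: Sequence[MazeMap],
    config: TaskConfig | None = None,
    seed: int = 0,
) -> list[Trial]:
    """Generate a full multi-session stimulus set under the balance criteria.

    Per trial the generator draws (map, initial pose, two movements) such that
    every movement is effective, the third (forward) movement is legal, the
    assigned view part can be flipped legally, and the target part's true
    status matches a pre-shuffled balanced wall/path deck.  Flipped parts and
    maps follow shuffled round-robin assignments, so their counts differ by at
    most one over the set; trial order is randomized within session.
    """
    config = config or TaskConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x747269616C]))
    n_total = config.sessions * config.trials_per_session

    coverage = float("nan")
    for attempt in range(config.max_set_retries):
        trials = _generate_trials_once(maps, config, rng, n_total)
        if trials is None:
            continue
        coverage = _position_coverage(trials, maps)
        if coverage >= config.coverage_min:
            return trials
    raise TrialGenerationError(
        f"could not satisfy balance criteria after {config.max_set_retries} "
        f"attempts (last post-move position coverage {coverage:.2f} "
        f"< {config.coverage_min})"
    )


def _balanced_deck(n: int, rng: np.random.Generator) -> list[bool]:
    deck = [WALL] * (n // 2) + [PATH] * (n // 2)
    if n % 2:
        deck.append(PATH if rng.random() < 0.5 else WALL)
    rng.shuffle(deck)
    return deck


def _session_assignment(values, n, offset, rng):
    """Shuffled round-robin draw of ``n`` items, rotated by ``offset`` so
    remainders spread evenly across sessions."""
    out = [values[(i + offset) % len(values)] for i in range(n)]
    rng.shuffle(out)
    return out


def _flip_feasible_cells(maze: MazeMap) -> np.ndarray:
    """Boolean 7x7 mask: flipping this square keeps the map pattern-clean."""
    ok = np.zeros((GRID_SIZE, GRID_SIZE), dtype=bool)
    for r in range(GRID_SIZE):
        for c in range(GRID_SIZE):
            flipped = maze.grid.copy()
            flipped[r, c] = ~flipped[r, c]
            ok[r, c] = _pattern_score(flipped) == 0
    return ok


#: memo of state-sequence catalogs keyed by (map_id, grid bytes)
_CATALOG_CACHE: dict[tuple[int, bytes], dict] = {}


def _trial_catalog(maze: MazeMap) -> dict[tuple[str, bool], list]:
    """All legal state sequences of a map, bucketed by (part, part status).

    Enumerates every (initial pose, movement 1, movement 2) with effective
    movements and a legal third forward move, then records, per view part of
    the post-move scene, whether the part's square can be flipped legally.
    Each bucket entry is ``(pose0, (m1, m2, 'FWD'), post_pose)``.
    """
    key = (maze.map_id, maze.grid.tobytes())
    if key in _CATALOG_CACHE:
        return _CATALOG_CACHE[key]
    flip_ok = _flip_feasible_cells(maze)
    catalog: dict[tuple[str, bool], list] = {
        (p, s): [] for p in VIEW_PARTS for s in (PATH, WALL)
    }
    for r, c in np.argwhere(maze.grid):
        for heading in HEADINGS:
            pose = Pose(int(r), int(c), heading)
            for m1 in _effective_movements(maze, pose):
                p1 = apply_movement(pose, m1, maze)
                for m2 in _effective_movements(maze, p1):
                    p2 = apply_movement(p1, m2, maze)
                    try:
                        post = apply_movement(p2, "FWD", maze)
                    except InvalidMovementError:
                        continue  # third movement must be effective
                    for part in VIEW_PARTS:
                        pr, pc = view_part_cell(post, part)
                        if not (0 <= pr < GRID_SIZE and 0 <= pc < GRID_SIZE):
                            continue
                        if flip_ok[pr, pc]:
                            status = bool(maze.grid[pr, pc])
                            catalog[(part, status)].append((pose, (m1, m2, "FWD"), post))
    _CATALOG_CACHE[key] = catalog
    return catalog


def _generate_trials_once(maps, config, rng, n_total):
    by_id = {m.map_id: m for m in maps}
    catalogs = {m.map_id: _trial_catalog(m) for m in maps}

    trials: list[Trial] = []
    visited: set[tuple[int, int, int]] = set()  # (map_id, row, col) post cells
    idx = 0
    for session in range(1, config.sessions + 1):
        # per-session counterbalancing of flipped parts and maps, and a
        # per-session balanced wall/path deck for each part's target status
        parts = _session_assignment(VIEW_PARTS, config.trials_per_session,
                                    session - 1, rng)
        map_ids = _session_assignment([m.map_id for m in maps],
                                      config.trials_per_session, session - 1, rng)
        decks = {p: _balanced_deck(parts.count(p), rng) for p in VIEW_PARTS}
        deck_pos = {p: 0 for p in VIEW_PARTS}
        n_jitter = config.trials_per_session - config.delay5_per_session
        delays = [5] * config.delay5_per_session + [1 if i % 2 == 0 else 3 for i in range(n_jitter)]
        rng.shuffle(delays)
        for j, delay in enumerate(delays):
            part = parts[j]
            maze = by_id[map_ids[j]]
            want = decks[part][deck_pos[part]]
            bucket = catalogs[maze.map_id][(part, want)]
            if not bucket:  # desired status infeasible on this map: accept either
                bucket = (catalogs[maze.map_id][(part, PATH)]
                          + catalogs[maze.map_id][(part, WALL)])
            if not bucket:
                return None
            # prefer sequences ending on a not-yet-visited square (diversity)
            draws = rng.integers(len(bucket), size=6)
            pose0, movements, post = bucket[draws[0]]
            for d in draws:
                cand = bucket[d]
                if (maze.map_id, cand[2].row, cand[2].col) not in visited:
                    pose0, movements, post = cand
                    break
            visited.add((maze.map_id, post.row, post.col))
            scene = observe_scene(maze, post)
            trials.append(Trial(
                trial_id=idx + 1,
                session_id=session,
                map_id=maze.map_id,
                initial_pose=pose0,
                movements=movements,
                delay_s=delay,
                post_pose=post,
                correct_scene=scene,
                distracter=scene.with_part_flipped(part),
                flipped_part=part,
                target_position="UP" if rng.random() < 0.5 else "DOWN",
            ))
            deck_pos[part] += 1
            idx += 1
    return trials


def _position_coverage(trials: list[Trial], maps: Sequence[MazeMap]) -> float:
    visited = {(t.map_id, t.post_pose.row, t.post_pose.col) for t in trials}
    n_path = sum(m.n_paths for m in maps)
    return len(visited) / n_path


# ---------------------------------------------------------------------------
# simulated behavior
# ---------------------------------------------------------------------------

@dataclass
class BehaviorModel:
    """Stochastic choice/RT model of a practiced participant.

    Defaults emulate the reported behavioral pattern: ~93% correct overall,
    ~1% missed, with forward-center flipped trials slightly more accurate and
    faster than forward-left/right ones.  RTs are drawn lognormal per view
    part and z-scored within session.
    """

    p_correct_by_part: Mapping[str, float] = field(
        default_factory=lambda: {"FL": 0.93, "FC": 0.97, "FR": 0.93}
    )
    p_miss: float = 0.01
    rt_location: Mapping[str, float] = field(
        default_factory=lambda: {"FL": -0.15, "FC": -0.30, "FR": -0.15}
    )
    rt_scale: Mapping[str, float] = field(
        default_factory=lambda: {"FL": 0.25, "FC": 0.25, "FR": 0.25}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for p, v in self.p_correct_by_part.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"p_correct_by_part[{p}]={v} outside [0, 1]")
        if not 0.0 <= self.p_miss <= 1.0:
            raise ValueError(f"p_miss={self.p_miss} outside [0, 1]")


def simulate_behavior(trials: Iterable[Trial], model: BehaviorModel) -> list[Trial]:
    """Draw outcomes and z-scored reaction times for every trial, in place.

    A miss is drawn first with ``p_miss``; otherwise the trial is CORRECT with
    the view-part-specific probability, else INCORRECT (the distracter was
    chosen).  Raw lognormal RTs are z-scored within each session over non-miss
    trials.
    """
    trials = list(trials)
    rng = np.random.default_rng(np.random.SeedSequence([model.seed, 0x626568]))
    raw_rt: dict[int, float] = {}
    for t in trials:
        if rng.random() < model.p_miss:
            t.outcome = "MISS"
            t.rt_z = None
            continue
        p = model.p_correct_by_part[t.flipped_part]
        t.outcome = "CORRECT" if rng.random() < p else "INCORRECT"
        raw_rt[t.trial_id] = float(
            np.exp(model.rt_location[t.flipped_part]
                   + model.rt_scale[t.flipped_part] * rng.standard_normal())
        )
    for session in sorted({t.session_id for t in trials}):
        ids = [t.trial_id for t in trials
               if t.session_id == session and t.trial_id in raw_rt]
        if not ids:
            continue
        vals = np.array([raw_rt[i] for i in ids])
        sd = vals.std()
        z = (vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals)
        zmap = dict(zip(ids, z))
        for t in trials:
            if t.trial_id in zmap:
                t.rt_z = float(zmap[t.trial_id])
    return trials


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

def trials_to_frame(trials: Sequence[Trial], maps: Sequence[MazeMap]) -> pd.DataFrame:
    """One row per trial: design columns, the 12 truth codes and, for the
    upcoming view, the codes of the scene the participant actually chose
    (identical to truth on correct trials, distracter codes on incorrect
    ones, NA on misses)."""
    rows = []
    for t in trials:
        labels = derive_trial_labels(t, maps)
        row = {
            "trial_id": t.trial_id,
            "session_id": t.session_id,
            "map_id": t.map_id,
            "init_row": t.initial_pose.row,
            "init_col": t.initial_pose.col,
            "init_heading": t.initial_pose.heading,
            "move1": t.movements[0],
            "move2": t.movements[1],
            "move3": t.movements[2],
            "delay_s": t.delay_s,
            "post_row": t.post_pose.row,
            "post_col": t.post_pose.col,
            "post_heading": t.post_pose.heading,
            "flipped_part": t.flipped_part,
            "target_position": t.target_position,
            "outcome": t.outcome,
            "rt_z": t.rt_z,
        }
        row.update(labels.as_dict())
        chosen = t.chosen_scene
        for name, part in zip(CHOSEN_CODE_NAMES, VIEW_PARTS):
            row[name] = int(chosen.part(part)) if chosen is not None else pd.NA
        rows.append(row)
    return pd.DataFrame(rows)


def write_trials_tsv(path, trials: Sequence[Trial], maps: Sequence[MazeMap]) -> None:
    trials_to_frame(trials, maps).to_csv(path, sep="\t", index=False)


def read_trials_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
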