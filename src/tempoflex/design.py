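"""Stimulus-design construction for duration-discrimination and paced-tapping sessions.

Two experiment profiles are supported:

* Experiment 1: a 200–998 ms inter-onset-interval (IOI) grid in 2 ms steps
  (400 rates), ten comparison-deviation (DEV) levels of ±2/7/11/16/20 %
  assigned once per 10-IOI bin, presented either in a *linear* order
  (monotone ±4 ms ramps) or a *random-alternating* order (ΔIOI maximized,
  sign alternating every trial), blocked as 50 + 7×51 = 407 trials where
  the first trial of blocks 2–8 repeats the previous block's last IOI.
* Experiment 2: an 81-rate 200–1000 ms grid in 10 ms steps, fixed DEV of
  ±13 % with complementary signs across two blocks, and a paced-tapping
  session that reuses the identical rate order.

All randomization goes through an explicit :class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IoiGrid",
    "TrialSpec",
    "SessionPlan",
    "TrialTimeline",
    "DesignError",
    "EXP1_DEV_LEVELS",
    "build_ioi_grid",
    "exp1_grid",
    "exp2_grid",
    "assign_dev",
    "linear_order",
    "random_alternating_order",
    "blockify",
    "exp1_session_plan",
    "exp2_matched_design",
    "continuation_allowance",
    "trial_timeline",
    "counterbalance",
]

#: Signed DEV levels used in Experiment 1 (±2, 7, 11, 16, 20 %).
EXP1_DEV_LEVELS: tuple[float, ...] = (
    -0.20, -0.16, -0.11, -0.07, -0.02, 0.02, 0.07, 0.11, 0.16, 0.20,
)


class DesignError(ValueError):
    """Raised when a stimulus design request is internally inconsistent."""


@dataclass(frozen=True)
class IoiGrid:
    """Evenly spaced pool of stimulus inter-onset intervals (ms)."""

    start_ms: float
    stop_ms: float
    step_ms: float
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class TrialSpec:
    """One planned trial."""

    trial_index: int  # 1-based, continuous across blocks
    block: int  # 1-based
    ioi_ms: float
    dev: float | None  # signed proportion; None for tapping trials
    is_boundary_repeat: bool = False
    task: str = "discrimination"  # or "paced_tapping"


@dataclass
class SessionPlan:
    """Ordered trial plan for one session of one task."""

    session_type: str
    trials: list[TrialSpec]
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    @property
    def analyzed_iois(self) -> np.ndarray:
        """IOIs of non-boundary-repeat trials, in presentation order."""
        return np.array(
            [t.ioi_ms for t in self.trials if not t.is_boundary_repeat]
        )

    @property
    def presented_iois(self) -> np.ndarray:
        return np.array([t.ioi_ms for t in self.trials])


@dataclass(frozen=True)
class TrialTimeline:
    """Stimulus onset times (ms, trial-relative) for one discrimination trial.

    The standard is five sounds (four intervals of ``ioi_ms``); a silent gap
    of six IOIs separates the last standard onset from the first comparison
    onset; the comparison pair spans ``ioi_ms * (1 + dev)``.
    """

    standard_onsets: tuple[float, ...]
    gap_ms: float
    comparison_onsets: tuple[float, float]
    comparison_interval_ms: float


def build_ioi_grid(start_ms: float, stop_ms: float, step_ms: float) -> IoiGrid:
    """Build an inclusive, evenly spaced IOI grid.

    Raises :class:`DesignError` if the step is non-positive or does not
    divide the span.
    """
    if step_ms <= 0 or start_ms <= 0:
        raise DesignError("IOI grid requires positive start and step")
    if stop_ms < start_ms:
        raise DesignError("IOI grid requires start_ms <= stop_ms")
    span = stop_ms - start_ms
    n_steps = round(span / step_ms)
    if abs(n_steps * step_ms - span) > 1e-9:
        raise DesignError(
            f"step {step_ms} does not divide the span {start_ms}..{stop_ms}"
        )
    values = start_ms + step_ms * np.arange(n_steps + 1)
    return IoiGrid(start_ms, stop_ms, step_ms, values)


def exp1_grid() -> IoiGrid:
    """The Experiment 1 pool: 200–998 ms in 2 ms steps (400 rates)."""
    return build_ioi_grid(200.0, 998.0, 2.0)


def exp2_grid() -> IoiGrid:
    """The Experiment 2 pool: 200–1000 ms in 10 ms steps (81 rates)."""
    return build_ioi_grid(200.0, 1000.0, 10.0)


def assign_dev(
    grid: IoiGrid,
    dev_levels=EXP1_DEV_LEVELS,
    rng: np.random.Generator | None = None,
) -> dict[float, float]:
    """Assign one DEV level to each grid IOI, balanced within consecutive bins.

    The grid is divided into ``len(grid)/len(dev_levels)`` bins of consecutive
    IOIs; within each bin the DEV levels appear as a random permutation, so
    each level occurs the same number of times globally.
    """
    rng = np.random.default_rng() if rng is None else rng
    k = len(dev_levels)
    if len(grid) % k != 0:
        raise DesignError(
            f"grid size {len(grid)} not divisible by {k} DEV levels"
        )
    mapping: dict[float, float] = {}
    levels = np.asarray(dev_levels, dtype=float)
    for b in range(len(grid) // k):
        perm = rng.permutation(levels)
        for ioi, dev in zip(grid.values[b * k : (b + 1) * k], perm):
            mapping[float(ioi)] = float(dev)
    return mapping


def linear_order(grid: IoiGrid, start_mode: str = "fast_start") -> np.ndarray:
    """Monotone two-ramp order covering every grid value exactly once.

    ``fast_start`` ascends ``start, start+2*step, ...`` to ``stop - step`` and
    then descends ``stop, stop-2*step, ...`` to ``start + step``; every ΔIOI
    within a ramp is ``±2*step`` (±4 ms on the Experiment 1 grid).
    ``slow_start`` is the mirror image (``start+stop`` minus the fast-start
    sequence), beginning at the slowest rate.
    """
    if len(grid) % 2 != 0:
        raise DesignError("linear order requires an even-sized grid")
    v = grid.values
    fast = np.concatenate([v[0::2], v[::-1][0::2]])
    if start_mode == "fast_start":
        return fast
    if start_mode == "slow_start":
        return grid.start_ms + grid.stop_ms - fast
    raise DesignError(f"unknown start_mode {start_mode!r}")


def random_alternating_order(
    grid: IoiGrid, rng: np.random.Generator
) -> np.ndarray:
    """Random order with strictly alternating ΔIOI sign and large |ΔIOI|.

    The grid is split at its median into a fast (short-IOI) and a slow
    (long-IOI) half; values are drawn without replacement, alternating
    halves. Because every fast value is below every slow value, the sign of
    the trial-to-trial rate change alternates by construction and every
    |ΔIOI| is at least one grid step. For even grids the starting half is
    random; for odd grids the fast half holds the median value and starts.
    """
    n = len(grid)
    if n < 2:
        raise DesignError("alternating order needs at least two grid values")
    n_fast = (n + 1) // 2
    fast = rng.permutation(grid.values[:n_fast])
    slow = rng.permutation(grid.values[n_fast:])
    if n % 2 == 0 and rng.random() < 0.5:
        fast, slow = slow, fast
    out = np.empty(n)
    out[0::2] = fast
    out[1::2] = slow
    return out


def blockify(
    sequence: np.ndarray,
    first_block: int = 50,
    later_block: int = 51,
    n_blocks: int = 8,
    task: str = "discrimination",
    dev_map: dict[float, float] | None = None,
) -> list[TrialSpec]:
    """Split an IOI sequence into blocks with boundary-repeat first trials.

    Blocks 2..n start with a flagged repeat of the previous block's last
    IOI, so the analyzed (unflagged) trials reproduce the input sequence and
    between-trial histories are preserved across block breaks.
    """
    n = len(sequence)
    expected = first_block + (later_block - 1) * (n_blocks - 1)
    if expected != n:
        raise DesignError(
            f"block arithmetic mismatch: {first_block} + "
            f"({later_block}-1)x{n_blocks - 1} = {expected} != {n} trials"
        )

    def make(idx, block, ioi, repeat):
        dev = None
        if task == "discrimination":
            dev = dev_map[float(ioi)] if dev_map is not None else 0.0
        return TrialSpec(idx, block, float(ioi), dev, repeat, task)

    trials: list[TrialSpec] = []
    pos = 0
    t_idx = 1
    for block in range(1, n_blocks + 1):
        if block > 1:
            trials.append(make(t_idx, block, trials[-1].ioi_ms, True))
            t_idx += 1
        take = first_block if block == 1 else later_block - 1
        for ioi in sequence[pos : pos + take]:
            trials.append(make(t_idx, block, ioi, False))
            t_idx += 1
        pos += take
    return trials


def exp1_session_plan(
    session_type: str,
    rng: np.random.Generator,
    start_mode: str = "fast_start",
    seed: int | None = None,
) -> SessionPlan:
    """Full Experiment 1 discrimination session (407 trials, 8 blocks).

    ``session_type`` is ``"linear"`` (monotone ±4 ms ramps; ``start_mode``
    selects the fast- or slow-start counterbalancing arm) or ``"random"``
    (maximized, sign-alternating ΔIOI).
    """
    grid = exp1_grid()
    dev_map = assign_dev(grid, EXP1_DEV_LEVELS, rng)
    if session_type == "linear":
        seq = linear_order(grid, start_mode)
        label = f"linear_{start_mode}"
    elif session_type == "random":
        seq = random_alternating_order(grid, rng)
        label = "random_alternating"
    else:
        raise DesignError(f"unknown session_type {session_type!r}")
    trials = blockify(seq, 50, 51, 8, "discrimination", dev_map)
    return SessionPlan(label, trials, seed=seed, extra={"grid": grid})


def continuation_allowance(ioi_ms: float) -> float:
    """Allowed continuation-tapping duration in the paced-tapping task.

    Seven IOIs for fast stimuli (IOI < 300 ms), six otherwise. The boundary
    IOI of exactly 300 ms takes the slower (6×) allowance.
    """
    return 7.0 * ioi_ms if ioi_ms < 300.0 else 6.0 * ioi_ms


def exp2_matched_design(
    rng: np.random.Generator, seed: int | None = None
) -> tuple[SessionPlan, SessionPlan]:
    """Matched Experiment 2 discrimination and paced-tapping plans.

    One random-alternating order over the 81-rate grid is generated per call;
    the discrimination session presents it twice (two blocks) with DEV of
    ±0.13 randomly signed per rate in block 1 and the complementary sign in
    block 2, and the tapping session presents the identical order once, each
    trial carrying its continuation allowance.
    """
    grid = exp2_grid()
    order = random_alternating_order(grid, rng)
    signs = rng.choice([-1.0, 1.0], size=len(order))
    disc: list[TrialSpec] = []
    idx = 1
    for block, flip in ((1, 1.0), (2, -1.0)):
        for ioi, s in zip(order, signs):
            disc.append(
                TrialSpec(idx, block, float(ioi), float(0.13 * s * flip),
                          False, "discrimination")
            )
            idx += 1
    tap = [
        TrialSpec(i + 1, 1, float(ioi), None, False, "paced_tapping")
        for i, ioi in enumerate(order)
    ]
    disc_plan = SessionPlan("exp2_matched", disc, seed=seed,
                            extra={"grid": grid})
    tap_plan = SessionPlan(
        "exp2_matched", tap, seed=seed,
        extra={"grid": grid,
               "allowance_ms": [continuation_allowance(i) for i in order]},
    )
    return disc_plan, tap_plan


def trial_timeline(ioi_ms: float, dev: float) -> TrialTimeline:
    """Onset times for one discrimination trial.

    Five standard onsets spaced at the IOI, a silent gap of six IOIs, then
    the comparison pair spanning ``ioi_ms * (1 + dev)``.
    """
    if ioi_ms <= 0:
        raise DesignError("ioi_ms must be positive")
    if abs(dev) >= 1:
        raise DesignError("|dev| must be < 1")
    standard = tuple(ioi_ms * k for k in range(5))
    gap = 6.0 * ioi_ms
    first_cmp = standard[-1] + gap
    cmp_interval = ioi_ms * (1.0 + dev)
    return TrialTimeline(standard, gap, (first_cmp, first_cmp + cmp_interval),
                         cmp_interval)


def counterbalance(participant_index: int) -> dict[str, str]:
    """Deterministic cohort counterbalancing of start mode and session order.

    Cycles through the four combinations of linear-session start mode and
    session order by participant index.
    """
    start_mode = "fast_start" if participant_index % 2 == 0 else "slow_start"
    order = (
        ("linear", "random")
        if (participant_index // 2) % 2 == 0
        else ("random", "linear")
    )
    return {"start_mode": start_mode, "session_order": order}
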