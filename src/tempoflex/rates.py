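"""Preferred-rate estimation and harmonic-correspondence statistics.

The preferred rate of a participant is estimated as the stimulus
inter-onset interval (IOI) at which task performance peaks: accuracy for
duration discrimination (maximum), absolute tempo-matching error |TME| for
paced tapping (minimum). Performance is first smoothed along the IOI axis
with a Gaussian-weighted moving average whose window size is optimized so
that every participant's smoothed curve has a unique global extremum.

Correspondence between two sets of estimates that may be related 1:1, 2:1
or 1:2 (octave harmonics) is tested with two permutation statistics:

* the *harmonic residual* test — summed perpendicular distance of the
  (x, y) estimate pairs to the closest of the y=x, y=2x, y=x/2 lines;
* the *modular diversion* test — median of ``mod(slow, fast)/fast`` across
  pairs, measuring proportional deviation from an exact integer multiple.

Both compare the observed statistic against a null built by shuffling the
y values, counting the fraction of null statistics *strictly smaller* than
the observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .flexibility import fit_logistic

__all__ = [
    "PreferredRateEstimate",
    "PermutationResult",
    "WindowOptimizationError",
    "gaussian_smooth",
    "optimize_window",
    "preferred_rate_from_curve",
    "curve_from_trials",
    "harmonic_residual",
    "harmonic_permutation_test",
    "modular_diversion",
    "modular_permutation_test",
    "detuning_dataset",
    "detuning_slopes",
    "motor_component",
    "stepsize_scan",
]


@dataclass(frozen=True)
class PreferredRateEstimate:
    """A per-participant preferred-rate estimate (ms) and how it was obtained."""

    estimate_ms: float
    window: int
    objective: str  # "max_accuracy" | "min_abs_tme" | "median_iti" | ...
    task: str = ""
    participant_id: str = ""


@dataclass(frozen=True)
class PermutationResult:
    """Observed statistic, permutation null, and strict-smaller p-value."""

    observed_stat: float
    null_stats: np.ndarray
    p: float
    n_perm: int
    seed: int | None = None


class WindowOptimizationError(RuntimeError):
    """No window in the search range yields a unique extremum for everyone."""


def _kernel_offsets(window: int) -> np.ndarray:
    # Centered window; for even sizes the extra sample precedes the center
    # (moving-window convention of the original analysis tool).
    if window % 2 == 1:
        half = (window - 1) // 2
        return np.arange(-half, half + 1)
    half = window // 2
    return np.arange(-half, half)


def gaussian_smooth(values, window: int) -> np.ndarray:
    """Gaussian-weighted moving average with edge renormalization.

    The kernel is a Gaussian of SD ``window / 5`` truncated to the window;
    at the series edges the weights are renormalized over the in-bounds
    samples. ``window=1`` returns the input unchanged.
    """
    x = np.asarray(values, dtype=float)
    if len(x) == 0:
        raise ValueError("cannot smooth an empty series")
    if window < 1:
        raise ValueError("window must be >= 1")
    if window == 1:
        return x.copy()
    offsets = _kernel_offsets(window)
    sd = window / 5.0
    w = np.exp(-0.5 * (offsets / sd) ** 2)
    n = len(x)
    num = np.zeros(n)
    den = np.zeros(n)
    for off, wk in zip(offsets, w):
        lo_dst, hi_dst = max(0, -off), min(n, n - off)
        if lo_dst >= hi_dst:
            continue
        num[lo_dst:hi_dst] += wk * x[lo_dst + off : hi_dst + off]
        den[lo_dst:hi_dst] += wk
    return num / den


def _unique_extremum(smoothed: np.ndarray, objective: str, tol: float = 1e-12) -> bool:
    ext = smoothed.max() if objective == "max" else smoothed.min()
    return int(np.sum(np.abs(smoothed - ext) <= tol)) == 1


def optimize_window(
    curves: list[np.ndarray],
    w_min: int = 1,
    w_max: int | None = None,
    objective: str = "max",
    strict: bool = True,
) -> int:
    """Smallest window giving every curve a unique smoothed global extremum.

    ``curves`` holds one performance series per participant, already sorted
    by IOI. Values within 1e-12 of the extremum count as tied. Raises
    :class:`WindowOptimizationError` (with diagnostics) if no window in
    ``[w_min, w_max]`` qualifies; ``w_max`` defaults to a quarter of the
    shortest curve. With ``strict=False``, an exhaustive tie (e.g. a
    ceiling-performance curve that is 1 everywhere) falls back to the
    window with the fewest tied curves (smallest such window), with a
    warning, instead of raising — remaining ties are broken toward the
    smaller IOI downstream.
    """
    if w_min < 1:
        raise ValueError("w_min must be >= 1")
    if not curves:
        raise ValueError("no curves supplied")
    if w_max is None:
        w_max = max(w_min, min(len(c) for c in curves) // 4)
    tie_counts = []
    for w in range(w_min, w_max + 1):
        n_bad = sum(
            not _unique_extremum(gaussian_smooth(c, w), objective)
            for c in curves
        )
        if n_bad == 0:
            return w
        tie_counts.append((n_bad, w))
    if not strict and tie_counts:
        n_bad, w = min(tie_counts)
        warnings.warn(
            f"no window in [{w_min}, {w_max}] gives unique extrema for all "
            f"{len(curves)} curves; using window {w} ({n_bad} tied curves, "
            f"ties broken toward the smaller IOI)"
        )
        return w
    raise WindowOptimizationError(
        f"no window in [{w_min}, {w_max}] yields a unique global "
        f"{'maximum' if objective == 'max' else 'minimum'} for all "
        f"{len(curves)} curves (tried {len(tie_counts)} windows)"
    )


def preferred_rate_from_curve(
    ioi_sorted,
    values,
    window: int,
    objective: str = "max",
    task: str = "",
    participant_id: str = "",
) -> PreferredRateEstimate:
    """Preferred rate as the smoothed IOI at the smoothed-performance extremum.

    Both the performance values and the IOI axis are smoothed with the same
    window (so the estimate lives on the same smoothed scale); ties within
    1e-12 of the extremum are broken toward the smaller IOI.
    """
    ioi = np.asarray(ioi_sorted, dtype=float)
    val = np.asarray(values, dtype=float)
    if len(ioi) == 0 or len(ioi) != len(val):
        raise ValueError("ioi and values must be equal-length and non-empty")
    if np.any(np.diff(ioi) < 0):
        raise ValueError("ioi_sorted must be nondecreasing")
    s_val = gaussian_smooth(val, window)
    s_ioi = gaussian_smooth(ioi, window)
    ext = s_val.max() if objective == "max" else s_val.min()
    tied = np.flatnonzero(np.abs(s_val - ext) <= 1e-12)
    best = tied[np.argmin(s_ioi[tied])]
    name = "max_accuracy" if objective == "max" else "min_abs_tme"
    return PreferredRateEstimate(float(s_ioi[best]), window, name, task,
                                 participant_id)


def curve_from_trials(
    trials: pd.DataFrame,
    value_col: str = "accuracy",
    average_repeats: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """IOI-sorted performance curve from a trial table.

    Boundary-repeat trials (if flagged) are dropped; repeated presentations
    of the same IOI are averaged by default (as when two blocks present the
    same rates with complementary deviations).
    """
    df = trials
    if "is_boundary_repeat" in df.columns:
        df = df[~df["is_boundary_repeat"].astype(bool)]
    if average_repeats:
        g = df.groupby("ioi_ms", sort=True)[value_col].mean()
        return g.index.to_numpy(float), g.to_numpy(float)
    df = df.sort_values("ioi_ms", kind="stable")
    return df["ioi_ms"].to_numpy(float), df[value_col].to_numpy(float)


_HARMONIC_SLOPES = (1.0, 2.0, 0.5)


def harmonic_residual(x: float, y: float) -> float:
    """Perpendicular distance of (x, y) to the nearest harmonic line.

    ``min_k |k*x - y| / sqrt(k^2 + 1)`` over the lines y=x, y=2x, y=x/2.
    """
    if x <= 0 or y <= 0:
        raise ValueError("estimates must be positive")
    return min(abs(k * x - y) / np.sqrt(k * k + 1.0) for k in _HARMONIC_SLOPES)


def _summed_harmonic_residuals(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Summed residuals for each row of ``ys`` (2-D: one row per permutation)."""
    dists = np.stack(
        [np.abs(k * xs[None, :] - ys) / np.sqrt(k * k + 1.0)
         for k in _HARMONIC_SLOPES]
    )
    return dists.min(axis=0).sum(axis=1)


def _strict_smaller_p(observed: float, null: np.ndarray,
                      conservative: bool = False) -> float:
    b = int(np.sum(null < observed))
    if conservative:
        return (b + 1) / (len(null) + 1)
    return b / len(null)


def harmonic_permutation_test(
    xs,
    ys,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    conservative: bool = False,
) -> PermutationResult:
    """Permutation test of harmonic correspondence between paired estimates.

    Observed statistic: summed :func:`harmonic_residual` over pairs. The
    null shuffles ``ys`` against ``xs``; the p-value is the fraction of
    null sums strictly smaller than the observed sum (``conservative=True``
    uses the (b+1)/(n+1) variant).
    """
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    if len(xs) != len(ys):
        raise ValueError("xs and ys must have equal length")
    if len(xs) < 3:
        raise ValueError("need at least 3 pairs")
    rng = np.random.default_rng() if rng is None else rng
    observed = float(_summed_harmonic_residuals(xs, ys[None, :])[0])
    perms = np.stack([rng.permutation(ys) for _ in range(n_perm)])
    null = _summed_harmonic_residuals(xs, perms)
    return PermutationResult(observed, null,
                             _strict_smaller_p(observed, null, conservative),
                             n_perm)


def modular_diversion(fast: float, slow: float) -> tuple[float, float]:
    """Deviation of the slower estimate from a multiple of the faster one.

    Returns ``(slow mod fast, (slow mod fast) / fast)``; e.g. estimates of
    295 and 603 ms give 13 ms, a proportional diversion of ~4 %. Note the
    statistic is asymmetric: a value just *below* a multiple wraps to a
    large modulus.
    """
    if fast <= 0:
        raise ValueError("faster estimate must be positive")
    if fast > slow:
        raise ValueError("expected fast <= slow")
    abs_ms = float(np.mod(slow, fast))
    return abs_ms, abs_ms / fast


def _median_diversion(xs: np.ndarray, ys: np.ndarray) -> float:
    lo = np.minimum(xs, ys)
    hi = np.maximum(xs, ys)
    return float(np.median(np.mod(hi, lo) / lo))


def modular_permutation_test(
    xs,
    ys,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    conservative: bool = False,
) -> PermutationResult:
    """Permutation test on the median proportional modular diversion.

    Each pair contributes ``mod(max, min)/min``; the median (the diversion
    distribution is non-normal) is compared against the shuffled-``ys``
    null with strict-smaller counting.
    """
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    if len(xs) != len(ys):
        raise ValueError("xs and ys must have equal length")
    if len(xs) < 3:
        raise ValueError("need at least 3 pairs")
    rng = np.random.default_rng() if rng is None else rng
    observed = _median_diversion(xs, ys)
    null = np.array(
        [_median_diversion(xs, rng.permutation(ys)) for _ in range(n_perm)]
    )
    return PermutationResult(observed, null,
                             _strict_smaller_p(observed, null, conservative),
                             n_perm)


def detuning_dataset(
    trials: pd.DataFrame,
    preferred_ms: float,
    equal_to: str = "faster",
) -> pd.DataFrame:
    """Annotate trials with detuning side and within-side z-scored IOI.

    Trials with IOI below the preferred-rate estimate form the ``"faster"``
    side, above it the ``"slower"`` side (an IOI exactly equal to the
    estimate joins ``equal_to``). IOI is z-scored within each side. Sides
    with fewer than 2 trials are dropped with a warning.
    """
    df = trials.copy()
    if "is_boundary_repeat" in df.columns:
        df = df[~df["is_boundary_repeat"].astype(bool)].copy()
    faster = df["ioi_ms"] < preferred_ms
    if equal_to == "faster":
        faster |= df["ioi_ms"] == preferred_ms
    df["side"] = np.where(faster, "faster", "slower")
    keep = []
    for side in ("faster", "slower"):
        sub = df[df["side"] == side]
        if len(sub) < 2:
            warnings.warn(f"detuning side {side!r} has <2 trials; dropped")
            continue
        z = (sub["ioi_ms"] - sub["ioi_ms"].mean()) / sub["ioi_ms"].std(ddof=0)
        sub = sub.assign(z_ioi=z)
        keep.append(sub)
    return pd.concat(keep) if keep else df.iloc[0:0].assign(z_ioi=[])


def detuning_slopes(annotated: pd.DataFrame) -> tuple[float, float, float]:
    """Per-side logistic slopes of accuracy on z-scored IOI.

    Returns ``(slope_faster, slope_slower, avg_slope)`` where the slower
    side is sign-flipped before averaging (it quantifies an accuracy
    *decrease* past the preferred rate), so larger average slopes mean
    performance more sharply concentrated at the preferred rate.
    """
    slopes = {}
    for side in ("faster", "slower"):
        sub = annotated[annotated["side"] == side]
        if len(sub) < 2:
            raise ValueError(f"detuning side {side!r} missing")
        _, slope, _ = fit_logistic(sub["z_ioi"].to_numpy(),
                                   sub["accuracy"].to_numpy())
        slopes[side] = slope
    avg = (slopes["faster"] + (-slopes["slower"])) / 2.0
    return slopes["faster"], slopes["slower"], avg


def motor_component(
    smt_ms: float, tap_est_ms: float, disc_est_ms: float
) -> tuple[float, float]:
    """Difference scores isolating the motor slowing of preferred rates.

    Returns ``(paced tapping - discrimination, SMT - discrimination)``; a
    shared motor component makes the two scores correlate across people.
    """
    if min(smt_ms, tap_est_ms, disc_est_ms) <= 0:
        raise ValueError("estimates must be positive")
    return tap_est_ms - disc_est_ms, smt_ms - disc_est_ms


def stepsize_scan(
    sessions: dict[str, dict[str, pd.DataFrame]],
    steps=(4, 6, 8, 10, 12, 14, 16, 18, 20),
    value_col: str = "accuracy",
    w_max: int | None = None,
) -> pd.DataFrame:
    """Grid-coarsening scan for choosing a stimulus-rate step size.

    ``sessions`` maps participant id -> session label -> trial table on a
    fine IOI grid. For each candidate step the trials are downsampled to
    the sub-grid ``{min IOI, min+step, ...}``, preferred rates are
    re-estimated (window re-optimized per dataset collection), and two
    summed harmonic differences are reported: original vs downsampled
    estimates, and downsampled session 1 vs session 2. Steps incompatible
    with the native grid are skipped with a warning.

    Returns a table indexed by step with columns ``orig_vs_down`` and
    ``between_sessions``; the scan's argmin (by ``orig_vs_down``) is stored
    in ``df.attrs["argmin_step"]``.
    """
    # Original-resolution estimates per participant/session.
    originals: dict[str, dict[str, float]] = {}
    curves = []
    for pid, per_session in sessions.items():
        for label, df in per_session.items():
            curves.append(curve_from_trials(df, value_col)[1])
    w0 = optimize_window(curves, w_max=w_max, strict=False)
    for pid, per_session in sessions.items():
        originals[pid] = {}
        for label, df in per_session.items():
            ioi, val = curve_from_trials(df, value_col)
            originals[pid][label] = preferred_rate_from_curve(
                ioi, val, w0
            ).estimate_ms

    all_iois = np.concatenate(
        [df["ioi_ms"].to_numpy(float)
         for per_session in sessions.values() for df in per_session.values()]
    )
    start, stop = all_iois.min(), all_iois.max()
    native = np.unique(all_iois)
    native_step = np.min(np.diff(native)) if len(native) > 1 else 1.0

    rows = []
    for s in steps:
        if abs(round(s / native_step) * native_step - s) > 1e-9:
            warnings.warn(f"step {s} incompatible with native grid; skipped")
            continue
        sub_grid = np.arange(start, stop + 1e-9, s)
        down_curves = []
        down_data = {}
        ok = True
        for pid, per_session in sessions.items():
            down_data[pid] = {}
            for label, df in per_session.items():
                keep = df[np.isin(df["ioi_ms"].round(6),
                                  sub_grid.round(6))]
                if keep["ioi_ms"].nunique() < 3:
                    ok = False
                    break
                down_data[pid][label] = keep
                down_curves.append(curve_from_trials(keep, value_col)[1])
            if not ok:
                break
        if not ok:
            warnings.warn(f"step {s} leaves too few rates; skipped")
            continue
        try:
            w = optimize_window(down_curves, w_max=w_max, strict=False)
        except WindowOptimizationError:
            w = w0
        orig_vs_down = 0.0
        between = 0.0
        for pid, per_session in down_data.items():
            ests = {}
            for label, df in per_session.items():
                ioi, val = curve_from_trials(df, value_col)
                ests[label] = preferred_rate_from_curve(ioi, val, w).estimate_ms
                orig_vs_down += harmonic_residual(originals[pid][label],
                                                  ests[label])
            labels = sorted(ests)
            if len(labels) >= 2:
                between += harmonic_residual(ests[labels[0]], ests[labels[1]])
        rows.append((s, orig_vs_down, between))

    out = pd.DataFrame(rows, columns=["step", "orig_vs_down",
                                      "between_sessions"]).set_index("step")
    if len(out):
        out.attrs["argmin_step"] = int(out["orig_vs_down"].idxmin())
    return out
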